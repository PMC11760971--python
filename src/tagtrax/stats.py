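"""Transformation-aware two-group comparison of the behavioral traits.

For each trait, an ordinary least squares model of the (possibly
transformed) trait on the tag factor (untagged = reference, treatment
coding) plus the experimental block factor; the tag effect is tested with
a Type II F-test (1 numerator df).  If the Shapiro-Wilk test rejects
normality of the residuals at alpha, the trait is re-fit under the next
transformation on the ladder.  The per-study transformation choices of the
original protocol are available as named presets: ``rfid`` (square root
for every trait) and ``marker`` (identity for speed, log for walk counts,
cube x**3 for exploration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

TRAITS = ("avg_speed_mm_s", "n_walks", "n_zones_explored")

#: default ladder tried in order until the residuals look normal
DEFAULT_LADDER = ("identity", "sqrt", "log", "cube")

PRESETS = {
    "rfid": {t: "sqrt" for t in TRAITS},
    "marker": {
        "avg_speed_mm_s": "identity",
        "n_walks": "log",
        "n_zones_explored": "cube",
    },
}


@dataclass
class GroupComparison:
    """Tag-effect estimate for one trait on its analysis scale."""

    trait: str
    transformation: str
    effect_estimate: float
    std_error: float
    f_value: float
    df_num: int
    df_den: int
    p_value: float
    shapiro_w: float
    shapiro_p_raw: float
    shapiro_p_final: float
    group_means_raw: dict[str, float]
    normality_ok: bool = True

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        means = d.pop("group_means_raw")
        d["mean_tagged_raw"] = means.get("tagged", float("nan"))
        d["mean_untagged_raw"] = means.get("untagged", float("nan"))
        return d


def apply_transformation(values: np.ndarray, transformation: str) -> np.ndarray:
    """Apply one rung of the ladder.

    ``cube`` is the literal x**3 (``cuberoot`` is offered as the alternate
    reading).  Exact zeros under ``log`` receive a half-count offset
    (0 -> 0.5), logged loudly; negative values make sqrt/log inapplicable.
    """
    v = np.asarray(values, dtype=float)
    if transformation == "identity":
        return v
    if transformation == "sqrt":
        if (v < 0).any():
            raise ValueError("sqrt transformation requires non-negative values")
        return np.sqrt(v)
    if transformation == "log":
        if (v < 0).any():
            raise ValueError("log transformation requires non-negative values")
        n_zero = int((v == 0).sum())
        if n_zero:
            logger.warning(
                "log transform: %d zero value(s) offset to 0.5 before taking logs",
                n_zero,
            )
            v = np.where(v == 0, 0.5, v)
        return np.log(v)
    if transformation == "cube":
        return v**3
    if transformation == "cuberoot":
        return np.cbrt(v)
    raise ValueError(f"unknown transformation {transformation!r}")


def check_normality(residuals: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value for a residual vector."""
    r = np.asarray(residuals, dtype=float)
    if not 3 <= r.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={r.size}")
    if np.ptp(r) == 0:
        raise ValueError("residuals are constant; normality test undefined")
    w, p = scipy.stats.shapiro(r)
    return float(w), float(p)


def _design(table: pd.DataFrame, with_tag: bool, drop_block: bool) -> np.ndarray:
    """Intercept + tagged dummy + treatment-coded block dummies."""
    n = len(table)
    cols = [np.ones(n)]
    if with_tag:
        cols.append((table["tag_group"] == "tagged").to_numpy(float))
    if not drop_block:
        blocks = sorted(table["block"].astype(str).unique())
        for b in blocks[1:]:  # first block is the reference level
            cols.append((table["block"].astype(str) == b).to_numpy(float))
    return np.column_stack(cols)


def fit_tag_model(
    table: pd.DataFrame, trait: str, transformation: str = "identity"
) -> GroupComparison:
    """OLS of the transformed trait on tag + block; Type II F for tag.

    The tag coefficient is the tagged-minus-untagged difference on the
    analysis scale.  Blocks containing only one group make the factors
    partially confounded; the block factor is then dropped with a warning.
    With a single block level the model reduces to the two-group contrast.
    """
    counts = table.groupby("tag_group").size()
    if counts.reindex(["tagged", "untagged"]).fillna(0).min() < 2:
        raise ValueError("need at least 2 individuals per tag group")
    y = apply_transformation(table[trait].to_numpy(float), transformation)
    if not np.isfinite(y).all():
        raise ValueError(f"trait {trait!r} has non-finite values after {transformation}")

    one_sided = (
        table.groupby("block")["tag_group"].nunique().min() < 2
        if table["block"].nunique() > 1
        else False
    )
    drop_block = table["block"].nunique() < 2 or one_sided
    if one_sided:
        logger.warning(
            "a block contains only one tag group (singular design); block "
            "factor dropped from the model for trait %r", trait,
        )
    X_full = _design(table, with_tag=True, drop_block=drop_block)
    X_red = _design(table, with_tag=False, drop_block=drop_block)

    if np.ptp(y) == 0:
        raise ValueError(
            f"trait {trait!r} is constant after {transformation}; no comparison possible"
        )
    fit_full = sm.OLS(y, X_full).fit()
    fit_red = sm.OLS(y, X_red).fit()
    if fit_full.ssr == 0:
        raise ValueError(
            f"trait {trait!r} has zero residual variance under "
            f"{transformation}; the F test is degenerate"
        )
    # Type II F for the 1-df tag factor == nested-model F against the
    # block-only model (no interactions in the design).
    df_den = int(fit_full.df_resid)
    rss_full = float(fit_full.ssr)
    rss_red = float(fit_red.ssr)
    f_value = (rss_red - rss_full) / (rss_full / df_den)
    p_value = float(scipy.stats.f.sf(f_value, 1, df_den))

    w, shapiro_p = check_normality(fit_full.resid)
    raw = table[trait].to_numpy(float)
    means = {
        g: float(raw[(table["tag_group"] == g).to_numpy()].mean())
        for g in ("tagged", "untagged")
    }
    return GroupComparison(
        trait=trait,
        transformation=transformation,
        effect_estimate=float(fit_full.params[1]),
        std_error=float(fit_full.bse[1]),
        f_value=float(f_value),
        df_num=1,
        df_den=df_den,
        p_value=p_value,
        shapiro_w=w,
        shapiro_p_raw=shapiro_p,
        shapiro_p_final=shapiro_p,
        group_means_raw=means,
    )


def transformation_ladder(
    table: pd.DataFrame,
    trait: str,
    ladder: tuple[str, ...] = DEFAULT_LADDER,
    alpha: float = 0.05,
) -> GroupComparison:
    """Fit with each transformation in order; keep the first with normal residuals.

    The ladder must begin with identity.  If no rung passes the
    Shapiro-Wilk check the last applicable fit is returned flagged
    non-normal.  Inapplicable rungs (e.g. log of negative values) are
    skipped with a notice.
    """
    if not ladder or ladder[0] != "identity":
        raise ValueError("transformation ladder must begin with 'identity'")
    first = None
    last = None
    for rung in ladder:
        try:
            comp = fit_tag_model(table, trait, rung)
        except ValueError as exc:
            logger.info("transformation %r inapplicable for %r: %s", rung, trait, exc)
            continue
        if first is None:
            first = comp
        last = comp
        if comp.shapiro_p_final >= alpha:
            comp.shapiro_p_raw = first.shapiro_p_raw
            return comp
    if last is None:
        raise ValueError(f"no transformation on the ladder is applicable to {trait!r}")
    last.normality_ok = False
    last.shapiro_p_raw = first.shapiro_p_raw
    logger.warning(
        "residuals non-normal for %r under every transformation tried "
        "(last Shapiro-Wilk p=%.3g)", trait, last.shapiro_p_final,
    )
    return last


def run_study(
    table: pd.DataFrame,
    preset: str = "auto",
    alpha: float = 0.05,
    traits: tuple[str, ...] = TRAITS,
    holm: bool = False,
) -> tuple[list[GroupComparison], pd.DataFrame]:
    """One GroupComparison per trait plus a results table.

    ``preset="auto"`` walks the transformation ladder per trait;
    ``"rfid"``/``"marker"`` fix the transformations used in the original
    per-study analyses.  ``holm=True`` adds a Holm-adjusted p-value column
    across the traits (off by default: the original protocol applied no
    multiplicity correction).
    """
    if preset not in ("auto",) and preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; use auto|rfid|marker")
    comparisons = []
    for trait in traits:
        try:
            if preset == "auto":
                comp = transformation_ladder(table, trait, alpha=alpha)
            else:
                comp = fit_tag_model(table, trait, PRESETS[preset][trait])
        except ValueError as exc:
            # degenerate trait (e.g. constant in a tiny study): report an
            # empty comparison rather than aborting the other traits
            logger.error("comparison for %r failed: %s", trait, exc)
            nan = float("nan")
            comp = GroupComparison(
                trait=trait, transformation="none", effect_estimate=nan,
                std_error=nan, f_value=nan, df_num=1, df_den=0, p_value=nan,
                shapiro_w=nan, shapiro_p_raw=nan, shapiro_p_final=nan,
                group_means_raw={}, normality_ok=False,
            )
        comparisons.append(comp)
    report = pd.DataFrame([c.to_dict() for c in comparisons])
    if holm:
        from statsmodels.stats.multitest import multipletests

        pvals = report["p_value"].to_numpy(float)
        finite = np.isfinite(pvals)
        adjusted = np.full_like(pvals, np.nan)
        if finite.any():
            adjusted[finite] = multipletests(pvals[finite], method="holm")[1]
        report["p_value_holm"] = adjusted
    return comparisons, report


def plot_study(table: pd.DataFrame, out_path, traits: tuple[str, ...] = TRAITS):
    """Per-trait box plots by group (median line, mean diamond, outliers)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = {"untagged": "No", "tagged": "Yes"}
    colors = {"untagged": "tab:orange", "tagged": "tab:blue"}
    titles = {
        "avg_speed_mm_s": "Average speed (mm/s)",
        "n_walks": "Number of walks",
        "n_zones_explored": "Zones explored",
    }
    fig, axes = plt.subplots(1, len(traits), figsize=(3 * len(traits), 3.2))
    for ax, trait in zip(np.atleast_1d(axes), traits):
        groups = ["untagged", "tagged"]
        data = [table.loc[table["tag_group"] == g, trait].to_numpy(float) for g in groups]
        bp = ax.boxplot(
            data, tick_labels=[labels[g] for g in groups], showmeans=True,
            meanprops=dict(marker="D", markerfacecolor="black", markeredgecolor="black"),
            medianprops=dict(color="black"), patch_artist=True,
        )
        for patch, g in zip(bp["boxes"], groups):
            patch.set_facecolor(colors[g])
        ax.set_title(titles.get(trait, trait))
        ax.set_xlabel("Tagged")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
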