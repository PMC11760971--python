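"""Independent reference implementations used only by the tests.

These deliberately avoid the vectorised code paths of the package: the
walk oracles enumerate runs positionally, and the regression oracle solves
the normal equations and forms the F ratio from nested residual sums of
squares directly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import scipy.stats


def walks_quadratic(speed, valid, threshold, min_duration_s, fps):
    """O(n^2) enumeration of all windows; keep maximal fully-supra-threshold
    windows meeting the duration.  For small n only."""
    n = len(speed)
    good = [bool(valid[i]) and speed[i] > threshold for i in range(n)]
    bouts = []
    for i in range(n):
        for j in range(i, n):
            if not all(good[k] for k in range(i, j + 1)):
                continue
            # maximality: cannot extend either side
            if i > 0 and good[i - 1]:
                continue
            if j < n - 1 and good[j + 1]:
                continue
            if (j - i + 1) / fps + 1e-9 >= min_duration_s:
                bouts.append((i, j))
    return bouts


def walks_runs(speed, valid, threshold, min_duration_s, fps):
    """Run-length oracle built on itertools.groupby (linear, loop-based)."""
    flags = [bool(v) and s > threshold for s, v in zip(speed, valid)]
    bouts = []
    pos = 0
    for key, group in itertools.groupby(flags):
        length = sum(1 for _ in group)
        if key and length / fps + 1e-9 >= min_duration_s:
            bouts.append((pos, pos + length - 1))
        pos += length
    return bouts


def ols_tag_oracle(table, trait, transform=lambda v: v):
    """Normal-equations OLS of transform(trait) on tag + block, with the tag
    F ratio from nested residual sums of squares.

    Returns (effect, se, F, p, df_den).  Blocks are treatment-coded with the
    alphabetically first level as reference; drops the block factor if any
    block holds a single group (mirrors the documented model behaviour).
    """
    y = transform(np.asarray(table[trait], dtype=float))
    tag = (np.asarray(table["tag_group"]) == "tagged").astype(float)
    blocks = sorted(set(str(b) for b in table["block"]))
    one_sided = False
    if len(blocks) > 1:
        for b in blocks:
            sub = table[table["block"].astype(str) == b]
            if len(set(sub["tag_group"])) < 2:
                one_sided = True
    use_block = len(blocks) > 1 and not one_sided

    def design(with_tag):
        cols = [np.ones(len(y))]
        if with_tag:
            cols.append(tag)
        if use_block:
            for b in blocks[1:]:
                cols.append((np.asarray(table["block"].astype(str)) == b).astype(float))
        return np.column_stack(cols)

    Xf = design(True)
    Xr = design(False)
    bf = np.linalg.solve(Xf.T @ Xf, Xf.T @ y)
    br = np.linalg.solve(Xr.T @ Xr, Xr.T @ y)
    rf = y - Xf @ bf
    rr = y - Xr @ br
    rss_f = float(rf @ rf)
    rss_r = float(rr @ rr)
    df_den = len(y) - Xf.shape[1]
    sigma2 = rss_f / df_den
    cov = sigma2 * np.linalg.inv(Xf.T @ Xf)
    se = math.sqrt(cov[1, 1])
    F = (rss_r - rss_f) / sigma2
    p = float(scipy.stats.f.sf(F, 1, df_den))
    return float(bf[1]), se, float(F), p, df_den
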