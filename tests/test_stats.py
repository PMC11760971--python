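"""Linear-model tag comparison, normality checking and the transformation ladder."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from tagtrax.stats import (
    PRESETS,
    apply_transformation,
    check_normality,
    fit_tag_model,
    run_study,
    transformation_ladder,
)

from conftest import make_metrics_table
from _oracles import ols_tag_oracle


def simple_table(tagged_vals, untagged_vals, blocks=None):
    rows = []
    vals = list(tagged_vals) + list(untagged_vals)
    groups = ["tagged"] * len(tagged_vals) + ["untagged"] * len(untagged_vals)
    for i, (v, g) in enumerate(zip(vals, groups)):
        rows.append({
            "individual_id": f"i{i}",
            "tag_group": g,
            "block": blocks[i] if blocks else "b0",
            "avg_speed_mm_s": v,
            "n_walks": max(0, int(v)),
            "n_zones_explored": min(18, max(1, int(v))),
        })
    return pd.DataFrame(rows)


class TestFitTagModel:
    def test_saturated_two_group_contrast(self, rng):
        table = simple_table([4.0 + 1e-9 * k for k in range(5)], [2.0 + 1e-9 * k for k in range(5)])
        comp = fit_tag_model(table, "avg_speed_mm_s", "identity")
        assert comp.effect_estimate == pytest.approx(2.0, abs=1e-6)
        assert comp.df_num == 1

    def test_positive_shift_gives_positive_effect(self, rng):
        table = make_metrics_table(rng, tag_shift=3.0)
        comp = fit_tag_model(table, "avg_speed_mm_s", "identity")
        assert comp.effect_estimate > 0

    def test_matches_normal_equations_oracle_on_random_fixtures(self, rng):
        for _ in range(30):
            n_blocks = int(rng.integers(1, 5))
            table = make_metrics_table(
                rng,
                n_tagged=int(rng.integers(4, 12)),
                n_untagged=int(rng.integers(4, 12)),
                n_blocks=n_blocks,
                tag_shift=float(rng.normal(0, 2)),
            )
            comp = fit_tag_model(table, "avg_speed_mm_s", "identity")
            eff, se, F, p, dfd = ols_tag_oracle(table, "avg_speed_mm_s")
            assert comp.effect_estimate == pytest.approx(eff, abs=1e-8)
            assert comp.std_error == pytest.approx(se, abs=1e-8)
            assert comp.f_value == pytest.approx(F, abs=1e-8)
            assert comp.p_value == pytest.approx(p, abs=1e-8)
            assert comp.df_den == dfd

    def test_agrees_with_statsmodels_formula_type2_anova(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        table = make_metrics_table(rng, n_tagged=10, n_untagged=10, n_blocks=3, tag_shift=1.0)
        comp = fit_tag_model(table, "avg_speed_mm_s", "identity")
        model = smf.ols(
            "avg_speed_mm_s ~ C(tag_group, Treatment('untagged')) + C(block)", table
        ).fit()
        anova = anova_lm(model, typ=2)
        row = anova.loc["C(tag_group, Treatment('untagged'))"]
        assert comp.f_value == pytest.approx(float(row["F"]), abs=1e-8)
        assert comp.p_value == pytest.approx(float(row["PR(>F)"]), abs=1e-8)

    def test_type2_equals_type1_with_tag_last_in_balanced_design(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        table = make_metrics_table(rng, n_tagged=8, n_untagged=8, n_blocks=2)
        comp = fit_tag_model(table, "avg_speed_mm_s", "identity")
        model = smf.ols(
            "avg_speed_mm_s ~ C(block) + C(tag_group, Treatment('untagged'))", table
        ).fit()
        seq = anova_lm(model, typ=1)
        row = seq.loc["C(tag_group, Treatment('untagged'))"]
        assert comp.f_value == pytest.approx(float(row["F"]), abs=1e-8)

    def test_p_invariant_to_block_relabeling(self, rng):
        table = make_metrics_table(rng, n_blocks=3, tag_shift=0.5)
        comp1 = fit_tag_model(table, "avg_speed_mm_s", "identity")
        renamed = table.assign(block=table["block"].map(
            {"block0": "zebra", "block1": "apple", "block2": "mango"}))
        comp2 = fit_tag_model(renamed, "avg_speed_mm_s", "identity")
        assert comp1.p_value == pytest.approx(comp2.p_value, abs=1e-10)

    def test_one_sided_block_drops_block_factor(self, rng, caplog):
        table = simple_table([4.0, 5.0, 6.0], [2.0, 3.0, 4.0],
                             blocks=["b0", "b0", "b0", "b1", "b1", "b1"])
        comp = fit_tag_model(table, "avg_speed_mm_s", "identity")
        # must equal the block-free model
        no_block = table.assign(block="b0")
        ref = fit_tag_model(no_block, "avg_speed_mm_s", "identity")
        assert comp.f_value == pytest.approx(ref.f_value, abs=1e-10)

    def test_too_few_individuals_rejected(self):
        table = simple_table([4.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="at least 2"):
            fit_tag_model(table, "avg_speed_mm_s")

    def test_null_p_values_uniform(self, rng):
        """Monte-Carlo calibration: permuting labels under the null gives
        uniform p-values (reduced replicate count; KS test)."""
        pvals = []
        for _ in range(400):
            table = make_metrics_table(rng, n_tagged=8, n_untagged=8, n_blocks=2)
            pvals.append(fit_tag_model(table, "avg_speed_mm_s", "identity").p_value)
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01


class TestNormality:
    def test_normal_sample_usually_passes(self, rng):
        rejections = sum(
            check_normality(rng.standard_normal(30))[1] < 0.05 for _ in range(1000)
        )
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_exponential_sample_usually_rejected(self, rng):
        rejections = sum(
            check_normality(rng.exponential(size=30))[1] < 0.05 for _ in range(300)
        )
        assert rejections / 300 > 0.5

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            check_normality(np.full(30, 2.0))

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            check_normality(np.array([1.0, 2.0]))


class TestTransformations:
    def test_cube_is_literal_third_power(self):
        np.testing.assert_allclose(apply_transformation(np.array([2.0]), "cube"), [8.0])

    def test_cuberoot_alternative(self):
        np.testing.assert_allclose(apply_transformation(np.array([8.0]), "cuberoot"), [2.0])

    def test_log_zero_offset(self, caplog):
        out = apply_transformation(np.array([0.0, 1.0]), "log")
        np.testing.assert_allclose(out, [np.log(0.5), 0.0])

    def test_ladder_stops_at_identity_when_normal(self, rng):
        table = make_metrics_table(rng, n_tagged=12, n_untagged=12, sd=1.0)
        comp = transformation_ladder(table, "avg_speed_mm_s")
        assert comp.transformation == "identity"

    def test_ladder_moves_on_for_skewed_trait(self, rng):
        table = make_metrics_table(rng, n_tagged=15, n_untagged=15)
        table["avg_speed_mm_s"] = rng.lognormal(0, 1.2, 30)
        comp = transformation_ladder(table, "avg_speed_mm_s")
        assert comp.transformation != "identity"

    def test_ladder_must_start_with_identity(self, rng):
        table = make_metrics_table(rng)
        with pytest.raises(ValueError, match="identity"):
            transformation_ladder(table, "avg_speed_mm_s", ladder=("sqrt",))

    def test_presets_match_study_choices(self, rng):
        table = make_metrics_table(rng, tag_shift=1.0)
        _, report_marker = run_study(table, preset="marker")
        by_trait = report_marker.set_index("trait")["transformation"]
        assert by_trait["avg_speed_mm_s"] == "identity"
        assert by_trait["n_walks"] == "log"
        assert by_trait["n_zones_explored"] == "cube"
        _, report_rfid = run_study(table, preset="rfid")
        assert set(report_rfid["transformation"]) == {"sqrt"}


class TestRunStudy:
    def test_one_comparison_per_trait(self, rng):
        comps, report = run_study(make_metrics_table(rng), preset="auto")
        assert [c.trait for c in comps] == ["avg_speed_mm_s", "n_walks", "n_zones_explored"]
        assert len(report) == 3

    def test_deterministic_report(self, rng):
        table = make_metrics_table(rng, tag_shift=2.0)
        _, r1 = run_study(table)
        _, r2 = run_study(table)
        pd.testing.assert_frame_equal(r1, r2)

    def test_holm_adjustment_is_monotone_and_optional(self, rng):
        table = make_metrics_table(rng, tag_shift=1.0)
        _, plain = run_study(table)
        assert "p_value_holm" not in plain.columns
        _, adj = run_study(table, holm=True)
        assert (adj["p_value_holm"] >= adj["p_value"] - 1e-12).all()

    def test_unknown_preset(self, rng):
        with pytest.raises(ValueError, match="preset"):
            run_study(make_metrics_table(rng), preset="bogus")
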