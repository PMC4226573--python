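"""SBP categorization and the two-way sex × SBP-category ANOVA."""

import numpy as np
import pandas as pd
import pytest

from pulsedecomp import (
    assign_sbp_category,
    default_cohort_spec,
    generate_cohort,
    group_summary,
    null_cohort_spec,
    two_way_anova,
)
from pulsedecomp.errors import DesignError, InputError


class TestCategoryAssignment:
    @pytest.mark.parametrize(
        "sbp,expected",
        [
            (110, "<=110"),
            (111, "111-120"),
            (120, "111-120"),
            (121, "121-130"),
            (130, "121-130"),
            (131, ">=131"),
            (130.5, "121-130"),  # rounds to 130 (half-to-even)
            (95, "<=110"),
            (160, ">=131"),
        ],
    )
    def test_boundaries(self, sbp, expected):
        assert assign_sbp_category(sbp) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(InputError):
            assign_sbp_category(0)


def _balanced_2x2(means, n_per_cell, noise_sd, seed=0):
    """Balanced two-factor table with known cell means."""
    rng = np.random.default_rng(seed)
    rows = []
    for (sex, cat), mu in means.items():
        for _ in range(n_per_cell):
            rows.append({"sex": sex, "sbp_category": cat, "y": mu + noise_sd * rng.standard_normal()})
    return pd.DataFrame(rows)


def _closed_form_balanced_anova(table):
    """Textbook two-way ANOVA for a balanced design (independent oracle)."""
    y = table["y"].to_numpy()
    cells = table.groupby(["sex", "sbp_category"])["y"]
    n = cells.size().iloc[0]
    a_means = table.groupby("sex")["y"].mean()
    b_means = table.groupby("sbp_category")["y"].mean()
    cell_means = cells.mean()
    grand = y.mean()
    a, b = len(a_means), len(b_means)
    ss_a = n * b * ((a_means - grand) ** 2).sum()
    ss_b = n * a * ((b_means - grand) ** 2).sum()
    ss_cells = n * ((cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ((y - cells.transform("mean").to_numpy()) ** 2).sum()
    df_a, df_b, df_ab, df_e = a - 1, b - 1, (a - 1) * (b - 1), len(y) - a * b
    return {
        "sex": (ss_a / df_a) / (ss_err / df_e),
        "sbp_category": (ss_b / df_b) / (ss_err / df_e),
        "interaction": (ss_ab / df_ab) / (ss_err / df_e),
    }


class TestTwoWayAnova:
    def test_matches_closed_form_on_balanced_design(self):
        means = {
            ("men", "<=110"): 10.0,
            ("men", ">=131"): 12.0,
            ("women", "<=110"): 11.0,
            ("women", ">=131"): 14.5,
        }
        table = _balanced_2x2(means, n_per_cell=8, noise_sd=1.0, seed=1)
        oracle = _closed_form_balanced_anova(table)
        res = two_way_anova(table, "y")
        for effect in ("sex", "sbp_category", "interaction"):
            assert res[effect].F == pytest.approx(oracle[effect], abs=1e-9)

    def test_type_II_agrees_on_balanced_design(self):
        means = {("men", "<=110"): 1.0, ("men", ">=131"): 2.0, ("women", "<=110"): 1.5, ("women", ">=131"): 3.0}
        table = _balanced_2x2(means, n_per_cell=6, noise_sd=0.5, seed=2)
        r3 = two_way_anova(table, "y", ss_type=3)
        r2 = two_way_anova(table, "y", ss_type=2)
        assert r3["sex"].F == pytest.approx(r2["sex"].F, rel=1e-9)

    def test_constant_response_gives_zero_f(self):
        table = generate_cohort(default_cohort_spec(seed=0))
        table["flat"] = 3.0
        res = two_way_anova(table, "flat")
        for effect in ("sex", "sbp_category", "interaction"):
            assert res[effect].F == 0.0
            assert res[effect].p == 1.0

    def test_reference_cohort_detects_sbp_effect(self):
        """Cohorts drawn from the reference parameterization show a strong
        SBP-category effect on the reflection interval; the sex effect is
        usually absent."""
        sbp_hits, sex_ns = 0, 0
        n_seeds = 30
        for seed in range(n_seeds):
            table = generate_cohort(default_cohort_spec(seed=seed))
            res = two_way_anova(table, "C_ref_forw")
            sbp_hits += res["sbp_category"].p < 0.01
            sex_ns += res["sex"].p > 0.05
        assert sbp_hits >= int(0.9 * n_seeds)
        assert sex_ns > n_seeds / 2

    def test_empty_cell_rejected(self):
        table = generate_cohort(default_cohort_spec(seed=0))
        trimmed = table[~((table.sex == "men") & (table.sbp_category == ">=131"))]
        with pytest.raises(DesignError):
            two_way_anova(trimmed, "C_ref_forw")

    def test_single_level_factor_rejected(self):
        table = generate_cohort(default_cohort_spec(seed=0))
        men = table[table.sex == "men"]
        with pytest.raises(DesignError):
            two_way_anova(men, "C_ref_forw")


class TestGroupSummary:
    def test_reference_cell_counts(self):
        table = generate_cohort(default_cohort_spec(seed=3))
        summary = group_summary(table, ["C_ref_forw"])
        counts = summary.set_index(["sex", "sbp_category"])["n"]
        assert counts[("men", "<=110")] == 22
        assert counts[("men", "111-120")] == 29
        assert counts[("men", "121-130")] == 33
        assert counts[("men", ">=131")] == 21
        assert counts[("women", "<=110")] == 17
        assert counts[("women", "111-120")] == 25
        assert counts[("women", "121-130")] == 25
        assert counts[("women", ">=131")] == 18

    def test_degenerate_cohort_has_zero_sd(self):
        spec = default_cohort_spec(seed=0)
        cells = {
            key: type(cell)(n=cell.n, means=cell.means, sds={k: 0.0 for k in cell.sds})
            for key, cell in spec.cells.items()
        }
        table = generate_cohort(type(spec)(cells=cells, seed=1))
        summary = group_summary(table, ["C1", "H1"])
        assert (summary["C1_sd"] == 0.0).all()
        row = summary[(summary.sex == "men") & (summary.sbp_category == "<=110")]
        assert row["C1_mean"].iloc[0] == 136.0

    def test_single_subject_cell_warns(self):
        table = pd.DataFrame(
            {
                "sex": ["men", "men", "women", "women"],
                "sbp_category": ["<=110", ">=131", "<=110", ">=131"],
                "y": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.warns(UserWarning, match="n=1"):
            summary = group_summary(table, ["y"])
        assert (summary["y_sd"] == 0.0).all()


class TestNullCalibration:
    def test_type_one_error_near_nominal(self):
        """Quick null check: rejection rate at 0.05 is near nominal.

        The full 2000-replicate calibration lives in the acceptance suite;
        here 150 replicates bound the rate loosely.
        """
        rejections, total = 0, 0
        for seed in range(150):
            table = generate_cohort(null_cohort_spec(seed=seed))
            res = two_way_anova(table, "C_ref_forw")
            for effect in ("sex", "sbp_category", "interaction"):
                rejections += res[effect].p < 0.05
                total += 1
        rate = rejections / total
        assert 0.01 < rate < 0.10
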