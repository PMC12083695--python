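"""Mixed-design ANOVA, corrections, baseline checks, infarct tests.

The RM-ANOVA implementation is cross-checked against two independent
routes: a brute-force sums-of-squares oracle written directly from group /
subject / cell means at tiny n, and pingouin's mixed_anova on random
balanced data.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isoipipe.stats import (
    baseline_equality_check,
    correct_pvalues,
    infarct_group_tests,
    posthoc_time_contrasts,
    rm_anova,
)


def long_table(y, groups, animals=None):
    """(n, 2) responses -> tidy long table."""
    n = y.shape[0]
    animals = animals or [f"S{i}" for i in range(n)]
    rows = []
    for i in range(n):
        for j, tp in enumerate(("baseline", "h24")):
            rows.append(
                {"animal": animals[i], "group": groups[i], "timepoint": tp, "y": y[i, j]}
            )
    return pd.DataFrame(rows)


def brute_force_mixed_anova(y, groups):
    """Textbook decomposition computed cell-by-cell in pure python."""
    n, t = y.shape
    labels = sorted(set(groups))
    grand = y.mean()
    ss_group = 0.0
    for g in labels:
        sel = [i for i in range(n) if groups[i] == g]
        ss_group += t * len(sel) * (y[sel].mean() - grand) ** 2
    ss_subj = sum(t * (y[i].mean() - grand) ** 2 for i in range(n)) - ss_group
    ss_time = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(t))
    ss_cells = 0.0
    for g in labels:
        sel = [i for i in range(n) if groups[i] == g]
        for j in range(t):
            ss_cells += len(sel) * (y[sel, j].mean() - grand) ** 2
    ss_inter = ss_cells - ss_group - ss_time
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj - ss_time - ss_inter
    g = len(labels)
    return {
        "F_group": (ss_group / (g - 1)) / (ss_subj / (n - g)),
        "F_time": (ss_time / (t - 1)) / (ss_err / ((n - g) * (t - 1))),
        "F_inter": (ss_inter / (g - 1)) / (ss_err / ((n - g) * (t - 1))),
    }


class TestRmAnova:
    def test_matches_brute_force_oracle_small_n(self, rng):
        y = rng.normal(0, 1, size=(6, 2))
        groups = [1, 1, 1, 2, 2, 2]
        res = rm_anova(long_table(y, groups), "y")
        oracle = brute_force_mixed_anova(y, groups)
        eff = res.effects.set_index("effect")
        assert eff.loc["group", "F"] == pytest.approx(oracle["F_group"])
        assert eff.loc["time", "F"] == pytest.approx(oracle["F_time"])
        assert eff.loc["group_x_time", "F"] == pytest.approx(oracle["F_inter"])

    def test_matches_pingouin_balanced(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(0, 1, size=(20, 2)) + rng.normal(0, 1, size=(20, 1))
        groups = [1] * 5 + [2] * 5 + [3] * 5 + [4] * 5
        table = long_table(y, groups)
        res = rm_anova(table, "y")
        pg = pingouin.mixed_anova(
            data=table, dv="y", within="timepoint", subject="animal", between="group"
        ).set_index("Source")
        eff = res.effects.set_index("effect")
        assert eff.loc["group", "F"] == pytest.approx(pg.loc["group", "F"])
        assert eff.loc["time", "F"] == pytest.approx(pg.loc["timepoint", "F"])
        assert eff.loc["group_x_time", "F"] == pytest.approx(pg.loc["Interaction", "F"])
        assert eff.loc["group", "p"] == pytest.approx(pg.loc["group", "p_unc"])

    def test_df_consistent_with_design(self, rng):
        y = rng.normal(size=(40, 2))
        groups = np.repeat([1, 2, 3, 4, 5], 8)
        eff = rm_anova(long_table(y, groups), "y").effects.set_index("effect")
        assert eff.loc["group", ["df_num", "df_den"]].tolist() == [4, 35]
        assert eff.loc["time", ["df_num", "df_den"]].tolist() == [1, 35]
        assert eff.loc["group_x_time", ["df_num", "df_den"]].tolist() == [4, 35]

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 2**16))
    def test_ss_partition_identity(self, seed):
        """SS_total = SS_between_subjects + SS_within_subjects, computed
        through independent routes, to 1e-8 relative."""
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 16)) * 2
        y = r.normal(0, r.uniform(0.5, 5), size=(n, 2))
        groups = np.repeat([1, 2], n // 2)
        res = rm_anova(long_table(y, groups), "y")
        lhs = res.ss_total
        rhs = res.ss_between_subjects + res.ss_within_subjects
        assert abs(lhs - rhs) <= 1e-8 * max(lhs, 1e-12)

    def test_constant_response_flagged_degenerate(self):
        y = np.full((8, 2), 3.0)
        res = rm_anova(long_table(y, [1] * 4 + [2] * 4), "y")
        assert res.degenerate
        assert np.isnan(res.effects.set_index("effect").loc["group_x_time", "F"]) or (
            res.effects.set_index("effect").loc["group_x_time", "F"] == 0
        )

    def test_missing_timepoint_listwise_excluded(self, rng):
        y = rng.normal(size=(8, 2))
        table = long_table(y, [1] * 4 + [2] * 4)
        table = table.drop(table[(table.animal == "S0") & (table.timepoint == "h24")].index)
        with pytest.warns(UserWarning, match="excluded 1"):
            res = rm_anova(table, "y")
        assert res.n_excluded == 1
        assert len(res.data_wide) == 7

    def test_single_animal_group_rejected(self, rng):
        y = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            rm_anova(long_table(y, [1, 1, 1, 1, 2]), "y")

    def test_time_only_effect_pattern(self, rng):
        """A pure time shift is detected without spurious group effects."""
        hits = {"time": 0, "group": 0, "group_x_time": 0}
        for rep in range(20):
            r = np.random.default_rng(1000 + rep)
            subj = r.normal(0, 1, size=(16, 1))
            y = subj + r.normal(0, 0.5, size=(16, 2))
            y[:, 1] += 1.0  # time effect d = 2 vs within-noise
            eff = rm_anova(long_table(y, [1] * 8 + [2] * 8), "y").effects.set_index("effect")
            for k in hits:
                hits[k] += eff.loc[k, "p"] < 0.05
        assert hits["time"] == 20
        assert hits["group"] <= 4 and hits["group_x_time"] <= 4


class TestCorrections:
    def test_closed_forms(self):
        assert correct_pvalues(np.array([0.01]), 5, "bonferroni")[0] == pytest.approx(0.05)
        assert correct_pvalues(np.array([0.01]), 5, "sidak")[0] == pytest.approx(
            1 - 0.99**5
        )
        assert correct_pvalues(np.array([0.4]), 5, "bonferroni")[0] == 1.0

    def test_single_contrast_uncorrected(self):
        for m in ("bonferroni", "sidak"):
            assert correct_pvalues(np.array([0.037]), 1, m)[0] == pytest.approx(0.037)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(p=st.floats(0, 1), k=st.integers(1, 50))
    def test_bonferroni_at_least_sidak(self, p, k):
        bon = correct_pvalues(np.array([p]), k, "bonferroni")[0]
        sid = correct_pvalues(np.array([p]), k, "sidak")[0]
        assert bon >= sid - 1e-12

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            correct_pvalues(np.array([0.1]), 2, "holm")


class TestPosthocContrasts:
    def test_detects_group_specific_change(self, rng):
        subj = rng.normal(0, 0.3, size=(16, 1))
        y = subj + rng.normal(0, 0.2, size=(16, 2))
        y[8:, 1] -= 3.0  # group 2 collapses at 24 h
        res = rm_anova(long_table(y, [1] * 8 + [2] * 8), "y")
        con = posthoc_time_contrasts(res, correction="sidak").set_index("group")
        assert not con.loc[1, "significant"]
        assert con.loc[2, "significant"]
        assert con.loc[2, "estimate"] == pytest.approx(-3.0, abs=0.3)
        assert (con["p_bonferroni"] >= con["p_sidak"] - 1e-12).all()
        assert (con["p_corrected"] >= con["p_raw"] - 1e-15).all()

    def test_paired_error_option(self, rng):
        y = rng.normal(size=(12, 2))
        res = rm_anova(long_table(y, [1] * 6 + [2] * 6), "y")
        con = posthoc_time_contrasts(res, error="paired")
        assert (con["df"] == 5).all()


class TestBaselineEquality:
    def test_null_groups_not_rejected_on_average(self):
        rejections = 0
        for rep in range(40):
            r = np.random.default_rng(rep)
            table = long_table(r.normal(size=(40, 2)), np.repeat([1, 2, 3, 4, 5], 8))
            if baseline_equality_check(table, "y")["p"] < 0.05:
                rejections += 1
        assert rejections <= 6  # ~5% expected

    def test_shifted_group_detected(self, rng):
        y = rng.normal(size=(40, 2))
        y[:8, 0] += 5.0  # group 1 baseline shifted by 5 sd
        table = long_table(y, np.repeat([1, 2, 3, 4, 5], 8))
        assert baseline_equality_check(table, "y")["p"] < 1e-3

    def test_requires_all_five_groups(self, rng):
        table = long_table(rng.normal(size=(8, 2)), [1] * 4 + [2] * 4)
        with pytest.raises(ValueError):
            baseline_equality_check(table, "y")


class TestInfarctTests:
    def make_table(self, volumes_by_group):
        rows = []
        for g, vols in volumes_by_group.items():
            for i, v in enumerate(vols):
                rows.append({"animal": f"G{g}A{i}", "group": g, "corrected_volume_mm3": v})
        return pd.DataFrame(rows)

    def test_identical_groups_null(self):
        table = self.make_table({1: [2.0] * 5, 2: [2.0] * 5})
        res = infarct_group_tests(table)
        row = res["t_tests"].iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0 and row["degenerate"]

    def test_separated_groups_detected(self, rng):
        table = self.make_table(
            {1: rng.normal(0, 1, 8).tolist(), 2: rng.normal(3, 1, 8).tolist()}
        )
        res = infarct_group_tests(table)
        assert res["t_tests"].iloc[0]["p"] < 0.01
        assert res["anova"]["p"] < 0.01

    def test_welch_flag(self, rng):
        table = self.make_table({1: rng.normal(size=8).tolist(), 2: rng.normal(size=8).tolist()})
        assert infarct_group_tests(table)["t_tests"]["welch"].all()
        assert not infarct_group_tests(table, equal_var=True)["t_tests"]["welch"].any()

    def test_zero_variance_unequal_means_raises(self):
        table = self.make_table({1: [0.0] * 4, 2: [5.0] * 4})
        with pytest.raises(ValueError):
            infarct_group_tests(table)

    def test_small_group_rejected(self):
        table = self.make_table({1: [1.0], 2: [2.0, 3.0]})
        with pytest.raises(ValueError):
            infarct_group_tests(table)
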