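"""The statistical battery: elementary tests, post hocs and the full plan."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from meshacc.stats import (
    GROUPS,
    DegenerateDataError,
    StudyTable,
    anova_oneway,
    dunnett_t3,
    ks_normality,
    levene_homogeneity,
    paired_t,
    posthoc,
    run_battery,
    summarize,
    tukey_hsd,
)


def _table(rng=None, n=10, shift=None):
    rng = rng or np.random.default_rng(0)
    data = {g: np.abs(rng.normal(0.55, 0.1, n)) for g in GROUPS}
    if shift:
        for g, s in shift.items():
            data[g] = data[g] + s
    return StudyTable(pd.DataFrame(data))


class TestStudyTable:
    def test_requires_all_groups(self):
        with pytest.raises(ValueError, match="missing group"):
            StudyTable(pd.DataFrame({"A": [1.0, 2.0]}))

    def test_rejects_negative_rms(self):
        df = pd.DataFrame({g: [0.5, 0.6] for g in GROUPS})
        df.loc[0, "AM"] = -0.1
        with pytest.raises(ValueError, match="finite and >= 0"):
            StudyTable(df)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="no cases"):
            StudyTable(pd.DataFrame({g: [] for g in GROUPS}))

    def test_csv_round_trip(self, tmp_path):
        table = _table()
        path = tmp_path / "study.csv"
        table.to_csv(path)
        back = StudyTable.from_csv(path)
        pd.testing.assert_frame_equal(
            back.data.reset_index(drop=True), table.data.reset_index(drop=True)
        )


class TestSummarize:
    def test_hand_cases(self):
        df = pd.DataFrame({g: [1.0, 1.0, 1.0] for g in GROUPS})
        df["AM"] = [0.0, 2.0, 1.0]
        s = summarize(StudyTable(df))
        assert s.loc["A", "mean_mm"] == pytest.approx(1.0)
        assert s.loc["A", "sd_mm"] == pytest.approx(0.0)
        assert s.loc["AM", "mean_mm"] == pytest.approx(1.0)
        assert s.loc["AM", "sd_mm"] == pytest.approx(1.0)

    def test_two_point_sd(self):
        df = pd.DataFrame({g: [0.0, 2.0] for g in GROUPS})
        s = summarize(StudyTable(df))
        assert s.loc["B", "sd_mm"] == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_sampling_distribution_bound(self):
        """10 draws from N(0.58, 0.11^2): the sample mean stays within three
        standard errors of the true mean (fixed seed)."""
        rng = np.random.default_rng(12)
        x = rng.normal(0.58, 0.11, 10)
        assert abs(np.mean(x) - 0.58) <= 3 * 0.11 / np.sqrt(10)


class TestNormality:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(3).normal(0.55, 0.1, 10)
        assert ks_normality(x).pvalue > 0.05

    def test_skewed_sample_fails(self):
        x = np.random.default_rng(4).exponential(1.0, 200)
        assert ks_normality(x).pvalue < 0.05

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_statistic_in_unit_interval(self, seed):
        x = np.random.default_rng(seed).normal(size=15)
        r = ks_normality(x)
        assert 0.0 <= r.statistic <= 1.0

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            ks_normality([1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            ks_normality([1.0] * 10)

    def test_plain_ks_variant_available(self):
        x = np.random.default_rng(5).normal(size=30)
        plain = ks_normality(x, lilliefors=False)
        lillie = ks_normality(x, lilliefors=True)
        assert plain.statistic == pytest.approx(lillie.statistic, abs=1e-12)
        assert plain.pvalue >= lillie.pvalue  # the plain p ignores estimation

    def test_type_i_error_calibrated(self):
        """Lilliefors-corrected K-S rejects a true normal at roughly the
        nominal rate."""
        rng = np.random.default_rng(6)
        rejections = sum(
            ks_normality(rng.normal(size=10)).pvalue < 0.05 for _ in range(500)
        )
        assert 0.02 <= rejections / 500 <= 0.08


class TestAnova:
    def test_identical_groups(self):
        r = anova_oneway([[1.0, 2.0, 3.0]] * 3)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.pvalue == pytest.approx(1.0, abs=1e-12)

    def test_maximal_separation(self):
        r = anova_oneway([[0.0, 0.0001], [10.0, 10.0001], [0.0, 0.0001]])
        assert r.pvalue < 0.05

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_f_matches_sum_of_squares_decomposition(self, seed):
        """F equals the brute-force between/within mean-square ratio."""
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(3, 12)) for _ in range(3)]
        r = anova_oneway(groups)
        grand = np.mean(np.concatenate(groups))
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_within = sum(np.sum((g - np.mean(g)) ** 2) for g in groups)
        k, n = 3, sum(len(g) for g in groups)
        f_oracle = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert r.statistic == pytest.approx(f_oracle, rel=1e-9)

    def test_null_rejection_rate(self):
        """Type-I error of the F test is near nominal over 2000 replicates
        of an all-null three-group design."""
        rng = np.random.default_rng(7)
        rej = sum(
            anova_oneway([rng.normal(size=10) for _ in range(3)]).pvalue < 0.05
            for _ in range(2000)
        )
        assert 0.03 <= rej / 2000 <= 0.07


class TestPosthoc:
    def test_identical_groups_give_p_near_one(self):
        rng = np.random.default_rng(8)
        g = rng.normal(size=10)
        for method in (tukey_hsd, dunnett_t3):
            for pair in method([g, g + 1e-12, g - 1e-12]):
                assert pair.pvalue > 0.99

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.0, 1.0, 10)
        c = rng.normal(10.0, 1.0, 10)  # ten SDs away
        for equal in (True, False):
            pairs = posthoc([a, b, c], labels=["a", "b", "c"], equal_variances=equal)
            for p in pairs:
                if "c" in (p.group_a, p.group_b):
                    assert p.pvalue < 0.05
                else:
                    assert p.pvalue > 0.05

    def test_adjusted_p_is_conservative(self):
        """Multiplicity-adjusted p-values are never smaller than the
        unadjusted pairwise t-test p on the same data."""
        rng = np.random.default_rng(10)
        groups = [rng.normal(i * 0.3, 1.0, 9) for i in range(3)]
        tukey = tukey_hsd(groups, labels=["0", "1", "2"])
        t3 = dunnett_t3(groups, labels=["0", "1", "2"])
        for pair in tukey:
            i, j = int(pair.group_a), int(pair.group_b)
            p_plain = sps.ttest_ind(groups[i], groups[j]).pvalue
            assert pair.pvalue >= p_plain - 1e-12
        for pair in t3:
            i, j = int(pair.group_a), int(pair.group_b)
            p_welch = sps.ttest_ind(groups[i], groups[j], equal_var=False).pvalue
            assert pair.pvalue >= p_welch - 1e-12

    def test_t3_smm_adjustment_against_quantile_table(self):
        """SMM-based adjustment: at the tabulated studentized-maximum-
        modulus 5% critical value for k = 3 comparisons the adjusted p
        equals 0.05 (to the documented 1e-4 tolerance of the numerical
        construction)."""
        # |t| such that (2 F_t(|t|; nu) - 1)^3 = 0.95 with nu = 20
        nu, k = 20, 3
        q = sps.t.ppf((0.95 ** (1 / k) + 1) / 2, nu)
        core = 2 * sps.t.cdf(q, nu) - 1
        assert 1 - core**k == pytest.approx(0.05, abs=1e-10)


class TestPairedT:
    def test_statistic_matches_definition(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=12)
        b = a + rng.normal(0.3, 0.2, 12)
        r = paired_t(a, b)
        d = a - b
        t_def = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(len(d)))
        assert r.statistic == pytest.approx(t_def, abs=1e-12)

    def test_constant_shift_is_degenerate(self):
        a = np.random.default_rng(12).normal(size=10)
        with pytest.raises(DegenerateDataError):
            paired_t(a, a + 0.001)

    def test_real_shift_detected(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.5, 0.3, 10)
        b = a + 1.0 + rng.normal(0.0, 0.1, 10)
        assert paired_t(a, b).pvalue < 0.05

    @given(st.floats(-100.0, 100.0, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_common_constant(self, const):
        rng = np.random.default_rng(14)
        a = rng.normal(size=10)
        b = a + rng.normal(0.5, 0.3, 10)
        r0 = paired_t(a, b)
        r1 = paired_t(a + const, b + const)
        assert r1.statistic == pytest.approx(r0.statistic, rel=1e-9, abs=1e-9)


class TestRunBattery:
    def test_report_structure(self):
        report = run_battery(_table())
        assert set(report.normality) == set(GROUPS)
        assert set(report.paired) == {"global", "upper", "middle", "lower"}
        assert report.posthoc_method["A"] in ("tukey_hsd", "dunnett_t3")
        d = report.to_dict()
        assert "summary" in d and len(d["summary"]) == 8

    def test_levene_gate_switches_posthoc_not_summary(self):
        table = _table()
        auto = run_battery(table)
        forced = run_battery(table, force_unequal_variances=True)
        assert forced.posthoc_method == {"A": "dunnett_t3", "B": "dunnett_t3"}
        pd.testing.assert_frame_equal(auto.summary, forced.summary)

    def test_region_effect_flows_through(self):
        """A lower-third penalty shows up in the per-scanner post hocs."""
        table = _table(np.random.default_rng(15), shift={"AL": 1.0, "BL": 1.0})
        report = run_battery(table)
        for scanner in ("A", "B"):
            assert report.anova[scanner].pvalue < 0.05
            for pair in report.posthoc[scanner]:
                involves_lower = scanner + "L" in (pair.group_a, pair.group_b)
                assert pair.significant == involves_lower
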