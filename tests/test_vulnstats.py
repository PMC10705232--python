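"""Univariate statistics: Pearson, correlation tables, class tests,
Bonferroni, chi-squared goodness of fit, selection frequencies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy import stats as sps

from missvuln import (
    SyntheticConfig,
    bonferroni,
    chi2_gof,
    class_representation_test,
    class_tests,
    correlation_table,
    generate_bundle,
    pearson,
    selection_frequency,
)
from missvuln.regions import aggregate_voxels_to_regions, remove_seed_regions
from missvuln.vulnstats import CorrelationTable


class TestPearson:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3], [1, -2, 1], 0.0),
    ])
    def test_hand_values(self, x, y, expected):
        r, _ = pearson(np.array(x, float), np.array(y, float))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_reported_missing(self):
        r, p = pearson(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
        assert np.isnan(r) and np.isnan(p)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(3, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, _ = pearson(x, y)
            xc, yc = x - x.mean(), y - y.mean()
            want = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert r == pytest.approx(want, abs=1e-12)


class TestCorrelationTable:
    def test_noiseless_single_source_mean_r_is_one(self):
        cfg = SyntheticConfig(n_genes=40, n_celltypes=4, n_voxels=40,
                              n_regions=8, n_datasets=3, markers_per_type=3,
                              tau_noise_sd=0.0, n_vulnerable=1, n_resilient=0,
                              seed=21)
        gt = generate_bundle(cfg)
        D_reg = aggregate_voxels_to_regions(gt.D_true, gt.parcellation)
        regional, tau = {}, {}
        for ds in gt.tau_datasets:
            regional[ds.name], tau[ds.name] = remove_seed_regions(D_reg, ds)
        tab = correlation_table(regional, tau)
        assert tab.mean_R["T1"] == pytest.approx(1.0, abs=1e-10)

    def test_independent_entity_has_small_mean_r(self):
        rng = np.random.default_rng(17)
        regions = [f"R{i}" for i in range(100)]
        names = [f"D{i}" for i in range(12)]
        regional = {
            d: pd.DataFrame(rng.normal(size=(1, 100)), index=["noise"],
                            columns=regions)
            for d in names
        }
        tau = {d: pd.Series(rng.normal(size=100), index=regions) for d in names}
        tab = correlation_table(regional, tau)
        assert abs(tab.mean_R["noise"]) < 0.2

    def test_dataset_order_invariance(self, default_result):
        tab = default_result.celltype_table
        shuffled = tab.R[list(tab.R.columns)[::-1]]
        pd.testing.assert_series_equal(shuffled.mean(axis=1), tab.mean_R,
                                       check_names=False)

    def test_too_few_regions_marked_missing(self, caplog):
        regional = {"d": pd.DataFrame([[1.0, 2.0]], index=["t"],
                                      columns=["A", "B"])}
        tau = {"d": pd.Series([1.0, 2.0], index=["A", "B"])}
        with caplog.at_level("WARNING", logger="missvuln.vulnstats"):
            tab = correlation_table(regional, tau)
        assert np.isnan(tab.R.loc["t", "d"])


class TestClassTests:
    def make_table(self, values: dict[str, list[float]]) -> CorrelationTable:
        R = pd.DataFrame(values).T
        return CorrelationTable(R=R, p=R * np.nan, mean_R=R.mean(axis=1))

    def test_all_zero_class(self):
        tab = self.make_table({"a": [0, 0, 0], "b": [0, 0, 0]})
        res = class_tests(tab, {"a": "c1", "b": "c1"})
        assert res.one_sample.loc["c1", "t"] == 0.0
        assert res.one_sample.loc["c1", "p"] == 1.0

    def test_constant_nonzero_class_degenerate(self):
        tab = self.make_table({"a": [0.5, 0.5, 0.5]})
        res = class_tests(tab, {"a": "c1"})
        assert np.isinf(res.one_sample.loc["c1", "t"])
        assert res.one_sample.loc["c1", "p"] == 0.0
        assert bool(res.one_sample.loc["c1", "degenerate"])

    def test_planted_class_significant_null_class_not(self, default_result):
        res = default_result.class_result
        assert res.one_sample.loc["hippocampal glutamatergic", "p_corrected"] < 0.01
        assert res.one_sample.loc["hippocampal glutamatergic", "t"] > 0
        # the cortical-glutamatergic-like types carry no planted tau signal
        assert res.one_sample.loc["cortical glutamatergic", "p_corrected"] > 0.01

    def test_corrected_never_below_nominal(self, default_result):
        one = default_result.class_result.one_sample
        assert (one["p_corrected"] >= one["p"]).all()
        assert (one["p_corrected"] <= 1).all()


class TestBonferroni:
    @pytest.mark.parametrize("p,n,expected", [
        (0.01, 5, 0.05),
        (0.3, 4, 1.0),
        (0.02, 1, 0.02),
    ])
    def test_hand_values(self, p, n, expected):
        assert bonferroni(p, n) == pytest.approx(expected)

    @given(st.floats(0, 1), st.integers(1, 10_000))
    @settings(deadline=None, max_examples=200)
    def test_monotone_and_capped(self, p, n):
        corr = bonferroni(p, n)
        assert p <= corr <= 1.0
        assert bonferroni(p, n + 1) >= corr

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)


class TestChi2:
    def test_perfect_fit(self):
        stat, df, p = chi2_gof([5, 5], [5, 5])
        assert stat == 0.0 and p == 1.0

    def test_hand_value(self):
        stat, df, p = chi2_gof([10, 0], [5, 5])
        assert stat == pytest.approx(10.0)
        assert df == 1
        assert p == pytest.approx(1.5654e-3, rel=1e-3)

    def test_statistic_15_at_df_2(self):
        """The df=2 tail of a 15.0 statistic is ~5.5e-4 (df is an explicit
        parameter: four categories would default to df=3)."""
        stat, df, p = chi2_gof([20, 5, 5, 0], [7.5, 7.5, 7.5, 7.5], df=2)
        assert p == pytest.approx(sps.chi2.sf(stat, 2))
        assert sps.chi2.sf(15.0, 2) == pytest.approx(5.5e-4, rel=0.01)

    @pytest.mark.parametrize("df", range(1, 11))
    def test_tail_matches_numerical_integration(self, df):
        stat = 3.7
        _, _, p = chi2_gof([stat], [stat], df=df)  # p for stat 0; use sf direct
        want, _ = integrate.quad(lambda x: sps.chi2.pdf(x, df), stat, np.inf)
        assert sps.chi2.sf(stat, df) == pytest.approx(want, abs=1e-8)

    def test_mismatched_totals_rejected(self):
        with pytest.raises(ValueError):
            chi2_gof([10, 10], [5, 5])


class TestSelectionFrequency:
    def test_counts_and_order_invariance(self):
        models = [["a", "b"], ["a"], ["c", "a"]]
        c1 = selection_frequency(models, ["a", "b", "c", "d"])
        c2 = selection_frequency(models[::-1], ["a", "b", "c", "d"])
        assert c1["a"] == 3 and c1["d"] == 0
        pd.testing.assert_series_equal(c1, c2)

    def test_empty_model_list(self):
        counts = selection_frequency([], ["a", "b"])
        assert (counts == 0).all()

    def test_proportional_expected_counts(self):
        counts = pd.Series({"a": 4, "b": 0, "c": 2})
        classes = {"a": "X", "b": "X", "c": "Y"}
        totals, stat, df, p = class_representation_test(counts, classes)
        assert totals["X"] == 4 and totals["Y"] == 2
        # expected: 6 * (2/3, 1/3) = (4, 2) → perfect fit
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
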