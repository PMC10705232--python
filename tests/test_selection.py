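"""MRx3 gene selection: normalization, rank-one noise scores vs refit oracle,
variance criterion, redundancy, greedy selection vs brute force, size sweep."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from missvuln import ConfigurationError
from missvuln.selection import (
    estimate_incremental_noise,
    f_statistic,
    mrmr_select_next,
    mrx3,
    normalize_inputs,
    pick_elbow,
    redundancy,
    trim_noisy_genes,
)


def random_instance(seed, n_genes=5, n_types=2, n_vox=4):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    E = pd.DataFrame(rng.uniform(0.1, 1, (n_genes, n_vox)), index=genes)
    C = pd.DataFrame(rng.uniform(0.1, 1, (n_genes, n_types)), index=genes)
    return E, C


# ---------------------------------------------------------------- oracles --

def brute_force_noise_scores(E, C):
    """Leave-one-gene-out refit from scratch; the defining oracle."""
    Em, Cm = np.asarray(E, float), np.asarray(C, float)
    n_genes, n_vox = Em.shape
    D_full, *_ = np.linalg.lstsq(Cm, Em, rcond=None)
    rss_full = ((Em - Cm @ D_full) ** 2).sum()
    scores = []
    for g in range(n_genes):
        keep = np.arange(n_genes) != g
        D_wo, *_ = np.linalg.lstsq(Cm[keep], Em[keep], rcond=None)
        rss_wo = ((Em[keep] - Cm[keep] @ D_wo) ** 2).sum()
        scores.append((rss_full - rss_wo) / n_vox)
    return pd.Series(scores, index=E.index)


def brute_force_greedy(C, n):
    """Re-evaluate the full selection criterion from scratch at every step."""
    Cm = np.asarray(C, float)
    genes = list(C.index)
    S = []
    for _ in range(n):
        best, best_v = None, -np.inf
        for g in genes:
            if g in S:
                continue
            i = list(C.index).index(g)
            F = np.var(Cm[i], ddof=1)
            if S:
                rs = []
                for j in S:
                    jj = list(C.index).index(j)
                    a, b = Cm[i] - Cm[i].mean(), Cm[jj] - Cm[jj].mean()
                    denom = np.linalg.norm(a) * np.linalg.norm(b)
                    rs.append(abs(a @ b / denom) if denom > 0 else 0.0)
                V = F / max(np.mean(rs), 1e-12)
            else:
                V = F
            if V > best_v:
                best, best_v = g, V
        S.append(best)
    return S


# ------------------------------------------------------------------ tests --

class TestNormalization:
    def test_row_max_scheme(self):
        E = pd.DataFrame([[2.0, 4.0]], index=["g"])
        C = pd.DataFrame([[1.0]], index=["g"])
        En, _, meta = normalize_inputs(E, C)
        np.testing.assert_array_equal(En.values, [[0.5, 1.0]])
        assert meta["e_scheme"] == "max"

    def test_column_sum_scheme(self):
        E = pd.DataFrame([[1.0], [1.0]], index=["a", "b"])
        C = pd.DataFrame([[1.0], [3.0]], index=["a", "b"], columns=["t"])
        _, Cn, _ = normalize_inputs(E, C)
        np.testing.assert_allclose(Cn["t"].values, [0.25, 0.75])

    def test_zero_column_passes_through(self, caplog):
        E = pd.DataFrame([[1.0]], index=["a"])
        C = pd.DataFrame([[0.0]], index=["a"], columns=["t"])
        with caplog.at_level("WARNING", logger="missvuln.selection"):
            _, Cn, _ = normalize_inputs(E, C)
        assert (Cn.values == 0).all()
        assert any("all-zero" in r.message for r in caplog.records)

    def test_unknown_scheme_rejected(self):
        E, C = random_instance(0)
        with pytest.raises(ConfigurationError):
            normalize_inputs(E, C, e_scheme="quantile")


class TestIncrementalNoise:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_refit(self, seed):
        E, C = random_instance(seed)
        got = estimate_incremental_noise(E, C)
        want = brute_force_noise_scores(E, C)
        np.testing.assert_allclose(got.values, want.values, rtol=1e-8, atol=1e-12)

    def test_larger_instance_matches_oracle(self):
        E, C = random_instance(99, n_genes=30, n_types=5, n_vox=12)
        got = estimate_incremental_noise(E, C)
        want = brute_force_noise_scores(E, C)
        np.testing.assert_allclose(got.values, want.values, rtol=1e-8, atol=1e-12)

    def test_perfectly_explained_genes_score_zero(self):
        rng = np.random.default_rng(5)
        C = pd.DataFrame(rng.uniform(0.1, 1, (6, 2)), index=list("abcdef"))
        D = rng.uniform(0.1, 1, (2, 4))
        E = pd.DataFrame(C.values @ D, index=C.index)  # consistent system
        scores = estimate_incremental_noise(E, C)
        np.testing.assert_allclose(scores.values, 0.0, atol=1e-18)

    def test_duplicated_gene_rows_score_equally(self):
        E, C = random_instance(7, n_genes=6)
        E.iloc[1], C.iloc[1] = E.iloc[0], C.iloc[0]
        scores = estimate_incremental_noise(E, C)
        assert scores.iloc[0] == pytest.approx(scores.iloc[1], rel=1e-10)


class TestTrim:
    def test_removes_ceil_fraction(self):
        E, C = random_instance(0, n_genes=10)
        scores = pd.Series(np.arange(10, dtype=float), index=E.index)
        kept, E2, _ = trim_noisy_genes(scores, E, C, frac=0.10)
        assert len(kept) == 9 and E2.shape[0] == 9
        assert E.index[-1] not in kept  # highest score removed

    def test_frac_zero_is_identity(self):
        E, C = random_instance(0)
        kept, E2, C2 = trim_noisy_genes(pd.Series(1.0, index=E.index), E, C, 0.0)
        assert kept == list(E.index)
        pd.testing.assert_frame_equal(E2, E)

    def test_tie_removes_earlier_gene(self):
        E, C = random_instance(0, n_genes=5)
        scores = pd.Series([5.0, 5.0, 1.0, 0.5, 0.2], index=E.index)
        kept, _, _ = trim_noisy_genes(scores, E, C, frac=0.2)  # removes 1
        assert E.index[0] not in kept and E.index[1] in kept

    def test_invalid_fraction(self):
        E, C = random_instance(0)
        with pytest.raises(ConfigurationError):
            trim_noisy_genes(pd.Series(1.0, index=E.index), E, C, frac=1.0)


class TestVarianceCriterion:
    @pytest.mark.parametrize("row,expected", [
        ([1, 1, 1, 1], 0.0),
        ([0, 2], 2.0),
        ([1, 2, 3], 1.0),
    ])
    def test_hand_values(self, row, expected):
        assert f_statistic(np.array(row, float)) == pytest.approx(expected)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20))
    @settings(deadline=None, max_examples=200)
    def test_equals_sample_variance(self, row):
        arr = np.asarray(row, float)
        assert f_statistic(arr) == pytest.approx(np.var(arr, ddof=1), abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(np.array([1.0]))


class TestRedundancy:
    def test_identical_row_gives_one(self):
        C = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["i", "j"], dtype=float)
        assert redundancy("i", ["j"], C) == pytest.approx(1.0)

    def test_hand_mixed_correlations(self):
        C = pd.DataFrame([[1, 2, 3], [2, 4, 6], [1, -2, 1]],
                         index=["i", "j1", "j2"], dtype=float)
        # |R(i,j1)| = 1, |R(i,j2)| = 0 → mean 0.5
        assert redundancy("i", ["j1", "j2"], C) == pytest.approx(0.5)

    def test_empty_set_undefined(self):
        C = pd.DataFrame([[1, 2]], index=["i"], dtype=float)
        with pytest.raises(ValueError):
            redundancy("i", [], C)


class TestGreedySelection:
    def test_first_pick_maximizes_variance(self):
        C = pd.DataFrame([[0, 3], [0, 1]], index=["a", "b"], dtype=float)
        g, v = mrmr_select_next(["a", "b"], [], C)
        assert g == "a" and v == pytest.approx(4.5)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(6, 13))
        n = int(rng.integers(2, 6))
        _, C = random_instance(seed, n_genes=n_genes, n_types=6)
        S, cands = [], list(C.index)
        for _ in range(n):
            g, _ = mrmr_select_next(cands, S, C)
            S.append(g)
            cands.remove(g)
        assert S == brute_force_greedy(C, n)

    def test_tie_broken_by_gene_order(self):
        C = pd.DataFrame([[1, 5], [1, 5], [1, 2]],
                         index=["a", "b", "c"], dtype=float)
        g, _ = mrmr_select_next(["a", "b", "c"], [], C)
        assert g == "a"


class TestMrx3:
    def test_single_gene_is_max_variance_of_trimmed_pool(self):
        E, C = random_instance(3, n_genes=20, n_types=4, n_vox=10)
        subset = mrx3(E, C, n=1)
        pool = [g for g in C.index if g not in subset.trimmed_genes]
        variances = C.loc[pool].var(axis=1, ddof=1)
        assert subset.genes[0] == variances.idxmax()

    def test_prefix_property(self):
        E, C = random_instance(8, n_genes=30, n_types=5, n_vox=15)
        full = mrx3(E, C, n=8)
        for n in (3, 5, 8):
            assert mrx3(E, C, n=n).genes == full.genes[:n]

    def test_no_duplicates_and_n_too_large(self):
        E, C = random_instance(4, n_genes=10, n_types=3, n_vox=6)
        subset = mrx3(E, C, n=5)
        assert len(set(subset.genes)) == 5
        with pytest.raises(ConfigurationError):
            mrx3(E, C, n=10)  # only 9 survive the 10% trim


class TestSubsetSizeChoice:
    def test_elbow_on_convex_decreasing_curve(self):
        assert pick_elbow([10, 20, 30, 40, 50], [10, 4, 2, 1.5, 1.4]) == 20

    def test_flat_curve_returns_smallest(self, caplog):
        with caplog.at_level("WARNING", logger="missvuln.selection"):
            chosen = pick_elbow([5, 10, 15], [1.0, 1.0, 1.0])
        assert chosen == 5

    def test_two_sizes_returns_min_residual(self):
        assert pick_elbow([5, 10], [3.0, 1.0]) == 10
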