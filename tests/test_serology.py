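"""Array preprocessing, SAM permutation q-values, imputation, clustering, ELISA."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.stats import rankdata

from ifncyto import serology, synth
from ifncyto.errors import DataError
from ifncyto.serology import (MFIMatrix, background_subtract,
                              elisa_detection_limit, hcluster_average,
                              knn_impute, preprocess_mfi, sam_rank,
                              sam_signed_rank)


# ---------------------------------------------------------------------------
# independent SAM oracle: naive loops, exhaustive enumeration


def sam_oracle(mfi: pd.DataFrame, groups: pd.Series, pi0=1.0):
    """Brute-force delta-sweep SAM with standardized rank-sum statistics."""
    samples = list(mfi.index)
    n = len(samples)
    g2 = sorted(groups.unique())[1]
    n2 = sum(groups[s] == g2 for s in samples)

    def zstats(idx2):
        out = []
        for a in mfi.columns:
            r = rankdata(mfi[a].to_numpy())
            W = sum(r[i] for i in idx2)
            expect = n2 * (n + 1) / 2
            var = (n - n2) * n2 / (n * (n - 1)) * (sum(x * x for x in r) - n * (n + 1) ** 2 / 4)
            out.append(0.0 if var <= 0 else (W - expect) / np.sqrt(var))
        return np.array(out)

    obs_idx2 = [i for i, s in enumerate(samples) if groups[s] == g2]
    d = zstats(obs_idx2)
    perms = [zstats(list(c)) for c in combinations(range(n), n2)]
    perm_sorted = np.sort(np.array(perms), axis=1)
    dbar_sorted = perm_sorted.mean(axis=0)
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]

    q = np.full(len(d), 1.0)
    for delta in np.unique(np.abs(d_sorted - dbar_sorted)):
        diff = d_sorted - dbar_sorted
        ups = [i for i in range(len(d)) if diff[i] >= delta]
        los = [i for i in range(len(d)) if -diff[i] >= delta]
        cut_up = d_sorted[min(ups)] if ups else np.inf
        cut_low = d_sorted[max(los)] if los else -np.inf
        if cut_low >= cut_up:
            cut_up, cut_low = d_sorted.min(), d_sorted.max()
        called = (d >= cut_up) | (d <= cut_low)
        if called.sum() == 0:
            continue
        false = [sum((z >= cut_up) | (z <= cut_low)) for z in perms]
        fdr = min(1.0, pi0 * np.mean(false) / called.sum())
        q[called] = np.minimum(q[called], fdr)
    return d, q


class TestPreprocess:
    def _m(self, arr, undet=None):
        df = pd.DataFrame(arr, columns=[f"A{i}" for i in range(np.shape(arr)[1])])
        df.index = [f"S{i}" for i in range(len(df))]
        und = None if undet is None else pd.DataFrame(undet, index=df.index,
                                                      columns=df.columns)
        return MFIMatrix(df, pd.Series("g", index=df.index), "IgG", und)

    def test_undetected_set_to_one(self):
        m, _ = preprocess_mfi(self._m([[2000.0, 50.0]], [[False, True]]))
        assert m.mfi.iloc[0, 1] == 1.0
        assert m.mfi.iloc[0, 0] == 2000.0

    def test_nonreactive_strictly_below_1000(self):
        m, flags = preprocess_mfi(self._m([[999.0, 1000.0]]))
        assert not flags["A0"] and flags["A1"]

    def test_no_undetected_identity(self):
        m0 = self._m([[2000.0, 1500.0]])
        m, _ = preprocess_mfi(m0)
        assert (m.mfi.values == m0.mfi.values).all()

    def test_negative_mfi_rejected(self):
        with pytest.raises(DataError):
            preprocess_mfi(self._m([[-5.0, 10.0]]))


class TestSamRank:
    def test_exhaustive_matches_oracle(self, toy_sam_data):
        clean, flags, _ = toy_sam_data
        res = sam_rank(clean, n_perm="exhaustive", q_call=0.05)
        d, q = sam_oracle(clean.mfi, clean.groups)
        assert np.allclose(res["observed_stat"].to_numpy(), d, atol=1e-12)
        assert np.allclose(res["q"].to_numpy(), q, atol=1e-12)

    def test_monte_carlo_converges_to_exhaustive(self, toy_sam_data):
        clean, _, _ = toy_sam_data
        ex = sam_rank(clean, n_perm="exhaustive", q_call=0.05)
        mc = sam_rank(clean, n_perm=10000, seed=3, q_call=0.05)
        assert np.abs(ex["q"] - mc["q"]).max() <= 0.02

    def test_planted_antigen_called(self, toy_sam_data):
        clean, flags, truth = toy_sam_data
        res = sam_rank(clean, n_perm="exhaustive", q_call=0.05)
        assert res["q"].idxmin() in truth.reactive_antigens
        assert res.loc["Ag0", "q"] < 0.05

    def test_complete_separation_attains_min_q(self):
        rng = np.random.default_rng(1)
        n = 5
        df = pd.DataFrame(rng.uniform(1000, 2000, (2 * n, 10)),
                          columns=[f"A{i}" for i in range(10)],
                          index=[f"S{i}" for i in range(2 * n)])
        df.iloc[:n, 0] = np.linspace(1000, 1100, n)     # group a low
        df.iloc[n:, 0] = np.linspace(5000, 5100, n)     # group b high: separated
        groups = pd.Series(["a"] * n + ["b"] * n, index=df.index)
        m = MFIMatrix(df, groups)
        res = sam_rank(m, n_perm="exhaustive", q_call=0.05)
        d, q = sam_oracle(df, groups)
        assert res.loc["A0", "q"] == pytest.approx(q[0], abs=1e-12)
        assert res.loc["A0", "q"] == res["q"].min()
        assert res.loc["A0", "q"] >= 1.0 / 252  # C(10,5) distinct assignments

    def test_null_rarely_calls(self):
        """Identically distributed groups: no calls at the q<0.001 stringency
        in >=95% of seeds (with 924 distinct 6v6 assignments the observed one
        alone keeps every estimated FDR at or above 1/924)."""
        n_called = []
        for s in range(100):
            mfim, _ = synth.generate_array_data(
                6, [f"Ag{i}" for i in range(10)], reactive={}, seed=1000 + s)
            clean, _ = preprocess_mfi(mfim)
            res = sam_rank(clean, n_perm="exhaustive", q_call=0.001)
            n_called.append(int(res["called"].sum()))
        assert np.mean([c == 0 for c in n_called]) >= 0.95

    def test_calls_nested_in_threshold(self, toy_sam_data):
        clean, _, _ = toy_sam_data
        res = sam_rank(clean, n_perm="exhaustive")
        strict = set(res.index[res["q"] < 0.01])
        loose = set(res.index[res["q"] < 0.10])
        assert strict <= loose

    def test_one_level_groups_rejected(self, toy_sam_data):
        clean, _, _ = toy_sam_data
        with pytest.raises(DataError):
            sam_rank(clean, groups=pd.Series("x", index=clean.mfi.index))


def test_sam_signed_rank_detects_paired_shift():
    rng = np.random.default_rng(4)
    diffs = pd.DataFrame(rng.normal(0, 1, (10, 8)),
                         columns=[f"A{i}" for i in range(8)])
    diffs["A0"] += 3.0
    res = sam_signed_rank(diffs, n_perm="exhaustive", q_call=0.05)
    assert res["q"].idxmin() == "A0"
    assert res.loc["A0", "q"] < 0.05


class TestKnnImpute:
    def test_nearest_neighbor_by_hand(self):
        df = pd.DataFrame({"a": [1.0, 1.1, 10.0], "b": [np.nan, 500.0, 900.0]},
                          index=["s1", "s2", "s3"])
        out = knn_impute(df, k=1)
        assert out.loc["s1", "b"] == 500.0  # s2 is nearest on shared antigen a

    def test_no_missing_identity_and_nondestruction(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.uniform(1, 100, (5, 4)))
        pd.testing.assert_frame_equal(knn_impute(df, k=2), df)
        df2 = df.copy()
        df2.iloc[0, 0] = np.nan
        out = knn_impute(df2, k=2)
        assert (out.values[~df2.isna().values] == df2.values[~df2.isna().values]).all()

    def test_all_missing_antigen_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(DataError, match="b"):
            knn_impute(df)


class TestHCluster:
    def test_first_merge_closest_pair(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 10.0]}, index=["p", "q", "r"])
        Z, leaves = hcluster_average(df)
        assert sorted(Z[0, :2]) == [0, 1]  # p and q merge first
        assert set(leaves) == {"p", "q", "r"}

    def test_identical_items_merge_at_zero(self):
        df = pd.DataFrame({"x": [5.0, 5.0, 9.0]})
        Z, _ = hcluster_average(df)
        assert Z[0, 2] == 0.0

    def test_topology_invariant_to_input_order(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.uniform(0, 10, (6, 3)),
                          index=[f"s{i}" for i in range(6)])
        Z1, _ = hcluster_average(df)
        perm = [3, 1, 5, 0, 2, 4]
        Z2, _ = hcluster_average(df.iloc[perm])
        # cophenetic distances between the same named pairs must agree
        from scipy.spatial.distance import squareform
        c1 = pd.DataFrame(squareform(hierarchy.cophenet(Z1)),
                          index=df.index, columns=df.index)
        c2 = pd.DataFrame(squareform(hierarchy.cophenet(Z2)),
                          index=df.index[perm], columns=df.index[perm])
        c2 = c2.loc[df.index, df.index]
        assert np.allclose(c1.values, c2.values)

    def test_nan_rejected(self):
        df = pd.DataFrame({"x": [1.0, np.nan]})
        with pytest.raises(DataError, match="impute"):
            hcluster_average(df)


class TestElisa:
    def test_hand_sd(self):
        assert elisa_detection_limit([1, 2, 3]) == pytest.approx(2.0, abs=1e-12)

    def test_constant_blanks(self):
        assert elisa_detection_limit([4, 4, 4]) == 0.0

    def test_homogeneity(self):
        b = np.array([1.0, 3.0, 7.0])
        assert elisa_detection_limit(3 * b) == pytest.approx(3 * elisa_detection_limit(b))

    def test_too_few_blanks_rejected(self):
        with pytest.raises(DataError):
            elisa_detection_limit([1.0])

    def test_background_subtraction(self):
        out = background_subtract([100.0, 200.0], bsa=[10.0, 30.0])
        assert out == pytest.approx([80.0, 180.0])
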