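import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import plnotu as P
from plnotu.transforms import LN10, undefined_zero_log
from conftest import random_table


def _table(rows, otus=None, factors=None):
    counts = pd.DataFrame(rows, index=[f"s{i+1}" for i in range(len(rows))],
                          columns=otus or [f"o{j+1}" for j in range(len(rows[0]))])
    return P.CountTable(counts, factors)


class TestSizeFactors:
    def test_equal_totals_unit_factors(self):
        f = P.size_factors(_table([[50, 50], [60, 40]]))
        np.testing.assert_allclose(f.to_numpy(), [1.0, 1.0])

    def test_unequal_totals(self):
        f = P.size_factors(_table([[100, 0], [300, 0]]))
        np.testing.assert_allclose(f.to_numpy(), [2.0, 2.0 / 3.0])

    def test_literal_direction_is_reciprocal(self):
        t = _table([[100, 0], [300, 0]])
        np.testing.assert_allclose(
            P.size_factors(t, literal=True).to_numpy(),
            1.0 / P.size_factors(t).to_numpy(),
        )

    def test_normalized_totals_equal_grand_mean_exactly(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, n_samples=9, n_otus=7, lam=35.0)
        f = P.size_factors(t)
        norm_totals = t.counts.mul(f, axis=0).sum(axis=1)
        np.testing.assert_allclose(
            norm_totals.to_numpy(), t.sample_totals.mean(), rtol=1e-12
        )

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            P.size_factors(_table([[0, 0], [1, 1]]))


class TestStartedLog:
    def test_zero_maps_to_minus_one(self):
        tm = P.started_log(_table([[0, 10], [10, 10]]))
        assert tm.values.iloc[0, 0] == pytest.approx(-1.0)

    def test_count_ten_factor_one_maps_to_one(self):
        tm = P.started_log(_table([[10, 5], [10, 5]]))  # factors are 1
        assert tm.values.iloc[0, 0] == pytest.approx(1.0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 999))
    def test_monotone_within_sample(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_samples=4, n_otus=10, lam=5.0)
        tm = P.started_log(t)
        for s in t.sample_ids:
            c = t.counts.loc[s].to_numpy()
            v = tm.values.loc[s].to_numpy()
            order = np.argsort(c, kind="stable")
            dc, dv = np.diff(c[order]), np.diff(v[order])
            assert (dv[dc > 0] > 0).all()
            assert np.allclose(dv[dc == 0], 0.0)


class TestHybridLog:
    def test_continuity_at_knot(self):
        c = 1.0
        t = _table([[2, 3], [4, 5]])
        tm = P.hybrid_log(t, c=c)
        # both branches at x = c give log10(c)
        x = c
        log_branch = np.log10(x)
        lin_branch = np.log10(c) + (x - c) / (c * LN10)
        assert log_branch == pytest.approx(lin_branch)

    def test_zero_with_unit_knot(self):
        tm = P.hybrid_log(_table([[0, 4], [4, 4]]), c=1.0)
        assert tm.values.iloc[0, 0] == pytest.approx(-1.0 / LN10)

    def test_tracks_started_log_closely(self):
        rng = np.random.default_rng(1)
        t = random_table(rng, n_samples=20, n_otus=30, lam=8.0)
        a = P.started_log(t).values.to_numpy().ravel()
        b = P.hybrid_log(t).values.to_numpy().ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.99


class TestPcaPrepare:
    def test_presence_boundary_is_strict(self):
        # 57 samples: presence 5/57 (8.8%) dropped, 6/57 (10.5%) kept
        n = 57
        rare = np.zeros(n, dtype=int); rare[:5] = 3
        edge = np.zeros(n, dtype=int); edge[:6] = 3
        common = np.ones(n, dtype=int) * 4
        t = _table(np.column_stack([rare, edge, common]).tolist(),
                   otus=["rare", "edge", "common"])
        _tm, retained = P.pca_prepare(t)
        assert retained == ["edge", "common"]

    def test_zero_min_presence_keeps_all_detected(self):
        rng = np.random.default_rng(2)
        t = random_table(rng, n_samples=8, n_otus=6, lam=4.0)
        _tm, retained = P.pca_prepare(t, min_presence=0.0)
        detected = [o for o in t.otu_ids if (t.counts[o] > 0).any()]
        assert retained == detected

    def test_kaiser_count_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, n_samples=30, n_otus=12, lam=15.0)
        tm, _ = P.pca_prepare(t)
        res = P.run_pca(tm)
        eig = np.linalg.eigvalsh(np.corrcoef(tm.values.to_numpy(), rowvar=False))
        assert res.kaiser_n == int(np.sum(np.sqrt(np.maximum(eig, 0)) > 1.0))
        # covariance-matrix variant against its own eigendecomposition
        res2 = P.run_pca(tm, scale=False)
        X = tm.values.to_numpy()
        eig2 = np.linalg.eigvalsh(np.cov(X - X.mean(axis=0), rowvar=False))
        assert res2.kaiser_n == int(np.sum(np.sqrt(np.maximum(eig2, 0)) > 1.0))

    def test_scores_match_sklearn(self):
        from sklearn.decomposition import PCA as SkPCA
        rng = np.random.default_rng(4)
        t = random_table(rng, n_samples=25, n_otus=9, lam=12.0)
        tm, _ = P.pca_prepare(t)
        res = P.run_pca(tm, scale=False)
        sk = SkPCA().fit(tm.values.to_numpy())
        np.testing.assert_allclose(
            np.abs(res.scores.to_numpy()[:, :5]),
            np.abs(sk.transform(tm.values.to_numpy())[:, :5]),
            atol=1e-8,
        )
        np.testing.assert_allclose(
            res.proportion_explained[:5], sk.explained_variance_ratio_[:5], atol=1e-10
        )


class TestParalogCorrelations:
    def test_exact_copy_is_candidate_paralog(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(30, 12) + 1
        t = _table(np.column_stack([base, base, rng.poisson(30, 12) + 1]).tolist(),
                   otus=["a", "a_copy", "other"])
        res = P.paralog_correlations(t)
        assert res.r.loc["a", "a_copy"] == pytest.approx(1.0)
        assert res.labels.loc["a", "a_copy"] == "candidate-paralog"

    def test_anticorrelated_pair_supports_distinct_genomes(self):
        # one haplotype substitutes for another across samples: strong
        # negative abundance correlation on the log scale
        rng = np.random.default_rng(6)
        n = 20
        mix = rng.uniform(0.15, 0.85, n)
        depth = 2000
        a = np.maximum(1, rng.poisson(depth * mix))
        b = np.maximum(1, rng.poisson(depth * (1 - mix)))
        t = _table(np.column_stack([a, b]).tolist(), otus=["iv", "ii"])
        res = P.paralog_correlations(t)
        assert res.r.loc["iv", "ii"] < 0
        assert res.p.loc["iv", "ii"] < 0.001
        assert res.labels.loc["iv", "ii"] == "distinct-genome"

    def test_two_copresent_samples_not_assessable(self):
        rows = [[5, 7], [3, 2], [0, 4], [6, 0], [0, 5]]
        t = _table(rows, otus=["x", "y"])
        # co-present samples: rows 1 and 2 only
        res = P.paralog_correlations(t)
        assert res.labels.loc["x", "y"] == "not-assessable"
        assert np.isnan(res.r.loc["x", "y"])
        assert res.n.loc["x", "y"] == 2

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, n_samples=15, n_otus=5, lam=10.0)
        res = P.paralog_correlations(t)
        r = res.r.to_numpy()
        np.testing.assert_allclose(r, r.T, equal_nan=True)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_zeros_are_undefined_in_transform(self):
        t = _table([[0, 3], [2, 4]])
        tm = undefined_zero_log(t)
        assert np.isnan(tm.values.iloc[0, 0])
        assert np.isfinite(tm.values.iloc[1, 0])
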