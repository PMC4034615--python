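import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

import plnotu as P
from plnotu.model import SUM_OTU_ID, build_design, log_posterior
from conftest import quick_fit


def mc_pln_pmf(y, psi, sigma2, n=10**6, seed=0):
    """Independent Monte-Carlo estimate of the PLN pmf, with its SE."""
    rng = np.random.default_rng(seed)
    lam = np.exp(psi + rng.normal(0.0, np.sqrt(sigma2), n))
    vals = np.exp(y * np.log(lam) - lam - gammaln(y + 1))
    return vals.mean(), vals.std(ddof=1) / np.sqrt(n)


class TestPlnPmf:
    def test_sigma_zero_is_poisson(self):
        assert P.pln_pmf(0, 0.0, 0.0) == pytest.approx(np.exp(-1), abs=1e-12)
        for y in (0, 1, 5, 20):
            for psi in (-1.0, 0.0, 2.0):
                assert P.pln_pmf(y, psi, 0.0) == pytest.approx(
                    stats.poisson.pmf(y, np.exp(psi)), abs=1e-12
                )

    def test_normalization(self):
        # Poisson(e^1) with lognormal overdispersion 0.5: mass beyond y=200
        # is negligible, so the head must sum to 1 within quadrature error
        total = sum(P.pln_pmf(y, 1.0, 0.5) for y in range(201))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_monte_carlo_oracle(self):
        val = P.pln_pmf(3, 0.7, 1.2)
        est, se = mc_pln_pmf(3, 0.7, 1.2, n=10**7, seed=1)
        assert abs(val - est) < 3 * se

    def test_mean_identity(self):
        # E[Y] = exp(psi + sigma2/2)
        psi, s2 = 0.4, 0.8
        mean = sum(y * P.pln_pmf(y, psi, s2) for y in range(400))
        assert mean == pytest.approx(np.exp(psi + s2 / 2), rel=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            P.pln_pmf(1, 0.0, -0.1)


def _tiny_table():
    counts = pd.DataFrame(
        [[5, 0], [3, 7]], index=["s1", "s2"], columns=["oA", "oB"]
    )
    fac = pd.DataFrame({"grp": ["x", "y"]}, index=counts.index)
    return P.CountTable(counts, fac)


class TestBuildDesign:
    def test_response_includes_sum_otu_rows(self):
        d = build_design(_tiny_table(), P.ModelSpec(fixed_factors=["grp"]))
        assert d.y.size == 6  # 4 real cells + 2 sum-OTU rows
        assert d.unit_ids == ["oA", "oB", SUM_OTU_ID]
        # the sum-OTU count for s2 with counts (3, 7) is 10
        sum_rows = d.y[d.unit_idx == 2]
        assert sum_rows.tolist() == [5, 10]

    def test_single_level_factor_rejected(self):
        counts = pd.DataFrame([[1], [2]], index=["s1", "s2"], columns=["o"])
        fac = pd.DataFrame({"grp": ["x", "x"]}, index=counts.index)
        with pytest.raises(ValueError, match="single level"):
            build_design(P.CountTable(counts, fac), P.ModelSpec(fixed_factors=["grp"]))

    def test_against_hand_built_design_matrix(self):
        # 2x2 factorial, one sample per cell, 3 OTUs + sum-OTU:
        # 4 units x 3 non-reference cells fixed effects + 4 intercepts + 4 c_k
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(10, (4, 3)), index=["s1", "s2", "s3", "s4"],
            columns=["o1", "o2", "o3"],
        )
        fac = pd.DataFrame(
            {"sp": ["f", "f", "g", "g"], "bk": ["e", "w", "e", "w"]},
            index=counts.index,
        )
        table = P.CountTable(counts, fac)
        d = build_design(table, P.ModelSpec(fixed_factors=["sp", "bk"]))
        assert d.cells == ["f.e", "f.w", "g.e", "g.w"]
        assert d.idx_B.shape == (4, 3)

        # independent construction straight from the model definition
        units = ["o1", "o2", "o3", SUM_OTU_ID]
        samples = list(counts.index)
        cells = ["f.e", "f.w", "g.e", "g.w"]
        cell_of = dict(zip(samples, cells))
        X = np.zeros((16, len(d.col_names)))
        col = {name: i for i, name in enumerate(d.col_names)}
        y = []
        row = 0
        for u in units:
            for s in samples:
                y.append(counts.loc[s, u] if u != SUM_OTU_ID else counts.loc[s].sum())
                X[row, col[f"I:{u}"]] = 1
                if cell_of[s] != "f.e":
                    X[row, col[f"B:{u}:{cell_of[s]}"]] = 1
                X[row, col[f"c:{s}"]] = 1
                row += 1
        np.testing.assert_array_equal(d.X, X)
        np.testing.assert_array_equal(d.y, np.array(y))


class TestLogPosterior:
    def _state(self, d, beta=None, eta=None):
        P_ = d.n_params
        return {
            "beta": np.zeros(P_) if beta is None else beta,
            "eta": np.zeros(d.y.size) if eta is None else eta,
            "sigma2": np.ones(d.n_units),
            "var_c": 1.0,
        }

    def test_zero_state_closed_form(self):
        # all effects zero, eta = 0: Poisson part is sum(y*0 - 1 - log y!)
        table = _tiny_table()
        d = build_design(table, P.ModelSpec(fixed_factors=["grp"]))
        pr = P.PriorSpec()
        lp = log_posterior(self._state(d), d, pr)
        y = d.y
        expect = np.sum(-1.0 - gammaln(y + 1))
        expect += d.y.size * stats.norm.logpdf(0.0)          # eps terms
        expect += d.n_samples * stats.norm.logpdf(0.0)       # c_k terms
        n_fixed = d.n_units * 2
        expect += n_fixed * stats.norm.logpdf(0.0, scale=1e4)
        from plnotu.model import _log_sinvchi2
        expect += _log_sinvchi2(1.0, pr.eff_nu(pr.coverage_nu), 1.0)
        nu_r = pr.resolved_residual_nu(d.n_units)
        expect += d.n_units * _log_sinvchi2(1.0, nu_r, 1.0)
        assert lp == pytest.approx(expect, rel=1e-12)

    def test_replicating_data_doubles_likelihood_part(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(6, (2, 2)), index=["s1", "s2"],
                              columns=["o1", "o2"])
        fac = pd.DataFrame({"g": ["x", "y"]}, index=counts.index)
        t1 = P.CountTable(counts, fac)
        c2 = pd.concat([counts, counts.set_axis(["s3", "s4"])])
        f2 = pd.concat([fac, fac.set_axis(["s3", "s4"])])
        t2 = P.CountTable(c2, f2)
        d1 = build_design(t1, P.ModelSpec(fixed_factors=["g"]))
        d2 = build_design(t2, P.ModelSpec(fixed_factors=["g"]))
        pr = P.PriorSpec()

        def likelihood_part(d):
            y, eta = d.y, np.zeros(d.y.size)
            pois = np.sum(y * eta - np.exp(eta) - gammaln(y + 1))
            eps = d.y.size * stats.norm.logpdf(0.0)
            return pois + eps

        lp1 = log_posterior(self._state(d1), d1, pr)
        lp2 = log_posterior(self._state(d2), d2, pr)
        # subtract the (data-size independent) prior and c_k parts
        prior1 = lp1 - likelihood_part(d1) - d1.n_samples * stats.norm.logpdf(0.0)
        prior2 = lp2 - likelihood_part(d2) - d2.n_samples * stats.norm.logpdf(0.0)
        assert prior1 == pytest.approx(prior2, rel=1e-12)
        assert likelihood_part(d2) == pytest.approx(2 * likelihood_part(d1), rel=1e-12)

    def test_nonfinite_parameter_rejected(self):
        d = build_design(_tiny_table(), P.ModelSpec(fixed_factors=["grp"]))
        s = self._state(d)
        s["beta"][0] = np.nan
        with pytest.raises(ValueError, match="nonfinite"):
            log_posterior(s, d, P.PriorSpec())


class TestSampler:
    def test_seed_determinism_bit_identical(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(15, (6, 3)),
                              index=[f"s{i}" for i in range(6)],
                              columns=["o1", "o2", "o3"])
        fac = pd.DataFrame({"g": ["x", "y"] * 3}, index=counts.index)
        t = P.CountTable(counts, fac)
        f1 = quick_fit(t, seed=5, iterations=600, burn_in=100, thin=5,
                       fixed_factors=["g"])
        f2 = quick_fit(t, seed=5, iterations=600, burn_in=100, thin=5,
                       fixed_factors=["g"])
        pd.testing.assert_frame_equal(f1.draws, f2.draws)

    def test_retained_draw_count(self):
        spec = P.ModelSpec(fixed_factors=["g"], iterations=1100, burn_in=100, thin=10)
        assert spec.n_retained == 100

    def test_sum_otu_consistency_single_otu(self):
        # with a single OTU the sum-OTU is the OTU itself: relative effects ~ 0
        rng = np.random.default_rng(3)
        counts = pd.DataFrame({"only": rng.poisson(50, 12)},
                              index=[f"s{i}" for i in range(12)])
        fac = pd.DataFrame({"g": ["x", "y"] * 6}, index=counts.index)
        fit = quick_fit(P.CountTable(counts, fac), seed=1, iterations=2000,
                        burn_in=500, thin=2, fixed_factors=["g"])
        rel = P.relative_effects(fit)
        # OTU and sum-OTU share the data but have independent latent
        # residuals, so relative effects vanish in posterior mean (within
        # Monte-Carlo noise), not draw by draw
        assert np.abs(rel.values.mean(axis=0)).max() < 0.15
        props = P.abundance_proportions(fit, fit.cells[0])
        assert props["proportion_mean"].iloc[0] == pytest.approx(1.0, abs=0.15)

    def test_intercept_matches_quadrature_posterior(self):
        # one OTU, residual variance pinned by a sharp prior, coverage
        # pinned near zero: the intercept posterior is available by
        # deterministic quadrature of prod_k PLN(y_k | I, sigma2)
        rng = np.random.default_rng(4)
        sigma2 = 0.3
        y = rng.poisson(np.exp(2.0 + rng.normal(0, np.sqrt(sigma2), 10)))
        counts = pd.DataFrame({"o": y}, index=[f"s{i}" for i in range(10)])
        fac = pd.DataFrame({"g": ["x"] * 5 + ["y"] * 5}, index=counts.index)
        t = P.CountTable(counts, fac)
        pr = P.PriorSpec(
            residual_nu=10**7, residual_V=sigma2,
            coverage_nu=10**7, coverage_V=1e-8,
        )
        spec = P.ModelSpec(fixed_factors=["g"], iterations=12000, burn_in=2000,
                           thin=5, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = P.sample_posterior(t, spec, pr)
        # quadrature over I for the reference-cell samples only (B absorbs
        # the other cell), single-unit likelihood; the sum-OTU unit carries
        # identical data, which doubles the likelihood for the *shared*
        # parameters; here OTU and sum-OTU have separate intercepts, so the
        # OTU intercept posterior depends only on its own likelihood
        ys = y[:5]
        grid = np.linspace(0.5, 3.5, 601)
        loglik = np.zeros_like(grid)
        for k, I in enumerate(grid):
            loglik[k] = sum(np.log(P.pln_pmf(int(yy), I, sigma2)) for yy in ys)
        w = np.exp(loglik - loglik.max())
        w /= w.sum()
        quad_mean = float(np.sum(grid * w))
        chain = fit.intercept_chain("o")
        import arviz as az
        ess = az.ess(chain)
        se = chain.std(ddof=1) / np.sqrt(ess)
        assert abs(chain.mean() - quad_mean) < 3 * se + 0.02

    def test_pln_mean_identity_from_simulation(self):
        # empirical mean of PLN(lambda, s2) draws -> lambda * exp(s2/2)
        rng = np.random.default_rng(9)
        lam, s2, n = 3.0, 0.5, 200_000
        draws = rng.poisson(np.exp(np.log(lam) + rng.normal(0, np.sqrt(s2), n)))
        expect = lam * np.exp(s2 / 2)
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - expect) < 4 * se
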