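"""Poisson-lognormal GLMM for OTU counts with a sum-OTU coverage control.

Model
-----
Count ``y_oijk`` of OTU *o* under condition cell *i*, group *j*, sample *k*
follows a Poisson-lognormal distribution ``PLN(lambda, sigma2_o)``: Poisson
with rate ``exp(psi + eps)`` where ``psi = log(lambda)`` and
``eps ~ Normal(0, sigma2_o)`` (so ``E[y] = lambda * exp(sigma2_o / 2)``).
The log-rate decomposes additively::

    psi_oijk = I_o + B_oi + c_k + a_oj

with OTU intercepts ``I_o``, OTU-by-condition fixed effects ``B_oi``
(reference-cell coded), a shared per-sample coverage random effect ``c_k``
and optional OTU-by-group random effects ``a_oj``.  An artificial *sum-OTU*
whose per-sample count is the sample total is modelled jointly; expressing
OTU effects relative to the sum-OTU's (see :mod:`plnotu.inference`) cancels
systematic coverage biases across conditions and turns intercepts into
log-proportions of total.

Fitting is Bayesian MCMC: vectorised random-walk Metropolis on the latent
log-rates (adaptive step during burn-in only), a joint conjugate Gaussian
draw for all location effects given the latents, and conjugate
scaled-inverse-chi-square draws for variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import gammaln

from .counts import CountTable

__all__ = [
    "SUM_OTU_ID",
    "ModelSpec",
    "PriorSpec",
    "Design",
    "PosteriorSamples",
    "pln_pmf",
    "build_design",
    "log_posterior",
    "sample_posterior",
]

#: id of the artificial total-count unit appended to every design
SUM_OTU_ID = "sumOTU"

CELL_SEP = "."


# ---------------------------------------------------------------------------
# Poisson-lognormal pmf
# ---------------------------------------------------------------------------

def _pln_pmf_scalar(y: int, psi: float, sigma2: float) -> float:
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if y < 0 or y != int(y):
        raise ValueError("y must be a nonnegative integer")
    y = int(y)
    if sigma2 == 0.0:
        return float(stats.poisson.pmf(y, np.exp(psi)))
    sd = np.sqrt(sigma2)

    def integrand(e: float) -> float:
        lam_log = psi + e
        return np.exp(
            y * lam_log - np.exp(lam_log) - gammaln(y + 1)
            - 0.5 * e * e / sigma2
        ) / np.sqrt(2.0 * np.pi * sigma2)

    # the integrand is a product of two unimodal factors; anchor quadrature
    # near both modes (eps = 0 and eps = log(max(y,1)) - psi)
    mode = np.log(max(y, 0.5)) - psi
    lo = min(-12.0 * sd, mode - 12.0 * sd)
    hi = max(12.0 * sd, mode + 12.0 * sd)
    val, _ = integrate.quad(
        integrand, lo, hi, points=[p for p in (0.0, mode) if lo < p < hi],
        epsabs=1e-12, epsrel=1e-10, limit=400,
    )
    return float(val)


def pln_pmf(y, psi, sigma2):
    """Probability mass P(Y = y) of the Poisson-lognormal distribution.

    ``PLN(exp(psi), sigma2)``: Poisson with log-rate ``psi + eps``,
    ``eps ~ Normal(0, sigma2)``.  Computed by adaptive quadrature over the
    latent; exact Poisson in the ``sigma2 = 0`` limit.  Broadcasts over
    array inputs.
    """
    b = np.broadcast(np.asarray(y), np.asarray(psi), np.asarray(sigma2))
    if b.ndim == 0:
        return _pln_pmf_scalar(y, float(psi), float(sigma2))
    out = np.empty(b.shape)
    out.flat = [_pln_pmf_scalar(int(yy), float(pp), float(ss)) for yy, pp, ss in b]
    return out


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """What to fit: fixed condition factors, random groupings, MCMC settings.

    ``fixed_factors`` are crossed into condition cells (a saturated
    cell-means layout, i.e. main effects plus all interactions of the listed
    factors); ``random_groups`` name factors that enter as OTU-specific
    Gaussian random effects ``a_oj``.
    """

    fixed_factors: list[str] = field(default_factory=list)
    random_groups: list[str] = field(default_factory=list)
    iterations: int = 55_000
    burn_in: int = 5_000
    thin: int = 50
    seed: int | None = None
    reference_cell: str | None = None

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not self.fixed_factors:
            raise ValueError("at least one fixed factor is required")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PriorSpec:
    """Priors: wide Normal on fixed effects, scaled-inverse-chi-square
    (1x1 inverse-Wishart) on variance components.

    Defaults follow the noninformative choices customary for this model:
    Normal(0, 1e8) fixed effects; V = 1, nu = 0 for the coverage and group
    variances (nu clamped to ``nu_floor`` for propriety); V = 1 and
    nu = (number of units including the sum-OTU) - 0.998 for the residual
    log-variances (``residual_nu=None`` selects that rule).
    """

    fixed_effect_variance: float = 1e8
    coverage_V: float = 1.0
    coverage_nu: float = 0.0
    group_V: float = 1.0
    group_nu: float = 0.0
    residual_V: float = 1.0
    residual_nu: float | None = None
    nu_floor: float = 0.002

    def __post_init__(self) -> None:
        for v in (self.fixed_effect_variance, self.coverage_V, self.group_V, self.residual_V):
            if v <= 0:
                raise ValueError("prior scale parameters must be > 0")
        for nu in (self.coverage_nu, self.group_nu):
            if nu < 0:
                raise ValueError("nu must be >= 0")

    def eff_nu(self, nu: float) -> float:
        return max(nu, self.nu_floor)

    def resolved_residual_nu(self, n_units: int) -> float:
        nu = self.residual_nu if self.residual_nu is not None else n_units - 0.998
        return self.eff_nu(nu)


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """Long-format response with the appended sum-OTU and its design matrix.

    Rows are unit-major: all samples of unit 0, then unit 1, ...  The last
    unit is the sum-OTU, whose count is the sample total.
    """

    y: np.ndarray                  # (N,) counts
    X: np.ndarray                  # (N, P) dense 0/1 design
    col_names: list[str]
    unit_ids: list[str]            # real OTUs then SUM_OTU_ID
    sample_ids: list[str]
    cells: list[str]               # sorted cell labels; cells[0] is reference
    cell_of_sample: np.ndarray     # (K,) int
    unit_idx: np.ndarray           # (N,) int
    sample_idx: np.ndarray         # (N,) int
    idx_I: np.ndarray              # (U,) column of each unit intercept
    idx_B: np.ndarray              # (U, C-1) columns of non-reference effects
    idx_c: np.ndarray              # (K,) columns of coverage effects
    group_levels: dict             # factor -> list of levels
    idx_a: dict                    # factor -> (U, L) column index array
    factors: pd.DataFrame

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    @property
    def reference_cell(self) -> str:
        return self.cells[0]


def _cell_labels(factors: pd.DataFrame, fixed: list[str]) -> pd.Series:
    return factors[fixed].agg(CELL_SEP.join, axis=1)


def build_design(table: CountTable, spec: ModelSpec) -> Design:
    """Build the joint response/design including the artificial sum-OTU.

    The response stacks every (unit, sample) cell; the sum-OTU's count for a
    sample is that sample's total.  Fixed effects are reference-cell coded
    over the crossed condition cells (alphabetically first cell is the
    reference unless ``spec.reference_cell`` overrides it).
    """
    for f in spec.fixed_factors + spec.random_groups:
        if f not in table.factor_names:
            raise ValueError(f"factor {f!r} not present in table")
    for f in spec.fixed_factors:
        if table.factors[f].nunique() < 2:
            raise ValueError(f"fixed factor {f!r} has a single level")
    if SUM_OTU_ID in table.otu_ids:
        raise ValueError(f"OTU id collides with reserved sum-OTU id {SUM_OTU_ID!r}")

    unit_ids = [*table.otu_ids, SUM_OTU_ID]
    sample_ids = table.sample_ids
    U, K = len(unit_ids), len(sample_ids)
    counts = np.column_stack(
        [table.counts.to_numpy().T.reshape(len(table.otu_ids), K).T,
         table.sample_totals.to_numpy()[:, None]]
    )  # (K, U)

    cell_lab = _cell_labels(table.factors, spec.fixed_factors)
    cells = sorted(cell_lab.unique())
    if spec.reference_cell is not None:
        if spec.reference_cell not in cells:
            raise ValueError(f"reference cell {spec.reference_cell!r} not found")
        cells = [spec.reference_cell, *[c for c in cells if c != spec.reference_cell]]
    cell_of_sample = np.array([cells.index(c) for c in cell_lab], dtype=np.intp)

    C = len(cells)
    ncols = U + U * (C - 1) + K
    group_levels: dict[str, list[str]] = {}
    for g in spec.random_groups:
        group_levels[g] = sorted(table.factors[g].unique())
        ncols += U * len(group_levels[g])

    col_names: list[str] = []
    idx_I = np.arange(U, dtype=np.intp) * (1 + (C - 1))
    idx_B = np.empty((U, C - 1), dtype=np.intp)
    p = 0
    for u, uid in enumerate(unit_ids):
        col_names.append(f"I:{uid}")
        idx_I[u] = p
        p += 1
        for ci in range(1, C):
            col_names.append(f"B:{uid}:{cells[ci]}")
            idx_B[u, ci - 1] = p
            p += 1
    idx_c = np.arange(p, p + K, dtype=np.intp)
    col_names.extend(f"c:{s}" for s in sample_ids)
    p += K
    idx_a: dict[str, np.ndarray] = {}
    for g, levels in group_levels.items():
        idx_a[g] = np.empty((U, len(levels)), dtype=np.intp)
        for u, uid in enumerate(unit_ids):
            for li, lev in enumerate(levels):
                col_names.append(f"a:{g}:{uid}:{lev}")
                idx_a[g][u, li] = p
                p += 1
    assert p == ncols

    N = U * K
    unit_idx = np.repeat(np.arange(U, dtype=np.intp), K)
    sample_idx = np.tile(np.arange(K, dtype=np.intp), U)
    y = counts.T.reshape(N)

    X = np.zeros((N, ncols))
    rows = np.arange(N)
    X[rows, idx_I[unit_idx]] = 1.0
    samp_cell = cell_of_sample[sample_idx]
    nonref = samp_cell > 0
    X[rows[nonref], idx_B[unit_idx[nonref], samp_cell[nonref] - 1]] = 1.0
    X[rows, idx_c[sample_idx]] = 1.0
    for g, levels in group_levels.items():
        lev_of_sample = np.array(
            [levels.index(v) for v in table.factors[g]], dtype=np.intp
        )
        X[rows, idx_a[g][unit_idx, lev_of_sample[sample_idx]]] = 1.0

    return Design(
        y=y.astype(np.int64), X=X, col_names=col_names, unit_ids=unit_ids,
        sample_ids=list(sample_ids), cells=cells, cell_of_sample=cell_of_sample,
        unit_idx=unit_idx, sample_idx=sample_idx, idx_I=idx_I, idx_B=idx_B,
        idx_c=idx_c, group_levels=group_levels, idx_a=idx_a,
        factors=table.factors.copy(),
    )


# ---------------------------------------------------------------------------
# Joint log posterior (used for testing and diagnostics)
# ---------------------------------------------------------------------------

def _log_sinvchi2(x: float, nu: float, V: float) -> float:
    """Log density of the scaled inverse-chi-square (1x1 inverse-Wishart)."""
    half = nu / 2.0
    return (
        half * np.log(half * V) - gammaln(half)
        - (half + 1.0) * np.log(x) - half * V / x
    )


def log_posterior(state: dict, design: Design, priors: PriorSpec) -> float:
    """Joint log density of data and parameters at ``state``.

    ``state`` maps ``beta`` (location effects, design column order), ``eta``
    (latent log-rates per observation), ``sigma2`` (per-unit residual
    log-variance), ``var_c`` and optionally ``var_a[(factor, unit)]``.
    """
    beta = np.asarray(state["beta"], dtype=float)
    eta = np.asarray(state["eta"], dtype=float)
    sigma2 = np.asarray(state["sigma2"], dtype=float)
    var_c = float(state["var_c"])
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(eta))):
        raise ValueError("nonfinite parameter")
    if np.any(sigma2 <= 0) or var_c <= 0:
        raise ValueError("variance components must be > 0")

    y = design.y
    psi = design.X @ beta
    lp = float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))
    s2_obs = sigma2[design.unit_idx]
    eps = eta - psi
    lp += float(np.sum(stats.norm.logpdf(eps, scale=np.sqrt(s2_obs))))

    c = beta[design.idx_c]
    lp += float(np.sum(stats.norm.logpdf(c, scale=np.sqrt(var_c))))
    fixed_cols = np.concatenate([design.idx_I, design.idx_B.reshape(-1)])
    lp += float(np.sum(stats.norm.logpdf(
        beta[fixed_cols], scale=np.sqrt(priors.fixed_effect_variance))))

    nu_c = priors.eff_nu(priors.coverage_nu)
    lp += _log_sinvchi2(var_c, nu_c, priors.coverage_V)
    nu_r = priors.resolved_residual_nu(design.n_units)
    for s2 in sigma2:
        lp += _log_sinvchi2(float(s2), nu_r, priors.residual_V)

    var_a = state.get("var_a", {})
    nu_g = priors.eff_nu(priors.group_nu)
    for g, levels in design.group_levels.items():
        for u in range(design.n_units):
            va = float(var_a[(g, design.unit_ids[u])])
            a = beta[design.idx_a[g][u]]
            lp += float(np.sum(stats.norm.logpdf(a, scale=np.sqrt(va))))
            lp += _log_sinvchi2(va, nu_g, priors.group_V)
    return lp


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus chain metadata.

    ``draws`` has one row per retained draw and one named column per
    parameter (``I:<unit>``, ``B:<unit>:<cell>``, ``c:<sample>``, ``var_c``,
    ``a:<factor>:<unit>:<level>``, ``var_a:<factor>:<unit>``,
    ``sigma2:<unit>`` and optionally ``eps:<unit>:<sample>``).
    """

    draws: pd.DataFrame
    unit_ids: list[str]
    cells: list[str]
    sample_ids: list[str]
    iterations: int
    burn_in: int
    thin: int
    seed: int | None
    ess: pd.Series | None = None
    acceptance: pd.Series | None = None

    @property
    def otu_ids(self) -> list[str]:
        return [u for u in self.unit_ids if u != SUM_OTU_ID]

    @property
    def reference_cell(self) -> str:
        return self.cells[0]

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def intercept_chain(self, unit: str) -> np.ndarray:
        return self.draws[f"I:{unit}"].to_numpy()

    def fixed_chain(self, unit: str, cell: str) -> np.ndarray:
        """B_{unit, cell} draws; identically zero for the reference cell."""
        if cell == self.reference_cell:
            return np.zeros(self.n_draws)
        return self.draws[f"B:{unit}:{cell}"].to_numpy()

    def fixed_effect_columns(self, unit: str) -> list[str]:
        pre = f"B:{unit}:"
        return [c for c in self.draws.columns if c.startswith(pre)]

    def to_tsv(self, path) -> None:
        out = self.draws.copy()
        out.insert(0, "draw", np.arange(1, len(out) + 1))
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _sinvchi2_draw(rng, nu: float, nu_V_plus_ss, n) -> np.ndarray:
    """Posterior draw of a scaled-inv-chi-square variance: (nu*V + SS)/chi2."""
    return nu_V_plus_ss / rng.chisquare(nu + n)


def sample_posterior(
    table: CountTable,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    store_latent: bool = False,
    ess_warn: float = 100.0,
) -> PosteriorSamples:
    """Fit the PLN GLMM by MCMC; deterministic given ``spec.seed``.

    Returns retained chains for every parameter and per-parameter effective
    sample sizes for the fixed effects and intercepts.  Emits a warning
    (never an error) when any fixed-effect ESS falls below ``ess_warn``.
    """
    priors = priors or PriorSpec()
    design = build_design(table, spec)
    cell_sizes = np.bincount(design.cell_of_sample, minlength=len(design.cells))
    if np.any(cell_sizes < 2):
        warnings.warn("a condition cell has fewer than 2 samples", stacklevel=2)

    rng = np.random.default_rng(spec.seed)
    y = design.y
    U, K, N, P = design.n_units, design.n_samples, design.y.size, design.n_params
    unit_idx, sample_idx = design.unit_idx, design.sample_idx
    X = design.X

    # per-unit Gram blocks: X'WX = sum_u X_u'X_u / sigma2_u
    unit_rows = [np.flatnonzero(unit_idx == u) for u in range(U)]
    grams = np.stack([X[r].T @ X[r] for r in unit_rows])          # (U, P, P)
    Xu_T = [X[r].T.copy() for r in unit_rows]                     # (P, K) each

    # prior precision bookkeeping
    fixed_cols = np.concatenate([design.idx_I, design.idx_B.reshape(-1)])
    prior_prec = np.zeros(P)
    prior_prec[fixed_cols] = 1.0 / priors.fixed_effect_variance

    nu_c = priors.eff_nu(priors.coverage_nu)
    nu_g = priors.eff_nu(priors.group_nu)
    nu_r = priors.resolved_residual_nu(U)

    # initial state
    eta = np.log(y + 0.5)
    sigma2 = np.ones(U)
    var_c = 0.25
    var_a = {
        (g, u): 0.25 for g in design.group_levels for u in range(U)
    }
    A0 = grams.sum(axis=0) + np.eye(P) * 1e-4
    beta = np.linalg.solve(A0, X.T @ eta)

    step = np.full(U, 0.8)
    n_ret = spec.n_retained
    rec_beta = np.empty((n_ret, P))
    rec_sigma2 = np.empty((n_ret, U))
    rec_var_c = np.empty(n_ret)
    rec_var_a = {k: np.empty(n_ret) for k in var_a}
    rec_eps = np.empty((n_ret, N)) if store_latent else None
    acc_count = np.zeros(U)
    acc_sweeps = 0

    unit_counts = np.bincount(unit_idx, minlength=U).astype(float)
    ridx = 0
    for t in range(1, spec.iterations + 1):
        psi = X @ beta

        # --- latent log-rates: vectorised random-walk Metropolis -------
        s2_obs = sigma2[unit_idx]
        prop = eta + step[unit_idx] * rng.standard_normal(N)
        log_acc = (
            y * (prop - eta) - (np.exp(prop) - np.exp(eta))
            - ((prop - psi) ** 2 - (eta - psi) ** 2) / (2.0 * s2_obs)
        )
        accept = np.log(rng.random(N)) < log_acc
        eta = np.where(accept, prop, eta)
        rate_u = np.bincount(unit_idx, weights=accept, minlength=U) / unit_counts
        if t <= spec.burn_in:
            step *= np.exp((rate_u - 0.44) / np.sqrt(1.0 + t / 50.0))
            step = np.clip(step, 1e-3, 10.0)
        else:
            acc_count += rate_u
            acc_sweeps += 1

        # --- location effects: joint conjugate Gaussian -----------------
        prior_prec[design.idx_c] = 1.0 / var_c
        for g in design.group_levels:
            for u in range(U):
                prior_prec[design.idx_a[g][u]] = 1.0 / var_a[(g, u)]
        w = 1.0 / sigma2
        A = np.tensordot(w, grams, axes=1)
        A[np.diag_indices_from(A)] += prior_prec
        b = np.zeros(P)
        for u in range(U):
            b += w[u] * (Xu_T[u] @ eta[unit_rows[u]])
        cf = cho_factor(A, lower=True)
        mean = cho_solve(cf, b)
        z = rng.standard_normal(P)
        beta = mean + solve_triangular(cf[0], z, lower=True, trans="T")

        # recentre coverage effects; shift absorbed by all unit intercepts
        m = beta[design.idx_c].mean()
        beta[design.idx_c] -= m
        beta[design.idx_I] += m

        # --- variance components ----------------------------------------
        psi = X @ beta
        eps = eta - psi
        ss_u = np.bincount(unit_idx, weights=eps * eps, minlength=U)
        sigma2 = (nu_r * priors.residual_V + ss_u) / rng.chisquare(
            nu_r + unit_counts
        )
        c = beta[design.idx_c]
        var_c = float(
            (nu_c * priors.coverage_V + c @ c) / rng.chisquare(nu_c + K)
        )
        for g, levels in design.group_levels.items():
            for u in range(U):
                a = beta[design.idx_a[g][u]]
                var_a[(g, u)] = float(
                    (nu_g * priors.group_V + a @ a)
                    / rng.chisquare(nu_g + len(levels))
                )

        if t > spec.burn_in and (t - spec.burn_in) % spec.thin == 0 and ridx < n_ret:
            rec_beta[ridx] = beta
            rec_sigma2[ridx] = sigma2
            rec_var_c[ridx] = var_c
            for k in var_a:
                rec_var_a[k][ridx] = var_a[k]
            if store_latent:
                rec_eps[ridx] = eps
            ridx += 1

    cols: dict[str, np.ndarray] = {
        name: rec_beta[:, p] for p, name in enumerate(design.col_names)
    }
    for u, uid in enumerate(design.unit_ids):
        cols[f"sigma2:{uid}"] = rec_sigma2[:, u]
    cols["var_c"] = rec_var_c
    for (g, u), arr in rec_var_a.items():
        cols[f"var_a:{g}:{design.unit_ids[u]}"] = arr
    if store_latent:
        for n in range(N):
            uid = design.unit_ids[unit_idx[n]]
            sid = design.sample_ids[sample_idx[n]]
            cols[f"eps:{uid}:{sid}"] = rec_eps[:, n]
    draws = pd.DataFrame(cols)

    ess = _effect_ess(draws, design)
    low = ess[ess < ess_warn]
    if len(low):
        warnings.warn(
            f"low effective sample size (<{ess_warn:g}) for: "
            + ", ".join(low.index[:5]),
            stacklevel=2,
        )
    acc = pd.Series(
        acc_count / max(acc_sweeps, 1), index=design.unit_ids, name="acceptance"
    )
    return PosteriorSamples(
        draws=draws, unit_ids=design.unit_ids, cells=design.cells,
        sample_ids=design.sample_ids, iterations=spec.iterations,
        burn_in=spec.burn_in, thin=spec.thin, seed=spec.seed,
        ess=ess, acceptance=acc,
    )


def _effect_ess(draws: pd.DataFrame, design: Design) -> pd.Series:
    import arviz as az

    names = [design.col_names[p] for p in design.idx_I]
    names += [design.col_names[p] for p in design.idx_B.reshape(-1)]
    vals = {n: az.ess(draws[n].to_numpy()) for n in names}
    return pd.Series(vals, name="ess")
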