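"""Posterior summaries: sum-OTU-relative effects, pairwise contrasts with
MCMC p-values and FDR correction, proportion-scale abundances, trellis plots.

All effects are reported *relative to the sum-OTU*: for OTU ``o`` and
condition cell ``i`` the relative effect is ``(I_o + B_oi) - (I^s + B_i^s)``,
which cancels systematic coverage biases shared by all OTUs in a condition
and makes ``exp(relative effect)`` the model-scale share of total counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import arviz as az
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import SUM_OTU_ID, PosteriorSamples

__all__ = [
    "RelativeEffects",
    "relative_effects",
    "mcmc_pvalue",
    "pairwise_contrasts",
    "abundance_proportions",
    "plot_otu_panels",
]


@dataclass
class RelativeEffects:
    """Per-draw OTU log-abundances net of the sum-OTU.

    ``values[d, o, i]`` is draw ``d``'s relative log abundance of OTU ``o``
    in condition cell ``i`` (intercept' + effect'); ``effects[d, o, i]``
    carries only the condition part ``B_oi - B_i^s``.
    """

    otu_ids: list[str]
    cells: list[str]
    values: np.ndarray   # (draws, otus, cells)
    effects: np.ndarray  # (draws, otus, cells)


def relative_effects(fit: PosteriorSamples, otus=None) -> RelativeEffects:
    """Express each OTU's intercept and fixed effects relative to the sum-OTU."""
    otus = list(otus) if otus is not None else fit.otu_ids
    unknown = [o for o in otus if o not in fit.unit_ids or o == SUM_OTU_ID]
    if unknown:
        raise ValueError(f"unknown OTU ids: {unknown}")
    cells = fit.cells
    D = fit.n_draws
    i_sum = fit.intercept_chain(SUM_OTU_ID)
    b_sum = np.column_stack([fit.fixed_chain(SUM_OTU_ID, c) for c in cells])
    vals = np.empty((D, len(otus), len(cells)))
    effs = np.empty_like(vals)
    for oi, otu in enumerate(otus):
        i_o = fit.intercept_chain(otu)
        for ci, cell in enumerate(cells):
            b = fit.fixed_chain(otu, cell) - b_sum[:, ci]
            effs[:, oi, ci] = b
            vals[:, oi, ci] = (i_o - i_sum) + b
    return RelativeEffects(otu_ids=otus, cells=list(cells), values=vals, effects=effs)


def mcmc_pvalue(diff: np.ndarray) -> float:
    """Two-sided posterior tail probability of a sampled difference.

    ``p = 2 * min(#{d > 0} + 1, #{d < 0} + 1) / (N + 1)``, capped at 1, so a
    finite chain never yields p = 0.
    """
    d = np.asarray(diff)
    n_pos = int(np.sum(d > 0))
    n_neg = int(np.sum(d < 0))
    p = 2.0 * (min(n_pos, n_neg) + 1) / (d.size + 1)
    return min(p, 1.0)


def _interval(draws: np.ndarray, prob: float, method: str) -> tuple[float, float]:
    if method == "hdi":
        lo, hi = az.hdi(np.asarray(draws), hdi_prob=prob)
    elif method == "eti":
        a = (1.0 - prob) / 2.0
        lo, hi = np.quantile(draws, [a, 1.0 - a])
    else:
        raise ValueError(f"unknown interval method {method!r}")
    return float(lo), float(hi)


def pairwise_contrasts(
    fit: PosteriorSamples,
    otus=None,
    prob: float = 0.95,
    interval: str = "hdi",
) -> pd.DataFrame:
    """All pairwise condition-cell differences of sum-OTU-relative effects.

    One row per (OTU, unordered cell pair) with the posterior mean log-fold
    difference, a 95% highest-density interval by default, the two-sided
    MCMC p-value and Benjamini-Hochberg q-values computed jointly over the
    whole table.
    """
    if len(fit.cells) < 2:
        raise ValueError("pairwise contrasts need at least two condition cells")
    rel = relative_effects(fit, otus)
    rows = []
    for oi, otu in enumerate(rel.otu_ids):
        for (ca, cb) in combinations(range(len(rel.cells)), 2):
            d = rel.effects[:, oi, ca] - rel.effects[:, oi, cb]
            lo, hi = _interval(d, prob, interval)
            rows.append(
                {
                    "otu_id": otu,
                    "condition_A": rel.cells[ca],
                    "condition_B": rel.cells[cb],
                    "posterior_mean_logdiff": float(d.mean()),
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_mcmc": mcmc_pvalue(d),
                }
            )
    out = pd.DataFrame(rows)
    out["q_fdr"] = multipletests(out["p_mcmc"].to_numpy(), method="fdr_bh")[1]
    return out


def abundance_proportions(
    fit: PosteriorSamples,
    condition: str,
    otus=None,
    prob: float = 0.95,
    interval: str = "hdi",
) -> pd.DataFrame:
    """Posterior proportion-of-total summaries for one condition cell.

    The proportion is ``exp(relative log abundance)`` — the share of total
    implied by the sum-OTU reference — not a renormalisation across the
    retained OTUs.
    """
    if condition not in fit.cells:
        raise ValueError(f"unknown condition cell {condition!r}")
    rel = relative_effects(fit, otus)
    ci = rel.cells.index(condition)
    rows = []
    for oi, otu in enumerate(rel.otu_ids):
        props = np.exp(rel.values[:, oi, ci])
        lo, hi = _interval(props, prob, interval)
        rows.append(
            {
                "otu_id": otu,
                "condition": condition,
                "proportion_mean": float(props.mean()),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def _significance_stars(q: float) -> str:
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def plot_otu_panels(table, contrasts: pd.DataFrame, path, fixed_factors=None) -> None:
    """Trellis figure: one panel per OTU, observed proportion of sample total
    by condition cell, annotated with FDR-significant pairwise contrasts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .model import CELL_SEP

    fixed_factors = fixed_factors or table.factor_names
    cell = table.factors[fixed_factors].agg(CELL_SEP.join, axis=1)
    cells = sorted(cell.unique())
    otus = (
        list(pd.unique(contrasts["otu_id"])) if len(contrasts) else table.otu_ids
    )
    totals = table.sample_totals.to_numpy().astype(float)

    ncol = min(4, max(1, len(otus)))
    nrow = int(np.ceil(len(otus) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3.0 * ncol, 2.6 * nrow), squeeze=False, sharex=True
    )
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for k, otu in enumerate(otus):
        ax = axes[k // ncol][k % ncol]
        prop = table.counts[otu].to_numpy() / totals
        for ci, c in enumerate(cells):
            mask = (cell == c).to_numpy()
            x = ci + rng.uniform(-0.15, 0.15, mask.sum())
            ax.plot(x, prop[mask], "o", ms=3, alpha=0.6)
        sig = contrasts[
            (contrasts["otu_id"] == otu) & (contrasts["q_fdr"] < 0.05)
        ] if len(contrasts) else contrasts
        note = "; ".join(
            f"{r.condition_A}~{r.condition_B}{_significance_stars(r.q_fdr)}"
            for r in sig.itertuples()
        )
        title = otu if not note else f"{otu}  [{note}]"
        ax.set_title(title, fontsize=8)
        ax.set_yscale("log")
        ax.set_xticks(range(len(cells)))
        ax.set_xticklabels(cells, rotation=45, fontsize=6, ha="right")
    for k in range(len(otus), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.suptitle("OTU proportion of sample total by condition", fontsize=10)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
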