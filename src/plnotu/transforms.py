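"""Model-free companion analyses on normalized log abundances.

Size-factor normalization equalizes sequencing depth; the "started log"
transform (zeros replaced by a small positive constant, 0.1 by default,
before log10) and the "log-linear hybrid" transform (log10 above a knot,
linear below it, continuous and once-differentiable at the knot) map counts
onto a scale suitable for PCA.  Pairwise correlations computed with zeros
left undefined flag putative paralogs of a multicopy marker: two OTUs from
the same genome should co-vary positively across samples, while OTUs from
different genomes competing for the same read pool tend to anticorrelate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountTable

__all__ = [
    "TransformedMatrix",
    "size_factors",
    "started_log",
    "hybrid_log",
    "pca_prepare",
    "run_pca",
    "kaiser_components",
    "paralog_correlations",
]

LN10 = np.log(10.0)


@dataclass
class TransformedMatrix:
    """Normalized log-abundances (samples x OTUs) with a zero-handling tag.

    ``zero_policy`` is ``("started_log", zero_sub)``, ``("hybrid", knot)``
    or ``("undefined", None)``; under the last policy entries are NaN
    exactly where counts were zero.
    """

    values: pd.DataFrame
    zero_policy: tuple
    size_factors: pd.Series


def size_factors(table: CountTable, literal: bool = False) -> pd.Series:
    """Per-sample scalars equalizing sequencing depth.

    Default (equalizing) direction: ``mean(sample totals) / total_k``, so
    multiplying sample *k*'s counts by its factor makes every sample total
    equal the grand mean.  ``literal=True`` gives the reciprocal
    (sample/mean) convention instead.
    """
    totals = table.sample_totals.astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero-total samples have no size factor: {bad}")
    mean_total = totals.mean()
    f = totals / mean_total if literal else mean_total / totals
    f.name = "size_factor"
    return f


def _normalized(table: CountTable) -> tuple[pd.DataFrame, pd.Series]:
    f = size_factors(table)
    norm = table.counts.mul(f, axis=0).astype(float)
    return norm, f


def started_log(table: CountTable, zero_sub: float = 0.1) -> TransformedMatrix:
    """log10 of size-factor-normalized counts, zeros mapped to log10(zero_sub)."""
    if zero_sub <= 0:
        raise ValueError("zero_sub must be positive")
    norm, f = _normalized(table)
    vals = pd.DataFrame(
        np.where(table.counts.to_numpy() > 0,
                 np.log10(np.where(norm.to_numpy() > 0, norm.to_numpy(), 1.0)),
                 np.log10(zero_sub)),
        index=norm.index, columns=norm.columns,
    )
    return TransformedMatrix(vals, ("started_log", zero_sub), f)


def hybrid_log(table: CountTable, c: float = 1.0) -> TransformedMatrix:
    """Log-linear hybrid transform of normalized counts.

    ``log10(x)`` for ``x >= c``; the tangent line
    ``log10(c) + (x - c) / (c * ln 10)`` for ``x < c`` — continuous and
    once-differentiable at the knot ``c``.
    """
    if c <= 0:
        raise ValueError("knot c must be positive")
    norm, f = _normalized(table)
    x = norm.to_numpy()
    vals = np.where(
        x >= c, np.log10(np.where(x >= c, x, c)), np.log10(c) + (x - c) / (c * LN10)
    )
    return TransformedMatrix(
        pd.DataFrame(vals, index=norm.index, columns=norm.columns),
        ("hybrid", c), f,
    )


def undefined_zero_log(table: CountTable) -> TransformedMatrix:
    """log10 normalized counts with original zeros left undefined (NaN)."""
    norm, f = _normalized(table)
    x = norm.to_numpy()
    raw = table.counts.to_numpy()
    vals = np.where(raw > 0, np.log10(np.where(raw > 0, x, 1.0)), np.nan)
    return TransformedMatrix(
        pd.DataFrame(vals, index=norm.index, columns=norm.columns),
        ("undefined", None), f,
    )


def pca_prepare(
    table: CountTable, min_presence: float = 0.10, zero_sub: float = 0.1
) -> tuple[TransformedMatrix, list[str]]:
    """Presence-filter OTUs and started-log-transform for PCA.

    OTUs detected (raw count > 0) in strictly more than ``min_presence`` of
    samples are retained; the rest are dropped before transforming.
    """
    presence = (table.counts > 0).mean(axis=0)
    retained = [o for o in table.otu_ids if presence[o] > min_presence]
    sub = table.subset(otus=retained)
    return started_log(sub, zero_sub=zero_sub), retained


@dataclass
class PCAResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # OTUs x components
    sdev: np.ndarray            # component standard deviations
    proportion_explained: np.ndarray
    kaiser_n: int               # components with sdev > 1


def run_pca(tm: TransformedMatrix, scale: bool = True) -> PCAResult:
    """Principal components of a transformed matrix, via SVD.

    Columns are centered and, by default, scaled to unit variance
    (correlation-matrix PCA) so that Kaiser's criterion — retain components
    with standard deviation above 1, i.e. above the average — is
    scale-free.  ``scale=False`` gives covariance-matrix PCA.
    """
    X = tm.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA input must not contain undefined entries")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    n = X.shape[0]
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    sdev = s / np.sqrt(n - 1)
    var = sdev**2
    prop = var / var.sum() if var.sum() > 0 else var
    comps = [f"PC{i+1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=tm.values.index, columns=comps)
    loadings = pd.DataFrame(vt.T, index=tm.values.columns, columns=comps)
    return PCAResult(scores, loadings, sdev, prop, kaiser_components(sdev))


def kaiser_components(sdev: np.ndarray) -> int:
    """Number of components retained under Kaiser's criterion (sd > 1)."""
    return int(np.sum(np.asarray(sdev) > 1.0))


@dataclass
class CorrelationResult:
    """Pairwise OTU abundance correlations with zeros left undefined.

    ``r``/``p`` are symmetric matrices (NaN where a pair shares fewer than
    ``min_pairs`` co-present samples); ``n`` counts co-present samples;
    ``labels`` classifies each pair.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    labels: pd.DataFrame


def paralog_correlations(
    table: CountTable,
    method: str = "pearson",
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> CorrelationResult:
    """Pairwise correlations of log abundances over co-present samples.

    Correlates started-log values only across samples where *both* OTUs have
    nonzero counts (original zeros are left undefined).  A pair is
    ``candidate-paralog`` when r > 0 with p < alpha, ``distinct-genome``
    when r < 0 with p < alpha, ``not-assessable`` with fewer than
    ``min_pairs`` co-present samples, else ``ns``.
    """
    tm = undefined_zero_log(table)
    X = tm.values.to_numpy()
    otus = table.otu_ids
    m = len(otus)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    n = np.zeros((m, m), dtype=int)
    labels = np.full((m, m), "ns", dtype=object)
    np.fill_diagonal(labels, "self")
    np.fill_diagonal(r, 1.0)
    for i, j in combinations(range(m), 2):
        both = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
        k = int(both.sum())
        n[i, j] = n[j, i] = k
        if k < min_pairs:
            labels[i, j] = labels[j, i] = "not-assessable"
            continue
        xi, xj = X[both, i], X[both, j]
        if np.std(xi) == 0 or np.std(xj) == 0:
            labels[i, j] = labels[j, i] = "not-assessable"
            continue
        if method == "pearson":
            rr, pp = stats.pearsonr(xi, xj)
        elif method == "spearman":
            rr, pp = stats.spearmanr(xi, xj)
        else:
            raise ValueError(f"unknown method {method!r}")
        r[i, j] = r[j, i] = rr
        p[i, j] = p[j, i] = pp
        if pp < alpha and rr > 0:
            lab = "candidate-paralog"
        elif pp < alpha and rr < 0:
            lab = "distinct-genome"
        else:
            lab = "ns"
        labels[i, j] = labels[j, i] = lab
    idx = pd.Index(otus)
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        labels=pd.DataFrame(labels, index=idx, columns=idx),
    )
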