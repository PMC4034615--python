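"""Data screening: outlier samples, quantifiable OTUs, unreliable chains.

Three rules applied around the model fit, in this order:

1. drop samples whose log total counts sit >= ``z`` standard deviations
   below the mean log total (one-sided low by default — the typical failure
   is a sample that sequenced poorly);
2. keep only OTUs comprising at least ``min_fraction`` (default 0.1%) of the
   global count sum — rarer OTUs sit at the method's detection limit and are
   not quantifiable;
3. after fitting, discard OTUs whose intercept or fixed-effect chains show
   high autocorrelation, the signature of an OTU too sparse across samples
   for its parameters to be estimable.
"""

from __future__ import annotations

import numpy as np

from .counts import CountTable
from .model import PosteriorSamples

__all__ = [
    "detect_outlier_samples",
    "select_quantifiable_otus",
    "flag_unreliable_otus",
    "screen_table",
]


def detect_outlier_samples(
    table: CountTable, z: float = 2.5, two_sided: bool = False
) -> list[str]:
    """Samples whose natural-log total counts are >= z SD below the mean.

    One-sided low unless ``two_sided``; ties at exactly ``mean - z*SD`` are
    flagged.  Requires at least 3 samples and strictly positive totals.
    """
    totals = table.sample_totals
    if len(totals) < 3:
        raise ValueError("outlier screening needs at least 3 samples")
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(
            f"samples with zero total counts must be removed before screening: {bad}"
        )
    logs = np.log(totals.to_numpy(dtype=float))
    mu, sd = logs.mean(), logs.std(ddof=1)
    if sd == 0:
        return []
    low = logs <= mu - z * sd
    flag = low | (logs >= mu + z * sd) if two_sided else low
    return [s for s, f in zip(table.sample_ids, flag) if f]


def select_quantifiable_otus(
    table: CountTable, min_fraction: float = 0.001
) -> tuple[list[str], list[str]]:
    """Partition OTUs by the global-share rule, order preserved.

    An OTU is kept iff its total count is at least ``min_fraction`` of the
    grand total (inclusive), the detection limit established for amplicon
    metabarcoding of low-frequency haplotypes.
    """
    if len(table.otu_ids) == 0 or len(table.sample_ids) == 0:
        raise ValueError("table must be nonempty")
    grand = table.grand_total
    sums = table.counts.sum(axis=0)
    kept = [o for o in table.otu_ids if sums[o] >= min_fraction * grand]
    dropped = [o for o in table.otu_ids if o not in set(kept)]
    return kept, dropped


def chain_autocorrelation(chain: np.ndarray, lag: int) -> float:
    """Lag-``lag`` autocorrelation of a (thinned) chain."""
    x = np.asarray(chain, dtype=float)
    if len(x) < 10 * lag:
        raise ValueError(
            f"chain of length {len(x)} too short for a reliable lag-{lag} diagnostic"
        )
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 0.0
    return float(x[:-lag] @ x[lag:]) / denom


def flag_unreliable_otus(
    fit: PosteriorSamples, ac_lag: int = 10, ac_threshold: float = 0.1
) -> list[str]:
    """OTUs whose intercept or any fixed-effect chain mixes too slowly.

    Flagged when any of those thinned chains has lag-``ac_lag``
    autocorrelation above ``ac_threshold``; flagged OTUs should be excluded
    from contrast reporting.
    """
    flagged = []
    for otu in fit.otu_ids:
        chains = [fit.intercept_chain(otu)] + [
            fit.draws[c].to_numpy() for c in fit.fixed_effect_columns(otu)
        ]
        if any(chain_autocorrelation(ch, ac_lag) > ac_threshold for ch in chains):
            flagged.append(otu)
    return flagged


def screen_table(
    table: CountTable, z: float = 2.5, min_fraction: float = 0.001
) -> tuple[CountTable, dict]:
    """Apply pre-fit screening (outlier samples, then quantifiable OTUs).

    Returns the screened table and a report dict suitable for JSON output.
    """
    outliers = detect_outlier_samples(table, z=z)
    keep_samples = [s for s in table.sample_ids if s not in set(outliers)]
    trimmed = table.subset(samples=keep_samples)
    kept, dropped = select_quantifiable_otus(trimmed, min_fraction=min_fraction)
    screened = trimmed.subset(otus=kept)
    report = {
        "outlier_samples": outliers,
        "kept_otus": kept,
        "dropped_otus": dropped,
        "parameters": {"z": z, "min_fraction": min_fraction},
    }
    return screened, report
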