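import warnings

import numpy as np
import pandas as pd
import pytest

import plnotu as P


def random_table(rng, n_samples=6, n_otus=5, factors=("group",), levels=("a", "b"),
                 lam=20.0) -> P.CountTable:
    counts = pd.DataFrame(
        rng.poisson(lam, size=(n_samples, n_otus)),
        index=[f"s{i+1}" for i in range(n_samples)],
        columns=[f"otu{j+1}" for j in range(n_otus)],
    )
    fac = pd.DataFrame(
        {f: [levels[i % len(levels)] for i in range(n_samples)] for f in factors},
        index=counts.index,
    )
    return P.CountTable(counts, fac)


def make_posterior(draws: dict, unit_ids, cells, sample_ids=(), **meta) -> P.PosteriorSamples:
    """Assemble a PosteriorSamples from explicit chains (for unit tests)."""
    df = pd.DataFrame(draws)
    defaults = dict(iterations=len(df), burn_in=0, thin=1, seed=0)
    defaults.update(meta)
    return P.PosteriorSamples(
        draws=df, unit_ids=list(unit_ids), cells=list(cells),
        sample_ids=list(sample_ids), **defaults,
    )


def quick_fit(table, seed, iterations=6000, burn_in=1000, thin=5, **kw):
    spec = P.ModelSpec(
        fixed_factors=kw.pop("fixed_factors", ["species", "bank"]),
        iterations=iterations, burn_in=burn_in, thin=thin, seed=seed, **kw,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return P.sample_posterior(table, spec)


@pytest.fixture(scope="session")
def preset_truth():
    return P.orbicella_like_preset(seed=7)


@pytest.fixture(scope="session")
def preset_table(preset_truth):
    return P.simulate_counts(preset_truth)


@pytest.fixture(scope="session")
def preset_fit(preset_table):
    """One reduced-chain fit of the screened reference dataset, shared."""
    screened, _ = P.screen_table(preset_table)
    return screened, quick_fit(screened, seed=42)
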