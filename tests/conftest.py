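import numpy as np
import pandas as pd
import pytest

import homeologdiv as hd


@pytest.fixture(scope="session")
def small_catalogue() -> hd.HybridCatalogue:
    """30 pairs at 7% divergence, 2 identity groups, 5 singletons, 400 bp."""
    return hd.build_catalogue(
        n_pairs=30, n_identity_groups=2, group_size=2, n_singletons=5,
        divergence=0.07, length_sampler=400, seed=11,
    )


@pytest.fixture(scope="session")
def design() -> hd.SimulationDesign:
    return hd.SimulationDesign(library_size=5e5, seed=23)


@pytest.fixture(scope="session")
def simulated(small_catalogue, design):
    counts, truth = hd.simulate_counts(small_catalogue, design)
    return counts, truth


@pytest.fixture(scope="session")
def normalized(small_catalogue, simulated):
    counts, _ = simulated
    return hd.normalize_counts(counts, small_catalogue.lengths())


def toy_counts(seed: int = 0, n_genes: int = 1000, n_samples: int = 4,
               frac_de: float = 0.0, fold: float = 8.0) -> pd.DataFrame:
    """Poisson count matrix with optional asymmetric DE in the last sample."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    cols = {}
    depth = rng.uniform(0.5, 2.0, size=n_samples)
    for s in range(n_samples):
        m = mu * depth[s]
        if frac_de > 0 and s == n_samples - 1:
            m = m.copy()
            m[: int(frac_de * n_genes)] *= fold
        cols[f"s{s + 1}"] = rng.poisson(m)
    return pd.DataFrame(cols)
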