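import warnings

import numpy as np
import pandas as pd
import pytest

import shuttlegp as sg


@pytest.fixture(scope="session")
def small_config() -> sg.SimulationConfig:
    """A reduced two-site experiment with an exactly representable
    main + interaction decomposition (equal per-site targets)."""
    return sg.SimulationConfig(
        n_genotypes=60,
        n_markers=150,
        n_chromosomes=4,
        sites=[
            sg.SiteConfig("PAL", 88.2, sigma2_block=0.9,
                          sigma2_residual=5.0, target_h2_trial=0.8),
            sg.SiteConfig("SRO", 82.2, sigma2_block=0.9,
                          sigma2_residual=5.0, target_h2_trial=0.8),
        ],
        genetic_correlation=0.6,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return sg.simulate_dataset(small_config)


@pytest.fixture()
def tiny_phenotypes() -> pd.DataFrame:
    """A hand-sized balanced two-site table (4 genotypes x 2 reps x 2 sites)."""
    rng = np.random.default_rng(7)
    rows = []
    for site, shift in (("A", 0.0), ("B", 2.0)):
        for rep in (1, 2):
            for gi, g in enumerate(["g1", "g2", "g3", "g4"]):
                rows.append(
                    {
                        "genotype": g,
                        "site": site,
                        "year": 2017,
                        "rep": rep,
                        "block": 1 + gi // 2,
                        "y": 10.0 + shift + gi + rng.normal(0.0, 1.5),
                    }
                )
    return pd.DataFrame(rows)


def balanced_single_site(n_geno=8, n_rep=3, s2g=4.0, s2e=1.0, seed=0,
                         site="S", mean=20.0) -> pd.DataFrame:
    """Balanced one-site table, no block structure, known variances."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, np.sqrt(s2g), n_geno)
    rows = []
    for rep in range(1, n_rep + 1):
        for i in range(n_geno):
            rows.append(
                {
                    "genotype": f"g{i}",
                    "site": site,
                    "year": 2017,
                    "rep": rep,
                    "block": 1,
                    "y": mean + g[i] + rng.normal(0.0, np.sqrt(s2e)),
                }
            )
    return pd.DataFrame(rows)
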