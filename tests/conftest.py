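import numpy as np
import pandas as pd
import pytest

from polygs.dosage import DosageMatrix
from polygs.phenomodel import VcovStructure
from polygs.simpop import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale polycross: 6 families x 12 offspring, 4 harvests."""
    return SimConfig(
        n_dams=6,
        n_sires=8,
        family_size=12,
        n_blocks=4,
        plants_per_plot=3,
        n_checks=2,
        n_markers=120,
        n_harvests=4,
        seed=42,
        heritability=0.6,
        genetic_rho=0.9,
        residual_vcov_spec=VcovStructure("AR1", 4, {"sigma2": 1.0, "rho": 0.4}),
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def polycross_population():
    """Larger genotype-only population for kinship / prediction tests."""
    cfg = SimConfig(
        n_dams=10,
        n_sires=12,
        family_size=20,
        n_blocks=4,
        plants_per_plot=5,
        n_markers=400,
        seed=7,
    )
    from polygs.simpop import simulate_founders, simulate_polycross

    rng = cfg.rng()
    founders = simulate_founders(cfg, rng)
    offspring, pedigree = simulate_polycross(founders, cfg, rng)
    return {"config": cfg, "founders": founders, "offspring": offspring, "pedigree": pedigree}


def make_dosage(data, ploidy=4, metadata=None) -> DosageMatrix:
    data = np.asarray(data, dtype=np.int8)
    n, p = data.shape
    return DosageMatrix(
        data,
        pd.Index([f"i{k}" for k in range(n)]),
        pd.Index([f"m{k}" for k in range(p)]),
        ploidy,
        metadata,
    )
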