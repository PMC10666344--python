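import numpy as np
import pytest

from ssnpblup.pedigree import PedigreeRecord, sort_and_validate
from ssnpblup.synthetic_data import SimulationConfig, simulate_dataset


def random_pedigree(rng, n=120, n_founders=30, complete=True):
    """Random multi-generation pedigree with complete parentage by default."""
    recs = []
    males, females = [], []
    for i in range(n_founders):
        sex = "M" if rng.random() < 0.5 else "F"
        recs.append(PedigreeRecord(f"p{i}", sex=sex, birth_year=1990))
        (males if sex == "M" else females).append(f"p{i}")
    for i in range(n_founders, n):
        if not males or not females:
            break
        sex = "M" if rng.random() < 0.5 else "F"
        sire = males[rng.integers(len(males))]
        dam = females[rng.integers(len(females))]
        if not complete and rng.random() < 0.2:
            sire = ""
        # strictly increasing birth years keep parents older than offspring
        recs.append(PedigreeRecord(f"p{i}", sire, dam, sex, 1991 + i))
        (males if sex == "M" else females).append(f"p{i}")
    return sort_and_validate(recs)


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic population shared across tests (~200 animals)."""
    cfg = SimulationConfig(
        seed=7, n_founders=40, n_generations=4, matings_per_generation=20,
        offspring_per_mating=2, n_snps=60, genotyped_last_generations=2,
        phenotyped_from_generation=2, drp_from_generation=2,
        unknown_parent_rate_early=0.0, unknown_parent_rate_late=0.0)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def grouped_dataset():
    """Small population with unknown parents, i.e. with genetic groups."""
    cfg = SimulationConfig(
        seed=11, n_founders=40, n_generations=4, matings_per_generation=20,
        offspring_per_mating=2, n_snps=50, genotyped_last_generations=2,
        phenotyped_from_generation=2, drp_from_generation=2,
        unknown_parent_rate_early=0.2, unknown_parent_rate_late=0.05)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
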