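import logging

import numpy as np
import pandas as pd
import pytest

from cagewas.pedigree import PedigreeTable, build_A
from cagewas.simdata import SimConfig, simulate_all

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_sim():
    """One small full simulation shared by read-only tests."""
    cfg = SimConfig(n_batches=3, cages_per_batch=8, n_snps=60, seed=42)
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def three_gen_pedigree():
    """12-animal, 3-generation pedigree with an inbred final generation."""
    animal = ["f1", "f2", "f3", "f4", "s1", "s2", "d1", "d2", "g1", "g2", "g3", "g4"]
    sire = [None, None, None, None, "f1", "f1", "f3", "f3", "s1", "s1", "s2", "s2"]
    dam = [None, None, None, None, "f2", "f2", "f4", "f4", "d1", "d2", "d1", "d1"]
    return PedigreeTable.from_records(animal, sire, dam)


@pytest.fixture(scope="session")
def three_gen_A(three_gen_pedigree):
    return build_A(three_gen_pedigree)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_individual_frame(n, rng, n_cages=None, n_litters=None):
    """Random but well-formed individual phenotype labels (no trait values)."""
    n_cages = n_cages or max(2, n // 6)
    n_litters = n_litters or max(2, n // 4)
    return pd.DataFrame(
        {
            "animal": [f"a{i}" for i in range(n)],
            "batch": rng.choice([f"B{j}" for j in range(1, 4)], n),
            "parity": rng.integers(1, 5, n),
            "litter_size_class": rng.integers(1, 8, n),
            "cage_size_class": rng.choice(["LS", "SS"], n),
            "cage": rng.choice([f"c{j}" for j in range(n_cages)], n),
            "litter": rng.choice([f"l{j}" for j in range(n_litters)], n),
            "regime": "F",
        }
    )
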