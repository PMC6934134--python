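"""Shared fixtures: tiny hand-built pedigrees and small simulated data."""

import numpy as np
import pandas as pd
import pytest

from ssblend.pedigree import pedigree_from_frame
from ssblend.simulate import SimConfig, simulate


@pytest.fixture
def trio_frame():
    """Sire, dam, offspring; unrelated non-inbred parents."""
    return pd.DataFrame(
        {
            "animal": ["s1", "d1", "o1"],
            "sire": ["0", "0", "s1"],
            "dam": ["0", "0", "d1"],
        }
    )


@pytest.fixture
def trio(trio_frame):
    return pedigree_from_frame(trio_frame)


@pytest.fixture
def fullsib_mating():
    """Two founders, their full-sib offspring c and d, and e = c x d
    (so F(e) = 0.125)."""
    return pedigree_from_frame(
        pd.DataFrame(
            {
                "animal": ["a", "b", "c", "d", "e"],
                "sire": ["0", "0", "a", "a", "c"],
                "dam": ["0", "0", "b", "b", "d"],
            }
        )
    )


def _random_pedigree(seed: int, n_founders: int = 12, n_extra: int = 80):
    """A random overlapping-generation pedigree with inbreeding loops."""
    rng = np.random.default_rng(seed)
    animal, sire, dam = [], [], []
    for i in range(n_founders):
        animal.append(f"f{i}")
        sire.append("0")
        dam.append("0")
    for i in range(n_extra):
        s, d = rng.choice(len(animal), size=2, replace=False)
        animal.append(f"x{i}")
        sire.append(animal[s])
        dam.append(animal[d])
    return pedigree_from_frame(
        pd.DataFrame({"animal": animal, "sire": sire, "dam": dam})
    )


@pytest.fixture
def random_pedigree():
    """Factory fixture: seeded random pedigrees with inbreeding loops."""
    return _random_pedigree


@pytest.fixture(scope="session")
def small_sim():
    """A small five-trait simulated population reused across tests."""
    cfg = SimConfig(seed=12345, generations=5, n_sires=10, n_dams=40,
                    offspring_per_dam=4, n_markers=500, genotyped_share=0.5)
    return simulate(cfg)


@pytest.fixture(scope="session")
def tiny_sim_single_trait():
    """A single-trait population small enough for dense oracles."""
    cfg = SimConfig(seed=999, traits=("bw",), generations=4, n_sires=6,
                    n_dams=18, offspring_per_dam=3, n_markers=300,
                    genotyped_share=1.0)
    return simulate(cfg)
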