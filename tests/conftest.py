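"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from gpacc.relationships import Pedigree, RelationshipMatrix
from gpacc.simulator import GenomeSpec, SimConfig, simulate_historical


@pytest.fixture(scope="session")
def small_genome():
    return GenomeSpec(k=3, L=1.0, n_loci=900)


@pytest.fixture(scope="session")
def small_pool(small_genome):
    """A modest founder pool with drift-generated LD, shared across tests."""
    return simulate_historical(small_genome, ne=80, n_generations=60, seed=7)


@pytest.fixture(scope="session")
def small_cfg(small_genome):
    return SimConfig(
        genome=small_genome,
        n_hist_generations=60,
        hist_ne=80,
        n_qtl=30,
        n_markers_target=300,
        h2=0.4,
        n_sires=5,
        n_dams=20,
        progeny_per_dam=6,
        n_generations=3,
        selection="random",
        seed=3,
    )


@pytest.fixture
def halfsib_pedigree():
    """One sire, five unrelated dams, four progeny each (founders unknown)."""
    rows = [(1, 0, 0, 0)] + [(d, 0, 0, 0) for d in range(2, 7)]
    next_id = 7
    for d in range(2, 7):
        for _ in range(4):
            rows.append((next_id, 1, d, 1))
            next_id += 1
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "generation"]))


def random_psd_matrix(n: int, seed: int) -> RelationshipMatrix:
    """A well-conditioned random relationship-like matrix for solver tests."""
    rng = np.random.default_rng(seed)
    B = rng.normal(size=(n, n + 5))
    K = B @ B.T / (n + 5) + 0.5 * np.eye(n)
    return RelationshipMatrix(K, np.arange(1, n + 1), "G_method1")
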