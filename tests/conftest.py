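"""Shared fixtures: planted-partition benchmarks and small random matrices."""

import numpy as np
import pytest

from pclust.matrix import RawScoreMatrix, SimilarityMatrix, symmetrize
from pclust.synthetic import PlantedSpec, planted_matrix


@pytest.fixture(scope="session")
def default_benchmark():
    """Desk-scale benchmark at the generator defaults (N=200, 12 blocks,
    10% singletons, within 96-100, between 0-60)."""
    spec = PlantedSpec()
    raw, truth = planted_matrix(spec)
    return spec, symmetrize(raw), truth


@pytest.fixture(scope="session")
def separated_benchmark():
    """Perfectly separated benchmark whose overlapped clusters provably
    equal the planted blocks.

    The between range is narrow (24-26, jitter 0.5) so every profile's
    score against a foreign representative sits far below its mean score
    over all representatives, which is pulled up by its own block's
    ~96-100 entry; the self-regulated re-assignment therefore adds no
    memberships and every cluster stays exactly one block of 20.
    """
    spec = PlantedSpec(
        n_profiles=200,
        n_blocks=10,
        singleton_fraction=0.0,
        within_range=(96.0, 100.0),
        between_range=(24.0, 26.0),
        asymmetry_jitter=0.5,
        seed=4242,
    )
    raw, truth = planted_matrix(spec)
    return spec, symmetrize(raw), truth


def random_similarity(n: int, seed: int) -> SimilarityMatrix:
    """A small random symmetric score matrix (no planted structure)."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.0, 100.0, size=(n, n))
    np.fill_diagonal(values, 100.0)
    ids = tuple(f"R{i:03d}" for i in range(n))
    return symmetrize(RawScoreMatrix(values=values, ids=ids))
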