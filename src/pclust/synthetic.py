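"""Seeded generators for planted-partition similarity data.

The generators emulate, at desk scale, the structure of an all-against-all
profile-profile similarity matrix over a curated family database: blocks
of mutually similar profiles (families of families), a background of low
cross-block similarity, orientation-dependent raw scores, and a fraction
of profiles attached to no block. Query vectors are noisy copies of a
database profile's similarity row, standing in for an external sequence
that resembles one family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pclust.clustering import Partition, _make_partition
from pclust.matrix import RawScoreMatrix, SimilarityMatrix

DEFAULT_SEED = 1337


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a planted-block similarity matrix.

    Within-block scores are drawn uniformly from ``within_range`` and all
    other pairs from ``between_range`` (both on the 0-100 scale); each
    orientation of a raw pair is then jittered independently by up to
    ``asymmetry_jitter``. A spec is "separated" when the within range
    lies entirely above the between range, in which case thresholding
    recovers the blocks exactly. ``singleton_fraction`` of the profiles
    are planted unattached: they score in the between range against
    everything.

    Defaults are the desk-scale benchmark: 200 profiles in 12 balanced
    blocks with 10% singletons, within 96-100 vs between 0-60, jitter 2.
    """

    n_profiles: int = 200
    n_blocks: int = 12
    block_sizes: tuple[int, ...] | None = None
    within_range: tuple[float, float] = (96.0, 100.0)
    between_range: tuple[float, float] = (0.0, 60.0)
    asymmetry_jitter: float = 2.0
    singleton_fraction: float = 0.10
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("within_range", self.within_range),
                               ("between_range", self.between_range)):
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi <= 100, got ({lo}, {hi})")
        if self.n_profiles < 1:
            raise ValueError("n_profiles must be >= 1")
        if self.asymmetry_jitter < 0:
            raise ValueError("asymmetry_jitter must be non-negative")
        if self.block_sizes is not None:
            if any(s < 1 for s in self.block_sizes):
                raise ValueError("block sizes must be positive")
            if sum(self.block_sizes) + self.n_singletons != self.n_profiles:
                raise ValueError(
                    "block sizes plus singletons must sum to n_profiles: "
                    f"{sum(self.block_sizes)} + {self.n_singletons} != {self.n_profiles}"
                )
        elif self.n_blocks < 1 or self.n_blocks > self.n_profiles - self.n_singletons:
            raise ValueError("n_blocks must fit the non-singleton profiles")

    @property
    def n_singletons(self) -> int:
        return int(round(self.n_profiles * self.singleton_fraction))

    @property
    def separated(self) -> bool:
        return self.within_range[0] > self.between_range[1]

    def resolved_block_sizes(self) -> tuple[int, ...]:
        """Explicit block sizes; balanced split when none were given."""
        if self.block_sizes is not None:
            return self.block_sizes
        n_blocked = self.n_profiles - self.n_singletons
        base, extra = divmod(n_blocked, self.n_blocks)
        return tuple(base + (1 if b < extra else 0) for b in range(self.n_blocks))


def planted_matrix(spec: PlantedSpec) -> tuple[RawScoreMatrix, Partition]:
    """Generate a raw (asymmetric) score matrix with planted blocks.

    Returns the matrix together with the ground-truth partition: one
    cluster per block plus one singleton cluster per unattached profile.
    Deterministic under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = spec.resolved_block_sizes()
    n = spec.n_profiles
    ids = tuple(f"P{i:04d}" for i in range(n))

    # block label per profile; -1 marks planted singletons (placed last)
    labels = np.full(n, -1, dtype=int)
    pos = 0
    for b, size in enumerate(sizes):
        labels[pos:pos + size] = b
        pos += size

    wlo, whi = spec.within_range
    blo, bhi = spec.between_range
    co_blocked = (labels[:, None] == labels[None, :]) & (labels[:, None] >= 0)

    base = rng.uniform(blo, bhi, size=(n, n))
    within = rng.uniform(wlo, whi, size=(n, n))
    base[co_blocked] = within[co_blocked]
    # base scores are symmetric by construction of the pair value; enforce
    # by mirroring the upper triangle, then jitter each orientation freely
    base = np.triu(base, k=1)
    base = base + base.T
    if spec.asymmetry_jitter > 0:
        jitter = rng.uniform(-spec.asymmetry_jitter, spec.asymmetry_jitter, size=(n, n))
        np.fill_diagonal(jitter, 0.0)
        base = base + jitter
    values = np.clip(base, 0.0, 100.0)
    np.fill_diagonal(values, 100.0)

    groups = [
        {ids[i] for i in np.flatnonzero(labels == b)} for b in range(len(sizes))
    ] + [{ids[i]} for i in np.flatnonzero(labels == -1)]
    truth = _make_partition(groups, "planted", {"seed": spec.seed})
    return RawScoreMatrix(values=values, ids=ids), truth


def dot_product_scorer(a, b) -> float:
    """Toy pairwise scorer over numeric-vector payloads.

    Scores the projection of *b* onto *a* relative to *a*'s own norm,
    scaled to [0, 100]: a profile scores itself 100 exactly, and the
    score is asymmetric (the denominator depends on which profile plays
    the query role), like real profile-profile search scores.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = float(a @ a)
    if denom == 0.0:
        raise ValueError("zero-norm profile payload")
    return 100.0 * float(np.clip((a @ b) / denom, 0.0, 1.0))


def random_profiles(n: int, dim: int = 8, seed: int = 0) -> tuple[np.ndarray, ...]:
    """Random non-negative payload vectors for the toy scorer."""
    rng = np.random.default_rng(seed)
    return tuple(rng.uniform(0.1, 1.0, size=dim) for _ in range(n))


def make_query_vector(
    matrix: SimilarityMatrix,
    source_id: str,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """A query score vector resembling one database profile.

    The source profile's similarity row is perturbed by seeded Gaussian
    noise and clipped to [0, 100]; the self entry is kept at least as
    large as every other entry, mirroring a query most similar to the
    family it was drawn from.
    """
    row = matrix.row(source_id)  # raises KeyError for unknown IDs
    rng = np.random.default_rng(seed)
    vec = np.clip(row + rng.normal(0.0, noise_sd, size=row.shape), 0.0, 100.0)
    i = matrix.index_of(source_id)
    vec[i] = max(float(vec.max()), float(vec[i]))
    return vec
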