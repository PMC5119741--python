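"""Profile collections and all-against-all similarity matrices.

Scores live on the 0-100 percent scale throughout (the profile-profile
"probability" score of HH-suite style search tools, where >= 95 means
near-certain homology). Raw all-against-all scores are asymmetric because
a profile-profile score depends on which profile plays the query role;
the symmetric matrix used for clustering keeps the larger of the two
orientations for each pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Pairwise scorer contract: (profile_a_payload, profile_b_payload) -> score
#: in [0, 100]. Must be deterministic; self-score is 100 by definition.
PairScorer = Callable[[object, object], float]

SYMMETRY_TOL = 1e-9


class QueryScorer(Protocol):
    """Scores one query against a requested subset of database profiles.

    Implementations must report exactly one comparison per requested
    target so that comparison accounting stays exact.
    """

    def __call__(self, query: object, target_ids: Sequence[str]) -> Mapping[str, float]:
        ...

    @property
    def comparisons(self) -> int:
        """Total pairwise comparisons performed so far."""
        ...


class MatrixValidationError(ValueError):
    """A score matrix violates a structural invariant."""


class MatrixParseError(ValueError):
    """A matrix file could not be parsed."""


@dataclass(frozen=True)
class ProfileDB:
    """An ordered collection of uniquely identified profiles.

    The identifier order is stable and defines the row/column order of
    every matrix built from the database. Payloads are opaque data a
    scorer may consume (e.g. paths to profile files); they are optional.
    """

    ids: tuple[str, ...]
    payloads: tuple[object, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise ValueError("a profile database must contain at least one profile")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise ValueError(f"duplicate profile identifiers: {dupes}")
        if self.payloads is not None and len(self.payloads) != len(self.ids):
            raise ValueError("payloads must align one-to-one with ids")

    @classmethod
    def from_ids(cls, ids: Sequence[str], payloads: Sequence[object] | None = None) -> "ProfileDB":
        return cls(tuple(ids), tuple(payloads) if payloads is not None else None)

    def __len__(self) -> int:
        return len(self.ids)

    def payload(self, i: int) -> object:
        """Payload for profile index *i*; falls back to the ID itself."""
        return self.payloads[i] if self.payloads is not None else self.ids[i]


def _validate_scores(values: np.ndarray, context: str) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise MatrixValidationError(f"{context}: matrix must be square, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise MatrixValidationError(f"{context}: non-finite scores present")
    if values.min() < 0.0 or values.max() > 100.0:
        bad = np.argwhere((values < 0.0) | (values > 100.0))[0]
        raise MatrixValidationError(
            f"{context}: score {values[tuple(bad)]} at {tuple(bad)} outside [0, 100]"
        )


@dataclass(frozen=True)
class RawScoreMatrix:
    """Asymmetric all-against-all score matrix on the 0-100 scale."""

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        _validate_scores(self.values, "raw score matrix")
        if self.values.shape[0] != len(self.ids):
            raise MatrixValidationError("id list does not match matrix dimension")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric all-against-all similarity matrix, diagonal forced to 100."""

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        _validate_scores(self.values, "similarity matrix")
        if self.values.shape[0] != len(self.ids):
            raise MatrixValidationError("id list does not match matrix dimension")
        if not np.allclose(self.values, self.values.T, atol=SYMMETRY_TOL, rtol=0.0):
            raise MatrixValidationError(
                "matrix is not symmetric; pass symmetrize_on_load=True or call symmetrize()"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, profile_id: str) -> int:
        try:
            return self._id_index[profile_id]
        except AttributeError:
            object.__setattr__(self, "_id_index", {p: i for i, p in enumerate(self.ids)})
            return self._id_index[profile_id]

    def row(self, profile_id: str) -> np.ndarray:
        return self.values[self.index_of(profile_id)]

    def score(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def submatrix(self, member_ids: Sequence[str]) -> np.ndarray:
        idx = np.array([self.index_of(m) for m in member_ids])
        return self.values[np.ix_(idx, idx)]


def build_raw_matrix(db: ProfileDB, scorer: PairScorer) -> RawScoreMatrix:
    """Score every ordered pair of database profiles.

    The diagonal is forced to 100 (self-homology is certain by
    definition); a scorer that disagrees triggers a warning, not an
    error. A scorer returning a value outside [0, 100] for any ordered
    pair is a validation error naming the pair.
    """
    n = len(db)
    values = np.empty((n, n), dtype=float)
    for i in range(n):
        for j in range(n):
            if i == j:
                s = float(scorer(db.payload(i), db.payload(j)))
                if abs(s - 100.0) > 1e-9:
                    logger.warning(
                        "scorer returned %.4f for self-comparison of %s; forcing 100",
                        s, db.ids[i],
                    )
                values[i, j] = 100.0
                continue
            s = float(scorer(db.payload(i), db.payload(j)))
            if not (0.0 <= s <= 100.0) or not np.isfinite(s):
                raise MatrixValidationError(
                    f"scorer returned {s} for pair ({db.ids[i]}, {db.ids[j]}); "
                    "scores must lie in [0, 100]"
                )
            values[i, j] = s
    return RawScoreMatrix(values=values, ids=db.ids)


def symmetrize(raw: RawScoreMatrix) -> SimilarityMatrix:
    """Collapse the two orientations of each pair to their maximum.

    Idempotent; never decreases an entry; the diagonal stays 100.
    """
    values = np.maximum(raw.values, raw.values.T)
    np.fill_diagonal(values, 100.0)
    return SimilarityMatrix(values=values, ids=raw.ids)


def save_matrix(m: SimilarityMatrix | RawScoreMatrix, path: str | Path) -> None:
    """Write a matrix as tab-separated text: ID header row, ID first column.

    Cells carry 6 significant digits, which round-trips exactly through
    :func:`load_matrix` at the same precision.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(("id",) + m.ids) + "\n")
        for pid, row in zip(m.ids, m.values):
            cells = "\t".join(format(v, ".6g") for v in row)
            fh.write(f"{pid}\t{cells}\n")


def _parse_cell(token: str, row: int, col: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise MatrixParseError(f"non-numeric cell {token!r} at row {row}, column {col}") from None


def load_matrix(
    path: str | Path,
    *,
    symmetrize_on_load: bool = False,
    ids: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Load a similarity matrix from delimited text.

    Two dialects are accepted: the package's own format (first row and
    first column are profile IDs) and a headerless square numeric dump,
    for which IDs come from the *ids* sidecar list or default to
    ``P0000...``. Asymmetric input is an error unless
    ``symmetrize_on_load`` is set, in which case the transpose-maximum
    is taken. Symmetry is checked to 1e-9.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise MatrixParseError(f"{path}: empty file")

    first = lines[0].split("\t") if "\t" in lines[0] else lines[0].split()
    headered = True
    try:
        float(first[-1])
        headered = False
    except ValueError:
        pass

    if headered:
        file_ids = tuple(first[1:])
        if len(set(file_ids)) != len(file_ids):
            raise MatrixParseError(f"{path}: duplicate profile IDs in header")
        n = len(file_ids)
        if len(lines) - 1 != n:
            raise MatrixParseError(f"{path}: expected {n} data rows, found {len(lines) - 1}")
        values = np.empty((n, n), dtype=float)
        for r, line in enumerate(lines[1:]):
            tokens = line.split("\t") if "\t" in line else line.split()
            if len(tokens) != n + 1:
                raise MatrixParseError(
                    f"{path}: ragged row {r + 1}: expected {n + 1} fields, got {len(tokens)}"
                )
            if tokens[0] != file_ids[r]:
                raise MatrixParseError(
                    f"{path}: row label {tokens[0]!r} at row {r + 1} does not match "
                    f"header order ({file_ids[r]!r})"
                )
            for c, tok in enumerate(tokens[1:]):
                values[r, c] = _parse_cell(tok, r + 1, c + 1)
    else:
        rows = []
        width = None
        for r, line in enumerate(lines):
            tokens = line.split("\t") if "\t" in line else line.split()
            if width is None:
                width = len(tokens)
            elif len(tokens) != width:
                raise MatrixParseError(
                    f"{path}: ragged row {r}: expected {width} fields, got {len(tokens)}"
                )
            rows.append([_parse_cell(t, r, c) for c, t in enumerate(tokens)])
        values = np.asarray(rows, dtype=float)
        if values.shape[0] != values.shape[1]:
            raise MatrixParseError(f"{path}: headerless matrix is not square: {values.shape}")
        n = values.shape[0]
        if ids is not None:
            if len(ids) != n:
                raise MatrixParseError(f"{path}: sidecar ID list length {len(ids)} != {n}")
            if len(set(ids)) != len(ids):
                raise MatrixParseError(f"{path}: duplicate IDs in sidecar list")
            file_ids = tuple(ids)
        else:
            file_ids = tuple(f"P{i:04d}" for i in range(n))

    if symmetrize_on_load:
        return symmetrize(RawScoreMatrix(values=values, ids=file_ids))
    return SimilarityMatrix(values=values, ids=file_ids)
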