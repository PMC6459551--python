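"""Core in-memory containers: the binary association matrix and similarity views.

The association matrix ``Y`` is a dense binary q x p matrix with diseases on
rows and miRNAs on columns, carrying ordered identifier lists for both axes.
A :class:`SimilarityView` is one named square similarity matrix over a single
entity space (diseases or miRNAs); the solver fuses several views per space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["AssociationMatrix", "SimilarityView", "SPACES"]

SPACES = ("disease", "mirna")


def _check_ids(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary disease x miRNA association matrix with axis identifiers.

    Parameters
    ----------
    matrix:
        q x p array with entries in {0, 1}; rows are diseases, columns miRNAs.
    disease_ids, mirna_ids:
        Ordered, duplicate-free identifier lists for the two axes.
    """

    matrix: np.ndarray
    disease_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        Y = np.asarray(self.matrix)
        if Y.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        object.__setattr__(self, "matrix", Y.astype(np.int8))
        object.__setattr__(self, "disease_ids", _check_ids(self.disease_ids, "disease"))
        object.__setattr__(self, "mirna_ids", _check_ids(self.mirna_ids, "miRNA"))
        q, p = Y.shape
        if q != len(self.disease_ids) or p != len(self.mirna_ids):
            raise ValueError(
                f"matrix shape {Y.shape} does not match id lists "
                f"({len(self.disease_ids)}, {len(self.mirna_ids)})"
            )

    @property
    def n_diseases(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_mirnas(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.matrix.sum())

    def with_matrix(self, matrix: np.ndarray) -> "AssociationMatrix":
        """Return a copy carrying ``matrix`` with the same identifiers."""
        return replace(self, matrix=matrix)

    def positives(self) -> np.ndarray:
        """Indices (i, j) of known associations, one row per positive."""
        return np.argwhere(self.matrix == 1)


@dataclass(frozen=True)
class SimilarityView:
    """One named square similarity matrix over a single entity space."""

    name: str
    space: str
    matrix: np.ndarray
    ids: tuple[str, ...]
    noise_level: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise ValueError(f"space must be one of {SPACES}, got {self.space!r}")
        A = np.asarray(self.matrix, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"similarity matrix must be square, got {A.shape}")
        if not np.isfinite(A).all():
            raise ValueError(f"view {self.name!r} contains non-finite entries")
        object.__setattr__(self, "matrix", A)
        object.__setattr__(self, "ids", _check_ids(self.ids, self.space))
        if A.shape[0] != len(self.ids):
            raise ValueError(
                f"view {self.name!r}: matrix dimension {A.shape[0]} != {len(self.ids)} ids"
            )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def reindexed(self, ids: Sequence[str]) -> "SimilarityView":
        """Return the view restricted/reordered to ``ids`` (all must be present)."""
        pos = {d: k for k, d in enumerate(self.ids)}
        missing = [d for d in ids if d not in pos]
        if missing:
            from .errors import ReconciliationError

            raise ReconciliationError(
                f"view {self.name!r} is missing identifiers: {missing[:10]}"
            )
        idx = np.array([pos[d] for d in ids])
        return replace(self, matrix=self.matrix[np.ix_(idx, idx)], ids=tuple(ids))
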