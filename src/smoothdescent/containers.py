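"""Core in-memory containers shared across the package.

All matrices follow a single convention: rows are markers in the *input*
order (which stays fixed for the lifetime of a run), columns are either
parental homologues (phase) or offspring individuals (dosage).  A
:class:`GeneticMap` carries a permutation of the marker rows together with
cM positions; the data matrices themselves are never reordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HomologueMatrix",
    "DosageMatrix",
    "IBDTensor",
    "GeneticMap",
    "MISSING",
]

#: Sentinel used for missing dosages in float arrays.
MISSING = np.nan


def _default_marker_ids(n: int) -> list[str]:
    return [f"M{i + 1}" for i in range(n)]


@dataclass
class HomologueMatrix:
    """Phased parental haplotypes.

    ``values`` is a markers x p binary matrix: entry (m, h) is 1 when
    homologue ``h`` carries the alternative allele at marker ``m``.  The
    first ``ploidy_p1`` columns belong to parent 1, the rest to parent 2.
    """

    values: np.ndarray
    ploidy_p1: int
    ploidy_p2: int
    marker_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("homologue matrix must be 2-D (markers x homologues)")
        if self.ploidy_p1 % 2 or self.ploidy_p2 % 2:
            raise ValueError("parental ploidies must be even (bivalent pairing)")
        if self.values.shape[1] != self.p:
            raise ValueError(
                f"expected {self.p} homologue columns, got {self.values.shape[1]}"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("homologue matrix entries must be 0 or 1")
        if not self.marker_ids:
            self.marker_ids = _default_marker_ids(self.values.shape[0])
        elif len(self.marker_ids) != self.values.shape[0]:
            raise ValueError("marker_ids length does not match row count")

    @property
    def p(self) -> int:
        """Total homologue count across both parents."""
        return self.ploidy_p1 + self.ploidy_p2

    @property
    def parent_split(self) -> int:
        """Column index where parent 2's homologues begin."""
        return self.ploidy_p1

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]

    @property
    def offspring_ploidy(self) -> int:
        return (self.ploidy_p1 + self.ploidy_p2) // 2

    def parent1(self) -> np.ndarray:
        return self.values[:, : self.ploidy_p1]

    def parent2(self) -> np.ndarray:
        return self.values[:, self.ploidy_p1:]


@dataclass
class DosageMatrix:
    """Offspring allele dosages (markers x individuals), NaN = missing."""

    values: np.ndarray
    marker_ids: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (markers x individuals)")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.allclose(finite, np.round(finite)):
            raise ValueError("dosages must be integers (or NaN for missing)")
        if not self.marker_ids:
            self.marker_ids = _default_marker_ids(self.values.shape[0])
        if not self.individual_ids:
            self.individual_ids = [f"I{i + 1}" for i in range(self.values.shape[1])]

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]

    def as_int(self, missing: int = -1) -> np.ndarray:
        """Integer view with ``missing`` substituted for NaN."""
        out = np.where(np.isfinite(self.values), self.values, missing)
        return out.astype(np.int64)

    def copy(self) -> "DosageMatrix":
        return DosageMatrix(
            self.values.copy(), list(self.marker_ids), list(self.individual_ids)
        )


@dataclass
class IBDTensor:
    """Per-homologue inheritance probabilities (markers x homologues x individuals).

    ``probs`` entries lie in [0, 1]; NaN marks uninformative cells (missing
    genotype, or a genotype incompatible with the parental phase).  The
    ``impossible`` matrix flags marker/individual cells whose observed
    genotype matches no inheritance configuration — a strong signal of a
    genotyping error, tracked separately so downstream correction can act
    on it.
    """

    probs: np.ndarray
    ploidy_p1: int
    ploidy_p2: int
    impossible: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3:
            raise ValueError("IBD tensor must be 3-D (markers x homologues x individuals)")
        if self.impossible is None:
            self.impossible = np.zeros(
                (self.probs.shape[0], self.probs.shape[2]), dtype=bool
            )

    @property
    def n_markers(self) -> int:
        return self.probs.shape[0]

    @property
    def p(self) -> int:
        return self.probs.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[2]


@dataclass
class GeneticMap:
    """An ordered set of markers with cM positions.

    ``order`` is a permutation of marker row indices; ``positions`` are the
    nondecreasing cM coordinates of the markers *in that order*, starting
    at 0.
    """

    order: np.ndarray
    positions: np.ndarray
    marker_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.order.shape != self.positions.shape:
            raise ValueError("order and positions must have equal length")
        if np.any(np.diff(self.positions) < -1e-9):
            raise ValueError("map positions must be nondecreasing")
        if self.positions.size:
            self.positions = self.positions - self.positions[0]

    @property
    def n_markers(self) -> int:
        return self.order.size

    @property
    def length(self) -> float:
        """Map length in cM (max position minus min position)."""
        if self.positions.size == 0:
            return 0.0
        return float(self.positions[-1] - self.positions[0])

    def positions_by_marker(self) -> np.ndarray:
        """cM position indexed by *original* marker row index."""
        out = np.empty(self.n_markers, dtype=float)
        out[self.order] = self.positions
        return out

    @classmethod
    def from_positions(
        cls, positions: np.ndarray, marker_ids: list[str] | None = None
    ) -> "GeneticMap":
        """Build a map from per-marker positions given in input row order."""
        positions = np.asarray(positions, dtype=float)
        order = np.argsort(positions, kind="stable")
        return cls(order, positions[order], marker_ids or [])
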