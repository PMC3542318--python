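"""Core domain types shared across the package.

Coordinates are 1-based inclusive in every public interface (the convention
used for mature-protein numbering in amyloid region annotations); internal
arrays are 0-based numpy vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Non-standard codes accepted on input but flagged; predictors treat these
#: positions as "no propensity value" and they can never be hits.
EXTENDED_AA = "XBZUO"

#: Sentinel for "no score available at this residue".  NaN compares False
#: against every threshold, so sentinel positions can never become hits.
NO_SCORE = math.nan


class AmylconsError(Exception):
    """Base class for all package errors."""


class LoadError(AmylconsError):
    """Raised when an input file fails validation."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein record: identifier plus one-letter residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise LoadError(f"sequence {self.id!r}: empty sequence")
        allowed = set(STANDARD_AA) | set(EXTENDED_AA)
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in allowed:
                raise LoadError(
                    f"sequence {self.id!r}: illegal residue {aa!r} at position {pos}"
                )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def nonstandard_positions(self) -> tuple[int, ...]:
        """1-based positions carrying a non-standard residue code."""
        return tuple(
            i for i, aa in enumerate(self.residues, start=1) if aa in EXTENDED_AA
        )

    def mutate(self, position: int, new: str) -> "ProteinSequence":
        """Return a copy with a single substitution at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} out of range 1..{self.length}")
        res = self.residues[: position - 1] + new.upper() + self.residues[position:]
        return ProteinSequence(self.id, res)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort 1-based inclusive intervals and merge overlapping/adjacent ones."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class RegionAnnotation:
    """Experimentally verified amyloidogenic intervals for one sequence.

    Intervals are 1-based inclusive and are normalized (sorted, merged) on
    construction, which makes normalization idempotent.
    """

    sequence_id: str
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for start, end in self.intervals:
            if start < 1:
                raise LoadError(
                    f"region {self.sequence_id!r}: start {start} < 1"
                )
            if start > end:
                raise LoadError(
                    f"region {self.sequence_id!r}: inverted interval ({start}, {end})"
                )
        self.intervals = merge_intervals(self.intervals)

    def validate_against(self, seq: ProteinSequence) -> None:
        if self.sequence_id != seq.id:
            raise LoadError(
                f"annotation for {self.sequence_id!r} checked against {seq.id!r}"
            )
        for start, end in self.intervals:
            if end > seq.length:
                raise LoadError(
                    f"region {self.sequence_id!r}: interval ({start}, {end}) "
                    f"exceeds sequence length {seq.length}"
                )

    def mask(self, length: int) -> np.ndarray:
        """Boolean per-residue vector: True inside any interval."""
        m = np.zeros(length, dtype=bool)
        for start, end in self.intervals:
            if end > length:
                raise LoadError(
                    f"region {self.sequence_id!r}: interval ({start}, {end}) "
                    f"exceeds length {length}"
                )
            m[start - 1 : end] = True
        return m


@dataclass
class AccessibilityTrack:
    """Per-residue solvent-accessible surface area (DSSP ACC), in A^2."""

    sequence_id: str
    acc: np.ndarray

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        if np.any(self.acc < 0):
            raise LoadError(
                f"accessibility for {self.sequence_id!r}: negative ACC value"
            )

    def validate_against(self, seq: ProteinSequence) -> None:
        if len(self.acc) != seq.length:
            raise LoadError(
                f"accessibility for {self.sequence_id!r}: {len(self.acc)} values "
                f"for a {seq.length}-residue sequence"
            )


@dataclass
class MethodResult:
    """One predictor's per-residue output for one sequence."""

    method: str
    sequence_id: str
    scores: np.ndarray
    hits: np.ndarray
    config: "object" = None
    status: str = "ok"  # ok | skipped_too_short | external_missing

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.hits = np.asarray(self.hits, dtype=bool)
        if len(self.scores) != len(self.hits):
            raise ValueError("scores and hits length mismatch")

    @property
    def length(self) -> int:
        return len(self.hits)

    def hit_regions(self) -> list[tuple[int, int]]:
        return mask_to_regions(self.hits)


def mask_to_regions(mask: Sequence[bool]) -> list[tuple[int, int]]:
    """Maximal runs of True, as 1-based inclusive intervals."""
    regions: list[tuple[int, int]] = []
    start = None
    for i, hit in enumerate(mask, start=1):
        if hit and start is None:
            start = i
        elif not hit and start is not None:
            regions.append((start, i - 1))
            start = None
    if start is not None:
        regions.append((start, len(mask)))
    return regions


def regions_to_mask(regions: Iterable[tuple[int, int]], length: int) -> np.ndarray:
    m = np.zeros(length, dtype=bool)
    for start, end in regions:
        m[start - 1 : end] = True
    return m


@dataclass
class ConsensusResult:
    """Per-residue vote histogram and the thresholded consensus call."""

    sequence_id: str
    n_methods: int
    threshold: int
    votes: np.ndarray
    hits: np.ndarray = field(init=False)
    regions: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=int)
        if np.any(self.votes < 0) or np.any(self.votes > self.n_methods):
            raise ValueError("votes out of range 0..n_methods")
        self.hits = self.votes >= self.threshold
        self.regions = mask_to_regions(self.hits)

    @property
    def length(self) -> int:
        return len(self.votes)
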