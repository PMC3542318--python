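"""Per-residue consensus voting over component predictors.

A residue is a consensus hit when at least ``floor(n/2)`` of the ``n``
participating methods flag it (clamped to 1 for the degenerate ``n = 1``
case).  ``n`` counts only methods that actually produced output (status
``ok``); methods skipped for length or missing external scores do not count
as "no" votes — this adjusts the threshold on short sequences and is a
documented behavioral choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import ConsensusResult, MethodResult, ProteinSequence
from .predictors import run_all

__all__ = ["consensus_threshold", "vote", "substitution_scan", "ScanDelta"]


def consensus_threshold(n: int) -> int:
    """Vote count required for a consensus hit among ``n`` methods."""
    if n < 1:
        raise ValueError(f"method count must be >= 1, got {n}")
    return max(1, n // 2)


def vote(
    results: Sequence[MethodResult],
    threshold_override: int | None = None,
) -> ConsensusResult:
    """Combine per-method hit vectors into a consensus call.

    Only results with status ``ok`` participate; at least one is required.
    ``threshold_override`` replaces the floor(n/2) rule (the server-side
    sweep "all possible thresholds" use case).
    """
    if not results:
        raise ValueError("no method results supplied")
    seq_ids = {r.sequence_id for r in results}
    if len(seq_ids) != 1:
        raise ValueError(f"mixed sequence ids in results: {sorted(seq_ids)}")
    lengths = {r.length for r in results}
    if len(lengths) != 1:
        raise ValueError("method results disagree on sequence length")
    participating = [r for r in results if r.status == "ok"]
    if not participating:
        raise ValueError("zero participating methods (none returned status ok)")
    n = len(participating)
    threshold = (
        threshold_override if threshold_override is not None else consensus_threshold(n)
    )
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    votes = np.sum([r.hits for r in participating], axis=0).astype(int)
    return ConsensusResult(
        sequence_id=seq_ids.pop(),
        n_methods=n,
        threshold=threshold,
        votes=votes,
    )


@dataclass(frozen=True)
class ScanDelta:
    """Region-level difference between two consensus results."""

    lost: tuple[tuple[int, int], ...]
    gained: tuple[tuple[int, int], ...]

    def __bool__(self) -> bool:
        return bool(self.lost or self.gained)


def _region_delta(
    before: ConsensusResult, after: ConsensusResult
) -> ScanDelta:
    lost = tuple(r for r in before.regions if r not in after.regions)
    gained = tuple(r for r in after.regions if r not in before.regions)
    return ScanDelta(lost=lost, gained=gained)


def parse_mutation(notation: str) -> tuple[str, int, str]:
    """Parse ``<wt><1-based pos><new>`` notation, e.g. ``T28G``."""
    if len(notation) < 3 or not notation[0].isalpha() or not notation[-1].isalpha():
        raise ValueError(f"malformed mutation {notation!r}; expected e.g. T28G")
    wt, new = notation[0].upper(), notation[-1].upper()
    try:
        pos = int(notation[1:-1])
    except ValueError:
        raise ValueError(f"malformed mutation {notation!r}; expected e.g. T28G") from None
    return wt, pos, new


def substitution_scan(
    seq: ProteinSequence,
    mutations: Sequence[tuple[int, str] | str],
    selection: set[str] | None = None,
    external_scores: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    mutant_external_scores: Mapping[str, Mapping[str, np.ndarray]] | None = None,
    threshold_override: int | None = None,
) -> tuple[ConsensusResult, ConsensusResult, ScanDelta]:
    """Consensus before/after a set of point substitutions, plus the delta.

    Mutations are ``(position, new_residue)`` pairs or ``T28G``-style
    strings (whose wild-type letter is checked against the sequence).
    Adapter methods need re-supplied external scores for the mutant
    (``mutant_external_scores``); otherwise they are dropped from BOTH runs
    so the comparison stays symmetric.
    """
    mutant = seq
    for m in mutations:
        if isinstance(m, str):
            wt, pos, new = parse_mutation(m)
            if not 1 <= pos <= seq.length:
                raise ValueError(f"mutation {m!r}: position {pos} out of range")
            if seq.residues[pos - 1] != wt:
                raise ValueError(
                    f"mutation {m!r}: sequence has {seq.residues[pos - 1]!r} "
                    f"at position {pos}, not {wt!r}"
                )
        else:
            pos, new = m
        mutant = mutant.mutate(pos, new)

    external_scores = dict(external_scores or {})
    mutant_external_scores = dict(mutant_external_scores or {})
    from .predictors import ADAPTER_METHODS, METHOD_IDS

    sel = set(selection) if selection is not None else set(METHOD_IDS)
    for method_id in sorted(sel & set(ADAPTER_METHODS)):
        has_before = method_id in external_scores
        has_after = method_id in mutant_external_scores
        if not (has_before and has_after):
            # drop asymmetric adapters from both runs
            sel.discard(method_id)
            external_scores.pop(method_id, None)
            mutant_external_scores.pop(method_id, None)
    if not sel:
        raise ValueError("no methods left after dropping unscored adapters")

    before = vote(
        run_all(seq, sel, external_scores), threshold_override=threshold_override
    )
    after = vote(
        run_all(mutant, sel, mutant_external_scores),
        threshold_override=threshold_override,
    )
    return before, after, _region_delta(before, after)
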