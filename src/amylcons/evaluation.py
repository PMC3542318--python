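"""Per-residue benchmark protocol.

Predictions are scored residue-by-residue against annotated intervals:

* sensitivity = TP / (TP + FN), as a percentage
* specificity = TN / (TN + FP), as a percentage
* Q = (sensitivity + specificity) / 2
* MCC = (TP*TN - FP*FN) / sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP))

Percentages and MCC are kept at full precision internally and rounded to
two decimals only in reports.  Any metric whose denominator is zero reports
0 and is flagged degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AccessibilityTrack,
    ConsensusResult,
    MethodResult,
    ProteinSequence,
    RegionAnnotation,
)

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion_counts",
    "metrics",
    "aggregate",
    "macro_mcc",
    "classify_exposure",
    "benchmark",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-residue confusion counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity/specificity/Q as percentages, MCC in [-1, 1].

    Values are full precision; use :meth:`rounded` for report formatting.
    ``degenerate`` marks zero-denominator conventions.
    """

    sensitivity: float
    specificity: float
    q: float
    mcc: float
    degenerate: bool = False

    def rounded(self, ndigits: int = 2) -> "MetricSet":
        return MetricSet(
            round(self.sensitivity, ndigits),
            round(self.specificity, ndigits),
            round(self.q, ndigits),
            round(self.mcc, ndigits),
            self.degenerate,
        )


def confusion_counts(
    predicted: Sequence[bool] | np.ndarray, truth: RegionAnnotation
) -> ConfusionCounts:
    """Count per-residue TP/TN/FP/FN for one sequence."""
    pred = np.asarray(predicted, dtype=bool)
    mask = truth.mask(len(pred))
    return ConfusionCounts(
        tp=int(np.sum(pred & mask)),
        tn=int(np.sum(~pred & ~mask)),
        fp=int(np.sum(pred & ~mask)),
        fn=int(np.sum(~pred & mask)),
    )


def metrics(c: ConfusionCounts) -> MetricSet:
    degenerate = False

    def _ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return 100.0 * num / den

    sensitivity = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    q = (sensitivity + specificity) / 2.0
    denom = (
        (c.tn + c.fn) * (c.tn + c.fp) * (c.tp + c.fn) * (c.tp + c.fp)
    )
    if denom == 0:
        degenerate = True
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricSet(sensitivity, specificity, q, mcc, degenerate)


def aggregate(per_protein: Sequence[ConfusionCounts]) -> ConfusionCounts:
    """Element-wise sum (pooled counts over a protein set)."""
    if not per_protein:
        raise ValueError("empty list of confusion counts")
    total = ConfusionCounts(0, 0, 0, 0)
    for c in per_protein:
        total = total + c
    return total


def macro_mcc(per_protein_mcc: Sequence[float]) -> float:
    """Equal-weight (per-protein) mean of MCC values."""
    if not per_protein_mcc:
        raise ValueError("empty MCC list")
    return float(sum(per_protein_mcc)) / len(per_protein_mcc)


#: Exposure cut-offs in A^2: mean >= 20 surface, 10 <= mean < 20 semi-surface.
SURFACE_CUTOFF = 20.0
SEMI_SURFACE_CUTOFF = 10.0


def classify_exposure(
    interval: tuple[int, int],
    acc: AccessibilityTrack,
    mode: str = "mean",
) -> str:
    """Classify one peptide interval as surface / semi-surface / buried.

    ``mode="mean"`` (default) applies the cut-offs to the peptide's mean
    per-residue accessibility; ``mode="all"`` requires every residue of the
    peptide to clear the cut-off individually.
    """
    start, end = interval
    if not 1 <= start <= end <= len(acc.acc):
        raise ValueError(f"interval ({start}, {end}) out of range")
    values = acc.acc[start - 1 : end]
    if mode == "mean":
        stat = float(values.mean())
        if stat >= SURFACE_CUTOFF:
            return "surface"
        if stat >= SEMI_SURFACE_CUTOFF:
            return "semi-surface"
        return "buried"
    if mode == "all":
        if np.all(values >= SURFACE_CUTOFF):
            return "surface"
        if np.all(values >= SEMI_SURFACE_CUTOFF):
            return "semi-surface"
        return "buried"
    raise ValueError(f"unknown exposure mode {mode!r}")


def benchmark(
    sequences: Sequence[ProteinSequence],
    annotations: Sequence[RegionAnnotation],
    method_results: Mapping[str, Mapping[str, MethodResult]],
    consensus_results: Mapping[str, ConsensusResult] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the pooled benchmark table and the per-protein MCC supplement.

    ``method_results`` maps method id -> (sequence id -> MethodResult);
    ``consensus_results`` maps sequence id -> ConsensusResult and adds a
    ``consensus`` row.  Returns ``(pooled, per_protein)`` data frames.
    The pooled table has one row per method: TP/TN/FP/FN plus metrics.  The
    per-protein table has one MCC column per method and a final equal-weight
    ``macro`` row.
    """
    ann_by_id = {a.sequence_id: a for a in annotations}
    for seq in sequences:
        if seq.id not in ann_by_id:
            raise ValueError(f"missing annotation for sequence {seq.id!r}")
        ann_by_id[seq.id].validate_against(seq)

    rows: dict[str, Mapping[str, object]] = {}
    for method_id, per_seq in method_results.items():
        for seq in sequences:
            if seq.id not in per_seq:
                raise ValueError(
                    f"method {method_id!r}: missing output for sequence {seq.id!r}"
                )
        rows[method_id] = {s.id: per_seq[s.id].hits for s in sequences}
    if consensus_results is not None:
        for seq in sequences:
            if seq.id not in consensus_results:
                raise ValueError(f"missing consensus for sequence {seq.id!r}")
        rows["consensus"] = {s.id: consensus_results[s.id].hits for s in sequences}

    pooled_records = []
    per_protein_mcc: dict[str, dict[str, float]] = {}
    for name, hits_by_seq in rows.items():
        per_seq_counts = [
            confusion_counts(hits_by_seq[s.id], ann_by_id[s.id]) for s in sequences
        ]
        pooled = aggregate(per_seq_counts)
        m = metrics(pooled)
        pooled_records.append(
            {
                "method": name,
                "TP": pooled.tp,
                "TN": pooled.tn,
                "FP": pooled.fp,
                "FN": pooled.fn,
                "sensitivity": round(m.sensitivity, 2),
                "specificity": round(m.specificity, 2),
                "Q": round(m.q, 2),
                "MCC": round(m.mcc, 2),
            }
        )
        mcc_by_seq = {
            s.id: metrics(c).mcc for s, c in zip(sequences, per_seq_counts)
        }
        mcc_by_seq["macro"] = macro_mcc(list(mcc_by_seq.values()))
        per_protein_mcc[name] = {k: round(v, 2) for k, v in mcc_by_seq.items()}

    pooled_df = pd.DataFrame.from_records(pooled_records).set_index("method")
    per_protein_df = pd.DataFrame(per_protein_mcc)
    per_protein_df.index.name = "sequence_id"
    return pooled_df, per_protein_df
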