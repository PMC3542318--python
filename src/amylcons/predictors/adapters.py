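"""Threshold adapters for externally computed predictor scores.

Six methods (tango, netcssp, pafig, secstr, hce, amylmut) are consumed as
per-residue score tables produced by their original implementations; this
module only applies the published decision thresholds.  Score-table columns
expected per method:

====== ==================================================================
method columns
====== ==================================================================
tango   ``beta`` (percentage beta-aggregation; hit strictly above 5.00)
hce     ``energy`` (conformational energy; hit strictly below -27.00)
pafig   ``ri`` (reliability index; hit at 7 or above)
netcssp ``pbeta``, ``phelix`` (hit iff pbeta/phelix > 1 and pbeta > 6)
secstr  ``switch`` (1 = conformational-switch call)
amylmut ``score`` (1 = predicted amyloidogenic position)
====== ==================================================================
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from ..model import NO_SCORE, MethodResult, ProteinSequence
from .registry import MethodConfig, compare

__all__ = ["apply_method_threshold"]


def _derive_columns(
    config: MethodConfig, columns: dict[str, np.ndarray]
) -> dict[str, np.ndarray] | None:
    """Add derived columns (e.g. netcssp's hbp = pbeta/phelix) in place."""
    for name, recipe in (config.params.get("derived") or {}).items():
        op, *operands = recipe
        if op != "ratio":
            raise ValueError(f"unknown derived-column op {op!r}")
        num_name, den_name = operands
        if num_name not in columns or den_name not in columns:
            return None
        num, den = columns[num_name], columns[den_name]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den != 0, num / den, np.nan)
        columns[name] = ratio
    return columns


def apply_method_threshold(
    config: MethodConfig,
    scores: Mapping[str, np.ndarray],
    sequence: ProteinSequence,
) -> MethodResult:
    """Turn one external score table into a per-residue hit vector.

    ``scores`` maps column name to a per-residue vector (NaN = no score);
    vectors shorter than the sequence are padded with the no-score sentinel.
    A residue is a hit iff every comparison in the method's rule holds; rule
    columns missing from the table yield status ``external_missing``.
    """
    n = sequence.length
    if n < config.min_length:
        return MethodResult(
            method=config.method,
            sequence_id=sequence.id,
            scores=np.full(n, NO_SCORE),
            hits=np.zeros(n, dtype=bool),
            config=config,
            status="skipped_too_short",
        )
    columns: dict[str, np.ndarray] = {}
    for name, vector in scores.items():
        vector = np.asarray(vector, dtype=float)
        if len(vector) > n:
            raise ValueError(
                f"{config.method}: score vector for {sequence.id!r} has "
                f"{len(vector)} entries for a {n}-residue sequence"
            )
        if len(vector) < n:
            vector = np.concatenate([vector, np.full(n - len(vector), NO_SCORE)])
        columns[name] = vector

    missing = _derive_columns(config, columns) is None or any(
        col not in columns for col, _, _ in config.threshold_rule
    )
    if missing or not config.threshold_rule:
        return MethodResult(
            method=config.method,
            sequence_id=sequence.id,
            scores=np.full(n, NO_SCORE),
            hits=np.zeros(n, dtype=bool),
            config=config,
            status="external_missing",
        )

    hits = np.ones(n, dtype=bool)
    for col, comparator, cutoff in config.threshold_rule:
        hits &= compare(columns[col], comparator, cutoff)
    primary = columns[config.threshold_rule[0][0]]
    hits &= ~np.isnan(primary)  # a hit always has a real primary score
    return MethodResult(config.method, sequence.id, primary, hits, config)
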