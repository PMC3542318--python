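"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (sequences), a bespoke region TSV (``sequence_id  start  end``,
1-based inclusive), a bespoke score TSV (``sequence_id  index  col1 [col2...]``
with a header line), classic fixed-column DSSP text (ACC field only), plain
two-column accessibility TSV, and GFF3 export of predicted regions.
"""

from __future__ import annotations

import io
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    NO_SCORE,
    AccessibilityTrack,
    LoadError,
    ProteinSequence,
    RegionAnnotation,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_regions",
    "write_regions",
    "read_score_table",
    "write_score_table",
    "read_accessibility",
    "write_gff3",
]


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into validated :class:`ProteinSequence` records.

    Residues are uppercased and surrounding whitespace stripped; record
    order is preserved.  An empty file yields an empty list.
    """
    path = Path(path)
    sequences: list[ProteinSequence] = []
    for i, record in enumerate(_BioSeqIO.parse(str(path), "fasta"), start=1):
        if not record.id:
            raise LoadError(f"{path}: record {i}: malformed or empty header")
        residues = str(record.seq).strip().upper()
        if not residues:
            raise LoadError(f"{path}: record {record.id!r}: empty sequence")
        try:
            sequences.append(ProteinSequence(record.id, residues))
        except LoadError as exc:
            raise LoadError(f"{path}: {exc}") from exc
    return sequences


def write_fasta(sequences: Sequence[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    _BioSeqIO.write(records, str(Path(path)), "fasta")


def read_regions(
    path: str | Path,
    sequences: Sequence[ProteinSequence] | None = None,
) -> list[RegionAnnotation]:
    """Read the region TSV; intervals are grouped, sorted and merged per id.

    When ``sequences`` is given, every annotation is validated against the
    matching sequence's length.
    """
    path = Path(path)
    grouped: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise LoadError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            seq_id, start_s, end_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise LoadError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start > end:
                raise LoadError(
                    f"{path}:{lineno}: inverted interval ({start}, {end}) for {seq_id!r}"
                )
            if start < 1:
                raise LoadError(f"{path}:{lineno}: start {start} < 1")
            if seq_id not in grouped:
                grouped[seq_id] = []
                order.append(seq_id)
            grouped[seq_id].append((start, end))
    annotations = [RegionAnnotation(seq_id, grouped[seq_id]) for seq_id in order]
    if sequences is not None:
        by_id = {s.id: s for s in sequences}
        for ann in annotations:
            if ann.sequence_id not in by_id:
                raise LoadError(
                    f"{path}: annotation for unknown sequence {ann.sequence_id!r}"
                )
            ann.validate_against(by_id[ann.sequence_id])
    return annotations


def write_regions(annotations: Sequence[RegionAnnotation], path: str | Path) -> None:
    with open(Path(path), "w") as handle:
        for ann in annotations:
            for start, end in ann.intervals:
                handle.write(f"{ann.sequence_id}\t{start}\t{end}\n")


def read_score_table(path: str | Path) -> dict[str, dict[str, np.ndarray]]:
    """Read an external predictor's per-residue score TSV.

    Layout: a header line ``sequence_id  index  <col>...`` followed by one
    row per scored residue (1-based index).  Returns, per sequence id, a
    dense vector per score column sized to the largest index seen; residues
    without a row carry the NO_SCORE sentinel (NaN).
    """
    path = Path(path)
    with open(path) as handle:
        header = handle.readline().strip()
        if not header:
            raise LoadError(f"{path}: empty score table")
        cols = header.split("\t") if "\t" in header else header.split()
        if len(cols) < 3 or cols[0] != "sequence_id" or cols[1] != "index":
            raise LoadError(
                f"{path}: header must start with 'sequence_id index <score columns>'"
            )
        score_cols = cols[2:]
        rows: dict[str, dict[int, list[float]]] = {}
        for lineno, line in enumerate(handle, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != len(cols):
                raise LoadError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            seq_id = fields[0]
            try:
                idx = int(fields[1])
                values = [float(v) for v in fields[2:]]
            except ValueError as exc:
                raise LoadError(f"{path}:{lineno}: malformed row") from exc
            if idx < 1:
                raise LoadError(f"{path}:{lineno}: index {idx} < 1")
            per_seq = rows.setdefault(seq_id, {})
            if idx in per_seq:
                raise LoadError(
                    f"{path}:{lineno}: duplicate row for ({seq_id!r}, {idx})"
                )
            per_seq[idx] = values
    result: dict[str, dict[str, np.ndarray]] = {}
    for seq_id, per_seq in rows.items():
        length = max(per_seq)
        vectors = {
            col: np.full(length, NO_SCORE) for col in score_cols
        }
        for idx, values in per_seq.items():
            for col, value in zip(score_cols, values):
                vectors[col][idx - 1] = value
        result[seq_id] = vectors
    return result


def write_score_table(
    scores: Mapping[str, Mapping[str, Sequence[float]]], path: str | Path
) -> None:
    """Inverse of :func:`read_score_table`; NaN positions are omitted."""
    first = next(iter(scores.values()))
    cols = list(first)
    with open(Path(path), "w") as handle:
        handle.write("sequence_id\tindex\t" + "\t".join(cols) + "\n")
        for seq_id, vectors in scores.items():
            length = len(next(iter(vectors.values())))
            for i in range(length):
                values = [vectors[col][i] for col in cols]
                if all(math.isnan(v) for v in values):
                    continue
                handle.write(
                    f"{seq_id}\t{i + 1}\t"
                    + "\t".join(f"{v:g}" for v in values)
                    + "\n"
                )


# -- accessibility -----------------------------------------------------------

# Classic DSSP data lines are fixed-column: chain id at offset 11, insertion
# code at offset 10, ACC right-aligned in offsets 34:38.
_DSSP_CHAIN = 11
_DSSP_ICODE = 10
_DSSP_ACC = slice(34, 38)


def _parse_dssp(handle: io.TextIOBase, path: Path, chain: str | None) -> list[float]:
    in_data = False
    acc_values: list[float] = []
    chains_seen: set[str] = set()
    for line in handle:
        if not in_data:
            if line.lstrip().startswith("#  RESIDUE"):
                in_data = True
            continue
        if len(line) < 38:
            continue
        if line[13] == "!":  # chain break record
            continue
        chains_seen.add(line[_DSSP_CHAIN])
        if chain is not None and line[_DSSP_CHAIN] != chain:
            continue
        if line[_DSSP_ICODE].strip():
            raise LoadError(f"{path}: insertion codes are not supported")
        acc_values.append(float(line[_DSSP_ACC]))
    if not in_data:
        raise LoadError(f"{path}: not a DSSP file (no '#  RESIDUE' header)")
    if chain is None and len(chains_seen) > 1:
        raise LoadError(
            f"{path}: multi-chain DSSP file; select a chain from {sorted(chains_seen)}"
        )
    if chain is not None and chain not in chains_seen:
        raise LoadError(f"{path}: chain {chain!r} not present")
    return acc_values


def read_accessibility(
    path: str | Path,
    sequence: ProteinSequence,
    dialect: str = "tsv",
    chain: str | None = None,
) -> AccessibilityTrack:
    """Read per-residue solvent accessibility (A^2) for one sequence.

    ``dialect`` is ``"tsv"`` (two columns: 1-based index, ACC) or ``"dssp"``
    (classic fixed-column DSSP output; ``chain`` selects the chain in
    multi-chain files).
    """
    path = Path(path)
    if dialect == "dssp":
        with open(path) as handle:
            values = _parse_dssp(handle, path, chain)
    elif dialect == "tsv":
        values = []
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != 2:
                    raise LoadError(f"{path}:{lineno}: expected 2 fields")
                idx, acc = int(fields[0]), float(fields[1])
                if idx != len(values) + 1:
                    raise LoadError(
                        f"{path}:{lineno}: indices must be contiguous from 1"
                    )
                values.append(acc)
    else:
        raise ValueError(f"unknown accessibility dialect {dialect!r}")
    if len(values) != sequence.length:
        raise LoadError(
            f"{path}: {len(values)} ACC values for {sequence.id!r} "
            f"({sequence.length} residues)"
        )
    track = AccessibilityTrack(sequence.id, np.array(values))
    track.validate_against(sequence)
    return track


def write_gff3(
    regions_by_seq: Mapping[str, Sequence[tuple[int, int]]],
    path: str | Path,
    source: str = "amylcons",
    feature_type: str = "polypeptide_region",
) -> None:
    """Write predicted regions as GFF3 (1-based inclusive, like the rest)."""
    with open(Path(path), "w") as handle:
        handle.write("##gff-version 3\n")
        for seq_id, regions in regions_by_seq.items():
            for start, end in regions:
                handle.write(
                    f"{seq_id}\t{source}\t{feature_type}\t{start}\t{end}"
                    f"\t.\t.\t.\tNote=aggregation-prone region\n"
                )
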