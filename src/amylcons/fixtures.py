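"""Deterministic synthetic fixtures: random polar-biased background
sequences with planted aggregation-prone motifs and exactly matching region
annotations, so every pipeline stage is testable without any downloads.

The background alphabet deliberately excludes residues that score high on
the packaged propensity scales (hydrophobics/aromatics), so the contrast
between planted motifs and background is controllable.  This provides
statistical structure for testing, not a simulation of aggregation physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import ProteinSequence, RegionAnnotation
from . import seqio

__all__ = ["FixtureSpec", "Fixture", "generate", "write_fixture", "read_fixture"]

#: Polar/charged background; contains no F/I/Y (pattern position 5) and no
#: strongly aggregation-prone residue on any packaged scale.
DEFAULT_BACKGROUND = "ADEGKNPQRS"

DEFAULT_MOTIFS = ("STVIIE", "GNNQQNY", "NNQQNY")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_sequences: int = 6
    length: int = 80
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    background: str = DEFAULT_BACKGROUND
    motifs_per_sequence: int = 1

    def __post_init__(self) -> None:
        need = self.motifs_per_sequence * (max(map(len, self.motifs), default=0) + 2)
        if self.motifs and self.length < need:
            raise ValueError(
                f"length {self.length} too short to plant "
                f"{self.motifs_per_sequence} motif(s); need >= {need}"
            )


@dataclass
class Fixture:
    sequences: list[ProteinSequence]
    annotations: list[RegionAnnotation]
    manifest: dict = field(default_factory=dict)


def _plant_positions(
    rng: np.random.Generator, length: int, motif_lengths: list[int]
) -> list[int]:
    """Non-overlapping 0-based start offsets with >= 1 residue of spacing."""
    for _ in range(1000):
        starts = sorted(
            int(rng.integers(0, length - ml + 1)) for ml in motif_lengths
        )
        ok = True
        for (s1, l1), (s2, _) in zip(
            zip(starts, motif_lengths), zip(starts[1:], motif_lengths[1:])
        ):
            if s1 + l1 + 1 > s2:  # overlap or adjacency
                ok = False
                break
        if ok:
            return starts
    raise ValueError("infeasible planting density")


def generate(spec: FixtureSpec) -> Fixture:
    """Produce sequences, annotations and a manifest, reproducibly by seed."""
    rng = np.random.default_rng(spec.seed)
    background = list(spec.background)
    sequences: list[ProteinSequence] = []
    annotations: list[RegionAnnotation] = []
    planted: dict[str, list[dict]] = {}
    for i in range(spec.n_sequences):
        seq_id = f"fix{i + 1:03d}"
        residues = list(rng.choice(background, size=spec.length))
        intervals: list[tuple[int, int]] = []
        records: list[dict] = []
        if spec.motifs and spec.motifs_per_sequence > 0:
            motifs = [
                spec.motifs[int(rng.integers(0, len(spec.motifs)))]
                for _ in range(spec.motifs_per_sequence)
            ]
            starts = _plant_positions(rng, spec.length, [len(m) for m in motifs])
            for start, motif in zip(starts, motifs):
                residues[start : start + len(motif)] = list(motif)
                intervals.append((start + 1, start + len(motif)))
                records.append(
                    {"motif": motif, "start": start + 1, "end": start + len(motif)}
                )
        sequences.append(ProteinSequence(seq_id, "".join(residues)))
        if intervals:
            annotations.append(RegionAnnotation(seq_id, intervals))
        planted[seq_id] = records
    manifest = {
        "spec": {
            "seed": spec.seed,
            "n_sequences": spec.n_sequences,
            "length": spec.length,
            "motifs": list(spec.motifs),
            "background": spec.background,
            "motifs_per_sequence": spec.motifs_per_sequence,
        },
        "planted": planted,
    }
    return Fixture(sequences, annotations, manifest)


def write_fixture(spec: FixtureSpec, directory: str | Path) -> Fixture:
    """Generate and write FASTA + region TSV + JSON manifest into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fixture = generate(spec)
    seqio.write_fasta(fixture.sequences, directory / "sequences.fasta")
    seqio.write_regions(fixture.annotations, directory / "regions.tsv")
    with open(directory / "manifest.json", "w") as handle:
        json.dump(fixture.manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return fixture


def read_fixture(directory: str | Path) -> Fixture:
    directory = Path(directory)
    sequences = seqio.read_fasta(directory / "sequences.fasta")
    annotations = seqio.read_regions(directory / "regions.tsv", sequences)
    with open(directory / "manifest.json") as handle:
        manifest = json.load(handle)
    return Fixture(sequences, annotations, manifest)
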