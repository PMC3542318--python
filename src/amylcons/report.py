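"""Plain-text / TSV report writers for prediction runs."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from .model import ConsensusResult, MethodResult, ProteinSequence

__all__ = ["write_text_report", "write_votes_tsv"]


def _fmt_regions(regions: Sequence[tuple[int, int]]) -> str:
    return ", ".join(f"{s}-{e}" for s, e in regions) if regions else "-"


def write_text_report(
    path: str | Path,
    sequences: Sequence[ProteinSequence],
    method_results: Mapping[str, Sequence[MethodResult]],
    consensus_results: Mapping[str, ConsensusResult],
) -> None:
    """Flat-file report: per-method hit intervals, consensus intervals, and
    the per-residue vote histogram for each sequence."""
    with open(Path(path), "w") as handle:
        for seq in sequences:
            cons = consensus_results[seq.id]
            handle.write(f"# sequence: {seq.id} ({seq.length} residues)\n")
            handle.write(
                f"# consensus: {cons.threshold} of {cons.n_methods} methods\n"
            )
            for result in method_results[seq.id]:
                if result.status != "ok":
                    handle.write(f"{result.method:<12}[{result.status}]\n")
                else:
                    handle.write(
                        f"{result.method:<12}{_fmt_regions(result.hit_regions())}\n"
                    )
            handle.write(f"{'consensus':<12}{_fmt_regions(cons.regions)}\n")
            handle.write("votes       ")
            handle.write(" ".join(str(v) for v in cons.votes))
            handle.write("\n\n")


def write_votes_tsv(
    path: str | Path,
    sequences: Sequence[ProteinSequence],
    consensus_results: Mapping[str, ConsensusResult],
) -> None:
    """Per-residue table: sequence_id, index, residue, votes, consensus hit."""
    with open(Path(path), "w") as handle:
        handle.write("sequence_id\tindex\tresidue\tvotes\thit\n")
        for seq in sequences:
            cons = consensus_results[seq.id]
            for i, aa in enumerate(seq.residues):
                handle.write(
                    f"{seq.id}\t{i + 1}\t{aa}\t{cons.votes[i]}"
                    f"\t{int(bool(cons.hits[i]))}\n"
                )
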