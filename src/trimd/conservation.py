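"""Alignment-based phospho-site presence scoring and S/T-P motif scanning.

Consumes a pre-built multiple alignment (aligned FASTA); no ortholog
retrieval or tree building happens here.  An optional clade-label table
(TSV: seq_id, clade) enables per-clade summaries, e.g. testing whether a
site is restricted to one clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd
from Bio import SeqIO

GAP = "-"


@dataclass
class AlignedSet:
    """Gapped sequences of equal length, keyed by unique ids (input order kept)."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows differ in length: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)


def read_alignment(path: Union[str, Path]) -> AlignedSet:
    """Read an aligned FASTA file."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return AlignedSet(sequences=seqs)


def map_reference_position(
    aln: AlignedSet, ref_id: str, ref_pos_unaligned: int
) -> int:
    """Alignment column (1-based) holding the reference's 1-based ungapped position."""
    if ref_id not in aln.sequences:
        raise KeyError(f"reference id {ref_id!r} not in alignment")
    if ref_pos_unaligned < 1:
        raise ValueError("positions are 1-based")
    row = aln.sequences[ref_id]
    count = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            count += 1
            if count == ref_pos_unaligned:
                return col
    raise ValueError(
        f"position {ref_pos_unaligned} beyond ungapped length {count} of {ref_id!r}"
    )


def site_presence(
    aln: AlignedSet, column: int, residue: str = "Y"
) -> tuple[dict[str, bool], float]:
    """Which sequences carry ``residue`` at an alignment column (1-based).

    Gaps count as absent.  Returns (per-sequence flags, conservation
    fraction = mean of the flags).
    """
    if not 1 <= column <= aln.length:
        raise ValueError(f"column {column} outside alignment length {aln.length}")
    residue = residue.upper()
    flags = {
        sid: seq[column - 1].upper() == residue for sid, seq in aln.sequences.items()
    }
    fraction = sum(flags.values()) / len(flags) if flags else 0.0
    return flags, fraction


def stp_motif_scan(sequence: str) -> list[int]:
    """1-based positions i with sequence[i] in {S, T} followed by P."""
    seq = sequence.upper().replace(GAP, "")
    return [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in ("S", "T") and seq[i + 1] == "P"
    ]


def presence_report(
    aln: AlignedSet,
    sites: dict[str, tuple[str, int, str]],
    clades: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate site presence across an alignment.

    ``sites`` maps a label (e.g. 'Y88') to (ref_id, ref_pos, residue).
    Output columns: seq_id, clade, site_label, residue_observed, present.
    """
    rows = []
    for label, (ref_id, ref_pos, residue) in sites.items():
        col = map_reference_position(aln, ref_id, ref_pos)
        flags, _ = site_presence(aln, col, residue)
        for sid, present in flags.items():
            rows.append(
                {
                    "seq_id": sid,
                    "clade": (clades or {}).get(sid, ""),
                    "site_label": label,
                    "residue_observed": aln.sequences[sid][col - 1],
                    "present": int(present),
                }
            )
    return pd.DataFrame(rows)


def read_clades(path: Union[str, Path]) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["seq_id"], df["clade"]))
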