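"""Per-contig GC and length statistics and whole-assembly summaries.

GC fraction is defined literally as the number of G or C bases divided by the
contig length, so ambiguous bases (N and other IUPAC codes) count in the
denominator only. Soft-masked (lowercase) bases count like their uppercase
forms: masking is an annotation, not composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Tuple

import pandas as pd
from Bio import SeqIO

from ._io import xopen
from .errors import FormatError

__all__ = ["AssemblySummary", "gc_fraction", "n50", "summarize_assembly"]

_GC = frozenset("GCgc")


@dataclass(frozen=True)
class AssemblySummary:
    n_contigs: int
    span: int
    mean_length: float
    n50: int

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"n_contigs\t{self.n_contigs}\n")
            fh.write(f"span\t{self.span}\n")
            fh.write(f"mean_length\t{self.mean_length:.1f}\n")
            fh.write(f"n50\t{self.n50}\n")


def gc_fraction(sequence: str) -> float:
    """Fraction of G/C bases over the full sequence length (N in denominator only)."""
    if not sequence:
        raise ValueError("gc_fraction of an empty sequence is undefined")
    return sum(1 for b in sequence if b in _GC) / len(sequence)


def n50(lengths: Iterable[int]) -> int:
    """Length L such that contigs of length >= L contain half the total span.

    Scanning from the largest contig down, returns the first length at which
    the cumulative span reaches half of the total; the result is always a
    member of the input.
    """
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValueError("n50 of an empty length set is undefined")
    half = sum(ls) / 2
    acc = 0
    for length in ls:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def summarize_assembly(fasta_path) -> Tuple[AssemblySummary, pd.DataFrame]:
    """Scan an assembly FASTA into a per-contig stats table plus a summary.

    Returns ``(summary, table)`` where the table has one row per contig with
    columns ``contig_id``, ``length``, ``gc_fraction``. Duplicate contig IDs
    are a format error because IDs key every downstream join.
    """
    ids, lengths, gcs = [], [], []
    seen = set()
    with xopen(fasta_path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate contig ID {rec.id!r} in {fasta_path}")
            seen.add(rec.id)
            seq = str(rec.seq)
            if not seq:
                raise FormatError(f"contig {rec.id!r} is empty")
            ids.append(rec.id)
            lengths.append(len(seq))
            gcs.append(gc_fraction(seq))
    if not ids:
        raise FormatError(f"no FASTA records in {fasta_path}")
    table = pd.DataFrame({"contig_id": ids, "length": lengths, "gc_fraction": gcs})
    span = int(table["length"].sum())
    summary = AssemblySummary(
        n_contigs=len(table),
        span=span,
        mean_length=span / len(table),
        n50=n50(lengths),
    )
    return summary, table
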