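"""Bin-directed read-pair extraction.

Once a contig bin has been chosen, every read pair with at least one mate
best-placed on a bin contig is pulled from the original FASTQ files, yielding
the enriched read set that feeds the stringent reassembly. Extraction is a
two-pass stream: pass 1 derives the selected pair-ID set from the placement
table, pass 2 filters the FASTQ files; memory scales with the selected set,
not the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Set, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._io import pair_id, xopen
from .errors import IntegrityError

__all__ = ["BinReadSet", "select_pairs", "write_pairs"]


@dataclass
class BinReadSet:
    """The set of read pairs attributed to a contig bin."""

    pair_ids: Set[str] = field(default_factory=set)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)


def select_pairs(
    placements: Mapping[Tuple[str, int], str],
    bin_contigs: Iterable[str],
) -> BinReadSet:
    """Pairs with >=1 mate whose best placement is a bin contig.

    Unmapped mates (absent from the placement table) never exclude a pair.
    """
    bins = set(bin_contigs)
    selected = {
        pair_id(read_id)
        for (read_id, _mate), contig in placements.items()
        if contig in bins
    }
    return BinReadSet(pair_ids=selected)


def write_pairs(
    selected: BinReadSet,
    in1,
    in2,
    out1,
    out2,
) -> Dict[str, int]:
    """Write both mates of each selected pair, preserving input order.

    Returns a manifest ``{"n_pairs": ..., "n_bases": ...}``. Every selected
    pair must occur in the input files, and mates must stay synchronized;
    otherwise an :class:`IntegrityError` is raised.
    """
    wanted = set(selected.pair_ids)
    found: Set[str] = set()
    n_pairs = 0
    n_bases = 0
    with xopen(in1, "rt") as f1, xopen(in2, "rt") as f2, \
            xopen(out1, "wt") as o1, xopen(out2, "wt") as o2:
        it2 = FastqGeneralIterator(f2)
        for title1, seq1, qual1 in FastqGeneralIterator(f1):
            rec2 = next(it2, None)
            if rec2 is None:
                raise IntegrityError("mate files desynchronized: file 2 is shorter")
            title2, seq2, qual2 = rec2
            pid = pair_id(title1)
            if pid != pair_id(title2):
                raise IntegrityError(f"mate ID mismatch: {title1!r} vs {title2!r}")
            if pid in wanted:
                found.add(pid)
                n_pairs += 1
                n_bases += len(seq1) + len(seq2)
                o1.write(f"@{title1}\n{seq1}\n+\n{qual1}\n")
                o2.write(f"@{title2}\n{seq2}\n+\n{qual2}\n")
    missing = wanted - found
    if missing:
        raise IntegrityError(
            f"{len(missing)} selected pairs absent from input, e.g. {sorted(missing)[:3]}"
        )
    return {"n_pairs": n_pairs, "n_bases": n_bases}
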