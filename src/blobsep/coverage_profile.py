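"""Per-contig read depth, best-placement tables and insert-size estimation.

Reads are aligned back to the preliminary assembly upstream (any SAM/BAM
producing mapper); this module post-processes the alignments:

* mean depth per contig — total aligned reference bases divided by contig
  length, which equals the mean of the per-base pileup under the SAM
  convention that only M/=/X operations cover reference bases;
* a (read, mate) -> best contig table ("mapped best" = highest alignment
  score, AS tag when present, mapping quality otherwise);
* a robust insert-size estimate (median and MAD of the outer distance of
  proper pairs) used to parameterize the stringent reassembly.

No sort order is assumed for the input alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pysam

from .errors import ConsistencyError, EstimationError

__all__ = [
    "InsertSizeEstimate",
    "mean_depth_per_contig",
    "best_placement_table",
    "estimate_insert_size",
    "write_depth_tsv",
    "write_placements_tsv",
]

# CIGAR operation codes that consume reference bases AND cover them (M, =, X).
_COVERING_OPS = (0, 7, 8)


@dataclass(frozen=True)
class InsertSizeEstimate:
    """Median/MAD summary of the outer-distance distribution of proper pairs."""

    median: float
    dispersion: float  # median absolute deviation, bases
    n_pairs_used: int

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"insert_median\t{self.median:.1f}\n")
            fh.write(f"insert_mad\t{self.dispersion:.1f}\n")
            fh.write(f"n_pairs_used\t{self.n_pairs_used}\n")


def _covering_ref_length(rec: "pysam.AlignedSegment") -> int:
    return sum(length for op, length in rec.cigartuples or () if op in _COVERING_OPS)


def _open(alignments):
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments, False
    return pysam.AlignmentFile(str(alignments), check_sq=False), True


def mean_depth_per_contig(
    alignments,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> Dict[str, float]:
    """Mean read depth per contig from primary alignments.

    ``contig_lengths`` defaults to the lengths in the SAM/BAM header; passing
    it explicitly also validates that every record maps to a known contig.
    Contigs with no alignments get depth 0.
    """
    af, close = _open(alignments)
    try:
        if contig_lengths is None:
            contig_lengths = dict(zip(af.references, af.lengths))
        aligned: Dict[str, int] = {}
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.reference_name
            if name not in contig_lengths:
                raise ConsistencyError(f"alignment references unknown contig {name!r}")
            aligned[name] = aligned.get(name, 0) + _covering_ref_length(rec)
    finally:
        if close:
            af.close()
    return {c: aligned.get(c, 0) / length for c, length in contig_lengths.items()}


def _score(rec: "pysam.AlignedSegment") -> float:
    try:
        return float(rec.get_tag("AS"))
    except KeyError:
        return float(rec.mapping_quality)


def best_placement_table(alignments) -> Dict[Tuple[str, int], str]:
    """Map every observed (read_id, mate_flag) to the contig of its best alignment.

    Primary alignments outrank secondary/supplementary ones regardless of
    score; within a rank the highest score wins and ties keep the first record
    encountered. Unmapped mates are absent from the map.
    """
    af, close = _open(alignments)
    best: Dict[Tuple[str, int], Tuple[int, float, str]] = {}
    try:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            mate = 2 if rec.is_read2 else 1
            key = (rec.query_name, mate)
            rank = (0 if (rec.is_secondary or rec.is_supplementary) else 1, _score(rec))
            cur = best.get(key)
            if cur is None or rank > cur[:2]:
                best[key] = (rank[0], rank[1], rec.reference_name)
    finally:
        if close:
            af.close()
    return {key: contig for key, (_, _, contig) in best.items()}


def estimate_insert_size(alignments) -> InsertSizeEstimate:
    """Median/MAD of outer distances over proper pairs.

    A proper pair has both mates primary-mapped to the same contig on opposite
    strands; its outer distance is rightmost end − leftmost start + 1. The
    even-count median is the mean of the two central values.
    """
    af, close = _open(alignments)
    ends: Dict[str, Tuple[str, int, int, bool]] = {}
    inserts = []
    try:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or not rec.is_paired:
                continue
            key = rec.query_name
            span = (rec.reference_name, rec.reference_start,
                    rec.reference_start + _covering_ref_length(rec), rec.is_reverse)
            other = ends.pop(key, None)
            if other is None:
                ends[key] = span
                continue
            if other[0] == span[0] and other[3] != span[3]:
                outer = max(other[2], span[2]) - min(other[1], span[1])
                inserts.append(outer)
    finally:
        if close:
            af.close()
    if not inserts:
        raise EstimationError("no proper pairs found; cannot estimate insert size")
    arr = np.asarray(inserts, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    return InsertSizeEstimate(median=med, dispersion=mad, n_pairs_used=len(arr))


def write_depth_tsv(depths: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tmean_depth\n")
        for contig, depth in depths.items():
            fh.write(f"{contig}\t{depth:.6g}\n")


def write_placements_tsv(placements: Mapping[Tuple[str, int], str], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmate\tcontig_id\n")
        for (read_id, mate), contig in placements.items():
            fh.write(f"{read_id}\t{mate}\t{contig}\n")


def read_placements_tsv(path) -> Dict[Tuple[str, int], str]:
    placements: Dict[Tuple[str, int], str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ConsistencyError(f"{path}: unexpected placements header")
        for line in fh:
            read_id, mate, contig = line.rstrip("\n").split("\t")
            placements[(read_id, int(mate))] = contig
    return placements
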