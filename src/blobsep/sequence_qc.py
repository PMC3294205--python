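"""Read quality control: 3'-end quality trimming and pair length filtering.

The preparation rules applied to raw Illumina paired-end data before the
preliminary assembly are deliberately simple and fully deterministic:

* every 3'-terminal base with a Phred quality below a floor (default 20) is
  removed — i.e. the maximal contiguous low-quality run at the 3' end is cut;
* a pair is discarded if either mate ends up shorter than a minimum length
  (default 35 bases);
* long-insert mate-pair reads are additionally hard-truncated to a fixed
  length (50 bases) after quality trimming, to reduce the chance of reading
  through a circularization junction into chimeric sequence.

Trimming is applied first and truncation second; the two rules are orthogonal,
so reads that become empty after trimming are kept as zero-length records and
removed only by the pair filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._io import pair_id, xopen
from .errors import MalformedRecordError, PairingError

__all__ = [
    "ReadRecord",
    "QcPolicy",
    "QcSummary",
    "trim_read",
    "filter_pair",
    "qc_pairs",
    "qc_stream",
]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with per-base Phred qualities.

    ``mate_flag`` is 1 or 2 for the first/second read of a pair.
    """

    read_id: str
    sequence: str
    qualities: Tuple[int, ...]
    mate_flag: int = 1

    def __post_init__(self):
        if not self.read_id:
            raise MalformedRecordError("read_id must be nonempty")
        if len(self.sequence) != len(self.qualities):
            raise MalformedRecordError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QcPolicy:
    """Quality-trimming and pair-filtering parameters.

    phred_floor:
        3'-terminal bases with quality strictly below this are trimmed.
    min_length_after_trim:
        pairs with either mate shorter than this (after trimming) are discarded.
    hard_trim_length:
        if set, reads are truncated to at most this many bases from the 5' end
        after quality trimming (mate-pair libraries use 50).
    phred_offset:
        ASCII offset of the FASTQ quality encoding (33 for modern files).
    """

    phred_floor: int = 20
    min_length_after_trim: int = 35
    hard_trim_length: Optional[int] = None
    phred_offset: int = 33

    def __post_init__(self):
        if self.phred_floor < 0:
            raise ValueError("phred_floor must be >= 0")
        if self.min_length_after_trim < 1:
            raise ValueError("min_length_after_trim must be >= 1")
        if self.hard_trim_length is not None and self.hard_trim_length < self.min_length_after_trim:
            raise ValueError("hard_trim_length must be >= min_length_after_trim")


@dataclass
class QcSummary:
    """Counts of reads/bases flowing through :func:`qc_stream`."""

    pairs_in: int = 0
    pairs_out: int = 0
    reads_in: int = 0
    reads_out: int = 0
    bases_in: int = 0
    bases_out: int = 0

    def as_rows(self) -> list:
        return [(k, getattr(self, k)) for k in
                ("pairs_in", "pairs_out", "reads_in", "reads_out", "bases_in", "bases_out")]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.as_rows():
                fh.write(f"{key}\t{value}\n")


def trim_read(read: ReadRecord, policy: QcPolicy) -> ReadRecord:
    """Remove the maximal 3'-terminal run of bases below the quality floor.

    If the policy carries a ``hard_trim_length``, the quality-trimmed read is
    then truncated to at most that many bases from the 5' end. The result may
    be empty; empty reads are eliminated later by :func:`filter_pair`.
    """
    quals = read.qualities
    end = len(quals)
    floor = policy.phred_floor
    while end > 0 and quals[end - 1] < floor:
        end -= 1
    if policy.hard_trim_length is not None:
        end = min(end, policy.hard_trim_length)
    if end == len(quals):
        return read
    return replace(read, sequence=read.sequence[:end], qualities=quals[:end])


def filter_pair(read1: ReadRecord, read2: ReadRecord, policy: QcPolicy) -> bool:
    """Keep a (trimmed) pair iff both mates reach the minimum length."""
    m = policy.min_length_after_trim
    return len(read1) >= m and len(read2) >= m


def qc_pairs(
    pairs: Iterable[Tuple[ReadRecord, ReadRecord]],
    policy: QcPolicy,
    summary: Optional[QcSummary] = None,
) -> Iterator[Tuple[ReadRecord, ReadRecord]]:
    """Trim and filter an in-memory stream of read pairs, updating *summary*."""
    for r1, r2 in pairs:
        if summary is not None:
            summary.pairs_in += 1
            summary.reads_in += 2
            summary.bases_in += len(r1) + len(r2)
        t1 = trim_read(r1, policy)
        t2 = trim_read(r2, policy)
        if filter_pair(t1, t2, policy):
            if summary is not None:
                summary.pairs_out += 1
                summary.reads_out += 2
                summary.bases_out += len(t1) + len(t2)
            yield t1, t2


def _read_fastq(path, mate_flag: int, offset: int) -> Iterator[ReadRecord]:
    with xopen(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield ReadRecord(
                read_id=title,
                sequence=seq,
                qualities=tuple(ord(c) - offset for c in qual),
                mate_flag=mate_flag,
            )


def _write_fastq_record(fh, read: ReadRecord, offset: int) -> None:
    qual = "".join(chr(q + offset) for q in read.qualities)
    fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def _paired_source(in1, in2, offset: int) -> Iterator[Tuple[ReadRecord, ReadRecord]]:
    it1 = _read_fastq(in1, 1, offset)
    it2 = _read_fastq(in2, 2, offset)
    for r1 in it1:
        r2 = next(it2, None)
        if r2 is None:
            raise PairingError(f"{in1} has more records than {in2}")
        if pair_id(r1.read_id) != pair_id(r2.read_id):
            raise PairingError(f"mate ID mismatch: {r1.read_id!r} vs {r2.read_id!r}")
        yield r1, r2
    if next(it2, None) is not None:
        raise PairingError(f"{in2} has more records than {in1}")


def _interleaved_source(path, offset: int) -> Iterator[Tuple[ReadRecord, ReadRecord]]:
    it = _read_fastq(path, 1, offset)
    for r1 in it:
        r2 = next(it, None)
        if r2 is None:
            raise PairingError(f"{path}: odd record count for interleaved input")
        if pair_id(r1.read_id) != pair_id(r2.read_id):
            raise PairingError(f"mate ID mismatch: {r1.read_id!r} vs {r2.read_id!r}")
        yield r1, replace(r2, mate_flag=2)


def qc_stream(
    in1,
    in2,
    out1,
    out2,
    policy: QcPolicy = QcPolicy(),
    *,
    interleaved: bool = False,
) -> QcSummary:
    """Apply trim + pair-filter to FASTQ files and write the surviving pairs.

    With ``interleaved=True``, *in1* and *out1* are used as the single
    interleaved input/output and *in2*/*out2* are ignored.
    """
    summary = QcSummary()
    offset = policy.phred_offset
    if interleaved:
        source = _interleaved_source(in1, offset)
        with xopen(out1, "wt") as o:
            for t1, t2 in qc_pairs(source, policy, summary):
                _write_fastq_record(o, t1, offset)
                _write_fastq_record(o, t2, offset)
    else:
        source = _paired_source(in1, in2, offset)
        with xopen(out1, "wt") as o1, xopen(out2, "wt") as o2:
            for t1, t2 in qc_pairs(source, policy, summary):
                _write_fastq_record(o1, t1, offset)
                _write_fastq_record(o2, t2, offset)
    return summary
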