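"""Shared test utilities: minimal SAM construction and naive oracles."""

from typing import Dict, List, Optional, Tuple


def write_sam(path, contig_lengths: Dict[str, int], records: List[dict]) -> str:
    """Write a SAM file from plain record dicts.

    Record keys: qname, flag, rname, pos (1-based), cigar; optional mapq,
    rnext, pnext, tlen, seq, tags (list of strings).
    """
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in contig_lengths.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for rec in records:
        seq = rec.get("seq", "*")
        qual = "*" if seq == "*" else "I" * len(seq)
        fields = [
            rec["qname"], str(rec["flag"]), rec["rname"], str(rec["pos"]),
            str(rec.get("mapq", 60)), rec["cigar"], rec.get("rnext", "*"),
            str(rec.get("pnext", 0)), str(rec.get("tlen", 0)), seq, qual,
        ] + list(rec.get("tags", []))
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)


def parse_cigar(cigar: str) -> List[Tuple[str, int]]:
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def pileup_depths(
    contig_lengths: Dict[str, int], records: List[dict]
) -> Dict[str, float]:
    """Independent per-base pileup oracle over plain record dicts.

    Walks each primary mapped record's CIGAR, incrementing a depth array for
    reference positions covered by M/=/X, then averages over the contig.
    """
    arrays = {name: [0] * length for name, length in contig_lengths.items()}
    for rec in records:
        flag = rec["flag"]
        if flag & 0x4 or flag & 0x100 or flag & 0x800:
            continue
        pos = rec["pos"] - 1
        arr = arrays[rec["rname"]]
        for op, length in parse_cigar(rec["cigar"]):
            if op in "M=X":
                for i in range(pos, pos + length):
                    arr[i] += 1
                pos += length
            elif op in "DN":
                pos += length
            # I/S/H/P consume no reference
    return {name: sum(arr) / len(arr) for name, arr in arrays.items()}


def naive_qc_pair(
    seq1: str, quals1: List[int], seq2: str, quals2: List[int],
    floor: int, min_len: int, hard: Optional[int] = None,
) -> Optional[Tuple[str, List[int], str, List[int]]]:
    """Record-at-a-time re-implementation of trim + pair filter."""

    def trim(seq, quals):
        end = len(quals)
        while end > 0 and quals[end - 1] < floor:
            end -= 1
        if hard is not None:
            end = min(end, hard)
        return seq[:end], quals[:end]

    s1, q1 = trim(seq1, quals1)
    s2, q2 = trim(seq2, quals2)
    if len(s1) >= min_len and len(s2) >= min_len:
        return s1, q1, s2, q2
    return None
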