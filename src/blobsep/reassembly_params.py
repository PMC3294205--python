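"""Parameter derivation for the stringent coverage-aware reassembly.

De Bruijn assemblers such as Velvet are parameterized in k-mer coverage
rather than read coverage; the two are linearly related,

    C_k = C * (L - k + 1) / L

for read length L and word size k. This module converts the binned contigs'
read depth into an expected k-mer coverage, proposes a minimum k-mer coverage
cutoff by locating the valley between the low-depth noise mode and the main
coverage mode of the bin's depth histogram (automating the manual
histogram-inspection step), and bundles these with the insert-size estimate
and a k-mer scan range into a report for the external assembler run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .coverage_profile import InsertSizeEstimate

__all__ = [
    "ReassemblyReport",
    "kmer_coverage",
    "suggest_min_kmer_coverage",
    "build_report",
]

#: default k-mer scan range handed to the assembler optimizer
DEFAULT_KMER_RANGE = (41, 63)


@dataclass(frozen=True)
class ReassemblyReport:
    kmer_range: Tuple[int, int]
    read_length: int
    read_coverage: float
    expected_kmer_coverage: float
    min_kmer_coverage_suggestion: float
    insert_median: float
    insert_mad: float
    n_bin_contigs: int

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def kmer_coverage(read_coverage: float, read_length: int, k: int) -> float:
    """Convert read coverage to k-mer coverage: C * (L - k + 1) / L."""
    if not 1 <= k <= read_length:
        raise ValueError(f"k={k} outside [1, read_length={read_length}]")
    return read_coverage * (read_length - k + 1) / read_length


def suggest_min_kmer_coverage(depths: Sequence[float], expected: float) -> float:
    """Valley-point minimum-coverage cutoff from a depth distribution.

    Histograms the depths, takes the dominant bin at or above half the
    expected coverage as the main mode and the dominant bin below it as the
    noise mode, and returns the centre of the emptiest bin strictly between
    the two. Falls back to ``expected / 2`` when the distribution has no such
    interior minimum (unimodal bins, or nothing below the main mode). The
    suggestion is always below ``expected``.
    """
    arr = np.asarray(list(depths), dtype=float)
    if arr.size == 0:
        raise ValueError("empty depth distribution")
    if expected <= 0:
        raise ValueError("expected coverage must be > 0")
    fallback = expected / 2
    counts, edges = np.histogram(arr, bins=64, range=(0.0, 1.2 * expected))
    centres = (edges[:-1] + edges[1:]) / 2
    high = np.flatnonzero((centres >= expected / 2) & (counts > 0))
    if high.size == 0:
        return fallback
    main = high[np.argmax(counts[high])]
    low = np.flatnonzero((np.arange(len(counts)) < main)
                         & (centres < expected / 2) & (counts > 0))
    if low.size == 0:
        return fallback
    noise = low[np.argmax(counts[low])]
    interior = np.arange(noise + 1, main)
    if interior.size == 0:
        return fallback
    valley = interior[np.argmin(counts[interior])]
    return float(min(centres[valley], expected * 0.999))


def _clip_odd(value: int, read_length: int) -> int:
    value = min(value, read_length)
    if value % 2 == 0:
        value -= 1
    return value


def build_report(
    bin_stats: pd.DataFrame,
    insert: InsertSizeEstimate,
    read_length: int,
    kmer_range: Tuple[int, int] = DEFAULT_KMER_RANGE,
) -> ReassemblyReport:
    """Assemble the reassembly parameter report for a contig bin.

    *bin_stats* needs a ``mean_depth`` column for the bin members. The read
    coverage of the bin is its median contig depth (robust to repeat
    contigs); the expected k-mer coverage is computed at the top of the scan
    range, the k the optimizer tends to select at high coverage. The scan
    range is clipped to the read length and forced odd.
    """
    if bin_stats.empty:
        raise ValueError("empty bin: no contigs to derive parameters from")
    low, high = kmer_range
    low, high = _clip_odd(low, read_length), _clip_odd(high, read_length)
    low = min(low, high)
    read_cov = float(np.median(bin_stats["mean_depth"]))
    expected = kmer_coverage(read_cov, read_length, high)
    kmer_depths = [kmer_coverage(d, read_length, high) for d in bin_stats["mean_depth"]]
    suggestion = suggest_min_kmer_coverage(kmer_depths, expected)
    return ReassemblyReport(
        kmer_range=(low, high),
        read_length=read_length,
        read_coverage=read_cov,
        expected_kmer_coverage=expected,
        min_kmer_coverage_suggestion=suggestion,
        insert_median=insert.median,
        insert_mad=insert.dispersion,
        n_bin_contigs=len(bin_stats),
    )
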