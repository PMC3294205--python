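"""Rule-based contig binning from two taxon-restricted similarity searches.

The assembly is BLASTed against a target-restricted database (e.g. the
symbiont's class) and one or more counter-restricted databases (e.g. the
host's phylum, a suspected contaminant genome). Each contig is classified
from its best bit score on each side:

* scores below a floor (default 50 bits) are treated as absent;
* both sides absent            -> NEITHER
* only one side present        -> that side's label (TARGET or COUNTER)
* both present, |diff| >= margin (default 50 bits) -> the stronger side
* both present, |diff| <  margin                   -> BOTH

The final target bin keeps every TARGET contig plus those BOTH/NEITHER contigs
whose mean depth reaches a coverage floor chosen from the target cluster's
depth (250x in a sample whose symbiont cluster sits above 1000x); COUNTER
contigs are never binned. A symmetric host-side bin (COUNTER plus the
low-coverage BOTH/NEITHER remainder) is emitted from the same run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .taxonomy_annotation import BlastHit

__all__ = [
    "BinLabel",
    "BinPolicy",
    "classify_contig",
    "best_scores",
    "assign_bins",
    "suggest_coverage_floor",
    "exhaustive_rule_check",
]


class BinLabel(str, Enum):
    TARGET = "TARGET"
    COUNTER = "COUNTER"
    BOTH = "BOTH"
    NEITHER = "NEITHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class BinPolicy:
    """Parameters of the four-way classification and final bin filter.

    The 50-bit number plays two distinct roles that are kept independently
    configurable: a floor below which a best hit counts as no hit at all
    (``min_bitscore``) and a margin by which one side must beat the other to
    win an ambiguous contig (``bitscore_margin``).
    """

    evalue_cutoff: float = 1e-5
    bitscore_margin: float = 50.0
    min_bitscore: float = 50.0
    coverage_floor_for_ambiguous: float = 250.0
    target_label: str = "target"
    counter_label: str = "counter"

    def __post_init__(self):
        if self.bitscore_margin < 0:
            raise ValueError("bitscore_margin must be >= 0")
        if self.coverage_floor_for_ambiguous < 0:
            raise ValueError("coverage_floor_for_ambiguous must be >= 0")


def classify_contig(
    best_target: Optional[float],
    best_counter: Optional[float],
    policy: BinPolicy,
) -> BinLabel:
    """Four-way label from the best bit score against each database."""
    t = best_target if (best_target is not None and best_target >= policy.min_bitscore) else None
    c = best_counter if (best_counter is not None and best_counter >= policy.min_bitscore) else None
    if t is None and c is None:
        return BinLabel.NEITHER
    if c is None:
        return BinLabel.TARGET
    if t is None:
        return BinLabel.COUNTER
    if abs(t - c) >= policy.bitscore_margin and t != c:
        return BinLabel.TARGET if t > c else BinLabel.COUNTER
    return BinLabel.BOTH


def best_scores(hits: Iterable[BlastHit], evalue_cutoff: float) -> Dict[str, float]:
    """Best bit score per query among hits passing the E-value cutoff."""
    best: Dict[str, float] = {}
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        if hit.query_id not in best or hit.bitscore > best[hit.query_id]:
            best[hit.query_id] = hit.bitscore
    return best


def assign_bins(
    stats: pd.DataFrame,
    target_hits: Iterable[BlastHit],
    counter_hits,
    policy: BinPolicy,
) -> pd.DataFrame:
    """Classify every contig and apply the coverage filter for the final bins.

    *stats* needs columns ``contig_id`` and ``mean_depth``. ``counter_hits``
    may be a single hit iterable or a sequence of them (multiple contaminant
    databases); the per-contig maximum across all counter sources is used, the
    conservative generalization. Returns one row per contig with the label,
    the best score on each side, the ``final_bin_member`` flag for the target
    bin and the symmetric ``host_bin_member`` flag.
    """
    contig_ids = list(stats["contig_id"])
    known = set(contig_ids)
    t_best = best_scores(target_hits, policy.evalue_cutoff)
    # counter_hits: one hit iterable, or a list/tuple of them (multiple databases)
    if counter_hits is None:
        sources = []
    elif isinstance(counter_hits, (list, tuple)):
        if counter_hits and isinstance(counter_hits[0], BlastHit):
            sources = [counter_hits]
        else:
            sources = list(counter_hits)
    else:
        sources = [counter_hits]
    c_best: Dict[str, float] = {}
    for source in sources:
        for cid, score in best_scores(source, policy.evalue_cutoff).items():
            if score > c_best.get(cid, -math.inf):
                c_best[cid] = score
    for cid in set(t_best) | set(c_best):
        if cid not in known:
            raise ConsistencyError(f"hit references unknown contig {cid!r}")

    depths = dict(zip(stats["contig_id"], stats["mean_depth"]))
    floor = policy.coverage_floor_for_ambiguous
    rows = []
    for cid in contig_ids:
        bt = t_best.get(cid)
        bc = c_best.get(cid)
        label = classify_contig(bt, bc, policy)
        depth = depths[cid]
        ambiguous = label in (BinLabel.BOTH, BinLabel.NEITHER)
        in_bin = label is BinLabel.TARGET or (ambiguous and depth >= floor)
        in_host = label is BinLabel.COUNTER or (ambiguous and depth < floor)
        if label is BinLabel.TARGET:
            reason = "target-hit"
        elif label is BinLabel.COUNTER:
            reason = "counter-hit"
        elif in_bin:
            reason = f"{label.value.lower()}-depth>={floor:g}"
        else:
            reason = f"{label.value.lower()}-depth<{floor:g}"
        rows.append((cid, label.value, bt, bc, depth, in_bin, in_host, reason))
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id", "label", "best_target_bitscore", "best_counter_bitscore",
            "mean_depth", "final_bin_member", "host_bin_member", "reason",
        ],
    )


def suggest_coverage_floor(target_depths: Sequence[float], fraction: float = 0.25) -> float:
    """Suggest a coverage floor as a fraction of the target cluster's median depth.

    With the default 0.25, a target cluster sitting above 1000x suggests a
    floor near 250x. The suggestion is advisory; the floor is always an
    explicit policy parameter.
    """
    arr = np.asarray(list(target_depths), dtype=float)
    if arr.size == 0:
        raise ValueError("no target-labeled contigs to suggest a floor from")
    return float(fraction * np.median(arr))


def exhaustive_rule_check(
    scores: Sequence[Optional[float]],
    policy: BinPolicy,
) -> Dict[Tuple[Optional[float], Optional[float]], str]:
    """Classify every (target, counter) pair over a score lattice.

    Self-test helper: the returned truth table can be compared against an
    independently written oracle to verify the four-branch rule exhaustively.
    """
    return {
        (t, c): classify_contig(t, c, policy).value
        for t in scores
        for c in scores
    }
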