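"""Taxonomic annotation of contigs from BLAST tabular hits.

A random subsample of contigs (10,000 in a typical run) is searched against a
nucleotide database upstream; this module parses the tabular hits, resolves
each contig's best hit (maximum bit score, E-value as tie-break) to a taxon at
a chosen rank via an NCBI-taxdump-style table, and emits an annotation table.
Contigs whose hits all fail the E-value cutoff are labelled ``no-hit``; hits
whose taxid cannot be walked to the requested rank are ``unresolved``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence

import pandas as pd

from .errors import FormatError, UnknownTaxidError

__all__ = [
    "BlastHit",
    "TaxonomyTable",
    "NO_HIT",
    "UNRESOLVED",
    "subsample_contigs",
    "read_blast_tsv",
    "annotate_contigs",
]

NO_HIT = "no-hit"
UNRESOLVED = "unresolved"

#: default column order of the tabular hit files this package reads/writes
DEFAULT_COLUMNS = ("qseqid", "sseqid", "evalue", "bitscore", "staxid")


@dataclass(frozen=True)
class BlastHit:
    """One similarity hit of a contig against a database subject."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    subject_taxid: int


class TaxonomyTable:
    """A rooted taxonomy: parent links, rank names and scientific names.

    Built from taxdump-dialect ``nodes.dmp``/``names.dmp`` tables (fields
    separated by ``\\t|\\t``). An optional merged-taxid remap table handles
    retired IDs; taxids that resolve through neither table raise
    :class:`UnknownTaxidError`.
    """

    def __init__(
        self,
        parent: Mapping[int, int],
        rank: Mapping[int, str],
        name: Mapping[int, str],
        merged: Optional[Mapping[int, int]] = None,
    ):
        self.parent = dict(parent)
        self.rank = dict(rank)
        self.name = dict(name)
        self.merged = dict(merged or {})

    @classmethod
    def from_taxdump(cls, nodes_path, names_path, merged_path=None) -> "TaxonomyTable":
        parent: Dict[int, int] = {}
        rank: Dict[int, str] = {}
        with open(nodes_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
                if len(fields) < 3:
                    raise FormatError(f"{nodes_path}: malformed nodes line {line!r}")
                taxid, par, rk = int(fields[0]), int(fields[1]), fields[2]
                parent[taxid] = par
                rank[taxid] = rk
        name: Dict[int, str] = {}
        with open(names_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
                if len(fields) >= 4 and fields[3] != "scientific name":
                    continue
                name[int(fields[0])] = fields[1]
        merged: Dict[int, int] = {}
        if merged_path is not None:
            with open(merged_path) as fh:
                for line in fh:
                    fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
                    merged[int(fields[0])] = int(fields[1])
        return cls(parent, rank, name, merged)

    @classmethod
    def from_dir(cls, taxdump_dir) -> "TaxonomyTable":
        d = Path(taxdump_dir)
        merged = d / "merged.dmp"
        return cls.from_taxdump(
            d / "nodes.dmp", d / "names.dmp", merged if merged.exists() else None
        )

    def resolve(self, taxid: int) -> int:
        """Apply the merged-taxid remap; error if the result is unknown."""
        taxid = self.merged.get(taxid, taxid)
        if taxid not in self.parent:
            raise UnknownTaxidError(f"taxid {taxid} not in taxonomy table")
        return taxid

    def lineage_at_rank(self, taxid: int, rank: str) -> str:
        """Scientific name of the first ancestor (inclusive) at *rank*.

        Walks parent links to the root; returns :data:`UNRESOLVED` if no
        ancestor carries the requested rank.
        """
        node = self.resolve(taxid)
        seen = set()
        while node not in seen:
            seen.add(node)
            if self.rank.get(node) == rank:
                return self.name.get(node, str(node))
            par = self.parent[node]
            if par == node:  # root links to itself in taxdump
                break
            node = par
        return UNRESOLVED


def subsample_contigs(contig_ids: Sequence[str], n: int, seed: int) -> List[str]:
    """Uniform sample of min(n, population) distinct IDs, reproducible by seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    ids = list(contig_ids)
    k = min(n, len(ids))
    return random.Random(seed).sample(ids, k)


def read_blast_tsv(
    path,
    columns: Sequence[str] = DEFAULT_COLUMNS,
    taxid_map: Optional[Mapping[str, int]] = None,
) -> Iterator[BlastHit]:
    """Parse a tabular hit file with a configurable column layout.

    ``columns`` names the file's columns; ``qseqid``, ``evalue`` and
    ``bitscore`` are required. If the file lacks a ``staxid`` column, a
    ``taxid_map`` from subject accession to taxid must be supplied (older
    tabular dialects). Malformed rows are skipped.
    """
    idx = {name: i for i, name in enumerate(columns)}
    for req in ("qseqid", "evalue", "bitscore"):
        if req not in idx:
            raise FormatError(f"hit file columns must include {req!r}")
    if "staxid" not in idx and taxid_map is None:
        raise FormatError("no staxid column and no accession->taxid map supplied")
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                qid = fields[idx["qseqid"]]
                sid = fields[idx["sseqid"]] if "sseqid" in idx else ""
                if "staxid" in idx:
                    taxid = int(fields[idx["staxid"]])
                else:
                    taxid = taxid_map[sid]
                yield BlastHit(
                    query_id=qid,
                    subject_id=sid,
                    evalue=float(fields[idx["evalue"]]),
                    bitscore=float(fields[idx["bitscore"]]),
                    subject_taxid=taxid,
                )
            except (IndexError, ValueError, KeyError):
                continue


def annotate_contigs(
    hits: Iterable[BlastHit],
    rank: str,
    evalue_cutoff: float,
    taxonomy: TaxonomyTable,
    contig_ids: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Best-hit taxon annotation at *rank* for every contig.

    Hits with ``evalue > evalue_cutoff`` are discarded; among the survivors of
    each contig the maximal bit score wins (ties: lower E-value, then first
    encountered). ``contig_ids``, when given, defines the annotation universe
    (e.g. the BLASTed subsample) so contigs without surviving hits appear as
    ``no-hit`` rows. Returns columns ``contig_id``, ``taxon_label``,
    ``supporting_bitscore``.
    """
    best: Dict[str, BlastHit] = {}
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        cur = best.get(hit.query_id)
        if cur is None or (hit.bitscore, -hit.evalue) > (cur.bitscore, -cur.evalue):
            best[hit.query_id] = hit
    universe = list(contig_ids) if contig_ids is not None else list(best)
    rows = []
    for cid in universe:
        hit = best.get(cid)
        if hit is None:
            rows.append((cid, NO_HIT, float("nan")))
            continue
        try:
            label = taxonomy.lineage_at_rank(hit.subject_taxid, rank)
        except UnknownTaxidError:
            label = UNRESOLVED
        rows.append((cid, label, hit.bitscore))
    return pd.DataFrame(rows, columns=["contig_id", "taxon_label", "supporting_bitscore"])
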