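"""Fully labelled synthetic host+symbiont sequencing mixtures.

Generates everything the separation pipeline consumes — genomes, contigs,
paired reads, read-to-contig alignments, mock similarity hits and a toy
taxonomy — together with complete ground truth, so every stage can be tested
end-to-end without external data or tools.

The default two-genome preset emulates the situation that motivates the
method: a nematode-like host genome at moderate depth and low GC, and an
intracellular-symbiont-like genome at much higher depth (>6x the host's) with
a GC range overlapping the host's, so depth separates the genomes where base
composition cannot. A multi-contaminant preset adds several bacterial genomes
from distinct orders at assorted depths and GC values.

Reads are emitted error-free at uniform quality by default (sequencing errors
are irrelevant to the binning logic under test); an optional uniform
substitution rate supports robustness checks. Scale defaults are reduced
relative to a real project but preserve the depth ratios and composition
overlaps that make the problem hard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._io import xopen
from .taxonomy_annotation import TaxonomyTable

__all__ = [
    "GenomeSpec",
    "MixtureSpec",
    "FixtureBundle",
    "TOY_TAXONOMY_NODES",
    "toy_taxonomy",
    "write_taxdump",
    "simulate_genome",
    "fragment_to_contigs",
    "simulate_reads",
    "mock_blast_hits",
    "build_fixture",
    "fig2_spec",
    "fig3_spec",
    "build_fig2_fixture",
    "build_fig3_fixture",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

# Fixed 3-level toy taxonomy (superkingdom -> class -> order, plus one species
# leaf per order): (taxid, parent, rank, scientific name).
TOY_TAXONOMY_NODES: Tuple[Tuple[int, int, str, str], ...] = (
    (1, 1, "no rank", "root"),
    (2, 1, "superkingdom", "Bacteria"),
    (3, 1, "superkingdom", "Eukaryota"),
    (10, 2, "class", "Alphaproteobacteria"),
    (11, 2, "class", "Gammaproteobacteria"),
    (12, 2, "class", "Bacilli"),
    (13, 3, "class", "Chromadorea"),
    (20, 10, "order", "Rickettsiales"),
    (21, 10, "order", "Rhodospirillales"),
    (22, 10, "order", "Rhizobiales"),
    (23, 11, "order", "Enterobacterales"),
    (24, 11, "order", "Pseudomonadales"),
    (25, 12, "order", "Bacillales"),
    (26, 12, "order", "Lactobacillales"),
    (27, 13, "order", "Spirurida"),
    (28, 13, "order", "Rhabditida"),
) + tuple(
    (100 + oid, oid, "species", f"{name} sp.")
    for oid, name in (
        (20, "Rickettsiales"), (21, "Rhodospirillales"), (22, "Rhizobiales"),
        (23, "Enterobacterales"), (24, "Pseudomonadales"), (25, "Bacillales"),
        (26, "Lactobacillales"), (27, "Spirurida"), (28, "Rhabditida"),
    )
)

_ORDER_TAXID = {name: taxid for taxid, _, rank, name in TOY_TAXONOMY_NODES if rank == "order"}
_SPECIES_OF_ORDER = {oid: 100 + oid for oid in _ORDER_TAXID.values()}


def toy_taxonomy() -> TaxonomyTable:
    parent = {t: p for t, p, _, _ in TOY_TAXONOMY_NODES}
    rank = {t: r for t, _, r, _ in TOY_TAXONOMY_NODES}
    name = {t: n for t, _, _, n in TOY_TAXONOMY_NODES}
    return TaxonomyTable(parent, rank, name)


def write_taxdump(outdir) -> Path:
    """Write the toy taxonomy as taxdump-dialect nodes.dmp/names.dmp."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "nodes.dmp", "w") as fh:
        for taxid, parent, rank, _ in TOY_TAXONOMY_NODES:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(outdir / "names.dmp", "w") as fh:
        for taxid, _, _, name in TOY_TAXONOMY_NODES:
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
    return outdir


@dataclass(frozen=True)
class GenomeSpec:
    """One genome of the mixture: composition, depth and taxonomic origin."""

    label: str
    genome_length: int
    gc_target: float
    read_coverage: float
    order: str  # order name in the toy taxonomy

    def __post_init__(self):
        if not 0 < self.gc_target < 1 and self.gc_target != 1.0:
            raise ValueError("gc_target must be in (0, 1]")
        if self.read_coverage <= 0:
            raise ValueError("read_coverage must be > 0")
        if self.order not in _ORDER_TAXID:
            raise ValueError(f"unknown toy-taxonomy order {self.order!r}")


@dataclass(frozen=True)
class MixtureSpec:
    """Study conditions of a simulated mixture."""

    genomes: Tuple[GenomeSpec, ...]
    read_length: int = 100
    insert_mean: float = 340.0
    insert_sd: float = 30.0
    contig_mean_length: int = 2000
    contig_min_length: int = 200
    hit_accuracy: float = 0.95
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.hit_accuracy <= 1:
            raise ValueError("hit_accuracy must be in [0, 1]")
        if self.contig_min_length < 200:
            raise ValueError("contig_min_length must be >= 200")


def simulate_genome(length: int, gc_target: float, seed) -> str:
    """Random genome with i.i.d. bases, P(G)+P(C)=gc_target split evenly."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half_gc = gc_target / 2
    half_at = (1 - gc_target) / 2
    idx = rng.choice(4, size=length, p=[half_gc, half_gc, half_at, half_at])
    return np.frombuffer(b"GCAT", dtype="S1")[idx].tobytes().decode()


@dataclass(frozen=True)
class ContigTruth:
    contig_id: str
    label: str
    genome_start: int  # 0-based within its genome of origin
    length: int


def fragment_to_contigs(
    genome: str,
    label: str,
    seed,
    mean_length: int = 2000,
    min_length: int = 200,
) -> List[Tuple[ContigTruth, str]]:
    """Tile a genome into non-overlapping contigs with noisy lengths.

    Lengths are drawn around *mean_length* (normal, sd = mean/3) and clipped
    to at least *min_length*; a short terminal remainder is absorbed into the
    last contig. Stands in for a preliminary single-end assembly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: List[Tuple[ContigTruth, str]] = []
    pos, i = 0, 0
    n = len(genome)
    while pos < n:
        length = max(min_length, int(rng.normal(mean_length, mean_length / 3)))
        if n - (pos + length) < min_length:
            length = n - pos  # absorb the tail
        truth = ContigTruth(f"{label}_c{i:05d}", label, pos, length)
        out.append((truth, genome[pos:pos + length]))
        pos += length
        i += 1
    return out


@dataclass(frozen=True)
class SimPair:
    pair_id: str
    label: str
    fragment_start: int  # 0-based within the genome of origin
    insert: int


def simulate_reads(
    genome: str,
    coverage: float,
    read_length: int,
    insert_mean: float,
    insert_sd: float,
    seed,
    *,
    label: str = "g",
    error_rate: float = 0.0,
) -> Tuple[List[SimPair], List[Tuple[str, str]], List[Tuple[str, str]]]:
    """Uniform paired-end fragments from one genome.

    Pair count is ``round(coverage * genome_length / (2 * read_length))``;
    fragment starts are uniform, the second mate is the reverse complement of
    the fragment end. Returns ``(truth, mate1, mate2)`` where mate lists hold
    ``(read_id, sequence)`` tuples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(genome)
    if n <= insert_mean:
        raise ValueError("genome must be longer than the mean insert")
    n_pairs = round(coverage * n / (2 * read_length))
    inserts = np.clip(
        np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)), read_length, n
    ).astype(int)
    starts = (rng.random(n_pairs) * (n - inserts + 1)).astype(int)
    truth: List[SimPair] = []
    mate1: List[Tuple[str, str]] = []
    mate2: List[Tuple[str, str]] = []
    for i in range(n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        pid = f"{label}_r{i:07d}"
        seq1 = genome[s:s + read_length]
        seq2 = genome[s + ins - read_length:s + ins].translate(_COMP)[::-1]
        truth.append(SimPair(pid, label, s, ins))
        mate1.append((pid, seq1))
        mate2.append((pid, seq2))
    if error_rate > 0:
        mate1 = [(pid, _mutate(seq, error_rate, rng)) for pid, seq in mate1]
        mate2 = [(pid, _mutate(seq, error_rate, rng)) for pid, seq in mate2]
    return truth, mate1, mate2


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    if hit.size:
        subs = np.frombuffer(b"ACGT", dtype="S1")[rng.integers(0, 4, size=hit.size)]
        arr[hit] = subs
    return arr.tobytes().decode()


def _locate(offsets: np.ndarray, contigs: Sequence[ContigTruth], start: int, end: int) -> Optional[int]:
    """Index of the contig fully containing [start, end), or None."""
    i = int(np.searchsorted(offsets, start, side="right")) - 1
    if i < 0:
        return None
    c = contigs[i]
    if start >= c.genome_start and end <= c.genome_start + c.length:
        return i
    return None


def _sam_records_for_genome(
    pairs: Sequence[SimPair],
    mate1: Sequence[Tuple[str, str]],
    mate2: Sequence[Tuple[str, str]],
    contigs: Sequence[ContigTruth],
    read_length: int,
) -> List[str]:
    """True alignment records (SAM lines) for reads fully inside one contig.

    Reads spanning a contig junction are unmapped (the preliminary assembly
    fragmented the genome there) and get no record.
    """
    offsets = np.array([c.genome_start for c in contigs])
    lines: List[str] = []
    qual = "I" * read_length
    for pair, (pid, seq1), (_, seq2) in zip(pairs, mate1, mate2):
        s1, e1 = pair.fragment_start, pair.fragment_start + read_length
        s2, e2 = pair.fragment_start + pair.insert - read_length, pair.fragment_start + pair.insert
        i1 = _locate(offsets, contigs, s1, e1)
        i2 = _locate(offsets, contigs, s2, e2)
        cigar = f"{read_length}M"
        if i1 is not None and i2 is not None:
            c1, c2 = contigs[i1], contigs[i2]
            p1, p2 = s1 - c1.genome_start + 1, s2 - c2.genome_start + 1
            if i1 == i2:
                flags, rn1, rn2, tlen = (99, 147), "=", "=", pair.insert
                lines.append(f"{pid}\t99\t{c1.contig_id}\t{p1}\t60\t{cigar}\t=\t{p2}\t{tlen}\t{seq1}\t{qual}\tAS:i:{read_length}")
                lines.append(f"{pid}\t147\t{c2.contig_id}\t{p2}\t60\t{cigar}\t=\t{p1}\t{-tlen}\t{seq2}\t{qual}\tAS:i:{read_length}")
            else:
                lines.append(f"{pid}\t97\t{c1.contig_id}\t{p1}\t60\t{cigar}\t{c2.contig_id}\t{p2}\t0\t{seq1}\t{qual}\tAS:i:{read_length}")
                lines.append(f"{pid}\t145\t{c2.contig_id}\t{p2}\t60\t{cigar}\t{c1.contig_id}\t{p1}\t0\t{seq2}\t{qual}\tAS:i:{read_length}")
        elif i1 is not None:
            c1 = contigs[i1]
            p1 = s1 - c1.genome_start + 1
            lines.append(f"{pid}\t73\t{c1.contig_id}\t{p1}\t60\t{cigar}\t*\t0\t0\t{seq1}\t{qual}\tAS:i:{read_length}")
        elif i2 is not None:
            c2 = contigs[i2]
            p2 = s2 - c2.genome_start + 1
            lines.append(f"{pid}\t153\t{c2.contig_id}\t{p2}\t60\t{cigar}\t*\t0\t0\t{seq2}\t{qual}\tAS:i:{read_length}")
    return lines


def _strong_bitscore(length: int, rng: np.random.Generator) -> float:
    return round(1.8 * min(length, 2000) + rng.normal(0, 10), 1)


def _weak_bitscore(rng: np.random.Generator) -> float:
    return round(rng.uniform(25, 80), 1)


def mock_blast_hits(
    contig_truth: Sequence[ContigTruth],
    genome_orders: Dict[str, str],
    hit_accuracy: float,
    seed,
    *,
    target_labels: Sequence[str],
    counter_labels: Sequence[str],
) -> Dict[str, List[Tuple[str, str, float, float, int]]]:
    """Fabricate tabular similarity hits for the annotation and binning steps.

    Returns hit-row lists (qseqid, sseqid, evalue, bitscore, staxid) for three
    databases: ``all`` emulates a search of the full nucleotide database (true
    taxon with probability *hit_accuracy*, else a decoy order or no hit),
    while ``target`` and ``counter`` emulate taxon-restricted databases —
    contigs of the matching genomes hit strongly with probability
    *hit_accuracy*; other contigs pick up a weak spurious hit with probability
    1 − *hit_accuracy*.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_orders = sorted(_ORDER_TAXID)
    dbs: Dict[str, List[Tuple[str, str, float, float, int]]] = {"all": [], "target": [], "counter": []}
    target_set, counter_set = set(target_labels), set(counter_labels)
    # a spurious hit in a taxon-restricted database must carry a subject from
    # that database's clade, not the contig's own
    db_rep_order = {
        "target": genome_orders[sorted(target_set)[0]] if target_set else all_orders[0],
        "counter": genome_orders[sorted(counter_set)[0]] if counter_set else all_orders[0],
    }
    for contig in contig_truth:
        true_order = genome_orders[contig.label]
        true_sp = _SPECIES_OF_ORDER[_ORDER_TAXID[true_order]]
        u = rng.random()
        if u < hit_accuracy:
            dbs["all"].append((contig.contig_id, f"acc_{true_sp}", 1e-40,
                               _strong_bitscore(contig.length, rng), true_sp))
        elif u < hit_accuracy + (1 - hit_accuracy) / 2:
            decoy = all_orders[rng.integers(0, len(all_orders))]
            sp = _SPECIES_OF_ORDER[_ORDER_TAXID[decoy]]
            dbs["all"].append((contig.contig_id, f"acc_{sp}", 1e-12,
                               _weak_bitscore(rng) + 40, sp))
        # else: no hit in the general database
        for db, members in (("target", target_set), ("counter", counter_set)):
            if contig.label in members:
                if rng.random() < hit_accuracy:
                    dbs[db].append((contig.contig_id, f"acc_{true_sp}", 1e-40,
                                    _strong_bitscore(contig.length, rng), true_sp))
            elif rng.random() < (1 - hit_accuracy):
                sp = _SPECIES_OF_ORDER[_ORDER_TAXID[db_rep_order[db]]]
                dbs[db].append((contig.contig_id, f"acc_{sp}", 1e-6,
                                _weak_bitscore(rng), sp))
    return dbs


@dataclass
class FixtureBundle:
    """Paths and in-memory truth for one generated mixture."""

    directory: Path
    spec: MixtureSpec
    paths: Dict[str, str]
    contig_truth: pd.DataFrame  # contig_id, label, genome_start, length
    read_truth: pd.DataFrame    # pair_id, label, fragment_start, insert


def _write_hits(rows, path) -> None:
    with open(path, "w") as fh:
        for qid, sid, evalue, bitscore, taxid in rows:
            fh.write(f"{qid}\t{sid}\t{evalue:g}\t{bitscore:g}\t{taxid}\n")


def build_fixture(
    spec: MixtureSpec,
    outdir,
    *,
    target_labels: Sequence[str],
    counter_labels: Sequence[str],
) -> FixtureBundle:
    """Generate a complete labelled mixture bundle under *outdir*.

    Writes contig FASTA, gzipped paired FASTQ, true-placement SAM, three hit
    tables, taxdump tables, truth TSVs and a JSON manifest. Regeneration under
    the same spec (seed included) is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    contig_truths: List[ContigTruth] = []
    fasta_path = outdir / "contigs.fasta"
    sam_body: List[str] = []
    pair_truths: List[SimPair] = []
    all_m1: List[Tuple[str, str]] = []
    all_m2: List[Tuple[str, str]] = []
    contig_records: List[Tuple[ContigTruth, str]] = []

    for genome_spec in spec.genomes:
        genome = simulate_genome(genome_spec.genome_length, genome_spec.gc_target, rng)
        contigs = fragment_to_contigs(
            genome, genome_spec.label, rng,
            mean_length=spec.contig_mean_length, min_length=spec.contig_min_length,
        )
        contig_records.extend(contigs)
        truths = [t for t, _ in contigs]
        contig_truths.extend(truths)
        pairs, m1, m2 = simulate_reads(
            genome, genome_spec.read_coverage, spec.read_length,
            spec.insert_mean, spec.insert_sd, rng,
            label=genome_spec.label, error_rate=spec.error_rate,
        )
        pair_truths.extend(pairs)
        all_m1.extend(m1)
        all_m2.extend(m2)
        sam_body.extend(_sam_records_for_genome(pairs, m1, m2, truths, spec.read_length))

    with open(fasta_path, "w") as fh:
        for truth, seq in contig_records:
            fh.write(f">{truth.contig_id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    r1_path, r2_path = outdir / "reads_1.fastq.gz", outdir / "reads_2.fastq.gz"
    qual = "I" * spec.read_length
    with xopen(r1_path, "wt") as o1, xopen(r2_path, "wt") as o2:
        for (pid, seq1), (_, seq2) in zip(all_m1, all_m2):
            o1.write(f"@{pid}/1\n{seq1}\n+\n{qual}\n")
            o2.write(f"@{pid}/2\n{seq2}\n+\n{qual}\n")

    sam_path = outdir / "alignments.sam"
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for truth, _ in contig_records:
            fh.write(f"@SQ\tSN:{truth.contig_id}\tLN:{truth.length}\n")
        for line in sam_body:
            fh.write(line + "\n")

    genome_orders = {g.label: g.order for g in spec.genomes}
    dbs = mock_blast_hits(
        contig_truths, genome_orders, spec.hit_accuracy, rng,
        target_labels=target_labels, counter_labels=counter_labels,
    )
    hits_paths = {}
    for db in ("all", "target", "counter"):
        path = outdir / f"hits_{db}.tsv"
        _write_hits(dbs[db], path)
        hits_paths[db] = path

    taxdump_dir = write_taxdump(outdir / "taxdump")

    contig_truth_df = pd.DataFrame(
        [(c.contig_id, c.label, c.genome_start, c.length) for c in contig_truths],
        columns=["contig_id", "label", "genome_start", "length"],
    )
    read_truth_df = pd.DataFrame(
        [(p.pair_id, p.label, p.fragment_start, p.insert) for p in pair_truths],
        columns=["pair_id", "label", "fragment_start", "insert"],
    )
    contig_truth_df.to_csv(outdir / "truth_contigs.tsv", sep="\t", index=False)
    read_truth_df.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)

    paths = {
        "contigs": str(fasta_path),
        "reads_1": str(r1_path),
        "reads_2": str(r2_path),
        "alignments": str(sam_path),
        "hits_all": str(hits_paths["all"]),
        "hits_target": str(hits_paths["target"]),
        "hits_counter": str(hits_paths["counter"]),
        "taxdump": str(taxdump_dir),
        "truth_contigs": str(outdir / "truth_contigs.tsv"),
        "truth_reads": str(outdir / "truth_reads.tsv"),
    }
    manifest = {
        "seed": spec.seed,
        "genomes": [
            {"label": g.label, "length": g.genome_length, "gc": g.gc_target,
             "coverage": g.read_coverage, "order": g.order}
            for g in spec.genomes
        ],
        "read_length": spec.read_length,
        "insert_mean": spec.insert_mean,
        "insert_sd": spec.insert_sd,
        "hit_accuracy": spec.hit_accuracy,
        "target_labels": list(target_labels),
        "counter_labels": list(counter_labels),
        # bundle-relative so regenerated bundles are byte-identical anywhere
        "paths": {k: str(Path(v).relative_to(outdir)) for k, v in paths.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = str(outdir / "manifest.json")

    return FixtureBundle(
        directory=outdir, spec=spec, paths=paths,
        contig_truth=contig_truth_df, read_truth=read_truth_df,
    )


def fig2_spec(seed: int = 42, hit_accuracy: float = 0.95) -> MixtureSpec:
    """Two-genome host/symbiont conditions: overlapping GC, >6x depth ratio."""
    return MixtureSpec(
        genomes=(
            GenomeSpec("host", 400_000, 0.25, 60.0, "Spirurida"),
            GenomeSpec("symbiont", 50_000, 0.32, 400.0, "Rickettsiales"),
        ),
        hit_accuracy=hit_accuracy,
        seed=seed,
    )


def build_fig2_fixture(seed: int, outdir, hit_accuracy: float = 0.95) -> FixtureBundle:
    """Host + high-depth symbiont bundle (target = symbiont, counter = host)."""
    return build_fixture(
        fig2_spec(seed=seed, hit_accuracy=hit_accuracy), outdir,
        target_labels=["symbiont"], counter_labels=["host"],
    )


def fig3_spec(seed: int = 42, hit_accuracy: float = 0.95) -> MixtureSpec:
    """Host plus six bacterial co-bionts from distinct orders at assorted depths."""
    contaminants = (
        GenomeSpec("cobiont_entero", 30_000, 0.50, 300.0, "Enterobacterales"),
        GenomeSpec("cobiont_pseudo", 25_000, 0.62, 40.0, "Pseudomonadales"),
        GenomeSpec("cobiont_bacillus", 25_000, 0.43, 900.0, "Bacillales"),
        GenomeSpec("cobiont_lacto", 20_000, 0.38, 25.0, "Lactobacillales"),
        GenomeSpec("cobiont_rhodo", 20_000, 0.65, 120.0, "Rhodospirillales"),
        GenomeSpec("cobiont_rhizo", 25_000, 0.58, 15.0, "Rhizobiales"),
    )
    return MixtureSpec(
        genomes=(GenomeSpec("host", 200_000, 0.25, 50.0, "Spirurida"),) + contaminants,
        hit_accuracy=hit_accuracy,
        seed=seed,
    )


def build_fig3_fixture(seed: int, outdir, hit_accuracy: float = 0.95) -> FixtureBundle:
    """Multi-co-biont bundle (target = host, counter = every contaminant)."""
    spec = fig3_spec(seed=seed, hit_accuracy=hit_accuracy)
    return build_fixture(
        spec, outdir,
        target_labels=["host"],
        counter_labels=[g.label for g in spec.genomes if g.label != "host"],
    )
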