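"""End-to-end driver chaining the separation stages.

qc -> assembly stats -> coverage/placements/insert -> taxonomic annotation ->
blob table -> contig binning -> read-pair extraction -> reassembly parameters.

Each stage is a thin call into the corresponding module; this driver only
wires file paths and intermediate tables together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import (
    binning,
    blobplot,
    contig_stats,
    coverage_profile,
    read_extraction,
    reassembly_params,
    sequence_qc,
    taxonomy_annotation,
)

__all__ = ["SeparationResult", "run_separation"]


@dataclass
class SeparationResult:
    qc_summary: sequence_qc.QcSummary
    assembly_summary: contig_stats.AssemblySummary
    stats: pd.DataFrame               # contig_id, length, gc_fraction, mean_depth
    insert: coverage_profile.InsertSizeEstimate
    annotations: pd.DataFrame
    blob_table: pd.DataFrame
    bins: pd.DataFrame
    bin_contigs: list
    read_set: read_extraction.BinReadSet
    extraction_manifest: Dict[str, int]
    report: reassembly_params.ReassemblyReport
    paths: Dict[str, str]


def run_separation(
    contigs_fasta,
    reads1,
    reads2,
    alignments,
    hits_all,
    hits_target,
    hits_counter,
    taxdump_dir,
    workdir,
    *,
    qc_policy: Optional[sequence_qc.QcPolicy] = None,
    bin_policy: Optional[binning.BinPolicy] = None,
    annotate_rank: str = "order",
    annotate_evalue: float = 1e-10,
    subsample_n: int = 10_000,
    seed: int = 0,
    render_plot: bool = False,
) -> SeparationResult:
    """Run the full host/symbiont separation on one dataset.

    The target bin (symbiont side) is extracted; all intermediate files land
    under *workdir*.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    qc_policy = qc_policy or sequence_qc.QcPolicy()
    bin_policy = bin_policy or binning.BinPolicy()

    qc1, qc2 = workdir / "qc_1.fastq.gz", workdir / "qc_2.fastq.gz"
    qc_summary = sequence_qc.qc_stream(reads1, reads2, qc1, qc2, qc_policy)

    assembly_summary, stats = contig_stats.summarize_assembly(contigs_fasta)

    lengths = dict(zip(stats["contig_id"], stats["length"]))
    depths = coverage_profile.mean_depth_per_contig(alignments, lengths)
    placements = coverage_profile.best_placement_table(alignments)
    insert = coverage_profile.estimate_insert_size(alignments)
    stats = stats.assign(mean_depth=stats["contig_id"].map(depths))

    taxonomy = taxonomy_annotation.TaxonomyTable.from_dir(taxdump_dir)
    subsample = taxonomy_annotation.subsample_contigs(
        list(stats["contig_id"]), subsample_n, seed
    )
    annotations = taxonomy_annotation.annotate_contigs(
        taxonomy_annotation.read_blast_tsv(hits_all),
        annotate_rank, annotate_evalue, taxonomy, contig_ids=subsample,
    )

    blob_table = blobplot.build_blob_table(stats, annotations)
    paths: Dict[str, str] = {"qc_1": str(qc1), "qc_2": str(qc2)}
    if render_plot:
        plot_path = workdir / "blobplot.png"
        companion = blobplot.render_blob_plot(blob_table, plot_path)
        paths["blobplot"] = str(plot_path)
        paths["blobplot_tsv"] = str(companion)

    bins = binning.assign_bins(
        stats,
        taxonomy_annotation.read_blast_tsv(hits_target),
        taxonomy_annotation.read_blast_tsv(hits_counter),
        bin_policy,
    )
    bin_contigs = list(bins.loc[bins["final_bin_member"], "contig_id"])

    read_set = read_extraction.select_pairs(placements, bin_contigs)
    ex1, ex2 = workdir / "bin_1.fastq.gz", workdir / "bin_2.fastq.gz"
    manifest = read_extraction.write_pairs(read_set, qc1, qc2, ex1, ex2)
    paths.update(bin_reads_1=str(ex1), bin_reads_2=str(ex2))

    bin_stats = stats[stats["contig_id"].isin(bin_contigs)]
    read_length = qc_policy.hard_trim_length or _modal_read_length(qc1)
    report = reassembly_params.build_report(bin_stats, insert, read_length)
    report_path = workdir / "reassembly_params.json"
    report.write_json(report_path)
    paths["reassembly_params"] = str(report_path)

    return SeparationResult(
        qc_summary=qc_summary,
        assembly_summary=assembly_summary,
        stats=stats,
        insert=insert,
        annotations=annotations,
        blob_table=blob_table,
        bins=bins,
        bin_contigs=bin_contigs,
        read_set=read_set,
        extraction_manifest=manifest,
        report=report,
        paths=paths,
    )


def _modal_read_length(fastq_path, sample: int = 1000) -> int:
    from collections import Counter

    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    from ._io import xopen

    counts: Counter = Counter()
    with xopen(fastq_path, "rt") as fh:
        for i, (_, seq, _) in enumerate(FastqGeneralIterator(fh)):
            counts[len(seq)] += 1
            if i >= sample:
                break
    if not counts:
        raise ValueError(f"{fastq_path}: no reads to derive a read length from")
    return counts.most_common(1)[0][0]
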