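import gzip
import math
from pathlib import Path

import numpy as np
import pytest

from blobsep.synthetic_data import (
    GenomeSpec,
    MixtureSpec,
    build_fixture,
    fragment_to_contigs,
    mock_blast_hits,
    simulate_genome,
    simulate_reads,
    toy_taxonomy,
)


class TestSimulateGenome:
    def test_realized_gc_within_binomial_bound(self):
        n, gc = 1_000_000, 0.5
        genome = simulate_genome(n, gc, seed=1)
        realized = sum(1 for b in genome if b in "GC") / n
        bound = 3 * math.sqrt(gc * (1 - gc) / n)
        assert abs(realized - gc) < bound

    def test_extreme_gc_target(self):
        genome = simulate_genome(500, 1.0, seed=2)
        assert set(genome) <= {"G", "C"}

    def test_deterministic_under_seed(self):
        assert simulate_genome(1000, 0.4, seed=5) == simulate_genome(1000, 0.4, seed=5)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(0, 0.5, seed=1)


class TestFragmentToContigs:
    def test_tiling_respects_minimum_and_span(self):
        genome = simulate_genome(10_000, 0.4, seed=3)
        contigs = fragment_to_contigs(genome, "g", seed=3, mean_length=1000)
        assert all(t.length >= 200 for t, _ in contigs)
        assert sum(t.length for t, _ in contigs) <= len(genome)
        # non-overlapping, ordered tiling
        pos = 0
        for truth, seq in contigs:
            assert truth.genome_start == pos
            assert genome[pos:pos + truth.length] == seq
            pos += truth.length

    def test_contig_gc_within_binomial_bound(self):
        gc = 0.3
        genome = simulate_genome(50_000, gc, seed=4)
        contigs = fragment_to_contigs(genome, "g", seed=4, mean_length=2000)
        for truth, seq in contigs:
            realized = sum(1 for b in seq if b in "GC") / truth.length
            bound = 4 * math.sqrt(gc * (1 - gc) / truth.length)  # 4 sigma: many tries
            assert abs(realized - gc) < bound


class TestSimulateReads:
    def test_pair_count_closed_form(self):
        genome = simulate_genome(100_000, 0.4, seed=6)
        truth, m1, m2 = simulate_reads(genome, 10, 100, 340, 30, seed=6)
        assert len(truth) == len(m1) == len(m2) == 5000

    def test_mates_are_fragment_ends(self):
        comp = str.maketrans("ACGT", "TGCA")
        genome = simulate_genome(5000, 0.5, seed=7)
        truth, m1, m2 = simulate_reads(genome, 2, 50, 300, 10, seed=7)
        for pair, (pid1, seq1), (_, seq2) in zip(truth, m1, m2):
            assert pid1 == pair.pair_id
            assert seq1 == genome[pair.fragment_start:pair.fragment_start + 50]
            end = pair.fragment_start + pair.insert
            assert seq2 == genome[end - 50:end].translate(comp)[::-1]

    def test_deterministic_under_seed(self):
        genome = simulate_genome(10_000, 0.4, seed=8)
        a = simulate_reads(genome, 5, 100, 340, 30, seed=9)
        b = simulate_reads(genome, 5, 100, 340, 30, seed=9)
        assert a == b

    def test_error_rate_perturbs_bases(self):
        genome = simulate_genome(20_000, 0.5, seed=10)
        _, clean1, _ = simulate_reads(genome, 5, 100, 340, 30, seed=11)
        _, noisy1, _ = simulate_reads(genome, 5, 100, 340, 30, seed=11, error_rate=0.05)
        diffs = sum(
            a != b
            for (_, s1), (_, s2) in zip(clean1, noisy1)
            for a, b in zip(s1, s2)
        )
        total = sum(len(s) for _, s in clean1)
        # substitutions land at ~rate * 3/4 (a quarter resample the same base)
        assert 0.02 < diffs / total < 0.05


class TestMockHits:
    def _contigs(self, n_each=200):
        from blobsep.synthetic_data import ContigTruth

        return (
            [ContigTruth(f"h{i}", "host", i * 1000, 1000) for i in range(n_each)]
            + [ContigTruth(f"s{i}", "symbiont", i * 1000, 1000) for i in range(n_each)]
        )

    def test_perfect_accuracy_recovers_truth(self):
        from blobsep.taxonomy_annotation import annotate_contigs

        contigs = self._contigs()
        dbs = mock_blast_hits(
            contigs, {"host": "Spirurida", "symbiont": "Rickettsiales"},
            hit_accuracy=1.0, seed=12,
            target_labels=["symbiont"], counter_labels=["host"],
        )
        from blobsep.taxonomy_annotation import BlastHit

        hits = [BlastHit(q, s, e, b, t) for q, s, e, b, t in dbs["all"]]
        table = annotate_contigs(hits, "order", 1e-10, toy_taxonomy())
        want = {"host": "Spirurida", "symbiont": "Rickettsiales"}
        by_label = dict(zip((c.contig_id for c in contigs),
                            (c.label for c in contigs)))
        assert len(table) == len(contigs)
        assert all(
            row.taxon_label == want[by_label[row.contig_id]]
            for row in table.itertuples()
        )

    def test_intermediate_accuracy_within_binomial_bound(self):
        contigs = self._contigs(500)  # 1000 contigs total
        acc = 0.9
        dbs = mock_blast_hits(
            contigs, {"host": "Spirurida", "symbiont": "Rickettsiales"},
            hit_accuracy=acc, seed=13,
            target_labels=["symbiont"], counter_labels=["host"],
        )
        sp_of = {"h": 127, "s": 120}  # species taxids of Spirurida / Rickettsiales
        true_hits = sum(1 for q, _s, _e, _b, t in dbs["all"] if t == sp_of[q[0]])
        observed = true_hits / len(contigs)
        bound = 3 * math.sqrt(acc * (1 - acc) / len(contigs))
        assert abs(observed - acc) < bound

    def test_zero_accuracy_gives_no_true_strong_hits(self):
        contigs = self._contigs(100)
        dbs = mock_blast_hits(
            contigs, {"host": "Spirurida", "symbiont": "Rickettsiales"},
            hit_accuracy=0.0, seed=14,
            target_labels=["symbiont"], counter_labels=["host"],
        )
        assert dbs["target"] == [] or all(b < 200 for _, _, _, b, _ in dbs["target"])


@pytest.fixture(scope="module")
def spec():
    return MixtureSpec(
        genomes=(
            GenomeSpec("host", 30_000, 0.25, 15.0, "Spirurida"),
            GenomeSpec("symbiont", 8_000, 0.32, 100.0, "Rickettsiales"),
        ),
        contig_mean_length=1000,
        hit_accuracy=1.0,
        seed=21,
    )


class TestFixtureBundle:
    def test_regenerates_byte_identically(self, spec, tmp_path):
        kwargs = dict(target_labels=["symbiont"], counter_labels=["host"])
        a = build_fixture(spec, tmp_path / "a", **kwargs)
        b = build_fixture(spec, tmp_path / "b", **kwargs)
        for key, path_a in a.paths.items():
            if key == "taxdump":
                continue
            path_b = b.paths[key]
            assert Path(path_a).read_bytes() == Path(path_b).read_bytes(), key

    def test_files_round_trip_through_readers(self, spec, tmp_path):
        from blobsep.contig_stats import summarize_assembly
        from blobsep.coverage_profile import mean_depth_per_contig
        from blobsep.sequence_qc import QcPolicy, qc_stream
        from blobsep.taxonomy_annotation import TaxonomyTable, read_blast_tsv

        bundle = build_fixture(spec, tmp_path / "rt",
                               target_labels=["symbiont"], counter_labels=["host"])
        summary, stats = summarize_assembly(bundle.paths["contigs"])
        assert summary.n_contigs == len(bundle.contig_truth)
        assert set(stats["contig_id"]) == set(bundle.contig_truth["contig_id"])

        qc = qc_stream(bundle.paths["reads_1"], bundle.paths["reads_2"],
                       tmp_path / "q1.fq", tmp_path / "q2.fq", QcPolicy())
        assert qc.pairs_in == len(bundle.read_truth)
        assert qc.pairs_out == qc.pairs_in  # perfect-quality reads all survive

        depths = mean_depth_per_contig(bundle.paths["alignments"])
        assert set(depths) == set(stats["contig_id"])

        tax = TaxonomyTable.from_dir(bundle.paths["taxdump"])
        hits = list(read_blast_tsv(bundle.paths["hits_all"]))
        assert hits and all(
            tax.lineage_at_rank(h.subject_taxid, "order") in
            {"Spirurida", "Rickettsiales"} for h in hits
        )

    def test_emitted_depth_near_requested_coverage(self, spec, tmp_path):
        from blobsep.coverage_profile import mean_depth_per_contig

        bundle = build_fixture(spec, tmp_path / "cov",
                               target_labels=["symbiont"], counter_labels=["host"])
        depths = mean_depth_per_contig(bundle.paths["alignments"])
        truth = bundle.contig_truth
        for label, want in (("host", 15.0), ("symbiont", 100.0)):
            ids = list(truth.loc[truth.label == label, "contig_id"])
            lengths = dict(zip(truth.contig_id, truth.length))
            total = sum(depths[c] * lengths[c] for c in ids)
            mean = total / sum(lengths[c] for c in ids)
            # reads spanning a contig junction are unmapped; with 100-base
            # reads on ~1 kb contigs that sheds ~(L-1)/contig_len ~ 10% of
            # coverage, so compare against the junction-corrected expectation
            mean_contig = sum(lengths[c] for c in ids) / len(ids)
            expected = want * (1 - 99 / mean_contig)
            assert mean == pytest.approx(expected, rel=0.10)

    def test_depth_ratio_and_gc_overlap_in_default_conditions(self):
        from blobsep.synthetic_data import fig2_spec

        genomes = {g.label: g for g in fig2_spec().genomes}
        host, symbiont = genomes["host"], genomes["symbiont"]
        assert symbiont.read_coverage / host.read_coverage >= 6
        # GC targets are close enough that composition alone cannot separate
        assert abs(symbiont.gc_target - host.gc_target) < 0.10


class TestFig3Conditions:
    def test_seven_distinct_orders(self):
        from blobsep.synthetic_data import fig3_spec

        spec = fig3_spec()
        orders = {g.order for g in spec.genomes}
        assert len(orders) == 7
        assert len(spec.genomes) == 7
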