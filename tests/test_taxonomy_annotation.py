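import random

import pytest

from blobsep.errors import UnknownTaxidError
from blobsep.synthetic_data import toy_taxonomy, write_taxdump
from blobsep.taxonomy_annotation import (
    NO_HIT,
    UNRESOLVED,
    BlastHit,
    TaxonomyTable,
    annotate_contigs,
    read_blast_tsv,
    subsample_contigs,
)


class TestSubsample:
    def test_distinct_and_bounded(self):
        ids = [f"c{i}" for i in range(500)]
        picked = subsample_contigs(ids, 100, seed=1)
        assert len(picked) == 100 and len(set(picked)) == 100
        assert set(picked) <= set(ids)

    def test_n_exceeding_population_returns_all(self):
        ids = ["a", "b", "c"]
        assert sorted(subsample_contigs(ids, 10, seed=1)) == ids

    def test_deterministic_under_seed(self):
        ids = [f"c{i}" for i in range(200)]
        assert subsample_contigs(ids, 50, 9) == subsample_contigs(ids, 50, 9)
        assert subsample_contigs(ids, 50, 9) != subsample_contigs(ids, 50, 10)


class TestLineage:
    def test_own_rank_returns_own_name(self):
        tax = toy_taxonomy()
        assert tax.lineage_at_rank(20, "order") == "Rickettsiales"

    def test_walks_to_ancestor(self):
        tax = toy_taxonomy()
        assert tax.lineage_at_rank(120, "order") == "Rickettsiales"  # species leaf
        assert tax.lineage_at_rank(120, "class") == "Alphaproteobacteria"
        assert tax.lineage_at_rank(120, "superkingdom") == "Bacteria"

    def test_root_has_no_order(self):
        assert toy_taxonomy().lineage_at_rank(1, "order") == UNRESOLVED

    def test_unknown_taxid_is_an_error_not_unresolved(self):
        with pytest.raises(UnknownTaxidError):
            toy_taxonomy().lineage_at_rank(99999, "order")

    def test_merged_taxid_remap(self):
        tax = toy_taxonomy()
        tax.merged[55555] = 20
        assert tax.lineage_at_rank(55555, "order") == "Rickettsiales"

    def test_matches_path_enumeration_oracle(self):
        # random tree: node i's parent is a uniform pick among 0..i-1
        rng = random.Random(31)
        ranks = ["superkingdom", "class", "order", "family", "no rank"]
        parent, rank, name = {0: 0}, {0: "no rank"}, {0: "root"}
        for i in range(1, 150):
            parent[i] = rng.randrange(i)
            rank[i] = rng.choice(ranks)
            name[i] = f"n{i}"
        tax = TaxonomyTable(parent, rank, name)

        def oracle(node, want):
            path = [node]
            while path[-1] != 0:
                path.append(parent[path[-1]])
            for n in path:
                if rank[n] == want:
                    return name[n]
            return UNRESOLVED

        for _ in range(200):
            node = rng.randrange(150)
            want = rng.choice(ranks[:4])
            assert tax.lineage_at_rank(node, want) == oracle(node, want)

    def test_taxdump_round_trip(self, tmp_path):
        write_taxdump(tmp_path)
        tax = TaxonomyTable.from_dir(tmp_path)
        assert tax.lineage_at_rank(127, "order") == "Spirurida"
        assert tax.lineage_at_rank(27, "class") == "Chromadorea"


def hit(q, bitscore, taxid, evalue=1e-20):
    return BlastHit(q, f"s{taxid}", evalue, bitscore, taxid)


class TestAnnotate:
    def test_best_hit_is_max_bitscore(self):
        tax = toy_taxonomy()
        table = annotate_contigs(
            [hit("c1", 90, 127), hit("c1", 120, 120)], "order", 1e-10, tax
        )
        assert table.set_index("contig_id").loc["c1", "taxon_label"] == "Rickettsiales"

    def test_evalue_filter_forces_no_hit(self):
        tax = toy_taxonomy()
        table = annotate_contigs(
            [hit("c1", 90, 127, evalue=1e-5)], "order", 1e-10, tax,
            contig_ids=["c1"],
        )
        assert table.set_index("contig_id").loc["c1", "taxon_label"] == NO_HIT

    def test_bitscore_tie_broken_by_lower_evalue(self):
        tax = toy_taxonomy()
        table = annotate_contigs(
            [hit("c1", 100, 127, evalue=1e-15), hit("c1", 100, 120, evalue=1e-30)],
            "order", 1e-10, tax,
        )
        assert table.set_index("contig_id").loc["c1", "taxon_label"] == "Rickettsiales"

    def test_unmappable_taxid_labelled_unresolved(self):
        tax = toy_taxonomy()
        table = annotate_contigs([hit("c1", 100, 4242)], "order", 1e-10, tax)
        assert table.set_index("contig_id").loc["c1", "taxon_label"] == UNRESOLVED

    def test_matches_group_filter_max_oracle(self):
        tax = toy_taxonomy()
        rng = random.Random(8)
        taxids = [120, 123, 127, 125]
        hits = []
        for _ in range(1000):
            hits.append(hit(
                f"c{rng.randrange(300)}",
                rng.randint(30, 500),
                rng.choice(taxids),
                evalue=rng.choice([1e-30, 1e-12, 1e-8]),
            ))
        table = annotate_contigs(hits, "order", 1e-10, tax).set_index("contig_id")
        # oracle: per contig, filter then argmax
        by_contig = {}
        for h in hits:
            if h.evalue > 1e-10:
                continue
            cur = by_contig.get(h.query_id)
            if cur is None or (h.bitscore, -h.evalue) > (cur.bitscore, -cur.evalue):
                by_contig[h.query_id] = h
        assert len(table) == len(by_contig)
        for cid, best in by_contig.items():
            assert table.loc[cid, "taxon_label"] == tax.lineage_at_rank(
                best.subject_taxid, "order")
            assert table.loc[cid, "supporting_bitscore"] == best.bitscore

    def test_tightening_cutoff_never_creates_annotations(self):
        tax = toy_taxonomy()
        rng = random.Random(12)
        hits = [hit(f"c{i % 40}", rng.randint(40, 200), 127,
                    evalue=rng.choice([1e-30, 1e-12, 1e-6])) for i in range(200)]
        loose = annotate_contigs(hits, "order", 1e-5, tax,
                                 contig_ids=[f"c{i}" for i in range(40)])
        tight = annotate_contigs(hits, "order", 1e-20, tax,
                                 contig_ids=[f"c{i}" for i in range(40)])
        loose_nohit = set(loose.loc[loose.taxon_label == NO_HIT, "contig_id"])
        tight_nohit = set(tight.loc[tight.taxon_label == NO_HIT, "contig_id"])
        assert loose_nohit <= tight_nohit


class TestReadBlastTsv:
    def test_default_columns_and_malformed_rows_skipped(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "c1\tacc1\t1e-20\t250\t120\n"
            "broken line without tabs\n"
            "c2\tacc2\t1e-8\t80\t127\n"
        )
        hits = list(read_blast_tsv(path))
        assert [h.query_id for h in hits] == ["c1", "c2"]
        assert hits[0].subject_taxid == 120

    def test_accession_map_for_older_dialect(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("c1\tACC.1\t1e-20\t250\n")
        hits = list(read_blast_tsv(
            path, columns=("qseqid", "sseqid", "evalue", "bitscore"),
            taxid_map={"ACC.1": 120},
        ))
        assert hits[0].subject_taxid == 120
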