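"""Evidence parsing, hit filtering, taxonomic assignment, integration."""

import io

import numpy as np
import pytest

from gitkit.errors import ArgumentError, GitkitError, MalformedRowError
from gitkit.fixtures import FixtureSpec, generate, make_boundary_hits
from gitkit.integration import (
    SearchHit,
    Thresholds,
    assign_taxonomy,
    best_hit,
    chunk_sequences,
    filter_hits,
    integrate,
    parse_blast_tab,
    parse_interpro_tsv,
    tag_filters,
)
from gitkit.git_format import GeneRecord
from gitkit.taxonomy import UNASSIGNED


def make_hit(query="q", subject="s", pid=90.0, qstart=1, qend=90, qlen=100,
             evalue=1e-40, bitscore=200.0):
    return SearchHit(query, subject, pid, qend - qstart + 1, qstart, qend,
                     evalue, bitscore, qlen)


class TestBlastParsing:
    def test_coverage_from_span_and_length(self):
        row = "q\ts\t90.0\t50\t5\t0\t1\t50\t10\t59\t1e-20\t100.0"
        (hit,) = parse_blast_tab(row, {"q": 100})
        assert hit.percent_query_coverage == pytest.approx(50.0)
        (hit,) = parse_blast_tab("q\ts\t90\t1\t0\t0\t7\t7\t1\t1\t1e-5\t60", {"q": 100})
        assert hit.percent_query_coverage == pytest.approx(1.0)

    def test_random_coordinates_match_span_oracle(self):
        rng = np.random.default_rng(0)
        rows, lengths = [], {}
        for i in range(100):
            qlen = int(rng.integers(50, 500))
            qstart = int(rng.integers(1, qlen))
            qend = int(rng.integers(qstart, qlen + 1))
            name = f"q{i}"
            lengths[name] = qlen
            rows.append(f"{name}\ts\t90\t{qend-qstart+1}\t0\t0\t{qstart}\t{qend}\t1\t9\t1e-9\t80")
        hits = parse_blast_tab("\n".join(rows), lengths)
        for hit in hits:
            span = hit.query_end - hit.query_start + 1
            assert hit.percent_query_coverage == pytest.approx(100.0 * span / hit.query_length)

    def test_unknown_query_length_is_an_error(self):
        with pytest.raises(GitkitError, match="no length"):
            parse_blast_tab("q\ts\t90\t10\t0\t0\t1\t10\t1\t10\t1e-5\t60", {})

    def test_non_numeric_field_is_an_error(self):
        with pytest.raises(MalformedRowError):
            parse_blast_tab("q\ts\tNA\t10\t0\t0\t1\t10\t1\t10\t1e-5\t60", {"q": 100})


class TestFiltering:
    def test_boundary_hits_exact(self):
        thresholds = Thresholds()
        for hit, expected_kept in make_boundary_hits():
            kept = bool(filter_hits([hit], thresholds))
            assert kept == expected_kept, hit

    def test_order_preserved_and_conjunction(self):
        hits = [make_hit(subject=s, bitscore=b) for s, b in [("a", 60), ("b", 40), ("c", 70)]]
        kept = filter_hits(hits, Thresholds())
        assert [h.subject_id for h in kept] == ["a", "c"]


class TestBestHit:
    def test_single_and_score_ordering(self):
        lone = make_hit()
        assert best_hit([lone]) is lone
        strong, weak = make_hit(subject="a", bitscore=80), make_hit(subject="b", bitscore=60)
        assert best_hit([weak, strong]) is strong
        assert best_hit([]) is None

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            hits = [
                make_hit(subject=f"s{int(rng.integers(0, 6))}",
                         bitscore=float(rng.choice([50, 60, 60, 70])),
                         evalue=float(rng.choice([1e-10, 1e-20, 1e-20])))
                for _ in range(int(rng.integers(1, 8)))
            ]
            expected = sorted(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))[0]
            assert best_hit(hits) == expected

    def test_mixed_queries_rejected(self):
        with pytest.raises(ArgumentError):
            best_hit([make_hit(query="a"), make_hit(query="b")])


class TestAssignTaxonomy:
    def test_single_hit_both_modes(self, fixture_set):
        xref = fixture_set.universe.xref
        accession = fixture_set.universe.ref_proteins[0]
        expected = xref.protein_info[accession].taxon_id
        hits = [make_hit(subject=accession)]
        for mode in ("best_hit", "lca"):
            assert assign_taxonomy(hits, fixture_set.tree, xref, mode=mode) == expected

    def test_equal_hits_to_siblings_give_parent(self, fixture_set):
        tree = fixture_set.tree
        xref = fixture_set.universe.xref
        children = {}
        for taxon, node in tree.nodes.items():
            if taxon != tree.root:
                children.setdefault(node.parent_id, []).append(taxon)
        parent, kids = next((p, k) for p, k in sorted(children.items()) if len(k) >= 2)
        # two same-score hits to proteins planted on sibling taxa
        xref.protein_info["sib1"] = type(xref.protein_info[next(iter(xref.protein_info))])(
            taxon_id=kids[0])
        xref.protein_info["sib2"] = type(xref.protein_info[next(iter(xref.protein_info))])(
            taxon_id=kids[1])
        hits = [make_hit(subject="sib1"), make_hit(subject="sib2")]
        assert assign_taxonomy(hits, tree, xref, mode="lca") == parent
        del xref.protein_info["sib1"], xref.protein_info["sib2"]

    def test_no_hits_means_unassigned(self, fixture_set):
        assert assign_taxonomy([], fixture_set.tree, fixture_set.universe.xref) == UNASSIGNED


class TestInterproParsing:
    ROW = ("g1\t-\t300\tPfam\tPF01738\tdesc\t1\t100\t1e-10\tT\t2019-01-01"
           "\tIPR002735\tentry\tGO:0003735|GO:0005840")

    def test_domains_and_go_recorded(self):
        result = parse_interpro_tsv(self.ROW)
        domains, gos = result["g1"]
        assert domains == ["PF01738", "IPR002735"]
        assert gos == ["GO:0003735", "GO:0005840"]

    def test_duplicate_rows_deduplicated(self):
        result = parse_interpro_tsv(self.ROW + "\n" + self.ROW)
        domains, gos = result["g1"]
        assert len(domains) == len(set(domains))
        assert len(gos) == len(set(gos))

    def test_matches_groupby_oracle(self, fixture_set):
        text = fixture_set.interpro_tsv()
        parsed = parse_interpro_tsv(text)
        oracle = {}
        for line in text.splitlines():
            fields = line.split("\t")
            domains, gos = oracle.setdefault(fields[0], (set(), set()))
            domains.update({fields[4], fields[11]})
            gos.update(fields[13].split("|"))
        assert set(parsed) == set(oracle)
        for gene, (domains, gos) in parsed.items():
            assert set(domains) == oracle[gene][0]
            assert set(gos) == oracle[gene][1]

    def test_malformed_row_names_line(self):
        with pytest.raises(MalformedRowError, match="line 1"):
            parse_interpro_tsv("too\tfew")


class TestFilterTagging:
    def test_tagging_adds_class_subtoken_and_is_idempotent(self):
        record = GeneRecord(gene_id="g1")
        table = {"g1": "tetracycline"}
        tagged = tag_filters(record, table)
        assert tagged.filters == [
            "F.AntiBiotic.Resistance",
            "F.AntiBiotic.Resistance.tetracycline",
        ]
        assert tag_filters(tagged, table).filters == tagged.filters
        untouched = tag_filters(GeneRecord(gene_id="g2"), table)
        assert untouched.filters == []


class TestIntegrate:
    def test_gene_conservation_and_empty_records(self, fixture_set, git_records):
        complete = fixture_set.complete_genes()
        assert len(git_records) == len(complete)
        assert [r.gene_id for r in git_records] == [g.gene_id for g in complete]
        empty = [r for r in git_records
                 if not fixture_set.truth[r.gene_id].annotatable]
        assert empty
        for record in empty:
            assert record.taxon_id == UNASSIGNED
            assert record.ko_id == "" and record.cog_id == ""
            assert record.source == "none"

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ArgumentError):
            integrate([("g", 100), ("g", 100)])

    @pytest.mark.parametrize("fraction", [0.0, 0.3, 1.0])
    def test_planted_fraction_recovered_exactly(self, fraction):
        fx = generate(FixtureSpec(seed=5, n_genes=80, annotatable_fraction=fraction))
        records = fx.run_integration()
        annotated = [r for r in records if r.source != "none"]
        assert len(annotated) == round(fraction * 80)
        for record in records:
            assert (record.source != "none") == fx.truth[record.gene_id].annotatable

    def test_planted_taxa_recovered_exactly(self, fixture_set, git_records):
        for record in git_records:
            truth = fixture_set.truth[record.gene_id]
            if truth.annotatable:
                assert record.taxon_id == truth.true_taxon
                assert record.ko_id == truth.true_ko

    def test_threshold_monotonicity(self, fixture_set):
        previous = None
        for min_cov in (50.0, 60.0, 70.0, 80.0):
            thresholds = Thresholds(min_query_coverage=min_cov,
                                    stringent_query_coverage=80.0)
            count = sum(1 for r in fixture_set.run_integration(thresholds)
                        if r.source != "none")
            if previous is not None:
                assert count <= previous
            previous = count
        previous = None
        for min_bitscore in (50.0, 150.0, 250.0):
            thresholds = Thresholds(min_bitscore=min_bitscore)
            count = sum(1 for r in fixture_set.run_integration(thresholds)
                        if r.source != "none")
            if previous is not None:
                assert count <= previous
            previous = count

    def test_stringent_coverage_yields_nested_assignments(self, fixture_set, git_records):
        stringent_records = fixture_set.run_integration(Thresholds().stringent())
        assigned_default = {r.gene_id for r in git_records if r.taxon_id != UNASSIGNED}
        assigned_stringent = {r.gene_id for r in stringent_records
                              if r.taxon_id != UNASSIGNED}
        assert assigned_stringent <= assigned_default
        expected_stringent = {g for g, t in fixture_set.truth.items()
                              if t.annotatable and t.stringent_coverage}
        assert assigned_stringent == expected_stringent

    def test_determinism(self, fixture_set, git_records):
        again = fixture_set.run_integration()
        assert again == git_records


class TestChunking:
    @staticmethod
    def fasta(records):
        return io.StringIO("".join(f">{name}\n{seq}\n" for name, seq in records))

    def test_small_input_single_chunk(self):
        chunks = chunk_sequences(self.fasta([("a", "ACGT"), ("b", "GGCC")]))
        assert len(chunks) == 1
        assert [r.id for r in chunks[0]] == ["a", "b"]

    def test_greedy_packing_six_and_four(self):
        records = [(f"r{i}", "A" * 300_000) for i in range(10)]
        chunks = chunk_sequences(self.fasta(records), chunk_size=2_000_000)
        assert [len(c) for c in chunks] == [6, 4]

    def test_conservation_and_oversize_record(self):
        records = [("big", "A" * 2_500_000), ("small", "ACGT")]
        chunks = chunk_sequences(self.fasta(records), chunk_size=2_000_000)
        flattened = [r.id for chunk in chunks for r in chunk]
        assert flattened == ["big", "small"]
        assert len(chunks[0]) == 1  # oversize record alone in its chunk
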