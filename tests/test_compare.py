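"""Category counting, deltas, fold changes, alpha diversity, marker OTUs."""

import math

import numpy as np
import pytest

from gitkit.compare import (
    CountVector,
    alpha_diversity,
    annotation_delta,
    category_counts,
    fold_change_matrix,
    marker_otu_count,
    percent_unique_genes,
    taxonomic_affiliation,
)
from gitkit.errors import ArgumentError
from gitkit.git_format import GeneRecord


class TestCategoryCounts:
    def test_ko_counts_and_unassigned(self):
        records = [GeneRecord(gene_id=f"g{i}", ko_id="K18220") for i in range(3)]
        records.append(GeneRecord(gene_id="g3"))
        vector = category_counts(records, "ko")
        assert vector.counts == {"K18220": 3, "unassigned": 1}

    def test_ec_class_is_first_digit(self):
        record = GeneRecord(gene_id="g", ec_ids=["3.2.1.4"])
        assert category_counts([record], "ec_class").counts == {"3": 1}

    def test_matches_groupby_oracle(self, git_records):
        import pandas as pd

        vector = category_counts(git_records, "ko")
        frame = pd.DataFrame(
            {"label": [r.ko_id or "unassigned" for r in git_records]}
        )
        oracle = frame.groupby("label").size().to_dict()
        assert vector.counts == oracle

    def test_multilabel_go_counts_each_label(self):
        record = GeneRecord(gene_id="g", go_ids=["GO:1", "GO:2"])
        vector = category_counts([record], "go")
        assert vector.total() == 2

    def test_taxon_category_projection_consistency(self, fixture_set, git_records):
        tree = fixture_set.tree
        deep = category_counts(git_records, "taxon", tree=tree, rank="species")
        shallow = category_counts(git_records, "taxon", tree=tree, rank="phylum")
        # re-projecting species labels to phylum reproduces the direct tally
        names = {tree.name(t): t for t in tree.nodes}
        reprojected = {}
        for label, count in deep.counts.items():
            if label == "unassigned":
                reprojected[label] = reprojected.get(label, 0) + count
                continue
            phylum = tree.project_rank(names[label], "phylum")
            key = tree.name(phylum) if phylum else "unassigned"
            reprojected[key] = reprojected.get(key, 0) + count
        assert reprojected == shallow.counts

    def test_unknown_category_rejected(self):
        with pytest.raises(ArgumentError):
            category_counts([], "nonsense")


class TestPercentUnique:
    def test_all_and_none(self):
        records = {"h": [GeneRecord(gene_id="g1", ko_id="K1"),
                         GeneRecord(gene_id="g2", ko_id="K1")]}
        assert percent_unique_genes(records, lambda r: bool(r.ko_id)) == {"h": 100.0}
        assert percent_unique_genes(records, lambda r: False) == {"h": 0.0}
        assert percent_unique_genes({"empty": []}, lambda r: True) == {"empty": None}

    def test_planted_fraction_and_complement(self, git_records):
        habitats = {"hab": git_records}
        predicate = lambda r: r.source != "none"
        positive = percent_unique_genes(habitats, predicate)["hab"]
        negative = percent_unique_genes(habitats, lambda r: not predicate(r))["hab"]
        assert positive + negative == pytest.approx(100.0)
        expected = 100.0 * sum(predicate(r) for r in git_records) / len(git_records)
        assert positive == pytest.approx(expected)


class TestFoldChange:
    def test_identity_and_zero_handling(self):
        a = CountVector("ko", {"K1": 9})
        b = CountVector("ko", {})
        assert fold_change_matrix(a, b, pseudocount=1.0) == {"K1": 10.0}
        same = fold_change_matrix(a, a)
        assert all(v == 1.0 for v in same.values())

    def test_swap_inverts(self):
        a = CountVector("ko", {"K1": 4, "K2": 0})
        b = CountVector("ko", {"K1": 1, "K3": 7})
        forward = fold_change_matrix(a, b)
        backward = fold_change_matrix(b, a)
        for label in forward:
            assert forward[label] * backward[label] == pytest.approx(1.0)

    def test_category_mismatch(self):
        with pytest.raises(ArgumentError):
            fold_change_matrix(CountVector("ko", {}), CountVector("go", {}))


class TestAnnotationDelta:
    @staticmethod
    def records(labels):
        return [GeneRecord(gene_id=f"g{i}", ko_id=label)
                for i, label in enumerate(labels)]

    def test_set_algebra(self):
        v1 = self.records(["K00001", "K00002"])
        v2 = self.records(["K00002", "K00003", ""])
        delta = annotation_delta(v1, v2, "ko")
        assert delta.labels_v1_only == {"K00001"}
        assert delta.labels_v2_only == {"K00003"}
        assert delta.labels_shared == {"K00002"}
        assert delta.genes_assigned_v1 == 2
        assert delta.genes_assigned_v2 == 2

    def test_identical_versions_and_antisymmetry(self, git_records):
        delta = annotation_delta(git_records, git_records, "ko")
        assert not delta.labels_v1_only and not delta.labels_v2_only
        half = git_records[: len(git_records) // 2]
        forward = annotation_delta(half, git_records, "ko")
        backward = annotation_delta(git_records, half, "ko")
        assert forward.labels_v1_only == backward.labels_v2_only
        assert forward.labels_v2_only == backward.labels_v1_only
        assert forward.labels_shared == backward.labels_shared


class TestAlphaDiversity:
    def test_uniform_closed_forms(self):
        for n in range(1, 51):
            vector = CountVector("ko", {f"K{i:05d}": 7 for i in range(n)})
            metrics = alpha_diversity(vector)
            assert metrics.shannon == pytest.approx(math.log(n), rel=1e-12, abs=1e-12)
            assert metrics.simpson == pytest.approx(1 - 1 / n, rel=1e-12, abs=1e-12)
            assert metrics.inv_simpson == pytest.approx(n, rel=1e-12)
            assert metrics.richness == n

    def test_single_label_degenerate(self):
        metrics = alpha_diversity(CountVector("ko", {"K1": 12}))
        assert metrics == (0.0, 0.0, 1.0, 1)

    def test_inverse_simpson_identity_random(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            counts = {f"K{i}": int(c) for i, c in
                      enumerate(rng.integers(0, 50, size=rng.integers(2, 30)))}
            if not any(counts.values()):
                continue
            metrics = alpha_diversity(CountVector("ko", counts))
            assert metrics.inv_simpson == pytest.approx(1 / (1 - metrics.simpson), rel=1e-9)
            assert metrics.shannon <= math.log(metrics.richness) + 1e-12

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.diversity import alpha as ref

        rng = np.random.default_rng(9)
        for _ in range(20):
            values = rng.integers(1, 100, size=12)
            vector = CountVector("ko", {f"K{i}": int(v) for i, v in enumerate(values)})
            metrics = alpha_diversity(vector)
            assert metrics.shannon == pytest.approx(ref.shannon(values, base=math.e))
            assert metrics.simpson == pytest.approx(ref.simpson(values))
            assert metrics.inv_simpson == pytest.approx(ref.enspie(values))

    def test_unassigned_excluded_and_empty_rejected(self):
        vector = CountVector("ko", {"unassigned": 10, "K1": 5})
        assert alpha_diversity(vector).richness == 1
        with pytest.raises(ArgumentError):
            alpha_diversity(CountVector("ko", {"unassigned": 3}))


class TestMarkerOtu:
    def test_criteria_conjunction(self, tree):
        taxon = next(t for t, n in tree.nodes.items() if n.rank == "species")
        base = dict(interpro_ids=["PF01738"], taxon_id=taxon,
                    percent_identity=85.0, percent_coverage=90.0)
        counted = GeneRecord(gene_id="ok", **base)
        low_coverage = GeneRecord(gene_id="lowcov", **{**base, "percent_coverage": 70.0})
        no_domain = GeneRecord(gene_id="nodom", **{**base, "interpro_ids": []})
        unassigned = GeneRecord(gene_id="notax", **{**base, "taxon_id": 0})
        counts = marker_otu_count([counted, low_coverage, no_domain, unassigned], tree)
        assert sum(counts.values()) == 1

    def test_planted_superkingdom_counts(self, fixture_set, git_records):
        counts = marker_otu_count(git_records, fixture_set.tree)
        expected = {}
        for truth in fixture_set.truth.values():
            if truth.marker:
                expected[truth.superkingdom] = expected.get(truth.superkingdom, 0) + 1
        assert counts == expected


class TestTaxonomicAffiliation:
    def test_matches_category_counts_on_subset(self, fixture_set, git_records):
        tree = fixture_set.tree
        result = taxonomic_affiliation({"hab": git_records}, "K18220", tree, rank="phylum")
        carrying = [r for r in git_records if r.ko_id == "K18220"]
        if carrying:
            oracle = category_counts(carrying, "taxon", tree=tree, rank="phylum")
            assert result["hab"] == oracle.counts
        assert taxonomic_affiliation({"hab": git_records}, "K99999", tree)["hab"] == {}
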