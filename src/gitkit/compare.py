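"""Cross-sample and cross-catalog analytics over Gene Information Tables.

Everything here consumes GeneRecords: unique-gene counts per annotation
category (KO, EC class, GO, COG, eggNOG, filter tokens, or taxa projected
to a rank), percent-unique-gene queries, fold-change matrices between
count vectors, label/assignment deltas between two annotation versions of
the same catalog, alpha diversity of annotation-label tallies (Shannon,
Simpson, inverse Simpson, richness), single-copy marker-gene OTU counting,
and per-habitat taxonomic affiliation of a KO.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, NamedTuple

from .errors import ArgumentError
from .git_format import GeneRecord
from .taxonomy import UNASSIGNED, TaxonomyTree

UNASSIGNED_LABEL = "unassigned"

CATEGORIES = ("taxon", "ko", "ec_class", "go", "cog", "eggnog", "filter")

DEFAULT_MARKER_DOMAIN = "PF01738"  # ribosomal protein S30 signature


@dataclass
class CountVector:
    """Unique-gene tallies per label within one annotation category."""

    category: str
    counts: dict[str, int]

    def total(self) -> int:
        return sum(self.counts.values())


def _taxon_label(record: GeneRecord, tree: TaxonomyTree, rank: str) -> list[str]:
    if record.taxon_id == UNASSIGNED or record.taxon_id not in tree:
        return [UNASSIGNED_LABEL]
    projected = tree.project_rank(record.taxon_id, rank)
    if projected is None:
        return [UNASSIGNED_LABEL]
    return [tree.name(projected) or str(projected)]


def _labels_for(record: GeneRecord, category: str,
                tree: TaxonomyTree | None, rank: str | None) -> list[str]:
    if category == "taxon":
        assert tree is not None and rank is not None
        return _taxon_label(record, tree, rank)
    if category == "ko":
        return [record.ko_id] if record.ko_id else [UNASSIGNED_LABEL]
    if category == "ec_class":
        classes = sorted({ec.split(".")[0] for ec in record.ec_ids if ec})
        return classes or [UNASSIGNED_LABEL]
    if category == "go":
        return list(dict.fromkeys(record.go_ids)) or [UNASSIGNED_LABEL]
    if category == "cog":
        return [record.cog_id] if record.cog_id else [UNASSIGNED_LABEL]
    if category == "eggnog":
        return [record.eggnog_id] if record.eggnog_id else [UNASSIGNED_LABEL]
    if category == "filter":
        return list(dict.fromkeys(record.filters)) or [UNASSIGNED_LABEL]
    raise ArgumentError(f"unknown category {category!r}; expected one of {CATEGORIES}")


def category_counts(records: Iterable[GeneRecord], category: str,
                    tree: TaxonomyTree | None = None,
                    rank: str | None = None) -> CountVector:
    """Count unique genes per label of one category.

    Each gene contributes once to every distinct label it carries
    (multi-valued categories such as GO can therefore sum above the gene
    count); genes without a label in the category count as ``unassigned``.
    Taxa are projected to ``rank`` first.
    """
    if category not in CATEGORIES:
        raise ArgumentError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    if category == "taxon" and (tree is None or rank is None):
        raise ArgumentError("taxon category needs a taxonomy tree and a rank")
    counts: dict[str, int] = {}
    for record in records:
        for label in _labels_for(record, category, tree, rank):
            counts[label] = counts.get(label, 0) + 1
    return CountVector(category if category != "taxon" else f"taxon@{rank}", counts)


def percent_unique_genes(records_by_habitat: Mapping[str, Iterable[GeneRecord]],
                         predicate: Callable[[GeneRecord], bool]) -> dict[str, float | None]:
    """Percent of a habitat's (non-redundant) genes matching a predicate.

    Empty habitats report ``None`` (undefined fraction).
    """
    result: dict[str, float | None] = {}
    for habitat, records in records_by_habitat.items():
        records = list(records)
        if not records:
            result[habitat] = None
            continue
        matching = sum(1 for record in records if predicate(record))
        result[habitat] = 100.0 * matching / len(records)
    return result


def fold_change_matrix(a: CountVector, b: CountVector,
                       pseudocount: float = 1.0) -> dict[str, float]:
    """Per-label (count_a + pc) / (count_b + pc) over the union of labels."""
    if a.category != b.category:
        raise ArgumentError(
            f"fold change across categories: {a.category!r} vs {b.category!r}"
        )
    labels = set(a.counts) | set(b.counts)
    return {
        label: (a.counts.get(label, 0) + pseudocount) / (b.counts.get(label, 0) + pseudocount)
        for label in sorted(labels)
    }


class AnnotationDelta(NamedTuple):
    labels_v1_only: set[str]
    labels_v2_only: set[str]
    labels_shared: set[str]
    genes_assigned_v1: int
    genes_assigned_v2: int


def annotation_delta(v1: Iterable[GeneRecord], v2: Iterable[GeneRecord],
                     category: str, tree: TaxonomyTree | None = None,
                     rank: str | None = None) -> AnnotationDelta:
    """Observed-label differences between two annotation versions.

    ``genes_assigned`` counts genes carrying at least one real (non
    ``unassigned``) label in the category for that version.
    """
    v1, v2 = list(v1), list(v2)

    def observed(records):
        labels: set[str] = set()
        assigned = 0
        for record in records:
            record_labels = set(_labels_for(record, category, tree, rank))
            record_labels.discard(UNASSIGNED_LABEL)
            if record_labels:
                assigned += 1
            labels |= record_labels
        return labels, assigned

    labels1, assigned1 = observed(v1)
    labels2, assigned2 = observed(v2)
    return AnnotationDelta(
        labels_v1_only=labels1 - labels2,
        labels_v2_only=labels2 - labels1,
        labels_shared=labels1 & labels2,
        genes_assigned_v1=assigned1,
        genes_assigned_v2=assigned2,
    )


class AlphaDiversity(NamedTuple):
    shannon: float
    simpson: float
    inv_simpson: float
    richness: int


def alpha_diversity(counts: CountVector, log_base: float = math.e) -> AlphaDiversity:
    """Shannon/Simpson/inverse-Simpson/richness of a label-count vector.

    With p_i = n_i / N over labels with positive count (``unassigned``
    excluded first): Shannon H = -sum p_i log p_i (natural log by default),
    Simpson D = 1 - sum p_i^2, inverse Simpson = 1 / sum p_i^2, richness =
    number of labels present.
    """
    values = [count for label, count in counts.counts.items()
              if label != UNASSIGNED_LABEL and count > 0]
    if not values:
        raise ArgumentError("alpha diversity of an all-zero/unassigned vector")
    total = sum(values)
    proportions = [value / total for value in values]
    sum_sq = sum(p * p for p in proportions)
    shannon = -sum(p * math.log(p, log_base) for p in proportions)
    return AlphaDiversity(
        shannon=shannon,
        simpson=1.0 - sum_sq,
        inv_simpson=1.0 / sum_sq,
        richness=len(values),
    )


def marker_otu_count(records: Iterable[GeneRecord], tree: TaxonomyTree,
                     marker_domain: str = DEFAULT_MARKER_DOMAIN,
                     min_identity: float = 30.0, min_coverage: float = 80.0,
                     grouping_rank: str = "superkingdom") -> dict[str, int]:
    """Count marker-gene variants (OTU proxies) per taxon group.

    A gene counts as an OTU when it carries the single-copy marker domain,
    its hit statistics reach the identity/coverage floor, and it is taxon
    assigned.  Counts are grouped at ``grouping_rank``; genes whose lineage
    lacks that rank fall under ``unassigned``.
    """
    result: dict[str, int] = {}
    for record in records:
        if marker_domain not in record.interpro_ids:
            continue
        if record.percent_identity is None or record.percent_identity < min_identity:
            continue
        if record.percent_coverage is None or record.percent_coverage < min_coverage:
            continue
        if record.taxon_id == UNASSIGNED or record.taxon_id not in tree:
            continue
        projected = tree.project_rank(record.taxon_id, grouping_rank)
        group = (tree.name(projected) or str(projected)) if projected else UNASSIGNED_LABEL
        result[group] = result.get(group, 0) + 1
    return result


def taxonomic_affiliation(records_by_habitat: Mapping[str, Iterable[GeneRecord]],
                          ko_id: str, tree: TaxonomyTree,
                          rank: str = "phylum") -> dict[str, dict[str, int]]:
    """Per habitat, unique-gene counts per taxon (at ``rank``) among genes
    carrying one KO — e.g. where tetM sits taxonomically in each habitat."""
    result: dict[str, dict[str, int]] = {}
    for habitat, records in records_by_habitat.items():
        carrying = [record for record in records if record.ko_id == ko_id]
        if not carrying:
            result[habitat] = {}
            continue
        vector = category_counts(carrying, "taxon", tree=tree, rank=rank)
        result[habitat] = dict(vector.counts)
    return result
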