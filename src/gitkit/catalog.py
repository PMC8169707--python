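"""Gene catalog construction: complete-gene filtering, greedy redundancy
clustering, catalog merging and gene x sample abundance matrices.

A habitat's catalog is built from full-length (complete) predicted genes
only — genes closed at both ends (partial flag ``"00"``) and at least 100 bp
long — clustered greedily, longest first, so that each gene joins the first
existing representative it matches at the identity/coverage cutoffs (95% or
90% identity with 80% query coverage for habitat catalogs; 90% identity with
an 80% length-difference prefilter when merging catalogs at the protein
level).  Representatives are the retained catalog entries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .errors import ArgumentError, GitkitError

VALID_PARTIAL_FLAGS = ("00", "01", "10", "11")

#: Minimum contig length used upstream at assembly time (validation constant).
MIN_CONTIG_LENGTH = 500

DEFAULT_MIN_GENE_LENGTH = 100


@dataclass
class PredictedGene:
    gene_id: str
    sequence: str
    partial_flag: str = "00"
    sample_id: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ArgumentError(f"gene {self.gene_id!r} has an empty sequence")
        if self.partial_flag not in VALID_PARTIAL_FLAGS:
            raise ArgumentError(
                f"gene {self.gene_id!r}: partial flag {self.partial_flag!r} "
                f"not in {VALID_PARTIAL_FLAGS}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Cluster:
    representative: str
    members: list[str]


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    identity_threshold: float
    coverage_threshold: float

    def member_to_representative(self) -> dict[str, str]:
        mapping = {}
        for cluster in self.clusters:
            for member in cluster.members:
                mapping[member] = cluster.representative
        return mapping

    def representatives(self) -> list[str]:
        return [cluster.representative for cluster in self.clusters]


def filter_complete_genes(genes: Iterable[PredictedGene],
                          min_length: int = DEFAULT_MIN_GENE_LENGTH) -> list[PredictedGene]:
    """Keep only genes closed at both ends and at least ``min_length`` long."""
    return [g for g in genes if g.partial_flag == "00" and g.length >= min_length]


_PARTIAL_ATTR_RE = re.compile(r"partial=([01]{2})")


def read_predicted_genes(fasta_path, sample_id: str = "") -> list[PredictedGene]:
    """Read genes from a FASTA whose headers carry ``partial=XY`` attributes
    (gene-caller style); headers without the attribute default to complete."""
    genes = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        match = _PARTIAL_ATTR_RE.search(record.description)
        flag = match.group(1) if match else "00"
        genes.append(PredictedGene(record.id, str(record.seq), flag, sample_id))
    return genes


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    # Free terminal gaps: overhangs of either sequence are not penalized.
    try:
        aligner.end_deletion_score = 0.0
        aligner.end_insertion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.query_end_gap_score = 0.0
        aligner.target_end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """(percent identity, percent query coverage of ``a``) for one pair.

    Alignment is semi-global with free terminal gaps, so a short gene
    contained in a longer one aligns end to end.  Identity is matches over
    aligned columns (first to last aligned pair, internal gaps included);
    coverage is the aligned span on ``a`` over its length.
    """
    if not a or not b:
        raise ArgumentError("pairwise_identity requires non-empty sequences")
    alignment = _ALIGNER.align(a, b)[0]
    target_blocks, query_blocks = alignment.aligned  # target = a, query = b
    if len(target_blocks) == 0:
        return 0.0, 0.0
    matches = 0
    paired = 0
    for (a_start, a_end), (b_start, b_end) in zip(target_blocks, query_blocks):
        paired += a_end - a_start
        matches += sum(
            1 for x, y in zip(a[a_start:a_end], b[b_start:b_end]) if x == y
        )
    span_a = int(target_blocks[-1][1] - target_blocks[0][0])
    span_b = int(query_blocks[-1][1] - query_blocks[0][0])
    columns = span_a + span_b - paired
    identity = 100.0 * matches / columns
    coverage = 100.0 * span_a / len(a)
    return float(identity), float(coverage)


def _greedy_cluster(genes: Sequence[PredictedGene], identity_threshold: float,
                    coverage_threshold: float,
                    min_length_ratio: float | None = None) -> ClusterSet:
    if not genes:
        raise ArgumentError("cluster_genes requires a non-empty gene list")
    for name, value in (("identity", identity_threshold), ("coverage", coverage_threshold)):
        if not (0.0 < value <= 100.0):
            raise ArgumentError(f"{name} threshold {value} outside (0, 100]")
    ordered = sorted(genes, key=lambda g: (-g.length, g.gene_id))
    clusters: list[Cluster] = []
    rep_genes: list[PredictedGene] = []
    for gene in ordered:
        placed = False
        for cluster, rep in zip(clusters, rep_genes):
            if min_length_ratio is not None and gene.length < min_length_ratio * rep.length:
                continue
            identity, coverage = pairwise_identity(gene.sequence, rep.sequence)
            if identity >= identity_threshold and coverage >= coverage_threshold:
                cluster.members.append(gene.gene_id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(gene.gene_id, [gene.gene_id]))
            rep_genes.append(gene)
    return ClusterSet(clusters, identity_threshold, coverage_threshold)


def cluster_genes(genes: Sequence[PredictedGene], identity_threshold: float = 95.0,
                  coverage_threshold: float = 80.0) -> ClusterSet:
    """Greedy incremental clustering, longest gene first (ties by id).

    Each gene joins the first representative, in founding order, that it
    matches at ``identity_threshold`` percent identity and
    ``coverage_threshold`` percent coverage of the incoming (query) gene;
    otherwise it founds a new cluster.  Deterministic for a given input set.
    """
    return _greedy_cluster(genes, identity_threshold, coverage_threshold)


@dataclass
class MergedCatalog:
    cluster_set: ClusterSet
    #: representative gene id -> sorted list of source catalog labels
    provenance: dict[str, list[str]] = field(default_factory=dict)


def merge_catalogs(catalogs: Mapping[str, Sequence[PredictedGene]],
                   identity_threshold: float = 90.0,
                   coverage_threshold: float = 80.0,
                   min_length_difference: float = 80.0) -> MergedCatalog:
    """Merge habitat catalog representatives into one global set.

    ``min_length_difference`` (percent) is a shorter/longer length-ratio
    prefilter applied before alignment, so genes differing in length by
    more than it never merge.  Provenance records, per retained
    representative, which source catalogs its members came from.
    """
    if not (0.0 < min_length_difference <= 100.0):
        raise ArgumentError("min_length_difference must be in (0, 100]")
    pooled: list[PredictedGene] = []
    origin: dict[str, str] = {}
    for label, genes in catalogs.items():
        for gene in genes:
            if gene.gene_id in origin:
                raise ArgumentError(f"gene id {gene.gene_id!r} appears in multiple catalogs")
            origin[gene.gene_id] = label
            pooled.append(gene)
    cluster_set = _greedy_cluster(pooled, identity_threshold, coverage_threshold,
                                  min_length_ratio=min_length_difference / 100.0)
    provenance = {
        cluster.representative: sorted({origin[m] for m in cluster.members})
        for cluster in cluster_set.clusters
    }
    return MergedCatalog(cluster_set, provenance)


@dataclass
class AbundanceMatrix:
    """Catalog representatives x samples, non-negative abundances."""

    table: pd.DataFrame

    def __post_init__(self):
        if (self.table.values < 0).any():
            raise ArgumentError("abundance cells must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def samples(self) -> list[str]:
        return list(self.table.columns)

    def total(self) -> float:
        return float(self.table.values.sum())


def build_abundance_matrix(cluster_map: Mapping[str, str],
                           per_sample_counts: Mapping[str, Mapping[str, float]]) -> AbundanceMatrix:
    """Aggregate member-level counts onto representatives.

    ``cluster_map`` sends every counted gene to its representative; a gene
    missing from it is an error.  Cells absent from the input are zero.
    """
    reps = sorted(set(cluster_map.values()))
    samples = sorted(per_sample_counts)
    table = pd.DataFrame(0.0, index=reps, columns=samples)
    for sample, counts in per_sample_counts.items():
        for gene, count in counts.items():
            if gene not in cluster_map:
                raise GitkitError(f"counted gene {gene!r} has no cluster assignment")
            table.loc[cluster_map[gene], sample] += count
    return AbundanceMatrix(table)


def shared_unique_summary(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-sample counts of genes unique to it vs shared with other samples.

    A gene is unique to sample ``s`` iff ``s`` holds its only nonzero cell;
    every other nonzero occurrence counts as shared for each sample carrying
    it.  Returns a DataFrame indexed by sample with columns
    ``unique``/``shared``.
    """
    present = matrix.table.values > 0
    n_samples_per_gene = present.sum(axis=1)
    unique = ((present) & (n_samples_per_gene == 1)[:, None]).sum(axis=0)
    shared = ((present) & (n_samples_per_gene > 1)[:, None]).sum(axis=0)
    return pd.DataFrame(
        {"unique": unique, "shared": shared}, index=matrix.table.columns
    )


def write_cluster_file(cluster_set: ClusterSet, path) -> None:
    """One line per cluster: representative first, then members, tab-separated."""
    with open(path, "w", encoding="utf-8") as handle:
        for cluster in cluster_set.clusters:
            rest = [m for m in cluster.members if m != cluster.representative]
            handle.write("\t".join([cluster.representative] + rest) + "\n")
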