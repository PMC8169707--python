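"""Annotation integration: raw homology/domain/ARG evidence -> GeneRecords.

This is the integration stage of the annotation pipeline: protein-level
searches against a general protein knowledgebase give taxonomy plus COG /
eggNOG / gene-name cross-references, searches against KO-labelled KEGG
sequences give functional-role (KO) assignments with EC cross-references,
domain scans give InterPro signatures and GO terms, and an ARG prediction
table tags antibiotic-resistance filter tokens.  Hits are filtered at a
bitscore cutoff (default 50), minimum percent identity (default 30) and
minimum percent query coverage (default 50; 80 in the stringent setting)
before any assignment is made.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

from Bio import SeqIO

from .errors import ArgumentError, GitkitError, MalformedRowError
from .git_format import GeneRecord
from .taxonomy import UNASSIGNED, TaxonomyTree

ARG_FILTER_TOKEN = "F.AntiBiotic.Resistance"


@dataclass(frozen=True)
class Thresholds:
    """Hit-retention cutoffs applied before any assignment."""

    min_bitscore: float = 50.0
    min_percent_identity: float = 30.0
    min_query_coverage: float = 50.0
    stringent_query_coverage: float = 80.0

    def __post_init__(self):
        if min(self.min_bitscore, self.min_percent_identity,
               self.min_query_coverage, self.stringent_query_coverage) < 0:
            raise ArgumentError("thresholds must be non-negative")
        if self.min_query_coverage > self.stringent_query_coverage:
            raise ArgumentError("stringent coverage must be >= default coverage")

    def stringent(self) -> "Thresholds":
        return Thresholds(
            self.min_bitscore,
            self.min_percent_identity,
            self.stringent_query_coverage,
            self.stringent_query_coverage,
        )


@dataclass(frozen=True)
class SearchHit:
    """One pairwise homology hit in the 12-column tabular dialect."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    query_start: int
    query_end: int
    evalue: float
    bitscore: float
    query_length: int

    @property
    def percent_query_coverage(self) -> float:
        return 100.0 * (self.query_end - self.query_start + 1) / self.query_length


@dataclass
class ProteinXref:
    taxon_id: int = UNASSIGNED
    cog_id: str = ""
    eggnog_id: str = ""
    gene_name: str = ""


@dataclass
class KoXref:
    ec_ids: list[str] = field(default_factory=list)
    module_ids: list[str] = field(default_factory=list)
    pathway_ids: list[str] = field(default_factory=list)


@dataclass
class CrossRefMap:
    """Accession cross-references routed during integration.

    ``protein_info`` keys general protein accessions; ``kegg_to_ko`` maps
    KEGG gene accessions to their KO family; ``ko_info`` maps a KO to its
    enzyme/module/pathway cross-references.
    """

    protein_info: dict[str, ProteinXref] = field(default_factory=dict)
    kegg_to_ko: dict[str, str] = field(default_factory=dict)
    ko_info: dict[str, KoXref] = field(default_factory=dict)


def write_xref(xref: CrossRefMap) -> str:
    """Serialize a cross-reference map as a typed three-section TSV."""
    lines = []
    for accession in sorted(xref.protein_info):
        info = xref.protein_info[accession]
        lines.append("\t".join(["protein", accession, str(info.taxon_id),
                                info.cog_id, info.eggnog_id, info.gene_name]))
    for accession in sorted(xref.kegg_to_ko):
        lines.append("\t".join(["kegg", accession, xref.kegg_to_ko[accession]]))
    for ko in sorted(xref.ko_info):
        info = xref.ko_info[ko]
        lines.append("\t".join(["ko", ko, "|".join(info.ec_ids),
                                "|".join(info.module_ids), "|".join(info.pathway_ids)]))
    return "\n".join(lines) + "\n"


def read_xref(source: str | TextIO | Iterable[str]) -> CrossRefMap:
    if isinstance(source, str):
        source = io.StringIO(source)
    xref = CrossRefMap()
    for line_number, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        kind = fields[0]
        if kind == "protein" and len(fields) >= 6:
            xref.protein_info[fields[1]] = ProteinXref(
                int(fields[2]), fields[3], fields[4], fields[5]
            )
        elif kind == "kegg" and len(fields) >= 3:
            xref.kegg_to_ko[fields[1]] = fields[2]
        elif kind == "ko" and len(fields) >= 5:
            xref.ko_info[fields[1]] = KoXref(
                [x for x in fields[2].split("|") if x],
                [x for x in fields[3].split("|") if x],
                [x for x in fields[4].split("|") if x],
            )
        else:
            raise MalformedRowError(f"unrecognized cross-reference row {line!r}", line_number)
    return xref


def parse_blast_tab(source: str | TextIO | Iterable[str],
                    query_lengths: Mapping[str, int]) -> list[SearchHit]:
    """Parse 12-column tabular search output; coverage needs query lengths.

    Columns: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore.  Coordinates are 1-based
    inclusive; a reversed query interval is normalized.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    hits = []
    for line_number, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise MalformedRowError(
                f"expected >=12 tab-separated columns, got {len(fields)}", line_number
            )
        query_id, subject_id = fields[0], fields[1]
        if query_id not in query_lengths:
            raise GitkitError(f"line {line_number}: no length known for query {query_id!r}")
        try:
            pident = float(fields[2])
            align_length = int(fields[3])
            qstart, qend = int(fields[6]), int(fields[7])
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError as exc:
            raise MalformedRowError(f"non-numeric field ({exc})", line_number) from None
        if qstart > qend:
            qstart, qend = qend, qstart
        qlen = query_lengths[query_id]
        if qend > qlen:
            raise MalformedRowError(
                f"query end {qend} exceeds query length {qlen} for {query_id!r}",
                line_number,
            )
        hits.append(SearchHit(query_id, subject_id, pident, align_length,
                              qstart, qend, evalue, bitscore, qlen))
    return hits


def parse_blast_tab_file(path, query_lengths: Mapping[str, int]) -> list[SearchHit]:
    with open(path, encoding="utf-8") as handle:
        return parse_blast_tab(handle, query_lengths)


def filter_hits(hits: Iterable[SearchHit], thresholds: Thresholds) -> list[SearchHit]:
    """Retain hits meeting all three cutoffs; order preserved."""
    return [
        hit
        for hit in hits
        if hit.bitscore >= thresholds.min_bitscore
        and hit.percent_identity >= thresholds.min_percent_identity
        and hit.percent_query_coverage >= thresholds.min_query_coverage
    ]


def _hit_order_key(hit: SearchHit):
    # bitscore desc, evalue asc, subject lexicographic: a total order.
    return (-hit.bitscore, hit.evalue, hit.subject_id)


def best_hit(hits: Sequence[SearchHit]) -> SearchHit | None:
    """Top hit under (bitscore desc, evalue asc, subject asc); None if empty."""
    if not hits:
        return None
    if len({hit.query_id for hit in hits}) > 1:
        raise ArgumentError("best_hit requires hits from a single query")
    return min(hits, key=_hit_order_key)


def assign_taxonomy(hits: Sequence[SearchHit], tree: TaxonomyTree, xref: CrossRefMap,
                    mode: str = "lca", lca_bitscore_window: float = 0.1) -> int:
    """Taxon for one query from its retained protein hits.

    ``best_hit`` mode takes the top hit's subject taxon.  ``lca`` mode takes
    the lowest common ancestor of all hits whose bitscore is within
    ``lca_bitscore_window`` (fraction) of the top bitscore.  Subjects with
    no cross-reference contribute unassigned evidence.  Returns 0 when
    nothing survives.
    """
    if mode not in ("best_hit", "lca"):
        raise ArgumentError(f"unknown taxonomic-assignment mode {mode!r}")
    top = best_hit(hits)
    if top is None:
        return UNASSIGNED
    if mode == "best_hit":
        info = xref.protein_info.get(top.subject_id)
        return info.taxon_id if info else UNASSIGNED
    floor = top.bitscore * (1.0 - lca_bitscore_window)
    taxa = set()
    for hit in hits:
        if hit.bitscore >= floor:
            info = xref.protein_info.get(hit.subject_id)
            taxa.add(info.taxon_id if info else UNASSIGNED)
    return tree.lca(taxa)


def parse_interpro_tsv(source: str | TextIO | Iterable[str]) -> dict[str, tuple[list[str], list[str]]]:
    """Aggregate a domain-scan TSV into per-gene (interpro_ids, go_ids).

    Rows follow the InterProScan tabular layout: column 1 gene id, column 5
    signature accession, column 12 (optional) InterPro accession, column 14
    (optional) ``|``-separated GO terms.  ``-`` marks an absent value.
    Accession lists are deduplicated, first-seen order.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    result: dict[str, tuple[list[str], list[str]]] = {}
    for line_number, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise MalformedRowError(
                f"expected >=5 tab-separated columns, got {len(fields)}", line_number
            )
        gene_id = fields[0]
        domains, gos = result.setdefault(gene_id, ([], []))
        for accession in (fields[4], fields[11] if len(fields) > 11 else "-"):
            if accession and accession != "-" and accession not in domains:
                domains.append(accession)
        if len(fields) > 13 and fields[13] and fields[13] != "-":
            for go in fields[13].split("|"):
                go = go.split("(")[0]  # strip optional evidence suffix
                if go and go not in gos:
                    gos.append(go)
    return result


def parse_arg_table(source: str | TextIO | Iterable[str]) -> dict[str, str]:
    """Two-column gene -> ARG class table."""
    if isinstance(source, str):
        source = io.StringIO(source)
    table = {}
    for line_number, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise MalformedRowError("expected 2 tab-separated columns", line_number)
        table[fields[0]] = fields[1]
    return table


def tag_filters(record: GeneRecord, arg_table: Mapping[str, str]) -> GeneRecord:
    """Add ARG filter tokens to a record present in the ARG table (idempotent)."""
    if record.gene_id not in arg_table:
        return record
    arg_class = arg_table[record.gene_id]
    tagged = record.copy()
    for token in (ARG_FILTER_TOKEN, f"{ARG_FILTER_TOKEN}.{arg_class}"):
        if token not in tagged.filters:
            tagged.filters.append(token)
    return tagged


def integrate(genes: Sequence[tuple[str, int]],
              *,
              sample_id: str = "",
              protein_hits: Iterable[SearchHit] = (),
              ko_hits: Iterable[SearchHit] = (),
              domain_annotations: Mapping[str, tuple[list[str], list[str]]] | None = None,
              arg_table: Mapping[str, str] | None = None,
              xref: CrossRefMap | None = None,
              tree: TaxonomyTree | None = None,
              thresholds: Thresholds = Thresholds(),
              tax_mode: str = "lca",
              lca_bitscore_window: float = 0.1) -> list[GeneRecord]:
    """Produce exactly one GeneRecord per input gene.

    Taxonomy comes from the protein-database hits (best-hit or LCA), the KO
    from the best qualifying hit against KO-labelled sequences, EC numbers
    via the KO cross-reference, COG/eggNOG/gene name via the protein best
    hit's cross-reference, and GO/InterPro from the domain scan.  The
    ``source`` column and the recorded evalue/identity/coverage come from
    the hit behind the primary functional assignment (KO first, then
    protein, then domain scan); genes with no surviving evidence are
    emitted unannotated with source ``none``.
    """
    gene_ids = [gene_id for gene_id, _ in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise ArgumentError("duplicate gene ids in integrate() input")
    domain_annotations = domain_annotations or {}
    arg_table = arg_table or {}
    xref = xref or CrossRefMap()

    protein_by_query: dict[str, list[SearchHit]] = {}
    for hit in protein_hits:
        protein_by_query.setdefault(hit.query_id, []).append(hit)
    ko_by_query: dict[str, list[SearchHit]] = {}
    for hit in ko_hits:
        ko_by_query.setdefault(hit.query_id, []).append(hit)

    records = []
    for gene_id, _length in genes:
        retained_protein = filter_hits(protein_by_query.get(gene_id, ()), thresholds)
        retained_ko = filter_hits(ko_by_query.get(gene_id, ()), thresholds)

        if tree is not None and retained_protein:
            taxon = assign_taxonomy(retained_protein, tree, xref,
                                    mode=tax_mode, lca_bitscore_window=lca_bitscore_window)
        else:
            taxon = UNASSIGNED

        top_ko_hit = best_hit(retained_ko)
        ko_id = xref.kegg_to_ko.get(top_ko_hit.subject_id, "") if top_ko_hit else ""
        ko_ref = xref.ko_info.get(ko_id) if ko_id else None

        top_protein_hit = best_hit(retained_protein)
        protein_ref = (
            xref.protein_info.get(top_protein_hit.subject_id) if top_protein_hit else None
        )

        domains, gos = domain_annotations.get(gene_id, ([], []))

        if ko_id and top_ko_hit is not None:
            source, stat_hit = "KEGG", top_ko_hit
        elif top_protein_hit is not None:
            source, stat_hit = "UniProtKB", top_protein_hit
        elif domains or gos:
            source, stat_hit = "InterPro", None
        else:
            source, stat_hit = "none", None

        record = GeneRecord(
            gene_id=gene_id,
            sample_id=sample_id,
            gene_name=protein_ref.gene_name if protein_ref else "",
            go_ids=list(gos),
            ec_ids=list(ko_ref.ec_ids) if ko_ref else [],
            interpro_ids=list(domains),
            taxon_id=taxon,
            ko_id=ko_id,
            cog_id=protein_ref.cog_id if protein_ref else "",
            eggnog_id=protein_ref.eggnog_id if protein_ref else "",
            weight=1.0,
            source=source,
            evalue=stat_hit.evalue if stat_hit else None,
            percent_identity=stat_hit.percent_identity if stat_hit else None,
            percent_coverage=round(stat_hit.percent_query_coverage, 4) if stat_hit else None,
        )
        records.append(tag_filters(record, arg_table))
    return records


DEFAULT_CHUNK_SIZE = 2_000_000  # bytes of sequence data per parallel work unit


def chunk_sequences(source, chunk_size: int = DEFAULT_CHUNK_SIZE) -> list[list]:
    """Split a FASTA stream into chunks of at most ``chunk_size`` bytes.

    Greedy packing in input order; a record is never split, so a single
    record larger than the chunk size occupies a chunk of its own.  The
    concatenation of all chunks reproduces the input record list.
    """
    if chunk_size <= 0:
        raise ArgumentError("chunk_size must be positive")
    try:
        records = list(SeqIO.parse(source, "fasta"))
    except ValueError as exc:
        raise MalformedRowError(f"malformed FASTA: {exc}") from None
    chunks: list[list] = []
    current: list = []
    current_size = 0
    for record in records:
        size = len(record.id) + len(record.seq) + 2  # ">id\n" + sequence + "\n"
        if current and current_size + size > chunk_size:
            chunks.append(current)
            current, current_size = [], 0
        current.append(record)
        current_size += size
    if current:
        chunks.append(current)
    return chunks
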