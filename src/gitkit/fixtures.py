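"""Deterministic synthetic data with planted ground truth.

Real gene catalogs are built from thousands of public metagenomic samples
and versioned reference databases; none of that is reproducible on a
desktop, so every input the toolkit consumes is generated here instead: a
rank-laddered taxonomy, a reference protein universe with cross-references,
KO-labelled sequences, KEGG-style module definitions, predicted genes with
partial flags, homology/domain/ARG evidence straddling the annotation
cutoffs, and per-sample abundance counts.  Every planted assignment is
recorded in a truth table, so recovery by the pipeline is exactly
checkable, and generation is fully deterministic per seed (byte-identical
files).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import PredictedGene
from .errors import ArgumentError
from .integration import (
    CrossRefMap,
    KoXref,
    ProteinXref,
    SearchHit,
    Thresholds,
    integrate,
    write_xref,
)
from .kegg_modules import ModuleDefinition, parse_module_definition, write_module_definitions
from .taxonomy import TaxNode, TaxonomyTree, dump_taxonomy

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

SUPERKINGDOMS = ("Bacteria", "Archaea", "Eukaryota")

#: The tetracycline / beta-lactamase ARG demo KOs: tetV, tetM, tetX, blaTEM.
ARG_KOS = ("K18215", "K18220", "K18221", "K18698")

#: Thirty antibiotic classes, mirroring the ~30 ARG classes of the
#: deepARG-style reference the filter tokens are derived from.
ARG_CLASSES = (
    "aminocoumarin", "aminoglycoside", "bacitracin", "beta-lactam", "bleomycin",
    "chloramphenicol", "elfamycin", "ethambutol", "fosfomycin", "fosmidomycin",
    "fusidic-acid", "glycopeptide", "isoniazid", "kasugamycin", "macrolide",
    "multidrug", "mupirocin", "nitrofurantoin", "nitroimidazole", "peptide",
    "polymyxin", "puromycin", "pyrazinamide", "quinolone", "rifamycin",
    "streptothricin", "sulfonamide", "tetracenomycin", "tetracycline",
    "triclosan",
)

_NUCLEOTIDES = np.array(list("ACGT"))
_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_taxa: int = 80
    n_ref_proteins: int = 120
    n_genes: int = 200
    n_samples: int = 4
    annotatable_fraction: float = 0.7
    identity_noise: float = 0.05
    arg_fraction: float = 0.1
    n_modules: int = 8
    max_module_kos: int = 6
    n_kos: int = 40
    n_incomplete_genes: int = 24
    min_gene_length: int = 150
    max_gene_length: int = 600
    #: marker (PF01738) genes planted per superkingdom
    marker_counts: tuple[int, int, int] = (5, 2, 3)

    def __post_init__(self):
        for name in ("annotatable_fraction", "identity_noise", "arg_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ArgumentError(f"{name} must lie in [0, 1]")
        if self.n_taxa < 3:
            raise ArgumentError("n_taxa must be at least 3")


# ---------------------------------------------------------------- taxonomy

def make_taxonomy(spec: FixtureSpec) -> TaxonomyTree:
    """Random rank-laddered tree: root, three superkingdoms, one seeded
    chain down to species per superkingdom, then uniform attachment of the
    remaining nodes one rank below a uniformly chosen parent."""
    rng = np.random.default_rng(spec.seed)
    nodes = [TaxNode(1, 1, "no rank", "root")]
    by_level: list[list[int]] = [[] for _ in RANKS]
    next_id = 2
    for name in SUPERKINGDOMS:
        nodes.append(TaxNode(next_id, 1, RANKS[0], name))
        by_level[0].append(next_id)
        next_id += 1
    for sk_id in list(by_level[0]):
        parent = sk_id
        for level in range(1, len(RANKS)):
            nodes.append(TaxNode(next_id, parent, RANKS[level], f"{RANKS[level]}_{next_id}"))
            by_level[level].append(next_id)
            parent = next_id
            next_id += 1
    while len(nodes) < spec.n_taxa:
        level = int(rng.integers(1, len(RANKS)))
        parent = int(rng.choice(by_level[level - 1]))
        nodes.append(TaxNode(next_id, parent, RANKS[level], f"{RANKS[level]}_{next_id}"))
        by_level[level].append(next_id)
        next_id += 1
    return TaxonomyTree(nodes)


def _superkingdom_of(tree: TaxonomyTree, taxon_id: int) -> str | None:
    projected = tree.project_rank(taxon_id, "superkingdom")
    return tree.name(projected) if projected is not None else None


# ---------------------------------------------------------------- universe

@dataclass
class Universe:
    kos: list[str]
    arg_kos: tuple[str, ...]
    modules: list[ModuleDefinition]
    xref: CrossRefMap
    ref_proteins: list[str]
    ref_sequences: dict[str, str]
    #: proteins grouped by the superkingdom of their taxon
    proteins_by_superkingdom: dict[str, list[str]]
    #: Pfam signature -> (InterPro accession, GO terms)
    domain_info: dict[str, tuple[str, list[str]]]


def _random_sequence(rng, length: int, alphabet) -> str:
    return "".join(rng.choice(alphabet, size=length))


def _make_modules(rng, arg_kos, other_kos, n_modules: int, max_kos: int) -> list[ModuleDefinition]:
    modules = []
    for index in range(n_modules):
        module_id = f"M{index + 1:05d}"
        pool = list(arg_kos) if index < 2 else list(other_kos)
        budget = min(max_kos, len(pool))
        chosen = list(rng.choice(pool, size=budget, replace=False))
        steps = []
        while chosen and len(steps) < 3:
            form = int(rng.integers(0, 3)) if len(chosen) >= 2 else 0
            if form == 0:
                steps.append(chosen.pop())
            elif form == 1:
                steps.append(f"({chosen.pop()},{chosen.pop()})")
            else:
                steps.append(f"{chosen.pop()}+{chosen.pop()}")
        modules.append(parse_module_definition(module_id, " ".join(steps)))
    return modules


def make_annotated_universe(spec: FixtureSpec, tree: TaxonomyTree) -> Universe:
    rng = np.random.default_rng(spec.seed + 1)
    other_kos = [f"K{50000 + i:05d}" for i in range(max(spec.n_kos - len(ARG_KOS), 4))]
    kos = list(ARG_KOS) + other_kos
    modules = _make_modules(rng, ARG_KOS, other_kos, spec.n_modules, spec.max_module_kos)

    ko_modules: dict[str, list[str]] = {ko: [] for ko in kos}
    for module in modules:
        for ko in sorted(module.leaves()):
            ko_modules.setdefault(ko, []).append(module.module_id)
    xref = CrossRefMap()
    for ko in kos:
        ec = (f"{int(rng.integers(1, 7))}.{int(rng.integers(1, 30))}."
              f"{int(rng.integers(1, 30))}.{int(rng.integers(1, 200))}")
        pathway = f"map{int(rng.integers(1, 1200)):05d}"
        xref.ko_info[ko] = KoXref([ec], ko_modules.get(ko, []), [pathway])
        for copy in range(2):
            xref.kegg_to_ko[f"kg:{ko}g{copy + 1}"] = ko

    species = sorted(
        taxon for taxon, node in tree.nodes.items() if node.rank == "species"
    )
    ref_proteins = []
    ref_sequences = {}
    by_superkingdom: dict[str, list[str]] = {name: [] for name in SUPERKINGDOMS}
    for i in range(spec.n_ref_proteins):
        accession = f"P{i:05d}"
        taxon = int(rng.choice(species))
        xref.protein_info[accession] = ProteinXref(
            taxon_id=taxon,
            cog_id=f"COG{int(rng.integers(1, 4000)):04d}",
            eggnog_id=f"ENOG{int(rng.integers(1, 90000)):05d}",
            gene_name=f"gene_{i:04d}",
        )
        ref_proteins.append(accession)
        ref_sequences[accession] = _random_sequence(rng, int(rng.integers(80, 300)), _AMINO_ACIDS)
        superkingdom = _superkingdom_of(tree, taxon)
        if superkingdom in by_superkingdom:
            by_superkingdom[superkingdom].append(accession)

    domain_info = {"PF01738": ("IPR002735", ["GO:0003735", "GO:0005840"])}
    for i in range(1, 13):
        domain_info[f"PF{i:05d}"] = (
            f"IPR{i:06d}",
            [f"GO:{3674 + i:07d}"],
        )
    return Universe(kos, ARG_KOS, modules, xref, ref_proteins, ref_sequences,
                    by_superkingdom, domain_info)


# ---------------------------------------------------------------- genes + evidence

@dataclass
class GeneTruth:
    gene_id: str
    length: int
    partial_flag: str
    annotatable: bool = False
    sub_threshold: bool = False
    true_protein: str = ""
    true_taxon: int = 0
    true_ko: str = ""
    domains: list[str] = field(default_factory=list)
    gos: list[str] = field(default_factory=list)
    arg_class: str = ""
    marker: bool = False
    superkingdom: str = ""
    stringent_coverage: bool = False


def _coverage_hit(rng, gene_id: str, subject: str, qlen: int, identity: float,
                  coverage_target: float, bitscore: float) -> SearchHit:
    qend = max(1, min(qlen, int(round(coverage_target / 100.0 * qlen))))
    span = qend  # qstart = 1
    exponent = int(rng.integers(20, 120))
    return SearchHit(
        query_id=gene_id,
        subject_id=subject,
        percent_identity=identity,
        align_length=span,
        query_start=1,
        query_end=qend,
        evalue=10.0 ** -exponent,
        bitscore=bitscore,
        query_length=qlen,
    )


@dataclass
class FixtureSet:
    """All generated inputs plus the truth table, in memory."""

    spec: FixtureSpec
    tree: TaxonomyTree
    universe: Universe
    genes: list[PredictedGene]
    truth: dict[str, GeneTruth]
    protein_hits: list[SearchHit]
    ko_hits: list[SearchHit]
    domain_annotations: dict[str, tuple[list[str], list[str]]]
    arg_table: dict[str, str]
    counts: dict[str, dict[str, int]]

    def complete_genes(self) -> list[PredictedGene]:
        return [g for g in self.genes if g.partial_flag == "00" and g.length >= 100]

    def query_lengths(self) -> dict[str, int]:
        return {g.gene_id: g.length for g in self.genes}

    def run_integration(self, thresholds: Thresholds = Thresholds(),
                        tax_mode: str = "lca", sample_id: str = "catalog"):
        gene_list = [(g.gene_id, g.length) for g in self.complete_genes()]
        return integrate(
            gene_list,
            sample_id=sample_id,
            protein_hits=self.protein_hits,
            ko_hits=self.ko_hits,
            domain_annotations=self.domain_annotations,
            arg_table=self.arg_table,
            xref=self.universe.xref,
            tree=self.tree,
            thresholds=thresholds,
            tax_mode=tax_mode,
        )

    # ------------------------------------------------------------ file output

    def interpro_tsv(self) -> str:
        lines = []
        for gene_id in sorted(self.domain_annotations):
            domains, _ = self.domain_annotations[gene_id]
            signatures = [d for d in domains if d.startswith("PF")]
            for signature in signatures:
                ipr, gos = self.universe.domain_info[signature]
                length = self.truth[gene_id].length
                lines.append("\t".join([
                    gene_id, "-", str(length), "Pfam", signature,
                    f"{signature} domain", "1", str(max(1, length // 3)),
                    "1e-10", "T", "2019-01-01", ipr, f"{ipr} entry",
                    "|".join(gos),
                ]))
        return "\n".join(lines) + "\n" if lines else ""

    def _blast_lines(self, hits: list[SearchHit]) -> str:
        lines = []
        for hit in hits:
            span = hit.query_end - hit.query_start + 1
            mismatches = int(round(span * (100.0 - hit.percent_identity) / 100.0))
            lines.append("\t".join([
                hit.query_id, hit.subject_id,
                format(hit.percent_identity, ".12g"), str(hit.align_length),
                str(mismatches), "0", str(hit.query_start), str(hit.query_end),
                "1", str(span), format(hit.evalue, ".12g"),
                format(hit.bitscore, ".12g"),
            ]))
        return "\n".join(lines) + "\n" if lines else ""

    def genes_fasta(self) -> str:
        pieces = []
        for index, gene in enumerate(self.genes):
            header = (f">{gene.gene_id} # 1 # {gene.length} # 1 # "
                      f"ID={index + 1}_1;partial={gene.partial_flag};start_type=ATG")
            pieces.append(header)
            pieces.append(gene.sequence)
        return "\n".join(pieces) + "\n"

    def genes_gff(self) -> str:
        lines = ["##gff-version 3"]
        for index, gene in enumerate(self.genes):
            lines.append("\t".join([
                f"contig_{index + 1}", "gene_caller", "CDS", "1", str(gene.length),
                ".", "+", "0", f"ID={gene.gene_id};partial={gene.partial_flag}",
            ]))
        return "\n".join(lines) + "\n"

    def truth_tsv(self) -> str:
        header = ("#gene_id\tlength\tpartial\tannotatable\tsub_threshold\ttrue_protein\t"
                  "true_taxon\ttrue_ko\tdomains\tgos\targ_class\tmarker\tsuperkingdom\t"
                  "stringent_coverage")
        lines = [header]
        for gene in self.genes:
            t = self.truth[gene.gene_id]
            lines.append("\t".join([
                t.gene_id, str(t.length), t.partial_flag, str(int(t.annotatable)),
                str(int(t.sub_threshold)), t.true_protein, str(t.true_taxon),
                t.true_ko, "||".join(t.domains), "||".join(t.gos), t.arg_class,
                str(int(t.marker)), t.superkingdom, str(int(t.stringent_coverage)),
            ]))
        return "\n".join(lines) + "\n"

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nodes_text, names_text = dump_taxonomy(self.tree)
        (outdir / "nodes.dmp").write_text(nodes_text)
        (outdir / "names.dmp").write_text(names_text)
        ref_lines = []
        for accession in self.universe.ref_proteins:
            ref_lines.append(f">{accession}")
            ref_lines.append(self.universe.ref_sequences[accession])
        (outdir / "ref.fasta").write_text("\n".join(ref_lines) + "\n")
        (outdir / "xref.tsv").write_text(write_xref(self.universe.xref))
        (outdir / "genes.fasta").write_text(self.genes_fasta())
        (outdir / "genes.gff").write_text(self.genes_gff())
        (outdir / "uniprot_hits.tsv").write_text(self._blast_lines(self.protein_hits))
        (outdir / "kegg_hits.tsv").write_text(self._blast_lines(self.ko_hits))
        (outdir / "interpro.tsv").write_text(self.interpro_tsv())
        (outdir / "arg.tsv").write_text(
            "".join(f"{g}\t{c}\n" for g, c in sorted(self.arg_table.items()))
        )
        (outdir / "modules.tsv").write_text(write_module_definitions(self.universe.modules))
        counts_dir = outdir / "counts"
        counts_dir.mkdir(exist_ok=True)
        for sample in sorted(self.counts):
            lines = [f"{g}\t{c}" for g, c in sorted(self.counts[sample].items())]
            (counts_dir / f"{sample}.tsv").write_text("\n".join(lines) + "\n")
        (outdir / "truth.tsv").write_text(self.truth_tsv())


def generate(spec: FixtureSpec) -> FixtureSet:
    """Build the whole fixture set: taxonomy, universe, genes, evidence."""
    tree = make_taxonomy(spec)
    universe = make_annotated_universe(spec, tree)
    return make_evidence(spec, universe, tree)


def make_evidence(spec: FixtureSpec, universe: Universe, tree: TaxonomyTree) -> FixtureSet:
    rng = np.random.default_rng(spec.seed + 2)
    xref = universe.xref

    n = spec.n_genes
    lengths = rng.integers(spec.min_gene_length, spec.max_gene_length + 1, size=n)
    genes: list[PredictedGene] = []
    truth: dict[str, GeneTruth] = {}
    for i in range(n):
        gene_id = f"g{i:05d}"
        sequence = _random_sequence(rng, int(lengths[i]), _NUCLEOTIDES)
        genes.append(PredictedGene(gene_id, sequence, "00"))
        truth[gene_id] = GeneTruth(gene_id, int(lengths[i]), "00")

    n_annot = int(round(spec.annotatable_fraction * n))
    annot_indices = sorted(rng.choice(n, size=n_annot, replace=False).tolist())
    annot_ids = [genes[i].gene_id for i in annot_indices]

    # ARG genes: forced onto the demo ARG KOs with a class token.
    n_arg = int(round(spec.arg_fraction * n_annot))
    arg_ids = set(rng.choice(annot_ids, size=n_arg, replace=False).tolist()) if n_arg else set()

    # marker genes: planted per superkingdom, forced into the stringent set
    marker_plan: list[tuple[str, str]] = []
    for superkingdom, count in zip(SUPERKINGDOMS, spec.marker_counts):
        marker_plan.extend((superkingdom, "") for _ in range(count))
    non_arg_annot = [g for g in annot_ids if g not in arg_ids]
    if len(marker_plan) > len(non_arg_annot):
        marker_plan = marker_plan[: len(non_arg_annot)]
    marker_ids = list(rng.choice(non_arg_annot, size=len(marker_plan), replace=False)) \
        if marker_plan else []
    marker_assignment = {gene_id: marker_plan[k][0] for k, gene_id in enumerate(marker_ids)}

    protein_hits: list[SearchHit] = []
    ko_hits: list[SearchHit] = []
    domain_annotations: dict[str, tuple[list[str], list[str]]] = {}
    arg_table: dict[str, str] = {}
    domain_pool = sorted(d for d in universe.domain_info if d != "PF01738")

    for order, gene_id in enumerate(annot_ids):
        t = truth[gene_id]
        t.annotatable = True
        if gene_id in marker_assignment:
            superkingdom = marker_assignment[gene_id]
            pool = universe.proteins_by_superkingdom[superkingdom]
            protein = str(rng.choice(pool))
            t.marker = True
            t.superkingdom = superkingdom
            stringent = True
        else:
            protein = str(rng.choice(universe.ref_proteins))
            stringent = bool(order % 2 == 0)
        t.true_protein = protein
        t.true_taxon = xref.protein_info[protein].taxon_id
        t.stringent_coverage = stringent

        identity = round(100.0 * (1.0 - spec.identity_noise) - float(rng.uniform(0.0, 25.0)), 1)
        identity = max(identity, 40.0)
        coverage_target = float(rng.uniform(82.0, 98.0)) if stringent \
            else float(rng.uniform(56.0, 78.0))
        bitscore = round(2.0 * identity + 60.0, 1)
        protein_hits.append(
            _coverage_hit(rng, gene_id, protein, t.length, identity, coverage_target, bitscore)
        )
        # decoys fall outside the 10% LCA bitscore window so the planted
        # taxon is recovered exactly
        for _ in range(int(rng.integers(0, 3))):
            decoy = str(rng.choice(universe.ref_proteins))
            decoy_identity = max(35.0, round(identity - float(rng.uniform(10.0, 25.0)), 1))
            protein_hits.append(
                _coverage_hit(rng, gene_id, decoy, t.length, decoy_identity,
                              min(coverage_target, 75.0), round(bitscore * 0.7, 1))
            )

        if gene_id in arg_ids:
            t.true_ko = str(rng.choice(list(universe.arg_kos)))
            t.arg_class = str(rng.choice(list(ARG_CLASSES)))
            arg_table[gene_id] = t.arg_class
        elif t.marker:
            # marker genes keep the stringent protein hit as their primary
            # evidence so the recorded identity/coverage reflect it
            pass
        elif rng.uniform() < 0.8:
            t.true_ko = str(rng.choice([k for k in universe.kos if k not in universe.arg_kos]))
        if t.true_ko:
            subject = f"kg:{t.true_ko}g1"
            ko_identity = max(40.0, round(identity - float(rng.uniform(0.0, 10.0)), 1))
            ko_hits.append(
                _coverage_hit(rng, gene_id, subject, t.length, ko_identity,
                              float(rng.uniform(60.0, 95.0)), round(2.0 * ko_identity + 55.0, 1))
            )

        has_domain = t.marker or rng.uniform() < 0.7
        if has_domain:
            domains = ["PF01738"] if t.marker else \
                sorted(rng.choice(domain_pool, size=int(rng.integers(1, 3)), replace=False))
            accessions: list[str] = []
            gos: list[str] = []
            for signature in domains:
                ipr, signature_gos = universe.domain_info[signature]
                accessions.extend([signature, ipr])
                gos.extend(go for go in signature_gos if go not in gos)
            t.domains = accessions
            t.gos = gos
            domain_annotations[gene_id] = (accessions, gos)

    # sub-threshold evidence for a rotating subset of non-annotatable genes:
    # each hit fails exactly one cutoff (bitscore / identity / coverage)
    unannotated = [g.gene_id for g in genes if not truth[g.gene_id].annotatable]
    for index, gene_id in enumerate(unannotated[: max(3, len(unannotated) // 2)]):
        t = truth[gene_id]
        t.sub_threshold = True
        protein = str(rng.choice(universe.ref_proteins))
        mode = index % 3
        if mode == 0:
            hit = _coverage_hit(rng, gene_id, protein, t.length, 80.0, 90.0, 49.0)
        elif mode == 1:
            hit = _coverage_hit(rng, gene_id, protein, t.length, 29.9, 90.0, 80.0)
        else:
            hit = _coverage_hit(rng, gene_id, protein, t.length, 80.0, 49.0, 80.0)
        protein_hits.append(hit)

    # incomplete / short genes: excluded by the complete-gene filter
    flags = ("01", "10", "11")
    for i in range(spec.n_incomplete_genes):
        gene_id = f"gx{i:04d}"
        if i % 4 == 3:  # complete flag but under the 100 bp floor
            flag, length = "00", int(rng.integers(60, 100))
        else:
            flag, length = flags[i % 4], int(rng.integers(spec.min_gene_length,
                                                          spec.max_gene_length + 1))
        sequence = _random_sequence(rng, length, _NUCLEOTIDES)
        genes.append(PredictedGene(gene_id, sequence, flag))
        truth[gene_id] = GeneTruth(gene_id, length, flag)

    # per-sample abundance counts over the complete genes; each gene is
    # always present in its home sample, sometimes elsewhere
    samples = [f"s{j + 1:02d}" for j in range(spec.n_samples)]
    counts: dict[str, dict[str, int]] = {sample: {} for sample in samples}
    complete_ids = [g.gene_id for g in genes if g.partial_flag == "00" and g.length >= 100]
    for i, gene_id in enumerate(complete_ids):
        home = samples[i % len(samples)]
        counts[home][gene_id] = 1 + int(rng.poisson(2.0))
        for sample in samples:
            if sample != home and rng.uniform() < 0.3:
                counts[sample][gene_id] = 1 + int(rng.poisson(1.0))

    return FixtureSet(spec, tree, universe, genes, truth, protein_hits, ko_hits,
                      domain_annotations, arg_table, counts)


# ---------------------------------------------------------------- targeted fixtures

def make_boundary_hits(query_length: int = 1000) -> list[tuple[SearchHit, bool]]:
    """Hits straddling the retention cutoffs, paired with whether the
    default thresholds (bitscore 50, identity 30, coverage 50) keep them."""

    def hit(identity, qend, bitscore):
        return SearchHit("gq", "subject", identity, qend, 1, qend, 1e-30,
                         bitscore, query_length)

    q90 = int(0.9 * query_length)
    return [
        (hit(80.0, q90, 49.0), False),   # bitscore just below
        (hit(80.0, q90, 50.0), True),    # bitscore at the cutoff
        (hit(29.9, q90, 80.0), False),   # identity just below
        (hit(30.0, q90, 80.0), True),    # identity at the cutoff
        (hit(80.0, int(0.499 * query_length), 80.0), False),  # coverage 49.9
        (hit(80.0, int(0.5 * query_length), 80.0), True),     # coverage 50.0
    ]


@dataclass
class ClusterFixture:
    genes: list[PredictedGene]
    #: (member gene id, founder gene id, planted percent identity)
    planted_pairs: list[tuple[str, str, float]]


def make_cluster_fixture(seed: int, n_families: int = 4,
                         max_members: int = 6,
                         founder_length_range: tuple[int, int] = (150, 400)) -> ClusterFixture:
    """Families of related nucleotide genes for clustering tests.

    Each family has a founder plus exact duplicates and substitution-only
    mutants at planted identities between 90 and 99%; mutants are never
    longer than the founder, so the founder is the greedy representative.
    """
    rng = np.random.default_rng(seed)
    genes: list[PredictedGene] = []
    planted: list[tuple[str, str, float]] = []
    for family in range(n_families):
        length = int(rng.integers(*founder_length_range))
        founder_seq = _random_sequence(rng, length, _NUCLEOTIDES)
        founder_id = f"f{family}m0"
        genes.append(PredictedGene(founder_id, founder_seq, "00"))
        for member in range(1, int(rng.integers(2, max_members + 1))):
            member_id = f"f{family}m{member}"
            if member == 1:  # exact duplicate
                genes.append(PredictedGene(member_id, founder_seq, "00"))
                planted.append((member_id, founder_id, 100.0))
                continue
            target_identity = float(rng.uniform(90.0, 99.0))
            n_mutations = int(round((1.0 - target_identity / 100.0) * length))
            # interior positions only: terminal substitutions would let the
            # free-end-gap alignment trim them, shifting identity off the
            # planted value
            positions = rng.choice(np.arange(1, length - 1), size=n_mutations,
                                   replace=False)
            mutated = list(founder_seq)
            for position in positions:
                current = mutated[position]
                mutated[position] = str(rng.choice([b for b in "ACGT" if b != current]))
            genes.append(PredictedGene(member_id, "".join(mutated), "00"))
            planted.append((member_id, founder_id,
                            100.0 * (length - n_mutations) / length))
    return ClusterFixture(genes, planted)
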