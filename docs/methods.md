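# Methods

## Problem setting

Assembly-based shotgun metagenomics produces, per habitat, a catalog of
full-length (complete) predicted genes pooled over many samples, made
non-redundant by sequence clustering and then annotated against protein,
ortholog, and domain reference databases. `gitkit` implements the desk-scale
computational core of that workflow: the Gene Information Table (GIT)
exchange format, the evidence-integration rules that populate it, the
catalog construction steps, KEGG module completeness evaluation, and the
cross-catalog analytics. External search engines (BLAST-style aligners,
domain scanners, ARG predictors) are *not* run by the toolkit; their tabular
outputs are parsed and integrated.

## The GIT format

One tab-separated row per gene, sixteen canonical columns:

```
1 gene_id  2 sample_id  3 gene_name  4 go_ids  5 ec_ids  6 interpro_ids
7 taxon_id  8 ko_id  9 cog_id  10 eggnog_id  11 weight  12 source
13 evalue  14 filters  15 percent_identity  16 percent_coverage
```

Multi-valued cells use `||` as a separator (it cannot collide with commas
in free-text names). The filters field — reserved tokens such as
`F.AntiBiotic.Resistance` plus per-antibiotic class subtokens — sits at
column 14. Missing numeric evidence serializes as the empty string and
parses back as *unassigned* (`None`; taxon 0), never as numeric zero; the
weight column (a gene copy/abundance weight with no prescribed units)
defaults to 1. Numbers are written with `%.12g`, which makes canonical
serialization a fixed point: `write ∘ read ∘ write` is byte-identical and
stable under repetition. Validation is report-only and checks key
uniqueness of `(gene_id, sample_id)`, numeric ranges
(identity/coverage in [0, 100], non-negative weight/evalue), and token
syntax (no whitespace, no separator characters).

## Taxonomy and assignment

The taxonomy is a parent-pointer tree in the nodes/names dump dialect with
exactly one self-parented root; loading validates parents and acyclicity.
LCA over a taxon set drops unassigned members (taxon 0) first so that
missing cross-references never drag an assignment to the root; an
all-unassigned set stays unassigned. `project_rank` returns the deepest
lineage node carrying the requested rank (deterministic even on malformed
lineages with repeated ranks); rank labels are compared case-insensitively
and no synonym aliasing is applied.

## Evidence integration

Hits arrive in the standard 12-column tabular dialect; query coverage is
computed on the query (gene) side as `100·(qend − qstart + 1)/qlen` with
1-based inclusive coordinates. A hit is retained when **all** of

* bitscore ≥ 50,
* percent identity ≥ 30,
* percent query coverage ≥ 50 (80 in the stringent setting)

hold; the cutoffs are a `Thresholds` dataclass and every one is
overridable. Best-hit selection uses the total order (bitscore desc,
e-value asc, subject id asc). Taxonomic assignment supports both best-hit
and LCA modes; the LCA candidate set is every retained hit within 10% of
the top bitscore (a conventional top-score window; configurable), since
the assignment procedure itself does not prescribe the hit set.

Integration emits exactly one record per input gene. The KO comes from the
best qualifying hit against KO-labelled sequences and is deliberately
independent of the protein-database hit (the two searches are routed
separately); EC numbers are cross-referenced from the KO, COG/eggNOG/gene
name from the protein best hit, GO/InterPro from the domain scan, and ARG
filter tokens from a two-column gene→class table (tagging is idempotent).
The `source` column and the recorded e-value/identity/coverage come from
the hit behind the *primary functional* assignment — KO first, then
protein, then domain-only (`InterPro`, with no hit statistics), else
`none`. This primary-evidence rule is a design choice where the record
layout leaves the statistics' provenance open.

Large FASTA inputs are split into 2 MB chunks for embarrassingly parallel
searching; chunking is greedy in input order, never splits a record, and
concatenating chunks reproduces the input exactly.

## Catalog construction

Only complete genes — partial flag `"00"` (closed at both ends) and length
≥ 100 bp — enter a catalog. Clustering is greedy and incremental in the
CD-HIT style: genes sorted by length descending (ties by id), each gene
joins the *first* existing representative it matches at the identity and
query-coverage cutoffs, else founds a cluster; representatives are
therefore the longest members and the scheme is fully deterministic.
Habitat catalogs default to identity 95% (or 90%) with 80% coverage of the
incoming gene; an alternative parameterization (identity 90, coverage 95,
length difference 80) is reachable through the same arguments, as the two
conventions circulate side by side. Catalog merging pools representative
sets at identity 90% with a shorter/longer ≥ 0.8 length-ratio prefilter
applied before any alignment, and retains per-representative provenance.

Pairwise identity is computed from a semi-global dynamic-programming
alignment (`Bio.Align.PairwiseAligner`; match +1, mismatch −1, gap open
−2, extend −0.5) with free terminal gaps on both sequences, so a short
gene contained in a longer one aligns end to end. Identity is matches over
aligned columns (first to last aligned pair, internal gaps included);
coverage is the aligned span on the query over its length. Freeing end
gaps on both sequences rather than only the longer one is symmetric,
standard for overlap detection, and indistinguishable on the regimes the
thresholds operate in.

Abundance matrices aggregate member-level per-sample counts onto
representatives (cells are sums, absences zero, totals conserved); a gene
is *unique* to a sample iff that sample holds its only nonzero cell.

## KEGG module completeness

Definitions follow the public grammar: space = ordered step (AND), comma =
alternative (OR), `+` = complex subunit (AND), `-` prefix = optional
component, `--` = definition gap (always satisfied), parentheses group.
The parser is a small recursive descent with positional errors; leaves
must match `K\d{5}` and every module must have at least one non-optional
leaf. Parse → canonical serialization → parse is a fixed point.

Completeness is strict: a module is **complete** iff every top-level step
evaluates true under KO-set membership (optional components always true),
**not detected** iff additionally no non-optional leaf is present and no
step is satisfied, else **incomplete** — the deterministic reading of the
red/grey/white heatmap display. A `max-missing-steps` allowance is not
applied (strictness matches the binary display); KO sets are
presence/absence, not abundance-weighted. With a filter restriction
(e.g. `F.AntiBiotic.Resistance`), only genes carrying the token contribute
KOs; definitions are untouched. The heatmap renders as a self-contained
HTML table (red `#c62828`, grey `#9e9e9e`, white), each cell carrying
module id, sample and satisfied/total step counts as hover metadata.

## Comparison analytics

Category counting tallies unique genes per label (KO, COG, eggNOG, GO,
filter tokens, EC *class* = first EC digit, or taxa projected to a rank);
genes without a label count under `unassigned`. Alpha diversity is
computed on these label-assignment tallies with `unassigned` excluded
first: Shannon (natural log, base exposed), Simpson `1 − Σp²`, inverse
Simpson `1/Σp²`, richness = labels present. Fold changes use a
pseudocount (default 1) on both sides over the label union, so swapping
arguments inverts every ratio. Annotation deltas between two versions of
the same catalog report observed-label set differences and per-version
assigned-gene counts; "possible label" vocabularies (database-wide label
universes) are the caller's to supply.

Marker-OTU counting treats taxon-assigned variants of a universal
single-copy gene as an OTU proxy: a gene counts iff it carries the marker
domain (default PF01738, ribosomal protein S30), reaches identity ≥ 30 and
coverage ≥ 80, and is taxon-assigned; counts are grouped at a
caller-chosen rank (default superkingdom, the natural
bacteria/archaea/eukaryota grouping).

## Synthetic data

The generator produces every input with known ground truth, deterministic
per seed (byte-identical files):

* **Taxonomy** — root, the three superkingdoms, one seeded chain to
  species under each, remaining nodes attached one rank below uniformly
  chosen parents. Default 80 nodes (500 for LCA stress tests).
* **Universe** — 120 reference proteins on random species with
  COG/eggNOG/gene-name cross-references; 40 KOs of which four are the ARG
  demo set (tetV K18215, tetM K18220, tetX K18221, blaTEM K18698); module
  definitions sampled over the KO pool (the first two exclusively over ARG
  KOs); ARG classes drawn from a fixed 30-name antibiotic-class list.
* **Genes** — default 200 (1,000 in the heavier checks), uniform-composition
  nucleotide sequences of 150–600 bp, plus a block of incomplete genes
  (partial flags 01/10/11 and sub-100 bp genes) that must be removed by the
  complete-gene filter.
* **Evidence** — a chosen fraction (default 0.7) of genes gets evidence
  strictly above every cutoff: identities ≥ 40, bitscores a monotone
  function of identity (so best-hit order matches the planted subject),
  coverage planted either ≥ 82% (the stringent half) or 56–78% — making the
  stringent-versus-default assignment sets exactly predictable. Decoy hits
  sit outside the 10% LCA window so planted taxa are recovered exactly.
  Unannotatable genes get either nothing or hits failing exactly one
  cutoff (bitscore 49, identity 29.9, or coverage 49%), recorded as
  sub-threshold in the truth table — closure means there is no third state.
* **Markers/ARGs** — ten marker genes (5 bacterial, 2 archaeal, 3
  eukaryotic) carry PF01738 with stringent-coverage protein evidence as
  their primary statistics; ARG genes are forced onto the four demo KOs
  and into the ARG class table.
* **Clustering fixtures** — families of a founder plus exact duplicates
  and substitution-only mutants at planted identities of 90–99%;
  substitutions avoid terminal positions so the free-end-gap alignment
  cannot trim them and planted identity is analytically exact. Indels are
  off by default for the same reason.

What the generator does **not** emulate: real database accession
namespaces, read-level noise and quality scores, indel-rich divergence,
compositional bias, chimeric assemblies, or abundance structure beyond a
home-sample-plus-spillover pattern. Passing tests therefore demonstrate the
correctness of the algorithms under controlled conditions, not annotation
accuracy on real environmental data.

## Numerical and scale choices

All randomness flows through seeded `numpy` generators; outputs are
byte-deterministic per seed. Float serialization uses `%.12g`. Test and
verification problem sizes — 1,000-gene integration fixtures, a 500-node
taxonomy with 1,000 random LCA queries, 50 clustering sets of ≤ 30 genes,
25 modules enumerated over all KO subsets (≤ 64 each) — were chosen so the
full suite completes in a couple of minutes on one CPU while still
exercising every rule at its boundaries.

## Known limitations

* The greedy clusterer is O(n·k) pairwise alignments (k = representatives)
  with no k-mer prefilter; it is meant for desk-scale catalogs and
  oracle-verifiable correctness, not for hundred-million-gene production
  runs.
* Name-based taxon resolution, rank-synonym aliasing (superkingdom vs
  domain), and live reference-database access are out of scope.
* `not_detected` vs `incomplete` depends on the strict-step semantics; a
  module whose only satisfied steps are `--` gaps is reported incomplete,
  not not-detected.
* GIT weights are opaque non-negative reals; no normalization is implied.
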