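# gitkit

Gene Information Tables and gene-catalog analytics for assembly-based
shotgun metagenomics.

## What it is for

Comparative metagenomics built on *complete* genes: predicted coding
sequences closed at both ends are pooled per habitat, clustered into a
non-redundant gene catalog, annotated against protein / KEGG-ortholog /
domain references, and integrated — one row per gene — into a **Gene
Information Table (GIT)**: a plain tab-separated format carrying gene name,
GO, EC, InterPro, taxon, KO, COG/eggNOG, a weight, annotation source,
homology statistics (e-value, percent identity, percent query coverage)
and filter tokens such as `F.AntiBiotic.Resistance` for antibiotic
resistance genes. GITs are the exchange currency for everything downstream:
cross-habitat comparison, alpha diversity of annotation labels, marker-gene
OTU proxies, and KEGG module completeness heatmaps.

`gitkit` is aimed at bioinformaticians who have the search outputs
(BLAST-style tabular hits, InterProScan-style domain scans, ARG
predictions) and want a deterministic, testable integration and analysis
layer — on the command line or as a Python library.

## The core rules

* **Hit retention** — a hit survives iff bitscore ≥ 50 ∧ identity ≥ 30% ∧
  query coverage ≥ 50% (stringent mode: 80%), with coverage =
  `100·(qend − qstart + 1)/qlen` on the gene side.
* **Taxonomy** — best hit, or the lowest common ancestor (LCA) of all
  retained hits within 10% of the top bitscore; unassigned evidence never
  forces the root.
* **Catalogs** — complete genes only (`partial=00`, ≥ 100 bp), clustered
  greedily longest-first at 95%/90% identity with 80% query coverage;
  catalog merging at 90% identity with an 80% length-difference prefilter.
* **Module completeness** — KEGG definition grammar (space = step, comma =
  OR, `+` = complex, `-` = optional, parentheses); a module is *complete*
  iff every step is satisfied by the sample's KO set, *not detected* iff
  none of its non-optional KOs occur, else *incomplete*.
* **Diversity** — Shannon (−Σ pᵢ ln pᵢ), Simpson (1 − Σ pᵢ²), inverse
  Simpson (1/Σ pᵢ²) and richness over per-label unique-gene tallies.

Everything is exercised against planted ground truth from a built-in
deterministic synthetic-data generator (`gitkit.fixtures` /
`gitkit fixtures`), so no external downloads are needed.

## Worked example

```python
from gitkit.fixtures import FixtureSpec, generate
from gitkit.compare import category_counts, alpha_diversity, marker_otu_count
from gitkit.kegg_modules import module_matrix

fx = generate(FixtureSpec(seed=42, n_genes=200))   # synthetic habitat
records = fx.run_integration()                     # evidence -> GIT rows

annotated = sum(1 for r in records if r.source != "none")
print("genes in GIT:", len(records))
print("annotated:", annotated, f"({100*annotated/len(records):.1f}%)")

div = alpha_diversity(category_counts(records, "ko"))
print(f"KO diversity: shannon={div.shannon:.3f} simpson={div.simpson:.4f} "
      f"inv_simpson={div.inv_simpson:.2f} richness={div.richness}")
print("marker OTUs:", marker_otu_count(records, fx.tree))

m = module_matrix(None, fx.universe.modules,
                  records_by_sample={"catalog": records},
                  restrict_to_filter="F.AntiBiotic.Resistance")
print(m.to_tsv(), end="")
```

prints

```
genes in GIT: 200
annotated: 140 (70.0%)
KO diversity: shannon=3.539 simpson=0.9681 inv_simpson=31.36 richness=39
marker OTUs: {'Eukaryota': 3, 'Bacteria': 5, 'Archaea': 2}
#sample	M00001	M00002	M00003	M00004	M00005	M00006	M00007	M00008
catalog	complete:3/3	complete:3/3	not_detected:0/3	not_detected:0/3	not_detected:0/3	not_detected:0/3	not_detected:0/3	not_detected:0/3
```

The dataset was generated with a 70% annotatable fraction, and exactly
70.0% of records come back annotated — the generator plants evidence
strictly above or below the retention cutoffs, so recovery is exact. The
ten planted single-copy marker genes (PF01738, identity ≥ 30, coverage
≥ 80, taxon-assigned) are recovered per superkingdom, and restricting KO
sets to the ARG filter leaves only the two modules built from the
tetV/tetM/tetX/blaTEM demo KOs complete.

The same flow on the command line:

```bash
gitkit fixtures --seed 42 --n-genes 200 --out fx/
gitkit integrate --genes fx/genes.fasta --uniprot-hits fx/uniprot_hits.tsv \
    --kegg-hits fx/kegg_hits.tsv --interpro fx/interpro.tsv --arg fx/arg.tsv \
    --xref fx/xref.tsv --nodes fx/nodes.dmp --names fx/names.dmp -o catalog.git
gitkit cluster --genes fx/genes.fasta --identity 95 --coverage 80 \
    -o catalog.fasta --clusters catalog.clstr
gitkit modules --git catalog.git --modules fx/modules.tsv \
    --filter F.AntiBiotic.Resistance -o heatmap.html --table matrix.tsv
gitkit compare --git catalog.git --category ko --diversity
gitkit validate catalog.git
```

## Layout

```
src/gitkit/
  git_format.py    GIT read/write/validate (16 canonical columns)
  taxonomy.py      nodes/names dump loader, lineage, LCA, rank projection
  integration.py   hit parsing/filtering, best-hit & LCA assignment, integrate()
  catalog.py       complete-gene filter, greedy clustering, merging, abundance
  kegg_modules.py  definition grammar, completeness, heatmap rendering
  compare.py       category counts, deltas, fold changes, diversity, marker OTUs
  fixtures.py      deterministic synthetic data with planted ground truth
  cli.py           the `gitkit` command group
docs/methods.md    model, rules, parameter defaults, limitations
```
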