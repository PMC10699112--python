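# meiocascade

Reusable pipeline for identifying apex ("master") regulators of two
biological phases from two-condition expression data, and for comparing the
strength of purifying selection acting on the two phase cascades.

Stages:

1. **diffexpr** — quantile normalization, per-gene Welch t-test on log2
   intensities (optional variance moderation), Benjamini–Hochberg control,
   and the phase set logic (intersection of replicate up-sets; up-set minus
   return-to-growth down-set).
2. **netbuild** — protein-interaction subnetwork induction (optionally with
   first neighbors), TF-binding-table restriction, above-mean-target TF
   selection, and integration of TF→TF / TF→TG regulatory edges with
   reciprocal TG–TG physical pairs into a directed cascade. Node hierarchy
   is summarized by `v = (out − in) / (out + in)`; TFs at `v = 1` are
   called master regulators.
3. **enrich** — one-tailed hypergeometric over-representation against GMT
   gene sets with BH control, consensus between annotation runs, and
   extraction of the enriched gene pool.
4. **cascade_compare** — role-wise (MR / TF / TG) unique-vs-common
   partition of two phase cascades.
5. **molevo** — ortholog-pair filtering (orthology type, confidence,
   per-species percent identity), Nei–Gojobori (1986) dN/dS with
   Jukes–Cantor correction, a codon-column bootstrap Z-test for purifying
   selection, Rosner's generalized ESD outlier removal, and per-species
   Mann–Whitney comparison of ω distributions.
6. **synthetic** — seeded generators for every input (expression matrices
   with planted up-regulated genes, networks with planted zero-in-degree
   regulators, annotations with planted enriched terms, codon alignment
   pairs evolved under a target ω), with ground truth for recovery tests.
7. **io / cli / pipeline** — flat-file TSV/FASTA/GMT/SIF/GraphML readers
   and writers, a click CLI, and a YAML-configured `run-all` driver.

## CLI

```bash
# write a complete seeded synthetic study (expression, networks,
# annotations, ortholog alignments, ground truth, pipeline config)
meiocascade simulate --outdir study --seed 1

# run every stage end to end; results land in study/results/
meiocascade run-all --config study/config.yaml

# individual stages
meiocascade deg --matrix M.tsv --conditions C.tsv --control YPA --treatment SPM --alpha 0.05 --lfc 1
meiocascade network --seeds genes.txt --ppin ppin.tsv --grn grn.tsv --expand-neighbors
meiocascade enrich --gmt go.gmt --genes set.txt --alpha 0.05
meiocascade evolve --pairs pairs.tsv --aln-dir alns/ --nboot 1000 --seed 42
meiocascade compare-evolution --dnds dnds.tsv
meiocascade compare-cascades --a init_summary.json --b commit_summary.json
```

`run-all` writes a machine-readable `report.json` (counts, MR lists,
per-species U and p) plus per-phase node/edge tables, GraphML and SIF
exports; identical config + seed gives a byte-identical report.

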