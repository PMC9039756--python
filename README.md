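# xreact

Allele-specific analysis of X-chromosome reactivation (XCR) from F1-hybrid
RNA-seq. In female mouse cells one X chromosome is silenced (XCI); in a
Cast/EiJ × C57BL/6 hybrid, strain SNPs let every read be assigned to the
inactive-X (cast) or active-X (Bl6) allele. After perturbing the silencing
machinery (*Xist* knockdown plus a DNMT1 inhibitor), some X-linked genes
re-express from the inactive X. `xreact` classifies each gene from its
allelic counts, correlates reactivation with genomic features, tests spatial
clustering within TADs, and analyses promoter methylation. A synthetic-data
generator with planted ground truth makes every stage testable end to end.

Intended users: computational biologists working on XCI/XCR, allele-specific
expression, or anyone needing a tested reference pipeline for
allelic-imbalance class calling.

## The model

For gene *g*, condition *c* and replicate *r*, let `k_gcr` cast reads out of
`n_gcr` total allelic reads. The **allelic ratio** is `k / n` pooled over
replicates, and the per-gene reactivation effect is the ratio difference

    Δ_g = ratio_g(treated) − ratio_g(control).

Classification proceeds in three steps:

1. **Informative filter** — keep genes with mean `n` ≥ 10 per condition
   (both conditions analysed).
2. **Escapees** — genes whose mean control cast ratio ≥ 0.10 are already
   expressed from the inactive X and are excluded from testing.
3. **Reactivation test** — per remaining gene, replicate cast counts are
   modelled beta-binomially, `k_gcr ~ BB(n_gcr, μ_gc, ρ_g)`, with a
   condition-specific mean and a gene-level dispersion shared between
   conditions. The likelihood-ratio test of H0: `μ_g,treated = μ_g,control`
   is referred to χ²(1); per-gene ML dispersions are moderated toward the
   across-gene median before the final fixed-dispersion fit (the standard
   few-replicate practice). Benjamini–Hochberg FDR < 0.05 with `Δ_g > 0`
   calls a gene reactivated. A pooled Fisher exact test is available as
   `--method fisher` and serves as the independent oracle in the test suite.

Downstream: Mann-Whitney comparisons of per-gene features (CpGs in the 2 kb
upstream of the TSS, SINE/LINE counts within ±100 kb by midpoint, distance
to the nearest escapee), metagene signal profiles (TSS ± 3 kb and scaled
gene bodies), a per-TAD two-sided exact binomial test of the reactivated
fraction against the chromosome-wide fraction, differential promoter
methylation on MeD-seq-style counts (pooled two-proportion test, BH-FDR),
promoter clustering with a permutation purity test, and repeat-flank
methylation with gene-level permutation calibration.

## Worked example

```bash
xreact all --seed 1 --out-dir xreact_out
```

or, in Python:

```python
from xreact import SimulationConfig, simulate_dataset, classify_genes, rank_reactivated
from xreact.classify import load_count_table
from xreact.core import read_gene_table

bundle, truth = simulate_dataset(SimulationConfig(seed=1), "xreact_out")
genes = read_gene_table(bundle["genes"])
table = load_count_table(bundle["counts"])
classes = classify_genes(table, [g.gene_id for g in genes])
print(classes["status"].value_counts().to_string())
```

prints

```
status
uninformative      2165
non_reactivated     316
reactivated          86
escapee              45
```

i.e. of the 2,612 simulated X-linked genes, 447 carry sufficient allelic
information (the remaining 2,165 are too shallow to call), 45 escape
silencing in the control, and 86 show significant cast-allele reactivation
in the treated population. Ranking the reactivated genes by significance:

```python
mecp2 = truth.genes.loc[truth.genes["tier"] == "mecp2", "gene_id"].iloc[0]
ordered, above = rank_reactivated(classes, mecp2)
print("genes more significant than Mecp2:", above)
```

```
genes more significant than Mecp2: 7
```

`ordered` starts with the strongest effects, e.g. gene `G0450`
(p ≈ 8.3e-62, Δ ≈ 0.32): its inactive-X allele rose from ~0 to ~32% of its
expression. The `all` command additionally writes the feature comparisons
(reactivated genes have more upstream CpGs and SINEs and fewer LINEs), the
per-TAD enrichment table (4 TADs enriched for reactivated genes, 1
depleted), the differential promoter methylation table (16 reactivated-gene
promoters significantly hypomethylated), the clustering and repeat-flank
reports, and a manifest of output hashes.

## Layout

```
src/xreact/core.py        intervals, genes, repeats, signal tracks; BED/bedGraph/TSV I/O
src/xreact/simulate.py    synthetic bundle generator + ground truth
src/xreact/classify.py    informative filter, escapee calls, beta-binomial LRT
src/xreact/features.py    per-gene features, Mann-Whitney, metagene profiles
src/xreact/tads.py        per-TAD binomial enrichment and TAD summaries
src/xreact/methylation.py promoter methylation, clustering, repeat flanks
src/xreact/overlap.py     gene-list overlap statistics
src/xreact/pipeline.py    end-to-end orchestration (+ YAML config)
src/xreact/cli.py         `xreact` command line
docs/methods.md           modelling choices, defaults and limitations
```
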