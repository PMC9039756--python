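# Methods

## Coordinates and formats

All coordinates are 0-based half-open (BED convention). A gene's TSS is a
single base: `start` on the plus strand, `end − 1` on the minus strand.
Strand-aware TSS windows treat the TSS base itself as excluded when the
downstream extent is zero, so the "2 kb upstream" promoter bin is
`[tss − 2000, tss)` on the plus strand and its mirror image on the minus
strand. Only `chrX` is exercised; records on other chromosomes pass through
unvalidated. Repeat annotations ride in an extended BED (name =
`class:family`, score = age rank, column 7 = element length); signal tracks
are plain bedGraph, validated sorted and overlap-free, with gaps read as
zero signal.

## Allelic classification

The analysed unit is the per-gene, per-replicate pair (cast reads, Bl6
reads). Allelic fractions are scale-free, so no library-size normalisation
enters the test; a CPM export exists for display only.

* **Informative filter**: mean total allelic reads ≥ 10 per condition, in
  the control and treated conditions (the two the differential test uses).
  The threshold is the community convention for allelic calling and is a
  config knob.
* **Escapee call**: mean over control replicates of the per-replicate cast
  ratio ≥ 0.10, following the operational definitions in the escapee
  literature; config knob. Escapees are excluded from the reactivation test
  — they are already expressed from the inactive X.
* **Reactivation test**: beta-binomial likelihood-ratio test. Under H1 each
  condition has its own mean cast fraction; a single per-gene dispersion ρ
  is shared between conditions and estimated by maximum likelihood
  (Nelder-Mead on logit-transformed parameters; ρ ∈ (0, 0.5); the binomial
  limit is used below ρ = 1e−6 for numerical stability). With three
  replicates per condition the per-gene ML dispersion is very noisy —
  chance replicate heterogeneity moves the LRT by orders of magnitude — so
  the per-gene estimates are moderated toward the across-gene median,
  ρ\* = (d₀·ρ_median + d·ρ_gene)/(d₀ + d) with d₀ = 20, d = 4, before a
  final LRT at fixed ρ\* (means re-profiled under H0 and H1). This is the
  usual few-replicate dispersion-moderation strategy; without it the
  significance *ranking* of genes with identical true effects is dominated
  by dispersion noise. p-values come from χ²(1), Benjamini–Hochberg FDR is
  applied across tested genes, and "reactivated" additionally requires a
  positive treated-minus-control pooled ratio difference. Genes with zero
  allelic reads in a condition are recorded untested (missing p, status
  non-reactivated). A pooled Fisher exact test (`method="fisher"`) is both
  a fallback and the cross-check oracle in the test suite.
* **Ranking**: reactivated genes are ordered by ascending p, ties broken by
  descending Δratio then gene id; "count above the reference" counts
  strictly smaller ranks.

## Feature correlates

Per-gene features: CpG positions falling in the strand-aware upstream 2 kb
window; SINE/LINE elements whose midpoint (floor of (start+end)/2) lies in
the closed ±100 kb window around the TSS — midpoint membership avoids
double-counting an element between adjacent gene windows; LINE strata by
length (full-length ≥ 6 kb, boundary inclusive) and by age rank (age ranks
are a required input annotation, not a built-in table); TSS-to-TSS distance
to the nearest escapee with self-exclusion (missing when no other escapee
exists) and to the *Xist* locus.

Group comparisons use the two-sided Mann-Whitney U test: exact when
n₁·n₂ ≤ 400 (the untied exact distribution, or full enumeration of group
assignments when ties are present and the combination count is ≤ 3×10⁵),
otherwise the normal approximation with tie and continuity correction.
Identical pooled samples return p = 1.

Metagene profiles average per-bin mean signal across genes, minus-strand
genes reversed. `tss` mode bins `[tss − 3 kb, tss + 3 kb)` at 50 bp;
`scaled_body` mode concatenates upstream flank bins, the gene body rescaled
to 100 bins, and downstream flank bins; genes shorter than the body bin
count are skipped with a warning. A constant track yields a constant
profile (mass conservation), which the tests assert.

## TAD enrichment

Genes are assigned to the TAD containing their TSS (half-open intervals;
gap TSSs unassigned). The chromosome-wide fraction p₀ is reactivated /
(reactivated + non-reactivated) among genes inside TADs; escapees and
uninformative genes are excluded from both numerator and denominator (a
flag can include escapees in the denominator). Each TAD with ≥ 1 classified
gene gets a two-sided exact binomial p by minimum-likelihood summation —
p = Σ pmf(k) over all k with pmf(k) ≤ pmf(observed) — plus a signed
−log₁₀ p (positive above p₀, zero at exact equality). Flags use raw
p < 0.05 by default, mirroring the conventional per-TAD display; BH
correction across TADs is available but off. TAD feature summaries report
SINE/LINE/CpG densities per Mb and mean track signal per TAD, compared
between significantly enriched TADs and non-significant TADs (the depleted
TAD excluded from the comparison group).

## Methylation

MeD-seq-style counts per region per sample are normalised to counts per
million region reads within each sample, so global demethylation or depth
differences cancel. Promoters are TSS ± 1 kb (config knob). Differential
methylation pools replicates within condition and tests each region's share
of its condition's reads (chi-square with continuity correction; Fisher
exact when an expected cell is below 5), BH-corrected over all tested
regions; "significantly lower" additionally requires a lower treated rate.
Regions with zero pooled counts in both conditions are recorded untested.

Promoter clustering: average-linkage Euclidean clustering of per-region
z-scored rates, cut at k = 2; purity is the larger fraction of
reactivated-gene promoters captured by one cluster, with a permutation p
from 1,000 class-label shuffles. Because rows are z-scored, only *patterns*
across samples (not overall levels) can separate clusters.

Repeat-flank methylation: each element with midpoint within 100 kb of a
classified TSS is assigned to the class of the nearest such TSS (an element
between genes of both classes goes to the closer one). Its flank statistic
is the coverage-normalised methylation density over
`[start − 1 kb, start) ∪ [end, end + 1 kb)`: region rates (CPM averaged
across samples) are overlap-weighted and divided by the covered bases.
Counted regions may overlap (a promoter window on top of a background bin),
so a raw sum would track local region geometry — gene density — rather than
methylation level; the density form removes that confound. The group
comparison keeps the Mann-Whitney U statistic but calibrates its p-value by
permuting class labels over the nearest *genes*: elements flanking the same
gene share DNA and counted regions, so the gene, not the element, is the
exchangeable unit (element-level asymptotics are wildly anti-conservative
here). The pipeline runs this comparison on baseline (control) samples,
keeping it independent of any induced promoter changes.

The male sample (single replicate, condition `male_xa`) is consumed
descriptively only, as the active-X methylation baseline.

## Synthetic data generator

The generator emulates the structure of the study design: 2,612 X-linked
genes on a 171 Mb chromosome, 447 allelically informative, 45 escapees
(one designated *Xist*, cast fraction 0.95), 86 reactivated in the treated
condition only (one designated *Mecp2* plus 7 with strictly larger
effects), four conditions × 3 replicates plus a male baseline methylation
sample, 112 TADs with 4 seeded enriched and 1 depleted, and 16
hypomethylated reactivated promoters.

Counts: totals are negative binomial (mean 200 reads/replicate for
informative genes, 1 for uninformative; dispersion 1/60), cast reads
binomial given the total. Default cast fractions: silenced 0.001
(repression in this system is effectively complete; the residual is a free
parameter), escapees U(0.15, 0.50), reactivated genes in the treated
condition tiered as U(0.08, 0.09) for the bulk, 0.18 for *Mecp2* and
U(0.28, 0.30) for the seven stronger genes. The tiers are separated widely
enough that class recovery and the significance ranking are
near-deterministic at default depth — by design, since the recovery checks
compare exact counts. With effect sizes zeroed (`zero_effect()`), the
pipeline's false-call rate calibrates against the FDR level.

Placement: TADs tile the chromosome with ±20% width jitter. Classified
genes are apportioned so each background TAD's reactivated fraction sits at
the chromosome-wide fraction (largest-remainder allocation) — independent
placement would create spurious 3/3-reactivated TADs — while enriched TADs
receive ~7/8 reactivated genes and the depleted TAD ~20 genes with none.
A configurable fraction of escapees is placed 50–400 kb from a random
reactivated gene (the proximity effect); other genes are uniform.

Features: per-gene Poisson counts of CpGs in the upstream 2 kb (means 35
reactivated/escapee vs 15 otherwise) and of SINEs/LINEs in ±100 kb (SINE
55 vs 25; LINE 10 vs 32). Because neighbouring ±100 kb windows overlap,
each gene's observed count includes class-independent background from its
neighbours, which dilutes the per-gene contrast — the planted separations
account for that. Signal tracks are deterministic class-amplitude Gaussian
TSS peaks (CTCF, Rad21, H3K4me3, H3K27me3) and flat gene-body coverage for
the *Xist* CHART analogue, emitted as run-length-encoded bedGraph.

Methylation: Poisson counts at depth 150 per unit rate over a registry of
per-gene promoters plus a 2 kb grid tiling ±102 kb around informative
genes (so arbitrary flank intervals are covered by counted regions).
Female base rates are spatially flat (1.0 everywhere) — the only female
effect is the 16 planted hypomethylated promoters (×0.4 in the treated
condition). Flat female rates are what make the repeat-flank comparison
null *by construction*; class-dependent promoter rates would plant a
spatial methylation confound near reactivated genes. The expressed-gene
promoter hypomethylation signal is carried by the male baseline sample
(rate 0.2 at informative promoters), matching its role as an inference aid.

What the generator does **not** emulate: read-level noise (mapping bias,
SNP coverage heterogeneity), correlated feature landscapes (real CpG
islands, repeat clustering beyond gene neighbourhoods), condition-dependent
expression changes (totals are condition-independent), partial or skewed
XCI, and autosomes. Passing recovery tests therefore demonstrates that the
statistical machinery recovers a planted structure of the reported shape —
not that the pipeline is robust to every artefact of real allelic RNA-seq.

## Problem sizes and determinism

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical (config, seed) gives bit-identical
bundles, and `regenerate_counts_only` redraws count noise over a fixed
truth for stability and power checks. The test suite runs the full-size
population once (seed 1) and uses a ~400-gene configuration for property
and calibration tests; the 20-run calibration checks use the scaled
configuration with fresh noise per run. The acceptance script runs the
full-size population at the caller's seed.

## Known limitations

* The beta-binomial LRT relies on the χ²(1) asymptotics with 3+3
  replicates; its FDR behaviour is verified empirically on the generator's
  null, not proven.
* Exact Mann-Whitney with ties falls back to the normal approximation when
  the enumeration would exceed 3×10⁵ assignments.
* The repeat-flank analysis infers flank methylation from region-level
  counts by overlap weighting; with coarse regions this is an
  approximation to base-resolution methylation.
* External gene lists for the overlap module must be pre-curated symbol
  lists; no alias resolution is attempted.
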