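# Methods

This note documents the statistical models and design choices behind each
stage of the pipeline, the synthetic study conditions, and what the packaged
checks do and do not demonstrate.

## Coordinates and region assignment

All intervals are 0-based half-open in memory. The per-cytosine report
dialect uses 1-based positions on disk (the convention of cytosine reports
emitted by bisulfite callers); the reader/writer converts at the boundary.

Promoters are strand-aware upstream windows of configurable width
(default 2,000 bp — matching the 2-kb flanks used in the metagene profiles;
genome annotations rarely define promoters explicitly), truncated at
chromosome ends. Every base maps to exactly one leaf label under the
precedence **promoter > exon > intron > TE > intergenic**; the precedence is
configurable, and `region_base_counts` verifies that the leaf labels
partition the genome exactly. Point features (cytosines, sRNAs) are assigned
by a single anchor — the strand-aware 5′-most mapped base — so a read
spanning a boundary is never double-counted; for sRNAs the 5′ end is also
the biologically loaded end. Where genes overlap each other, a warning is
logged and interval associations keep all gene–feature pairs. In the sRNA
length × region table the genome is dichotomized genic vs. intergenic, so
TE-anchored records fold into the intergenic column; the DMR composition
report keeps TE as its own category.

## Methylation model

The level of a site is m/(m+u). The level of a *region* is always the
weighted methylation level, Σm/Σ(m+u) over its covered cytosines — deeply
covered sites dominate, and the statistic is invariant to how the region is
partitioned. Undefined levels (no coverage) are NaN, never 0, because 0 is a
meaningful observation.

**DMCs.** Replicate counts are pooled per condition (the calling rules
describe a single test per comparison with two replicates; pooling is the
simplest faithful reading) and each site is tested with a two-sided Fisher
exact test. A site is a DMC when pooled depth ≥ 3 in both conditions, the
absolute difference of pooled levels is ≥ 0.33, and p ≤ 0.05. Two-sided
because both hyper- and hypo-methylation are of interest; "difference"
is absolute, not relative. No multiple-testing correction is applied by
default — the thresholds are the procedure — but the enrichment module
exposes BH adjustment for users who want it.

Fisher p-values for tables with grand total ≤ 500 are computed with exact
big-integer arithmetic (sums of binomial-coefficient products over a common
denominator), so they agree with a rational brute-force enumeration to float
rounding; larger tables use log-space hypergeometric mass with a relative
tie tolerance of 1e-12.

**DMRs.** Maximal runs of ≥ 3 same-context, same-direction DMCs with
consecutive gaps ≤ 300 bp, spanning first to last member DMC (half-open).
Contexts are never merged — CHH signal would be diluted by CG baselines.
Each region is re-tested by Fisher on counts pooled over *all* cytosines of
the context in the span (not only the member DMCs) and dropped if p > 0.05.
Consensus red-light hypo-DMRs are the interval **intersections** of
overlapping same-context hypo regions from the R-vs-normal and R-vs-FR
comparisons — the conservative choice for a region claimed in both.

**Metagene profiles.** Each gene body is divided into 20 equal bins
(width = length/20, so boundaries partition the body exactly); each 2-kb
flank into 20 fixed 100-bp bins; bins are orientation-corrected so bin 0 is
the distal 5′ flank. Counts are pooled across genes per bin and converted to
weighted levels. Genes shorter than the bin count are skipped with a
warning.

A caveat stated once and used twice below: the Fisher test assumes binomial
(within-condition) sampling. Under biological overdispersion it is
anti-conservative, which is a property of the stated rule set, not of this
implementation.

## Differential expression

Fold-changes are ratios of pseudocounted (0.5 CPM; zeros are common) mean
CPMs. The p-value comes from a negative-binomial exact test: counts are
pooled per condition after scaling to a common library size, and the
double-tail probability of the split given the total is computed with NB
shape n_reps/φ per side. With φ = 0 — including unreplicated input, where φ
cannot be estimated — the test reduces to the classical conditioned
hypergeometric (Fisher) test on the 2×2 count split. The common dispersion φ
is estimated by conditional maximum likelihood over all replicated
conditions: the likelihood of within-condition counts given their sum does
not involve the mean, and maximizing it pools information across all genes.
A two-replicate moment estimator was rejected because a one-degree-of-freedom
variance falls below its expectation more often than not, biasing φ low and
making every test anti-conservative; the CML estimate recovers the
generating dispersion of the synthetic data to within a few percent.

A gene is DE when |log2 FC| ≥ 1 and p ≤ 0.001; the pipeline-level DE set is
the **union** over all nine R-vs-FR condition pairs (any red sample against
any far-red sample), with the contrast list configurable. The union is
faithful to the stated selection rule but multiplies the null rate: with a
perfectly calibrated per-pair test at α = 0.001, the expected fraction of
null genes in the union is ≈ 9α. Users wanting a family-wise guarantee
should restrict the pairs or adjust α; the package deliberately does not do
so silently.

Expression profiles are log2((CPM+0.5)/(CPM_normal+0.5)) per condition in
the fixed order FR5, FR2, FR1, normal, R1, R2, R5, then mean-centered.
Clustering is plain k-means (Euclidean, k-means++ seeding, 50 restarts,
fixed RNG seed), with cluster ids renumbered by descending size so labels
are reproducible. Term enrichment is the one-sided hypergeometric upper
tail over a user-supplied gene→term map; no ontology-graph propagation is
performed, and ties for "most significant term" resolve lexicographically.

## The candidate cascade

A gene is nominated when (1) it is in the supplied metabolic gene set (an
input file — deriving it would require a functional annotation pipeline out
of scope here); (2) a consensus hypo-DMR overlaps its promoter or gene body
(which one is recorded; a promoter-only mode exists); (3) at least one
perfect-unique sRNA is 24 nt with 5′ ∈ {A, G, U}, maps wholly inside that
DMR, is present (pooled count ≥ 1) under FR or normal and absent (pooled
count = 0, configurable) under R; and (4) the gene is DE with higher
expression under red light. Predicate 4 can be toggled off for
methylation-only screens. Candidates carry all supporting evidence and are
ranked by |log2 FC| × ΔmC × log10(1 + pooled FR sRNA count) — a
deterministic stand-in for the manual shortlisting a curator would do; the
score is monotone in each evidence axis and zero when any axis vanishes.

## Synthetic study conditions

The generator emulates the data regime the analysis assumes; defaults are
the study conditions and are not tuned per run.

* **Genome**: 2 chromosomes × 1.8 Mb, 500 genes (1–3 kb, 1–4 exons),
  2-kb promoters, TEs scattered in intergenic gaps.
* **Methylome**: 3 conditions × 2 replicates; cytosines at mean spacing
  15 bp (context mix CG/CHG/CHH = 0.25/0.25/0.5); depth 1 + Poisson(9);
  beta-binomial counts with context means CG 0.8, CHG 0.4, CHH 0.1 and
  intra-class overdispersion 0.1.
* **Planted RdDM targets**: 20 genes carry a 1,000-bp promoter-proximal
  window that is CHH-hypermethylated (level 0.5 — the level siRNA-maintained
  promoter methylation plausibly holds) under normal/FR; under R the CHH and
  CHG window means drop by 0.4 (CHG from 0.4 to 0.0). A naive "subtract the
  effect from the genome-wide CHH baseline of 0.1" is infeasible (levels
  cannot go negative), which is why the windows are modelled as maintained
  targets that *lose* methylation under red light — the biology the cascade
  is looking for.
* **sRNAs**: 4,000 background records with lengths drawn from the packaged
  reference marginal (71.93 % at 24 nt), uniform sequences (collisions
  re-drawn, so uniqueness holds by construction), per-sample Poisson counts
  around a lognormal abundance (median 10); 5 % of records are emitted with
  a mismatch or a second genomic hit to exercise the perfect-unique filter.
  Each planted gene gets 3 planted 24-nt sRNAs with AGO4-compatible 5′
  bases, embedded in the central part of its window, Poisson(30) counts
  under normal/FR and hard zeros under R.
* **Expression**: 7 conditions × 2 replicates, NB counts (dispersion 0.1)
  around lognormal base means (median ≈ 55). Planted genes follow a
  monotone ramp: multiplier fc^(1/3), fc^(2/3), fc^1 at days 1, 2, 5 under
  R and the reciprocals under FR (fc = 3 by default), the antagonistic
  pattern the clustering is expected to find.

A single seed determines every draw; identical seeds give byte-identical
output files (data files — the run manifest contains a timestamp and is
excluded from checksum comparisons).

## What the packaged checks show — and do not

The evaluation scenarios in `rddmkit.benchmarks` (run by the test suite and
`scripts/acceptance.py`) are desk-scale substitutes for dataset-scale
results that would require the original sequencing reads:

* **Null DMC size** is measured on a binomial methylome (overdispersion 0)
  with the ratio-difference filter off — i.e. under the Fisher test's own
  null — where the discrete test must sit at or below its nominal 0.05.
  Under the default overdispersion 0.1 the same test is anti-conservative;
  that is inherent to Fisher-on-pooled-counts (see above).
* **Candidate recovery** (20 planted among 500 genes, 10 seeds) measures
  seed-averaged precision and recall of the full cascade.
* **DE error rates** use planted 2.5× effects. Recall of the union DE set is
  high; its measured null rate (~0.007–0.01) reflects the 9-way union of
  calibrated per-pair tests, as derived above, and is reported rather than
  hidden.
* **Metagene flatness** uses a uniform binomial methylome at level 0.5, so
  any bin deviation beyond sampling noise would indicate a binning or
  weighting defect.
* **k-means archetype recovery** plants 16 centered profile archetypes with
  coordinate noise at 1/5 of their minimum separation and scores the
  partition by adjusted Rand index.

Passing these checks shows the machinery is correct and well calibrated on
data matching its assumptions. It does **not** show that real bisulfite
data meet the binomial sampling assumption, that real sRNA libraries are
composition-stable across conditions (no TMM-style normalization is
implemented), or that 2-kb promoters and the midpoint/anchor assignment
conventions match any particular genome's architecture. Problem sizes in
the checks (genome size, seed counts, enumeration grids) are the package's
own defaults chosen to keep the full evaluation in the low minutes on a
single core.

## Known limitations

* No bisulfite conversion-error model, no beta-binomial DMC caller, no
  smoothing-based DMR methods: the implemented caller is the stated
  threshold procedure, exactly.
* Fisher- and NB-exact tests condition on totals; there is no per-replicate
  concordance requirement for DMCs (replicates are pooled).
* CPM normalization carries library-composition bias when a large mass
  fraction of the transcriptome shifts; the planted fraction in the default
  scenario keeps this below ~8 %.
* The GO-style enrichment treats terms as flat sets; no DAG propagation.
* The step from the nominated candidate list to a handful of genes for
  bench validation remains a curation decision; the rank score orders the
  list but does not replace judgment.
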