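# rddmkit

Multi-omics analysis of RNA-directed DNA methylation (RdDM) under light
treatments, built for studies that profile a plant (the motivating system is
*Aquilaria agallocha*, the agarwood tree) under red light (R), far-red light
(FR) and normal white light, with whole-genome bisulfite sequencing, small-RNA
sequencing, and a time-course RNA-seq design.

The package answers one integrative question: **which genes are plausibly
de-repressed by red light through loss of siRNA-directed promoter
methylation?** In the RdDM pathway, 24-nt siRNAs loaded on AGO4 (which prefers
a 5′-terminal A, G or U) guide de novo cytosine methylation in all three plant
contexts (CG, CHG and CHH, H ∈ {A, T, C}); methylation of a promoter generally
represses the gene. A gene regulated this way should show four coordinated
signals: a red-light **hypo**-methylated region (hypo-DMR) at its promoter,
AGO4-compatible siRNAs inside that region that are present under FR/normal but
undetectable under R, and higher expression under red light.

## What it computes

* **Methylome** — per-cytosine methylation levels from bisulfite count
  tables; differentially methylated cytosines (DMCs) by a two-sided Fisher
  exact test on replicate-pooled counts (depth ≥ 3 in both conditions,
  |Δ level| ≥ 0.33, p ≤ 0.05); DMRs as runs of ≥ 3 same-direction,
  same-context DMCs with gaps ≤ 300 bp, re-tested on all cytosines in the
  span; consensus red-light hypo-DMRs as intersections of the R-vs-normal and
  R-vs-FR calls; DMR composition over promoter / gene body / TE / intergenic;
  60-bin metagene profiles of the *weighted* methylation level
  w = Σ methylated reads / Σ total reads (20 bins per 2-kb flank, 20
  length-scaled bins per gene body).
* **sRNAome** — perfect-unique mapping filter (0 mismatches, 0 gaps, 1 hit);
  length × region characterization of distinct sRNA sequences anchored at
  their 5′ base (rows 20–30 nt; columns satisfy Mapped = Intergenic + Genic,
  Genic = Promoter + G.Body, G.Body = Intron + Exon); AGO4 filter (24 nt,
  5′ ∈ {A, G, U}); TPM normalization and per-condition presence calls.
* **Transcriptome** — CPM normalization; differential expression at the
  classic thresholds (fold-change ≥ 2, p ≤ 0.001) with a negative-binomial
  exact test using a conditional-ML common dispersion estimated from
  replicates; the DE set is the union over all R-vs-FR condition pairs;
  centered log2 fold-change profiles over the fixed order FR5, FR2, FR1,
  normal, R1, R2, R5; k-means clustering (k = 16) with deterministic seeding;
  hypergeometric term enrichment per cluster.
* **Integration** — the four-predicate candidate cascade (metabolic gene ∧
  consensus hypo-DMR on promoter/gene body ∧ FR/normal-specific AGO4 sRNA
  inside it ∧ red-up-regulation), a deterministic composite rank score
  |log2 FC| × ΔmC × log10(1 + sRNA support), and recovery metrics against
  planted ground truth.
* **Synthetic data** — a fully seeded generator producing GFF3 annotation,
  beta-binomial cytosine counts, a 24-nt-dominant sRNA population and
  negative-binomial expression counts with planted RdDM target genes, plus
  the machine-readable ground truth.

## Worked example

```python
from rddmkit.synthetic import SimulationConfig, simulate
from rddmkit.pipeline import run_pipeline

dataset = simulate(SimulationConfig(seed=7))      # 500 genes, 20 planted
result = run_pipeline(dataset, seed=7)
print(len(result.consensus_hypo), int(result.de["de"].sum()),
      len(result.candidates), result.recovery)
```

prints

```
66 23 20 RecoveryMetrics(precision=1.0, recall=1.0, f1=1.0)
```

i.e. 66 consensus red-light hypo-DMRs, 23 DE genes, and 20 nominated
candidate genes that are exactly the 20 planted RdDM targets. The top
candidate on this seed (`g334`) carries a CHH consensus hypo-DMR with a level
difference of 0.45, three FR-specific AGO4-compatible sRNAs inside it, and a
4.3-fold red-light up-regulation (log2 FC 4.29 across the strongest R-vs-FR
pair). Characterizing the consensus regions places 77 % of them in promoters
— the planted promoter-proximal signal dominating a small background.

The same analysis is scriptable from a shell:

```bash
rddmkit simulate --seed 7 --out data/
rddmkit dmr --cytosines data/cytosines.tsv --out dmr/
rddmkit srna-table --data data/ --out srna/
rddmkit de-cluster --data data/ --seed 7 --out de/
rddmkit integrate --data data/ --seed 7 --out integrate/
rddmkit report --data data/ --gene g334 --out report/
```

Every output directory contains a `manifest.json` recording the tool
version, the thresholds actually used, the seed and the SHA-256 checksums of
inputs and outputs; identical seeds and configs give byte-identical data
files.

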