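# tfdirect

Inference of transcription-factor **direct target genes** from multi-factor
ChIP-seq co-binding plus multi-knockdown RNA-seq concordance, with the
downstream patient-cohort analytics used to connect those targets to
bronchial premalignant lesion (PML) biology — metagene scoring, histologic
grade trends, progression enrichment, and immune cell-type scores.

The package is aimed at regulatory-genomics analysts who have, for a set of
cooperating factors (e.g. YAP/TAZ–TEAD–TP63 in bronchial basal cells):

- narrowPeak files per factor per ChIP-seq replicate,
- knockdown-vs-control RNA-seq count matrices (one siRNA arm per factor,
  shared controls),
- a promoter-capture Hi-C style fragment-interaction table,
- and optionally a multi-patient biopsy cohort with ordinal histologic
  grades and lesion progression labels.

Every stage is also covered by a synthetic-data generator with planted
ground truth (`tfdirect.simulate`), so the whole pipeline can be exercised
and validated with no external downloads.

## Method

**Co-bound regions.** Peaks are filtered by summit fold-change (> 2,
strict), optionally blacklist-subtracted, reduced to replicate-consensus
regions (overlap clusters containing every replicate), and intersected
across factors; a cross-factor cluster's merged region is its union span.
Overlap means ≥ 1 shared base in half-open coordinates. Peak/target overlap
significance is assessed with a width-preserving per-chromosome permutation
null.

**Candidate targets.** A gene enters the candidate universe if its TSS lies
within 50 kb of a co-bound region (gap to the nearest covered base), or if
a retained chromatin interaction (p ≤ 0.05) has one fragment containing the
TSS and the partner fragment overlapping a co-bound region.

**Concordance classification.** Per knockdown arm, counts are filtered
(IQR > 0 and total > 1), TMM-normalized, transformed to log₂ CPM, and fit
gene-wise with a linear model (treatment + cell line) with empirical-Bayes
variance moderation and BH FDR. A candidate is a **repressed** target if
logFC > 0.5 and FDR < 0.05 (strict) in *every* arm — i.e. it rises when the
factors are depleted — and an **induced** target if logFC < −0.5 in every
arm. Genes are ranked by moderated t for preranked GSEA between arms.

**Cohort analytics.** Induced/repressed target sets are scored per sample
with a rank-based single-sample statistic (ssGSEA, τ = 0.25; AUCell for
per-cell data). Score-vs-grade trends use a random-intercept model
s = β·grade + b_patient + ε fit by profiled REML; progression rank lists
come from per-gene random-intercept fits of expression on a
regressive-vs-progressive/persistent indicator, followed by preranked GSEA
of the target sets; immune cell-type sets are scored the same way and
correlated with a designated gene (e.g. a CIITA-like repressed target).

## Worked example

Run the full pipeline on a small synthetic dataset (500 genes, 40 planted
targets, three factors × three replicates, triplicate knockdown arms, a
30-patient × 3-biopsy cohort):

```python
from tfdirect.cohort import PipelineConfig, run_pipeline
from tfdirect.simulate import SimulationConfig

cfg = PipelineConfig(
    outdir="example_run", seed=7,
    simulation=SimulationConfig(seed=7, n_genes=500,
                                n_cobound_target_genes=40,
                                chrom_length_bp=10_000_000),
    nperm=499, subtype_filter=None,
)
res = run_pipeline(cfg)
print("recovery:", res.recovery)
print(res.grade.table.round(4))
print(res.progression[["es", "nes", "p", "enriched_in"]].round(4))
```

which prints:

```text
recovery: {'sensitivity': 0.375, 'precision': 1.0, 'n_induced_found': 8,
           'n_repressed_found': 7, 'n_cobound_regions': 40, 'n_universe': 120}

grade trend:
                    slope      se        t    p  model
induced_targets    0.0581  0.0043  13.5545  0.0  mixed
repressed_targets -0.0744  0.0054 -13.8364  0.0  mixed

progression GSEA:
                       es     nes       p             enriched_in
induced_targets   -0.9654 -1.8455  0.0039  progressive/persistent
repressed_targets  0.9513  1.7289  0.0044              regressive
```

Reading the numbers: all 40 planted co-bound regions are recovered and the
candidate universe holds 120 genes (neighbours within 50 kb share regions);
15 of the 40 planted targets pass the strict tri-arm concordance filter,
with no false positives (precision 1.0 — the concordance rule is
conservative at triplicate sample sizes, trading sensitivity for purity).
The induced-target metagene rises with histologic grade and the
repressed-target metagene falls (slopes per grade step in score units, with
patient random intercepts), and the repressed set is significantly enriched
among genes up-regulated in regressive lesions — the planted direction
structure.

A command-line entry point wraps the same functionality:

```sh
tfdirect simulate --seed 1 --out bundle/        # synthetic input bundle
tfdirect run --seed 1 --out run1/               # end-to-end pipeline
tfdirect peaks consensus r1.narrowPeak r2.narrowPeak --out cons.narrowPeak
tfdirect peaks permtest query.narrowPeak target.narrowPeak sizes.tsv
```

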