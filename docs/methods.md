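# Methods

This note documents the models, conventions, and numerical choices behind
`tfdirect`, and what the synthetic-data validation does and does not
establish.

## Interval engine

Coordinates are 0-based half-open everywhere (`[start, end)`), matching
narrowPeak/BED files bit-for-bit. "Overlap" means at least `min_overlap_bp`
(default 1) shared bases; abutting intervals do not overlap. Cross-set
overlap is defined on the connected components of the pairwise-overlap
graph over the pooled intervals: a component qualifies when every input set
contributes at least one interval, and its merged region is the union span.
The sweep uses a union-find with an active set keyed on interval ends; it
is exact for any `min_overlap_bp` (a naive max-end sweep is not, because a
short interval can fail to connect while a later, longer one still reaches
back — the property tests pin this against an all-pairs oracle).

Replicate consensus is the same clustering with replicates as the input
sets. The summit fold-change filter (narrowPeak column 7, strict `> 2`) and
blacklist subtraction (whole-peak removal on ≥ 1 bp contact) run before
consensus. Peak-to-TSS distance is measured from the summit when present,
else the floor midpoint; the sign is positive when the anchor lies
downstream of the TSS in the gene's orientation, and absolute-distance ties
resolve to the lexicographically smallest gene id.

Overlap significance uses the simplest defensible null: query peaks are
re-placed uniformly within their own chromosome with widths preserved,
shuffled peaks may overlap each other, and the statistic is the number of
query peaks touching any target peak; p = (1 + #{perm ≥ obs})/(nperm + 1),
so p ∈ [1/(nperm+1), 1].

## Target assignment and classification

- Proximal rule: gene assigned when the gap from its TSS to the nearest
  covered base of any co-bound region is ≤ 50,000 bp (half-open
  arithmetic; a TSS inside a region has gap 0). The window is a threshold
  object field, so enlarging it can only grow the universe (monotonicity is
  property-tested).
- Distal rule: interactions are retained at p ≤ 0.05 (inclusive — the
  cutoff convention is ambiguous in common usage, so it is documented and
  configurable); a fragment is promoter-containing when it covers ≥ 1 TSS
  of any gene; a gene is assigned when a retained record has its TSS in one
  fragment and the partner fragment overlapping a region, in either
  orientation.
- Classification is strict on both thresholds: repressed requires
  fdr < 0.05 AND logFC > +0.5 in *all* knockdown contrasts, induced
  requires logFC < −0.5 in all; boundary values (logFC exactly ±0.5, FDR
  exactly 0.05) are excluded. Genes missing from any DE table are dropped
  with a logged count. Induced and repressed sets are disjoint by
  construction.

## Expression models

Gene filtering keeps genes with interquartile range > 0 (linear-interpolated
quartiles) and total count > 1. TMM follows Robinson–Oshlack: M and A
values against a reference sample (the one whose upper-quartile count
proportion is closest to the mean of those), double trimming at 30% (M) and
5% (A), inverse-asymptotic-variance weights, factors rescaled to multiply
to one; it matches edgeR's `calcNormFactors` to 1e-6 on random counts (an
independent-oracle test). log-CPM is
`log2((count + 0.5) / (lib·factor + 1) · 1e6)`.

Differential expression is ordinary least squares on log-CPM per gene, with
treatment plus dummy-coded covariates; precision weighting is deliberately
not used — the downstream products (t rank lists and threshold sets) depend
on relative ordering, which OLS preserves, and the simpler model is exactly
reproducible. Residual variances are shrunk by an empirical-Bayes
scaled-inverse-χ² prior whose (d₀, s₀²) are estimated by method of moments
on the F-distributed variance ratios (Var(s²)/E(s²)² = 2(d+d₀−2)/(d(d₀−4)));
when the observed spread is no larger than pure χ² noise the prior is
treated as infinite (fully pooled, normal reference). The moderated t uses
d₀ + d degrees of freedom and BH FDR. On 2,000 null simulated genes the
empirical type-I error at p < 0.05 sits inside [0.035, 0.065].

The random-intercept model y_ij = x_ij'β + b_i + e_ij (b_i ~ N(0, σ_g²),
e ~ N(0, σ²)) is fit by REML with the restricted likelihood profiled down
to λ = σ_g²/σ²: V₀ = I + λZZ' is block diagonal, so per group
V₀⁻¹ = I − λ/(1+λm)·J and |V₀| = 1+λm in closed form, and the 1-D
optimization runs on log λ (bounded ±12, xatol 1e-10) with an explicit
boundary check at λ = 0. The optimum matches a dense grid-search oracle to
1e-4 in log-likelihood and statsmodels MixedLM to 1e-5 in the slope. Wald
inference on the coefficient of interest uses n − p degrees of freedom.
Groups with one observation each make the intercept unidentifiable; the
fit falls back to OLS with a warning and records `model="ols"`.

Grade is coded as equally spaced integers 0…6 in the order normal,
hyperplasia, metaplasia, mild/moderate/severe dysplasia, carcinoma in situ.
Progressive and persistent lesions are pooled against regressive ones; the
progression indicator is coded regressive = 1, so positive t means higher
expression in regressive lesions. Supplied covariates (batch, TIN) enter as
linear fixed effects; categorical ones are dummy-coded.

## Gene-set statistics

ssGSEA: per sample, genes get average ranks (top gene ≈ N); the raw score
is Σ over list positions of (weighted in-set ECDF − out-set ECDF) with
in-set weights rank^τ, τ = 0.25; the score is divided by the max-minus-min
attainable for that set size and gene count, making scores comparable
across sets. It replaces the Gaussian-kernel GSVA variant: both are
rank-based single-sample statistics and the cohort conclusions rest on
relative ordering, which both preserve. AUCell: genes ranked descending
with seeded random tie-breaks; the score is the area under the top-k
recovery curve (k ≤ ⌈5% of genes⌉, the wrapped tool's default) normalized
by the maximal attainable area. Both scores are invariant to any strictly
monotone per-sample transform of the expression values.

Preranked GSEA: weighted KS running sum (hit steps |t|^w normalized over
the set, default exponent 1; miss steps 1/(N−|S|)); ES is the extremum of
largest magnitude. The null permutes gene labels (random same-size sets),
matching the preranked setting; NES divides ES by the mean |null ES| of the
same sign and p counts same-sign nulls as or more extreme, with the +1
correction. When C(N,|S|) ≤ 1e5 an exhaustive mode enumerates all
placements; at N = 8, |S| = 3 it reproduces the enumeration oracle to
1e-12. Permutation p-values are validity-tested: P(p ≤ α) ≤ α + 0.02 under
the null at nperm = 999.

Fisher set-overlap uses the conditional exact test (scipy); the odds ratio
is ad/bc with a flagged Haldane 0.5 correction on zero cells. Pathway
over-representation is the one-sided hypergeometric tail with BH FDR.
Pearson correlations report t-based two-sided p with BH across all pairs;
constant vectors are reported NaN and excluded from the FDR.

## Synthetic-data generator

The generator emulates the study designs end to end, with defaults fixed at
the reference conditions: a 2 × 25 Mb genome with 2,000 genes (TSS uniform
with a 200 kb margin, collisions re-drawn); 3 factors × 3 replicates; 90
planted co-bound target genes (⅔ induced), each receiving one co-localized
peak per factor present in all replicates — within 50 kb of the TSS, or,
for a 20% chromatin-linked fraction, > 50 kb away with a significant
fragment-pair interaction back to the promoter; 150 per-replicate noise
peaks (which cannot survive replicate consensus) and 200 noise interactions
with uniform p-values. Knockdown counts are negative binomial with variance
μ + αμ² (α = 0.1), baseline means log-normal(log 100, 1), library factors
uniform on [0.5, 2], per-gene cell-line offsets N(0, 0.15²) in log₂, shared
triplicate controls, and planted shifts of ∓1.5 log₂ units for
induced/repressed targets in every arm. The cohort (30 patients × 3
biopsies, 7 grade levels) plants a per-sample latent score
s = 0.5·grade + b_patient + ε (σ_b = 1, σ_ε = 0.5) added to induced-gene
and subtracted from repressed-gene log₂ means; the progression label
thresholds s plus noise at its median, so repressed targets are elevated in
regressive lesions by construction; one immune set (Th1-like) is coupled to
the designated repressed target, the other 23 are neutral. Identical
configurations produce byte-identical output files (per-stage seeded
substreams), and all emitted files round-trip through the package's own
readers.

What the generator does **not** emulate: read-level noise, GC/length bias,
peak-shape structure, correlated gene programs beyond the planted sets,
missing data, or single-cell sparsity. Passing tests therefore establish
the correctness and calibration of the pipeline's logic and statistics
under a clean generative model — not performance guarantees on real data.

## Problem sizes and known limitations

- Validation problem sizes: interval oracles up to ~1,000 intervals per
  instance; DE calibration at 2,000 genes; mixed-model recovery over 50
  cohort draws; direction coherence over 20 cohort draws; permutation
  calibration over 600 null sets at nperm = 999. These sizes give tight
  Monte-Carlo error while keeping the default suite fast.
- At the reference noise level (α = 0.1) and triplicate arms, the strict
  tri-arm concordance rule is conservative: precision against the planted
  truth is at or near 1.0, while sensitivity is ≈ 0.3–0.5 — the same as a
  voom/limma analysis of the identical counts, since the per-arm moderated
  t for a 1.5 log₂FC effect sits near the BH rejection boundary. Larger
  arms or lower dispersion move sensitivity up; the classification rule
  itself is the binding constraint, not the implementation.
- The moment-matched variance prior is coarser than profile-likelihood
  fitting of (d₀, s₀²); it is accurate enough for rank lists and calibrated
  type-I error, which is what the pipeline consumes.
- Wald df for the mixed model is n − p (no Satterthwaite correction);
  grade-trend p-values at 90 samples are insensitive to this choice.
- Molecular subtyping is an input label, not computed; Hi-C significance
  calling, motif analysis, and read-level processing are out of scope.
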