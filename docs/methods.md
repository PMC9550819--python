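# Methods

## Overview

`sestrat` stratifies tumors by super-enhancer RNA (seRNA) activity and
characterizes each stratum's regulatory program. The pipeline assumes an
seRNA matrix (SE loci × samples) with SE coordinates, a matched mRNA matrix,
gene TSS annotations, promoter sequences, a PWM library, and a survival
table. All expression enters the statistics on the log2(x+1) scale; raw
matrices are tagged and transformed exactly once. Genomic coordinates are
0-based half-open throughout (BED convention); a TSS is a single 0-based
position.

## Consensus clustering and k selection

Features are reduced to the top-N SEs (default 2,000) by median absolute
deviation on log2 values, then z-scored per feature. For each candidate k,
samples are subsampled without replacement (80% by default, 1,000 resamples;
smaller counts in tests for runtime) and clustered with K-means (k-means++,
best of `n_init` restarts). The consensus entry for a sample pair is the
fraction of resamples containing both in which they co-clustered; pairs
never co-sampled (vanishingly rare at the defaults) get consensus 0 with a
warning. Final labels come from average-linkage hierarchical clustering of
1 − consensus, which is deterministic. k is chosen by minimizing PAC — the
empirical-CDF mass of upper-triangle consensus values between 0.1 and 0.9 —
with ties and flat profiles (max − min PAC < 0.02, "no structure") resolved
toward smaller k. The change in area under the consensus CDF across k is
also reported for transparency. PAC is a deliberate design choice: it is
the standard stability statistic for consensus clustering, and the
selection rule is recorded in run metadata because different rules can
change the chosen k on weakly structured data.

## SE–gene linkage

A candidate pair is an SE and a gene whose TSS lies within `window_bp`
(default 500,000, boundary inclusive) of the SE interval on the same
chromosome; distance is measured TSS-to-interval (0 inside the SE), not to
the midpoint, which matches the idea of a window "around" the SE. Pairs are
scored by Spearman correlation across samples by default (robust to the
log-normal marginals; Pearson is available), with p-values from the
t-approximation, or exact permutation when n ≤ 9. BH correction is applied
jointly over all candidate pairs in a run — a single testing family with
plain FDR semantics — rather than per SE. SPGs are genes with at least one
link passing ρ ≥ 0.3, q ≤ 0.05, positive sign; all three gates are
configurable and recorded in metadata, since no canonical cutoffs exist for
this screen.

## Differential expression

One-vs-rest per cluster, per feature: two-sided Wilcoxon rank-sum on
log2(x+1) values — exact enumeration when both groups have ≤ 8 samples and
values are tie-free, otherwise the tie-corrected normal approximation with
continuity correction. The exact and approximate branches can differ by at
most 0.0109 at the 8+8 boundary (exhaustive enumeration over the U
distribution), which bounds the branch-switch discontinuity. Effect size is
the difference of group means on the log2 scale; DEG sets use q ≤ 0.05 and
|log2FC| ≥ 1. This rank test is a deliberate, fully specified stand-in for
negative-binomial DE machinery: it is exact at small n, assumption-light,
and adequate for calling large planted shifts; it does not model counts,
dispersion, or covariates.

## Overlap and motif enrichment

SE-regulated genes are SPGs intersected with the cluster's directed DEG set
(the direction — activated or repressed — is taken per cluster as whichever
direction dominates the SPG/DEG intersection); the overlap is tested
one-sided against the expressed-gene universe with Fisher's exact test
(hypergeometric tail), odds ratios using Haldane's 0.5 correction on zero
cells. Promoters (default window −500..+100 around the TSS, strand-aware,
in the synthetic data; any FASTA in general) are scanned with each PWM as
log2-odds against a uniform background on both strands; N bases contribute
0. A hit requires score ≥ 0.8 × the maximum achievable score; PWMs are
formed from counts with pseudocount 0.01. A gene is a hit if its promoter
has ≥ 1 scan hit; per motif, foreground-vs-background hit counts are tested
one-sided (over-representation is the question) and BH-adjusted across
motifs. Known-PWM enrichment, not de novo discovery, is the design choice:
it answers which TFs' motifs mark each cluster's SE-regulated promoters and
is exactly testable against planted motifs.

## Core-TF LASSO and the multi-TF index

Candidate TF expression (log2) is standardized per TF. For each cluster, a
one-vs-rest L1-penalized logistic regression is fit by cyclic coordinate
descent on the IRLS quadratic approximation (observation weights floored at
1e-5, intercept unpenalized), with a step-halving safeguard that keeps the
penalized objective non-increasing, convergence when the maximum
coefficient change is < 1e-7, and the KKT stationarity conditions verified
at the solution (weights below 1e-8 are snapped to exact zero — ties
between duplicated features leave such remainders that are zero in exact
arithmetic). One-vs-rest rather than multinomial because the analysis wants
one core TF per cluster, which one-vs-rest yields directly. The penalty is
chosen per cluster on a 50-point log grid from λ_max (the smallest
all-zero-solution penalty) down to 0.001·λ_max by stratified 10-fold CV
under the 1-SE rule (largest λ within one standard error of the minimum
mean validation deviance); a fold whose training half lacks a class is
re-drawn up to 10 times. The cluster's core TF is its top-|weight| nonzero
coefficient. The scalar index is the intercept-free linear predictor of the
worst-prognosis cluster's model (lowest restricted-mean survival time among
the discovered clusters), so higher means "more like the poor-prognosis
stratum"; survival dichotomization uses the cohort median. Cluster
prediction is the argmax over per-cluster linear predictors with ties to
the lower cluster number.

## Survival and signature scoring

Kaplan–Meier curves use the product-limit estimator with the standard
convention that censored observations tied with events are removed after
the events; the k-group log-rank statistic sums observed-minus-expected
event counts with hypergeometric covariance over event times (df = k − 1).
Both are computed via lifelines; an independent textbook O−E/V
recomputation serves as the oracle in the tests. Signature scores are the
per-sample mean of per-gene z-scores on the log2 scale (zero-variance genes
dropped); mean-z is the simplest defensible single-sample score, chosen
because rank-based alternatives add machinery without changing the
between-cluster comparison the score feeds.

## Synthetic cohort

The generator emulates the statistical structure the pipeline assumes, not
any real cohort's technical artifacts. On the log2 scale, every SE and gene
has a Normal(5, 1) baseline per feature plus unit-variance sample noise
(raw values are 2^log2, hence log-normal); planted effects are additive
mean shifts in within-cluster-SD units. Defaults are the study conditions
the recovery analyses assume: 3 equal clusters of 300 samples, 500 SEs with
20 specifically active per cluster at +2 SD, 30 linked genes per cluster
(mRNA = seRNA + Normal(0, 0.5) on log2), 20 candidate TFs with one driver
per cluster at +2 SD, a 22-gene signature at +1 SD in the worst-prognosis
cluster, exponential survival with hazards (0.02, 0.02, 0.08) and 20%
uniform censoring (the censoring horizon is solved numerically to hit the
requested rate in expectation). Each cluster's active SEs sit on their own
synthetic chromosome at 1.2 Mb spacing with their target TSSs 20–60 kb
away; decoy genes are placed 10 kb beyond the 500 kb window of background
SEs, making window-boundary behavior unambiguous. Driver-TF motifs
(length-8 PWMs, consensus probability 0.88, mutually ≥ 3 mismatches apart)
are planted as consensus sequences in ⌈80%⌉ of the cluster's linked-gene
promoters; all other promoter sequence is i.i.d. uniform A/C/G/T. One
global seed expands into fixed per-component substreams, so adding a
component never perturbs earlier draws and outputs are byte-identical
across runs.

What passing on this cohort does not show: robustness to library-size or
batch effects, dependent noise between features, non-exponential hazards,
promoter GC structure, or motif variants — none of which the generator
models. Recovery thresholds in the tests therefore certify the
implementation, not performance on real tumors.

## Numerical choices and degenerate inputs

Correlations are clipped to [−1, 1]; p-values floored at the smallest
positive double and capped at 1. Constant features get p = 1 in the DE test
(no rank information). Zero-variance vectors make correlations undefined
and those pairs are skipped with a warning; zero-variance candidate TFs are
an error (standardization needs positive SDs). `fcluster` occasionally
merges groups in degenerate geometry; labels are relabeled to a contiguous
1..k' range. Problem sizes in the test suite (e.g. 150–300 samples, 250
resamples, 5 seeds) are chosen as the smallest cohorts at which the planted
effects are comfortably identifiable, keeping the default run fast.

## Known limitations

- The DE stand-in has no dispersion modeling or covariate adjustment.
- Prediction by argmax over shrunken one-vs-rest models is slightly
  miscalibrated when per-cluster penalties differ; with a single driver TF
  per cluster the attainable accuracy is Bayes-limited near 0.89 at a 2-SD
  effect.
- The pipeline assumes motif ids name TF genes present in the mRNA matrix
  when building the candidate panel.
- No Cox models, competing risks, or hazard-ratio intervals; validation is
  KM + log-rank only.
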