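# Methods

## The screening model

The package treats "angiogenic activity" as a latent per-sample quantity
A_s and asks which miRNAs are negatively coupled to it strongly enough to
surface in three independent data layers: histology (microvessel density),
transcriptome (a signature score over pro-angiogenic genes) and outcome
(overall survival). Each layer has its own statistic; the pipeline is their
conjunction, so the false-positive rate of the shortlist is roughly the
product of the per-layer rates while a genuinely coupled miRNA survives all
three.

## Signature score

score(s) = (1/N) Σ_n I_n(s), with I_n(s) = +1 iff sample s expresses panel
gene n strictly above that gene's median over all samples of the input
matrix, else −1. Design choices:

* equality with the median maps to −1 (the indicator is "strictly above,
  otherwise −1"), which also makes constant genes contribute −1 everywhere;
* the even-n median is the mean of the two central order statistics;
* medians are always recomputed on the full sample set of the matrix passed
  in — subsetting samples changes the score, by construction;
* the panel consistency filter keeps genes present in the matrix and above
  `expression_floor` in ≥ `min_fraction_expressed` of samples (defaults 0.0
  and 0.8; "consistently expressed" has no canonical quantification, so both
  are explicit parameters and dropped genes are logged with reasons).

Because only ranks matter, the score is invariant under strictly increasing
per-gene transforms; score·N is an integer with the parity of N — both are
property-tested.

## MVD screen

Groups are assigned by strict inequalities (> 36 vessels/HPF high,
< 16 low; boundary samples excluded). A miRNA passes when
median_high < 0.2 · median_low (strictly), i.e. "decreased by more than
80%" read as a ratio of group medians — the groups are unpaired, so a
median-of-pairwise-decreases reading is not available. The screen applies no
normalization of its own: scaling all counts by a constant cannot change any
pass flag (tested), so callers may pass raw or total-count-scaled counts.
A zero low-group median leaves the decrease undefined and the miRNA failing,
with a log entry.

## Spearman layers

Mid-rank Spearman with two-sided p from the t approximation on n−2 df (the
intended cohorts have hundreds of samples); an exact permutation p is
available for n ≤ 9. Constant inputs yield an explicitly flagged result
rather than NaN. Rankings are ascending in rho (strongest negative correlate
first) with exact ties broken lexicographically by feature name, so output
order is deterministic. Methylation and copy-number tracks reuse one
per-track routine; tracks with < 3 complete pairs are reported as skipped,
not dropped silently. BH q-values are appended because the scan is run
across many features; the shortlist criterion itself uses the nominal
p < 1e-4 flag.

## Survival scan

Kaplan–Meier and the unweighted log-rank statistic are computed directly
(hypergeometric mean/variance per distinct event time; censored subjects
remain at risk at their tied event time). The implementation is vectorized
over many group assignments of one dataset at once, which is what makes the
percentile scan and its permutation adjustment affordable; lifelines serves
as an independent oracle in the tests.

The scan dichotomizes at the linear-interpolation quantile for each
percentile in [0.25, 0.75] step 0.01 (51 cutoffs; samples exactly at the
quantile go to the low group), takes the smallest nominal p, and breaks ties
toward the smaller percentile. Nominal min-p is primary — but it is
anti-conservative (under the null ~20–30% of scans flag at α = 0.05 instead
of 5%, reproduced in the acceptance suite), so `n_permutations > 0` adds a
whole-scan adjusted p: marker values are permuted against the survival
records, each permuted scan contributes its min-p, and
adjusted_p = (1 + #{perm min-p ≤ observed}) / (B + 1). This estimator is
exactly uniform on its grid under the null, which the calibration test
checks by Kolmogorov–Smirnov over 200 replicates (n = 60 per replicate,
B = 199 — sizes chosen so the discrete grid of the estimator is far finer
than the KS resolution at 200 replicates).

A note on the 4-subject worked example (groups {1,2} vs {3,4}, all events):
the chi-square is exactly 49/17 ≈ 2.882, but the permutation null there has
support on only six label assignments, so its exact permutation p is 1/3 —
small-sample agreement between the asymptotic and permutation p is only
meaningful at moderate n, and the permutation-agreement test therefore runs
at n = 40.

## TF cascade

Both filters are anti-monotone in their thresholds (tested): binding keeps
TFs with strictly more than `min_genes` distinct angiogenic targets at
matrix-similarity ≥ `min_score` (the published boundary is "more than five",
so 6 passes and 5 fails; the score cutoff is inclusive since no strictness
is stated); targeting keeps TFs supported by ≥ `min_algorithms` distinct
algorithms (4 passes, 3 fails). Duplicate (TF, gene) rows collapse to the
maximum score with a log entry; input row order never affects output. The
single-gene-promoter variant (one-gene panel, `min_genes=0`, cutoff 0.95) is
the same code path via parameters. The numbers any real run produces depend
entirely on the prediction databases supplied as input tables.

## Random-walk relevance

From node i the walk moves to neighbour j with probability
value(j) / Σ_{k∈N(i)} value(k); relevance is the stationary distribution
obtained by power iteration (L1 residual < tol, default 1e-10). Choices:

* a lazy stay-probability of 0.01 guards periodicity when restart = 0
  (bipartite graphs otherwise oscillate); lazy damping provably leaves the
  stationary vector unchanged, and the tests compare against a direct left-
  eigenvector solution of the undamped transition matrix;
* the restart distribution (when restart > 0) is data-value-proportional,
  consistent with values-as-transition-probabilities, and configurable;
* non-positive node values are floored to 1e-6 of the median positive value
  with a warning;
* edge flux = π_i P(i→j) + π_j P(j→i) on the pure walk probabilities,
  normalized to sum 1.

This is a faithful-in-spirit re-implementation of a commercial network
scorer's published description; numeric parity with that tool is not
claimed.

## Synthetic cohorts: what they emulate and what they do not

Generative model (defaults in parentheses):

* latent activity A_s ~ N(0,1), n = 400 samples;
* panel genes (20): μ + β·A + N(0, σ²), β = 1, μ = 8, σ = 1;
* planted miRNAs: negative-binomial counts with mean ν·exp(−γA)
  (ν = 500, γ = 0.8, dispersion 0.2) in the default counts mode, or Gaussian
  ν − γA + N(0, σ²) in gaussian mode — both modes exist because the
  upstream platforms mix arrays and counting chemistry; null miRNAs (50)
  are uncoupled;
* MVD ~ Poisson(exp(α₀ + α₁A)), α₀ = log 24, α₁ = 0.4 — centred so the
  strict >36 / <16 thresholds catch roughly the upper and lower sixths of
  cohort, mirroring an extremes-only profiling design;
* survival: event time ~ Exponential(h₀·exp(θA)) with h₀ = 0.1, θ = 1
  (higher angiogenic activity, worse outcome), censored at
  min(Exponential(0.04), 15) giving ≈ 30% censoring — the censoring
  structure is a modelling choice, not an empirical claim;
* methylation betas: inverse-logit(δ₀ + δ₁A) + Uniform(±0.2), clipped to
  [0,1] (rising with A, hence anti-correlated with planted miRNAs);
* TF tables: planted TFs get ≥-cutoff scores on their true targets and the
  truth count of algorithm flags; three decoys each violate exactly one
  cascade rule;
* Nanostring fixtures: 12 + 12 samples, per-miRNA base means log-normally
  spread around 800 counts, NB dispersion 0.15, planted miRNAs scaled down
  by their decrease fraction in the high-MVD group.

Every component draws from a sub-stream keyed by (seed, component name), so
cohorts are byte-identical under a fixed seed and adding a component never
perturbs another's draws.

Deliberately not modelled: batch effects, tumour purity/stromal
contamination, platform chemistry, copy-number segmentation structure, and
any correlation between genes beyond the shared latent factor. Passing
recovery tests therefore shows the cascade is correct and well calibrated
under its own assumptions — not that those assumptions hold in any real
cohort.

## Problem sizes used in the automated checks

Score oracle: 1,000 random matrices (tests) / 200 (acceptance script), ≤ 20
genes × ≤ 50 samples. Permutation–chi-square agreement: 20 datasets, n = 40,
B = 4,000. Null calibration: 200 replicates (tests) / 100 (script), n = 60,
B = 199. Recovery: 100 seeds (tests) / 50 (script) at n = 400. TF truth
recovery: 50 / 25 seeds. Walk eigen-agreement: 20 random 8-node graphs to
1e-8.

## Known limitations

* The nominal min-p cutoff scan is reported because it is the published
  procedure, but it should never be interpreted at face value; use the
  adjusted p for inference.
* The quantile-normalization tie rule (tied values receive the mean of the
  reference values at their tied ranks) makes the transform exactly
  idempotent only on tie-free data; with ties a second application can move
  values slightly.
* `correlate_tracks` loops per track (methylation panels are small); the
  matrix-vs-vector routines are the vectorized paths.
* Exponential survival implies constant baseline hazard; the generator is
  not suitable for studying time-varying effects.
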