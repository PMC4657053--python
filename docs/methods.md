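# Methods

## The score

`lineagescore` quantifies how strongly one tumor expression profile
resembles each cell type of a reference lineage compendium. The statistic
is a permutation-normalized, weighted running-sum comparison in the
single-sample enrichment family (BASE-style), not a gene-set overlap test:
the *weights* carry graded information about how differential each gene is
in a cell type, and the *ranking* carries the patient's expression ordering.

### Reference weights

A reference compendium (genes × arrays, log-scale intensities) becomes two
weight matrices per cell type:

1. each gene's across-column median is subtracted (log-scale values, so
   relative expression is a difference — dividing would be wrong);
2. each column is z-transformed (sample sd, ddof=1, fixed for
   bit-reproducibility); replicate arrays of one cell type are averaged
   per gene and the column re-z-transformed;
3. z-scores split into an up subset (negatives zeroed) and a down subset
   (positives zeroed);
4. each retained z becomes −log10 of a one-sided standard-normal tail
   probability (upper tail for up, lower tail for down), trimmed at 10
   (−log10 p = 10 ⇔ |z| ≈ 6.4). Genes zeroed by the split keep weight 0:
   non-regulated genes must carry no weight, otherwise every gene would
   contribute a floor of −log10(0.5) ≈ 0.3 and the complementary-weight
   background below would lose meaning;
5. all values are divided by one global maximum over both subsets and all
   cell types, so weights live in [0, 1] on a common scale. (A
   per-cell-type maximum is available via `scale="per_celltype"`, but the
   global choice keeps cell types comparable and is the default.)

Down-subset weights are stored as positive magnitudes; direction lives in
the subset label.

### Scoring one (patient, cell type) pair

The patient's genes are sorted by decreasing expression (stable sort; ties
keep input order); let a_j = |g_j| be the magnitude at rank j. Against a
weight vector w the foreground and background cumulative distributions are

    f(i) = Σ_{j≤i} a_j w_j / Σ_j a_j w_j
    b(i) = Σ_{j≤i} a_j (1−w_j) / Σ_j a_j (1−w_j)

and d(i) = f(i) − b(i). The pre-score is the signed maximum deviation:
pLSS⁺ = max(0, max d), pLSS⁻ = min(0, min d), returning whichever has the
larger magnitude (ties, a measure-zero event, return the positive branch).
Positive values mean highly expressed patient genes carry high weights.
Magnitudes a_j = |g_j| keep f and b monotone in [0, 1] for two-channel
log-ratios, whose sign information already lives in the rank order; for
one-channel data (all relative values after preparation) the choice is
moot.

Each pre-score is divided by the mean |pre-score| under permutation of the
gene labels in the ranked list (default 1000 permutations), yielding
LSS_up and LSS_dn. Two-channel data combine them as LSS = LSS_up − LSS_dn;
one-channel (absolute-intensity) platforms use LSS_up alone, because the
bottom of an absolute-intensity ranking is dominated by cross-hybridization
noise and the down-subset score is not interpretable there.

One permutation of a patient's ranked list scrambles every cell type's
weight vector identically, so the implementation draws one stream of
permutations per patient and evaluates all (cell type, subset) null means
on it. The null value is still specific to each (patient, cell type,
subset); sharing the draws only correlates the Monte-Carlo estimates.
Permutation streams are keyed to the patient identifier (not the column
position), so results are independent of evaluation order.

### Numerical choices

- Deviations with |d| < 1e-12 snap to zero. This makes the degenerate
  constant-weight case exact: mathematically f ≡ b there, but the two
  cumulative sums are not bitwise equal in floating point.
- A 0/0 normalization (pre-score 0 with null mean 0, e.g. constant
  weights) is defined as LSS = 0 — no concordance, no evidence. A zero
  null mean with a nonzero pre-score is an error (it cannot arise from a
  valid weight vector).
- The background cumsum is derived from the identity
  a(1−w) = a − aw, and the permutation-null inner loop is a fused,
  numba-compiled single pass (falling back to a chunked numpy path when
  numba is unavailable); both paths implement the same formula and agree
  to floating-point accuracy.
- Sample sd (ddof=1) everywhere a standard deviation is taken.

## Patient preparation

- Probeset-level matrices collapse to genes by keeping, per gene, the
  probeset with the highest mean intensity across all samples (ties: first
  in input order).
- One-channel intensities are log2(x+1)-transformed (the pseudocount
  guards zeros; the base only scales the ranking monotonically) and
  median-centered per gene across samples. Two-channel log-ratios pass
  through unchanged.
- Reference and patient gene namespaces are matched by bare
  case-insensitive symbol equality (murine Title-case vs human
  UPPER-case); no homology expansion.
- Genes missing a value for a patient are dropped from that patient's
  ranking only.

## Survival association

Per cell type, a univariate Cox proportional-hazards model is fitted with
the continuous score as sole covariate (lifelines; Efron tie handling);
Wald p-values are Benjamini-Hochberg-adjusted once across all tested cell
types. Non-converging or degenerate (constant-score) fits are flagged and
excluded from the adjustment rather than crashing the screen. Multivariate
models add clinical covariates (complete-case; categoricals dummy-coded
against stated reference levels — FAB M1, FLT3 wildtype, favorable risk,
no prior malignancy; configurable); a rank-deficient design is rejected
with the aliased columns named. Survival time units are whatever the
clinical table provides; the library is unit-agnostic and records the
unit string.

For Kaplan–Meier display, scores are dichotomized from a Gaussian KDE
(Silverman bandwidth, 512-point grid): if exactly two modes pass a 10%
relative-prominence filter, the cut is the density minimum between them;
otherwise the cut is the density mode. The mode-split rule for unimodal
scores is a documented convention — "split at the most typical value" —
since no operational definition is standard. Group comparisons use
Kruskal-Wallis (>2 groups) and the Wilcoxon rank-sum test (two-sided by
default; one-sided available).

## Synthetic data

The generator emulates the structure the pipeline consumes, not microarray
physics: no probe-level noise, batch effects, or differentiation
hierarchy. Each cell type owns disjoint up/down modules of `module_size`
genes shifted by ±`effect_z`·`noise_sd` on a N(0, noise_sd²) log-scale
background, with `n_replicates_per_celltype` replicate arrays per cell
type. Patients mix one planted cell type's mean profile with noise via
α_i ~ Beta(2, 2) (spread without mass at the extremes), and survival is
exponential with hazard `baseline_hazard`·exp(β·α_i) — a constant baseline
keeps the planted log-hazard-ratio interpretable. Censoring is an
independent Uniform(0, c_max) time with c_max set to the (1−rate) quantile
of T_i/U_i, which hits the target censoring fraction exactly up to
rounding. Defaults: 2000 genes, 20 cell types, 3 replicates, module size
40, effect_z 3, noise_sd 1, 200 patients, β 1.5, baseline hazard 0.1,
censor rate 0.3.

Passing the planted-signal checks shows the chain recovers a known mixing
coefficient and hazard under these idealized conditions; it does not show
robustness to cross-platform effects, annotation mismatch, or non-Gaussian
expression noise in real cohorts.

Fixture bundles write expression at 1e-4 resolution — far below the
simulated noise — so the short decimal representations round-trip exactly
through the TSV readers and a default bundle stays small.

## Problem sizes in the test suite and acceptance script

The statistical checks run at desk scale, chosen as the package's own
testing configuration: null calibration of the Cox screen uses 200-patient,
20-cell-type cohorts with 100 genes, 200 permutations and 200 replicate
cohorts; planted-signal recovery uses 500 genes, module size 12, 300
patients, β = 1.5 across 20 seeds; `scripts/acceptance.py` repeats the
planted-signal run at 200 permutations plus a 60-cohort null calibration.
Monte-Carlo tolerances in the tests follow binomial/standard-error bounds
at those sizes.

## Known limitations

- The permutation null is sampled, not exhaustive; LSS values carry
  Monte-Carlo error of a few percent at 1000 permutations (checked by a
  coefficient-of-variation test).
- The KDE dichotomization depends on bandwidth and prominence settings;
  both are exposed as parameters.
- No proportional-hazards diagnostics, time-varying covariates, or
  competing risks.
- Cross-species matching by symbol equality silently drops genes whose
  orthologs are named differently.
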