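# Methods

## Problem and data model

A *virtual pullback* is the Murray's law-based quantitative flow ratio
(μFR) — an angiography-derived, unitless surrogate of the pressure-wire
FFR — plotted against distance from the coronary ostium. Alongside the
μFR trace, quantitative coronary analysis (QCA) supplies co-registered
minimal lumen diameter (MLD) and reference vessel diameter (RVD) curves.
All curves live on a uniform 0.35-mm grid (`PullbackCurve`); a
`VesselRecord` couples one curve with the distal μFR, the proximal
reference diameter, and an optional expert pattern label (focal, diffuse,
mixed, serial).

Vessels with distal μFR > 0.95 are regarded as free of functional disease
and excluded from every pattern analysis; distal μFR ≤ 0.80 flags
haemodynamic significance.

## Physiological indices

Raw traces are first projected onto the non-increasing envelope
(pool-adjacent-violators, `monotonize`) — pressure ratios cannot recover
along a pullback, so upward wobbles are treated as measurement noise.
The raw curve is kept untouched for functional data analysis.

The pullback pressure gradient index is

    PPGi = ( MaxPPG20mm / ΔμFR_vessel + (1 − L_disease / L_total) ) / 2

with

- **ΔμFR_vessel** — proximal-minus-distal endpoint difference of the
  monotonized trace (virtual pullbacks start at the normalized proximal
  value, so endpoint difference and max-minus-min coincide after
  monotonization);
- **MaxPPG20mm** — the largest drop across any 20-mm along-vessel window,
  scanned at grid resolution (57 steps of 0.35 mm = 19.95 mm). Vessels
  shorter than 20 mm return the whole-vessel drop, making the first
  bracketed term 1;
- **L_disease** — "length with functional disease" has no published
  operational definition on the μFR trace. It is implemented as the total
  length of grid segments whose local monotonized drop is at least a
  configurable gradient threshold, default **0.001/mm** — an order of
  magnitude below the 0.025/mm major-gradient cut-off, acting as a noise
  floor. This reproduces the intended contrast between a short lesion
  (small diseased fraction, PPGi → 1) and vessel-wide disease (fraction
  → 1, PPGi → ΔμFR-window ratio / 2).

PPGi is undefined (error) when the monotonized trace shows no drop; such
vessels should already have been excluded by the 0.95 rule.

The local severity index dμFR/ds is the maximum negative first difference
of the monotonized trace divided by the spacing, after a centered moving
average of ≈ 2 mm (rounded to an odd number of grid points, 7 at 0.35 mm).
The 2-mm window keeps the estimate stable on 0.35-mm grids while leaving
the slope of any ramp longer than the window unchanged; it is
configurable. Whether the per-vessel summary should be the maximum or
some other functional of the local gradient is not settled in the
literature; the maximum is used.

Boundary conventions are inclusive exactly as validated clinically:
focal iff PPGi ≥ 0.78, major gradient iff dμFR/ds ≥ 0.025/mm,
significant iff distal μFR ≤ 0.80, excluded iff distal μFR > 0.95.

## Synthetic cohort generator

Clinical angiograms are not available, so the generator emulates the four
morphologies from their definitions: a focal lesion is one abrupt drop
(≥ 0.05) within ≤ 20 mm; serial disease is ≥ 2 such drops separated by
> 20 mm of healthy segment; diffuse disease is a gradual vessel-wide
decline with no discrete lesion; mixed superimposes both.

Construction per vessel: μFR = 1 − (sum of logistic lesion drops +
linear diffuse decline) + smooth noise, clipped to [0, 1] and resampled
at 0.35 mm. The logistic width parameter is defined so the stated lesion
width contains 90% of the drop. Noise is moving-average-filtered white
noise (sd 0.005) with the linear ramp between its endpoints removed, so
the proximal and distal values are exact; total drops are rescaled upward
when needed so the distal μFR on the final grid never exceeds 0.95.
RVD tapers linearly from a proximal diameter drawn from the 3.61 ± 0.66 mm
marginal; MLD is RVD scaled down by a Gaussian narrowing profile inside
lesions plus a uniform narrowing proportional to the diffuse burden.

Defaults emulate the 343-vessel reference population: class proportions
160 focal / 74 diffuse / 82 mixed / 27 serial; class-conditional
covariate marginals (age, sex, smoking, hypertension, diabetes,
dyslipidaemia) computed from the published per-class counts; lesion-drop
and diffuse-decline distributions chosen once so the distal μFR class
means land near 0.71 (focal), 0.82 (diffuse), 0.74 (mixed), 0.68
(serial). Vessel lengths are uniform on 40–120 mm (60–120 mm for serial,
which needs room for two separated lesions). One patient is generated per
vessel; the mild patient-level clustering of the real cohort (291
patients, 343 vessels) is not modelled.

Labelling emulates the eight-rater adjudication: each rater reports the
truth with probability 1 − ε (default ε = 0.1) and otherwise an
adjacent-confusable class, with "mixed" as the preferred confusion hub;
≥ 5/8 concordant votes adopt that label (unanimous = full first-round
consensus), and the second adjudication stage — described only as
resolution of divergences — is emulated as convergence to ground truth.

**What passing tests do and do not show.** The generator's classes
separate more cleanly than clinical data: diffuse vessels are exactly
linear, lesions are exact sigmoids, and trace noise is small, so absolute
classification metrics on synthetic cohorts are far higher than the
clinically reported ones (e.g. cut-off sensitivity ≈ 0.95 instead of 0.53). Tests
therefore assert the *orderings* that are structural rather than
dataset-specific — adding PPGi to the feature set improves AUC; the 0.78
cut-off is more specific for diffuse than sensitive for focal — and exact
arithmetic of the metrics layer on the published confusion counts.

## MFPCA

Each vessel's (μFR, MLD) curve pair is registered onto a common grid by
linearly rescaling its domain to [0, 1] (101 points by default). Shape
registration discards absolute length, which is deliberate: length
information reaches the classifiers through PPGi, the distal μFR and the
gradient features. RVD-based variables can be swapped in via the
`variables` argument.

Estimation is the standard two-stage multivariate Karhunen–Loève scheme:

1. per variable, eigendecompose the quadrature-weighted sample covariance
   (trapezoid weights, divisor n − 1) via SVD; keep the smallest number
   of components whose cumulative eigenvalue fraction reaches `pve`
   (default 0.99); eigenfunctions are unit-norm under the weighted inner
   product with sign fixed so the weighted integral is non-negative
   (ties: first nonzero loading positive);
2. eigendecompose the covariance of the stacked univariate score
   vectors; the eigenvectors form the combination matrix mapping stacked
   scores to multivariate scores, and the eigenvalues are the
   multivariate variances. Both variables carry unit weight — no
   between-variable weighting scheme is imposed.

Three multivariate components are retained for the classifiers. With one
variable and unit ("uniform") weights the procedure reduces exactly to
matrix PCA of the discretized curves, which the tests exploit as an
oracle. Models serialize to a single JSON file.

## Classifiers

Feature sets: the 12-feature curve model (age, sex, smoking, diabetes,
dyslipidaemia, hypertension, three MFPCA scores, reference diameter,
distal μFR, max dμFR/ds) and the 13-feature model appending PPGi.
Sex is encoded male = 1; smoking enters as current/previous indicators
against the non-smoker baseline, so the encoded matrix has 13 (resp. 14)
columns. Missing inputs raise; nothing is imputed silently.

The elastic-net logistic model minimizes

    (1/n) Σ −log L + λ ( α‖β‖₁ + (1 − α)‖β‖₂²/2 )

on standardized columns, with α = 0.5 by default (the mixing parameter is
not published; it is an exposed knob). The λ grid is log-spaced from
λ_max = max_j |x_jᵀ(y − ȳ)|/(nα) — the smallest λ at which every slope is
zero — down by a factor 10⁻⁴ over 100 points; λ is selected by
stratified 10-fold cross-validated deviance (minimum rule by default, a
one-standard-error rule is available). Three-class problems use the
symmetric multinomial likelihood; one-vs-rest appears only in ROC
computation. The solver is warm-started saga along the decreasing path;
because saga leaves the unpenalized intercept essentially unmoved when
the effective step size collapses at very large λ, any path point with
all-zero slopes gets the exact closed-form null intercept (class
log-odds) substituted. Coefficients are reported on the original feature
scale via the standardization inverse, and the full path plus CV curve
are stored.

The random forest is 500 bagged trees, √p candidate features per split,
out-of-bag probability estimates, fully seeded. No tuning is applied.

## Evaluation protocol

Tasks: focal vs. diffuse (only those two labels, n ≈ 234 of 343);
focal vs. non-focal (diffuse + mixed + serial pooled); three-class
(focal, diffuse, others = mixed + serial). Splits are 75/25, stratified
on the original four-pattern label with per-stratum train size
round(0.75·n) half away from zero — reproducing 176/58 on the 234-vessel
composition and 258/85 on the full one.

Within every iteration MFPCA, feature standardization and the classifier
are fitted on the training vessels only, then applied to the held-out
set — any other choice lets test curves influence the fitted basis and
invalidates the metrics. Iteration i uses seed base_seed + i; test sets
missing a class are re-drawn with a logged count so the iteration total
stays fixed. Binary metrics are accuracy, sensitivity, specificity, PPV,
NPV (zero denominators reported as NaN) and AUC by the tie-corrected
Mann–Whitney rank formula; the cut-off rule produces no probabilities and
hence no AUC. Summaries are per-metric means with 95% percentile
intervals (2.5/97.5) across iterations; a normal-approximation interval
is available. Percentages print with half-away-from-zero rounding
(84/160 → 53%).

Problem sizes: the repeated harness defaults to a 30-point λ grid down to
10⁻³·λ_max with 5-fold CV — at n ≈ 200–350 training vessels and 13–14
standardized features the selected λ and test metrics are insensitive to
the denser default grid, and a 50-iteration three-method run on the
343-vessel cohort completes in a few minutes on one CPU. Acceptance-style
desk runs use 50 iterations; the full 500-iteration protocol is the CLI
default for `evaluate`.

## Known limitations

- The functional disease length definition is a stand-in for an
  unpublished operational rule; PPGi values on near-flat noisy vessels
  are sensitive to its threshold.
- Shape-only registration for MFPCA ignores absolute vessel length.
- The generator produces idealized morphologies (exact sigmoids, linear
  diffuse decline, small stationary noise, one patient per vessel);
  absolute synthetic performance figures should not be read as clinical
  estimates.
- The elastic-net mixing α and the original tuning rule are unpublished;
  both remain configuration knobs.
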