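# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Spectral preprocessing

A plasma transmission spectrum referenced against pure water goes negative
wherever the sample holds less water than the reference.  The correction
adds back a scaled water spectrum `A_corr = A + c·W` with the scalar `c`
chosen to minimize the L2 norm of the first derivative of `A_corr` over
2000–2300 cm⁻¹, a window in which plasma itself shows no biologically
relevant absorbance.  Derivatives are first-order finite differences on the
uniform grid; the L2 objective makes the problem a scalar least squares
with the closed form `c = −⟨A′, W′⟩ / ⟨W′, W′⟩`.  A reference with zero
derivative energy in the window is rejected as degenerate.  The sign
convention is that `c > 0` means water deficit (the correction *adds*
water).  An L1 "minimal derivative" reading was rejected: it is
non-smooth, needs an iterative solver, and ties the result to solver
tolerances for no benefit.

Spectra are then truncated to 1000–3000 cm⁻¹ and the silent 1800–2800 cm⁻¹
region is removed; both intervals are closed (points at exactly 1800 and
2800 cm⁻¹ survive).  On the default 2 cm⁻¹ grid this retains
401 + 101 = 502 points.  Finally each spectrum is scaled to unit Euclidean
norm, which cancels per-sample dilution and effective-path-length
variation.  Masking precedes normalization; the opposite order would let
the discarded water-stretch region dominate the norm.

## Chained multilabel classifier

The five phenotype labels — dyslipidemia, hypertension, prediabetes,
type-2 diabetes (t2d), healthy — are not independent: t2d excludes
prediabetes, and healthy is by definition the conjunction of the four
negations, leaving 12 feasible combinations of the 2⁵.  The chain exploits
this: one L2-regularized logistic regression per label, in a fixed order;
link *k* is trained on the spectral features plus the *true* labels of the
k−1 preceding phenotypes, and at prediction time consumes its
predecessors' *thresholded predictions* (probability > 0.5; a probability
exactly at the threshold is classified negative).  Passing hard labels
rather than probabilities at test time matches the training-time contract
(links only ever saw 0/1 label features) and is the default; probability
propagation is available behind `propagate_probabilities`.

The default order places healthy last, where it can be read off the other
four.  `search_chain_order` scores every permutation (120 for five
labels) by k-fold cross-validated exact match ratio; ties break toward
the lexicographically smallest order so reruns are reproducible.

Raw chain outputs are reported as-is and may be infeasible (e.g.
prediabetes and t2d both positive).  An optional projection
(`project_feasible`) resolves the glycemic conflict toward the higher
probability and recomputes healthy, but is off by default: enforcement at
prediction time is a post-processing choice, not part of the model, and
reported metrics should reflect what the classifier actually said.

The penalty weight λ defaults to 1 (inverse regularization C = 1) with no
inner tuning loop, keeping the 120-order search tractable; λ is a
parameter everywhere.  Numerically, each link standardizes its feature
columns with training-fold statistics before solving and folds the
scaling back into the returned coefficients, so models always operate on
raw features.  Without this the ridge penalty, applied to L2-normalized
absorbances of widely different column variances, over-shrinks weak but
informative directions (on synthetic data, sex classification collapses
from AUC ≈ 0.91 to ≈ 0.57).  The logistic solver is L-BFGS at tolerance
1e-8, deterministic because the objective is strictly convex.

## Multilabel metrics and the chance benchmark

For truth `y_i` and prediction `ŷ_i` over n samples and L labels:

* exact match ratio = `(1/n) Σ I(y_i = ŷ_i)` — all-or-nothing per sample;
* Hamming score = mean per-sample Jaccard `|y_i ∩ ŷ_i| / |y_i ∪ ŷ_i|`
  over positive-label sets.  A row with empty truth *and* prediction
  contributes 1 (with a warning); feasible phenotype vectors always have a
  positive entry, so the convention only matters for generic inputs;
* 1 − Hamming loss = concordant fraction of the n·L label cells.

EMR ≤ Hamming score always holds (an exact match scores 1 in both; any
partial credit raises only the Hamming score).

The chance benchmark asks what these metrics look like for a predictor
that knows the label distribution but nothing sample-specific: two
independent samples of `n_draws` vectors are drawn from the empirical
distribution over observed label combinations, paired, and scored.
Alongside the draws it reports the analytic expectations
`E[EMR] = Σ_k p_k²` (combination probabilities `p_k`) and
`E[1−HL] = 1 − (1/L) Σ_j 2 q_j (1−q_j)` (label marginals `q_j`), plus
Monte-Carlo standard errors.  Drawing two independent samples is
distributionally equivalent to drawing one and shuffling it; the former is
implemented.  `n_draws` defaults to 100,000 — at that size the MC standard
error on EMR is ≈ 0.0013, far below any effect of interest — and is
configurable.

ROC curves group tied scores; AUC is the trapezoid integral, which equals
the tie-corrected Mann–Whitney probability `P(s⁺ > s⁻) + ½P(s⁺ = s⁻)`
(asserted against an O(n²) counting oracle in the tests).

## Validation regimes and matching

Three regimes mirror a two-visit study: 10-fold CV within sample set 1,
the same within set 2, and a *sample-set-independent* regime.  For the
latter, the individuals who attended both visits are partitioned into k
disjoint near-equal groups; iteration *i* trains on every visit-1 sample
whose individual is not in group *i* and tests on group *i*'s visit-2
samples.  Partitioning (rather than k independent 10% draws) guarantees
every overlap individual is tested exactly once.  Every emitted plan
satisfies — and `audit_leakage` asserts — that no individual appears on
both sides of any fold.

Within-set CV stratifies folds by label combination where a combination
has at least k members (rarer combinations are pooled and spread
unstratified); stratification reduces fold variance and is disabled
automatically where it cannot be honored.  Fold sizes differ by at most
one.

Pair matching for case-control designs is greedy 1:1 nearest-neighbor
without replacement: exact on sex, Euclidean on age and BMI standardized
over the pooled cohort, with cases processed in order of scarcity (fewest
sex-compatible controls first) and an optional caliper.  Optimal matching
was rejected as unneeded complexity at these cohort sizes.

## Analyte calibration

Ridge regression (penalized least squares with an unpenalized intercept)
maps fingerprints to analyte concentrations, analyte ratios, age and BMI;
sex uses the logistic machinery with ROC/AUC.  Features are standardized
with training-fold statistics only.  R² is the *out-of-sample* coefficient
of determination, `1 − SSE/SST` with SST about the test-fold mean — a
model no better than the fold mean scores ≤ 0, and shuffled-target nulls
land there.  RMSE is reported in the analyte's own units.  Per-wavenumber
Pearson correlation maps flag zero-variance columns as undefined (NaN)
rather than forcing r = 0, so downstream consumers can distinguish "no
signal" from "no variance".

## Metabolic syndrome

Risk factors follow the harmonized IDF/AHA-NHLBI criteria: waist ≥ 94 cm
(males) / ≥ 80 cm (females); SBP ≥ 130 or DBP ≥ 85 mmHg or
antihypertensive treatment; fasting glucose ≥ 100 mg/dL or antidiabetic
medication; HDL < 40 (males) / < 50 (females) mg/dL or fibrates;
triglycerides ≥ 150 mg/dL or fibrates.  MetS ⇔ ≥ 3 factors; one or two
factors constitute pre-MetS.  The clinical table stores HDL in mmol/L and
the criteria are printed in mg/dL, so the scorer converts with
38.67 (mg/dL)/(mmol/L) for cholesterol (88.57 for triglycerides, exposed
for completeness).  The single fibrates flag satisfies both lipid
medication overrides, as the criteria word it.  A sample missing any of
the five factors has no defined count and is excluded from factor-count
analyses; medication overrides can still decide an individual factor when
its laboratory value is missing.

The incident-MetS experiment takes individuals MetS-negative at baseline
with a usable follow-up, labels them by whether they meet the definition
at follow-up, and classifies from *baseline* spectra only (follow-up data
enter solely through the outcome).  `|cases| + |controls|` equals the
number of baseline-negative linked individuals by construction.  Forecast
CV folds are unstratified by default (a flag exists), matching the plain
reading of a 10-fold design.

## The synthetic cohort generator

The generator is the package's test bed and stands in for restricted
population data.  What it emulates:

* a two-visit design (defaults 3044/2140 samples, 2015 overlapping
  individuals; `default_cohort_config()` gives the 2000/1400/1000
  desk-scale cohort used by the test suite and acceptance script, chosen
  so the full pipeline runs in minutes on one CPU);
* ages 32–88, sex-balanced, BMI ≈ N(26.8, 4²);
* analyte concentrations that are log-normal with linear predictors on
  the log scale (sex, age, BMI), a per-individual random effect, and
  three correlated latent axes — lipid, blood-pressure, glycemic — tied
  together by a shared metabolic-load factor (loadings 0.75/0.95/0.75).
  The sharing makes conditions co-occur the way they do in adult
  populations, and it is the only channel through which blood pressure
  (not itself a plasma constituent) becomes spectrally predictable;
  blood pressure additionally receives direct contributions from the
  lipid and glycemic axes;
* non-HDL cholesterol generated directly and total = non-HDL + HDL, so
  total ≥ HDL holds by construction;
* phenotype labels derived from the records by the same cutoffs the
  analysis uses (non-HDL > 4.1 mmol/L; 140/90 mmHg or medication;
  WHO-style glycemic staging — fasting ≥ 126 or 2 h ≥ 200 mg/dL for
  t2d, 110–125 or 140–199 for prediabetes, medication override — the
  staging cutoffs are configurable since conventions vary);
* spectra from a Beer–Lambert forward model: per-constituent Gaussian
  band libraries (glucose in 1000–1180 cm⁻¹, ester C=O at 1725–1750,
  lipid CH at 2800–2975, carbohydrate C–O at 1100–1275, protein amides at
  1550–1700), a bulk protein background, per-visit path-length and
  storage-tilt batch effects, per-sample baseline tilt, a water-deficit
  term `−d·W(ν)` with the true `d` recorded as ground truth, per-sample
  dilution jitter (log-SD 0.05), and white noise (5·10⁻⁴ AU);
* visit-2 dynamics: ages advance by the 6.5-year follow-up horizon, BMI
  drifts, and each individual's metabolic factor takes a persistent drift
  step, so a realistic minority of baseline-negative individuals convert
  to MetS by follow-up and converters are already near-threshold — hence
  forecastable — at baseline.  Setting `visit2_independent=True` redraws
  visit-2 latents fresh, removing the forecastable signal (the null used
  in tests);
* label-wise missingness (default rate 0.005 per maskable field, ≈ 3% of
  samples end up with an unknown label vector) applied to the reported
  clinical table only; ground truth stays complete.

Effect sizes, band amplitudes and noise levels are the generator's
definition of its operating point and were fixed, once, so that the
synthetic population exhibits the qualitative regime the pipeline is
meant for: prevalences of roughly 47/32/15/11% for
dyslipidemia/hypertension/prediabetes+t2d with healthy the largest single
group, every phenotype one-vs-rest detectable at AUC > 0.8, glucose
calibration R² > 0.9, an exact match ratio near 0.6 falling to ≈ 0.5
under sample-set-independent testing, and a MetS conversion fraction
near 20%.  Amplitudes are arbitrary units — the study's dilution and
path-length constants are not public — calibrated only to give that
signal-to-noise.

What the generator does *not* emulate: interferograms and instrument
line-shape functions, atmospheric CO₂/water-vapor lines, scattering
artifacts, nonlinear detector response, assay error in the clinical truth
(e.g. serum-vs-plasma albumin discrepancies), and any real biochemical
pathway structure beyond the latent-factor correlations.  Passing tests
therefore demonstrate that the *pipeline* is correct and leakage-free and
that it recovers known structure at realistic SNR — not that any specific
clinical performance level would be attained on real measurements.

## Numerical choices and degenerate inputs

* Differential-signature SD uses the unbiased (n−1) estimator.
* Chain probabilities are clipped to [1e-12, 1−1e-12] so the open-interval
  contract survives floating-point saturation.
* Threshold ties classify negative (strict `p > τ`).
* `fit_binary` refuses single-class targets; `roc_auc` refuses single-class
  outcomes; `l2_normalize` refuses zero vectors; water correction refuses
  references with no windowed derivative energy; calibration refuses
  constant targets (undefined R²).
* Spectra CSV writing uses shortest round-trip float repr and reading uses
  round-trip parsing, so write→read is bit-exact.
* All randomness flows from named integer seeds through
  `numpy.random.default_rng`; re-running any stage with the same seed and
  inputs reproduces its outputs (up to BLAS summation order in large
  matrix products).

## Known limitations

* The chain assumes linear decision boundaries per link; phenotypes
  defined by an interval of a latent variable (prediabetes) are handled
  only through label correlations and multiple correlated channels.
* The set-independent regime tests generalization across the generator's
  batch effects; real between-campaign variation (cuvette aging, operator
  differences) is richer than a path-length factor plus a tilt.
* Greedy matching is order-dependent and not globally optimal; with a
  heavily imbalanced covariate distribution, late cases receive worse
  matches.
* The chance benchmark conditions on the empirical label distribution of
  the supplied population; it is not a significance test.
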