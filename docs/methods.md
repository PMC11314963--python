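# Methods

`volsense` implements an end-to-end analysis for discriminating poultry-meat
samples by their volatile fingerprints, combining a six-sensor metal-oxide
(MOX) electronic nose with SPME-GC-MS peak profiling. The experimental frame
is 4 diets (CONTROL, ST, LL, LD) × 2 cooking states (RAW, CK) = 8 classes,
48 samples, 10 e-nose cycles and 3 GC-MS replicates per sample. Because no
raw recordings for such a campaign are publicly deposited, a first-class
synthetic generator defines the data-generating process; every statistical
component is then validated against closed forms, independent oracles and
recovery of known generator parameters.

## Sensor-response model

Each MOX sensor is an n-type SnO2-based layer (plain, Pd- or Au-doped, two
of each) whose resistance falls when reducing volatiles react at its heated
surface. One measurement cycle follows a fixed schedule: 100 s stabilization
in filtered air, 200 s sample-headspace analysis, 500 s recovery (800 s at
the default 1 Hz sampling; bench bookkeeping rounds a cycle to 13 min,
which we store as design metadata only — the phase durations are operative).

The clean trace is piecewise first-order:

* stabilization: R(t) = R_b (baseline resistance);
* analysis: R(t) = R_b · (1 − a·(1 − e^{−t'/τ_on})), t' from the phase
  start; the fractional drop a ∈ [0, 1) is the (sensor, class) amplitude;
* recovery: exponential relaxation back to R_b with time constant τ_off.

τ_on (15–25 s) and τ_off (60–90 s) per sensor give the monotone
drop-and-recover shape characteristic of MOX arrays; τ = 0 is supported and
means an instantaneous transition (useful for closed-form checks: the
analysis minimum is then exactly R_b(1 − a), so ΔR/R0 = a through the full
normalize → segment → delta_response path).

Noise is multiplicative log-normal (σ = 0.01 by default) because resistance
is positive and spans decades across sensors, plus a linear baseline drift
(10⁻⁵ s⁻¹). The generator does **not** model humidity/temperature
covariates, sensor aging, adsorption saturation or cross-cycle carry-over;
passing recovery tests therefore demonstrate correctness of the analysis
chain under the stated kinetic model, not robustness to every artifact of
real hardware.

### Class structure and the separation dial

A 6 × 8 amplitude matrix encodes the classes: a per-sensor base response,
an additive cooked-state boost on every sensor (cooking releases more
volatiles), and a diet-specific pattern across sensors. A scalar
`separation` rescales each sensor's between-class deviations about its class
mean: separation 0 collapses all classes (discrimination must fall to
chance), 1 is the default condition. End-to-end parameter-recovery tests use
the grid {0, 0.005, 1}: the low point sits where class deviations are
comparable to the per-feature noise floor, producing intermediate accuracy,
so the chance → intermediate → perfect progression and its monotonicity are
all exercised. Test and acceptance runs use scaled-down campaigns (e.g. 20
samples × 5 replicates for the recovery grid, 48 × 10 for the headline run)
— sizes chosen to make the statistical properties measurable while keeping
the default suite fast.

## Signal preprocessing

R0 is the **stabilization-phase mean** resistance, not the literal first
sample; a single noisy acquisition should not scale a whole cycle.
Segmentation uses 0-based half-open index ranges computed by rounding phase
durations × sampling rate; samples recorded past the scheduled span join
recovery, shorter traces are rejected. Two distinct response magnitudes
coexist deliberately: the preprocessing ΔR/R0 = 1 − min(R/R0) over the
analysis phase, and the feature-set ΔR = max − min excursion of the whole
track; both are implemented and kept separate.

## Feature set

Eleven descriptors per sensor (66 per cycle), computed on normalized R/R0
traces so arrays with different baselines are comparable:
four mean/SD "Sharpe" indices on the leading/trailing 25%/50% of the track
(windows of ⌈fraction·n⌉ points, sample SD; a zero-SD window yields a
configurable sentinel, default 0, with a logged warning); derivative
extrema and the trapezoidal integral on the *closed* analysis span (so a
constant unit trace integrates to exactly the 200-s window length); the
max − min excursion; Σ ln(xᵢ) (the "logarithm of sum" is implemented as the
sum of natural logs, well-defined since normalized resistances are positive;
ln Σxᵢ is available behind `FeatureConfig.log_sum_mode`); and the track
minimum and maximum. The interval policy ("analysis" vs "full") is
configurable because the descriptor definitions leave the evaluation
interval open; the analysis phase is the default for derivative/integral
since that is where the gas interaction occurs.

## Linear discriminant analysis

Written from first principles (statsmodels-style `Model.fit() → Results`):
pooled within-class scatter S_w and between-class scatter S_b, discriminant
basis from the generalized symmetric eigenproblem S_b v = λ S_w v (top ≤
k − 1 eigenvectors; sign fixed by making each direction's
largest-magnitude component positive). With p = 66 features and tens of
cycles per class S_w is singular, so S_w is shrunk toward its diagonal,
(1−λ)S_w + λ·diag(S_w), with λ = 0.1 by default; λ = 0 reproduces classical
LDA exactly and is what the oracle tests use (Fisher closed form, reference
implementation agreement). Classification uses Gaussian class conditionals
with the pooled covariance of the *projected* training data and
frequency-estimated priors; posteriors are normalized with log-sum-exp and
ties resolve to the earlier class label.

Evaluation splits are stratified: each class contributes
⌈test_fraction · n_c⌉ held-out samples (capped to keep one training sample)
— ceiling is the only rounding consistent with held-out sizes of 46/228 and
42/209 at 20%. Stratification is seeded and reported; it is a deliberate
choice to avoid empty-class folds at small n.

## ROC and confusion evaluation

Confusion matrices use row (true-class) percentage normalization. ROC is
one-vs-rest with grouped tie thresholds. AUC ships twice by design —
trapezoid over the (FPR, TPR) staircase and the Mann–Whitney pair statistic
from midranks — and the suite enforces ≤ 1e−12 agreement between them.
Micro-averaging pools all (indicator, score) pairs into one binary problem;
macro-averaging reports the unweighted mean of class AUCs and a mean-TPR
curve on the pooled FPR grid. Note the macro curve is interpolated, so its
own trapezoid can differ slightly from the mean-of-AUCs value; the `auc`
field of the macro curve is the mean of class AUCs. The chance baseline in
ROC panels is the diagonal.

## GC-MS profiling

Peaks with area ≥ 500 (inclusive: "not less than") are retained; a run with
fewer than 70 survivors is flagged by QC but not discarded — synthetic
tables are intentionally smaller (20 library compounds), so the flag fires
by design there. Quantification is relative abundance (% of total retained
GC area, summing to 100 per run). Replicates are matched by exact compound
name; a compound absent from a replicate counts as 0% there (so mean ± SD
is always defined; present-only averaging is available behind a flag).
Class profiles report per-compound mean ± sample SD, per-chemical-class
compound counts and summed abundances; raw-vs-cooked comparison returns
count and abundance deltas per class plus state-exclusive compound lists.
The synthetic libraries encode hexanal-dominant aldehyde profiles, cooked
enrichment of aldehydes/alcohols/ketones and raw enrichment of carboxylic
acids/esters/ethers, with log-normal area dispersion (σ_log = 0.2).

## Numerical and degenerate-input conventions

* All index ranges are 0-based, half-open; the feature integral alone uses
  the closed analysis time span (see above).
* Zero-variance Sharpe windows → sentinel, logged; they occur for exactly
  constant (noise-free) traces only.
* `eigh` on (S_b, shrunk S_w) requires positive-definite S_w; a singular
  scatter with shrinkage 0 raises a dedicated error telling the caller to
  refit with shrinkage.
* A tiny ridge (1e−12) is added to the projected-space covariance before
  inversion.
* Unbalanced designs (n_samples not divisible by the class count) are
  rejected rather than silently unbalanced.
* Per-cycle RNG streams are spawned from the campaign seed, so datasets are
  bit-identical under regeneration and independent of generation order.

## Known limitations

* The kinetic trace model is deterministic given class amplitude; real
  arrays show inter-sample biological variance beyond sensor noise, so the
  default conditions are an easier discrimination problem than real
  campaigns (the default-separation runs reach 100% test accuracy).
* Compound identity in GC-MS is by name only; spectral-library matching,
  retention indices and odor-threshold weighting are out of scope.
* No drift correction or smoothing is applied anywhere, matching the
  no-smoothing convention of the chromatographic integration.
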