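# volsense

Volatilome-based discrimination of food samples with a six-sensor MOX
electronic nose and SPME-GC-MS peak profiling.

The motivating problem: broiler chickens raised on different diets —
conventional (CONTROL), soybean-free sustainable (ST), and sustainable diets
supplemented with live (LL) or dehydrated (LD) black-soldier-fly larvae —
emit distinguishable volatile fingerprints from their meat, raw and cooked.
A cheap, portable array of six metal-oxide (SnO2, SnO2+Pd, SnO2+Au) gas
sensors can separate these 4 diets × 2 cooking states, while GC-MS peak
tables explain *which* compound classes (hexanal-dominated aldehydes,
alcohols, ketones, fatty acids, …) shift between raw and cooked meat.

`volsense` provides the whole analysis chain as a tested library plus a thin
CLI:

* **simulate** — seeded six-sensor resistance cycles with the
  100 s / 200 s / 500 s stabilization–analysis–recovery schedule,
  class-dependent response amplitudes, multiplicative log-normal noise and
  baseline drift; and GC-MS peak tables with class-dependent compound
  abundances. (No public recordings exist for such campaigns; the generator
  is first-class, tested code that defines the data-generating process.)
* **signal** — R/R0 normalization against the stabilization-phase baseline,
  phase segmentation, ΔR/R0 response magnitude.
* **features** — 11 descriptors per sensor (Sharpe-style mean/SD indices on
  leading/trailing track fractions, derivative extrema, integral, max−min
  excursion, Σ ln x, min, max) → 66-dimensional cycle vectors.
* **lda** — linear discriminant analysis written from scratch in the
  statsmodels Model/Results style, with diagonal shrinkage of the
  within-class scatter, Gaussian posterior classification, stratified
  ceiling-rounded train/test splits.
* **evaluation** — row-normalized confusion matrices, one-vs-rest ROC with
  dual AUC implementations (trapezoid and Mann–Whitney pair statistic),
  micro/macro averaging, JSON + plot reports.
* **gcms** — area-threshold peak filtering with a ≥70-peak QC flag,
  relative abundance (% GC area), triplicate mean ± SD class profiles,
  raw-vs-cooked per-class comparison.

## The statistics at the core

For classes c = 1…k with class means μ_c and pooled within-class scatter
S_w, LDA takes the top eigenvectors of S_w⁻¹S_b (S_b the between-class
scatter), yielding at most k − 1 discriminant axes. Because 66 features
exceed the per-class sample counts, S_w is regularized as
(1−λ)S_w + λ·diag(S_w). Classification in the discriminant space uses
Gaussian class conditionals with shared covariance and frequency priors.
One-vs-rest AUC is computed both as the trapezoid area under the ROC
staircase and as the Mann–Whitney statistic
(concordant pairs + ½ ties)/(n⁺n⁻); the two must agree to 1e−12.

## Worked example

```python
import volsense as vs
from volsense import evaluation

design = vs.ExperimentDesign(n_samples=24, enose_replicates=5)
crm = vs.default_response_matrix()
cycles, _ = vs.simulate_dataset(design, crm, vs.default_sensor_array(),
                                vs.PhaseSchedule(), vs.NoiseModel(seed=1))
X, y = vs.build_matrix(cycles)          # (120, 66) feature matrix

mask = y.str.startswith("CK").to_numpy()  # cooked samples only
ev = vs.evaluate_split(X[mask], y[mask], test_fraction=0.2, seed=1)
print(ev.results.summary())
```

```
Linear Discriminant Analysis Results
============================================
No. observations: 48
No. features:     66
Classes (4):     CK_CONTROL, CK_LD, CK_LL, CK_ST
Shrinkage:        0.100
Components:       3
Eigenvalues:      1.362e+05, 1.156e+05, 3.781e+04
Explained ratio:  0.470, 0.399, 0.131
Training accuracy: 1.0000
Priors:           CK_CONTROL=0.250, CK_LD=0.250, CK_LL=0.250, CK_ST=0.250
```

Three discriminant axes (k − 1 for k = 4 classes); the first two carry ~87%
of the between/within eigenvalue mass. Held-out evaluation:

```python
labels = ev.results.class_labels
curves = [evaluation.roc_ovr(ev.y_test, ev.scores[:, j], c)
          for j, c in enumerate(labels)]
micro = evaluation.micro_average(ev.y_test, ev.scores, labels)
macro = evaluation.macro_average(curves)
print(f"test accuracy: {100*ev.accuracy:.2f}%  "
      f"micro AUC: {micro.auc:.2f}  macro AUC: {macro.auc:.2f}")
```

```
test accuracy: 100.00%  micro AUC: 1.00  macro AUC: 1.00
```

Under the default generator conditions the four cooked diets are fully
separable; dialing `vs.default_response_matrix(separation=0.005)` moves the
problem into an intermediate regime and `separation=0` to chance level —
the recovery tests in `tests/` sweep exactly this grid.

The same workflow is available from a shell:

```bash
volsense simulate --config sim.yaml --seed 3 --out traces.csv
volsense train    --traces traces.csv --model-out model.json
volsense evaluate --traces traces.csv --seed 0 --out-dir metrics/
```

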