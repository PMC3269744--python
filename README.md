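# svrqsar

Support-vector-regression QSAR modeling with nonlinear descriptor
selection and F-test interpretability.

`svrqsar` is for modelers who have a small chemical series — a few
dozen compounds with measured potencies — and a large table of
computed molecular descriptors, and who want a nonlinear
structure–activity model that (a) uses only a small, defensible subset
of descriptors, (b) is validated on an external test set, and (c) can
say which descriptors matter and in which direction. The packaged
activity fixture is a series of 22 ARC-111 analogues (topoisomerase-I
inhibitors) with pIC50 measured in RPMI8402 leukemia cells, plus
published comparator metrics for seven reference models on the same
series.

## The method

The regression model is ε-support-vector regression under the libsvm
kernel codes t = 0 (linear), 1 (polynomial of degree d), 2 (radial
basis), 3 (sigmoid). Model quality is always the mean squared error of
pooled out-of-fold predictions under seeded k-fold or leave-one-out
cross-validation:

    MSE      = Σᵢ (yᵢ − ŷᵢ)² / n
    R²       = [Σ(yᵢ−ȳ)(ŷᵢ−ŷ̄)]² / [Σ(yᵢ−ȳ)² · Σ(ŷᵢ−ŷ̄)²]
    R²_pred  = 1 − Σ(yᵢ−ŷᵢ)² / Σ(yᵢ−ȳ_train)²     (external test set)

with the conventional acceptability bar R²_pred > 0.6.

Descriptor selection is a two-stage wrapper:

1. **HDSN** (high-dimensional descriptor selection, nonlinear) —
   coarse screen: each round ranks every surviving descriptor by the
   10-fold CV MSE of a single-descriptor SVR and keeps the best half
   (with a floor), stopping early if the retained-set model's CV MSE
   worsens.
2. **WDEM** (worst descriptor elimination, multi-round) — careful
   screen: each round refits the model with each one descriptor left
   out on identical folds and removes the descriptor whose removal
   most lowers the CV MSE, halting when no single removal helps.

Interpretability treats the fitted values of the final (nonlinear)
model with ANOVA-style F statistics — overall
F = (SSR/p)/(SSE/(n−p−1)) at df (p, n−p−1), per-descriptor
F_j = (SSE_without_j − SSE_full)/(SSE_full/(n−p−1)) at df (1, n−p−1)
via leave-one-descriptor-out refits — and draws single-factor effect
curves (prediction along one descriptor's range, all others at
training means) to assign each retained descriptor a direction of
influence.

A seeded synthetic-data generator plants known informative
descriptors, correlated near-duplicates, irrelevant columns and
constants, so selection and interpretation are testable against a
ground truth. See `docs/methods.md` for assumptions, defaults, and an
honest account of what wrapper selection can and cannot recover at
n ≪ D sample sizes.

## Worked example

```python
import svrqsar as q

report = q.run_pipeline({
    "synthetic": {"n": 40, "D": 60, "k": 5, "r": 1, "rho": 0.85,
                  "n_constant": 3, "noise_sd": 0.25, "effect": "linear",
                  "seed": 5},
    "seed": 5,
})
```

This simulates 40 compounds with 60 descriptors of which 5 drive the
response, selects descriptors (HDSN then WDEM), picks a kernel by
leave-one-out CV, fits, and validates externally. Output
(`examples/05_full_pipeline.py`):

```
retained 10 descriptors: ['inf1', 'inf2', 'inf4', 'inf5', 'inf3_cor1',
                          'irr5', 'irr20', 'irr27', 'irr36', 'irr44']

kernel comparison (LOO CV MSE on the retained set):
  t=0           0.587  <- chosen
  t=1,d=2       5.688
  ...

external test set (n=8):
  MSE      = 0.566
  R^2      = 0.876
  R^2_pred = 0.864  (acceptable if > 0.6: True)
```

Four of the five planted descriptors are recovered directly and the
fifth through its correlated copy (`inf3_cor1`); the retained noise
columns are the price of wrapper selection with 32 training rows. The
external R²_pred of 0.864 means the model explains 86% of the test-set
variance relative to the naive training-mean predictor, clearing the
0.6 acceptability bar.

The other example scripts cover the activity fixture and pIC50
conversion (`01`), kernel comparison by CV (`02`), the selection trace
round by round (`03`), and the F-test / effect-curve reports (`04`).
A thin CLI mirrors the stages:

```sh
svrqsar simulate --n 40 --descriptors 300 --seed 1 --out-prefix bench
svrqsar select bench_descriptors.csv bench_activities.csv --seed 1
svrqsar run config.yaml --out report.json
```

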