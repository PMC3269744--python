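# Methods

## Problem setting

`svrqsar` builds quantitative structure–activity relationship (QSAR)
models for small chemical series: a response vector of potencies
(pIC50 = −log10 of the molar IC50) over a few dozen compounds, and a
descriptor matrix with anywhere from a handful to thousands of numeric
molecular descriptors per compound. The regime of interest is n ≪ D —
tens of compounds against thousands of computed descriptors, most of
which are irrelevant or near-duplicates of one another. The package
covers four stages: ε-support-vector regression (ε-SVR) modeling,
two-stage nonlinear descriptor selection, external validation, and
F-test-based interpretability for the (nonlinear) fitted model.

The packaged activity fixture is the ARC-111 analogue series: 22
dibenzonaphthyridinone topoisomerase-I inhibitors with experimental
pIC50 against the RPMI8402 T-cell leukemia line (range 6.071–9.523),
split 18 train / 4 test (test compounds 8, 10, 15, 20), plus 12
theoretical designs whose published model predictions are carried as
reference metadata only. The descriptor values for this series were
never published, so the fixture supports fixture-level checks and
user-supplied descriptor files, not replication of the original
models; published test-set metrics for seven reference models
(stepwise MLR, PLS, ANN, four SVR variants) are shipped as display
comparators in `svrqsar.reference`.

## Model and cross-validation

The regression model is libsvm-style ε-SVR (via scikit-learn) under
the four kernel codes t = 0 (linear), 1 (polynomial, degree d), 2
(radial basis), 3 (sigmoid); kernel screening enumerates the five
standard configurations t=0; t=1,d=2; t=1,d=3; t=2; t=3. Model quality
is the mean squared error of pooled out-of-fold predictions under
k-fold (default k=10) or leave-one-out CV. Folds are a seeded shuffle
followed by contiguous blocks (sizes differing by at most one); one
fold assignment is drawn per procedure and reused for every candidate
model, so all MSE comparisons — between candidates within a selection
round and between rounds for the stop rules — are paired.

Hyperparameters default to C = 10, ε = 0.1, γ = 1/D on z-scored
descriptors (γ = 1/D is the conventional width heuristic for
standardized inputs; C and ε sit in the broad plateau that matters for
relative model comparisons rather than absolute accuracy, which is
what the selection procedures consume). A log-grid search
(`svr.grid_search`, C ∈ 0.1…1000, γ ∈ 1e-3…1, ε ∈ {0.01, 0.1, 0.5})
scored by the same CV criterion is available but off by default. The
solver tolerance is fixed at 1e-6 so repeated fits are bitwise
reproducible and elimination decisions cannot flip on solver jitter.

Descriptors are z-scored using training-row statistics only; test rows
are transformed with the stored training parameters. Zero-variance
(constant) training columns are removed before scaling, with the
removal logged. Missing values are rejected, never imputed.

## Descriptor selection

**HDSN (coarse screen, high-dimensional inputs).** Each round scores
every surviving descriptor by the 10-fold CV MSE of an SVR fit on that
descriptor alone, retains the best `retain_fraction` (default 0.5,
floor `min_features` = 10, cap `max_rounds` = 10; ties keep the
earlier column), and tracks the CV MSE of the full retained-set model.
It stops at the cap, at the floor, or as soon as the full-model MSE
worsens relative to the previous round, in which case the previous
round's set is returned. Because the single-descriptor score does not
depend on the rest of the set and the folds are fixed, each descriptor
is scored once and cached across rounds.

**WDEM (careful backward elimination).** Each round fits one
leave-this-descriptor-out model per survivor and removes the
descriptor whose removal gives the lowest CV MSE, provided that MSE
does not exceed the current full model's; otherwise it halts. The set
achieving the minimum full-model MSE seen over rounds is returned (for
the monotone stop rule this is the final set). Equal candidate MSEs
eliminate the later column, logged for reproducibility. Within a
round, γ = "auto" is resolved once at the current set size and used
for the full model and every candidate, so the comparison isolates the
feature's contribution rather than mixing it with a kernel-width
change; the current full-model MSE is re-evaluated each round at that
round's γ.

`select_descriptors` chains the two: HDSN is skipped when the input is
already low-dimensional (D ≤ 30 by default), mirroring direct backward
elimination on a literature-sized descriptor set.

## Validation statistics

For observed y and predicted ŷ:

- MSE = Σ(yᵢ − ŷᵢ)²/n;
- R² = the squared Pearson correlation
  [Σ(yᵢ−ȳ)(ŷᵢ−ŷ̄)]² / [Σ(yᵢ−ȳ)² Σ(ŷᵢ−ŷ̄)²];
- R²_pred = 1 − Σ(yᵢ−ŷᵢ)² / Σ(yᵢ−ȳ_train)² on the external test set,
  with ȳ_train from training rows only.

R²_pred compares the model with the constant training-mean predictor
(1 = perfect, 0 = no better than the mean, negative = worse); a model
is flagged acceptable only when R²_pred > 0.6, the conventional bar
for external validation of QSAR models. Undefined statistics (constant
vectors, zero denominators) raise `UndefinedMetricError` rather than
returning sentinels, so selection can never consume a NaN silently.

## Interpretability

For a nonlinear fit SSR + SSE ≠ SST, so the F statistics are computed
from the fitted values directly: SSR = Σ(ŷᵢ−ȳ)², SSE = Σ(yᵢ−ŷᵢ)²,
F_model = (SSR/p)/(SSE/(n−p−1)) at df (p, n−p−1). When the fitted
values come from OLS this reduces exactly to the classical regression
ANOVA F (tested against statsmodels). Per-descriptor importance refits
the model without one descriptor at a time with literally identical
hyperparameters (γ resolved once from the full model) and measures
F_j = (SSE_without_j − SSE_full)/(SSE_full/(n−p−1)) at df (1, n−p−1);
negative numerators (possible for redundant descriptors under a
nonlinear fit) are floored at zero and flagged. Significance stars
compare against the upper 5% and 1% F critical values at the stated
df. A zero SSE is reported as a perfect-fit flag, not an infinite F.

Single-factor effect curves trace the prediction along a 100-point
grid spanning one descriptor's observed training range with all other
descriptors fixed at training means (medians by flag). The direction
label is the sign of the Spearman correlation between grid and
response, with |ρ| < 0.1 or a numerically constant response labeled
flat. Because the label is rank-based it should be read together with
the descriptor's F value and the curve amplitude: a non-significant
descriptor can still receive a sign from a low-amplitude wiggle.

## Synthetic benchmark

The generator plants known structure so recovery is measurable:
k informative standard-normal descriptors with recorded coefficients
β ~ U(0.5, 1.5); r correlated copies per informative descriptor
(copy = ρ·source + √(1−ρ²)·fresh noise); irrelevant standard-normal
columns filling up to D; constant columns; response
y = Σβⱼxⱼ [+ β_int·x₁x₂ or + sin(πx₁)] + N(0, σ²); 80/20 train/test
split by seeded shuffle. The default benchmark is n=40, D=300, k=5,
r=2, ρ=0.9, 5 constants, σ=0.3, linear+interaction — desk-scale but
with the same n ≪ D character as a real high-dimensional descriptor
table. Gaussian marginals are a simplification: real descriptor blocks
are heavy-tailed, discrete-valued, and correlated in groups, so
passing recovery tests here demonstrates the machinery's correctness
and its behavior in the n ≪ D regime, not performance on real
chemistry. A log-normal marginal option exists to stress scaling.

## What the benchmark shows about wrapper selection at n ≪ D

With 32 training rows and ~280 irrelevant columns, spurious absolute
correlations with the response reach ≈ 0.5, while a β = 0.5–0.7
informative feature has expected marginal correlation 0.2–0.35 —
further degraded by chance in-sample collinearity among the planted
columns. Consequently *any* marginal screen (including an exact
Pearson ranking, which upper-bounds the HDSN score) loses the weakest
planted features in most realizations; measured over 20 seeds, even
the exact-correlation oracle keeps all five planted features in its
top quarter in only ~10% of replicates. The same sample-level
ambiguity means backward elimination sometimes benefits, in true CV
terms, from deleting a weak genuine feature. The test suite therefore
contains recovery assertions that fail at strict thresholds; they are
kept deliberately as an honest record of what this class of wrapper
selection can and cannot do at these sample sizes, while the
machinery-correctness properties (pairing, determinism, stop rules,
oracle equivalences) all hold.

## Numerical and degenerate-input choices

- Fold seeds, generator seeds and solver tolerance fully determine a
  run; identical config + seed gives byte-identical reports.
- Ties in selection scores break by column order (earlier kept in
  HDSN, later removed in WDEM) and are deterministic.
- Duplicate descriptor headers, duplicate compound IDs, non-numeric
  cells and missing values are hard errors naming the offender.
- A single-descriptor WDEM input is returned unchanged with zero
  rounds; importance testing requires p ≥ 2 and n − p − 1 ≥ 1.
- pIC50 conversion assumes micromolar IC50 input
  (pIC50 = 6 − log10 IC50[µM]), the convention consistent with the
  fixture's 6.07–9.52 range for µM-scale potencies.

## Known limitations

- Wrapper selection at n ≈ 30–40 is intrinsically unstable (see
  above); retained sets should be read as "a small set sufficient for
  this CV criterion", not as the unique causal descriptors.
- Greedy backward elimination makes no global-optimality claim.
- The F-test machinery borrows linear-model df conventions for a
  kernel model; the resulting p-values are heuristic significance
  guides, standard in this application area, not exact tests.
- Descriptor computation from structures is out of scope; inputs are
  numeric descriptor tables.

## Problem sizes used in the test suite

Unit tests run on 10–50-compound, ≤ 120-descriptor instances; the
recovery suite runs the full default benchmark (40×300) over 20 seeds;
the acceptance script runs one benchmark replicate plus 20-replicate
rates for the cheap sub-studies. These sizes keep a full run at
minutes on one CPU while preserving the n ≪ D regime.
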