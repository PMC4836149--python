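# Methods

## Problem and model

`mciconv` implements a classification framework for predicting conversion
from mild cognitive impairment (MCI) to Alzheimer's disease from structural
MRI morphometry alone.  Subjects are described by 204 FreeSurfer-style ROI
scalars — cortical thickness (CT, mm), cortical volume (CV, mm³) and
cortical surface area (CS, mm²) over the 68 Desikan–Killiany ROIs — plus a
binary diagnosis: converter (MCIc, coded +1) or non-converter (MCInc, −1).

The pipeline has four stages.

**1. Thickness-similarity networks.**  Each subject's CT vector defines a
weighted graph on the 68 ROIs with edge weights

    w(i, j) = exp(−(CT_i − CT_j)² / α),    α = 0.01,

so regions of similar thickness are strongly connected; the graph encodes
within-subject co-variation of regional atrophy that the raw scalars miss.
The weighted graph is binarized at a *connection cost* — the fraction of the
68·67/2 = 2278 possible edges retained, keeping the largest weights.  At the
default cost of 18% this is 410 edges.  From the binary graph we take per
node: degree k_i (edge count), path length L_i (mean shortest-path hop count
to the other 67 nodes) and Watts–Strogatz clustering C_i = 2e_i/(k_i(k_i−1)).
Nodal degree (ND) and nodal path length (NL) contribute 2 × 68 = 136 network
features; clustering drives cost selection (below).

**2. Feature assembly.**  The five categories CT, CV, CS, NL, ND give
5 × 68 = 340 candidate features, named `{CAT}:{ROI}_{HEMI}` in a fixed
category-major, atlas-ordered layout so column indices are reproducible.

**3. Combination-iterated stability selection.**  Rather than committing to
one category subset, all 2⁵ − 1 = 31 non-empty subsets are used.  Within
each combination an L1-penalized linear regression of the ±1 labels on the
standardized features (lasso, objective ½‖Xw − y‖² + λ‖w‖₁) is fitted on
repeated random subsamples of the training subjects; a feature's stability
score is its maximum selection frequency over a descending λ grid, and the
top K = 10 features per combination are recorded.  The *selection
likelihood* of a feature is the fraction of the 31 combinations whose top-10
contains it; the final K features of highest likelihood go to the
classifier.  Note a structural ceiling: each category appears in exactly 16
of the 31 subsets, so the likelihood can never exceed 16/31 ≈ 0.52.  For
that reason per-feature *outer-fold frequencies* (share of outer CV folds in
which a feature makes the final top-K, 0–100%) are reported alongside; they
are the quantity comparable to published per-feature selection percentages.

**4. Nested cross-validation with an RBF-SVM.**  The outer loop is
leave-one-out; *all* data-dependent steps — standardization, the entire
selection stack, hyperparameter tuning — run inside each outer training set,
so the held-out subject never influences its own prediction.  The inner loop
is a stratified 10-fold grid search over (C, σ) for a soft-margin SVM with
kernel K(x₁,x₂) = exp(−‖x₁−x₂‖²/σ²) (sklearn's `gamma` = 1/σ²).  Pooled
held-out decision scores yield accuracy/sensitivity/specificity (converters
positive) and the ROC/AUC, with ties handled so that the trapezoidal AUC
equals the Mann–Whitney statistic with half credit for ties.

## Connection-cost selection and leakage

`select_cost` scans costs 8–40% in 1% steps (33 candidates) and returns the
cost at which mean nodal clustering differs most between groups (ties to the
smallest cost).  Selecting the cost once on the full cohort re-uses every
subject — including future held-out ones — and is therefore a leakage path.
The pipeline default is consequently a *fixed* cost of 0.18; data-driven
selection is available as `cost="auto"`, which re-selects the cost inside
every outer training fold (leak-free, but ~30× the network-stage work).

## Synthetic cohorts

The generator emulates group-level cortical atrophy:

* CT per subject is an equicorrelated Gaussian (default mean 2.5 mm,
  SD 0.25 mm, equicorrelation ρ = 0.3 via a single shared factor);
  converters have `effect_size_ct` subtracted in the designated effect ROIs
  (default IPC_L, MTG_L, PCUN_L — regions repeatedly implicated in
  conversion).  Draws are floored at 0.5 mm rather than resampled so one
  seed stream yields bitwise-reproducible cohorts.
* CS is independent Gaussian (2000 ± 250 mm²); CV = CT × CS + noise
  (SD 250 mm³), mimicking volume ≈ thickness × area.  CV therefore inherits
  the atrophy signal; CS does not.
* Default group sizes 83/76 reproduce the baseline-pair class imbalance.

The injected CT reduction also perturbs the thickness network: an atrophic
ROI sits further from every other ROI in thickness space, loses edges at a
fixed cost, and its degree drops — an *emergent* network difference the
tests verify.  Ground truth for recovery checks is the CT/CV/ND/NL columns
of the effect ROIs (12 columns for 3 effect ROIs).

What the generator does **not** emulate: region-specific baseline thickness
profiles (all ROIs share one mean), realistic anatomical covariance
(equicorrelation only), site/scanner effects, age/sex covariates and
neuropsychological scores.  Passing recovery tests therefore demonstrates
that the pipeline finds the kind of signal it assumes, not that it would
reach any particular accuracy on real cohorts; published accuracies from
restricted clinical data are not reproducible here and are not targets.

## Numerical choices

* **Lasso solver.**  Cyclic coordinate descent on the residual with warm
  starts along the λ grid and glmnet-style active-set iteration
  (numba-compiled).  Convergence: largest coefficient update < 1e-4 within a
  sweep (1e-8 for the single-λ `lasso_fit`).  Support threshold 1e-8.  The
  solver is verified against closed forms, a brute-force objective grid and
  sklearn's `Lasso` in the test suite.  One solver property worth knowing:
  with *exactly* collinear columns the minimizer is non-unique and cyclic CD
  deterministically assigns the shared coefficient to the lower column
  index.
* **λ grid.**  30 geometric values from λ_max = ‖Xᵀy‖∞ down to 0.05·λ_max,
  recomputed per subsample.  Far below that the active set approaches the
  subsample size and carries no ranking information for a top-10 selection,
  while coordinate descent cost grows steeply; an explicit `lambda_grid`
  overrides the default.
* **Standardization.**  Columns are z-scored with statistics of exactly the
  rows being fitted (each subsample; each outer training set), never with
  whole-cohort statistics.  Zero-variance columns get unit scale and stay
  identically zero in the lasso.
* **Binarization rounding and ties.**  Retained edges =
  round(cost × 2278), half away from zero.  Ties at the threshold are
  broken by (weight descending, then (i, j) lexicographic), making the
  binary graph deterministic even for degenerate all-equal weights.
* **Unreachable node pairs** in the path length are assigned distance
  V = graph size (finite, penalizes disconnection); `unreachable="exclude"`
  averages over reachable partners instead.
* **Grid-search ties** resolve to the smallest C, then the smallest σ;
  stability and likelihood ties resolve to the lower column index; cost
  ties to the smallest cost.
* **Seeds.**  A single master seed expands into per-fold, per-stage streams
  via `numpy.random.SeedSequence` spawning, so isolated stage re-runs match
  the full run.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.01 | thickness-kernel width (squared-mm scale) |
| cost | 0.18 | fraction of the 2278 possible edges retained |
| cost grid | 0.08–0.40 step 0.01 | candidates for data-driven selection |
| K | 10 | final features handed to the SVM |
| per-combination K | 10 | features kept per category combination |
| subsamples | 100 | stability-selection draws (fraction 0.8, no replacement) |
| λ grid | 30 values, to 0.05·λ_max | lasso path per subsample |
| C grid | 2⁻⁵…2¹⁵ step 2² | SVM penalty |
| σ² grid | (2⁻¹⁵…2³ step 2²)·m | RBF width, scaled by feature count m |
| inner folds | 10 | stratified hyperparameter CV |

Class weighting is off by default (an inverse-frequency option exists); the
evaluation metrics are designed for the imbalanced two-group setting
instead.

## Problem sizes in tests and the acceptance script

End-to-end checks run the full protocol (31 combinations, LOOCV outer loop,
10-fold inner CV) at reduced stochastic-replication sizes chosen as the
package's desk-scale defaults: 10 stability subsamples over a 20-value λ
grid down to 0.1·λ_max, and a 4 × 4 (C, σ²) SVM grid.  Recovery runs use
n = 40/40 with a 2×SD effect in three ROIs over 10 generator seeds; null
calibration permutes labels on n = 20/20 cohorts over 20 seeds.  These
sizes affect only the Monte-Carlo resolution of the checks, not the
protocol being checked.

## Known limitations

* The clustering coefficient used for cost selection is the standard binary
  Watts–Strogatz nodal form (mean over nodes per subject); no statistical
  test accompanies the group difference, which is a selection heuristic.
* LOOCV variance is high at small n; single-seed AUCs on permuted labels
  scatter widely (the calibration criterion is a 20-seed mean).
* The stability-selection score uses the pointwise maximum frequency over
  the λ grid; it ranks features but is not a calibrated selection
  probability.
* `cost="auto"` is O(n_folds × n_subjects × n_costs) in graph analyses and
  is intended for moderate cohorts.
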