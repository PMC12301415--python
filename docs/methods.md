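# Methods

`floodrisk` re-implements an interpretable AutoML pipeline for predicting
ICU delirium in emergency polytrauma patients: a synthetic two-group cohort
generator, a swarm optimizer (the Flood Algorithm and its improved variant),
wrapper-based joint feature selection and hyperparameter tuning, threshold
and ranking metrics with decision-curve analysis, Shapley attribution, and a
rule-augmented decision-support report. This note records the models, the
parameters that matter, and the design choices made where the problem was
genuinely open.

## Synthetic cohort generator

The original multicenter patient data are not publicly deposited, so the
package ships a parametric generator that reproduces the published baseline
table of the cohort: 956 patients, 326 (34.1%) with delirium, an 80/20 split
into 764 training (250 delirium) and 192 test (76 delirium) patients.
Nineteen candidate predictors are sampled **independently within outcome
group** from families fitted to the printed group summaries:

- mean ± SD rows → normal (age, BMI, CFS, systolic BP, hemoglobin,
  fibrinogen, FDP);
- median (Q1, Q3) rows → lognormal with the log-scale median matched exactly
  and sigma fitted to the IQR, `sigma = (ln(Q3) − ln(Q1)) / (2 z_{0.75})`
  (GCS, heart rate, lactate, CRP, RTS, ISS); body temperature uses a
  30 °C-shifted lognormal because its support is far from zero;
- n (%) rows → Bernoulli (sex, smoking, alcohol, TBI);
- the Charlson comorbidity index, whose printed summary is typographically
  ambiguous, is Poisson with rates 0.6 (delirium) / 0.3 (control): median 0
  in both groups with the delirium group stochastically larger, matching the
  printed direction of the contrast.

Samples are clipped to physically legal ranges (GCS 3–15, RTS 0–7.84,
CFS 1–9, …) and rounded to chart precision. Two published summaries are
physically impossible (a GCS group mean above the scale maximum of 15; RTS
quantiles above the 7.84 ceiling): the generator uses the median (IQR) GCS
row and clips both scales to their legal ranges — physical validity is
preferred over replicating what are evidently typos. A median sitting on a
scale ceiling (control GCS printed 15 (14–15)) makes a two-sided IQR fit
impossible; sigma is then fitted one-sided from the finite arm and the
ceiling clip restores the boundary mass.

**Independence assumption.** The published table gives marginals only, so
variables are sampled independently within group; the label signal comes
entirely from group-conditional marginal separation. Real data have strong
cross-correlations (GCS–TBI, lactate–RTS, …) which this generator does not
model; passing tests therefore demonstrate pipeline correctness and
sensitivity to marginal group separation, not expected performance on real
patients. Because several predictors (age, FDP) separate the groups by
2+ SD, any competent classifier reaches ROC-AUC ≈ 0.99 on this synthetic
cohort — far above what the heldout clinical data could support.

**Missingness.** Cells are masked completely at random per variable. FDP
carries the documented worst-case rate of 2.6%; the other 18 variables share
a default rate of 2.56%, calibrated so the expected overall cell
completeness over the 19 predictor columns is 97.44% while FDP remains the
strictly highest rate. Rates above 5% are rejected as configuration errors.
Imputation is the routine clinical-ML recipe: training-partition median for
continuous/ordinal/count variables and training-partition mode for binary
ones, reused unchanged on the test partition so the test set never informs
its own imputation (fitting on the training partition only is standard practice).

## Flood Algorithm and its improved variant

The original report of this pipeline does not print the baseline update
equations (it defers to the algorithm's own publication), so the package defines it explicitly from the
water-mass metaphor. At iteration t of T, each agent i proposes

    y_i = x_i + r1 ⊙ (x_best − x_i) + r2 ⊙ (x_a − x_b)

with r1, r2 per-dimension U(0,1) and a ≠ b random agents (downhill flow
toward the best plus differential diffusion), clipped to the box and
accepted greedily; then with probability `overflow_fraction · (1 − t/T)` the
worst ⌈overflow_fraction·N⌉ agents are re-seeded uniformly ("overflow").
Re-seeded agents carry sentinel fitness +∞ and are re-evaluated through
their next proposal, which keeps the total evaluation count within
N·(T+1) + T.

The improved variant (IFLA) layers two changes on the identical step so that
FLA-vs-IFLA comparisons isolate their effect:

1. **Sine-map initialization.** Initial coordinates come from independent
   orbits of `c_{k+1} = gain · |sin(π c_k)|` (gain 0.99), rescaled to the
   box. Orbits below 1e-6 restart from a fresh uniform draw — the map has a
   measure-zero absorbing orbit at 0. The map's invariant density is
   space-filling but not uniform: its long-run variance on (0,1) is ≈ 0.107
   versus 1/12 ≈ 0.083 for uniform draws (measured by direct iteration; the
   initialization test pins this value).
2. **Cauchy mutation.** Once per iteration the global best is perturbed by
   `scale ⊙ C` with C standard Cauchy via inverse CDF
   (`C = tan(π(u − 1/2))`) and `scale = mutation_scale0 · (upper − lower) ·
   (1 − t/T)`, accepted only on strict improvement. Heavy tails give
   occasional long escape jumps; greedy acceptance keeps the best-so-far
   history monotone. Ties keep the incumbent, for determinism.

Defaults follow the stated benchmark protocol: population 30, 500
iterations, 30 independent runs (run k uses seed base+k), dimension 10.

## Benchmark suite

The original report names only three of its twelve test functions (Schwefel,
Rosenbrock, Lunacek bi-Rastrigin) and the official CEC-2017 suite requires
external rotation-matrix data files, so the suite here uses analytic
classical forms: those three plus sphere, Rastrigin, Ackley, Griewank,
Zakharov and Levy, and three hybrids composing pairs of multimodal cores
under seeded random orthogonal rotations. Nine classics carry seeded random
shifts within 30% of their box; Schwefel and Lunacek keep their canonical
off-origin optima. Schwefel's per-dimension minimizer is refined numerically
at suite construction (bounded scalar minimization to 1e-13) so every
function's documented optimum verifies to 1e-9. Algorithms are compared by
per-function run statistics and two-sided Wilcoxon rank-sum tests on the
per-run bests (α = 0.05, the field convention), with boxplot-ready per-run
values and mean convergence curves exported as CSV.

## AutoML

The base learner is a gradient-boosted decision-tree classifier (LightGBM),
the most consistent reading given that the boosted-tree baseline is the
strongest conventional model in the published comparison. The search space
is the 19-gene feature mask plus: learning_rate [0.01, 0.3] (log),
n_estimators [50, 500] (int), max_depth [2, 8] (int), min_child_samples
[5, 50] (int), subsample [0.5, 1.0], colsample [0.5, 1.0]. Histograms use
max_bin = 63, which at this cohort size costs no measurable AUC and keeps a
full wrapper search affordable on one core.

Fitness is `(1 − mean out-of-fold ROC-AUC)` over stratified five-fold
cross-validation plus `λ·|mask|/19` with λ = 0.01 — small enough that a
five-feature panel is reachable rather than forced (one pp of CV-AUC buys
about two features). The classification threshold for confusion-matrix
metrics is 0.5. The desk-scale optimizer budget for AutoML is population 20
× 60 iterations (≈1 280 genome evaluations, ≈6 400 booster fits); the
30 × 500 benchmark budget remains configurable but buys little on this
synthetic cohort, where CV fitness saturates within a few dozen iterations.
ISS is kept in the candidate set (the original report is self-contradictory about its
exclusion) and selection decides.

## Evaluation

Confusion metrics (PRE, SEN, SPE, ACC, ER = 1 − ACC, F1) treat a probability
≥ threshold as positive and report PRE/F1 as absent (NaN) when there are no
positive predictions, as the published tables print for their degenerate
SVM. ROC-AUC is the tie-grouped threshold sweep, identical to the pairwise
statistic P(s⁺ > s⁻) + ½P(tie) — the test suite checks this equality against
a brute-force O(n²) oracle to 1e-12. PR-AUC uses step interpolation
(average precision); trapezoidal PR interpolation is rejected as
optimistically biased. Decision curves report
`NB(p_t) = TP/n − FP/n · p_t/(1 − p_t)` on a 99-point grid 0.01…0.99
(p_t = 1 diverges and is excluded), against treat-all and treat-none.

## Shapley attribution

The value function is interventional: v(S) = mean over background rows of
the model prediction with coalition features from the explained row and the
rest from the background. Exact enumeration (all 2^d coalitions, batched
into a single model call) is used up to d = 12 selected features and
satisfies efficiency to machine precision; beyond that a permutation-
sampling estimator (one background row and one feature ordering per
iteration) provides an unbiased, seeded approximation. The default
background is 100 seeded training rows, bounding v(S) cost while keeping the
base value stable. Summary-plot exports carry raw feature values;
color-mapping is left to the plotting layer.

## Decision-support report

`predict_patient` maps (model, feature dict) to probability, risk tier and
triggered marker rules. Tier cut points default to 0.3 / 0.7
(low / moderate / high) — the original report does not state its interface's cut points, so
these are package defaults and configurable. The rules encode the published
intervention thresholds: lactate > 2 mmol/L (hypoperfusion), lactate >
4 mmol/L (threshold-effect alert), CFS ≥ 5 (frailty bundle), FDP > 20 µg/mL
(coagulopathy monitoring), GCS ≤ 12 (high-risk consciousness); they live in
an editable YAML file. Rules fire only on values actually supplied; absent
model features are imputed with stored training statistics before scoring.

## Numerical choices and degenerate inputs

- Lognormal quantile fits reproduce the printed median exactly (tested to
  1e-9) before clipping; clipping and rounding shift means by amounts small
  relative to their sampling error at n = 250.
- Optimizer tie-breaks keep the incumbent; all randomness derives from one
  integer seed per run; identical inputs give bit-identical outputs,
  including CSV round-trips of generated cohorts.
- A cross-validation fold with a single class raises (cannot occur at the
  default counts with stratification); an entirely missing column raises
  naming the column; non-finite objective values raise naming the position.
- Problem sizes used by the shipped tests: the full 956-patient cohort, the
  pop 20 × 60 AutoML budget, 30-run optimizer comparisons at dimension 10,
  and 10–20 explained rows per attribution check.

## Known limitations

- No inter-variable correlation structure, no longitudinal dynamics, no
  diagnostic-instrument (CAM-ICU) simulation; synthetic performance is an
  upper bound far above what real data would yield, and the published
  clinical AUCs (0.9690 train / 0.8929 test) are not reproducible without
  the original cohort.
- The baseline flood update is this package's explicit reconstruction from
  the stated metaphor, not the original authors' code.
- Exact Shapley is exponential in panel size; the d ≤ 12 budget is a hard
  gate with the Monte Carlo path beyond it.
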