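# Methods

`mddpredict` implements a predictor-discovery pipeline for binary
improvement of major depressive disorder (MDD) in a three-arm remote
trial of smartphone-delivered interventions, together with a synthetic
cohort generator that reproduces the statistical structure such a trial
export exhibits. This note records the models, the defaults and why they
are what they are, the numerical choices, and what the synthetic results
do and do not establish.

## Outcome and cohort definitions

Treatment response ("improvement") at the outcome week is

    improved  ⇔  PHQ-9_followup < 10  AND  PHQ-9_followup ≤ ½ · PHQ-9_baseline.

The 50% criterion is evaluated as `2·f ≤ b` in exact integer arithmetic,
so the boundary case (baseline 18, follow-up 9) is an improvement and no
floating-point rounding can flip it. Screening retains participants with
baseline PHQ-9 ≥ 10 (10 itself included) and no affirmatively endorsed
bipolar history (lithium prescription, mania medication, or bipolar
diagnosis); a missing history item counts as not endorsed, because
exclusion requires an endorsement. Baseline questionnaire scores (GAD-7,
SDS, AUDIT-C) are the earliest response within 5 days of enrollment —
day 5 included, since only responses *more than* five days out are
discarded.

Encodings: gender female=1; race/ethnicity collapsed to five categories
(the three smallest raw options pooled into "Multiracial/other") and
represented as five indicator columns that enter or leave models as one
unit; marital status, education and income satisfaction binarized
(income distress = "can't make ends meet"); one indicator per treatment
arm, each individually selectable. Continuous columns (age and the four
questionnaire scores) are rescaled to mean 0, SD 1 with the *population*
SD convention, matching the default of the ML stack used for the
classifiers; a zero-variance column is centered with scale 1.
Standardization is refit on the training fold of every CV split rather
than once globally — the leakage-free choice where the source procedure
is ambiguous; fitting per imputed dataset instead would only shrink
fold-to-fold variation slightly at these sample sizes.

## Synthetic cohort generator

The generator is the test bed for every downstream stage; its defaults
*are* the study conditions of the trial being emulated (n = 638 after
screening, three equal-probability arms).

* **Scores.** Baseline PHQ-9 is a discretized normal (mean 15, SD 4)
  truncated to [10, 27]. GAD-7 (mean 10, SD 5, range 0–21) and SDS
  (mean 16, SD 7, range 0–30) are rounded, clipped transforms of a
  latent bivariate normal. The latent Pearson correlation is obtained
  from the target Spearman ρ_s = 0.67 by the exact bivariate-normal
  relation r = 2·sin(π·ρ_s/6); rounding is monotone up to ties and the
  measured attenuation at these scales is < 0.01, well inside sampling
  noise, so no further calibration map is needed.
* **Outcome model.** P(improve) follows a logistic model whose log-odds
  drop by ln(OR_true) when GAD-7 ≥ threshold (defaults: threshold 11,
  OR_true 0.18). The below-threshold rate defaults to 0.58, which
  implies a marginal improvement rate ≈ 0.40 given the default GAD-7
  distribution (P(GAD-7 ≥ 11) ≈ 0.46) — the ~41% rate the emulated
  trial reports. A closed form for the implied marginal rate
  (`implied_improvement_rate`) integrates the discretized latent GAD-7
  distribution and is cross-checked in tests against an independent
  numerical integration and 20,000-participant simulation.
* **Trajectories.** Weekly follow-up PHQ-9 is constructed *after* the
  outcome draw so that applying the response criteria to the generated
  week-4 score reproduces the latent label exactly. Improved
  participants end at a uniform draw from the admissible set
  {0, …, min(9, ⌊b/2⌋)}; non-improved participants split (default
  50/50, configurable) between the two violation modes — still ≥ 10 at
  week 4, or < 10 but reduced by less than half (the latter only exists
  for baselines ≤ 17, and is used only there). Intermediate weeks
  interpolate linearly with integer noise. Real trajectories are surely
  not linear-with-noise; nothing downstream depends on their shape,
  only on the week-4 value and on follow-up scores being plausible
  regressors for imputation.
* **Missingness.** Applied after generation, so the latent truth is
  unaffected: first a block-missing subgroup (41% by default) that
  loses *all* questionnaires and follow-ups (MCAR by default, with an
  MAR option that raises block probability with baseline severity);
  then per-questionnaire item missingness among the remaining
  participants (default 10%, so overall baseline-questionnaire
  missingness is 0.41 + 0.59·0.10 ≈ 47%); income satisfaction is
  missing for 53% of everyone; weekly follow-up missingness is
  specified as the *overall* marginal target (defaults 52/58/59/60% at
  weeks 1–4) with the conditional rate among non-block participants
  derived internally. Dependence between item-level missingness
  indicators beyond the block structure is not modeled.

Because the generator encodes a single-threshold, single-variable causal
structure with MCAR/MAR missingness, passing recovery tests show that
the pipeline finds such a signal through realistic missingness — not
that real cohorts contain one, nor that the imputation is robust to
missingness that depends on the unobserved scores themselves (MNAR).

## Multiple imputation (chained random forests + PMM)

Missing baseline variables and weekly follow-up PHQ-9 are imputed by
chained equations with random-forest conditional models and predictive
mean matching (PMM). Per stream: initialize missing cells by sampling
observed values; then for a fixed number of sweeps (default 5) visit
variables in ascending order of missingness fraction; regress each on
all other analysis columns over its observed rows; replace each missing
entry with the observed value of one of the `pmm_donors` (default 5)
rows whose predicted mean is nearest, ties at the cut distance enlarging
the pool; binary variables are instead drawn from the forest's class
probabilities. PMM guarantees imputed values lie in the observed
support, hence inside instrument ranges, with no post-hoc clipping.
Defaults (M = 100 streams, 100 trees, 5 donors, 5 sweeps) follow common
chained-forest practice; stream m is seeded by (seed, m) only, so any
subset of streams is reproducible in isolation. Follow-up PHQ-9 is
imputed on the raw score scale and the binary outcome re-derived per
completed dataset — the outcome is a deterministic function of scores,
and re-deriving it propagates imputation uncertainty coherently into
Rubin pooling. No convergence diagnostics are computed (fixed sweep
count); this matches the non-goal list.

## Monte-Carlo CV, the paired ΔAUC test, and forward selection

Every model evaluation runs N Monte-Carlo cross-validation iterations
(default 10,000; the desk-scale profile uses 500). Iteration i draws —
from an RNG stream indexed only by (seed, i) — one imputed dataset
uniformly at random and an 80/20 participant split, standardizes on the
training fold, fits, and records the held-out AUC (midrank/tie-aware
rank statistic) and accuracy at the family's default decision rule (0.5
on probabilities, 0 on margins; accuracy is descriptive only). Because
the draws depend only on (seed, i), any two models under the same CV
config see identical resamples; the ΔAUC test is therefore genuinely
paired. A held-out fold with a single outcome class is redrawn inside
the iteration (counted in the log) rather than skipped, which keeps the
AUC vectors aligned across models. The improvement test computes the
empirical distribution of paired differences, its mean and 2.5/97.5
percentiles, and p = P(ΔAUC ≤ 0) with the add-one estimator
(#{Δ ≤ 0} + 1)/(N + 1), so a finite sample never reports p = 0.

Forward selection starts from the 0.5 chance reference, evaluates every
remaining feature (the race indicator block moves as one feature; each
arm indicator is separate), and accepts the candidate with the highest
mean AUC among those that both survive Benjamini–Hochberg FDR control at
q = 0.05 and improve mean AUC by at least 0.02; otherwise it stops.
Ties in mean AUC break by the canonical feature listing order
(deterministic and arbitrary-but-fixed). The BH family defaults to all
comparisons accumulated for a model type — across steps and, for trees,
across the depth sweep — re-adjusted as comparisons accrue
(`bh_scope="cumulative"`); a `per_step` scope is provided because the
alternative reading is defensible. The ≥ 0.02 rule is applied to the
*mean* ΔAUC, not a CI bound: it is a practical-magnitude requirement
layered on top of the significance test, not a second test. Tree-based
families sweep maximum depths 1–5 and keep the depth with the highest
final mean AUC, ties to the shallower (more interpretable) tree.

Model families: logistic regression, linear SVM (`LinearSVC`; the linear
kernel is what "standard linear classifier" implies), decision tree,
random forest, k-nearest-neighbors — all at library defaults apart from
the swept tree depth.

## Threshold extraction and pooled odds ratios

The clinical deliverable is a depth-1 rule. A depth-1 tree of outcome on
the selected score is refit on *each* completed dataset (all rows); the
real-valued split — a midpoint between adjacent integers on integer
data — is integerized by ceiling (a split at 10.5 becomes "≥ 11"), and
the reported cut is the median across imputations (lower median on even
M). The association is summarized by the 2×2 odds ratio of improvement
for high vs. low scorers: per imputation, OR = ad/bc with Wald variance
1/a + 1/b + 1/c + 1/d on the log scale, adding 0.5 to all cells when any
cell is zero (Haldane–Anscombe; per-arm tables at these sample sizes can
plausibly contain zeros). Log-scale estimates are combined with Rubin's
rules: T = Ū + (1 + 1/M)·B and df = (M−1)(1 + Ū/((1+1/M)B))²; when
B = 0 (identical imputations) the reference degenerates to the normal
and pooled results equal the single-table Wald analysis to machine
precision — a reduction the tests assert. The post-hoc GAD-7/SDS
Spearman correlation is computed on observed (pre-imputation) pairs with
a Fisher-z CI (SE 1/√(n−3)); a pair-resampling bootstrap CI is available
because the z-interval undercovers at extreme ρ or tiny n.

## Problem sizes and numerical choices

Defaults follow the emulated study (M = 100 imputations, N = 10,000 CV
iterations, all five families with the full depth sweep). The package's
test and acceptance runs use its desk-scale profile, chosen so the whole
suite runs on one CPU in well under half an hour: N = 500 CV iterations,
M = 5–10 imputation streams, imputation forests of 10–20 trees with 3
chained sweeps, and 5-tree evaluation forests for the random-forest
family in the null-calibration check. Forest sizes affect only the
smoothness of conditional means, not the logic under test (support,
sharing, calibration, recovery); the statistical conditions themselves —
cohort size 638, missingness profile, effect size, iteration and seed
counts — are kept at the study values. The acceptance script
(`scripts/acceptance.py`) likewise runs at desk scale by default
(M = 20 imputation streams, N = 500 CV iterations).

Other numerics: the add-one p floor (above); donor-distance ties include
all tied donors (no order dependence); a variable with fewer than two
observed rows aborts imputation with its name; degenerate one-class
validation folds are redrawn; zero-variance features are kept with scale
1 rather than dropped, so feature sets stay aligned across folds;
`extract_threshold` raises if the depth-1 tree refuses to split
(constant feature or constant outcome) naming the offending imputation.

## Known limitations

* The generator's missingness is MCAR (optionally MAR on baseline
  severity); MNAR mechanisms are out of scope, so imputation validity
  under MNAR is untested.
* Item-level (question-by-question) questionnaire responses and app
  engagement are not simulated.
* The per-arm odds-ratio machinery assumes a common threshold rule; no
  formal arm-by-threshold interaction test is provided.
* Off-schedule follow-up responses are not modeled: synthetic data uses
  exact week indices, so the "which record is week 4" question real
  exports pose does not arise here.
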