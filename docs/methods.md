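# Methods

## The problem

In people living with multiple long-term conditions (MLTC, multimorbidity:
two or more chronic diagnoses), risk of sarcopenia — accelerated loss of
muscle strength and mass — rises with the number of conditions, but simple
counts ignore the possibility that *specific combinations* of conditions
carry disproportionate risk. `ltcmine` implements a pipeline for finding
such combinations: cost-sensitive classification trees are bagged into an
ensemble, every root-to-leaf rule predicting "at risk" is read off and
reduced to the conditions it requires to be *present*, the resulting
combinations are scored and ranked, and the survivors are checked against
conventional logistic regression, including the relative excess risk due to
interaction (RERI) on the additive scale.

Because the motivating cohort data (a large mid-life/later-life biobank) are
access-restricted, the package ships a synthetic cohort generator that
reproduces the statistical structure the analysis assumes; all tests and the
worked examples run against it.

## Outcome construction

A participant is classified **at risk of sarcopenia** when their maximum
grip strength falls strictly below a sex-specific cutoff: 32 kg for men and
19 kg for women in the main configuration (2 SD below young-adult reference
means), 27/16 kg in the EWGSOP2 preset used for sensitivity analysis.
Participants unable to attempt the grip test for health reasons are also
classified at risk; participants who could have attempted it but have no
recorded grip are unclassifiable and are excluded when the sample is
restricted to classifiable participants with ≥ 2 conditions. A value exactly
at the threshold is *not* at risk (the comparison is strict). When several
grip trials exist upstream, the maximum over available trials is the input;
the package takes `grip_max_kg` as given.

## Cost-sensitive trees

Features are the 53 binary condition indicators of the packaged registry
(one, endometriosis, is structurally zero for men). The learner is a CART
specialisation for binary features and binary outcome:

* **Loss matrix.** At-risk prevalence is ~20%, so misclassifying an at-risk
  participant (false negative) is penalised more heavily than the reverse.
  The penalty is derived directly from the outcome proportions:
  `fn_penalty = (1 − p)/p`, `fp_penalty = 1`. This equalises the two
  classes' total expected loss at the root — the altered-priors balance —
  and is applied as per-observation class weights, the standard CART
  equivalence of a loss matrix for two classes (matching rpart's handling).
* **Splitting.** Weighted Gini impurity `2q(1−q)` with `q` the weighted
  positive fraction; the split with the largest impurity decrease wins, with
  exact ties broken by lowest registry index so fitting is deterministic
  given the data. A feature never reappears on a path (a second split on a
  binary feature is degenerate).
* **Constraints.** Maximum depth 10; minimum terminal-node size 25, read as
  the terminal bound with `min_split = 2 × 25` (the source method names a
  single "minimum node size"; both knobs are exposed). `complexity_penalty`
  defaults to 0 — depth and node size govern growth — and can be set to
  0.01 to mimic rpart's default pruning.
* **Leaf class.** Minimum expected loss: a leaf predicts at-risk when its
  positive fraction strictly exceeds `fp/(fp + fn)`, not one half. Ties go
  to not-at-risk.

The greedy learner was checked two ways: against a brute-force enumeration
of all valid depth-≤2 trees (its training loss is always achievable by a
member of that space, and equals the optimum whenever the root gain
maximiser is unique under the default node-size constraints), and against
scikit-learn's class-weighted `DecisionTreeClassifier`, which reproduces its
training predictions exactly on matched configurations. Note that greedy,
impurity-driven induction is *not* guaranteed loss-optimal in general; with
terminal nodes far smaller than the packaged 25 the greedy tree can be
strictly worse than the best depth-2 tree, which is why the optimality check
is stated under the packaged constraints.

## Ensemble, rule extraction and composite score

1000 trees (200 in the scaled-down recovery study) are fitted on
with-replacement bootstrap resamples, one spawned child seed per tree so the
ensemble is reproducible and independent of worker-thread count. The loss
matrix is recomputed from each resample's outcome proportions (a flag
freezes it at the full-sample value).

Every leaf predicting at-risk yields a rule — the conjunction of condition
literals on its path. Literals requiring a condition to be *absent* are
disregarded; the remaining positive literals form the combination. A
reduction with no positive literals is discarded (counted in the log). A
singleton combination is read as "condition X and any other LTC": the
cohort is all-multimorbid, so X present implies at least one other
condition.

Each contributing leaf adds its in-bag at-risk fraction — the probability
of a correct classification at that leaf — to the combination's **composite
score**; distinct trees containing the combination are counted separately
(`n_trees_appearing`). The score thus blends discovery frequency with
classification accuracy, and the top 12 combinations per sex are retained.
The source describes the score only verbally; the plain sum over leaves is
implemented, with in-bag leaf probabilities (an out-of-bag variant was
considered but the in-bag fraction is what the fitted tree actually stores
and audits against its node counts).

Retained combinations are evaluated on the analytic sample via the 2×2
exposure (all conditions present) × outcome table: prevalence, positive
predictive value, sensitivity, specificity, accuracy. These satisfy the
identity `accuracy = sensitivity·p + specificity·(1−p)` with `p` the
at-risk prevalence, which the tests enforce to 0.01 percentage points.

## Triangulation and additive interaction

Each retained combination is re-examined with logistic regression (IRLS via
statsmodels GLM, deviance tolerance 1e-8, separation detected and flagged):

* per-condition odds ratios, each from its own fit (conditions outside the
  combination are not adjusted for, mirroring per-combination reporting; a
  flag enables mutual adjustment);
* for two-condition combinations, the joint model
  `logit P = β0 + β1A + β2B + β3AB` giving OR10, OR01,
  OR11 = exp(β1+β2+β3), and

      RERI = OR11 − OR10 − OR01 + 1,

  with a delta-method (Hosmer–Lemeshow) 95% CI propagated through the
  coefficient covariance; a participant-resampling bootstrap (2000 reps,
  percentile) is the alternative. Within-stratum ORs of each condition in
  the presence/absence of the other are reported in a Knol–VanderWeele-style
  table. RERI is computed only for two-condition combinations; singletons
  get the single OR and larger combinations get the all-present exposure OR.
* Age adjustment refits the full model with age as a continuous covariate.

Odds ratios stand in for risk ratios inside RERI; with ~20% outcome
prevalence this overstates interaction magnitude, a caveat the reports
carry. Significance is judged by the 95% CI excluding 0. No multiplicity
correction is applied; the report logs the number of tests.

## Synthetic cohorts

The generator draws, per sex: uniform integer ages (40–70 by default);
independent Bernoulli condition indicators at configurable prevalences
(defaults span 0.02%–67%, matching a realistic multimorbid biobank profile),
optionally correlated through a Gaussian copula thresholded at prevalence
quantiles; and latent grip strength

    grip = intercept_sex − slope·(age − age_min) − Σ main_effects·X
           − Σ synergy·X_a·X_b + Normal(0, sd_sex),

with intercepts 27.5/44.0 kg (F/M), slope 0.2 kg/year, noise SD 6.0/8.5 kg —
chosen so the classified cohort lands near the observed grip means
(~23/39 kg) and at-risk fractions (~20%) of the motivating population — and
a 0.12% "unable to test" rate applied uniformly at random (grip then
missing). Dichotomising this latent grip at the cutoffs makes the generated
outcome *exactly* the analysis outcome, and makes the true additive
interaction of any condition pair computable: the oracle forces the pair
into each of the four exposure cells with common random draws of age and the
other conditions, integrates the Gaussian noise analytically
(`P(at risk | covariates) = u + (1−u)·Φ((cutoff − μ)/sd)`), and reports RERI
on both the risk-ratio scale and the odds-ratio scale with batch-mean
Monte-Carlo errors. The odds-scale value is the exact estimand of the
saturated logistic interaction model and is the truth used in the coverage
study; in the rare-outcome coverage configuration the two scales nearly
coincide.

What the generator does **not** emulate: empirical age distributions (age
enters the analysis only as a covariate), realistic comorbidity clustering
unless a copula is configured, longitudinal grip decline, or any covariate
structure in who cannot perform the grip test. Passing tests therefore
demonstrate correctness of the machinery under the stated mechanism, not
epidemiological validity on real cohorts.

### Packaged presets

* `biobank-like` — realistic per-sex prevalences, 5000 per sex (test speed),
  no planted synergy.
* `full-scale` — the same at 77 488 women / 62 513 men.
* `recovery` — two planted synergistic pairs, (diabetes, osteoarthritis)
  and (asthma, depression), each with a 20 kg extra decrement when both
  are present, 20 000 per sex. The pairs are moderately prevalent (joint
  prevalence 2–5%) so an at-risk leaf of ≥ 25 observations is reliably
  formable; a 20 kg decrement pushes nearly everyone with both conditions
  below the cutoff. The recovery study (20 seeds, 200 trees) requires each
  planted pair in the top 12 in ≥ 90% of runs.
* `coverage` — a minimal two-condition configuration (prevalence 0.25 each,
  3 kg main effects, 4 kg synergy, baseline far above the cutoff, no age
  slope, no unable rate) for confidence-interval calibration: cell risks are
  clean functions of the grip model, and 95% delta-method CIs must cover the
  oracle truth in 93–97% of 500 cohorts of 20 000.

## Sensitivity analyses

Four single perturbations, each rerunning the full pipeline with the main
run's seed stream (so differences reflect the perturbation, not bootstrap
noise; fresh seeds are an option): EWGSOP2 cutoffs; false-negative penalty
doubled (multiplier on the per-bootstrap recomputed penalty); hypertension
(the most prevalent condition) removed from the feature set — eligibility
and condition counts are unchanged, since removal probes the tree inputs,
not the sample definition; and age-adjusted triangulation models. Agreement
is summarised as the overlap of top-12 condition *sets* (rank ignored).

## Numerical and design notes

* Split gains below 1e-12 are treated as zero to keep float noise from
  fabricating splits; accepted splits therefore have strictly positive gain.
* Seeds are mandatory everywhere; one master seed spawns per-stage child
  seeds by a fixed counter scheme, so adding a stage never perturbs earlier
  stages, and reruns are byte-identical including across thread counts.
* Empty exposure cells abort a joint fit with the cell named; degenerate
  strata report a missing OR with the reason. Separation is flagged, never
  silent.
* Scaled-down problem sizes used by the test suite (5000 per sex for the
  default preset, 200-tree ensembles and 20 seeds in the recovery study,
  500 replicates in the coverage study) were chosen as the smallest sizes at
  which the targeted properties are statistically clean; the full-scale
  presets remain available.

## Known limitations

* OR-based RERI is an approximation to risk-scale additivity at ~20%
  outcome prevalence (documented above and in output captions).
* The composite score's exact functional form in the source method is
  stated only verbally; the plain per-leaf sum is one reasonable reading.
* Greedy induction is not globally loss-optimal; optimality statements hold
  only under the packaged node-size constraints.
* Conditions are simulated independently by default; real multimorbidity
  clusters. The copula option exists but no calibrated dependence preset is
  shipped.
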