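# Methods

`popkin` models a 20-second tablet game in which bubbles rise in five vertical
lanes and a child pops them by touch.  The package has four scientific layers:
a generative simulator of game sessions, an extractor of motor features from
session logs, a battery of group statistics, and a cross-validated classifier
evaluation.  This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic studies do and do
not establish.

## Game model

Geometry is metric, origin at the screen's top-left corner, x rightward and y
downward.  The default screen is 160 × 220 mm (portrait, approximating a
10.2-inch tablet); all sizes are configurable through `GameConfig`.

* One bubble per lane is on screen at a time.  A bubble's center starts at
  the bottom edge and rises linearly at `bubble_speed_mm_s` (default
  20 mm/s), leaving the screen once it clears the top edge.  Successive
  lanes start 0.25 s apart so the lanes desynchronise.
* A touch pops a bubble iff the touch **onset** lies within
  `pop_radius_mm = 18.5` mm of the bubble's instantaneous center.  The
  boundary is inclusive (d = 18.5 mm pops); this is configurable because the
  protocol only fixes the radius, not the boundary convention.
* A popped bubble respawns in the same lane with the same cartoon character
  one sensor frame later; a bubble that exits the top is replaced by a
  uniformly random character.  This respawn asymmetry is what makes
  repetitive play (re-popping the same character) distinguishable from
  exploration.
* Sensors run at 60 Hz for the 20 s analysis window (1,200 inertial
  samples).  The pre-game training phase is not modelled; records represent
  only the analysed window.

The default bubble speed and one-bubble-per-lane density were chosen so a
20 s session offers roughly 10–25 pop opportunities, the plausible range for
the task; both are config knobs because the true game kinematics are not
published.

## Agent model

`AgentProfile` parameterises a child's touch behavior:

| parameter | meaning | NT default | autistic-like default |
|---|---|---|---|
| `aim_sd_mm` | isotropic Gaussian aim error around the target's center | 10 | 15 (+50%) |
| `touch_duration_mean_s`, `touch_duration_sd_s` | lognormal touch duration (moment-matched) | 0.25, 0.10 | 0.375, 0.15 (+50%) |
| `path_length_scale_mm` | total finger-drag path per touch (random walk at 60 Hz) | 6 | 9 (+50%) |
| `inter_touch_mean_s` | exponential gap between touches | 0.8 | 0.8 |
| `touches_per_target_mean` | geometric number of attempts per targeted bubble | 1.5 | 2.0 |
| `repeat_prob` | probability of re-targeting the just-popped lane | 0.4 | 0.55 |
| `force_scale` | peak of the touch-impact acceleration impulse (m/s²) | 1.0 | 1.0 |
| `double_touch_prob` | probability a touch is followed by a rapid nearby touch | 0.10 | 0.10 |
| `accel_noise_sd` | white sensor noise per axis (m/s²) | 0.05 | 0.05 |

The +50% multipliers on aim error, duration and path length are the planted
effect sizes used by every recovery study; with them, the case group pops at
a visibly lower rate (≈0.64 vs ≈0.87), lands ~1.6 mm farther from centers,
and is more variable — the direction pattern of the reported younger-cohort
contrasts.  A note on one non-contrast: the *SD of the pop distance* has no
identified direction here, because pops condition the distance on
d ≤ 18.5 mm and the truncation caps the conditional spread.

The agent event loop: pick a target (just-popped lane with probability
`repeat_prob`, else the nearest on-screen bubble); draw a geometric number of
attempts; per attempt, aim at the bubble's current center with Gaussian
error, hold for a lognormal duration while the finger drifts along a
fixed-step random walk, and advance by an exponential gap.  A hit ends the
attempt run.  When nothing is on screen the agent waits rather than poking.

The inertial stream is gravity (9.81 m/s² on z) plus white noise plus a
Gaussian impulse at each touch onset (peak `force_scale`, scale 20 ms, i.e.
~80 ms of support).  The analytic integral of the squared impulse,
A²·σ·√π, anchors the force-proxy tests.

## Age and clinical-score models

`AgeModel` tilts profile parameters linearly in age around the cohort
midpoint (default range 18–36 months): per month, aim error −0.15 mm, touch
duration −6 ms, duration SD −2 ms, path length −0.15 mm, inter-touch gap
−18 ms, all clipped to legal domains.  Older simulated children therefore
touch more, pop more, land closer to centers and touch more briefly — the
canonical age trends, used as sign checks only.

Clinical scores are linear-Gaussian in a latent motor skill, defined as the
*negative cohort-standardised aim error*: `score = loading × skill + N(0,
noise_sd)`.  The default cohort carries a fine-motor-like score (loading 8,
noise 6; population correlation with skill 0.8) and a composite-like score
(loading 6, noise 8).  The linear-Gaussian form makes partial-correlation
recovery analytically predictable: a zero loading implies zero partial
correlation with every feature.

IQ is drawn per group (NT: 100 ± 15; case: 90 ± 18) and is available as a
second covariate.

## Feature conventions

Thirty-seven columns from nineteen families; `FEATURE_COLUMNS` fixes the
order.  Conventions that resolve ambiguities:

* Rates and percentages are proportions in [0, 1]; accuracies in [0, 100].
* SDs are sample SDs (n−1) and NaN below two observations; medians average
  the middle pair.  Ratios with empty denominators are NaN, never 0.
* **Targeting**: a touch belongs to the nearest bubble within
  `targeting_radius_mm` (default 1.5 × pop radius = 27.75 mm) of its onset.
  Consecutive assigned touches on the same bubble form a *target episode*
  ending at the bubble's pop/exit or the last touch's offset, whichever is
  first.  Unassigned touches do not break an episode.  Episodes yield the
  targeted-bubble count, touches per target, time on target and touch
  frequency (NaN for zero-duration episodes).
* **Popping accuracy** is 100% inside the bubble disc (radius 18.5 mm) and
  decays linearly over `accuracy_decay_mm` = 18.5 mm beyond the edge,
  floored at 0.  It is evaluated per *sample* against the episode's bubble
  at the sample's timestamp (a moving target, frozen at the track endpoints
  outside its lifetime), then summarised per touch (mean/max/SD) and per
  session.  Only targeted touches have a reference bubble, so only they
  enter accuracy features.
* **Double touches**: touch i+1 is a double iff it starts within 0.3 s of
  touch i's offset and within 10 mm of touch i's onset; both thresholds are
  config knobs since only the behavior, not the rule, is fixed.
* **Force proxy**: per axis, a centred 1 s running median is subtracted
  (gravity and slow tilt removal); the proxy is the trapezoidal integral of
  the squared magnitude of the residual over the touch window, 0 for
  zero-duration touches.  The median window and the trapezoid are package
  choices; the contract is "integral of squared high-passed acceleration
  over the touch duration".
* **Repeat percentage** counts consecutive pop pairs with the same lane and
  character over (pops − 1); **transitions** count consecutive pop pairs in
  different lanes.
* **Exploration** tiles the screen with 10 mm cells (partial edge cells
  count) and reports the fraction containing any touch sample.
* Pop detection recomputed from a log must reproduce the logged pops: for
  each touch onset in time order, the nearest on-screen not-yet-popped
  bubble pops iff the onset is within the pop radius; ties break by spawn
  time then id.

## Statistics

* **ANCOVA**: least squares of the feature on intercept + covariates +
  dummy-coded group; the group term is tested by the full-vs-reduced F
  (Type II — order-invariant with a single categorical and no
  interactions).  η² is classical (SS_group/SS_total), matching the
  .01/.04/.14 effect-size conventions; partial η² is not reported.  Rows
  with any missing value are dropped listwise; a zero-residual fit raises a
  degenerate-model error.  With no covariates the procedure is textbook
  one-way ANOVA (verified to 1e-10).
* **FDR**: Benjamini–Hochberg step-up across the feature family of one
  comparison; features skipped for degeneracy or missingness are excluded
  from the family.  (BH is a one-shot transform; it is not idempotent on its
  own output, so no such property is claimed.)
* **Mann–Whitney**: exact enumeration when n₁+n₂ ≤ 20 without ties, else
  normal approximation with tie and continuity corrections; effect size is
  rank-biserial r = 1 − 2U/(n₁n₂).
* **Partial Spearman**: rank-then-partial — variables are midrank
  transformed, ranked x and y are residualised on ranked covariates plus an
  intercept, rho is the Pearson correlation of residuals, and p uses
  t = ρ√((n−2−k)/(1−ρ²)) on n−2−k df.  The alternative
  (Spearman of raw-data residuals) differs slightly; rank-then-partial
  matches the common implementation (pingouin agrees to 1e-9 in tests).
* **Proportion z-test**: pooled two-sample z with a degenerate-pooled-rate
  error.

## Classifier evaluation

Greedy forward selection maximises the pooled leave-one-out cross-validated
AUC of a regularised logistic regression.  Inside every training fold, and
only there: the minority class is up-sampled with replacement to parity
(fold-specific seed), features are standardised with training-fold
statistics, and hyperparameters are chosen by inner stratified 3-fold AUC.
The held-out probabilities are pooled into a single ROC — with one-sample
folds, pooling is the only coherent curve.  AUC uncertainty uses the
Hanley–McNeil closed-form SE with Wald intervals clipped to [0, 1].

The default search grid spans C ∈ [0.01, 100] (9 log-spaced points), L1/L2/no
penalty, intercept on/off; any optimizer reaching the penalized-likelihood
optimum is acceptable (liblinear for L1/L2, lbfgs unpenalised).
Hyperparameter search is nested inside the LOOCV (no selection leakage); a
single search on all data would be cheaper but optimistic.  Simulation
studies (recovery, leakage, null calibration) use a reduced L2-only grid
(C ∈ {0.1, 1, 10}, intercept on) — `ClassifierSpec.small_grid()` — as the
package's standing problem-size choice for Monte-Carlo work; the full grid is
exercised on small n in the unit tests.

Seed policy: one master seed; fold f uses `seed·100003 + f` (kept below
2³¹), so runs are reproducible and folds are independent under parallelism.

## Simulation study sizes

The test suite's Monte-Carlo checks use: type-I calibration, 500 null
cohorts of n = 60/60 (per-feature rejection band 0.03–0.07; features whose
ANCOVA is degenerate in most null replicates — the two usually-constant
median features — are only required to be conservative); Hanley–McNeil
coverage, 1,000 binormal score sets at true AUC 0.7 with n = 50/50 (band
0.90–0.98); effect recovery, 50 cohorts of n = 60/60 with the +50% case
profile (distance-to-center survives FDR in ≥90%); greedy recovery, 20
planted-feature matrices (two informative columns at 1.5 SD shift among five
noise columns, n = 40/40; a planted column must win step 1 in ≥80%, and the
three-feature model's pooled AUC must reach 0.85); label-permutation leakage,
25 runs (mean AUC within 0.5 ± 0.1).

## What the synthetic studies show — and do not

The simulator reproduces the *structure* of the task (geometry, respawn
rules, sensors, engagement filter) and plants known group, age and
clinical-score effects, so every downstream stage can be tested for
correctness, calibration and recovery against a known truth.  It does not
emulate real toddler behavior: no fatigue, learning or caregiver
interference; aim error is isotropic and stationary; touch paths are
random walks rather than ballistic drags; clinical scores are
linear-Gaussian in a single latent skill.  Passing tests therefore establish
that the pipeline measures what the generative model encodes — not that the
features would separate real diagnostic groups, which requires real data.

## Known limitations

* The force proxy's gravity-removal and integration details are package
  choices; absolute proxy values are comparable only within a convention.
* Near-degenerate features (e.g. medians that are constant when almost all
  touches are accurate) are skipped per comparison rather than imputed;
  their type-I behavior is conservative by construction.
* The engagement filter keys on touch count only (≥3 touches kept), as the
  protocol specifies; no other compliance signal is modelled.
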