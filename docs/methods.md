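# Methods

This note documents the models and procedures implemented in `dimvision`, the
defaults and why they were chosen, and what the synthetic data can and cannot
show.

## Photometry

The light environment is a table of four levels with decision-box
illuminances 469, 28, 1.83 and 0.47 lux below a constant 1400-lux flight
cage, ND attenuations expressed in log₁₀ units relative to level 1, and fixed
positive-target luminances (200, 10.4, 0.68, 0.19 cd m⁻²) for the
discrimination task. The 0.47-lux value is treated as ground truth even
though it was extrapolated by the original experimenters; instrument floor
effects are not modelled. Reported log-unit drops round to one decimal, half
away from zero (so 0.47 → 0.5 and 3.47 → 3.5). No radiometric conversion
between lux and cd m⁻² is attempted, and the stimulus geometry (9.6° target,
30.7° separation) is stored as metadata only: the effective viewing distance
inside the decision box is ambiguous, so the angles are not re-derived.

## Observer model

Choices are Bernoulli draws from a logistic psychometric function

p(x) = γ + (1 − γ − λ) · logistic(β(x − α))

with guess rate γ = 0.5 (2AFC), lapse rate λ = 0.02 by default, on the
log₁₀-luminance axis for detection and the Weber-fraction axis for
discrimination. The logistic is the standard minimal choice; nothing in the
pipeline depends on its exact shape. Default slopes are β = 8 per log₁₀ unit
(detection) and β = 10 per Weber unit (discrimination) — steep enough that a
staircase resolves the threshold within a session, shallow enough that
performance is probabilistic near it. Real birds' slopes are unknown; the
slope is a free simulation parameter, not an estimate. Observers are placed
by their 70.7 %-correct point (`from_percent_point`), which is what a
1-up/2-down staircase tracks, so the generator's target thresholds are the
quantity the pipeline should recover.

Per-level target thresholds default to the study conditions: detection
0.825 / 0.110 / 0.136 / 0.106 cd m⁻² at levels 1–4; discrimination Weber
fractions 0.45 / 0.42 / 0.54 / 0.41. Between-bird variation is a normal
offset per bird with SD 0.08 log₁₀ units (detection) and 0.05 Weber units
(discrimination) — chosen once as values consistent with the within-level
spread a 4-bird study of this kind shows; the staircase itself supplies the
session-to-session residual.

## Staircase

Trial-unit rules: two consecutive corrects at a level form a successful unit
(one step harder); one incorrect, or a correct followed by an incorrect,
forms an unsuccessful unit (one step easier) — units therefore contain one or
two trials, and a single incorrect first trial moves the level immediately.
A reversal is a completed unit whose outcome differs from the previous
completed unit's; its value is the level at which that unit was run, tagged
with the trial index that realised the flip.

Step schedules have exactly two decreases. The exact step values used in the
original apparatus are not available, so the defaults are 0.4 / 0.2 / 0.1
log₁₀ units (detection) and 0.2 / 0.1 / 0.05 Weber units (discrimination),
switching after reversals 2 and 4. The convention is that the smaller step
first applies to the move *following* the breakpoint-th reversal. Detection
tracks start 1.0 log unit above an anchor (the a-priori threshold guess) and
clamp at anchor ± 1.5; discrimination tracks start at k = 0.9 and clamp to
[0, 1]. Clamping never overshoots: a clamped repeat still forms trial units
but the level never leaves the bounds.

Stopping: a hard cap at 100 trials, or earlier once ≥ 8 reversals have been
recorded while the smallest step was in force — an explicit, configurable
proxy for "steady-state performance", which the original procedure left
qualitative — but never before 38 trials (35 for discrimination sessions,
whose floor was lower). Side assignment is semi-random in the Fellows style:
every block of 10 trials holds 5 left / 5 right (final partial block as
balanced as possible) and no side repeats more than 3 times in a row,
generated by per-block rejection sampling.

A 1-up/n-down rule targets the p with pⁿ = ½ (70.71 % correct for n = 2);
`convergence_probability` implements the closed form and is cross-checked in
the tests by long-run simulation against a known psychometric function.

## Threshold estimation

Reversals are re-derived from the logged outcomes and stimulus values, never
trusted from the controller, so deposited and simulated logs share one code
path. The session threshold is the arithmetic mean of the reversal values
whose trial index lies in the final 20 choices (window configurable); an odd
count drops the earliest in-window reversal so successful and unsuccessful
units get equal weight. Fewer than two in-window reversals is an estimation
error with a diagnostic, not a silent NaN. "Values at the reversals" is read
as the level of the unit that caused the flip (not the level stepped to);
the alternative is a half-step shift and the choice is symmetric on average.

Detection thresholds are averaged and reported in absolute luminance
(cd m⁻²); the background at the dim levels is taken to be below the birds'
detection limit, so Weber normalisation against it would be meaningless.
Discrimination thresholds convert the reversal-averaged negative-target
luminance to k = (I₊ − I⁻)/I₊; since I₊ is fixed within a session, averaging
fractions or converting the average are identical.

Averaging in linear luminance while the staircase steps on a log grid makes
the estimator a small amount higher than the geometric mean of the reversal
levels; simulation (200 sessions per condition, in the tests) puts the net
bias of the whole estimator below 0.02 log₁₀ units against the observer's
70.7 % point, well inside the 0.1 log-unit recovery tolerance asserted.

## Mixed models

The model is y_ij = x_ij'β + b_i + e_ij with a per-bird random intercept
b_i ~ N(0, σ_b²), fitted by full maximum likelihood (not REML) so that
likelihood-ratio tests on fixed effects are valid. The likelihood is profiled
over the variance ratio λ = σ_b²/σ²: per group V_i = I + λ11' has closed-form
inverse and log-determinant, β and σ² follow by generalized least squares,
and a bounded scalar search over log λ (xatol 1e-10, search range e⁻¹⁶–e¹²)
plus an explicit evaluation at λ = 0 finds the optimum deterministically. A
boundary optimum returns σ_b² = 0 and coincides with ordinary least squares.
Fits are cross-checked in the tests against an independent ML implementation
(statsmodels `MixedLM(reml=False)`) to ~1e-6 in log-likelihood.

Responses are log₁₀-transformed for thresholds (the choice of base is
irrelevant once back-transformation is applied consistently) and
inverse-transformed for response times. The LRT compares the full model
(light level fixed) to the reduced model without it, χ² reference with
df = difference in fixed-effect count (3 for four levels). AIC is
−2ℓ + 2k with variance components counted in k. Per-level estimates are
Wald: point and 95 % interval on the transformed scale mapped through the
inverse transform, endpoints swapped for the (decreasing) inverse map, and a
non-positive bound under a non-identity transform is flagged as NaN rather
than silently mapped. Pairwise comparisons are Wald-z contrasts with Holm
(default) or Bonferroni adjustment — a documented approximation to
single-step Tukey adjustment, which (like Satterthwaite-df F tests) is out of
scope. Back-transformed level estimates hold numeric covariates at their data
means and other factors at their reference level; covariate-by-factor
interaction columns are not re-centred in those prediction rows, so level
estimates are intended for the threshold models (factor-only) rather than
the interaction-bearing timing models.

ML likelihood-ratio tests are asymptotic; at the 48-observation study size
the type-I error at α = 0.05 measures ≈ 0.05–0.06 in the calibration test,
inside the asserted [0.03, 0.07] band.

## Timing

Response times are log-normal, medians 1.17 s (detection) and 0.98 s
(discrimination), log-SDs 0.40 and 0.32 matched to the reported quartile
ratios. Inter-trial times are gamma with shape 4 and medians 8.33 s /
7.79 s — right-skewed with roughly the reported quartile spread (a gamma
cannot match both reported quartile ratios exactly; the median is the
calibrated quantity). Trials in successful units are 5 % faster (an effect of
order 10⁻² s, matching the reported direction and magnitude), and 3 % of
trials are flagged multiple-entry with 3× inflated response times; the
analysis excludes flagged trials from response-time summaries and models but
keeps them for inter-trial summaries. The timing analysis selects the
fixed-effect structure by AIC among six nested candidates up to the full
model (inter-trial time, light level, trial unit, and the
inter-trial-time×unit and level×unit interactions) and reports an LRT of the
winner against the null.

## What the generator does and does not emulate

It emulates: the two designs (48 balanced detection sessions; 40
discrimination sessions with birds 2 and 4 under-represented), session
lengths bounded at 38–100 (35–100) choices, staircase-driven stimulus
sequences, Fellows-constrained side assignment, study-scale thresholds and
their between-bird spread, and timing distributions with a small
trial-unit effect. It does not emulate: adaptation dynamics within or across
trials, position biases or side preferences, motivation drift across a
session, correlations between response time and accuracy beyond the unit
effect, or any photoreceptor mechanism. Passing tests therefore validate the
measurement-and-inference pipeline — the staircase logic, estimator and
models — not any claim about real birds' vision.

## Problem sizes

The test suite and the acceptance script use: 20 000-trial runs for staircase
convergence; exhaustive 4096 length-12 outcome sequences for
controller-oracle equivalence; 200 sessions per condition for threshold
recovery; 1000 null replicates of the 48-threshold design for LRT
calibration; 100 replicate studies for end-to-end power; and one full
88-session study for the headline quantities. These sizes put Monte-Carlo
error comfortably below the asserted tolerances while keeping a full run in
the low minutes.

## Known limitations

* The random-effects structure is a single random intercept; random slopes
  and crossed factors are out of scope.
* Wald intervals, not profile likelihood; Holm contrasts, not exact Tukey.
* The step schedules are plausible defaults, not the original apparatus
  values; absolute threshold variance across sessions depends on them.
* The external-data adapter maps columns by configuration and validates
  structure, but has only been exercised against synthetic foreign tables.
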