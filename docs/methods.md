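# Methods

This note records the models, defaults and numerical choices behind
`sleepart`, and what the synthetic-data experiments do and do not establish.

## Actigraphy preprocessing

**Nonwear.** Wrist devices produce exact zeros when removed.  Any maximal
run of zero counts strictly longer than 4 h flags nonwear, and the full 24 h
window *centred on the run's midpoint* is excluded (clipped at the recording
edges).  Centering is a choice — the convention could equally anchor on the
run's start or its calendar day — so it is exposed as the `window_h` /
`min_run_h` parameters of `flag_nonwear`.  Genuine sleep rarely yields >4 h
of literal zeros at 15 s resolution; in the simulator this only happens when
sleep count suppression is set exactly to zero with no count noise, a
configuration used for detector oracles, where nonwear flagging is then
deliberately skipped.

**Downsampling.** The rest-detection algorithm class is validated at 60 s
epochs, so the 15 s series is low-pass filtered and decimated 4:1.  The
filter is a 65-tap Hamming-window FIR with cutoff at the new Nyquist
(1/120 Hz), applied forward–backward (zero phase, odd-extension padding, so
constant signals pass exactly); a 60 s epoch is excluded if any of its four
source epochs was.  Filtered counts are clipped at zero since the FIR can
undershoot at sharp sleep/wake edges.

**Rest detection.** Per noon-to-noon day (so a night is never split):
ln(count+1); threshold at the midpoint of the two cluster centres of a 1-D
2-means split (deterministic Lloyd iteration initialised at the 10th/90th
percentiles); binary rest classification with masked epochs forced to
"active"; morphological opening then closing with a 30 min structuring
element (opening removes sub-30-min rest flecks caused by count noise in
quiet waking hours, closing bridges brief within-sleep arousals); longest
rest bout wins.  Bouts over 18 h are discarded as invalid (e.g. a device
left on a table), implemented so that an all-quiet day falls back to an
all-rest classification and is then removed by the cap.  Days with under
50% unmasked epochs yield no interval.  Threshold separation below 0.25
log-units is treated as "no bimodal structure" with a fixed fallback split
at ln(11).  On simulated days with a known 23:30–07:30 sleep window the
detector recovers onset/offset within ±2 min noise-free and within ±15 min
under realistic count noise.

**Valid days.** A recording day is valid when fully covered by the
recording and ≥ 90% unmasked (the fraction is configurable); a sleep day
additionally contains a detected interval onset.  Sessions enter the
rest–activity-rhythm sample with ≥ 5 valid recording days and the sleep
sample with ≥ 5 valid sleep days.

## Features

**Extended cosine model.**  `y(t) = min + amp·F(cos(2π(t−φ)/24))` with
anti-logistic `F(c) = expit(β(c−α))`.  Bounded least squares
(`scipy.optimize.least_squares`, trf) over (min ≥ 0, amp ≥ 0, φ, α ∈ [−1,1],
β ∈ [0.01, 50]), with the acrophase multi-started at {0, 6, 12, 18} h plus
the empirical peak hour.  "Partial" convergence means the optimiser
converged with α or β pinned at a bound; failed fits (constant series,
non-convergence, vanishing amplitude) carry no usable parameters, mirroring
the analytic rule that at least partial convergence is required.

**IS / IV.**  Computed on hourly-binned means of unmasked epochs (hourly
bins are the convention of the nonparametric rest–activity literature; the
bin width is not configurable because the nominal IV range [0, 2] is
bin-width dependent).  A partial trailing day is dropped so the length is a
multiple of 24; hours with under half their epochs unmasked are imputed
with that hour-of-day's mean across other days to keep the successive
differences in IV meaningful.  IV values outside [0, 2] (possible for
pathological alternation) are returned flagged, not capped.

**Circular statistics.**  Rest midpoints and acrophase live on the 24 h
circle.  Midpoint SD is computed on deviations unwrapped to (−12, 12] h
around the circular mean, and reported as ln(SD + ε) with ε = 1/120 h
(30 s) so perfectly regular sessions stay finite.  Both the offset and the
unwrapping convention are package choices; the log transform itself is the
standard variance-stabilising choice for timing variability.

## Pathway assignment

Dementia label iff any dementia diagnosis (onset = first dementia visit
age); otherwise stable MCI iff two consecutive MCI visits; otherwise
normal.  "Consecutive" means adjacent visits no more than 1.5 yr apart
(configurable), reflecting annual visit cadence.  MCI onset is the age at
the *first* visit of the earliest qualifying pair — the moment stable
impairment began; the second-visit convention would date its confirmation
instead.  On the dementia pathway an MCI onset is recorded only when a
qualifying pair completes before the first dementia visit.  A lone MCI
diagnosis at the end of follow-up classifies as normal under the literal
rule but is flagged (`lone_terminal_mci`), since follow-up may simply have
been censored before a confirming year.

## Trajectory model

For outcome `y_ij` of subject `i` at visit age `a_ij` (centred at 82, the
median first-visit age, for conditioning):

    y_ij = x_ij'β + b_0i + b_1i·a_ij + e_ij,
    (b_0i, b_1i) ~ N(0, Ψ),  e_ij ~ N(0, σ²/w_ij)

with fixed effects: 1, a, a², a³; pathway mains; all age-term × pathway
interactions; truncated cubics ((age − k_MCI)₊)³ and ((age − k_dem)₊)³ at
the subject's own onset ages; and covariates.  A single truncated cubic per
event keeps the trajectory C² at each knot — adding lower-order truncated
terms would reintroduce the linear-spline elbow the cubic basis exists to
avoid.  Continuous covariates are mean-centred and categorical dummies
proportion-centred, so the zero covariate vector *is* the average-covariate
profile used for typical-subject prediction.

**Estimation.**  REML, profiling β and σ² and optimising the 2×2 relative
random-effect covariance through its Cholesky factor (L-BFGS-B plus a
Nelder-Mead polish; per-subject Woodbury identities make each objective
evaluation O(n)).  Observation weights (valid actigraphy days; 1 for
self-report) divide the residual variance; they are normalised to mean one
inside the fit, so rescaling all weights changes nothing and the reported
residual variance refers to an average-weight observation.  Zero variance
components are admitted as boundary solutions and flagged.  On equal-weight
problems the fit agrees with `statsmodels` MixedLM (REML) to ~1e-6 in the
fixed effects, which the test suite checks as an independent oracle; the
in-house fitter exists because the analysis requires residual weights.

**Inference and elimination.**  Wald t statistics with residual
df = n_obs − rank; with thousands of observations this is effectively the
z approximation, and the simulation suite verifies 95% CI coverage is
nominal.  Backward elimination removes, one at a time, the currently
removable term with the largest p ≥ 0.05 and refits.  Removable terms are
the age mains, age×pathway interactions and knot terms, under the
hierarchy: an interaction is blocked by a higher-order interaction of the
same pathway; an age main is blocked by any higher-order main or any
same-or-higher-order interaction; pathway mains, the intercept and
covariates are never candidates.  Consequence worth noting: with truly
null cubic terms, each cubic column is pruned with probability ≈ 0.95 per
pass (the test's type-I rate), but the cubic *main* only becomes removable
after both its interactions leave, so the joint probability that all three
cubic columns vanish has a structural ceiling near 0.95³ ≈ 0.86; the
simulation suite therefore tracks the per-term elimination rate.

## Contrasts

Benchmark sets are four increasing ages with implied diagnosis schedules
(MCI at the 2nd age, dementia at the 3rd for the dementia pathway).
Primary set {82, 86, 90, 94}; sensitivity sets {80,84,88,92},
{84,88,92,96}, {82,85,88,91}, {80,86,90,94}.  Segments use a 0.1 yr
boundary offset ({82–86, 86.1–90, 90.1–94}), configurable; with abutting
boundaries segment d's sum exactly to the overall change.

The standardizer is σ_std = √(Ψ₀₀ + σ²): the model-based SD of a single
observation for an average-age subject.  Alternatives (residual SD only)
are available; the choice scales every d by a common factor and is the main
caveat when comparing standardized magnitudes across studies.  CIs are Wald
intervals treating σ_std as fixed — uncertainty in the variance components
is ignored, which is anti-conservative in principle but negligible at
cohort sizes of several hundred subjects.  Benjamini–Hochberg runs within
each (aim, domain, benchmark-set) family; the segment contrasts form their
own family so exploratory segment tests do not dilute the primary
within-pathway family.

## Synthetic cohorts

The generator emulates the *structure* of a community cognitive-aging
cohort, with defaults matched to published marginal summaries of such a
cohort: pathway mixture (59% normal, 13.4% stable MCI, 27.6% dementia),
entry age ~ N(81.2, 7.1²) truncated at 65, annual visits with ±0.1 yr
jitter truncated by a 0.2/yr dropout hazard (≈ 4.2 visits on average, max
10), MCI onset ~ N(85.7, 6.05²) and dementia onset ~ N(88.2, 6.7²) snapped
to the realized visit grid, 51% of dementia-path subjects with a stable-MCI
prodrome, 75% female, education ~ N(15.3, 3.05²).  Subjects whose sampled
pathway needs more visits than their sampled follow-up provides (a
stable-MCI pair needs two) have follow-up extended to the minimum, keeping
the mixture exact.  Diagnosis sequences are generated to be consistent with
the assignment rules by construction (isolated MCI visits only, for normal;
one terminal MCI run, for stable MCI; non-reverting dementia), which is
what makes the 100% label round-trip a meaningful structural check rather
than a tautology: it exercises the full rule set including onset dating.

Epoch-level actigraphy: counts are negative-binomial (size = 5 by default,
the over-dispersion typical of wrist counts; size 0 means deterministic
rounded means) around an extended-cosine mean curve, multiplied by a
suppression factor (default 0.05) inside the sleep window (default
23:30–07:30), with nonwear inserted as forced zero runs.  The default
cosinor width α = −0.4 aligns the curve's trough with the sleep window, as
in real data where the trough *is* the sleep period; a wide-trough
configuration would instead create hours of trough-level waking activity
before bed, which belongs to no realistic wear pattern and defeats any
threshold detector.

**What passing tests show — and don't.**  The simulator contains no naps,
no within-sleep wake bouts, no weekday/weekend structure, no seasonal or
device drift, and nonwear only as clean zero runs; feature-extraction
accuracy on it bounds algorithmic error, not performance on real
recordings.  Feature-level outcome simulation draws from exactly the model
the estimator fits, so recovery tests validate the estimation machinery
(REML, weights, elimination, contrasts), not the substantive adequacy of
cubic splines for real sleep trajectories.  Informative missingness is
limited to a pathway-independent dropout hazard plus a death-indicator
covariate; mortality-informative dropout is out of scope.

## Problem sizes

Simulation studies in the test suite use: CI calibration, 200 replicates of
500 subjects; null-cubic elimination, 50 replicates of 800 subjects;
end-to-end effect recovery, 20 seeds of 300 subjects; detector and cosinor
recovery, 100 days / 50 sessions.  The acceptance script runs the same
experiments at 60 / 25 / 10 replicates respectively, as a compact
re-verification; all quantities it reports are recomputed at run time from
the seed it is given.
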