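# Methods

This note documents the models and procedures implemented in `foragerow`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish.

## Task and data model

Participants navigate a square virtual track with four reward zones. At each
zone an offer — a reward category plus a delay of 3–29 s — is presented
inside an *offer zone*; the participant stays (waits out the delay for a
short video or candy), skips, or quits after starting the delay. Sessions
carry per-trial event timestamps (ms), offer-zone trajectory samples
(time, x, y, heading) and, for the food variant, magazine beam-break logs.
Timestamps are integer milliseconds internally; delays are float seconds.
Quit trials carry both the 0-coded choice (for threshold fitting) and the
waited time (for the sunk-cost analyses). Trajectory samples after the first
offer-zone exit (re-entries) are excluded at both the writer and the reader.
Magazine beam breaks of 50 ms–10 s (both bounds inclusive — the conservative
reading of "between") within the first 20 min count as retrievals.

## Delay thresholds

Choices (stay = 1, skip/quit = 0) per reward category are fit with a step
function of delay: predict stay strictly below a candidate threshold, score
a candidate by misclassification count. Before fitting, the set is padded
with one synthetic stay at (min delay − 1 s) and one synthetic skip at
(max delay + 1 s) so all-accept / all-reject patterns keep a finite step.
Padded points are flagged and never treated as real trials.

Open choices, fixed as follows:

- **Candidate set** — midpoints between consecutive sorted unique delays.
  On integer delay grids any threshold between two adjacent offers is
  observationally equivalent; midpoints are the symmetric representative.
  Error ties return the mean of all minimizing candidates (deterministic,
  order-independent; verified against a 0.1 s brute-force grid scan).
- **Leave-one-out** — the threshold attached to trial *i* is fit on every
  other offer of the category, *re-padded on that subset*, so each sub-fit
  is self-contained. The category threshold is the arithmetic mean of the
  per-trial thresholds. Fewer than 2 real trials ⇒ unclassified.
- **Response patterns** — the same LOO procedure runs on inverted choices.
  Mean forward error < mean inverse error ⇒ `normal`; greater ⇒
  `long_delay_pref`; on a tie, ≥ 75% acceptance ⇒ `full_stay`, ≤ 25% ⇒
  `full_skip`, else `unclassified`. "Average error" is taken over the LOO
  sub-fits (the text leaves the averaging set open).
- **Offer value** — value = threshold − offered delay; positive values are
  better-than-threshold ("good") offers, zero is the maximally difficult
  boundary. (The prose elsewhere uses the opposite sign; the figure
  convention, positive = good, is adopted.) Boundary and
  non-`normal`-pattern trials carry no value type and drop out of the
  value-typed analyses rather than being imputed.

## Offer-zone (VTE) measures

Per trial, over the trajectory from offer presentation (versions 1–2) or
first movement (versions 3–4, which gate the avatar) to the first exit:

- decision latency (ms): exit minus offer/movement time;
- reaction time (ms, versions 3–4): movement minus offer time; values over
  15 s are not analyzed (strictly greater);
- path distance: summed Euclidean inter-sample distance (track units);
- total rotation: summed absolute heading change with differences wrapped to
  (−180°, 180°] — the human analogue of the rodent IdPhi measure. Any other
  wrap convention inflates rotation at the 0/360 seam;
- rotation reversals: sign changes of the wrapped heading increments after
  discarding increments below a 1° jitter threshold (raw sign changes on
  noisy logs over-count); not normalized downstream;
- pause time (ms): summed intervals with displacement < 1e-6 units and
  heading change < 1° (exact-stop reading with float tolerance);
- entry bias: 100 × entry position, in percent of hallway width, −50
  (reward side) to +50 (exit side).

Exclusions follow the stated scopes exactly: latency > 15 s removes the
trial from *all* offer-zone measures; rotation > 360° removes the rotation
and reversal measures only. Exclusion tallies are logged per session and
summed per run so the filters are auditable.

Latency, distance, rotation, pause and reaction are log10-transformed (their
distributions are strongly right-skewed) and z-scored within session over
the retained trials. Zeros are offset by half the smallest positive value of
that measure in the session before the log; a zero-variance measure yields
z = 0 with a warning. Z-scoring within session is the mechanism used for
removing person-level nuisance (age/gender/hardware); full covariate
regression is deliberately out of scope and covariates are carried for
stratified summaries only.

**Value tuning.** Per participant, each normalized measure is binned over
signed value (2 s bins, one bin centered on 0) and summarized by the OLS
slope of z on |value| — negative when the measure is elevated near value 0,
the deliberation signature. Cohort summaries are means with t-based 95% CIs
across participants; cohort bin profiles mask bins with fewer than 10
contributing participants.

## Economic context labels

With values from the LOO thresholds and the immediately preceding trial as
the "previous zone" (the track is unidirectional):

- **regret**: poor current offer after *rejecting* (skip or quit) a good
  offer; **control-1**: poor current offer after *accepting* a good offer;
  **control-2**: poor current offer after rejecting a poor offer; all other
  trials `none`.
- **sequence cells**: previous × current decision (Skip/Skip … Stay/Stay);
  the first trial is undefined. Quits group with skips by default,
  consistent with the 0-coding; a flag instead voids pairs touching a quit.
- **override**: accepting a poor offer or rejecting a good one.

Context contrasts compute participant-level cell means, drop participants
missing either cell, and test with the Wilcoxon signed-rank across
participants (≥ 5 required). Both z-scored and raw metrics can be passed;
the pipeline reports z metrics.

## Sunk-cost analyses

**Conditional completion curves.** Among trials whose delay countdown
started ("invested" is waited time from `t_delay_start`), for each
investment T the curve restricts to trials with waited ≥ T and delay > T
and tabulates completion probability against integer remaining seconds
(delay − T; the generator uses integer delays, real data are rounded).
The slope comes from trial-count-weighted least squares; its 95% CI from a
seeded participant-level bootstrap (2,000 resamples, percentile). Pooled
counts are the default; a flag switches to averaging per-participant
proportions.

*Common-support slopes.* When slopes at different investments are
*compared*, every curve is fit over the same remaining-time support
(≤ 19 s). This matters: the exact hazard-model curves show that with each
curve on its own support, the longer range of small investments dilutes
their slope enough to destroy — even reverse — the expected
|slope|-decreasing-in-investment ordering, because a linear fit to a convex
completion curve is range-dependent. On a common support the ordering is a
clean monotone function of the hazard ahead of each investment. Single-curve
estimates keep the full range.

**Entry-bias choice model.** Entering the offer zone off-center is an
effort investment made before the offer is revealed (crossing the full
hallway takes ~1.25 s, on the order of the median decision latency).
Stay(1)/skip(0) is modeled as logistic in deviation-coded value type
(−0.5 good / +0.5 poor), continuous entry bias (width fraction), optionally
gender (−0.5 male / +0.5 female), their two-way interactions, and a fixed
intercept per participant. Fitting is penalized maximum likelihood: a weak
ridge (0.5) on the participant intercepts only, which leaves the slopes
untouched and keeps intercepts finite for participants with one-sided
choices (separation is detected and warned). The step-halving Newton solver
monitors the penalized log-likelihood.

Slope standard errors default to a delete-one-participant jackknife with a
t(G−1) reference. In simulation the naive Wald and CR1 cluster-sandwich SEs
undercovered a true null coefficient (~93% at nominal 95% over 150
replications) while the jackknife hit the nominal rate; all three are
selectable. The model-predicted acceptance changes at shifted entry points
(poor offers at 25% toward the reward side, good offers at 25% toward the
exit, each versus center entry) are evaluated at the mean participant
intercept.

A caveat established during test design: the binary value-type covariate
only approximates the agent's latent delay valuation, and logistic
regression is non-collapsible — omitted latent variance attenuates the
marginal entry-bias coefficient by roughly 1/√(1 + 0.346 σ²), where σ is
the residual latent-logit SD. The planted-coefficient recovery test
therefore generates choices with gentle noise (temperature 12 s) and uses
ground-truth value labels, where estimand and generative coefficient
coincide to a few percent; under the default sharp agent only the sign is
asserted. On real data the coefficient should be read as the conditional
effect given the binary value type, not a structural constant.

## Delay-discounting scoring

Each questionnaire item (immediate amount vs. larger delayed amount) is an
indifference probe at its implied k = (delayed/immediate − 1)/delay under
hyperbolic discounting V = A/(1 + kD). Candidate rates are the geometric
midpoints of the sorted implied ks plus one geometric step beyond each
extreme; each candidate is scored by the fraction of responses matching
"choose delayed iff implied k > candidate", items numerically at the
candidate counting as consistent with either response. The best candidates'
geometric mean is the reported k; the same scan within magnitude bins gives
per-bin rates, and differences of per-bin log10 k quantify the magnitude
effect. Missing responses drop items (refusing above 30% missing); scoring
is item-order invariant.

The bundled 21-item monetary and 27-item food banks are **synthetic
reconstructions** (their filenames say so): the published amounts live in
the original questionnaire sources, so the shipped banks reproduce the
*structure* — three magnitude bins crossed with geometric implied-k ranks
spanning ~2×10⁻⁴ to ~2.8×10⁻¹ per day — and are plain CSVs meant to be
replaced for scoring real administrations.

## Synthetic agent

The generator is the testing counterpart of the analyses, with one
ground-truth parameter per estimand:

| parameter | default | role |
|---|---|---|
| thresholds θ_c | (9, 14, 19, 24) s | per-category stay/skip threshold, heterogeneous across the 3–29 s offer range |
| choice temperature τ | 1 s | P(stay) = logistic((θ_c − delay)/τ); τ = 0 is an exact step agent |
| response styles | normal ×4 | `reversed` flips the drive sign; `full_stay`/`full_skip` ignore delay deterministically |
| entry_bias_sd | 0.15 width | entry position ~ Normal(0, sd) clipped to [−0.5, 0.5] |
| bias_choice_coef β | 1 | stay log-odds −= β × entry position |
| deliberation gain/width | 1.5 / 3 s | VTE episodes per trial ~ Poisson(gain·exp(−\|value\|/width)), value from the *true* θ |
| base_latency | 2000 ms | forward offer-zone travel; lateral travel adds \|entry − exit\|·1.25 s |
| quit_hazard_base q₀ | 0.0015 /s | per-second quit hazard after delay start, applied in 1 s steps |
| sunk_cost_strength s | 0.5 | hazard h(t) = q₀/(1 + s·t_invested) |

Trajectories are a straight entry→exit pass at constant speed (1.25 s to
cross the full width), sampled at 20 Hz (the logs' rate is unspecified, so
it is a config default), with each VTE episode inserting an out-and-back
heading excursion of 60–120° over 400 ms, optionally followed by a
200–800 ms stationary pause. This reproduces every measured quantity —
latency, distance, rotation, reversals, pause — with controllable ground
truth; it does not attempt kinematic realism (no curvature, no speed
profiles, no heading noise), so passing tests show estimator correctness,
not robustness to messy human logs. Episode magnitudes are free parameters
chosen only to exercise the metrics. The defaults put quits near 0.7%
of started delays and median latency near 2.7 s for center entries,
matching the coarse anatomy of human cohorts on these tasks.

Cohort generation draws participant-level parameters from priors via a
spawned seed sequence, so extending a cohort never perturbs existing
participants, and can apply covariate-linked offsets (e.g. a subgroup with
reduced β) for group-contrast recovery tests.

Version semantics: only measurement availability is emulated (versions 3–4
log first movement and hence reaction time); practice phases, delay-range
escalation and the fixation task of the real task versions are not.

## Problem sizes and calibration of the test suite

Simulation-based checks run at sizes where the planted effects are
identifiable at desk scale: threshold recovery uses 200 agents × 4
categories (noiseless ≥ 99% within 1 s; τ = 1 s bias within ±0.5 s);
deliberation-peak detection 100 cohorts of 50 agents (≥ 90% peak in the
value-0 bin) plus 60 null cohorts for slope-CI calibration. The null
cohorts zero the entry-bias choice coupling as well as the deliberation
gain: with the coupling active, near-threshold choices align with the entry
side and shorten lateral travel, a genuine latency–value dependence that is
not part of the deliberation null.

The memoryless quit calibration runs 100 simulations of 60 participants at
a 2%/s hazard — frequent enough quits for the participant bootstrap to be
calibrated (rare-event cluster resampling is anti-conservative) while the
geometric completion curve stays in its linear regime, the premise for
slope equality across investments — and reads "indistinguishable" as a
difference below the 99% bootstrap interval half-width (equivalence-style
conservatism). The sunk-cost ordering check uses one 279-participant
(~30,000 delay-start) run: an analytic power calculation on the exact
hazard-model curves caps the smallest slope gap near z ≈ 1.2 per 10,000
trials for every hazard configuration, so a strict three-way ordering needs
the larger run to be reliable; the analytic oracle's ordering is asserted
alongside. Entry-bias recovery uses 100 participants and 100 null runs of
40. The full suite runs in a few minutes on one CPU.

## Known limitations

- The paper-scale human analyses replaced here by per-participant summaries
  and penalized logistic/OLS fits (the originals use Bayesian mixed models)
  recover signs and scales, not the published coefficients; real-data
  quantities (correlations among tasks and surveys, printed effect sizes)
  are dataset-specific and out of scope.
- Trajectory synthesis is schematic (see above); metrics are sample-wise and
  rate-agnostic, but no claim is made about behavior under heavy logging
  jitter or dropped samples beyond the 1° jitter threshold.
- The entry-bias coefficient is a conditional estimand (see the
  non-collapsibility caveat).
- Magazine-entry scoring assumes time-sorted, non-overlapping beam breaks;
  overlapping breaks are scored independently.
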