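# Methods

This note documents the models, defaults and design choices behind the
package, and what the test suite does and does not establish.

## Task and design

A session is 32 blocks × 24 trials (768 trials).  Each trial: a coloured
incentive cue (1500 ms) signalling reward (±3 points for correct/error)
or control (0 points); two dot clouds shown until response or 1200 ms,
responses accepted until 3000 ms post-onset; accuracy feedback (1500 ms).
There is **no inter-trial interval** — a deliberate reproduction of the
original paradigm, with the documented consequence that slow pupillary
responses bleed across phase boundaries.

Within every block, 12 reward and 12 control trials are randomized.
Ratios (4:3, 5:4, 8:7, 10:9) cycle within each incentive half of a block,
giving 192 trials per ratio per session; the larger-side assignment
alternates per (incentive, ratio) cell via a session-wide counter, so
sides balance exactly.  Dot pairs are drawn uniformly from the admissible
integer pairs for a ratio within 12–32 dots (e.g. 10:9 admits only
(20, 18) and (30, 27)); the generation is deterministic given a seed.

The 15 bonus levels map 3:1 onto five win options whose thresholds are
percentile ranks {0.05, 35, 85, 95, 99.9} of a reference score
distribution.  How the intermediate levels interpolate is not specified
anywhere, so the package linearly interpolates ranks between successive
option cut points (the top level of option *i* sits exactly at its
rank).  Percentiles use sorted-index lookup (`ceil(p/100·n) − 1`), which
degrades gracefully to tied levels on degenerate distributions.  Negative
point totals floor at zero for level computation — levels are
motivational UI, not analysis input.  Omitted responses score as errors
with missing RT and are excluded from all RT-based summaries.

## Decision model

Behaviour is generated and analysed under the standard two-boundary
drift-diffusion model with drift `v` (evidence units/s), boundary
separation `a`, non-decision time `t_ER` (s) and the conventional
diffusion scaling `s = 0.1`; the start point is unbiased (`a/2`).

**Simulation** is an Euler–Maruyama walk, `dx = v·dt + s·√dt·ξ`, with
`dt = 1 ms` and a 5 s cap (unabsorbed walks are timeouts, treated as
omissions).  Discrete-time crossing detection misses between-step
excursions, which is the classic O(√dt) first-passage bias: at `dt =
1 ms` it inflates mean decision times and recovered boundary separations
by roughly 2–3 % in this task's parameter range.  Tests that compare
simulation against the closed forms use tolerances that cover this known
bias; the parameter-recovery results below include it.

**Estimation** inverts the closed-form EZ equations from `(Pc, MRT,
VRT)`, with `MRT`/`VRT` over correct trials only (unbiased variance) and
the standard edge correction (`Pc ∈ {0, ½, 1}` nudged by `1/(2n)`).  The
forward map uses the algebraically exact inverse, including `VRT = s⁴ L
(L Pc² − L Pc + Pc − ½) / v⁴` with `L = av/s²`, so
`ez_fit(ez_forward(θ)) = θ` holds to machine precision (the suite asserts
≤ 1e−8 over a 160-point grid).  Suitability diagnostics flag
near-ceiling/chance accuracy, non-right-skewed correct-RT distributions,
small post-filter counts and negative recovered non-decision times; they
are advisory only.

**RT filter.**  Analysis keeps 250 ms ≤ RT ≤ 1500 ms (closed interval).
A hard upper cutoff truncates the slow tail, deflating `VRT`/`MRT` and
biasing EZ estimates upward in `v` and `t_ER` for slow regimes: with
children-like parameters (`v≈0.12, a≈0.13, t_ER≈0.38`, ~2.7 % of RTs
above 1.5 s) the windowed fit overestimates `v` by ~12 % at large n,
while adolescent-like regimes are essentially unaffected.  This is a
property of the published analysis pipeline, reproduced rather than
corrected.  At the study's cohort composition (23 children : 30
adolescents) the *median* relative bias over 200 simulated subjects stays
within 5 % for all three parameters, with truth–estimate correlation
r ≈ 0.96 for drift — the acceptance script recomputes this.

## Synthetic cohort

Per-subject generative parameters are drawn around group-level means with
subject-level random intercepts shared across conditions (SDs: v 0.03,
a 0.012, t_ER 0.03 s, pupil amplitude 0.04 mm, tonic 0.35 mm).  The group
means encode the study's qualitative findings — reward raises drift and
lengthens non-decision time in both groups; adolescents have higher
drift and shorter non-decision time; children are more cautious in
control trials but relax the boundary under reward; cue-phase pupil
amplitudes are larger under reward with a wider gap in adolescents;
children blink more.  Magnitudes are the package's own choices (chosen
once, to sit in the realistic range for this task: accuracies 0.83–0.91,
mean RTs ≈ 0.49–0.73 s), because mapping the published effect sizes back
to generative parameters is underdetermined.  An `effect_scale` knob
shrinks all condition contrasts (0 = per-subject null), which calibration
tests use.

**Pupil signal.**  Diameter = tonic + phase-locked kernels + noise.  The
phasic kernel is the gamma-family impulse response `h(t) =
(t/t_p)^k e^{−k(t/t_p − 1)}` with shape `k = 10` and peak latency
`t_p = 900 ms`, normalized to unit peak so an event of amplitude A
produces a maximal dilation of exactly A.  Kernels attach to cue,
stimulus and feedback onsets; feedback onset equals the response time
(the design states no feedback latency).  Both eyes share the signal and
a common noise term (default SD 0.02 mm) plus small independent per-eye
noise (0.008 mm), yielding inter-eye correlations > 0.95.  Blinks are
Poisson-onset missing segments (uniform 80–400 ms durations; children
default 0.30 Hz vs adolescents 0.15 Hz, emulating the higher documented
data loss in children); gaze is a fixation/saccade process concentrated
near screen centre (dispersion ~1°) with occasional eccentric
excursions, and a low rate of unclassifiable ("none") samples.  The
generator records its blink schedule, which the QC oracle tests enumerate
against.  Untruncated kernels are evaluated over an 8 s window, beyond
which the tail is below 1e−25 — numerically exact.  An optional hard
kernel support exists for analytic end-to-end checks (below).

What the generator does **not** emulate: luminance responses (the stimuli
were luminance-matched by design), pupil foreshortening as a continuous
function of gaze angle, saccade kinematics, motion artifacts beyond
missing segments, and any RT–pupil coupling.  Passing tests therefore
establish that the *pipeline* is correct and calibrated, not that it is
robust to every artifact structure of real eye-tracker data.

## Pupillometry pipeline

Defaults (all configurable): maximum interpolatable gap 500 ms, per-trial
missing-fraction limit 25 %, 40 ms guard margins around missing runs
(blink edges are distorted by the closing lid), cubic interpolation
through two valid samples on each flank, centred unweighted 5-point
moving average with shrinking edge windows.  The "excessive blinking"
threshold is not printed in the original report; these values are the
package's documented defaults.  Missing runs touching a trace boundary
stay missing.  Trials keep their native 60 Hz grid; no resampling.

Epochs: cue and feedback are stimulus-locked `[onset, onset+1500 ms)`;
the stimulus phase is response-locked, 1500 ms ending 200 ms after the
press (omissions contribute no stimulus epoch).  Baselines are the mean
of the 200 ms immediately preceding the phase onset (for the
response-locked window, preceding its start, which may overlap the cue
phase — an accepted consequence of the missing inter-trial interval).
Epochs with unfilled samples or invalid baselines are dropped; a
condition average requires ≥ 10 valid epochs, and a subject missing any
condition × phase cell is excluded from pupil (not behavioural)
analyses.  Peaks: cue = max − min of the condition-average curve (the
baseline-corrected cue trace starts near its maximum while the pupil
still recovers from the previous trial); stimulus/feedback = max.

**Fidelity check.**  The noise-free end-to-end test injects one phase's
kernel at a time at 5000 Hz with a 2.5 s hard kernel support and asserts
the recovered peak equals the injected amplitude to ≤ 1e−6 mm.  The high
rate bounds the two discretization errors (sample spacing at the curved
peak and the 5-point average's attenuation, both O(Δt²)) below the
tolerance; the finite support prevents the previous trial's tail
(~1e−5 mm at 3 s) from contaminating the next baseline, which is
unavoidable in the no-ITI paradigm with an infinite-tail kernel.  At the
native 60 Hz the same pipeline is accurate to ~1e−3 mm — negligible
against the ~0.1–0.3 mm effects of interest but not against a 1e−6
tolerance.

Gaze QC: per trial × phase, the percent of fixation/saccade sample time
with radial eccentricity < 5° (half the 10° central area); blink and
unclassifiable samples leave the denominator; trials with no usable gaze
time in a phase are skipped.  Eccentricity is the planar Euclidean angle
from screen centre (small-angle approximation).

## Inference

With one observation per subject × condition and a two-level within
factor, the maximum-likelihood random-intercept model's F tests reduce to
the classical between-within decomposition on per-subject condition means
`m_i` and differences `d_i`: Age Group tests `m̄₁ − m̄₂`, the interaction
tests `d̄₁ − d̄₂`, and the Incentive main effect tests the
subject-weighted grand mean of `d` (the sequential-ANOVA convention of
nlme-style model comparison, which pingouin's mixed ANOVA matches to
machine precision in the cross-check tests).  Every term gets
`F(1, N − 2)` — `F(1, 51)` at the study's 53 subjects.  Effect sizes are
`η_p² = F·df₁/(F·df₁ + df₂)`, which reproduces all seventeen published
(F, df) → η_p² pairs of the study at two decimals.  Satterthwaite-style
dfs are deliberately not the default; the convention above is the one the
published statistics follow.

Posthocs are paired t-tests within subjects and Welch t-tests between
groups, Holm-corrected (step-down, monotonicity enforced, capped at 1;
order-invariant).  When Shapiro–Wilk rejects residual normality, seeded
permutation p-values accompany the parametric ones: within-subject
condition-label swaps (sign flips of `d`) for Incentive, subject-level
group shuffles for Age Group and the interaction; default 5000
permutations, refusing below 100.  `p = (1 + #{F* ≥ F}) / (n_perm + 1)`.

The gaze ANOVA (Incentive × Phase × Age Group) is computed via
orthonormal within-subject contrasts with Greenhouse–Geisser epsilon from
the pooled contrast-score covariance; single-df terms are unaffected
(ε = 1) and the three-level Phase terms get ε-corrected dfs.  The
implementation is validated against R's `car::Anova` (type III,
sum-to-zero contrasts) on a frozen dataset, matching every F and ε.

**Calibration.**  Type-I error is checked under the model's null
generative form (Gaussian random intercepts + condition noise, no fixed
effects): under that null the subject means and differences are
independent normals, so 1000 replicates of a 20-subject cohort with 400
permutations each run in under a second.  Parametric and permutation
rejection rates at α = 0.05 are required to fall in [0.03, 0.07] per
term.  A full-diffusion null at this replicate count would be hours of
compute for the same check of the same statistics; the dv-level null is
the scaled-down design.

## Problem sizes used by the checks

Parameter recovery: 200 subjects × 768 trials (one shared session
layout), ~370–384 kept trials per condition.  Round-trip: 160-point
parameter grid.  Fidelity: 24 trials at 5000 Hz per phase.  Calibration:
1000 × 20 subjects × 400 permutations.  The analysis drivers default to
8 of the 32 blocks so a full cohort simulation with pupillometry stays
around half a minute; `--full` restores the complete session.

## Known limitations

- Effect magnitudes in the generator are plausible choices; only
  directions and orderings are meaningful, and end-to-end "known-effect"
  tests assert direction, never published group means.
- The RT-window truncation bias (above) is inherited from the analysis
  design; drift estimates for slow subjects are accordingly optimistic.
- Phase overlap in the no-ITI paradigm is reproduced, not deconvolved.
- The Euler simulator's O(√dt) bias is accepted at dt = 1 ms and covered
  by test tolerances rather than corrected (no Brownian-bridge crossing).
- The permutation scheme treats subjects as exchangeable within group and
  conditions as exchangeable within subject; it does not cover
  heteroscedastic group differences in the within-subject noise.
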