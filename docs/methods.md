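# Methods

`pupilexplore` implements an analysis chain for restless three-armed bandit
experiments in which baseline pupil size and prefrontal population activity
are measured alongside choices, plus a synthetic-data generator that encodes
the world those analyses are designed to detect. This note documents the
models, the defaults and why they are what they are, the numerical choices,
and what a green test does and does not establish.

## Explore/exploit hidden Markov model

Choices `y_t ∈ {1..N}` are emissions from a latent goal state
`z_t ∈ {explore, exploit_1..exploit_N}`:

- explore emits uniformly: `p(y_t = k | explore) = 1/N`;
- exploit_i emits arm i with probability 1;
- the chain starts in explore;
- explore persists with `p_e`; its leaving mass `(1 − p_e)` is split equally
  over the N exploit states;
- each exploit state persists with `p_x`; its leaving mass goes entirely to
  explore. Direct exploit_i → exploit_j transitions have probability 0:
  with deterministic emissions they are unidentifiable from a switch routed
  through a one-trial explore, and the model has exactly two free
  parameters (`p_e`, `p_x`) by design.

Fitting is expectation–maximization on the forward–backward statistics with
parameter tying across exploit states (the M-step for each persistence is the
ratio of expected stay transitions to expected transitions out of that state
class). Defaults: 20 random restarts with initial persistences drawn uniform
on (0.5, 0.999), convergence when the log-likelihood gain falls below 1e-6,
at most 500 iterations. Estimates that land within 1e-4 of the 0/1 boundary
are flagged `degenerate` (e.g. a constant single-arm session). The decoded
path is the Viterbi maximum a posteriori path; ties prefer staying in the
current state, then the lowest state index, so decoding is deterministic.

An exploration *onset* is an explore trial whose predecessor is exploit;
session-initial explore trials are not onsets. The symmetric
start-of-exploitation flag is provided for the specificity control.

**Identifiability cap on onset recovery.** An onset whose uniform explore
choice happens to repeat the currently exploited arm is emission-identical
to continued exploitation. At the default persistences this alone caps exact
onset recall near 2/3 for any decoder; the recovery tests therefore check
exact recall above 0.5 and ±1-trial recall above 0.8 on identifiable onsets
(those whose choice differs from the exploited arm), rather than a recall
that no algorithm could reach in this world.

## Rescorla–Wagner alternative labeler

`V_{i,t+1} = V_{i,t} + α (r_t − V_{i,t})` for the chosen arm, values
unchanged otherwise; choice probabilities are a softmax with inverse
temperature β. Initial values are 0.5, the prior mean of a Bernoulli
reward. Maximum likelihood by multi-start L-BFGS-B with α ∈ [0, 1] and
β ∈ [0, 50]. A choice is labeled exploratory when its value is strictly
below the maximum value that trial; exact ties count as maximizing. This
labeler equates exploration with errors of reward maximization, and on
generator data its state-label accuracy is below the HMM's — the package
reproduces that ordering as a property test.

The one-trial-back learning index is
`[p(switch_{t+1}|reward_t) − p(switch_{t+1}|no reward_t)] / p(switch_{t+1})`
by direct counting; more reward-driven staying is more negative, and a
`flip_sign` option reports the reversed sign for "larger = more learning"
readings. It is NaN (with a warning) when the subset lacks one of the two
reward outcomes or contains no switches.

## Pupil preprocessing and dynamics

Baseline pupil enters as one level (and optionally one first-to-last change)
value per trial from a short fixation epoch under constant luminance; the
millisecond trace is out of scope. Trials whose level or change lies beyond
6 session SDs of the session mean (computed on raw values) are excluded;
survivors are z-scored within session, so 0 is "baseline". Sessions with
fewer than 10 valid trials are flagged unusable.

Peri-event alignment (±15 trials by default) masks lag positions that cross
a session edge and, when states are supplied, positions whose path back to
the event contains an explore trial (the continuous-exploit-run rule).
The lagged-change analysis takes 25-trial segments containing at most one
explore bout and measures pupil change from the segment's first exploit
trial to each later exploit trial, flagging pairs that span exploration.
Matched-reward controls are found per session by exhaustive search: for each
onset preceded by ≥ k (default 6) exploit trials, every k-trial exploit
window with a bitwise-identical reward vector, not followed by an explore
trial and not overlapping an onset window, is a control; all controls are
kept (no subsampling).

## Wavelet phase and circular statistics

Per-trial pupil phase comes from convolution with a complex Morlet wavelet:
a complex sine at frequency `1/period` (default period 5 trials) under a
Gaussian envelope with `σ = cycles/(2π·frequency)` (default 5 cycles). The
envelope is truncated at ±5σ: the conventional ±3σ truncation leaks enough
of the negative-frequency component to bias phases by ~1e-4 rad on a pure
tone, and 5σ brings that below 1e-6. No padding is used; trials within half
the wavelet support of a session boundary are masked — padding would invent
data on a nonstationary signal.

**Phase convention (fixed, load-bearing):** phase 0 at the local
oscillation peak, phase increasing over trials, so the *rising* phase of the
oscillation is the angle interval (−π, 0). The angular reference of
published mean phases is not recoverable from their text, so no numeric mean
angle is compared against; only concentration statistics are.

Phase concentration is the resultant length `R = |mean unit vector|`,
tested with the Hodges–Ajne omnibus statistic (exact combinatorial formula
`p = (n − 2m) C(n, m) 2^(1−n)` for n ≤ 50, the standard large-sample
approximation otherwise) and against a bootstrap null. The primary null
draws n phases uniformly on the circle per bootstrap sample (1000 samples);
its mean R reproduces the closed form `√(π/4n)` and, at n = 1135, the
published null level 0.026 with 95% upper bound ≈ 0.057. A resample-observed
("shuffle") null is available as an option. Two-sample comparisons use
Watson's U² (rank form) with a permutation p-value. No circular-statistics
package is available in the target environment, so these are implemented
here and each is pinned to an independent oracle in the tests.

Quantile–response curves bin pupil within session (default 10 quantiles;
the bin count is not fixed by any published value) and fit linear and
quadratic identity-link GLMs with session dummies to the bin means,
compared by AIC weights.

## Population analyses

Counts are mean-imputed per unit over held trials; units with mean rate
below 2 spikes/s are excluded (their hyperplane weights are poorly
identified). The choice subspace is a multinomial softmax classifier with
the sum-to-zero constraint built into the parameterization: two weight
vectors are optimized (L-BFGS with analytic gradients) and the third is
exactly the negative of their sum, so the three decision-function
coefficient vectors sum to the zero vector by construction rather than by
penalty. A small ridge (default 1e-3) stabilizes near-separable sessions.
A published version of the decoder formula has `1 − exp(−βX)` in the
denominator; that is treated as a typographical slip for the standard
logistic `1 + exp(−βX)`, which is what a softmax reduces to. Fitting is
in-sample per session by default; cross-validated decoding exists as an
option but is off to match the source procedure.

Within the 2-d subspace coordinates (projections onto the two fitted weight
vectors; intercepts do not affect distances):

- decoded choice probability = the softmax probability assigned to the arm
  actually chosen; accuracy = argmax agreement;
- scatter index = per-trial mean Euclidean distance to same-choice trials
  divided by mean distance to different-choice trials (1 = no clustering
  difference; trials in singleton classes are masked);
- neural speed = mean Euclidean displacement between consecutive time-bin
  projections (default 20 ms bins over 0–400 ms, i.e. 19 steps) divided by
  the bin width, in subspace units per second.

Epochs are explicit config: subspace training nominally uses the
target-to-saccade epoch and the trial-level statistics the 200 ms pre-target
window; both are plain arguments because the source procedures use
different windows in different analyses.

Single-unit tuning is `rate ~ C(choice) * pupil` per unit by OLS with
type-II F-tests at α = 0.05, reporting the counts of choice-tuned,
pupil-modulated, and interaction units; zero-variance units are flagged and
never significant.

## Shared statistics

GLMs are identity-link with normal errors (OLS), session as a k−1
dummy-coded factor. Binary outcomes (explore/onset flags) are linear
probability models under the same identity link — deliberately, to match
the source analysis — not logistic fits. AIC is `2k − 2logL` counting the
intercept and the error variance in k; the variance term cancels in every
comparison. Akaike weights are `exp(−Δ_i/2)` normalized.

Mediation is the three-regression structural model: total effect c,
mediator path a, and joint model giving b and the direct effect c′, all
with session dummies (on by default; the source is silent on this, so a
flag disables them) and with x and the mediator z-scored within session.
The indirect effect ab carries the Sobel delta-method standard error
`√(b²SE_a² + a²SE_b²)` and a two-sided normal p. For linear fits on a
common sample `c = c′ + ab` holds exactly and is asserted at 1e-8.

Paired comparisons report t, df = n−1, two-sided p, Cohen's d for paired
designs (`mean(diff)/SD(diff)`, which equals `t/√n`), and a 95% CI.
Discrimination is rank-based AUC with midrank ties. Multiple comparisons
use Holm–Bonferroni (statsmodels' step-down implementation behind a thin
wrapper).

## The synthetic world

The generator's defaults are the stated task conditions: 3 arms, 10% step
chance per arm per trial, ±0.1 steps bounded at [0.1, 0.9] (a step that
would exit the bounds is cancelled; walks update every trial because
synthetic sessions have no incorrect trials), 778 trials/session so that 28
sessions give the ~21,793-trial benchmark corpus, 3 s trials. The agent
uses `p_stay_explore = 0.7`, `p_stay_exploit = 0.95` (the recovery targets
used throughout the tests) and exploits the arm with the highest running
Rescorla–Wagner value (learning rate 0.3) — the labeling model is agnostic
about this, but some value guidance is needed for realistic switch
statistics.

The pupil is an exact sum of: a ramp (0.004 z/trial, the published
across-trial slope), a quasi-periodic oscillation (amplitude 0.3 z, period
5 trials, phase drifting as a Gaussian random walk of 0.1 rad/trial with a
random starting angle), omission transients (+0.2 z after unrewarded
trials), onset resets (0.5 z subtracted starting the trial *after* each
onset, decaying linearly over 5 trials), and Gaussian noise (0.3 z). Two of
these choices are worth flagging:

- *Reset timing.* A literal reading would start the reset on the onset
  trial itself, but the measured direction is that pupil grows into the
  onset and shrinks only once exploration has begun; starting the reset on
  the onset trial would invert the onset–pupil relation the analyses exist
  to detect, so the reset begins one trial after the onset.
- *Phase drift.* A drift-free oscillation with an integer period puts every
  event phase on a 5-point lattice, which an omnibus circular test
  correctly rejects as non-uniform even with no entrainment — a degenerate
  artifact of trial-locked periodicity that real quasi-periodic arousal
  rhythms (and variable trial durations) do not produce. The drift restores
  a continuous phase distribution; amplitude and noise defaults are chosen
  once as plausible z-scale values and not revisited.

When `phase_gate` is on, exploit → explore transitions are admitted only on
the oscillation's rising phase (the gate is derived from the same phase
path that builds the oscillation, so states and pupil are jointly
resampled). Poisson units have round-robin preferred arms, 5 spikes/s base
rate, 8 spikes/s tuning gain, and a tuning gain factor
`max(0, 1 − 0.25·pupil_z)`, so tuning flattens as pupil grows.

All randomness flows from named streams (environment, agent, pupil,
neurons) spawned from one seed; identical seeds give byte-identical fixture
files.

**What green tests establish.** The generator emulates trial-level
structure only: no millisecond pupil samples, no eye traces, no spike
waveforms, no luminance or blink physics, no inter-subject heterogeneity,
and reward-independent state transitions (so there is no true pupil→onset
coupling unless the gate is on). A green recovery test shows the estimators
are correct and well-calibrated in this stated world, not that the
empirical effect sizes of any particular dataset will reproduce.

## Known limitations

- The EM surface for the two-persistence HMM is benign in practice, but
  boundary-degenerate sessions (constant-arm) return a flagged estimate
  rather than an error.
- Exact onset recall is information-limited (see above); consumers should
  treat onset labels near bout boundaries as ±1 trial.
- The exploit-heavy agent produces high reward rates, so 6-trial reward
  histories collide by chance more often than balanced Bernoulli(0.5)
  rewards would; matched-control *counts* are therefore generous in the
  synthetic world relative to real data.
- Watson U² uses a permutation p-value (seeded), not the asymptotic table;
  with very large samples this is the slow path of the battery.
- The mediation model is linear (identity link) end to end, matching the
  source; a logistic outcome model is out of scope.
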