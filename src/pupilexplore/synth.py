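"""Synthetic restless-bandit sessions with known ground truth.

Every downstream analysis in this package has a recovery test against the
generator in this module.  The stated world is a restless three-armed bandit
(per-arm reward probabilities random-walk on a 0.1 grid inside [0.1, 0.9],
10% step chance per arm per trial), a two-parameter latent explore/exploit
Markov agent, a trial-level baseline pupil built from interpretable additive
components (across-trial ramp, a ~5-trial oscillation, reward-omission
transients, a post-onset reset, Gaussian noise), and Poisson units whose
choice tuning flattens as pupil size grows.

Randomness is organised as named seed streams (environment, agent, pupil,
neurons) so each component can be re-randomized independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

EXPLORE = 0  # latent-state code shared with :mod:`pupilexplore.behavior`


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class BanditConfig:
    """Restless bandit environment.

    Each arm's reward probability performs an independent random walk: with
    probability ``p_change`` per trial it moves by ``±step``; a move that
    would exit ``bounds`` is cancelled (the value stays put).
    """

    n_arms: int = 3
    p_change: float = 0.1
    step: float = 0.1
    bounds: tuple[float, float] = (0.1, 0.9)
    n_trials: int = 778
    trial_duration_s: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_arms < 2:
            raise ValueError("n_arms must be >= 2")
        if not 0.0 <= self.p_change <= 1.0:
            raise ValueError("p_change must be in [0, 1]")
        if self.step <= 0:
            raise ValueError("step must be positive")
        lo, hi = self.bounds
        if lo >= hi:
            raise ValueError("bounds must satisfy lo < hi")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be positive")


@dataclass
class AgentConfig:
    """Latent explore/exploit Markov agent.

    The latent chain starts in explore.  Explore persists with
    ``p_stay_explore`` and emits a uniform choice; exploit persists with
    ``p_stay_exploit`` and deterministically repeats its arm.  On entering
    exploit, the exploited arm is the one with the highest running
    Rescorla–Wagner value estimate (``value_learning_rate``).
    """

    p_stay_explore: float = 0.7
    p_stay_exploit: float = 0.95
    value_learning_rate: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_stay_explore", "p_stay_exploit", "value_learning_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PupilGenConfig:
    """Trial-level baseline pupil, in session z-units.

    Components are strictly additive: ramp + oscillation + omission
    transients + onset resets + Gaussian noise.  With all gains and the
    noise at zero, the output is identically zero.

    The oscillation is quasi-periodic: its phase advances by ``2*pi/period``
    per trial plus a Gaussian random-walk increment (``phase_drift_sd``) and
    starts at a random angle, emulating a Mayer-wave-like rhythm that is not
    coherent over a whole session and is not locked to trial boundaries
    (trial durations vary in the real task).  With zero drift the phase is
    exactly periodic in trials, which puts event phases on an n-point
    lattice — a degenerate world no circular test should be run against.
    """

    ramp_per_trial: float = 0.004
    osc_amplitude: float = 0.3
    osc_period_trials: float = 5.0
    phase_drift_sd: float = 0.1
    random_init_phase: bool = True
    omission_gain: float = 0.2
    onset_reset: float = 0.5
    reset_decay_trials: int = 5
    noise_sd: float = 0.3
    phase_gate: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.osc_period_trials <= 0:
            raise ValueError("osc_period_trials must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.phase_drift_sd < 0:
            raise ValueError("phase_drift_sd must be nonnegative")
        if self.reset_decay_trials < 1:
            raise ValueError("reset_decay_trials must be >= 1")


@dataclass
class NeuralGenConfig:
    """Poisson units with arm tuning that flattens with pupil size.

    Expected rate of unit *u* on trial *t* is::

        base_rate + tuning_gain * 1[choice_t = preferred_u]
                  * max(0, 1 - flattening_per_z * pupil_z_t)

    Counts are Poisson with mean ``rate * bin_s``.
    """

    n_units: int = 24
    base_rate: float = 5.0
    tuning_gain: float = 8.0
    flattening_per_z: float = 0.25
    bin_s: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_units < 3:
            raise ValueError("n_units must be >= 3")
        if self.base_rate < 0 or self.tuning_gain < 0:
            raise ValueError("rates must be nonnegative")
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def simulate_reward_walk(config: BanditConfig, rng=None) -> np.ndarray:
    """Simulate per-arm reward-probability random walks.

    Returns an ``(n_trials, n_arms)`` array.  Initial probabilities are drawn
    uniformly from the step grid ``{lo, lo+step, ..., hi}``.  A step that
    would exit the bounds is cancelled, so values stay on the grid.
    """
    rng = _rng(config.seed if rng is None else rng)
    lo, hi = config.bounds
    n_grid = int(round((hi - lo) / config.step)) + 1
    grid = lo + config.step * np.arange(n_grid)
    p = rng.choice(grid, size=config.n_arms)
    walk = np.empty((config.n_trials, config.n_arms))
    walk[0] = p
    for t in range(1, config.n_trials):
        changes = rng.random(config.n_arms) < config.p_change
        steps = np.where(rng.random(config.n_arms) < 0.5, config.step, -config.step)
        proposed = p + np.where(changes, steps, 0.0)
        # cancel steps that would exit the bounds
        ok = (proposed >= lo - 1e-12) & (proposed <= hi + 1e-12)
        p = np.where(ok, proposed, p)
        walk[t] = p
    return walk


def walk_stationary_distribution(config: BanditConfig) -> np.ndarray:
    """Exact stationary distribution of a single arm's walk on its grid.

    Used as an analytic oracle: with cancelled boundary steps the chain is a
    lazy symmetric walk whose stationary distribution is uniform over the
    grid.  Computed here from the explicit transition matrix rather than
    asserted.
    """
    lo, hi = config.bounds
    n = int(round((hi - lo) / config.step)) + 1
    q = config.p_change / 2.0
    T = np.zeros((n, n))
    for i in range(n):
        up = i + 1 if i + 1 < n else i
        dn = i - 1 if i - 1 >= 0 else i
        T[i, up] += q
        T[i, dn] += q
        T[i, i] += 1.0 - 2 * q
    vals, vecs = np.linalg.eig(T.T)
    k = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, k])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# agent
# ---------------------------------------------------------------------------

@dataclass
class AgentResult:
    """Ground-truth behavioral record from :func:`simulate_agent`."""

    states: np.ndarray   # 0 = explore, i+1 = exploit arm i
    choices: np.ndarray
    rewards: np.ndarray
    values: np.ndarray   # (n_trials, n_arms) running value estimates


def simulate_agent(
    walk: np.ndarray,
    config: AgentConfig,
    rng=None,
    explore_gate: np.ndarray | None = None,
) -> AgentResult:
    """Simulate the latent explore/exploit agent on a reward walk.

    ``explore_gate``, when given, is a per-trial boolean mask: exploit ->
    explore transitions are suppressed on trials where the gate is False
    (used by :func:`generate_session` to entrain exploration onsets to the
    pupil oscillation's rising phase).
    """
    walk = np.asarray(walk, dtype=float)
    if walk.ndim != 2 or walk.size == 0:
        raise ValueError("walk must be a nonempty (n_trials, n_arms) array")
    n_trials, n_arms = walk.shape
    rng = _rng(config.seed if rng is None else rng)
    if explore_gate is not None and len(explore_gate) != n_trials:
        raise ValueError("explore_gate length must match walk")

    states = np.empty(n_trials, dtype=np.int64)
    choices = np.empty(n_trials, dtype=np.int64)
    rewards = np.empty(n_trials, dtype=np.int64)
    values = np.empty((n_trials, n_arms))
    v = np.full(n_arms, 0.5)
    state = EXPLORE
    for t in range(n_trials):
        values[t] = v
        states[t] = state
        if state == EXPLORE:
            c = int(rng.integers(n_arms))
        else:
            c = state - 1
        choices[t] = c
        r = int(rng.random() < walk[t, c])
        rewards[t] = r
        v[c] += config.value_learning_rate * (r - v[c])
        # transition to the next trial's state
        if state == EXPLORE:
            if rng.random() >= config.p_stay_explore:
                state = 1 + int(np.argmax(v))
        else:
            if rng.random() >= config.p_stay_exploit:
                if explore_gate is None or (t + 1 < n_trials and explore_gate[t + 1]):
                    state = EXPLORE
    return AgentResult(states=states, choices=choices, rewards=rewards, values=values)


# ---------------------------------------------------------------------------
# pupil
# ---------------------------------------------------------------------------

@dataclass
class PupilComponents:
    """Additive breakdown of the generated pupil series (conservation: the
    emitted series equals the sum of components exactly)."""

    total: np.ndarray
    ramp: np.ndarray
    oscillation: np.ndarray
    omission: np.ndarray
    reset: np.ndarray
    noise: np.ndarray


def wrap_angle(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    ph = np.asarray(phi) % (2 * np.pi)
    return np.where(ph > np.pi, ph - 2 * np.pi, ph)


def oscillation_phase_trajectory(
    n_trials: int, config: PupilGenConfig, rng=None
) -> np.ndarray:
    """Ground-truth phase path of the generator's oscillation (unwrapped).

    Phase 0 is the oscillation peak; phase increases by ``2*pi/period`` per
    trial plus a random-walk drift, so the rising phase is where the wrapped
    angle lies in (-pi, 0).
    """
    rng = _rng(rng)
    phi0 = rng.uniform(0.0, 2 * np.pi) if config.random_init_phase else 0.0
    drift = (
        np.cumsum(rng.normal(0.0, config.phase_drift_sd, n_trials))
        if config.phase_drift_sd > 0
        else np.zeros(n_trials)
    )
    return phi0 + 2 * np.pi * np.arange(n_trials) / config.osc_period_trials + drift


def _onset_indices(states: np.ndarray) -> np.ndarray:
    states = np.asarray(states)
    prev = states[:-1]
    cur = states[1:]
    on = np.flatnonzero((cur == EXPLORE) & (prev != EXPLORE)) + 1
    return on


def simulate_pupil(
    states: np.ndarray,
    rewards: np.ndarray,
    config: PupilGenConfig,
    rng=None,
    osc_phase: np.ndarray | None = None,
) -> PupilComponents:
    """Generate trial-level baseline pupil from latent states and rewards.

    output = ramp + oscillation + omission transients + onset resets + noise.
    Each exploration onset triggers a reset: ``onset_reset`` is subtracted
    beginning on the trial after the onset, decaying linearly to zero over
    ``reset_decay_trials`` trials.  The onset trial itself is untouched —
    pupil grows into the onset and shrinks only once exploration has begun,
    which is what makes the onset the best-predicted event.
    ``osc_phase`` (unwrapped radians per trial) injects a precomputed
    oscillation phase path — used by :func:`generate_session` so the same
    path can gate the agent's transitions; when omitted, a path is drawn
    here (phase draws precede the noise draws on the stream).
    """
    states = np.asarray(states)
    rewards = np.asarray(rewards)
    if len(states) != len(rewards):
        raise ValueError("states and rewards must have equal length")
    n = len(states)
    rng = _rng(config.seed if rng is None else rng)

    t = np.arange(n)
    ramp = config.ramp_per_trial * t
    if osc_phase is None:
        osc_phase = oscillation_phase_trajectory(n, config, rng)
    osc = config.osc_amplitude * np.cos(osc_phase)
    omission = np.zeros(n)
    if n > 1:
        omission[1:] = config.omission_gain * (rewards[:-1] == 0)
    reset = np.zeros(n)
    h = config.reset_decay_trials
    for onset in _onset_indices(states):
        j = np.arange(onset + 1, min(onset + 1 + h, n))
        reset[j] -= config.onset_reset * (1.0 - (j - onset - 1) / h)
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
    total = ramp + osc + omission + reset + noise
    return PupilComponents(
        total=total, ramp=ramp, oscillation=osc, omission=omission, reset=reset, noise=noise
    )


def inject_pupil_artifacts(
    values: np.ndarray, fraction: float = 0.008, magnitude_sd: float = 20.0, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Inject blink-like outliers into a pupil series.

    A ``fraction`` of trials is replaced by values ``magnitude_sd`` raw
    standard deviations from the mean (random sign).  Returns the corrupted
    copy and the injected indices.
    """
    rng = _rng(rng)
    values = np.asarray(values, dtype=float).copy()
    n = len(values)
    k = int(round(fraction * n))
    idx = rng.choice(n, size=k, replace=False)
    sd = values.std()
    sign = np.where(rng.random(k) < 0.5, 1.0, -1.0)
    values[idx] = values.mean() + sign * magnitude_sd * max(sd, 1e-12)
    return values, np.sort(idx)


# ---------------------------------------------------------------------------
# neurons
# ---------------------------------------------------------------------------

def preferred_arms(n_units: int, n_arms: int = 3) -> np.ndarray:
    """Round-robin assignment of preferred arms to units."""
    return np.arange(n_units) % n_arms


def expected_rates(
    choices: np.ndarray, pupil_z: np.ndarray, config: NeuralGenConfig, n_arms: int = 3
) -> np.ndarray:
    """Expected firing rate (spikes/s) for each trial x unit, after
    flattening and clipping at zero."""
    choices = np.asarray(choices)
    pupil_z = np.asarray(pupil_z, dtype=float)
    pref = preferred_arms(config.n_units, n_arms)
    tuned = (choices[:, None] == pref[None, :]).astype(float)
    factor = np.maximum(0.0, 1.0 - config.flattening_per_z * pupil_z)[:, None]
    rates = config.base_rate + config.tuning_gain * tuned * factor
    n_clipped = int(np.sum(rates < 0))
    if n_clipped:
        logger.info("clipped %d negative expected rates at 0", n_clipped)
    return np.maximum(rates, 0.0)


def simulate_population(
    choices: np.ndarray,
    pupil_z: np.ndarray,
    config: NeuralGenConfig,
    rng=None,
    n_arms: int = 3,
    n_bins: int = 1,
) -> np.ndarray:
    """Simulate Poisson spike counts.

    Returns ``(n_trials, n_units)`` counts over a single ``bin_s`` window, or
    ``(n_trials, n_units, n_bins)`` when ``n_bins > 1`` (each bin of width
    ``bin_s``, e.g. 20 ms bins for the neural-speed epoch).
    """
    if len(choices) != len(pupil_z):
        raise ValueError("choices and pupil_z must have equal length")
    rng = _rng(config.seed if rng is None else rng)
    rates = expected_rates(choices, pupil_z, config, n_arms)
    lam = rates * config.bin_s
    if n_bins == 1:
        return rng.poisson(lam)
    return rng.poisson(lam[:, :, None], size=(*lam.shape, n_bins))


# ---------------------------------------------------------------------------
# full sessions
# ---------------------------------------------------------------------------

@dataclass
class SessionData:
    """One synthetic session: trial table, population counts, ground truth."""

    trials: pd.DataFrame
    counts: np.ndarray                 # (n_trials, n_units), pre-target epoch
    binned_counts: np.ndarray          # (n_trials, n_units, n_bins), post-target
    unit_meta: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)
    configs: dict = field(default_factory=dict)
    session_id: int = 0


def generate_session(
    bandit: BanditConfig | None = None,
    agent: AgentConfig | None = None,
    pupil: PupilGenConfig | None = None,
    neural: NeuralGenConfig | None = None,
    seed: int | None = None,
    session_id: int = 0,
    out_dir: str | Path | None = None,
    speed_bins: int = 20,
    speed_bin_s: float = 0.02,
) -> SessionData:
    """Generate a full synthetic session; optionally write fixture files.

    Randomness flows from four named streams (environment, agent, pupil,
    neurons) spawned from ``seed``; identical seeds give byte-identical
    fixture files.  When ``pupil.phase_gate`` is set, exploit -> explore
    transitions are only admitted on the rising phase of the pupil
    oscillation, so exploration onsets entrain to it.
    """
    bandit = bandit or BanditConfig()
    agent = agent or AgentConfig()
    pupil = pupil or PupilGenConfig()
    neural = neural or NeuralGenConfig()

    ss = np.random.SeedSequence(seed)
    env_rng, agent_rng, pupil_rng, neuron_rng, aux_rng = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    walk = simulate_reward_walk(bandit, rng=env_rng)
    osc_phase = oscillation_phase_trajectory(bandit.n_trials, pupil, pupil_rng)
    gate = None
    if pupil.phase_gate:
        gate = wrap_angle(osc_phase) < 0.0  # rising phase of the oscillation
    beh = simulate_agent(walk, agent, rng=agent_rng, explore_gate=gate)
    comp = simulate_pupil(beh.states, beh.rewards, pupil, rng=pupil_rng, osc_phase=osc_phase)

    counts = simulate_population(beh.choices, comp.total, neural, rng=neuron_rng)
    binned_cfg = dataclasses.replace(neural, bin_s=speed_bin_s)
    binned = simulate_population(
        beh.choices, comp.total, binned_cfg, rng=neuron_rng, n_bins=speed_bins
    )

    onsets = np.zeros(bandit.n_trials, dtype=bool)
    onsets[_onset_indices(beh.states)] = True
    is_explore = beh.states == EXPLORE
    # response time slows and saccade velocity changes mildly with arousal /
    # state, echoing the behavioral phenomenology the analyses probe
    rt = 0.25 + 0.03 * comp.total + aux_rng.normal(0, 0.05, bandit.n_trials)
    rt = np.maximum(rt, 0.05)
    vel = 450.0 + 15.0 * is_explore + aux_rng.normal(0, 30.0, bandit.n_trials)

    trials = pd.DataFrame(
        {
            "session": session_id,
            "trial": np.arange(bandit.n_trials),
            "choice": beh.choices,
            "reward": beh.rewards,
            "pupil_z": comp.total,
            "rt": rt,
            "sacc_vel": vel,
            "true_state": beh.states,
            "true_onset": onsets.astype(int),
        }
    )
    pref = preferred_arms(neural.n_units, bandit.n_arms)
    unit_meta = pd.DataFrame(
        {
            "unit": np.arange(neural.n_units),
            "preferred_arm": pref,
            "mean_rate": counts.mean(axis=0) / neural.bin_s,
        }
    )
    data = SessionData(
        trials=trials,
        counts=counts,
        binned_counts=binned,
        unit_meta=unit_meta,
        ground_truth={
            "walk": walk,
            "states": beh.states,
            "onsets": onsets,
            "values": beh.values,
            "pupil_components": comp,
            "osc_phase": osc_phase,
        },
        configs={"bandit": bandit, "agent": agent, "pupil": pupil, "neural": neural},
        session_id=session_id,
    )
    if out_dir is not None:
        write_session(data, out_dir, seed=seed)
    return data


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_session(data: SessionData, out_dir: str | Path, seed: int | None = None) -> dict:
    """Write a session's fixture files (CSV + YAML + JSON manifest)."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        tag = f"session{data.session_id:03d}"
        trials_path = out / f"{tag}_trials.csv"
        counts_path = out / f"{tag}_counts.csv"
        units_path = out / f"{tag}_units.csv"
        cfg_path = out / f"{tag}_config.yaml"
        data.trials.to_csv(trials_path, index=False, float_format="%.10g")
        pd.DataFrame(data.counts).to_csv(counts_path, index=False, float_format="%.10g")
        data.unit_meta.to_csv(units_path, index=False, float_format="%.10g")
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(
                {k: dataclasses.asdict(v) for k, v in data.configs.items()},
                fh, sort_keys=True,
            )
        manifest = {
            "session_id": data.session_id,
            "seed": seed,
            "files": {
                p.name: _sha256(p)
                for p in (trials_path, counts_path, units_path, cfg_path)
            },
        }
        with open(out / f"{tag}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except OSError as exc:
        raise OSError(f"failed writing session fixtures under {out}: {exc}") from exc
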