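"""Explore/exploit labeling of bandit choices.

Two labelers are provided:

1. A two-parameter hidden Markov model in which choices are emissions from a
   latent goal state.  The explore state emits choices uniformly over the
   ``N`` arms; each exploit state deterministically repeats its arm.  The
   chain starts in explore, explore persists with ``p_stay_explore``,
   exploit persists with ``p_stay_exploit``; leaving exploit always passes
   through explore (direct exploit->exploit transitions are unidentifiable
   from a one-trial explore switch under deterministic emissions, so they
   get probability 0), and leaving explore distributes equally over the
   exploit states.  Fit by expectation-maximization with random restarts;
   the maximum a posteriori path is recovered with the Viterbi algorithm.

2. A Rescorla-Wagner softmax model; choices that do not maximize the fitted
   subjective values are labeled exploratory.

Also provides onset/bout segmentation and a one-trial-back learning index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize

EXPLORE = 0  # latent-state code: 0 = explore, i + 1 = exploit arm i


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExploreHMMParams:
    """The two free parameters of the explore/exploit HMM."""

    p_stay_explore: float
    p_stay_exploit: float
    n_arms: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_stay_explore <= 1.0:
            raise ValueError("p_stay_explore must be in [0, 1]")
        if not 0.0 <= self.p_stay_exploit <= 1.0:
            raise ValueError("p_stay_exploit must be in [0, 1]")
        if self.n_arms < 2:
            raise ValueError("n_arms must be >= 2")

    def transition_matrix(self) -> np.ndarray:
        """(N+1) x (N+1) row-stochastic transition matrix; state 0 = explore."""
        n = self.n_arms
        A = np.zeros((n + 1, n + 1))
        A[0, 0] = self.p_stay_explore
        A[0, 1:] = (1.0 - self.p_stay_explore) / n
        for i in range(1, n + 1):
            A[i, i] = self.p_stay_exploit
            A[i, 0] = 1.0 - self.p_stay_exploit
        return A

    def emission_matrix(self) -> np.ndarray:
        """(N+1) x N emission matrix: uniform explore row, indicator exploit rows."""
        n = self.n_arms
        B = np.zeros((n + 1, n))
        B[0] = 1.0 / n
        for i in range(1, n + 1):
            B[i, i - 1] = 1.0
        return B


@dataclass
class StateSequence:
    """A decoded latent path with onset flags."""

    states: np.ndarray           # per-trial code in {0, 1..N}
    onset: np.ndarray            # first explore trial after >=1 exploit
    log_likelihood: float        # log joint probability of the decoded path


@dataclass
class ExploreHMMFit:
    params: ExploreHMMParams
    log_likelihood: float
    n_iter: int
    converged: bool
    degenerate: bool             # parameter pinned at a 0/1 boundary
    restart_log_likelihoods: np.ndarray


@dataclass
class RescorlaWagnerFit:
    """Maximum-likelihood Rescorla-Wagner softmax fit."""

    alpha: float
    beta: float
    values: np.ndarray           # (n_trials, n_arms) pre-decision values
    log_likelihood: float


@dataclass
class OnsetSegmentation:
    onset: np.ndarray            # explore trial whose predecessor is exploit
    exploit_start: np.ndarray    # exploit trial whose predecessor is explore
    bouts: list = field(default_factory=list)  # (start, stop_exclusive, label)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_pass(choices, n_arms, pe, px):
    """Scaled forward recursion. Returns (alpha_hat, scale, bad_t)."""
    T = choices.shape[0]
    K = n_arms + 1
    alpha = np.zeros((T, K))
    c = np.zeros(T)
    alpha[0, 0] = 1.0 / n_arms        # must start in explore
    c[0] = alpha[0, 0]
    alpha[0, 0] = 1.0
    for t in range(1, T):
        o = choices[t]
        # explore target
        s = alpha[t - 1, 0] * pe
        for i in range(1, K):
            s += alpha[t - 1, i] * (1.0 - px)
        alpha[t, 0] = s / n_arms
        # exploit targets (only the one matching the emission survives)
        j = o + 1
        alpha[t, j] = alpha[t - 1, 0] * (1.0 - pe) / n_arms + alpha[t - 1, j] * px
        ct = 0.0
        for k in range(K):
            ct += alpha[t, k]
        if ct <= 0.0:
            return alpha, c, t
        c[t] = ct
        for k in range(K):
            alpha[t, k] /= ct
    return alpha, c, -1


@njit(cache=True)
def _em_counts(choices, n_arms, pe, px):
    """One E-step: returns (loglik, num_e, den_e, num_x, den_x, bad_t)."""
    T = choices.shape[0]
    K = n_arms + 1
    alpha, c, bad = _forward_pass(choices, n_arms, pe, px)
    if bad >= 0:
        return -np.inf, 0.0, 0.0, 0.0, 0.0, bad
    ll = 0.0
    for t in range(T):
        ll += np.log(c[t])
    beta = np.zeros((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        o = choices[t + 1]
        be = beta[t + 1, 0] / n_arms          # explore emission folded in
        bj = beta[t + 1, o + 1]               # matching exploit state
        # from explore
        beta[t, 0] = pe * be + (1.0 - pe) / n_arms * bj
        # from exploit i
        for i in range(1, K):
            v = (1.0 - px) * be
            if i == o + 1:
                v += px * bj
            beta[t, i] = v
        for k in range(K):
            beta[t, k] /= c[t + 1]
    num_e = 0.0
    den_e = 0.0
    num_x = 0.0
    den_x = 0.0
    for t in range(T - 1):
        o = choices[t + 1]
        # normalizer for xi at t (equals 1 with consistent scaling; keep exact)
        z = 0.0
        g = np.zeros(K)
        for i in range(K):
            g[i] = alpha[t, i] * beta[t, i]
            z += g[i]
        # xi_t(i, j) = alpha_hat_t(i) A_ij B_j(o_{t+1}) beta_hat_{t+1}(j) / c_{t+1};
        # z (== 1 under exact scaling) guards against drift
        be = beta[t + 1, 0] / (n_arms * c[t + 1])
        bj = beta[t + 1, o + 1] / c[t + 1]
        num_e += alpha[t, 0] * pe * be / z
        den_e += g[0] / z
        for i in range(1, K):
            if i == o + 1:
                num_x += alpha[t, i] * px * bj / z
            den_x += g[i] / z
    return ll, num_e, den_e, num_x, den_x, -1


@njit(cache=True)
def _viterbi(choices, n_arms, pe, px):
    """MAP path with deterministic tie-breaks (prefer staying, then lowest
    state index). Returns (path, log_joint, bad_t)."""
    T = choices.shape[0]
    K = n_arms + 1
    NEG = -1.0e300
    delta = np.full((T, K), NEG)
    psi = np.zeros((T, K), dtype=np.int64)
    log_pe = np.log(pe) if pe > 0 else NEG
    log_lpe = np.log((1.0 - pe) / n_arms) if pe < 1 else NEG
    log_px = np.log(px) if px > 0 else NEG
    log_lpx = np.log(1.0 - px) if px < 1 else NEG
    log_unif = np.log(1.0 / n_arms)

    delta[0, 0] = log_unif          # start in explore; emits any arm
    path = np.zeros(T, dtype=np.int64)
    for t in range(1, T):
        o = choices[t]
        for j in range(K):
            if j != 0 and j != o + 1:
                continue            # zero emission probability
            best = NEG
            best_i = -1
            for i in range(K):
                if delta[t - 1, i] <= NEG:
                    continue
                if j == 0:
                    la = log_pe if i == 0 else log_lpx
                else:
                    if i == 0:
                        la = log_lpe
                    elif i == j:
                        la = log_px
                    else:
                        continue    # exploit -> different exploit forbidden
                if la <= NEG:
                    continue
                v = delta[t - 1, i] + la
                if v > best:
                    best = v
                    best_i = i
                elif v == best and i == j and best_i != j:
                    best_i = i      # tie: prefer staying in the current state
            if best_i >= 0:
                emit = log_unif if j == 0 else 0.0
                delta[t, j] = best + emit
                psi[t, j] = best_i
        ok = False
        for j in range(K):
            if delta[t, j] > NEG:
                ok = True
        if not ok:
            return path, NEG, t
    best = NEG
    best_j = 0
    for j in range(K):
        if delta[T - 1, j] > best:
            best = delta[T - 1, j]
            best_j = j
    path[T - 1] = best_j
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best, -1


@njit(cache=True)
def _rw_nll_and_values(choices, rewards, alpha, beta, n_arms):
    """Negative log-likelihood of the RW-softmax model plus the value path."""
    T = choices.shape[0]
    v = np.full(n_arms, 0.5)
    values = np.zeros((T, n_arms))
    ll = 0.0
    for t in range(T):
        for j in range(n_arms):
            values[t, j] = v[j]
        mx = beta * v[0]
        for j in range(1, n_arms):
            if beta * v[j] > mx:
                mx = beta * v[j]
        se = 0.0
        for j in range(n_arms):
            se += np.exp(beta * v[j] - mx)
        c = choices[t]
        ll += beta * v[c] - mx - np.log(se)
        v[c] += alpha * (rewards[t] - v[c])
    return -ll, values


# ---------------------------------------------------------------------------
# HMM operations
# ---------------------------------------------------------------------------

def _check_choices(choices, n_arms) -> np.ndarray:
    choices = np.asarray(choices, dtype=np.int64)
    if choices.ndim != 1 or choices.size == 0:
        raise ValueError("choices must be a nonempty 1-d sequence")
    if choices.min() < 0 or choices.max() >= n_arms:
        raise ValueError(f"arm indices must lie in [0, {n_arms - 1}]")
    return choices


def hmm_log_likelihood(choices, params: ExploreHMMParams) -> float:
    """Forward-algorithm log marginal likelihood of a choice sequence.

    The initial distribution puts probability 1 on the explore state.
    """
    choices = _check_choices(choices, params.n_arms)
    _, c, bad = _forward_pass(
        choices, params.n_arms, params.p_stay_explore, params.p_stay_exploit
    )
    if bad >= 0:
        return -np.inf
    return float(np.sum(np.log(c)))


def fit_explore_hmm(
    choices,
    n_arms: int = 3,
    n_restarts: int = 20,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ExploreHMMFit:
    """Fit the two persistence parameters by EM with random restarts.

    Restart initializations are drawn uniformly on (0.5, 0.999) for both
    persistences; the restart with the highest log-likelihood wins.  EM
    iterates until the log-likelihood gain falls below ``tol``.
    """
    choices = _check_choices(choices, n_arms)
    if len(choices) < 50:
        warnings.warn("fewer than 50 trials: HMM parameters may be poorly constrained")
    rng = np.random.default_rng(seed)
    inits = rng.uniform(0.5, 0.999, size=(n_restarts, 2))

    best = (-np.inf, None, 0, False)
    restart_ll = np.full(n_restarts, -np.inf)
    for r in range(n_restarts):
        pe, px = inits[r]
        prev_ll = -np.inf
        ll = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            ll, num_e, den_e, num_x, den_x, bad = _em_counts(choices, n_arms, pe, px)
            if bad >= 0:
                break
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                converged = True
                break
            prev_ll = ll
            if den_e > 0:
                pe = min(max(num_e / den_e, 1e-8), 1.0 - 1e-8)
            if den_x > 0:
                px = min(max(num_x / den_x, 1e-8), 1.0 - 1e-8)
        restart_ll[r] = ll
        if ll > best[0]:
            best = (ll, (pe, px), it, converged)

    ll, (pe, px), n_iter, converged = best
    degenerate = bool(
        min(pe, 1 - pe) < 1e-4 or min(px, 1 - px) < 1e-4
    )
    return ExploreHMMFit(
        params=ExploreHMMParams(pe, px, n_arms),
        log_likelihood=float(ll),
        n_iter=n_iter,
        converged=converged,
        degenerate=degenerate,
        restart_log_likelihoods=restart_ll,
    )


def viterbi_states(choices, params: ExploreHMMParams) -> StateSequence:
    """Decode the maximum a posteriori latent path and flag onsets."""
    choices = _check_choices(choices, params.n_arms)
    path, logp, bad = _viterbi(
        choices, params.n_arms, params.p_stay_explore, params.p_stay_exploit
    )
    if bad >= 0:
        raise ValueError(
            f"choice sequence has zero probability under params; first impossible trial: {bad}"
        )
    seg = detect_onsets(path)
    return StateSequence(states=path, onset=seg.onset, log_likelihood=float(logp))


def detect_onsets(states) -> OnsetSegmentation:
    """Segment a state path into bouts and flag exploration onsets.

    An onset is an explore trial whose predecessor is an exploit trial;
    session-initial explore trials are not onsets.  ``exploit_start`` flags
    the symmetric event (first exploit trial after explore), used as the
    control analysis for the specificity of pupil effects.
    """
    states = np.asarray(states)
    n = len(states)
    onset = np.zeros(n, dtype=bool)
    exploit_start = np.zeros(n, dtype=bool)
    if n > 1:
        prev_explore = states[:-1] == EXPLORE
        cur_explore = states[1:] == EXPLORE
        onset[1:] = cur_explore & ~prev_explore
        exploit_start[1:] = ~cur_explore & prev_explore
    bouts = []
    start = 0
    for t in range(1, n + 1):
        boundary = t == n or (states[t] == EXPLORE) != (states[start] == EXPLORE)
        if boundary:
            label = "explore" if states[start] == EXPLORE else "exploit"
            bouts.append((start, t, label))
            start = t
    return OnsetSegmentation(onset=onset, exploit_start=exploit_start, bouts=bouts)


# ---------------------------------------------------------------------------
# Rescorla-Wagner alternative labeler
# ---------------------------------------------------------------------------

def rescorla_wagner_log_likelihood(
    choices, rewards, alpha: float, beta: float, n_arms: int = 3
) -> float:
    choices = _check_choices(choices, n_arms)
    rewards = np.asarray(rewards, dtype=np.float64)
    nll, _ = _rw_nll_and_values(choices, rewards, float(alpha), float(beta), n_arms)
    return -float(nll)


def fit_rescorla_wagner(
    choices,
    rewards,
    n_arms: int = 3,
    n_starts: int = 10,
    seed: int | None = None,
    beta_max: float = 50.0,
) -> RescorlaWagnerFit:
    """Maximum-likelihood fit of the Rescorla-Wagner softmax model.

    ``V[i, t+1] = V[i, t] + alpha * (r_t - V[i, t])`` for the chosen arm,
    values unchanged otherwise; choice probabilities are a softmax with
    inverse temperature ``beta``.  Initial values are 0.5 (the prior mean of
    a Bernoulli reward).  Multi-start L-BFGS-B with alpha in [0, 1] and beta
    in [0, beta_max].
    """
    choices = _check_choices(choices, n_arms)
    rewards = np.asarray(rewards, dtype=np.float64)
    if len(rewards) != len(choices):
        raise ValueError("choices and rewards must have equal length")
    if not np.all(np.isin(rewards, (0.0, 1.0))):
        raise ValueError("rewards must be binary (0/1)")

    def nll(theta):
        a, b = theta
        val, _ = _rw_nll_and_values(choices, rewards, a, b, n_arms)
        return val

    rng = np.random.default_rng(seed)
    starts = np.column_stack(
        [rng.uniform(0.05, 0.95, n_starts), rng.uniform(0.5, min(beta_max, 15.0), n_starts)]
    )
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=[(0.0, 1.0), (0.0, beta_max)]
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = best.x
    nll_val, values = _rw_nll_and_values(choices, rewards, float(a), float(b), n_arms)
    return RescorlaWagnerFit(
        alpha=float(a), beta=float(b), values=values, log_likelihood=-float(nll_val)
    )


def rl_explore_labels(fit: RescorlaWagnerFit, choices) -> np.ndarray:
    """Label choices that do not maximize the fitted values as exploratory.

    Exact ties count as maximizing (not explore).
    """
    choices = np.asarray(choices, dtype=np.int64)
    if fit.values.shape[0] != len(choices):
        raise ValueError("fit.values must be aligned with choices")
    v_chosen = fit.values[np.arange(len(choices)), choices]
    v_max = fit.values.max(axis=1)
    return v_chosen < v_max


# ---------------------------------------------------------------------------
# learning index
# ---------------------------------------------------------------------------

def learning_index(choices, rewards, trial_subset=None, flip_sign: bool = False) -> float:
    """One-trial-back learning index over a trial subset.

    ``[p(switch_{t+1} | reward_t) - p(switch_{t+1} | no reward_t)] /
    p(switch_{t+1})`` computed by direct counting; switch means
    ``choice_{t+1} != choice_t``.  More reward-driven staying gives a more
    negative index; ``flip_sign`` reports the reversed sign so that larger
    values mean more learning.  Returns NaN when the subset lacks one of the
    two reward outcomes (the index is undefined there).
    """
    choices = np.asarray(choices)
    rewards = np.asarray(rewards)
    n = len(choices)
    if trial_subset is None:
        trial_subset = np.arange(n - 1)
    t = np.asarray(trial_subset, dtype=np.int64)
    t = t[t < n - 1]
    if t.size == 0:
        raise ValueError("trial subset is empty")
    switch = choices[t + 1] != choices[t]
    rew = rewards[t] == 1
    if rew.all() or (~rew).all():
        warnings.warn("learning index undefined: only one reward outcome in subset")
        return np.nan
    p_s = switch.mean()
    if p_s == 0:
        warnings.warn("learning index undefined: no switches in subset")
        return np.nan
    val = (switch[rew].mean() - switch[~rew].mean()) / p_s
    return -val if flip_sign else val
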