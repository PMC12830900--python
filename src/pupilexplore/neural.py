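"""Choice-predictive subspaces and population statistics.

The choice subspace is found with targeted dimensionality reduction: a
multinomial logistic model whose separating hyperplanes best discriminate
each upcoming choice from the alternatives.  With three arms, two classifier
hyperplanes are fitted and the third is exactly the negative of their sum; we
enforce that constraint in the optimizer's parameterization, so the three
decision-function coefficient vectors sum to the zero vector by
construction.  (Note the logistic denominator is the standard
``1 + exp(-z)``.)  A small ridge penalty stabilizes near-separable sessions.

Within the fitted 2-d subspace coordinates we compute: the decoded
probability of the actual choice, the per-trial scatter index
``d_within / d_between`` (mean Euclidean distance to same-choice trials over
mean distance to different-choice trials; 1 means no difference in
clustering), and the neural speed (mean displacement between consecutive
time-bin projections, normalized to the bin width).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.spatial.distance import squareform, pdist


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PopulationTensor:
    """Trial x unit activity with imputation and inclusion bookkeeping."""

    counts: np.ndarray            # (n_trials, n_units), imputed
    epoch: str = "pre_target"     # or "post_target" / "pre_saccade"
    bin_s: float = 0.2
    included: np.ndarray = None   # units with mean rate >= 2 spikes/s
    imputed: np.ndarray = None    # (n_trials, n_units) bool
    unit_meta: pd.DataFrame = None

    @property
    def rates(self) -> np.ndarray:
        return self.counts / self.bin_s


@dataclass
class ChoiceSubspace:
    """Choice-discriminating hyperplanes; rows of ``weights`` sum to zero."""

    weights: np.ndarray           # (n_classes, n_units)
    intercepts: np.ndarray        # (n_classes,)
    classes: np.ndarray
    training_epoch: str = "pre_saccade"
    ridge: float = 1e-3
    converged: bool = True

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights.T + self.intercepts

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_function(X)
        s -= s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def project(self, X) -> np.ndarray:
        """Coordinates in the 2-d subspace spanned by the two fitted
        hyperplane normals (the third is their negative sum)."""
        return np.asarray(X, dtype=float) @ self.weights[:-1].T


@dataclass
class ScatterResult:
    d_within: np.ndarray
    d_between: np.ndarray
    scatter: np.ndarray           # NaN where a class has a single trial


@dataclass
class DecodingResult:
    proba: np.ndarray             # (n_trials, n_classes)
    p_choice: np.ndarray          # probability assigned to the actual choice
    accuracy: float


# ---------------------------------------------------------------------------
# preparation
# ---------------------------------------------------------------------------

def prepare_population(
    raw_counts,
    hold_mask=None,
    min_rate: float = 2.0,
    bin_s: float = 0.2,
    epoch: str = "pre_target",
    unit_meta: pd.DataFrame | None = None,
) -> PopulationTensor:
    """Impute unheld entries and flag low-rate units.

    ``hold_mask`` is a (n_trials, n_units) boolean array, True where the
    unit was held; unheld entries are imputed with the unit's mean over held
    trials.  Units with mean rate below ``min_rate`` spikes/s are marked
    excluded (their weights are hard to identify); units held on zero trials
    are dropped from the inclusion set with a warning.
    """
    counts = np.asarray(raw_counts, dtype=float).copy()
    n_trials, n_units = counts.shape
    if hold_mask is None:
        hold_mask = np.ones_like(counts, dtype=bool)
    else:
        hold_mask = np.asarray(hold_mask, dtype=bool)
        if hold_mask.shape != counts.shape:
            raise ValueError("hold_mask must match counts shape")
    imputed = ~hold_mask
    included = np.ones(n_units, dtype=bool)
    for u in range(n_units):
        held = hold_mask[:, u]
        if not held.any():
            warnings.warn(f"unit {u} held on zero trials; dropped")
            included[u] = False
            counts[:, u] = 0.0
            continue
        if imputed[:, u].any():
            counts[~held, u] = counts[held, u].mean()
    mean_rates = counts.mean(axis=0) / bin_s
    included &= mean_rates >= min_rate
    return PopulationTensor(
        counts=counts, epoch=epoch, bin_s=bin_s, included=included,
        imputed=imputed, unit_meta=unit_meta,
    )


# ---------------------------------------------------------------------------
# subspace fitting (constrained multinomial logistic regression)
# ---------------------------------------------------------------------------

def _softmax_nll_grad(theta, X, Y, K, ridge):
    """NLL and gradient under the sum-to-zero parameterization: the last
    class's weight vector is the negative sum of the first K-1."""
    n, d = X.shape
    W = theta[: (K - 1) * d].reshape(K - 1, d)
    b = theta[(K - 1) * d :]
    Wfull = np.vstack([W, -W.sum(axis=0)])
    bfull = np.concatenate([b, [-b.sum()]])
    S = X @ Wfull.T + bfull
    S -= S.max(axis=1, keepdims=True)
    E = np.exp(S)
    P = E / E.sum(axis=1, keepdims=True)
    ll = np.sum(np.log(P[np.arange(n), Y] + 1e-300))
    nll = -ll + 0.5 * ridge * np.sum(Wfull**2)
    D = P.copy()
    D[np.arange(n), Y] -= 1.0  # dNLL/dS
    gW = np.empty_like(W)
    gb = np.empty_like(b)
    for k in range(K - 1):
        # S_k depends on W_k directly; S_{K-1} depends via the constraint
        gW[k] = (D[:, k] - D[:, K - 1]) @ X + ridge * (Wfull[k] - Wfull[K - 1])
        gb[k] = D[:, k].sum() - D[:, K - 1].sum()
    return nll, np.concatenate([gW.ravel(), gb])


def fit_choice_subspace(
    tensor,
    choices,
    ridge: float = 1e-3,
    epoch: str = "pre_saccade",
    maxiter: int = 2000,
) -> ChoiceSubspace:
    """Fit the choice-predictive hyperplanes by multinomial logistic
    regression with the third classifier constrained to the negative sum of
    the first two.

    ``tensor`` may be a :class:`PopulationTensor` (included units are used)
    or a plain (n_trials, n_units) matrix.  Warns when trials are fewer than
    10 x units.
    """
    if isinstance(tensor, PopulationTensor):
        X = tensor.counts[:, tensor.included]
    else:
        X = np.asarray(tensor, dtype=float)
    choices = np.asarray(choices, dtype=np.int64)
    classes = np.unique(choices)
    K = len(classes)
    if K < 3:
        raise ValueError(f"need >= 3 distinct choices, got classes {classes}")
    n, d = X.shape
    if n < 10 * d:
        warnings.warn("fewer than 10 trials per unit; subspace may be unstable")
    Y = np.searchsorted(classes, choices)

    theta0 = np.zeros((K - 1) * d + (K - 1))
    res = optimize.minimize(
        _softmax_nll_grad,
        theta0,
        args=(X, Y, K, ridge),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-9},
    )
    W = res.x[: (K - 1) * d].reshape(K - 1, d)
    b = res.x[(K - 1) * d :]
    weights = np.vstack([W, -W.sum(axis=0)])
    intercepts = np.concatenate([b, [-b.sum()]])
    return ChoiceSubspace(
        weights=weights, intercepts=intercepts, classes=classes,
        training_epoch=epoch, ridge=ridge, converged=bool(res.success),
    )


def decode_choice_probability(tensor, subspace: ChoiceSubspace, choices) -> DecodingResult:
    """Per-trial multinomial probability of the actual choice and overall
    argmax accuracy."""
    if isinstance(tensor, PopulationTensor):
        X = tensor.counts[:, tensor.included]
    else:
        X = np.asarray(tensor, dtype=float)
    choices = np.asarray(choices, dtype=np.int64)
    proba = subspace.predict_proba(X)
    y = np.searchsorted(subspace.classes, choices)
    p_choice = proba[np.arange(len(y)), y]
    accuracy = float(np.mean(np.argmax(proba, axis=1) == y))
    return DecodingResult(proba=proba, p_choice=p_choice, accuracy=accuracy)


# ---------------------------------------------------------------------------
# population geometry
# ---------------------------------------------------------------------------

def scatter_index(projections, choices) -> ScatterResult:
    """Per-trial ratio of mean distance to same-choice trials over mean
    distance to different-choice trials, in subspace coordinates."""
    P = np.asarray(projections, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    choices = np.asarray(choices)
    n = len(choices)
    if P.shape[0] != n:
        raise ValueError("projections and choices must be aligned")
    D = squareform(pdist(P))
    same = choices[:, None] == choices[None, :]
    np.fill_diagonal(same, False)
    diff = choices[:, None] != choices[None, :]
    n_same = same.sum(axis=1)
    n_diff = diff.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_within = np.where(n_same > 0, (D * same).sum(axis=1) / np.maximum(n_same, 1), np.nan)
        d_between = np.where(n_diff > 0, (D * diff).sum(axis=1) / np.maximum(n_diff, 1), np.nan)
        scatter = d_within / d_between
    return ScatterResult(d_within=d_within, d_between=d_between, scatter=scatter)


def neural_speed(binned, subspace: ChoiceSubspace, bin_s: float = 0.02) -> np.ndarray:
    """Mean per-second displacement between consecutive time-bin projections.

    ``binned`` is (n_trials, n_units, n_bins); each bin is projected into
    the 2-d subspace and the Euclidean displacement between consecutive bins
    is averaged within trial and divided by the bin width.  20 bins give 19
    displacement steps.
    """
    binned = np.asarray(binned, dtype=float)
    if binned.ndim != 3:
        raise ValueError("binned must be (n_trials, n_units, n_bins)")
    n_trials, n_units, n_bins = binned.shape
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    W2 = subspace.weights[:-1]     # (2, n_units)
    # project: (n_trials, n_bins, 2)
    proj = np.tensordot(binned.transpose(0, 2, 1), W2.T, axes=([2], [0]))
    steps = np.diff(proj, axis=1)
    disp = np.linalg.norm(steps, axis=2)
    return disp.mean(axis=1) / bin_s


# ---------------------------------------------------------------------------
# single-unit tuning
# ---------------------------------------------------------------------------

def unit_tuning_glm(rates, choices, pupil, alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Per-unit linear model ``rate ~ C(choice) + pupil + C(choice):pupil``.

    Term-level F-tests (type-II ANOVA) at ``alpha``; returns a per-unit
    frame and a population summary with the counts and percentages of
    choice-tuned, pupil-modulated, and interaction units.
    """
    rates = np.asarray(rates, dtype=float)
    choices = np.asarray(choices)
    pupil = np.asarray(pupil, dtype=float)
    if rates.ndim == 1:
        rates = rates[:, None]
    n_trials, n_units = rates.shape
    rows = []
    for u in range(n_units):
        y = rates[:, u]
        if y.std() == 0:
            rows.append((u, np.nan, np.nan, np.nan, False, False, False, True))
            continue
        df = pd.DataFrame({"rate": y, "choice": choices, "pupil": pupil})
        model = sm.OLS.from_formula("rate ~ C(choice) * pupil", data=df).fit()
        an = sm.stats.anova_lm(model, typ=2)
        p_choice = float(an.loc["C(choice)", "PR(>F)"])
        p_pupil = float(an.loc["pupil", "PR(>F)"])
        p_inter = float(an.loc["C(choice):pupil", "PR(>F)"])
        rows.append(
            (u, p_choice, p_pupil, p_inter,
             p_choice < alpha, p_pupil < alpha, p_inter < alpha, False)
        )
    table = pd.DataFrame(
        rows,
        columns=["unit", "p_choice", "p_pupil", "p_interaction",
                 "sig_choice", "sig_pupil", "sig_interaction", "zero_variance"],
    )
    summary = {
        "n_units": n_units,
        "n_choice_tuned": int(table["sig_choice"].sum()),
        "n_pupil_modulated": int(table["sig_pupil"].sum()),
        "n_interaction": int(table["sig_interaction"].sum()),
        "pct_choice_tuned": 100.0 * table["sig_choice"].mean(),
        "pct_pupil_modulated": 100.0 * table["sig_pupil"].mean(),
        "pct_interaction": 100.0 * table["sig_interaction"].mean(),
    }
    return table, summary
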