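"""Shared statistical machinery.

GLMs are identity-link with normally distributed errors, fit by ordinary
least squares with session included as a dummy-coded factor to absorb
session-to-session variability.  Binary outcomes (explore/onset flags) are
deliberately fit as linear probability models under the same identity link
rather than with a logistic link; a logistic option is available where it
matters.  AIC here counts the intercept and the error variance among the
free parameters (``AIC = 2 k - 2 logL``); since the variance term is counted
identically in every compared model, AIC differences and weights are
unaffected by the convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# GLM with session dummies
# ---------------------------------------------------------------------------

@dataclass
class GLMResult:
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    log_likelihood: float
    aic: float
    n: int
    df_resid: float

    def to_record(self, term: str = "x1") -> dict:
        """JSON-ready record for a single term."""
        return {
            "estimate": float(self.params[term]),
            "se": float(self.bse[term]),
            "ci": [float(self.conf_int.loc[term, 0]), float(self.conf_int.loc[term, 1])],
            "p": float(self.pvalues[term]),
            "n": int(self.n),
            "df": float(self.df_resid),
            "aic": float(self.aic),
        }


def _design(X, sessions, order: int, extra: pd.DataFrame | None = None) -> pd.DataFrame:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    cols = {f"x{i + 1}": X[:, i] for i in range(X.shape[1])}
    if order == 2:
        cols["x1_sq"] = X[:, 0] ** 2
    elif order != 1:
        raise ValueError("order must be 1 or 2")
    design = pd.DataFrame(cols)
    if extra is not None:
        design = pd.concat([design.reset_index(drop=True), extra.reset_index(drop=True)], axis=1)
    if sessions is not None:
        sessions = pd.Series(np.asarray(sessions), name="session")
        if sessions.nunique() > 1:
            dummies = pd.get_dummies(sessions, prefix="session", drop_first=True, dtype=float)
            design = pd.concat([design.reset_index(drop=True), dummies.reset_index(drop=True)], axis=1)
    design.insert(0, "const", 1.0)
    return design


def _check_rank(design: pd.DataFrame) -> None:
    mat = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the offending columns by greedy QR-style elimination
        bad = []
        keep: list[int] = []
        for j in range(mat.shape[1]):
            cand = keep + [j]
            if np.linalg.matrix_rank(mat[:, cand]) == len(cand):
                keep.append(j)
            else:
                bad.append(design.columns[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def glm_session_dummies(y, X, sessions=None, order: int = 1) -> GLMResult:
    """Identity-link, normal-error GLM with k-1 session dummy columns.

    ``order=2`` adds a squared term for the first predictor.  The reported
    AIC counts the intercept and the error variance as free parameters.
    """
    y = np.asarray(y, dtype=float)
    design = _design(X, sessions, order)
    if len(design) != len(y):
        raise ValueError("y and predictors must be aligned")
    _check_rank(design)
    res = sm.OLS(y, design).fit()
    k = len(res.params) + 1  # + error variance
    aic = 2.0 * k - 2.0 * res.llf
    ci = res.conf_int()
    ci.columns = [0, 1]
    return GLMResult(
        params=res.params,
        bse=res.bse,
        conf_int=ci,
        pvalues=res.pvalues,
        log_likelihood=float(res.llf),
        aic=float(aic),
        n=int(res.nobs),
        df_resid=float(res.df_resid),
    )


# ---------------------------------------------------------------------------
# AIC weights
# ---------------------------------------------------------------------------

def aic_weights(aics) -> np.ndarray:
    """Akaike weights: ``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)`` with
    ``d_i = AIC_i - min(AIC)``."""
    aics = np.asarray(aics, dtype=float)
    if aics.size < 2:
        raise ValueError("need at least two AIC values")
    if not np.all(np.isfinite(aics)):
        raise ValueError("AIC values must be finite")
    d = aics - aics.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# mediation (three-regression structural model + Sobel test)
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    """a, b, c, c' decomposition of pupil -> mediator -> onset paths.

    For purely linear least-squares paths on a common sample the identity
    ``c = c' + a*b`` holds exactly.
    """

    c: float
    a: float
    b: float
    c_prime: float
    ab: float
    se_a: float
    se_b: float
    se_c_prime: float
    sobel_se: float
    sobel_z: float
    sobel_p: float
    intercepts: tuple[float, float, float]
    n: int


def _zscore_by_session(x: np.ndarray, sessions: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    for sid in np.unique(sessions):
        idx = sessions == sid
        v = x[idx]
        sd = v.std()
        out[idx] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    return out


def mediation_sobel(
    x,
    mediator,
    y,
    sessions=None,
    standardize: bool = True,
    session_dummies: bool = True,
) -> MediationResult:
    """Mediation analysis via three least-squares fits and Sobel's test.

    Model 1: ``y = g1 + c x``; model 2: ``m = g2 + a x``; model 3:
    ``y = g3 + b m + c' x`` (all with session dummies by default).  The
    indirect effect is ``ab`` with delta-method (Sobel) standard error
    ``sqrt(b^2 SE_a^2 + a^2 SE_b^2)`` and a two-sided normal p-value.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sessions = np.zeros(n, dtype=int) if sessions is None else np.asarray(sessions)
    if m.std() == 0:
        raise ValueError("mediator has zero variance")
    if standardize:
        x = _zscore_by_session(x, sessions)
        m = _zscore_by_session(m, sessions)
    sess = sessions if session_dummies else None

    r1 = glm_session_dummies(y, x, sess)
    r2 = glm_session_dummies(m, x, sess)
    r3 = glm_session_dummies(y, np.column_stack([m, x]), sess)

    c = float(r1.params["x1"])
    a = float(r2.params["x1"])
    b = float(r3.params["x1"])
    c_prime = float(r3.params["x2"])
    se_c_prime = float(r3.bse["x2"])
    se_a = float(r2.bse["x1"])
    se_b = float(r3.bse["x1"])
    ab = a * b
    sobel_se = float(np.sqrt(b**2 * se_a**2 + a**2 * se_b**2))
    z = ab / sobel_se if sobel_se > 0 else np.nan
    p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return MediationResult(
        c=c, a=a, b=b, c_prime=c_prime, ab=ab,
        se_a=se_a, se_b=se_b, se_c_prime=se_c_prime, sobel_se=sobel_se,
        sobel_z=float(z), sobel_p=float(p),
        intercepts=(
            float(r1.params["const"]), float(r2.params["const"]), float(r3.params["const"])
        ),
        n=n,
    )


# ---------------------------------------------------------------------------
# paired tests, AUC, multiple comparisons
# ---------------------------------------------------------------------------

@dataclass
class PairedStats:
    t: float
    df: int
    p: float
    cohen_d: float
    mean_diff: float
    ci: tuple[float, float]
    n: int
    degenerate: bool = False


def paired_effect_stats(values_a, values_b) -> PairedStats:
    """Two-sided paired t-test with Cohen's d for paired designs
    (``mean(diff)/SD(diff)``) and a 95% CI on the mean difference."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedStats(
            t=np.nan, df=n - 1, p=np.nan, cohen_d=0.0 if d.mean() == 0 else np.inf,
            mean_diff=float(d.mean()), ci=(float(d.mean()), float(d.mean())),
            n=n, degenerate=True,
        )
    t, p = sps.ttest_rel(a, b)
    se = sd / np.sqrt(n)
    half = sps.t.ppf(0.975, n - 1) * se
    return PairedStats(
        t=float(t), df=n - 1, p=float(p),
        cohen_d=float(d.mean() / sd),
        mean_diff=float(d.mean()),
        ci=(float(d.mean() - half), float(d.mean() + half)),
        n=n,
    )


def auc_discriminate(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = labels.sum()
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm procedure; returns (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj
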