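"""Transition-specific Cox proportional-hazards estimation from first principles.

Each transition q->r of the progressive three-state model is fitted with its
own semi-parametric intensity

    lambda_qr(t | x) = lambda_qr0(t) * exp(beta_qr' x),

maximising the delayed-entry (left-truncated, right-censored) partial
likelihood over the at-risk intervals of the counting-process data.  Subjects
enter the 1->2 risk set only from the day they reach the mild state, so risk
sets at an event time u are {i : entry_i < u <= exit_i}.

Implemented here:

* Newton-Raphson maximisation with step-halving; Breslow (default) or Efron
  handling of tied event times.
* Wald covariance from the inverse observed information, 95% CIs and
  two-sided p-values on the hazard-ratio scale.
* Breslow estimator of the cumulative baseline hazard and the nonparametric
  Nelson-Aalen cumulative transition hazard (the increments that feed the
  Aalen-Johansen product integral).

Breslow is the default tie method because the study software's default is the
Breslow approximation; on tie-free data Breslow and Efron coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .event_history import COVARIATE_NAMES

__all__ = [
    "CoxFit",
    "CumulativeHazard",
    "fit_cox",
    "nelson_aalen",
    "breslow_baseline",
    "score_max_norm",
]


@dataclass
class CumulativeHazard:
    """Right-continuous non-decreasing step function A(t) with A(0) = 0."""

    transition: tuple
    times: np.ndarray  # increasing event times carrying positive increments
    increments: np.ndarray  # dA at each time, >= 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        if np.any(self.increments < 0):
            raise ValueError("cumulative-hazard increments must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __call__(self, t) -> np.ndarray:
        """A(t), evaluated right-continuously on scalar or array t."""
        t = np.asarray(t, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(self.increments)])
        idx = np.searchsorted(self.times, t, side="right")
        return cum[idx]


@dataclass
class CoxFit:
    """Result of one transition-specific proportional-hazards fit."""

    transition: tuple
    covariate_names: tuple
    beta: np.ndarray
    covariance: np.ndarray
    log_partial_likelihood: float
    n_subjects: int
    n_events: int
    baseline_cumhaz: CumulativeHazard
    ties_method: str
    converged: bool
    n_iter: int
    dropped_covariates: tuple = ()

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci_lower(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.beta - 1.959963984540054 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        # divergent (non-converged) coefficients produce infinite upper limits
        with np.errstate(over="ignore"):
            return np.exp(self.beta + 1.959963984540054 * self.se)

    @property
    def p_values(self) -> np.ndarray:
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": list(self.covariate_names),
                "coef": self.beta,
                "se": self.se,
                "hr": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p_values,
            }
        )

    def to_table_rows(self) -> list[dict]:
        """JSON-friendly per-covariate rows (hazard-ratio table layout)."""
        return [
            {
                "covariate": name,
                "hr": float(h),
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "p": float(p),
            }
            for name, h, lo, hi, p in zip(
                self.covariate_names, self.hr, self.ci_lower, self.ci_upper, self.p_values
            )
        ]


def _transition_arrays(rows: pd.DataFrame, transition, covariate_names):
    sub = rows[(rows["from_state"] == transition[0]) & (rows["to_state"] == transition[1])]
    if sub.empty:
        raise ValueError(f"no counting-process rows for transition {transition}")
    entry = sub["entry"].to_numpy(dtype=float)
    exit_ = sub["exit"].to_numpy(dtype=float)
    status = sub["status"].to_numpy(dtype=int)
    X = sub[list(covariate_names)].to_numpy(dtype=float)
    ids = sub["patient_id"].to_numpy()
    return entry, exit_, status, X, ids


def _loglik_score_info(beta, entry, exit_, status, X, ties):
    """Log partial likelihood, score vector and observed information.

    Risk set at event time u: entry < u <= exit.  Breslow treats the d tied
    events at u as sharing one denominator; Efron removes the event subjects'
    contributions in d graded steps.
    """
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    event_times = np.unique(exit_[status == 1])
    for u in event_times:
        at_risk = (entry < u) & (u <= exit_)
        D = at_risk & (exit_ == u) & (status == 1)
        d = int(D.sum())
        if d == 0:
            continue
        wR = w[at_risk]
        XR = X[at_risk]
        S0 = wR.sum()
        S1 = wR @ XR
        S2 = XR.T @ (XR * wR[:, None])
        xD = X[D]
        wD = w[D]
        if ties == "breslow":
            loglik += eta[D].sum() - d * np.log(S0)
            score += xD.sum(axis=0) - d * S1 / S0
            info += d * (S2 / S0 - np.outer(S1, S1) / S0**2)
        else:  # efron
            S0d = wD.sum()
            S1d = wD @ xD
            S2d = xD.T @ (xD * wD[:, None])
            loglik += eta[D].sum()
            for k in range(d):
                f = k / d
                s0 = S0 - f * S0d
                s1 = S1 - f * S1d
                s2 = S2 - f * S2d
                loglik -= np.log(s0)
                score += xD.sum(axis=0) / d - s1 / s0
                info += s2 / s0 - np.outer(s1, s1) / s0**2
    return loglik, score, info


def fit_cox(
    rows: pd.DataFrame,
    transition: tuple,
    ties: str = "breslow",
    covariate_names: Sequence[str] = COVARIATE_NAMES,
    max_iter: int = 50,
    score_tol: float = 1e-6,
    loglik_rtol: float = 1e-9,
) -> CoxFit:
    """Fit the Cox model for one transition of the counting-process data.

    Convergence requires the score max-norm <= ``score_tol`` or a relative
    log-partial-likelihood change < ``loglik_rtol``.  Constant covariate
    columns are dropped with a warning (their coefficients are reported as
    NaN).  A monotone partial likelihood (no finite maximiser, e.g. a binary
    covariate perfectly separating events) is flagged ``converged=False`` with
    the runaway coefficients left at their last value.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    entry, exit_, status, X, ids = _transition_arrays(rows, transition, covariate_names)
    n_events = int(status.sum())
    if n_events == 0:
        raise ValueError(f"no events on transition {transition}; cannot fit")

    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = tuple(covariate_names[j] for j in range(X.shape[1]) if j not in keep)
    if dropped:
        warnings.warn(
            f"dropping constant covariate(s) {dropped} on transition {transition}",
            stacklevel=2,
        )
    Xk = X[:, keep]
    p = Xk.shape[1]

    # standardize for numerical stability of Newton steps; back-transform after
    center = Xk.mean(axis=0)
    scale = Xk.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (Xk - center) / scale

    beta = np.zeros(p)
    loglik, score, info = _loglik_score_info(beta, entry, exit_, status, Z, ties)
    converged = p == 0
    n_iter = 0
    for n_iter in range(1, max_iter + 1 if p else 0):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving until the likelihood does not decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            new_loglik, new_score, new_info = _loglik_score_info(
                cand, entry, exit_, status, Z, ties
            )
            if np.isfinite(new_loglik) and new_loglik >= loglik - 1e-12:
                break
            factor /= 2.0
        rel = abs(new_loglik - loglik) / max(abs(loglik), 1.0)
        beta, score, info = cand, new_score, new_info
        loglik = new_loglik
        if np.max(np.abs(score)) <= score_tol:
            converged = True
            break
        if rel < loglik_rtol:
            converged = np.max(np.abs(score)) <= np.sqrt(score_tol)
            break
    cov_z = np.linalg.inv(info) if p else np.zeros((0, 0))
    if p:
        # monotone / quasi-separated likelihood: a coefficient running away on
        # the standardized scale, or an exploding standard error, means the
        # partial likelihood has no finite maximizer in that direction
        se_z = np.sqrt(np.clip(np.diag(cov_z), 0, None))
        runaway_mask = (np.abs(beta) > 8) | (se_z > 50)
        if np.any(runaway_mask):
            runaway = [covariate_names[keep[j]] for j in np.where(runaway_mask)[0]]
            warnings.warn(
                f"monotone partial likelihood on transition {transition}: "
                f"coefficient(s) {runaway} diverge (sign indicates direction)",
                stacklevel=2,
            )
            converged = False
    # back-transform beta and covariance to the original covariate scale
    beta_full = np.full(len(covariate_names), np.nan)
    cov_full = np.full((len(covariate_names), len(covariate_names)), np.nan)
    beta_orig = beta / scale
    cov_orig = cov_z / np.outer(scale, scale)
    for a, j in enumerate(keep):
        beta_full[j] = beta_orig[a]
        for b, k in enumerate(keep):
            cov_full[j, k] = cov_orig[a, b]

    # log partial likelihood is invariant to the affine covariate rescaling
    fit = CoxFit(
        transition=tuple(transition),
        covariate_names=tuple(covariate_names),
        beta=beta_full,
        covariance=cov_full,
        log_partial_likelihood=float(loglik),
        n_subjects=len(np.unique(ids)),
        n_events=n_events,
        baseline_cumhaz=None,  # filled below
        ties_method=ties,
        converged=bool(converged),
        n_iter=n_iter,
    )
    fit.dropped_covariates = dropped
    fit.baseline_cumhaz = breslow_baseline(fit, rows)
    return fit


def score_max_norm(fit: CoxFit, rows: pd.DataFrame) -> float:
    """Max-norm of the partial-likelihood score at the fitted coefficients.

    Evaluated on the internally standardized covariate scale (the scale on
    which the Newton iteration converges), so the value is comparable to the
    fitting tolerance.
    """
    kept = [n for n in fit.covariate_names if n not in fit.dropped_covariates]
    entry, exit_, status, X, _ids = _transition_arrays(rows, fit.transition, kept)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale
    beta_orig = np.array([fit.beta[fit.covariate_names.index(n)] for n in kept])
    beta_z = beta_orig * scale
    _ll, score, _info = _loglik_score_info(beta_z, entry, exit_, status, Z, fit.ties_method)
    return float(np.max(np.abs(score)))


def nelson_aalen(rows: pd.DataFrame, transition: tuple) -> CumulativeHazard:
    """Nelson-Aalen cumulative transition hazard A_qr(t).

    The increment at an event time u is d_qr(u) / Y_q(u-): tied events on the
    transition divided by the subjects at risk in the source state just before
    u (entry < u <= exit on the transition's rows).
    """
    entry, exit_, status, _X, _ids = _transition_arrays(rows, transition, [])
    event_times = np.unique(exit_[status == 1])
    times, incs = [], []
    for u in event_times:
        at_risk = (entry < u) & (u <= exit_)
        d = int(((exit_ == u) & (status == 1) & at_risk).sum())
        y = int(at_risk.sum())
        if d and y:
            times.append(u)
            incs.append(d / y)
    return CumulativeHazard(tuple(transition), np.array(times), np.array(incs))


def breslow_baseline(fit: CoxFit, rows: pd.DataFrame) -> CumulativeHazard:
    """Breslow cumulative baseline hazard at the fitted coefficients.

    dA_0(u) = d(u) / sum_{i at risk} exp(beta' x_i); with all coefficients
    zero this reduces exactly to the Nelson-Aalen estimator.
    """
    kept = [n for n in fit.covariate_names if n not in fit.dropped_covariates]
    entry, exit_, status, X, _ids = _transition_arrays(rows, fit.transition, kept)
    beta = np.array([fit.beta[fit.covariate_names.index(n)] for n in kept])
    w = np.exp(X @ beta) if len(kept) else np.ones(len(entry))
    event_times = np.unique(exit_[status == 1])
    times, incs = [], []
    for u in event_times:
        at_risk = (entry < u) & (u <= exit_)
        d = int(((exit_ == u) & (status == 1) & at_risk).sum())
        denom = w[at_risk].sum()
        if d and denom > 0:
            times.append(u)
            incs.append(d / denom)
    return CumulativeHazard(tuple(fit.transition), np.array(times), np.array(incs))
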