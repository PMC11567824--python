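"""Model-based planning index from two-step stay/switch behavior.

Each participant's trial sequence is decomposed into consecutive-trial
stay events; a logistic regression of the stay indicator on the previous
trial's outcome (o = +/-1), and the outcome-by-transition interaction
(o*tau, tau = +/-1 for common/rare) yields:

* the outcome main effect — the model-free weight (repeat what was just
  rewarded);
* the interaction coefficient — the *model-based index*, the degree to
  which reward repetition is qualified by knowledge of the transition
  structure.

Estimation is per-subject penalized maximum likelihood (a small ridge
keeps estimates finite under separation, e.g. an all-stay player), with
an optional empirical-Bayes normal shrinkage of the per-subject
coefficients toward the cohort mean (precision-weighted), approximating
a hierarchical fit at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "MBIndexResult",
    "build_stay_table",
    "fit_stay_regression",
    "estimate_cohort_indices",
    "ridge_logistic_fit",
]


@dataclass(frozen=True)
class MBIndexResult:
    """Stay-regression coefficients for one participant."""

    participant_id: str
    b0_hat: float
    b_mf_hat: float
    b_mb_hat: float
    se_b0: float
    se_mf: float
    se_mb: float
    n_stay_events: int
    converged: bool
    estimator: Literal["per_subject", "pooled_shrinkage"] = "per_subject"


def build_stay_table(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per consecutive trial pair, per participant.

    Columns: ``stay`` (response), ``outcome`` (+1 good / -1 bad),
    ``transition`` (+1 common / -1 rare), ``interaction`` (their
    product).  Requires >= 2 trials per participant.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    frames = []
    for pid, tt in trials.groupby("participant_id", sort=False):
        tt = tt.sort_values("trial")
        if len(tt) < 2:
            raise ValueError(f"participant {pid!r} has fewer than 2 trials")
        actions = tt["action"].to_numpy()
        stay = (actions[1:] == actions[:-1]).astype(int)
        o = np.where(tt["outcome"].to_numpy()[:-1] == "good", 1.0, -1.0)
        tau = np.where(tt["transition"].to_numpy()[:-1] == "common", 1.0, -1.0)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "stay": stay,
                    "outcome": o,
                    "transition": tau,
                    "interaction": o * tau,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def ridge_logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-4,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """L2-penalized logistic ML by damped Newton iteration.

    Minimizes ``-loglik + ridge/2 * ||beta||^2``.  Returns
    ``(beta, se, converged)`` with Wald SEs from the penalized Hessian.
    The ridge guarantees a finite optimum even under complete
    separation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False

    def neg_loglik(b: np.ndarray) -> float:
        eta = X @ b
        # log(1 + exp(eta)) - y*eta, numerically stable
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * ridge * b @ b)

    f = neg_loglik(beta)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        grad = X.T @ (y - mu) - ridge * beta
        W = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = X.T @ (X * W[:, None]) + ridge * np.eye(p)
        step = np.linalg.solve(H, grad)
        # damped line search on the penalized objective
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            fc = neg_loglik(cand)
            if fc <= f + 1e-12:
                break
            scale *= 0.5
        beta, f = cand, fc
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    mu = expit(X @ beta)
    W = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = X.T @ (X * W[:, None]) + ridge * np.eye(p)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se, converged


def fit_stay_regression(
    design: pd.DataFrame,
    ridge: float = 1e-4,
    include_transition_main: bool = False,
) -> MBIndexResult:
    """Fit one participant's stay regression.

    The design table must come from :func:`build_stay_table` and contain
    a single participant.  An all-stay or all-switch response pattern is
    separable; the ridge keeps the estimate finite and the result is
    flagged ``converged=False``.
    """
    if len(design) == 0:
        raise ValueError("empty design table")
    ids = design["participant_id"].unique()
    if len(ids) != 1:
        raise ValueError("fit_stay_regression expects a single participant")
    y = design["stay"].to_numpy(float)
    cols = [np.ones(len(design)), design["outcome"].to_numpy(float)]
    if include_transition_main:
        cols.append(design["transition"].to_numpy(float))
    cols.append(design["interaction"].to_numpy(float))
    X = np.column_stack(cols)
    beta, se, newton_ok = ridge_logistic_fit(X, y, ridge=ridge)
    degenerate = y.min() == y.max()
    i_mb = X.shape[1] - 1
    return MBIndexResult(
        participant_id=str(ids[0]),
        b0_hat=float(beta[0]),
        b_mf_hat=float(beta[1]),
        b_mb_hat=float(beta[i_mb]),
        se_b0=float(se[0]),
        se_mf=float(se[1]),
        se_mb=float(se[i_mb]),
        n_stay_events=int(len(design)),
        converged=bool(newton_ok and not degenerate),
    )


def _shrink(estimates: np.ndarray, ses: np.ndarray) -> np.ndarray:
    """Empirical-Bayes normal shrinkage toward the precision-weighted mean.

    The between-subject variance tau^2 is method-of-moments: variance of
    the estimates minus the mean squared SE, floored at zero (complete
    pooling when the data carry no between-subject signal).
    """
    w0 = 1.0 / ses**2
    mu = float(np.sum(w0 * estimates) / np.sum(w0))
    tau2 = max(float(np.var(estimates, ddof=1) - np.mean(ses**2)), 0.0)
    if tau2 == 0.0:
        return np.full_like(estimates, mu)
    post = (estimates / ses**2 + mu / tau2) / (1.0 / ses**2 + 1.0 / tau2)
    return post


def estimate_cohort_indices(
    trials: pd.DataFrame,
    estimator: Literal["per_subject", "pooled_shrinkage"] = "per_subject",
    ridge: float = 1e-4,
) -> pd.DataFrame:
    """Per-subject stay-regression coefficients for a whole cohort.

    Returns one row per participant with ``b0_hat``, ``b_mf_hat``,
    ``b_mb_hat`` (the model-based index), their SEs, stay-event counts
    and convergence flags.  With ``pooled_shrinkage`` the per-subject
    coefficients are shrunk toward the cohort mean with weights inverse
    to their squared SEs.
    """
    design = build_stay_table(trials)
    results = [
        fit_stay_regression(g, ridge=ridge)
        for _, g in design.groupby("participant_id", sort=False)
    ]
    df = pd.DataFrame([r.__dict__ for r in results])
    df["estimator"] = estimator
    if estimator == "pooled_shrinkage" and len(df) > 1:
        for col, se_col in (("b0_hat", "se_b0"), ("b_mf_hat", "se_mf"), ("b_mb_hat", "se_mb")):
            df[col] = _shrink(df[col].to_numpy(float), df[se_col].to_numpy(float))
    elif estimator not in ("per_subject", "pooled_shrinkage"):
        raise ValueError(f"unknown estimator {estimator!r}")
    return df
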