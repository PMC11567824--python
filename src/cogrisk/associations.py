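"""Risk-factor association suites: preparation, descriptive models,
primary / binarized / depression-adjusted / age-interaction analyses.

Coding and scaling rules follow the study's analysis plan:

* every continuous variable (predictors and outcomes) is z-scored within
  sample;
* binary predictors are coded 0/2 so that a "2-unit" change plays the
  role of one SD (exactly true only at prevalence 0.5 — the residual
  discrepancy is surfaced in the fit log);
* all variables are oriented so higher = worse cognition / higher risk
  (working-memory accuracy, planning index, education, SES, social
  network and exercise are reverse-coded);
* gender is contrast-coded with cisgender male as the reference;
* one model per (outcome, risk factor), adjusted for age and gender
  (linear age only; the quadratic age term lives in the descriptive
  models); Bonferroni families are per dependent variable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .mb_index import ridge_logistic_fit
from .synthetic_cohort import REVERSED_PREDICTORS

__all__ = [
    "PreparedCohort",
    "AssociationResult",
    "prepare",
    "descriptive_age_gender_models",
    "correlate_measures",
    "fit_association",
    "binarize_objective",
    "run_primary_suite",
    "run_depression_adjusted",
    "run_age_interaction_suite",
    "significant_pairs",
    "CONTINUOUS_PREDICTORS",
    "BINARY_PREDICTORS",
    "ALL_PREDICTORS",
    "OBJECTIVE_OUTCOMES",
    "ALL_OUTCOMES",
]

CONTINUOUS_PREDICTORS = (
    "education",
    "ses",
    "depression",
    "loneliness",
    "social_network",
    "hearing_handicap",
    "exercise",
)
BINARY_PREDICTORS = (
    "tinnitus",
    "stroke",
    "diabetes",
    "hypertension",
    "smoking",
    "family_history",
)
ALL_PREDICTORS = CONTINUOUS_PREDICTORS + BINARY_PREDICTORS

OBJECTIVE_OUTCOMES = (
    "visual_working_memory",
    "cognitive_flexibility",
    "model_based_index",
)
ALL_OUTCOMES = OBJECTIVE_OUTCOMES + ("subjective_memory",)

#: outcomes whose natural orientation is "higher = better" (reverse-coded)
REVERSED_OUTCOMES = ("visual_working_memory", "model_based_index")


@dataclass
class PreparedCohort:
    """Analysis-ready cohort: oriented, scaled and coded."""

    df: pd.DataFrame
    q: float  # observed subjective-complaint prevalence
    continuous: tuple[str, ...] = CONTINUOUS_PREDICTORS
    binary: tuple[str, ...] = BINARY_PREDICTORS
    outcomes: tuple[str, ...] = ALL_OUTCOMES
    log: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class AssociationResult:
    """One fitted model's coefficient of interest."""

    outcome: str
    risk_factor: str
    covariates: str  # "age_gender" or "age_gender_depression"
    family: Literal["linear", "logistic"]
    beta: float
    se: float
    t_or_z: float
    p: float
    or_value: Optional[float]
    ci_low: float
    ci_high: float
    alpha: float
    significant: bool
    term: str = "main"
    converged: bool = True

    def __post_init__(self) -> None:
        if self.family == "logistic" and self.or_value is not None:
            assert abs(self.or_value - math.exp(self.beta)) < 1e-12 * max(1.0, self.or_value)


def _zscore(x: np.ndarray, name: str = "") -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"zero-variance column {name!r} cannot be standardized")
    return (x - x.mean()) / sd


def prepare(cohort: pd.DataFrame) -> PreparedCohort:
    """Apply the orientation / scaling / coding rules.

    Requires complete data in all analysis columns.  Emits a
    ``PreparedCohort`` whose continuous columns have mean 0 / SD 1
    (ddof=1), whose binary predictors take values in {0, 2}, with
    ``female`` as the 0/1 gender contrast (cis male reference), and with
    standardized ``age`` plus a re-standardized quadratic ``age_sq``.
    """
    needed = list(ALL_PREDICTORS) + list(ALL_OUTCOMES) + ["age", "gender", "participant_id"]
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort lacks analysis columns: {missing_cols}")
    sub = cohort[needed]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in analysis columns: {bad}")

    out = pd.DataFrame({"participant_id": cohort["participant_id"].to_numpy()})
    log: list[str] = []

    out["female"] = (cohort["gender"].to_numpy() == "cis_female").astype(int)
    out["age"] = _zscore(cohort["age"].to_numpy(float), "age")
    out["age_sq"] = _zscore(out["age"].to_numpy() ** 2, "age_sq")

    for name in CONTINUOUS_PREDICTORS:
        x = cohort[name].to_numpy(float)
        if name in REVERSED_PREDICTORS:
            x = -x
        out[name] = _zscore(x, name)
    for name in BINARY_PREDICTORS:
        x = cohort[name].to_numpy(float)
        vals = set(np.unique(x))
        if not vals <= {0.0, 1.0}:
            raise ValueError(f"binary predictor {name!r} not 0/1 coded: {sorted(vals)}")
        if len(vals) < 2:
            raise ValueError(f"zero-variance column {name!r} cannot be analyzed")
        out[name] = 2.0 * x
        p = x.mean()
        sd = out[name].std(ddof=1)
        log.append(
            f"{name}: 0/2 coding, prevalence {p:.3f}, SD {sd:.4f}"
            + ("" if abs(sd - 1) < 0.01 else " (deviates from 1; exact only at p=0.5)")
        )

    for name in OBJECTIVE_OUTCOMES:
        x = cohort[name].to_numpy(float)
        if name in REVERSED_OUTCOMES:
            x = -x
        out[name] = _zscore(x, name)
    out["subjective_memory"] = cohort["subjective_memory"].astype(int).to_numpy()

    q = float(out["subjective_memory"].mean())
    return PreparedCohort(df=out, q=q, log=log)


def _wald_ci(beta: float, se: float) -> tuple[float, float]:
    z = norm.ppf(0.975)
    return beta - z * se, beta + z * se


def _fit_logistic(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Logistic ML via statsmodels; ridge-Newton fallback on separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(res.bse)) and np.max(np.abs(res.params)) < 50:
                return np.asarray(res.params), np.asarray(res.bse), True
        except Exception:
            pass
    beta, se, _ = ridge_logistic_fit(X, y, ridge=1e-4)
    return beta, se, False


def fit_association(
    prep: PreparedCohort,
    outcome: str,
    risk_factor: str,
    covariates: Sequence[str] = ("age", "female"),
    alpha: float = 0.05,
) -> AssociationResult:
    """One univariate association model, adjusted for the given covariates.

    Linear regression (standardized beta) for continuous outcomes,
    logistic regression (beta on the logit scale, OR = exp(beta) with
    Wald 95% CI) for binary outcomes.
    """
    df = prep.df
    for col in (outcome, risk_factor, *covariates):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not present in prepared cohort")
    y = df[outcome].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(df)), df[risk_factor].to_numpy(float)]
        + [df[c].to_numpy(float) for c in covariates]
    )
    binary_outcome = set(np.unique(y)) <= {0.0, 1.0}
    cov_label = "age_gender_depression" if "depression" in covariates else "age_gender"
    if binary_outcome:
        beta_vec, se_vec, ok = _fit_logistic(y, X)
        beta, se = float(beta_vec[1]), float(se_vec[1])
        z = beta / se
        p = 2 * norm.sf(abs(z))
        lo, hi = _wald_ci(beta, se)
        return AssociationResult(
            outcome, risk_factor, cov_label, "logistic", beta, se, z, p,
            math.exp(beta), math.exp(lo), math.exp(hi), alpha, p < alpha,
            converged=ok,
        )
    res = sm.OLS(y, X).fit()
    beta, se = float(res.params[1]), float(res.bse[1])
    if not np.isfinite(se) or se <= 0:
        raise ValueError(
            f"degenerate fit for {risk_factor!r} -> {outcome!r} (SE {se})"
        )
    t = beta / se
    p = float(res.pvalues[1])
    lo, hi = _wald_ci(beta, se)
    return AssociationResult(
        outcome, risk_factor, cov_label, "linear", beta, se, t, p,
        None, lo, hi, alpha, p < alpha,
    )


def descriptive_age_gender_models(prep: PreparedCohort) -> pd.DataFrame:
    """Age (+ quadratic) and gender models per cognitive outcome.

    Linear fits for the objective measures, logistic for the subjective
    item; one tidy row per term.
    """
    rows = []
    for outcome in prep.outcomes:
        y = prep.df[outcome].to_numpy(float)
        X = np.column_stack(
            [
                np.ones(prep.n),
                prep.df["age"].to_numpy(float),
                prep.df["age_sq"].to_numpy(float),
                prep.df["female"].to_numpy(float),
            ]
        )
        terms = ["intercept", "age", "age_sq", "female"]
        if outcome == "subjective_memory":
            beta, se, _ = _fit_logistic(y, X)
            family = "logistic"
        else:
            res = sm.OLS(y, X).fit()
            beta, se = np.asarray(res.params), np.asarray(res.bse)
            family = "linear"
        for i, term in enumerate(terms):
            z = beta[i] / se[i]
            lo, hi = _wald_ci(float(beta[i]), float(se[i]))
            rows.append(
                {
                    "outcome": outcome,
                    "term": term,
                    "family": family,
                    "beta": float(beta[i]),
                    "se": float(se[i]),
                    "t_or_z": float(z),
                    "p": float(2 * norm.sf(abs(z))),
                    "or_value": math.exp(float(beta[i])) if family == "logistic" else np.nan,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)


def _polyserial(cont: np.ndarray, binary: np.ndarray) -> float:
    """Two-step polyserial correlation of a continuous and a binary column.

    Threshold from the observed prevalence via the normal quantile, then
    the moment-based latent correlation r_pb * sqrt(p(1-p)) / phi(z_p).
    """
    p = float(binary.mean())
    if not 0 < p < 1:
        raise ValueError("binary column is constant")
    r_pb = float(np.corrcoef(cont, binary)[0, 1])
    z_p = norm.ppf(1 - p)
    return r_pb * math.sqrt(p * (1 - p)) / norm.pdf(z_p)


def correlate_measures(prep: PreparedCohort) -> pd.DataFrame:
    """Pairwise correlations among the four cognitive measures.

    Pearson for continuous pairs; for pairs involving the binary
    subjective item both the point-biserial and the two-step polyserial
    estimate are reported (the matrix-style summary uses the
    polyserial).
    """
    rows = []
    for i, a in enumerate(prep.outcomes):
        for b in prep.outcomes[i + 1:]:
            xa = prep.df[a].to_numpy(float)
            xb = prep.df[b].to_numpy(float)
            if a == "subjective_memory" or b == "subjective_memory":
                cont, bina = (xb, xa) if a == "subjective_memory" else (xa, xb)
                if np.std(cont) == 0:
                    raise ValueError("constant column in correlation")
                r_pb = float(np.corrcoef(cont, bina)[0, 1])
                rows.append(
                    {
                        "measure_a": a,
                        "measure_b": b,
                        "method": "polyserial",
                        "r": _polyserial(cont, bina),
                        "point_biserial": r_pb,
                    }
                )
            else:
                if np.std(xa) == 0 or np.std(xb) == 0:
                    raise ValueError("constant column in correlation")
                rows.append(
                    {
                        "measure_a": a,
                        "measure_b": b,
                        "method": "pearson",
                        "r": float(np.corrcoef(xa, xb)[0, 1]),
                        "point_biserial": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def binarize_objective(prep: PreparedCohort, q: Optional[float] = None) -> PreparedCohort:
    """Dichotomize the objective outcomes at the subjective-complaint rate.

    The worst ``round(q * n)`` participants on each (impairment-
    oriented) objective measure are flagged poor (value 1).  Ties at the
    boundary are broken by stable (score, participant order) sorting so
    the flagged count is exact and reproducible.  Adds columns
    ``<outcome>_poor``.
    """
    q = prep.q if q is None else q
    if not 0 <= q < 1:
        raise ValueError(f"quantile cut-off must be in [0, 1), got {q}")
    df = prep.df.copy()
    n = len(df)
    k = int(round(q * n))
    log = list(prep.log)
    for outcome in OBJECTIVE_OUTCOMES:
        scores = df[outcome].to_numpy(float)
        # stable argsort: worst (highest impairment) first, original order on ties
        order = np.argsort(-scores, kind="stable")
        flag = np.zeros(n, dtype=int)
        flag[order[:k]] = 1
        df[f"{outcome}_poor"] = flag
        n_ties = int(np.sum(scores == scores[order[k - 1]])) if k > 0 else 0
        if n_ties > 1:
            log.append(
                f"{outcome}: {n_ties} scores tied at the binarization boundary; "
                "stable participant-order tie-break applied"
            )
    return PreparedCohort(df=df, q=prep.q, continuous=prep.continuous,
                          binary=prep.binary, outcomes=prep.outcomes, log=log)


def _results_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    # sort by effect size within outcome, largest first
    return (
        df.sort_values(["outcome", "beta"], ascending=[True, False])
        .reset_index(drop=True)
    )


@dataclass
class SuiteResult:
    """A family of association models plus its Bonferroni rule."""

    results: pd.DataFrame
    alpha: float
    n_models: int
    binarized: Optional[pd.DataFrame] = None


def run_primary_suite(prep: PreparedCohort, factors: Sequence[str] = ALL_PREDICTORS) -> SuiteResult:
    """13 factors x 4 outcomes, age+gender adjusted, alpha = 0.05/13.

    Also fits the 13 x 3 logistic models on the binarized objective
    outcomes for OR comparability (reported separately).
    """
    alpha = 0.05 / len(factors)
    results = [
        fit_association(prep, outcome, factor, alpha=alpha)
        for outcome in prep.outcomes
        for factor in factors
    ]
    prep_bin = binarize_objective(prep)
    bin_results = [
        fit_association(prep_bin, f"{outcome}_poor", factor, alpha=alpha)
        for outcome in OBJECTIVE_OUTCOMES
        for factor in factors
    ]
    return SuiteResult(
        results=_results_frame(results),
        alpha=alpha,
        n_models=len(results),
        binarized=_results_frame(bin_results),
    )


def run_depression_adjusted(prep: PreparedCohort) -> SuiteResult:
    """12 factors x 4 outcomes, additionally adjusted for depression."""
    factors = [f for f in ALL_PREDICTORS if f != "depression"]
    alpha = 0.05 / len(ALL_PREDICTORS)
    results = [
        fit_association(prep, outcome, factor,
                        covariates=("age", "female", "depression"), alpha=alpha)
        for outcome in prep.outcomes
        for factor in factors
    ]
    return SuiteResult(results=_results_frame(results), alpha=alpha, n_models=len(results))


def significant_pairs(suite: SuiteResult) -> list[tuple[str, str]]:
    """(risk_factor, outcome) pairs significant in a suite's main results."""
    sig = suite.results[suite.results["significant"]]
    return list(zip(sig["risk_factor"], sig["outcome"]))


def run_age_interaction_suite(
    prep: PreparedCohort, pairs: Sequence[tuple[str, str]]
) -> SuiteResult:
    """Age x factor interaction models for previously significant pairs.

    alpha = 0.05 / number of pairs; an empty pair set yields an empty
    table.
    """
    if len(pairs) == 0:
        empty = pd.DataFrame(
            columns=[f.name for f in AssociationResult.__dataclass_fields__.values()]
        )
        return SuiteResult(results=empty, alpha=np.nan, n_models=0)
    alpha = 0.05 / len(pairs)
    rows = []
    df = prep.df
    for factor, outcome in pairs:
        y = df[outcome].to_numpy(float)
        x = df[factor].to_numpy(float)
        age = df["age"].to_numpy(float)
        X = np.column_stack(
            [np.ones(len(df)), x, age, df["female"].to_numpy(float), age * x]
        )
        binary_outcome = set(np.unique(y)) <= {0.0, 1.0}
        if binary_outcome:
            beta_vec, se_vec, ok = _fit_logistic(y, X)
            family = "logistic"
        else:
            res = sm.OLS(y, X).fit()
            beta_vec, se_vec, ok = np.asarray(res.params), np.asarray(res.bse), True
            family = "linear"
        beta, se = float(beta_vec[-1]), float(se_vec[-1])
        z = beta / se
        p = 2 * norm.sf(abs(z))
        lo, hi = _wald_ci(beta, se)
        rows.append(
            AssociationResult(
                outcome, factor, "age_gender", family, beta, se, z, p,
                math.exp(beta) if family == "logistic" else None,
                math.exp(lo) if family == "logistic" else lo,
                math.exp(hi) if family == "logistic" else hi,
                alpha, p < alpha, term="age_x_factor", converged=ok,
            )
        )
    return SuiteResult(results=_results_frame(rows), alpha=alpha, n_models=len(rows))
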