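"""Seeded synthetic cohorts for the risk-factor / cognition association suite.

Emulates a cross-sectional smartphone cohort (N ~ 3327, age 18-84) with
13 self-report dementia risk factors, a binary subjective-memory item,
and three latent objective cognition variables (visual working memory,
cognitive flexibility, model-based planning).  Defaults reproduce the
study conditions: published marginal means/SDs/prevalences, a 40.5%
subjective-complaint prevalence, weak objective-subjective correlations,
and the published standardized age+gender-adjusted effect of each risk
factor on each cognitive outcome.

Effect injection is calibrated so that the *univariate* association
models fitted downstream (one factor at a time, adjusted for age and
gender, with continuous predictors z-scored and binary predictors coded
0/2) recover the injected standardized coefficients:

* linear outcomes — the factor weights ``w`` solve ``C w = diag(Var u) t``
  against the sample covariance ``C`` of the observed (coded) predictors,
  so each marginal projection coefficient equals its target ``t_j``;
* the binary subjective outcome — same idea on the logit scale, with a
  fixed-point inflation for the attenuation caused by omitted predictor
  heterogeneity in marginal logistic fits (the 16*sqrt(3)/(15*pi)
  logistic-probit moment approximation).

All randomness flows from one ``numpy`` ``SeedSequence`` split into named
per-variable streams, so marginals are reproducible even when effect
configurations change.
"""

from __future__ import annotations

import hashlib
import json
import math
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import optimize, stats
from scipy.special import expit, ndtri

__all__ = [
    "ContinuousMarginal",
    "EffectSpec",
    "generate_cohort",
    "attach_task_traits",
    "write_cohort",
    "CONTINUOUS_FACTORS",
    "BINARY_FACTORS",
    "RISK_FACTORS",
    "OBJECTIVE_OUTCOMES",
    "OUTCOMES",
]

# squared moment-matching constant for expit(x) ~ Phi(c * x)
_C2 = (16.0 * math.sqrt(3.0) / (15.0 * math.pi)) ** 2


class ContinuousMarginal(BaseModel):
    """Target mean/SD and admissible range of a bounded ordinal/continuous scale."""

    mean: float
    sd: float = Field(gt=0)
    low: float
    high: float
    integer: bool = True

    @model_validator(mode="after")
    def _ordered(self) -> "ContinuousMarginal":
        if not self.low < self.high:
            raise ValueError("marginal range must satisfy low < high")
        return self


#: scale totals; descriptive targets for the default cohort
CONTINUOUS_FACTORS: dict[str, ContinuousMarginal] = {
    "education": ContinuousMarginal(mean=2.82, sd=1.00, low=0, high=5),
    "ses": ContinuousMarginal(mean=5.95, sd=1.77, low=1, high=10),
    "depression": ContinuousMarginal(mean=17.96, sd=13.59, low=0, high=60),
    "loneliness": ContinuousMarginal(mean=21.10, sd=15.54, low=0, high=60),
    "social_network": ContinuousMarginal(mean=15.96, sd=6.46, low=0, high=30),
    "hearing_handicap": ContinuousMarginal(mean=5.60, sd=7.47, low=0, high=40),
    "exercise": ContinuousMarginal(mean=32.70, sd=25.48, low=0, high=119),
}

#: yes/no items with their default cohort prevalences
BINARY_FACTORS: dict[str, float] = {
    "tinnitus": 0.298,
    "stroke": 0.014,
    "diabetes": 0.052,
    "hypertension": 0.154,
    "smoking": 0.341,
    "family_history": 0.168,
}

RISK_FACTORS: tuple[str, ...] = tuple(CONTINUOUS_FACTORS) + tuple(BINARY_FACTORS)

#: scales whose natural direction is protective; the analysis stage
#: reverse-codes them so higher = risk, and injected effects are stated
#: on that reversed orientation
REVERSED_PREDICTORS: tuple[str, ...] = ("education", "ses", "social_network", "exercise")

OBJECTIVE_OUTCOMES: tuple[str, ...] = (
    "visual_working_memory",
    "cognitive_flexibility",
    "model_based_index",
)
OUTCOMES: tuple[str, ...] = OBJECTIVE_OUTCOMES + ("subjective_memory",)

# Default injected standardized effects of each risk factor on each outcome,
# all on the "higher = worse / higher risk" orientation used by the analysis
# stage (age+gender-adjusted univariate coefficients; logit scale for the
# subjective item).  Binary-factor coefficients are per unit of the 0/2 coding.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "depression":       {"visual_working_memory": 0.15, "cognitive_flexibility": 0.11, "model_based_index": 0.07, "subjective_memory": 0.60},
    "ses":              {"visual_working_memory": 0.06, "cognitive_flexibility": 0.08, "model_based_index": 0.06, "subjective_memory": 0.50},
    "hearing_handicap": {"visual_working_memory": 0.04, "cognitive_flexibility": 0.06, "model_based_index": 0.00, "subjective_memory": 0.46},
    "loneliness":       {"visual_working_memory": 0.07, "cognitive_flexibility": 0.06, "model_based_index": 0.03, "subjective_memory": 0.42},
    "education":        {"visual_working_memory": 0.16, "cognitive_flexibility": 0.14, "model_based_index": 0.12, "subjective_memory": 0.33},
    "exercise":         {"visual_working_memory": 0.02, "cognitive_flexibility": 0.04, "model_based_index": 0.03, "subjective_memory": 0.34},
    "smoking":          {"visual_working_memory": 0.06, "cognitive_flexibility": 0.07, "model_based_index": 0.03, "subjective_memory": 0.29},
    "tinnitus":         {"visual_working_memory": 0.01, "cognitive_flexibility": -0.01, "model_based_index": -0.03, "subjective_memory": 0.28},
    "social_network":   {"visual_working_memory": 0.06, "cognitive_flexibility": 0.07, "model_based_index": 0.03, "subjective_memory": 0.24},
    "stroke":           {"visual_working_memory": 0.24, "cognitive_flexibility": 0.40, "model_based_index": 0.06, "subjective_memory": 0.61},
    "family_history":   {"visual_working_memory": -0.02, "cognitive_flexibility": 0.00, "model_based_index": 0.00, "subjective_memory": 0.11},
    "diabetes":         {"visual_working_memory": 0.12, "cognitive_flexibility": 0.09, "model_based_index": 0.01, "subjective_memory": 0.17},
    "hypertension":     {"visual_working_memory": 0.09, "cognitive_flexibility": 0.09, "model_based_index": 0.02, "subjective_memory": 0.07},
}

# age (linear, quadratic) and gender (cis-female vs cis-male reference)
# effects on the impairment-oriented outcomes; subjective effects on the
# logit scale.
DEFAULT_AGE_EFFECTS: dict[str, tuple[float, float]] = {
    "visual_working_memory": (0.20, 0.07),
    "cognitive_flexibility": (0.34, 0.13),
    "model_based_index": (0.09, 0.07),
    "subjective_memory": (0.09, 0.00),
}
DEFAULT_GENDER_EFFECTS: dict[str, float] = {
    "visual_working_memory": 0.00,
    "cognitive_flexibility": -0.04,
    "model_based_index": 0.05,
    "subjective_memory": math.log(1.24),
}

# target total correlations among impairment-oriented objective outcomes
DEFAULT_OUTCOME_CORR: dict[frozenset, float] = {
    frozenset(("visual_working_memory", "cognitive_flexibility")): 0.45,
    frozenset(("visual_working_memory", "model_based_index")): 0.26,
    frozenset(("cognitive_flexibility", "model_based_index")): 0.15,
}


class EffectSpec(BaseModel):
    """Complete configuration of one synthetic cohort."""

    n: int = Field(default=3327, ge=0)
    seed: int = 0
    marginals: dict[str, ContinuousMarginal] = Field(
        default_factory=lambda: dict(CONTINUOUS_FACTORS)
    )
    prevalences: dict[str, float] = Field(default_factory=lambda: dict(BINARY_FACTORS))
    effects: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {f: dict(v) for f, v in DEFAULT_EFFECTS.items()}
    )
    age_effects: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_AGE_EFFECTS)
    )
    gender_effects: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_GENDER_EFFECTS)
    )
    subjective_prevalence: float = 0.405
    factor_correlation: float = Field(default=0.10, ge=0.0, lt=1.0)
    outcome_residual_corr: dict[str, float] = Field(
        default_factory=lambda: {
            "visual_working_memory:cognitive_flexibility": 0.45,
            "visual_working_memory:model_based_index": 0.26,
            "cognitive_flexibility:model_based_index": 0.15,
        }
    )
    noise_sd: Optional[dict[str, float]] = None
    prop_female: float = Field(default=0.663, gt=0.0, lt=1.0)
    age_mean: float = 45.74
    age_sd: float = Field(default=14.55, gt=0)
    age_range: tuple[float, float] = (18.0, 84.0)
    mb_index_mean: float = 0.27
    mb_index_sd: float = Field(default=0.33, gt=0)

    @model_validator(mode="after")
    def _validate(self) -> "EffectSpec":
        if not 0.0 < self.subjective_prevalence < 1.0:
            raise ValueError("subjective_prevalence must be in (0, 1)")
        for name, p in self.prevalences.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence of {name!r} must be in (0, 1), got {p}")
        known = set(self.marginals) | set(self.prevalences)
        for factor, per_outcome in self.effects.items():
            if factor not in known:
                raise ValueError(f"effect key names unknown risk factor {factor!r}")
            for outcome in per_outcome:
                if outcome not in OUTCOMES:
                    raise ValueError(f"effect on unknown outcome {outcome!r}")
        if self.noise_sd is not None:
            for outcome, sd in self.noise_sd.items():
                if outcome not in OBJECTIVE_OUTCOMES:
                    raise ValueError(f"noise_sd key must be an objective outcome, got {outcome!r}")
                if sd < 0:
                    raise ValueError("noise_sd must be >= 0")
        return self

    @classmethod
    def null(cls, n: int = 3327, seed: int = 0, **kwargs) -> "EffectSpec":
        """Spec with every risk-factor, age, and gender effect set to zero."""
        payload = dict(
            n=n,
            seed=seed,
            effects={f: {o: 0.0 for o in OUTCOMES} for f in RISK_FACTORS},
            age_effects={o: (0.0, 0.0) for o in OUTCOMES},
            gender_effects={o: 0.0 for o in OUTCOMES},
        )
        payload.update(kwargs)
        return cls(**payload)

    def factor_names(self) -> tuple[str, ...]:
        return tuple(self.marginals) + tuple(self.prevalences)

    def spec_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    if len(x) < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _effect_vector(spec: EffectSpec, outcome: str) -> np.ndarray:
    return np.array(
        [spec.effects.get(f, {}).get(outcome, 0.0) for f in spec.factor_names()], float
    )


def _design_columns(cohort: pd.DataFrame, spec: EffectSpec) -> np.ndarray:
    """Predictors as they enter the association models: oriented so higher
    = risk, continuous z-scored, binary coded 0/2 (centered here;
    centering only shifts intercepts)."""
    cols = []
    for name in spec.marginals:
        x = cohort[name].to_numpy(float)
        if name in REVERSED_PREDICTORS:
            x = -x
        cols.append(_zscore(x))
    for name in spec.prevalences:
        u = 2.0 * cohort[name].to_numpy(float)
        cols.append(u - u.mean())
    return np.column_stack(cols) if cols else np.empty((len(cohort), 0))


def _solve_linear_weights(C: np.ndarray, var_u: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Weights w with marginal projection coefficient (Cw)_j / Var(u_j) = t_j."""
    if np.allclose(targets, 0.0):
        return np.zeros_like(targets)
    rhs = targets * var_u
    try:
        return np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(C, rhs, rcond=None)[0]


def _solve_logit_weights(
    C: np.ndarray, var_u: np.ndarray, targets: np.ndarray, n_iter: int = 60
) -> np.ndarray:
    """Fixed-point inflation so *marginal* logistic ML coefficients hit targets.

    A marginal logistic fit of y on one predictor (plus independent
    covariates) attenuates the conditional coefficient by roughly
    1 / sqrt(1 + c^2 * s^2) where s^2 is the variance of the omitted
    linear predictor (Zeger-Liang moment approximation).  Iterate
    eta_j = t_j * sqrt(1 + c^2 * s_j^2) to invert that attenuation.
    """
    if np.allclose(targets, 0.0):
        return np.zeros_like(targets)
    eta = targets.copy()
    w = _solve_linear_weights(C, var_u, eta)
    for _ in range(n_iter):
        lp_var = float(w @ C @ w)
        s2 = np.maximum(lp_var - eta**2 * var_u, 0.0)
        eta_new = targets * np.sqrt(1.0 + _C2 * s2)
        w_new = _solve_linear_weights(C, var_u, eta_new)
        if np.max(np.abs(eta_new - eta)) < 1e-12:
            w = w_new
            break
        eta, w = eta_new, w_new
    return w


def _refine_logit_weights(
    U: np.ndarray,
    C: np.ndarray,
    var_u: np.ndarray,
    targets: np.ndarray,
    covariate_lp: np.ndarray,
    model_covariates: np.ndarray,
    q: float,
    w0: np.ndarray,
    n_outer: int = 10,
    tol: float = 5e-4,
) -> np.ndarray:
    """Sharpen the logit weights on the realized sample.

    The moment fixed point leaves a small residual attenuation bias.
    Here the *exact* large-sample marginal coefficient on this sample is
    computed by fitting each univariate logistic model to the true
    per-subject probabilities (a fractional-response fit has the same
    score expectation as the realized Bernoulli responses), and the
    calibrated projection coefficients are rescaled until every marginal
    coefficient matches its target.
    """
    from .mb_index import ridge_logistic_fit

    n = U.shape[0]
    nz = targets != 0.0
    if not nz.any():
        return w0
    eta = targets.copy()
    w = w0.copy()
    ones = np.ones(n)
    for _ in range(n_outer):
        lp = U @ w + covariate_lp
        a0 = optimize.brentq(lambda a: float(expit(a + lp).mean()) - q, -30.0, 30.0)
        pi = expit(a0 + lp)
        m = np.zeros_like(targets)
        for j in np.flatnonzero(nz):
            X = np.column_stack([ones, U[:, j], model_covariates])
            m[j] = ridge_logistic_fit(X, pi, ridge=1e-8)[0][1]
        if np.max(np.abs(m[nz] - targets[nz])) < tol:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(nz & (m != 0), targets / m, 1.0)
        eta = eta * np.clip(ratio, 0.5, 2.0)
        w = _solve_linear_weights(C, var_u, eta)
    return w


def _residual_noise(
    spec: EffectSpec,
    rngs: Mapping[str, np.random.Generator],
    lps: dict[str, np.ndarray],
    n: int,
) -> dict[str, np.ndarray]:
    """Correlated Gaussian residuals for the three objective outcomes.

    Residual SDs top the latent outcomes up to unit variance (unless
    overridden); residual correlations are chosen so the *total*
    correlations among the impairment latents approach the configured
    targets, clipped into a PD-feasible range.
    """
    sigmas = {}
    for o in OBJECTIVE_OUTCOMES:
        if spec.noise_sd is not None and o in spec.noise_sd:
            sigmas[o] = spec.noise_sd[o]
        else:
            lp_var = float(np.var(lps[o], ddof=1)) if n > 1 else 0.0
            sigmas[o] = math.sqrt(max(1.0 - lp_var, 0.05))
    R = np.eye(3)
    for i, oi in enumerate(OBJECTIVE_OUTCOMES):
        for j, oj in enumerate(OBJECTIVE_OUTCOMES):
            if i >= j:
                continue
            key = f"{oi}:{oj}"
            target = spec.outcome_residual_corr.get(
                key, spec.outcome_residual_corr.get(f"{oj}:{oi}", 0.0)
            )
            if sigmas[oi] == 0 or sigmas[oj] == 0:
                r = 0.0
            else:
                struct = float(np.cov(lps[oi], lps[oj], ddof=1)[0, 1]) if n > 1 else 0.0
                r = (target - struct) / (sigmas[oi] * sigmas[oj])
            R[i, j] = R[j, i] = float(np.clip(r, -0.95, 0.95))
    # guard positive definiteness (possible under extreme user configs)
    evals, evecs = np.linalg.eigh(R)
    if evals.min() < 1e-6:
        evals = np.clip(evals, 1e-6, None)
        R = evecs @ np.diag(evals) @ evecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    L = np.linalg.cholesky(R)
    z = rngs["noise"].standard_normal((n, 3)) @ L.T
    return {
        o: z[:, i] * sigmas[o] for i, o in enumerate(OBJECTIVE_OUTCOMES)
    }


def generate_cohort(spec: EffectSpec) -> pd.DataFrame:
    """Generate one synthetic cohort table (one row per participant).

    Deterministic for a fixed spec+seed.  Columns: participant_id, age,
    gender, the 13 risk-factor scales on their natural ranges, the three
    objective cognition columns in their natural orientations
    (``visual_working_memory`` higher = better, ``cognitive_flexibility``
    time-like higher = worse, ``model_based_index`` on the planning-index
    scale, higher = better), and the 0/1 ``subjective_memory`` item.
    """
    n = spec.n
    factor_names = list(spec.factor_names())
    stream_names = (
        ["age", "gender", "copula_common", "noise", "subjective"]
        + [f"factor:{name}" for name in factor_names]
    )
    rngs = _streams(spec.seed, stream_names)

    lo, hi = spec.age_range
    a, b = (lo - spec.age_mean) / spec.age_sd, (hi - spec.age_mean) / spec.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rngs["age"]
    )
    age = np.round(age).astype(int)
    female = (rngs["gender"].random(n) < spec.prop_female).astype(int)

    # exchangeable Gaussian copula over the risk-factor latents
    rho = spec.factor_correlation
    common = rngs["copula_common"].standard_normal(n)
    cohort = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:05d}" for i in range(n)],
            "age": age,
            "gender": np.where(female == 1, "cis_female", "cis_male"),
        }
    )
    for name in factor_names:
        z = math.sqrt(rho) * common + math.sqrt(1.0 - rho) * rngs[
            f"factor:{name}"
        ].standard_normal(n)
        if name in spec.marginals:
            marg = spec.marginals[name]
            x = marg.mean + marg.sd * z
            if marg.integer:
                x = np.round(x)
            cohort[name] = np.clip(x, marg.low, marg.high)
        else:
            thresh = ndtri(1.0 - spec.prevalences[name])
            cohort[name] = (z > thresh).astype(int)

    if n == 0:
        for o in OBJECTIVE_OUTCOMES:
            cohort[o] = pd.Series(dtype=float)
        cohort["subjective_memory"] = pd.Series(dtype=int)
        return cohort

    age_z = _zscore(age)
    age2_z = _zscore(age_z**2)
    female_c = female - female.mean()

    U = _design_columns(cohort, spec)
    inject = n > len(factor_names) + 2
    if inject:
        C = np.cov(U, rowvar=False, ddof=1)
        var_u = np.diag(C).copy()
    lps: dict[str, np.ndarray] = {}
    for o in OBJECTIVE_OUTCOMES:
        t = _effect_vector(spec, o)
        w = _solve_linear_weights(C, var_u, t) if inject else np.zeros(len(factor_names))
        a1, a2 = spec.age_effects.get(o, (0.0, 0.0))
        g = spec.gender_effects.get(o, 0.0)
        lps[o] = U @ w + a1 * age_z + a2 * age2_z + g * female_c

    eps = _residual_noise(spec, rngs, lps, n)
    impair = {o: lps[o] + eps[o] for o in OBJECTIVE_OUTCOMES}

    # subjective item: logistic in the coded predictors, intercept calibrated
    # so the expected prevalence equals the target exactly on this sample
    t_subj = _effect_vector(spec, "subjective_memory")
    a1, a2 = spec.age_effects.get("subjective_memory", (0.0, 0.0))
    g = spec.gender_effects.get("subjective_memory", 0.0)
    cov_lp = a1 * age_z + a2 * age2_z + g * female_c
    q = spec.subjective_prevalence
    if inject:
        w_subj = _solve_logit_weights(C, var_u, t_subj)
        w_subj = _refine_logit_weights(
            U, C, var_u, t_subj, cov_lp,
            np.column_stack([age_z, female_c]), q, w_subj,
        )
    else:
        w_subj = np.zeros(len(factor_names))
    lp_subj = U @ w_subj + cov_lp

    def prevalence_gap(intercept: float) -> float:
        return float(expit(intercept + lp_subj).mean()) - q

    a0 = optimize.brentq(prevalence_gap, -30.0, 30.0)
    cohort["subjective_memory"] = (
        rngs["subjective"].random(n) < expit(a0 + lp_subj)
    ).astype(int)

    # natural-orientation display columns
    cohort["visual_working_memory"] = -impair["visual_working_memory"]
    cohort["cognitive_flexibility"] = impair["cognitive_flexibility"]
    cohort["model_based_index"] = (
        spec.mb_index_mean - spec.mb_index_sd * impair["model_based_index"]
    )
    return cohort


def attach_task_traits(cohort: pd.DataFrame, spec: EffectSpec) -> pd.DataFrame:
    """Attach standardized impairment-oriented latent traits.

    ``wm_trait``, ``flex_trait`` and ``mb_trait`` are z-scored versions of
    the latent cognition columns, all oriented so that *higher = worse
    cognition* (the analysis stage's global convention).  They drive the
    trial-level task simulators.
    """
    out = cohort.copy()
    out["wm_trait"] = _zscore(-cohort["visual_working_memory"].to_numpy(float))
    out["flex_trait"] = _zscore(cohort["cognitive_flexibility"].to_numpy(float))
    out["mb_trait"] = _zscore(-cohort["model_based_index"].to_numpy(float))
    return out


def write_cohort(cohort: pd.DataFrame, path, spec: EffectSpec) -> None:
    """Write the cohort CSV plus a sidecar JSON recording seed and spec hash."""
    from pathlib import Path

    path = Path(path)
    cohort.to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "seed": spec.seed,
        "n": spec.n,
        "spec_hash": spec.spec_hash(),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=2) + "\n")
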