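"""Preparation rules, association models, suites, binarization, correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from cogrisk import (
    EffectSpec,
    binarize_objective,
    correlate_measures,
    descriptive_age_gender_models,
    fit_association,
    generate_cohort,
    prepare,
    run_age_interaction_suite,
    run_depression_adjusted,
    run_primary_suite,
    significant_pairs,
)
from cogrisk.associations import (
    ALL_OUTCOMES,
    ALL_PREDICTORS,
    BINARY_PREDICTORS,
    CONTINUOUS_PREDICTORS,
    PreparedCohort,
)
from cogrisk.associations import _polyserial  # noqa: used as an internal oracle hook


def toy_cohort(n=600, seed=0):
    """Hand-assembled cohort frame with independent columns."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "age": rng.integers(18, 85, n),
            "gender": rng.choice(["cis_male", "cis_female"], n),
            "education": rng.integers(0, 6, n),
            "ses": rng.integers(1, 11, n),
            "depression": rng.integers(0, 61, n),
            "loneliness": rng.integers(0, 61, n),
            "social_network": rng.integers(0, 31, n),
            "hearing_handicap": rng.integers(0, 41, n),
            "exercise": rng.integers(0, 120, n),
            "tinnitus": rng.integers(0, 2, n),
            "stroke": rng.integers(0, 2, n),
            "diabetes": rng.integers(0, 2, n),
            "hypertension": rng.integers(0, 2, n),
            "smoking": rng.integers(0, 2, n),
            "family_history": rng.integers(0, 2, n),
            "visual_working_memory": rng.standard_normal(n),
            "cognitive_flexibility": rng.standard_normal(n),
            "model_based_index": rng.standard_normal(n),
            "subjective_memory": rng.integers(0, 2, n),
        }
    )
    return df


class TestPrepare:
    def test_continuous_standardized(self, default_prep):
        df = default_prep.df
        for name in CONTINUOUS_PREDICTORS + ("visual_working_memory",
                                             "cognitive_flexibility",
                                             "model_based_index", "age"):
            assert abs(df[name].mean()) < 1e-10
            assert abs(df[name].std(ddof=1) - 1) < 1e-10

    def test_binaries_zero_two(self, default_prep):
        for name in BINARY_PREDICTORS:
            assert set(default_prep.df[name].unique()) <= {0.0, 2.0}

    def test_balanced_binary_sd_is_one(self):
        c = toy_cohort(2000, seed=1)
        c["smoking"] = np.tile([0, 1], 1000)  # exactly p = 0.5
        prep = prepare(c)
        assert prep.df["smoking"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_unbalanced_binary_sd_documents_discrepancy(self):
        # at p = 0.405 the 0/2 coding gives SD 2*sqrt(p(1-p)) ~ 0.982, not 1
        c = toy_cohort(1000, seed=2)
        flags = np.zeros(1000, int)
        flags[:405] = 1
        c["tinnitus"] = flags
        prep = prepare(c)
        expected = 2 * math.sqrt(0.405 * 0.595)
        assert prep.df["tinnitus"].std(ddof=0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9819, abs=2e-4)
        assert any("tinnitus" in line and "deviates" in line for line in prep.log)

    def test_orientation_reversal(self):
        c = toy_cohort(500, seed=3)
        prep = prepare(c)
        # education is protective: prepared column anti-correlates with raw
        r = np.corrcoef(prep.df["education"], c["education"])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)
        # working-memory display column is performance: also reversed
        r2 = np.corrcoef(prep.df["visual_working_memory"], c["visual_working_memory"])[0, 1]
        assert r2 == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_named_in_error(self):
        c = toy_cohort(200, seed=4)
        c["stroke"] = 0
        with pytest.raises(ValueError, match="stroke"):
            prepare(c)

    def test_missing_values_rejected(self):
        c = toy_cohort(100, seed=5)
        c.loc[3, "ses"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            prepare(c)

    def test_prevalence_recorded(self, default_prep):
        assert default_prep.q == pytest.approx(
            default_prep.df["subjective_memory"].mean()
        )


class TestFitAssociation:
    def test_standardized_beta_invariant_to_predictor_scale(self):
        c = toy_cohort(800, seed=6)
        r1 = fit_association(prepare(c), "cognitive_flexibility", "loneliness")
        c2 = c.copy()
        c2["loneliness"] = c2["loneliness"] * 3.7
        r2 = fit_association(prepare(c2), "cognitive_flexibility", "loneliness")
        assert r1.beta == pytest.approx(r2.beta, abs=1e-8)

    def test_duplication_halves_se(self, default_prep):
        r1 = fit_association(default_prep, "visual_working_memory", "depression")
        doubled = PreparedCohort(
            df=pd.concat([default_prep.df] * 2, ignore_index=True),
            q=default_prep.q,
        )
        r2 = fit_association(doubled, "visual_working_memory", "depression")
        assert r2.beta == pytest.approx(r1.beta, abs=1e-10)
        assert r2.se == pytest.approx(r1.se / math.sqrt(2), rel=0.02)

    def test_or_equals_exp_beta(self, default_prep):
        r = fit_association(default_prep, "subjective_memory", "depression")
        assert r.or_value == pytest.approx(math.exp(r.beta), rel=1e-12)
        assert r.ci_low < r.or_value < r.ci_high

    def test_null_factor_beta_small(self):
        prep = prepare(generate_cohort(EffectSpec.null(n=2000, seed=42)))
        r = fit_association(prep, "cognitive_flexibility", "diabetes")
        assert abs(r.beta) < 3 * r.se


class TestBinarize:
    def test_exact_count_distinct_scores(self):
        c = toy_cohort(1000, seed=7)
        prep = prepare(c)
        out = binarize_objective(prep, q=0.405)
        for o in ("visual_working_memory", "cognitive_flexibility", "model_based_index"):
            assert out.df[f"{o}_poor"].sum() == 405

    def test_q_zero_flags_none(self, default_prep):
        out = binarize_objective(default_prep, q=0.0)
        assert out.df["visual_working_memory_poor"].sum() == 0

    def test_ties_broken_stably(self):
        c = toy_cohort(1000, seed=8)
        # 600 identical scores straddling the cut
        scores = np.concatenate([np.linspace(3, 4, 200), np.zeros(600), np.linspace(-4, -3, 200)])
        c["cognitive_flexibility"] = scores
        prep = prepare(c)
        out = binarize_objective(prep, q=0.405)
        flags = out.df["cognitive_flexibility_poor"]
        assert flags.sum() == 405
        assert any("tied" in line for line in out.log)
        # rerun is identical (stable tie-break)
        again = binarize_objective(prep, q=0.405)
        assert (again.df["cognitive_flexibility_poor"] == flags).all()

    def test_invalid_q_rejected(self, default_prep):
        with pytest.raises(ValueError):
            binarize_objective(default_prep, q=1.2)


class TestSuites:
    def test_primary_counts_and_alpha(self, default_prep):
        suite = run_primary_suite(default_prep)
        assert suite.n_models == 52
        assert len(suite.results) == 52
        assert len(suite.binarized) == 39
        assert round(suite.alpha, 4) == 0.0038
        assert set(suite.results["outcome"]) == set(ALL_OUTCOMES)
        # significance flags honor the family alpha
        flagged = suite.results["significant"]
        assert (flagged == (suite.results["p"] < suite.alpha)).all()

    def test_adjusted_excludes_depression(self, default_prep):
        suite = run_depression_adjusted(default_prep)
        assert suite.n_models == 48
        assert "depression" not in set(suite.results["risk_factor"])
        assert set(suite.results["covariates"]) == {"age_gender_depression"}

    def test_interaction_alpha_with_31_pairs(self, default_prep):
        pairs = [(f, o) for o in ALL_OUTCOMES for f in ALL_PREDICTORS][:31]
        suite = run_age_interaction_suite(default_prep, pairs)
        assert suite.n_models == 31
        assert round(suite.alpha, 4) == 0.0016

    def test_interaction_empty_pairs(self, default_prep):
        suite = run_age_interaction_suite(default_prep, [])
        assert suite.n_models == 0
        assert len(suite.results) == 0

    def test_all_null_suite_rarely_rejects(self):
        n_sig = 0
        for seed in range(6):
            prep = prepare(generate_cohort(EffectSpec.null(n=1200, seed=900 + seed)))
            n_sig += int(run_primary_suite(prep).results["significant"].sum())
        # expectation ~ 6 runs * 52 * 0.0038 ~ 1.2 significant results
        assert n_sig <= 5

    def test_adjustment_removes_mediated_effect(self):
        """A factor acting on cognition only through depression loses its
        association once depression enters the model."""
        rng = np.random.default_rng(12)
        n = 4000
        c = toy_cohort(n, seed=13)
        dep_latent = rng.standard_normal(n)
        c["loneliness"] = np.clip(
            np.round(30 + 10 * (0.7 * dep_latent + 0.71 * rng.standard_normal(n))), 0, 60
        )
        c["depression"] = np.clip(np.round(25 + 12 * dep_latent), 0, 60)
        c["cognitive_flexibility"] = 0.4 * dep_latent + rng.standard_normal(n)
        prep = prepare(c)
        unadj = fit_association(prep, "cognitive_flexibility", "loneliness")
        adj = fit_association(
            prep, "cognitive_flexibility", "loneliness",
            covariates=("age", "female", "depression"),
        )
        assert unadj.beta > 0.15
        assert abs(adj.beta) < 3 * adj.se

    def test_adjustment_leaves_independent_factor_alone(self):
        spec = EffectSpec(n=4000, seed=14, factor_correlation=0.0)
        prep = prepare(generate_cohort(spec))
        unadj = fit_association(prep, "visual_working_memory", "education")
        adj = fit_association(
            prep, "visual_working_memory", "education",
            covariates=("age", "female", "depression"),
        )
        assert adj.beta == pytest.approx(unadj.beta, abs=0.03)


class TestDescriptiveModels:
    def test_age_effect_recovered(self, full_prep):
        tab = descriptive_age_gender_models(full_prep)
        row = tab[(tab["outcome"] == "cognitive_flexibility") & (tab["term"] == "age")].iloc[0]
        assert abs(row["beta"] - 0.34) < 2 * row["se"]
        subj = tab[(tab["outcome"] == "subjective_memory") & (tab["term"] == "female")].iloc[0]
        assert subj["family"] == "logistic"
        assert np.isfinite(subj["or_value"])

    def test_quadratic_only_age_effect(self):
        spec = EffectSpec.null(
            n=6000, seed=15,
            age_effects={"visual_working_memory": (0.0, 0.30),
                         "cognitive_flexibility": (0.0, 0.0),
                         "model_based_index": (0.0, 0.0),
                         "subjective_memory": (0.0, 0.0)},
        )
        prep = prepare(generate_cohort(spec))
        tab = descriptive_age_gender_models(prep)
        wm = tab[tab["outcome"] == "visual_working_memory"].set_index("term")
        assert abs(wm.loc["age_sq", "beta"] - 0.30) < 2 * wm.loc["age_sq", "se"]
        assert abs(wm.loc["age", "beta"]) < 0.05


class TestCorrelations:
    def test_identical_columns_give_unity(self):
        c = toy_cohort(500, seed=16)
        c["cognitive_flexibility"] = -c["visual_working_memory"]  # same after orientation
        r = correlate_measures(prepare(c))
        row = r[(r["measure_a"] == "visual_working_memory")
                & (r["measure_b"] == "cognitive_flexibility")].iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-12)

    def test_independent_columns_near_zero(self):
        prep = prepare(toy_cohort(10_000, seed=17))
        r = correlate_measures(prep)
        assert (r["r"].abs() < 0.03).all()

    def test_polyserial_recovers_latent_correlation(self):
        rng = np.random.default_rng(18)
        n = 20_000
        x = rng.standard_normal(n)
        latent = 0.3 * x + math.sqrt(1 - 0.09) * rng.standard_normal(n)
        y = (latent > norm.ppf(1 - 0.405)).astype(int)
        r_ps = _polyserial(x, y)
        r_pb = float(np.corrcoef(x, y)[0, 1])
        assert r_ps == pytest.approx(0.3, abs=0.03)
        assert abs(r_pb) < abs(r_ps)  # point-biserial is attenuated
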