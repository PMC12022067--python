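"""Priors, the naive Bayes likelihood-ratio combiner, LRTS elimination,
and the Jaccard redundancy filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogdecline import (
    FeatureDefinition,
    ModelFeature,
    PrognosticModel,
    estimate_priors,
    fit_model,
    generate_cohort,
    jaccard_index,
    label_cohort,
    lrts_backward_elimination,
    model_log_likelihood,
    study_like_config,
    predict_label,
    redundancy_filter,
)
from cogdecline.errors import (
    ContractError,
    EstimationError,
    IndeterminateEvidenceError,
)
from cogdecline.model import AgeBracketPriors, LRTS_CRITICAL


def flag_def(name, source=None, group=None):
    return FeatureDefinition(name=name, source=source or name,
                             comparator="flag", hypothesis_group=group)


def single_bracket_priors(prior, n=100):
    d = int(round(prior * n))
    return AgeBracketPriors(
        brackets=[(30.0, 100.0)], n_per_bracket=[n], decliners_per_bracket=[d],
        overall_n=n, overall_decliners=d,
    )


def simple_model(prior, features):
    return PrognosticModel(priors=single_bracket_priors(prior),
                           features=features)


class TestPriors:
    def test_overall_prior_from_single_cohort(self):
        df = pd.DataFrame({"decline": [1] * 49 + [0] * 137,
                           "age_of_onset": 60.0})
        priors = estimate_priors(df)
        assert priors.overall_prior == pytest.approx(49 / 186)
        assert round(100 * priors.overall_prior) == 26

    def test_pooled_bracket_prior(self):
        a = pd.DataFrame({"decline": [1] * 5 + [0] * 3, "age_of_onset": 80.0})
        b = pd.DataFrame({"decline": [1] * 2 + [0] * 1, "age_of_onset": 77.0})
        priors = estimate_priors([a, b], brackets=[(75.0, 100.0)])
        assert priors.prior_per_bracket[0] == pytest.approx(7 / 11)
        assert round(priors.prior_per_bracket[0], 2) == 0.64

    def test_missing_age_counts_only_overall(self):
        df = pd.DataFrame(
            {"decline": [1, 0, 1, 0], "age_of_onset": [60.0, 60.0, None, None]}
        )
        priors = estimate_priors(df, brackets=[(55.0, 65.0)])
        assert priors.n_per_bracket == [2]
        assert priors.overall_n == 4
        assert priors.lookup(None) == pytest.approx(0.5)
        assert priors.lookup(60.0) == pytest.approx(0.5)

    def test_empty_bracket_falls_back(self):
        df = pd.DataFrame({"decline": [1, 0], "age_of_onset": [60.0, 61.0]})
        priors = estimate_priors(df, brackets=[(55.0, 65.0), (65.0, 75.0)])
        assert math.isnan(priors.prior_per_bracket[1])
        assert priors.lookup(70.0) == priors.overall_prior

    def test_no_subjects_is_error(self):
        with pytest.raises(EstimationError):
            estimate_priors(pd.DataFrame({"decline": [], "age_of_onset": []}))


class TestPosterior:
    def test_odds_arithmetic_worked_example(self):
        model = simple_model(
            0.27,
            [ModelFeature(flag_def("fainting"), 2.80, 0.97, "risk"),
             ModelFeature(flag_def("vocalization"), 2.70, 0.56, "risk")],
        )
        # independent odds arithmetic: (0.27/0.73 * 2.8 * 2.7) / (1 + ...)
        odds = 0.27 / 0.73 * 2.8 * 2.7
        expected = odds / (1 + odds)
        post = model.posterior(50.0, {"fainting": True, "vocalization": True})
        assert post == pytest.approx(expected)
        assert post == pytest.approx(0.7366, abs=5e-4)

    def test_no_evidence_returns_prior(self):
        model = simple_model(
            0.27, [ModelFeature(flag_def("fainting"), 2.80, 0.97, "risk")]
        )
        # risk-only feature contributes nothing when absent
        assert model.posterior(50.0, {"fainting": False}) == pytest.approx(0.27)

    @pytest.mark.parametrize("prior", [0.01, 0.27, 0.5, 0.99])
    def test_infinite_lr_forces_posterior_one(self, prior):
        model = simple_model(
            prior,
            [ModelFeature(flag_def("stroke"), float("inf"), 0.94, "risk")],
        )
        assert model.posterior(50.0, {"stroke": True}) == 1.0

    def test_zero_prior_with_infinite_lr_is_indeterminate(self):
        model = PrognosticModel(
            priors=single_bracket_priors(0.0),
            features=[ModelFeature(flag_def("stroke"), float("inf"), 0.94,
                                   "risk")],
        )
        assert model.posterior(50.0, {"stroke": False}) == 0.0
        with pytest.raises(IndeterminateEvidenceError):
            model.posterior(50.0, {"stroke": True})

    def test_unaligned_vector_is_contract_error(self):
        model = simple_model(
            0.3, [ModelFeature(flag_def("a"), 2.0, 0.5, "both")]
        )
        with pytest.raises(ContractError):
            model.posterior(50.0, [True, False])
        with pytest.raises(ContractError):
            model.posterior(50.0, {"b": True})

    def test_protective_feature_applies_when_absent(self):
        model = simple_model(
            0.5, [ModelFeature(flag_def("upsit_low"), 1.21, 0.27, "protective")]
        )
        assert model.posterior(50.0, {"upsit_low": True}) == pytest.approx(0.5)
        assert model.posterior(50.0, {"upsit_low": False}) == pytest.approx(
            0.27 / 1.27
        )

    @given(
        prior=st.floats(0.01, 0.99),
        lr1=st.floats(0.1, 50),
        lr2=st.floats(0.1, 50),
    )
    def test_posterior_monotone_in_prior_and_lr(self, prior, lr1, lr2):
        lo, hi = sorted([lr1, lr2])
        f_lo = [ModelFeature(flag_def("f"), lo, 0.5, "risk")]
        f_hi = [ModelFeature(flag_def("f"), hi, 0.5, "risk")]
        m_lo = simple_model(prior, f_lo)
        m_hi = simple_model(prior, f_hi)
        assert m_hi.posterior(50.0, {"f": True}) >= m_lo.posterior(
            50.0, {"f": True}
        )
        m2 = simple_model(min(prior + 0.2, 0.99), f_lo)
        assert m2.posterior(50.0, {"f": True}) >= m_lo.posterior(
            50.0, {"f": True}
        )

    @pytest.mark.parametrize(
        "posterior, expected", [(0.50, True), (0.4999, False), (1.0, True),
                                (0.0, False)]
    )
    def test_predict_label_inclusive_cutoff(self, posterior, expected):
        assert predict_label(posterior, 0.5) is expected


class TestNaiveBayesOracle:
    def test_equals_enumerated_joint_bayes(self):
        """With class-conditionally independent features and role='both',
        the sequential LR combiner must equal the exact Bayes posterior from
        the enumerated joint distribution (spot check; the acceptance suite
        runs 1000 random configurations)."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = rng.integers(1, 4)
            prior = rng.uniform(0.05, 0.95)
            sens = rng.uniform(0.05, 0.95, m)
            spec = rng.uniform(0.05, 0.95, m)
            pattern = rng.random(m) < 0.5
            features = [
                ModelFeature(
                    flag_def(f"f{i}"),
                    sens[i] / (1 - spec[i]),
                    (1 - sens[i]) / spec[i],
                    "both",
                )
                for i in range(m)
            ]
            model = simple_model(prior, features)
            prior = model.priors.lookup(50.0)  # count-quantized prior
            post = model.posterior(50.0, list(pattern))
            like1 = np.prod(np.where(pattern, sens, 1 - sens))
            like0 = np.prod(np.where(pattern, 1 - spec, spec))
            exact = prior * like1 / (prior * like1 + (1 - prior) * like0)
            assert post == pytest.approx(exact, abs=1e-12)


class TestLogLikelihoodAndLRTS:
    def test_closed_forms(self):
        model = simple_model(0.5, [])
        df = pd.DataFrame({"decline": [0, 1] * 10, "age_of_onset": 50.0})
        assert model_log_likelihood(model, df) == pytest.approx(
            -20 * math.log(2)
        )

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "decline": rng.integers(0, 2, 30),
                "age_of_onset": 50.0,
                "f": rng.integers(0, 2, 30).astype(float),
            }
        )
        model = simple_model(
            0.4, [ModelFeature(flag_def("f"), 2.5, 0.6, "both")]
        )
        p = model.predict_proba(df)
        expected = sum(
            math.log(pi if yi else 1 - pi)
            for pi, yi in zip(p, df["decline"].astype(bool))
        )
        assert model_log_likelihood(model, df) == pytest.approx(expected)

    def test_null_feature_removed_first(self):
        rng = np.random.default_rng(4)
        n = 400
        decline = rng.random(n) < 0.3
        strong = np.where(decline, rng.random(n) < 0.6, rng.random(n) < 0.1)
        df = pd.DataFrame(
            {
                "decline": decline.astype(int),
                "age_of_onset": 50.0,
                "null_f": rng.integers(0, 2, n).astype(float),
                "strong_f": strong.astype(float),
            }
        )
        model = simple_model(
            0.3,
            [
                ModelFeature(flag_def("null_f"), 1.0, 1.0, "both"),
                ModelFeature(flag_def("strong_f"), 6.0, 0.45, "both"),
            ],
        )
        reduced, trace = lrts_backward_elimination(model, df)
        step0 = trace[trace["step"] == 0].set_index("feature")
        assert step0.loc["null_f", "lrts"] == pytest.approx(0.0, abs=1e-9)
        assert step0.loc["null_f", "removed"]
        assert reduced.feature_names == ["strong_f"]

    def test_reduces_to_prior_only_model(self):
        df = pd.DataFrame(
            {"decline": [1, 0, 1, 0] * 10, "age_of_onset": 50.0,
             "f": [0.0, 0.0, 0.0, 0.0] * 10}
        )
        model = simple_model(0.5, [ModelFeature(flag_def("f"), 1.2, 0.9,
                                                "both")])
        reduced, _ = lrts_backward_elimination(model, df)
        assert reduced.features == []
        assert reduced.predict_proba(df.head(3)) == pytest.approx(
            [0.5, 0.5, 0.5]
        )

    def test_critical_value(self):
        assert LRTS_CRITICAL == pytest.approx(3.841, abs=5e-4)


class TestJaccard:
    def test_identity_and_disjoint(self):
        a = np.array([1, 1, 0, 0], bool)
        assert jaccard_index(a, a) == 1.0
        assert jaccard_index(a, ~a) == 0.0
        assert jaccard_index(np.zeros(4, bool), np.zeros(4, bool)) == 0.0

    def test_half_overlap_is_kept_at_threshold(self):
        """J = 0.5 exactly: 3 co-present, 3 present in exactly one — not
        removed at threshold 0.5 (strictly greater than)."""
        f1 = np.array([1, 1, 1, 1, 1, 0, 0, 0], bool)
        f2 = np.array([1, 1, 1, 0, 0, 1, 0, 0], bool)
        assert jaccard_index(f1, f2) == pytest.approx(0.5)
        df = pd.DataFrame(
            {
                "decline": [1, 1, 1, 0, 0, 1, 0, 0],
                "age_of_onset": 50.0,
                "a": f1.astype(float),
                "b": f2.astype(float),
            }
        )
        model = simple_model(
            0.5,
            [ModelFeature(flag_def("a", group="g"), 2.0, 0.5, "both"),
             ModelFeature(flag_def("b", group="g"), 2.0, 0.5, "both")],
        )
        filtered, dropped = redundancy_filter(model, df, threshold=0.5)
        assert dropped == []
        assert len(filtered.features) == 2

    def test_redundant_same_hypothesis_pair_dropped(self):
        rng = np.random.default_rng(6)
        n = 200
        decline = rng.random(n) < 0.3
        strong = np.where(decline, rng.random(n) < 0.7, rng.random(n) < 0.15)
        clone = strong.copy()
        clone[:5] = ~clone[:5]  # J close to but below 1
        df = pd.DataFrame(
            {"decline": decline.astype(int), "age_of_onset": 50.0,
             "a": strong.astype(float), "b": clone.astype(float)}
        )
        make = lambda g1, g2: simple_model(
            0.3,
            [ModelFeature(flag_def("a", group=g1), 4.0, 0.4, "both"),
             ModelFeature(flag_def("b", group=g2), 3.5, 0.45, "both")],
        )
        filtered, dropped = redundancy_filter(make("g", "g"), df)
        assert len(dropped) == 1 and len(filtered.features) == 1
        # different hypotheses are never merged
        filtered2, dropped2 = redundancy_filter(make("g", "h"), df)
        assert dropped2 == [] and len(filtered2.features) == 2


class TestFitAndSerialization:
    def test_round_trip_identical_predictions(self, tmp_path):
        config = study_like_config(n_subjects=2000, seed=2)
        cohort = label_cohort(generate_cohort(config))
        model, trace = fit_model(cohort, config.feature_definitions())
        path = tmp_path / "model.json"
        model.save(path)
        loaded = PrognosticModel.load(path)
        assert loaded.to_dict() == model.to_dict()
        np.testing.assert_array_equal(
            loaded.predict_proba(cohort), model.predict_proba(cohort)
        )

    def test_calibration_recovery(self, big_cohort, study_config,
                                  four_question_model):
        """Refitting the pipeline on a large cohort generated from the
        published model's world recovers posteriors correlating > 0.99 with
        the generator's."""
        refit, _ = fit_model(big_cohort, study_config.feature_definitions())
        p_true = four_question_model.predict_proba(big_cohort)
        p_refit = refit.predict_proba(big_cohort)
        assert np.corrcoef(p_true, p_refit)[0, 1] > 0.99
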