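"""Tests of outcome coding, imputation, the survey-weighted c-statistic,
candidate fitting, CV model selection, importances and predictive margins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pregsae import GroundTruth
from pregsae import models, synthetic
from pregsae.errors import (
    InvalidArgumentError,
    UndefinedMetricError,
    UnsupportedOperationError,
)
from pregsae.models import (
    ConstantModel,
    MissingIndicatorImputer,
    code_intendedness,
    fit_candidate,
    importance_report,
    predictive_margins,
    select_model,
    weighted_cstat,
)

from conftest import FAST_GRID


# ---------------------------------------------------------------------------
# outcome coding


class TestCoding:
    @pytest.mark.parametrize(
        "response,expected",
        [
            ("I wanted to be pregnant later", 1),
            ("I didn't want to be pregnant then or at any time in the future", 1),
            ("I wanted to be pregnant sooner", 0),
            ("I wanted to be pregnant then", 0),
            ("I wasn't sure what I wanted", 0),
        ],
    )
    def test_default_scheme_binary_coding(self, response, expected):
        assert code_intendedness(response) == expected

    def test_unsure_handling_across_schemes(self):
        unsure = "I wasn't sure what I wanted"
        assert code_intendedness(unsure, "unsure_as_not_unintended") == 0
        assert code_intendedness(unsure, "unsure_as_unintended") == 1
        assert code_intendedness(unsure, "drop_unsure") is None
        # non-unsure responses are scheme-invariant
        assert code_intendedness("later", "drop_unsure") == 1

    def test_short_codes_accepted(self):
        assert code_intendedness("never") == 1
        assert code_intendedness("then") == 0

    def test_unknown_category_rejected(self):
        with pytest.raises(InvalidArgumentError):
            code_intendedness("maybe next year")
        with pytest.raises(InvalidArgumentError):
            code_intendedness("later", "unknown_scheme")


# ---------------------------------------------------------------------------
# imputation


def _imputer():
    return MissingIndicatorImputer(continuous=["x"], binary=["b"])


class TestImputer:
    def test_complete_rows_pass_through_with_zero_indicators(self):
        frame = pd.DataFrame({"x": [1.0, 2.0], "b": [0.0, 1.0]})
        out = _imputer().fit_transform(frame)
        assert (out["x"] == frame["x"]).all()
        assert (out["b"] == frame["b"]).all()
        assert (out[["x_mi", "b_mi"]] == 0).all().all()

    def test_missing_binary_becomes_zero_with_indicator(self):
        frame = pd.DataFrame({"x": [1.0, 2.0], "b": [np.nan, 1.0]})
        out = _imputer().fit_transform(frame)
        assert out["b"].iloc[0] == 0.0
        assert out["b_mi"].tolist() == [1.0, 0.0]

    def test_missing_continuous_gets_observed_median(self):
        frame = pd.DataFrame({"x": [2.0, 4.0, 10.0, np.nan], "b": [0.0] * 4})
        out = _imputer().fit_transform(frame)
        assert out["x"].iloc[3] == 4.0  # median of {2, 4, 10}
        assert out["x_mi"].iloc[3] == 1.0

    def test_all_missing_continuous_rejected(self):
        frame = pd.DataFrame({"x": [np.nan, np.nan], "b": [0.0, 1.0]})
        with pytest.raises(InvalidArgumentError):
            _imputer().fit(frame)

    def test_frozen_medians_apply_to_new_tables(self):
        imp = _imputer().fit(pd.DataFrame({"x": [2.0, 4.0, 10.0], "b": [0.0] * 3}))
        out = imp.transform(pd.DataFrame({"x": [np.nan, 100.0], "b": [1.0, np.nan]}))
        assert out["x"].iloc[0] == 4.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        xs=st.lists(st.one_of(st.none(), st.floats(-50, 50)), min_size=2, max_size=20),
        bs=st.lists(st.one_of(st.none(), st.sampled_from([0.0, 1.0])), min_size=2, max_size=20),
    )
    def test_imputation_is_idempotent(self, xs, bs):
        n = min(len(xs), len(bs))
        frame = pd.DataFrame({"x": pd.array(xs[:n], dtype="float64"),
                              "b": pd.array(bs[:n], dtype="float64")})
        if frame["x"].dropna().empty:
            return
        imp = _imputer().fit(frame)
        once = imp.transform(frame)
        twice = imp.transform(once)
        pd.testing.assert_frame_equal(once, twice)


# ---------------------------------------------------------------------------
# weighted c-statistic


def brute_force_cstat(scores, labels, weights):
    """Independent oracle: explicit sum over all positive x negative pairs."""
    num = den = 0.0
    for si, yi, wi in zip(scores, labels, weights):
        if yi != 1:
            continue
        for sj, yj, wj in zip(scores, labels, weights):
            if yj == 1:
                continue
            den += wi * wj
            if si > sj:
                num += wi * wj
            elif si == sj:
                num += 0.5 * wi * wj
    return num / den


class TestWeightedCstat:
    def test_perfect_separation_scores_one(self):
        assert weighted_cstat([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], [1, 2, 3, 4]) == 1.0

    def test_all_tied_scores_half(self):
        assert weighted_cstat([0.5] * 6, [1, 0, 1, 0, 1, 0], [1, 2, 3, 4, 5, 6]) == 0.5

    def test_two_pair_example(self):
        # pair (0.9 vs 0.8) wins weight 2; pair (0.3 vs 0.8) loses weight 2
        assert weighted_cstat([0.9, 0.8, 0.3], [1, 0, 1], [1, 2, 1]) == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [5, 37, 200])
    def test_matches_brute_force_pairwise_oracle(self, n):
        rng = np.random.default_rng(n)
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        weights = rng.uniform(0.2, 3.0, n)
        assert weighted_cstat(scores, labels, weights) == pytest.approx(
            brute_force_cstat(scores, labels, weights), abs=1e-12
        )

    def test_unit_weights_match_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        w = rng.uniform(0.5, 2.0, 300)
        assert weighted_cstat(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )
        assert weighted_cstat(scores, labels, w) == pytest.approx(
            roc_auc_score(labels, scores, sample_weight=w), abs=1e-10
        )

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            weighted_cstat([0.1, 0.2], [1, 1], [1, 1])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_bounded_and_complement_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        w = rng.uniform(0.1, 5.0, n)
        c = weighted_cstat(scores, labels, w)
        assert 0.0 <= c <= 1.0
        # reversing the ranking reverses the statistic
        assert weighted_cstat(-scores, labels, w) == pytest.approx(1.0 - c, abs=1e-12)


# ---------------------------------------------------------------------------
# candidate fitting


def _toy_table(n, seed=0, k=4):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)]), rng


class TestFitCandidate:
    def test_null_outcome_predictions_concentrate_at_weighted_mean(self):
        table, rng = _toy_table(20_000, seed=1)
        w = rng.uniform(0.5, 2.0, len(table))
        y = (rng.random(len(table)) < 0.3).astype(float)
        target = np.average(y, weights=w)
        for family in ("logistic", "random_forest"):
            params = {"min_samples_leaf": 200, "n_estimators": 50} if family == "random_forest" else {}
            model = fit_candidate(table, y, w, family, params, seed=0)
            preds = model.predict(table)
            assert abs(preds.mean() - target) < 0.05

    def test_duplicated_row_equals_doubled_weight_for_logistic(self):
        table, rng = _toy_table(400, seed=2)
        y = (rng.random(400) < 0.4).astype(float)
        w = np.ones(400)

        dup = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        y_dup = np.append(y, y[0])
        w2 = w.copy()
        w2[0] = 2.0

        m_dup = fit_candidate(dup, y_dup, np.ones(401), "logistic", seed=0)
        m_w = fit_candidate(table, y, w2, "logistic", seed=0)
        grid, _ = _toy_table(50, seed=3)
        np.testing.assert_allclose(m_dup.predict(grid), m_w.predict(grid), atol=1e-6)

    @pytest.mark.parametrize("family", ["logistic", "random_forest", "gradient_boosting",
                                        "neural_net", "linear_sgd"])
    def test_fixed_seed_is_deterministic_and_probabilistic(self, family):
        table, rng = _toy_table(600, seed=4)
        y = (table["x0"] + rng.normal(0, 1, 600) > 0).astype(float)
        w = rng.uniform(0.5, 2.0, 600)
        params = {"n_estimators": 30} if family in ("random_forest", "gradient_boosting") else {}
        holdout, _ = _toy_table(100, seed=5)
        a = fit_candidate(table, y, w, family, params, seed=7).predict(holdout)
        b = fit_candidate(table, y, w, family, params, seed=7).predict(holdout)
        np.testing.assert_array_equal(a, b)
        assert (a >= 0).all() and (a <= 1).all()

    def test_single_class_outcome_rejected(self):
        table, _ = _toy_table(50)
        with pytest.raises(InvalidArgumentError):
            fit_candidate(table, np.ones(50), np.ones(50), "logistic")


class TestSelectModel:
    def test_singleton_grid_returns_that_candidate(self):
        table, rng = _toy_table(300, seed=6)
        y = (table["x0"] > 0).astype(float)
        model = select_model(table, y, None, FAST_GRID, k_folds=3, seed=0)
        assert model.family == "logistic"
        assert 0.0 <= model.cv_cstat <= 1.0

    def test_nonlinear_signal_selects_tree_family_over_logistic(self):
        # XOR-style interaction: zero linear signal, strong tree signal
        rng = np.random.default_rng(8)
        n = 10_000
        table = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x0", "x1", "x2"])
        p = np.where(np.sign(table["x0"] * table["x1"]) > 0, 0.85, 0.15)
        y = (rng.random(n) < p).astype(float)
        grid = [
            {"family": "logistic", "params": {"C": 1.0}},
            {"family": "random_forest", "params": {"n_estimators": 100, "min_samples_leaf": 20}},
        ]
        model = select_model(table, y, None, grid, k_folds=3, seed=0)
        assert model.family == "random_forest"

    def test_winner_never_below_any_candidate_mean(self, fitted_f):
        means = fitted_f.cv_table.groupby("candidate")["cstat"].mean()
        assert fitted_f.cv_cstat == pytest.approx(means.max())

    def test_cv_cstat_reproducible_to_reported_precision(self, small_bundle):
        from pregsae.models import fit_intendedness_model

        a = fit_intendedness_model(small_bundle.survey_table, k_folds=3, seed=11,
                                   candidate_grid=FAST_GRID)
        b = fit_intendedness_model(small_bundle.survey_table, k_folds=3, seed=11,
                                   candidate_grid=FAST_GRID)
        assert round(a.cv_cstat, 2) == round(b.cv_cstat, 2)
        assert a.cv_cstat == b.cv_cstat

    def test_invalid_folds_rejected(self):
        table, _ = _toy_table(50)
        with pytest.raises(InvalidArgumentError):
            select_model(table, (table["x0"] > 0).astype(float), None, FAST_GRID, k_folds=1)


# ---------------------------------------------------------------------------
# importances


class TestImportance:
    def test_single_informative_feature_takes_all_importance(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame({"x0": rng.normal(size=2000)})
        y = (table["x0"] > 0).astype(float)
        model = fit_candidate(table, y, None, "random_forest", {"n_estimators": 50}, seed=0)
        report = importance_report(model, top_k=1)
        assert report["ranked"][0][0] == "x0"
        assert report["top_k_share"] == pytest.approx(1.0)

    def test_shares_sum_to_one(self, fitted_f):
        if fitted_f.family not in ("random_forest", "gradient_boosting"):
            pytest.skip("selected family has no impurity importances")
        report = importance_report(fitted_f, top_k=5)
        assert sum(s for _, s in report["ranked"]) == pytest.approx(1.0, abs=1e-9)

    def test_strong_features_occupy_top_ranks(self):
        # 5 strong + 20 null independent features; the strong set should
        # dominate the ranking (the "few variables carry the signal" regime)
        rng = np.random.default_rng(10)
        n, k = 20_000, 25
        table = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
        strong = ["x0", "x1", "x2", "x3", "x4"]
        lp = sum(1.2 * table[c] for c in strong)
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        model = fit_candidate(table, y, None, "random_forest",
                              {"n_estimators": 100, "min_samples_leaf": 20}, seed=0)
        report = importance_report(model, top_k=5)
        assert {name for name, _ in report["ranked"][:5]} == set(strong)
        assert report["top_k_share"] > 0.8

    def test_family_without_importances_rejected(self):
        table, _ = _toy_table(100)
        y = (table["x0"] > 0).astype(float)
        model = fit_candidate(table, y, None, "logistic", seed=0)
        with pytest.raises(UnsupportedOperationError):
            importance_report(model)


# ---------------------------------------------------------------------------
# predictive margins


class TestMargins:
    def test_constant_model_collapses_every_summary(self):
        table = pd.DataFrame({"married": [0.0, 1.0, 0.0], "x": [1.0, 2.0, 3.0]})
        summaries = predictive_margins(ConstantModel(0.25), table, "married", [0, 1])
        for s in summaries:
            assert s.mean == s.p25 == s.p50 == s.p75 == 25.0
            assert s.lower_adjacent == s.upper_adjacent == 25.0

    def test_mean_margin_matches_naive_recomputation_exactly(self, fitted_f, small_bundle):
        births = small_bundle.birth_table.head(500)
        summaries = predictive_margins(fitted_f, births, "married", [0.0, 1.0])
        for s in summaries:
            forced = births.copy()
            forced["married"] = s.level
            preds = 100.0 * fitted_f.predict(forced)
            assert s.mean == pytest.approx(preds.mean(), abs=1e-12)
            assert s.p50 == pytest.approx(np.percentile(preds, 50), abs=1e-12)

    def test_box_ordering_invariant(self, fitted_f, small_bundle):
        births = small_bundle.birth_table.head(400)
        for s in predictive_margins(fitted_f, births, "parity", [0.0, 2.0, 4.0]):
            assert s.lower_adjacent <= s.p25 <= s.p50 <= s.p75 <= s.upper_adjacent

    def test_null_feature_margins_flat(self):
        # a covariate absent from the true model should move margins < 1 point
        truth = GroundTruth(
            seed=21, area_count=1, births_per_area=20_000,
            intendedness_coefficients={"married": -0.9, "mother_age": -0.35},
            missingness_rates={}, area_covariate_sd=0.0, area_size_sd=0.0,
        )
        polys = synthetic.generate_polygons(1, seed=21)
        births = synthetic.generate_birth_table(truth, polys)
        survey = synthetic.generate_survey_table(births, 1.0, 0.0, seed=21)
        model = models.fit_intendedness_model(survey, k_folds=2, seed=21,
                                              candidate_grid=FAST_GRID)
        margins = predictive_margins(model, births, "infant_male", [0.0, 1.0])
        assert abs(margins[0].mean - margins[1].mean) < 1.0

    def test_unknown_feature_rejected(self, fitted_f, small_bundle):
        with pytest.raises(InvalidArgumentError):
            predictive_margins(fitted_f, small_bundle.birth_table, "nope", [0])


class TestMarginRecovery:
    def test_marriage_margin_recovers_true_effect(self):
        # correctly-specified logistic fit on a 50,000-birth frame: the
        # fitted marriage margin must match the generating model's within
        # 2 percentage points
        truth = GroundTruth(
            seed=31, area_count=1, births_per_area=50_000,
            missingness_rates={}, area_covariate_sd=0.0, area_size_sd=0.0,
        )
        polys = synthetic.generate_polygons(1, seed=31)
        births = synthetic.generate_birth_table(truth, polys)
        survey = synthetic.generate_survey_table(births, 0.1, 0.2, seed=31)
        model = models.fit_intendedness_model(survey, k_folds=2, seed=31,
                                              candidate_grid=FAST_GRID)
        fitted = predictive_margins(model, births, "married", [0.0, 1.0])
        fitted_effect = fitted[1].mean - fitted[0].mean

        from scipy.special import expit

        lp = synthetic.linear_predictor(births, truth.intendedness_coefficients)
        alpha = synthetic.calibrate_intercept(lp, truth.baseline_unintended_share)
        true_margin = {}
        for level in (0.0, 1.0):
            forced = births.copy()
            forced["married"] = level
            lp_f = synthetic.linear_predictor(forced, truth.intendedness_coefficients)
            true_margin[level] = 100.0 * expit(alpha + lp_f).mean()
        true_effect = true_margin[1.0] - true_margin[0.0]
        assert abs(fitted_effect - true_effect) < 2.0
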