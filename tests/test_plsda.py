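"""NIPALS PLS-DA: oracle equivalences, geometry and model contracts."""

import numpy as np
import pytest

from coamscreen import (
    OutcomeLabel,
    PLSDAModel,
    SyntheticConfig,
    autoscale_fit,
    classify,
    decision_boundary_lv,
    feature_matrix,
    generate_training_screen,
    nipals_fit,
    response_from_scores,
)
from coamscreen.errors import (
    ContractError,
    DegenerateFeatureError,
    DegenerateTrainingError,
    DimensionalityError,
    DomainError,
)

from .oracles import ols_fitted, svd_pls1


def _random_problem(seed, n=12, p=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.zeros(n)
    y[: n // 2] = 1.0
    rng.shuffle(y)
    return X, y


class TestAutoscale:
    def test_hand_example(self):
        sp = autoscale_fit(np.array([[0.0, 0.0], [2.0, 2.0]]))
        assert np.allclose(sp.means, [1.0, 1.0])
        assert np.allclose(sp.scales, [np.sqrt(2.0), np.sqrt(2.0)])

    def test_constant_column_is_degenerate(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(DegenerateFeatureError, match="x1"):
            autoscale_fit(X)

    def test_scaled_matrix_is_standardised(self, rng):
        X = rng.normal(size=(20, 5))
        sp = autoscale_fit(X)
        Z = sp.apply(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.var(axis=0, ddof=1), 1.0, atol=1e-12)


class TestNipalsOracles:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_full_component_fit_equals_least_squares(self, seed):
        X, y = _random_problem(seed)
        model = nipals_fit(X, y, n_components=5)
        pls = np.array([model.predict_value(row) for row in X])
        assert np.allclose(pls, ols_fitted(X, y), atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_regression_vector_matches_svd_oracle(self, seed, n_components):
        X, y = _random_problem(seed)
        model = nipals_fit(X, y, n_components=n_components)
        b_ref, T_ref = svd_pls1(X, y, n_components)
        assert np.allclose(model.regression_vector, b_ref, atol=1e-6)
        assert np.allclose(model.training_scores, T_ref, atol=1e-6)

    def test_predictions_match_sklearn_pls(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_problem(7)
        model = nipals_fit(X, y, n_components=2)
        ref = sklearn.PLSRegression(n_components=2, scale=True).fit(X, y)
        mine = np.array([model.predict_value(row) for row in X])
        assert np.allclose(mine, ref.predict(X).ravel(), atol=1e-6)

    def test_rank_one_limit_reproduces_response(self, rng):
        """With X spanned by a single direction carrying the class split,
        one latent variable captures all X variance and fits y exactly."""
        v = rng.normal(size=4) + np.array([2.0, 2.0, 2.0, 2.0])
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        X = np.outer(y, v)
        model = nipals_fit(X, y, n_components=1)
        fitted = np.array([model.predict_value(row) for row in X])
        assert np.allclose(fitted, y, atol=1e-8)
        t = model.training_scores[:, 0]
        Xs = model.scaling.apply(X)
        explained = np.outer(t, model.x_loadings[:, 0])
        assert np.linalg.norm(Xs - explained) <= 1e-8 * np.linalg.norm(Xs)


class TestModelStructure:
    def test_weights_unit_norm_and_scores_orthogonal(self, fitted_model):
        W = fitted_model.weights
        assert np.allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-12)
        T = fitted_model.training_scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_determinism_bit_identical(self, synthetic_screen):
        X = feature_matrix(synthetic_screen)
        y = synthetic_screen.experimental_labels()
        m1, m2 = nipals_fit(X, y), nipals_fit(X, y)
        assert m1.to_json() == m2.to_json()

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(DegenerateTrainingError):
            nipals_fit(X, np.ones(6))

    def test_n_components_bounds(self):
        X, y = _random_problem(0)
        with pytest.raises(DomainError):
            nipals_fit(X, y, n_components=6)

    def test_serialization_round_trip_exact(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        fitted_model.save(path)
        loaded = PLSDAModel.load(path)
        assert np.array_equal(loaded.regression_vector, fitted_model.regression_vector)
        assert np.array_equal(loaded.weights, fitted_model.weights)
        assert np.array_equal(loaded.scaling.means, fitted_model.scaling.means)
        assert loaded.y_mean == fitted_model.y_mean
        assert loaded.scaling.feature_order == fitted_model.scaling.feature_order
        x = fitted_model.scaling.means + fitted_model.scaling.scales
        assert loaded.predict_value(x) == fitted_model.predict_value(x)


class TestProjection:
    def test_training_mean_projects_to_origin(self, fitted_model):
        scores = fitted_model.project(fitted_model.scaling.means)
        assert np.allclose(scores.lv, 0.0, atol=1e-10)

    def test_training_rows_reproduce_training_scores(self, synthetic_screen):
        X = feature_matrix(synthetic_screen)
        model = nipals_fit(X, synthetic_screen.experimental_labels())
        for i, row in enumerate(X.to_numpy()):
            assert np.allclose(model.project(row).lv, model.training_scores[i], atol=1e-8)

    def test_feature_order_mismatch_is_contract_error(self, fitted_model):
        wrong = tuple(reversed(fitted_model.scaling.feature_order))
        with pytest.raises(ContractError, match="feature order"):
            fitted_model.project(fitted_model.scaling.means, feature_order=wrong)

    def test_scale_invariance_of_predictions(self, synthetic_screen):
        """Multiplying a feature column by a positive constant changes
        nothing after autoscaling."""
        X = feature_matrix(synthetic_screen).to_numpy()
        y = synthetic_screen.experimental_labels()
        base = nipals_fit(X, y)
        X2 = X.copy()
        X2[:, 2] *= 1000.0
        scaled = nipals_fit(X2, y)
        for row, row2 in zip(X[:5], X2[:5]):
            assert scaled.predict_value(row2) == pytest.approx(
                base.predict_value(row), abs=1e-8
            )


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.864, OutcomeLabel.COAM),
            (0.443, OutcomeLabel.NOT_COAM),
            (0.500, OutcomeLabel.COAM),  # threshold is inclusive
            (0.463, OutcomeLabel.NOT_COAM),
        ],
    )
    def test_threshold_rule(self, value, expected):
        assert classify(value) is expected

    def test_centroid_queries_fall_on_their_class_sides(self):
        config = SyntheticConfig(seed=3)
        screen = generate_training_screen(config)
        X = feature_matrix(screen)
        model = nipals_fit(X, screen.experimental_labels())
        assert model.predict_value(np.array(config.coam_centroid)) > model.threshold
        assert model.predict_value(np.array(config.notcoam_centroid)) < model.threshold

    def test_values_are_not_clamped(self, fitted_model):
        far = np.array(SyntheticConfig().coam_centroid)
        far[2:4] -= 10.0  # deep into the COAM-favourable region
        assert fitted_model.predict_value(far) > 1.0


class TestDecisionBoundary:
    def test_boundary_reconstruction_matches_threshold(self, fitted_model):
        line = decision_boundary_lv(fitted_model)
        lv1 = np.linspace(-3, 3, 7)
        if line.vertical:
            values = response_from_scores(fitted_model, line.x0, lv1)
        else:
            values = response_from_scores(
                fitted_model, lv1, line.intercept + line.slope * lv1
            )
        assert np.allclose(values, fitted_model.threshold, atol=1e-10)

    def test_lv1_only_response_gives_vertical_line(self, fitted_model):
        import dataclasses

        model = dataclasses.replace(
            fitted_model, y_loadings=np.array([0.7, 0.0])
        )
        line = decision_boundary_lv(model)
        assert line.vertical
        assert line.x0 == pytest.approx((model.threshold - model.y_mean) / 0.7)

    def test_coam_side_points_all_classify_coam(self, fitted_model, rng):
        line = decision_boundary_lv(fitted_model)
        kept = []
        while len(kept) < 100:
            pts = rng.uniform(-5, 5, size=(200, 2))
            if line.vertical:
                side = (pts[:, 0] >= line.x0) == line.coam_right
            else:
                above = pts[:, 1] >= line.intercept + line.slope * pts[:, 0]
                side = above == line.coam_above
            kept.extend(pts[side])
        pts = np.array(kept[:100])
        values = response_from_scores(fitted_model, pts[:, 0], pts[:, 1])
        assert np.all(values >= fitted_model.threshold - 1e-12)

    def test_one_lv_model_rejected(self, synthetic_screen):
        X = feature_matrix(synthetic_screen)
        model = nipals_fit(X, synthetic_screen.experimental_labels(), n_components=1)
        with pytest.raises(DimensionalityError):
            decision_boundary_lv(model)
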