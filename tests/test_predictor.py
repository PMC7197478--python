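"""Training, grid-likelihood prediction, circular error, and LOIO CV."""

import json

import numpy as np
import pytest

from cyclephase.model_io import deserialize_model, serialize_model
from cyclephase.predictor import (
    DEFAULT_PREDICTOR_GENES,
    PhaseGrid,
    TrainedPredictor,
    circular_error,
    cross_validate_by_individual,
    evaluate_trend_at,
    predict_phase,
    train_predictor,
)
from cyclephase.trend import CyclicTrend


def toy_model(K=100):
    """Two-gene cos/sin model with dense training angles."""
    theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    trends = [
        CyclicTrend("cosg", theta, np.cos(theta), sigma=0.1, pve=0.9, lam=1.0),
        CyclicTrend("sing", theta, np.sin(theta), sigma=0.1, pve=0.9, lam=1.0),
    ]
    return TrainedPredictor(trends=trends, grid=PhaseGrid(K))


class TestEvaluateTrendAt:
    def test_training_angle_exact(self):
        t = CyclicTrend("g", [0.0, 1.0, 2.0], [5.0, 7.0, -1.0], 0.1, 0.5, 1.0)
        assert evaluate_trend_at(t, 1.0) == 7.0

    def test_midpoint_is_mean(self):
        t = CyclicTrend("g", [0.0, 1.0, 2.0], [5.0, 7.0, -1.0], 0.1, 0.5, 1.0)
        assert evaluate_trend_at(t, 0.5) == pytest.approx(6.0)

    def test_wraparound_interpolates_to_first(self):
        t = CyclicTrend("g", [0.0, np.pi], [2.0, 4.0], 0.1, 0.5, 1.0)
        # halfway through the seam interval [pi, 2pi] -> mean of 4 and 2
        assert evaluate_trend_at(t, 1.5 * np.pi) == pytest.approx(3.0)
        # just below 2pi approaches the value at theta = 0
        assert evaluate_trend_at(t, 2 * np.pi - 1e-9) == pytest.approx(2.0, abs=1e-6)


class TestPredictPhase:
    def test_exact_observation_recovers_grid_angle(self):
        model = toy_model()
        theta0 = model.grid.angles[37]
        obs = np.array([np.cos(theta0), np.sin(theta0)])
        pred = predict_phase(obs, model)
        assert pred.theta_hat == pytest.approx(theta0)
        assert circular_error(pred.theta_hat, theta0) <= 0.005

    def test_profile_length_is_grid_size(self):
        pred = predict_phase(np.array([1.0, 0.0]), toy_model())
        assert pred.loglik_profile.size == 100
        assert pred.theta_hat in toy_model().grid.angles

    def test_quadrature_recovery_under_noise(self):
        rng = np.random.default_rng(13)
        model = toy_model()
        theta0 = rng.uniform(0, 2 * np.pi, 100)
        obs = np.column_stack([np.cos(theta0), np.sin(theta0)])
        preds = predict_phase(obs, model)
        errs = circular_error(np.array([p.theta_hat for p in preds]), theta0)
        assert errs.mean() < 0.02

    def test_batch_equals_single(self):
        rng = np.random.default_rng(14)
        model = toy_model()
        obs = rng.normal(size=(10, 2))
        batch = predict_phase(obs, model)
        singles = [predict_phase(row, model) for row in obs]
        for b, s in zip(batch, singles):
            assert b.theta_hat == s.theta_hat
            np.testing.assert_array_equal(b.loglik_profile, s.loglik_profile)

    def test_missing_gene_rejected(self):
        with pytest.raises(ValueError, match="genes"):
            predict_phase(np.array([1.0]), toy_model())
        with pytest.raises(ValueError, match="missing"):
            predict_phase(np.array([1.0, np.nan]), toy_model())

    def test_rotation_equivariance(self):
        # rotating training angles by a grid multiple rotates predictions
        rng = np.random.default_rng(15)
        K = 100
        delta = 2 * np.pi * 13 / K
        theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)

        def build(shift):
            th = np.mod(theta + shift, 2 * np.pi)
            order = np.argsort(th)
            trends = [
                CyclicTrend("c", th[order], np.cos(theta)[order], 0.1, 0.9, 1.0),
                CyclicTrend("s", th[order], np.sin(theta)[order], 0.1, 0.9, 1.0),
            ]
            return TrainedPredictor(trends=trends, grid=PhaseGrid(K))

        obs = rng.normal(size=(20, 2)) * 0.5
        p0 = predict_phase(obs, build(0.0))
        p1 = predict_phase(obs, build(delta))
        for a, b in zip(p0, p1):
            got = np.mod(b.theta_hat - a.theta_hat, 2 * np.pi)
            assert got == pytest.approx(delta, abs=1e-9)


class TestCircularError:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (0.0, np.pi, 0.5),
            (0.1, 2 * np.pi - 0.1, 0.2 / (2 * np.pi)),
            (1.234, 1.234, 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert circular_error(a, b) == pytest.approx(expected)

    def test_random_guess_baseline(self):
        rng = np.random.default_rng(16)
        a = rng.uniform(0, 2 * np.pi, 200_000)
        b = rng.uniform(0, 2 * np.pi, 200_000)
        assert circular_error(a, b).mean() == pytest.approx(0.25, abs=0.002)

    def test_never_exceeds_half(self):
        grid = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        errs = circular_error(grid[:, None], grid[None, :])
        assert errs.max() <= 0.5


class TestTraining:
    def test_sigma_bounded_on_noiseless_panel(self):
        theta = np.linspace(0, 2 * np.pi, 500, endpoint=False)
        offsets = np.linspace(0, 2 * np.pi, 5, endpoint=False)
        Y = np.array([np.cos(theta + o) for o in offsets])
        model = train_predictor(Y, theta, [f"g{i}" for i in range(5)])
        assert all(t.sigma < 0.15 for t in model.trends)

    def test_single_gene_rejected(self):
        theta = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        with pytest.raises(ValueError, match="single gene|unidentifiable"):
            train_predictor(np.cos(theta)[None, :], theta, ["g0"])

    def test_default_gene_panel_names(self):
        assert DEFAULT_PREDICTOR_GENES == ("CDK1", "UBE2C", "TOP2A", "H4C5", "H4C3")


class TestCrossValidation:
    def test_one_fold_per_individual(self, sinusoid_panel):
        p = sinusoid_panel
        indiv = np.tile([f"I{i}" for i in range(6)], 50)
        table = cross_validate_by_individual(
            p["Y_train"], p["theta_train"], indiv, p["gene_ids"],
            n_top_genes_list=(2,), n_lambda=10,
        )
        assert len(table) == 6
        assert set(table.individual) == {f"I{i}" for i in range(6)}
        assert (table.mean_error < 0.25).all()

    def test_single_individual_rejected(self, sinusoid_panel):
        p = sinusoid_panel
        with pytest.raises(ValueError, match="individual"):
            cross_validate_by_individual(
                p["Y_train"], p["theta_train"],
                np.repeat("only", p["theta_train"].size), p["gene_ids"],
            )


class TestSerialization:
    def test_roundtrip_predictions_identical(self, tmp_path, sinusoid_panel):
        p = sinusoid_panel
        model = train_predictor(
            p["Y_train"][:2], p["theta_train"], p["gene_ids"][:2], n_lambda=10
        )
        path = tmp_path / "model.json"
        serialize_model(model, path)
        model2 = deserialize_model(path)
        a = predict_phase(p["Y_test"][:2].T, model)
        b = predict_phase(p["Y_test"][:2].T, model2)
        for x, y in zip(a, b):
            assert x.theta_hat == y.theta_hat
            np.testing.assert_array_equal(x.loglik_profile, y.loglik_profile)
        payload = json.loads(path.read_text())
        assert len(payload["genes"]) == 2

    def test_unknown_schema_version(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"schema_version": "9.9", "genes": []}))
        with pytest.raises(ValueError, match="schema_version"):
            deserialize_model(path)

    def test_invalid_sigma_rejected(self, tmp_path):
        payload = {
            "schema_version": "1.0",
            "grid_K": 100,
            "genes": [
                {"gene_id": "g0", "train_thetas": [0.0, 1.0],
                 "fitted_values": [0.0, 1.0], "sigma": -1.0, "pve": 0.5,
                 "lambda": 1.0},
                {"gene_id": "g1", "train_thetas": [0.0, 1.0],
                 "fitted_values": [0.0, 1.0], "sigma": 0.5, "pve": 0.5,
                 "lambda": 1.0},
            ],
        }
        path = tmp_path / "sigma.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="sigma"):
            deserialize_model(path)

    def test_truncated_file(self, tmp_path):
        path = tmp_path / "trunc.json"
        path.write_text('{"schema_version": "1.0", "genes": [')
        with pytest.raises(json.JSONDecodeError):
            deserialize_model(path)
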