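import numpy as np
import pytest

from soilspec import (
    ModelConfig,
    SyntheticConfig,
    TrainConfig,
    build_multicnn_1d,
    evaluate,
    generate,
    r_squared,
    rmse,
    rpd,
    split_dataset,
    train,
)
from soilspec.exceptions import ValidationError


class TestMetrics:
    def test_r_squared_hand_values(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)
        assert r_squared(y, [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_r_squared_zero_variance_sentinel(self):
        assert np.isnan(r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))

    def test_rmse_hand_values(self):
        assert rmse([1, 2], [1, 2]) == 0.0
        assert rmse([0.0, 0.0], [1.0, -1.0]) == pytest.approx(1.0)
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(np.sqrt(1 / 3), abs=1e-4)

    def test_rpd_hand_values(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rpd(y, 1.0) == pytest.approx(np.std(y, ddof=1))
        r = rmse(y, [1.0, 2.0, 4.0])
        assert rpd(y, r) == pytest.approx(np.sqrt(3), abs=1e-4)  # 1.0 / 0.5774

    def test_rpd_scale_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(50)
        yhat = y + 0.3 * rng.standard_normal(50)
        base = rpd(y, rmse(y, yhat))
        for c in (0.1, 3.0, 100.0):
            assert rpd(c * y, rmse(c * y, c * yhat)) == pytest.approx(base, rel=1e-9)

    def test_rpd_zero_rmsep_warns_infinite(self):
        with pytest.warns(UserWarning):
            assert rpd([1.0, 2.0], 0.0) == np.inf

    def test_rpd_times_rmsep_equals_test_sd(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(30) * 5
        yhat = y + rng.standard_normal(30)
        r = rmse(y, yhat)
        assert rpd(y, r) * r == pytest.approx(np.std(y, ddof=1), abs=1e-9)


class _Memorizer:
    """Predictor that looks predictions up by input row, for oracle tests."""

    mode = "single_input"

    def __init__(self, x, y):
        self.table = {xr.tobytes(): yr for xr, yr in zip(x, y)}
        self.fallback = y.mean(axis=0)

    def predict(self, x1d, x2d=None):
        return np.stack([self.table.get(row.tobytes(), self.fallback) for row in x1d])


class _MeanPredictor:
    mode = "single_input"

    def __init__(self, mean):
        self.mean = np.asarray(mean)

    def predict(self, x1d, x2d=None):
        return np.tile(self.mean, (x1d.shape[0], 1))


class TestEvaluate:
    def test_memorizing_model_has_perfect_calibration(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 10))
        y = rng.standard_normal((20, 3))
        split = split_dataset(20, (0.7, 0.3), seed=0)
        rep = evaluate(_Memorizer(x, y), x, y, split, ["a", "b", "c"])
        for name in ("a", "b", "c"):
            assert rep.rc2[name] == pytest.approx(1.0)
            assert rep.rmsec[name] == pytest.approx(0.0, abs=1e-12)

    def test_mean_of_train_predictor_has_near_zero_rp2(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((500, 3))
        x = rng.standard_normal((500, 4))
        split = split_dataset(500, (0.7, 0.3), seed=1)
        rep = evaluate(_MeanPredictor(y[split.indices["train"]].mean(axis=0)), x, y, split, ["a", "b", "c"])
        for name in ("a", "b", "c"):
            assert abs(rep.rp2[name]) < 0.1

    def test_report_schema_complete(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((20, 5))
        y = rng.standard_normal((20, 3))
        split = split_dataset(20, (0.6, 0.2, 0.2), seed=0)
        rep = evaluate(_Memorizer(x, y), x, y, split, ["TC", "TN", "AN"])
        d = rep.to_dict()
        for key in ("rc2", "rmsec", "rp2", "rmsep", "rpd"):
            assert set(d[key]) == {"TC", "TN", "AN"}
        assert rep.n_per_split == {"train": 12, "val": 4, "test": 4}
        assert "TC" in rep.to_text()


def _tiny_training_problem(n=10, c=64, seed=0):
    ss, at, _ = generate(SyntheticConfig(n_samples=n, n_channels=c, wavelength_range=(400.0, 700.0), seed=seed))
    split = split_dataset(n, (0.7, 0.3), seed=seed)
    handle = build_multicnn_1d(ModelConfig(input_length=c), seed=seed)
    return handle, ss.intensities, at.values, split


class TestTraining:
    def test_one_epoch_history(self):
        handle, x, y, split = _tiny_training_problem()
        hist = train(handle, x, y, split, TrainConfig(max_epochs=1, seed=0))
        assert len(hist["train_loss"]) == 1 and np.isfinite(hist["train_loss"][0])

    def test_seeded_runs_identical(self):
        losses = []
        for _ in range(2):
            handle, x, y, split = _tiny_training_problem(seed=3)
            hist = train(handle, x, y, split, TrainConfig(max_epochs=3, seed=3))
            losses.append(hist["train_loss"])
        assert losses[0] == losses[1]

    def test_zero_variance_target_trains_and_reports_sentinel(self):
        handle, x, y, split = _tiny_training_problem()
        y = y.copy()
        y[:, 1] = 5.0
        hist = train(handle, x, y, split, TrainConfig(max_epochs=1, seed=0))
        assert np.isfinite(hist["train_loss"][0])
        rep = evaluate(handle, x, y, split, ["a", "b", "c"])
        assert np.isnan(rep.rp2["b"]) and np.isfinite(rep.rp2["a"])

    def test_target_standardization_inverts_to_raw_units(self):
        """Predictions come back in raw units even though optimization runs
        on standardized targets (AN-scale column stays AN-scale)."""
        handle, x, y, split = _tiny_training_problem()
        y = y.copy()
        y[:, 2] = y[:, 2] * 100 + 500  # mg/kg-like scale
        # enough epochs for batch-norm running statistics to converge
        train(handle, x, y, split, TrainConfig(max_epochs=80, seed=0))
        pred = handle.predict(x[split.indices["train"]])
        target_mean = y[split.indices["train"], 2].mean()
        assert pred[:, 2].mean() == pytest.approx(target_mean, rel=0.2)
        assert pred[:, 2].mean() > 100 * y[:, 1].max()  # clearly on the rescaled-column scale

    def test_loss_decreases_over_training(self, small_dataset):
        """Median train loss over the last 5 epochs beats the first 5 on the
        synthetic fixture (30 epochs, fixed seed)."""
        ss, at, _ = small_dataset
        split = split_dataset(ss.n_samples, (0.7, 0.3), seed=0)
        handle = build_multicnn_1d(ModelConfig(input_length=ss.n_channels), seed=0)
        hist = train(handle, ss.intensities, at.values, split, TrainConfig(max_epochs=30, seed=0))
        losses = hist["train_loss"]
        assert np.median(losses[-5:]) < np.median(losses[:5])

    def test_early_stopping_restores_best_weights(self):
        handle, x, y, split0 = _tiny_training_problem(n=20)
        split = split_dataset(20, (0.6, 0.2, 0.2), seed=0)
        hist = train(handle, x, y, split,
                     TrainConfig(max_epochs=60, early_stopping_patience=5, seed=0))
        assert len(hist["train_loss"]) <= 60
        assert "val_loss" in hist

    def test_empty_split_rejected(self):
        handle, x, y, split = _tiny_training_problem()
        split.indices["train"] = np.array([], dtype=int)
        with pytest.raises(ValidationError):
            train(handle, x, y, split, TrainConfig(max_epochs=1))
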