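"""SELU network regression: transforms, determinism, learning sanity."""

import numpy as np
import pandas as pd
import pytest

from aggsense.nn import (
    SeluNetRegressor,
    cross_validate,
    evaluate,
    load_model,
    predict,
    save_model,
    train_model,
)


def _toy_linear_data(n=60, seed=0):
    """Aggregate conc proportional to g, monomer to f: a linear task any
    regressor must master."""
    rng = np.random.default_rng(seed)
    feats = pd.DataFrame({
        "d": rng.uniform(0.5, 2.0, n),
        "f": rng.uniform(100.0, 900.0, n),
        "g": rng.uniform(0.002, 0.01, n),
    })
    Y = np.column_stack([0.5 * feats["f"], 2.0e4 * feats["g"]])
    return feats, Y


def test_learns_linear_task():
    feats, Y = _toy_linear_data()
    model = train_model(feats, Y, mode="dissociation_only", seed=0)
    rep = evaluate(model.predict(feats[["d", "f", "g"]].to_numpy()), Y)
    assert rep.r_squared_monomer > 0.99
    assert rep.r_squared_aggregate > 0.99


def test_seed_determinism():
    feats, Y = _toy_linear_data()
    p1 = train_model(feats, Y, seed=5).predict(feats[["d", "f", "g"]].to_numpy())
    p2 = train_model(feats, Y, seed=5).predict(feats[["d", "f", "g"]].to_numpy())
    np.testing.assert_array_equal(p1, p2)


def test_training_loss_decreases():
    feats, Y = _toy_linear_data()
    model = train_model(feats, Y, seed=1)
    assert model.loss_curve_[-1] < model.loss_curve_[0]


def test_predictions_positive_by_construction():
    feats, Y = _toy_linear_data()
    model = train_model(feats, Y, seed=2, epochs=50)  # even a barely trained net
    assert np.all(model.predict(feats[["d", "f", "g"]].to_numpy()) > 0)


def test_target_transform_round_trip():
    feats, Y = _toy_linear_data(n=20)
    model = train_model(feats, Y, seed=0, epochs=10)
    Z = model._forward_target(Y)
    np.testing.assert_allclose(model._inverse_target(Z), Y, rtol=1e-12)


def test_batch_equals_rowwise_prediction():
    feats, Y = _toy_linear_data(n=30)
    model = train_model(feats, Y, seed=0, epochs=100)
    X = feats[["d", "f", "g"]].to_numpy()
    batch = model.predict(X)
    rows = np.vstack([model.predict(x) for x in X])
    np.testing.assert_allclose(batch, rows, rtol=1e-12)


def test_memorizes_tiny_training_set():
    feats, Y = _toy_linear_data(n=3, seed=3)
    model = train_model(feats, Y, seed=0, epochs=4000)
    P = model.predict(feats[["d", "f", "g"]].to_numpy())
    assert np.all(np.abs(P - Y) / Y < 0.05)


def test_standardization_makes_fit_affine_invariant():
    feats, Y = _toy_linear_data()
    m1 = train_model(feats, Y, seed=4)
    scaled = feats.copy()
    scaled["f"] = scaled["f"] * 100.0 + 5.0
    m2 = train_model(scaled, Y, seed=4)
    p1 = m1.predict(feats[["d", "f", "g"]].to_numpy())
    p2 = m2.predict(scaled[["d", "f", "g"]].to_numpy())
    np.testing.assert_allclose(p1, p2, rtol=1e-8)


def test_seven_layer_structure():
    feats, Y = _toy_linear_data(n=20)
    model = train_model(feats, Y, seed=0, epochs=10, hidden=16)
    # four linear layers (alternating with three SELUs): 3 -> 16 -> 16 -> 16 -> 2
    assert [W.shape for W in model.weights_] == [(3, 16), (16, 16), (16, 16), (16, 2)]


def test_rejects_nonpositive_concentrations_and_drops_nan_rows():
    feats, Y = _toy_linear_data(n=20)
    with pytest.raises(ValueError):
        train_model(feats, np.zeros_like(Y))
    feats2 = feats.copy()
    feats2.loc[feats2.index[0], "g"] = np.nan
    with pytest.warns(UserWarning, match="non-finite"):
        train_model(feats2, Y, seed=0, epochs=10)


class TestEvaluate:
    def test_perfect_predictions(self):
        E = np.abs(np.random.default_rng(0).normal(50, 10, (10, 2))) + 1
        rep = evaluate(E, E)
        assert rep.r_squared_monomer == pytest.approx(1.0)
        assert rep.mean_pct_error_aggregate == pytest.approx(0.0)

    def test_ten_percent_bias(self):
        E = np.abs(np.random.default_rng(1).normal(50, 10, (10, 2))) + 1
        rep = evaluate(1.1 * E, E)
        assert rep.mean_pct_error_monomer == pytest.approx(10.0)
        assert rep.mean_pct_error_aggregate == pytest.approx(10.0)

    def test_anticorrelation_warns(self):
        E = np.column_stack([np.linspace(1, 10, 5), np.linspace(1, 10, 5)])
        P = E[::-1]
        with pytest.warns(UserWarning, match="anti-correlated"):
            rep = evaluate(P, E)
        assert rep.r_squared_monomer > 0.99  # squared correlation, sign warned

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.empty((0, 2)), np.empty((0, 2)))


def test_save_load_round_trip(tmp_path):
    feats, Y = _toy_linear_data(n=30)
    model = train_model(feats, Y, seed=0, epochs=200)
    save_model(model, tmp_path / "m.json")
    clone = load_model(tmp_path / "m.json")
    np.testing.assert_allclose(
        predict(clone, feats), predict(model, feats), rtol=1e-12
    )


def test_mode_mismatch_detected(tmp_path):
    feats, Y = _toy_linear_data(n=30)
    model = train_model(feats, Y, mode="dissociation_only", seed=0, epochs=10)
    with pytest.raises(ValueError, match="feature"):
        model.predict(np.ones((2, 6)))


def test_cross_validation_reports_are_stable():
    feats, Y = _toy_linear_data(n=50)
    reports = cross_validate(feats, Y, k=5, seed=0, epochs=800)
    assert len(reports) == 5
    errs = [r.mean_pct_error_monomer for r in reports]
    assert np.std(errs) < np.mean(errs) + 5.0  # folds agree in scale
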