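"""Exponential-reduction neural-network regression of monomer and aggregate
concentrations.

Each sensorgram is reduced to the parameters of its per-phase exponential fits
(d, f, g from the dissociation phase alone, or a, b, c, d, f, g from both
phases).  A seven-layer network — four linear layers alternating with three
scaled exponential linear units (SELU) — maps the standardized parameters to
the two concentrations.  Targets are log-transformed (and z-scored) during
training, which both standardizes the outputs across their wide dynamic range
and makes predictions positive by construction after the inverse transform.

The network is implemented directly in NumPy (hand-written backprop, Adam,
full-batch MSE); it is small enough that CPU training takes seconds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "SeluNetRegressor",
    "EvaluationReport",
    "MODE_COLUMNS",
    "train_model",
    "predict",
    "evaluate",
    "train_and_evaluate",
    "cross_validate",
    "save_model",
    "load_model",
]

# SELU self-normalizing constants (Klambauer et al.)
_SELU_ALPHA = 1.6732632423543772
_SELU_LAMBDA = 1.0507009873554805

MODE_COLUMNS = {
    "dissociation_only": ["d", "f", "g"],
    "both_phases": ["a", "b", "c", "d", "f", "g"],
}


def _selu(x):
    return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * np.expm1(x))


def _selu_grad(x):
    return _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(x))


@dataclass
class EvaluationReport:
    """Prediction quality on one declared split.

    R^2 is the squared Pearson correlation of predicted vs expected values;
    mean percent error is mean(|pred - expected| / expected) * 100.
    """

    r_squared_monomer: float
    r_squared_aggregate: float
    mean_pct_error_monomer: float
    mean_pct_error_aggregate: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


class SeluNetRegressor(BaseEstimator, RegressorMixin):
    """Seven-layer linear/SELU network for (monomer, aggregate) regression.

    Layer sequence: linear, SELU, linear, SELU, linear, SELU, linear; hidden
    width ``hidden`` throughout, output dimension 2.  Inputs are z-scored and
    targets log-transformed then z-scored, with statistics learned on the
    training data; ``predict`` applies the inverse transform, so outputs are
    strictly positive.

    Training: full-batch Adam on the MSE of the transformed targets,
    LeCun-normal initialisation (the standard pairing with SELU),
    deterministic given ``seed``.
    """

    def __init__(self, hidden: int = 16, epochs: int = 2000,
                 learning_rate: float = 0.01, seed: int = 0):
        self.hidden = hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed

    # -- transforms ---------------------------------------------------------
    def _forward_target(self, Y):
        return (np.log(Y) - self.target_mean_) / self.target_scale_

    def _inverse_target(self, Z):
        return np.exp(Z * self.target_scale_ + self.target_mean_)

    def _forward_raw(self, X):
        """Network forward pass on standardized inputs; returns activations."""
        zs, h = [], X
        for i, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            z = h @ W + b
            zs.append((h, z))
            h = _selu(z) if i < len(self.weights_) - 1 else z
        return h, zs

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or Y.shape[1] != 2:
            raise ValueError("X must be (n, p) and Y (n, 2)")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 training rows")
        keep = np.all(np.isfinite(X), axis=1) & np.all(np.isfinite(Y), axis=1)
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} rows with non-finite features")
            X, Y = X[keep], Y[keep]
        if np.any(Y <= 0):
            raise ValueError("concentrations must be > 0 for the log transform")

        self.input_mean_ = X.mean(axis=0)
        self.input_scale_ = X.std(axis=0, ddof=0)
        self.input_scale_[self.input_scale_ == 0] = 1.0
        logY = np.log(Y)
        self.target_mean_ = logY.mean(axis=0)
        self.target_scale_ = logY.std(axis=0, ddof=0)
        self.target_scale_[self.target_scale_ == 0] = 1.0

        Xs = (X - self.input_mean_) / self.input_scale_
        Z = self._forward_target(Y)

        rng = np.random.default_rng(self.seed)
        dims = [X.shape[1], self.hidden, self.hidden, self.hidden, 2]
        self.weights_ = [
            rng.normal(0.0, 1.0 / np.sqrt(fin), size=(fin, fout))
            for fin, fout in zip(dims[:-1], dims[1:])
        ]
        self.biases_ = [np.zeros(fout) for fout in dims[1:]]

        params = self.weights_ + self.biases_
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        n = Xs.shape[0]
        self.loss_curve_ = np.empty(self.epochs)

        for epoch in range(self.epochs):
            out, zs = self._forward_raw(Xs)
            err = out - Z
            self.loss_curve_[epoch] = float(np.mean(err**2))
            grad = 2.0 * err / (n * Z.shape[1])
            gW = [None] * len(self.weights_)
            gB = [None] * len(self.biases_)
            for i in range(len(self.weights_) - 1, -1, -1):
                h_in, z = zs[i]
                gW[i] = h_in.T @ grad
                gB[i] = grad.sum(axis=0)
                if i > 0:
                    grad = (grad @ self.weights_[i].T) * _selu_grad(zs[i - 1][1])
            grads = gW + gB
            t = epoch + 1
            for j, (p, g) in enumerate(zip(params, grads)):
                m[j] = b1 * m[j] + (1 - b1) * g
                v[j] = b2 * v[j] + (1 - b2) * g * g
                mhat = m[j] / (1 - b1**t)
                vhat = v[j] / (1 - b2**t)
                p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_mean_.size:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match the trained "
                f"model ({self.input_mean_.size}); check the feature mode"
            )
        Xs = (X - self.input_mean_) / self.input_scale_
        out, _ = self._forward_raw(Xs)
        return self._inverse_target(out)


def _design_matrix(features: pd.DataFrame, mode: str) -> np.ndarray:
    try:
        cols = MODE_COLUMNS[mode]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}; use one of {list(MODE_COLUMNS)}")
    missing = set(cols) - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")
    return features[cols].to_numpy(dtype=float)


def train_model(features: pd.DataFrame, targets, mode: str = "dissociation_only",
                seed: int = 0, **hyper) -> SeluNetRegressor:
    """Train the network on a feature table and (monomer, aggregate) targets.

    ``targets`` is (n, 2) in consistent concentration units (ug/mL in the
    canned designs).  The fitted estimator stores the mode for later
    dimension checking.
    """
    X = _design_matrix(features, mode)
    reg = SeluNetRegressor(seed=seed, **hyper).fit(X, np.asarray(targets, dtype=float))
    reg.mode_ = mode
    return reg


def predict(model: SeluNetRegressor, features: pd.DataFrame) -> np.ndarray:
    """(monomer, aggregate) predictions for a feature table."""
    return model.predict(_design_matrix(features, getattr(model, "mode_", "dissociation_only")))


def _pearson_r2(pred, expected):
    if np.std(pred) == 0 or np.std(expected) == 0:
        return float("nan")
    r = float(np.corrcoef(pred, expected)[0, 1])
    if r < 0:
        warnings.warn("predicted and expected values are anti-correlated")
    return r * r


def evaluate(predictions, expected) -> EvaluationReport:
    """Score paired (monomer, aggregate) predictions against known values."""
    P = np.asarray(predictions, dtype=float)
    E = np.asarray(expected, dtype=float)
    if P.size == 0 or P.shape != E.shape or P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("predictions and expected must be matching (n, 2) arrays")
    if np.any(E <= 0):
        raise ValueError("expected concentrations must be > 0")
    pct = np.abs(P - E) / E * 100.0
    return EvaluationReport(
        r_squared_monomer=_pearson_r2(P[:, 0], E[:, 0]),
        r_squared_aggregate=_pearson_r2(P[:, 1], E[:, 1]),
        mean_pct_error_monomer=float(pct[:, 0].mean()),
        mean_pct_error_aggregate=float(pct[:, 1].mean()),
        n=P.shape[0],
    )


def _targets_from_manifest(df: pd.DataFrame) -> np.ndarray:
    mono = df["total_mg_per_ml"] * (1 - df["aggregate_fraction"]) * 1000.0
    agg = df["total_mg_per_ml"] * df["aggregate_fraction"] * 1000.0
    return np.column_stack([mono.to_numpy(), agg.to_numpy()])


def train_and_evaluate(features: pd.DataFrame, manifest: pd.DataFrame,
                       mode: str = "dissociation_only", seed: int = 0,
                       **hyper):
    """Train on the manifest's train split, evaluate on its validation split.

    Returns (model, validation EvaluationReport, predictions DataFrame).
    """
    df = features.merge(
        manifest[["sample_id", "total_mg_per_ml", "aggregate_fraction", "split"]],
        on="sample_id",
    )
    train = df[df["split"] == "train"]
    val = df[df["split"] == "validation"]
    if val.empty:
        raise ValueError("manifest has no validation split")
    model = train_model(train, _targets_from_manifest(train), mode=mode,
                        seed=seed, **hyper)
    P = predict(model, val)
    E = _targets_from_manifest(val)
    report = evaluate(P, E)
    preds = pd.DataFrame({
        "sample_id": val["sample_id"].to_numpy(),
        "predicted_monomer_ug_per_ml": P[:, 0],
        "predicted_aggregate_ug_per_ml": P[:, 1],
        "expected_monomer_ug_per_ml": E[:, 0],
        "expected_aggregate_ug_per_ml": E[:, 1],
    })
    return model, report, preds


def cross_validate(features: pd.DataFrame, targets, mode: str = "dissociation_only",
                   k: int = 5, seed: int = 0, **hyper):
    """Seeded k-fold cross-validation; returns the per-fold EvaluationReports."""
    X = np.arange(len(features))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(X)
    folds = np.array_split(perm, k)
    targets = np.asarray(targets, dtype=float)
    reports = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        model = train_model(features.iloc[train_idx], targets[train_idx],
                            mode=mode, seed=seed + i, **hyper)
        P = predict(model, features.iloc[test_idx])
        reports.append(evaluate(P, targets[test_idx]))
    return reports


_MODEL_VERSION = 1


def save_model(model: SeluNetRegressor, path: "str | Path") -> None:
    """Serialize a trained model to versioned, self-describing JSON."""
    payload = {
        "format": "aggsense-selu-net",
        "version": _MODEL_VERSION,
        "mode": getattr(model, "mode_", None),
        "hyper": model.get_params(),
        "input_mean": model.input_mean_.tolist(),
        "input_scale": model.input_scale_.tolist(),
        "target_mean": model.target_mean_.tolist(),
        "target_scale": model.target_scale_.tolist(),
        "weights": [W.tolist() for W in model.weights_],
        "biases": [b.tolist() for b in model.biases_],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: "str | Path") -> SeluNetRegressor:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "aggsense-selu-net":
        raise ValueError(f"{path}: not an aggsense model file")
    model = SeluNetRegressor(**payload["hyper"])
    model.mode_ = payload["mode"]
    model.input_mean_ = np.array(payload["input_mean"])
    model.input_scale_ = np.array(payload["input_scale"])
    model.target_mean_ = np.array(payload["target_mean"])
    model.target_scale_ = np.array(payload["target_scale"])
    model.weights_ = [np.array(W) for W in payload["weights"]]
    model.biases_ = [np.array(b) for b in payload["biases"]]
    return model
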