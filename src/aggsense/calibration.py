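"""Endpoint calibration of aggregate concentration with LOD/LOQ.

The response at the end of the dissociation phase (r_300) is dominated by the
slowly dissociating aggregate species and is calibrated against known
aggregate concentrations:

* a saturating one-site curve R = R0 + R_cap * C / (C + K_half) describes the
  full concentration range (R0 absorbs the residual monomer tail);
* a straight line fitted to the sub-saturating points (r_300 at or below the
  exclusion threshold, 550 pm by default) is inverted to predict unknown
  aggregate concentrations;
* LOD = 3.3*sigma/S and LOQ = 10*sigma/S use the residual standard deviation
  sigma and slope S of a linear fit restricted to the stated low-concentration
  window (9-21 ug/mL by default).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CalibrationModel",
    "EndpointCalibrator",
    "fit_calibration",
    "lod_loq",
    "predict_aggregate",
    "calibrate_from_features",
    "predict_controls",
]

BELOW_DETECTION = "below detection"
BELOW_QUANTIFICATION = "detected, below quantification"
QUANTIFIED = "quantified"


@dataclass
class CalibrationModel:
    """Fitted endpoint-vs-concentration calibration.

    Concentrations in ug/mL, responses in pm.  ``linear_slope`` /
    ``linear_intercept`` belong to the prediction line (sub-saturating
    points); ``sigma`` and ``lod_slope`` to the LOD/LOQ window fit, so that
    lod = 3.3*sigma/lod_slope and loq = 10*sigma/lod_slope hold exactly.
    """

    curve_r_cap: float
    curve_k_half: float
    curve_r0: float
    curve_r_squared: float
    linear_slope: float
    linear_intercept: float
    linear_r_squared: float
    sigma: float
    lod_slope: float
    lod: float
    loq: float
    linear_range: tuple
    exclusion_threshold: float
    n_points: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["linear_range"] = list(d["linear_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        d = dict(d)
        d["linear_range"] = tuple(d["linear_range"])
        return cls(**d)


def lod_loq(sigma: float, slope: float) -> tuple:
    """(LOD, LOQ) = (3.3*sigma/S, 10*sigma/S) in concentration units."""
    if slope <= 0:
        raise ValueError(f"slope must be > 0, got {slope}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return 3.3 * sigma / slope, 10.0 * sigma / slope


def _linefit(conc: np.ndarray, resp: np.ndarray):
    """OLS line with residual sd using an (n-2) denominator."""
    slope, intercept = np.polyfit(conc, resp, 1)
    resid = resp - (slope * conc + intercept)
    dof = max(conc.size - 2, 1)
    sigma = float(np.sqrt(resid @ resid / dof))
    sst = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else float("nan")
    return float(slope), float(intercept), sigma, r2


def fit_calibration(
    points,
    exclusion_threshold: float = 550.0,
    linear_range: Optional[tuple] = None,
    lod_range: tuple = (9.0, 21.0),
    fit_offset: bool = True,
) -> CalibrationModel:
    """Fit the calibration from (aggregate_conc ug/mL, r_300 pm) pairs.

    ``linear_range`` optionally restricts the prediction line to a
    concentration window; by default all points under the exclusion threshold
    are used.  ``lod_range`` is the window of the LOD/LOQ line; if it holds
    fewer than 3 points the prediction line's sigma and slope are used
    instead.  ``fit_offset=False`` forces the one-site curve through the
    origin.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need >= 5 (conc, r_300) points")
    conc, resp = pts[:, 0], pts[:, 1]
    if np.ptp(conc) <= 0:
        raise ValueError("points must span a nonzero concentration range")

    # one-site saturation curve over all points
    if fit_offset:
        def curve(c, r_cap, k_half, r0):
            return r0 + r_cap * c / (c + k_half)
        p0 = (float(resp.max()), float(np.median(conc)), float(resp.min()))
        bounds = ([0, 1e-9, -np.inf], [np.inf, np.inf, np.inf])
    else:
        def curve(c, r_cap, k_half):
            return r_cap * c / (c + k_half)
        p0 = (float(resp.max()), float(np.median(conc)))
        bounds = ([0, 1e-9], [np.inf, np.inf])
    popt, _ = curve_fit(curve, conc, resp, p0=p0, bounds=bounds, maxfev=20000)
    pred = curve(conc, *popt)
    sst = float(np.sum((resp - resp.mean()) ** 2))
    curve_r2 = 1.0 - float(np.sum((resp - pred) ** 2)) / sst if sst > 0 else float("nan")
    r_cap, k_half = float(popt[0]), float(popt[1])
    r0 = float(popt[2]) if fit_offset else 0.0

    keep = resp <= exclusion_threshold
    if linear_range is not None:
        keep &= (conc >= linear_range[0]) & (conc <= linear_range[1])
    if keep.sum() < 2:
        raise ValueError("no linear range: too few points under the exclusion threshold")
    slope, intercept, lin_sigma, lin_r2 = _linefit(conc[keep], resp[keep])
    if slope <= 0:
        raise ValueError("calibration slope is non-positive")

    in_lod = keep & (conc >= lod_range[0]) & (conc <= lod_range[1])
    if in_lod.sum() >= 3:
        lod_slope, _, sigma, _ = _linefit(conc[in_lod], resp[in_lod])
        if lod_slope <= 0:  # a degenerate narrow window falls back to the main line
            lod_slope, sigma = slope, lin_sigma
    else:
        lod_slope, sigma = slope, lin_sigma
    lod, loq = lod_loq(sigma, lod_slope)

    return CalibrationModel(
        curve_r_cap=r_cap, curve_k_half=k_half, curve_r0=r0,
        curve_r_squared=curve_r2,
        linear_slope=slope, linear_intercept=intercept, linear_r_squared=lin_r2,
        sigma=sigma, lod_slope=float(lod_slope), lod=float(lod), loq=float(loq),
        linear_range=tuple(linear_range) if linear_range else
        (float(conc[keep].min()), float(conc[keep].max())),
        exclusion_threshold=float(exclusion_threshold),
        n_points=int(pts.shape[0]),
    )


def predict_aggregate(model: CalibrationModel, r_300: float):
    """Invert the linear calibration for one endpoint response.

    Returns (concentration ug/mL, flag); responses above the exclusion
    threshold are outside the linear range and raise.
    """
    if r_300 > model.exclusion_threshold:
        raise ValueError(
            f"r_300={r_300:.1f} pm above exclusion threshold "
            f"{model.exclusion_threshold} pm: outside the linear range"
        )
    conc = (r_300 - model.linear_intercept) / model.linear_slope
    if conc < model.lod:
        flag = BELOW_DETECTION
    elif conc < model.loq:
        flag = BELOW_QUANTIFICATION
    else:
        flag = QUANTIFIED
    return float(conc), flag


class EndpointCalibrator(BaseEstimator, RegressorMixin):
    """sklearn-style wrapper: fit on (conc, r_300) pairs, predict conc from r_300."""

    def __init__(self, exclusion_threshold: float = 550.0,
                 linear_range: Optional[tuple] = None,
                 lod_range: tuple = (9.0, 21.0), fit_offset: bool = True):
        self.exclusion_threshold = exclusion_threshold
        self.linear_range = linear_range
        self.lod_range = lod_range
        self.fit_offset = fit_offset

    def fit(self, X, y):
        """X: (n, 1) aggregate concentrations ug/mL; y: r_300 responses pm."""
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        self.model_ = fit_calibration(
            np.column_stack([X, y]),
            exclusion_threshold=self.exclusion_threshold,
            linear_range=self.linear_range,
            lod_range=self.lod_range,
            fit_offset=self.fit_offset,
        )
        return self

    def predict(self, X):
        """Predict aggregate concentration from r_300 values (n,) or (n, 1)."""
        X = np.asarray(X, dtype=float).reshape(-1)
        return np.array([predict_aggregate(self.model_, r)[0] for r in X])


def _with_truth(features: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    df = features.merge(
        manifest[["sample_id", "total_mg_per_ml", "aggregate_fraction", "split"]],
        on="sample_id",
    )
    df["aggregate_ug_per_ml"] = (
        df["total_mg_per_ml"] * df["aggregate_fraction"] * 1000.0
    )
    df["monomer_ug_per_ml"] = (
        df["total_mg_per_ml"] * (1.0 - df["aggregate_fraction"]) * 1000.0
    )
    return df


def calibrate_from_features(features: pd.DataFrame, manifest: pd.DataFrame,
                            exclusion_threshold: float = 550.0,
                            lod_range: tuple = (9.0, 21.0)) -> CalibrationModel:
    """Fit the calibration on the manifest's training split."""
    df = _with_truth(features, manifest)
    train = df[df["split"] == "train"]
    return fit_calibration(
        train[["aggregate_ug_per_ml", "r_300"]].to_numpy(),
        exclusion_threshold=exclusion_threshold, lod_range=lod_range,
    )


def predict_controls(model: CalibrationModel, features: pd.DataFrame,
                     manifest: pd.DataFrame) -> pd.DataFrame:
    """Predict aggregate concentration for the control split."""
    df = _with_truth(features, manifest)
    ctrl = df[df["split"] == "control"]
    rows = []
    for _, row in ctrl.iterrows():
        try:
            conc, flag = predict_aggregate(model, row["r_300"])
        except ValueError:
            conc, flag = float("nan"), "out of linear range"
        rows.append({
            "sample_id": row["sample_id"],
            "r_300": row["r_300"],
            "predicted_ug_per_ml": conc,
            "expected_ug_per_ml": row["aggregate_ug_per_ml"],
            "flag": flag,
        })
    return pd.DataFrame(rows)
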