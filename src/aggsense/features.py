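"""Scalar and curve features of sensorgrams used for aggregate quantification.

Two feature families are produced:

* endpoint/derivative features — maximum response, response at the end of the
  dissociation phase (300 s in the standard protocol), smoothed-derivative
  maximum and the derivative just after dissociation starts (the "112 s"
  landmark, generalised to dissociation start + 2 s);
* dimensional-reduction features — the triples of single-exponential fits
  a + b*exp(-c*t) (association) and d + f*exp(-g*t) (dissociation), which
  compress each phase to three parameters for the downstream regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .kinetics import Sensorgram

__all__ = [
    "ExponentialFit",
    "FeatureSet",
    "response_at",
    "derivative_trace",
    "summary_features",
    "fit_exponentials",
    "ExponentialFeaturizer",
    "extract_features",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "sample_id", "r_max_obs", "r_300", "d_max", "d_112",
    "a", "b", "c", "d", "f", "g", "rms_assoc", "rms_dissoc",
]

#: below this amplitude (pm) an exponential fit is considered degenerate and
#: its rate is pinned to 0
DEGENERATE_AMPLITUDE = 1e-6


@dataclass(frozen=True)
class ExponentialFit:
    """offset + amplitude * exp(-rate * t) fitted over one phase window."""

    offset: float
    amplitude: float
    rate: float
    rms: float
    degenerate: bool = False

    def as_tuple(self) -> tuple:
        return (self.offset, self.amplitude, self.rate)


@dataclass(frozen=True)
class FeatureSet:
    r_max_obs: float
    r_300: float
    d_max: float
    d_112: float
    assoc_params: "ExponentialFit | None" = None
    dissoc_params: "ExponentialFit | None" = None


def response_at(trace: Sensorgram, t: float) -> float:
    """Linearly interpolated response at time ``t`` (exact at grid points)."""
    if t < trace.time[0] or t > trace.time[-1]:
        raise ValueError(
            f"t={t} outside trace range [{trace.time[0]}, {trace.time[-1]}]"
        )
    return float(np.interp(t, trace.time, trace.response))


def derivative_trace(trace: Sensorgram, window: int = 11) -> Sensorgram:
    """Savitzky-Golay (order 2) smoothed first derivative, pm/s.

    The derivative lives on the same time grid; edges are handled by the
    filter's polynomial extension.  ``window`` must be odd, >= 3 and no larger
    than the trace.
    """
    n = trace.time.size
    if window % 2 == 0 or window < 3 or window > n:
        raise ValueError(f"window must be odd, >=3 and <= {n}, got {window}")
    deriv = savgol_filter(
        trace.response, window_length=window, polyorder=min(2, window - 1),
        deriv=1, delta=trace.dt, mode="interp",
    )
    return Sensorgram(
        time=trace.time.copy(), response=deriv, protocol=trace.protocol,
        metadata={**trace.metadata, "derivative": True},
    )


def derivative_at(trace: Sensorgram, t: float, window: int = 11) -> float:
    return response_at(derivative_trace(trace, window), t)


def _phase_window(trace: Sensorgram, phase: str) -> np.ndarray:
    p = trace.protocol
    if phase == "association":
        return (trace.time >= p.t_baseline_end) & (trace.time < p.t_assoc_end)
    if phase == "dissociation":
        return trace.time >= p.t_assoc_end
    raise ValueError(f"unknown phase {phase!r}")


def _fit_single_exponential(t: np.ndarray, y: np.ndarray,
                            rate_grid=(1e-4, 1e-1, 7)) -> ExponentialFit:
    """Least-squares fit of offset + amplitude*exp(-rate*t).

    For each candidate rate on a log-spaced grid the linear pair
    (offset, amplitude) is solved exactly; the best candidate seeds a full
    nonlinear refinement.  Near-zero amplitude pins the rate to 0.
    """
    t = t - t[0]

    def linear_solve(rate):
        e = np.exp(-rate * t)
        A = np.column_stack([np.ones_like(t), e])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        return coef, float(resid @ resid)

    best_rate, best_coef, best_ssr = None, None, np.inf
    for rate in np.geomspace(rate_grid[0], rate_grid[1], int(rate_grid[2])):
        coef, ssr = linear_solve(rate)
        if ssr < best_ssr:
            best_rate, best_coef, best_ssr = rate, coef, ssr

    def residual(theta):
        off, amp, lograte = theta
        return off + amp * np.exp(-np.exp(lograte) * t) - y

    theta0 = np.array([best_coef[0], best_coef[1], np.log(best_rate)])
    sol = least_squares(residual, theta0, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                        max_nfev=200)
    off, amp, rate = sol.x[0], sol.x[1], float(np.exp(sol.x[2]))
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    if abs(amp) < DEGENERATE_AMPLITUDE:
        # flat signal: rate unidentifiable, pinned to 0 by convention
        return ExponentialFit(offset=float(np.mean(y)), amplitude=0.0, rate=0.0,
                              rms=float(np.std(y)), degenerate=True)
    return ExponentialFit(offset=float(off), amplitude=float(amp), rate=rate,
                          rms=rms)


def fit_exponentials(trace: Sensorgram, phase: str = "both"):
    """Fit the per-phase single-exponential reduction.

    Returns an :class:`ExponentialFit` for ``phase`` in
    {"association", "dissociation"}; for "both", a tuple
    (association_fit, dissociation_fit).  Time is re-zeroed at the window
    start, so for a pure 1:1 dissociation the fitted rate equals k_off and
    the amplitude equals the response at dissociation start.
    """
    if phase == "both":
        return (fit_exponentials(trace, "association"),
                fit_exponentials(trace, "dissociation"))
    mask = _phase_window(trace, phase)
    if mask.sum() < 4:
        raise ValueError(f"{phase} window is degenerate ({int(mask.sum())} points)")
    return _fit_single_exponential(trace.time[mask], trace.response[mask])


def summary_features(trace: Sensorgram, derivative_window: int = 11,
                     with_exponentials: bool = True) -> FeatureSet:
    """Endpoint and derivative landmarks of one sensorgram.

    r_max_obs: maximum response over the association phase (incl. endpoint);
    r_300: response at the protocol's end time; d_max: maximum smoothed
    derivative over association; d_112: smoothed derivative at dissociation
    start + 2 s.
    """
    p = trace.protocol
    assoc = (trace.time >= p.t_baseline_end) & (trace.time <= p.t_assoc_end)
    deriv = derivative_trace(trace, derivative_window)
    assoc_fit = dissoc_fit = None
    if with_exponentials:
        assoc_fit, dissoc_fit = fit_exponentials(trace, "both")
    return FeatureSet(
        r_max_obs=float(np.max(trace.response[assoc])),
        r_300=response_at(trace, p.t_end),
        d_max=float(np.max(deriv.response[assoc])),
        d_112=response_at(deriv, p.t_assoc_end + 2.0),
        assoc_params=assoc_fit,
        dissoc_params=dissoc_fit,
    )


class ExponentialFeaturizer(BaseEstimator, TransformerMixin):
    """Transform sensorgrams into the per-sample feature table.

    A stateless transformer (fit is a no-op) so it composes with sklearn
    pipelines operating on lists of :class:`Sensorgram`.
    """

    def __init__(self, derivative_window: int = 11):
        self.derivative_window = derivative_window

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = []
        for i, trace in enumerate(X):
            fs = summary_features(trace, self.derivative_window)
            rows.append({
                "sample_id": trace.metadata.get("sample_id", f"trace{i}"),
                "r_max_obs": fs.r_max_obs, "r_300": fs.r_300,
                "d_max": fs.d_max, "d_112": fs.d_112,
                "a": fs.assoc_params.offset, "b": fs.assoc_params.amplitude,
                "c": fs.assoc_params.rate,
                "d": fs.dissoc_params.offset, "f": fs.dissoc_params.amplitude,
                "g": fs.dissoc_params.rate,
                "rms_assoc": fs.assoc_params.rms,
                "rms_dissoc": fs.dissoc_params.rms,
            })
        return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def extract_features(manifest: pd.DataFrame, derivative_window: int = 11) -> pd.DataFrame:
    """Feature table for every sample of a manifest with attached traces."""
    from .io import load_manifest_traces

    manifest = load_manifest_traces(manifest)
    traces = [manifest.attrs["traces"][sid] for sid in manifest["sample_id"]]
    for sid, tr in zip(manifest["sample_id"], traces):
        tr.metadata.setdefault("sample_id", sid)
    return ExponentialFeaturizer(derivative_window).transform(traces)
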