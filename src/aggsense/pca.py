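"""PCA discrimination of low-aggregate samples.

Feature columns are the raw responses sampled over a late-dissociation window
(190-300 s by default, where aggregate retention dominates) concatenated with
smoothed derivatives over an early-dissociation window (110-122 s, where the
dissociation rate contrast is largest).  PC1 of the mean-centred matrix then
separates samples by aggregate level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .features import derivative_trace, response_at
from .kinetics import Sensorgram

__all__ = ["PCAResult", "build_feature_matrix", "SensorgramPCA", "run_pca"]


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    explained_variance: np.ndarray
    feature_names: list
    sample_ids: list


def _window_grid(window: tuple, stride: float) -> np.ndarray:
    lo, hi = window
    if hi <= lo or stride <= 0:
        raise ValueError("window must satisfy hi > lo and stride > 0")
    n = int(np.floor((hi - lo) / stride + 1e-9)) + 1
    return lo + stride * np.arange(n)


def build_feature_matrix(
    traces,
    response_window: tuple = (190.0, 300.0),
    derivative_window: tuple = (110.0, 122.0),
    stride: float = 1.0,
    smoothing_window: int = 11,
    sample_ids=None,
) -> pd.DataFrame:
    """Sample responses and derivatives on regular grids inside two windows.

    Returns a DataFrame with one row per trace and columns ``r_<t>`` /
    ``d_<t>``; grid endpoints are inclusive (a 190-300 s window at stride 1
    gives 111 response columns).
    """
    traces = list(traces)
    if sample_ids is None:
        sample_ids = [
            tr.metadata.get("sample_id", f"trace{i}") for i, tr in enumerate(traces)
        ]
    r_grid = _window_grid(response_window, stride)
    d_grid = _window_grid(derivative_window, stride)
    cols = [f"r_{t:g}" for t in r_grid] + [f"d_{t:g}" for t in d_grid]
    rows = []
    for tr in traces:
        if r_grid[0] < tr.time[0] or r_grid[-1] > tr.time[-1]:
            raise ValueError("response window outside trace range")
        if d_grid[0] < tr.time[0] or d_grid[-1] > tr.time[-1]:
            raise ValueError("derivative window outside trace range")
        dtr = derivative_trace(tr, smoothing_window)
        rows.append(
            [response_at(tr, t) for t in r_grid] + [response_at(dtr, t) for t in d_grid]
        )
    return pd.DataFrame(rows, columns=cols, index=pd.Index(sample_ids, name="sample_id"))


class SensorgramPCA(BaseEstimator, TransformerMixin):
    """Mean-centred PCA with a deterministic sign convention.

    Per component, the sign is chosen so the largest-magnitude loading is
    positive.  ``scale=True`` additionally divides columns by their sd
    (unit-variance scaling); the default keeps responses and derivatives on
    their native pm / pm-per-s scales.
    """

    def __init__(self, n_components=None, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("need >= 2 samples and >= 2 features")
        if not np.any(X.std(axis=0) > 0):
            raise ValueError("degenerate input: zero variance in every feature")
        self.scale_ = X.std(axis=0, ddof=0) if self.scale else np.ones(X.shape[1])
        self.scale_[self.scale_ == 0] = 1.0
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        self._pca.fit(X / self.scale_)
        flip = np.ones(self._pca.components_.shape[0])
        for k, comp in enumerate(self._pca.components_):
            if comp[np.argmax(np.abs(comp))] < 0:
                flip[k] = -1.0
        self.flip_ = flip
        self.components_ = self._pca.components_ * flip[:, None]
        self.explained_variance_ = self._pca.explained_variance_
        self.mean_ = self._pca.mean_ * self.scale_
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return self._pca.transform(X / self.scale_) * self.flip_[None, :]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def run_pca(matrix: pd.DataFrame, n_components=None, scale: bool = False) -> PCAResult:
    """PCA of a feature matrix; scores/loadings under the fixed sign convention."""
    est = SensorgramPCA(n_components=n_components, scale=scale)
    scores = est.fit_transform(matrix.to_numpy())
    return PCAResult(
        scores=scores,
        loadings=est.components_.T,
        explained_variance=est.explained_variance_,
        feature_names=list(matrix.columns),
        sample_ids=list(matrix.index),
    )
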