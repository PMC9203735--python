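"""Temporal cleaning of network time series.

Zero-phase Butterworth band-pass (default 0.01-0.1 Hz), CompCor-style
principal-component noise regressors, confound regression, and motion-outlier
censoring at the standard FD > 0.5 mm / standardized DVARS > 1.5 thresholds.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .containers import (
    REASON_BOTH,
    REASON_DVARS,
    REASON_FD,
    CensorMask,
    ConfoundTable,
    TimeSeriesMatrix,
)

__all__ = [
    "BandpassFilter",
    "CompCor",
    "ConfoundRegressor",
    "bandpass",
    "compcor_components",
    "regress_confounds",
    "censor_outliers",
]

logger = logging.getLogger(__name__)

DEFAULT_FD_THRESH_MM = 0.5
DEFAULT_DVARS_THRESH = 1.5


class BandpassFilter(BaseEstimator, TransformerMixin):
    """Zero-phase forward-backward Butterworth band-pass (order 4).

    Stateless transformer; ``fit`` only validates the band against Nyquist.
    """

    def __init__(self, low_hz: float = 0.01, high_hz: float = 0.1,
                 sampling_interval: float = 2.0, order: int = 4):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.sampling_interval = sampling_interval
        self.order = order

    def _validate_band(self, tr: float) -> None:
        nyquist = 0.5 / tr
        if self.high_hz >= nyquist:
            raise ValueError(
                f"band edge {self.high_hz} Hz is at or above the Nyquist "
                f"frequency {nyquist} Hz for sampling interval {tr} s"
            )
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")

    def fit(self, X=None, y=None) -> "BandpassFilter":
        tr = X.sampling_interval if isinstance(X, TimeSeriesMatrix) else self.sampling_interval
        self._validate_band(tr)
        self.fitted_ = True
        return self

    def transform(self, X):
        tr = X.sampling_interval if isinstance(X, TimeSeriesMatrix) else self.sampling_interval
        self._validate_band(tr)
        values = X.values if isinstance(X, TimeSeriesMatrix) else np.asarray(X, dtype=float)
        nyquist = 0.5 / tr
        sos = signal.butter(
            self.order, [self.low_hz / nyquist, self.high_hz / nyquist],
            btype="bandpass", output="sos",
        )
        demeaned = values - values.mean(axis=0)
        out = signal.sosfiltfilt(sos, demeaned, axis=0)
        out = out - out.mean(axis=0)  # finite-length edge effects leave a tiny mean
        if isinstance(X, TimeSeriesMatrix):
            return X.copy_with(out)
        return out


def bandpass(ts: TimeSeriesMatrix, low_hz: float = 0.01, high_hz: float = 0.1) -> TimeSeriesMatrix:
    """Zero-phase band-pass of every channel; output is mean-free per channel."""
    return BandpassFilter(low_hz, high_hz, ts.sampling_interval).fit(ts).transform(ts)


class CompCor(BaseEstimator, TransformerMixin):
    """Principal-component noise regressors from noise-compartment series.

    Fit on a frames x voxels matrix from noise compartments (CSF/WM-like);
    ``components_`` holds the top-k unit-variance, mutually orthogonal
    component time courses. Voxel series are variance-normalized before PCA.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X, y=None) -> "CompCor":
        X = np.asarray(X, dtype=float)
        t, v = X.shape
        k = self.n_components
        if k > 0 and k >= min(t, v):
            raise ValueError(
                f"n_components = {k} must be < min(frames, voxels) = {min(t, v)}"
            )
        if k == 0:
            self.components_ = np.empty((t, 0))
            return self
        sd = X.std(axis=0, ddof=1)
        if np.all(sd == 0):
            raise ValueError("degenerate noise series: all voxels constant")
        keep = sd > 0
        xn = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(xn)  # (T, k), orthogonal columns
        scores = scores / scores.std(axis=0, ddof=1)
        self.components_ = scores
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self

    def transform(self, X):
        return self.components_


def compcor_components(noise_series: np.ndarray, k: int = 5) -> np.ndarray:
    """Top-k unit-variance principal-component time courses of noise voxels."""
    return CompCor(n_components=k).fit(noise_series).components_


class ConfoundRegressor(BaseEstimator, TransformerMixin):
    """Residualize each channel on [intercept, regressors] by least squares."""

    def __init__(self, regressors: np.ndarray | None = None):
        self.regressors = regressors

    def fit(self, X=None, y=None) -> "ConfoundRegressor":
        self.fitted_ = True
        return self

    def transform(self, X):
        values = X.values if isinstance(X, TimeSeriesMatrix) else np.asarray(X, dtype=float)
        reg = self.regressors
        t = values.shape[0]
        if reg is None or np.size(reg) == 0:
            out = values - values.mean(axis=0)
        else:
            reg = np.asarray(reg, dtype=float)
            if reg.ndim == 1:
                reg = reg[:, None]
            if reg.shape[0] != t:
                raise ValueError("regressors must have one row per frame")
            design = np.column_stack([np.ones(t), reg])
            design = _drop_collinear(design)
            beta, *_ = np.linalg.lstsq(design, values, rcond=None)
            out = values - design @ beta
        if isinstance(X, TimeSeriesMatrix):
            return X.copy_with(out)
        return out


def _drop_collinear(design: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Drop columns that add no rank, keeping earlier columns."""
    keep: list[int] = []
    for j in range(design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(design.shape)) > len(keep):
            keep.append(j)
        else:
            logger.warning("dropping collinear regressor column %d", j)
    return design[:, keep]


def regress_confounds(ts: TimeSeriesMatrix, regressors: np.ndarray | None) -> TimeSeriesMatrix:
    """Least-squares residuals of each channel on [intercept, regressors]."""
    return ConfoundRegressor(regressors).fit().transform(ts)


def censor_outliers(
    conf: ConfoundTable,
    fd_thresh: float = DEFAULT_FD_THRESH_MM,
    dvars_thresh: float = DEFAULT_DVARS_THRESH,
) -> CensorMask:
    """Flag motion outliers: FD strictly above ``fd_thresh`` mm OR standardized
    DVARS strictly above ``dvars_thresh``. Frames are flagged, not removed."""
    if fd_thresh <= 0 or dvars_thresh <= 0:
        raise ValueError("thresholds must be positive")
    fd_bad = conf.fd > fd_thresh
    dv_bad = conf.std_dvars > dvars_thresh
    bad = fd_bad | dv_bad
    reasons: dict[int, str] = {}
    for i in np.flatnonzero(bad):
        if fd_bad[i] and dv_bad[i]:
            reasons[int(i)] = REASON_BOTH
        elif fd_bad[i]:
            reasons[int(i)] = REASON_FD
        else:
            reasons[int(i)] = REASON_DVARS
    return CensorMask(keep=~bad, reasons=reasons)
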