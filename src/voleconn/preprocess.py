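"""Signal cleaning for resting-state functional series.

The cleaning pipeline mirrors common rsfMRI practice for small-animal data:
discard the first volumes acquired before signal equilibrium, regress out
nuisance signals (top principal-component time series of the non-gray-matter
compartment plus six rigid-body motion parameters), band-pass to the
0.01-0.1 Hz band where resting-state fluctuations live, and box-smooth
volumes spatially.  All steps are linear operators.

The band-pass is a zero-phase (forward-backward) Butterworth filter of
order 5; the family is a package choice, constrained to pass 0.9 of a
passband sinusoid and at most 0.1 of a sinusoid at twice the upper cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator, TransformerMixin


def drop_initial_volumes(series: np.ndarray, k: int) -> np.ndarray:
    """Remove the first ``k`` rows (time points) of a series."""
    series = np.asarray(series)
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= series.shape[0]:
        raise ValueError(f"cannot discard {k} of {series.shape[0]} volumes")
    return series[k:]


def extract_nuisance_eigenvectors(nongray_series: np.ndarray, k: int = 5) -> np.ndarray:
    """Top-k left singular vectors of the column-centered voxel matrix.

    These orthonormal time series summarize non-neuronal signal sources
    (vasculature, ventricles, white matter) and are regressed out of the
    gray-matter series.
    """
    x = np.asarray(nongray_series, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D time x voxel matrix")
    if k < 1 or k > min(x.shape):
        raise ValueError(f"k must be in [1, {min(x.shape)}]")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    if s[0] <= 1e-12 * max(x.shape):
        raise ValueError("input has rank 0 after centering (all-constant)")
    return u[:, :k]


@dataclass
class NuisanceSet:
    """Nuisance regressors: k orthonormal eigenvector series + 6 motion columns."""

    eigenvectors: np.ndarray
    motion: np.ndarray | None = None

    def design(self, n_rows: int) -> tuple[np.ndarray, list[str]]:
        cols = [np.ones((n_rows, 1))]
        names = ["intercept"]
        ev = np.asarray(self.eigenvectors, dtype=float)
        if ev.shape[0] != n_rows:
            raise ValueError("eigenvector rows do not match the series")
        cols.append(ev)
        names += [f"ev{i + 1}" for i in range(ev.shape[1])]
        if self.motion is not None:
            mo = np.asarray(self.motion, dtype=float)
            if mo.shape[0] != n_rows:
                raise ValueError("motion rows do not match the series")
            cols.append(mo)
            names += [f"motion{i + 1}" for i in range(mo.shape[1])]
        return np.hstack(cols), names


def regress_confounds(series: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """OLS residuals of each column after regressing out the nuisance design.

    An intercept is always included, so residuals are mean-centered, which
    downstream correlation estimates require.
    """
    y = np.asarray(series, dtype=float)
    x, names = nuisance.design(y.shape[0])
    # name collinear columns via the QR diagonal
    r = np.linalg.qr(x, mode="r")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    if np.any(diag < tol):
        bad = [names[i] for i in np.flatnonzero(diag < tol)]
        raise ValueError(f"rank-deficient confound design; collinear: {', '.join(bad)}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def bandpass(series: np.ndarray, tr: float, low: float = 0.01,
             high: float = 0.1, order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis (axis 0)."""
    series = np.asarray(series, dtype=float)
    fs = 1.0 / tr
    nyq = fs / 2.0
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz is at or above Nyquist {nyq} Hz")
    if low == 0:
        sos = signal.butter(order, high, btype="lowpass", fs=fs, output="sos")
        filtered = signal.sosfiltfilt(sos, series, axis=0)
        return filtered - filtered.mean(axis=0, keepdims=True)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, series, axis=0)


def box_smooth(volume: np.ndarray, kernel_voxels: int = 3) -> np.ndarray:
    """Spatial box (moving-average) smoothing of a 3-D or 4-D volume.

    At the edges the window shrinks to the in-bounds voxels, so constant
    volumes are left unchanged.  For 4-D input the kernel acts on the three
    spatial axes only.
    """
    vol = np.asarray(volume, dtype=float)
    if kernel_voxels < 1 or kernel_voxels % 2 == 0:
        raise ValueError("kernel size must be an odd positive integer")
    if vol.ndim not in (3, 4):
        raise ValueError("expected a 3-D or 4-D array")
    if kernel_voxels == 1:
        return vol.copy()
    size = (kernel_voxels,) * 3 + ((1,) if vol.ndim == 4 else ())
    num = ndimage.uniform_filter(vol, size=size, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(np.ones(vol.shape[:3]), size=(kernel_voxels,) * 3,
                                 mode="constant", cval=0.0)
    if vol.ndim == 4:
        den = den[..., None]
    return num / den


class ConfoundRegressor(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`regress_confounds`."""

    def __init__(self, eigenvectors=None, motion=None):
        self.eigenvectors = eigenvectors
        self.motion = motion

    def fit(self, X, y=None):
        self.nuisance_ = NuisanceSet(
            eigenvectors=np.asarray(self.eigenvectors, dtype=float),
            motion=None if self.motion is None else np.asarray(self.motion, dtype=float),
        )
        return self

    def transform(self, X):
        return regress_confounds(X, self.nuisance_)


class BandpassFilter(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`bandpass`."""

    def __init__(self, tr: float = 2.0, low: float = 0.01, high: float = 0.1,
                 order: int = 5):
        self.tr = tr
        self.low = low
        self.high = high
        self.order = order

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return bandpass(X, tr=self.tr, low=self.low, high=self.high,
                        order=self.order)


class BoxSmoother(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`box_smooth`."""

    def __init__(self, kernel_voxels: int = 3):
        self.kernel_voxels = kernel_voxels

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return box_smooth(X, kernel_voxels=self.kernel_voxels)


def preprocess_series(series: np.ndarray, tr: float, nuisance: NuisanceSet | None = None,
                      n_discard: int = 5, low: float = 0.01, high: float = 0.1) -> np.ndarray:
    """Full cleaning pipeline in canonical order: discard, confound
    regression, band-pass."""
    out = drop_initial_volumes(series, n_discard)
    if nuisance is not None:
        out = regress_confounds(out, nuisance)
    return bandpass(out, tr=tr, low=low, high=high)
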