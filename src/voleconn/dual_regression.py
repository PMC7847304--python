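"""Dual regression of group spatial maps and paired sign-flip testing.

Group-level spatial maps (e.g. from a group ICA, treated here as inputs)
are back-projected in two ordinary-least-squares stages: stage 1 regresses
the maps into each subject's space-time data to obtain subject-specific
time series; stage 2 regresses those time series into the same data to
obtain subject-specific spatial maps.  Session differences in the subject
maps are tested voxelwise with paired t-tests whose family-wise error is
controlled by the max-|t| distribution under random sign flips of the
subject difference maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator


@dataclass
class SpatialMapSet:
    """k group maps over a common voxel grid, Z-scaled, with a threshold."""

    maps: np.ndarray          # (k, n_voxels)
    threshold: float = 2.3

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def thresholded(self) -> np.ndarray:
        out = self.maps.copy()
        out[out < self.threshold] = 0.0
        return out


def _check_full_rank(a: np.ndarray, what: str):
    if np.linalg.matrix_rank(a) < min(a.shape):
        raise ValueError(f"{what} are collinear (rank-deficient)")


def dual_regression_stage1(group_maps: np.ndarray, subject_data: np.ndarray) -> np.ndarray:
    """Subject time series: per time point, OLS of the volume on the maps.

    ``group_maps`` is (k, voxels); ``subject_data`` is (time, voxels).
    Returns (time, k) coefficient series.
    """
    maps = np.asarray(group_maps, dtype=float)
    data = np.asarray(subject_data, dtype=float)
    if maps.shape[1] != data.shape[1]:
        raise ValueError("voxel grids of maps and data do not match")
    _check_full_rank(maps.T, "group maps")
    coef, *_ = np.linalg.lstsq(maps.T, data.T, rcond=None)
    return coef.T


def dual_regression_stage2(subject_data: np.ndarray, subject_series: np.ndarray) -> np.ndarray:
    """Subject maps: per voxel, OLS of its time course on the k series.

    Returns (k, voxels) coefficient maps.
    """
    data = np.asarray(subject_data, dtype=float)
    series = np.asarray(subject_series, dtype=float)
    if series.shape[0] != data.shape[0]:
        raise ValueError("time axes of series and data do not match")
    _check_full_rank(series, "subject time series")
    coef, *_ = np.linalg.lstsq(series, data, rcond=None)
    return coef


def paired_signflip_test(maps_a: np.ndarray, maps_b: np.ndarray,
                         n_perm: int = 5000, seed: int | None = None):
    """Voxelwise paired t-test with max-statistic sign-flip FWE control.

    ``maps_a``/``maps_b`` are matched (subjects, voxels) arrays for the two
    sessions.  Returns (t, p_fwe, null_max_abs_t): the paired t per voxel,
    the FWE-corrected p per voxel ``(1 + #{null max |t| >= |t|}) /
    (1 + n_perm)``, and the null distribution itself.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("sessions have unmatched subjects or grids")
    n = a.shape[0]
    if n < 6:
        raise ValueError("need at least 6 matched pairs")
    d = a - b
    rng = np.random.default_rng(seed)

    def paired_t(signed_mean, mean_sq):
        var = (mean_sq - signed_mean ** 2) * n / (n - 1.0)
        se = np.sqrt(np.maximum(var, 0.0) / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, signed_mean / se, 0.0)
        return t

    mean_sq = np.mean(d * d, axis=0)
    t_obs = paired_t(d.mean(axis=0), mean_sq)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null_means = (signs @ d) / n
    null_t = paired_t(null_means, mean_sq[None, :])
    null_max = np.max(np.abs(null_t), axis=1)
    p_fwe = (1 + np.sum(null_max[:, None] >= np.abs(t_obs)[None, :], axis=0)) \
        / (1.0 + n_perm)
    return t_obs, p_fwe, null_max


class DualRegression(BaseEstimator):
    """Two-stage back-projection of group maps to subject series and maps.

    ``fit`` stores the group maps; ``transform`` maps one subject's
    (time, voxels) dataset to ``(series, maps)``.  With
    ``normalize_series=True`` the stage-1 series are variance-normalized
    before stage 2 (off by default).
    """

    def __init__(self, normalize_series: bool = False):
        self.normalize_series = normalize_series

    def fit(self, group_maps, y=None):
        maps = group_maps.maps if isinstance(group_maps, SpatialMapSet) \
            else np.asarray(group_maps, dtype=float)
        _check_full_rank(maps.T, "group maps")
        self.group_maps_ = maps
        return self

    def transform(self, subject_data):
        series = dual_regression_stage1(self.group_maps_, subject_data)
        if self.normalize_series:
            sd = series.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            series = series / sd
        maps = dual_regression_stage2(subject_data, series)
        return series, maps
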