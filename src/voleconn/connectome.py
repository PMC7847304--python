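"""Partial-correlation functional connectomes.

A connectome here is an ROI-by-ROI matrix of Fisher z-transformed partial
correlations.  The partial correlation between two regions is the
correlation of their BOLD time series after regressing out the time series
of every other region; it is computed from the inverse sample covariance
(precision) matrix, which is algebraically identical to the
residual-regression definition but a single O(p^3) operation.

The canonical 16-region network of the pair-bonding literature and the
9-region control network are shipped as module constants so that edge
indices are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

#: The 16 regions implicated in pair-bond formation and maintenance.
ROI_16 = [
    "ACC", "AON", "BLA", "BNST", "LS", "MeA", "MOB", "mPFC",
    "NAcc", "RSC", "PVN", "VP", "VTA", "DG", "dHIP", "vHIP",
]

#: Nine control regions not expected to be involved in social behavior.
ROI_CONTROL_9 = ["AUDp", "CBX", "fmi", "LD", "MOp", "MY", "SSs", "VISp", "Vent"]


def n_edges(n_rois: int) -> int:
    """Number of unordered ROI pairs."""
    return n_rois * (n_rois - 1) // 2


def edge_index_map(roi_names: list[str]) -> list[tuple[str, str]]:
    """Edge id -> (ROI_i, ROI_j) for the upper triangle in row-major order."""
    p = len(roi_names)
    return [(roi_names[i], roi_names[j]) for i in range(p) for j in range(i + 1, p)]


def edge_pairs(p: int) -> np.ndarray:
    """Integer (i, j) node pairs for each edge id, shape (n_edges, 2)."""
    iu = np.triu_indices(p, k=1)
    return np.column_stack(iu)


def vectorize_edges(matrix: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Upper-triangle (i < j) values of a symmetric matrix in row-major order.

    Raises ``ValueError`` if the matrix is asymmetric beyond ``atol``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(matrix, matrix.T, atol=atol, rtol=0.0):
        raise ValueError(f"matrix is asymmetric beyond tolerance {atol}")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def devectorize_edges(edges: np.ndarray, p: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`; the diagonal is filled with ``diag``."""
    edges = np.asarray(edges, dtype=float)
    if edges.size != n_edges(p):
        raise ValueError(f"expected {n_edges(p)} edges for {p} ROIs, got {edges.size}")
    out = np.full((p, p), diag)
    iu = np.triu_indices(p, k=1)
    out[iu] = edges
    out.T[iu] = edges
    return out


def fisher_z(r):
    """Fisher z-transform, ``z = arctanh(r)``; requires ``|r| < 1``."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("Fisher z requires |r| < 1")
    out = np.arctanh(r)
    return out if out.ndim else float(out)


def partial_correlation_matrix(series: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Partial correlations between all column pairs of a time x ROI matrix.

    Entry (i, j) is the correlation of the residuals of columns i and j after
    regressing out every other column, obtained from the inverse covariance:
    ``p_ij = -theta_ij / sqrt(theta_ii * theta_jj)``.  The diagonal is set
    to 1.  ``ridge`` adds ``ridge * mean(diag(cov)) * I`` before inversion
    for use when the number of time points is close to the number of ROIs;
    the default 0 keeps the plain sample estimator.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D time x ROI matrix")
    n, p = x.shape
    if n <= p + 2:
        raise ValueError(f"need more than {p + 2} time points for {p} ROIs, got {n}")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [str(c) for c in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant column(s): {', '.join(bad)}")
    cov = np.cov(x, rowvar=False)
    if ridge > 0:
        cov = cov + ridge * np.mean(np.diag(cov)) * np.eye(p)
    try:
        theta = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("singular covariance matrix") from exc
    if not np.all(np.isfinite(theta)):
        raise ValueError("singular covariance matrix")
    d = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return (pc + pc.T) / 2.0


def roi_mean_timeseries(volume_series: np.ndarray, roi_masks: np.ndarray,
                        roi_names: list[str]) -> np.ndarray:
    """Average voxel time series within each ROI mask.

    ``volume_series`` is a 4-D array (x, y, z, time); ``roi_masks`` is a 3-D
    integer label image in which label ``r + 1`` marks ROI ``roi_names[r]``
    (0 = background).  Returns a time x ROI matrix in ``roi_names`` order.
    """
    vol = np.asarray(volume_series, dtype=float)
    lab = np.asarray(roi_masks)
    if vol.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, time) array")
    if lab.shape != vol.shape[:3]:
        raise ValueError("mask grid does not match the volume grid")
    n_t = vol.shape[3]
    out = np.empty((n_t, len(roi_names)))
    flat = vol.reshape(-1, n_t)
    lab_flat = lab.reshape(-1)
    for r, name in enumerate(roi_names):
        sel = lab_flat == r + 1
        if not sel.any():
            raise ValueError(f"empty mask for ROI {name!r}")
        out[:, r] = flat[sel].mean(axis=0)
    return out


class PartialCorrelation(BaseEstimator, TransformerMixin):
    """Transformer from ROI time series to Fisher-z partial-correlation edges.

    ``transform`` maps one time x ROI matrix (or a list of them) to the
    vector of Fisher z-transformed partial correlations over the upper
    triangle, the edge representation used by all network statistics here.

    Parameters
    ----------
    ridge : float, default 0.0
        Relative ridge added to the covariance diagonal before inversion.
    apply_fisher_z : bool, default True
        If False, raw partial correlations are returned.
    """

    def __init__(self, ridge: float = 0.0, apply_fisher_z: bool = True):
        self.ridge = ridge
        self.apply_fisher_z = apply_fisher_z

    def fit(self, X, y=None):
        first = X[0] if isinstance(X, (list, tuple)) else X
        self.n_rois_ = np.asarray(first).shape[1]
        self.n_edges_ = n_edges(self.n_rois_)
        return self

    def transform(self, X):
        single = not isinstance(X, (list, tuple))
        items = [X] if single else X
        out = []
        for series in items:
            pc = partial_correlation_matrix(series, ridge=self.ridge)
            edges = vectorize_edges(pc)
            if self.apply_fisher_z:
                edges = fisher_z(edges)
            out.append(edges)
        return out[0] if single else np.asarray(out)


@dataclass
class ConnectomeStack:
    """Fisher-z partial-correlation matrices stacked over (subject, session).

    ``matrices`` maps ``(subject, session)`` to a symmetric ROI x ROI matrix
    of Fisher-z partial correlations (diagonal by convention 0 in the edge
    view, which only reads the upper triangle).
    """

    matrices: dict[tuple[int, int], np.ndarray]
    roi_names: list[str]
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_rois)

    @property
    def edge_names(self) -> list[tuple[str, str]]:
        return edge_index_map(self.roi_names)

    def keys(self) -> list[tuple[int, int]]:
        return sorted(self.matrices)

    def edge_long_table(self) -> pd.DataFrame:
        """Long-format table with one row per (subject, session, edge)."""
        rows = []
        for (subj, sess) in self.keys():
            z = vectorize_edges(self.matrices[(subj, sess)])
            rows.append(pd.DataFrame({
                "subject": subj, "session": sess,
                "edge": np.arange(z.size), "z": z,
            }))
        table = pd.concat(rows, ignore_index=True)
        if len(self.meta):
            table = table.merge(
                self.meta[["subject", "sex"]].drop_duplicates(), on="subject",
                how="left",
            )
        return table

    def session_edge_matrix(self, session: int) -> tuple[np.ndarray, np.ndarray]:
        """(subjects, edges) matrix for one session plus the subject ids."""
        keys = [k for k in self.keys() if k[1] == session]
        subjects = np.array([k[0] for k in keys])
        mat = np.vstack([vectorize_edges(self.matrices[k]) for k in keys])
        return mat, subjects


def build_connectome_stack(panel, ridge: float = 0.0) -> ConnectomeStack:
    """Compute a :class:`ConnectomeStack` from an ROI time-series panel."""
    transformer = PartialCorrelation(ridge=ridge)
    matrices = {}
    for key, series in panel.data.items():
        edges = transformer.fit(series).transform(series)
        matrices[key] = devectorize_edges(edges, len(panel.roi_names))
    return ConnectomeStack(matrices=matrices, roi_names=list(panel.roi_names),
                           meta=panel.meta.copy())
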