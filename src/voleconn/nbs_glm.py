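"""Network-based statistic (NBS) for edge-covariate association.

Per edge, an ordinary least-squares model tests the linear association
between connectivity and a behavioral covariate.  Edges whose T statistic
exceeds a fixed threshold (default 1.7) in the tested direction form a
graph on the ROIs; each connected component is scored by its "intensity"
(sum of absolute edge statistics), and family-wise error is controlled by
comparing the observed component strengths with the maximum component
strength over permutations of the covariate.  With nuisance covariates the
permutation follows the Freedman-Lane scheme (permuting reduced-model
residuals).  The FWE p-value uses the (k+1)/(n+1) estimator, so p is never
zero and never below 1/(n_perm+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _cc
from sklearn.base import BaseEstimator

from .connectome import edge_pairs


@dataclass
class NetworkComponent:
    """A connected set of suprathreshold edges."""

    nodes: tuple[int, ...]
    edges: tuple[int, ...]
    strength: float
    p_fwe: float | None = None

    def named(self, roi_names, edge_names) -> dict:
        return {
            "nodes": [roi_names[i] for i in self.nodes],
            "edges": [list(edge_names[e]) for e in self.edges],
            "edge_ids": list(self.edges),
            "strength": self.strength,
            "p_fwe": self.p_fwe,
        }


@dataclass
class NbsResult:
    """Observed components, per-edge statistics and the permutation null."""

    components: list[NetworkComponent]
    edge_stats: np.ndarray
    null_max_strength: np.ndarray
    t_thresh: float
    direction: str
    n_perm: int
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def min_p_fwe(self) -> float:
        if not self.components:
            return 1.0
        return min(c.p_fwe for c in self.components)


def edge_glm_stats(edge_values: np.ndarray, covariate: np.ndarray,
                   nuisance_covariates: np.ndarray | None = None) -> np.ndarray:
    """Per-edge OLS T statistic for the covariate term (intercept included)."""
    t, _ = _glm_t(np.asarray(edge_values, dtype=float),
                  _design(covariate, nuisance_covariates))
    return t


def _design(covariate, nuisance) -> np.ndarray:
    x = np.asarray(covariate, dtype=float).reshape(-1, 1)
    if np.all(x == x[0]):
        raise ValueError("constant covariate: zero design variance")
    cols = [np.ones_like(x), x]
    if nuisance is not None:
        nu = np.asarray(nuisance, dtype=float)
        if nu.ndim == 1:
            nu = nu.reshape(-1, 1)
        cols.append(nu)
    return np.hstack(cols)


def _glm_t(y: np.ndarray, x: np.ndarray, term: int = 1):
    """Vectorized OLS T for one design column across many responses."""
    n, k = x.shape
    if y.shape[0] != n:
        raise ValueError("edge_values and covariate row counts differ")
    if n <= k:
        raise ValueError("need more subjects than regressors")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    df = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(sigma2 * xtx_inv[term, term])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[term] / se
    return t, df


def threshold_and_components(stats: np.ndarray, n_rois: int, t_thresh: float,
                             direction: str = "positive") -> list[NetworkComponent]:
    """Connected components of the suprathreshold edge graph.

    Edges with ``stat > t_thresh`` ("positive") or ``stat < -t_thresh``
    ("negative") are kept; maximal connected components with at least one
    edge are returned, each scored by the sum of absolute edge statistics.
    """
    if t_thresh <= 0:
        raise ValueError("t_thresh must be positive")
    stats = np.asarray(stats, dtype=float)
    if direction == "positive":
        keep = np.flatnonzero(stats > t_thresh)
    elif direction == "negative":
        keep = np.flatnonzero(stats < -t_thresh)
    else:
        raise ValueError("direction must be 'positive' or 'negative'")
    if keep.size == 0:
        return []
    pairs = edge_pairs(n_rois)[keep]
    adj = sparse.coo_matrix(
        (np.ones(keep.size), (pairs[:, 0], pairs[:, 1])), shape=(n_rois, n_rois))
    n_comp, labels = _cc(adj, directed=False)
    comps = []
    for c in range(n_comp):
        edge_sel = keep[labels[pairs[:, 0]] == c]
        if edge_sel.size == 0:
            continue
        nodes = tuple(sorted(np.flatnonzero(labels == c)))
        comps.append(NetworkComponent(
            nodes=nodes, edges=tuple(int(e) for e in edge_sel),
            strength=component_strength(edge_sel, stats)))
    comps.sort(key=lambda c: -c.strength)
    return comps


def component_strength(component_edges, stats) -> float:
    """Component "intensity": sum of absolute edge statistics."""
    idx = np.asarray(list(component_edges), dtype=int)
    if idx.size == 0:
        raise ValueError("component must contain at least one edge")
    return float(np.abs(np.asarray(stats, dtype=float)[idx]).sum())


def _max_component_strength(stats, n_rois, t_thresh, direction) -> float:
    comps = threshold_and_components(stats, n_rois, t_thresh, direction)
    return comps[0].strength if comps else 0.0


def nbs_permutation_test(edge_values: np.ndarray, covariate: np.ndarray,
                         t_thresh: float = 1.7, n_perm: int = 5000,
                         seed: int | None = None, direction: str = "negative",
                         nuisance_covariates: np.ndarray | None = None,
                         extent: bool = False) -> NbsResult:
    """Full NBS: observed components plus the permutation null of the
    maximum component strength.

    ``extent=True`` scores components by edge count instead of summed
    statistics.  The covariate is permuted across subjects (Freedman-Lane
    on reduced-model residuals when nuisance covariates are present).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    y = np.asarray(edge_values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    n, m = y.shape
    n_rois = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    rng = np.random.default_rng(seed)

    strength_of = ((lambda s: _max_component_extent(s, n_rois, t_thresh, direction))
                   if extent else
                   (lambda s: _max_component_strength(s, n_rois, t_thresh, direction)))

    obs_t, _ = _glm_t(y, _design(x, nuisance_covariates))
    comps = threshold_and_components(obs_t, n_rois, t_thresh, direction)
    if extent:
        for c in comps:
            c.strength = float(len(c.edges))

    if nuisance_covariates is None:
        null = _null_simple(y, x, rng, n_perm, strength_of)
    else:
        null = _null_freedman_lane(y, x, nuisance_covariates, rng, n_perm,
                                   strength_of)

    for c in comps:
        c.p_fwe = float((1 + np.sum(null >= c.strength)) / (1 + n_perm))
    return NbsResult(components=comps, edge_stats=obs_t,
                     null_max_strength=null, t_thresh=t_thresh,
                     direction=direction, n_perm=n_perm, seed=seed)


def _max_component_extent(stats, n_rois, t_thresh, direction) -> float:
    comps = threshold_and_components(stats, n_rois, t_thresh, direction)
    return float(max((len(c.edges) for c in comps), default=0))


def _null_simple(y, x, rng, n_perm, strength_of) -> np.ndarray:
    """Null via permutation of the covariate; T computed from correlations.

    With a single covariate plus intercept, the OLS T for the slope is
    ``r * sqrt(df / (1 - r^2))`` with ``r`` the sample correlation, which
    lets all permutations be computed as one matrix product.
    """
    n, m = y.shape
    df = n - 2
    yc = y - y.mean(axis=0)
    ysd = np.sqrt(np.einsum("ij,ij->j", yc, yc))
    ysd[ysd == 0] = np.inf
    xs = np.empty((n_perm, n))
    for i in range(n_perm):
        xs[i] = rng.permutation(x)
    xs -= xs.mean(axis=1, keepdims=True)
    xnorm = np.sqrt(np.einsum("ij,ij->i", xs, xs))
    r = (xs @ yc) / (xnorm[:, None] * ysd[None, :])
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt(df / (1.0 - r * r))
    return np.array([strength_of(t[i]) for i in range(n_perm)])


def _null_freedman_lane(y, x, nuisance, rng, n_perm, strength_of) -> np.ndarray:
    """Freedman-Lane: permute residuals of the nuisance-only model."""
    n = y.shape[0]
    nu = np.asarray(nuisance, dtype=float)
    if nu.ndim == 1:
        nu = nu.reshape(-1, 1)
    zfull = np.hstack([np.ones((n, 1)), nu])
    hz = zfull @ np.linalg.pinv(zfull)
    resid = y - hz @ y
    fitted = y - resid
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        ystar = fitted + resid[perm]
        t, _ = _glm_t(ystar, _design(x, nu))
        null[i] = strength_of(t)
    return null


class NBSGLM(BaseEstimator):
    """Network-based statistic for edge-covariate association.

    Scikit-learn-style estimator: ``fit(X, y)`` takes a (subjects, edges)
    matrix of Fisher-z connectivity values and a per-subject behavioral
    covariate, and runs the NBS permutation test in each requested
    direction.

    Parameters
    ----------
    t_thresh : float, default 1.7
        Fixed edge-statistic threshold defining suprathreshold connections.
    n_perm : int, default 5000
        Number of covariate permutations for the max-strength null.
    directions : tuple, default ("positive", "negative")
        Contrast directions to test; both share the permutation stream seed.
    seed : int or None
        Seed of the permutation stream.
    extent : bool, default False
        Score components by edge count instead of summed statistics.

    Attributes
    ----------
    results_ : dict direction -> :class:`NbsResult`
    edge_stats_ : ndarray, per-edge observed T statistics
    components_ : list of (direction, :class:`NetworkComponent`) pairs
    """

    def __init__(self, t_thresh: float = 1.7, n_perm: int = 5000,
                 directions=("positive", "negative"), seed: int | None = None,
                 extent: bool = False):
        self.t_thresh = t_thresh
        self.n_perm = n_perm
        self.directions = directions
        self.seed = seed
        self.extent = extent

    def fit(self, X, y, nuisance=None):
        self.results_ = {}
        for direction in self.directions:
            self.results_[direction] = nbs_permutation_test(
                X, y, t_thresh=self.t_thresh, n_perm=self.n_perm,
                seed=self.seed, direction=direction,
                nuisance_covariates=nuisance, extent=self.extent)
        first = next(iter(self.results_.values()))
        self.edge_stats_ = first.edge_stats
        self.components_ = [(d, c) for d, res in self.results_.items()
                            for c in res.components]
        return self

    def significant_components(self, alpha: float = 0.05):
        return [(d, c) for d, c in self.components_ if c.p_fwe <= alpha]
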