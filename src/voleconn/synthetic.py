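"""Synthetic longitudinal connectivity cohorts with known ground truth.

The generator emulates the design of a longitudinal pair-bonding imaging
study: 32 subjects (16 female, 16 male), three scanning sessions (baseline,
24 h and 2 weeks after the onset of cohabitation), 16 regions of interest,
300 retained volumes at TR = 2 s, and a missingness pattern in which six
(subject, session) cells are lost so that 90 of 96 datasets remain.

Latent structure is specified on the Fisher-z partial-correlation scale,
the scale on which every downstream statistic operates.  For each subject
and session a target partial-correlation matrix is assembled from

* a base matrix (identity by default, i.e. no true coupling),
* planted per-session additive shifts on chosen edges (session effects),
* a per-subject "network factor" shared by the edges of a chosen
  subnetwork, which creates stable individual differences in connectivity,
* independent per-subject deviations on edges coupled to behavior.

Each ROI time-series matrix is then drawn row-i.i.d. from a zero-mean
multivariate Gaussian whose true partial correlations equal the target
(constructed through a unit-diagonal precision matrix).  Behavioral values
are linear in the subject's true Fisher-z of the coupled edge plus Gaussian
noise.  An optional AR(1) knob adds temporal autocorrelation (band-passed
BOLD is autocorrelated); it is off by default and preserves the stationary
covariance when on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import ROI_16, edge_pairs, n_edges

#: Missing (subject, session) cells reproducing the 90-of-96 accounting:
#: two subjects missed the baseline acquisition, two baseline datasets were
#: dropped for signal loss, and two subjects missed the 2-week session.
DEFAULT_MISSING_SESSIONS = [(0, 1), (1, 1), (2, 1), (3, 1), (4, 3), (5, 3)]


@dataclass
class SyntheticConfig:
    """Study-design parameters for one synthetic cohort.

    ``session_effects`` maps edge id -> {session: additive shift on the
    latent Fisher-z}.  ``behavior_couplings`` maps (edge id, session) ->
    (slope, noise_sd): the behavioral value is
    ``intercept + slope * true_z(edge, session) + N(0, noise_sd)`` per
    subject.  ``network_edges`` lists the edges that share the per-subject
    network factor (sd ``subject_sd``); edges coupled to behavior but not in
    this set get independent per-subject deviations of the same sd.
    """

    n_subjects: int = 32
    n_female: int = 16
    n_rois: int = 16
    n_volumes: int = 300
    tr: float = 2.0
    roi_names: list[str] | None = None
    base_partials: np.ndarray | None = None
    session_effects: dict[int, dict[int, float]] = field(default_factory=dict)
    behavior_couplings: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    behavior_names: dict[tuple[int, int], str] = field(default_factory=dict)
    behavior_intercepts: dict[tuple[int, int], float] = field(default_factory=dict)
    network_edges: tuple[int, ...] = ()
    subject_sd: float = 0.12
    missing_sessions: list[tuple[int, int]] = field(
        default_factory=lambda: list(DEFAULT_MISSING_SESSIONS))
    ar_coef: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_female > self.n_subjects:
            raise ValueError("n_female cannot exceed n_subjects")
        m = n_edges(self.n_rois)
        touched = set(self.session_effects) | {e for e, _ in self.behavior_couplings}
        touched |= set(self.network_edges)
        if any(e < 0 or e >= m for e in touched):
            raise ValueError(f"edge index out of range for {self.n_rois} ROIs ({m} edges)")
        for subj, sess in self.missing_sessions:
            if subj < 0 or subj >= self.n_subjects:
                raise ValueError(f"missing_sessions references unknown subject {subj}")
            if sess not in (1, 2, 3):
                raise ValueError(f"missing_sessions references unknown session {sess}")
        if self.roi_names is None:
            self.roi_names = (list(ROI_16) if self.n_rois == 16
                              else [f"ROI{i + 1}" for i in range(self.n_rois)])
        if len(self.roi_names) != self.n_rois:
            raise ValueError("roi_names length must equal n_rois")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests.

    ``true_z`` holds every subject's latent Fisher-z edge vector for every
    session (including cells later dropped as missing).
    """

    base_z: np.ndarray
    session_z: dict[int, np.ndarray]
    true_z: dict[tuple[int, int], np.ndarray]
    session_effect_edges: tuple[int, ...]
    behavior_edges: dict[str, int]
    behavior_slopes: dict[str, float]


@dataclass
class RoiTimeSeriesPanel:
    """Per (subject, session) time x ROI matrices plus subject metadata."""

    data: dict[tuple[int, int], np.ndarray]
    roi_names: list[str]
    tr: float
    meta: pd.DataFrame

    def keys(self) -> list[tuple[int, int]]:
        return sorted(self.data)


def _precision_from_partials(latent_partials: np.ndarray) -> np.ndarray:
    p = np.asarray(latent_partials, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("latent_partials must be square")
    if not np.allclose(p, p.T, atol=1e-10):
        raise ValueError("latent_partials must be symmetric")
    if not np.allclose(np.diag(p), 1.0):
        raise ValueError("latent_partials must have unit diagonal")
    theta = np.eye(p.shape[0]) * 2.0 - p  # unit diagonal, off-diag -p_ij
    return theta


def generate_subject_timeseries(latent_partials: np.ndarray, n_volumes: int,
                                seed=None, ar_coef: float = 0.0) -> np.ndarray:
    """Draw a time x ROI matrix whose true partial correlations equal
    ``latent_partials``.

    Rows are i.i.d. N(0, Sigma) with Sigma the inverse of the unit-diagonal
    precision matrix implied by the target partial correlations.  With
    ``ar_coef`` = phi > 0, rows follow a stationary AR(1) process with the
    same marginal covariance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = _precision_from_partials(latent_partials)
    try:
        lc = np.linalg.cholesky(theta)
    except np.linalg.LinAlgError as exc:
        raise ValueError("invalid latent structure: precision matrix is not "
                         "positive definite") from exc
    # Sigma = theta^-1; draw z then solve L^T x = z so that cov(x) = Sigma
    p = theta.shape[0]
    z = rng.standard_normal((int(n_volumes), p))
    x = np.linalg.solve(lc.T, z.T).T
    if ar_coef:
        phi = float(ar_coef)
        if not -1 < phi < 1:
            raise ValueError("ar_coef must be in (-1, 1)")
        out = np.empty_like(x)
        out[0] = x[0]
        scale = np.sqrt(1.0 - phi ** 2)
        for t in range(1, x.shape[0]):
            out[t] = phi * out[t - 1] + scale * x[t]
        x = out
    return x


def _latent_z_cell(config: SyntheticConfig, edge_dev: np.ndarray,
                   session: int) -> np.ndarray:
    """Latent Fisher-z edge vector for one subject-session cell."""
    m = n_edges(config.n_rois)
    if config.base_partials is None:
        z = np.zeros(m)
    else:
        iu = np.triu_indices(config.n_rois, k=1)
        z = np.arctanh(np.asarray(config.base_partials, dtype=float)[iu])
    for edge, shifts in config.session_effects.items():
        z[edge] += shifts.get(session, 0.0)
    return z + edge_dev


def generate_cohort(config: SyntheticConfig):
    """Generate one cohort: (RoiTimeSeriesPanel, behavior table, GroundTruth)."""
    rng = np.random.default_rng(config.seed)
    p = config.n_rois
    m = n_edges(p)
    pairs = edge_pairs(p)
    missing = set(config.missing_sessions)
    sex = np.array(["F"] * config.n_female +
                   ["M"] * (config.n_subjects - config.n_female))

    # per-subject deviations: shared network factor + independent deviations
    # on behavior-coupled edges outside the network
    factor = rng.normal(0.0, config.subject_sd, size=config.n_subjects)
    extra_edges = sorted({e for e, _ in config.behavior_couplings}
                         - set(config.network_edges))
    extra_dev = rng.normal(0.0, config.subject_sd,
                           size=(config.n_subjects, len(extra_edges)))
    edge_dev = np.zeros((config.n_subjects, m))
    for e in config.network_edges:
        edge_dev[:, e] += factor
    for j, e in enumerate(extra_edges):
        edge_dev[:, e] += extra_dev[:, j]

    true_z: dict[tuple[int, int], np.ndarray] = {}
    session_z = {s: _latent_z_cell(config, np.zeros(m), s) for s in (1, 2, 3)}
    data = {}
    for subj in range(config.n_subjects):
        for sess in (1, 2, 3):
            z = _latent_z_cell(config, edge_dev[subj], sess)
            true_z[(subj, sess)] = z
            mat = np.eye(p)
            r = np.tanh(z)
            mat[pairs[:, 0], pairs[:, 1]] = r
            mat[pairs[:, 1], pairs[:, 0]] = r
            # the stream below must advance identically whether or not the
            # cell is retained, so missingness does not perturb other cells
            ts = generate_subject_timeseries(mat, config.n_volumes, seed=rng,
                                             ar_coef=config.ar_coef)
            if (subj, sess) not in missing:
                data[(subj, sess)] = ts

    meta = pd.DataFrame({"subject": np.arange(config.n_subjects), "sex": sex})
    panel = RoiTimeSeriesPanel(data=data, roi_names=list(config.roi_names),
                               tr=config.tr, meta=meta)

    behavior = _behavior_table(config, rng, true_z, sex)
    gt = GroundTruth(
        base_z=_latent_z_cell(config, np.zeros(m), 0),
        session_z=session_z,
        true_z=true_z,
        session_effect_edges=tuple(sorted(config.session_effects)),
        behavior_edges={_coupling_name(config, key): key[0]
                        for key in config.behavior_couplings},
        behavior_slopes={_coupling_name(config, key): slope
                         for key, (slope, _) in config.behavior_couplings.items()},
    )
    return panel, behavior, gt


def _coupling_name(config: SyntheticConfig, key: tuple[int, int]) -> str:
    return config.behavior_names.get(key, f"beh_e{key[0]}_s{key[1]}")


def _behavior_table(config: SyntheticConfig, rng: np.random.Generator,
                    true_z, sex) -> pd.DataFrame:
    """Behavioral measurements: a 3-h partner-preference test plus
    cohabitation latencies, with any configured connectivity couplings."""
    n = config.n_subjects
    total_test = 180.0  # minutes, 3-h partner preference test
    # fraction of the test spent in the two social incentive areas (~80%)
    social_frac = np.clip(rng.normal(0.80, 0.10, n), 0.3, 0.98)
    ppi = np.clip(rng.normal(0.61, 0.12, n), 0.05, 0.95)
    social_time = social_frac * total_test
    table = pd.DataFrame({
        "subject": np.arange(n),
        "sex": sex,
        "test_period": np.where(np.arange(n) % 2 == 0, "48h", "72h"),
        "time_partner": social_time * ppi,
        "time_stranger": social_time * (1.0 - ppi),
        "total_test_time": total_test,
        "percent_social_time": social_frac * 100.0,
        "ppi": ppi,
        "huddling_latency": np.clip(rng.normal(69.5, 40.0, n), 1.0, 360.0),
    })
    for key, (slope, noise_sd) in config.behavior_couplings.items():
        edge, sess = key
        z = np.array([true_z[(s, sess)][edge] for s in range(n)])
        intercept = config.behavior_intercepts.get(key, 0.0)
        values = intercept + slope * z + rng.normal(0.0, noise_sd, n)
        table[_coupling_name(config, key)] = values
    return table


def path_edges(nodes: list[int], n_rois: int) -> list[int]:
    """Edge ids of the path visiting ``nodes`` in order."""
    pairs = edge_pairs(n_rois)
    lookup = {(int(i), int(j)): k for k, (i, j) in enumerate(pairs)}
    out = []
    for a, b in zip(nodes[:-1], nodes[1:]):
        i, j = min(a, b), max(a, b)
        out.append(lookup[(i, j)])
    return out


def huddling_scenario(n_rois: int = 10, n_subjects: int = 28, seed: int = 0,
                      slope: float = -150.0, noise_sd: float = 6.0,
                      intercept: float = 69.5) -> SyntheticConfig:
    """Cohort with a 9-edge path network whose baseline connectivity is
    negatively coupled to huddling latency (minutes).

    The path spans the first 10 ROIs; the per-subject network factor makes
    all nine edges co-vary across subjects, so the latency is associated
    with the whole path.
    """
    edges = path_edges(list(range(10)), n_rois)
    key = (edges[0], 1)
    return SyntheticConfig(
        n_subjects=n_subjects, n_female=n_subjects // 2, n_rois=n_rois,
        network_edges=tuple(edges),
        behavior_couplings={key: (slope, noise_sd)},
        behavior_names={key: "huddling_latency_coupled"},
        behavior_intercepts={key: intercept},
        missing_sessions=[], seed=seed,
    )


def session_change_scenario(n_rois: int = 12, seed: int = 0,
                            shift: float = 0.25) -> SyntheticConfig:
    """Cohort with a planted session effect on a connected 10-edge path.

    Connectivity on the path (11 nodes) rises by ``shift`` (Fisher-z) at
    24 h and stays elevated at 2 weeks; the default missingness pattern
    (90 of 96 cells) is kept.
    """
    edges = path_edges(list(range(11)), n_rois)
    effects = {e: {2: shift, 3: shift} for e in edges}
    return SyntheticConfig(n_rois=n_rois, session_effects=effects, seed=seed)
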