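"""Longitudinal network statistics via per-edge linear mixed models.

Each connection (edge) is modelled over the three scanning sessions with a
linear mixed model: fixed effects for sex and session (optionally their
interaction) and subject-level random effects for the repeated measures.
Edges with a term p-value below ``alpha_edge`` form a graph on the ROIs;
connected components are scored by the sum of their edges' z-equivalent
statistics (square root of the Wald F, signed by the dominant contrast),
and family-wise error is controlled by a permutation null of the maximum
component strength.  Exchangeability is respected: session labels are
permuted within each subject for within-subject terms, sex labels across
subjects for between-subject terms.

Degrees of freedom follow the inner-outer rule of hierarchical models:
within-subject terms use ``n_obs - n_subjects - p_within`` (90 - 32 - 2 =
56 for a 3-level session factor in the additive model), between-subject
terms use ``n_subjects - p_between - 1`` (32 - 1 - 1 = 30 for sex).

Two fitting routes are provided.  :func:`fit_edge_lmm` fits one edge by
REML with a random intercept plus per-subject session deviations
(diagonal covariance), falling back to a random intercept alone when the
richer structure does not converge.  The permutation machinery uses a
random-intercept REML engine whose single variance ratio is profiled on a
grid, which evaluates all edges and all candidate ratios as batched linear
algebra; observed and permuted statistics always go through the same
engine so that the null is exchangeable with the observation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .nbs_glm import NbsResult, threshold_and_components

logger = logging.getLogger(__name__)

SESSIONS = (1, 2, 3)


# ---------------------------------------------------------------------------
# degrees of freedom (inner-outer rule)

def within_subject_df(n_obs: int, n_subjects: int, n_within_params: int = 2) -> int:
    """Residual df for within-subject terms: n_obs - n_subjects - p_within."""
    return int(n_obs) - int(n_subjects) - int(n_within_params)


def between_subject_df(n_subjects: int, n_between_params: int = 1) -> int:
    """Residual df for between-subject terms: n_subjects - p_between - 1."""
    return int(n_subjects) - int(n_between_params) - 1


# ---------------------------------------------------------------------------
# design construction

def _design(sex_m: np.ndarray, session: np.ndarray, interaction: bool):
    """Fixed-effects design: intercept, sex, session dummies (+ interaction).

    Returns (X, column names, term -> column indices, p_within, p_between).
    """
    s2 = (session == 2).astype(float)
    s3 = (session == 3).astype(float)
    cols = [np.ones_like(s2), sex_m.astype(float), s2, s3]
    names = ["intercept", "sexM", "session2", "session3"]
    terms = {"sex": [1], "session": [2, 3]}
    p_within, p_between = 2, 1
    if interaction:
        cols += [sex_m * s2, sex_m * s3]
        names += ["sexM:session2", "sexM:session3"]
        terms["interaction"] = [4, 5]
        p_within = 4
    return np.column_stack(cols), names, terms, p_within, p_between


def _term_dfs(n_obs, n_subjects, terms, p_within, p_between):
    dfs = {}
    for term in terms:
        if term == "sex":
            dfs[term] = between_subject_df(n_subjects, p_between)
        else:
            dfs[term] = within_subject_df(n_obs, n_subjects, p_within)
    return dfs


# ---------------------------------------------------------------------------
# fast random-intercept REML engine (vectorized over edges)

DEFAULT_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-3.0, 4.0, 36)])


class RandomInterceptEngine:
    """Profiled-REML random-intercept LMM for many responses at once.

    The variance ratio ``lambda = sigma_b^2 / sigma_e^2`` is profiled on a
    fixed grid; for each candidate the model reduces to OLS on whitened
    data, so the whole grid, all edges, is a stack of batched QR solves.
    ``refine=True`` polishes each response's ratio with a scalar bounded
    search (used for reported single-edge fits; the grid alone is used
    inside permutation loops so observed and null statistics match).
    """

    def __init__(self, Y: np.ndarray, groups: np.ndarray,
                 lam_grid: np.ndarray | None = None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        self.Y = Y
        self.n, self.n_edges = Y.shape
        self.codes = pd.factorize(np.asarray(groups))[0]
        self.n_groups = self.codes.max() + 1
        self.counts = np.bincount(self.codes).astype(float)
        self.lam_grid = (DEFAULT_LAMBDA_GRID if lam_grid is None
                         else np.asarray(lam_grid, dtype=float))
        L = self.lam_grid.size
        # shrink coefficient per group and grid point
        self._c = 1.0 - 1.0 / np.sqrt(1.0 + self.lam_grid[:, None] * self.counts[None, :])
        self._logdetV = np.sum(np.log1p(self.lam_grid[:, None] * self.counts[None, :]),
                               axis=1)
        self.Yt = self._whiten(Y)                      # (L, n, E)
        self.ynorm2 = np.einsum("lne,lne->le", self.Yt, self.Yt)

    def _whiten(self, U: np.ndarray) -> np.ndarray:
        """Apply the per-grid-point whitening transform to columns of U."""
        U = np.asarray(U, dtype=float)
        means = np.zeros((self.n_groups, U.shape[1]))
        np.add.at(means, self.codes, U)
        means /= self.counts[:, None]
        crow = self._c[:, self.codes]                  # (L, n)
        return U[None, :, :] - crow[:, :, None] * means[self.codes][None, :, :]

    def fit(self, X: np.ndarray, contrasts: dict[str, np.ndarray],
            refine: bool = False):
        """Fit all responses; returns a dict of per-edge arrays.

        ``contrasts`` maps term name -> (q, p) contrast matrix on the fixed
        effects.  Output keys: ``lam``, ``sigma2``, ``beta`` (p, E),
        ``F`` (term -> E), ``contrast_t`` (term -> (q, E) t-like ratios).
        """
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        Xt = self._whiten(X)                           # (L, n, p)
        Q, R = np.linalg.qr(Xt)                        # batched
        QtY = np.matmul(np.transpose(Q, (0, 2, 1)), self.Yt)     # (L, p, E)
        rss = np.maximum(self.ynorm2 - np.einsum("lpe,lpe->le", QtY, QtY),
                         1e-300)
        logdetXtX = 2.0 * np.sum(np.log(np.abs(np.diagonal(R, axis1=1, axis2=2))),
                                 axis=1)
        crit = ((n - p) * np.log(rss) + self._logdetV[:, None]
                + logdetXtX[:, None])                  # (L, E)
        idx = np.argmin(crit, axis=0)                  # (E,)

        beta_all = np.linalg.solve(R, QtY)             # (L, p, E)
        Rinv = np.linalg.inv(R)
        cov_u = np.matmul(Rinv, np.transpose(Rinv, (0, 2, 1)))   # (L, p, p)
        sigma2_all = rss / (n - p)

        E = self.n_edges
        ar = np.arange(E)
        out = {
            "lam": self.lam_grid[idx],
            "sigma2": sigma2_all[idx, ar],
            "beta": beta_all[idx, :, ar].T,            # (p, E)
            "cov_unscaled": cov_u[idx],                # (E, p, p)
            "n": n, "p": p,
        }
        if refine:
            self._refine(X, contrasts, out)
        out["F"] = {}
        out["contrast_t"] = {}
        for term, Lc in contrasts.items():
            Fv, tv = _wald_many(out["beta"], out["cov_unscaled"], out["sigma2"], Lc)
            out["F"][term] = Fv
            out["contrast_t"][term] = tv
        return out

    def _crit_single(self, lam: float, X: np.ndarray, y: np.ndarray):
        """REML criterion and fit pieces for one response at one ratio."""
        c = 1.0 - 1.0 / np.sqrt(1.0 + lam * self.counts)
        def wh(u):
            means = np.zeros((self.n_groups,) + u.shape[1:])
            np.add.at(means, self.codes, u)
            means = (means.T / self.counts).T
            return u - (c[self.codes].T * means[self.codes].T).T
        Xt, yt = wh(X), wh(y)
        q, r = np.linalg.qr(Xt)
        qty = q.T @ yt
        rss = max(float(yt @ yt - qty @ qty), 1e-300)
        n, p = X.shape
        crit = ((n - p) * np.log(rss)
                + np.sum(np.log1p(lam * self.counts))
                + 2.0 * np.sum(np.log(np.abs(np.diag(r)))))
        return crit, (q, r, qty, rss)

    def _refine(self, X, contrasts, out):
        from scipy.optimize import minimize_scalar
        n, p = X.shape
        for e in range(self.n_edges):
            y = self.Y[:, e]
            res = minimize_scalar(
                lambda ll: self._crit_single(np.exp(ll) - 1e-8, X, y)[0],
                bounds=(np.log(1e-8), np.log(1e6)), method="bounded",
                options={"xatol": 1e-10})
            lam = max(np.exp(res.x) - 1e-8, 0.0)
            crit0, _ = self._crit_single(0.0, X, y)
            if crit0 <= res.fun:
                lam = 0.0
            crit, (qq, rr, qty, rss) = self._crit_single(lam, X, y)
            rinv = np.linalg.inv(rr)
            out["lam"][e] = lam
            out["sigma2"][e] = rss / (n - p)
            out["beta"][:, e] = rinv @ qty
            out["cov_unscaled"][e] = rinv @ rinv.T


def _wald_many(beta, cov_unscaled, sigma2, Lc):
    """Wald F (and per-row t ratios) for a contrast across many responses."""
    Lc = np.atleast_2d(np.asarray(Lc, dtype=float))
    q = Lc.shape[0]
    B = Lc @ beta                                       # (q, E)
    A = np.einsum("qp,eps,rs->eqr", Lc, cov_unscaled, Lc)  # (E, q, q)
    Ainv = np.linalg.inv(A)
    quad = np.einsum("qe,eqr,re->e", B, Ainv, B)
    F = quad / (q * sigma2)
    tv = B / np.sqrt(np.einsum("eqq->qe", A * sigma2[:, None, None]))
    return F, tv


# ---------------------------------------------------------------------------
# per-edge fit (rich random structure, statsmodels route)

@dataclass
class LmmEdgeResult:
    """Fixed-effect estimates and per-term tests for one edge."""

    edge: int
    params: pd.Series
    cov: pd.DataFrame
    terms: dict[str, dict]
    n_obs: int
    n_subjects: int
    p_within: int
    converged: bool
    random_structure: str
    sigma2: float = np.nan
    extra: dict = field(default_factory=dict)

    @property
    def session_df(self) -> int:
        return within_subject_df(self.n_obs, self.n_subjects, self.p_within)


def _prep_edge_frame(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    if df.duplicated(["subject", "session"]).any():
        raise ValueError("duplicated (subject, session) cells")
    df = df.sort_values(["subject", "session"]).reset_index(drop=True)
    sess_counts = df.groupby("subject")["session"].nunique()
    if (sess_counts >= 2).sum() < 2:
        raise ValueError("need at least 2 sessions for at least 2 subjects")
    return df


def fit_edge_lmm(table: pd.DataFrame, interaction: bool = False,
                 include_sex: bool = True,
                 random_structure: str = "intercept+session") -> LmmEdgeResult:
    """REML fit of one edge's longitudinal model.

    ``table`` needs columns subject, sex, session (1/2/3) and z.  The
    default random structure is a random intercept plus independent
    per-subject session deviations; if that fit fails to converge the model
    falls back to a random intercept alone (logged).  Term tests are Wald
    F tests with inner-outer degrees of freedom.
    """
    df = _prep_edge_frame(table)
    if np.allclose(df["z"].to_numpy(), df["z"].iloc[0]):
        raise ValueError("degenerate edge: all values identical")
    y = df["z"].to_numpy(dtype=float)
    sex_m = (df["sex"].astype(str).to_numpy() == "M").astype(float)
    session = df["session"].to_numpy(dtype=int)
    X, names, terms, p_within, p_between = _design(sex_m, session, interaction)
    if not include_sex:
        keep = [i for i, nm in enumerate(names) if not nm.startswith("sexM")]
        X = X[:, keep]
        names = [names[i] for i in keep]
        terms = {"session": [names.index("session2"), names.index("session3")]}
        p_between = 0
    n_obs = len(df)
    n_subjects = df["subject"].nunique()

    params = cov = None
    used = random_structure
    converged = True
    if random_structure == "intercept+session":
        fitted = _fit_mixedlm_vc(df, X, names)
        if fitted is None:
            logger.warning("edge fit: intercept+session structure failed to "
                           "converge; falling back to random intercept")
            used = "intercept"
            converged = False
        else:
            params, cov, sigma2 = fitted
    if params is None:
        engine = RandomInterceptEngine(y, df["subject"].to_numpy())
        contrasts = {t: _contrast(len(names), idx) for t, idx in terms.items()}
        res = engine.fit(X, contrasts, refine=True)
        params = pd.Series(res["beta"][:, 0], index=names)
        cov = pd.DataFrame(res["cov_unscaled"][0] * res["sigma2"][0],
                           index=names, columns=names)
        sigma2 = float(res["sigma2"][0])

    term_tests = {}
    dfs = _term_dfs(n_obs, n_subjects, terms, p_within, p_between)
    for term, idx in terms.items():
        Lc = _contrast(len(names), idx)
        F, tv = _wald_many(params.to_numpy()[:, None],
                           cov.to_numpy()[None, :, :], np.array([1.0]), Lc)
        Fv = float(F[0])
        term_tests[term] = {
            "F": Fv, "df_num": len(idx), "df_den": dfs[term],
            "p": float(stats.f.sf(Fv, len(idx), dfs[term])),
            "z_equiv": float(np.sign(tv[np.argmax(np.abs(tv[:, 0])), 0])
                             * np.sqrt(Fv)),
        }
    return LmmEdgeResult(
        edge=int(table["edge"].iloc[0]) if "edge" in table else -1,
        params=params, cov=cov, terms=term_tests, n_obs=n_obs,
        n_subjects=n_subjects, p_within=p_within, converged=converged,
        random_structure=used, sigma2=sigma2)


def _contrast(p: int, idx: list[int]) -> np.ndarray:
    Lc = np.zeros((len(idx), p))
    for r, i in enumerate(idx):
        Lc[r, i] = 1.0
    return Lc


def _fit_mixedlm_vc(df: pd.DataFrame, X: np.ndarray, names: list[str]):
    """Random intercept + per-subject session deviations via statsmodels."""
    import statsmodels.api as sm

    data = pd.DataFrame(X, columns=[n.replace(":", "_") for n in names])
    data["z"] = df["z"].to_numpy()
    data["subject"] = df["subject"].to_numpy()
    data["sess_cat"] = df["session"].astype(str).to_numpy()
    fixed = " + ".join(c for c in data.columns
                       if c not in ("z", "subject", "sess_cat", "intercept"))
    formula = f"z ~ {fixed}" if fixed else "z ~ 1"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM.from_formula(
                formula, groups="subject", re_formula="1",
                vc_formula={"session": "0 + C(sess_cat)"}, data=data)
            res = md.fit(reml=True, method="lbfgs", maxiter=200)
        if not res.converged or not np.all(np.isfinite(res.fe_params)):
            return None
    except Exception:
        return None
    k = X.shape[1]
    fe = res.fe_params.copy()
    cov = res.cov_params().iloc[:k, :k]
    # statsmodels orders: Intercept first, then the passed columns
    order = ["Intercept"] + [n.replace(":", "_") for n in names
                             if n != "intercept"]
    fe = fe.loc[order]
    cov = cov.loc[order, order]
    fe.index = names
    cov.index = names
    cov.columns = names
    return fe, cov, float(res.scale)


# ---------------------------------------------------------------------------
# estimated-marginal-means post hocs

SESSION_CONTRASTS = {
    "s2-s1": {"session2": 1.0},
    "s3-s1": {"session3": 1.0},
    "s3-s2": {"session3": 1.0, "session2": -1.0},
}


def emm_posthoc(results: list[LmmEdgeResult], fdr_q: float = 0.05) -> pd.DataFrame:
    """Pairwise session contrasts of the estimated marginal means.

    In the additive model the sex effect cancels in every session contrast,
    so the EMM difference equals the session-coefficient difference.  The
    Benjamini-Hochberg adjustment is applied across all contrasts of all
    edges passed in (one FDR family per significant component).
    """
    rows = []
    for res in results:
        names = list(res.params.index)
        for label, weights in SESSION_CONTRASTS.items():
            c = np.zeros(len(names))
            for nm, w in weights.items():
                c[names.index(nm)] = w
            est = float(c @ res.params.to_numpy())
            se = float(np.sqrt(c @ res.cov.to_numpy() @ c))
            df_den = res.session_df
            t = est / se
            rows.append({
                "edge": res.edge, "contrast": label, "estimate": est,
                "se": se, "t": t, "df": df_den,
                "p": float(2.0 * stats.t.sf(abs(t), df_den)),
            })
    out = pd.DataFrame(rows)
    rej, p_adj, *_ = multipletests(out["p"], alpha=fdr_q, method="fdr_bh")
    out["p_fdr"] = p_adj
    out["significant"] = rej
    return out


# ---------------------------------------------------------------------------
# component-level permutation test (NBS framework on LMM terms)

def _cells_from_table(table: pd.DataFrame):
    """Pivot a long edge table into (subject, session) cells x edges."""
    wide = table.pivot_table(index=["subject", "session"], columns="edge",
                             values="z")
    if wide.isna().any().any():
        raise ValueError("edge table has incomplete edges within a cell")
    subj = wide.index.get_level_values("subject").to_numpy()
    sess = wide.index.get_level_values("session").to_numpy()
    sex_map = (table[["subject", "sex"]].drop_duplicates()
               .set_index("subject")["sex"])
    sex_m = (sex_map.loc[subj].astype(str).to_numpy() == "M").astype(float)
    return wide.to_numpy(dtype=float), subj, sess, sex_m


def _permute_sessions_within(rng, subj_codes, sess, n_groups):
    out = sess.copy()
    for g in range(n_groups):
        rows = np.flatnonzero(subj_codes == g)
        out[rows] = sess[rows][rng.permutation(rows.size)]
    return out


def nbr_component_test(table: pd.DataFrame, alpha_edge: float = 0.05,
                       n_perm: int = 5000, seed: int | None = None,
                       terms=("sex", "session", "interaction"),
                       include_sex: bool = True,
                       lam_grid: np.ndarray | None = None) -> dict[str, NbsResult]:
    """Permutation FWE test of connected components of LMM-significant edges.

    ``table`` is a long edge table (subject, sex, session, edge, z).  For
    each requested term, edges with term p < ``alpha_edge`` are thresholded
    into components whose strength (sum of sqrt-F z-equivalents) is compared
    with the permutation null of the maximum component strength.  Sex and
    session main effects are tested in the additive model; the interaction
    in the full model.  Setting ``include_sex=False`` drops the sex term
    from the model entirely (the secondary analysis path).
    """
    Y, subj, sess, sex_m = _cells_from_table(table)
    n_obs, m = Y.shape
    n_rois = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    subj_codes = pd.factorize(subj)[0]
    n_subjects = subj_codes.max() + 1
    rng = np.random.default_rng(seed)

    sd = Y.std(axis=0)
    good = sd > 1e-12
    if not good.all():
        logger.warning("excluding %d degenerate edge(s): %s",
                       (~good).sum(), np.flatnonzero(~good).tolist())

    engine = RandomInterceptEngine(Y, subj_codes, lam_grid=lam_grid)
    if not include_sex:
        terms = tuple(t for t in terms if t == "session")

    def term_stats(term, sess_labels, sex_labels):
        interaction = term == "interaction"
        if include_sex:
            X, names, tmap, p_w, p_b = _design(sex_labels, sess_labels, interaction)
        else:
            X = np.column_stack([np.ones(n_obs), (sess_labels == 2).astype(float),
                                 (sess_labels == 3).astype(float)])
            names = ["intercept", "session2", "session3"]
            tmap, p_w, p_b = {"session": [1, 2]}, 2, 0
        Lc = _contrast(len(names), tmap[term])
        res = engine.fit(X, {term: Lc})
        dfs = _term_dfs(n_obs, n_subjects, tmap, p_w, p_b)
        F = res["F"][term]
        p = stats.f.sf(F, Lc.shape[0], dfs[term])
        tv = res["contrast_t"][term]
        sign = np.sign(np.take_along_axis(
            tv, np.abs(tv).argmax(axis=0)[None, :], axis=0))[0]
        z = sign * np.sqrt(F)
        return p, z

    out: dict[str, NbsResult] = {}
    for term in terms:
        p_obs, z_obs = term_stats(term, sess, sex_m)
        # suprathreshold mask comes from the edge p-values; component
        # strength sums |z| over the masked edges
        stat = np.where(good & (p_obs < alpha_edge), np.abs(z_obs), 0.0)
        comps = threshold_and_components(stat, n_rois, t_thresh=1e-12,
                                         direction="positive")
        null = np.empty(n_perm)
        for i in range(n_perm):
            if term == "sex":
                perm_sex_by_subj = rng.permutation(
                    pd.Series(sex_m).groupby(subj_codes).first().to_numpy())
                sex_p = perm_sex_by_subj[subj_codes]
                p_i, z_i = term_stats(term, sess, sex_p)
            else:
                sess_p = _permute_sessions_within(rng, subj_codes, sess,
                                                  n_subjects)
                p_i, z_i = term_stats(term, sess_p, sex_m)
            stat_i = np.where(good & (p_i < alpha_edge), np.abs(z_i), 0.0)
            comps_i = threshold_and_components(stat_i, n_rois, t_thresh=1e-12,
                                               direction="positive")
            null[i] = comps_i[0].strength if comps_i else 0.0
        for c in comps:
            c.p_fwe = float((1 + np.sum(null >= c.strength)) / (1 + n_perm))
        out[term] = NbsResult(components=comps, edge_stats=z_obs,
                              null_max_strength=null, t_thresh=alpha_edge,
                              direction="two-sided", n_perm=n_perm, seed=seed,
                              extra={"term": term, "edge_p": p_obs})
    return out


class NBSLMM:
    """Longitudinal network-based statistic over LMM terms.

    ``fit(table)`` runs :func:`nbr_component_test` on a long edge table and
    stores per-term results in ``results_``; ``posthoc(term)`` computes the
    estimated-marginal-means session contrasts (FDR-corrected) for the
    edges of the significant components of that term.
    """

    def __init__(self, alpha_edge: float = 0.05, n_perm: int = 5000,
                 terms=("sex", "session", "interaction"), seed: int | None = None,
                 include_sex: bool = True, fdr_q: float = 0.05):
        self.alpha_edge = alpha_edge
        self.n_perm = n_perm
        self.terms = terms
        self.seed = seed
        self.include_sex = include_sex
        self.fdr_q = fdr_q

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("alpha_edge", "n_perm", "terms", "seed", "include_sex", "fdr_q")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, table: pd.DataFrame):
        self.table_ = table
        self.results_ = nbr_component_test(
            table, alpha_edge=self.alpha_edge, n_perm=self.n_perm,
            seed=self.seed, terms=self.terms, include_sex=self.include_sex)
        return self

    def significant_components(self, alpha: float = 0.05):
        return [(t, c) for t, res in self.results_.items()
                for c in res.components if c.p_fwe <= alpha]

    def posthoc(self, term: str = "session", alpha: float = 0.05) -> pd.DataFrame:
        frames = []
        for comp in self.results_[term].components:
            if comp.p_fwe > alpha:
                continue
            fits = []
            for e in comp.edges:
                sub = self.table_[self.table_["edge"] == e]
                fits.append(fit_edge_lmm(sub, include_sex=self.include_sex))
            ph = emm_posthoc(fits, fdr_q=self.fdr_q)
            ph.insert(0, "component_nodes", [comp.nodes] * len(ph))
            frames.append(ph)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)
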