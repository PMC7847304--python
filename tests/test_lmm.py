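"""Tests of the longitudinal (mixed-model) network statistics."""

import numpy as np
import pandas as pd
import pytest

import voleconn as v
from voleconn.lmm import (NBSLMM, RandomInterceptEngine, _contrast, _design,
                          emm_posthoc, fit_edge_lmm, nbr_component_test)


def edge_table(y, subj, sess, sex=None):
    if sex is None:
        sex = np.where(np.asarray(subj) % 2 == 0, "F", "M")
    return pd.DataFrame({"subject": subj, "sex": sex, "session": sess,
                         "edge": 0, "z": y})


def simulate_edge(rng, n_subjects=32, shift3=0.0, resid_sd=0.15,
                  subj_sd=0.1, missing=()):
    rows = []
    b = rng.normal(0, subj_sd, n_subjects)
    for s in range(n_subjects):
        for k in (1, 2, 3):
            if (s, k) in missing:
                continue
            mu = b[s] + (shift3 if k == 3 else 0.0)
            rows.append((s, k, mu + rng.normal(0, resid_sd)))
    arr = np.array(rows)
    return edge_table(arr[:, 2], arr[:, 0].astype(int), arr[:, 1].astype(int))


class TestDegreesOfFreedom:
    def test_inner_outer_rule(self):
        assert v.within_subject_df(90, 32, 2) == 56
        assert v.between_subject_df(32, 1) == 30

    def test_fit_reports_study_dfs(self, rng):
        missing = {(0, 1), (1, 1), (2, 1), (3, 1), (4, 3), (5, 3)}
        table = simulate_edge(rng, missing=missing)
        res = fit_edge_lmm(table)
        assert res.n_obs == 90
        assert res.session_df == 56
        assert res.terms["session"]["df_den"] == 56
        assert res.terms["sex"]["df_den"] == 30


class TestRandomInterceptEngine:
    def test_matches_statsmodels_reml(self, rng):
        import statsmodels.api as sm
        table = simulate_edge(rng, subj_sd=0.2, resid_sd=0.1)
        y = table["z"].to_numpy()
        sexm = (table["sex"] == "M").to_numpy().astype(float)
        sess = table["session"].to_numpy()
        X, names, terms, _, _ = _design(sexm, sess, False)
        eng = RandomInterceptEngine(y, table["subject"].to_numpy())
        res = eng.fit(X, {t: _contrast(4, i) for t, i in terms.items()},
                      refine=True)
        ref = sm.MixedLM(y, X, groups=table["subject"].to_numpy()).fit(reml=True)
        assert np.abs(res["beta"][:, 0] - ref.fe_params).max() < 1e-6
        assert res["sigma2"][0] == pytest.approx(ref.scale, rel=1e-4)

    def test_balanced_session_f_matches_rm_anova_oracle(self, rng):
        # complete balanced data, random intercept only: the session Wald F
        # must equal MS_session / MS_error of the repeated-measures
        # decomposition
        table = simulate_edge(rng, n_subjects=12, subj_sd=0.25, shift3=0.1)
        res = fit_edge_lmm(table, include_sex=False,
                           random_structure="intercept")
        wide = table.pivot(index="subject", columns="session", values="z").to_numpy()
        s, k = wide.shape
        grand = wide.mean()
        m_sess = wide.mean(axis=0)
        m_subj = wide.mean(axis=1)
        ss_sess = s * np.sum((m_sess - grand) ** 2)
        sse = np.sum((wide - m_subj[:, None] - m_sess[None, :] + grand) ** 2)
        f_oracle = (ss_sess / (k - 1)) / (sse / ((s - 1) * (k - 1)))
        assert res.terms["session"]["F"] == pytest.approx(f_oracle, abs=1e-6)

    def test_null_estimates_within_three_se(self, rng):
        table = simulate_edge(rng, subj_sd=0.0)
        res = fit_edge_lmm(table)
        se = np.sqrt(np.diag(res.cov.to_numpy()))
        assert np.all(np.abs(res.params.to_numpy()[1:]) < 3 * se[1:])


class TestEdgeFit:
    def test_planted_shift_recovered_within_mc_interval(self):
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(3000 + seed)
            table = simulate_edge(rng, shift3=0.3, resid_sd=0.15)
            res = fit_edge_lmm(table)
            estimates.append(res.params["session3"])
        mean, se = np.mean(estimates), np.std(estimates) / 10
        assert mean - 1.96 * se < 0.3 < mean + 1.96 * se

    def test_degenerate_edge_rejected(self):
        table = edge_table(np.zeros(12), np.repeat(np.arange(4), 3),
                           np.tile([1, 2, 3], 4))
        with pytest.raises(ValueError, match="degenerate"):
            fit_edge_lmm(table)

    def test_duplicated_cells_rejected(self, rng):
        table = simulate_edge(rng, n_subjects=4)
        table = pd.concat([table, table.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicated"):
            fit_edge_lmm(table)


class TestPosthoc:
    def test_balanced_emm_equals_session_mean_differences(self, rng):
        table = simulate_edge(rng, n_subjects=10, shift3=0.2)
        res = fit_edge_lmm(table, include_sex=False,
                           random_structure="intercept")
        ph = emm_posthoc([res])
        means = table.groupby("session")["z"].mean()
        got = ph.set_index("contrast")["estimate"]
        assert got["s2-s1"] == pytest.approx(means[2] - means[1], abs=1e-8)
        assert got["s3-s1"] == pytest.approx(means[3] - means[1], abs=1e-8)
        assert got["s3-s2"] == pytest.approx(means[3] - means[2], abs=1e-8)
        assert (ph["df"] == v.within_subject_df(30, 10, 2)).all()

    def test_fdr_matches_step_up_oracle(self, rng):
        fits = [fit_edge_lmm(simulate_edge(rng, shift3=sh))
                for sh in (0.0, 0.1, 0.3)]
        ph = emm_posthoc(fits)
        p = ph["p"].to_numpy()
        m = p.size
        order = np.argsort(p)
        adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(ph["p_fdr"].to_numpy(), expected, atol=1e-12)
        # BH preserves the ordering of raw p
        assert (np.argsort(ph["p_fdr"].to_numpy()[order]) ==
                np.arange(m)).all()

    def test_shift_only_in_session3_flags_right_contrasts(self):
        hits_3, hits_2 = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(5000 + seed)
            table = simulate_edge(rng, shift3=0.3, resid_sd=0.1)
            ph = emm_posthoc([fit_edge_lmm(table)]).set_index("contrast")
            hits_3 += ph.loc["s3-s1", "p"] < 0.05
            hits_2 += ph.loc["s2-s1", "p"] < 0.05
        assert hits_3 >= 18
        assert hits_2 <= 4


def small_null_table(seed, n_rois=8, n_subjects=20):
    rng = np.random.default_rng(seed)
    m = n_rois * (n_rois - 1) // 2
    cells = [(s, k) for s in range(n_subjects) for k in (1, 2, 3)]
    rows = []
    for s, k in cells:
        rows.append(pd.DataFrame({
            "subject": s, "sex": "F" if s % 2 else "M", "session": k,
            "edge": np.arange(m), "z": rng.normal(0, 0.1, m)}))
    return pd.concat(rows, ignore_index=True)


class TestComponentTest:
    def test_deterministic_given_seed(self):
        table = small_null_table(1)
        a = nbr_component_test(table, n_perm=150, seed=9, terms=("session",))
        b = nbr_component_test(table, n_perm=150, seed=9, terms=("session",))
        np.testing.assert_array_equal(a["session"].null_max_strength,
                                      b["session"].null_max_strength)

    def test_observed_stats_unaffected_by_other_terms(self):
        table = small_null_table(2)
        both = nbr_component_test(table, n_perm=100, seed=1,
                                  terms=("sex", "session"))
        only = nbr_component_test(table, n_perm=100, seed=1,
                                  terms=("session",))
        np.testing.assert_allclose(both["session"].edge_stats,
                                   only["session"].edge_stats, atol=1e-12)

    def test_dropping_sex_uses_same_component_machinery(self):
        table = small_null_table(3)
        res = nbr_component_test(table, n_perm=100, seed=4,
                                 terms=("sex", "session"), include_sex=False)
        assert set(res) == {"session"}
        r = res["session"]
        assert r.null_max_strength.shape == (100,)
        assert all(c.p_fwe >= 1 / 101 for c in r.components)

    def test_degenerate_edge_excluded_with_log(self, caplog):
        table = small_null_table(5, n_rois=5)
        table.loc[table["edge"] == 2, "z"] = 0.7
        with caplog.at_level("WARNING", logger="voleconn.lmm"):
            res = nbr_component_test(table, n_perm=100, seed=0,
                                     terms=("session",))
        assert "degenerate" in caplog.text
        assert 2 not in {e for c in res["session"].components for e in c.edges}

    def test_planted_session_network_recovered(self):
        cfg = v.session_change_scenario(seed=21)
        panel, _, _ = v.generate_cohort(cfg)
        stack = v.build_connectome_stack(panel)
        est = NBSLMM(n_perm=400, terms=("session",), seed=13).fit(
            stack.edge_long_table())
        sig = est.significant_components()
        assert sig
        planted = set(v.path_edges(list(range(11)), 12))
        got = set(sig[0][1].edges)
        assert len(got & planted) / len(planted) >= 0.8
        ph = est.posthoc("session")
        assert {"contrast", "p_fdr"} <= set(ph.columns)
        assert (ph["df"] == v.within_subject_df(90, 32, 2)).all()
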