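"""Behavioral measures and statistics for pair-bonding assays.

Covers the partner-preference test (a 3-h choice test between the partner
and an opposite-sex stranger), huddling-latency scoring during
cohabitation, rank-based group comparisons with an effect size, and
a-posteriori correlations between connectivity edges and behavior.

The Mann-Whitney effect size follows the convention ``r = |Z| / sqrt(N)``
where ``Z`` is the large-sample normal approximation of U *without*
continuity correction and ``N`` is the number of unique subjects
contributing observations (e.g. 32 when the same 32 animals provide both
the partner and the stranger proportions); this is the convention under
which all four printed (U, r) pairs of the source behavioral dataset are
mutually consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def partner_preference_index(time_partner: float, time_stranger: float):
    """Proportion of social-incentive time spent next to the partner.

    Returns NaN (with a warning) when both times are zero.
    """
    if time_partner < 0 or time_stranger < 0:
        raise ValueError("times must be non-negative")
    total = time_partner + time_stranger
    if total == 0:
        warnings.warn("partner preference undefined: no social-incentive time")
        return float("nan")
    return time_partner / total


def percent_social_time(time_partner: float, time_stranger: float,
                        total_test_time: float) -> float:
    """Percentage of the whole test spent in either social incentive area."""
    if total_test_time <= 0:
        raise ValueError("total_test_time must be positive")
    return 100.0 * (time_partner + time_stranger) / total_test_time


def huddle_latency(contact_bouts, min_bout: float = 10.0):
    """Latency (minutes) to the first contact bout lasting >= ``min_bout`` s.

    ``contact_bouts`` is a sorted list of non-overlapping (start, end) times
    in seconds.  Bouts shorter than ``min_bout`` do not count (huddling is
    only scored for continuous side-to-side contact of at least 10 s);
    returns NaN when no qualifying bout exists.
    """
    prev_end = -np.inf
    for start, end in contact_bouts:
        if end < start:
            raise ValueError(f"negative-duration bout ({start}, {end})")
        if start < prev_end:
            raise ValueError("bouts must be sorted and non-overlapping")
        prev_end = end
    for start, end in contact_bouts:
        if end - start >= min_bout:
            return start / 60.0
    return float("nan")


def u_effect_size(u: float, n1: int, n2: int, n_subjects: int) -> float:
    """Effect size r = |Z| / sqrt(n_subjects) from a printed U statistic.

    Z is the normal approximation (no ties, no continuity correction):
    ``Z = (U - n1*n2/2) / sqrt(n1*n2*(n1+n2+1)/12)``.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    mu = n1 * n2 / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (u - mu) / sd
    return abs(z) / np.sqrt(n_subjects)


@dataclass
class MannWhitneyResult:
    u: float
    z: float
    p: float
    r_effect: float


def mann_whitney_with_effect(x, y, n_subjects: int,
                             tail: str = "two") -> MannWhitneyResult:
    """Mann-Whitney U with normal-approximation p and effect size.

    U is the rank-sum statistic of ``x`` with midranks for ties; the Z
    used for the effect size carries the tie-corrected variance but no
    continuity correction, and ``r = |Z| / sqrt(n_subjects)``.  ``tail``
    is "one" or "two"; the one-tailed p is for the observed direction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1.0))
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        z = 0.0
    else:
        z = (u - mu) / np.sqrt(var)
    if tail == "two":
        p = 2.0 * stats.norm.sf(abs(z))
    elif tail == "one":
        p = stats.norm.sf(abs(z))
    else:
        raise ValueError("tail must be 'one' or 'two'")
    return MannWhitneyResult(u=float(u), z=float(z), p=float(min(p, 1.0)),
                             r_effect=float(abs(z) / np.sqrt(n_subjects)))


def edge_behavior_correlation(edge_values, behavior, method: str = "pearson"):
    """Edge-behavior correlation with df = n - 2 and a two-tailed p.

    Pairwise-complete: rows with a missing value in either vector are
    dropped.  Pearson p comes from the t distribution; Spearman from the
    t approximation on rho.
    """
    x = np.asarray(edge_values, dtype=float)
    y = np.asarray(behavior, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), n - 2, float(p)


def cohort_manifest(n_subjects: int, sessions: int = 3,
                    exclusions=()) -> dict:
    """Dataset accounting: retained cell count and per-session availability.

    ``exclusions`` lists (subject, session, reason) triples; duplicate
    (subject, session) cells are collapsed.
    """
    cells = set()
    per_session = {s: n_subjects for s in range(1, sessions + 1)}
    reasons = []
    for subj, sess, reason in exclusions:
        if not (0 <= subj < n_subjects):
            raise ValueError(f"exclusion references unknown subject {subj}")
        if not (1 <= sess <= sessions):
            raise ValueError(f"exclusion references unknown session {sess}")
        if (subj, sess) not in cells:
            cells.add((subj, sess))
            per_session[sess] -= 1
        reasons.append({"subject": subj, "session": sess, "reason": reason})
    return {
        "n_subjects": n_subjects,
        "sessions": sessions,
        "retained": n_subjects * sessions - len(cells),
        "per_session": per_session,
        "exclusions": reasons,
    }


#: Exclusions reproducing the study's accounting: two subjects missed the
#: baseline scan, two baseline datasets failed QC (signal loss), two
#: subjects missed the 2-week scan.
STUDY_EXCLUSIONS = (
    (0, 1, "missed acquisition"), (1, 1, "missed acquisition"),
    (2, 1, "signal loss"), (3, 1, "signal loss"),
    (4, 3, "missed acquisition"), (5, 3, "missed acquisition"),
)


def behavior_summary(table: pd.DataFrame) -> dict:
    """Descriptives + rank tests of a behavior table (ppi, sex, period)."""
    ppi = table["ppi"].to_numpy(dtype=float)
    n = len(table)
    res_pref = mann_whitney_with_effect(ppi, 1.0 - ppi, n_subjects=n, tail="one")
    sex = table["sex"].astype(str).to_numpy()
    res_sex = mann_whitney_with_effect(ppi[sex == "M"], ppi[sex == "F"],
                                       n_subjects=n, tail="two")
    out = {
        "median_partner_proportion": float(np.median(ppi)),
        "median_stranger_proportion": float(np.median(1.0 - ppi)),
        "partner_vs_stranger": res_pref.__dict__,
        "male_vs_female_partner": res_sex.__dict__,
    }
    if "percent_social_time" in table:
        pst = table["percent_social_time"].to_numpy(dtype=float)
        out["mean_percent_social_time"] = float(np.mean(pst))
        r, df, p = edge_behavior_correlation(pst, ppi, method="spearman")
        out["social_time_vs_ppi_spearman"] = {"rs": r, "df": df, "p": p}
    return out
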