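"""qPCR relative telomere length (T/S) and group comparisons.

The monochrome multiplex qPCR assay reports, per sample, a cycle
threshold for the telomere amplicon (ct_tel) and for a single-copy
internal control gene, albumin (ct_alb). Relative telomere length is

    T/S = 2 ** -(ct_tel - ct_alb)

so a sample whose telomere signal crosses threshold one cycle later than
albumin has half the relative telomeric content. Distribution comparisons
between groups use the Wilcoxon rank-sum (Mann-Whitney) test — exact by
enumeration at small combined n, normal approximation with tie and
continuity correction otherwise — plus Welch's t test and one-way ANOVA
for mean comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: combined-n at or below which the Wilcoxon p-value is exact
EXACT_WILCOXON_MAX_N = 10

_ALTERNATIVES = {"a_greater": "greater", "a_less": "less", "two_sided": "two-sided"}


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    group: str
    ct_tel: float
    ct_alb: float


@dataclass(frozen=True)
class TSRecord:
    sample_id: str
    group: str
    delta_ct: float
    t_s: float

    def to_dict(self) -> dict:
        return asdict(self)


def compute_ts(record: CtRecord) -> TSRecord:
    """T/S relative telomere length from one pair of Ct values."""
    if not (math.isfinite(record.ct_tel) and math.isfinite(record.ct_alb)):
        raise ValueError(f"non-finite Ct for sample {record.sample_id!r}")
    delta = record.ct_tel - record.ct_alb
    return TSRecord(
        sample_id=record.sample_id,
        group=record.group,
        delta_ct=delta,
        t_s=2.0 ** (-delta),
    )


def compute_ts_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Vectorized T/S over a Ct table; appends delta_ct and t_s columns.

    Ct values outside the plausible qPCR range (0, 45) are flagged in a
    ``ct_flag`` column but still computed.
    """
    vals = ct[["ct_tel", "ct_alb"]].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("Ct table contains non-finite values")
    out = ct.copy()
    out["delta_ct"] = out["ct_tel"] - out["ct_alb"]
    out["t_s"] = np.exp2(-out["delta_ct"])
    in_range = ((vals > 0) & (vals < 45)).all(axis=1)
    out["ct_flag"] = np.where(in_range, "", "ct_out_of_range")
    return out


def _rank_sum_u(a_ranks: np.ndarray, n_a: int) -> float:
    return float(a_ranks.sum() - n_a * (n_a + 1) / 2)


def _exact_wilcoxon_p(ranks: np.ndarray, n_a: int, u_obs: float, alternative: str) -> float:
    """Exact p by enumerating every assignment of the pooled midranks to
    group A. Handles ties because the enumeration runs over the observed
    midranks, not over 1..n."""
    n = len(ranks)
    offset = n_a * (n_a + 1) / 2
    total = math.comb(n, n_a)
    ge = le = 0
    eps = 1e-9
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - offset
        if u >= u_obs - eps:
            ge += 1
        if u <= u_obs + eps:
            le += 1
    p_greater = ge / total
    p_less = le / total
    if alternative == "a_greater":
        return p_greater
    if alternative == "a_less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def compare_length_distributions(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two_sided",
    exact_max_n: int = EXACT_WILCOXON_MAX_N,
) -> dict:
    """Wilcoxon rank-sum test between two relative-length samples.

    ``alternative`` is one of a_greater / a_less / two_sided, stated for
    group A. For combined n <= ``exact_max_n`` the p-value is computed by
    full enumeration over all C(n, n_a) rank assignments (midranks, so
    ties are exact too); above that, the normal approximation with tie
    correction and continuity correction. Returns the Mann-Whitney U of
    group A as the statistic.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = _rank_sum_u(ranks[: a.size], a.size)
    n = a.size + b.size
    if n <= exact_max_n:
        p = _exact_wilcoxon_p(ranks, a.size, u_obs, alternative)
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative=_ALTERNATIVES[alternative],
            method="asymptotic", use_continuity=True,
        )
        p = float(res.pvalue)
        method = "normal_approx"
    return {"statistic": u_obs, "p_value": p, "method": method, "alternative": alternative}


def compare_means(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Welch two-sample t test (unequal variances)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t_statistic": float(t), "p_value": float(p)}


def anova(groups: Sequence[Sequence[float]]) -> dict:
    """One-way fixed-effects ANOVA across 3+ groups."""
    if len(groups) < 3:
        raise ValueError("ANOVA here is for 3 or more groups; use compare_means for 2")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in arrays):
        raise ValueError("each group needs at least 2 values")
    f, p = stats.f_oneway(*arrays)
    return {"F": float(f), "p_value": float(p)}
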