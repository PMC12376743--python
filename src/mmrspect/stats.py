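"""Nonparametric tests used throughout, with explicit, reproducible contracts.

Thin wrappers over scipy/statsmodels where those exist (rank-sum, signed-rank,
Fisher, chi-square goodness-of-fit, Benjamini-Hochberg); the
Jonckheere-Terpstra trend test is implemented here since neither scipy nor
statsmodels provides it.  Every result records its method, sidedness and
sample sizes so downstream tables are self-describing.

Defaults are two-sided; sidedness is always recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: combined-n below which exact methods are used
EXACT_RANKSUM_N = 20
EXACT_JT_N = 10


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    sided: str
    n: int
    n_groups: tuple = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def rank_sum(x, y, sided: str = "two-sided") -> TestResult:
    """Mann-Whitney U rank-sum test.

    Exact null distribution below combined n of 20 (and no ties), else the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x) + len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n
    method = "exact" if (n < EXACT_RANKSUM_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=_alt(sided), method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"rank-sum ({method})", sided, n, (len(x), len(y)))


def signed_rank(pairs, sided: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test on paired values or precomputed differences.

    Zero differences are dropped (Wilcoxon's exclusion rule); if every
    difference is zero the test is degenerate and p = 1.
    """
    arr = np.asarray(pairs, float)
    d = arr[:, 0] - arr[:, 1] if arr.ndim == 2 else arr
    d = d[d != 0]
    if len(d) == 0:
        return TestResult(0.0, 1.0, "signed-rank (degenerate)", sided, 0)
    mode = "exact" if (len(d) < 25 and len(np.unique(np.abs(d))) == len(d)) \
        else "approx"
    res = sps.wilcoxon(d, alternative=_alt(sided), method=mode,
                       correction=(mode == "approx"))
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"signed-rank ({mode})", sided, len(d))


def fisher_exact(table, sided: str = "two-sided") -> TestResult:
    tab = np.asarray(table, dtype=np.int64).reshape(2, 2)
    odds, p = sps.fisher_exact(tab, alternative=_alt(sided))
    return TestResult(float(odds), float(p), "Fisher exact", sided,
                      int(tab.sum()))


def chi2_gof(observed, expected_props) -> TestResult:
    """Goodness-of-fit chi-square of counts against expected proportions
    (df = k - 1)."""
    obs = np.asarray(observed, float)
    props = np.asarray(expected_props, float)
    if obs.sum() <= 0:
        raise ValueError("observed counts sum to zero")
    if not np.isclose(props.sum(), 1.0, atol=1e-8):
        raise ValueError("expected proportions must sum to 1")
    stat, p = sps.chisquare(obs, f_exp=obs.sum() * props)
    return TestResult(float(stat), float(p), "chi-square GOF", "two-sided",
                      int(obs.sum()))


def _jt_statistic(groups: list[np.ndarray]) -> float:
    """JT = sum over ordered group pairs i<j of the Mann-Whitney count
    #(x_i < y_j) + 0.5 #(x_i == y_j)."""
    stat = 0.0
    for gi, gj in combinations(groups, 2):
        diff = gj[None, :] - gi[:, None]
        stat += (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return stat


def jonckheere_terpstra(groups, sided: str = "two-sided") -> TestResult:
    """Jonckheere-Terpstra test for an ordered trend across k groups.

    Normal approximation with tie correction; exact permutation (full
    enumeration over group assignments) below 10 total observations or when
    requested sample sizes make it cheap.  One-sided 'greater' tests for an
    increasing trend in the given group order.
    """
    groups = [np.asarray(g, float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty ordered groups")
    sizes = np.array([len(g) for g in groups])
    n = int(sizes.sum())
    obs = _jt_statistic(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):  # no ordering information at all
        return TestResult(obs, 1.0, "Jonckheere-Terpstra (degenerate)",
                          sided, n, tuple(sizes))
    if n < EXACT_JT_N:
        stats_all = _jt_permutations(pooled, sizes)
        p_ge = np.mean(stats_all >= obs - 1e-12)
        p_le = np.mean(stats_all <= obs + 1e-12)
        p = {"greater": p_ge, "less": p_le,
             "two-sided": min(1.0, 2 * min(p_ge, p_le))}[sided]
        return TestResult(obs, float(p), "Jonckheere-Terpstra (exact)",
                          sided, n, tuple(sizes))
    mean = (n * n - (sizes ** 2).sum()) / 4.0
    _, ties = np.unique(pooled, return_counts=True)
    t1 = (ties * (ties - 1) * (2 * ties + 5)).sum()
    n1 = (sizes * (sizes - 1) * (2 * sizes + 5)).sum()
    var = (n * (n - 1) * (2 * n + 5) - n1 - t1) / 72.0
    var += ((sizes * (sizes - 1) * (sizes - 2)).sum()
            * (ties * (ties - 1) * (ties - 2)).sum()) \
        / (36.0 * n * (n - 1) * (n - 2))
    var += ((sizes * (sizes - 1)).sum() * (ties * (ties - 1)).sum()) \
        / (8.0 * n * (n - 1))
    if var <= 0:  # all values tied
        return TestResult(obs, 1.0, "Jonckheere-Terpstra (degenerate)",
                          sided, n, tuple(sizes))
    z = (obs - mean) / np.sqrt(var)
    if sided == "greater":
        p = sps.norm.sf(z)
    elif sided == "less":
        p = sps.norm.cdf(z)
    else:
        p = 2 * sps.norm.sf(abs(z))
    return TestResult(obs, float(min(p, 1.0)),
                      "Jonckheere-Terpstra (normal approx)", sided, n,
                      tuple(sizes))


def _jt_permutations(pooled: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """JT statistic over every assignment of the pooled values to groups of
    the given sizes (exact permutation null)."""
    out: list[float] = []
    idx_all = np.arange(len(pooled))

    def rec(remaining: np.ndarray, k: int, chosen: list[np.ndarray]) -> None:
        if k == len(sizes):
            out.append(_jt_statistic([pooled[c] for c in chosen]))
            return
        for comb in combinations(remaining, int(sizes[k])):
            comb_arr = np.array(comb)
            rest = np.setdiff1d(remaining, comb_arr, assume_unique=True)
            rec(rest, k + 1, chosen + [comb_arr])

    rec(idx_all, 0, [])
    return np.array(out)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _alt(sided: str) -> str:
    if sided not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sided!r}")
    return sided
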