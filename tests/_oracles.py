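"""Independent brute-force oracles used by the equivalence tests.

Everything here is deliberately naive (string slicing, full enumeration,
direct formulas) and shares no code with the implementation it checks.
"""

from itertools import combinations, permutations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def naive_channel(ref: str, alt: str, context: str) -> str:
    """Per-mutation channel lookup by explicit pyrimidine normalisation."""
    if ref in "AG":
        ref, alt = _COMP[ref], _COMP[alt]
        context = revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def naive_spectrum(rows, genome_str_by_chrom) -> dict:
    """96-channel counts via string slicing, one mutation at a time."""
    counts: dict[str, int] = {}
    for chrom, pos, ref, alt in rows:
        seq = genome_str_by_chrom[chrom]
        ctx = seq[pos - 2: pos + 1]
        if "N" in ctx:
            continue
        ch = naive_channel(ref, alt, ctx)
        counts[ch] = counts.get(ch, 0) + 1
    return counts


def naive_overlap(pos: int, intervals) -> bool:
    """1-based position vs 0-based half-open intervals, by direct scan."""
    return any(s <= pos - 1 < e for s, e in intervals)


def jt_statistic(groups) -> float:
    stat = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for x in groups[i]:
                for y in groups[j]:
                    if x < y:
                        stat += 1
                    elif x == y:
                        stat += 0.5
    return stat


def jt_exact_p(groups, sided="greater") -> float:
    """Exact JT p by full enumeration of group assignments."""
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    obs = jt_statistic(groups)
    stats = []

    def rec(remaining, k, chosen):
        if k == len(sizes):
            stats.append(jt_statistic(chosen))
            return
        for comb in combinations(range(len(remaining)), sizes[k]):
            sel = [remaining[i] for i in comb]
            rest = [remaining[i] for i in range(len(remaining))
                    if i not in set(comb)]
            rec(rest, k + 1, chosen + [sel])

    rec(pooled, 0, [])
    stats = np.array(stats)
    p_ge = np.mean(stats >= obs - 1e-12)
    p_le = np.mean(stats <= obs + 1e-12)
    if sided == "greater":
        return float(p_ge)
    if sided == "less":
        return float(p_le)
    return float(min(1.0, 2 * min(p_ge, p_le)))


def ranksum_perm_p(x, y, sided="two-sided") -> float:
    """Exact rank-sum p by enumerating group assignments of the pooled
    sample (rank-sum statistic of the first group)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = _rankdata(pooled)
    obs = ranks[:n].sum()
    stats = [sum(ranks[list(comb)])
             for comb in combinations(range(len(pooled)), n)]
    stats = np.array(stats)
    p_ge = np.mean(stats >= obs - 1e-12)
    p_le = np.mean(stats <= obs + 1e-12)
    if sided == "greater":
        return float(p_ge)
    if sided == "less":
        return float(p_le)
    return float(min(1.0, 2 * min(p_ge, p_le)))


def signed_rank_perm_p(diffs, sided="two-sided") -> float:
    """Exact signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray([v for v in diffs if v != 0], float)
    n = len(d)
    ranks = _rankdata(np.abs(d))
    obs = ranks[d > 0].sum()
    stats = []
    for mask in range(2 ** n):
        signs = [(mask >> i) & 1 for i in range(n)]
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.array(stats)
    p_ge = np.mean(stats >= obs - 1e-12)
    p_le = np.mean(stats <= obs + 1e-12)
    if sided == "greater":
        return float(p_ge)
    if sided == "less":
        return float(p_le)
    return float(min(1.0, 2 * min(p_ge, p_le)))


def _rankdata(a):
    a = np.asarray(a, float)
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(len(a))
    i = 0
    sorted_a = a[order]
    while i < len(a):
        j = i
        while j + 1 < len(a) and sorted_a[j + 1] == sorted_a[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def bh_stepup(p):
    """Direct BH step-up formula: p_(i) * m / i with cumulative minimum
    from the largest p downwards."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def fisher_2x2_p(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    from math import comb
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return float(sum(prob(k) for k in range(lo, hi + 1)
                     if prob(k) <= p_obs * (1 + 1e-9)))
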