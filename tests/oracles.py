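"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition (branch
enumeration, rank assignment enumeration, step-up definition) rather than
calling the code paths they check.
"""

import itertools
import math

import numpy as np


def unifrac_oracle(tree, counts_a, counts_b, weighted, normalized=True):
    """UniFrac by explicit enumeration of every branch and its leaf set."""
    names = [t.name for t in tree.tips()]
    a = np.array([counts_a.get(n, 0) for n in names], dtype=float)
    b = np.array([counts_b.get(n, 0) for n in names], dtype=float)
    pa, pb = a / a.sum(), b / b.sum()
    pos = {n: i for i, n in enumerate(names)}
    num = den = 0.0
    for node in tree.postorder(include_self=False):
        length = node.length or 0.0
        leaves = [node.name] if node.is_tip() else [t.name for t in node.tips()]
        idx = [pos[n] for n in leaves]
        mass_a, mass_b = pa[idx].sum(), pb[idx].sum()
        if weighted:
            num += length * abs(mass_a - mass_b)
            den += length * (mass_a + mass_b)
        else:
            if (mass_a > 0) != (mass_b > 0):
                num += length
            if mass_a > 0 or mass_b > 0:
                den += length
    if weighted and not normalized:
        return num
    return num / den if den else 0.0


def ace_oracle(counts, rare_threshold=10):
    """ACE richness from the abundance-based coverage estimator definition."""
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    rare = counts[counts <= rare_threshold]
    abundant = counts[counts > rare_threshold]
    s_rare, s_abund = len(rare), len(abundant)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    if s_rare == 0:
        return float(s_abund)
    c_ace = 1 - f1 / n_rare
    fk = np.array([(rare == k).sum() for k in range(1, rare_threshold + 1)])
    k = np.arange(1, rare_threshold + 1)
    gamma2 = max(
        (s_rare / c_ace) * (k * (k - 1) * fk).sum() / (n_rare * (n_rare - 1)) - 1, 0.0
    )
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def wilcoxon_exact_oracle(x, y):
    """Two-sided exact rank-sum p by enumerating all rank assignments.

    Requires tie-free pooled data.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle needs tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    nx = len(x)
    w_obs = sum(ranks[v] for v in x)
    mean_w = nx * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), nx):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def bh_oracle(p):
    """Benjamini-Hochberg step-up q-values straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = math.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        q[i] = min(running_min, 1.0)
    return q


def spearman_oracle(x, y):
    """Rank-then-Pearson Spearman rho with average ranks for ties."""
    def average_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2
            i = j
        return ranks

    rx, ry = average_ranks(x), average_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
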