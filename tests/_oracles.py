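"""Independent brute-force oracles used by the test suite.

Each oracle is written step-by-step from the published definition of the
quantity it checks, deliberately without reusing any code path from the
package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def tmm_factor_oracle(obs, ref, logratio_trim=0.3, sum_trim=0.05):
    """TMM factor of one sample vs a reference, spelled out step by step.

    Plain loops and explicit rank bookkeeping; returns the unscaled
    2^(weighted trimmed mean of M) factor.
    """
    obs = np.asarray(obs, float)
    ref = np.asarray(ref, float)
    n_obs, n_ref = obs.sum(), ref.sum()
    m_vals, a_vals, w_vals = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            p_o, p_r = o / n_obs, r / n_ref
            m_vals.append(math.log2(p_o / p_r))
            a_vals.append(0.5 * math.log2(p_o * p_r))
            w_vals.append(1.0 / (1 / o - 1 / n_obs + 1 / r - 1 / n_ref))
    n = len(m_vals)
    if n == 0:
        return 1.0
    if max(abs(m) for m in m_vals) < 1e-6:
        return 1.0

    def avg_ranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rm = avg_ranks(m_vals)
    ra = avg_ranks(a_vals)
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    num = den = 0.0
    kept = 0
    for m, a, w, r1, r2 in zip(m_vals, a_vals, w_vals, rm, ra):
        if lo_m <= r1 <= hi_m and lo_a <= r2 <= hi_a:
            num += w * m
            den += w
            kept += 1
    if kept == 0 or den == 0:
        return 1.0
    return 2.0 ** (num / den)


def hypergeom_tail_oracle(N, K, n, k):
    """P[overlap >= k] by exhaustive enumeration of all n-subsets.

    The group is the first K of N labelled items; every n-subset of the
    universe is enumerated and its overlap with the group tallied.
    """
    total = 0
    hits = 0
    items = range(N)
    group = set(range(K))
    for subset in combinations(items, n):
        total += 1
        if len(group.intersection(subset)) >= k:
            hits += 1
    return hits / total


def bh_oracle(pvals):
    """Benjamini-Hochberg step-up applied literally from its definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * n / rank_from_top)
        q[i] = min(val, 1.0)
        prev = val
    return q


def wls_normal_equations_oracle(X, y, w):
    """Weighted least squares by explicitly solving X' W X b = X' W y."""
    X = np.asarray(X, float)
    W = np.diag(np.asarray(w, float))
    y = np.asarray(y, float)
    xtwx = X.T @ W @ X
    xtwy = X.T @ W @ y
    beta = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = float(resid @ W @ resid) / df
    cov_unscaled = np.linalg.inv(xtwx)
    return beta, s2, cov_unscaled, df


def pooled_t_test_oracle(y, group_index, pair):
    """Ordinary per-gene t-test with variance pooled across all groups.

    ``group_index`` maps group -> column indices of ``y`` (1-D per gene);
    returns (t, p, df) for the difference pair[0] - pair[1].
    """
    from scipy import stats

    means = {g: y[idx].mean() for g, idx in group_index.items()}
    rss = sum(((y[idx] - means[g]) ** 2).sum() for g, idx in group_index.items())
    df = len(y) - len(group_index)
    s2 = rss / df
    a, b = pair
    na, nb = len(group_index[a]), len(group_index[b])
    se = math.sqrt(s2 * (1 / na + 1 / nb))
    t = (means[a] - means[b]) / se if se > 0 else 0.0
    p = 2 * stats.t.sf(abs(t), df)
    return t, p, df
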