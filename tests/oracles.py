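"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's optimized code paths: posteriors
by explicit path enumeration over all state configurations, sliding
maxima by direct window scans, and rank statistics from first
principles.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_state_posterior(pi, A, emissions) -> np.ndarray:
    """P(state_i = 0 | obs) by summing over every state path.

    ``emissions`` is a T x 2 array of per-position state likelihoods.
    """
    pi = np.asarray(pi, dtype=float)
    A = np.asarray(A, dtype=float)
    e = np.asarray(emissions, dtype=float)
    T = len(e)
    numer = np.zeros(T)
    total = 0.0
    for path in itertools.product((0, 1), repeat=T):
        p = pi[path[0]] * e[0, path[0]]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * e[t, path[t]]
        total += p
        for t in range(T):
            if path[t] == 0:
                numer[t] += p
    return numer / total


def sliding_window_max(values, mask, neighborhood) -> np.ndarray:
    """Direct O(n*w) normalized peak heights."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    half = neighborhood // 2
    out = np.zeros_like(values)
    for i in range(len(values)):
        if mask[i]:
            lo, hi = max(0, i - half), min(len(values), i + half + 1)
            out[i] = values[i] / max(values[lo:hi])
    return out


def rank_sum_statistic(x, y) -> float:
    """Rank sum of x in the combined sample, midranks for ties."""
    combined = list(x) + list(y)
    order = sorted(range(len(combined)), key=lambda i: combined[i])
    ranks = [0.0] * len(combined)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and combined[order[j + 1]] == combined[order[i]]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    return float(sum(ranks[: len(x)]))


def chi_squared_2x2(table) -> float:
    """Sum over cells of (observed - expected)^2 / expected."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            expected = row[i] * col[j] / n
            chi2 += (table[i, j] - expected) ** 2 / expected
    return chi2
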