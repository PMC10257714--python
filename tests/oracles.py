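"""Independent brute-force reference implementations used as oracles.

Everything here is written as plain double/triple loops straight from the
defining formulas, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def bf_weighted_jaccard(w: np.ndarray) -> np.ndarray:
    s = w.shape[0]
    d = np.zeros((s, s))
    for i in range(s):
        for j in range(s):
            if i == j:
                continue
            num = sum(min(w[i, a], w[j, a]) for a in range(w.shape[1]))
            den = sum(max(w[i, a], w[j, a]) for a in range(w.shape[1]))
            d[i, j] = 1.0 - num / den
    return d


def bf_gini_simpson(p: np.ndarray) -> float:
    return sum(p[i] * p[j] for i in range(len(p)) for j in range(len(p)) if i != j)


def bf_rao(p: np.ndarray, d: np.ndarray) -> float:
    return sum(
        d[i, j] * p[i] * p[j]
        for i in range(len(p))
        for j in range(len(p))
        if i != j
    )


def bf_fr(p: np.ndarray, d: np.ndarray) -> float:
    return sum(
        (1.0 - d[i, j]) * p[i] * p[j]
        for i in range(len(p))
        for j in range(len(p))
        if i != j
    )


def bf_nodf(b: np.ndarray) -> float:
    """NODF by explicit enumeration of all row pairs and column pairs."""
    def pair_sum(mat):
        n = mat.shape[0]
        total = 0.0
        for u in range(n):
            for v in range(u + 1, n):
                fu, fv = mat[u].sum(), mat[v].sum()
                if fu == fv or min(fu, fv) == 0:
                    continue
                hi, lo = (u, v) if fu > fv else (v, u)
                overlap = int(np.logical_and(mat[hi], mat[lo]).sum())
                total += overlap / mat[lo].sum()
        return total

    s, f = b.shape
    n_pairs = s * (s - 1) // 2 + f * (f - 1) // 2
    return (pair_sum(b) + pair_sum(b.T)) / n_pairs


def bf_jsd(a_hist: np.ndarray, b_hist: np.ndarray) -> float:
    """JSD from normalized histograms via the direct formula,
    0.5*KL(a||m) + 0.5*KL(b||m), log base 2."""
    m = 0.5 * (a_hist + b_hist)
    kl_a = sum(x * np.log2(x / y) for x, y in zip(a_hist, m) if x > 0)
    kl_b = sum(x * np.log2(x / y) for x, y in zip(b_hist, m) if x > 0)
    return 0.5 * kl_a + 0.5 * kl_b
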