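"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (explicit loops over cells,
pairs and neighbours, plain ``math.log``) so it shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def entropy_bits(counts) -> float:
    """-sum p log2 p over a count/probability vector, 0 log 0 = 0."""
    counts = [float(c) for c in np.asarray(counts).ravel()]
    n = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            h -= p * math.log(p, 2)
    return h


def mi_bits(table) -> float:
    """Mutual information via the cell-wise sum p log2 p/(px pd)."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    px = table.sum(axis=1) / n
    pd_ = table.sum(axis=0) / n
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            p = table[i, j] / n
            if p > 0:
                mi += p * math.log(p / (px[i] * pd_[j]), 2)
    return mi


def table_from_columns(cols, labels) -> np.ndarray:
    """(3^k, 2) contingency table built cell by cell."""
    k = len(cols)
    n = len(labels)
    table = np.zeros((3**k, 2))
    for s in range(n):
        state = 0
        for c in cols:
            state = state * 3 + int(c[s])
        table[state, int(labels[s])] += 1
    return table


def ig2_bits(gA, gB, labels) -> float:
    """IG(A;B;D) = I(AB;D) - I(A;D) - I(B;D), every term from its own table."""
    return (mi_bits(table_from_columns([gA, gB], labels))
            - mi_bits(table_from_columns([gA], labels))
            - mi_bits(table_from_columns([gB], labels)))


def ig3_bits(gA, gB, gC, labels) -> float:
    """Three-way gain with all mains and pairwise gains subtracted term by term."""
    cols = [gA, gB, gC]
    total = mi_bits(table_from_columns(cols, labels))
    mains = sum(mi_bits(table_from_columns([c], labels)) for c in cols)
    pair_igs = sum(ig2_bits(cols[i], cols[j], labels)
                   for i, j in combinations(range(3), 2))
    return total - pair_igs - mains


def hwe_chi2(n0, n1, n2):
    """(chi2, p) for HWE goodness of fit, from first principles."""
    from scipy.stats import chi2 as chi2_dist

    n = n0 + n1 + n2
    p = (2 * n0 + n1) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 0.0, 1.0
    exp = [n * p * p, n * 2 * p * q, n * q * q]
    stat = sum((o - e) ** 2 / e for o, e in zip((n0, n1, n2), exp))
    return stat, float(chi2_dist.sf(stat, 1))


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation via explicit sums."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return 0.0
    return (sxy * sxy) / (sxx * syy)


def relieff_weights(X, y, k) -> np.ndarray:
    """ReliefF by literal neighbour enumeration.

    Manhattan distance on codes for the neighbour search (ties by sample
    index), 0/1 mismatch in the weight update, every sample a reference.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    n, p = X.shape
    w = np.zeros(p)
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            d = sum(abs(int(X[i, a]) - int(X[j, a])) for a in range(p))
            dists.append((d, j))
        dists.sort()
        hits = [j for d, j in dists if y[j] == y[i]][:k]
        misses = [j for d, j in dists if y[j] != y[i]][:k]
        for a in range(p):
            for j in hits:
                w[a] -= X[i, a] != X[j, a]
            for j in misses:
                w[a] += X[i, a] != X[j, a]
    return w / (n * k)


def auc_pair_counting(probs, labels) -> float:
    """AUC as (concordant + 0.5 ties) / (positives x negatives)."""
    pos = [p for p, l in zip(probs, labels) if l == 1]
    neg = [p for p, l in zip(probs, labels) if l == 0]
    score = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                score += 1.0
            elif a == b:
                score += 0.5
    return score / (len(pos) * len(neg))


def xor_ig2_analytic(h: float) -> float:
    """Closed-form two-way gain of the XOR model at MAF 0.5, infinite n.

    Enumerates the 9 genotype cells x 2 outcomes under HWE(0.5) exactly.
    """
    freqs = [0.25, 0.5, 0.25]
    joint = np.zeros((9, 2))
    for a in range(3):
        for b in range(3):
            pc = 0.5 + h if (a + b) % 2 == 1 else 0.5 - h
            joint[a * 3 + b, 1] = freqs[a] * freqs[b] * pc
            joint[a * 3 + b, 0] = freqs[a] * freqs[b] * (1 - pc)
    # P(D) is not exactly 0.5 under this sampling scheme only when quotas are
    # forced; at the population level it is 0.5 by symmetry of the parity model
    total = mi_bits(joint * 1e6)  # scale-invariant: mi_bits normalises
    gA = np.zeros((3, 2))
    for a in range(3):
        for b in range(3):
            gA[a] += joint[a * 3 + b]
    main = mi_bits(gA * 1e6)
    return total - 2 * main


def parity3_ig3_analytic(h: float) -> float:
    """Closed-form three-way gain of the parity model at MAF 0.5 (27 cells)."""
    freqs = [0.25, 0.5, 0.25]
    joint = np.zeros((27, 2))
    for a in range(3):
        for b in range(3):
            for c in range(3):
                pc = 0.5 + h if (a + b + c) % 2 == 1 else 0.5 - h
                w = freqs[a] * freqs[b] * freqs[c]
                s = (a * 3 + b) * 3 + c
                joint[s, 1] = w * pc
                joint[s, 0] = w * (1 - pc)
    total = mi_bits(joint)
    # marginals: by parity symmetry all one- and two-locus tables are
    # independent of D, so mains and pairwise gains are exactly 0
    return total
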