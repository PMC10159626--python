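"""Independently coded brute-force oracles.

Every function here deliberately uses plain loops, sorting, and hand
arithmetic — never the package's own code paths — so the implementations
can be checked against them on random small instances.
"""

import itertools

import numpy as np


def oracle_moving_average(x, k):
    """Centered moving average with edge truncation, via explicit windows."""
    n = len(x)
    half_lo = (k - 1) // 2
    half_hi = k - 1 - half_lo
    out = []
    for i in range(n):
        window = [x[j] for j in range(max(0, i - half_lo), min(n - 1, i + half_hi) + 1)]
        out.append(sum(window) / len(window))
    return np.array(out)


def oracle_quantile(values, q):
    """Sort-based linear-interpolation quantile."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def oracle_ground_state(trace, kernel, q):
    """Smoothed sub-quantile mean, all by loops."""
    sm = oracle_moving_average(trace, kernel)
    qv = oracle_quantile(sm, q)
    below = [v for v in sm if v < qv]
    return sum(below) / len(below) if below else qv


def oracle_integrate(values, time, start, window):
    total = 0.0
    for v, tt in zip(values, time):
        if start <= tt < start + window:
            total += v
    return total


def oracle_macro_f1(y_true, y_pred, classes):
    """Hand precision/recall arithmetic."""
    scores = []
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        scores.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    return sum(scores) / len(scores)


def oracle_ols(y, X):
    """Normal equations with an explicit intercept column."""
    Xc = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
    resid = y - Xc @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return beta, 1.0 - ss_res / ss_tot


def oracle_kmeans_2part(values):
    """Exhaustive enumeration of every 2-partition of |values|."""
    vals = [abs(v) for v in values]
    n = len(vals)
    best = None
    for assignment in itertools.product([0, 1], repeat=n):
        groups = {0: [], 1: []}
        for a, v in zip(assignment, vals):
            groups[a].append(v)
        if not groups[0] or not groups[1]:
            continue
        ss = 0.0
        for g in groups.values():
            m = sum(g) / len(g)
            ss += sum((v - m) ** 2 for v in g)
        if best is None or ss < best[0] - 1e-15:
            best = (ss, assignment)
    ss, assignment = best
    means = {a: np.mean([v for aa, v in zip(assignment, vals) if aa == a])
             for a in (0, 1)}
    hi = max(means, key=means.get)
    return ss, [a == hi for a in assignment]
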