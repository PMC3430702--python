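"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions, not from the package
internals, so the tests compare two separately-derived answers.
"""

import numpy as np


def oracle_stat(values, i, j):
    """Two-sample pooled-sd contrast between values[i:j] and the rest."""
    values = np.asarray(values, dtype=float)
    arc = values[i:j]
    comp = np.concatenate([values[:i], values[j:]])
    diff = abs(arc.mean() - comp.mean())
    ss = np.sum((arc - arc.mean()) ** 2) + np.sum((comp - comp.mean()) ** 2)
    dof = max(len(values) - 2, 1)
    denom = np.sqrt(ss / dof * (1 / len(arc) + 1 / len(comp)))
    if denom == 0:
        return 0.0 if diff == 0 else np.inf
    return diff / denom


def oracle_max_arc(values, min_width=2):
    """Exhaustive enumeration of every (i, j); first maximum in (i, j) order."""
    n = len(values)
    best = (-1.0, 0, n)
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            L = j - i
            if L < min_width or L > n - 1:
                continue
            if i != 0 and i < min_width:
                continue
            if j != n and n - j < min_width:
                continue
            s = oracle_stat(values, i, j)
            if s > best[0]:
                best = (s, i, j)
    if best[0] < 0:
        return 0.0, 0, n
    return best


def oracle_segment_noiseless(values, min_width=2):
    """Recursive exhaustive segmentation for noiseless piecewise-constant input.

    A split is accepted exactly when the contrast is infinite, i.e. the arc
    and its complement are each internally constant with different levels;
    for sd=0 data that is the zero-p-value condition.
    """
    breakpoints = []
    stack = [(0, len(values))]
    while stack:
        lo, hi = stack.pop(0)
        stat, i, j = oracle_max_arc(values[lo:hi], min_width)
        if not np.isinf(stat):
            continue
        cuts = [c for c in (i, j) if 0 < c < hi - lo]
        breakpoints.extend(lo + c for c in cuts)
        edges = [0, *cuts, hi - lo]
        for a, b in zip(edges[:-1], edges[1:]):
            stack.append((lo + a, lo + b))
    return sorted(set(breakpoints))


def oracle_most_overlapping(starts, ends, hits):
    """Enumerate every probe interval [a, b); support = samples aberrant on
    all of it. Returns (start_bp, end_bp, support) maximizing
    (support, bp length, leftmost)."""
    n = len(starts)
    best = None
    for a in range(n):
        for b in range(a + 1, n + 1):
            support = int(np.sum(hits[:, a:b].all(axis=1)))
            if support == 0:
                continue
            span = (int(starts[a]), int(ends[b - 1]))
            key = (support, span[1] - span[0], -span[0])
            if best is None or key > best[0]:
                best = (key, span, support)
    if best is None:
        raise ValueError("class absent")
    return best[1][0], best[1][1], best[2]


def oracle_pearson(x, y):
    """Pearson r from the textbook formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
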