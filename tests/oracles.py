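"""Definition-level brute-force oracles, kept deliberately naive.

Each function recomputes a statistic straight from its textbook definition
with explicit Python loops, independently of the library's vectorized
implementations, so equivalence tests are meaningful.
"""
from __future__ import annotations

import math


def kappa_oracle(a, b, k):
    """Linear-weighted kappa by enumerating the weighted observed/expected sums."""
    n = len(a)
    obs = [[0.0] * k for _ in range(k)]
    for x, y in zip(a, b):
        obs[x - 1][y - 1] += 1.0 / n
    row = [sum(obs[i]) for i in range(k)]
    col = [sum(obs[i][j] for i in range(k)) for j in range(k)]
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = abs(i - j) / (k - 1)
            num += w * obs[i][j]
            den += w * row[i] * col[j]
    if den == 0.0:
        return None
    return 1.0 - num / den


def icc_oracle(matrix):
    """ICC(2,1) from explicitly looped two-way ANOVA sums of squares."""
    n = len(matrix)
    m = len(matrix[0])
    grand = sum(sum(row) for row in matrix) / (n * m)
    row_means = [sum(row) / m for row in matrix]
    col_means = [sum(matrix[i][j] for i in range(n)) / n for j in range(m)]
    ss_rows = m * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_total = sum((matrix[i][j] - grand) ** 2 for i in range(n) for j in range(m))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (m - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (m - 1))
    return (msr - mse) / (msr + (m - 1) * mse + m * (msc - mse) / n)


def _euclid(p, q):
    return math.sqrt(sum((pi - qi) ** 2 for pi, qi in zip(p, q)))


def dbi_oracle(points, labels):
    """Davies-Bouldin by looping over every class pair."""
    classes = sorted(set(labels), key=str)
    members = {c: [p for p, l in zip(points, labels) if l == c] for c in classes}
    centroids = {
        c: [sum(p[d] for p in pts) / len(pts) for d in range(len(pts[0]))]
        for c, pts in members.items()
    }
    scatter = {
        c: sum(_euclid(p, centroids[c]) for p in pts) / len(pts)
        for c, pts in members.items()
    }
    total = 0.0
    for ci in classes:
        best = -math.inf
        for cj in classes:
            if cj == ci:
                continue
            best = max(best, (scatter[ci] + scatter[cj]) / _euclid(centroids[ci], centroids[cj]))
        total += best
    return total / len(classes)


def silhouette_oracle(points, labels):
    """Mean silhouette with the singleton-contributes-1 convention, by loops."""
    classes = sorted(set(labels), key=str)
    svals = []
    for i, (p, l) in enumerate(zip(points, labels)):
        own = [q for j, (q, lj) in enumerate(zip(points, labels)) if lj == l and j != i]
        if not own:
            svals.append(1.0)
            continue
        a = sum(_euclid(p, q) for q in own) / len(own)
        b = math.inf
        for c in classes:
            if c == l:
                continue
            other = [q for q, lj in zip(points, labels) if lj == c]
            b = min(b, sum(_euclid(p, q) for q in other) / len(other))
        m = max(a, b)
        svals.append(0.0 if m == 0.0 else (b - a) / m)
    return sum(svals) / len(svals)


def ks_oracle(x, y):
    """Two-sample KS by sweeping the ECDF gap over every pooled point."""
    best = 0.0
    for t in list(x) + list(y):
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best
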