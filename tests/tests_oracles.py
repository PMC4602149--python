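"""Independent brute-force oracles used by the validation suite.

These deliberately avoid the vectorised code paths of the package: the DS
index is accumulated component by component in a scalar loop, and the
silhouette is computed with explicit O(n^2) pairwise distance loops.
"""

import math

import numpy as np


def brute_force_dsi(rates, directions_deg) -> float:
    x = y = total = 0.0
    for r, d in zip(rates, directions_deg):
        x += r * math.cos(math.radians(d))
        y += r * math.sin(math.radians(d))
        total += r
    return math.sqrt(x * x + y * y) / total


def brute_force_silhouette_oracle(X, labels) -> float:
    n = len(X)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = sum(math.dist(X[i], X[j]) for j in same) / len(same)
        b = math.inf
        for c in set(labels.tolist()) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(math.dist(X[i], X[j]) for j in other) / len(other))
        m = max(a, b)
        scores.append(0.0 if m == 0 else (b - a) / m)
    return float(np.mean(scores))
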