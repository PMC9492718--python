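"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the Welch p-value
comes from numerically integrating the t density written out from the
gamma-function formula, and the agglomerative oracle is a naive O(n^3)
loop over cluster pairs.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln


def welch_closed_form(x, y):
    """Textbook Welch statistic and Welch-Satterthwaite df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1) / nx
    vy = y.var(ddof=1) / ny
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (nx - 1) + vy ** 2 / (ny - 1))
    return t, df


def t_density(u, df):
    logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)
    return np.exp(logc) * (1 + u * u / df) ** (-(df + 1) / 2)


def t_tail_p(t, df):
    """Two-sided p by numeric integration of the t density."""
    tail, _ = quad(t_density, abs(t), np.inf, args=(df,), epsabs=1e-12,
                   epsrel=1e-12)
    return 2.0 * tail


def permutation_p(x, y):
    """Exact two-sided permutation p-value for the mean difference."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    nx = len(x)
    obs = abs(x.mean() - y.mean())
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        sel = np.zeros(len(pooled), bool)
        sel[list(idx)] = True
        d = abs(pooled[sel].mean() - pooled[~sel].mean())
        count += d >= obs - 1e-12
        total += 1
    return count / total


def brute_force_agglomerate(D, method="complete"):
    """Naive agglomerative clustering on a square distance matrix.

    Returns (heights, partitions) where partitions[k] is the set of
    frozensets of leaf indices obtained after cutting at k clusters.
    """
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    partitions = {n: set(clusters)}
    heights = []

    def cluster_dist(a, b):
        ds = [D[i, j] for i in a for j in b]
        return max(ds) if method == "complete" else float(np.mean(ds))

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = cluster_dist(a, b)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
        partitions[len(clusters)] = set(clusters)
    return heights, partitions
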