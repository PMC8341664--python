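"""Naive, loop-level reference implementations of the ECDF statistics.

Deliberately written as direct piecewise-constant evaluations of the
defining integrals/suprema (no rank shortcuts, no vectorized tricks) so
they stay independent of the package's implementations.  Valid for
tie-free inputs, which is how the random fixtures are generated.
"""

import numpy as np


def _ecdf(values, t):
    values = np.asarray(values, dtype=float)
    return float(np.mean(values <= t))


def oracle_ks(x, y):
    pooled = np.concatenate([x, y])
    return max(abs(_ecdf(x, t) - _ecdf(y, t)) for t in pooled)


def oracle_kuiper(x, y):
    pooled = np.concatenate([x, y])
    diffs = [_ecdf(x, t) - _ecdf(y, t) for t in pooled]
    return max(max(diffs), 0.0) + max(max(-d for d in diffs), 0.0)


def oracle_cvm(x, y):
    """nm/N^2 times the sum of squared ECDF differences at every pooled point."""
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    s = sum((_ecdf(x, t) - _ecdf(y, t)) ** 2 for t in pooled)
    return n * m / (n + m) ** 2 * s


def oracle_ad(x, y):
    """Sum over the N-1 smallest pooled order statistics of the
    variance-normalized squared ECDF difference (tie-free inputs)."""
    n, m = len(x), len(y)
    N = n + m
    pooled = np.sort(np.concatenate([x, y]))
    s = 0.0
    for k in range(1, N):  # skip the largest, where H = 1
        t = pooled[k - 1]
        h = k / N
        s += (_ecdf(x, t) - _ecdf(y, t)) ** 2 / (h * (1 - h))
    return n * m / N ** 2 * s


def oracle_wasserstein(x, y):
    z = np.sort(np.unique(np.concatenate([x, y])))
    total = 0.0
    for a, b in zip(z[:-1], z[1:]):
        total += abs(_ecdf(x, a) - _ecdf(y, a)) * (b - a)
    return total


def oracle_dts(x, y):
    pooled = np.concatenate([x, y])
    z = np.sort(np.unique(pooled))
    total = 0.0
    for a, b in zip(z[:-1], z[1:]):
        fp = _ecdf(pooled, a)
        if 0.0 < fp < 1.0:
            total += abs(_ecdf(x, a) - _ecdf(y, a)) / np.sqrt(fp * (1 - fp)) * (b - a)
    return total
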