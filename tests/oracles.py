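"""Independent brute-force oracles: literal, loop-based translations of the
feature and statistics definitions, kept deliberately separate from the
package's vectorized implementations."""
from __future__ import annotations

import math
from bisect import bisect_right
from itertools import combinations

import numpy as np


def oracle_mean_sd(x):
    n = len(x)
    mean = sum(float(v) for v in x) / n
    var = sum((float(v) - mean) ** 2 for v in x) / n
    return mean, math.sqrt(var)


def oracle_katz(x):
    n = len(x)
    dists = [math.hypot(1.0, float(x[i + 1]) - float(x[i])) for i in range(n - 1)]
    s = sum(dists)
    m = s / len(dists)
    d = max(math.hypot(i, float(x[i]) - float(x[0])) for i in range(1, n))
    return math.log(s / m) / math.log(d / m)


def oracle_petrosian(x):
    n = len(x)
    avg = sum(float(v) for v in x) / n
    bits = [1 if float(v) > avg else 0 for v in x]
    n_delta = sum(1 for i in range(n - 1) if bits[i] != bits[i + 1])
    return math.log10(n) / (math.log10(n) + math.log10(n / (n + 0.4 * n_delta)))


def oracle_higuchi(x, k_max):
    n = len(x)
    log_lk, log_inv_k = [], []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(1, k + 1):
            n_i = (n - m) // k
            if n_i < 1:
                continue
            total = 0.0
            for i in range(1, n_i + 1):
                total += abs(float(x[m + i * k - 1]) - float(x[m + (i - 1) * k - 1]))
            lengths.append(total * (n - 1) / (n_i * k * k))
        log_lk.append(math.log(sum(lengths) / len(lengths)))
        log_inv_k.append(math.log(1.0 / k))
    # least-squares slope
    mx = sum(log_inv_k) / len(log_inv_k)
    my = sum(log_lk) / len(log_lk)
    num = sum((a - mx) * (b - my) for a, b in zip(log_inv_k, log_lk))
    den = sum((a - mx) ** 2 for a in log_inv_k)
    return num / den


def _oracle_chebyshev_pairs(x, length, count):
    templates = [tuple(float(v) for v in x[i:i + length]) for i in range(count)]
    dists = []
    for i, j in combinations(range(count), 2):
        dists.append(max(abs(a - b) for a, b in zip(templates[i], templates[j])))
    return dists


def oracle_sampen(x, m=2, r=None, r_frac=0.15):
    if r is None:
        _, sd = oracle_mean_sd(x)
        r = r_frac * sd
    count = len(x) - m
    b = sum(1 for d in _oracle_chebyshev_pairs(x, m, count) if d <= r)
    a = sum(1 for d in _oracle_chebyshev_pairs(x, m + 1, count) if d <= r)
    if a == 0 or b == 0:
        return None
    return math.log(b / a)


def oracle_profile(x, m=2, r_resolution=0.001, max_points=1000):
    """(r_grid, sampen_values) per the data-driven quantized-distance grid."""
    count = len(x) - m
    dm = [round(d / r_resolution) * r_resolution
          for d in _oracle_chebyshev_pairs(x, m, count)]
    dm1 = [round(d / r_resolution) * r_resolution
           for d in _oracle_chebyshev_pairs(x, m + 1, count)]
    grid = sorted({d for d in dm if d > 0})
    dm_sorted, dm1_sorted = sorted(dm), sorted(dm1)
    rs, vals = [], []
    for r in grid:
        b = bisect_right(dm_sorted, r)
        a = bisect_right(dm1_sorted, r)
        if a > 0 and b > 0:
            rs.append(r)
            vals.append(math.log(b / a))
    if len(rs) > max_points:
        keep = sorted({int(round(k)) for k in
                       np.linspace(0, len(rs) - 1, max_points)})
        rs = [rs[k] for k in keep]
        vals = [vals[k] for k in keep]
    return rs, vals


def oracle_mw_exact(a, b):
    """Two-sided permutation p for the Mann-Whitney U, rank-free counting."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    pooled = a + b
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0

    def u_of(sel):
        sel_set = set(sel)
        xs = [pooled[i] for i in sel]
        ys = [pooled[i] for i in range(len(pooled)) if i not in sel_set]
        u = 0.0
        for xv in xs:
            for yv in ys:
                if xv > yv:
                    u += 1.0
                elif xv == yv:
                    u += 0.5
        return u

    u_obs = u_of(range(n1))
    dev = abs(u_obs - mu)
    hits = total = 0
    for comb in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(comb) - mu) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


def oracle_auc(a, b):
    count = 0.0
    for xv in a:
        for yv in b:
            if float(xv) > float(yv):
                count += 1.0
            elif float(xv) == float(yv):
                count += 0.5
    return count / (len(a) * len(b))
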