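"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths (and, where practical, the
libraries) used by the implementation: connected components by explicit
flood fill, image moments by direct per-pixel summation, the KS statistic
by enumerating all 2n step discrepancies, and the rank statistics from a
hand-rolled mid-rank walk with the normal CDF taken from ``math.erfc``.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# image oracles


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """Connected foreground regions by explicit stack-based flood fill."""
    binary = np.asarray(binary, dtype=bool)
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    components = []
    for r0 in range(h):
        for c0 in range(w):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            comp = set()
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            components.append(comp)
    return components


def direct_moments(pixels: set[tuple[int, int]]) -> tuple[float, float, float, float]:
    """Centroid, area and orientation by direct summation over (row, col) pixels.

    Central second moments are accumulated as exact integers (scaled by the
    area) so that the orientation of symmetric regions is well defined.
    """
    m00 = 0
    m10 = 0
    m01 = 0
    s_cc = 0
    s_rr = 0
    s_rc = 0
    for r, c in pixels:
        m00 += 1
        m10 += c
        m01 += r
        s_cc += c * c
        s_rr += r * r
        s_rc += r * c
    cx = m10 / m00
    cy = m01 / m00
    mu20 = m00 * s_cc - m10 * m10
    mu02 = m00 * s_rr - m01 * m01
    mu11 = m00 * s_rc - m10 * m01
    angle = 0.5 * math.degrees(math.atan2(2.0 * mu11, float(mu20 - mu02)))
    if angle >= 90.0:
        angle -= 180.0
    elif angle < -90.0:
        angle += 180.0
    return cx, cy, float(m00), angle


# ---------------------------------------------------------------------------
# statistics oracles


def _norm_cdf(x: float) -> float:
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


def _norm_sf(x: float) -> float:
    return 0.5 * math.erfc(x / math.sqrt(2.0))


def ks_statistic_enumerated(sample, mu: float, sd: float) -> float:
    """sup|F_n - F| by checking both step endpoints at every data point."""
    x = sorted(float(v) for v in sample)
    n = len(x)
    best = 0.0
    for i, xi in enumerate(x):
        f = _norm_cdf((xi - mu) / sd)
        best = max(best, abs((i + 1) / n - f), abs(i / n - f))
    return best


def midranks(pooled) -> list[float]:
    """Mid-ranks by walking runs of equal values in a sorted copy."""
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j + 2) / 2.0  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tie_term(pooled) -> float:
    """sum(t^3 - t) over runs of equal values."""
    counts: dict[float, int] = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    return float(sum(t**3 - t for t in counts.values()))


def bf_kruskal_h(groups) -> float:
    pooled = [float(v) for g in groups for v in g]
    ranks = midranks(pooled)
    n_tot = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += len(g) * (sum(r) / len(r)) ** 2
    h = 12.0 / (n_tot * (n_tot + 1)) * h - 3.0 * (n_tot + 1)
    correction = 1.0 - tie_term(pooled) / (n_tot**3 - n_tot)
    return 0.0 if correction == 0 else h / correction


def bf_dunn(groups) -> tuple[np.ndarray, np.ndarray]:
    """Dunn z and Bonferroni-adjusted p matrices from first principles."""
    pooled = [float(v) for g in groups for v in g]
    ranks = midranks(pooled)
    n_tot = len(pooled)
    k = len(groups)
    mean_ranks = []
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        mean_ranks.append(sum(r) / len(r))
    var_core = n_tot * (n_tot + 1) / 12.0 - tie_term(pooled) / (12.0 * (n_tot - 1))
    m = k * (k - 1) // 2
    z = np.zeros((k, k))
    p_adj = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(var_core * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            zij = (mean_ranks[i] - mean_ranks[j]) / se
            z[i, j], z[j, i] = zij, -zij
            p = min(1.0, m * 2.0 * _norm_sf(abs(zij)))
            p_adj[i, j] = p_adj[j, i] = p
    return z, p_adj
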