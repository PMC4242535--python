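"""Independent brute-force oracles for the threshold algorithms.

Deliberately written with plain-Python loops over all 256 candidate
thresholds (no shared code with the package) so that agreement with the
vectorized implementations is a genuine two-route check.
"""

from __future__ import annotations

import math


def oracle_otsu(counts) -> int:
    total = sum(counts)
    best_t, best = None, -math.inf
    for t in range(256):
        w0 = sum(counts[g] for g in range(t + 1))
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(g * counts[g] for g in range(t + 1)) / w0
        mu1 = sum(g * counts[g] for g in range(t + 1, 256)) / w1
        obj = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if obj > best:
            best, best_t = obj, t
    return best_t


def oracle_isodata(counts) -> int | None:
    """First t (scanning up from the lowest occupied value) at or past the
    class-mean midpoint; None when no such t exists below the top value."""
    nonzero = [g for g in range(256) if counts[g] > 0]
    for t in range(nonzero[0], nonzero[-1]):
        w0 = sum(counts[g] for g in range(t + 1))
        w1 = sum(counts[g] for g in range(t + 1, 256))
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(g * counts[g] for g in range(t + 1)) / w0
        mu1 = sum(g * counts[g] for g in range(t + 1, 256)) / w1
        if t >= (mu0 + mu1) / 2.0:
            return t
    return None


def oracle_max_entropy(counts) -> int:
    total = sum(counts)
    p = [c / total for c in counts]
    best_t, best = None, -math.inf
    for t in range(256):
        p0 = sum(p[: t + 1])
        p1 = 1.0 - p0
        if p0 <= 0 or p1 <= 0:
            continue
        h0 = -sum(
            (p[g] / p0) * math.log(p[g] / p0) for g in range(t + 1) if p[g] > 0
        )
        h1 = -sum(
            (p[g] / p1) * math.log(p[g] / p1) for g in range(t + 1, 256) if p[g] > 0
        )
        if h0 + h1 > best:
            best, best_t = h0 + h1, t
    return best_t


def oracle_min_error(counts, min_var: float = 1e-9) -> int | None:
    """Exhaustive Kittler–Illingworth minimizer; None if nothing admissible."""
    total = sum(counts)
    best_t, best = None, math.inf
    for t in range(256):
        n0 = sum(counts[g] for g in range(t + 1))
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = sum(g * counts[g] for g in range(t + 1)) / n0
        mu1 = sum(g * counts[g] for g in range(t + 1, 256)) / n1
        var0 = sum(counts[g] * (g - mu0) ** 2 for g in range(t + 1)) / n0
        var1 = sum(counts[g] * (g - mu1) ** 2 for g in range(t + 1, 256)) / n1
        if var0 <= min_var or var1 <= min_var:
            continue
        w0, w1 = n0 / total, n1 / total
        j = (
            1.0
            + 2.0 * (w0 * math.log(math.sqrt(var0)) + w1 * math.log(math.sqrt(var1)))
            - 2.0 * (w0 * math.log(w0) + w1 * math.log(w1))
        )
        if j < best:
            best, best_t = j, t
    return best_t


def _maxima_runs(values) -> list[tuple[int, int]]:
    """(start, end) spans of local-maximum runs; plateaus count once."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((values[start], start, i - 1))
            start = i
    out = []
    for k, (v, s, e) in enumerate(runs):
        left = k == 0 or v > runs[k - 1][0]
        right = k == len(runs) - 1 or v > runs[k + 1][0]
        if left and right:
            out.append((s, e))
    return out


def _minimum_run_between(values, lo_end: int, hi_start: int) -> tuple[int, int]:
    seg = values[lo_end + 1 : hi_start]
    m = min(seg)
    first = lo_end + 1 + seg.index(m)
    last = first
    while last + 1 < hi_start and values[last + 1] == m:
        last += 1
    return first, last


def oracle_minimum(counts, max_passes: int = 10_000) -> int | None:
    """Re-implementation of the smoothed-valley rule; None on non-convergence."""
    h = [float(c) for c in counts]
    for _ in range(max_passes + 1):
        maxima = _maxima_runs(h)
        if len(maxima) == 2:
            lo, hi = _minimum_run_between(h, maxima[0][1], maxima[1][0])
            return (lo + hi) // 2
        if len(maxima) < 2:
            return None
        padded = [h[0]] + h + [h[-1]]
        h = [(padded[i] + padded[i + 1] + padded[i + 2]) / 3.0 for i in range(len(h))]
    return None


def oracle_minimum_histogram(counts, max_width: int = 128) -> int | None:
    for w in range(1, max_width + 1):
        binned = [
            float(sum(counts[k * w : min((k + 1) * w, 256)]))
            for k in range((255 // w) + 1)
        ]
        maxima = _maxima_runs(binned)
        if len(maxima) == 2:
            lo_bin, hi_bin = _minimum_run_between(binned, maxima[0][1], maxima[1][0])
            gray_lo = lo_bin * w
            gray_hi = min((hi_bin + 1) * w - 1, 255)
            return (gray_lo + gray_hi) // 2
    return None


def oracle_edge_value(values_2d, mask_2d, t: int) -> float | None:
    """Mean contrast over 4-neighbor opposite-class pairs for one threshold."""
    h = len(values_2d)
    w = len(values_2d[0])
    diffs = []
    for y in range(h):
        for x in range(w):
            if not mask_2d[y][x]:
                continue
            for dy, dx in ((0, 1), (1, 0)):
                ny, nx = y + dy, x + dx
                if ny >= h or nx >= w or not mask_2d[ny][nx]:
                    continue
                a, b = values_2d[y][x], values_2d[ny][nx]
                if (a <= t) != (b <= t):
                    diffs.append(abs(a - b))
    if not diffs:
        return None
    return sum(diffs) / len(diffs)


def oracle_edge_detection(values_2d, mask_2d) -> int | None:
    best_t, best = None, -math.inf
    for t in range(256):
        ev = oracle_edge_value(values_2d, mask_2d, t)
        if ev is not None and ev > best:
            best, best_t = ev, t
    return best_t
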