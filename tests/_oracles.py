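"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive each quantity from its defining criterion by
exhaustive scan or direct evaluation, sharing no code with the package.
"""

from __future__ import annotations

import numpy as np

N_BINS = 256


def isodata_threshold_bruteforce(counts: np.ndarray, lo: float,
                                 width: float) -> float:
    """Iterate the intermeans recurrence by scanning every candidate cut.

    Scans cuts upward from the lowest occupied bin; at the first cut c
    whose intermeans level (mean of bin centers below-or-at c and above
    c, averaged) falls below c + 2, that level is the threshold.
    """
    idx = np.arange(N_BINS, dtype=float)
    nz = np.nonzero(counts)[0]
    mn, mx = int(nz[0]), int(nz[-1])
    for c in range(mn, mx):
        below = counts[: c + 1]
        above = counts[c + 1: mx + 1]
        if below.sum() == 0 or above.sum() == 0:
            continue
        mean_below = float((idx[: c + 1] * below).sum() / below.sum())
        mean_above = float((idx[c + 1: mx + 1] * above).sum() / above.sum())
        g = 0.5 * (mean_below + mean_above)
        if (c + 1) + 1 > g or (c + 1) >= mx - 1:
            return lo + (g + 0.5) * width
    raise AssertionError("scan never terminated")


def moments_threshold_bruteforce(counts: np.ndarray, lo: float,
                                 width: float) -> float:
    """Moment-preserving threshold from the raw moment system.

    Solves for the two gray levels (z0, z1) preserving the first three
    moments via the quadratic's roots (numpy.roots), then scans the
    cumulative histogram for the first bin reaching the below-level
    fraction p0.
    """
    p = counts / counts.sum()
    i = np.arange(N_BINS, dtype=float)
    m1, m2, m3 = (p * i).sum(), (p * i ** 2).sum(), (p * i ** 3).sum()
    cd = m2 - m1 ** 2
    c0 = (-m2 ** 2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    z = np.sort(np.roots([1.0, c1, c0]).real)
    z0, z1 = z
    p0 = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(p)
    for c in range(N_BINS):
        if cum[c] >= p0 - 1e-12:
            return lo + (c + 1) * width
    return lo + N_BINS * width


def moments_binary_m3_error(counts: np.ndarray, cut: int) -> float:
    """Third-moment error of the best two-level image splitting at ``cut``.

    Given the split, the two levels are chosen to preserve the first two
    moments exactly; the returned value is the resulting absolute error
    in the third moment (zero iff the split is moment-preserving).
    """
    p = counts / counts.sum()
    i = np.arange(N_BINS, dtype=float)
    m1, m2, m3 = (p * i).sum(), (p * i ** 2).sum(), (p * i ** 3).sum()
    p0 = p[: cut + 1].sum()
    p1 = 1.0 - p0
    if p0 <= 0 or p1 <= 0:
        return np.inf
    # solve p0 z0 + p1 z1 = m1 ; p0 z0^2 + p1 z1^2 = m2
    # substitute z1 = (m1 - p0 z0)/p1 -> quadratic in z0
    a = p0 + p0 ** 2 / p1
    b = -2.0 * m1 * p0 / p1
    c = m1 ** 2 / p1 - m2
    disc = b ** 2 - 4 * a * c
    if disc < 0:
        return np.inf
    best = np.inf
    for sign in (-1.0, 1.0):
        z0 = (-b + sign * np.sqrt(disc)) / (2 * a)
        z1 = (m1 - p0 * z0) / p1
        if z0 <= z1:
            best = min(best, abs(p0 * z0 ** 3 + p1 * z1 ** 3 - m3))
    return best


def hertz_force_scalar(delta: float, E: float, nu: float, R: float) -> float:
    """High-precision scalar Hertz evaluation via logarithms."""
    if delta <= 0:
        return 0.0
    import math
    return math.exp(math.log(4.0 / 3.0) + math.log(E) - math.log(1 - nu ** 2)
                    + 0.5 * (math.log(R) + 3.0 * math.log(delta)))


def pooled_ttest_by_hand(x, y):
    """Closed-form pooled two-sample t; returns (t, df)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) \
        / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    return float(t), nx + ny - 2


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.astype(bool), b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0


def match_dice(truth_labels: np.ndarray, pred_labels: np.ndarray) -> list[float]:
    """Best-match Dice of every ground-truth instance against predictions."""
    out = []
    for t in np.unique(truth_labels):
        if t == 0:
            continue
        tm = truth_labels == t
        best = 0.0
        for p in np.unique(pred_labels[tm]):
            if p == 0:
                continue
            best = max(best, dice(tm, pred_labels == p))
        out.append(best)
    return out
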