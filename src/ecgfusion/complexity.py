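"""Nonlinear complexity measures for short physiological series.

Sample, approximate and fuzzy entropy follow the template-counting
definitions (Chebyshev distance, tolerance r, embedding dimension m);
fractal dimensions (Higuchi, Katz, Petrosian), detrended fluctuation
alpha-1, Poincare descriptors and Hjorth parameters round out the set.
All functions return ``nan`` when the series is too short or degenerate
rather than raising, so callers can apply a uniform sentinel policy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, cdist


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """Delay-embedding matrix of shape (N - m + 1, m)."""
    n = x.size - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def sample_entropy(x, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -ln(A/B) with A, B counts of Chebyshev-close template
    pairs of length m+1 and m (self-matches excluded, d <= r)."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        return np.nan
    if r is None:
        r = 0.2 * np.std(x)
    # Count over the same number of templates for both lengths.
    tm = _embed(x, m)[: x.size - m]
    tm1 = _embed(x, m + 1)
    b = np.sum(pdist(tm, metric="chebyshev") <= r)
    a = np.sum(pdist(tm1, metric="chebyshev") <= r)
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))


def approximate_entropy(x, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) = phi_m - phi_{m+1}, self-matches included."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        return np.nan
    if r is None:
        r = 0.2 * np.std(x)

    def phi(mm):
        t = _embed(x, mm)
        d = cdist(t, t, metric="chebyshev")
        c = np.mean(d <= r, axis=1)
        return np.mean(np.log(c))

    return float(phi(m) - phi(m + 1))


def fuzzy_entropy(x, m: int = 2, r: float | None = None) -> float:
    """FuzzyEn(m, r) with Gaussian membership exp(-(d/r)^2) on
    baseline-removed templates."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        return np.nan
    if r is None:
        r = 0.2 * np.std(x)
    if r == 0:
        return np.nan

    def phi(mm):
        t = _embed(x, mm)[: x.size - m]
        t = t - t.mean(axis=1, keepdims=True)
        d = pdist(t, metric="chebyshev")
        if d.size == 0:
            return np.nan
        return np.mean(np.exp(-((d / r) ** 2)))

    pm, pm1 = phi(m), phi(m + 1)
    if not np.isfinite(pm) or not np.isfinite(pm1) or pm <= 0 or pm1 <= 0:
        return np.nan
    return float(np.log(pm) - np.log(pm1))


def higuchi_fd(x, k_max: int = 10) -> float:
    """Higuchi fractal dimension from curve-length scaling."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * k_max:
        return np.nan
    lk, ks = [], []
    for k in range(1, k_max + 1):
        lengths = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if idx.size < 2:
                continue
            ln = np.sum(np.abs(np.diff(x[idx]))) * (n - 1) / ((idx.size - 1) * k)
            lengths.append(ln / k)
        if lengths:
            lk.append(np.mean(lengths))
            ks.append(k)
    lk = np.asarray(lk)
    if np.any(lk <= 0):
        return np.nan
    slope = np.polyfit(np.log(1.0 / np.asarray(ks)), np.log(lk), 1)[0]
    return float(slope)


def katz_fd(x) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.nan
    dists = np.abs(np.diff(x))
    total = dists.sum()
    if total == 0:
        return np.nan
    d = np.max(np.abs(x - x[0]))
    n = x.size - 1
    if d == 0:
        return np.nan
    return float(np.log10(n) / (np.log10(n) + np.log10(d / total)))


def petrosian_fd(x) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return np.nan
    diff = np.diff(x)
    nsc = np.sum(diff[:-1] * diff[1:] < 0)  # sign changes of the derivative
    if nsc == 0:
        return np.nan
    return float(np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * nsc))))


def dfa_alpha(x, scales=None) -> float:
    """Detrended fluctuation analysis exponent (short-range alpha-1 by
    default: box sizes 4..16)."""
    x = np.asarray(x, dtype=float)
    if scales is None:
        scales = [4, 5, 6, 8, 10, 13, 16]
    scales = [s for s in scales if s <= x.size // 2]
    if len(scales) < 3 or x.size < 8:
        return np.nan
    y = np.cumsum(x - np.mean(x))
    fl = []
    for s in scales:
        nseg = y.size // s
        segs = y[: nseg * s].reshape(nseg, s)
        t = np.arange(s)
        # least-squares linear detrend per segment
        tc = t - t.mean()
        beta = segs @ tc / (tc @ tc)
        resid = segs - segs.mean(axis=1, keepdims=True) - beta[:, None] * tc
        fl.append(np.sqrt(np.mean(resid ** 2)))
    fl = np.asarray(fl)
    if np.any(fl <= 0):
        return np.nan
    return float(np.polyfit(np.log(scales), np.log(fl), 1)[0])


def poincare_descriptors(rr) -> tuple[float, float, float, float]:
    """(SD1, SD2, SD2/SD1, ellipse area) of the RR Poincare plot."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        return (np.nan,) * 4
    d = np.diff(rr)
    sd1 = np.sqrt(np.var(d) / 2.0)
    sd2sq = 2.0 * np.var(rr) - np.var(d) / 2.0
    sd2 = np.sqrt(sd2sq) if sd2sq > 0 else np.nan
    ratio = sd2 / sd1 if (np.isfinite(sd2) and sd1 > 0) else np.nan
    area = np.pi * sd1 * sd2 if np.isfinite(sd2) else np.nan
    return float(sd1), float(sd2), float(ratio), float(area)


def hjorth_params(x) -> tuple[float, float]:
    """(mobility, complexity) from signal derivative variances."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.var(x) == 0:
        return np.nan, np.nan
    d1 = np.diff(x)
    d2 = np.diff(d1)
    v0, v1, v2 = np.var(x), np.var(d1), np.var(d2)
    if v1 == 0:
        return np.nan, np.nan
    mob = np.sqrt(v1 / v0)
    comp = np.sqrt(v2 / v1) / mob
    return float(mob), float(comp)


def shannon_entropy_hist(x, bins: int = 10) -> float:
    """Shannon entropy (nats) of the series' histogram distribution."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.nan
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def zero_crossing_rate(x) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return np.nan
    xc = x - np.mean(x)
    return float(np.mean(xc[:-1] * xc[1:] < 0))


def turning_point_ratio(x) -> float:
    """Fraction of interior points that are local extrema."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.nan
    a, b, c = x[:-2], x[1:-1], x[2:]
    tp = np.sum(((b > a) & (b > c)) | ((b < a) & (b < c)))
    return float(tp / (x.size - 2))
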