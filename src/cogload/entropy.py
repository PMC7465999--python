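"""Nonlinear complexity measures for inter-beat-interval series.

Sample entropy, approximate entropy, permutation entropy and detrended
fluctuation analysis (DFA). These quantify the regularity/fractal
structure of heart-rate fluctuations; under cognitive load the autonomic
balance shifts and these measures move with it.

Conventions (fixed here, used everywhere in the package):

* SampEn/ApEn: embedding dimension ``m = 2``, tolerance ``r = 0.2 × SD``
  of the series, Chebyshev distance, matches counted with ``d <= r``.
  SampEn excludes self-matches and is ``-ln(A/B)``; ApEn includes
  self-matches and is ``phi(m) - phi(m+1)`` with ``phi`` the mean of
  ``ln`` of per-template match fractions.
* Permutation entropy: ordinal patterns of order 3, delay 1, natural
  log, normalized by ``log(3!)`` so the value lies in [0, 1].
* DFA: first-order detrending, box sizes 4–16 samples, the scaling
  exponent alpha is the slope of log F(n) on log n.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np

__all__ = ["sample_entropy", "approximate_entropy", "permutation_entropy", "dfa_alpha"]


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """All length-m templates of x as rows, shape (n-m+1, m)."""
    n = x.size
    return np.lib.stride_tricks.sliding_window_view(x, m) if n >= m else np.empty((0, m))


def _resolve_r(x: np.ndarray, r: float | None) -> float:
    if r is not None:
        return float(r)
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    return 0.2 * sd


def sample_entropy(x, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) with Chebyshev distance, self-matches excluded.

    Returns NaN when no template pairs match at length m (undefined) or
    when the series is shorter than m+2.
    """
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        return math.nan
    r = _resolve_r(x, r)

    def pair_matches(mm: int) -> int:
        t = _embed(x, mm)
        # count unordered pairs i<j with Chebyshev distance <= r
        count = 0
        for i in range(t.shape[0] - 1):
            d = np.max(np.abs(t[i + 1 :] - t[i]), axis=1)
            count += int(np.count_nonzero(d <= r))
        return count

    # templates of length m are truncated to n-m so that every length-m
    # template has a length-(m+1) continuation (standard SampEn bookkeeping)
    n = x.size
    tm = _embed(x, m)[: n - m]
    b = 0
    for i in range(tm.shape[0] - 1):
        d = np.max(np.abs(tm[i + 1 :] - tm[i]), axis=1)
        b += int(np.count_nonzero(d <= r))
    a = pair_matches(m + 1)
    if b == 0 or a == 0:
        return math.nan
    return -math.log(a / b)


def approximate_entropy(x, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) with Chebyshev distance, self-matches included."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        return math.nan
    r = _resolve_r(x, r)

    def phi(mm: int) -> float:
        t = _embed(x, mm)
        nt = t.shape[0]
        logs = np.empty(nt)
        for i in range(nt):
            d = np.max(np.abs(t - t[i]), axis=1)
            logs[i] = math.log(np.count_nonzero(d <= r) / nt)
        return float(np.mean(logs))

    return phi(m) - phi(m + 1)


def permutation_entropy(
    x, order: int = 3, delay: int = 1, normalize: bool = True
) -> float:
    """Permutation entropy over ordinal patterns (natural log).

    Ties are broken by position (stable argsort), a deterministic rule.
    With ``normalize`` the value is divided by log(order!) and lies in
    [0, 1]; a constant series gives 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.size - (order - 1) * delay
    if n < 1:
        return math.nan
    patterns = {p: 0 for p in permutations(range(order))}
    for i in range(n):
        window = x[i : i + (order - 1) * delay + 1 : delay]
        patterns[tuple(np.argsort(window, kind="stable"))] += 1
    counts = np.array([c for c in patterns.values() if c > 0], dtype=float)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if normalize:
        h /= math.log(math.factorial(order))
    return h


def dfa_alpha(
    x, min_box: int = 4, max_box: int = 16, order: int = 1
) -> float:
    """DFA scaling exponent with polynomial detrending of given order.

    The profile (cumulative sum of the mean-centred series) is split
    into non-overlapping boxes of each size n in [min_box, max_box];
    F(n) is the RMS of residuals around the per-box polynomial fit.
    Alpha is the least-squares slope of log F(n) vs log n. White noise
    gives alpha ≈ 0.5, a random walk ≈ 1.5.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * max_box:
        return math.nan
    profile = np.cumsum(x - x.mean())
    sizes = np.arange(min_box, max_box + 1)
    log_f = []
    for n in sizes:
        nb = profile.size // n
        segs = profile[: nb * n].reshape(nb, n)
        t = np.arange(n, dtype=float)
        # vectorized per-box polynomial fit
        coeffs = np.polynomial.polynomial.polyfit(t, segs.T, order)
        fit = np.polynomial.polynomial.polyval(t, coeffs)
        f = math.sqrt(float(np.mean((segs - fit) ** 2)))
        log_f.append(math.log(f) if f > 0 else math.nan)
    log_f = np.asarray(log_f)
    ok = np.isfinite(log_f)
    if ok.sum() < 2:
        return math.nan
    slope = np.polyfit(np.log(sizes[ok]), log_f[ok], 1)[0]
    return float(slope)
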