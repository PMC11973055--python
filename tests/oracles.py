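"""Independent brute-force reference implementations used as test oracles.

These are deliberately slow, loop-based transliterations of the textbook
definitions, sharing no code with the package.  They exist so the vectorized
implementations can be checked for exact (1e-12) agreement on short windows.
"""

from __future__ import annotations

import math

import numpy as np


def chebyshev(a, b) -> float:
    return max(abs(p - q) for p, q in zip(a, b))


def apen_bruteforce(x, m: int, r: float) -> float:
    """Approximate entropy: phi_m(r) - phi_{m+1}(r), self-matches included."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm: int) -> float:
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for t in templates:
            c = sum(1 for u in templates if chebyshev(t, u) <= r)
            total += math.log(c / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Sample entropy: -ln(A/B), self-matches excluded, N-m templates."""
    x = list(map(float, x))
    n = len(x)
    tm = [x[i:i + m] for i in range(n - m)]
    tm1 = [x[i:i + m + 1] for i in range(n - m)]
    b = sum(1 for i in range(len(tm)) for j in range(i + 1, len(tm))
            if chebyshev(tm[i], tm[j]) <= r)
    a = sum(1 for i in range(len(tm1)) for j in range(i + 1, len(tm1))
            if chebyshev(tm1[i], tm1[j]) <= r)
    if a == 0 or b == 0:
        return 0.0
    return -math.log(a / b)


def perm_entropy_bruteforce(x, order: int, delay: int) -> float:
    """Normalized permutation entropy via explicit ordinal-pattern counting."""
    x = list(map(float, x))
    n = len(x) - (order - 1) * delay
    counts: dict[tuple, int] = {}
    for i in range(n):
        window = [x[i + j * delay] for j in range(order)]
        pattern = tuple(sorted(range(order), key=lambda k: window[k]))
        counts[pattern] = counts.get(pattern, 0) + 1
    h = -sum((c / n) * math.log(c / n) for c in counts.values())
    return h / math.log(math.factorial(order))


def petrosian_bruteforce(x) -> float:
    """Petrosian FD with the derivative sign changes counted by explicit loop."""
    x = list(map(float, x))
    n = len(x)
    diffs = [x[i + 1] - x[i] for i in range(n - 1)]
    signs = [d for d in diffs if d != 0]
    n_delta = sum(1 for i in range(len(signs) - 1)
                  if (signs[i] > 0) != (signs[i + 1] > 0))
    if n_delta == 0:
        return 0.0
    return math.log10(n) / (math.log10(n) + math.log10(n / (n + 0.4 * n_delta)))


def higuchi_bruteforce(x, kmax: int) -> float:
    """Higuchi FD via explicit curve-length loops and a hand-rolled LS fit."""
    x = list(map(float, x))
    n = len(x)
    log_k, log_l = [], []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = list(range(m, n, k))
            if len(idx) < 2:
                continue
            path = sum(abs(x[idx[j + 1]] - x[idx[j]]) for j in range(len(idx) - 1))
            lengths.append(path * (n - 1) / ((len(idx) - 1) * k) / k)
        if lengths and sum(lengths) > 0:
            log_k.append(math.log(k))
            log_l.append(math.log(sum(lengths) / len(lengths)))
    # least squares slope
    mk = sum(log_k) / len(log_k)
    ml = sum(log_l) / len(log_l)
    slope = (sum((a - mk) * (b - ml) for a, b in zip(log_k, log_l))
             / sum((a - mk) ** 2 for a in log_k))
    return -slope


def katz_bruteforce(x) -> float:
    x = list(map(float, x))
    n = len(x) - 1
    L = sum(abs(x[i + 1] - x[i]) for i in range(n))
    if L == 0:
        return 0.0
    d = max(abs(v - x[0]) for v in x)
    if d == L:
        return 1.0
    return math.log10(n) / (math.log10(n) + math.log10(d / L))


def percentile_bruteforce(x, q: float) -> float:
    """Linear-interpolation (type 7) percentile."""
    s = sorted(map(float, x))
    h = (len(s) - 1) * q / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def band_power_bruteforce(x, fs: float, low: float, high: float,
                          include_upper: bool = False) -> float:
    """Band power by direct DFT-sum periodogram integration."""
    x = np.asarray(x, dtype=float)
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2 / (fs * n)
    spec[1:] *= 2
    if n % 2 == 0:
        spec[-1] /= 2
    freqs = np.fft.rfftfreq(n, 1 / fs)
    df = fs / n
    total = 0.0
    for f, p in zip(freqs, spec):
        if f >= low and (f <= high if include_upper else f < high):
            total += p * df
    return total
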