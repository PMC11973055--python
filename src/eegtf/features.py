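"""Time-frequency feature bank: 43 metrics per 1-second window per channel.

The bank covers five families, computed on each sliding window of each
channel of a preprocessed recording:

* 6 entropy metrics — amplitude-histogram Shannon entropy, permutation
  entropy, spectral entropy, SVD entropy, approximate entropy (ApEn) and
  sample entropy (SampEn);
* 12 basic statistics — min, max, mean, RMS, variance, SD, crest factor,
  skewness, kurtosis and the 25th/50th/75th percentiles;
* 11 power-spectral-density metrics — total 1-40 Hz power, PSD peak and
  peak-to-peak, the five canonical band powers (delta, theta, alpha, beta,
  gamma) and the slowing ratios r1 = d/(a+b), r2 = t/(a+b),
  r3 = (d+t)/(a+b);
* 7 frequency-domain metrics — maximum / mean / median / peak frequency,
  summed spectral power, and power-weighted spectral skewness and kurtosis;
* 7 fractal and complexity metrics — zero crossings, Katz / Higuchi /
  Petrosian fractal dimensions, the DFA scaling exponent, and Hjorth
  mobility and complexity.

Conventions (fixed and documented rather than configurable wherever the
field has no single standard): population moments (divisor N, non-excess
kurtosis), linear-interpolation percentiles, rectangular-window periodogram
PSD, Chebyshev distance for ApEn/SampEn, and first differences left
unscaled by the sampling rate in derivative-based quantities.  Degenerate
(constant) windows map every undefined metric to 0 with a logged diagnostic
so that one flat window cannot abort a subject.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .recording import EEGRecording

logger = logging.getLogger(__name__)

#: Band edges used by the PSD family; half-open [low, high) except gamma,
#: which is closed at 40 Hz so the five bands exactly tile [1, 40].
DEFAULT_BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}

ENTROPY_FEATURES = (
    "shannon_amplitude_entropy", "permutation_entropy", "spectral_entropy",
    "svd_entropy", "approximate_entropy", "sample_entropy",
)
BASIC_STAT_FEATURES = (
    "min", "max", "mean", "rms", "variance", "std", "crest_factor",
    "skewness", "kurtosis", "p25", "p50", "p75",
)
PSD_FEATURES = (
    "total_power", "psd_peak", "psd_peak_to_peak", "delta_power",
    "theta_power", "alpha_power", "beta_power", "gamma_power",
    "r1", "r2", "r3",
)
FREQUENCY_FEATURES = (
    "max_frequency", "sum_frequencies", "mean_frequency", "median_frequency",
    "peak_frequency", "spectral_skewness", "spectral_kurtosis",
)
FRACTAL_FEATURES = (
    "zero_crossings", "katz_fd", "higuchi_fd", "dfa_alpha", "petrosian_fd",
    "hjorth_mobility", "hjorth_complexity",
)

#: Canonical ordering of the 43 features along the feature axis.
FEATURE_NAMES: tuple[str, ...] = (
    ENTROPY_FEATURES + BASIC_STAT_FEATURES + PSD_FEATURES
    + FREQUENCY_FEATURES + FRACTAL_FEATURES
)
assert len(FEATURE_NAMES) == 43


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window parameters: window length in seconds and overlap fraction."""

    window_seconds: float = 1.0
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class FeatureParams:
    """Estimator parameters of the feature bank.

    ApEn/SampEn use embedding dimension ``entropy_embedding_m`` and tolerance
    ``entropy_tolerance_r`` x window SD (literature-standard m=2, r=0.2);
    permutation and SVD entropies use order-3, delay-1 embeddings; amplitude
    entropy uses ``hist_bins`` histogram bins; Higuchi uses scales up to
    ``higuchi_kmax``; DFA uses ``dfa_n_scales`` log-spaced box sizes from
    ``dfa_min_scale`` to N/4.
    """

    entropy_embedding_m: int = 2
    entropy_tolerance_r: float = 0.2
    perm_order: int = 3
    perm_delay: int = 1
    svd_order: int = 3
    svd_delay: int = 1
    hist_bins: int = 16
    higuchi_kmax: int = 10
    dfa_min_scale: int = 4
    dfa_n_scales: int = 10
    band_edges: tuple[tuple[str, float, float], ...] = tuple(
        (name, lo, hi) for name, (lo, hi) in DEFAULT_BAND_EDGES.items()
    )
    ratio_defs: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
        ("r1", ("delta",), ("alpha", "beta")),
        ("r2", ("theta",), ("alpha", "beta")),
        ("r3", ("delta", "theta"), ("alpha", "beta")),
    )

    def __post_init__(self) -> None:
        if self.entropy_embedding_m < 1:
            raise ValueError("entropy_embedding_m must be >= 1")
        if self.entropy_tolerance_r <= 0:
            raise ValueError("entropy_tolerance_r must be positive")
        if self.perm_order < 2:
            raise ValueError("perm_order must be >= 2")
        if self.higuchi_kmax < 2:
            raise ValueError("higuchi_kmax must be >= 2")
        edges = [(lo, hi) for _, lo, hi in self.band_edges]
        if any(lo >= hi for lo, hi in edges):
            raise ValueError("band edges must be strictly increasing")


@dataclass
class FeatureCube:
    """Per-subject feature array indexed (channel, window, feature)."""

    subject_id: str
    group: str
    channel_names: list[str]
    feature_names: tuple[str, ...]
    values: np.ndarray
    window_times: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.channel_names),
                                 len(self.window_times),
                                 len(self.feature_names)):
            raise ValueError("values shape inconsistent with axis labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature cube contains non-finite values")


# ---------------------------------------------------------------------------
# windowing


def window_signal(channel: np.ndarray, fs: float,
                  cfg: WindowingConfig | None = None) -> np.ndarray:
    """Slice a channel into consecutive windows; returns (n_windows, w) array.

    The hop is ``window x (1 - overlap)`` samples and trailing samples that do
    not fill a window are discarded.
    """
    cfg = cfg or WindowingConfig()
    x = np.asarray(channel, dtype=float)
    w = int(round(cfg.window_seconds * fs))
    if w < 8:
        raise ValueError("window must contain at least 8 samples")
    if x.size < w:
        raise ValueError(f"signal of {x.size} samples shorter than one window ({w})")
    hop = max(1, int(round(w * (1.0 - cfg.overlap_fraction))))
    n_windows = (x.size - w) // hop + 1
    starts = np.arange(n_windows) * hop
    return np.stack([x[s:s + w] for s in starts])


def window_start_times(n_samples: int, fs: float,
                       cfg: WindowingConfig | None = None) -> np.ndarray:
    """Start times (s) of the windows :func:`window_signal` would produce."""
    cfg = cfg or WindowingConfig()
    w = int(round(cfg.window_seconds * fs))
    hop = max(1, int(round(w * (1.0 - cfg.overlap_fraction))))
    n_windows = (n_samples - w) // hop + 1
    return np.arange(n_windows) * hop / fs


# ---------------------------------------------------------------------------
# entropy family


def _embed(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    """Delay embedding: rows are length-``order`` subsequences."""
    n = x.size - (order - 1) * delay
    if n <= 0:
        raise ValueError("window too short for requested embedding")
    idx = np.arange(n)[:, None] + np.arange(order)[None, :] * delay
    return x[idx]


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def shannon_amplitude_entropy(x: np.ndarray, bins: int = 16) -> float:
    """Shannon entropy (nats) of the amplitude histogram with ``bins`` bins."""
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    return _shannon(counts / x.size)


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy in [0, 1] (ordinal-pattern Shannon entropy)."""
    patterns = np.argsort(_embed(x, order, delay), axis=1, kind="stable")
    codes = patterns @ (order ** np.arange(order))  # radix code, injective per pattern
    _, counts = np.unique(codes, return_counts=True)
    h = _shannon(counts / counts.sum())
    return h / math.log(math.factorial(order))


def spectral_entropy(x: np.ndarray, fs: float) -> float:
    """Normalized Shannon entropy of the one-sided periodogram (DC excluded)."""
    psd = np.abs(np.fft.rfft(x)[1:]) ** 2
    total = psd.sum()
    if total == 0:
        return 0.0
    return _shannon(psd / total) / math.log(psd.size)


def svd_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized Shannon entropy of singular values of the delay-embedding matrix."""
    s = np.linalg.svd(_embed(x, order, delay), compute_uv=False)
    total = s.sum()
    if total == 0:
        return 0.0
    return _shannon(s / total) / math.log(order)


def _apen_sampen(x: np.ndarray, m: int, r_frac: float) -> tuple[float, float]:
    """ApEn(m, r*SD) and SampEn(m, r*SD) with Chebyshev distance, sharing work.

    ApEn counts self-matches and averages log match frequencies; SampEn
    excludes self-matches and pools counts (-ln(A/B)).  Both return 0 on
    degenerate windows (constant, or no template matches).
    """
    n = x.size
    sd = float(np.std(x))
    if sd == 0 or n < m + 2:
        return 0.0, 0.0
    r = r_frac * sd
    diff = np.abs(x[:, None] - x[None, :])

    def running_max(length: int) -> np.ndarray:
        # Chebyshev distance between all pairs of length-`length` templates
        k = n - length + 1
        d = diff[:k, :k].copy()
        for off in range(1, length):
            np.maximum(d, diff[off:off + k, off:off + k], out=d)
        return d

    d_m = running_max(m)
    d_m1 = running_max(m + 1)

    # ApEn: phi_m - phi_{m+1}, self-matches included
    c_m = (d_m <= r).sum(axis=1) / d_m.shape[0]
    c_m1 = (d_m1 <= r).sum(axis=1) / d_m1.shape[0]
    apen = float(np.mean(np.log(c_m)) - np.mean(np.log(c_m1)))

    # SampEn: template range 0..n-m-1 for both lengths, self-matches excluded
    k = n - m
    b = int((d_m[:k, :k] <= r).sum()) - k
    a = int((d_m1 <= r).sum()) - d_m1.shape[0]
    sampen = 0.0 if a == 0 or b == 0 else float(-math.log(a / b))
    return apen, sampen


def approximate_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """ApEn(m, r*SD): regularity statistic, lower for more self-similar signals."""
    return _apen_sampen(np.asarray(x, float), m, r)[0]


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """SampEn(m, r*SD) = -ln(A/B) with self-matches excluded."""
    return _apen_sampen(np.asarray(x, float), m, r)[1]


def entropy_features(window: np.ndarray, fs: float,
                     params: FeatureParams | None = None) -> dict[str, float]:
    """The six entropy metrics of the bank for one window."""
    params = params or FeatureParams()
    x = np.asarray(window, dtype=float)
    apen, sampen = _apen_sampen(x, params.entropy_embedding_m,
                                params.entropy_tolerance_r)
    if np.ptp(x) == 0:
        logger.debug("constant window: entropy metrics set to 0")
        return dict.fromkeys(ENTROPY_FEATURES, 0.0)
    return {
        "shannon_amplitude_entropy": shannon_amplitude_entropy(x, params.hist_bins),
        "permutation_entropy": permutation_entropy(x, params.perm_order,
                                                   params.perm_delay),
        "spectral_entropy": spectral_entropy(x, fs),
        "svd_entropy": svd_entropy(x, params.svd_order, params.svd_delay),
        "approximate_entropy": apen,
        "sample_entropy": sampen,
    }


# ---------------------------------------------------------------------------
# basic statistics family


def basic_stat_features(window: np.ndarray) -> dict[str, float]:
    """Twelve distributional statistics of the raw window samples.

    Population (divisor-N) moments; kurtosis is non-excess (Gaussian -> 3);
    crest factor, skewness and kurtosis of a zero-variance window are 0.
    """
    x = np.asarray(window, dtype=float)
    mean = float(x.mean())
    var = float(x.var())
    std = math.sqrt(var)
    rms = math.sqrt(float(np.mean(x * x)))
    if std == 0:
        crest = skew = kurt = 0.0
    else:
        crest = float(np.max(np.abs(x)) / rms) if rms > 0 else 0.0
        z = (x - mean) / std
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4))
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return {
        "min": float(x.min()), "max": float(x.max()), "mean": mean, "rms": rms,
        "variance": var, "std": std, "crest_factor": crest,
        "skewness": skew, "kurtosis": kurt,
        "p25": float(q25), "p50": float(q50), "p75": float(q75),
    }


# ---------------------------------------------------------------------------
# PSD family


def _periodogram(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided rectangular-window periodogram: PSD in power/Hz on the DFT grid."""
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2 / (fs * n)
    spec[1:] *= 2.0
    if n % 2 == 0:
        spec[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, spec


def psd_features(window: np.ndarray, fs: float,
                 params: FeatureParams | None = None) -> dict[str, float]:
    """Eleven periodogram metrics: total/band powers, peak stats and ratios.

    Band powers integrate PSD x df over half-open bands ([low, high), gamma
    closed at its upper edge) so the five bands exactly partition the total
    1-40 Hz power on the DFT grid.  A vanishing ratio denominator maps the
    ratio to 0 with a diagnostic.
    """
    params = params or FeatureParams()
    x = np.asarray(window, dtype=float)
    freqs, psd = _periodogram(x, fs)
    df = fs / x.size
    lo_edge = min(lo for _, lo, _ in params.band_edges)
    hi_edge = max(hi for _, _, hi in params.band_edges)
    in_range = (freqs >= lo_edge) & (freqs <= hi_edge)
    psd_r = psd[in_range]
    out: dict[str, float] = {
        "total_power": float(psd_r.sum() * df) if psd_r.size else 0.0,
        "psd_peak": float(psd_r.max()) if psd_r.size else 0.0,
        "psd_peak_to_peak": float(psd_r.max() - psd_r.min()) if psd_r.size else 0.0,
    }
    band_power: dict[str, float] = {}
    for i, (name, lo, hi) in enumerate(params.band_edges):
        last = i == len(params.band_edges) - 1
        sel = (freqs >= lo) & ((freqs <= hi) if last else (freqs < hi))
        band_power[name] = float(psd[sel].sum() * df)
        out[f"{name}_power"] = band_power[name]
    for rname, num_bands, den_bands in params.ratio_defs:
        num = sum(band_power[b] for b in num_bands)
        den = sum(band_power[b] for b in den_bands)
        if den == 0:
            logger.debug("zero denominator in band ratio %s; ratio set to 0", rname)
            out[rname] = 0.0
        else:
            out[rname] = num / den
    return out


# ---------------------------------------------------------------------------
# frequency-domain family


def frequency_features(window: np.ndarray, fs: float,
                       band: tuple[float, float] = (1.0, 40.0),
                       rel_threshold: float = 1e-6) -> dict[str, float]:
    """Seven spectral-shape metrics from power weights w(f) = |X(f)|^2 on [1, 40] Hz.

    ``max_frequency`` is the largest frequency whose power exceeds
    ``rel_threshold`` x the peak power (a numerical reading of "highest
    nonzero spectral component").  An all-zero spectrum maps every metric
    to 0 with a diagnostic.
    """
    x = np.asarray(window, dtype=float)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    w = np.abs(np.fft.rfft(x)) ** 2
    sel = (freqs >= band[0]) & (freqs <= band[1])
    f, w = freqs[sel], w[sel]
    total = w.sum()
    if total == 0:
        logger.debug("all-zero spectrum: frequency metrics set to 0")
        return dict.fromkeys(FREQUENCY_FEATURES, 0.0)
    mean_f = float((f * w).sum() / total)
    cum = np.cumsum(w)
    median_f = float(f[np.searchsorted(cum, total / 2.0)])
    var_f = float(((f - mean_f) ** 2 * w).sum() / total)
    sd_f = math.sqrt(var_f)
    if sd_f == 0:
        skew_f = kurt_f = 0.0
    else:
        skew_f = float((((f - mean_f) / sd_f) ** 3 * w).sum() / total)
        kurt_f = float((((f - mean_f) / sd_f) ** 4 * w).sum() / total)
    return {
        "max_frequency": float(f[w > rel_threshold * w.max()].max()),
        "sum_frequencies": float(total),
        "mean_frequency": mean_f,
        "median_frequency": median_f,
        "peak_frequency": float(f[int(np.argmax(w))]),
        "spectral_skewness": skew_f,
        "spectral_kurtosis": kurt_f,
    }


# ---------------------------------------------------------------------------
# fractal / complexity family


def zero_crossings(x: np.ndarray) -> int:
    """Strict sign changes between consecutive samples, zeros skipped."""
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension from total path length L and extent d.

    KFD = log10(n) / (log10(n) + log10(d/L)) with n = N-1 steps,
    L = sum |x_{i+1} - x_i| and d = max_i |x_i - x_1|; a straight line gives
    d = L hence KFD = 1, and a flat window (L = 0) maps to 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.size - 1
    L = float(np.abs(np.diff(x)).sum())
    if L == 0:
        return 0.0
    d = float(np.abs(x - x[0]).max())
    if d == L:
        return 1.0
    den = math.log10(n) + math.log10(d / L)
    if den == 0:  # d/L = 1/n exactly; the estimator diverges on this set
        return 0.0
    return math.log10(n) / den


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension: -slope of log mean curve length vs log k."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if np.ptp(x) == 0:
        return 0.0
    log_k, log_l = [], []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            path = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths.append(path * norm / k)
        if lengths:
            mean_len = float(np.mean(lengths))
            if mean_len > 0:
                log_k.append(math.log(k))
                log_l.append(math.log(mean_len))
    if len(log_k) < 2:
        return 0.0
    slope = np.polyfit(log_k, log_l, 1)[0]
    return float(-slope)


def dfa_alpha(x: np.ndarray, min_scale: int = 4, n_scales: int = 10) -> float:
    """Detrended fluctuation analysis scaling exponent.

    Uses the cumulative-sum profile, non-overlapping boxes, least-squares
    linear detrending per box, and a log-log fit of the RMS fluctuation over
    log-spaced box sizes from ``min_scale`` to N/4.  White noise gives
    alpha ~= 0.5.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    max_scale = n // 4
    if max_scale <= min_scale or np.ptp(x) == 0:
        return 0.0
    scales = np.unique(np.geomspace(min_scale, max_scale, n_scales).astype(int))
    profile = np.cumsum(x - x.mean())
    log_s, log_f = [], []
    for s in scales:
        n_boxes = n // s
        seg = profile[: n_boxes * s].reshape(n_boxes, s)
        t = np.arange(s)
        # least-squares line per box via closed-form normal equations
        t_mean = t.mean()
        denom = ((t - t_mean) ** 2).sum()
        slope = ((seg - seg.mean(axis=1, keepdims=True)) * (t - t_mean)).sum(axis=1) / denom
        intercept = seg.mean(axis=1) - slope * t_mean
        resid = seg - (slope[:, None] * t + intercept[:, None])
        f = math.sqrt(float(np.mean(resid ** 2)))
        if f > 0:
            log_s.append(math.log(s))
            log_f.append(math.log(f))
    if len(log_s) < 2:
        return 0.0
    return float(np.polyfit(log_s, log_f, 1)[0])


def petrosian_fd(x: np.ndarray) -> float:
    """Petrosian fractal dimension from sign changes of the first difference."""
    x = np.asarray(x, dtype=float)
    n = x.size
    n_delta = zero_crossings(np.diff(x))
    if n_delta == 0:
        return 0.0
    log_n = math.log10(n)
    return log_n / (log_n + math.log10(n / (n + 0.4 * n_delta)))


def hjorth_params(x: np.ndarray) -> tuple[float, float]:
    """Hjorth mobility and complexity from variance ratios of differences.

    mobility = sqrt(var(dx)/var(x)); complexity = mobility(dx)/mobility(x).
    First differences are unscaled by fs (discrete convention); a
    zero-variance window yields (0, 0).
    """
    x = np.asarray(x, dtype=float)
    v0 = float(np.var(x))
    if v0 == 0:
        return 0.0, 0.0
    dx = np.diff(x)
    v1 = float(np.var(dx))
    mobility = math.sqrt(v1 / v0)
    if v1 == 0:
        return mobility, 0.0
    v2 = float(np.var(np.diff(dx)))
    complexity = math.sqrt(v2 / v1) / mobility
    return mobility, complexity


def fractal_complexity_features(window: np.ndarray, fs: float,
                                params: FeatureParams | None = None
                                ) -> dict[str, float]:
    """The seven waveform-complexity metrics for one window."""
    params = params or FeatureParams()
    x = np.asarray(window, dtype=float)
    if np.ptp(x) == 0:
        logger.debug("constant window: complexity metrics set to 0")
        return dict.fromkeys(FRACTAL_FEATURES, 0.0)
    mobility, complexity = hjorth_params(x)
    return {
        "zero_crossings": float(zero_crossings(x)),
        "katz_fd": katz_fd(x),
        "higuchi_fd": higuchi_fd(x, params.higuchi_kmax),
        "dfa_alpha": dfa_alpha(x, params.dfa_min_scale, params.dfa_n_scales),
        "petrosian_fd": petrosian_fd(x),
        "hjorth_mobility": mobility,
        "hjorth_complexity": complexity,
    }


# ---------------------------------------------------------------------------
# full bank


def compute_window_features(window: np.ndarray, fs: float,
                            params: FeatureParams | None = None) -> np.ndarray:
    """All 43 metrics of one window, in :data:`FEATURE_NAMES` order."""
    params = params or FeatureParams()
    values: dict[str, float] = {}
    values.update(entropy_features(window, fs, params))
    values.update(basic_stat_features(window))
    values.update(psd_features(window, fs, params))
    values.update(frequency_features(window, fs))
    values.update(fractal_complexity_features(window, fs, params))
    return np.array([values[name] for name in FEATURE_NAMES])


def compute_feature_cube(rec: EEGRecording,
                         wcfg: WindowingConfig | None = None,
                         params: FeatureParams | None = None) -> FeatureCube:
    """Run the 43-metric bank over every window of every channel.

    Returns a (channel, window, feature) cube; all values are finite (the
    degenerate-window conventions guarantee this).
    """
    wcfg = wcfg or WindowingConfig()
    params = params or FeatureParams()
    times = window_start_times(rec.n_samples, rec.fs, wcfg)
    values = np.empty((rec.n_channels, times.size, len(FEATURE_NAMES)))
    for c in range(rec.n_channels):
        windows = window_signal(rec.data[c], rec.fs, wcfg)
        for w in range(windows.shape[0]):
            values[c, w] = compute_window_features(windows[w], rec.fs, params)
    return FeatureCube(
        subject_id=rec.subject_id,
        group=rec.group,
        channel_names=list(rec.channel_names),
        feature_names=FEATURE_NAMES,
        values=values,
        window_times=times,
    )
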