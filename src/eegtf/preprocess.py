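"""Recording preprocessing: resampling, amplitude normalization, band-pass.

The pipeline brings every recording to a common sampling rate (256 Hz by
default), divides each channel by its own RMS, removes the channel mean, and
band-limits the signal to 1-40 Hz with a 5th-order Butterworth filter applied
forward-backward (zero phase).  A spectral-fidelity check compares magnitude
spectra before and after resampling and warns when their correlation drops
below a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .recording import EEGRecording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    target_fs : common sampling rate in Hz.
    filter_order : Butterworth order (doubled effectively by the
        forward-backward application).
    band : (low, high) pass band in Hz.
    resample_check_threshold : minimum acceptable spectral correlation.
    """

    target_fs: float = 256.0
    filter_order: int = 5
    band: tuple[float, float] = (1.0, 40.0)
    resample_check_threshold: float = 0.99

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.target_fs / 2):
            raise ValueError("band must satisfy 0 < low < high < target_fs/2")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


def resample_to_target(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Resample every channel to ``target_fs`` with an anti-aliased polyphase filter.

    A no-op when the recording already runs at the target rate.  The output
    sample count is ``round(n * target_fs / fs)``.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if rec.fs == target_fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    resampled = signal.resample_poly(rec.data, up, down, axis=1)
    n_target = int(round(rec.n_samples * target_fs / rec.fs))
    resampled = resampled[:, :n_target]
    return rec.with_data(resampled, fs=target_fs)


def check_resampling_fidelity(original: EEGRecording, resampled: EEGRecording,
                              band: tuple[float, float] = (1.0, 40.0),
                              threshold: float = 0.99,
                              edge_trim: float = 0.5) -> np.ndarray:
    """Per-channel Pearson correlation of magnitude spectra across resampling.

    Both signals are trimmed by ``edge_trim`` seconds at each end (boundary
    transients), their one-sided magnitude spectra are interpolated onto a
    common grid spanning ``band``, and the Pearson correlation is returned
    per channel.  Values below ``threshold`` trigger a warning.
    """
    if original.n_channels != resampled.n_channels:
        raise ValueError("channel counts differ between original and resampled")

    def trimmed_spectrum(data: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
        k = int(edge_trim * fs)
        seg = data[:, k: data.shape[1] - k] if k > 0 else data
        freqs = np.fft.rfftfreq(seg.shape[1], d=1.0 / fs)
        mags = np.abs(np.fft.rfft(seg, axis=1)) / seg.shape[1]
        return freqs, mags

    f_orig, m_orig = trimmed_spectrum(original.data, original.fs)
    f_res, m_res = trimmed_spectrum(resampled.data, resampled.fs)
    grid = np.linspace(band[0], band[1], 512)
    corrs = np.empty(original.n_channels)
    for ch in range(original.n_channels):
        a = np.interp(grid, f_orig, m_orig[ch])
        b = np.interp(grid, f_res, m_res[ch])
        corrs[ch] = np.corrcoef(a, b)[0, 1]
    bad = np.flatnonzero(corrs < threshold)
    if bad.size:
        logger.warning(
            "resampling fidelity below %.3f on channels %s (min corr %.4f)",
            threshold, bad.tolist(), corrs.min(),
        )
    return corrs


def rms_normalize(rec: EEGRecording) -> EEGRecording:
    """Divide each channel by its own RMS over the full recording."""
    rms = np.sqrt(np.mean(rec.data ** 2, axis=1))
    flat = np.flatnonzero(rms == 0.0)
    if flat.size:
        names = [rec.channel_names[i] for i in flat]
        raise ValueError(f"flat (zero-RMS) channels cannot be normalized: {names}")
    return rec.with_data(rec.data / rms[:, None])


def remove_mean(rec: EEGRecording) -> EEGRecording:
    """Subtract each channel's mean (centering)."""
    return rec.with_data(rec.data - rec.data.mean(axis=1, keepdims=True))


def bandpass(rec: EEGRecording, config: PreprocessConfig | None = None) -> EEGRecording:
    """Zero-phase Butterworth band-pass over ``config.band``."""
    config = config or PreprocessConfig()
    low, high = config.band
    if not (0 < low < high < rec.fs / 2):
        raise ValueError("band must lie inside (0, fs/2)")
    sos = signal.butter(config.filter_order, [low, high], btype="bandpass",
                        fs=rec.fs, output="sos")
    return rec.with_data(signal.sosfiltfilt(sos, rec.data, axis=1))


def preprocess_recording(rec: EEGRecording,
                         config: PreprocessConfig | None = None) -> EEGRecording:
    """Full chain: resample -> RMS normalize -> mean removal -> band-pass."""
    config = config or PreprocessConfig()
    rec = resample_to_target(rec, config.target_fs)
    rec = rms_normalize(rec)
    rec = remove_mean(rec)
    return bandpass(rec, config)
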