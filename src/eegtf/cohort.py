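"""Synthetic EEG cohort generator.

Produces multichannel recordings whose band-power structure mimics the
spectral slowing seen in Alzheimer's disease: AD-like profiles carry elevated
delta/theta power and suppressed alpha/beta power, control-like profiles the
reverse, and MCI-like profiles sit in between.  Each channel is an
independent realization of

    sum over bands of band-limited Gaussian noise  +  1/f^a background,

where each band component is scaled so its power equals the profile's band
weight and the background power is the total structured power divided by the
signal-to-noise ratio.  Band limiting uses the same 5th-order Butterworth
design as the preprocessing stage so the generator and the analysis agree on
what "in band" means.

Generation is deterministic: a single cohort seed drives per-subject,
per-channel substreams through ``numpy.random.SeedSequence`` spawn keys, so
adding subjects or channels never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .recording import CHANNELS_1020, EEGRecording, write_recording_csv

#: Canonical EEG band edges in Hz (half-open except gamma, which closes at 40).
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
}

BANDS: tuple[str, ...] = tuple(BAND_EDGES)


@dataclass(frozen=True)
class GroupProfile:
    """Spectral recipe for one group archetype.

    ``band_weights`` are relative linear power weights per band (>= 0, at
    least one positive); ``pink_exponent`` is the 1/f background slope and
    ``snr`` the ratio of structured band power to background power.
    """

    name: str
    band_weights: dict[str, float]
    sampling_rate: float = 256.0
    pink_exponent: float = 1.0
    snr: float = 4.0

    def __post_init__(self) -> None:
        unknown = set(self.band_weights) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown bands in profile: {sorted(unknown)}")
        weights = [self.band_weights.get(b, 0.0) for b in BANDS]
        if any(w < 0 for w in weights):
            raise ValueError("band weights must be non-negative")
        if not any(w > 0 for w in weights):
            raise ValueError("at least one band weight must be positive")
        if self.sampling_rate <= 80.0:
            raise ValueError("sampling rate must exceed 2 x 40 Hz")
        if self.pink_exponent < 0:
            raise ValueError("pink_exponent must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def default_profiles() -> dict[str, GroupProfile]:
    """The three built-in archetypes: control (200 Hz), MCI and AD (256 Hz).

    Control weights emphasise alpha/beta, AD weights delta/theta, MCI is the
    elementwise midpoint; magnitudes are free parameters of the generator.
    """
    control_w = dict(zip(BANDS, (0.5, 0.7, 1.5, 1.0, 0.3)))
    ad_w = dict(zip(BANDS, (1.5, 1.4, 0.6, 0.4, 0.2)))
    mci_w = {b: 0.5 * (control_w[b] + ad_w[b]) for b in BANDS}
    return {
        "control": GroupProfile("control", control_w, sampling_rate=200.0, snr=4.0),
        "mci": GroupProfile("mci", mci_w, sampling_rate=256.0, snr=4.0),
        "ad": GroupProfile("ad", ad_w, sampling_rate=256.0, snr=4.0),
    }


@dataclass
class CohortSpec:
    """Size, duration and per-group recipes of a synthetic cohort."""

    n_per_group: int = 7
    duration: float = 60.0
    n_channels: int = 19
    seed: int = 0
    profiles: dict[str, GroupProfile] = field(default_factory=default_profiles)

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        if self.n_channels <= 0:
            raise ValueError("n_channels must be positive")
        if not self.profiles:
            raise ValueError("at least one group profile is required")
        min_fs = min(p.sampling_rate for p in self.profiles.values())
        if self.duration * min_fs < 2 * min_fs:  # >= two 1-s analysis windows
            raise ValueError("duration must cover at least two analysis windows")


def _channel_names(n_channels: int) -> list[str]:
    if n_channels == len(CHANNELS_1020):
        return list(CHANNELS_1020)
    if n_channels < len(CHANNELS_1020):
        return list(CHANNELS_1020[:n_channels])
    return list(CHANNELS_1020) + [f"EX{i}" for i in range(n_channels - len(CHANNELS_1020))]


def _bandpass_sos(low: float, high: float, fs: float) -> np.ndarray:
    return signal.butter(5, [low, high], btype="bandpass", fs=fs, output="sos")


def _scaled_to_power(x: np.ndarray, power: float) -> np.ndarray:
    """Rescale ``x`` so its mean square equals ``power`` (zeros stay zero)."""
    ms = float(np.mean(x * x))
    if ms == 0.0 or power == 0.0:
        return np.zeros_like(x)
    return x * math.sqrt(power / ms)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^exponent Gaussian noise via spectral shaping (zero-mean)."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    spectrum = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0
    return np.fft.irfft(spectrum * scale, n=n)


def generate_recording(profile: GroupProfile, duration: float,
                       n_channels: int = 19, seed: int = 0,
                       subject_id: str | None = None) -> EEGRecording:
    """Generate one synthetic recording for the given group profile.

    Each channel sums five independently drawn band-limited Gaussian noise
    components, one per EEG band, scaled so the power of band ``b`` equals
    ``profile.band_weights[b]``, plus a 1/f^a background whose power is the
    total band power divided by ``profile.snr``.  Deterministic in
    ``(profile, duration, n_channels, seed)``.
    """
    if duration < 2.0:
        raise ValueError("duration must be at least 2 s")
    if n_channels <= 0:
        raise ValueError("n_channels must be positive")
    fs = profile.sampling_rate
    n = int(round(duration * fs))
    weights = {b: profile.band_weights.get(b, 0.0) for b in BANDS}
    total_structured = sum(weights.values())
    background_power = total_structured / profile.snr if math.isfinite(profile.snr) else 0.0

    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(ch,)))
        x = np.zeros(n)
        # pad generously so filter transients do not colour the kept segment
        pad = int(2 * fs)
        for band, (low, high) in BAND_EDGES.items():
            white = rng.standard_normal(n + 2 * pad)
            if weights[band] == 0.0:
                continue
            sos = _bandpass_sos(low, high, fs)
            shaped = signal.sosfiltfilt(sos, white)[pad:pad + n]
            x += _scaled_to_power(shaped, weights[band])
        if background_power > 0.0:
            x += _scaled_to_power(_pink_noise(rng, n, profile.pink_exponent),
                                  background_power)
        data[ch] = x

    return EEGRecording(
        subject_id=subject_id or f"{profile.name}-s{seed}",
        group=profile.name,
        fs=fs,
        data=data,
        channel_names=_channel_names(n_channels),
    )


def generate_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """Generate ``n_per_group`` recordings per group, reproducibly.

    Subject seeds are derived from the cohort seed with a fixed stride per
    (group index, subject index) pair, so regenerating with a larger
    ``n_per_group`` leaves existing subjects bit-identical.
    """
    recordings: list[EEGRecording] = []
    for g_idx, (group, profile) in enumerate(sorted(spec.profiles.items())):
        for s_idx in range(spec.n_per_group):
            sub_seed_seq = np.random.SeedSequence(spec.seed, spawn_key=(g_idx, s_idx))
            sub_seed = int(sub_seed_seq.generate_state(1)[0] % (2**31 - 1))
            rec = generate_recording(
                profile, spec.duration, spec.n_channels, seed=sub_seed,
                subject_id=f"{group}-{s_idx:02d}",
            )
            recordings.append(rec)
    return recordings


def write_cohort(recordings: list[EEGRecording], out_dir: str | Path) -> list[Path]:
    """Write one CSV per subject into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        path = out_dir / f"{rec.subject_id}.csv"
        write_recording_csv(rec, path)
        paths.append(path)
    return paths
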