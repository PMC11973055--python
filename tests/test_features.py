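"""Feature-bank correctness: oracle equivalence, closed forms, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegtf import (
    FEATURE_NAMES,
    FeatureParams,
    WindowingConfig,
    basic_stat_features,
    compute_feature_cube,
    compute_window_features,
    entropy_features,
    fractal_complexity_features,
    frequency_features,
    generate_recording,
    GroupProfile,
    psd_features,
    window_signal,
)
from eegtf import features as F

from . import oracles

FS = 256.0


def sine(freq, fs=FS, n=256, phase=0.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


# ---------------------------------------------------------------------------
# windowing


@pytest.mark.parametrize(
    "n, fs, window, overlap, expected_windows",
    [
        (15360, 256, 1.0, 0.0, 60),
        (300, 256, 1.0, 0.0, 1),
        (512, 256, 1.0, 0.5, 3),
    ],
)
def test_window_counts(n, fs, window, overlap, expected_windows):
    x = np.arange(n, dtype=float)
    cfg = WindowingConfig(window_seconds=window, overlap_fraction=overlap)
    windows = window_signal(x, fs, cfg)
    assert windows.shape == (expected_windows, int(window * fs))


def test_window_starts_with_overlap():
    x = np.arange(512, dtype=float)
    cfg = WindowingConfig(overlap_fraction=0.5)
    windows = window_signal(x, 256, cfg)
    assert [w[0] for w in windows] == [0, 128, 256]


def test_window_too_short_rejected():
    with pytest.raises(ValueError):
        window_signal(np.arange(100.0), 256, WindowingConfig())


# ---------------------------------------------------------------------------
# oracle equivalence on random windows


def test_entropy_and_fractal_match_bruteforce_oracles(random_windows):
    """Vectorized estimators agree with loop-based definitions to 1e-12."""
    params = FeatureParams()
    for x in random_windows:
        r = params.entropy_tolerance_r * float(np.std(x))
        m = params.entropy_embedding_m
        assert F.approximate_entropy(x) == pytest.approx(
            oracles.apen_bruteforce(x, m, r), abs=1e-12)
        assert F.sample_entropy(x) == pytest.approx(
            oracles.sampen_bruteforce(x, m, r), abs=1e-12)
        assert F.permutation_entropy(x) == pytest.approx(
            oracles.perm_entropy_bruteforce(x, 3, 1), abs=1e-12)
        assert F.petrosian_fd(x) == pytest.approx(
            oracles.petrosian_bruteforce(x), abs=1e-12)
        assert F.higuchi_fd(x, 10) == pytest.approx(
            oracles.higuchi_bruteforce(x, 10), abs=1e-10)
        assert F.katz_fd(x) == pytest.approx(
            oracles.katz_bruteforce(x), abs=1e-12)
        for q in (25, 50, 75):
            assert np.percentile(x, q) == pytest.approx(
                oracles.percentile_bruteforce(x, q), abs=1e-12)


# ---------------------------------------------------------------------------
# entropy family


def test_permutation_entropy_zero_for_monotone_window():
    assert F.permutation_entropy(np.arange(1.0, 257.0)) == 0.0


def test_constant_window_entropies_are_zero():
    vals = entropy_features(np.full(256, 3.14), FS)
    assert all(v == 0.0 for v in vals.values())


def test_spectral_entropy_high_for_white_noise():
    rng = np.random.default_rng(42)
    ents = [F.spectral_entropy(rng.standard_normal(256), FS) for _ in range(20)]
    assert min(ents) > 0.9


def test_sampen_printed_series_matches_bruteforce():
    """A short fixed series, checked against O(N^2) template counting."""
    x = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0, 1.5, 3.5, 2.5, 5.5,
                  4.5, 0.5, 6.5, 2.2, 3.3, 4.4, 1.1, 5.1, 0.9, 3.9])
    r = 0.2 * float(np.std(x))
    assert F.sample_entropy(x) == pytest.approx(
        oracles.sampen_bruteforce(x, 2, r), abs=1e-12)


# ---------------------------------------------------------------------------
# basic statistics


def test_sine_rms_and_crest_factor():
    x = sine(1.0, fs=256, n=256)  # one full period
    vals = basic_stat_features(x)
    assert vals["rms"] == pytest.approx(math.sqrt(0.5), rel=1e-3)
    assert vals["crest_factor"] == pytest.approx(math.sqrt(2), rel=1e-3)


def test_small_window_arithmetic():
    vals = basic_stat_features(np.array([1.0, 2.0, 3.0, 4.0]))
    assert vals["mean"] == 2.5
    assert vals["variance"] == 1.25
    assert vals["p50"] == 2.5
    assert vals["min"] == 1.0 and vals["max"] == 4.0


def test_gaussian_kurtosis_near_three():
    rng = np.random.default_rng(3)
    kurts = [basic_stat_features(rng.standard_normal(256))["kurtosis"]
             for _ in range(30)]
    assert abs(np.mean(kurts) - 3.0) < 0.8


def test_zero_variance_window_statistics():
    vals = basic_stat_features(np.full(64, 2.0))
    assert vals["crest_factor"] == 0.0
    assert vals["skewness"] == 0.0 and vals["kurtosis"] == 0.0
    assert vals["std"] == 0.0


# ---------------------------------------------------------------------------
# PSD family


def test_pure_alpha_tone_concentrates_alpha_band():
    vals = psd_features(sine(10.0), FS)
    assert vals["alpha_power"] / vals["total_power"] > 0.99


def test_equal_tones_give_equal_band_powers_and_unit_r3():
    x = sine(2.0) + sine(20.0)
    vals = psd_features(x, FS)
    assert vals["delta_power"] == pytest.approx(vals["beta_power"], rel=0.01)
    assert vals["r3"] == pytest.approx(vals["delta_power"] / vals["beta_power"],
                                       rel=0.01)
    assert vals["r3"] == pytest.approx(1.0, rel=0.02)


def test_band_powers_partition_total_power():
    rng = np.random.default_rng(11)
    for _ in range(10):
        x = rng.standard_normal(256)
        vals = psd_features(x, FS)
        bands = sum(vals[f"{b}_power"]
                    for b in ("delta", "theta", "alpha", "beta", "gamma"))
        assert bands == pytest.approx(vals["total_power"], rel=1e-9)


def test_band_power_matches_direct_integration_oracle():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(256)
    vals = psd_features(x, FS)
    assert vals["theta_power"] == pytest.approx(
        oracles.band_power_bruteforce(x, FS, 4, 8), abs=1e-12)
    assert vals["gamma_power"] == pytest.approx(
        oracles.band_power_bruteforce(x, FS, 30, 40, include_upper=True), abs=1e-12)


def test_zero_window_ratios_are_zero():
    vals = psd_features(np.zeros(256), FS)
    assert vals["r1"] == vals["r2"] == vals["r3"] == 0.0


# ---------------------------------------------------------------------------
# frequency family


def test_pure_tone_frequency_statistics():
    vals = frequency_features(sine(10.0), FS)
    assert vals["mean_frequency"] == pytest.approx(10.0, abs=0.01)
    assert vals["median_frequency"] == 10.0
    assert vals["peak_frequency"] == 10.0


def test_symmetric_two_tone_centered_mean_and_zero_skew():
    x = sine(8.0) + sine(12.0, phase=0.4)
    vals = frequency_features(x, FS)
    assert vals["mean_frequency"] == pytest.approx(10.0, abs=0.05)
    assert abs(vals["spectral_skewness"]) < 0.05


def test_bandpassed_noise_median_frequency_in_plausible_range():
    from scipy import signal as sps
    rng = np.random.default_rng(17)
    sos = sps.butter(5, [1, 40], btype="bandpass", fs=FS, output="sos")
    medians = []
    for _ in range(20):
        x = sps.sosfiltfilt(sos, rng.standard_normal(1024))[384:640]
        medians.append(frequency_features(x, FS)["median_frequency"])
    assert 15 <= np.mean(medians) <= 26


def test_all_zero_spectrum_maps_to_zeros():
    vals = frequency_features(np.zeros(256), FS)
    assert all(v == 0.0 for v in vals.values())


# ---------------------------------------------------------------------------
# fractal / complexity family


def test_straight_line_katz_and_zero_crossings():
    x = np.arange(256.0)
    vals = fractal_complexity_features(x, FS)
    assert vals["katz_fd"] == 1.0
    assert vals["zero_crossings"] == 0.0


def test_hjorth_mobility_of_sinusoid_closed_form():
    for f in (5.0, 10.0, 20.0):
        x = sine(f, n=2560)  # long window damps edge effects
        mob, _ = F.hjorth_params(x)
        assert mob == pytest.approx(2 * math.sin(math.pi * f / FS), rel=1e-3)


def test_alternating_window_crossings_and_petrosian():
    x = np.tile([1.0, -1.0], 128)
    vals = fractal_complexity_features(x, FS)
    assert vals["zero_crossings"] == 255.0
    assert vals["petrosian_fd"] == pytest.approx(
        oracles.petrosian_bruteforce(x), abs=1e-12)


def test_dfa_of_white_noise_near_half():
    rng = np.random.default_rng(23)
    alphas = [F.dfa_alpha(rng.standard_normal(1024)) for _ in range(20)]
    assert abs(np.mean(alphas) - 0.5) < 0.1


def test_constant_window_complexity_metrics_zero():
    vals = fractal_complexity_features(np.full(256, 1.0), FS)
    assert all(v == 0.0 for v in vals.values())


# ---------------------------------------------------------------------------
# full bank: structure and invariances

SCALE_INVARIANT = (
    "permutation_entropy", "spectral_entropy", "svd_entropy", "katz_fd",
    "higuchi_fd", "petrosian_fd", "dfa_alpha", "hjorth_mobility",
    "hjorth_complexity", "zero_crossings", "r1", "r2", "r3",
    "max_frequency", "mean_frequency", "median_frequency", "peak_frequency",
    "spectral_skewness", "spectral_kurtosis", "crest_factor", "skewness",
    "kurtosis",
)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), log_alpha=st.floats(-3, 3))
def test_amplitude_scale_invariance(seed, log_alpha):
    """Shape/complexity features ignore positive rescaling of the window."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(128)
    alpha = 10.0 ** log_alpha
    base = dict(zip(FEATURE_NAMES, compute_window_features(x, FS)))
    scaled = dict(zip(FEATURE_NAMES, compute_window_features(alpha * x, FS)))
    for name in SCALE_INVARIANT:
        assert scaled[name] == pytest.approx(base[name], rel=1e-9, abs=1e-9), name


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_permutation_entropy_monotone_invariance(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(100)
    assert F.permutation_entropy(np.exp(x)) == pytest.approx(
        F.permutation_entropy(x), abs=1e-12)
    assert F.permutation_entropy(x ** 3) == pytest.approx(
        F.permutation_entropy(x), abs=1e-12)


def test_feature_names_are_canonical_and_43():
    assert len(FEATURE_NAMES) == 43
    assert len(set(FEATURE_NAMES)) == 43
    window = np.random.default_rng(0).standard_normal(256)
    assert compute_window_features(window, FS).shape == (43,)


def test_feature_cube_shape_and_determinism(mini_cohort):
    rec = mini_cohort[0]
    from eegtf import preprocess_recording
    clean = preprocess_recording(rec)
    cube1 = compute_feature_cube(clean)
    cube2 = compute_feature_cube(clean)
    n_windows = int(clean.duration)
    assert cube1.values.shape == (rec.n_channels, n_windows, 43)
    np.testing.assert_array_equal(cube1.values, cube2.values)
    assert np.all(np.isfinite(cube1.values))


def test_slowing_ratio_and_entropy_separate_groups():
    """AD-like recordings show a larger slowing ratio r3 than control-like."""
    from eegtf import default_profiles, preprocess_recording
    profiles = default_profiles()
    r3_idx = FEATURE_NAMES.index("r3")
    diffs = []
    for seed in range(8):
        cubes = {}
        for name in ("control", "ad"):
            rec = generate_recording(profiles[name], 8.0, 2, seed=seed)
            cubes[name] = compute_feature_cube(preprocess_recording(rec))
        diffs.append(cubes["ad"].values[..., r3_idx].mean()
                     - cubes["control"].values[..., r3_idx].mean())
    assert all(d > 0 for d in diffs)
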