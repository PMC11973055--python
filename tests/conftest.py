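import time

import numpy as np
import pytest

from eegtf import (
    CohortSpec,
    GroupProfile,
    default_profiles,
    generate_cohort,
    recordings_to_vectors,
)


@pytest.fixture(scope="session")
def two_group_profiles():
    """Control-like (200 Hz) and AD-like (256 Hz) default archetypes."""
    profiles = default_profiles()
    return {"control": profiles["control"], "ad": profiles["ad"]}


@pytest.fixture(scope="session")
def balanced_vectors(two_group_profiles):
    """Full-size balanced cohort run through the whole feature pipeline.

    7 control-like + 7 AD-like subjects, 19 channels, 60-s recordings —
    the study-scale configuration.  Built once per session; the elapsed
    wall time of the end-to-end computation is returned alongside the
    compressed vectors.
    """
    spec = CohortSpec(n_per_group=7, duration=60.0, n_channels=19, seed=2024,
                      profiles=two_group_profiles)
    t0 = time.perf_counter()
    recordings = generate_cohort(spec)
    vectors = recordings_to_vectors(recordings)
    elapsed = time.perf_counter() - t0
    return vectors, elapsed


@pytest.fixture(scope="session")
def mini_cohort():
    """Tiny 3-channel, 8-s cohort for fast structural tests."""
    profiles = default_profiles()
    spec = CohortSpec(n_per_group=2, duration=8.0, n_channels=3, seed=7,
                      profiles=profiles)
    return generate_cohort(spec)


@pytest.fixture
def random_windows():
    """50 random short windows for oracle-equivalence checks."""
    rng = np.random.default_rng(1234)
    return [rng.standard_normal(rng.integers(48, 96)) for _ in range(50)]
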