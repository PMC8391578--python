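import numpy as np
import pytest

from eegcv import CohortSpec, ExperimentConfig, cohort_feature_table, generate_cohort
from eegcv.preprocess import CleanSegment


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Two subjects per class, one minute each: enough for shape checks."""
    return CohortSpec(n_per_class={"AD": 2, "CN": 2}, duration_s=60.0, seed=3)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_table(tiny_spec, tiny_cohort):
    cfg = ExperimentConfig(cohort=tiny_spec)
    return cohort_feature_table(tiny_cohort, cfg)


@pytest.fixture()
def noise_segment() -> CleanSegment:
    """20 s of seeded white noise at 250 Hz, two channels."""
    rng = np.random.default_rng(12)
    return CleanSegment(
        subject_id="S1", class_label="CN", fs_hz=250.0,
        channel_names=["ch1", "ch2"], samples=rng.standard_normal((2, 5000)))


def sinusoid_segment(freq_hz: float, fs_hz: float = 250.0, duration_s: float = 20.0,
                     amplitude: float = 1.0) -> CleanSegment:
    t = np.arange(int(duration_s * fs_hz)) / fs_hz
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return CleanSegment(subject_id="S1", class_label="CN", fs_hz=fs_hz,
                        channel_names=["ch1"], samples=x[None, :])
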