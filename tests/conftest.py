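import numpy as np
import pytest

from vocims import (
    Cohort,
    CVConfig,
    FeatureTable,
    PeakSpec,
    PreprocessConfig,
    RipSpec,
    SimulationConfig,
    Spectrum,
    simulate_cohort,
)


def make_spectrum(values, sample_id="s"):
    """Spectrum with integer axes 0..n-1 (convenient for window arithmetic)."""
    values = np.asarray(values, dtype=float)
    return Spectrum(
        values,
        np.arange(values.shape[0], dtype=float),
        np.arange(values.shape[1], dtype=float),
        sample_id=sample_id,
    )


def noise_feature_table(n_samples, n_retention, n_drift, seed):
    """Pure-noise table: features carry no class information whatsoever."""
    rng = np.random.default_rng(seed)
    values = np.abs(rng.normal(size=(n_samples, n_retention * n_drift)))
    labels = np.zeros(n_samples, dtype=int)
    labels[n_samples // 2 :] = 1
    return FeatureTable(
        values,
        np.linspace(0.0, 100.0, n_retention),
        np.linspace(0.0, 100.0, n_drift),
        [f"s{i:03d}" for i in range(n_samples)],
        labels,
    )


@pytest.fixture
def small_cohort():
    """Deterministic 12-sample cohort with one strongly planted peak."""
    peaks = (
        PeakSpec(0.2, 0.4, 0.05, 0.04, 10.0, class_effect=3.0),
        PeakSpec(0.4, 0.1, 0.05, 0.04, 8.0, class_effect=1.0),
    )
    config = SimulationConfig(
        n_class0=6,
        n_class1=6,
        n_retention=16,
        n_drift=16,
        peaks=peaks,
        rip=RipSpec(),
        noise_sd=0.2,
        baseline=1.0,
        seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture
def small_preprocess_config():
    return PreprocessConfig(
        crop_window=(0.0, 80.0, 0.0, 80.0),
        rip_line_retention=(70.0, 80.0),
        threshold=0.3,
    )
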