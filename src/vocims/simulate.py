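"""Synthetic GC-IMS cohorts with planted class structure.

Real GC-IMS output has three dominant components: a constant low background,
the reactant ion peak (RIP) — an intense vertical line at a fixed drift
position spanning every retention time — and analyte (VOC) signals appearing
as localised 2D blobs, concentrated at low retention and low drift times.
The generator reproduces exactly that geometry:

    intensity = baseline
              + RIP Gaussian column profile (per-sample amplitude jitter)
              + sum of separable 2D Gaussian peaks
              + additive Gaussian noise, clamped at zero.

A peak's amplitude is multiplied by ``class_effect`` for class-1 samples and
by a per-sample lognormal factor (mean 1, coefficient of variation
``amplitude_cv``), so a subset of peaks carries a known between-class
intensity difference that downstream feature selection should rediscover.

Effect sizes for real faecal VOCs are unknown; the defaults here are study
conditions chosen for the simulation, not measured values (see the methods
note).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .spectra import Cohort, Spectrum

__all__ = [
    "PeakSpec",
    "RipSpec",
    "SimulationConfig",
    "default_config",
    "simulate_spectrum",
    "simulate_cohort",
]

AXIS_MAX = 100.0  # axes are normalised to 0-100


@dataclass(frozen=True)
class PeakSpec:
    """One VOC peak: a separable 2D Gaussian.

    Centers and widths are fractions of the (0-100) axes; ``class_effect`` is
    the multiplicative class-1/class-0 intensity ratio (1.0 = carries no class
    information); ``amplitude_cv`` the lognormal per-sample coefficient of
    variation of the amplitude.
    """

    retention_center: float
    drift_center: float
    retention_width: float = 0.02
    drift_width: float = 0.015
    base_amplitude: float = 10.0
    class_effect: float = 1.0
    amplitude_cv: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.retention_center <= 1.0 and 0.0 <= self.drift_center <= 1.0):
            raise ConfigError("peak centers must lie in [0, 1]")
        if self.retention_width <= 0 or self.drift_width <= 0:
            raise ConfigError("peak widths must be positive")
        if self.base_amplitude <= 0:
            raise ConfigError("base_amplitude must be positive")
        if self.class_effect <= 0:
            raise ConfigError("class_effect must be positive")
        if self.amplitude_cv < 0:
            raise ConfigError("amplitude_cv must be non-negative")

    @property
    def is_discriminative(self) -> bool:
        return self.class_effect != 1.0


@dataclass(frozen=True)
class RipSpec:
    """The reactant ion peak: a Gaussian column profile at a fixed drift
    position, spanning all retention rows."""

    drift_position: float = 0.2
    drift_width: float = 0.01
    amplitude: float = 200.0
    per_sample_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drift_position <= 1.0:
            raise ConfigError("RIP drift_position must lie in [0, 1]")
        if self.drift_width <= 0:
            raise ConfigError("RIP drift_width must be positive")
        if self.amplitude < 0 or self.per_sample_jitter < 0:
            raise ConfigError("RIP amplitude and jitter must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings.

    Default cohort sizes (75 vs 109) mirror a two-group case/control design
    typical of paediatric IBD volatolomics studies.
    """

    n_class0: int = 75
    n_class1: int = 109
    n_retention: int = 64
    n_drift: int = 64
    peaks: tuple[PeakSpec, ...] = ()
    rip: RipSpec = field(default_factory=RipSpec)
    noise_sd: float = 0.0
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_class0 < 2 or self.n_class1 < 2:
            raise ConfigError("each class needs at least 2 samples")
        if self.n_retention < 8 or self.n_drift < 8:
            raise ConfigError("grid sizes must be at least 8")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        object.__setattr__(self, "peaks", tuple(self.peaks))


def default_config(
    n_class0: int = 75,
    n_class1: int = 109,
    n_retention: int = 64,
    n_drift: int = 64,
    n_peaks: int = 10,
    n_discriminative: int = 3,
    class_effect: float = 2.0,
    amplitude_cv: float = 0.3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SimulationConfig:
    """A ready-to-run condition: peaks placed randomly in the lower-left
    quadrant (low retention, low drift — where VOC signal concentrates),
    the first ``n_discriminative`` of them carrying ``class_effect``.

    Placement is seeded and avoids the RIP drift column.
    """
    rng = np.random.default_rng(seed)
    rip = RipSpec()
    peaks = []
    for i in range(n_peaks):
        while True:
            rc = rng.uniform(0.05, 0.5)
            dc = rng.uniform(0.05, 0.5)
            if abs(dc - rip.drift_position) > 5 * rip.drift_width:
                break
        peaks.append(
            PeakSpec(
                retention_center=rc,
                drift_center=dc,
                retention_width=rng.uniform(0.015, 0.03),
                drift_width=rng.uniform(0.01, 0.02),
                base_amplitude=rng.uniform(5.0, 20.0),
                class_effect=class_effect if i < n_discriminative else 1.0,
                amplitude_cv=amplitude_cv,
            )
        )
    return SimulationConfig(
        n_class0=n_class0,
        n_class1=n_class1,
        n_retention=n_retention,
        n_drift=n_drift,
        peaks=tuple(peaks),
        rip=rip,
        noise_sd=noise_sd,
        baseline=1.0,
        seed=seed,
    )


def _axes(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.linspace(0.0, AXIS_MAX, config.n_retention),
        np.linspace(0.0, AXIS_MAX, config.n_drift),
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0.0:
        return 1.0
    sigma2 = np.log1p(cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2)))


def simulate_spectrum(
    config: SimulationConfig,
    label: int,
    rng: np.random.Generator,
    sample_id: str = "",
) -> Spectrum:
    """Draw one spectrum for a sample of the given class.

    Intensity model (before clamping at zero):
    ``baseline + RIP column profile + Σ_k amp_k · class_effect_k^label ·
    lognormal_k + N(0, noise_sd)`` evaluated on the configured grid.
    """
    if label not in (0, 1):
        raise ConfigError(f"label must be 0 or 1, got {label!r}")
    retention, drift = _axes(config)
    img = np.full((config.n_retention, config.n_drift), config.baseline, dtype=float)

    rip = config.rip
    if rip.amplitude > 0:
        jitter = _lognormal_factor(rng, rip.per_sample_jitter)
        d0 = rip.drift_position * AXIS_MAX
        sd = rip.drift_width * AXIS_MAX
        profile = rip.amplitude * jitter * np.exp(-0.5 * ((drift - d0) / sd) ** 2)
        img += profile[np.newaxis, :]  # same profile on every retention row

    for peak in config.peaks:
        amp = peak.base_amplitude * (peak.class_effect ** label)
        amp *= _lognormal_factor(rng, peak.amplitude_cv)
        r0 = peak.retention_center * AXIS_MAX
        d0 = peak.drift_center * AXIS_MAX
        sr = peak.retention_width * AXIS_MAX
        sd = peak.drift_width * AXIS_MAX
        gr = np.exp(-0.5 * ((retention - r0) / sr) ** 2)
        gd = np.exp(-0.5 * ((drift - d0) / sd) ** 2)
        img += amp * np.outer(gr, gd)

    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)

    np.clip(img, 0.0, None, out=img)
    return Spectrum(img, retention, drift, sample_id=sample_id)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a full two-class cohort, class-0 samples first.

    Fully reproducible: each sample gets an independent child stream of the
    cohort seed, so the draw for sample *i* does not depend on how many
    samples precede it.
    """
    n = config.n_class0 + config.n_class1
    labels = np.concatenate(
        [np.zeros(config.n_class0, dtype=int), np.ones(config.n_class1, dtype=int)]
    )
    streams = np.random.SeedSequence(config.seed).spawn(n)
    spectra = [
        simulate_spectrum(
            config,
            int(labels[i]),
            np.random.default_rng(streams[i]),
            sample_id=f"s{i:04d}",
        )
        for i in range(n)
    ]
    truth = [
        (p.retention_center * AXIS_MAX, p.drift_center * AXIS_MAX, p.class_effect)
        for p in config.peaks
        if p.is_discriminative
    ]
    return Cohort(spectra, labels, truth)


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The same condition with every class effect removed (for null runs)."""
    peaks = tuple(replace(p, class_effect=1.0) for p in config.peaks)
    return replace(config, peaks=peaks)
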