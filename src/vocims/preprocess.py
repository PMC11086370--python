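"""Dimensionality-reduction chain applied identically to every sample.

Three stages, in fixed order:

1. **crop** — keep the axis window that contains the chemical signal
   (VOC peaks concentrate at low retention/drift, so most of the map is
   empty background).
2. **RIP subtraction** — the reactant ion peak is a vertical line at fixed
   drift position present in every sample; a drift-profile "line" is taken
   from retention rows known to contain no analyte signal and subtracted
   from every row.
3. **static threshold** — intensities strictly below a small constant are
   zeroed to suppress residual background noise.

The same crop window, RIP-line window and threshold are used for all samples
of a cohort; the settings actually applied are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import CohortError, ConfigError, ShapeError, WindowError
from .spectra import Cohort, Spectrum

__all__ = [
    "PreprocessConfig",
    "crop",
    "extract_rip_line",
    "subtract_rip",
    "apply_threshold",
    "suggest_threshold",
    "preprocess_cohort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Shared settings for one cohort.

    ``crop_window`` is ``(retention_lo, retention_hi, drift_lo, drift_hi)``
    in axis units, half-open on the high ends.  ``rip_line_retention`` is the
    retention window (inside the crop) whose rows are averaged into the RIP
    line; it must contain no analyte signal.  ``rip_mode`` selects whether
    the line is recomputed per sample (RIP amplitude varies per injection)
    or taken once from the cohort mean spectrum.  ``threshold`` may be the
    string ``"auto"``: 3x the median positive intensity after RIP
    subtraction, an implementation default, not a measured value.
    """

    crop_window: tuple[float, float, float, float]
    rip_line_retention: tuple[float, float]
    rip_mode: str = "per_sample"
    threshold: float | str = "auto"

    def __post_init__(self) -> None:
        rlo, rhi, dlo, dhi = self.crop_window
        if not (rlo < rhi and dlo < dhi):
            raise ConfigError("crop window must be non-empty")
        wlo, whi = self.rip_line_retention
        if not (rlo <= wlo < whi <= rhi):
            raise ConfigError("rip_line_retention must lie inside the crop window")
        if self.rip_mode not in ("per_sample", "global"):
            raise ConfigError(f"unknown rip_mode {self.rip_mode!r}")
        if not isinstance(self.threshold, str) and self.threshold < 0:
            raise ConfigError("threshold must be non-negative")
        if isinstance(self.threshold, str) and self.threshold != "auto":
            raise ConfigError(f"unknown threshold {self.threshold!r}")


def crop(spectrum: Spectrum, window: tuple[float, float, float, float]) -> Spectrum:
    """Sub-spectrum whose axis coordinates fall in [lo, hi) on each axis.

    Half-open on the high ends so adjacent windows tile without overlap.
    The input is not modified.
    """
    rlo, rhi, dlo, dhi = window
    rmask = (spectrum.retention_axis >= rlo) & (spectrum.retention_axis < rhi)
    dmask = (spectrum.drift_axis >= dlo) & (spectrum.drift_axis < dhi)
    if not rmask.any() or not dmask.any():
        raise WindowError(f"crop window {window} selects no pixels")
    return Spectrum(
        spectrum.intensities[np.ix_(rmask, dmask)].copy(),
        spectrum.retention_axis[rmask].copy(),
        spectrum.drift_axis[dmask].copy(),
        spectrum.sample_id,
    )


def extract_rip_line(
    spectrum: Spectrum, retention_window: tuple[float, float]
) -> np.ndarray:
    """Element-wise mean over the retention rows in [lo, hi): one intensity
    per drift column."""
    lo, hi = retention_window
    rmask = (spectrum.retention_axis >= lo) & (spectrum.retention_axis < hi)
    if not rmask.any():
        raise WindowError(f"retention window {retention_window} selects no rows")
    return spectrum.intensities[rmask].mean(axis=0)


def subtract_rip(spectrum: Spectrum, line: np.ndarray) -> Spectrum:
    """Subtract the drift-profile line from every retention row, clamping
    negative results to zero (detectors report non-negative counts)."""
    line = np.asarray(line, dtype=float)
    if line.shape != (spectrum.drift_axis.size,):
        raise ShapeError(
            f"line length {line.size} != drift dimension {spectrum.drift_axis.size}"
        )
    out = np.clip(spectrum.intensities - line[np.newaxis, :], 0.0, None)
    return Spectrum(
        out, spectrum.retention_axis.copy(), spectrum.drift_axis.copy(), spectrum.sample_id
    )


def apply_threshold(spectrum: Spectrum, tau: float) -> Spectrum:
    """Zero out intensities strictly below tau; values equal to tau survive."""
    if tau < 0:
        raise ConfigError("threshold must be non-negative")
    out = spectrum.intensities.copy()
    out[out < tau] = 0.0
    return Spectrum(
        out, spectrum.retention_axis.copy(), spectrum.drift_axis.copy(), spectrum.sample_id
    )


def suggest_threshold(spectra: list[Spectrum]) -> float:
    """3x the median of the positive intensities across the given spectra.

    Used for ``threshold="auto"`` after RIP subtraction; with most of the map
    clamped to zero, the median positive intensity tracks the noise floor.
    """
    positive = np.concatenate(
        [s.intensities[s.intensities > 0].ravel() for s in spectra]
    )
    if positive.size == 0:
        return 0.0
    return 3.0 * float(np.median(positive))


def preprocess_cohort(cohort: Cohort, config: PreprocessConfig) -> Cohort:
    """Crop, subtract the RIP line, threshold — one config for every sample.

    ``per_sample`` mode recomputes the line from each sample's own rows in
    the shared retention window; ``global`` mode takes it once from the
    element-wise mean spectrum of the cohort.
    """
    cohort.validate_axes()
    cropped = [crop(s, config.crop_window) for s in cohort.spectra]

    if config.rip_mode == "global":
        mean = Spectrum(
            np.mean([s.intensities for s in cropped], axis=0),
            cropped[0].retention_axis,
            cropped[0].drift_axis,
            "cohort-mean",
        )
        line = extract_rip_line(mean, config.rip_line_retention)
        subtracted = [subtract_rip(s, line) for s in cropped]
    else:
        subtracted = [
            subtract_rip(s, extract_rip_line(s, config.rip_line_retention))
            for s in cropped
        ]

    tau = (
        suggest_threshold(subtracted)
        if config.threshold == "auto"
        else float(config.threshold)
    )
    out = [apply_threshold(s, tau) for s in subtracted]

    logger.info(
        "preprocess: crop_window=%s rip_line_retention=%s rip_mode=%s threshold=%g "
        "(applied uniformly to %d samples)",
        config.crop_window,
        config.rip_line_retention,
        config.rip_mode,
        tau,
        len(out),
    )
    return Cohort(out, cohort.labels.copy(), list(cohort.truth))
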