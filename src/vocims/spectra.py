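"""Core in-memory containers: a single GC-IMS spectrum and a labelled cohort.

A GC-IMS measurement is a dense 2D intensity map: rows index gas-chromatography
retention time, columns index ion-mobility drift time.  Axes are stored in
normalised units (0-100) so spectra from different simulated "instruments" are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CohortError, ShapeError

__all__ = ["Spectrum", "Cohort"]


@dataclass
class Spectrum:
    """One sample's intensity map.

    Parameters
    ----------
    intensities
        Non-negative matrix, shape ``(n_retention, n_drift)``.
    retention_axis, drift_axis
        Strictly increasing coordinate vectors in normalised units (0-100).
    sample_id
        Identifier carried through preprocessing and into feature tables.
    """

    intensities: np.ndarray
    retention_axis: np.ndarray
    drift_axis: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.retention_axis = np.asarray(self.retention_axis, dtype=float)
        self.drift_axis = np.asarray(self.drift_axis, dtype=float)
        if self.intensities.ndim != 2:
            raise ShapeError("intensities must be a 2D matrix")
        nr, nd = self.intensities.shape
        if self.retention_axis.shape != (nr,) or self.drift_axis.shape != (nd,):
            raise ShapeError(
                f"axis lengths ({self.retention_axis.size}, {self.drift_axis.size}) "
                f"do not match matrix shape {self.intensities.shape}"
            )
        for name, ax in (("retention", self.retention_axis), ("drift", self.drift_axis)):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ShapeError(f"{name} axis must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.intensities.copy(),
            self.retention_axis.copy(),
            self.drift_axis.copy(),
            self.sample_id,
        )

    def same_axes(self, other: "Spectrum") -> bool:
        return (
            self.retention_axis.shape == other.retention_axis.shape
            and self.drift_axis.shape == other.drift_axis.shape
            and np.array_equal(self.retention_axis, other.retention_axis)
            and np.array_equal(self.drift_axis, other.drift_axis)
        )


@dataclass
class Cohort:
    """Ordered spectra with binary class labels and (for simulations) the
    planted ground truth.

    ``truth`` lists the discriminative peaks (class intensity ratio != 1) as
    ``(retention_center, drift_center, class_effect)`` in axis units, so tests
    can ask whether the pipeline rediscovers them.
    """

    spectra: list[Spectrum]
    labels: np.ndarray
    truth: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.spectra) != self.labels.size:
            raise CohortError(
                f"{len(self.spectra)} spectra but {self.labels.size} labels"
            )
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise CohortError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.spectra)

    def validate_axes(self) -> None:
        """Raise if the spectra do not share identical axes."""
        ref = self.spectra[0]
        for s in self.spectra[1:]:
            if not ref.same_axes(s):
                raise CohortError(
                    f"sample {s.sample_id!r} has axes differing from "
                    f"{ref.sample_id!r}"
                )
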