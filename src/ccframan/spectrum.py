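"""In-memory containers for Raman spectra.

A :class:`RamanSpectrum` is a single acquisition: a strictly increasing
wavenumber axis (Raman shift, cm^-1) and an intensity vector in arbitrary
counts, plus sample metadata. An :class:`AverageSpectrum` is the element-wise
mean and population standard deviation of a set of spectra sharing one axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AlignmentError, DataError

__all__ = ["RamanSpectrum", "AverageSpectrum"]


def _as_float_array(values) -> np.ndarray:
    return np.asarray(values, dtype=float)


@dataclass
class RamanSpectrum:
    """One Raman acquisition.

    Parameters
    ----------
    shifts
        Raman shift axis in cm^-1, strictly increasing.
    intensities
        Intensity in arbitrary counts; same length as ``shifts``, all finite.
    sample_id, group_id
        Free-text sample / group labels.
    replicate_index
        Technical replicate number within the sample (>= 0).
    """

    shifts: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    group_id: str = ""
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.shifts = _as_float_array(self.shifts)
        self.intensities = _as_float_array(self.intensities)
        if self.shifts.ndim != 1 or self.intensities.ndim != 1:
            raise DataError("shifts and intensities must be 1-D")
        if len(self.shifts) != len(self.intensities):
            raise DataError(
                f"axis length {len(self.shifts)} != intensity length "
                f"{len(self.intensities)}"
            )
        if len(self.shifts) and not np.all(np.diff(self.shifts) > 0):
            raise DataError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise DataError("intensities contain non-finite values")
        if self.replicate_index < 0:
            raise DataError("replicate_index must be >= 0")

    def __len__(self) -> int:
        return len(self.shifts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RamanSpectrum):
            return NotImplemented
        return (
            np.array_equal(self.shifts, other.shifts)
            and np.array_equal(self.intensities, other.intensities)
            and self.sample_id == other.sample_id
            and self.group_id == other.group_id
            and self.replicate_index == other.replicate_index
        )

    def with_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        """Copy of this spectrum with a new intensity vector, metadata kept."""
        return replace(self, intensities=_as_float_array(intensities))

    def resample(self, shifts: np.ndarray) -> "RamanSpectrum":
        """Linear interpolation onto a new axis.

        Resampling is never applied implicitly; axis mismatches raise
        :class:`~ccframan.errors.AlignmentError` unless the caller opts in
        through this method.
        """
        shifts = _as_float_array(shifts)
        new = np.interp(shifts, self.shifts, self.intensities)
        return RamanSpectrum(
            shifts=shifts,
            intensities=new,
            sample_id=self.sample_id,
            group_id=self.group_id,
            replicate_index=self.replicate_index,
        )


def require_common_axis(spectra) -> np.ndarray:
    """Return the shared axis of *spectra* or raise :class:`AlignmentError`."""
    spectra = list(spectra)
    if not spectra:
        raise AlignmentError("no spectra given")
    axis = spectra[0].shifts
    for s in spectra[1:]:
        if not np.array_equal(s.shifts, axis):
            raise AlignmentError(
                f"spectrum {s.sample_id!r} (replicate {s.replicate_index}) is "
                "on a different wavenumber axis; resample explicitly first"
            )
    return axis


@dataclass
class AverageSpectrum:
    """Element-wise mean and population SD of n spectra on a common axis."""

    shifts: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int
    group_id: str = ""

    def __post_init__(self) -> None:
        self.shifts = _as_float_array(self.shifts)
        self.mean = _as_float_array(self.mean)
        self.sd = _as_float_array(self.sd)
        if not (len(self.shifts) == len(self.mean) == len(self.sd)):
            raise DataError("shifts, mean and sd must have equal length")
        if np.any(self.sd < 0):
            raise DataError("sd must be elementwise non-negative")
        if self.n < 1:
            raise DataError("n must be >= 1")

    def __eq__(self, other) -> bool:
        if not isinstance(other, AverageSpectrum):
            return NotImplemented
        return (
            np.array_equal(self.shifts, other.shifts)
            and np.array_equal(self.mean, other.mean)
            and np.array_equal(self.sd, other.sd)
            and self.n == other.n
            and self.group_id == other.group_id
        )
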