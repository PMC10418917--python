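"""Synthetic Raman spectra of ccfDNA sample groups.

The generator emulates the statistical structure of dried-droplet ccfDNA
Raman acquisitions so that the downstream pipeline (despike, baseline
subtraction, averaging, peak calling) is testable without instrument data:

* pseudo-Voigt bands at the reference windows' representative positions,
* a smooth polynomial fluorescence-like background,
* i.i.d. additive Gaussian channel noise,
* sporadic single-channel cosmic-ray spikes (Poisson count, uniform height),
* a subjects x technical-replicates layout in which each subject's band
  centers are jittered once and shared across that subject's replicates.

Defaults follow the study design the pipeline targets: 300-3100 cm^-1 axis at
1 cm^-1 steps, 3 subjects x 5 replicates per group.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial import Polynomial

from .errors import ConfigurationError
from .reference import PeakWindow, ReferenceError_
from .spectrum import RamanSpectrum

__all__ = [
    "SyntheticPeak",
    "SyntheticGroupConfig",
    "pseudo_voigt",
    "simulate_spectrum",
    "simulate_group",
    "config_from_reference",
    "DEFAULT_BASELINE_COEFFS",
]

_AXIS_MIN, _AXIS_MAX = 300.0, 3100.0

# Gently decreasing fluorescence-like background: 800 counts at 300 cm^-1
# falling to 350 at 3100 cm^-1 (quadratic in the normalised axis), expressed
# in ascending powers of the raw wavenumber.
DEFAULT_BASELINE_COEFFS: np.ndarray = (
    Polynomial([800.0, -700.0, 250.0], domain=[_AXIS_MIN, _AXIS_MAX], window=[0.0, 1.0])
    .convert(kind=Polynomial)
    .coef
)


def pseudo_voigt(
    x: np.ndarray, center: float, amplitude: float, fwhm: float, shape_mix: float
) -> np.ndarray:
    """Height-normalised pseudo-Voigt profile.

    ``shape_mix`` blends a Gaussian (0) into a Lorentzian (1); both components
    share the same FWHM and unit peak height, so ``amplitude`` is the apex
    intensity.
    """
    d = np.asarray(x, dtype=float) - center
    gauss = np.exp(-4.0 * math.log(2.0) * d * d / (fwhm * fwhm))
    lorentz = 1.0 / (1.0 + 4.0 * d * d / (fwhm * fwhm))
    return amplitude * ((1.0 - shape_mix) * gauss + shape_mix * lorentz)


@dataclass(frozen=True)
class SyntheticPeak:
    """One synthetic Raman band (pseudo-Voigt)."""

    center: float
    amplitude: float
    fwhm: float
    shape_mix: float = 0.5

    def __post_init__(self) -> None:
        if not (_AXIS_MIN <= self.center <= _AXIS_MAX):
            raise ConfigurationError(
                f"peak center {self.center} outside [{_AXIS_MIN}, {_AXIS_MAX}] cm^-1"
            )
        if self.amplitude <= 0:
            raise ConfigurationError("peak amplitude must be > 0")
        if self.fwhm <= 0:
            raise ConfigurationError("peak fwhm must be > 0")
        if not (0.0 <= self.shape_mix <= 1.0):
            raise ConfigurationError("shape_mix must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticGroupConfig:
    """Generative description of one sample group's spectra.

    ``noise_sigma`` defaults to 5 counts, giving SNR around 20 for a median
    band of ~100 counts. ``subject_jitter_sigma`` is the inter-subject scatter
    of band centers (cm^-1), drawn once per subject and shared across that
    subject's technical replicates.
    """

    group_id: str = "synthetic"
    peaks: tuple[SyntheticPeak, ...] = ()
    baseline_coeffs: tuple[float, ...] = tuple(DEFAULT_BASELINE_COEFFS)
    noise_sigma: float = 5.0
    spike_rate: float = 1.0
    spike_amplitude_range: tuple[float, float] = (500.0, 2000.0)
    n_subjects: int = 3
    n_replicates: int = 5
    subject_jitter_sigma: float = 1.5
    axis_start: float = _AXIS_MIN
    axis_stop: float = _AXIS_MAX
    axis_step: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        object.__setattr__(self, "baseline_coeffs", tuple(self.baseline_coeffs))
        if self.axis_start >= self.axis_stop:
            raise ConfigurationError("axis_start must be < axis_stop")
        if self.axis_step <= 0:
            raise ConfigurationError("axis_step must be > 0")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.spike_rate < 0:
            raise ConfigurationError("spike_rate must be >= 0")
        lo, hi = self.spike_amplitude_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("spike_amplitude_range must be 0 <= lo <= hi")
        if self.n_subjects < 1 or self.n_replicates < 1:
            raise ConfigurationError("subject and replicate counts must be >= 1")
        if self.subject_jitter_sigma < 0:
            raise ConfigurationError("subject_jitter_sigma must be >= 0")

    def axis(self) -> np.ndarray:
        """Wavenumber axis covering [axis_start, axis_stop] at axis_step."""
        n = int(round((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)


def _subject_center_offsets(
    config: SyntheticGroupConfig, subject_index: int, seed: int
) -> np.ndarray:
    """Per-subject band-center jitter, shared across the subject's replicates."""
    rng = np.random.default_rng([seed, subject_index, 1])
    if config.subject_jitter_sigma == 0 or not config.peaks:
        return np.zeros(len(config.peaks))
    return rng.normal(0.0, config.subject_jitter_sigma, size=len(config.peaks))


def simulate_spectrum(
    config: SyntheticGroupConfig,
    subject_index: int,
    replicate_index: int,
    seed: int,
    return_components: bool = False,
):
    """Simulate one acquisition for (subject, replicate).

    The random stream is derived deterministically from
    ``(seed, subject_index, replicate_index)``; identical arguments give
    bitwise-identical spectra.

    With ``return_components=True`` a ``(spectrum, components)`` tuple is
    returned, where ``components`` retains the noiseless band sum, the true
    baseline, the noise vector, the pre-spike spectrum and the injected spike
    channels/amplitudes — ground truth for validating despiking and baseline
    recovery.
    """
    if seed < 0:
        raise ConfigurationError("seed must be a non-negative integer")
    if subject_index < 0 or replicate_index < 0:
        raise ConfigurationError("subject and replicate indices must be >= 0")
    x = config.axis()
    offsets = _subject_center_offsets(config, subject_index, seed)
    peak_sum = np.zeros_like(x)
    for pk, off in zip(config.peaks, offsets):
        peak_sum += pseudo_voigt(x, pk.center + off, pk.amplitude, pk.fwhm, pk.shape_mix)
    baseline = np.polynomial.polynomial.polyval(x, np.asarray(config.baseline_coeffs))
    baseline = np.broadcast_to(baseline, x.shape).astype(float)

    rng = np.random.default_rng([seed, subject_index, replicate_index, 2])
    noise = (
        rng.normal(0.0, config.noise_sigma, size=x.size)
        if config.noise_sigma > 0
        else np.zeros_like(x)
    )
    pre_spike = peak_sum + baseline + noise

    n_spikes = int(rng.poisson(config.spike_rate)) if config.spike_rate > 0 else 0
    spike_channels = rng.integers(0, x.size, size=n_spikes)
    lo, hi = config.spike_amplitude_range
    spike_amplitudes = rng.uniform(lo, hi, size=n_spikes)
    intensities = pre_spike.copy()
    np.add.at(intensities, spike_channels, spike_amplitudes)

    spectrum = RamanSpectrum(
        shifts=x,
        intensities=intensities,
        sample_id=f"{config.group_id}-s{subject_index}",
        group_id=config.group_id,
        replicate_index=replicate_index,
    )
    if not return_components:
        return spectrum
    components = {
        "peak_sum": peak_sum,
        "baseline": baseline,
        "noise": noise,
        "pre_spike": pre_spike,
        "spike_channels": spike_channels,
        "spike_amplitudes": spike_amplitudes,
        "center_offsets": offsets,
    }
    return spectrum, components


def simulate_group(config: SyntheticGroupConfig, seed: int) -> list[RamanSpectrum]:
    """All n_subjects x n_replicates acquisitions of one group."""
    return [
        simulate_spectrum(config, s, r, seed)
        for s in range(config.n_subjects)
        for r in range(config.n_replicates)
    ]


def _default_amplitude(group_id: str, window_id: str) -> float:
    """Deterministic log-uniform amplitude in [50, 200] counts.

    Seeded from a CRC32 of (group, window) so configs are reproducible
    without an explicit seed argument.
    """
    rng = np.random.default_rng(zlib.crc32(f"{group_id}|{window_id}".encode()))
    return float(np.exp(rng.uniform(math.log(50.0), math.log(200.0))))


def config_from_reference(
    group_id: str,
    reference: Sequence[PeakWindow],
    amplitude_policy: Mapping[str, float] | None = None,
    defaults: SyntheticGroupConfig | None = None,
    fwhm: float = 12.0,
    shape_mix: float = 0.5,
) -> SyntheticGroupConfig:
    """Build a group config with one band per reference window flagged present.

    Bands are centered at each flagged window's representative position.
    ``amplitude_policy`` maps window_id -> apex amplitude (counts); windows it
    omits get a deterministic log-uniform draw in [50, 200].
    """
    known = {g for w in reference for g in w.presence}
    if group_id not in known:
        raise ReferenceError_(
            f"group {group_id!r} is not a presence column of the reference table"
        )
    amplitude_policy = amplitude_policy or {}
    peaks = tuple(
        SyntheticPeak(
            center=w.representative,
            amplitude=float(
                amplitude_policy.get(w.window_id, _default_amplitude(group_id, w.window_id))
            ),
            fwhm=fwhm,
            shape_mix=shape_mix,
        )
        for w in reference
        if w.presence.get(group_id, False)
    )
    base = defaults if defaults is not None else SyntheticGroupConfig()
    return replace(base, group_id=group_id, peaks=peaks)
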