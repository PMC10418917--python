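"""Peak detection on corrected average spectra and reference-window assignment.

Detection is prominence-based relative to a robust noise estimate (the MAD of
the channel-differenced signal), with a matching floor on peak height above
the spectrum median so that isolated noise excursions on long flat segments
— whose prominence contour spans the full noise range — are not called.
Positions are refined to sub-channel precision by three-point parabolic
interpolation around each maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .errors import DataError, ParameterError, ReferenceError_
from .reference import PeakWindow
from .spectrum import AverageSpectrum, RamanSpectrum

__all__ = [
    "DetectedPeak",
    "PeakAssignment",
    "estimate_noise",
    "detect_peaks",
    "assign_peaks",
]


@dataclass(frozen=True)
class DetectedPeak:
    """A called peak: refined position (cm^-1), height above the local
    baseline level, prominence and FWHM (cm^-1)."""

    position: float
    height: float
    prominence: float
    fwhm: float

    def __post_init__(self) -> None:
        if self.prominence <= 0:
            raise DataError("prominence must be > 0")


@dataclass(frozen=True)
class PeakAssignment:
    """A peak matched to a reference window (or explicitly unassigned).

    ``distance`` is the gap between the peak position and the window interval
    (0 when the position lies inside the closed interval).
    """

    peak: DetectedPeak
    window_id: str | None
    distance: float = 0.0

    @property
    def assigned(self) -> bool:
        return self.window_id is not None


def estimate_noise(y: np.ndarray) -> float:
    """Robust channel-noise SD: 1.4826 x MAD of the differenced signal / sqrt(2).

    Differencing removes smooth structure (bands, residual background), so the
    estimate reflects channel noise rather than signal.
    """
    d = np.diff(np.asarray(y, dtype=float))
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _refine_position(shifts: np.ndarray, y: np.ndarray, idx: int) -> float:
    """Sub-channel apex position via a parabola through three points."""
    if idx <= 0 or idx >= len(y) - 1:
        return float(shifts[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(shifts[idx])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    step = 0.5 * (shifts[idx + 1] - shifts[idx - 1])
    return float(shifts[idx] + delta * step)


def detect_peaks(
    avg: AverageSpectrum | RamanSpectrum,
    min_prominence_snr: float = 5.0,
    min_separation: float = 8.0,
) -> list[DetectedPeak]:
    """Call peaks in a baseline-corrected (average) spectrum.

    Local maxima are kept when their prominence and their height above the
    spectrum median both reach ``min_prominence_snr`` times the robust noise
    estimate, and maxima are separated by at least ``min_separation`` cm^-1.
    Returned peaks are sorted by position.
    """
    if min_prominence_snr <= 0:
        raise ParameterError("min_prominence_snr must be > 0")
    if min_separation < 0:
        raise ParameterError("min_separation must be >= 0")
    if isinstance(avg, AverageSpectrum):
        shifts, y = avg.shifts, avg.mean
    else:
        shifts, y = avg.shifts, avg.intensities
    if not np.all(np.isfinite(y)):
        raise DataError("spectrum contains non-finite intensities")
    if y.size < 3:
        return []
    step = float(np.median(np.diff(shifts)))
    noise = estimate_noise(y)
    # Floor keeps thresholds meaningful on noise-free synthetic input.
    scale = max(noise, 1e-12 * max(1.0, float(np.max(np.abs(y)))))
    threshold = min_prominence_snr * scale
    level = float(np.median(y))
    distance = max(1, int(round(min_separation / step)))
    idx, props = find_peaks(
        y, prominence=threshold, distance=distance, height=level + threshold
    )
    if idx.size == 0:
        return []
    widths = peak_widths(y, idx, rel_height=0.5)[0] * step
    peaks = [
        DetectedPeak(
            position=_refine_position(shifts, y, i),
            height=float(y[i] - level),
            prominence=float(p),
            fwhm=float(w),
        )
        for i, p, w in zip(idx, props["prominences"], widths)
    ]
    return sorted(peaks, key=lambda p: p.position)


def assign_peaks(
    peaks: Sequence[DetectedPeak],
    windows: Sequence[PeakWindow],
    tolerance: float = 4.0,
) -> list[PeakAssignment]:
    """Assign each peak to at most one reference window.

    A peak matches the window whose closed interval, expanded by *tolerance*,
    contains its position; among several matches the smallest
    interval-distance wins, ties broken by distance to the window midpoint.
    When several peaks match one window, the most prominent keeps it and the
    others are returned unassigned, so every window receives at most one peak.
    The result is deterministic and sorted by peak position.
    """
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    for w in windows:
        if w.low > w.high:
            raise ReferenceError_(f"window {w.window_id}: low > high")

    provisional: list[tuple[DetectedPeak, PeakWindow | None, float]] = []
    for pk in sorted(peaks, key=lambda p: p.position):
        best: tuple[float, float, PeakWindow] | None = None
        for w in windows:
            d = w.distance(pk.position)
            if d > tolerance:
                continue
            key = (d, abs(pk.position - w.midpoint))
            if best is None or key < (best[0], best[1]):
                best = (key[0], key[1], w)
        if best is None:
            provisional.append((pk, None, 0.0))
        else:
            provisional.append((pk, best[2], best[0]))

    # One peak per window: highest prominence wins, deterministic tie-break.
    winners: dict[str, tuple[DetectedPeak, float]] = {}
    for pk, w, d in provisional:
        if w is None:
            continue
        held = winners.get(w.window_id)
        if held is None or (pk.prominence, -pk.position) > (
            held[0].prominence,
            -held[0].position,
        ):
            winners[w.window_id] = (pk, d)

    out: list[PeakAssignment] = []
    for pk, w, d in provisional:
        if w is not None and winners[w.window_id][0] == pk:
            out.append(PeakAssignment(peak=pk, window_id=w.window_id, distance=d))
        else:
            out.append(PeakAssignment(peak=pk, window_id=None, distance=0.0))
    return out
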