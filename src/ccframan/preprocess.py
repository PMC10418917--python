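"""Spectral preprocessing: despiking, polynomial baseline removal, averaging.

The chain mirrors standard Raman practice for biological samples on a
fluorescent background: cosmic-ray transients are removed first (so they
cannot distort the background fit), an iteratively clipped polynomial
("modified polyfit" / ModPoly) is subtracted per spectrum, and corrected
spectra are averaged with an element-wise population SD. No smoothing or
noise-cancellation filter is ever applied; the averaged output is exactly the
mean of the individually corrected spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import chebyshev
from scipy.ndimage import median_filter

from .errors import AlignmentError, ParameterError
from .spectrum import AverageSpectrum, RamanSpectrum, require_common_axis

__all__ = [
    "BaselineFit",
    "PreprocessParams",
    "despike",
    "fit_baseline",
    "subtract_baseline",
    "average_spectra",
    "preprocess_pipeline",
]


def despike(
    spectrum: RamanSpectrum, window: int = 7, z_threshold: float = 8.0
) -> RamanSpectrum:
    """Remove single-channel cosmic-ray transients.

    A running median of width *window* is subtracted and channels whose
    modified z-score (0.6745 x residual / MAD of the residuals) exceeds
    *z_threshold* are replaced by the running-median value, i.e. a local
    median interpolation. Channels below threshold are returned unchanged,
    bit for bit.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError("despike window must be odd and >= 3")
    if z_threshold <= 0:
        raise ParameterError("z_threshold must be > 0")
    y = spectrum.intensities
    med = median_filter(y, size=window, mode="nearest")
    resid = y - med
    center = np.median(resid)
    mad = np.median(np.abs(resid - center))
    if mad > 0:
        z = 0.6745 * (resid - center) / mad
    else:
        # Degenerate residual distribution (e.g. constant spectrum plus a
        # spike): fall back to the mean absolute residual as scale.
        mean_abs = float(np.mean(np.abs(resid)))
        if mean_abs == 0.0:
            return spectrum.with_intensities(y.copy())
        z = 0.6745 * resid / (mean_abs / 0.7979)
    flagged = np.abs(z) > z_threshold
    if not flagged.any():
        return spectrum.with_intensities(y.copy())
    out = y.copy()
    out[flagged] = med[flagged]
    return spectrum.with_intensities(out)


@dataclass
class BaselineFit:
    """Result of an iterative polynomial background fit.

    ``coefficients`` are ascending powers of the raw wavenumber; ``baseline``
    is the fitted curve evaluated on the spectrum's axis.
    """

    coefficients: np.ndarray
    baseline: np.ndarray
    order: int
    n_iterations: int

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.order < 0:
            raise ParameterError("order must be >= 0")
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")


def fit_baseline(
    spectrum: RamanSpectrum,
    order: int = 5,
    max_iterations: int = 100,
    tolerance: float = 1e-3,
) -> BaselineFit:
    """Estimate a polynomial background by modified polyfit (ModPoly).

    A degree-*order* polynomial is least-squares fitted, intensities above the
    fit are clipped down to it, and the fit is repeated until the relative
    change of the fitted curve falls below *tolerance* or *max_iterations* is
    reached. Peaks are thereby excluded from the fit, so the baseline tracks
    the smooth background and lies at or below band apexes.

    The fit uses a Chebyshev basis on the normalised axis for conditioning;
    reported ``coefficients`` are converted to ascending powers of the raw
    wavenumber.
    """
    if order < 0:
        raise ParameterError("order must be >= 0")
    if max_iterations < 1:
        raise ParameterError("max_iterations must be >= 1")
    if tolerance <= 0:
        raise ParameterError("tolerance must be > 0")
    x, y = spectrum.shifts, spectrum.intensities
    if 2 * (order + 1) > x.size:
        raise ParameterError(
            f"order {order} underdetermined for {x.size} channels"
        )
    lo, hi = float(x[0]), float(x[-1])
    t = 2.0 * (x - lo) / (hi - lo) - 1.0
    design = chebyshev.chebvander(t, order)
    # QR once; only the clipped intensities change between iterations.
    q, r = np.linalg.qr(design)

    work = y.astype(float).copy()
    prev = None
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        coef = np.linalg.solve(r, q.T @ work)
        base = design @ coef
        if prev is not None:
            denom = np.linalg.norm(prev)
            change = np.linalg.norm(base - prev) / denom if denom > 0 else 0.0
            if change < tolerance:
                prev = base
                break
        prev = base
        work = np.minimum(work, base)

    cheb = chebyshev.Chebyshev(coef, domain=[lo, hi])
    power = cheb.convert(kind=np.polynomial.Polynomial)
    return BaselineFit(
        coefficients=power.coef, baseline=prev, order=order, n_iterations=n_iter
    )


def subtract_baseline(spectrum: RamanSpectrum, fit: BaselineFit) -> RamanSpectrum:
    """Element-wise baseline subtraction; sample metadata is preserved."""
    if len(fit.baseline) != len(spectrum):
        raise AlignmentError(
            "baseline was fitted on a different axis than the spectrum"
        )
    return spectrum.with_intensities(spectrum.intensities - fit.baseline)


def average_spectra(spectra, group_id: str | None = None) -> AverageSpectrum:
    """Element-wise mean and population SD of spectra on a common axis."""
    spectra = list(spectra)
    axis = require_common_axis(spectra)
    stack = np.vstack([s.intensities for s in spectra])
    if group_id is None:
        groups = {s.group_id for s in spectra}
        group_id = groups.pop() if len(groups) == 1 else ""
    return AverageSpectrum(
        shifts=axis,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=0),
        n=len(spectra),
        group_id=group_id,
    )


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the preprocessing chain.

    ``despike_enabled`` / ``baseline_enabled`` switch stages off entirely
    (useful for already-corrected input); there is deliberately no smoothing
    option.
    """

    despike_window: int = 7
    despike_z: float = 8.0
    despike_enabled: bool = True
    baseline_order: int = 5
    baseline_max_iterations: int = 100
    baseline_tolerance: float = 1e-3
    baseline_enabled: bool = True


def preprocess_pipeline(
    spectra, params: PreprocessParams | None = None, group_id: str | None = None
) -> AverageSpectrum:
    """Despike, baseline-correct and average a set of raw spectra.

    Each spectrum is corrected individually and the corrected set is averaged;
    no convolution or smoothing is applied at any stage, so the output mean is
    exactly the mean of the individually corrected spectra.
    """
    params = params or PreprocessParams()
    spectra = list(spectra)
    require_common_axis(spectra)
    corrected = []
    for s in spectra:
        if params.despike_enabled:
            s = despike(s, params.despike_window, params.despike_z)
        if params.baseline_enabled:
            fit = fit_baseline(
                s,
                order=params.baseline_order,
                max_iterations=params.baseline_max_iterations,
                tolerance=params.baseline_tolerance,
            )
            s = subtract_baseline(s, fit)
        corrected.append(s)
    return average_spectra(corrected, group_id=group_id)
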