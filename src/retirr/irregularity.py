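"""Frequency-domain irregularity of a retinal contour.

The contour is detrended with a least-squares quadratic; the residual's DFT
moduli are corrected for the arc length of the imaged retina, giving the
irregularity spectrum in mm^2 per mm of retina — i.e. mm.  Bin k holds k
full periods across the 16 mm scan window (bin 1 = 16 mm period, bin 30 ≈
0.53 mm); the regional irregularity is the sum of the first 30 bins.

Window convention: the column grid is endpoint-inclusive (x runs 0..16 mm),
so the final sample duplicates the periodic boundary.  The transform drops
it, making the FFT window exactly (N-1)*dx = 16 mm; integer-bin sinusoids
are then exactly bin-aligned and an amplitude-A sinusoid at bin k yields
bin value A/2 on a flat contour.
"""

from __future__ import annotations

import numpy as np

from .containers import N_SPECTRUM_BINS, IrregularitySpectrum, RetinalContour
from .segment import contour_arc_length

_UNIFORM_RTOL = 1e-6


def detrend_contour(contour: RetinalContour) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares quadratic detrend.

    Returns (poly3, residual): the three polynomial coefficients
    (c0, c1, c2) in increasing order and the per-column residual z - fit in
    mm.  The residual is orthogonal to {1, x, x^2} by construction.
    """
    x, z = contour.x_mm, contour.z_mm
    if len(np.unique(x)) < 3:
        raise ValueError("detrending needs at least 3 distinct x positions")
    poly3 = np.polynomial.polynomial.polyfit(x, z, 2)
    residual = z - np.polynomial.polynomial.polyval(x, poly3)
    return poly3, residual


def _check_uniform(x: np.ndarray) -> float:
    dx = np.diff(x)
    step = dx.mean()
    if np.any(np.abs(dx - step) > _UNIFORM_RTOL * abs(step)):
        raise ValueError(
            "residual is not uniformly sampled in x; resample onto a uniform "
            "grid before computing the spectrum"
        )
    return float(step)


def irregularity_spectrum(
    residual: np.ndarray,
    contour: RetinalContour,
    n_bins: int = N_SPECTRUM_BINS,
    amplitude_factor: float = 1.0,
    curvature: float | None = None,
) -> IrregularitySpectrum:
    """Length-corrected DFT moduli of the residual.

    bin_k = amplitude_factor * |X_k| * dx / L for k = 1..n_bins, where X_k
    is the DFT of the residual over the periodic window (final duplicate
    sample dropped), dx the sample spacing and L the contour arc length.
    ``amplitude_factor`` selects an alternative normalization convention
    (e.g. 2 for one-sided amplitudes) without code change.
    """
    residual = np.asarray(residual, dtype=float)
    dx = _check_uniform(contour.x_mm)
    m = len(residual) - 1  # periodic window: drop the duplicate boundary sample
    if n_bins >= m / 2:
        raise ValueError(f"n_bins={n_bins} at or beyond Nyquist for {m} samples")
    moduli = np.abs(np.fft.rfft(residual[:m]))
    length = contour_arc_length(contour)
    bins = amplitude_factor * moduli[1 : n_bins + 1] * dx / length
    if curvature is None:
        curvature = float(np.polynomial.polynomial.polyfit(contour.x_mm, contour.z_mm, 2)[2])
    return IrregularitySpectrum(
        bins=bins, curvature=curvature, signal_length_mm=length, gaze=contour.gaze
    )


def analyze_contour(
    contour: RetinalContour,
    n_bins: int = N_SPECTRUM_BINS,
    amplitude_factor: float = 1.0,
) -> IrregularitySpectrum:
    """Detrend then transform: the full contour -> spectrum step."""
    poly3, residual = detrend_contour(contour)
    return irregularity_spectrum(
        residual, contour, n_bins=n_bins, amplitude_factor=amplitude_factor,
        curvature=float(poly3[2]),
    )


def regional_irregularity(spectrum: IrregularitySpectrum) -> float:
    """Total regional irregularity: the sum of the 30 bin values, in mm."""
    return float(spectrum.bins.sum())
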