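"""Shared in-memory containers for the OCT irregularity pipeline.

All physical quantities are in millimetres (depths, widths, spectrum bins)
or the units named on the field; pixel indices never leak past the
segmentation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Directions of gaze in the fixed feature order: "up" images the superior
#: retina, "down" the inferior retina.
GAZES = ("up", "down", "temporal", "nasal")

#: Diagnostic groups.  Label coding for the classifier: PVD -> 1, RD -> 2.
DIAGNOSES = ("PVD", "RD", "tear")

N_SPECTRUM_BINS = 30
N_FEATURES = 4 * N_SPECTRUM_BINS + 4 + 2  # bins + curvatures + axial length + age


def feature_names() -> list[str]:
    """Ordered names of the 126 candidate features.

    Positions (1-based): 1-30 up bins, 31-60 down, 61-90 temporal,
    91-120 nasal, 121-124 curvatures in the same gaze order, 125 axial
    length, 126 age.
    """
    names = [f"{g}_bin{k:02d}" for g in GAZES for k in range(1, N_SPECTRUM_BINS + 1)]
    names += [f"curvature_{g}" for g in GAZES]
    names += ["axial_length_mm", "age_years"]
    return names


class LowSignalError(ValueError):
    """Raised when an image has too little dynamic range to segment."""


@dataclass
class BScanImage:
    """A single grayscale OCT B-scan frame with its physical pixel scale.

    ``pixels`` is (n_rows, n_cols), row 0 at the top (shallowest depth),
    intensities in [0, 1].  The horizontal pitch is width_mm/(n_cols - 1):
    column j sits at x = j * dx_mm, spanning [0, width_mm] inclusive.
    """

    pixels: np.ndarray
    width_mm: float = 16.0
    depth_mm: float = 6.0
    gaze: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array (rows x columns)")
        if self.pixels.size == 0:
            raise ValueError("image is empty")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0, 1]; got [{lo}, {hi}]")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def dx_mm(self) -> float:
        return self.width_mm / (self.n_cols - 1)

    @property
    def dz_mm(self) -> float:
        return self.depth_mm / (self.n_rows - 1)


@dataclass
class RetinalContour:
    """Per-column RPE depth trace in mm.

    ``x_mm`` is strictly increasing; ``z_mm`` is depth from the top image
    row.  ``quality`` is the mean shortest-path cost per column when the
    contour came from segmentation (NaN otherwise).  ``truth`` carries the
    generating parameters for synthetic contours (ground-truth amplitudes,
    phases, polynomial, noiseless trace).
    """

    x_mm: np.ndarray
    z_mm: np.ndarray
    gaze: str | None = None
    quality: float = float("nan")
    truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        if self.x_mm.shape != self.z_mm.shape or self.x_mm.ndim != 1:
            raise ValueError("x_mm and z_mm must be 1-D arrays of equal length")
        if len(self.x_mm) >= 2 and not np.all(np.diff(self.x_mm) > 0):
            raise ValueError("x_mm must be strictly increasing")

    def __len__(self) -> int:
        return len(self.x_mm)


@dataclass
class IrregularitySpectrum:
    """First-30-bin length-corrected FFT moduli of a detrended contour.

    ``bins[k-1]`` is bin k: |X_k| * dx / L in mm, where bin k has k full
    periods across the scan window.  ``curvature`` is the x^2 coefficient
    of the detrending quadratic (mm per mm^2); ``signal_length_mm`` the
    contour arc length L used for the correction.
    """

    bins: np.ndarray
    curvature: float
    signal_length_mm: float
    gaze: str | None = None

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (N_SPECTRUM_BINS,):
            raise ValueError(f"expected {N_SPECTRUM_BINS} bins, got {self.bins.shape}")
        if np.any(self.bins < 0):
            raise ValueError("bin moduli must be nonnegative")


@dataclass
class EyeRecord:
    """One study eye: metadata, four regional spectra, fold/split labels."""

    eye_id: str
    diagnosis: str
    axial_length_mm: float
    age_years: float
    spectra: dict[str, IrregularitySpectrum] = field(default_factory=dict)
    fold: int | None = None
    split: str | None = None  # "train", "test" or "tear"
    contour_specs: dict[str, Any] = field(default_factory=dict)
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"diagnosis must be one of {DIAGNOSES}")
        if not (15.0 < self.axial_length_mm < 35.0):
            raise ValueError("axial length outside (15, 35) mm sanity bounds")
        if self.age_years <= 0:
            raise ValueError("age must be positive")

    @property
    def complete(self) -> bool:
        return all(g in self.spectra for g in GAZES)
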