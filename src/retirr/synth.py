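"""Synthetic B-scans and cohorts with known ground truth.

The generator emulates what the analysis assumes about the data: a bright
retinal-pigment-epithelium (RPE) band along a smooth quadratic contour,
perturbed by sinusoidal irregularity at integer bin frequencies of the
16 mm scan window, plus speckle; and cohorts of PVD / retinal-detachment /
retinal-tear eyes whose regional irregularity, axial-length coupling and
group differences carry the structure the downstream statistics and
classifier are meant to find.

Sinusoids are defined at integer bin frequencies over [0, width_mm] so that
the analyzer's FFT bins align exactly with the generated bins.  Bin values
in the analyzer's convention equal amplitude/2, so a configured 30-bin
regional total R corresponds to summed amplitudes of 2R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import DIAGNOSES, GAZES, N_SPECTRUM_BINS, BScanImage, EyeRecord, RetinalContour

logger = logging.getLogger(__name__)

# Imaging geometry of the study device: one composite 16 mm x 6 mm frame,
# 2047 x 3072 px.
DEFAULT_WIDTH_MM = 16.0
DEFAULT_DEPTH_MM = 6.0
DEFAULT_N_COLS = 2047
DEFAULT_N_ROWS = 3072

# Observed demographic ranges; draws are truncated to stay inside them.
AGE_RANGE = (47.0, 84.0)
AXIAL_RANGE = (22.14, 27.27)

#: Default base contour: gently bowed quadratic, apex 3.6 mm deep mid-scan,
#: 2.9 mm at the edges — keeps every contour well inside the 6 mm window.
DEFAULT_BASE_POLY = (2.9, 0.175, -0.0109375)


@dataclass
class ContourSpec:
    """Ground-truth description of one retinal contour.

    ``base_poly`` holds quadratic coefficients (c0, c1, c2) in mm, mm/mm,
    mm/mm^2 so that the smooth trend is c0 + c1*x + c2*x^2.
    ``bin_amplitudes[k]`` is the peak amplitude (mm) of the sinusoid with k
    full periods across the scan width; phases default to 0.
    """

    width_mm: float = DEFAULT_WIDTH_MM
    n_cols: int = DEFAULT_N_COLS
    base_poly: tuple[float, float, float] = DEFAULT_BASE_POLY
    bin_amplitudes: dict[int, float] = field(default_factory=dict)
    bin_phases: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.width_mm <= 0:
            raise ValueError("width_mm must be positive")
        if self.n_cols < 64:
            raise ValueError("n_cols must be at least 64")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for k, a in self.bin_amplitudes.items():
            if k < 1:
                raise ValueError(f"bin index {k} must be >= 1")
            if k >= self.n_cols / 2:
                raise ValueError(
                    f"bin index {k} at or beyond Nyquist ({self.n_cols / 2:g}): aliasing"
                )
            if a < 0:
                raise ValueError(f"amplitude for bin {k} must be nonnegative")


def generate_contour(spec: ContourSpec, seed: int | None = 0, gaze: str | None = None) -> RetinalContour:
    """Realize a contour from its spec; the ground truth rides along.

    z(x_j) = base_poly(x_j) + sum_k A_k sin(2*pi*k*x_j/width + phi_k) + eps_j
    on the endpoint-inclusive column grid x_j = j * width/(n_cols - 1).
    """
    x = np.linspace(0.0, spec.width_mm, spec.n_cols)
    z = np.polynomial.polynomial.polyval(x, spec.base_poly)
    for k, a in sorted(spec.bin_amplitudes.items()):
        phi = spec.bin_phases.get(k, 0.0)
        z = z + a * np.sin(2.0 * np.pi * k * x / spec.width_mm + phi)
    z_true = z.copy()
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        z = z + rng.normal(0.0, spec.noise_sd, size=spec.n_cols)
    truth = {
        "spec": spec,
        "z_true": z_true,
        "bin_amplitudes": dict(spec.bin_amplitudes),
        "bin_phases": {k: spec.bin_phases.get(k, 0.0) for k in spec.bin_amplitudes},
    }
    return RetinalContour(x_mm=x, z_mm=z, gaze=gaze, truth=truth)


def render_bscan(
    contour: RetinalContour,
    band_thickness_mm: float = 0.02,
    contrast: float = 0.85,
    speckle_seed: int | None = None,
    *,
    n_rows: int = DEFAULT_N_ROWS,
    depth_mm: float = DEFAULT_DEPTH_MM,
    speckle_looks: float = 50.0,
    background: float = 0.05,
    margin_mm: float = 0.2,
) -> BScanImage:
    """Render a B-scan: bright RPE band on the contour, dim inner bands above.

    The RPE is a Gaussian band (sigma = thickness/2) centred on the contour,
    so the per-column intensity peak sits at the ground-truth depth.  Two
    dimmer inner-retina bands are placed 0.18 and 0.30 mm above it.  Speckle
    is multiplicative gamma noise with mean 1 and shape ``speckle_looks``
    (the study device averaged 100 B-scan repetitions, so residual speckle
    contrast is low; smaller values give harsher speckle).
    ``speckle_seed=None`` disables speckle.
    """
    z0 = contour.z_mm
    bad = np.nonzero((z0 < margin_mm) | (z0 > depth_mm - margin_mm))[0]
    if bad.size:
        raise ValueError(
            f"contour exits the {depth_mm} mm depth window (margin {margin_mm} mm) "
            f"at column {int(bad[0])} (z = {z0[bad[0]]:.3f} mm)"
        )
    zg = np.linspace(0.0, depth_mm, n_rows)
    u = zg[:, None] - z0[None, :]  # signed offset from the RPE line
    sig = band_thickness_mm / 2.0
    sig_inner = 0.025
    img = background + contrast * (
        np.exp(-0.5 * (u / sig) ** 2)
        + 0.35 * np.exp(-0.5 * ((u + 0.30) / sig_inner) ** 2)
        + 0.22 * np.exp(-0.5 * ((u + 0.18) / sig_inner) ** 2)
    )
    if speckle_seed is not None and speckle_looks:
        rng = np.random.default_rng(speckle_seed)
        img = img * rng.gamma(speckle_looks, 1.0 / speckle_looks, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return BScanImage(
        pixels=img,
        width_mm=float(contour.x_mm[-1] - contour.x_mm[0]),
        depth_mm=depth_mm,
        gaze=contour.gaze,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: 1/k spectral profile over the 30 bins, normalized to sum 1 — smooth
#: anatomical contours put most irregularity in the long spatial periods.
def _bin_profile(n_bins: int = N_SPECTRUM_BINS) -> np.ndarray:
    w = 1.0 / np.arange(1, n_bins + 1)
    return w / w.sum()


@dataclass
class CohortConfig:
    """Study-condition parameters for a synthetic cohort.

    Demographics follow the study's groups (counts, age and axial-length
    means/SDs, truncated to the observed ranges).  Regional irregularity is
    parameterized by the expected 30-bin total per gaze; the inferior
    ("down") retina is the most irregular by default.  Detachment eyes
    receive an additive amplitude shift on the designated bins (superior
    bin 4, temporal bins 23 and 26 by default) with per-(eye, bin) lognormal
    magnitudes of the configured mean; tear eyes get the same shift scaled
    by ``tear_shift_fraction``.  PVD eyes' amplitudes scale with axial
    length via ``axial_irregularity_slope`` (relative change per mm).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"PVD": 88, "RD": 67, "tear": 53}
    )
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"PVD": (65.3, 6.1), "RD": (62.6, 8.5), "tear": (64.1, 6.5)}
    )
    axial_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"PVD": (24.41, 1.10), "RD": (25.10, 1.10), "tear": (24.41, 1.12)}
    )
    # Expected 30-bin totals (mm) per gaze; study regional ordering, scaled
    # to amplitudes that fit the 6 mm imaging window.
    regional_base_irregularity: dict[str, float] = field(
        default_factory=lambda: {"up": 0.604, "down": 0.970, "temporal": 0.606, "nasal": 0.601}
    )
    # Eye-level relative SD of the regional total (study CV per region).
    regional_cv: dict[str, float] = field(
        default_factory=lambda: {"up": 0.52, "down": 0.74, "temporal": 0.41, "nasal": 0.40}
    )
    # Per-(eye, region, bin) multiplicative noise: gamma with this shape,
    # mean 1 (CV = shape**-0.5).
    bin_noise_shape: float = 4.0
    # Fraction of a region's total drawn on a low-frequency profile (bins
    # 2-6) instead of the global 1/k profile.  The inferior retina's excess
    # irregularity comes from wide, shallow localized concavities (several mm
    # across, under 1 mm deep), which are low-bin features with little slope.
    regional_lowfreq_fraction: dict[str, float] = field(
        default_factory=lambda: {"up": 0.0, "down": 0.45, "temporal": 0.0, "nasal": 0.0}
    )
    # Mean bin-value shift (mm) added for detachment eyes at (gaze, bin).
    group_shift: dict[tuple[str, int], float] = field(
        default_factory=lambda: {("up", 4): 0.052, ("temporal", 23): 0.038, ("temporal", 26): 0.034}
    )
    tear_shift_fraction: float = 0.6
    # Fraction of PVD eyes that nonetheless express the anomaly (the at-risk
    # tail of the PVD population); 0 keeps the PVD class clean.
    pvd_shift_fraction: float = 0.0
    # Dispersion of the per-eye shift magnitude: lognormal sigma (mean fixed
    # at the configured shift).  Larger values concentrate the effect in a
    # minority of strongly affected eyes, adding class variance as well as
    # mean — the mechanism behind a U-shaped classifier score.
    group_shift_sigma: float = 2.4
    # Relative amplitude change per mm of axial length, PVD eyes only.
    axial_irregularity_slope: float = 0.07
    missing_scan_rate: float = 0.0
    # Depth budget for the realized irregularity waveform (mm, peak |residual|).
    # The imaging protocol guarantees the retina stays inside the 6 mm scan
    # window; draws whose waveform would leave it are rescaled to fit.
    waveform_budget_mm: float = 2.0
    # Slope budget (mm per mm) for the realized waveform: mid-peripheral
    # retinal relief is shallow, so pathologically steep draws are rescaled
    # the same way.  The base quadratic adds up to ~0.18 on top; the total
    # stays well inside the segmentation step bound (~4 mm/mm).
    slope_budget: float = 2.0
    # Contour realization.
    n_cols: int = DEFAULT_N_COLS
    width_mm: float = DEFAULT_WIDTH_MM
    base_poly: tuple[float, float, float] = DEFAULT_BASE_POLY
    # Sub-resolution positional jitter of the RPE line (mm); the device's
    # optical axial resolution is 6 um, so true white per-column jitter is
    # well below a pixel.
    contour_noise_sd: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in DIAGNOSES:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("group counts must be nonnegative")
        for d in (self.age_mean_sd, self.axial_mean_sd):
            for _, sd in d.values():
                if sd < 0:
                    raise ValueError("SDs must be nonnegative")
        base = self.regional_base_irregularity
        others = [base[g] for g in ("up", "temporal", "nasal")]
        if not all(base["down"] > b for b in others):
            raise ValueError(
                "inferior ('down') regional base irregularity must exceed the "
                "other three regions"
            )
        if not 0.0 <= self.missing_scan_rate < 1.0:
            raise ValueError("missing_scan_rate must be in [0, 1)")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig) -> list[EyeRecord]:
    """Draw a cohort of eyes with per-gaze ground-truth contour specs.

    Reproducible under a fixed ``config.seed``.  Negative draws of the
    regional total are clipped at 0 and the count logged.
    """
    rng = np.random.default_rng(config.seed)
    w = _bin_profile()
    eyes: list[EyeRecord] = []
    n_clipped = 0
    n_rescaled = 0
    # Coarse grid for the depth-budget check of the realized waveform.
    xg = np.linspace(0.0, config.width_mm, 1025)
    karr = np.arange(1, N_SPECTRUM_BINS + 1)
    phase_grid = 2.0 * np.pi * np.outer(karr, xg) / config.width_mm  # (30, 1025)
    slope_factor = 2.0 * np.pi * karr / config.width_mm
    for group in DIAGNOSES:
        n = config.n_per_group.get(group, 0)
        if n == 0:
            continue
        age_m, age_s = config.age_mean_sd[group]
        ax_m, ax_s = config.axial_mean_sd[group]
        ages = _truncnorm(rng, age_m, age_s, *AGE_RANGE, size=n)
        axials = _truncnorm(rng, ax_m, ax_s, *AXIAL_RANGE, size=n)
        pvd_ax_mean = config.axial_mean_sd["PVD"][0]
        for i in range(n):
            eye_id = f"{group}-{i:03d}"
            specs: dict[str, ContourSpec] = {}
            truth_totals: dict[str, float] = {}
            if group == "PVD":
                shift_frac = 1.0 if rng.random() < config.pvd_shift_fraction else 0.0
            elif group == "RD":
                shift_frac = 1.0
            else:
                shift_frac = config.tear_shift_fraction
            for gaze in GAZES:
                if config.missing_scan_rate and rng.random() < config.missing_scan_rate:
                    continue
                r0 = config.regional_base_irregularity[gaze]
                if group == "PVD":
                    coupling = 1.0 + config.axial_irregularity_slope * (axials[i] - pvd_ax_mean)
                    r0 = r0 * max(coupling, 0.1)
                r = rng.normal(r0, config.regional_cv[gaze] * config.regional_base_irregularity[gaze])
                if r < 0:
                    n_clipped += 1
                    r = 0.0
                eps = rng.gamma(config.bin_noise_shape, 1.0 / config.bin_noise_shape, N_SPECTRUM_BINS)
                f_low = config.regional_lowfreq_fraction.get(gaze, 0.0)
                amps = 2.0 * r * (1.0 - f_low) * w * eps  # bin value = amplitude / 2
                if f_low:
                    w_low = 1.0 / np.arange(2, 7)
                    w_low /= w_low.sum()
                    eps_low = rng.gamma(config.bin_noise_shape, 1.0 / config.bin_noise_shape, 5)
                    amps[1:6] += 2.0 * r * f_low * w_low * eps_low
                if shift_frac:
                    s = config.group_shift_sigma
                    for (sg, k), delta in config.group_shift.items():
                        if sg == gaze and delta:
                            # Per-(eye, bin) lognormal magnitude, mean 1: the
                            # anomaly is expressed with variable strength, so
                            # the affected class gains variance as well as
                            # mean on the designated features.
                            mag = rng.lognormal(-0.5 * s * s, s)
                            amps[k - 1] += 2.0 * shift_frac * delta * mag
                phases = rng.uniform(0.0, 2.0 * np.pi, N_SPECTRUM_BINS)
                wave = amps @ np.sin(phase_grid + phases[:, None])
                slope = (amps * slope_factor) @ np.cos(phase_grid + phases[:, None])
                peak = float(np.abs(wave).max())
                speak = float(np.abs(slope).max())
                scale = min(
                    1.0,
                    config.waveform_budget_mm / peak if peak > 0 else 1.0,
                    config.slope_budget / speak if speak > 0 else 1.0,
                )
                if scale < 1.0:
                    amps = amps * scale
                    n_rescaled += 1
                specs[gaze] = ContourSpec(
                    width_mm=config.width_mm,
                    n_cols=config.n_cols,
                    base_poly=config.base_poly,
                    bin_amplitudes={k + 1: float(amps[k]) for k in range(N_SPECTRUM_BINS)},
                    bin_phases={k + 1: float(phases[k]) for k in range(N_SPECTRUM_BINS)},
                    noise_sd=config.contour_noise_sd,
                )
                truth_totals[gaze] = float(amps.sum() / 2.0)
            eyes.append(
                EyeRecord(
                    eye_id=eye_id,
                    diagnosis=group,
                    axial_length_mm=float(axials[i]),
                    age_years=float(ages[i]),
                    contour_specs=specs,
                    truth={"regional_totals": truth_totals},
                )
            )
    if n_clipped:
        logger.info("generate_cohort: clipped %d negative regional draws at 0", n_clipped)
    if n_rescaled:
        logger.info(
            "generate_cohort: rescaled %d waveforms to the %.2f mm depth budget",
            n_rescaled, config.waveform_budget_mm,
        )
    return eyes


def contour_seed(base_seed: int, eye_index: int, gaze: str) -> int:
    """Deterministic per-(eye, gaze) seed below 2**31."""
    return (base_seed * 131071 + eye_index * 8191 + GAZES.index(gaze) * 127 + 1) % (2**31 - 1)


def null_config(n_per_group: dict[str, int] | None = None, seed: int = 0, **overrides) -> CohortConfig:
    """A no-signal variant: identical group distributions, zero shift."""
    cfg = CohortConfig(seed=seed, **overrides)
    cfg.group_shift = {k: 0.0 for k in cfg.group_shift}
    cfg.axial_irregularity_slope = 0.0
    pvd_age, pvd_ax = cfg.age_mean_sd["PVD"], cfg.axial_mean_sd["PVD"]
    cfg.age_mean_sd = {g: pvd_age for g in DIAGNOSES}
    cfg.axial_mean_sd = {g: pvd_ax for g in DIAGNOSES}
    if n_per_group is not None:
        cfg.n_per_group = dict(n_per_group)
    return cfg
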