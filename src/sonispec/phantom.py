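"""Synthetic tumor phantoms emulating in vivo NIRF hyperspectral acquisitions.

A phantom cube is built from three ingredients on an 18-channel 640-810 nm
grid (10 nm spacing):

* an **autofluorescence background** with a log-linear spectral slope,
  ``B * exp(slope * (w - w0))`` at every pixel. The slope must leave the
  background's mid-minus-low target value positive — the probe-to-background
  ratio divides by it, so a spectrally flat (or inverted) background would
  make the method's denominator vanish;
* a **cy5.5-like emission bump**, a Gaussian in wavelength
  ``A * exp(-(w - peak)^2 / (2 sigma^2))`` centered at 720 nm (inside the
  mid bins, which define what "signal" means here), added uniformly inside
  an elliptical tumor;
* additive zero-mean Gaussian **noise** (optionally Poisson shot noise),
  clipped at zero.

Because every ingredient is analytic, the probe-to-background ratio of a
noise-free phantom has a closed form,

    expected_ratio = 1 + A * dg / (B * de)

where ``dg`` and ``de`` are the mid-minus-low bin-mean differences of the
unit emission bump and the unit background profile. That closed form is the
oracle for the whole processing chain.

What the phantom does *not* emulate: photon-transport effects (depth-
dependent scattering/absorption), detector fixed-pattern artifacts, fur or
food-particle autofluorescence beyond the spectrally flat background.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .hsio import ROI, SpectralCube, roi_mask
from .ratio import BinSelection

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "expected_ratio",
    "visual_contrast",
    "generate_phantom",
    "extravasation_control",
    "masked_tumor_config",
]

DEFAULT_WAVELENGTHS = tuple(float(w) for w in range(640, 811, 10))


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, spectra, and noise of one synthetic mouse.

    Defaults give a bright, clearly detectable tumor (probe-to-background
    ratio ~3.1, in the range the in vivo method reports for visible tumors).
    """

    rows: int = 128
    cols: int = 128
    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS
    background_level: float = 100.0
    #: log-linear spectral slope per nm; positive so the background's
    #: mid-minus-low target value is a valid (positive) ratio denominator.
    background_slope: float = 0.01
    tumor_center: tuple[float, float] = (64.0, 80.0)
    tumor_axes: tuple[float, float] = (12.0, 9.0)
    tumor_amplitude: float = 300.0
    tumor_peak_nm: float = 720.0
    tumor_width_nm: float = 25.0
    skull_roi: tuple[float, float, float, float] = (20.0, 20.0, 36.0, 36.0)
    flank_roi: tuple[float, float, float, float] = (90.0, 20.0, 106.0, 36.0)
    noise_sd: float = 5.0
    noise_model: str = "gaussian"  # or "poisson"
    seed: int = 0
    # extravasation control site (None = no control region)
    control_center: tuple[float, float] | None = None
    control_axes: tuple[float, float] = (4.0, 3.0)
    control_multiplier: float = 5.0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("phantom shape must be positive")
        if self.tumor_amplitude < 0 or self.background_level < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        if self.tumor_width_nm <= 0:
            raise ValueError("tumor_width_nm must be positive")


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a phantom cube."""

    mask: np.ndarray
    expected_ratio: float
    background_target: float
    expected_control_ratio: float | None = None


def _unit_background(config: PhantomConfig) -> np.ndarray:
    w = np.asarray(config.wavelengths_nm, dtype=float)
    return np.exp(config.background_slope * (w - w[0]))


def _unit_bump(config: PhantomConfig) -> np.ndarray:
    w = np.asarray(config.wavelengths_nm, dtype=float)
    return np.exp(-((w - config.tumor_peak_nm) ** 2) / (2 * config.tumor_width_nm**2))


def _bin_diff(profile: np.ndarray, wavelengths: tuple[float, ...],
              bins: BinSelection) -> float:
    low_idx, mid_idx = bins.indices(np.asarray(wavelengths))
    return float(profile[mid_idx].mean() - profile[low_idx].mean())


def background_target(config: PhantomConfig, bins: BinSelection | None = None) -> float:
    """Closed-form background target value d = B * de."""
    bins = bins or BinSelection()
    return config.background_level * _bin_diff(
        _unit_background(config), config.wavelengths_nm, bins)


def expected_ratio(config: PhantomConfig, bins: BinSelection | None = None,
                   amplitude: float | None = None) -> float:
    """Closed-form probe-to-background ratio, 1 + A*dg / (B*de)."""
    bins = bins or BinSelection()
    a = config.tumor_amplitude if amplitude is None else amplitude
    d = background_target(config, bins)
    if d <= 0:
        raise ValueError(
            "background spectral slope gives a non-positive target value; "
            "the probe-to-background ratio is undefined for this config"
        )
    dg = _bin_diff(_unit_bump(config), config.wavelengths_nm, bins)
    return 1.0 + a * dg / d


def visual_contrast(config: PhantomConfig) -> float:
    """Best single-channel per-pixel contrast, max_w A*g(w) / noise_sd.

    This is what a viewer of one spectral band sees; values below ~2 mean
    the tumor is buried in per-pixel noise for single-band inspection.
    """
    if config.noise_sd == 0:
        return np.inf
    return float(config.tumor_amplitude * _unit_bump(config).max() / config.noise_sd)


def _ellipse_mask(rows: int, cols: int, center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return (((rr - center[0]) / axes[0]) ** 2
            + ((cc - center[1]) / axes[1]) ** 2) <= 1.0


def _phantom_rois(config: PhantomConfig) -> list[ROI]:
    probe_radius = max(1.0, min(config.tumor_axes))
    rois = [
        ROI(name="tumor", kind="circle",
            params=(config.tumor_center[0], config.tumor_center[1], probe_radius),
            role="probe"),
        ROI(name="skull", kind="rect", params=config.skull_roi, role="background"),
        ROI(name="flank", kind="rect", params=config.flank_roi, role="background"),
    ]
    if config.control_center is not None:
        r, c = config.control_center
        rois.append(ROI(name="tail_control", kind="circle",
                        params=(r, c, max(1.0, min(config.control_axes) - 1.0)),
                        role="control"))
    return rois


def generate_phantom(config: PhantomConfig,
                     bins: BinSelection | None = None
                     ) -> tuple[SpectralCube, PhantomTruth, list[ROI]]:
    """Build one seeded phantom cube with ground truth and its ROI set.

    Identical configs (including seed) give element-wise identical cubes.
    Raises if a background ROI overlaps the tumor or control region.
    """
    bins = bins or BinSelection()
    rows, cols = config.rows, config.cols
    shape = (rows, cols)

    tumor = _ellipse_mask(rows, cols, config.tumor_center, config.tumor_axes)
    control = None
    if config.control_center is not None:
        control = _ellipse_mask(rows, cols, config.control_center, config.control_axes)

    rois = _phantom_rois(config)
    signal_regions = tumor if control is None else (tumor | control)
    for roi in rois:
        if roi.role != "background":
            continue
        if np.any(roi_mask(roi, shape) & signal_regions):
            raise ValueError(
                f"background ROI {roi.name!r} overlaps the tumor/control region; "
                f"move it outside the lesion"
            )

    bg_profile = config.background_level * _unit_background(config)
    bump = _unit_bump(config)
    base = np.broadcast_to(bg_profile, (rows, cols, bg_profile.size)).copy()
    base[tumor] += config.tumor_amplitude * bump
    if control is not None:
        base[control] += config.tumor_amplitude * config.control_multiplier * bump

    rng = np.random.default_rng(config.seed)
    if config.noise_model == "poisson":
        data = rng.poisson(np.clip(base, 0, None)).astype(float)
    elif config.noise_sd > 0:
        data = base + rng.normal(0.0, config.noise_sd, size=base.shape)
    else:
        data = base
    data = np.clip(data, 0.0, None)

    cube = SpectralCube(intensities=data,
                        wavelengths_nm=np.asarray(config.wavelengths_nm),
                        name=f"phantom(seed={config.seed})")
    truth = PhantomTruth(
        mask=tumor,
        expected_ratio=expected_ratio(config, bins),
        background_target=background_target(config, bins),
        expected_control_ratio=(
            expected_ratio(config, bins,
                           amplitude=config.tumor_amplitude * config.control_multiplier)
            if control is not None else None),
    )
    return cube, truth, rois


def extravasation_control(config: PhantomConfig) -> PhantomConfig:
    """Add a positive-control site: a small, very bright extravasation spot.

    Emulates a tail injection site whose emission is ``control_multiplier``
    (default 5x) times the tumor amplitude, so its ratio dominates every
    other ROI.
    """
    return replace(config, control_center=(110.0, 100.0))


def masked_tumor_config(config: PhantomConfig) -> PhantomConfig:
    """Weak-signal close-up: a small tumor invisible to single-band viewing.

    Emulates the case of a tumor too small/dim for visual spectral display:
    the field of view narrows to a 32x32 close-up around the suspicious
    area, tumor axes shrink to (3, 2) pixels, the amplitude is set so the
    closed-form expected ratio is 1.8, and the noise level is raised so the
    best single-band per-pixel contrast is 1.8 noise-sd — below the ~2 sd
    rule-of-thumb for reliable visual detection. Band-averaged ratioing
    (8 bins) plus ROI/spatial pooling still recovers the lesion.
    """
    target_ratio = 1.8
    small = replace(
        config,
        rows=32, cols=32,
        tumor_center=(16.0, 20.0),
        tumor_axes=(3.0, 2.0),
        skull_roi=(4.0, 4.0, 12.0, 12.0),
        flank_roi=(22.0, 4.0, 30.0, 12.0),
        control_center=None,
    )
    d = background_target(small)
    dg = _bin_diff(_unit_bump(small), small.wavelengths_nm, BinSelection())
    amplitude = (target_ratio - 1.0) * d / dg
    noise_sd = amplitude * _unit_bump(small).max() / 1.8
    return replace(small, tumor_amplitude=amplitude, noise_sd=noise_sd)
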