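"""Band-ratio parametrization of hyperspectral fluorescence spectra.

The scalar that drives both the sonification and the statistics is built in
two steps:

1. **target value** of a spectrum: mean intensity over a set of *mid* bins
   (default 710-740 nm, where a cy5.5-like NIRF probe emits) minus the mean
   over a set of *low* bins (default 640-670 nm, where autofluorescence
   dominates). Spectrally flat emission — autofluorescence from skin, food
   particles, fur — cancels exactly, whatever its brightness.
2. **probe-to-background ratio**: the probe ROI's target value divided by the
   target value of a background ROI (typically skull). This normalization
   makes the parameter invariant to overall illumination/exposure scale.

The ratio is kept signed; clamping to a physically meaningful nonnegative
value happens only where it is mapped to an FM modulation index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hsio import ROI, SpectralCube, Spectrum, extract_roi_spectrum

__all__ = [
    "BinSelection",
    "ParamMap",
    "target_value",
    "normalize_target",
    "roi_ratio",
    "parameter_map",
    "roi_ratio_table",
]

DEFAULT_EPS = 1e-9


@dataclass(frozen=True)
class BinSelection:
    """Wavelength bins (nm) used for the target-value difference.

    Bins are keyed by wavelength, not channel index, so the same selection
    applies to cubes with different channel layouts; every listed wavelength
    must be present exactly in the cube. Other probes than cy5.5 are handled
    by moving the mid bins onto their emission band.
    """

    low_bins_nm: tuple[float, ...] = (640.0, 650.0, 660.0, 670.0)
    mid_bins_nm: tuple[float, ...] = (710.0, 720.0, 730.0, 740.0)

    def __post_init__(self) -> None:
        low = tuple(float(w) for w in self.low_bins_nm)
        mid = tuple(float(w) for w in self.mid_bins_nm)
        if not low or not mid:
            raise ValueError("both bin sets must be non-empty")
        if set(low) & set(mid):
            raise ValueError("low and mid bin sets must be disjoint")
        object.__setattr__(self, "low_bins_nm", low)
        object.__setattr__(self, "mid_bins_nm", mid)

    def indices(self, wavelengths_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Channel indices of (low, mid) bins in ``wavelengths_nm``."""
        wl = np.asarray(wavelengths_nm, dtype=float)

        def _find(bins: tuple[float, ...]) -> np.ndarray:
            idx = []
            for w in bins:
                hits = np.nonzero(wl == w)[0]
                if hits.size == 0:
                    raise ValueError(
                        f"bin wavelength {w:g} nm not present in cube wavelengths "
                        f"{wl.tolist()}"
                    )
                idx.append(int(hits[0]))
            return np.asarray(idx)

        return _find(self.low_bins_nm), _find(self.mid_bins_nm)


@dataclass
class ParamMap:
    """Per-pixel probe-to-background ratios for one cube.

    ``values[r, c]`` is the pixel's target value divided by the single
    ``background_target`` measured on the background ROI.
    """

    values: np.ndarray
    background_target: float
    bins: BinSelection = field(default_factory=BinSelection)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ParamMap values must be 2D (row, col)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ParamMap values must be finite")


def target_value(spectrum: Spectrum, bins: BinSelection | None = None) -> float:
    """Mid-bin mean minus low-bin mean of ``spectrum``; may be negative."""
    bins = bins or BinSelection()
    low_idx, mid_idx = bins.indices(spectrum.wavelengths_nm)
    v = spectrum.values
    return float(v[mid_idx].mean() - v[low_idx].mean())


def normalize_target(probe_target: float, background_target: float,
                     eps: float = DEFAULT_EPS) -> float:
    """Signed ratio ``probe_target / background_target``.

    The background target must exceed ``eps`` (in cube intensity units):
    a vanishing or negative denominator means the background ROI carries no
    usable spectral slope and the ratio is undefined.
    """
    if not np.isfinite(probe_target) or not np.isfinite(background_target):
        raise ValueError("target values must be finite")
    if background_target <= eps:
        raise ValueError(
            f"background target non-positive or below eps "
            f"({background_target:g} <= {eps:g}); choose a background ROI with "
            f"autofluorescence signal"
        )
    return float(probe_target / background_target)


def roi_ratio(cube: SpectralCube, probe_roi: ROI, background_roi: ROI,
              bins: BinSelection | None = None, eps: float = DEFAULT_EPS) -> float:
    """Probe-to-background ratio of ROI-mean spectra.

    By linearity of the target value, using the ROI-mean spectrum is
    identical to averaging per-pixel target values over the ROI.
    """
    bins = bins or BinSelection()
    probe_t = target_value(extract_roi_spectrum(cube, probe_roi), bins)
    background_t = target_value(extract_roi_spectrum(cube, background_roi), bins)
    return normalize_target(probe_t, background_t, eps)


def pixel_target_values(cube: SpectralCube, bins: BinSelection | None = None) -> np.ndarray:
    """Per-pixel target value, vectorized over the whole cube."""
    bins = bins or BinSelection()
    low_idx, mid_idx = bins.indices(cube.wavelengths_nm)
    data = cube.intensities.astype(float)
    return data[:, :, mid_idx].mean(axis=2) - data[:, :, low_idx].mean(axis=2)


def parameter_map(cube: SpectralCube, background_roi: ROI,
                  bins: BinSelection | None = None,
                  eps: float = DEFAULT_EPS) -> ParamMap:
    """Per-pixel probe-to-background ratios against one background ROI."""
    bins = bins or BinSelection()
    background_t = target_value(extract_roi_spectrum(cube, background_roi), bins)
    if background_t <= eps:
        raise ValueError(
            f"background target non-positive or below eps "
            f"({background_t:g} <= {eps:g}); choose a background ROI with "
            f"autofluorescence signal"
        )
    values = pixel_target_values(cube, bins) / background_t
    return ParamMap(values=values, background_target=background_t, bins=bins)


def roi_ratio_table(cube: SpectralCube, rois: list[ROI], background_name: str,
                    bins: BinSelection | None = None,
                    eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """Tabulate per-ROI target values and ratios against one background ROI.

    Columns: ``roi_name, role, target, background_target, ratio``.
    """
    bins = bins or BinSelection()
    by_name = {r.name: r for r in rois}
    if background_name not in by_name:
        raise ValueError(
            f"background ROI {background_name!r} not found; available: "
            f"{sorted(by_name)}"
        )
    background_t = target_value(
        extract_roi_spectrum(cube, by_name[background_name]), bins)
    rows = []
    for roi in rois:
        t = target_value(extract_roi_spectrum(cube, roi), bins)
        rows.append({
            "roi_name": roi.name,
            "role": roi.role,
            "target": t,
            "background_target": background_t,
            "ratio": normalize_target(t, background_t, eps),
        })
    return pd.DataFrame(rows)
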