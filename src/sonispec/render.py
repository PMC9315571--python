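"""Back-conversion of per-pixel ratios into rainbow-scale parametric images.

The per-pixel probe-to-background values are min-max rescaled to [0, 1] and
mapped through an explicit HSV rainbow: hue 240 deg (blue) at 0 sweeping to
0 deg (red) at 1, full saturation and value. The colormap is written out as
a formula rather than a named library palette so rendered images are
bit-reproducible.

Also provides overlay compositing on a grayscale photograph and a simple
detector (Gaussian smoothing + Otsu threshold) used to score how well the
map outlines a lesion against a ground-truth mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu

from .ratio import ParamMap

__all__ = [
    "RenderedMap",
    "rescale01",
    "rainbow_render",
    "render_param_map",
    "overlay",
    "otsu_mask",
    "dice",
]


@dataclass
class RenderedMap:
    """8-bit RGB rendering of a ParamMap plus the rescaling window used."""

    rgb: np.ndarray
    values01: np.ndarray
    scale_min: float
    scale_max: float

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be (row, col, 3)")
        if self.rgb.shape[:2] != self.values01.shape:
            raise ValueError("rgb and values01 spatial shapes must match")


def rescale01(values: np.ndarray | ParamMap,
              clip_percentiles: tuple[float, float] | None = None
              ) -> tuple[np.ndarray, float, float]:
    """Min-max rescale to [0, 1]; returns (scaled, scale_min, scale_max).

    A constant map rescales to all zeros (rendered cold blue rather than
    erroring: a no-signal image should look empty, not crash). With
    ``clip_percentiles=(lo, hi)`` the window is taken at those percentiles
    and values outside are saturated — useful for noisy maps, off by default.
    """
    v = values.values if isinstance(values, ParamMap) else np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("cannot rescale a map with non-finite values")
    if clip_percentiles is None:
        vmin, vmax = float(v.min()), float(v.max())
    else:
        lo, hi = clip_percentiles
        vmin, vmax = (float(x) for x in np.percentile(v, [lo, hi]))
    if vmax == vmin:
        return np.zeros_like(v), vmin, vmax
    scaled = np.clip((v - vmin) / (vmax - vmin), 0.0, 1.0)
    return scaled, vmin, vmax


def _hue_to_rgb01(h_deg: np.ndarray) -> np.ndarray:
    """HSV -> RGB at s = v = 1 for hue in degrees (vectorized)."""
    h = np.asarray(h_deg, dtype=float) / 60.0  # sextant coordinate
    x = 1.0 - np.abs(h % 2 - 1.0)
    sext = np.floor(h).astype(int) % 6
    r = np.choose(sext, [np.ones_like(x), x, np.zeros_like(x),
                         np.zeros_like(x), x, np.ones_like(x)])
    g = np.choose(sext, [x, np.ones_like(x), np.ones_like(x),
                         x, np.zeros_like(x), np.zeros_like(x)])
    b = np.choose(sext, [np.zeros_like(x), np.zeros_like(x), x,
                         np.ones_like(x), np.ones_like(x), x])
    return np.stack([r, g, b], axis=-1)


def rainbow_hue_deg(values01: np.ndarray) -> np.ndarray:
    """Hue angle of the rainbow scale: 240*(1 - v) degrees (blue -> red)."""
    return 240.0 * (1.0 - np.asarray(values01, dtype=float))


def rainbow_render(values01: np.ndarray) -> np.ndarray:
    """Map values in [0, 1] to 8-bit RGB through the rainbow scale.

    Quantization is round-half-up so the mapping is platform-stable.
    """
    v = np.asarray(values01, dtype=float)
    if v.min() < 0 or v.max() > 1:
        raise ValueError("rainbow_render expects values in [0, 1]")
    rgb01 = _hue_to_rgb01(rainbow_hue_deg(v))
    return np.floor(rgb01 * 255.0 + 0.5).astype(np.uint8)


def render_param_map(pmap: ParamMap,
                     clip_percentiles: tuple[float, float] | None = None
                     ) -> RenderedMap:
    """Rescale a ParamMap to [0, 1] and render it in the rainbow scale."""
    values01, vmin, vmax = rescale01(pmap, clip_percentiles)
    return RenderedMap(rgb=rainbow_render(values01), values01=values01,
                       scale_min=vmin, scale_max=vmax)


def overlay(gray: np.ndarray, rendered: RenderedMap, threshold: float = 0.0,
            alpha: float = 0.6) -> np.ndarray:
    """Blend the rainbow map over a grayscale photo where the map is bright.

    Pixels with ``values01 >= threshold`` become
    ``alpha*rainbow + (1-alpha)*gray``; the rest stay pure grayscale.
    ``gray`` may be any numeric range; it is min-max scaled to 8-bit.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.shape != rendered.values01.shape:
        raise ValueError(
            f"shape mismatch: photo {gray.shape} vs map {rendered.values01.shape}"
        )
    if not (0 <= threshold <= 1 and 0 <= alpha <= 1):
        raise ValueError("threshold and alpha must lie in [0, 1]")
    g01, _, _ = rescale01(gray)
    g8 = np.floor(g01 * 255.0 + 0.5)
    out = np.repeat(g8[:, :, None], 3, axis=2)
    hot = rendered.values01 >= threshold
    blended = alpha * rendered.rgb.astype(float) + (1 - alpha) * out
    out[hot] = blended[hot]
    return np.floor(out + 0.5).clip(0, 255).astype(np.uint8)


def otsu_mask(pmap: ParamMap | np.ndarray, smooth_sigma: float = 1.5) -> np.ndarray:
    """Detect high-ratio pixels: Gaussian smoothing then Otsu's threshold.

    The smoothing (default sigma 1.5 px) plays the role of the ROI averaging
    in interactive probing — single-pixel ratios are noisy, but lesions are
    compact blobs several pixels across, so mild spatial pooling raises
    their contrast without inventing structure.
    """
    v = pmap.values if isinstance(pmap, ParamMap) else np.asarray(pmap, dtype=float)
    if smooth_sigma > 0:
        v = gaussian_filter(v, sigma=smooth_sigma)
    return v > threshold_otsu(v)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)
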