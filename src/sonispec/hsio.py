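"""Hyperspectral cube and ROI handling.

A cube is a (rows, cols, channels) intensity array with one center wavelength
per channel. On disk a cube is a multi-page TIFF (page *i* = channel *i*) plus
a JSON sidecar with the same basename carrying ``wavelengths_nm`` and an
optional ``name`` — the portable stand-in for vendor hyperspectral formats.

Regions of interest are named 2D shapes (polygon, rectangle, or circle) in
pixel coordinates, rasterized by pixel-center containment. Conventions are
explicit because they matter for reproducibility:

* coordinates are 0-based ``(row, col)``, row-major;
* rectangles are half-open: ``[row0, row1) x [col0, col1)``;
* a pixel belongs to a polygon iff its center ``(row + 0.5, col + 0.5)`` is
  inside under the even-odd rule;
* a pixel ``(row, col)`` belongs to a circle iff its integer coordinate is
  within ``radius`` of the circle center, so ``(r, c, 0.4)`` selects exactly
  the single pixel ``(r, c)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "SpectralCube",
    "Spectrum",
    "ROI",
    "read_cube",
    "write_cube",
    "rasterize_roi",
    "extract_roi_spectrum",
    "read_rois",
    "write_rois",
]


@dataclass
class SpectralCube:
    """Hyperspectral image: intensities indexed (row, col, channel).

    ``wavelengths_nm`` gives the center wavelength of each channel and is the
    only carrier of channel semantics — code never assumes a particular
    channel count or spacing.
    """

    intensities: np.ndarray
    wavelengths_nm: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D (row, col, channel), got shape "
                f"{self.intensities.shape}"
            )
        if self.wavelengths_nm.ndim != 1:
            raise ValueError("wavelengths_nm must be a 1D vector")
        if self.intensities.shape[2] != self.wavelengths_nm.size:
            raise ValueError(
                f"channel count mismatch: intensities have "
                f"{self.intensities.shape[2]} channels but "
                f"{self.wavelengths_nm.size} wavelengths were given"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(np.asarray(self.intensities, dtype=float) < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (rows, cols)."""
        return self.intensities.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[2]


@dataclass
class Spectrum:
    """Per-channel values sampled at the cube's wavelengths."""

    values: np.ndarray
    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.shape != self.wavelengths_nm.shape:
            raise ValueError("values and wavelengths_nm must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")


_ROLES = ("probe", "background", "control")
_SHAPE_KINDS = ("polygon", "rect", "circle")


@dataclass
class ROI:
    """Named region of interest.

    ``kind`` is one of ``polygon`` (vertex list ``[(row, col), ...]``),
    ``rect`` (``(row0, col0, row1, col1)``, half-open) or ``circle``
    (``(row, col, radius)``). ``role`` tags the ROI for downstream analysis:
    ``probe`` (candidate lesion), ``background`` (reference tissue such as
    skull or flank) or ``control``.
    """

    name: str
    kind: str
    params: tuple | list
    role: str = "probe"

    def __post_init__(self) -> None:
        if self.kind not in _SHAPE_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}; expected one of {_SHAPE_KINDS}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown ROI role {self.role!r}; expected one of {_ROLES}")
        if self.kind == "polygon":
            verts = [tuple(map(float, v)) for v in self.params]
            if len(verts) < 3:
                raise ValueError(f"polygon ROI {self.name!r} needs >= 3 vertices")
            self.params = verts
        elif self.kind == "rect":
            r0, c0, r1, c1 = map(float, self.params)
            if not (r0 < r1 and c0 < c1):
                raise ValueError(
                    f"rect ROI {self.name!r} must satisfy row0 < row1 and col0 < col1"
                )
            self.params = (r0, c0, r1, c1)
        else:
            r, c, rad = map(float, self.params)
            if rad <= 0:
                raise ValueError(f"circle ROI {self.name!r} must have radius > 0")
            self.params = (r, c, rad)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_cube(cube: SpectralCube, path: str | Path) -> None:
    """Write ``cube`` as a multi-page TIFF plus JSON wavelength sidecar.

    Page *i* of the TIFF is channel *i*; the dtype of ``cube.intensities``
    is preserved, so integer cubes round-trip value-exactly.
    """
    path = Path(path)
    pages = np.ascontiguousarray(np.moveaxis(cube.intensities, 2, 0))
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "wavelengths_nm": [float(w) for w in cube.wavelengths_nm],
        "name": cube.name,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1) + "\n")


def read_cube(path: str | Path) -> SpectralCube:
    """Read a multi-page TIFF + JSON sidecar written by :func:`write_cube`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"wavelength sidecar not found: expected {sidecar} next to {path}"
        )
    meta = json.loads(sidecar.read_text())
    wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
    pages = tifffile.imread(path)
    if pages.ndim == 2:  # single-page TIFF
        pages = pages[None, :, :]
    if pages.shape[0] != wavelengths.size:
        raise ValueError(
            f"channel count mismatch: TIFF {path} has {pages.shape[0]} pages "
            f"but sidecar lists {wavelengths.size} wavelengths"
        )
    return SpectralCube(
        intensities=np.moveaxis(pages, 0, 2),
        wavelengths_nm=wavelengths,
        name=str(meta.get("name", "")),
    )


def _polygon_contains(vertices: Sequence[tuple[float, float]],
                      rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Even-odd containment of points (rows, cols) in a polygon, vectorized.

    Ray-casting along +col; a point on an edge follows the half-open
    crossing convention, which keeps adjacent polygons non-overlapping.
    """
    inside = np.zeros(rows.shape, dtype=bool)
    verts = np.asarray(vertices, dtype=float)
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        if r1 == r2:
            continue
        crosses = (r1 > rows) != (r2 > rows)
        # col coordinate where the edge crosses the point's row
        with np.errstate(invalid="ignore"):
            c_at = c1 + (rows - r1) * (c2 - c1) / (r2 - r1)
        inside ^= crosses & (cols < c_at)
    return inside


def rasterize_roi(roi: ROI, shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Pixel set of ``roi`` on an image of spatial ``shape``, row-major order.

    Raises ``ValueError("ROI outside image: ...")`` if no pixel center falls
    inside the shape after clipping to bounds.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError("image shape must be positive")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    centers_r = rr + 0.5
    centers_c = cc + 0.5
    if roi.kind == "rect":
        r0, c0, r1, c1 = roi.params
        mask = (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)
    elif roi.kind == "circle":
        r, c, rad = roi.params
        mask = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
    else:
        mask = _polygon_contains(roi.params, centers_r, centers_c)
    pix = np.argwhere(mask)
    if pix.size == 0:
        raise ValueError(f"ROI outside image: {roi.name!r} rasterizes to no pixels "
                         f"within shape {shape}")
    return [(int(r), int(c)) for r, c in pix]


def roi_mask(roi: ROI, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask form of :func:`rasterize_roi`."""
    mask = np.zeros(shape, dtype=bool)
    for r, c in rasterize_roi(roi, shape):
        mask[r, c] = True
    return mask


def extract_roi_spectrum(cube: SpectralCube, roi: ROI) -> Spectrum:
    """Arithmetic mean spectrum over the ROI's pixel set.

    Integer cubes are promoted to float64; no rescaling is applied.
    """
    pix = rasterize_roi(roi, cube.shape)
    idx = np.asarray(pix)
    values = cube.intensities[idx[:, 0], idx[:, 1], :].astype(float).mean(axis=0)
    return Spectrum(values=values, wavelengths_nm=cube.wavelengths_nm)


# --- ROI set JSON ------------------------------------------------------------

def write_rois(rois: Sequence[ROI], path: str | Path) -> None:
    """Write an ROI set as JSON: {"rois": [{"name", "role", "shape": {...}}]}."""
    out = {
        "rois": [
            {
                "name": roi.name,
                "role": roi.role,
                "shape": {roi.kind: [list(v) for v in roi.params]
                          if roi.kind == "polygon" else list(roi.params)},
            }
            for roi in rois
        ]
    }
    Path(path).write_text(json.dumps(out, indent=1) + "\n")


def read_rois(path: str | Path) -> list[ROI]:
    data = json.loads(Path(path).read_text())
    rois = []
    for entry in data["rois"]:
        shape = entry["shape"]
        if len(shape) != 1:
            raise ValueError(f"ROI {entry.get('name')!r}: shape must have exactly one kind")
        kind, params = next(iter(shape.items()))
        rois.append(ROI(name=entry["name"], kind=kind, params=params,
                        role=entry.get("role", "probe")))
    return rois
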