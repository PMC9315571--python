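"""Cube/ROI I/O: round trips, rasterization conventions, spectrum extraction."""

import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonispec.hsio import (ROI, SpectralCube, extract_roi_spectrum,
                           rasterize_roi, read_cube, read_rois, roi_mask,
                           write_cube, write_rois)
from sonispec.phantom import PhantomConfig, generate_phantom

WL18 = np.arange(640.0, 811.0, 10.0)


class TestCubeIO:
    @pytest.mark.parametrize("dtype", [np.uint16, np.float32])
    def test_round_trip_identity(self, tmp_path, rng, dtype):
        data = rng.uniform(0, 1000, size=(6, 7, 18))
        cube = SpectralCube(data.astype(dtype), WL18, name="rt")
        write_cube(cube, tmp_path / "c.tif")
        back = read_cube(tmp_path / "c.tif")
        np.testing.assert_array_equal(back.intensities, cube.intensities)
        np.testing.assert_array_equal(back.wavelengths_nm, WL18)
        assert back.name == "rt"

    def test_zero_cube_round_trip(self, tmp_path):
        cube = SpectralCube(np.zeros((3, 3, 4), dtype=np.uint16),
                            [640.0, 650, 660, 670])
        write_cube(cube, tmp_path / "z.tif")
        assert not read_cube(tmp_path / "z.tif").intensities.any()

    def test_18_channel_cube_reads_with_18_wavelengths(self, tmp_path, rng):
        cube = SpectralCube(rng.uniform(0, 10, (4, 4, 18)), WL18)
        write_cube(cube, tmp_path / "c.tif")
        assert read_cube(tmp_path / "c.tif").n_channels == 18

    def test_missing_sidecar_names_expected_path(self, tmp_path, rng):
        cube = SpectralCube(rng.uniform(0, 10, (4, 4, 18)), WL18)
        write_cube(cube, tmp_path / "c.tif")
        (tmp_path / "c.json").unlink()
        with pytest.raises(FileNotFoundError, match=r"c\.json"):
            read_cube(tmp_path / "c.tif")

    def test_page_wavelength_mismatch_reports_both_counts(self, tmp_path, rng):
        cube = SpectralCube(rng.uniform(0, 10, (4, 4, 17)), WL18[:17])
        write_cube(cube, tmp_path / "c.tif")
        sidecar = tmp_path / "c.json"
        sidecar.write_text(
            sidecar.read_text().replace("800.0", "800.0, 810.0"))
        with pytest.raises(ValueError, match="17.*18"):
            read_cube(tmp_path / "c.tif")

    def test_seeded_phantom_writes_are_byte_identical(self, tmp_path):
        for sub in ("a", "b"):
            cube, _, _ = generate_phantom(PhantomConfig(seed=42))
            (tmp_path / sub).mkdir()
            write_cube(cube, tmp_path / sub / "c.tif")
        digests = [hashlib.sha256((tmp_path / sub / "c.tif").read_bytes()).hexdigest()
                   for sub in ("a", "b")]
        assert digests[0] == digests[1]

    def test_channel_count_validation(self):
        with pytest.raises(ValueError, match="mismatch"):
            SpectralCube(np.zeros((2, 2, 3)), [640.0, 650.0])
        with pytest.raises(ValueError, match="increasing"):
            SpectralCube(np.zeros((2, 2, 2)), [650.0, 640.0])


class TestRasterize:
    def test_rect_is_half_open(self):
        roi = ROI("r", "rect", (0, 0, 2, 2))
        assert set(rasterize_roi(roi, (4, 4))) == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_small_circle_selects_single_pixel(self):
        roi = ROI("c", "circle", (1, 1, 0.4))
        assert rasterize_roi(roi, (4, 4)) == [(1, 1)]

    def test_polygon_square_matches_rect(self):
        poly = ROI("p", "polygon", [(0, 0), (0, 3), (3, 3), (3, 0)])
        rect = ROI("r", "rect", (0, 0, 3, 3))
        assert set(rasterize_roi(poly, (8, 8))) == set(rasterize_roi(rect, (8, 8)))

    def test_roi_fully_outside_raises(self):
        with pytest.raises(ValueError, match="ROI outside image"):
            rasterize_roi(ROI("r", "rect", (10, 10, 12, 12)), (4, 4))

    def test_clipping_to_bounds(self):
        roi = ROI("r", "rect", (2, 2, 10, 10))
        pix = rasterize_roi(roi, (4, 4))
        assert set(pix) == {(2, 2), (2, 3), (3, 2), (3, 3)}

    @staticmethod
    def _contains_oracle(verts, pr, pc):
        # even-odd parity by counting leftward ray crossings (independent
        # of the implementation's rightward cast)
        inside = False
        n = len(verts)
        for i in range(n):
            r1, c1 = verts[i]
            r2, c2 = verts[(i + 1) % n]
            if (r1 > pr) != (r2 > pr):
                c_at = c1 + (pr - r1) * (c2 - c1) / (r2 - r1)
                if pc > c_at:
                    inside = not inside
        # leftward parity equals rightward parity for points off the edges
        return inside

    @staticmethod
    def _on_edge(verts, pr, pc, tol=1e-9):
        n = len(verts)
        for i in range(n):
            (r1, c1), (r2, c2) = verts[i], verts[(i + 1) % n]
            dr, dc = r2 - r1, c2 - c1
            length2 = dr * dr + dc * dc
            if length2 == 0:
                d2 = (pr - r1) ** 2 + (pc - c1) ** 2
            else:
                t = max(0.0, min(1.0, ((pr - r1) * dr + (pc - c1) * dc) / length2))
                d2 = (pr - r1 - t * dr) ** 2 + (pc - c1 - t * dc) ** 2
            if d2 < tol:
                return True
        return False

    @given(st.lists(st.tuples(st.integers(-2, 17), st.integers(-2, 17)),
                    min_size=3, max_size=7))
    @settings(derandomize=True, max_examples=120, deadline=None)
    def test_polygon_rasterization_matches_exhaustive_containment(self, verts):
        # offset keeps most pixel centers off polygon edges; centers that
        # still fall exactly on an edge are excluded (the even-odd rule
        # leaves their membership tie-break unspecified)
        verts = [(r + 0.07, c + 0.07) for r, c in verts]
        roi = ROI("p", "polygon", verts)
        shape = (16, 16)
        try:
            got = set(rasterize_roi(roi, shape))
        except ValueError:
            got = set()
        interior = {
            (r, c)
            for r in range(shape[0]) for c in range(shape[1])
            if not self._on_edge(verts, r + 0.5, c + 0.5)
        }
        expected = {
            (r, c) for (r, c) in interior
            if self._contains_oracle(verts, r + 0.5, c + 0.5)
        }
        assert got & interior == expected


class TestExtractSpectrum:
    def test_single_pixel_roi_returns_pixel_vector(self, random_cube):
        roi = ROI("c", "circle", (2, 3, 0.4))
        spec = extract_roi_spectrum(random_cube, roi)
        np.testing.assert_array_equal(spec.values,
                                      random_cube.intensities[2, 3, :])

    def test_uniform_cube_gives_uniform_spectrum(self):
        profile = np.linspace(1, 18, 18)
        cube = SpectralCube(np.tile(profile, (4, 4, 1)), WL18)
        spec = extract_roi_spectrum(cube, ROI("r", "rect", (0, 0, 4, 4)))
        np.testing.assert_allclose(spec.values, profile)

    def test_matches_brute_force_mean(self, random_cube):
        roi = ROI("r", "rect", (1, 0, 4, 3))
        spec = extract_roi_spectrum(random_cube, roi)
        expected = np.zeros(18)
        npix = 0
        for r in range(1, 4):
            for c in range(0, 3):
                for k in range(18):
                    expected[k] += random_cube.intensities[r, c, k]
                npix += 1
        np.testing.assert_allclose(spec.values, expected / npix, rtol=1e-12)

    def test_linear_in_cube_intensities(self, random_cube, rect_roi):
        s1 = extract_roi_spectrum(random_cube, rect_roi).values
        scaled = SpectralCube(2.5 * random_cube.intensities,
                              random_cube.wavelengths_nm)
        np.testing.assert_allclose(
            extract_roi_spectrum(scaled, rect_roi).values, 2.5 * s1, rtol=1e-12)


class TestRoiJson:
    def test_round_trip(self, tmp_path):
        rois = [
            ROI("tumor", "polygon", [(0, 0), (0, 3), (3, 3)], role="probe"),
            ROI("skull", "rect", (1, 1, 3, 3), role="background"),
            ROI("tail", "circle", (2, 2, 1.5), role="control"),
        ]
        write_rois(rois, tmp_path / "rois.json")
        back = read_rois(tmp_path / "rois.json")
        assert [(r.name, r.kind, r.role) for r in back] == \
            [(r.name, r.kind, r.role) for r in rois]
        assert roi_mask(back[1], (4, 4)).sum() == 4
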