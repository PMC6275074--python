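"""Cube I/O, reflectance calibration and ROI spectrum extraction."""

import numpy as np
import pytest

from mangospec.hsi_io import (
    CALIBRATION_EPS,
    EnviCorruptionError,
    EnviFormatError,
    Hypercube,
    ReferenceFrames,
    RoiMask,
    WavelengthGrid,
    calibrate_reflectance,
    absorbance_to_reflectance,
    default_grid,
    extract_roi_mean,
    read_envi_cube,
    reflectance_to_absorbance,
    write_envi_cube,
)


def _random_cube(rng, shape=(4, 4, 256), dtype=np.float32):
    grid = WavelengthGrid(np.linspace(900, 1700, shape[2]))
    if np.dtype(dtype) == np.uint16:
        data = rng.integers(0, 4000, size=shape).astype(np.uint16)
    else:
        data = rng.random(shape).astype(dtype)
    return Hypercube(data, grid)


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bil", "bip", "bsq"])
    @pytest.mark.parametrize("dtype", [np.float32, np.uint16])
    def test_write_read_identity(self, tmp_path, rng, interleave, dtype):
        cube = _random_cube(rng, dtype=dtype)
        write_envi_cube(cube, tmp_path / "c.hdr", interleave=interleave)
        back = read_envi_cube(tmp_path / "c.hdr")
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_array_equal(back.grid.values, cube.grid.values)

    def test_interleaves_agree_with_index_arithmetic(self, tmp_path, rng):
        """BIL/BSQ byte layouts match an independent flat-index oracle."""
        cube = _random_cube(rng, shape=(3, 5, 7))
        lines, samples, bands = cube.shape
        for interleave in ("bil", "bsq", "bip"):
            data_path = write_envi_cube(
                cube, tmp_path / f"{interleave}.hdr", interleave=interleave
            )
            flat = np.fromfile(data_path, dtype="<f4")
            # oracle: compute each pixel's flat position from first principles
            for (l, s, b) in [(0, 0, 0), (1, 3, 2), (2, 4, 6), (1, 0, 5)]:
                if interleave == "bip":
                    pos = (l * samples + s) * bands + b
                elif interleave == "bil":
                    pos = (l * bands + b) * samples + s
                else:  # bsq
                    pos = (b * lines + l) * samples + s
                assert flat[pos] == cube.data[l, s, b].astype(np.float32)

    def test_size_mismatch_is_corruption_error(self, tmp_path, rng):
        cube = _random_cube(rng)
        data_path = write_envi_cube(cube, tmp_path / "c.hdr")
        payload = data_path.read_bytes()
        data_path.write_bytes(payload[:-4 * 16])  # drop 16 values
        with pytest.raises(EnviCorruptionError):
            read_envi_cube(tmp_path / "c.hdr")

    def test_missing_wavelengths_is_format_error(self, tmp_path, rng):
        cube = _random_cube(rng)
        write_envi_cube(cube, tmp_path / "c.hdr")
        hdr = (tmp_path / "c.hdr").read_text()
        (tmp_path / "c.hdr").write_text(
            "\n".join(l for l in hdr.splitlines() if not l.startswith("wavelength ="))
        )
        with pytest.raises(EnviFormatError):
            read_envi_cube(tmp_path / "c.hdr")


class TestCalibration:
    @pytest.fixture
    def refs(self, rng):
        white = 3000 + 100 * rng.random((5, 16))
        dark = 100 + 10 * rng.random((5, 16))
        return ReferenceFrames(white=white, dark=dark)

    def _grid16(self):
        return WavelengthGrid(np.linspace(900, 1700, 16))

    def test_white_maps_to_100(self, refs):
        raw = Hypercube(np.tile(refs.white, (3, 1, 1)), self._grid16())
        out = calibrate_reflectance(raw, refs)
        assert out.kind == "reflectance_percent"
        np.testing.assert_allclose(out.data, 100.0, atol=1e-10)

    def test_dark_maps_to_0(self, refs):
        raw = Hypercube(np.tile(refs.dark, (3, 1, 1)), self._grid16())
        np.testing.assert_allclose(
            calibrate_reflectance(raw, refs).data, 0.0, atol=1e-10
        )

    def test_midpoint_maps_to_50(self, refs):
        mid = (refs.white + refs.dark) / 2
        raw = Hypercube(np.tile(mid, (2, 1, 1)), self._grid16())
        np.testing.assert_allclose(
            calibrate_reflectance(raw, refs).data, 50.0, atol=1e-9
        )

    def test_degenerate_denominator_masked(self):
        white = np.full((2, 16), 100.0)
        dark = np.full((2, 16), 100.0)  # W - B = 0 < eps everywhere
        raw = Hypercube(np.full((2, 2, 16), 50.0), self._grid16())
        out = calibrate_reflectance(raw, ReferenceFrames(white, dark))
        assert np.isnan(out.data).all()

    def test_shape_mismatch_raises(self, refs):
        raw = Hypercube(np.zeros((3, 4, 16)), self._grid16())
        with pytest.raises(ValueError, match="shape"):
            calibrate_reflectance(raw, refs)


class TestAbsorbance:
    @pytest.mark.parametrize("r_pct,expected", [(100.0, 0.0), (10.0, 1.0), (1.0, 2.0)])
    def test_log_reference_points(self, r_pct, expected):
        absorb, n_masked = reflectance_to_absorbance(np.array([r_pct]))
        assert n_masked == 0
        assert absorb[0] == pytest.approx(expected, abs=1e-12)

    def test_round_trip_bijection(self, rng):
        r = 10 ** rng.uniform(-2, 2, size=500)  # percent reflectance in (0.01, 100)
        a, _ = reflectance_to_absorbance(r)
        np.testing.assert_allclose(absorbance_to_reflectance(a), r, rtol=1e-10)

    def test_non_positive_masked_with_count(self):
        with pytest.warns(UserWarning, match="non-positive"):
            absorb, n_masked = reflectance_to_absorbance(np.array([50.0, 0.0, -1.0]))
        assert n_masked == 2
        assert np.isnan(absorb[1:]).all() and np.isfinite(absorb[0])


class TestRoiMean:
    def _cube(self, values):
        p = values.shape[-1]
        return Hypercube(values, WavelengthGrid(np.linspace(900, 1700, p)),
                         kind="absorbance")

    def test_single_pixel_mask(self, rng):
        data = rng.random((4, 4, 8))
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 1] = True
        spec = extract_roi_mean(self._cube(data), RoiMask(mask, "one"))
        np.testing.assert_array_equal(spec.values, data[2, 1])

    def test_uniform_cube_any_mask(self, rng):
        data = np.broadcast_to(rng.random(8), (4, 4, 8)).copy()
        mask = rng.random((4, 4)) > 0.5
        mask[0, 0] = True
        spec = extract_roi_mean(self._cube(data), RoiMask(mask))
        np.testing.assert_allclose(spec.values, data[0, 0])

    def test_three_pixel_mask_matches_bruteforce(self, rng):
        data = rng.random((4, 4, 8))
        pixels = [(0, 1), (2, 2), (3, 0)]
        mask = np.zeros((4, 4), dtype=bool)
        for l, s in pixels:
            mask[l, s] = True
        expected = sum(data[l, s] for l, s in pixels) / 3  # brute-force oracle
        spec = extract_roi_mean(self._cube(data), RoiMask(mask))
        np.testing.assert_allclose(spec.values, expected, rtol=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no true pixel"):
            RoiMask(np.zeros((4, 4), dtype=bool))

    def test_raw_cube_rejected(self, rng):
        cube = Hypercube(rng.random((4, 4, 8)),
                         WavelengthGrid(np.linspace(900, 1700, 8)), kind="raw")
        with pytest.raises(ValueError, match="calibrate"):
            extract_roi_mean(cube, RoiMask(np.ones((4, 4), dtype=bool)))


class TestWavelengthGrid:
    def test_default_instrument_grid(self):
        g = default_grid()
        assert g.count == 256
        assert g.values[0] == 900.0 and g.values[-1] == 1700.0

    @pytest.mark.parametrize(
        "values", [[1000.0], [1000.0, 999.0], [100.0, 1000.0], [1000.0, 2700.0]]
    )
    def test_invalid_grids_rejected(self, values):
        with pytest.raises(ValueError):
            WavelengthGrid(np.array(values))
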