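"""Cube I/O, whiteboard calibration, ROI masks and band truncation."""

import numpy as np
import pytest

from pearhsi import (
    CalibrationPair,
    CalibrationError,
    ContractError,
    FormatError,
    Hypercube,
    ROISpec,
    SpectrumTable,
    elliptical_roi_mask,
    mean_roi_spectrum,
    read_envi_cube,
    read_hdf5_cube,
    reflectance_correct,
    truncate_bands,
    write_envi_cube,
    write_hdf5_cube,
)
from pearhsi.synthetic import wavelength_grid


def _cube(rng, rows=4, cols=4, bands=8, lo=900.0, hi=1700.0):
    wl = np.linspace(lo, hi, bands)
    return Hypercube(rng.uniform(0.1, 1.0, (rows, cols, bands)), wl)


class TestEnviIO:
    def test_round_trip_identity(self, tmp_path, rng):
        cube = _cube(rng)
        hdr = write_envi_cube(cube, tmp_path / "cube.hdr")
        back = read_envi_cube(hdr)
        np.testing.assert_allclose(back.data, cube.data, atol=1e-6)
        np.testing.assert_allclose(back.wavelengths, cube.wavelengths, atol=1e-4)

    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_interleaves(self, tmp_path, rng, interleave):
        cube = _cube(rng, 3, 5, 6)
        hdr = write_envi_cube(cube, tmp_path / f"c_{interleave}.hdr",
                              interleave=interleave, dtype="float64")
        back = read_envi_cube(hdr)
        np.testing.assert_allclose(back.data, cube.data)

    def test_512_band_instrument_grid(self, tmp_path, rng):
        wl = wavelength_grid()
        cube = Hypercube(rng.uniform(0, 1, (2, 2, len(wl))), wl)
        back = read_envi_cube(write_envi_cube(cube, tmp_path / "g.hdr"))
        assert back.n_bands == 512
        np.testing.assert_allclose(back.wavelengths, wl, atol=1e-4)

    def test_band_count_mismatch_is_format_error(self, tmp_path, rng):
        cube = _cube(rng, bands=8)
        hdr = write_envi_cube(cube, tmp_path / "bad.hdr")
        # truncate the data file to 7 bands' worth of values
        data = hdr.with_suffix(".dat")
        raw = np.fromfile(data, dtype=np.float32)
        raw[: 7 * 16].tofile(data)
        with pytest.raises(FormatError):
            read_envi_cube(hdr)

    def test_missing_data_file(self, tmp_path, rng):
        cube = _cube(rng)
        hdr = write_envi_cube(cube, tmp_path / "gone.hdr")
        hdr.with_suffix(".dat").unlink()
        with pytest.raises(FileNotFoundError):
            read_envi_cube(hdr)

    def test_hdf5_round_trip(self, tmp_path, rng):
        cube = _cube(rng)
        cube.metadata["note"] = "synthetic"
        back = read_hdf5_cube(write_hdf5_cube(cube, tmp_path / "c.h5"))
        np.testing.assert_allclose(back.data, cube.data)
        assert back.metadata["note"] == "synthetic"


class TestReflectanceCorrect:
    def _pair(self, rng, shape=(3, 3, 5)):
        wl = np.linspace(950, 1650, shape[2])
        white = Hypercube(rng.uniform(2000, 4000, shape), wl)
        dark = Hypercube(rng.uniform(50, 150, shape), wl)
        return wl, CalibrationPair(white, dark)

    def test_raw_equals_white_gives_unity(self, rng):
        wl, pair = self._pair(rng)
        out = reflectance_correct(Hypercube(pair.white.data.copy(), wl), pair)
        np.testing.assert_allclose(out.data, 1.0, atol=1e-12)

    def test_raw_equals_dark_gives_zero(self, rng):
        wl, pair = self._pair(rng)
        out = reflectance_correct(Hypercube(pair.dark.data.copy(), wl), pair)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        wl, pair = self._pair(rng)
        raw = Hypercube(rng.uniform(100, 3000, (3, 3, 5)), wl)
        out = reflectance_correct(raw, pair, clip_negative=False)
        expected = np.empty_like(raw.data)
        for i in range(3):
            for j in range(3):
                for k in range(5):
                    expected[i, j, k] = (
                        (raw.data[i, j, k] - pair.dark.data[i, j, k])
                        / (pair.white.data[i, j, k] - pair.dark.data[i, j, k]))
        np.testing.assert_allclose(out.data, expected, rtol=1e-14)

    def test_invariant_under_common_rescaling(self, rng):
        # scaling both (RO-RD) and (RW-RD) by the same factor leaves R fixed
        wl, pair = self._pair(rng)
        raw = Hypercube(rng.uniform(200, 3000, (3, 3, 5)), wl)
        base = reflectance_correct(raw, pair, clip_negative=False)
        c = 3.7
        raw2 = Hypercube(pair.dark.data + c * (raw.data - pair.dark.data), wl)
        white2 = Hypercube(pair.dark.data + c * (pair.white.data - pair.dark.data), wl)
        out2 = reflectance_correct(raw2, CalibrationPair(white2, pair.dark),
                                   clip_negative=False)
        np.testing.assert_allclose(out2.data, base.data, rtol=1e-10)

    def test_dead_pixels_filled_and_counted(self, rng):
        wl, pair = self._pair(rng)
        pair.white.data[1, 1, 2] = pair.dark.data[1, 1, 2]
        raw = Hypercube(rng.uniform(200, 3000, (3, 3, 5)), wl)
        out = reflectance_correct(raw, pair, fill_value=0.0)
        assert out.data[1, 1, 2] == 0.0
        assert out.metadata["invalid_pixels"] == "1"

    def test_identical_references_raise(self, rng):
        wl = np.linspace(950, 1650, 5)
        frame = rng.uniform(100, 200, (3, 3, 5))
        pair = CalibrationPair(Hypercube(frame.copy(), wl), Hypercube(frame.copy(), wl))
        with pytest.raises(CalibrationError):
            reflectance_correct(Hypercube(frame.copy(), wl), pair)

    def test_shape_mismatch_raises(self, rng):
        wl, pair = self._pair(rng)
        raw = Hypercube(rng.uniform(0, 1, (2, 3, 5)), wl)
        with pytest.raises(ContractError):
            reflectance_correct(raw, pair)

    def test_correction_commutes_with_roi_mean_for_shared_frames(self, rng):
        # spatially flat calibration frames: correcting the mean ROI spectrum
        # equals taking the mean of corrected pixel spectra
        shape = (6, 6, 5)
        wl = np.linspace(950, 1650, 5)
        white = Hypercube(np.broadcast_to(
            rng.uniform(2000, 4000, 5), shape).copy(), wl)
        dark = Hypercube(np.broadcast_to(rng.uniform(50, 150, 5), shape).copy(), wl)
        pair = CalibrationPair(white, dark)
        raw = Hypercube(rng.uniform(200, 3000, shape), wl)
        mask = elliptical_roi_mask((6, 6), ROISpec(2.5, 2.5, 2.0, 1.5))
        corrected_then_mean = mean_roi_spectrum(reflectance_correct(raw, pair), mask)
        mean_raw = mean_roi_spectrum(raw, mask)
        mean_then_corrected = (mean_raw - dark.data[0, 0]) / (
            white.data[0, 0] - dark.data[0, 0])
        np.testing.assert_allclose(corrected_then_mean, mean_then_corrected,
                                   rtol=1e-12)


class TestEllipticalROI:
    def test_matches_exhaustive_enumeration(self):
        roi = ROISpec(63.5, 63.5, 45, 30)
        mask = elliptical_roi_mask((128, 128), roi)
        count = 0
        for r in range(128):
            for c in range(128):
                if ((r - 63.5) / 45) ** 2 + ((c - 63.5) / 30) ** 2 <= 1:
                    count += 1
                    assert mask[r, c]
        assert mask.sum() == count
        assert abs(count - np.pi * 45 * 30) / count < 0.02

    def test_subpixel_ellipse_is_center_pixel(self):
        mask = elliptical_roi_mask((9, 9), ROISpec(4, 4, 0.5, 0.5))
        assert mask.sum() == 1 and mask[4, 4]

    def test_reflection_symmetry(self):
        mask = elliptical_roi_mask((41, 41), ROISpec(20, 20, 12, 7))
        np.testing.assert_array_equal(mask, mask[::-1, :])
        np.testing.assert_array_equal(mask, mask[:, ::-1])

    def test_orientation_swaps_axes(self):
        row_mask = elliptical_roi_mask((41, 41), ROISpec(20, 20, 12, 7, "row-aligned"))
        col_mask = elliptical_roi_mask((41, 41), ROISpec(20, 20, 12, 7, "col-aligned"))
        np.testing.assert_array_equal(row_mask, col_mask.T)

    def test_out_of_bounds_raises(self):
        with pytest.raises(ContractError):
            elliptical_roi_mask((40, 40), ROISpec(20, 20, 25, 10))


class TestMeanROISpectrum:
    def test_constant_cube(self, rng):
        wl = np.linspace(950, 1650, 4)
        cube = Hypercube(np.full((5, 5, 4), 0.7), wl)
        mask = elliptical_roi_mask((5, 5), ROISpec(2, 2, 2, 1))
        np.testing.assert_allclose(mean_roi_spectrum(cube, mask), 0.7)

    def test_hand_computed_mean(self):
        wl = np.array([1000.0, 1100.0])
        data = np.array([[[0.2, 0.4], [0.6, 0.8]],
                         [[1.0, 0.0], [0.2, 0.8]]])
        cube = Hypercube(data, wl)
        mask = np.array([[True, True], [True, False]])
        np.testing.assert_allclose(mean_roi_spectrum(cube, mask),
                                   [(0.2 + 0.6 + 1.0) / 3, (0.4 + 0.8 + 0.0) / 3])

    def test_single_pixel(self, rng):
        cube = _cube(rng, 3, 3, 5)
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = True
        np.testing.assert_allclose(mean_roi_spectrum(cube, mask), cube.data[1, 2])

    def test_empty_mask_raises(self, rng):
        cube = _cube(rng, 3, 3, 5)
        with pytest.raises(ContractError):
            mean_roi_spectrum(cube, np.zeros((3, 3), dtype=bool))


class TestTruncateBands:
    def test_fixed_grid_keeps_421(self, small_table):
        raw_wl = wavelength_grid()
        assert ((raw_wl >= 950) & (raw_wl <= 1650)).sum() == 421
        assert small_table.n_bands == 421

    def test_full_window_is_identity(self, rng):
        wl = np.linspace(950, 1650, 20)
        t = SpectrumTable(rng.uniform(0, 1, (3, 20)), wl)
        out = truncate_bands(t, 900, 1700)
        np.testing.assert_array_equal(out.spectra, t.spectra)

    def test_inclusive_endpoints_hand_grid(self, rng):
        wl = np.array([940.0, 950.0, 1000.0, 1650.0, 1651.0])
        t = SpectrumTable(rng.uniform(0, 1, (2, 5)), wl)
        out = truncate_bands(t, 950, 1650)
        np.testing.assert_array_equal(out.wavelengths, [950.0, 1000.0, 1650.0])

    def test_idempotent(self, rng):
        wl = np.linspace(900, 1700, 64)
        t = SpectrumTable(rng.uniform(0, 1, (4, 64)), wl)
        once = truncate_bands(t, 950, 1650)
        twice = truncate_bands(once, 950, 1650)
        np.testing.assert_array_equal(once.spectra, twice.spectra)

    def test_empty_selection_raises(self, rng):
        wl = np.linspace(900, 940, 8)
        t = SpectrumTable(rng.uniform(0, 1, (2, 8)), wl)
        with pytest.raises(ContractError):
            truncate_bands(t, 950, 1650)
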