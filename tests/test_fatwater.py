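"""Echo-train merging, field-map estimation, and water-fat decomposition."""

import numpy as np
import pytest

from marrowqib import phantom
from marrowqib.fatwater import (
    FatSpectrum,
    MultiEchoSeries,
    combine_series,
    decompose_water_fat,
    estimate_fieldmap,
    fat_modulation,
    mge_te_schedule,
    pdff_quality_flags,
    residual_landscape,
)
from marrowqib.io_formats import ImageVolume


def make_series(w, f, psi_hz, te_ms, shape=(1, 1, 1), spectrum=None, f0=300.0):
    """Noise-free series from the signal model (independent of the fit path)."""
    spectrum = spectrum or FatSpectrum()
    w = np.broadcast_to(np.asarray(w, dtype=complex), shape)
    f = np.broadcast_to(np.asarray(f, dtype=complex), shape)
    psi = np.broadcast_to(np.asarray(psi_hz, dtype=float), shape)
    echoes = []
    for te in te_ms:
        c = fat_modulation(np.array([te]), spectrum, f0)[0]
        s = (w + f * c) * np.exp(2j * np.pi * psi * te * 1e-3)
        echoes.append(ImageVolume(np.asarray(s), (0.1, 0.1, 0.3)))
    return MultiEchoSeries(echoes, list(te_ms), f0)


TE12 = sorted(te for series in mge_te_schedule() for te in series)


class TestCombineSeries:
    def test_paper_schedule_merges_sorted_and_interleaved(self, rng):
        shape = (2, 2, 1)
        series = []
        for te_list in mge_te_schedule():
            echoes = [
                ImageVolume(rng.standard_normal(shape) + 0j, (0.1, 0.1, 0.3))
                for _ in te_list
            ]
            series.append(MultiEchoSeries(echoes, list(te_list)))
        merged = combine_series(series)
        assert merged.te_ms == TE12
        assert merged.te_ms[:5] == [1.476, 1.793, 2.110, 2.427, 3.650]
        # the four staggered series interleave with 0.317 ms offsets
        offsets = np.diff(merged.te_ms[:4])
        np.testing.assert_allclose(offsets, 0.317, atol=1e-9)

    def test_shuffled_input_order_gives_identical_output(self, rng):
        shape = (2, 2, 1)
        series = []
        for te_list in mge_te_schedule():
            echoes = [ImageVolume(rng.standard_normal(shape) + 0j, (0.1, 0.1, 0.3)) for _ in te_list]
            series.append(MultiEchoSeries(echoes, list(te_list)))
        a = combine_series(series)
        b = combine_series(series[::-1])
        assert a.te_ms == b.te_ms
        for ea, eb in zip(a.echoes, b.echoes):
            np.testing.assert_array_equal(ea.data, eb.data)

    def test_single_series_passthrough(self, rng):
        echoes = [ImageVolume(rng.standard_normal((2, 2, 1)) + 0j, (0.1, 0.1, 0.3)) for _ in range(3)]
        s = MultiEchoSeries(echoes, [1.0, 2.0, 3.0])
        merged = combine_series([s])
        assert merged.te_ms == [1.0, 2.0, 3.0]

    def test_duplicate_te_rejected(self, rng):
        mk = lambda: ImageVolume(rng.standard_normal((2, 2, 1)) + 0j, (0.1, 0.1, 0.3))
        a = MultiEchoSeries([mk(), mk()], [1.0, 2.0])
        b = MultiEchoSeries([mk(), mk()], [2.0, 3.0])
        with pytest.raises(ValueError):
            combine_series([a, b])


class TestFieldmap:
    def test_single_voxel_known_psi_matches_brute_force_oracle(self):
        series = make_series(60.0, 40.0, 40.0, TE12)
        mask = np.ones((1, 1, 1), dtype=bool)
        grid = np.arange(-100.0, 100.1, 2.0)
        res = residual_landscape(series.signals(mask), TE12, FatSpectrum(), grid)
        brute = grid[int(np.argmin(res[0]))]
        assert brute == pytest.approx(40.0, abs=1.0)  # oracle itself hits the grid point
        fm = estimate_fieldmap(series, mask, psi_range_hz=100.0, psi_step_hz=2.0)
        assert fm.data[0, 0, 0] == pytest.approx(brute, abs=1.0)

    def test_pure_water_zero_psi_recovered_as_zero(self):
        series = make_series(80.0, 0.0, 0.0, TE12, shape=(4, 4, 1))
        mask = np.ones((4, 4, 1), dtype=bool)
        fm = estimate_fieldmap(series, mask, psi_range_hz=100.0, psi_step_hz=2.0)
        np.testing.assert_allclose(fm.data, 0.0, atol=1e-9)

    def test_two_region_field_recovered_without_global_swap(self):
        """±60 Hz split phantom: smoothing keeps both regions on the true
        branch (labels checked voxelwise against the constructed truth)."""
        psi = np.zeros((8, 8, 1))
        psi[:4] = -60.0
        psi[4:] = 60.0
        series = make_series(70.0, 30.0, psi, TE12, shape=(8, 8, 1))
        mask = np.ones((8, 8, 1), dtype=bool)
        # adequate smoothness: strong enough to couple neighbors, weak
        # enough not to erode the genuine two-region boundary
        fm = estimate_fieldmap(
            series, mask, psi_range_hz=200.0, psi_step_hz=2.0,
            smoothness_weight=0.005, refine=True,
        )
        np.testing.assert_allclose(fm.data, psi, atol=1.0)

    def test_refinement_reaches_off_grid_psi(self):
        series = make_series(60.0, 40.0, 37.3, TE12, shape=(3, 3, 1))
        mask = np.ones((3, 3, 1), dtype=bool)
        fm = estimate_fieldmap(series, mask, psi_range_hz=100.0, psi_step_hz=10.0, refine=True)
        np.testing.assert_allclose(fm.data, 37.3, atol=1e-6)

    def test_fewer_than_three_echoes_rejected(self):
        series = make_series(1.0, 0.0, 0.0, [1.0, 2.0])
        with pytest.raises(ValueError):
            estimate_fieldmap(series, np.ones((1, 1, 1), dtype=bool))


class TestDecomposition:
    def test_pure_water_gives_zero_pdff(self):
        series = make_series(80.0, 0.0, 0.0, TE12, shape=(2, 2, 1))
        mask = np.ones((2, 2, 1), dtype=bool)
        zero = ImageVolume(np.zeros((2, 2, 1)), (0.1, 0.1, 0.3))
        out = decompose_water_fat(series, zero, mask)
        np.testing.assert_allclose(out.pdff.values.data, 0.0, atol=1e-9)
        np.testing.assert_allclose(out.w_map.data, 80.0, rtol=1e-12)

    def test_equal_water_fat_gives_fifty_percent(self):
        series = make_series(50.0, 50.0, 0.0, TE12, shape=(2, 2, 1))
        mask = np.ones((2, 2, 1), dtype=bool)
        zero = ImageVolume(np.zeros((2, 2, 1)), (0.1, 0.1, 0.3))
        out = decompose_water_fat(series, zero, mask)
        np.testing.assert_allclose(out.pdff.values.data, 50.0, atol=1e-9)

    def test_phantom_voxel_truth_pdff_recovered(self):
        """17.7% truth voxel, noise-free with the correct psi: within 0.1."""
        series = make_series(82.3, 17.7, 25.0, TE12, shape=(1, 1, 1))
        mask = np.ones((1, 1, 1), dtype=bool)
        psi_vol = ImageVolume(np.full((1, 1, 1), 25.0), (0.1, 0.1, 0.3))
        out = decompose_water_fat(series, psi_vol, mask)
        assert out.pdff.values.data[0, 0, 0] == pytest.approx(17.7, abs=0.1)

    def test_rank_deficient_te_set_rejected(self):
        single = FatSpectrum(shifts_ppm=(4.70,), amplitudes=(1.0,))  # fat == water
        series = make_series(50.0, 50.0, 0.0, TE12, spectrum=single)
        zero = ImageVolume(np.zeros((1, 1, 1)), (0.1, 0.1, 0.3))
        with pytest.raises(ValueError):
            decompose_water_fat(series, zero, np.ones((1, 1, 1), dtype=bool), spectrum=single)


class TestQualityFlags:
    def _result(self, psi):
        shape = psi.shape
        series = make_series(70.0, 30.0, psi, TE12, shape=shape)
        mask = np.ones(shape, dtype=bool)
        vol = ImageVolume(psi, (0.1, 0.1, 0.3))
        return decompose_water_fat(series, vol, mask)

    def test_smooth_field_raises_no_flags(self):
        psi = np.linspace(-10, 10, 8 * 8).reshape(8, 8, 1)
        flags = pdff_quality_flags(self._result(psi), {"S1": np.ones((8, 8, 1), dtype=bool)})
        assert flags == {"S1": False}

    def test_checkerboard_swap_flags_the_section(self):
        """Alternating ±80 Hz (swap signature) in S3 flags S3 only."""
        smooth = np.zeros((8, 8, 1))
        checker = 80.0 * ((np.indices((8, 8, 1)).sum(axis=0) % 2) * 2 - 1.0)
        result_smooth = self._result(smooth)
        result_checker = self._result(checker)
        # stitch: S1 smooth field, S3 checkerboard field
        masks = {"S1": np.ones((8, 8, 1), dtype=bool), "S3": np.ones((8, 8, 1), dtype=bool)}
        assert pdff_quality_flags(result_smooth, {"S1": masks["S1"]}) == {"S1": False}
        assert pdff_quality_flags(result_checker, {"S3": masks["S3"]})["S3"] is True

    def test_infinite_thresholds_never_flag(self):
        checker = 80.0 * ((np.indices((8, 8, 1)).sum(axis=0) % 2) * 2 - 1.0)
        flags = pdff_quality_flags(
            self._result(checker),
            {"S3": np.ones((8, 8, 1), dtype=bool)},
            roughness_threshold_hz=np.inf,
            residual_fraction_threshold=np.inf,
        )
        assert flags == {"S3": False}


def test_noise_free_phantom_pdff_recovery(small_geometry):
    """End-to-end W/F/psi pipeline reproduces pdff_true to < 0.1 points."""
    truth = phantom.make_phantom_truth(
        {"ADC": (0.1,) * 3, "PDFF": (4.8, 9.6, 17.7), "MTR": (0.3,) * 3},
        geometry=small_geometry, field_amplitude_hz=20.0,
    )
    series = phantom.synthesize_mge(truth)
    merged = combine_series(series)
    fm = estimate_fieldmap(merged, truth.voi_mask, psi_step_hz=10.0, refine=True)
    out = decompose_water_fat(merged, fm, truth.voi_mask)
    err = np.abs(out.pdff.values.data - truth.pdff_true.data)[truth.voi_mask]
    assert err.max() < 0.1
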