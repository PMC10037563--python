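"""Synthetic phantom generator: truth construction and forward models."""

import numpy as np
import pytest

from marrowqib import phantom
from marrowqib.fatwater import FatSpectrum, fat_modulation
from marrowqib.sections import SECTION_NAMES


def section_means(truth, qib):
    vol = {"ADC": truth.adc_true, "PDFF": truth.pdff_true, "MTR": truth.mtr_true}[qib]
    return [float(vol.data[truth.section_set.masks[s]].mean()) for s in SECTION_NAMES]


class TestTruth:
    def test_requested_wildtype_pdff_section_means_recovered(self, wt_truth):
        got = section_means(wt_truth, "PDFF")
        for g, want in zip(got, (4.8, 9.6, 17.7)):
            assert g == pytest.approx(want, rel=0.01)

    def test_constant_request_gives_constant_volume(self, small_geometry):
        truth = phantom.make_phantom_truth(
            {"ADC": (0.2, 0.2, 0.2), "PDFF": (10, 10, 10), "MTR": (0.3, 0.3, 0.3)},
            geometry=small_geometry,
        )
        np.testing.assert_allclose(truth.adc_true.data, 0.2)

    def test_zero_amplitude_fieldmap_is_identically_zero(self, small_geometry):
        truth = phantom.make_phantom_truth(
            {"ADC": (0.1, 0.1, 0.1), "PDFF": (5, 5, 5), "MTR": (0.3, 0.3, 0.3)},
            geometry=small_geometry, field_amplitude_hz=0.0,
        )
        assert not truth.fieldmap_true.data.any()

    def test_out_of_range_section_values_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            phantom.make_phantom_truth(
                {"ADC": (0.1,) * 3, "PDFF": (5, 120, 5), "MTR": (0.3,) * 3},
                geometry=small_geometry,
            )
        with pytest.raises(ValueError):
            phantom.make_phantom_truth(
                {"ADC": (0.1,) * 3, "PDFF": (5,) * 3, "MTR": (0.3, 1.0, 0.3)},
                geometry=small_geometry,
            )

    def test_voi_tube_reaches_all_three_sections(self, wt_truth):
        for s in SECTION_NAMES:
            assert wt_truth.section_set.masks[s].any()


class TestDwiModel:
    def test_closed_form_signal_decay(self, small_geometry):
        adc = np.log(10) / 3.0  # 0.7675 um^2/ms
        truth = phantom.make_phantom_truth(
            {"ADC": (adc,) * 3, "PDFF": (5,) * 3, "MTR": (0.3,) * 3},
            geometry=small_geometry,
        )
        dwi = phantom.synthesize_dwi(truth, s0=1000.0)
        voi = truth.voi_mask
        np.testing.assert_allclose(dwi.s_bx.data[voi], 100.0, rtol=1e-12)
        np.testing.assert_allclose(dwi.s_b0.data[voi], 1000.0)  # b=0 -> S0 exactly

    def test_zero_adc_keeps_signal_at_s0(self, small_geometry):
        truth = phantom.make_phantom_truth(
            {"ADC": (0.0,) * 3, "PDFF": (5,) * 3, "MTR": (0.3,) * 3},
            geometry=small_geometry,
        )
        dwi = phantom.synthesize_dwi(truth, s0=500.0)
        np.testing.assert_allclose(dwi.s_bz.data[truth.voi_mask], 500.0)

    def test_negative_noise_sd_rejected(self, wt_truth, rng):
        with pytest.raises(ValueError):
            phantom.synthesize_dwi(wt_truth, noise_sd=-1.0, rng=rng)


class TestMgeModel:
    def test_pure_water_magnitude_constant_across_echoes(self, small_geometry):
        truth = phantom.make_phantom_truth(
            {"ADC": (0.1,) * 3, "PDFF": (0.0,) * 3, "MTR": (0.3,) * 3},
            geometry=small_geometry, field_amplitude_hz=0.0, s0_mge=80.0,
        )
        series = phantom.synthesize_mge(truth)
        for s in series:
            for e in s.echoes:
                np.testing.assert_allclose(np.abs(e.data[truth.voi_mask]), 80.0, rtol=1e-12)

    def test_pure_fat_single_peak_magnitude_constant(self, small_geometry):
        truth = phantom.make_phantom_truth(
            {"ADC": (0.1,) * 3, "PDFF": (100.0,) * 3, "MTR": (0.3,) * 3},
            geometry=small_geometry, field_amplitude_hz=0.0, s0_mge=60.0,
        )
        single = FatSpectrum(shifts_ppm=(1.30,), amplitudes=(1.0,))
        series = phantom.synthesize_mge(truth, spectrum=single)
        for e in series[0].echoes:
            np.testing.assert_allclose(np.abs(e.data[truth.voi_mask]), 60.0, rtol=1e-12)

    def test_in_phase_vs_opposed_phase_against_model_sum(self, small_geometry):
        """W=F: |s| large at in-phase TE, strongly cancelled at the
        opposed-phase TE (minor peaks keep it nonzero); every magnitude
        checked against brute-force evaluation of the multi-peak model sum."""
        truth = phantom.make_phantom_truth(
            {"ADC": (0.1,) * 3, "PDFF": (50.0,) * 3, "MTR": (0.3,) * 3},
            geometry=small_geometry, field_amplitude_hz=0.0, s0_mge=100.0,
        )
        spectrum = FatSpectrum()
        f_dom = spectrum.offsets_hz(300.0)[np.argmax(spectrum.amplitudes)]  # ~ -1020 Hz
        te_in = 1.0 / abs(f_dom) * 1e3  # ms, full cycle of the dominant peak
        te_opp = te_in / 2
        series = phantom.synthesize_mge(truth, te_schedule_ms=[[te_opp, te_in]])
        voxel = tuple(np.argwhere(truth.voi_mask)[0])
        s_opp, s_in = (abs(series[0].echoes[i].data[voxel]) for i in (0, 1))
        # independent oracle: direct evaluation of W + F*sum_p alpha_p e^{i 2 pi f_p TE}
        w = f = 50.0
        for te, measured in ((te_opp, s_opp), (te_in, s_in)):
            oracle = abs(w + f * fat_modulation(np.array([te]), spectrum, 300.0)[0])
            assert measured == pytest.approx(oracle, rel=1e-12)
        assert s_in > 4 * s_opp  # near-cancellation at opposed phase

    def test_unsorted_te_list_rejected(self, small_geometry, wt_truth):
        with pytest.raises(ValueError):
            phantom.synthesize_mge(wt_truth, te_schedule_ms=[[2.0, 1.0, 3.0]])


class TestMtModel:
    def test_closed_form_saturation(self, small_geometry):
        truth = phantom.make_phantom_truth(
            {"ADC": (0.1,) * 3, "PDFF": (5,) * 3, "MTR": (0.4, 0.4, 0.4)},
            geometry=small_geometry,
        )
        pair = phantom.synthesize_mt_pair(truth, s_off=100.0)
        voi = truth.voi_mask
        np.testing.assert_allclose(pair.mt_on.data[voi], 60.0, rtol=1e-12)

    def test_zero_mtr_means_no_saturation_effect(self, small_geometry):
        truth = phantom.make_phantom_truth(
            {"ADC": (0.1,) * 3, "PDFF": (5,) * 3, "MTR": (0.0,) * 3},
            geometry=small_geometry,
        )
        pair = phantom.synthesize_mt_pair(truth, s_off=50.0)
        np.testing.assert_array_equal(pair.mt_off.data, pair.mt_on.data)

    def test_coil_falloff_degrades_distal_snr(self, wt_truth):
        pair = phantom.synthesize_mt_pair(wt_truth, s_off=100.0, coil_falloff=0.5)
        masks = wt_truth.section_set.masks
        s1 = pair.mt_off.data[masks["S1"]].mean()
        s3 = pair.mt_off.data[masks["S3"]].mean()
        assert s3 < s1


class TestTestRetest:
    def test_zero_wsd_gives_identical_sessions(self, rng):
        animal = {("PDFF", "S2"): 20.0}
        t, r = phantom.make_test_retest_pair(animal, {("PDFF", "S2"): 0.0}, rng)
        assert t == r == animal

    def test_wsd_recovery_from_many_pairs(self):
        """200 pairs with injected wSD 5.58 recover it within 15%."""
        from marrowqib.repeatability import wsd

        rng = np.random.default_rng(7)
        animal = {("PDFF", "S2"): 21.85}
        target = {("PDFF", "S2"): 5.58}
        pairs = [
            tuple(d[("PDFF", "S2")] for d in phantom.make_test_retest_pair(animal, target, rng))
            for _ in range(200)
        ]
        est = wsd(pairs)
        assert est == pytest.approx(5.58, rel=0.15)
        diffs = np.diff(np.asarray(pairs), axis=1)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se  # zero-mean construction


class TestCohort:
    def test_same_seed_reproduces_cohort_exactly(self):
        cfg = phantom.CohortConfig(n_animals=4, seed=11)
        a = phantom.make_longitudinal_cohort(cfg)
        b = phantom.make_longitudinal_cohort(phantom.CohortConfig(n_animals=4, seed=11))
        assert a.equals(b)

    def test_zero_variability_reproduces_cohort_trajectory(self):
        cfg = phantom.CohortConfig(
            n_animals=3,
            trajectories={("PDFF", "S2"): {3.5: (34.2, 0.0), 9.5: (18.3, 0.0)}},
            wsd={("PDFF", "S2"): 0.0},
            seed=0,
        )
        df = phantom.make_longitudinal_cohort(cfg)
        assert set(df["value"][df["weeks"] == 3.5]) == {34.2}
        assert set(df["value"][df["weeks"] == 9.5]) == {18.3}

    def test_default_s2_pdff_trajectory_declines(self):
        traj = phantom.DISEASED_TRAJECTORIES[("PDFF", "S2")]
        means = [traj[w][0] for w in sorted(traj)]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_unknown_timepoint_rejected(self):
        with pytest.raises(ValueError):
            phantom.CohortConfig(n_animals=2, timepoints_weeks=(4.0,))
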