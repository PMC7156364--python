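import math

import numpy as np
import pytest
from dataclasses import replace

from phantomqc import (
    BlockDesign,
    ROISpec,
    TimeSeries4D,
    TimeSignalCurve,
    baseline_stability,
    compute_qc_report,
    detect_stimuli,
    ghosting_ratio,
    kspace_stability,
    motion_summary,
    psc,
    psc_per_level,
    roi_curve,
    sensitivity,
    sfnr,
    simulate_series,
    snr,
    static_spatial_noise,
    temporal_fluctuation_noise,
)
from phantomqc.exceptions import ConfigurationError, InputError
from phantomqc.io_cli import wire_roi
from phantomqc.qc_metrics import default_background_rois, roi_summary, tfn_map


def series_from(data: np.ndarray, tr_ms: float = 2000.0) -> TimeSeries4D:
    return TimeSeries4D(
        data=np.asarray(data, float), voxel_size_mm=(3.75, 3.75, 5.0), TR_ms=tr_ms
    )


def curve(values, tr_ms=2000.0):
    return TimeSignalCurve(values=np.asarray(values, float), TR_ms=tr_ms)


class TestROISpec:
    def test_pixel_count_conventions(self):
        assert ROISpec((5, 5, 0), 3).n_pixels == 9
        assert ROISpec((5, 5, 0), 2).n_pixels == 4

    def test_roi_must_fit_inside_image(self):
        series = series_from(np.zeros((8, 8, 1, 4)))
        with pytest.raises(ConfigurationError):
            roi_curve(series, ROISpec((0, 4, 0), 3))
        with pytest.raises(ConfigurationError):
            roi_curve(series, ROISpec((4, 4, 3), 3))

    def test_square_footprint(self):
        sx, sy, _ = ROISpec((5, 5, 0), 3).slices()
        assert (sx.start, sx.stop, sy.start, sy.stop) == (4, 7, 4, 7)


class TestStaticSpatialNoise:
    def test_identical_volumes_cancel(self):
        series = series_from(np.full((4, 4, 1, 100), 7.0))
        assert np.all(static_spatial_noise(series) == 0.0)

    def test_alternating_volumes_hand_computed(self):
        # volume t = c + (-1)^t * d (1-based t), 100 volumes -> |sum_odd - sum_even| = 100 d
        c, d = 50.0, 0.25
        t = np.arange(1, 101)
        vols = c + ((-1.0) ** t) * d
        data = np.broadcast_to(vols, (3, 3, 1, 100))
        np.testing.assert_allclose(static_spatial_noise(series_from(data)), 100 * d)

    def test_matches_brute_force_loop_on_toy_array(self, rng):
        data = rng.uniform(10, 20, size=(4, 4, 1, 6))
        expected = np.zeros((4, 4, 1))
        for i in range(4):
            for j in range(4):
                odd = even = 0.0
                for t in range(6):  # 1-based volume number t+1
                    if (t + 1) % 2 == 1:
                        odd += data[i, j, 0, t]
                    else:
                        even += data[i, j, 0, t]
                expected[i, j, 0] = abs(odd - even)
        np.testing.assert_array_equal(
            static_spatial_noise(series_from(data)), expected
        )

    def test_odd_volume_count_truncated(self, rng):
        data = rng.normal(size=(2, 2, 1, 7))
        np.testing.assert_array_equal(
            static_spatial_noise(series_from(data)),
            static_spatial_noise(series_from(data[..., :6])),
        )

    def test_gaussian_noise_scaling_monte_carlo(self, rng):
        # |sum_odd - sum_even| over 100 iid N(0, sigma) volumes is half-normal
        # with underlying SD 10 sigma, hence mean 10 sigma sqrt(2/pi)
        sigma = 3.0
        data = rng.normal(0.0, sigma, size=(50, 50, 1, 100))
        values = static_spatial_noise(series_from(data)).ravel()
        assert values.mean() == pytest.approx(
            10 * sigma * math.sqrt(2 / math.pi), rel=0.05
        )


class TestTemporalFluctuation:
    def test_constant_series_has_zero_tfn(self):
        series = series_from(np.full((4, 4, 1, 10), 3.0))
        assert temporal_fluctuation_noise(series, ROISpec((2, 2, 0), 2)) == 0.0

    def test_alternating_voxel_population_sd(self):
        c, d = 100.0, 4.0
        vols = c + ((-1.0) ** np.arange(10)) * d
        series = series_from(np.broadcast_to(vols, (4, 4, 1, 10)))
        assert temporal_fluctuation_noise(series, ROISpec((2, 2, 0), 2)) == pytest.approx(d)

    def test_gaussian_tfn_converges_to_sigma(self, rng):
        sigma = 2.5
        data = 100 + rng.normal(0, sigma, size=(20, 20, 1, 400))
        series = series_from(data)
        assert tfn_map(series).mean() == pytest.approx(sigma, rel=0.02)


class TestRatios:
    def test_sfnr_direct_ratio(self):
        vols = 100.0 + ((-1.0) ** np.arange(100)) * 2.0  # mean 100, SD 2
        series = series_from(np.broadcast_to(vols, (3, 3, 1, 100)))
        assert sfnr(series, ROISpec((1, 1, 0), 3)) == pytest.approx(50.0)

    def test_sfnr_degenerate_constant_series_flagged(self):
        series = series_from(np.full((3, 3, 1, 10), 5.0))
        assert math.isinf(sfnr(series, ROISpec((1, 1, 0), 3)))

    def test_snr_unit_noise_returns_signal(self):
        assert snr(420.0, 1.0) == 420.0

    def test_snr_zero_noise_flagged_not_raised(self):
        assert math.isinf(snr(100.0, 0.0))

    def test_snr_negative_noise_rejected(self):
        with pytest.raises(InputError):
            snr(100.0, -0.1)

    def test_sfnr_halves_when_noise_doubles(self, preset, fast_acq):
        geometry, _, _, noise = preset
        acq = replace(fast_acq, n_volumes=200)
        design = BlockDesign(current_levels_mA=(0.0,))
        ratios = []
        for sigma in (2.0, 4.0):
            nm = replace(noise, thermal_sigma=sigma, noise_law="gaussian")
            series = simulate_series(geometry, acq, design, nm)
            ratios.append(sfnr(series, ROISpec((32, 32, 0), 3)))
        assert ratios[0] / ratios[1] == pytest.approx(2.0, rel=0.05)


class TestGhostingRatio:
    @staticmethod
    def crafted_series(up, down, left, right, center=100.0):
        data = np.zeros((64, 64, 1, 10))
        data[24:40, 24:40, 0, :] = center  # bright phantom block
        data[31:34, 52:55, 0, :] = up
        data[31:34, 8:11, 0, :] = down
        data[52:55, 31:34, 0, :] = right
        data[8:11, 31:34, 0, :] = left
        return series_from(data)

    ROIS = {
        "up": ROISpec((32, 53, 0), 3, "up"),
        "down": ROISpec((32, 9, 0), 3, "down"),
        "right": ROISpec((53, 32, 0), 3, "right"),
        "left": ROISpec((9, 32, 0), 3, "left"),
    }

    def test_symmetric_background_is_zero(self):
        series = self.crafted_series(1.0, 1.0, 1.0, 1.0)
        assert ghosting_ratio(series, ROISpec((32, 32, 0), 3), self.ROIS) == 0.0

    def test_hand_computed_ratio(self):
        # (up + down) - (right + left) = 4 - 2 over 2 x 100 -> 1 %
        series = self.crafted_series(3.0, 1.0, 1.0, 1.0)
        assert ghosting_ratio(
            series, ROISpec((32, 32, 0), 3), self.ROIS
        ) == pytest.approx(1.0)

    def test_background_overlapping_phantom_rejected(self):
        series = self.crafted_series(1.0, 1.0, 1.0, 1.0)
        rois = dict(self.ROIS, up=ROISpec((32, 38, 0), 3, "up"))
        with pytest.raises(ConfigurationError):
            ghosting_ratio(series, ROISpec((32, 32, 0), 3), rois)

    def test_default_backgrounds_placed_outside_phantom(self, preset_series):
        rois = default_background_rois(preset_series, ROISpec((32, 32, 5), 3))
        assert set(rois) == {"up", "down", "left", "right"}

    def test_ratio_increases_with_injected_ghost(self, preset, fast_acq):
        geometry, _, _, noise = preset
        design = BlockDesign(current_levels_mA=(0.0,))
        ratios = []
        for g in (0.01, 0.05, 0.10):
            nm = replace(noise.silent(), ghost_fraction=g)
            series = simulate_series(geometry, fast_acq, design, nm)
            ratios.append(ghosting_ratio(series, ROISpec((32, 32, 0), 3)))
        assert ratios[0] < ratios[1] < ratios[2]


class TestPSC:
    DESIGN = BlockDesign(baseline_s=4.0, active_s=4.0, current_levels_mA=(24.0,))

    def test_no_change_gives_zero(self):
        assert psc(curve([100.0] * 8), self.DESIGN) == 0.0

    def test_three_percent_change(self):
        v = [100, 100, 103, 103] * 2
        assert psc(curve(v), self.DESIGN) == pytest.approx(3.0)

    def test_engineered_two_level_recovery_exact(self):
        # levels L and L (1 + p) -> PSC == 100 p, exactly
        L, p = 640.0, 0.042
        v = [L, L, L * (1 + p), L * (1 + p)] * 3
        assert psc(curve(v), self.DESIGN) == pytest.approx(100 * p, rel=1e-12)

    def test_transition_volume_excluded_from_active(self):
        # first active volume of each block is a switching transient
        v = [100, 100, 999, 103, 100, 100, 999, 103]
        design = BlockDesign(baseline_s=4.0, active_s=4.0)
        assert psc(curve(v), design) == pytest.approx(3.0)

    def test_design_free_mode_finds_obvious_change(self):
        v = np.full(40, 200.0)
        v[20:25] = 212.0
        assert psc(curve(v), None, window=5) == pytest.approx(6.0)

    def test_nonpositive_baseline_flagged(self):
        v = [0, 0, 1, 1] * 2
        assert math.isnan(psc(curve(v), self.DESIGN))

    def test_per_level_grouping(self):
        design = BlockDesign(
            baseline_s=4.0, active_s=4.0, current_levels_mA=(10.0, 20.0)
        )
        v = [100, 100, 101, 101, 100, 100, 104, 104] * 2
        out = psc_per_level(curve(v), design)
        assert out[10.0] == pytest.approx(1.0)
        assert out[20.0] == pytest.approx(4.0)


class TestDetectionAndSensitivity:
    def test_noise_free_stimuli_all_detected(self, preset, fast_acq):
        geometry, _, design, noise = preset
        series = simulate_series(geometry, fast_acq, design, noise.silent())
        n, flags = detect_stimuli(roi_curve(series, wire_roi(geometry, fast_acq)), design)
        assert n == len(flags) == 10

    def test_zero_current_detects_nothing(self, preset, fast_acq):
        geometry, _, _, noise = preset
        design = BlockDesign(current_levels_mA=(0.0,))
        series = simulate_series(geometry, fast_acq, design, noise.silent())
        n, _ = detect_stimuli(roi_curve(series, wire_roi(geometry, fast_acq)), design)
        assert n == 0

    def test_sensitivity_arithmetic(self):
        assert sensitivity(10, 10) == 100.0
        assert sensitivity(0, 10) == 0.0
        assert sensitivity(15, 20) == 75.0
        assert sensitivity(12, 20) == 60.0

    def test_sensitivity_input_validation(self):
        with pytest.raises(InputError):
            sensitivity(5, 0)
        with pytest.raises(InputError):
            sensitivity(11, 10)

    def test_curve_without_full_cycle_rejected(self):
        design = BlockDesign(baseline_s=4.0, active_s=4.0)
        with pytest.raises(InputError):
            detect_stimuli(curve([100.0, 100.0]), design)


class TestBaselineStability:
    def test_constant_curve(self):
        assert baseline_stability(curve([5.0] * 10)) == (0.0, 0.0)

    def test_hand_computed(self):
        pct, rng_ = baseline_stability(curve([100.0, 101.0, 99.0]))
        assert pct == pytest.approx(1.0)
        assert rng_ == pytest.approx(2.0)

    def test_preset_noise_keeps_baseline_quiet(self, preset_series, preset):
        geometry, acq, design, _ = preset
        report = compute_qc_report(
            preset_series, design, psc_roi=wire_roi(geometry, acq)
        )
        assert report.baseline_stability_pct < 1.0
        assert report.baseline_range < 10.0


class TestMotionSummary:
    def test_identical_volumes_no_motion(self, quiet_series):
        m = motion_summary(quiet_series)
        assert m["max_translation_mm"] == 0.0
        assert m["max_rotation_deg"] == 0.0

    def test_one_voxel_shift_translates_by_voxel_size(self, quiet_series):
        data = quiet_series.data[..., :4].copy()
        data[..., 2] = np.roll(data[..., 2], 1, axis=0)
        series = series_from(data)
        m = motion_summary(series)
        assert m["translation_mm"][2] == pytest.approx(3.75, abs=1e-6)

    def test_report_carries_qc_limits(self, preset_series, preset):
        geometry, acq, design, _ = preset
        report = compute_qc_report(
            preset_series, design, psc_roi=wire_roi(geometry, acq)
        )
        assert report.motion.translation_limit_mm == 0.1
        assert report.motion.rotation_limit_deg == 0.1
        assert report.motion.translation_ok and report.motion.rotation_ok


class TestKSpaceStability:
    def test_identical_volumes_zero_variation(self, quiet_series):
        assert kspace_stability(quiet_series)["max_variation"] == 0.0

    def test_spiked_volume_raises_variation(self, preset, fast_acq):
        geometry, _, _, noise = preset
        design = BlockDesign(current_levels_mA=(0.0,))
        base = simulate_series(geometry, fast_acq, design, noise.silent())
        spiked = base.data.copy()
        spiked[..., 7] *= 1.05
        v_clean = kspace_stability(base)["max_variation"]
        v_spiked = kspace_stability(series_from(spiked))["max_variation"]
        assert v_spiked > v_clean


class TestReportAssembly:
    def test_report_complete_and_serializable(self, preset_series, preset):
        geometry, acq, design, _ = preset
        report = compute_qc_report(
            preset_series, design, psc_roi=wire_roi(geometry, acq)
        )
        blob = report.model_dump_json()
        assert '"center_9px"' in blob and '"center_4px"' in blob
        assert report.rois[0].n_pixels == 9 and report.rois[1].n_pixels == 4
        assert set(report.psc_pct) == {"8 mA", "12 mA", "24 mA", "48 mA"}
        assert report.n_theoretical == 10
        assert report.ghosting_ratio_pct >= 0.0
        assert report.kspace_max_variation >= 0.0

    def test_roi_summary_on_2d_and_3d_maps(self, rng):
        m2 = rng.uniform(size=(8, 8))
        m3 = np.repeat(m2[:, :, None], 2, axis=2)
        roi = ROISpec((4, 4, 1), 3)
        assert roi_summary(m2, roi) == roi_summary(m3, roi)
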