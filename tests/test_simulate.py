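"""Tests of the indicator-dilution simulator: curve model, design defaults,
flow traces, image scenes and whole-study generation."""

from dataclasses import replace

import numpy as np
import pytest

from icgperf.curves import extract_roi_curve
from icgperf.simulate import (
    Group,
    KineticParams,
    PhaseSchedule,
    Roi,
    Timepoint,
    default_params,
    noiseless_signal,
    simulate_curve,
    simulate_flow_trace,
    simulate_scene,
    simulate_study,
)
from icgperf.scoring import chiu_grade

from conftest import fine_grid_oracle, random_draw_params


class TestSimulateCurve:
    def test_zero_inflow_yields_flat_curve_at_baseline(self):
        p = KineticParams(inflow_rate=0.0, baseline_offset=5.0, noise_sd=0.0)
        curve = simulate_curve(p)
        assert np.allclose(curve.intensity, 5.0, atol=1e-12)

    def test_pure_pooling_is_nondecreasing_after_delay(self):
        p = KineticParams(leak_fraction=1.0, noise_sd=0.0)
        curve = simulate_curve(p)
        after = curve.intensity[curve.time >= p.aif_delay]
        assert np.all(np.diff(after) >= -1e-12)

    @pytest.mark.parametrize("draw_seed", range(5))
    def test_peak_matches_fine_grid_quadrature_oracle(self, draw_seed):
        rng = np.random.default_rng(1000 + draw_seed)
        p = random_draw_params(rng)
        curve = simulate_curve(p)
        oracle_peak = fine_grid_oracle(p, duration=120.0)[0] + p.baseline_offset
        assert curve.intensity.max() == pytest.approx(oracle_peak, rel=0.01)

    def test_same_seed_gives_identical_curve(self):
        p = KineticParams(noise_sd=1.0)
        a = simulate_curve(p, seed=7)
        b = simulate_curve(p, seed=7)
        assert np.array_equal(a.intensity, b.intensity)
        c = simulate_curve(p, seed=8)
        assert not np.array_equal(a.intensity, c.intensity)

    @pytest.mark.parametrize(
        "bad_kwargs, field_name",
        [
            ({"inflow_rate": -1.0}, "inflow_rate"),
            ({"leak_fraction": 1.5}, "leak_fraction"),
            ({"aif_scale": 0.0}, "aif_scale"),
            ({"noise_sd": float("nan")}, "noise_sd"),
            ({"recirc_fraction": 1.0}, "recirc_fraction"),
        ],
    )
    def test_invalid_parameters_name_the_offending_field(self, bad_kwargs, field_name):
        with pytest.raises(ValueError, match=field_name):
            KineticParams(**bad_kwargs)

    def test_too_coarse_sampling_rejected(self):
        with pytest.raises(ValueError):
            simulate_curve(KineticParams(), duration=10.0, dt=2.0)

    def test_peak_and_slope_strictly_increase_with_inflow(self):
        """Flow/kinetics coupling on a grid of five inflow rates."""
        peaks, slopes = [], []
        for f in [0.5, 1.0, 2.0, 3.0, 5.0]:
            p = KineticParams(inflow_rate=f, noise_sd=0.0)
            c = simulate_curve(p)
            peaks.append(c.intensity.max() - p.baseline_offset)
            slopes.append(np.max(np.diff(c.intensity)) / c.dt)
        assert np.all(np.diff(peaks) > 0)
        assert np.all(np.diff(slopes) > 0)

    def test_leak_controls_late_dye_retention(self):
        """Pooling keeps >50% of the peak at 120 s; washout does not."""
        pooled = simulate_curve(KineticParams(leak_fraction=0.5, noise_sd=0.0))
        rel = (pooled.intensity[-1] - pooled.intensity[0]) / (
            pooled.intensity.max() - pooled.intensity[0]
        )
        assert rel > 0.5
        washed = simulate_curve(
            KineticParams(leak_fraction=0.0, washout_rate=0.05, noise_sd=0.0)
        )
        rel = (washed.intensity[-1] - washed.intensity[0]) / (
            washed.intensity.max() - washed.intensity[0]
        )
        assert rel < 0.5


class TestDefaultParams:
    def test_occluded_ischemic_zone_has_zero_inflow(self):
        p = default_params("I", "D1", "T1")
        assert p.inflow_rate == 0.0

    def test_occluded_noiseless_curve_has_zero_peak_minus_baseline(self):
        p = default_params("II", "D1", "T1", noise_sd=0.0)
        c = simulate_curve(p)
        assert c.intensity.max() - p.baseline_offset == pytest.approx(0.0, abs=1e-12)

    def test_transitional_zone_inflow_between_ischemic_and_control(self):
        for g in Group:
            d1 = default_params(g, "D1", "T1").inflow_rate
            d2 = default_params(g, "D2", "T1").inflow_rate
            d3 = default_params(g, "D3", "T1").inflow_rate
            assert d1 < d2 < d3

    def test_control_tissue_never_leaks(self):
        for g in Group:
            for tp in Timepoint:
                assert default_params(g, "D3", tp).leak_fraction == 0.0

    def test_reperfusion_restores_ischemic_inflow_above_baseline_in_group_ii(self):
        t0 = default_params("II", "D1", "T0").inflow_rate
        t2 = default_params("II", "D1", "T2").inflow_rate
        assert t2 > t0

    def test_leak_only_after_prolonged_ischemia(self):
        assert default_params("I", "D1", "T2").leak_fraction == 0.0
        assert default_params("II", "D1", "T2").leak_fraction > 0.0
        assert default_params("III", "D1", "T2").leak_fraction > 0.0
        assert default_params("II", "D1", "T1").leak_fraction == 0.0

    def test_unknown_enum_rejected(self):
        with pytest.raises(ValueError, match="Roi"):
            default_params("I", "D9", "T0")


class TestFlowTrace:
    def test_occlusion_flow_is_exactly_zero(self):
        for g in Group:
            trace = simulate_flow_trace(g, "T1", seed=0)
            assert np.all(trace.flow == 0.0)

    def test_seeded_determinism(self):
        a = simulate_flow_trace("III", "T2", seed=5)
        b = simulate_flow_trace("III", "T2", seed=5)
        assert np.array_equal(a.flow, b.flow)

    def test_monte_carlo_mean_matches_generator_hyperemia(self):
        means = [
            simulate_flow_trace("II", "T2", seed=s).mean_flow for s in range(1000)
        ]
        assert np.mean(means) == pytest.approx(97.1, abs=3.0)

    def test_baseline_mean_matches_generator(self):
        means = [
            simulate_flow_trace("I", "T0", seed=s).mean_flow for s in range(500)
        ]
        assert np.mean(means) == pytest.approx(69.7, abs=3.0)


class TestScene:
    def test_noiseless_mask_means_equal_generating_curves(self):
        sched = PhaseSchedule(group="II", phase="T0")
        params = {
            r.value: replace(default_params("II", r, "T0"), noise_sd=0.0)
            for r in Roi
        }
        scene = simulate_scene(sched, seed=3, params_by_roi=params)
        for roi in ("D1", "D2", "D3"):
            curve = extract_roi_curve(scene, roi)
            ref = noiseless_signal(params[roi], scene.frame_times, 0.5)
            assert np.allclose(curve.intensity, ref, rtol=1e-12, atol=1e-12)

    def test_seeded_scene_is_bit_identical(self):
        sched = PhaseSchedule(group="I", phase="T2")
        a = simulate_scene(sched, seed=11)
        b = simulate_scene(sched, seed=11)
        assert np.array_equal(a.frames, b.frames)

    def test_noisy_mask_mean_within_clt_bound_of_generating_curve(self):
        sched = PhaseSchedule(group="I", phase="T0")
        params = {
            r.value: replace(default_params("I", r, "T0"), noise_sd=2.0) for r in Roi
        }
        scene = simulate_scene(
            sched, image_size=(64, 170), seed=9, params_by_roi=params
        )
        for roi in ("D1", "D3"):
            mask_size = scene.roi_masks[roi].sum()
            assert mask_size >= 2500  # ~50x50
            curve = extract_roi_curve(scene, roi)
            ref = noiseless_signal(params[roi], scene.frame_times, 0.5)
            dev = np.abs(curve.intensity - ref)
            sigma = 2.0 / np.sqrt(mask_size)
            # 3-sigma bound holds at the CLT rate (99.7%), 5 sigma always
            assert np.mean(dev < 3.0 * sigma) >= 0.985
            assert np.all(dev < 5.0 * sigma)

    def test_frames_cover_120_seconds(self):
        scene = simulate_scene(PhaseSchedule(group="I", phase="T0"), seed=0)
        assert scene.frame_times[-1] == pytest.approx(120.0)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            simulate_scene(PhaseSchedule(group="I", phase="T0"), image_size=(8, 8))


class TestStudy:
    def test_default_design_has_18_animals_and_378_measurements(self):
        study = simulate_study(seed=0, dt=1.0)  # coarse dt: counting only
        assert len(study.animal_ids) == 18
        assert len(study) == 18 * 3 * 7

    def test_mild_groups_control_histology_maps_to_low_chiu_grade(self, small_study):
        for (animal, roi), desc in small_study.histology.items():
            if roi is Roi.D3 or roi is Roi.D2:
                assert chiu_grade(desc) <= 2

    def test_ischemic_zone_histology_tracks_ischemia_duration(self, small_study):
        expected = {"I": 3, "II": 4, "III": 5}
        for (animal, roi), desc in small_study.histology.items():
            if roi is Roi.D1:
                assert chiu_grade(desc) == expected[animal.split("-")[0]]

    def test_same_seed_reproduces_study(self):
        kw = dict(n_per_group={"I": 1, "II": 1, "III": 1}, seed=5, dt=0.5)
        a, b = simulate_study(**kw), simulate_study(**kw)
        for ma, mb in zip(a, b):
            assert ma.animal_id == mb.animal_id
            assert np.array_equal(ma.curve.intensity, mb.curve.intensity)
            assert ma.macro == mb.macro

    def test_control_area_macro_score_stays_at_floor(self, small_study):
        for m in small_study:
            if m.roi is Roi.D3:
                assert m.macro.components == (1, 1, 1, 1)

    def test_invalid_group_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_study(n_per_group={"I": 0, "II": 1, "III": 1}, seed=0)
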