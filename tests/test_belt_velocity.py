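"""Unit and property tests of the belt-velocity estimation chain."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beltspeed.belt_velocity import (BeltConfig, GatingVolume, VelocitySamples,
                                     aggregate_frames, check_alignment,
                                     compute_belt_velocity,
                                     filter_persistence, gate_by_volume,
                                     lowpass_series, marker_velocity,
                                     reject_outliers)
from beltspeed.exceptions import (ConfigError, DegenerateGeometryError,
                                  EmptyResultError, GapTooLongError,
                                  SeriesTooShortError)
from beltspeed.io_c3d import Trajectory
from beltspeed.synthetic import BeltSceneConfig, simulate_belt

BELT_DIR = np.array([0.0, -1.0, 0.0])  # default axis convention


def _segment(positions, start=0, label="seg"):
    positions = np.asarray(positions, float)
    return Trajectory(label=label, start_frame=start, positions=positions,
                      gap_mask=np.zeros(len(positions), bool))


class TestAlignment:
    def test_axis_aligned_line_passes(self):
        rep = check_alignment((0, 1, 0), (0, 0, 0), tol_deg=1.0)
        assert rep.yaw_deg == pytest.approx(0.0, abs=1e-12)
        assert rep.inclination_deg == pytest.approx(0.0, abs=1e-12)
        assert rep.passed

    def test_yaw_is_arctangent_of_lateral_offset(self):
        rep = check_alignment((0.1, 1, 0), (0, 0, 0), tol_deg=1.0)
        assert rep.yaw_deg == pytest.approx(np.degrees(np.arctan(0.1)),
                                            rel=1e-9)
        assert not rep.passed

    def test_inclination_detects_tilt(self):
        rep = check_alignment((0, 1, 0.05), (0, 0, 0), tol_deg=1.0)
        assert rep.inclination_deg == pytest.approx(
            np.degrees(np.arctan(0.05)), rel=1e-9)
        assert not rep.passed

    def test_coincident_markers_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            check_alignment((1, 2, 3), (1, 2, 3), 1.0)


class TestGating:
    VOLS = (GatingVolume((-0.3, -0.7, -0.05), (-0.2, 0.7, 0.05), "left"),
            GatingVolume((0.2, -0.7, -0.05), (0.3, 0.7, 0.05), "right"))

    def test_inside_marker_unchanged(self):
        pos = np.column_stack([np.full(50, -0.25), np.linspace(0.5, -0.5, 50),
                               np.zeros(50)])
        segs = gate_by_volume([_segment(pos)], self.VOLS)
        assert len(segs) == 1
        np.testing.assert_array_equal(segs[0].positions, pos)

    def test_overhead_reflection_dropped(self):
        pos = np.column_stack([np.full(50, -0.25), np.zeros(50),
                               np.full(50, 0.5)])
        assert gate_by_volume([_segment(pos)], self.VOLS) == []

    def test_transit_clipped_to_in_volume_span(self):
        n = 300
        y = np.linspace(1.5, -1.5, n)  # enters the box and leaves it
        pos = np.column_stack([np.full(n, 0.25), y, np.zeros(n)])
        segs = gate_by_volume([_segment(pos)], self.VOLS)
        assert len(segs) == 1
        inside = np.abs(y) <= 0.7
        assert segs[0].start_frame == int(np.flatnonzero(inside)[0])
        assert segs[0].n_frames == int(inside.sum())


class TestPersistence:
    def test_boundary_20_kept_19_dropped(self):
        keep = _segment(np.zeros((20, 3)))
        drop = _segment(np.zeros((19, 3)))
        out = filter_persistence([keep, drop], 20)
        assert out == [keep]

    def test_flickering_artifact_removed(self):
        flicker = _segment(np.zeros((5, 3)))
        assert filter_persistence([flicker], 20) == []


class TestMarkerVelocity:
    def test_constant_advance_gives_constant_speed(self):
        n = 100
        pos = np.zeros((n, 3))
        pos[:, 1] = -0.012 * np.arange(n)  # 12 mm/frame toward -AP
        samples = marker_velocity(_segment(pos), 250.0, BELT_DIR)
        np.testing.assert_allclose(samples.speeds, 3.0, atol=1e-12)
        assert samples.frames[0] == 1 and samples.frames[-1] == n - 2

    def test_stationary_marker_zero_speed(self):
        samples = marker_velocity(_segment(np.ones((30, 3))), 250.0, BELT_DIR)
        np.testing.assert_allclose(samples.speeds, 0.0, atol=1e-15)

    def test_sinusoidal_speed_recovered_to_second_order(self):
        rate = 250.0
        t = np.arange(1000) / rate
        # position = integral of v(t) = 3 + 0.1 sin(2*pi*2 t)
        y = -(3.0 * t - 0.1 / (2 * np.pi * 2) * np.cos(2 * np.pi * 2 * t))
        pos = np.column_stack([np.zeros_like(t), y, np.zeros_like(t)])
        samples = marker_velocity(_segment(pos), rate, BELT_DIR)
        v_true = 3.0 + 0.1 * np.sin(2 * np.pi * 2 * t[1:-1])
        np.testing.assert_allclose(samples.speeds, v_true, atol=1e-4)

    def test_short_segment_rejected(self):
        with pytest.raises(SeriesTooShortError):
            marker_velocity(_segment(np.zeros((2, 3))), 250.0, BELT_DIR)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_central_difference_oracle_on_cubics(self, seed):
        """The computed speed equals the central difference of the cubic,
        evaluated independently from its coefficients."""
        rng = np.random.default_rng(seed)
        coeffs = rng.normal(0, 1, (3, 4))  # per-axis cubic
        rate = 250.0
        t = np.arange(50) / rate
        pos = np.stack([np.polyval(c, t) for c in coeffs], axis=1)
        d = rng.normal(0, 1, 3)
        d /= np.linalg.norm(d)
        samples = marker_velocity(_segment(pos), rate, d)
        proj = pos @ d
        oracle = (proj[2:] - proj[:-2]) * rate / 2.0
        np.testing.assert_allclose(samples.speeds, oracle, rtol=0, atol=1e-9)


class TestOutlierRejection:
    def _samples(self, speeds):
        speeds = np.asarray(speeds, float)
        return VelocitySamples("m", np.arange(speeds.size), speeds)

    def test_above_limit_removed(self):
        out = reject_outliers(self._samples([3.91]), 3.0, 0.30)
        assert len(out) == 0

    def test_exactly_at_limit_kept(self):
        out = reject_outliers(self._samples([3.0 * 1.3]), 3.0, 0.30)
        assert len(out) == 1

    def test_double_speed_marker_fully_removed(self):
        for v_target in (0.5, 1.0, 3.0, 6.0):
            out = reject_outliers(self._samples([2 * v_target] * 10),
                                  v_target, 0.30)
            assert len(out) == 0

    def test_lower_limit_off_by_default(self):
        out = reject_outliers(self._samples([0.1]), 3.0, 0.30)
        assert len(out) == 1
        out = reject_outliers(self._samples([0.1]), 3.0, 0.30,
                              lower_limit_fraction=0.30)
        assert len(out) == 0


class TestAggregate:
    def test_single_marker_passthrough(self):
        s = VelocitySamples("m", np.arange(5) + 2, np.full(5, 3.3))
        raw, counts = aggregate_frames([s], 0, 10)
        np.testing.assert_allclose(raw[2:7], 3.3)
        assert np.isnan(raw[0]) and np.isnan(raw[9])
        np.testing.assert_array_equal(counts[2:7], 1)

    def test_mean_of_two_markers(self):
        a = VelocitySamples("a", [4], [2.9])
        b = VelocitySamples("b", [4], [3.1])
        raw, counts = aggregate_frames([a, b], 0, 6)
        assert raw[4] == pytest.approx(3.0)
        assert counts[4] == 2

    def test_noise_averaging_follows_sqrt_n(self):
        """Per-frame SD of the mean scales as sigma/sqrt(N) over markers."""
        rng = np.random.default_rng(42)
        n_frames, sigma = 2000, 0.1
        sds = {}
        for n_markers in (2, 5, 10):
            samples = [VelocitySamples(f"m{i}", np.arange(n_frames),
                                       3.0 + rng.normal(0, sigma, n_frames))
                       for i in range(n_markers)]
            raw, _ = aggregate_frames(samples, 0, n_frames)
            sds[n_markers] = raw.std()
        for n_markers, sd in sds.items():
            assert sd == pytest.approx(sigma / np.sqrt(n_markers), rel=0.2)


class TestLowpass:
    RATE = 250.0

    def test_dc_gain_unity(self):
        filtered, mask = lowpass_series(np.full(1000, 3.0), self.RATE)
        np.testing.assert_allclose(filtered, 3.0, atol=1e-9)
        assert not mask.any()

    def test_passband_amplitude_and_phase(self):
        t = np.arange(2000) / self.RATE
        x = np.sin(2 * np.pi * 2.0 * t)
        filtered, _ = lowpass_series(x, self.RATE, 20.0, 4)
        core = slice(200, -200)
        amp = np.ptp(filtered[core]) / np.ptp(x[core])
        assert amp == pytest.approx(1.0, abs=0.01)
        # zero phase: peak location unchanged
        assert abs(int(np.argmax(filtered[core])) -
                   int(np.argmax(x[core]))) <= 1

    def test_stopband_attenuation(self):
        t = np.arange(2000) / self.RATE
        x = np.sin(2 * np.pi * 60.0 * t)
        filtered, _ = lowpass_series(x, self.RATE, 20.0, 4)
        assert np.ptp(filtered[200:-200]) <= 0.05 * np.ptp(x)

    def test_missing_frames_interpolated_and_flagged(self):
        x = np.full(1000, 2.0)
        x[100:110] = np.nan
        filtered, mask = lowpass_series(x, self.RATE)
        assert mask[100:110].all() and mask.sum() == 10
        np.testing.assert_allclose(filtered, 2.0, atol=1e-9)

    def test_long_gap_aborts(self):
        x = np.full(1000, 2.0)
        x[100:200] = np.nan  # 0.4 s
        with pytest.raises(GapTooLongError):
            lowpass_series(x, self.RATE)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            lowpass_series(np.zeros(1000), self.RATE, cutoff_hz=130.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(SeriesTooShortError):
            lowpass_series(np.zeros(10), self.RATE)


class TestFullPipeline:
    def test_constant_speed_recovered_exactly(self, clean_belt_scene):
        cfg, session, truth = clean_belt_scene
        series = compute_belt_velocity(session, cfg.belt_config())
        core = series.interior()
        assert np.abs(series.filtered[core] - 3.0).max() < 1e-6

    def test_artifacts_do_not_change_output(self, clean_belt_scene):
        cfg, session, _ = clean_belt_scene
        base = compute_belt_velocity(session, cfg.belt_config())
        noisy_cfg = dataclasses.replace(cfg, n_spurious_static=5,
                                        n_spurious_fast=2)
        session2, _ = simulate_belt(noisy_cfg)
        out = compute_belt_velocity(session2, noisy_cfg.belt_config())
        assert np.abs(out.filtered - base.filtered).max() < 1e-6

    def test_dip_profile_rmse_under_centimeter_per_second(self,
                                                          dip_belt_scene):
        cfg, session, truth = dip_belt_scene
        series = compute_belt_velocity(session, cfg.belt_config())
        core = series.interior()
        rmse = np.sqrt(np.mean(
            (series.filtered[core] - truth.speed[core]) ** 2))
        assert rmse < 0.01

    def test_redundancy_single_marker_removal(self, dip_belt_scene):
        cfg, session, _ = dip_belt_scene
        base = compute_belt_velocity(session, cfg.belt_config())
        rng = np.random.default_rng(0)
        for k in rng.choice(len(session.unlabeled), size=10, replace=False):
            reduced = dataclasses.replace(
                session,
                unlabeled=[t for i, t in enumerate(session.unlabeled)
                           if i != k])
            out = compute_belt_velocity(reduced, cfg.belt_config())
            assert np.abs(out.filtered - base.filtered).max() \
                < 0.005 * cfg.target_speed

    def test_zero_phase_preserves_dip_timing(self, dip_belt_scene):
        cfg, session, truth = dip_belt_scene
        series = compute_belt_velocity(session, cfg.belt_config())
        td, to, _ = truth.cycles_frames()[3]
        i_raw = td + int(np.nanargmin(series.raw[td:to]))
        i_filt = td + int(np.argmin(series.filtered[td:to]))
        i_true = td + int(np.argmin(truth.speed[td:to]))
        assert abs(i_filt - i_true) <= 1
        assert abs(i_filt - i_raw) <= 2  # noise may wiggle the raw argmin

    def test_no_surviving_marker_names_stage(self, clean_belt_scene):
        cfg, session, _ = clean_belt_scene
        impossible = cfg.belt_config(min_persistence=10_000)
        with pytest.raises(EmptyResultError) as err:
            compute_belt_velocity(session, impossible)
        assert err.value.stage == "persistence"

    @pytest.mark.parametrize("v_target", [0.5, 1.0, 2.0, 4.5, 6.0])
    def test_constant_speed_recovery_across_speeds(self, v_target):
        cfg = BeltSceneConfig(target_speed=v_target, gait_type="run"
                              if v_target >= 2.5 else "walk",
                              dip_depth=0.0, noise_sd_mm=0.0,
                              occlusion_p=0.0, duration=3.0, seed=1)
        session, _ = simulate_belt(cfg)
        series = compute_belt_velocity(session, cfg.belt_config())
        core = series.interior()
        assert np.abs(series.filtered[core] - v_target).max() < 1e-6
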