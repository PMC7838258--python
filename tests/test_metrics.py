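"""Per-cycle TBV metrics, time normalization and trial summaries."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beltspeed.belt_velocity import BeltVelocitySeries
from beltspeed.metrics import (CycleMetrics, cycle_metrics, ensemble_average,
                               metrics_to_frame, NormalizedProfile,
                               summarize_trial, time_normalize)

RATE = 250.0


def make_series(values, first_frame=0, interpolated=None):
    values = np.asarray(values, float)
    return BeltVelocitySeries(
        first_frame=first_frame, frame_rate=RATE, raw=values.copy(),
        filtered=values, n_markers=np.full(values.size, 10),
        interpolated_mask=(np.zeros(values.size, bool) if interpolated is None
                           else interpolated),
        edge_margin_frames=0, config=None)


def dip_series(v_target=3.0, depth=0.18, stance_s=0.24,
               center_frac=0.30, width_frac=0.5, cycle_s=0.75):
    """Raised-cosine dip within stance; v(TD) equals the target speed."""
    n = int(cycle_s * RATE) * 4
    t = np.arange(n) / RATE
    td_s = 1.0
    center = td_s + center_frac * stance_s
    width = width_frac * stance_s
    v = np.full(n, v_target)
    m = np.abs(t - center) <= width / 2
    v[m] -= depth * 0.5 * (1 + np.cos(2 * np.pi * (t[m] - center) / width))
    td = int(td_s * RATE)
    to = td + int(stance_s * RATE)
    nxt = td + int(cycle_s * RATE)
    return make_series(v), (td, to, nxt)


class TestCycleMetrics:
    def test_constant_series_at_target(self):
        series = make_series(np.full(1000, 3.0))
        m = cycle_metrics(series, (100, 300, 500), 3.0)
        assert m.avg_tbv_stance_pct == pytest.approx(100.0)
        assert m.avg_tbv_cycle_pct == pytest.approx(100.0)
        assert m.braking_reduction_pct == pytest.approx(0.0)

    def test_two_percent_fast_belt(self):
        series = make_series(np.full(1000, 3.0 * 1.02))
        m = cycle_metrics(series, (100, 300, 500), 3.0)
        assert m.avg_tbv_stance_pct == pytest.approx(102.0)
        assert m.avg_tbv_cycle_pct == pytest.approx(102.0)

    def test_raised_cosine_dip_analytic(self):
        """Depth 0.18 m/s at 3.0 m/s centered at 30 % of a 0.24 s stance
        (dip center on the frame grid): reduction 6 %, timing 30 %."""
        series, cycle = dip_series()
        m = cycle_metrics(series, cycle, 3.0)
        assert m.braking_reduction_pct == pytest.approx(6.0, abs=1e-6)
        assert m.min_timing_pct_stance == pytest.approx(30.0, abs=1.0)

    def test_baseline_options(self):
        series, cycle = dip_series()
        td = cycle[0]
        series.filtered[:] += 0.03  # whole series 1 % above target
        m_td = cycle_metrics(series, cycle, 3.0, baseline="touchdown")
        m_target = cycle_metrics(series, cycle, 3.0, baseline="target")
        m_pre = cycle_metrics(series, cycle, 3.0, baseline="pre_td_max")
        assert m_td.braking_reduction_pct == pytest.approx(6.0, abs=1e-6)
        assert m_target.braking_reduction_pct == pytest.approx(5.0, abs=1e-6)
        assert m_pre.braking_reduction_pct == pytest.approx(6.0, abs=1e-6)

    def test_braking_floored_at_zero(self):
        v = np.full(1000, 3.0)
        v[400:] = 3.2  # belt only speeds up after touchdown
        series = make_series(v)
        m = cycle_metrics(series, (400, 600, 800), 3.0)
        assert m.braking_reduction_pct == 0.0

    def test_cycle_outside_series_rejected(self):
        series = make_series(np.full(100, 3.0))
        with pytest.raises(IndexError):
            cycle_metrics(series, (50, 90, 150), 3.0)

    def test_heavy_interpolation_flags_quality(self):
        interp = np.zeros(1000, bool)
        interp[100:200] = True
        series = make_series(np.full(1000, 3.0), interpolated=interp)
        with pytest.warns(UserWarning, match="interpolated"):
            m = cycle_metrics(series, (100, 250, 400), 3.0)
        assert m.quality_warning

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.25, 4.0), seed=st.integers(0, 10_000))
    def test_scale_equivariance(self, scale, seed):
        """Scaling speeds and target together leaves percentages fixed."""
        rng = np.random.default_rng(seed)
        v = 3.0 + 0.2 * rng.standard_normal(600).cumsum() / 100
        series = make_series(v)
        scaled = make_series(v * scale)
        cycle = (100, 250, 400)
        m1 = cycle_metrics(series, cycle, 3.0)
        m2 = cycle_metrics(scaled, cycle, 3.0 * scale)
        for name in CycleMetrics.METRIC_NAMES:
            assert getattr(m1, name) == pytest.approx(getattr(m2, name),
                                                      abs=1e-9)


class TestTimeNormalize:
    def test_constant_series_gives_flat_100(self):
        series = make_series(np.full(1000, 3.0))
        prof = time_normalize(series, (100, 300, 500), 3.0)
        np.testing.assert_allclose(prof.values, 100.0)
        assert prof.toe_off_pct == pytest.approx(50.0)

    def test_linear_ramp_stays_linear(self):
        v = np.linspace(2.0, 4.0, 401)
        series = make_series(v)
        prof = time_normalize(series, (0, 160, 400), 3.0)
        expect = np.linspace(v[0], v[400], 101) / 3.0 * 100
        np.testing.assert_allclose(prof.values, expect, rtol=1e-9)

    def test_dip_at_mid_stance_lands_at_sample_20(self):
        # stance is 40 % of the cycle; a dip at mid-stance sits at 20 %
        series, _ = dip_series(stance_s=0.3, center_frac=0.5, cycle_s=0.75)
        td = 250
        to = td + int(0.3 * RATE)
        nxt = td + int(0.75 * RATE)
        prof = time_normalize(series, (td, to, nxt), 3.0)
        assert int(np.argmin(prof.values)) == 20

    def test_profile_must_have_101_samples(self):
        with pytest.raises(ValueError):
            NormalizedProfile(values=np.zeros(100), toe_off_pct=40.0)


class TestEnsemble:
    def test_identical_profiles_zero_sd(self):
        p = NormalizedProfile(np.full(101, 100.0), 40.0)
        ens = ensemble_average([p, p, p])
        np.testing.assert_allclose(ens.sd, 0.0)
        np.testing.assert_allclose(ens.mean, 100.0)

    def test_two_profiles_sample_sd(self):
        p1 = NormalizedProfile(np.full(101, 98.0), 40.0)
        p2 = NormalizedProfile(np.full(101, 102.0), 42.0)
        ens = ensemble_average([p1, p2])
        np.testing.assert_allclose(ens.mean, 100.0)
        # sample SD of {98, 102} = 2 * sqrt(2)
        np.testing.assert_allclose(ens.sd, 2 * np.sqrt(2))
        assert ens.toe_off_pct == pytest.approx(41.0)

    def test_population_sd_option(self):
        p1 = NormalizedProfile(np.full(101, 98.0), 40.0)
        p2 = NormalizedProfile(np.full(101, 102.0), 42.0)
        ens = ensemble_average([p1, p2], ddof=0)
        np.testing.assert_allclose(ens.sd, 2.0)


class TestSummarize:
    def _metric(self, reduction, idx=0):
        return CycleMetrics(cycle_index=idx, avg_tbv_stance_pct=100.0,
                            avg_tbv_cycle_pct=100.0,
                            braking_reduction_pct=reduction,
                            min_timing_pct_stance=30.0, stance_s=0.25,
                            cycle_s=0.75)

    def test_single_cycle_flagged_with_zero_sd(self):
        with pytest.warns(UserWarning, match="at least 10"):
            s = summarize_trial([self._metric(5.0)])
        assert s.single_cycle
        assert s.sds["braking_reduction_pct"] == 0.0
        assert s.means["braking_reduction_pct"] == pytest.approx(5.0)

    def test_ten_identical_cycles_zero_sd(self):
        s = summarize_trial([self._metric(5.0, i) for i in range(10)])
        assert s.n_cycles == 10 and not s.single_cycle
        assert s.sds["braking_reduction_pct"] == 0.0

    def test_closed_form_mean_and_sample_sd(self):
        with pytest.warns(UserWarning):
            s = summarize_trial([self._metric(r, i)
                                 for i, r in enumerate((4.0, 5.0, 6.0))])
        assert s.means["braking_reduction_pct"] == pytest.approx(5.0)
        assert s.sds["braking_reduction_pct"] == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_trial([])

    def test_frame_export_carries_labels(self):
        s = summarize_trial([self._metric(5.0, i) for i in range(10)],
                            labels={"treadmill": "A", "body_mass_kg": 70.0})
        df = s.to_frame()
        assert df.loc[0, "treadmill"] == "A"
        assert df.loc[0, "braking_reduction_pct_mean"] == pytest.approx(5.0)


class TestFrameRateInvariance:
    def test_240_vs_250_hz_metrics_agree(self):
        from beltspeed.belt_velocity import compute_belt_velocity
        from beltspeed.synthetic import BeltSceneConfig, simulate_belt
        results = {}
        for rate in (240.0, 250.0):
            cfg = BeltSceneConfig(target_speed=3.0, dip_depth=0.18,
                                  duration=8.0, frame_rate=rate, seed=21)
            session, truth = simulate_belt(cfg)
            series = compute_belt_velocity(session, cfg.belt_config())
            mets = [cycle_metrics(series, c, 3.0, cycle_index=i)
                    for i, c in enumerate(truth.cycles_frames())]
            with pytest.warns(UserWarning, match="at least 10"):
                results[rate] = summarize_trial(mets).means
        a, b = results[240.0], results[250.0]
        for key in ("avg_tbv_stance_pct", "avg_tbv_cycle_pct",
                    "braking_reduction_pct"):
            assert abs(a[key] - b[key]) < 0.2
        assert abs(a["min_timing_pct_stance"]
                   - b["min_timing_pct_stance"]) < 1.5


def test_metrics_frame_has_one_row_per_cycle():
    series = make_series(np.full(2000, 3.0))
    cycles = [(i * 300, i * 300 + 180, (i + 1) * 300) for i in range(5)]
    mets = [cycle_metrics(series, c, 3.0, cycle_index=i)
            for i, c in enumerate(cycles)]
    df = metrics_to_frame(mets)
    assert len(df) == 5
    assert set(CycleMetrics.METRIC_NAMES) <= set(df.columns)
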