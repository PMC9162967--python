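import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import dense_aut, dense_differential_aut, random_piecewise_linear_trace
from conftest import make_record, make_trace
from oxiburden.burden_metrics import (
    AnalysisConfig,
    BurdenError,
    aut_absolute,
    aut_relative,
    burden_panel,
    compute_baseline,
    merge_renal,
    renal_specific_burden,
)
from oxiburden.synthetic_cohort import correlated_pair
from oxiburden.trace_model import OximetryTrace

RECT = AnalysisConfig(integration="rectangle")


def window_trace(values, dt=1.0, channel="renal_mean", lead=6.0):
    """Trace holding ``values`` over the analysis window with a flat lead-in."""
    values = np.asarray(values, dtype=float)
    n_lead = int(lead / dt)
    times = np.arange(-n_lead, values.size) * dt
    full = np.concatenate([np.full(n_lead, values[0]), values])
    return OximetryTrace(
        channel=channel,
        times=times,
        values=full,
        incision_time=0.0,
        end_time=float(values.size - 1) * dt,
    )


class TestBaseline:
    def test_constant_trace(self):
        tr = window_trace(np.full(11, 80.0))
        assert compute_baseline(tr).value == 80.0

    def test_symmetric_mean(self):
        tr = make_trace([75.0, 85.0, 80.0, 80.0], times=[-2.0, -1.0, 1.0, 5.0],
                        incision=0.0, end=5.0)
        b = compute_baseline(tr)
        assert b.value == 80.0 and b.n_samples == 2
        assert b.window == (-5.0, 0.0)

    def test_no_samples_errors_with_channel_name(self):
        tr = make_trace([80.0, 80.0], times=[1.0, 5.0], incision=0.5, end=5.0,
                        channel="cerebral")
        with pytest.raises(BurdenError, match="cerebral"):
            compute_baseline(tr)

    def test_recovers_generating_mean(self, rng):
        # 60 pre-incision samples from N(82, 1): mean within 3 standard errors
        times = np.arange(-60, 30, 1.0)
        vals = np.where(times < 0, rng.normal(82.0, 1.0, times.size), 82.0)
        tr = OximetryTrace(channel="renal_mean", times=times, values=vals,
                           incision_time=0.0, end_time=29.0)
        b = compute_baseline(tr, window_min=60.0)
        assert b.n_samples == 60
        assert b.value == pytest.approx(82.0, abs=3 * 1.0 / np.sqrt(60))


class TestAutAbsolute:
    def test_constant_deficit_closed_form_both_rules(self):
        tr = window_trace(np.full(11, 85.0))  # 10 min at 85%
        for cfg in (AnalysisConfig(), RECT):
            assert aut_absolute(tr, 90.0, cfg).aut == pytest.approx(50.0)

    def test_above_threshold_is_zero(self):
        tr = window_trace(np.full(31, 95.0))
        assert aut_absolute(tr, 90.0).aut == 0.0

    def test_linear_ramp_triangle_area(self):
        # 90% falling to 80% over 10 min below threshold 90: area = 50
        wide = AnalysisConfig(gap_tolerance=60.0)  # two-point ramp, no gap policy
        tr = window_trace([90.0, 80.0], dt=10.0)
        assert aut_absolute(tr, 90.0, wide).aut == pytest.approx(50.0)
        assert aut_absolute(tr, 90.0, wide).aut == pytest.approx(
            dense_aut(tr.times, tr.values, 0.0, 10.0, 90.0), abs=0.1
        )

    def test_crossing_inside_interval_is_exact(self):
        # 95 → 85 over 10 min crosses 90 at t=5: triangle area = 5*5/2
        wide = AnalysisConfig(gap_tolerance=60.0)
        tr = window_trace([95.0, 85.0], dt=10.0)
        assert aut_absolute(tr, 90.0, wide).aut == pytest.approx(12.5)

    def test_empty_window_errors(self):
        tr = make_trace([80.0, 80.0], times=[0.0, 1.0], incision=5.0, end=9.0)
        with pytest.raises(BurdenError):
            aut_absolute(tr, 90.0)

    def test_gap_contributes_zero_and_is_logged(self):
        # 5-min hole in an otherwise constant 80% trace, threshold 90
        times = np.array([-5.0, 0.0, 2.0, 3.0, 8.0, 9.0, 10.0])
        tr = OximetryTrace(channel="renal_mean", times=times,
                           values=np.full(7, 80.0), incision_time=0.0, end_time=10.0)
        res = aut_absolute(tr, 90.0)
        assert res.gap_min == pytest.approx(5.0)
        assert res.aut == pytest.approx(10.0 * 5.0)  # only the sampled 5 minutes


class TestAutRelative:
    def test_printed_formula_closed_form(self):
        # baseline 80, constant 72 for 5 min, 5% threshold: (76-72)*5 = 20
        tr = window_trace(np.full(6, 72.0), lead=0.0)
        tr = OximetryTrace(channel="renal_mean",
                           times=np.concatenate([np.arange(-6, 0, 1.0), tr.times]),
                           values=np.concatenate([np.full(6, 80.0), tr.values]),
                           incision_time=0.0, end_time=5.0)
        base = compute_baseline(tr)
        assert base.value == 80.0
        assert aut_relative(tr, base, 0.05).aut == pytest.approx(20.0)

    def test_never_below_threshold_is_zero(self):
        tr = window_trace(np.full(21, 79.0))
        base = compute_baseline(tr)  # 79; threshold 71.1 at 10%
        assert aut_relative(tr, base, 0.10).aut == 0.0

    def test_step_trace_rectangle_rule(self):
        # baseline 85, 10% threshold = 76.5; 76 for 3 min then 80 for 3 min
        vals = np.array([76.0, 76.0, 76.0, 80.0, 80.0, 80.0, 80.0])
        times = np.arange(-6.0, 1.0) + 6.0  # 0..6
        full_t = np.concatenate([np.arange(-6.0, 0.0), times])
        full_v = np.concatenate([np.full(6, 85.0), vals])
        tr = OximetryTrace(channel="renal_mean", times=full_t, values=full_v,
                           incision_time=0.0, end_time=6.0)
        base = compute_baseline(tr)
        assert base.value == 85.0
        assert aut_relative(tr, base, 0.10, RECT).aut == pytest.approx(1.5)


class TestMergeRenal:
    def _pair(self, left_vals, right_vals, times=None):
        left = make_trace(left_vals, times=times, channel="renal_left", incision=0.5)
        right = make_trace(right_vals, times=times, channel="renal_right", incision=0.5)
        return left, right

    def test_identical_sides(self):
        vals = np.array([80.0, 78.0, 82.0, 79.0])
        left, right = self._pair(vals, vals)
        merged = merge_renal(left, right)
        assert np.array_equal(merged.trace.values, vals)
        assert merged.spearman_rho == pytest.approx(1.0)
        assert merged.trace.channel == "renal_mean"

    def test_offset_sides_average(self):
        right = np.array([70.0, 72.0, 74.0, 71.0])
        left, right_tr = self._pair(right + 10.0, right)
        merged = merge_renal(left, right_tr)
        assert np.allclose(merged.trace.values, right + 5.0)

    def test_single_sided_samples_kept(self):
        left = make_trace([80.0, 82.0], times=[0.0, 2.0], channel="renal_left",
                          incision=0.5, end=2.0)
        right = make_trace([70.0, 72.0, 74.0], times=[0.0, 1.0, 2.0],
                           channel="renal_right", incision=0.5, end=2.0)
        merged = merge_renal(left, right)
        assert np.allclose(merged.trace.times, [0.0, 1.0, 2.0])
        assert np.allclose(merged.trace.values, [75.0, 72.0, 78.0])

    def test_no_overlap_errors(self):
        left = make_trace([80.0, 82.0], times=[0.0, 0.4], channel="renal_left",
                          incision=0.1, end=0.4)
        right = make_trace([70.0, 72.0], times=[0.1, 0.3], channel="renal_right",
                           incision=0.1, end=0.4)
        with pytest.raises(BurdenError):
            merge_renal(left, right)

    def test_target_rank_correlation_recovered(self, rng):
        z1, z2 = correlated_pair(0.80, 200, rng)
        left = make_trace(np.clip(80 + 5 * z1, 0, 100), channel="renal_left", incision=1.0)
        right = make_trace(np.clip(80 + 5 * z2, 0, 100), channel="renal_right", incision=1.0)
        merged = merge_renal(left, right)
        assert merged.n_pairs == 200
        assert merged.spearman_rho == pytest.approx(0.80, abs=0.10)


class TestRenalSpecific:
    def _trace(self, values, channel, dt=1.0):
        return window_trace(values, dt=dt, channel=channel)

    def test_both_at_baseline_is_zero(self):
        renal = self._trace(np.full(11, 78.0), "renal_mean")
        periph = self._trace(np.full(11, 84.0), "peripheral")
        res = renal_specific_burden(renal, periph, compute_baseline(renal),
                                    compute_baseline(periph))
        assert res.aut == 0.0

    def test_renal_drop_closed_form(self):
        # renal at 90% of baseline for the 10-min window, peripheral flat:
        # d(t) = 10% for 10 min = 100 %·min
        rb, pb = 80.0, 84.0
        t = np.arange(-6.0, 11.0)
        rv = np.where(t >= 0, 0.9 * rb, rb)
        pv = np.full(t.size, pb)
        renal = OximetryTrace(channel="renal_mean", times=t, values=rv,
                              incision_time=0.0, end_time=10.0)
        periph = OximetryTrace(channel="peripheral", times=t, values=pv,
                               incision_time=0.0, end_time=10.0)
        res = renal_specific_burden(renal, periph, compute_baseline(renal),
                                    compute_baseline(periph))
        assert res.aut == pytest.approx(100.0)

    def test_negative_excess_clipped_to_zero(self):
        # peripheral proportionally deeper than renal throughout
        renal = self._trace(np.full(11, 80.0), "renal_mean")
        pvals = np.concatenate([np.full(6, 84.0), np.full(11, 70.0)])
        pt = np.arange(-6.0, 11.0)
        periph = OximetryTrace(channel="peripheral", times=pt, values=pvals,
                               incision_time=0.0, end_time=10.0)
        res = renal_specific_burden(renal, periph, compute_baseline(renal),
                                    compute_baseline(periph))
        assert res.aut == 0.0

    def test_union_grid_matches_dense_oracle(self, rng):
        for _ in range(10):
            t1, v1, inc, end = random_piecewise_linear_trace(rng)
            t2, v2, _, _ = random_piecewise_linear_trace(rng)
            t2 = t2 * (t1[-1] / t2[-1])  # same support
            renal = OximetryTrace(channel="renal_mean", times=t1, values=v1,
                                  incision_time=inc, end_time=end)
            periph = OximetryTrace(channel="peripheral", times=t2, values=v2,
                                   incision_time=inc, end_time=end)
            rb = compute_baseline(renal)
            pb = compute_baseline(periph)
            res = renal_specific_burden(renal, periph, rb, pb)
            oracle = dense_differential_aut(t1, v1, t2, v2, rb.value, pb.value, inc, end)
            assert res.aut == pytest.approx(oracle, abs=0.1)


class TestBurdenPanel:
    def test_full_record_yields_16_burdens(self):
        panel = burden_panel(make_record())
        assert len(panel.burdens) == 16
        kinds = {(b.channel, b.kind) for b in panel.burdens.values()}
        assert ("peripheral", "relative") in kinds
        assert ("renal_specific", "renal_specific") in kinds
        assert ("peripheral", "absolute") not in kinds  # relative-10% only

    def test_flat_traces_have_zero_relative_burdens(self):
        panel = burden_panel(make_record())
        for key, b in panel.burdens.items():
            if b.kind == "relative":
                assert b.aut == 0.0, key

    def test_scripted_dip_matches_closed_form(self):
        # half-cosine dip depth 12%, duration 8 min in the renal channel:
        # AUT below the pre-dip level = depth*duration/2
        dt = 0.01
        t = np.arange(-6.0, 40.0 + dt, dt)
        base = 85.0
        dip = np.zeros_like(t)
        in_dip = (t >= 10.0) & (t <= 18.0)
        dip[in_dip] = 12.0 * np.sin(np.pi * (t[in_dip] - 10.0) / 8.0) ** 2
        tr = OximetryTrace(channel="renal_mean", times=t, values=base - dip,
                           incision_time=0.0, end_time=40.0)
        assert aut_absolute(tr, base).aut == pytest.approx(12.0 * 8.0 / 2.0, abs=0.01)


class TestQuadratureProperties:
    def test_threshold_monotonicity(self, rng):
        for _ in range(20):
            t, v, inc, end = random_piecewise_linear_trace(rng)
            tr = OximetryTrace(channel="renal_mean", times=t, values=v,
                               incision_time=inc, end_time=end)
            auts = [aut_absolute(tr, thr).aut for thr in (60, 70, 80, 90)]
            assert all(a <= b for a, b in zip(auts, auts[1:]))

    def test_additivity_at_sample_point(self, rng):
        t, v, inc, end = random_piecewise_linear_trace(rng)
        mid = float(t[(t > inc) & (t < end)][len(t[(t > inc) & (t < end)]) // 2])
        whole = aut_absolute(OximetryTrace("renal_mean", t, v, inc, end), 90.0).aut
        first = aut_absolute(OximetryTrace("renal_mean", t, v, inc, mid), 90.0).aut
        second = aut_absolute(OximetryTrace("renal_mean", t, v, mid, end), 90.0).aut
        assert whole == pytest.approx(first + second, abs=1e-9)

    def test_doubling_duration_doubles_burden(self):
        one = window_trace(np.full(11, 85.0))
        two = window_trace(np.full(21, 85.0))
        assert aut_absolute(two, 90.0).aut == pytest.approx(2 * aut_absolute(one, 90.0).aut)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), threshold=st.sampled_from([60.0, 70.0, 80.0, 90.0]))
    def test_matches_dense_oracle(self, seed, threshold):
        rng = np.random.default_rng(seed)
        t, v, inc, end = random_piecewise_linear_trace(rng)
        tr = OximetryTrace(channel="renal_mean", times=t, values=v,
                           incision_time=inc, end_time=end)
        res = aut_absolute(tr, threshold)
        assert res.aut >= 0.0
        assert res.aut == pytest.approx(
            dense_aut(t, v, inc, end, threshold), abs=0.1
        )
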