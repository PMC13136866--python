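"""Area integration, overlap resolution, aggregation, and the method matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from desatarea.areas import (
    aggregate_metric,
    compute_method_matrix,
    event_area,
    resolve_overlaps,
)
from desatarea.detection import detect_desaturations
from desatarea.signal_model import (
    EventSource,
    Hypnogram,
    SleepEvent,
    ZeroSleepTimeError,
)
from desatarea.windows import ALL_COMBOS, WindowFamily

from conftest import cosdip_trace, flat_trace, make_trace, random_smooth_trace, vdip_trace


def riemann_oracle(trace, window, baseline, oversample=10):
    """Independent area oracle: 10x-oversampled Riemann sum on the linearly
    interpolated trace, deficits clamped at zero, invalid samples excluded."""
    a, b = window
    dt = trace.sample_interval / oversample
    t = np.arange(a, b, dt) + dt / 2
    times = trace.times
    ok = trace.valid_mask
    total = 0.0
    for ti in t:
        k = int(np.floor((ti - trace.start_offset) / trace.sample_interval))
        if k < 0 or k + 1 >= len(trace) or not (ok[k] and ok[k + 1]):
            continue
        frac = (ti - times[k]) / trace.sample_interval
        v = trace.samples[k] + frac * (trace.samples[k + 1] - trace.samples[k])
        total += max(0.0, baseline - v) * dt
    return total


def _manual(start, end):
    return SleepEvent(start, end, source=EventSource.manual_respiratory)


class TestEventArea:
    def test_trace_at_baseline_is_zero(self):
        tr = flat_trace(95.0)
        assert event_area(tr, (100, 400), 95.0).area_pct_s == 0.0

    def test_trace_above_baseline_clamped_to_zero(self):
        tr = flat_trace(98.0)
        assert event_area(tr, (100, 400), 95.0).area_pct_s == 0.0

    def test_triangular_dip_closed_form(self):
        # depth 4%, total width 60 s, baseline at apex level: area = 0.5*4*60
        tr = vdip_trace(level=96.0, depth=4.0, center=300, halfwidth=30)
        got = event_area(tr, (200, 400), 96.0).area_pct_s
        assert got == pytest.approx(0.5 * 4.0 * 60.0, rel=1e-9)

    def test_raised_cosine_closed_form(self):
        # closed form: depth * halfwidth
        tr = cosdip_trace(level=96.0, depth=5.0, center=300.0, halfwidth=40.0)
        got = event_area(tr, (200, 420), 96.0).area_pct_s
        assert got == pytest.approx(5.0 * 40.0, rel=1e-3)

    def test_partial_baseline_crossing_matches_oracle(self):
        # baseline below the apex: only the sub-baseline part counts
        tr = vdip_trace(level=96.0, depth=4.0, center=300, halfwidth=30)
        got = event_area(tr, (200, 400), 94.0).area_pct_s
        # sub-94 triangle: depth 2, width 30 s -> 0.5*2*30
        assert got == pytest.approx(30.0, rel=1e-9)

    def test_invalid_samples_contribute_zero(self):
        tr = vdip_trace(level=96.0, depth=4.0, center=300, halfwidth=30)
        mask = tr.valid_mask.copy()
        mask[280:320] = False
        tr2 = make_trace(tr.samples, valid=mask)
        full = event_area(tr, (200, 400), 96.0).area_pct_s
        holed = event_area(tr2, (200, 400), 96.0).area_pct_s
        assert holed < full
        assert holed == pytest.approx(riemann_oracle(tr2, (200, 400), 96.0), rel=5e-3)

    def test_empty_window_clipped(self):
        tr = flat_trace(95.0, n=100)
        res = event_area(tr, (500, 600), 95.0)
        assert res.area_pct_s == 0.0
        assert res.clipped

    def test_fractional_window_bounds(self):
        tr = flat_trace(90.0, n=100)
        got = event_area(tr, (10.25, 20.75), 95.0).area_pct_s
        assert got == pytest.approx(5.0 * 10.5, rel=1e-9)

    def test_matches_riemann_oracle_on_random_fixtures(self, rng):
        """>= 200 random smooth traces: exact integrator within 0.5% of the
        10x-oversampled Riemann oracle."""
        for _ in range(200):
            n = int(rng.integers(200, 2000))
            tr = random_smooth_trace(rng, n=n)
            a = float(rng.uniform(0, n / 3))
            b = float(rng.uniform(a + 30, n - 1))
            baseline = float(rng.uniform(92, 100))
            got = event_area(tr, (a, b), baseline).area_pct_s
            want = riemann_oracle(tr, (a, b), baseline)
            assert got == pytest.approx(want, rel=5e-3, abs=0.5)

    def test_rejects_bad_baseline(self):
        with pytest.raises(ValueError):
            event_area(flat_trace(), (0, 10), 0.0)
        with pytest.raises(ValueError):
            event_area(flat_trace(), (0, 10), 101.0)


class TestResolveOverlaps:
    def test_disjoint_unchanged(self):
        ws = [(0.0, 50.0), (60.0, 100.0)]
        assert resolve_overlaps(ws) == ws

    def test_overlap_truncates_earlier(self):
        got = resolve_overlaps([(0.0, 100.0), (60.0, 160.0)])
        assert got == [(0.0, 60.0), (60.0, 160.0)]
        assert sum(b - a for a, b in got) == 160.0

    def test_nested_truncates_and_drops_tail(self):
        got = resolve_overlaps([(0.0, 100.0), (20.0, 40.0)])
        assert got == [(0.0, 20.0), (20.0, 40.0)]

    def test_union_preserved_and_disjoint(self, rng):
        for _ in range(100):
            starts = np.sort(rng.uniform(0, 1000, 8))
            ws = [(float(s), float(s + rng.uniform(5, 120))) for s in starts]
            got = resolve_overlaps(ws)
            # pairwise disjoint, ordered
            for (a1, b1), (a2, b2) in zip(got, got[1:]):
                assert b1 <= a2
            # output length never exceeds input length
            assert sum(b - a for a, b in got) <= sum(b - a for a, b in ws) + 1e-9
            # every output point lies in the input union; non-nested unions match
            grid = np.linspace(0, 1200, 4801)
            in_out = np.zeros_like(grid, dtype=bool)
            for a, b in got:
                in_out |= (grid >= a) & (grid < b)
            in_in = np.zeros_like(grid, dtype=bool)
            for a, b in ws:
                in_in |= (grid >= a) & (grid < b)
            assert not (in_out & ~in_in).any()

    def test_none_policy_passthrough(self):
        ws = [(0.0, 100.0), (60.0, 160.0)]
        assert resolve_overlaps(ws, policy="none") == ws

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1000, allow_nan=False),
                st.floats(1, 200, allow_nan=False),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_disjointness_and_containment_hold_for_any_windows(self, raw):
        ws = sorted((s, s + d) for s, d in raw)
        got = resolve_overlaps(ws)
        for (a1, b1), (a2, b2) in zip(got, got[1:]):
            assert b1 <= a2
        for a, b in got:
            assert b > a
            assert any(a >= wa - 1e-12 and b <= wb + 1e-12 for wa, wb in ws) or any(
                wa <= a < wb for wa, wb in ws
            )


class TestAggregation:
    def _area(self, pct_s):
        from desatarea.areas import EventArea

        return EventArea(0, (0.0, 10.0), 96.0, pct_s)

    def _combo(self, window):
        return next(c for c in ALL_COMBOS if c.window == window)

    def test_fixed_divides_by_3600(self):
        mv = aggregate_metric([self._area(360.0)], self._combo(WindowFamily.fixed), 7.0)
        assert mv.value == pytest.approx(0.1)
        assert mv.units == "%hours"

    def test_record_specific_pct_min_per_hour(self):
        mv = aggregate_metric(
            [self._area(600.0)], self._combo(WindowFamily.record_specific), 5.0
        )
        assert mv.value == pytest.approx(2.0)
        assert mv.units == "%min/h sleep"

    def test_event_specific_percent_of_sleep(self):
        # 360 %.s over 1 h of sleep -> 0.1%
        mv = aggregate_metric(
            [self._area(360.0)], self._combo(WindowFamily.event_specific), 1.0
        )
        assert mv.value == pytest.approx(0.1)
        assert mv.units == "%"

    def test_no_events_zero_everywhere(self):
        for combo in ALL_COMBOS:
            assert aggregate_metric([], combo, 7.0).value == 0.0

    def test_zero_tst_raises_for_per_tst_rules(self):
        with pytest.raises(ZeroSleepTimeError):
            aggregate_metric([self._area(10.0)], self._combo(WindowFamily.record_specific), 0.0)

    def test_linear_in_areas(self):
        for combo in ALL_COMBOS:
            one = aggregate_metric([self._area(100.0)], combo, 6.0).value
            two = aggregate_metric([self._area(200.0)], combo, 6.0).value
            assert two == pytest.approx(2 * one)


class TestMethodMatrix:
    def _recording(self, depth_scale=1.0, n=6000):
        t = np.arange(n, dtype=float)
        sig = np.full(n, 96.0)
        ends = [400, 900, 1400, 1900, 2400, 2900, 3400, 3900, 4400, 4900]
        for e in ends:
            c, w = e + 15, 35
            inside = np.abs(t - c) <= w
            sig -= np.where(
                inside, depth_scale * 5.0 * 0.5 * (1 + np.cos(np.pi * (t - c) / w)), 0.0
            )
        tr = make_trace(np.clip(sig, 50, 100))
        manual = [_manual(e - 25, e) for e in ends]
        hyp = Hypnogram(("n2",) * (n // 30))
        return tr, manual, hyp

    def test_flat_trace_no_events_all_zero(self):
        tr = flat_trace(95.0, n=3000)
        hyp = Hypnogram(("n2",) * 100)
        out = compute_method_matrix(tr, [], [], hyp)
        assert len(out) == 18
        assert all(m.value == 0.0 for m in out)

    def test_matrix_size_and_subset_flags(self):
        tr, manual, hyp = self._recording()
        auto = detect_desaturations(tr)
        out = compute_method_matrix(tr, manual, auto, hyp)
        assert len(out) == 18
        assert sum(m.combo.in_paper_subset for m in out) == 15
        assert all(np.isfinite(m.value) for m in out)
        assert all(m.value >= 0 for m in out)

    def test_monotone_under_dip_deepening(self):
        """Deepening every dip (same events, windows, baselines held fixed by
        construction) never decreases any matrix value."""
        tr1, manual, hyp = self._recording(depth_scale=1.0)
        tr2, _, _ = self._recording(depth_scale=1.4)
        auto1 = detect_desaturations(tr1)
        auto2 = detect_desaturations(tr2)
        assert len(auto1) == len(auto2)
        m1 = compute_method_matrix(tr1, manual, auto1, hyp)
        m2 = compute_method_matrix(tr2, manual, auto2, hyp)
        for a, b in zip(m1, m2):
            assert b.value >= a.value - 1e-9

    def test_fixed_baseline_dominates_record_baseline(self):
        from desatarea.windows import BaselineFamily

        tr, manual, hyp = self._recording()
        auto = detect_desaturations(tr)
        out = {(m.combo.source, m.combo.window, m.combo.baseline): m.value
               for m in compute_method_matrix(tr, manual, auto, hyp)}
        for (src, win, bl), v in out.items():
            if bl == BaselineFamily.fixed:
                assert v >= out[(src, win, BaselineFamily.record_specific)] - 1e-9

    def test_shift_equivalence_end_to_end(self):
        """Record-baseline metric computed via shifted signal + fixed 100%
        baseline equals the direct 99th-percentile computation exactly."""
        from desatarea.windows import (
            BaselineFamily,
            record_baseline,
            shifted_signal_emulation,
        )

        tr, manual, hyp = self._recording()
        auto = detect_desaturations(tr)
        p99 = record_baseline(tr)
        shifted = shifted_signal_emulation(tr, p99)
        direct = compute_method_matrix(tr, manual, auto, hyp)
        via = compute_method_matrix(shifted, manual, auto, hyp)
        for d, v in zip(direct, via):
            if d.combo.baseline == BaselineFamily.record_specific:
                partner = next(
                    m
                    for m in via
                    if m.combo.source == d.combo.source
                    and m.combo.window == d.combo.window
                    and m.combo.baseline == BaselineFamily.fixed
                )
                assert partner.value == pytest.approx(d.value, rel=1e-12, abs=1e-12)
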