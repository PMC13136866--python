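"""Sampling-window construction, baselines, and the signal-shift equivalence."""

import numpy as np
import pytest

from desatarea.signal_model import EventSource, SleepEvent
from desatarea.windows import (
    ALL_COMBOS,
    BaselineFamily,
    EnsembleWindow,
    WindowFamily,
    baseline_for_event,
    ensemble_average_window,
    record_baseline,
    shifted_signal_emulation,
    window_for_event,
)
from desatarea.areas import event_area

from conftest import flat_trace, make_trace, random_smooth_trace


def _manual(start, end):
    return SleepEvent(start, end, source=EventSource.manual_respiratory)


class TestMethodMatrixDefinition:
    def test_eighteen_distinct_combos_fifteen_in_subset(self):
        assert len(ALL_COMBOS) == 18
        assert len({(c.source, c.window, c.baseline) for c in ALL_COMBOS}) == 18
        assert sum(c.in_paper_subset for c in ALL_COMBOS) == 15
        assert len({c.label for c in ALL_COMBOS}) == 18

    def test_excluded_cells_are_manual_event_specific(self):
        for c in ALL_COMBOS:
            excluded = (
                c.source == EventSource.manual_respiratory
                and c.window == WindowFamily.event_specific
            )
            assert c.in_paper_subset == (not excluded)

    def test_canonical_labels(self):
        labels = {c.label for c in ALL_COMBOS}
        assert "Azarbarzin method" in labels
        assert "de Chazal method" in labels
        assert "Kulkas method" in labels
        assert "Azarbarzin method (record-specific baseline)" in labels
        assert "de Chazal method (record-specific baseline, desaturation events)" in labels

    def test_units_keyed_to_window_family(self):
        for c in ALL_COMBOS:
            expected = {
                WindowFamily.event_specific: "%",
                WindowFamily.record_specific: "%min/h sleep",
                WindowFamily.fixed: "%hours",
            }[c.window]
            assert c.units == expected


class TestEnsembleWindow:
    def _dip_trace(self, ends, n=4000, center_lag=10, halfwidth=40, depth=5.0):
        t = np.arange(n, dtype=float)
        sig = np.full(n, 96.0)
        for e in ends:
            c = e + center_lag
            inside = np.abs(t - c) <= halfwidth
            sig -= np.where(inside, depth * (1 - np.abs(t - c) / halfwidth), 0.0)
        return make_trace(sig)

    def test_symmetric_dips_recover_flanking_peaks(self):
        ends = [500, 1000, 1500, 2000, 2500, 3000]
        tr = self._dip_trace(ends, center_lag=10, halfwidth=40)
        evs = [_manual(e - 20, e) for e in ends]
        ens = ensemble_average_window(tr, evs)
        assert not ens.fallback_used
        # dip spans [-30, +50] around event end; smoothing blurs corners
        assert ens.pre_offset_s == pytest.approx(-30, abs=8)
        assert ens.post_offset_s == pytest.approx(50, abs=8)

    def test_single_event_average_is_that_segment(self):
        tr = self._dip_trace([500])
        ens = ensemble_average_window(tr, [_manual(480, 500)], min_events=1)
        assert ens.n_events_used == 1
        assert ens.pre_offset_s == pytest.approx(-30, abs=8)

    def test_flat_trace_falls_back(self):
        tr = flat_trace(95.0, n=2000)
        evs = [_manual(200 * i + 100, 200 * i + 120) for i in range(5)]
        ens = ensemble_average_window(tr, evs)
        assert ens.fallback_used
        assert (ens.pre_offset_s, ens.post_offset_s) == (-100.0, 100.0)

    def test_too_few_events_falls_back(self):
        tr = self._dip_trace([500, 1000, 1500])
        evs = [_manual(e - 20, e) for e in [500, 1000, 1500]]
        assert ensemble_average_window(tr, evs).fallback_used

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            ensemble_average_window(flat_trace(), [])

    def test_invariant_to_event_order_and_duplication(self):
        ends = [500, 1000, 1500, 2000, 2500]
        tr = self._dip_trace(ends)
        evs = [_manual(e - 20, e) for e in ends]
        a = ensemble_average_window(tr, evs)
        b = ensemble_average_window(tr, evs[::-1])
        c = ensemble_average_window(tr, evs + evs)
        assert (a.pre_offset_s, a.post_offset_s) == (b.pre_offset_s, b.post_offset_s)
        assert (a.pre_offset_s, a.post_offset_s) == (c.pre_offset_s, c.post_offset_s)


class TestWindowForEvent:
    def test_fixed_geometry_default_reading(self):
        # event [1000, 1020): midpoint 1010, length 2.5*T = 50
        ev = _manual(1000, 1020)
        assert window_for_event(ev, WindowFamily.fixed) == (1010.0, 1060.0)

    def test_fixed_geometry_alternative_reading(self):
        ev = _manual(1000, 1020)
        a, b = window_for_event(ev, WindowFamily.fixed, fixed_window_ends_at_2p5T=True)
        assert (a, b) == (1010.0, 1050.0)

    def test_fixed_length_is_2p5T(self):
        for T in (10.0, 27.0, 60.0):
            ev = _manual(500.0, 500.0 + T)
            a, b = window_for_event(ev, WindowFamily.fixed)
            assert b - a == pytest.approx(2.5 * T)

    def test_event_specific_is_identity(self):
        ev = _manual(100, 130)
        assert window_for_event(ev, WindowFamily.event_specific) == (100, 130)

    def test_record_specific_offsets(self):
        ens = EnsembleWindow(-45.0, 60.0, n_events_used=9)
        ev = _manual(1980, 2000)
        assert window_for_event(ev, WindowFamily.record_specific, ens) == (1955.0, 2060.0)

    def test_record_specific_requires_ensemble(self):
        with pytest.raises(ValueError):
            window_for_event(_manual(0, 10), WindowFamily.record_specific, None)


class TestBaselines:
    def test_record_baseline_constant(self):
        assert record_baseline(flat_trace(95.0)) == pytest.approx(95.0)

    def test_record_baseline_mixture(self):
        vals = np.concatenate([np.full(990, 94.0), np.full(10, 98.0)])
        # 99th percentile with linear interpolation: between the 989th and
        # 990th order statistics -> oracle via np.percentile on sorted copy
        expected = float(np.percentile(np.sort(vals), 99))
        assert record_baseline(make_trace(vals)) == pytest.approx(expected)
        assert record_baseline(make_trace(vals)) >= 94.0

    def test_record_baseline_ramp_closed_form(self):
        vals = np.linspace(90, 100, 1001)
        # linear percentile of a uniform ramp: 90 + 10 * 0.99
        assert record_baseline(make_trace(vals)) == pytest.approx(99.9, abs=0.1)

    def test_fixed_baseline_always_100(self):
        tr = flat_trace(90.0)
        ev = _manual(100, 120)
        assert baseline_for_event(tr, ev, BaselineFamily.fixed, 95.0) == 100.0

    def test_event_baseline_lookback_max(self):
        vals = np.full(400, 94.0)
        vals[150] = 97.0  # inside the 100-s lookback of an event ending at 200
        vals[40] = 99.0  # outside it
        tr = make_trace(vals)
        ev = _manual(180, 200)
        got = baseline_for_event(tr, ev, BaselineFamily.event_specific, 95.0)
        assert got == pytest.approx(97.0)

    def test_event_baseline_kulkas_within_window(self):
        vals = np.full(400, 94.0)
        vals[150] = 97.0
        vals[185] = 96.0
        tr = make_trace(vals)
        ev = _manual(180, 200)
        got = baseline_for_event(
            tr, ev, BaselineFamily.event_specific, 95.0, kulkas_within_event=True
        )
        assert got == pytest.approx(96.0)

    def test_record_family_returns_p99(self):
        tr = flat_trace(95.0)
        ev = _manual(100, 120)
        assert baseline_for_event(tr, ev, BaselineFamily.record_specific, 95.0) == 95.0

    def test_empty_span_falls_back_to_record(self):
        tr = flat_trace(95.0, n=300)
        ev = SleepEvent(500, 520, source=EventSource.manual_respiratory)  # beyond trace
        got = baseline_for_event(tr, ev, BaselineFamily.event_specific, 95.5)
        assert got == 95.5

    def test_fixed_dominates_record(self, rng):
        for _ in range(20):
            tr = random_smooth_trace(rng)
            assert 100.0 >= record_baseline(tr)


class TestShiftEquivalence:
    def test_shift_arithmetic(self):
        tr = flat_trace(90.0)
        shifted = shifted_signal_emulation(tr, 96.0)
        assert shifted.samples[0] == pytest.approx(94.0)

    def test_identity_at_p99_100(self):
        tr = flat_trace(97.0)
        shifted = shifted_signal_emulation(tr, 100.0)
        np.testing.assert_array_equal(shifted.samples, tr.samples)

    def test_area_equivalence_exact(self, rng):
        """Deficit below 100% on the shifted trace == deficit below the 99th
        percentile on the original, exactly, on random fixtures."""
        for _ in range(50):
            tr = random_smooth_trace(rng, n=800)
            p99 = record_baseline(tr)
            shifted = shifted_signal_emulation(tr, p99)
            a, b = 100.0, 700.0
            direct = event_area(tr, (a, b), p99).area_pct_s
            via_shift = event_area(shifted, (a, b), 100.0).area_pct_s
            assert via_shift == pytest.approx(direct, rel=1e-12, abs=1e-9)
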