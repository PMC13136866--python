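"""Desaturation-area integration and the three aggregation rules.

The deficit ``max(0, baseline - SpO2(t))`` is integrated exactly over each
sampling window, treating the trace as piecewise linear between samples
(so a baseline crossing inside a sample interval contributes its exact
clipped-trapezoid area).  Invalid samples contribute zero.  Window overlaps
within a method are resolved by truncating the earlier window at the later
window's start, so no time point is double counted.

Aggregation is keyed to the window family:

* event-specific windows  -> sum(%.s) / TST(s)            : percent
* record-specific windows -> (sum(%.s)/60) / TST(h)       : %min per h sleep
* fixed windows           -> sum(%.s) / 3600              : %hours
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .signal_model import (
    EventSource,
    Hypnogram,
    SleepEvent,
    SpO2Trace,
    ZeroSleepTimeError,
    total_sleep_time,
)
from .windows import (
    ALL_COMBOS,
    BaselineFamily,
    EnsembleWindow,
    MethodCombo,
    WindowFamily,
    baseline_for_event,
    ensemble_average_window,
    record_baseline,
    window_for_event,
)

__all__ = [
    "EventArea",
    "MetricValue",
    "event_area",
    "resolve_overlaps",
    "aggregate_metric",
    "compute_method_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EventArea:
    """Integrated saturation deficit for one event window, in %.seconds."""

    event_index: int
    window: tuple[float, float]
    baseline: float
    area_pct_s: float
    clipped: bool = False

    def __post_init__(self):
        if self.area_pct_s < 0:
            raise ValueError("area must be non-negative")


@dataclass(frozen=True)
class MetricValue:
    """One aggregated metric: a method-matrix cell evaluated on a recording."""

    combo: MethodCombo
    value: float
    units: str
    n_events: int


def event_area(
    trace: SpO2Trace,
    window: tuple[float, float],
    baseline: float,
    event_index: int = 0,
) -> EventArea:
    """Exact integral of ``max(0, baseline - SpO2(t))`` over ``window``.

    The trace is piecewise linear between sample starts; segments whose
    endpoints straddle the baseline are split at the crossing.  Segments with
    an invalid endpoint, and any part of the window outside the recording,
    contribute zero (the latter sets ``clipped``).
    """
    if not 0 < baseline <= 100:
        raise ValueError("baseline must be in (0, 100]")
    a, b = window
    t0, t1 = trace.start_offset, trace.start_offset + (len(trace) - 1) * trace.sample_interval
    clipped = a < t0 or b > t1
    a_eff, b_eff = max(a, t0), min(b, t1)
    if b_eff <= a_eff:
        return EventArea(event_index, window, baseline, 0.0, clipped=True)

    dt = trace.sample_interval
    # segment k spans [t0 + k*dt, t0 + (k+1)*dt]
    k0 = int(np.floor((a_eff - t0) / dt + 1e-9))
    k1 = int(np.ceil((b_eff - t0) / dt - 1e-9))  # segments k0 .. k1-1
    k1 = min(k1, len(trace) - 1)
    if k1 <= k0:
        return EventArea(event_index, window, baseline, 0.0, clipped=True)

    ks = np.arange(k0, k1)
    seg_l = t0 + ks * dt
    seg_r = seg_l + dt
    lo = np.maximum(seg_l, a_eff)
    hi = np.minimum(seg_r, b_eff)
    ok = trace.valid_mask[ks] & trace.valid_mask[ks + 1]
    with np.errstate(invalid="ignore"):
        d_l = baseline - trace.samples[ks]
        d_r = baseline - trace.samples[ks + 1]
    # deficits at the (possibly clipped) segment ends, linear in t
    fl = (lo - seg_l) / dt
    fr = (hi - seg_l) / dt
    y0 = d_l + (d_r - d_l) * fl
    y1 = d_l + (d_r - d_l) * fr
    w = hi - lo
    area = np.zeros(len(ks))
    both_pos = (y0 >= 0) & (y1 >= 0)
    area[both_pos] = 0.5 * (y0[both_pos] + y1[both_pos]) * w[both_pos]
    cross = (y0 > 0) != (y1 > 0)
    if cross.any():
        yp = np.where(y0[cross] > 0, y0[cross], y1[cross])
        yn = np.where(y0[cross] > 0, y1[cross], y0[cross])
        # triangle above zero: fraction of the segment where deficit > 0
        area[cross] = 0.5 * yp * w[cross] * yp / (yp - yn)
    area[~ok] = 0.0
    total = float(np.sum(area))
    return EventArea(event_index, window, baseline, max(total, 0.0), clipped=clipped)


def resolve_overlaps(
    windows: Sequence[tuple[float, float]], policy: str = "truncate"
) -> list[tuple[float, float]]:
    """Make time-ordered windows pairwise disjoint.

    Under the default ``truncate`` policy each later window's start truncates
    any earlier window that overruns it; every time point then belongs to at
    most one window and the union of the output equals the union of the
    input.  A window entirely nested inside a predecessor truncates it and
    the predecessor's tail is dropped (logged).  ``policy='none'`` returns
    the input unchanged.
    """
    if policy == "none":
        return [tuple(w) for w in windows]
    if policy != "truncate":
        raise ValueError(f"unknown overlap policy {policy!r}")
    return [w for w in _resolve_overlaps_paired(windows) if w is not None]


def _resolve_overlaps_paired(
    windows: Sequence[tuple[float, float]]
) -> list[Optional[tuple[float, float]]]:
    """Truncate-earlier-at-later-start, preserving the input pairing.

    Returns one entry per input window: the disjoint interval that survives
    for it, or ``None`` when a later start swallowed it entirely.  Inputs
    must be ordered by start.
    """
    out: list[Optional[tuple[float, float]]] = []
    for a, b in windows:
        if out and a < b:
            for j in range(len(out) - 1, -1, -1):
                if out[j] is None:
                    continue
                pa, pb = out[j]
                if pb <= a:
                    break  # kept windows are disjoint/ordered: earlier ones end sooner
                if pb > b:
                    logger.warning(
                        "window [%s, %s) nested in [%s, %s); predecessor tail dropped",
                        a, b, pa, pb,
                    )
                out[j] = (pa, a) if a > pa else None
        out.append((a, b) if b > a else None)
    return out


def aggregate_metric(
    areas: Sequence[EventArea], combo: MethodCombo, tst_h: float
) -> MetricValue:
    """Aggregate per-event areas into the combo's scalar metric."""
    total = float(sum(a.area_pct_s for a in areas))
    if combo.window == WindowFamily.fixed:
        value = total / 3600.0
    else:
        if tst_h <= 0:
            raise ZeroSleepTimeError("per-TST aggregation needs TST > 0")
        if combo.window == WindowFamily.event_specific:
            value = total / (tst_h * 3600.0)
        else:  # record_specific: %min per hour of sleep
            value = (total / 60.0) / tst_h
    return MetricValue(combo, value, combo.units, len(areas))


def compute_method_matrix(
    trace: SpO2Trace,
    manual_events: Sequence[SleepEvent],
    auto_events: Sequence[SleepEvent],
    hypnogram: Hypnogram,
    *,
    ensemble_kwargs: Optional[dict] = None,
    lookback_s: float = 100.0,
    overlap_policy: str = "truncate",
    fixed_window_ends_at_2p5T: bool = False,
    combos: Sequence[MethodCombo] = ALL_COMBOS,
) -> list[MetricValue]:
    """Evaluate every method-matrix cell on one recording.

    The ensemble window is computed once per event source and the record
    baseline once per recording; overlap resolution is applied independently
    within each combo.  A combo whose computation fails is reported as a
    missing (NaN) value rather than aborting the matrix.
    """
    tst_h = total_sleep_time(hypnogram)
    p99 = record_baseline(trace)
    ens_kwargs = ensemble_kwargs or {}
    events_by_source = {
        EventSource.manual_respiratory: list(manual_events),
        EventSource.auto_desaturation: list(auto_events),
    }
    ens_by_source: dict[EventSource, Optional[EnsembleWindow]] = {}
    for source, evs in events_by_source.items():
        ens_by_source[source] = (
            ensemble_average_window(trace, evs, **ens_kwargs) if evs else None
        )

    results: list[MetricValue] = []
    for combo in combos:
        evs = sorted(events_by_source[combo.source], key=lambda e: e.start_s)
        try:
            if not evs:
                results.append(MetricValue(combo, 0.0, combo.units, 0))
                continue
            raw_windows = [
                window_for_event(
                    e,
                    combo.window,
                    ens_by_source[combo.source],
                    fixed_window_ends_at_2p5T=fixed_window_ends_at_2p5T,
                )
                for e in evs
            ]
            order = np.argsort([w[0] for w in raw_windows], kind="stable")
            ordered = [raw_windows[i] for i in order]
            ordered_evs = [evs[i] for i in order]
            if overlap_policy == "none":
                resolved: list[Optional[tuple[float, float]]] = list(ordered)
            else:
                resolved = _resolve_overlaps_paired(ordered)
            areas: list[EventArea] = []
            for i, (ev, win) in enumerate(zip(ordered_evs, resolved)):
                if win is None:
                    continue
                bl = baseline_for_event(
                    trace,
                    ev,
                    combo.baseline,
                    p99,
                    lookback_s=lookback_s,
                    kulkas_within_event=combo.is_original_kulkas,
                    window=win,
                )
                areas.append(event_area(trace, win, bl, event_index=i))
            results.append(aggregate_metric(areas, combo, tst_h))
        except Exception:  # noqa: BLE001 - failed combos become missing cells
            logger.exception("combo %s failed; reported as missing", combo.label)
            results.append(MetricValue(combo, float("nan"), combo.units, 0))
    return results
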