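"""Sampling-window and baseline families for desaturation-area metrics.

Every desaturation-area metric is determined by three choices: which sleep
events anchor the integration, which sampling window is integrated over, and
which baseline the saturation deficit is measured from.  Crossing two event
sources (manually scored respiratory events, automatically detected
desaturations) with three window families and three baseline families yields
an 18-cell method matrix; 15 of the cells correspond to the combinations the
comparative literature has evaluated (the three event-specific-window x
manual-event cells being the historically uncomputed remainder) and are
flagged ``in_paper_subset``.

Window families
---------------
* ``event_specific`` — the event interval itself (for detected desaturations:
  apex to plateau-adjusted end).
* ``record_specific`` — a per-recording window around event end, bounded by
  the two peaks flanking the nadir of the event-locked ensemble-averaged
  SpO2 trace (the hypoxic-burden construction).
* ``fixed`` — starts at the event midpoint and extends for 2.5 event
  durations (the REDTA construction).

Baseline families
-----------------
* ``event_specific`` — maximum SpO2 in the 100 s before event end; for the
  original desaturation-severity combination (auto events, event window) the
  maximum within the event window instead.
* ``record_specific`` — the 99th percentile of the recording's valid samples.
* ``fixed`` — 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .signal_model import EventSource, SleepEvent, SpO2Trace

__all__ = [
    "WindowFamily",
    "BaselineFamily",
    "MethodCombo",
    "EnsembleWindow",
    "ALL_COMBOS",
    "ensemble_average_window",
    "window_for_event",
    "record_baseline",
    "baseline_for_event",
    "shifted_signal_emulation",
]


class WindowFamily(str, Enum):
    event_specific = "event_specific"
    record_specific = "record_specific"
    fixed = "fixed"


class BaselineFamily(str, Enum):
    event_specific = "event_specific"
    record_specific = "record_specific"
    fixed = "fixed"


@dataclass(frozen=True)
class MethodCombo:
    """One cell of the method matrix, with its canonical label."""

    source: EventSource
    window: WindowFamily
    baseline: BaselineFamily
    label: str
    in_paper_subset: bool

    @property
    def units(self) -> str:
        return {
            WindowFamily.event_specific: "%",
            WindowFamily.record_specific: "%min/h sleep",
            WindowFamily.fixed: "%hours",
        }[self.window]

    @property
    def is_original_kulkas(self) -> bool:
        """The original desaturation-severity cell, whose event baseline is
        the within-window maximum rather than the 100-s lookback."""
        return (
            self.source == EventSource.auto_desaturation
            and self.window == WindowFamily.event_specific
            and self.baseline == BaselineFamily.event_specific
        )


def _build_combos() -> tuple[MethodCombo, ...]:
    base_names = {
        WindowFamily.record_specific: "Azarbarzin method",
        WindowFamily.fixed: "de Chazal method",
        WindowFamily.event_specific: "Kulkas method",
    }
    combos = []
    for source in (EventSource.manual_respiratory, EventSource.auto_desaturation):
        for window in WindowFamily:
            for baseline in BaselineFamily:
                name = base_names[window]
                mods: list[str] = []
                # the native baseline of each base algorithm
                native = {
                    WindowFamily.record_specific: BaselineFamily.event_specific,
                    WindowFamily.fixed: BaselineFamily.fixed,
                    WindowFamily.event_specific: BaselineFamily.event_specific,
                }[window]
                if baseline != native:
                    mods.append(f"{baseline.value.replace('_', '-')} baseline")
                native_source = (
                    EventSource.auto_desaturation
                    if window == WindowFamily.event_specific
                    else EventSource.manual_respiratory
                )
                if source != native_source:
                    mods.append(
                        "desaturation events"
                        if source == EventSource.auto_desaturation
                        else "respiratory events"
                    )
                label = name if not mods else f"{name} ({', '.join(mods)})"
                in_subset = not (
                    source == EventSource.manual_respiratory
                    and window == WindowFamily.event_specific
                )
                combos.append(MethodCombo(source, window, baseline, label, in_subset))
    return tuple(combos)


#: The full 18-cell method matrix in canonical order.
ALL_COMBOS: tuple[MethodCombo, ...] = _build_combos()


@dataclass(frozen=True)
class EnsembleWindow:
    """Record-specific window offsets, in seconds relative to event end."""

    pre_offset_s: float
    post_offset_s: float
    n_events_used: int
    fallback_used: bool = False

    def __post_init__(self):
        if not (self.pre_offset_s <= 0 <= self.post_offset_s):
            raise ValueError("window must straddle event end")
        if not self.post_offset_s - self.pre_offset_s > 0:
            raise ValueError("window must have positive length")


#: Fallback used when the averaged trace has no resolvable dip structure.
FALLBACK_WINDOW = (-100.0, 100.0)


def ensemble_average_window(
    trace: SpO2Trace,
    events: Sequence[SleepEvent],
    span_pre_s: float = 120.0,
    span_post_s: float = 240.0,
    smooth_s: float = 10.0,
    min_events: int = 5,
) -> EnsembleWindow:
    """Locate the record-specific sampling window from the event-locked
    ensemble average of the SpO2 trace.

    Segments on ``[end_s - span_pre_s, end_s + span_post_s]`` are aligned at
    event end and averaged samplewise over events (invalid samples ignored),
    then smoothed with a centred moving average.  The window boundaries are
    the nearest local maxima flanking the averaged curve's nadir.  When fewer
    than ``min_events`` events exist or either flanking peak is undetectable
    the conventional (-100 s, +100 s) fallback is returned with
    ``fallback_used`` set.
    """
    if not events:
        raise ValueError("ensemble window requires at least one event")
    dt = trace.sample_interval
    n_rel = int(round((span_pre_s + span_post_s) / dt)) + 1
    rel_t = -span_pre_s + np.arange(n_rel) * dt
    acc = np.zeros(n_rel)
    cnt = np.zeros(n_rel)
    for ev in events:
        t0 = ev.end_s - span_pre_s
        idx = np.round((t0 + np.arange(n_rel) * dt - trace.start_offset) / dt).astype(int)
        ok = (idx >= 0) & (idx < len(trace))
        sel = idx[ok]
        good = trace.valid_mask[sel]
        acc[np.flatnonzero(ok)[good]] += trace.samples[sel[good]]
        cnt[np.flatnonzero(ok)[good]] += 1.0

    def fallback() -> EnsembleWindow:
        return EnsembleWindow(*FALLBACK_WINDOW, n_events_used=len(events), fallback_used=True)

    if len(events) < min_events or not (cnt > 0).any():
        return fallback()
    avg = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    # fill interior gaps so smoothing and peak finding see a contiguous curve
    ok = np.isfinite(avg)
    if ok.sum() < 3:
        return fallback()
    avg = np.interp(np.arange(n_rel), np.flatnonzero(ok), avg[ok])
    if smooth_s > dt:
        w = int(round(smooth_s / dt))
        if w % 2 == 0:
            w += 1
        kernel = np.ones(w) / w
        avg = np.convolve(np.pad(avg, w // 2, mode="edge"), kernel, mode="valid")

    nadir = int(np.argmin(avg))
    # walk uphill from the nadir on each side; the peak is where ascent stops
    left = nadir
    while left > 0 and avg[left - 1] > avg[left]:
        left -= 1
    right = nadir
    while right < n_rel - 1 and avg[right + 1] > avg[right]:
        right += 1
    if left == nadir or right == nadir:
        return fallback()
    pre = float(rel_t[left])
    post = float(rel_t[right])
    if not (pre <= 0 <= post) or post - pre <= 0:
        return fallback()
    return EnsembleWindow(pre, post, n_events_used=len(events), fallback_used=False)


def window_for_event(
    ev: SleepEvent,
    family: WindowFamily,
    ens: Optional[EnsembleWindow] = None,
    fixed_window_ends_at_2p5T: bool = False,
) -> tuple[float, float]:
    """Sampling interval ``[a, b)`` for one event under one window family.

    ``fixed`` windows start at the event midpoint; by default their length is
    2.5 event durations (end at ``start + 3T``).  Setting
    ``fixed_window_ends_at_2p5T`` instead ends the window at
    ``start + 2.5T`` (the alternative reading of the published geometry).
    Clipping to the recording span is the area engine's responsibility.
    """
    if family == WindowFamily.event_specific:
        return (ev.start_s, ev.end_s)
    if family == WindowFamily.record_specific:
        if ens is None:
            raise ValueError("record_specific window requires an EnsembleWindow")
        return (ev.end_s + ens.pre_offset_s, ev.end_s + ens.post_offset_s)
    T = ev.duration_s
    a = ev.start_s + T / 2.0
    b = ev.start_s + 2.5 * T if fixed_window_ends_at_2p5T else a + 2.5 * T
    return (a, b)


def record_baseline(trace: SpO2Trace) -> float:
    """Record-specific baseline: 99th percentile of the valid samples
    (linear-interpolation percentile)."""
    vals = trace.samples[trace.valid_mask]
    if vals.size == 0:
        raise ValueError("no valid samples for record baseline")
    return float(np.percentile(vals, 99))


def baseline_for_event(
    trace: SpO2Trace,
    ev: SleepEvent,
    family: BaselineFamily,
    record_p99: float,
    lookback_s: float = 100.0,
    kulkas_within_event: bool = False,
    window: Optional[tuple[float, float]] = None,
) -> float:
    """Baseline saturation (percent) for one event under one baseline family.

    ``fixed`` is 100%; ``record_specific`` is the recording's 99th percentile;
    ``event_specific`` is the maximum valid SpO2 in the ``lookback_s`` seconds
    before event end — except for the original desaturation-severity
    combination (``kulkas_within_event``), where it is the maximum within the
    event window.  If the relevant span holds no valid sample the record
    baseline is used as fallback.
    """
    if family == BaselineFamily.fixed:
        return 100.0
    if family == BaselineFamily.record_specific:
        return record_p99
    if kulkas_within_event:
        a, b = window if window is not None else (ev.start_s, ev.end_s)
    else:
        a, b = ev.end_s - lookback_s, ev.end_s
    i0, i1 = trace.slice_indices(a, b)
    seg = trace.samples[i0:i1][trace.valid_mask[i0:i1]]
    if seg.size == 0:
        return record_p99
    return float(seg.max())


def shifted_signal_emulation(trace: SpO2Trace, record_p99: float) -> SpO2Trace:
    """Raise every valid sample by ``100 - record_p99``.

    This reproduces the signal-shift trick by which a fixed-100% pipeline is
    made to integrate against the record-specific baseline: the deficit below
    100% on the shifted trace equals the deficit below the 99th percentile on
    the original.  Used to verify equivalence with the direct computation.
    """
    if record_p99 > 100:
        raise ValueError("record baseline cannot exceed 100%")
    shift = 100.0 - record_p99
    vals = np.where(trace.valid_mask, trace.samples + shift, trace.samples)
    return replace(trace, samples=vals)
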