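"""Automatic detection of oxygen desaturation events.

Implements the apex/nadir/plateau scan used for desaturation-severity style
metrics: a candidate event starts at a local saturation maximum (apex),
descends while the signal stays near its running minimum, and is emitted when
the apex-to-nadir drop reaches the detection threshold (3% by default, the
AASM-aligned criterion).  The sampling window runs from the apex to the nadir,
extended through any terminal plateau, and is capped at 180 s.

The recovery and plateau tolerances are this package's explicit choices,
surfaced in :class:`DetectionParams` and echoed into output metadata, since
published descriptions of the original software leave them unspecified.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .signal_model import EventKind, EventSource, SleepEvent, SpO2Trace

__all__ = ["DetectionParams", "detect_desaturations", "UncleanTraceError"]


class UncleanTraceError(ValueError):
    """Detection requires a cleaned trace (no out-of-band valid samples)."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable detection thresholds.

    min_drop_pct : minimum apex-to-nadir fall, percent (default 3.0).
    max_window_s : cap on the apex-to-window-end span, seconds (default 180).
    recovery_tolerance_pct : rise above the running minimum that terminates
        the descent, percent (default 1.0).
    plateau_tolerance_pct : band above the nadir within which trailing samples
        still extend the window, percent (default 0.5).
    smoothing_window_s : centred moving-average width applied before the scan;
        0 disables smoothing (the default — detection runs on the cleaned
        trace as-is).
    """

    min_drop_pct: float = 3.0
    max_window_s: float = 180.0
    recovery_tolerance_pct: float = 1.0
    plateau_tolerance_pct: float = 0.5
    smoothing_window_s: float = 0.0

    def __post_init__(self):
        if not self.min_drop_pct > 0:
            raise ValueError("min_drop_pct must be > 0")
        if not self.max_window_s > 0:
            raise ValueError("max_window_s must be > 0")
        if self.recovery_tolerance_pct < 0 or self.plateau_tolerance_pct < 0:
            raise ValueError("tolerances must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _valid_segments(mask: np.ndarray):
    """Yield (lo, hi) index ranges (inclusive) of maximal valid runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    splits = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, splits + 1):
        yield int(run[0]), int(run[-1])


def detect_desaturations(
    trace: SpO2Trace, p: DetectionParams = DetectionParams()
) -> list[SleepEvent]:
    """Scan a cleaned trace left-to-right for >= min_drop desaturation events.

    Within each maximal run of valid samples: a candidate apex is a sample
    from which the signal falls; the descent tracks the running minimum and
    ends when the signal rises more than ``recovery_tolerance_pct`` above it
    or climbs above the candidate apex itself (the higher point then
    supersedes the candidate).
    The nadir is the earliest sample attaining the running minimum.  An event
    is emitted iff apex - nadir >= ``min_drop_pct``.  The window end starts at
    the nadir and is pushed forward through samples within
    ``plateau_tolerance_pct`` of the nadir value, then the apex-to-end span is
    truncated to ``max_window_s`` (the nadir is re-located inside the
    truncated window if the original fell beyond it).  Returned events are
    pairwise disjoint and time-ordered; scanning resumes past each event.
    """
    vals = trace.samples
    with np.errstate(invalid="ignore"):
        bad = trace.valid_mask & ((vals < 50.0) | (vals > 100.0) | ~np.isfinite(vals))
    if bad.any():
        raise UncleanTraceError("trace contains out-of-band valid samples; run clean_trace first")

    if p.smoothing_window_s > trace.sample_interval:
        vals = _smooth(vals, trace.valid_mask, p.smoothing_window_s, trace.sample_interval)

    dt = trace.sample_interval
    events: list[SleepEvent] = []
    for lo, hi in _valid_segments(trace.valid_mask):
        i = lo
        while i < hi:
            # advance to the last sample before a strict fall (apex);
            # flats en route to the descent belong to the pre-event baseline
            while i < hi and vals[i + 1] >= vals[i]:
                i += 1
            if i >= hi:
                break
            apex = i
            # descend: track running min; stop on recovery or segment end
            min_idx = apex
            min_val = vals[apex]
            j = apex + 1
            while j <= hi:
                if vals[j] < min_val:
                    min_val = vals[j]
                    min_idx = j
                elif vals[j] > min_val + p.recovery_tolerance_pct or vals[j] > vals[apex]:
                    # recovered past tolerance, or climbed above the apex
                    # itself (a higher apex supersedes this candidate)
                    break
                j += 1
            drop = vals[apex] - min_val
            if drop >= p.min_drop_pct and min_idx > apex:
                # re-anchor the apex to the latest local maximum that is still
                # within the recovery tolerance of the original apex and a
                # full drop above the nadir: noise-level wobble at the top is
                # not the start of the descent, and without this a slow drift
                # preceding a deep dip would stretch the window over minutes
                apex0_val = vals[apex]
                for m in range(apex + 1, min_idx):
                    if (
                        vals[m] >= apex0_val - p.recovery_tolerance_pct
                        and vals[m] - min_val >= p.min_drop_pct
                        and vals[m] > vals[m + 1]
                        and vals[m] >= vals[m - 1]
                    ):
                        apex = m
                end_idx = min_idx
                while end_idx < hi and vals[end_idx + 1] <= min_val + p.plateau_tolerance_pct:
                    end_idx += 1
                # cap apex-to-end span; re-locate nadir inside if needed
                max_span = int(np.floor(p.max_window_s / dt))
                if end_idx + 1 - apex > max_span:
                    end_idx = apex + max_span - 1
                    if min_idx > end_idx:
                        win = vals[apex : end_idx + 1]
                        min_idx = apex + int(np.argmin(win))
                        min_val = vals[min_idx]
                t0 = trace.start_offset + apex * dt
                events.append(
                    SleepEvent(
                        start_s=t0,
                        end_s=trace.start_offset + (end_idx + 1) * dt,
                        kind=EventKind.desaturation,
                        source=EventSource.auto_desaturation,
                        apex_s=t0,
                        apex_val=float(vals[apex]),
                        nadir_s=trace.start_offset + min_idx * dt,
                        nadir_val=float(min_val),
                        plateau_end_s=trace.start_offset + (end_idx + 1) * dt,
                    )
                )
                i = end_idx + 1 if end_idx + 1 > j else j
            else:
                # no event: resume from the point the descent stopped, or step
                i = j if j > apex + 1 else apex + 1
    return events


def _smooth(vals: np.ndarray, mask: np.ndarray, width_s: float, dt: float) -> np.ndarray:
    w = max(int(round(width_s / dt)), 1)
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w)
    filled = np.where(mask, vals, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(mask.astype(float), kernel, mode="same")
    out = np.where(den > 0, num / np.maximum(den, 1e-12), np.nan)
    return np.where(mask, out, vals)
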