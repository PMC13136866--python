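"""Core signal and annotation types for overnight oximetry analysis.

The substrate of every desaturation-area computation is a uniformly sampled
SpO2 trace (percent saturation, nominally 1 Hz as in SHHS-style recordings)
together with a list of sleep events and a per-epoch hypnogram.  All times in
this package are seconds from recording start, and all intervals are half-open
``[start_s, end_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SpO2Trace",
    "EventKind",
    "EventSource",
    "SleepEvent",
    "Hypnogram",
    "CovariateSet",
    "UnusableRecordingError",
    "ZeroSleepTimeError",
    "clean_trace",
    "total_sleep_time",
    "compute_t90",
    "compute_ahi",
    "compute_minsat",
    "resample_to_1hz",
]

#: Physiological validity band for SpO2, in percent.  Oximeter dropouts
#: typically read 0 and must never enter an area integral.
VALID_BAND = (50.0, 100.0)

SLEEP_STAGES = ("wake", "n1", "n2", "n3", "rem")


class UnusableRecordingError(ValueError):
    """Raised when a trace contains no valid samples at all."""


class ZeroSleepTimeError(ValueError):
    """Raised when a per-TST quantity is requested for a record with TST == 0."""


@dataclass(frozen=True)
class SpO2Trace:
    """Uniformly sampled oxygen-saturation series with a validity mask.

    Parameters
    ----------
    samples
        Saturation values in percent.
    sample_interval
        Seconds per sample (1.0 for the canonical 1 Hz grid).
    start_offset
        Seconds from recording start to the first sample.
    valid_mask
        Per-sample validity; invalid samples contribute zero to any
        area integral and zero time to T90.
    """

    samples: np.ndarray
    sample_interval: float = 1.0
    start_offset: float = 0.0
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("trace must be a non-empty 1-D array")
        if not self.sample_interval > 0:
            raise ValueError("sample_interval must be > 0")
        if self.valid_mask is None:
            object.__setattr__(self, "valid_mask", np.isfinite(samples))
        else:
            mask = np.asarray(self.valid_mask, dtype=bool)
            if mask.shape != samples.shape:
                raise ValueError("valid_mask shape mismatch")
            object.__setattr__(self, "valid_mask", mask)
        if not np.all(np.isfinite(samples[self.valid_mask])):
            raise ValueError("valid samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample start times in seconds from recording start."""
        return self.start_offset + np.arange(len(self)) * self.sample_interval

    @property
    def duration_s(self) -> float:
        return len(self) * self.sample_interval

    @property
    def end_s(self) -> float:
        return self.start_offset + self.duration_s

    def slice_indices(self, start_s: float, end_s: float) -> tuple[int, int]:
        """Indices ``[i0, i1)`` of samples whose start time lies in [start_s, end_s)."""
        i0 = int(np.ceil((start_s - self.start_offset) / self.sample_interval - 1e-9))
        i1 = int(np.ceil((end_s - self.start_offset) / self.sample_interval - 1e-9))
        return max(i0, 0), min(max(i1, 0), len(self))


class EventKind(str, Enum):
    obstructive_apnea = "obstructive_apnea"
    hypopnea = "hypopnea"
    desaturation = "desaturation"


class EventSource(str, Enum):
    manual_respiratory = "manual_respiratory"
    auto_desaturation = "auto_desaturation"


@dataclass(frozen=True)
class SleepEvent:
    """One annotated respiratory event or detected desaturation.

    Manual respiratory events carry only timing and kind; automatically
    detected desaturations additionally carry apex/nadir/plateau geometry.
    """

    start_s: float
    end_s: float
    kind: EventKind = EventKind.hypopnea
    source: EventSource = EventSource.manual_respiratory
    apex_s: Optional[float] = None
    apex_val: Optional[float] = None
    nadir_s: Optional[float] = None
    nadir_val: Optional[float] = None
    plateau_end_s: Optional[float] = None

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValueError("end_s must exceed start_s")
        if self.source == EventSource.auto_desaturation:
            if self.apex_s is None or self.nadir_s is None:
                raise ValueError("auto events require apex/nadir")
            if not (self.apex_s <= self.nadir_s):
                raise ValueError("apex must not follow nadir")
            if self.plateau_end_s is not None and self.plateau_end_s < self.nadir_s:
                raise ValueError("plateau end before nadir")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch sleep staging; default 30-s epochs starting at time zero."""

    stages: tuple
    epoch_length_s: float = 30.0
    start_offset: float = 0.0

    def __post_init__(self):
        if not self.epoch_length_s > 0:
            raise ValueError("epoch_length_s must be > 0")
        stages = tuple(self.stages)
        if not stages:
            raise ValueError("hypnogram must be non-empty")
        for s in stages:
            if s not in SLEEP_STAGES:
                raise ValueError(f"unknown sleep stage {s!r}")
        object.__setattr__(self, "stages", stages)

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def span_s(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def sleep_mask(self) -> np.ndarray:
        return np.array([s != "wake" for s in self.stages], dtype=bool)

    def stage_at(self, t_s: float) -> str:
        idx = int((t_s - self.start_offset) // self.epoch_length_s)
        idx = min(max(idx, 0), self.n_epochs - 1)
        return self.stages[idx]

    def is_asleep_at(self, t_s: float) -> bool:
        return self.stage_at(t_s) != "wake"


@dataclass
class CovariateSet:
    """Per-subject covariates entering the survival models.

    ``tst_h``/``ahi``/``t90_pct``/``minsat_pct`` are derived from the
    recording; the remaining fields are demographic/clinical.
    """

    tst_h: float = np.nan
    ahi: float = np.nan
    t90_pct: float = np.nan
    minsat_pct: float = np.nan
    age: float = np.nan
    male: Optional[int] = None
    caucasian: Optional[int] = None
    smoking: Optional[str] = None  # never / former / current
    alcohol: float = np.nan
    copd: Optional[int] = None
    heart_failure: Optional[int] = None
    stroke: Optional[int] = None
    angina: Optional[int] = None
    revascularization: Optional[int] = None
    myocardial_infarction: Optional[int] = None

    def __post_init__(self):
        if np.isfinite(self.tst_h) and self.tst_h < 0:
            raise ValueError("tst_h must be >= 0")
        if np.isfinite(self.t90_pct) and not (0 <= self.t90_pct <= 100):
            raise ValueError("t90_pct must be in [0, 100]")
        if np.isfinite(self.ahi) and self.ahi < 0:
            raise ValueError("ahi must be >= 0")


# ---------------------------------------------------------------------------
# Trace cleaning


def clean_trace(raw: SpO2Trace, max_gap_s: float = 30.0) -> SpO2Trace:
    """Mask non-physiological samples and bridge short dropout gaps.

    Samples outside the [50, 100]% band (or non-finite) are marked invalid.
    Invalid runs no longer than ``max_gap_s`` that are flanked by valid
    samples are linearly interpolated and restored to validity; longer runs
    stay invalid and contribute zero to every downstream area integral.

    Raises
    ------
    UnusableRecordingError
        If no sample survives the validity screen.
    """
    samples = raw.samples.copy()
    finite = np.isfinite(samples)
    valid = raw.valid_mask & finite
    with np.errstate(invalid="ignore"):
        valid &= (samples >= VALID_BAND[0]) & (samples <= VALID_BAND[1])
    if not valid.any():
        raise UnusableRecordingError("no valid SpO2 samples in recording")

    max_gap_samples = int(np.floor(max_gap_s / raw.sample_interval))
    out_valid = valid.copy()
    n = len(samples)
    idx = np.flatnonzero(~valid)
    if idx.size:
        # group consecutive invalid indices into runs
        splits = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, splits + 1)
        for run in runs:
            lo, hi = run[0], run[-1]
            if len(run) > max_gap_samples:
                continue
            if lo == 0 or hi == n - 1:
                continue  # edge gaps cannot be bridged
            if not (valid[lo - 1] and valid[hi + 1]):
                continue
            frac = (run - (lo - 1)) / (hi + 2 - lo)
            samples[run] = samples[lo - 1] + frac * (samples[hi + 1] - samples[lo - 1])
            out_valid[run] = True
    samples[~out_valid] = np.nan
    return replace(raw, samples=samples, valid_mask=out_valid)


def resample_to_1hz(trace: SpO2Trace) -> SpO2Trace:
    """Linearly resample a trace onto the canonical 1-Hz grid.

    No-op when the trace is already at 1 Hz.  Target samples falling inside
    invalid source stretches remain invalid.
    """
    if trace.sample_interval == 1.0:
        return trace
    t_src = trace.times
    t_new = np.arange(trace.start_offset, trace.end_s, 1.0)
    ok = trace.valid_mask
    if ok.sum() < 2:
        raise UnusableRecordingError("too few valid samples to resample")
    vals = np.interp(t_new, t_src[ok], trace.samples[ok])
    # validity: nearest source sample must be valid
    nearest = np.clip(
        np.round((t_new - trace.start_offset) / trace.sample_interval).astype(int),
        0,
        len(trace) - 1,
    )
    mask = ok[nearest]
    vals = np.where(mask, vals, np.nan)
    return SpO2Trace(vals, 1.0, trace.start_offset, mask)


# ---------------------------------------------------------------------------
# Covariate derivation


def total_sleep_time(h: Hypnogram) -> float:
    """Total sleep time in hours: the summed duration of non-wake epochs."""
    return float(h.sleep_mask().sum() * h.epoch_length_s / 3600.0)


def compute_t90(trace: SpO2Trace, h: Hypnogram) -> float:
    """Percent of total sleep time spent with SpO2 below 90%.

    Invalid samples contribute no sub-90 time (but their epochs still count
    toward TST), so the measure never fabricates hypoxia from dropouts.
    """
    tst_h = total_sleep_time(h)
    if tst_h <= 0:
        raise ZeroSleepTimeError("T90 undefined with zero sleep time")
    t = trace.times
    epoch_idx = np.clip(
        ((t - h.start_offset) // h.epoch_length_s).astype(int), 0, h.n_epochs - 1
    )
    in_hypnogram = (t >= h.start_offset) & (t < h.start_offset + h.span_s)
    asleep = h.sleep_mask()[epoch_idx] & in_hypnogram
    with np.errstate(invalid="ignore"):
        below = trace.valid_mask & (trace.samples < 90.0)
    low_time_s = float(np.sum(asleep & below) * trace.sample_interval)
    return 100.0 * low_time_s / (tst_h * 3600.0)


def compute_ahi(events: Sequence[SleepEvent], tst_h: float) -> float:
    """Apnea-hypopnea index: manually scored respiratory events per hour of sleep."""
    if tst_h <= 0:
        raise ZeroSleepTimeError("AHI undefined with zero sleep time")
    n = sum(1 for e in events if e.source == EventSource.manual_respiratory)
    return n / tst_h


def compute_minsat(
    trace: SpO2Trace,
    events: Sequence[SleepEvent],
    assoc_windows: Optional[Sequence[tuple[float, float]]] = None,
    mode: str = "min_over_windows",
) -> Optional[float]:
    """Event-related minimum oxygen saturation, in percent.

    By default the minimum valid sample over the union of event-associated
    windows (the event interval itself when no explicit windows are given);
    ``mode='mean_of_nadirs'`` instead averages per-window minima.

    Returns ``None`` when there are no events or no valid samples in any
    window (a missing covariate, not an error).
    """
    if not events:
        return None
    if assoc_windows is None:
        assoc_windows = [(e.start_s, e.end_s) for e in events]
    per_window_min: list[float] = []
    for a, b in assoc_windows:
        i0, i1 = trace.slice_indices(a, b)
        seg = trace.samples[i0:i1][trace.valid_mask[i0:i1]]
        if seg.size:
            per_window_min.append(float(seg.min()))
    if not per_window_min:
        return None
    if mode == "mean_of_nadirs":
        return float(np.mean(per_window_min))
    return float(min(per_window_min))
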