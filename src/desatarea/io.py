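"""Readers and writers for traces, event lists, hypnograms and cohorts.

Canonical on-disk dialects:

* SpO2 trace CSV — columns ``t_s, spo2, valid``; 1 Hz, seconds from
  recording start.  Saturations encoded as fractions (0-1) are auto-detected
  and rescaled to percent with a warning.
* Event CSV — columns ``start_s, end_s`` (or ``duration_s``), ``type``,
  ``source`` and, for detected desaturations, ``apex_s, apex_val, nadir_s,
  nadir_val, plateau_end_s``.
* Hypnogram CSV — columns ``start_s, stage`` with uniform epochs.
* SHHS-style annotation XML — ``ScoredEvent`` elements with
  ``EventConcept``/``Start``/``Duration``, plus staging events.
* Cohort CSV — one row per subject: metric columns (``metric::<label>``),
  covariates, ``followup_years``, ``cvd_death``.

EDF reading (SpO2 channel) is available when :mod:`mne` is installed.
All parsers raise :class:`ParseError` naming the offending file and field.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .signal_model import EventKind, EventSource, Hypnogram, SleepEvent, SpO2Trace
from .survival import SubjectRecord

__all__ = [
    "ParseError",
    "read_trace_csv",
    "write_trace_csv",
    "read_events_csv",
    "write_events_csv",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "read_annotations_xml",
    "write_annotations_xml",
    "read_edf_spo2",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_recording",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message names the file and field."""


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# Traces


def write_trace_csv(trace: SpO2Trace, path) -> None:
    df = pd.DataFrame(
        {
            "t_s": trace.times,
            "spo2": np.where(trace.valid_mask, trace.samples, np.nan),
            "valid": trace.valid_mask.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_trace_csv(path) -> SpO2Trace:
    df = pd.read_csv(path)
    _require(df, ["t_s", "spo2"], path)
    t = df["t_s"].to_numpy(float)
    if len(t) < 2:
        raise ParseError(f"{path}: trace needs >= 2 samples")
    dt = float(np.median(np.diff(t)))
    if dt <= 0 or not np.allclose(np.diff(t), dt, atol=1e-6):
        raise ParseError(f"{path}: field t_s is not uniformly sampled")
    vals = df["spo2"].to_numpy(float)
    valid = (
        df["valid"].to_numpy(int).astype(bool)
        if "valid" in df.columns
        else np.isfinite(vals)
    )
    finite = vals[np.isfinite(vals)]
    if finite.size and np.nanmax(finite) <= 1.5:
        logger.warning("%s: saturation encoded 0-1; rescaling to percent", path)
        vals = vals * 100.0
    vals = np.where(valid & np.isfinite(vals), vals, np.nan)
    return SpO2Trace(vals, sample_interval=dt, start_offset=float(t[0]), valid_mask=valid)


def read_edf_spo2(
    path, channel_candidates: Sequence[str] = ("SaO2", "SpO2", "SAO2", "SPO2")
) -> SpO2Trace:
    """Read the oximetry channel of an EDF recording (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    name = next((c for c in channel_candidates if c in raw.ch_names), None)
    if name is None:
        raise ParseError(f"{path}: no SpO2 channel among {raw.ch_names}")
    data = raw.get_data(picks=[name])[0]
    if np.nanmax(data) <= 1.5:
        logger.warning("%s: EDF saturation encoded 0-1; rescaling to percent", path)
        data = data * 100.0
    return SpO2Trace(data, sample_interval=1.0 / raw.info["sfreq"])


# ---------------------------------------------------------------------------
# Events

_EVENT_COLS = ["start_s", "end_s", "type", "source",
               "apex_s", "apex_val", "nadir_s", "nadir_val", "plateau_end_s"]


def write_events_csv(events: Sequence[SleepEvent], path) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "start_s": e.start_s,
                "end_s": e.end_s,
                "type": e.kind.value,
                "source": e.source.value,
                "apex_s": e.apex_s,
                "apex_val": e.apex_val,
                "nadir_s": e.nadir_s,
                "nadir_val": e.nadir_val,
                "plateau_end_s": e.plateau_end_s,
            }
        )
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, index=False, float_format="%.6g")


def read_events_csv(path, default_source: str = "manual_respiratory") -> list[SleepEvent]:
    df = pd.read_csv(path)
    _require(df, ["start_s"], path)
    if "end_s" not in df.columns:
        _require(df, ["duration_s"], path)
        df = df.assign(end_s=df["start_s"] + df["duration_s"])
    events = []
    for i, row in df.iterrows():
        start, end = float(row["start_s"]), float(row["end_s"])
        if end <= start:
            raise ParseError(f"{path}: row {i}: end_s {end} <= start_s {start}")
        kind = EventKind(row["type"]) if "type" in df.columns else EventKind.hypopnea
        source = EventSource(row.get("source", default_source) or default_source)

        def opt(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        events.append(
            SleepEvent(
                start, end, kind, source,
                apex_s=opt("apex_s"), apex_val=opt("apex_val"),
                nadir_s=opt("nadir_s"), nadir_val=opt("nadir_val"),
                plateau_end_s=opt("plateau_end_s"),
            )
        )
    return events


# ---------------------------------------------------------------------------
# Hypnograms


def write_hypnogram_csv(h: Hypnogram, path) -> None:
    starts = h.start_offset + np.arange(h.n_epochs) * h.epoch_length_s
    pd.DataFrame({"start_s": starts, "stage": h.stages}).to_csv(path, index=False)


def read_hypnogram_csv(path) -> Hypnogram:
    df = pd.read_csv(path)
    _require(df, ["start_s", "stage"], path)
    starts = df["start_s"].to_numpy(float)
    if len(starts) < 2:
        raise ParseError(f"{path}: hypnogram needs >= 2 epochs")
    epoch = float(starts[1] - starts[0])
    if epoch <= 0 or not np.allclose(np.diff(starts), epoch, atol=1e-6):
        raise ParseError(f"{path}: field start_s is not uniformly spaced")
    return Hypnogram(tuple(df["stage"]), epoch_length_s=epoch, start_offset=float(starts[0]))


# ---------------------------------------------------------------------------
# SHHS-style annotation XML

_XML_CONCEPT = {
    EventKind.obstructive_apnea: "Obstructive apnea|Obstructive Apnea",
    EventKind.hypopnea: "Hypopnea|Hypopnea",
    EventKind.desaturation: "SpO2 desaturation|SpO2 desaturation",
}
_STAGE_CONCEPT = {
    "wake": "Wake|0",
    "n1": "Stage 1 sleep|1",
    "n2": "Stage 2 sleep|2",
    "n3": "Stage 3 sleep|3",
    "rem": "REM sleep|5",
}
_STAGE_FROM_CODE = {v.split("|")[1]: k for k, v in _STAGE_CONCEPT.items()}


def write_annotations_xml(
    events: Sequence[SleepEvent], path, hypnogram: Optional[Hypnogram] = None
) -> None:
    root = ET.Element("PSGAnnotation")
    scored = ET.SubElement(root, "ScoredEvents")
    for e in events:
        el = ET.SubElement(scored, "ScoredEvent")
        ET.SubElement(el, "EventType").text = (
            "Respiratory|Respiratory"
            if e.source == EventSource.manual_respiratory
            else "Desaturation|Desaturation"
        )
        ET.SubElement(el, "EventConcept").text = _XML_CONCEPT[e.kind]
        ET.SubElement(el, "Start").text = f"{e.start_s:.6g}"
        ET.SubElement(el, "Duration").text = f"{e.duration_s:.6g}"
    if hypnogram is not None:
        for i, stage in enumerate(hypnogram.stages):
            el = ET.SubElement(scored, "ScoredEvent")
            ET.SubElement(el, "EventType").text = "Stages|Stages"
            ET.SubElement(el, "EventConcept").text = _STAGE_CONCEPT[stage]
            ET.SubElement(el, "Start").text = (
                f"{hypnogram.start_offset + i * hypnogram.epoch_length_s:.6g}"
            )
            ET.SubElement(el, "Duration").text = f"{hypnogram.epoch_length_s:.6g}"
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_annotations_xml(path) -> tuple[list[SleepEvent], Optional[Hypnogram]]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ParseError(f"{path}: not well-formed XML: {exc}") from exc
    events: list[SleepEvent] = []
    stage_rows: list[tuple[float, float, str]] = []
    for el in root.iter("ScoredEvent"):
        etype = (el.findtext("EventType") or "").strip()
        concept = (el.findtext("EventConcept") or "").strip()
        try:
            start = float(el.findtext("Start"))
            dur = float(el.findtext("Duration"))
        except (TypeError, ValueError):
            raise ParseError(f"{path}: ScoredEvent missing numeric Start/Duration")
        if etype.startswith("Stages"):
            code = concept.split("|")[-1]
            if code not in _STAGE_FROM_CODE:
                raise ParseError(f"{path}: unknown stage concept {concept!r}")
            stage_rows.append((start, dur, _STAGE_FROM_CODE[code]))
            continue
        lowered = concept.lower()
        if "apnea" in lowered:
            kind = EventKind.obstructive_apnea
        elif "hypopnea" in lowered:
            kind = EventKind.hypopnea
        elif "desaturation" in lowered:
            kind = EventKind.desaturation
        else:
            continue  # non-respiratory scored events are ignored
        source = (
            EventSource.auto_desaturation
            if kind == EventKind.desaturation
            else EventSource.manual_respiratory
        )
        events.append(SleepEvent(start, start + dur, kind, source))
    hyp = None
    if stage_rows:
        stage_rows.sort()
        epoch = stage_rows[0][1]
        stages = []
        for start, dur, st in stage_rows:
            n = int(round(dur / epoch)) if epoch > 0 else 1
            stages.extend([st] * max(n, 1))
        hyp = Hypnogram(tuple(stages), epoch_length_s=epoch, start_offset=stage_rows[0][0])
    return events, hyp


# ---------------------------------------------------------------------------
# Cohorts


def write_cohort_csv(records: Sequence[SubjectRecord], path) -> None:
    from .survival import cohort_frame

    cohort_frame(records).to_csv(path, index=False, float_format="%.8g")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["followup_years", "cvd_death"], path)
    if (df["followup_years"] <= 0).any():
        raise ParseError(f"{path}: field followup_years must be > 0")
    return df


def read_recording(
    trace_path, events_path=None, hypnogram_path=None
) -> tuple[SpO2Trace, list[SleepEvent], Optional[Hypnogram]]:
    """Load a recording from the canonical dialects, dispatching on suffix."""
    trace_path = Path(trace_path)
    if trace_path.suffix.lower() == ".edf":
        trace = read_edf_spo2(trace_path)
    else:
        trace = read_trace_csv(trace_path)
    events: list[SleepEvent] = []
    hyp: Optional[Hypnogram] = None
    if events_path is not None:
        events_path = Path(events_path)
        if events_path.suffix.lower() == ".xml":
            events, hyp = read_annotations_xml(events_path)
        else:
            events = read_events_csv(events_path)
    if hypnogram_path is not None:
        hyp = read_hypnogram_csv(hypnogram_path)
    return trace, events, hyp
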