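"""Synthetic overnight oximetry recordings and survival cohorts.

The generator emulates the statistical structure the analysis pipeline
assumes about polysomnography: manually scored respiratory events placed by
a renewal process at a target AHI during sleep, each followed (after a
circulatory lag) by a smooth raised-cosine SpO2 dip; a configurable fraction
of events are arousal-associated hypopneas whose desaturation stays below
the 3% detection threshold, so that manual respiratory events outnumber
automatically detectable desaturations (about five-fold at the default
fraction of 0.8, matching what is observed when AASM-scored events are
compared with 3%-threshold automatic detection).  Mortality outcomes are
drawn from an exponential proportional-hazards model whose linear predictor
is tied to the true (generative) desaturation burden.

Raised-cosine dips have closed-form area (depth x half-width), so every
planted event's exact area under its generative baseline is recorded in a
truth log for oracle tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .signal_model import (
    CovariateSet,
    EventKind,
    EventSource,
    Hypnogram,
    SleepEvent,
    SpO2Trace,
)
from .survival import SubjectRecord

__all__ = [
    "SimParams",
    "CohortParams",
    "simulate_recording",
    "simulate_cohort",
    "InfeasiblePackingError",
]


class InfeasiblePackingError(ValueError):
    """Target AHI and event geometry cannot fit in the sleep span."""


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic recording.

    Depths are drawn from a normal truncated to [3, 30]% for desaturating
    events and to [0.5, 2.5]% for arousal-only events; durations from a
    normal truncated at 10 s (the minimum scoreable respiratory event).
    ``desat_lag_s`` is the delay from event end to dip nadir (circulatory
    transit, ~15 s); ``desat_halfwidth_s`` the dip half-width.
    """

    tst_h: float = 7.0
    ahi: float = 18.0
    event_duration_mean_s: float = 25.0
    event_duration_sd_s: float = 8.0
    desat_depth_mean_pct: float = 6.0
    desat_depth_sd_pct: float = 3.0
    desat_lag_s: float = 15.0
    desat_halfwidth_s: float = 30.0
    arousal_only_fraction: float = 0.8
    baseline_sat_pct: float = 96.0
    noise_sd_pct: float = 0.1
    wake_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.tst_h <= 0 or self.ahi < 0:
            raise ValueError("tst_h must be > 0 and ahi >= 0")
        if not (0 <= self.arousal_only_fraction <= 1):
            raise ValueError("arousal_only_fraction must be in [0, 1]")
        if self.desat_depth_sd_pct >= self.desat_depth_mean_pct:
            raise ValueError("depth SD must be below its mean (truncation stability)")
        if self.event_duration_mean_s <= 0 or self.desat_halfwidth_s <= 0:
            raise ValueError("durations must be > 0")


DEPTH_BOUNDS_DESAT = (3.0, 30.0)
DEPTH_BOUNDS_AROUSAL = (0.5, 2.5)
MIN_EVENT_DURATION_S = 10.0
#: Sampled dip half-widths are truncated to this range (s); the inter-event
#: refractory gap of 2 x the upper bound keeps planted dips disjoint.
HALFWIDTH_BOUNDS_S = (10.0, 45.0)


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    """Truncated normal by resampling (bounds are wide; few rejections)."""
    out = rng.normal(mean, sd, size=size)
    scalar = np.isscalar(out)
    out = np.atleast_1d(out)
    for _ in range(200):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    out = np.clip(out, lo, hi)
    return float(out[0]) if scalar else out


def _make_hypnogram(p: SimParams, rng: np.random.Generator) -> Hypnogram:
    epoch = 30.0
    n_sleep = int(round(p.tst_h * 3600.0 / epoch))
    n_wake = int(round(n_sleep * p.wake_fraction / (1 - p.wake_fraction)))
    stages = ["wake"] * n_wake + list(
        rng.choice(["n1", "n2", "n3", "rem"], size=n_sleep, p=[0.05, 0.5, 0.2, 0.25])
    )
    # keep sleep onset after a short wake lead-in, scatter remaining wake
    order = np.arange(len(stages))
    lead = min(2, n_wake)
    tail = order[lead:]
    rng.shuffle(tail)
    order = np.concatenate([order[:lead], tail])
    return Hypnogram(tuple(np.array(stages, dtype=object)[order]), epoch_length_s=epoch)


def simulate_recording(
    p: SimParams,
) -> tuple[SpO2Trace, list[SleepEvent], Hypnogram, list[dict]]:
    """Generate one recording: trace, manual event list, hypnogram, truth log.

    Events are placed on the sleep-time axis by a renewal process whose mean
    inter-onset interval is 3600/AHI s, then mapped through the hypnogram to
    recording time; each event's dip is centred ``desat_lag_s`` after event
    end.  The truth log records, per event, the sampled depth, half-width,
    arousal-only flag and the closed-form dip area (depth x half-width) under
    the generative resting baseline.

    Raises
    ------
    InfeasiblePackingError
        When the mean event footprint exceeds the mean inter-onset interval.
    """
    rng = np.random.default_rng(p.seed)
    hyp = _make_hypnogram(p, rng)
    n_samples = int(hyp.span_s)
    times = np.arange(n_samples, dtype=float)
    epoch_idx = np.clip((times // hyp.epoch_length_s).astype(int), 0, hyp.n_epochs - 1)
    sleep_sample = hyp.sleep_mask()[epoch_idx]
    sleep_times = times[sleep_sample]
    S = float(sleep_times.size)  # seconds of sleep

    min_sep = 2.0 * HALFWIDTH_BOUNDS_S[1]  # refractory gap: dips never overlap
    footprint = p.event_duration_mean_s + min_sep
    events: list[SleepEvent] = []
    truth: list[dict] = []
    if p.ahi > 0:
        mean_onset = 3600.0 / p.ahi
        if footprint >= mean_onset:
            raise InfeasiblePackingError(
                f"mean event footprint {footprint:.0f}s exceeds mean onset interval "
                f"{mean_onset:.0f}s at AHI {p.ahi}"
            )
        mean_gap = mean_onset - footprint
        t = float(rng.exponential(mean_gap))
        while True:
            dur = _trunc_normal(
                rng, p.event_duration_mean_s, p.event_duration_sd_s,
                MIN_EVENT_DURATION_S, 90.0,
            )
            if t + dur + min_sep > S:
                break
            start_rec = float(sleep_times[int(t)])
            end_rec = start_rec + dur
            arousal_only = bool(rng.random() < p.arousal_only_fraction)
            if arousal_only:
                depth = _trunc_normal(rng, 1.5, 0.6, *DEPTH_BOUNDS_AROUSAL)
                kind = EventKind.hypopnea
            else:
                depth = _trunc_normal(
                    rng, p.desat_depth_mean_pct, p.desat_depth_sd_pct, *DEPTH_BOUNDS_DESAT
                )
                kind = EventKind.obstructive_apnea if rng.random() < 0.3 else EventKind.hypopnea
            halfwidth = _trunc_normal(
                rng, p.desat_halfwidth_s, p.desat_halfwidth_s / 6, *HALFWIDTH_BOUNDS_S
            )
            events.append(
                SleepEvent(start_rec, end_rec, kind, EventSource.manual_respiratory)
            )
            truth.append(
                {
                    "start_s": start_rec,
                    "end_s": end_rec,
                    "nadir_s": end_rec + p.desat_lag_s,
                    "depth_pct": float(depth),
                    "halfwidth_s": float(halfwidth),
                    "arousal_only": arousal_only,
                    "area_pct_s": float(depth * halfwidth),
                }
            )
            t += dur + min_sep + float(rng.exponential(mean_gap))

    sig = np.full(n_samples, p.baseline_sat_pct, dtype=float)
    for rec in truth:
        c, w, d = rec["nadir_s"], rec["halfwidth_s"], rec["depth_pct"]
        lo = max(int(math.floor(c - w)), 0)
        hi = min(int(math.ceil(c + w)), n_samples - 1)
        tt = times[lo : hi + 1]
        sig[lo : hi + 1] -= d * 0.5 * (1.0 + np.cos(np.pi * (tt - c) / w)) * (np.abs(tt - c) <= w)
    if p.noise_sd_pct > 0:
        sig = sig + rng.normal(0.0, p.noise_sd_pct, size=n_samples)
    sig = np.clip(sig, 50.0, 100.0)
    trace = SpO2Trace(sig, sample_interval=1.0)
    return trace, events, hyp, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class CohortParams:
    """Generative settings for a survival cohort.

    ``true_log_hr_per_sd`` maps metric labels to their true log hazard ratio
    per cohort SD (a scalar is shorthand for {``target_label``: scalar}).
    Survival times are exponential with rate
    ``baseline_hazard * exp(linear predictor)``; censoring is uniform on
    ``[0, followup_horizon_years]``.
    """

    n_subjects: int = 500
    true_log_hr_per_sd: float | dict = 0.5
    target_label: str = "burden"
    baseline_hazard: float = 0.026  # per year; ~15% deaths over a 12-y horizon
    followup_horizon_years: float = 12.0
    age_effect: float = 0.05  # log-hazard per year of age, centred
    male_effect: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be >= 0")

    @property
    def effects(self) -> dict:
        if isinstance(self.true_log_hr_per_sd, dict):
            return dict(self.true_log_hr_per_sd)
        return {self.target_label: float(self.true_log_hr_per_sd)}


def _draw_covariates(rng: np.random.Generator, n: int) -> dict:
    """Demographics loosely matching a community sleep cohort of older adults."""
    return {
        "age": np.clip(rng.normal(64.0, 10.5, n), 40, 92),
        "male": (rng.random(n) < 0.46).astype(int),
        "caucasian": (rng.random(n) < 0.885).astype(int),
        "smoking": rng.choice(["never", "former", "current"], size=n, p=[0.465, 0.44, 0.095]),
        "alcohol": np.round(rng.gamma(1.2, 2.5, n), 1),  # drinks/week
        "copd": (rng.random(n) < 0.012).astype(int),
        "heart_failure": (rng.random(n) < 0.015).astype(int),
        "stroke": (rng.random(n) < 0.03).astype(int),
        "angina": (rng.random(n) < 0.05).astype(int),
        "revascularization": (rng.random(n) < 0.05).astype(int),
        "myocardial_infarction": (rng.random(n) < 0.05).astype(int),
    }


def _surrogate_burden(rng: np.random.Generator, sp: SimParams, tst_h: float, ahi: float,
                      depth_mean: float) -> tuple[float, float, float]:
    """Closed-form burden draw for one subject, without simulating the trace.

    Sums planted dip areas (depth x half-width, the same closed form the
    recording generator logs) over a Poisson number of events and normalises
    per hour of sleep.  Returns (burden %min/h, fraction desaturating,
    mean depth of desaturating events).
    """
    n_ev = rng.poisson(ahi * tst_h)
    if n_ev == 0:
        return 0.0, 0.0, np.nan
    arousal = rng.random(n_ev) < sp.arousal_only_fraction
    depths = np.empty(n_ev)
    if arousal.any():
        depths[arousal] = _trunc_normal(rng, 1.5, 0.6, *DEPTH_BOUNDS_AROUSAL, size=int(arousal.sum()))
    if (~arousal).any():
        depths[~arousal] = _trunc_normal(
            rng, depth_mean, sp.desat_depth_sd_pct, *DEPTH_BOUNDS_DESAT, size=int((~arousal).sum())
        )
    widths = _trunc_normal(rng, sp.desat_halfwidth_s, sp.desat_halfwidth_s / 6,
                           *HALFWIDTH_BOUNDS_S, size=n_ev)
    total_area = float(np.sum(depths * widths))  # %.s
    burden = (total_area / 60.0) / tst_h  # %min per hour of sleep
    desat_frac = float((~arousal).mean())
    mean_depth = float(depths[~arousal].mean()) if (~arousal).any() else np.nan
    return burden, desat_frac, mean_depth


def simulate_cohort(
    cp: CohortParams,
    sp: SimParams = SimParams(),
    burden_mode: str = "surrogate",
    metric_labels: Optional[Sequence[str]] = None,
    metric_noise_sd: float = 0.0,
) -> tuple[list[SubjectRecord], dict]:
    """Simulate a cohort of subjects with burden-linked CVD mortality.

    ``burden_mode='surrogate'`` (default) draws each subject's burden from
    the closed-form planted-area model — flagged in the returned truth dict —
    while ``'full'`` simulates every recording and reads the burden off the
    hypoxic-burden pipeline (slow; intended for small n).  Metric columns
    listed in ``metric_labels`` are populated as the burden plus independent
    Gaussian noise of SD ``metric_noise_sd`` (in cohort-SD units), so
    spike-in designs can dilute off-target columns; hazards follow
    ``cp.effects`` applied to the z-scores of the named columns.

    Returns ``(records, truth)`` where truth holds the generative settings
    and per-subject latent values.
    """
    rng = np.random.default_rng(cp.seed)
    n = cp.n_subjects
    cov = _draw_covariates(rng, n)
    tst = np.clip(rng.normal(6.4, 0.9, n), 4.0, 9.0)
    ahi = np.clip(np.exp(rng.normal(np.log(15.0), 0.55, n)), 4.0, 30.0)
    depth_mean = np.clip(rng.normal(sp.desat_depth_mean_pct, 1.2, n), 3.5, 15.0)

    burdens = np.empty(n)
    minsat = np.empty(n)
    t90 = np.empty(n)
    if burden_mode == "surrogate":
        for i in range(n):
            b, _, md = _surrogate_burden(rng, sp, tst[i], ahi[i], depth_mean[i])
            burdens[i] = b
            base = sp.baseline_sat_pct
            minsat[i] = base - (md if np.isfinite(md) else 1.0) - rng.normal(0, 0.5)
            t90[i] = float(np.clip(0.15 * b + rng.gamma(1.0, 1.0), 0, 60))
    elif burden_mode == "full":
        from .areas import compute_method_matrix  # deferred: heavy path
        from .detection import detect_desaturations
        from .signal_model import clean_trace, compute_minsat, compute_t90
        from .windows import BaselineFamily, WindowFamily

        for i in range(n):
            sp_i = replace(
                sp,
                tst_h=float(tst[i]),
                ahi=float(ahi[i]),
                desat_depth_mean_pct=float(depth_mean[i]),
                seed=int(rng.integers(2**31 - 1)),
            )
            trace, man_ev, hyp, _ = simulate_recording(sp_i)
            trace = clean_trace(trace)
            auto_ev = detect_desaturations(trace)
            matrix = compute_method_matrix(trace, man_ev, auto_ev, hyp)
            hb = next(
                m
                for m in matrix
                if m.combo.source == EventSource.manual_respiratory
                and m.combo.window == WindowFamily.record_specific
                and m.combo.baseline == BaselineFamily.event_specific
            )
            burdens[i] = hb.value
            minsat[i] = compute_minsat(trace, man_ev) or np.nan
            t90[i] = compute_t90(trace, hyp)
    else:
        raise ValueError(f"unknown burden_mode {burden_mode!r}")

    sd = burdens.std()
    if sd == 0:
        raise ValueError("zero-variance burden across cohort")

    labels = list(metric_labels) if metric_labels is not None else [cp.target_label]
    z_burden = (burdens - burdens.mean()) / sd
    metric_cols: dict[str, np.ndarray] = {}
    for lab in labels:
        col = z_burden.copy()
        if metric_noise_sd > 0:
            col = col + rng.normal(0.0, metric_noise_sd, n)
        # report on a burden-like scale rather than as a z-score
        metric_cols[lab] = burdens.mean() + col * sd

    lp = cp.age_effect * (cov["age"] - 64.0) + cp.male_effect * cov["male"]
    for lab, beta in cp.effects.items():
        if lab not in metric_cols:
            raise KeyError(f"effect on unknown metric {lab!r}")
        col = metric_cols[lab]
        lp = lp + beta * (col - col.mean()) / col.std()
    rate = cp.baseline_hazard * np.exp(lp)
    with np.errstate(divide="ignore"):
        t_death = np.where(rate > 0, rng.exponential(1.0, n) / np.maximum(rate, 1e-300), np.inf)
    censor = rng.uniform(0.0, cp.followup_horizon_years, n)
    followup = np.minimum(t_death, censor)
    death = (t_death <= censor).astype(int)
    followup = np.maximum(followup, 1e-4)  # strictly positive follow-up

    records = []
    for i in range(n):
        covariates = {
            "tst_h": float(tst[i]),
            "ahi": float(ahi[i]),
            "t90_pct": float(t90[i]),
            "minsat_pct": float(minsat[i]),
            "age": float(cov["age"][i]),
            "male": int(cov["male"][i]),
            "caucasian": int(cov["caucasian"][i]),
            "smoking": str(cov["smoking"][i]),
            "alcohol": float(cov["alcohol"][i]),
            "copd": int(cov["copd"][i]),
            "heart_failure": int(cov["heart_failure"][i]),
            "stroke": int(cov["stroke"][i]),
            "angina": int(cov["angina"][i]),
            "revascularization": int(cov["revascularization"][i]),
            "myocardial_infarction": int(cov["myocardial_infarction"][i]),
        }
        records.append(
            SubjectRecord(
                subject_id=f"S{i:05d}",
                metrics={lab: float(metric_cols[lab][i]) for lab in labels},
                covariates=covariates,
                followup_years=float(followup[i]),
                cvd_death=int(death[i]),
            )
        )
    truth = {
        "burden_mode": burden_mode,
        "surrogate_flagged": burden_mode == "surrogate",
        "effects": cp.effects,
        "burden": burdens,
        "event_rate": float(death.mean()),
    }
    return records, truth
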