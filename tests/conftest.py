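"""Shared fixtures: programmatic trace builders (no on-disk data)."""

from __future__ import annotations

import numpy as np
import pytest

from desatarea.signal_model import SpO2Trace


def make_trace(values, dt=1.0, offset=0.0, valid=None) -> SpO2Trace:
    return SpO2Trace(np.asarray(values, dtype=float), dt, offset, valid)


def flat_trace(level=95.0, n=600, dt=1.0) -> SpO2Trace:
    return make_trace(np.full(n, level), dt=dt)


def vdip_trace(level=96.0, depth=4.0, center=300, halfwidth=30, n=600) -> SpO2Trace:
    """Piecewise-linear V dip of given depth and half-width on a flat trace."""
    t = np.arange(n, dtype=float)
    dip = np.clip(1.0 - np.abs(t - center) / halfwidth, 0.0, None) * depth
    return make_trace(level - dip)


def cosdip_trace(level=96.0, depth=5.0, center=300.0, halfwidth=40.0, n=600) -> SpO2Trace:
    """Raised-cosine dip; closed-form area under the resting level = depth*halfwidth."""
    t = np.arange(n, dtype=float)
    inside = np.abs(t - center) <= halfwidth
    dip = np.where(inside, depth * 0.5 * (1 + np.cos(np.pi * (t - center) / halfwidth)), 0.0)
    return make_trace(level - dip)


def random_smooth_trace(rng: np.random.Generator, n=1000, level=96.0) -> SpO2Trace:
    """Smooth random saturation trace: a few random raised-cosine dips + slow drift."""
    t = np.arange(n, dtype=float)
    sig = np.full(n, level) + 0.5 * np.sin(2 * np.pi * t / rng.uniform(300, 900))
    for _ in range(rng.integers(1, 6)):
        c = rng.uniform(50, n - 50)
        w = rng.uniform(15, 80)
        d = rng.uniform(1.0, 10.0)
        inside = np.abs(t - c) <= w
        sig = sig - np.where(inside, d * 0.5 * (1 + np.cos(np.pi * (t - c) / w)), 0.0)
    return make_trace(np.clip(sig, 51, 100))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
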