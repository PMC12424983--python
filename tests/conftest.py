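"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from isletca import synthetic as syn


def planted_train(rng: np.random.Generator, lo_s=2.0, hi_s=6.0, spacing_factor=3.5,
                  t_start=20.0, t_end=580.0, amplitude=8.0):
    """Events with uniform FWHM in [lo, hi] and IEI = spacing_factor x FWHM."""
    events = []
    t = t_start
    while True:
        w = rng.uniform(lo_s, hi_s)
        t += spacing_factor * w
        if t > t_end:
            break
        events.append((t, w, amplitude))
    return events


@pytest.fixture
def benchmark_trace():
    """A 600 s / 20 Hz trace with a planted event train and mild bleaching."""
    rng = np.random.default_rng(7)
    events = planted_train(rng)
    trace = syn.make_trace(events, 600, 20, noise_sd=1.0, rng=rng, bleach_tau_s=900)
    return trace, events
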