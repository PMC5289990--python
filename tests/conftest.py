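"""Shared builders and fixtures for the blink-extraction test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ocublink import CandidateSignal, FilteredSignal, SignalKind
from ocublink.synth import SynthSpec, generate


def triangle_trace(
    n: int,
    srate: float,
    apex_frame: int,
    rise_s: float,
    fall_s: float,
    amplitude: float,
    baseline: float = 0.0,
) -> np.ndarray:
    """A single piecewise-linear tent on a flat baseline."""
    t = np.arange(n) / srate
    apex_t = apex_frame / srate
    up = (t - (apex_t - rise_s)) / rise_s
    down = ((apex_t + fall_s) - t) / fall_s
    return baseline + amplitude * np.clip(np.minimum(up, down), 0.0, 1.0)


def filtered_from(samples: np.ndarray, srate: float = 256.0, label: str = "t") -> FilteredSignal:
    """Wrap a constructed trace as an already-filtered signal.

    Landmark and index operations are defined on the band-passed trace;
    constructing that trace directly keeps unit tests exact.
    """
    return FilteredSignal(samples=np.asarray(samples, dtype=float), srate=srate, label=label)


def candidate_from(samples: np.ndarray, srate: float = 256.0, label: str = "t") -> CandidateSignal:
    return CandidateSignal(label=label, kind=SignalKind.EOG, samples=samples, srate=srate)


@pytest.fixture(scope="session")
def default_synth():
    """One 5-minute synthetic recording at the default study conditions."""
    spec = SynthSpec(durationS=300.0, seed=20)
    sig, events = generate(spec)
    return spec, sig, events


@pytest.fixture(scope="session")
def default_evaluation(default_synth):
    """The default recording pushed through per-signal evaluation once."""
    from ocublink import evaluate_signal

    _, sig, events = default_synth
    return evaluate_signal(sig), events
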