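"""Band-pass filtering and potential-blink detection.

Blink excursions are large, slow, positive deflections.  Each candidate
signal is band-pass filtered to [1, 20] Hz and intervals where the
filtered trace exceeds the overall mean by 1.5 standard deviations become
*potential blinks*, subject to a minimum duration (> 50 ms) and a minimum
separation (>= 50 ms) between consecutive candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import CandidateSignal


@dataclass
class FilteredSignal:
    """A band-passed candidate signal (same length and srate as its source)."""

    samples: np.ndarray
    srate: float
    band: tuple[float, float] = (1.0, 20.0)
    label: str = ""

    @property
    def n_frames(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class PotentialBlink:
    """A contiguous above-threshold run, frame indices inclusive."""

    startFrame: int
    endFrame: int

    def __post_init__(self) -> None:
        if self.endFrame < self.startFrame:
            raise ValueError("endFrame must be >= startFrame")

    def duration_s(self, srate: float) -> float:
        return (self.endFrame - self.startFrame + 1) / srate


def design_bandpass_fir(srate: float, low: float = 1.0, high: float = 20.0) -> np.ndarray:
    """Design the Hamming-windowed linear-phase band-pass FIR taps.

    The order scales as ``3 * srate / low`` so the normalized transition
    width (and hence stopband behaviour one octave outside the band) is
    independent of the sampling rate.  Taps are odd in number, so applying
    the filter symmetrically is exactly zero-phase.
    """
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= srate / 2:
        raise ValueError(f"high edge {high} Hz must be below Nyquist ({srate / 2} Hz)")
    numtaps = int(round(3 * srate / low))
    if numtaps % 2 == 0:
        numtaps += 1
    numtaps = max(numtaps, 9)
    return sps.firwin(numtaps, [low, high], pass_zero=False, window="hamming", fs=srate)


def bandpass(
    signal: CandidateSignal, low: float = 1.0, high: float = 20.0
) -> FilteredSignal:
    """Zero-phase band-pass of a candidate signal.

    The symmetric FIR is applied by convolution with reflection padding, so
    there is no group delay anywhere and edge transients are moderate.
    Passband gain is within ±5% of unity; attenuation one octave outside
    the band exceeds 20 dB.
    """
    taps = design_bandpass_fir(signal.srate, low, high)
    x = signal.samples
    half = len(taps) // 2
    pad = min(half, x.size - 1)
    xp = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
    y = sps.fftconvolve(xp, taps, mode="same")[pad : pad + x.size]
    return FilteredSignal(samples=y, srate=signal.srate, band=(low, high), label=signal.label)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as inclusive (start, end)."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size - 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def find_potential_blinks(
    filtered: FilteredSignal,
    k_sd: float = 1.5,
    min_dur_s: float = 0.050,
    min_sep_s: float = 0.050,
    separation_mode: str = "merge",
) -> list[PotentialBlink]:
    """Extract potential blinks by threshold crossing.

    The threshold is ``mean + k_sd * std`` of the filtered trace over all
    frames, which makes detection invariant to amplitude scaling and
    baseline shifts.  Runs separated by less than ``min_sep_s`` are merged
    into one (``separation_mode="merge"``, default) or all dropped
    (``"drop"``); runs whose duration does not exceed ``min_dur_s`` are
    then discarded.  A constant signal yields no potential blinks.
    """
    if separation_mode not in ("merge", "drop"):
        raise ValueError("separation_mode must be 'merge' or 'drop'")
    x = filtered.samples
    if x.size < 2:
        raise ValueError("filtered signal must have at least 2 frames")
    sd = float(np.std(x))
    if sd == 0.0:
        return []
    threshold = float(np.mean(x)) + k_sd * sd
    runs = _runs_above(x > threshold)
    srate = filtered.srate

    if separation_mode == "merge":
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and (s - merged[-1][1] - 1) / srate < min_sep_s:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        runs = [(s, e) for s, e in merged]
    else:  # drop every run involved in a too-close pair
        bad = set()
        for i in range(len(runs) - 1):
            if (runs[i + 1][0] - runs[i][1] - 1) / srate < min_sep_s:
                bad.update((i, i + 1))
        runs = [r for i, r in enumerate(runs) if i not in bad]

    return [
        PotentialBlink(s, e)
        for s, e in runs
        if (e - s + 1) / srate > min_dur_s
    ]
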