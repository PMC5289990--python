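"""Per-blink landmark anatomy and the tent fit.

For each potential blink the module locates, on the band-passed trace:

* ``maxFrame`` / ``maxValue`` — the blink peak (first frame on ties);
* ``leftZero`` / ``rightZero`` — the zero crossings flanking the peak,
  falling back to the amplitude minimum between neighbouring blinks when
  the trace never returns to zero;
* ``leftBase`` / ``rightBase`` — the first local minima outward of the
  maximum-velocity frames of the up- and down-strokes;
* a linear *tent fit* to the inner 80% (by amplitude) of each stroke,
  with its R² quality, the tent peak (line intersection) and the x-axis
  intercepts used for the tent duration.

Stereotypical blinks have a rounded tent shape, so the tent circumscribes
the trajectory: the tent peak sits slightly above and forward of the true
peak, and stroke R² values near 1 indicate a prototypical blink.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detect import FilteredSignal, PotentialBlink


@dataclass
class BlinkLandmarks:
    """All fitted per-blink anatomy (frame indices into the filtered trace)."""

    startFrame: int
    endFrame: int
    maxFrame: int
    maxValue: float
    leftZero: int
    rightZero: int
    leftBase: int
    rightBase: int
    maxPosVelFrame: int
    maxNegVelFrame: int
    leftFit: tuple[float, float] = (np.nan, np.nan)  # slope µV/frame, intercept µV
    rightFit: tuple[float, float] = (np.nan, np.nan)
    leftR2: float = 0.0
    rightR2: float = 0.0
    tentPeakFrame: float = np.nan
    tentPeakValue: float = np.nan
    tentLeftXIntercept: float = np.nan
    tentRightXIntercept: float = np.nan
    fittable: bool = False


def locate_max(filtered: FilteredSignal, blink: PotentialBlink) -> tuple[int, float]:
    """Peak of the blink interval; ties resolve to the smallest frame."""
    x = filtered.samples
    if blink.startFrame < 0 or blink.endFrame >= x.size:
        raise ValueError("blink interval outside signal")
    seg = x[blink.startFrame : blink.endFrame + 1]
    i = int(np.argmax(seg))  # argmax returns the first maximal index
    return blink.startFrame + i, float(seg[i])


def find_zeros(
    filtered: FilteredSignal,
    maxFrame: int,
    left_limit: int = 0,
    right_limit: int | None = None,
) -> tuple[int, int]:
    """Zero crossings flanking the peak, at frame resolution.

    ``leftZero`` is the last non-positive frame before ``maxFrame`` within
    ``[left_limit, maxFrame)`` — the previous blink's rightZero bounds the
    search (signal start for the first blink).  If the trace never touches
    zero there, the fall-back is the frame of lowest amplitude in the
    region.  ``rightZero`` is symmetric, bounded by ``right_limit``
    (exclusive; signal end for the last blink).
    """
    x = filtered.samples
    n = x.size
    if right_limit is None:
        right_limit = n
    lo = max(0, left_limit)
    hi = min(n, right_limit)

    left_region = np.arange(lo, maxFrame)
    if left_region.size == 0:
        leftZero = maxFrame
    else:
        nonpos = left_region[x[left_region] <= 0]
        if nonpos.size:
            leftZero = int(nonpos[-1])
        else:
            leftZero = int(left_region[np.argmin(x[left_region])])

    right_region = np.arange(maxFrame + 1, hi)
    if right_region.size == 0:
        rightZero = maxFrame
    else:
        nonpos = right_region[x[right_region] <= 0]
        if nonpos.size:
            rightZero = int(nonpos[0])
        else:
            rightZero = int(right_region[np.argmin(x[right_region])])
    return leftZero, rightZero


def velocity(filtered: FilteredSignal) -> np.ndarray:
    """Forward first difference scaled to µV/s; element i spans frames i..i+1."""
    return np.diff(filtered.samples) * filtered.srate


def _first_local_min_leftward(x: np.ndarray, start: int, floor: int) -> int | None:
    """First strict local minimum scanning left from ``start`` down to ``floor``."""
    for f in range(start, floor, -1):
        if 0 < f < x.size - 1 and x[f] < x[f - 1] and x[f] < x[f + 1]:
            return f
    return None


def _first_local_min_rightward(x: np.ndarray, start: int, ceil: int) -> int | None:
    for f in range(start, ceil):
        if 0 < f < x.size - 1 and x[f] < x[f - 1] and x[f] < x[f + 1]:
            return f
    return None


def find_bases(
    filtered: FilteredSignal,
    maxFrame: int,
    leftZero: int,
    rightZero: int,
    left_limit: int = 0,
    right_limit: int | None = None,
) -> tuple[int, int, int, int]:
    """Blink bases and maximum-velocity frames.

    The up-stroke's maximum-velocity frame is the argmax of velocity on
    ``[leftZero, maxFrame)``; the left base is the first strict local
    minimum of the trace scanning left from there (fall-back: leftZero).
    The scan is bounded by the inter-blink search region (``left_limit``,
    normally the previous blink's rightZero), not by leftZero itself: a
    pre-blink dip below zero legitimately places the base before the zero
    crossing.  Plateaus (equal neighbours) are traversed, which keeps the
    scan deterministic on quantized data.  The down-stroke side is
    symmetric.
    """
    if not (leftZero < maxFrame < rightZero):
        raise ValueError("need leftZero < maxFrame < rightZero")
    x = filtered.samples
    if right_limit is None:
        right_limit = x.size
    v = velocity(filtered)
    up = np.arange(leftZero, maxFrame)
    down = np.arange(maxFrame, rightZero)
    maxPosVelFrame = int(up[np.argmax(v[up])])
    maxNegVelFrame = int(down[np.argmin(v[down])])
    lb = _first_local_min_leftward(x, maxPosVelFrame, max(left_limit, 0))
    rb = _first_local_min_rightward(x, maxNegVelFrame + 1, min(right_limit, x.size))
    leftBase = lb if lb is not None else leftZero
    rightBase = rb if rb is not None else rightZero
    return leftBase, rightBase, maxPosVelFrame, maxNegVelFrame


def _stroke_fit(
    x: np.ndarray, frames: np.ndarray, maxValue: float, inner_mode: str
) -> tuple[tuple[float, float], float, np.ndarray]:
    """OLS line over the inner-80% window of one stroke.

    Returns ``((slope, intercept), r2, fit_frames)``; fewer than 3 usable
    frames mean the stroke is unfittable (r2 = 0).
    """
    y = x[frames]
    if inner_mode == "amplitude":
        lo = float(np.min(y))
        rise = maxValue - lo
        if rise <= 0:
            return (np.nan, np.nan), 0.0, frames[:0]
        keep = (y >= lo + 0.1 * rise) & (y <= lo + 0.9 * rise)
        sel = frames[keep]
    elif inner_mode == "frame":
        k = frames.size
        cut = int(np.floor(0.1 * k))
        sel = frames[cut : k - cut]
    else:
        raise ValueError("inner_mode must be 'amplitude' or 'frame'")
    if sel.size < 3:
        return (np.nan, np.nan), 0.0, sel
    res = stats.linregress(sel.astype(float), x[sel])
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return (float(res.slope), float(res.intercept)), min(r2, 1.0), sel


def fit_tent(
    filtered: FilteredSignal,
    maxFrame: int,
    maxValue: float,
    leftZero: int,
    rightZero: int,
    inner_mode: str = "amplitude",
) -> dict:
    """Linear fits to the inner 80% of the up- and down-strokes.

    The inner window keeps stroke frames whose amplitude lies between 10%
    and 90% of the stroke's rise above its own minimum (``inner_mode=
    "amplitude"``, default) or the middle 80% of the stroke's frames
    (``"frame"``).  R² is the squared Pearson correlation of the line with
    the data.  The tent peak is the intersection of the two lines; the
    x-intercepts are where each line crosses zero amplitude.
    """
    x = filtered.samples
    up = np.arange(leftZero, maxFrame + 1)
    down = np.arange(maxFrame, rightZero + 1)
    leftFit, leftR2, lsel = _stroke_fit(x, up, maxValue, inner_mode)
    rightFit, rightR2, rsel = _stroke_fit(x, down, maxValue, inner_mode)
    fittable = lsel.size >= 3 and rsel.size >= 3 and np.isfinite(leftFit[0]) and np.isfinite(rightFit[0])
    out = {
        "leftFit": leftFit,
        "rightFit": rightFit,
        "leftR2": leftR2 if fittable else 0.0,
        "rightR2": rightR2 if fittable else 0.0,
        "tentPeakFrame": np.nan,
        "tentPeakValue": np.nan,
        "tentLeftXIntercept": np.nan,
        "tentRightXIntercept": np.nan,
        "fittable": fittable,
    }
    if fittable:
        (a1, b1), (a2, b2) = leftFit, rightFit
        if a1 != a2:
            xf = (b2 - b1) / (a1 - a2)
            out["tentPeakFrame"] = xf
            out["tentPeakValue"] = a1 * xf + b1
        if a1 != 0:
            out["tentLeftXIntercept"] = -b1 / a1
        if a2 != 0:
            out["tentRightXIntercept"] = -b2 / a2
    return out


def compute_landmarks(
    filtered: FilteredSignal,
    blinks: list[PotentialBlink],
    inner_mode: str = "amplitude",
) -> list[BlinkLandmarks]:
    """Landmark every potential blink of one signal, left to right.

    The left zero-crossing search of each blink is bounded by the previous
    blink's rightZero; the right search by the next blink's startFrame.
    """
    out: list[BlinkLandmarks] = []
    prev_right_zero = 0
    for i, blink in enumerate(blinks):
        maxFrame, maxValue = locate_max(filtered, blink)
        right_limit = blinks[i + 1].startFrame if i + 1 < len(blinks) else None
        leftZero, rightZero = find_zeros(filtered, maxFrame, prev_right_zero, right_limit)
        if leftZero < maxFrame < rightZero:
            leftBase, rightBase, mpv, mnv = find_bases(
                filtered, maxFrame, leftZero, rightZero, prev_right_zero, right_limit
            )
            tent = fit_tent(filtered, maxFrame, maxValue, leftZero, rightZero, inner_mode)
        else:
            # degenerate candidate hugging a signal edge: keep the record,
            # mark it unfittable
            leftBase, rightBase = leftZero, rightZero
            mpv, mnv = maxFrame, maxFrame
            tent = {
                "leftFit": (np.nan, np.nan), "rightFit": (np.nan, np.nan),
                "leftR2": 0.0, "rightR2": 0.0, "tentPeakFrame": np.nan,
                "tentPeakValue": np.nan, "tentLeftXIntercept": np.nan,
                "tentRightXIntercept": np.nan, "fittable": False,
            }
        out.append(
            BlinkLandmarks(
                startFrame=blink.startFrame,
                endFrame=blink.endFrame,
                maxFrame=maxFrame,
                maxValue=maxValue,
                leftZero=leftZero,
                rightZero=rightZero,
                leftBase=leftBase,
                rightBase=rightBase,
                maxPosVelFrame=mpv,
                maxNegVelFrame=mnv,
                **tent,
            )
        )
        prev_right_zero = rightZero
    return out
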