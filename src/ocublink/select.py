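"""Signal-quality gating, blink/saccade discrimination, and signal selection.

A candidate signal is worth keeping only if its blinks stand out from the
background (blink-amplitude ratio gate), its blinks look like blinks
(stroke-R² tiers and the maximum-amplitude distribution criterion), and
its rapid events are not saccades (pAVR criterion).  Among surviving
candidates the signal with the most good blinks is selected, with a
*marginal* designation when no signal reaches a 70% good-blink ratio.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .detect import FilteredSignal
from .landmarks import BlinkLandmarks

#: scale factor turning the MAD into a consistent estimate of a normal SD
MAD_TO_SD = 1.4826


class SignalStatus(str, enum.Enum):
    SELECTED = "selected"
    USABLE = "usable"
    MARGINAL = "marginal"
    REJECTED = "rejected"


class Tier(str, enum.Enum):
    """Blink quality tier by stroke fit: tiers nest (best ⊂ better ⊂ good)."""

    BEST = "best"
    BETTER = "better"
    GOOD = "good"
    NONE = "none"


@dataclass
class SignalEvaluation:
    """Per-signal quality summary used by best-signal selection."""

    label: str
    bar: float | None = None
    nPotential: int = 0
    nGood: int = 0
    nBetter: int = 0
    nBest: int = 0
    nUsed: int = 0
    bestMedian: float = np.nan
    bestRobustStd: float = np.nan
    goodRatio: float = np.nan
    status: SignalStatus = SignalStatus.REJECTED
    reject_reason: str | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["status"] = self.status.value
        return d


def robust_std(values) -> float:
    """Robust standard deviation: 1.4826 × median absolute deviation.

    The scale factor makes the MAD a consistent estimator of the standard
    deviation under normality, so outliers can be flagged in familiar
    SD units without being dragged by the outliers themselves.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("robust_std of an empty sample")
    med = np.median(x)
    return MAD_TO_SD * float(np.median(np.abs(x - med)))


def compute_bar(
    filtered: FilteredSignal,
    landmarks: list[BlinkLandmarks],
    pooling: str = "pooled",
) -> float | None:
    """Blink-amplitude ratio: in-blink mean over positive out-of-blink mean.

    The numerator pools every sample between each blink's leftZero and
    rightZero (inclusive); the denominator pools the strictly positive
    samples of the complementary regions (previous rightZero to next
    leftZero, signal ends at the extremes).  Returns ``None`` when no
    positive sample exists outside the blinks (BAR undefined → signal
    rejected).  ``pooling="per_blink"`` averages per-blink region means
    instead of pooling samples.
    """
    if not landmarks:
        raise ValueError("BAR requires at least one landmarked blink")
    if pooling not in ("pooled", "per_blink"):
        raise ValueError("pooling must be 'pooled' or 'per_blink'")
    x = filtered.samples
    n = x.size
    inside_mask = np.zeros(n, dtype=bool)
    for lm in landmarks:
        inside_mask[lm.leftZero : lm.rightZero + 1] = True
    outside = x[~inside_mask]
    pos_outside = outside[outside > 0]
    if pos_outside.size == 0:
        return None
    if pooling == "pooled":
        num = float(np.mean(x[inside_mask]))
        den = float(np.mean(pos_outside))
    else:
        num = float(np.mean([np.mean(x[lm.leftZero : lm.rightZero + 1]) for lm in landmarks]))
        den = float(np.mean(pos_outside))
    return num / den


def gate_bar(bar: float | None, bar_range: tuple[float, float] = (3.0, 50.0)) -> bool:
    """BAR gate, inclusive at both ends; undefined BAR fails."""
    if bar is None:
        return False
    lo, hi = bar_range
    return lo <= bar <= hi


def blink_tier(
    lm: BlinkLandmarks,
    r2_good: float = 0.90,
    r2_better: float = 0.95,
    r2_best: float = 0.98,
) -> Tier:
    """Tier one blink by the weaker of its two stroke fits (conjunctive)."""
    r2 = min(lm.leftR2, lm.rightR2)
    if not lm.fittable:
        return Tier.NONE
    if r2 >= r2_best:
        return Tier.BEST
    if r2 >= r2_better:
        return Tier.BETTER
    if r2 >= r2_good:
        return Tier.GOOD
    return Tier.NONE


def tier_blinks(landmarks: list[BlinkLandmarks], **thresholds) -> list[Tier]:
    return [blink_tier(lm, **thresholds) for lm in landmarks]


def best_blink_stats(
    landmarks: list[BlinkLandmarks], tiers: list[Tier]
) -> tuple[float, float]:
    """Median and robust SD of the best-tier blinks' maximum amplitudes.

    Raises when no best-tier blink exists — the amplitude-distribution
    criterion is then undefined and the signal is unusable for selection.
    """
    amps = [lm.maxValue for lm, t in zip(landmarks, tiers) if t is Tier.BEST]
    if not amps:
        raise ValueError("no best-tier blinks: amplitude criterion undefined")
    return float(np.median(amps)), robust_std(amps)


def amplitude_criterion(
    landmarks: list[BlinkLandmarks],
    tiers: list[Tier],
    bestMedian: float,
    bestRobustStd: float,
    z_best: float = 5.0,
    z_good: float = 2.0,
) -> list[bool]:
    """Maximum-amplitude distribution criterion (bell around the best median).

    Best-tier blinks are kept within ``z_best`` robust SDs of the best
    median, good/better-tier blinks within ``z_good``; non-tiered blinks
    are never kept.  Bounds are inclusive.
    """
    keep = []
    for lm, t in zip(landmarks, tiers):
        dev = abs(lm.maxValue - bestMedian)
        if t is Tier.BEST:
            keep.append(dev <= z_best * bestRobustStd)
        elif t in (Tier.BETTER, Tier.GOOD):
            keep.append(dev <= z_good * bestRobustStd)
        else:
            keep.append(False)
    return keep


def pavr_criterion(pavrs, pavr_min: float = 3.0) -> list[bool]:
    """Saccade rejection: a candidate with pAVR ≤ ``pavr_min`` centiseconds
    has the sharp rising edge of a saccade, not the rounded rise of a
    blink, and is excluded.  Undefined (NaN) pAVR also excludes."""
    out = []
    for p in pavrs:
        out.append(bool(np.isfinite(p) and p > pavr_min))
    return out


def good_blink_ratio(
    landmarks: list[BlinkLandmarks],
    bestMedian: float,
    bestRobustStd: float,
    tiers: list[Tier] | None = None,
    z_good: float = 2.0,
    numerator: str = "within_band",
) -> float:
    """Fraction of potential blinks in the best-median amplitude band.

    Default numerator counts every potential blink whose peak amplitude
    lies within ``bestMedian ± z_good·bestRobustStd``; the alternative
    (``numerator="good_tier"``) additionally requires the good tier.
    Denominator: all potential blinks of the signal.
    """
    if not landmarks:
        return 0.0
    lo, hi = bestMedian - z_good * bestRobustStd, bestMedian + z_good * bestRobustStd
    count = 0
    for i, lm in enumerate(landmarks):
        in_band = lo <= lm.maxValue <= hi
        if numerator == "good_tier":
            in_band = in_band and tiers is not None and tiers[i] is not Tier.NONE
        count += in_band
    return count / len(landmarks)


def select_best_signal(
    evaluations: list[SignalEvaluation], good_ratio_min: float = 0.70
) -> tuple[str | None, list[SignalEvaluation]]:
    """Choose the signal to report blinks from.

    Among non-rejected candidates with ``goodRatio >= good_ratio_min`` the
    one with the most good blinks wins (ties: larger goodRatio, then input
    order).  If none qualifies, the candidate with the most good blinks is
    selected but designated *marginal*.  With no candidates at all the
    selection fails (``None``); failure is a status, not an exception.
    """
    candidates = [ev for ev in evaluations if ev.status is not SignalStatus.REJECTED]
    if not candidates:
        return None, evaluations
    qualifying = [ev for ev in candidates if ev.goodRatio >= good_ratio_min]
    pool, marginal = (qualifying, False) if qualifying else (candidates, True)
    order = {id(ev): i for i, ev in enumerate(evaluations)}
    winner = max(pool, key=lambda ev: (ev.nGood, ev.goodRatio, -order[id(ev)]))
    for ev in candidates:
        ev.status = SignalStatus.USABLE
    winner.status = SignalStatus.MARGINAL if marginal else SignalStatus.SELECTED
    return winner.label, evaluations


# ---------------------------------------------------------------------------
# IC scalp-map figure of merit
# ---------------------------------------------------------------------------

def ic_figure_of_merit(scalp_map: np.ndarray) -> tuple[float, np.ndarray]:
    """Frontality figure of merit of an interpolated IC scalp map.

    Eye-blink ICs project frontally and laterally symmetrically, so a
    useful score is the difference between the mean weights of the frontal
    and rear hemispheres of the (64×64, rows front→rear) interpolated
    map, cells outside the head disk (NaN) ignored.  Maps whose rear mean
    dominates are sign-flipped first (reorientation), so the returned
    figure of merit is always ≥ 0.
    """
    m = np.asarray(scalp_map, dtype=float)
    if m.ndim != 2:
        raise ValueError("scalp map must be 2-D")
    rows, cols = m.shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols]
    disk = ((yy - cy) / (rows / 2.0)) ** 2 + ((xx - cx) / (cols / 2.0)) ** 2 <= 1.0
    valid = disk & np.isfinite(m)
    front = valid & (yy < rows / 2.0)
    rear = valid & (yy >= rows / 2.0)
    if not front.any() or not rear.any():
        raise ValueError("scalp map has no valid cells in one hemisphere")
    fom = float(np.mean(m[front]) - np.mean(m[rear]))
    if fom < 0:
        m = -m
        fom = -fom
    return fom, m


# ---------------------------------------------------------------------------
# Cross-signal blink grouping
# ---------------------------------------------------------------------------

@dataclass
class BlinkGroup:
    """One cross-signal blink event: seed interval plus member blinks."""

    startFrame: int
    endFrame: int
    members: list[tuple[str, int]] = field(default_factory=list)  # (label, blink idx)

    @property
    def count(self) -> int:
        return len({label for label, _ in self.members})


def group_blinks(
    per_signal: dict[str, tuple[FilteredSignal, list[BlinkLandmarks], list[bool]]],
    k_sd: float = 1.5,
) -> list[BlinkGroup]:
    """Merge blinks detected on different usable signals into groups.

    Seed intervals are the maximal runs where *any* usable signal rises
    above ``k_sd`` robust SDs above zero (robust SD computed per signal
    over all frames of its band-passed trace).  A signal's used blink
    joins a group when its [leftZero, rightZero] span overlaps the seed
    interval; each group records how many signals contributed.
    """
    if not per_signal:
        raise ValueError("no usable signals to group")
    n = next(iter(per_signal.values()))[0].n_frames
    above = np.zeros(n, dtype=bool)
    for filtered, _, _ in per_signal.values():
        thr = k_sd * robust_std(filtered.samples)
        above |= filtered.samples > thr
    from .detect import _runs_above

    groups = [BlinkGroup(s, e) for s, e in _runs_above(above)]
    for label, (_, lms, used) in per_signal.items():
        for i, (lm, u) in enumerate(zip(lms, used)):
            if not u:
                continue
            for g in groups:
                if lm.leftZero <= g.endFrame and lm.rightZero >= g.startFrame:
                    g.members.append((label, i))
                    break
    return [g for g in groups if g.members]
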