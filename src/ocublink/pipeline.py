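"""Full-pipeline orchestration: detect → landmarks → select → indices.

``run_dataset`` evaluates every candidate signal of a dataset (or a
user-restricted subset), gates and scores them, selects the best signal,
and reports the dataset-level ocular indices from its used blinks.
``run_collection`` batches datasets and tabulates one row per dataset.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect, indices, landmarks as lmod, select as smod
from .io import (
    BLINK_TABLE_COLUMNS,
    CandidateSignal,
    Dataset,
    frame_to_seconds,
    write_blink_table,
    write_summary_json,
)

log = logging.getLogger("ocublink")


@dataclass
class RunConfig:
    """All pipeline tunables, with the standard defaults.

    Defaults: band [1, 20] Hz, detection threshold 1.5 SD, 50 ms minimum
    blink duration and separation, BAR gate [3, 50], R² tiers
    0.90/0.95/0.98, amplitude criterion at 5 (best) and 2 (good) robust
    SDs, pAVR cutoff 3 cs, good-blink ratio 0.70, group trigger 1.5
    robust SDs.
    """

    band_low_hz: float = 1.0
    band_high_hz: float = 20.0
    threshold_sd: float = 1.5
    min_blink_ms: float = 50.0
    min_separation_ms: float = 50.0
    separation_mode: str = "merge"  # or "drop"
    inner_fit_mode: str = "amplitude"  # or "frame"
    bar_range: tuple[float, float] = (3.0, 50.0)
    bar_pooling: str = "pooled"  # or "per_blink"
    r2_good: float = 0.90
    r2_better: float = 0.95
    r2_best: float = 0.98
    z_best: float = 5.0
    z_good: float = 2.0
    pavr_min: float = 3.0
    good_ratio_min: float = 0.70
    good_ratio_numerator: str = "within_band"  # or "good_tier"
    group_threshold_sd: float = 1.5
    signals: list[str] | None = None  # restriction list; None = all

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat key-value YAML config; explicit overrides win over the file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        cfg = cls(**data)
        if isinstance(cfg.bar_range, list):
            cfg.bar_range = tuple(cfg.bar_range)
        return cfg


@dataclass
class SignalResult:
    """Everything computed for one candidate signal."""

    evaluation: smod.SignalEvaluation
    filtered: detect.FilteredSignal | None = None
    landmarks: list[lmod.BlinkLandmarks] = field(default_factory=list)
    tiers: list[smod.Tier] = field(default_factory=list)
    properties: list[indices.BlinkProperties] = field(default_factory=list)
    used: list[bool] = field(default_factory=list)


@dataclass
class DatasetResult:
    """Outcome of a full pipeline run on one dataset."""

    name: str
    status: str  # selected | marginal | failed
    selected_label: str | None
    summary: indices.DatasetSummary | None
    signal_results: dict[str, SignalResult]
    groups: list[smod.BlinkGroup] = field(default_factory=list)
    failure_reason: str | None = None

    def blink_table(self) -> pd.DataFrame:
        """Per-blink records of every evaluated signal, one row per blink."""
        rows = []
        for label, sr in self.signal_results.items():
            srate = sr.filtered.srate if sr.filtered else np.nan
            for lm, tier, props, used in zip(sr.landmarks, sr.tiers, sr.properties, sr.used):
                rows.append(
                    {
                        "signal": label,
                        "maxFrame": lm.maxFrame,
                        "peakTimeS": frame_to_seconds(lm.maxFrame, srate),
                        "leftZero": lm.leftZero,
                        "rightZero": lm.rightZero,
                        "leftBase": lm.leftBase,
                        "rightBase": lm.rightBase,
                        "leftR2": lm.leftR2,
                        "rightR2": lm.rightR2,
                        "tier": tier.value,
                        "used": used,
                        "peakAmp": lm.maxValue,
                        "halfZeroDur": props.halfZeroDur,
                        "halfBaseDur": props.halfBaseDur,
                        "zeroDur": props.zeroDur,
                        "baseDur": props.baseDur,
                        "tentDur": props.tentDur,
                        "pAVR": props.pAVR,
                        "nAVR": props.nAVR,
                    }
                )
        return pd.DataFrame(rows, columns=BLINK_TABLE_COLUMNS)

    def signal_table(self) -> pd.DataFrame:
        return pd.DataFrame([sr.evaluation.to_dict() for sr in self.signal_results.values()])

    def summary_dict(self) -> dict:
        d = {"dataset": self.name, "status": self.status, "failureReason": self.failure_reason}
        if self.summary is not None:
            d.update(self.summary.to_dict())
        d["signals"] = [sr.evaluation.to_dict() for sr in self.signal_results.values()]
        d["nGroups"] = len(self.groups)
        return d


def evaluate_signal(signal: CandidateSignal, config: RunConfig | None = None) -> SignalResult:
    """Run detection, landmarking and all per-signal criteria on one signal.

    The BAR gate and the requirement of at least one best-tier blink
    decide the signal's candidate status; the used-flag combines tier,
    amplitude-distribution and pAVR criteria.
    """
    config = config or RunConfig()
    ev = smod.SignalEvaluation(label=signal.label)
    result = SignalResult(evaluation=ev)

    filtered = detect.bandpass(signal, config.band_low_hz, config.band_high_hz)
    result.filtered = filtered
    blinks = detect.find_potential_blinks(
        filtered,
        k_sd=config.threshold_sd,
        min_dur_s=config.min_blink_ms / 1000.0,
        min_sep_s=config.min_separation_ms / 1000.0,
        separation_mode=config.separation_mode,
    )
    ev.nPotential = len(blinks)
    if not blinks:
        ev.reject_reason = "no potential blinks"
        return result

    lms = lmod.compute_landmarks(filtered, blinks, inner_mode=config.inner_fit_mode)
    tiers = smod.tier_blinks(
        lms, r2_good=config.r2_good, r2_better=config.r2_better, r2_best=config.r2_best
    )
    props = [indices.blink_properties(filtered, lm) for lm in lms]
    result.landmarks, result.tiers, result.properties = lms, tiers, props
    ev.nGood = sum(t is not smod.Tier.NONE for t in tiers)
    ev.nBetter = sum(t in (smod.Tier.BEST, smod.Tier.BETTER) for t in tiers)
    ev.nBest = sum(t is smod.Tier.BEST for t in tiers)
    result.used = [False] * len(lms)

    # per-blink criteria first: these are meaningful even for signals the
    # BAR gate later rejects as selection candidates
    if ev.nBest > 0:
        ev.bestMedian, ev.bestRobustStd = smod.best_blink_stats(lms, tiers)
        amp_ok = smod.amplitude_criterion(
            lms, tiers, ev.bestMedian, ev.bestRobustStd, z_best=config.z_best, z_good=config.z_good
        )
        pavr_ok = smod.pavr_criterion([p.pAVR for p in props], pavr_min=config.pavr_min)
        result.used = [a and p for a, p in zip(amp_ok, pavr_ok)]
        ev.nUsed = sum(result.used)
        ev.goodRatio = smod.good_blink_ratio(
            lms,
            ev.bestMedian,
            ev.bestRobustStd,
            tiers=tiers,
            z_good=config.z_good,
            numerator=config.good_ratio_numerator,
        )

    bar = smod.compute_bar(filtered, lms, pooling=config.bar_pooling)
    ev.bar = bar
    if bar is None:
        ev.reject_reason = "undefined BAR (no positive background)"
        return result
    if not smod.gate_bar(bar, config.bar_range):
        ev.reject_reason = f"BAR {bar:.2f} outside {list(config.bar_range)}"
        return result
    if ev.nBest == 0:
        ev.reject_reason = "no best-tier blinks (amplitude criterion undefined)"
        return result

    ev.status = smod.SignalStatus.USABLE
    ev.reject_reason = None
    return result


def run_dataset(dataset: Dataset, config: RunConfig | None = None) -> DatasetResult:
    """Run the full pipeline on one dataset and summarize the result.

    Signals outside the restriction list are skipped; naming an absent
    label is a parameter error.  Dataset-level failure (no usable signal)
    is reported as status ``failed``, never as an exception.
    """
    config = config or RunConfig()
    labels = dataset.labels()
    if config.signals is not None:
        missing = [s for s in config.signals if s not in labels]
        if missing:
            raise ValueError(f"restriction list names absent signals: {missing}")
        use_labels = list(config.signals)
    else:
        use_labels = labels

    signal_results: dict[str, SignalResult] = {}
    for label in use_labels:
        sr = evaluate_signal(dataset[label], config)
        signal_results[label] = sr
        if sr.evaluation.reject_reason:
            log.info("signal %s rejected: %s", label, sr.evaluation.reject_reason)

    evaluations = [sr.evaluation for sr in signal_results.values()]
    selected, _ = smod.select_best_signal(evaluations, good_ratio_min=config.good_ratio_min)

    if selected is None:
        return DatasetResult(
            name=dataset.name,
            status="failed",
            selected_label=None,
            summary=indices.summarize([], dataset.duration_minutes, None, "failed"),
            signal_results=signal_results,
            failure_reason="no candidate signal passed the quality gates",
        )

    win = signal_results[selected]
    status = win.evaluation.status.value
    used_props = [p for p, u in zip(win.properties, win.used) if u]
    summary = indices.summarize(used_props, dataset.duration_minutes, selected, status)

    usable = {
        label: (sr.filtered, sr.landmarks, sr.used)
        for label, sr in signal_results.items()
        if sr.evaluation.status is not smod.SignalStatus.REJECTED and sr.filtered is not None
    }
    groups = smod.group_blinks(usable, k_sd=config.group_threshold_sd) if usable else []

    return DatasetResult(
        name=dataset.name,
        status=status,
        selected_label=selected,
        summary=summary,
        signal_results=signal_results,
        groups=groups,
    )


def write_outputs(result: DatasetResult, out_dir: str | Path) -> dict[str, Path]:
    """Write summary.json, blinks.tsv and signals.tsv for one run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": out_dir / "summary.json",
        "blinks": out_dir / "blinks.tsv",
        "signals": out_dir / "signals.tsv",
    }
    write_summary_json(result.summary_dict(), paths["summary"])
    write_blink_table(result.blink_table(), paths["blinks"])
    result.signal_table().to_csv(paths["signals"], sep="\t", index=False, float_format="%.6f")
    return paths


#: columns of the per-dataset rows in a collection table
COLLECTION_COLUMNS = [
    "dataset",
    "status",
    "selectedSignal",
    "nUsedBlinks",
    "blinkRatePerMin",
    "pctTimeClosed",
    "halfZeroDurMean",
    "halfBaseDurMean",
    "zeroDurMean",
    "baseDurMean",
    "tentDurMean",
    "pAVRMean",
    "nAVRMean",
]


def run_collection(datasets: list[Dataset], config: RunConfig | None = None) -> pd.DataFrame:
    """Run every dataset and tabulate one row each, plus status counts.

    A failing dataset contributes a row with status ``failed``; it is
    counted, not fatal.  Rows follow the input order.
    """
    if not datasets:
        raise ValueError("collection must contain at least one dataset")
    rows = []
    for ds in datasets:
        res = run_dataset(ds, config)
        s = res.summary
        row = {
            "dataset": res.name,
            "status": res.status,
            "selectedSignal": res.selected_label,
            "nUsedBlinks": s.nUsedBlinks if s else 0,
            "blinkRatePerMin": s.blinkRatePerMin if s else np.nan,
            "pctTimeClosed": s.pctTimeClosed if s else np.nan,
        }
        for m in indices.SUMMARY_MEASURES:
            row[f"{m}Mean"] = s.means[m] if s else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=COLLECTION_COLUMNS)


def collection_aggregate(table: pd.DataFrame) -> dict:
    """Aggregate a collection table: status counts and measure means."""
    agg = {
        "nDatasets": int(len(table)),
        "nSelected": int((table["status"] == "selected").sum()),
        "nMarginal": int((table["status"] == "marginal").sum()),
        "nFailed": int((table["status"] == "failed").sum()),
    }
    ok = table[table["status"] != "failed"]
    for col in COLLECTION_COLUMNS[4:]:
        agg[f"{col}Mean"] = float(ok[col].mean()) if len(ok) else np.nan
    return agg
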