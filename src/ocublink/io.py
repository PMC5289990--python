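"""Reading and writing of candidate-signal sets and per-blink tables.

A *candidate signal* is any single time series from which blinks might be
extracted: an EEG channel, an EOG lead, or an independent-component
activation.  A :class:`Dataset` is an ordered collection of candidate
signals sharing one sampling rate and frame count.

Frame convention: frames are zero-based and the time of frame ``i`` is
``i / srate`` seconds (see :func:`frame_to_seconds`).
"""

from __future__ import annotations

import enum
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class SignalKind(str, enum.Enum):
    """Origin of a candidate signal."""

    EEG = "EEG"
    EOG = "EOG"
    IC = "IC"


#: lower-cased substrings that mark a channel label as electrooculographic
_EOG_LABEL_HINTS = ("eog", "veo", "heo")


def infer_kind(label: str) -> SignalKind:
    """Infer EEG vs EOG from a channel label (case-insensitive substring).

    Labels containing ``eog``, ``veo`` or ``heo`` are classified as EOG,
    everything else as EEG.  Callers may override the inference: channel
    labels are not always trustworthy in practice.
    """
    low = label.lower()
    if any(h in low for h in _EOG_LABEL_HINTS):
        return SignalKind.EOG
    return SignalKind.EEG


def frame_to_seconds(frame: float, srate: float) -> float:
    """Time in seconds of (possibly fractional) zero-based frame ``frame``."""
    return float(frame) / float(srate)


def seconds_to_frame(t: float, srate: float) -> int:
    """Nearest zero-based frame to time ``t`` seconds."""
    return int(round(float(t) * float(srate)))


@dataclass
class CandidateSignal:
    """One labeled time series at a fixed sampling rate.

    Parameters
    ----------
    label : str
        Short identifier, e.g. ``"veou"``, ``"fp1"``, ``"ic03"``.
    kind : SignalKind
        Signal origin (EEG channel, EOG lead, or IC activation).
    samples : ndarray
        Amplitudes, µV for channels and arbitrary units for ICs.
    srate : float
        Sampling rate in Hz, > 0.
    """

    label: str
    kind: SignalKind
    samples: np.ndarray
    srate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("signal must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"signal {self.label!r} contains non-finite samples")
        if not (self.srate > 0):
            raise ValueError("sampling rate must be positive")
        self.kind = SignalKind(self.kind)

    @property
    def n_frames(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.srate


@dataclass
class Dataset:
    """An ordered collection of candidate signals with one srate and length."""

    name: str
    signals: list[CandidateSignal] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.signals:
            raise ValueError("dataset must contain at least one signal")
        srates = {s.srate for s in self.signals}
        lengths = {s.n_frames for s in self.signals}
        if len(srates) > 1:
            raise ValueError(f"signals have differing sampling rates: {sorted(srates)}")
        if len(lengths) > 1:
            raise ValueError(f"signals have differing frame counts: {sorted(lengths)}")

    @property
    def srate(self) -> float:
        return self.signals[0].srate

    @property
    def n_frames(self) -> int:
        return self.signals[0].n_frames

    @property
    def duration_minutes(self) -> float:
        return self.n_frames / (self.srate * 60.0)

    def labels(self) -> list[str]:
        return [s.label for s in self.signals]

    def __getitem__(self, label: str) -> CandidateSignal:
        for s in self.signals:
            if s.label == label:
                return s
        raise KeyError(label)


# ---------------------------------------------------------------------------
# EDF reading (via MNE) and a minimal EDF writer
# ---------------------------------------------------------------------------

def _edf_samples_per_record(path: Path) -> list[int]:
    """Read the per-channel samples-per-record fields from an EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise IOError(f"{path}: truncated EDF header")
        ns = int(header[252:256].decode("ascii").strip())
        chan_header = fh.read(ns * 256)
    off = ns * 216  # label(16)+transducer(80)+dim(8)+phys(8+8)+dig(8+8)+prefilter(80)
    vals = []
    for i in range(ns):
        raw = chan_header[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip()
        vals.append(int(raw))
    return vals


def read_edf(path: str | Path, kinds: dict[str, SignalKind] | None = None) -> Dataset:
    """Read an EDF/EDF+/BDF file into a :class:`Dataset`.

    One candidate signal is created per data channel; the signal kind is
    inferred from the channel label (see :func:`infer_kind`) unless
    overridden through ``kinds``.  Channel amplitudes are returned in µV.

    Raises
    ------
    IOError
        If the file is missing or unreadable.
    ValueError
        If channels have differing sampling rates (unsupported).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        spr = _edf_samples_per_record(path)
    except Exception as exc:  # malformed header
        raise IOError(f"cannot parse EDF header of {path}: {exc}") from exc
    # exclude the EDF+ annotation channel from the uniform-rate requirement
    if len(set(spr)) > 1:
        raise ValueError(
            f"{path}: channels have differing sampling rates ({sorted(set(spr))} "
            "samples/record); mixed-rate EDF is not supported"
        )
    suffix = path.suffix.lower()
    reader = mne.io.read_raw_bdf if suffix == ".bdf" else mne.io.read_raw_edf
    try:
        raw = reader(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    data = raw.get_data(units="uV")
    kinds = kinds or {}
    signals = []
    for i, label in enumerate(raw.ch_names):
        kind = kinds.get(label, infer_kind(label))
        signals.append(
            CandidateSignal(label=label, kind=kind, samples=data[i], srate=float(raw.info["sfreq"]))
        )
    return Dataset(name=path.stem, signals=signals)


def write_edf(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as a plain 16-bit EDF file.

    A deliberately minimal writer: the record size is the largest one that
    tiles the signal exactly (so frame counts survive the round-trip), the
    physical range is taken from the data, and the digital range is the
    full 16-bit span.  Amplitudes survive a round-trip to within the
    16-bit quantization of the physical range.  The sampling rate must be
    a whole number of Hz.
    """
    import math

    path = Path(path)
    srate = dataset.srate
    if abs(srate - round(srate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n = dataset.n_frames
    spr = math.gcd(n, int(round(srate)))
    n_records = n // spr
    ns = len(dataset.signals)

    def pad(value: str, width: int) -> bytes:
        b = value.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    phys_min, phys_max, digital = [], [], []
    for sig in dataset.signals:
        lo = float(np.min(sig.samples))
        hi = float(np.max(sig.samples))
        if hi <= lo:
            hi = lo + 1.0
        # round outward to keep the header fields within 8 ascii chars
        lo, hi = np.floor(lo - 1.0), np.ceil(hi + 1.0)
        phys_min.append(lo)
        phys_max.append(hi)
        scale = (hi - lo) / (32767 - (-32768))
        x = np.full(n_records * spr, lo)
        x[:n] = sig.samples
        dig = np.round((x - lo) / scale) + (-32768)
        digital.append(np.clip(dig, -32768, 32767).astype("<i2"))

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + ns)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad(f"{spr / srate:g}", 8),  # record duration, seconds
            pad(str(ns), 4),
        ]
    )
    fields = [
        [pad(s.label, 16) for s in dataset.signals],
        [pad("", 80)] * ns,
        [pad("uV", 8)] * ns,
        [pad(f"{v:g}", 8) for v in phys_min],
        [pad(f"{v:g}", 8) for v in phys_max],
        [pad("-32768", 8)] * ns,
        [pad("32767", 8)] * ns,
        [pad("", 80)] * ns,
        [pad(str(spr), 8)] * ns,
        [pad("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        for r in range(n_records):
            for d in digital:
                fh.write(d[r * spr : (r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# Delimited matrix I/O
# ---------------------------------------------------------------------------

def read_matrix(
    path: str | Path,
    srate: float,
    labels: Sequence[str] | None = None,
    kinds: Sequence[SignalKind] | None = None,
    name: str | None = None,
) -> Dataset:
    """Read a delimited numeric matrix (rows = candidate signals).

    The delimiter (comma or tab) is autodetected from the first line.
    Default labels are ``s1..sm``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing cells in matrix")
    m = df.shape[0]
    if labels is None:
        labels = [f"s{i + 1}" for i in range(m)]
    elif len(labels) != m:
        raise ValueError(f"got {len(labels)} labels for {m} matrix rows")
    if kinds is None:
        kinds = [infer_kind(lab) for lab in labels]
    elif len(kinds) != m:
        raise ValueError(f"got {len(kinds)} kinds for {m} matrix rows")
    signals = [
        CandidateSignal(label=lab, kind=k, samples=df.iloc[i].to_numpy(), srate=srate)
        for i, (lab, k) in enumerate(zip(labels, kinds))
    ]
    return Dataset(name=name or path.stem, signals=signals)


def write_matrix(dataset: Dataset, path: str | Path, sep: str = "\t") -> None:
    """Write the signals of a dataset as a delimited matrix, rows = signals."""
    arr = np.vstack([s.samples for s in dataset.signals])
    np.savetxt(path, arr, delimiter=sep, fmt="%.6f")


# ---------------------------------------------------------------------------
# Per-blink table and summary output
# ---------------------------------------------------------------------------

#: column order of the per-blink TSV
BLINK_TABLE_COLUMNS = [
    "signal",
    "maxFrame",
    "peakTimeS",
    "leftZero",
    "rightZero",
    "leftBase",
    "rightBase",
    "leftR2",
    "rightR2",
    "tier",
    "used",
    "peakAmp",
    "halfZeroDur",
    "halfBaseDur",
    "zeroDur",
    "baseDur",
    "tentDur",
    "pAVR",
    "nAVR",
]

_INT_COLUMNS = ("maxFrame", "leftZero", "rightZero", "leftBase", "rightBase")


def write_blink_table(blinks: pd.DataFrame, path: str | Path) -> None:
    """Write per-blink records as a TSV: frames as integers, times to 6 dp."""
    df = blinks.copy()
    for col in BLINK_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[BLINK_TABLE_COLUMNS]
    for col in _INT_COLUMNS:
        df[col] = df[col].astype("Int64")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_blink_table(path: str | Path) -> pd.DataFrame:
    """Read back a per-blink TSV written by :func:`write_blink_table`."""
    return pd.read_csv(path, sep="\t")


def write_summary_json(summary: dict, path: str | Path) -> None:
    """Write a per-dataset summary dict as JSON (NaN encoded as null)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, enum.Enum):
            return o.value
        raise TypeError(f"not JSON serializable: {type(o)}")

    clean = json.loads(json.dumps(summary, default=default))

    def scrub(obj):
        if isinstance(obj, float) and not np.isfinite(obj):
            return None
        if isinstance(obj, dict):
            return {k: scrub(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [scrub(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        json.dump(scrub(clean), fh, indent=2)
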