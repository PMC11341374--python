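"""Core domain types and file I/O.

The package operates on four plain containers:

* :class:`Recording` — continuous multichannel signal in microvolts,
* :class:`Scoring` — a hypnogram (one sleep-stage label per fixed epoch),
* :class:`ElectrodeLayout` — 3-D electrode positions and a neighbor map,
* :class:`EventTable` — channel-resolved artifact events in seconds.

Conventions used throughout: time is in seconds from recording start, all
intervals are half-open ``[start, end)``, sample indices are 0-based and
sample ``i`` covers ``[i/fs, (i+1)/fs)``.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel channel label for events that apply to the whole montage.
GLOBAL = "__GLOBAL__"

#: Canonical sleep-stage labels.
STAGES = ("W", "N1", "N2", "N3", "R", "unknown")

#: Default token -> stage alias table for hypnogram files.
DEFAULT_STAGE_ALIASES = {
    "W": "W", "WAKE": "W", "0": "W",
    "N1": "N1", "S1": "N1", "1": "N1",
    "N2": "N2", "S2": "N2", "2": "N2",
    "N3": "N3", "S3": "N3", "S4": "N3", "3": "N3", "4": "N3", "SWS": "N3",
    "R": "R", "REM": "R", "5": "R",
    "UNKNOWN": "unknown", "?": "unknown", "U": "unknown", "A": "unknown",
}

EVENT_COLUMNS = ["channel", "start_s", "end_s", "event_type", "detector"]


class FormatError(ValueError):
    """A file does not parse under the expected standard."""


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multichannel signal in microvolts.

    Parameters
    ----------
    channel_labels : list of str
        Unique channel names; one per data row.
    sample_rate_hz : float
        Sampling rate, > 0.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts, stored as float64.
    start_time_s : float
        Time of the first sample relative to the scoring origin.
    """

    channel_labels: list[str]
    sample_rate_hz: float
    data: np.ndarray
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but {self.data.shape[0]} data rows"
            )
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def subset(self, labels: list[str]) -> "Recording":
        """Return a new recording restricted to *labels* (order preserved)."""
        idx = [self.channel_index(lb) for lb in labels]
        return Recording(list(labels), self.sample_rate_hz,
                         self.data[idx].copy(), self.start_time_s)

    def copy(self) -> "Recording":
        return Recording(list(self.channel_labels), self.sample_rate_hz,
                         self.data.copy(), self.start_time_s)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class Scoring:
    """Hypnogram: one stage label per fixed-length epoch.

    Epoch ``e`` covers ``[offset_s + e*epoch_length_s,
    offset_s + (e+1)*epoch_length_s)``; time beyond the last scored epoch
    is stage ``unknown``.
    """

    stages: list[str]
    epoch_length_s: float = 30.0
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.epoch_length_s > 0:
            raise ValueError("epoch_length_s must be positive")
        if not self.stages:
            raise ValueError("scoring must contain at least one epoch")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def stage_at(self, t_s: float) -> str:
        """Stage label covering time *t_s* (``unknown`` outside scoring)."""
        e = int(np.floor((t_s - self.offset_s) / self.epoch_length_s))
        if 0 <= e < self.n_epochs:
            return self.stages[e]
        return "unknown"

    def sample_stages(self, n_samples: int, sample_rate_hz: float,
                      start_time_s: float = 0.0) -> np.ndarray:
        """Per-sample stage labels as an array of strings."""
        t = start_time_s + np.arange(n_samples) / sample_rate_hz
        e = np.floor((t - self.offset_s) / self.epoch_length_s).astype(np.int64)
        out = np.full(n_samples, "unknown", dtype=object)
        ok = (e >= 0) & (e < self.n_epochs)
        stages = np.asarray(self.stages, dtype=object)
        out[ok] = stages[e[ok]]
        return out


# ---------------------------------------------------------------------------
# ElectrodeLayout
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeLayout:
    """Per-channel 3-D coordinates plus a derived neighborhood map."""

    labels: list[str]
    positions: np.ndarray  # (n, 3)
    neighbor_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("layout labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("electrode coordinates must be finite")
        for lb, nbrs in self.neighbor_map.items():
            if lb in nbrs:
                raise ValueError(f"channel {lb!r} listed as its own neighbor")
            for nb in nbrs:
                if lb not in self.neighbor_map.get(nb, set()):
                    raise ValueError("neighbor map must be symmetric")

    def position_of(self, label: str) -> np.ndarray:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no position for channel {label!r}") from None
        return self.positions[i]

    def neighbors_of(self, label: str) -> set[str]:
        return set(self.neighbor_map.get(label, set()))

    @property
    def head_radius(self) -> float:
        """Median distance of electrodes from their centroid."""
        c = self.positions.mean(axis=0)
        return float(np.median(np.linalg.norm(self.positions - c, axis=1)))


def build_neighbors(layout: ElectrodeLayout, method: str = "distance",
                    threshold: float | None = None) -> ElectrodeLayout:
    """Return a copy of *layout* with a distance-based neighbor map.

    Channels a, b are neighbors iff their Euclidean distance is
    <= *threshold*. ``threshold=inf`` yields an all-to-all map. The default
    threshold is ``0.35 * median head radius`` of the layout.
    """
    if method != "distance":
        raise ValueError(f"unknown neighbor method {method!r}")
    if threshold is None:
        threshold = 0.35 * layout.head_radius
    if not threshold > 0:
        raise ValueError("neighbor distance threshold must be positive")
    n = len(layout.labels)
    nbr: dict[str, set[str]] = {lb: set() for lb in layout.labels}
    if n >= 2:
        d = np.linalg.norm(layout.positions[:, None, :]
                           - layout.positions[None, :, :], axis=-1)
        for i in range(n):
            for j in range(i + 1, n):
                if d[i, j] <= threshold:
                    nbr[layout.labels[i]].add(layout.labels[j])
                    nbr[layout.labels[j]].add(layout.labels[i])
    return ElectrodeLayout(list(layout.labels), layout.positions.copy(), nbr)


def read_layout(path) -> ElectrodeLayout:
    """Read electrode positions from rows of ``label,x,y,z``.

    Both comma- and whitespace-separated files are accepted (.sfp style);
    a single leading header line with non-numeric coordinates is skipped.
    """
    lines = Path(path).read_text().strip().splitlines()
    labels: list[str] = []
    coords: list[list[float]] = []
    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        if len(parts) != 4:
            raise FormatError(f"row {ln}: expected 'label x y z', got {line!r}")
        try:
            xyz = [float(v) for v in parts[1:]]
        except ValueError:
            if ln == 1 and not labels:  # header line
                continue
            raise FormatError(f"row {ln}: non-numeric coordinate in {line!r}") from None
        labels.append(parts[0])
        coords.append(xyz)
    if not labels:
        raise FormatError("layout file contains no electrode rows")
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate electrode labels in layout file")
    return ElectrodeLayout(labels, np.asarray(coords))


def read_scoring(path, epoch_length_s: float = 30.0,
                 aliases: dict[str, str] | None = None,
                 offset_s: float = 0.0) -> Scoring:
    """Read a plain-text hypnogram, one stage token per line.

    Tokens are mapped through *aliases* (case-insensitive; defaults to
    :data:`DEFAULT_STAGE_ALIASES`); unmappable tokens become ``unknown``
    with a logged warning.
    """
    if aliases is None:
        aliases = DEFAULT_STAGE_ALIASES
    aliases = {k.upper(): v for k, v in aliases.items()}
    tokens = [t.strip() for t in Path(path).read_text().splitlines() if t.strip()]
    if not tokens:
        raise FormatError("hypnogram file is empty")
    stages = []
    for tok in tokens:
        stage = aliases.get(tok.upper())
        if stage is None:
            logger.warning("unrecognized stage token %r mapped to 'unknown'", tok)
            stage = "unknown"
        stages.append(stage)
    return Scoring(stages, epoch_length_s=epoch_length_s, offset_s=offset_s)


# ---------------------------------------------------------------------------
# EventTable
# ---------------------------------------------------------------------------

class EventTable:
    """Channel-resolved artifact events.

    Thin wrapper around a DataFrame with columns
    ``channel, start_s, end_s, event_type, detector``. Intervals are
    half-open ``[start_s, end_s)`` and must be nonempty.
    """

    def __init__(self, rows=None):
        if rows is None or (isinstance(rows, list) and not rows):
            df = pd.DataFrame(columns=EVENT_COLUMNS)
        elif isinstance(rows, pd.DataFrame):
            df = rows.copy()
        else:
            df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
        missing = set(EVENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"event table missing columns {sorted(missing)}")
        df = df[EVENT_COLUMNS].reset_index(drop=True)
        df["start_s"] = df["start_s"].astype(float)
        df["end_s"] = df["end_s"].astype(float)
        if len(df) and not (df["start_s"] < df["end_s"]).all():
            bad = int((~(df["start_s"] < df["end_s"])).idxmax())
            raise ValueError(f"event row {bad}: start_s must be < end_s")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"EventTable({len(self)} events)"

    @property
    def channels(self) -> set[str]:
        return set(self.df["channel"])

    def for_channel(self, label: str) -> pd.DataFrame:
        return self.df[self.df["channel"] == label]

    def total_duration(self) -> float:
        return float((self.df["end_s"] - self.df["start_s"]).sum())

    @staticmethod
    def concat(tables: list["EventTable"]) -> "EventTable":
        frames = [t.df for t in tables if len(t)]
        if not frames:
            return EventTable()
        return EventTable(pd.concat(frames, ignore_index=True))


def write_event_table(events: EventTable, path) -> None:
    """Write an event table as CSV (6 decimal places on times)."""
    df = events.df.copy()
    df["start_s"] = df["start_s"].map(lambda v: f"{v:.6f}")
    df["end_s"] = df["end_s"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


def read_event_table(path) -> EventTable:
    df = pd.read_csv(path, dtype={"channel": str, "event_type": str, "detector": str})
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"event CSV missing columns {sorted(missing)}")
    for i, row in df.iterrows():
        try:
            s, e = float(row["start_s"]), float(row["end_s"])
        except (TypeError, ValueError):
            raise FormatError(f"row {i + 1}: non-numeric event times") from None
        if not s < e:
            raise FormatError(f"row {i + 1}: start_s ({s}) must be < end_s ({e})")
    if df.empty:
        return EventTable()
    return EventTable(df)


# ---------------------------------------------------------------------------
# ConfusionMetrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMetrics:
    """Confusion counts plus derived agreement metrics.

    Counts may be real-valued when reconstructed from rounded summary
    statistics. Ratios with zero denominators are NaN.
    """

    tp: float
    fp: float
    fn: float
    tn: float
    accuracy: float
    kappa: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("tp", "fp", "fn", "tn", "accuracy", "kappa",
                 "sensitivity", "specificity", "precision", "f1")}

    @classmethod
    def from_counts(cls, tp: float, fp: float, fn: float, tn: float) -> "ConfusionMetrics":
        def ratio(num, den):
            return num / den if den > 0 else float("nan")

        n = tp + fp + fn + tn
        acc = ratio(tp + tn, n)
        sens = ratio(tp, tp + fn)
        spec = ratio(tn, tn + fp)
        prec = ratio(tp, tp + fp)
        f1 = ratio(2 * prec * sens, prec + sens) if np.isfinite(prec) and np.isfinite(sens) else float("nan")
        prev_ref = ratio(tp + fn, n)
        prev_test = ratio(tp + fp, n)
        pe = prev_test * prev_ref + (1 - prev_test) * (1 - prev_ref)
        kappa = ratio(acc - pe, 1 - pe) if np.isfinite(pe) and (1 - pe) != 0 else float("nan")
        return cls(tp, fp, fn, tn, acc, kappa, sens, spec, prec, f1)


# ---------------------------------------------------------------------------
# EDF read/write
# ---------------------------------------------------------------------------

def read_recording(path, fmt: str = "edf") -> Recording:
    """Read a continuous recording from disk.

    Parameters
    ----------
    path : path-like
        For ``fmt='edf'``, an EDF file. For ``fmt='matrix'``, a CSV matrix
        (channels as columns, header row of labels) with a JSON sidecar
        ``<path>.json`` providing at least ``sample_rate_hz``.
    """
    if fmt == "edf":
        return _read_edf(path)
    if fmt in ("matrix", "matrix+sidecar"):
        return _read_matrix(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def _read_edf(path) -> Recording:
    import mne

    # check label uniqueness on the raw header: EDF readers commonly
    # de-duplicate labels silently, which would mask corrupt files
    with open(path, "rb") as f:
        header = f.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            nchan = int(header[252:256].decode("ascii").strip())
        except ValueError:
            raise FormatError(
                f"{path}: EDF header field 'number of signals' is not "
                "numeric") from None
        raw_labels = [f.read(16).decode("ascii", "replace").strip()
                      for _ in range(nchan)]
    if len(set(raw_labels)) != len(raw_labels):
        raise FormatError("EDF header field 'label': duplicate channel labels")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for bad headers
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    labels = list(raw.ch_names)
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return Recording(labels, float(raw.info["sfreq"]), data_uv)


def _read_matrix(path) -> Recording:
    import json

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"matrix sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    if "sample_rate_hz" not in meta:
        raise FormatError("matrix sidecar missing field 'sample_rate_hz'")
    df = pd.read_csv(path)
    return Recording(list(df.columns), float(meta["sample_rate_hz"]),
                     df.to_numpy().T,
                     start_time_s=float(meta.get("start_time_s", 0.0)))


def write_matrix(recording: Recording, path) -> None:
    """Write a recording as CSV (channels as columns) + JSON sidecar."""
    import json

    path = Path(path)
    pd.DataFrame(recording.data.T, columns=recording.channel_labels).to_csv(
        path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "sample_rate_hz": recording.sample_rate_hz,
        "start_time_s": recording.start_time_s,
        "unit": "uV",
    }))


def write_edf(recording: Recording, path) -> None:
    """Write a recording as a continuous EDF file.

    Signals are quantized to 16-bit integers over each channel's physical
    range, the EDF native encoding. The sample rate must allow an integral
    number of samples per data record (record duration 1 s, or a shorter
    power-of-ten fraction for fractional rates).
    """
    fs = recording.sample_rate_hz
    record_dur = 1.0
    if abs(fs * record_dur - round(fs * record_dur)) > 1e-9:
        raise ValueError("EDF writing requires an integral number of samples "
                         f"per 1 s record; got fs={fs}")
    spr = int(round(fs * record_dur))  # samples per record per channel
    nchan = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / spr))
    npad = n_records * spr - recording.n_samples

    data = recording.data
    phys_min = np.floor(np.min(data, axis=1))
    phys_max = np.ceil(np.max(data, axis=1))
    same = phys_max <= phys_min
    phys_max[same] = phys_min[same] + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")
    if npad:
        pad = np.full((nchan, npad), dig_min, dtype="<i2")
        digital = np.concatenate([digital, pad], axis=1)

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    now = datetime(2000, 1, 1)
    buf = io.BytesIO()
    buf.write(f("0", 8))                                   # version
    buf.write(f("X X X X", 80))                            # patient id
    buf.write(f("Startdate X X X X", 80))                  # recording id
    buf.write(f(now.strftime("%d.%m.%y"), 8))
    buf.write(f(now.strftime("%H.%M.%S"), 8))
    buf.write(f(str(256 * (1 + nchan)), 8))                # header bytes
    buf.write(f("EDF+C", 44))
    buf.write(f(str(n_records), 8))
    buf.write(f(f"{record_dur:g}", 8))
    buf.write(f(str(nchan), 4))
    for lb in recording.channel_labels:
        buf.write(f(lb, 16))
    for _ in range(nchan):
        buf.write(f("AgAgCl electrode", 80))               # transducer
    for _ in range(nchan):
        buf.write(f("uV", 8))
    for v in phys_min:
        buf.write(f(f"{v:g}"[:8], 8))
    for v in phys_max:
        buf.write(f(f"{v:g}"[:8], 8))
    buf.write(f(str(dig_min), 8) * nchan)
    buf.write(f(str(dig_max), 8) * nchan)
    for _ in range(nchan):
        buf.write(f("", 80))                               # prefiltering
    buf.write(f(str(spr), 8) * nchan)
    for _ in range(nchan):
        buf.write(f("", 32))                               # reserved
    for r in range(n_records):
        sl = digital[:, r * spr:(r + 1) * spr]
        buf.write(sl.tobytes())                            # channel-major per record
    Path(path).write_bytes(buf.getvalue())
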