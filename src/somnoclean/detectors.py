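"""The detector-set engine.

A detector is a declarative recipe: which channels and sleep stages to
consider, a chain of signal primitives to apply, and a detection criterion.
Channel-wise detectors threshold a per-sample scalar on each channel
independently; pairwise detectors cut the recording into fixed windows and
flag a target channel when a pairwise metric (correlation or maximum
absolute difference) against its designated partners meets the criterion
for a sufficient fraction of partners.

:func:`default_detector_set` builds the nine stock detectors targeting
high/low amplitude, excessive low/high-frequency power, signal jumps,
flatlines, deviant channels, bridged (near-identical) channels, and
reference failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import signal_ops
from .model_io import ElectrodeLayout, EventTable, Recording, Scoring

logger = logging.getLogger(__name__)

ALL = "ALL"

#: chain step name -> callable(recording, **params) -> recording
_CHAIN_OPS = {
    "bandpass": signal_ops.bandpass,
    "highpass": signal_ops.highpass,
    "envelope": signal_ops.envelope,
    "abs": signal_ops.rectify,
    "gradient_abs": signal_ops.gradient_abs,
    "median_filter": signal_ops.median_filter,
    # zscore is dispatched separately (needs the stage mask)
}


@dataclass
class DetectorSpec:
    """Declarative description of one artifact detector."""

    name: str
    scope: str  # channelwise | pairwise_local | pairwise_global
    chain: list = field(default_factory=list)  # [(op_name, params), ...]
    stages: object = ALL
    channels: object = ALL
    # channelwise criterion
    cmp: str | None = None
    threshold: float | None = None
    min_duration_s: float = 0.0
    # pairwise criterion
    window_s: float | None = None
    pair_metric: str | None = None  # pearson_r | max_abs_difference
    pair_cmp: str | None = None
    pair_threshold: float | None = None
    neighbor_fraction: float | None = None
    # post-processing
    padding_s: float = 0.0
    merge_gap_s: float = 0.0
    min_channels: int = 1

    def __post_init__(self) -> None:
        if self.scope not in ("channelwise", "pairwise_local", "pairwise_global"):
            raise ValueError(f"unknown detector scope {self.scope!r}")
        if self.scope == "channelwise":
            if self.cmp not in ("gt", "lt") or self.threshold is None:
                raise ValueError(f"detector {self.name}: channelwise specs "
                                 "need cmp and threshold")
        else:
            if not (self.window_s and self.window_s > 0):
                raise ValueError(f"detector {self.name}: pairwise specs need "
                                 "window_s > 0")
            if self.pair_metric not in ("pearson_r", "max_abs_difference"):
                raise ValueError(f"detector {self.name}: unknown pair metric")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chain"] = [[op, dict(params)] for op, params in self.chain]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorSpec":
        d = dict(d)
        d["chain"] = [(op, dict(params)) for op, params in d.get("chain", [])]
        return cls(**d)


@dataclass
class DetectorSet:
    """Ordered, uniquely named collection of detectors."""

    detectors: list[DetectorSpec]
    name: str = "custom"

    def __post_init__(self) -> None:
        names = [d.name for d in self.detectors]
        if len(set(names)) != len(names):
            raise ValueError("detector names must be unique")

    def __len__(self) -> int:
        return len(self.detectors)

    def __iter__(self):
        return iter(self.detectors)

    def names(self) -> list[str]:
        return [d.name for d in self.detectors]

    def to_dict(self) -> dict:
        return {"name": self.name,
                "detectors": [d.to_dict() for d in self.detectors]}

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorSet":
        return cls([DetectorSpec.from_dict(s) for s in d["detectors"]],
                   name=d.get("name", "custom"))


def default_detector_set(sample_rate_hz: float) -> DetectorSet:
    """The nine stock detectors, parameterized for *sample_rate_hz*.

    Sample-rate adjustments: the jump detector's median-filter order scales
    as the nearest odd integer to ``9 * fs/250``; the flatline gradient
    threshold scales as ``1 uV * 250/fs``; the highfreq band's upper edge is
    lowered toward Nyquist (``min(120, 0.95 * Nyquist)``) and the detector
    is omitted entirely (with a warning) when that edge drops to 80 Hz or
    below.
    """
    if not sample_rate_hz > 0:
        raise ValueError("sample_rate_hz must be positive")
    fs = sample_rate_hz
    specs = [
        DetectorSpec("highamp", "channelwise", chain=[("abs", {})],
                     cmp="gt", threshold=300.0, min_duration_s=0.0,
                     padding_s=0.1, merge_gap_s=1.0),
        DetectorSpec("lowamp", "channelwise", chain=[("abs", {})],
                     cmp="lt", threshold=5.0, min_duration_s=30.0,
                     padding_s=0.1, merge_gap_s=1.0),
        DetectorSpec("lowfreq", "channelwise",
                     chain=[("bandpass", {"low_hz": 0.3, "high_hz": 15.0}),
                            ("envelope", {"smooth_s": 0.2}),
                            ("zscore", {})],
                     cmp="gt", threshold=8.0, min_duration_s=0.0,
                     padding_s=3.0, merge_gap_s=1.0),
    ]
    hf_edge = min(120.0, 0.95 * fs / 2.0)
    if hf_edge > 80.0:
        specs.append(
            DetectorSpec("highfreq", "channelwise",
                         chain=[("bandpass", {"low_hz": 60.0, "high_hz": hf_edge}),
                                ("envelope", {"smooth_s": 0.2}),
                                ("zscore", {})],
                         cmp="gt", threshold=3.0, min_duration_s=0.0,
                         padding_s=0.1, merge_gap_s=1.0))
    else:
        logger.warning(
            "highfreq detector omitted: achievable upper band edge "
            "%.1f Hz <= 80 Hz at fs=%g", hf_edge, fs)
    jump_order = int(round(9 * fs / 250.0))
    if jump_order % 2 == 0:
        jump_order += 1
    jump_order = max(1, jump_order)
    specs += [
        DetectorSpec("jump", "channelwise",
                     chain=[("median_filter", {"order": jump_order}),
                            ("gradient_abs", {}),
                            ("zscore", {})],
                     cmp="gt", threshold=25.0, min_duration_s=0.0,
                     padding_s=0.1, merge_gap_s=1.0),
        DetectorSpec("flatline", "channelwise",
                     chain=[("gradient_abs", {})],
                     cmp="lt", threshold=1.0 * 250.0 / fs, min_duration_s=1.0,
                     padding_s=0.1, merge_gap_s=1.0),
        DetectorSpec("deviant", "pairwise_local", window_s=30.0,
                     pair_metric="pearson_r", pair_cmp="lt",
                     pair_threshold=0.3, neighbor_fraction=0.5,
                     merge_gap_s=60.0, min_channels=3),
        # a bridged pair is flagged when ANY local neighbor is numerically
        # near-identical, hence fraction 0 with a strict > comparison
        DetectorSpec("similar", "pairwise_local", window_s=30.0,
                     pair_metric="max_abs_difference", pair_cmp="lt",
                     pair_threshold=0.5, neighbor_fraction=0.0,
                     merge_gap_s=60.0, min_channels=3),
        DetectorSpec("similar2", "pairwise_global", window_s=5.0,
                     chain=[("highpass", {"low_hz": 2.0})],
                     pair_metric="pearson_r", pair_cmp="gt",
                     pair_threshold=0.9, neighbor_fraction=0.5,
                     merge_gap_s=5.0, min_channels=2),
    ]
    return DetectorSet(specs, name="default")


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

def _stage_mask(recording: Recording, spec: DetectorSpec,
                scoring: Scoring | None) -> np.ndarray | None:
    """Boolean per-sample mask of eligible samples, or None for all."""
    if spec.stages == ALL or spec.stages is None:
        return None
    if scoring is None:
        raise ValueError(f"detector {spec.name} restricts stages but no "
                         "scoring was supplied")
    wanted = set(spec.stages)
    labels = scoring.sample_stages(recording.n_samples,
                                   recording.sample_rate_hz,
                                   recording.start_time_s)
    return np.isin(labels, list(wanted))


def _apply_chain(recording: Recording, chain, valid: np.ndarray | None) -> Recording:
    rec = recording
    for op, params in chain:
        if op == "zscore":
            rec = _zscore_masked(rec, valid, **params)
        elif op in _CHAIN_OPS:
            rec = _CHAIN_OPS[op](rec, **params)
        else:
            raise ValueError(f"unknown chain operation {op!r}")
    return rec


def _zscore_masked(rec: Recording, valid: np.ndarray | None,
                   robust: bool = False) -> Recording:
    if valid is None:
        return signal_ops.zscore_per_channel(rec, robust=robust)
    x = rec.data[:, valid]
    sub = Recording(list(rec.channel_labels), rec.sample_rate_hz, x)
    if robust:
        center = np.median(x, axis=1, keepdims=True)
        spread = 1.4826 * np.median(np.abs(x - center), axis=1, keepdims=True)
    else:
        center = x.mean(axis=1, keepdims=True)
        spread = x.std(axis=1, keepdims=True)
    out = np.zeros_like(rec.data)
    ok = spread[:, 0] > 0
    out[ok] = (rec.data[ok] - center[ok]) / spread[ok]
    del sub
    return Recording(list(rec.channel_labels), rec.sample_rate_hz, out,
                     rec.start_time_s)


def run_detector(recording: Recording, spec: DetectorSpec,
                 scoring: Scoring | None = None,
                 layout: ElectrodeLayout | None = None) -> EventTable:
    """Run one detector; returns its event table (type = detector name)."""
    if spec.channels != ALL:
        recording = recording.subset(list(spec.channels))
    valid = _stage_mask(recording, spec, scoring)
    if spec.scope == "channelwise":
        return _run_channelwise(recording, spec, valid)
    return _run_pairwise(recording, spec, valid, layout)


def _run_channelwise(recording: Recording, spec: DetectorSpec,
                     valid: np.ndarray | None) -> EventTable:
    processed = _apply_chain(recording, spec.chain, valid)
    fs = recording.sample_rate_hz
    dur = recording.duration_s
    rows = []
    for ci, label in enumerate(recording.channel_labels):
        iv = signal_ops.threshold_intervals(
            processed.data[ci], fs, spec.cmp, spec.threshold,
            spec.min_duration_s, valid=valid)
        iv = signal_ops.pad_and_merge(iv, spec.padding_s, spec.merge_gap_s, dur)
        rows += [(label, s, e, spec.name, spec.name) for s, e in iv]
    return EventTable(rows)


def _partner_table(spec: DetectorSpec, labels: list[str],
                   layout: ElectrodeLayout | None) -> dict[str, list[str]]:
    present = set(labels)
    if spec.scope == "pairwise_global":
        return {lb: [o for o in labels if o != lb] for lb in labels}
    if layout is None or not layout.neighbor_map:
        raise ValueError(f"detector {spec.name} needs a layout with a "
                         "neighbor map")
    return {lb: sorted(layout.neighbors_of(lb) & present) for lb in labels}


def _run_pairwise(recording: Recording, spec: DetectorSpec,
                  valid: np.ndarray | None,
                  layout: ElectrodeLayout | None) -> EventTable:
    labels = recording.channel_labels
    if recording.n_channels < spec.min_channels:
        raise _SkipDetector(
            f"detector {spec.name} needs >= {spec.min_channels} channels, "
            f"got {recording.n_channels}")
    partners = _partner_table(spec, labels, layout)
    processed = _apply_chain(recording, spec.chain, valid)
    fs = recording.sample_rate_hz
    wlen = int(round(spec.window_s * fs))
    n_win = processed.n_samples // wlen
    flagged = np.zeros((len(labels), n_win), dtype=bool)
    idx = {lb: i for i, lb in enumerate(labels)}

    for w in range(n_win):
        sl = slice(w * wlen, (w + 1) * wlen)
        if valid is not None:
            mid = w * wlen + wlen // 2
            if not valid[mid]:
                continue
        x = processed.data[:, sl]
        if spec.pair_metric == "pearson_r":
            sd = x.std(axis=1)
            ok = sd > 0
            metric = np.full((len(labels), len(labels)), np.nan)
            if ok.sum() >= 2:
                c = np.corrcoef(x[ok])
                metric[np.ix_(ok, ok)] = c
        else:  # max_abs_difference
            metric = None
        for lb in labels:
            i = idx[lb]
            hits = 0
            n_valid = 0
            for p in partners[lb]:
                j = idx[p]
                if spec.pair_metric == "pearson_r":
                    v = metric[i, j]
                    if not np.isfinite(v):
                        continue  # undefined correlation: excluded
                else:
                    v = float(np.max(np.abs(x[i] - x[j])))
                n_valid += 1
                if (spec.pair_cmp == "lt" and v < spec.pair_threshold) or \
                   (spec.pair_cmp == "gt" and v > spec.pair_threshold):
                    hits += 1
            if n_valid and hits / n_valid > spec.neighbor_fraction:
                flagged[i, w] = True

    dur = recording.duration_s
    rows = []
    for i, lb in enumerate(labels):
        iv = [(w * spec.window_s, (w + 1) * spec.window_s)
              for w in np.flatnonzero(flagged[i])]
        iv = signal_ops.pad_and_merge(iv, spec.padding_s, spec.merge_gap_s, dur)
        rows += [(lb, s, e, spec.name, spec.name) for s, e in iv]
    return EventTable(rows)


class _SkipDetector(RuntimeError):
    """A detector cannot run on this recording (e.g. too few channels)."""


def run_detector_set(recording: Recording, detector_set: DetectorSet,
                     scoring: Scoring | None = None,
                     layout: ElectrodeLayout | None = None) -> dict[str, EventTable]:
    """Run every detector independently; failures warn and are skipped."""
    results: dict[str, EventTable] = {}
    for spec in detector_set:
        try:
            results[spec.name] = run_detector(recording, spec, scoring, layout)
        except _SkipDetector as exc:
            logger.warning("skipping detector: %s", exc)
        except Exception:
            logger.exception("detector %s failed; continuing with the rest",
                             spec.name)
    return results
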