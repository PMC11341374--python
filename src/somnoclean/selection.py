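"""Rejection-aware selection of analysis-ready clean data bouts.

Time covered by the requested sleep stages and by non-rejected grid
segments is split into maximal uninterrupted runs ("bouts"); runs shorter
than a minimum duration are dropped. The result can be returned as trials
(one data block per bout) or pseudocontinuous (blocks concatenated, with a
boundary table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import Recording, Scoring, STAGES


@dataclass
class Bout:
    start_s: float
    end_s: float
    stages: list[str]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BoutList:
    """Disjoint, sorted clean-data bouts plus the output mode used."""

    bouts: list[Bout] = field(default_factory=list)
    output_mode: str = "trials"

    def __len__(self) -> int:
        return len(self.bouts)

    def total_duration(self) -> float:
        return sum(b.duration_s for b in self.bouts)

    def to_frame(self, sample_rate_hz: float | None = None) -> pd.DataFrame:
        rows = []
        for b in self.bouts:
            row = {"start_s": b.start_s, "end_s": b.end_s,
                   "stages": "+".join(b.stages)}
            if sample_rate_hz is not None:
                row["n_samples"] = int(round(b.duration_s * sample_rate_hz))
            rows.append(row)
        cols = ["start_s", "end_s"] + (
            ["n_samples"] if sample_rate_hz is not None else []) + ["stages"]
        return pd.DataFrame(rows, columns=cols)


def select_clean(recording: Recording, rejection: np.ndarray,
                 segment_length_s: float, scoring: Scoring,
                 stages=("W", "N1", "N2", "N3", "R"),
                 min_duration_s: float = 0.0, mode: str = "trials",
                 stage_change_breaks: bool = False,
                 strict_min: bool = False):
    """Extract clean bouts of the requested stages.

    Parameters
    ----------
    rejection : boolean per grid segment (length ceil(duration/segment)).
    stages : stage labels to keep ("ALL" keeps every scored stage).
    min_duration_s : bouts shorter than this are dropped (``>=`` unless
        *strict_min*, then ``>``).
    mode : 'trials' returns one data block per bout; 'pseudocontinuous'
        concatenates the blocks (the bout table holds the boundaries).
    stage_change_breaks : when True, a change between two *requested*
        stages also ends a bout.

    Returns
    -------
    (BoutList, data) where data is a list of (channels x samples) blocks
    for trials mode, or one concatenated matrix for pseudocontinuous.
    """
    if stages == "ALL":
        stages = [s for s in STAGES if s != "unknown"]
    stages = list(stages)
    if not stages:
        raise ValueError("stage set must not be empty")
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages requested: {sorted(bad)}")
    if mode not in ("trials", "pseudocontinuous"):
        raise ValueError(f"unknown mode {mode!r}")

    fs = recording.sample_rate_hz
    n = recording.n_samples
    rejection = np.asarray(rejection, dtype=bool)

    sample_stage = scoring.sample_stages(n, fs, recording.start_time_s)
    keep = np.isin(sample_stage, stages)
    # map each sample to its grid segment; rejected segments are excluded
    seg_of = np.minimum((np.arange(n) / fs // segment_length_s).astype(int),
                        len(rejection) - 1)
    keep &= ~rejection[seg_of]

    # break points: mask edges, plus (optionally) requested-stage changes
    starts, ends = _mask_runs(keep)
    runs: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if stage_change_breaks:
            sub = sample_stage[s:e]
            cuts = np.flatnonzero(sub[1:] != sub[:-1]) + 1
            prev = s
            for c in cuts:
                runs.append((prev, s + int(c)))
                prev = s + int(c)
            runs.append((prev, e))
        else:
            runs.append((int(s), int(e)))

    bouts: list[Bout] = []
    blocks: list[np.ndarray] = []
    for s, e in runs:
        dur = (e - s) / fs
        ok = dur > min_duration_s if strict_min else dur >= min_duration_s
        if not ok or e <= s:
            continue
        covered = list(dict.fromkeys(sample_stage[s:e]))
        bouts.append(Bout(s / fs, e / fs, covered))
        blocks.append(recording.data[:, s:e])

    bout_list = BoutList(bouts, output_mode=mode)
    if mode == "trials":
        return bout_list, blocks
    data = (np.concatenate(blocks, axis=1) if blocks
            else np.empty((recording.n_channels, 0)))
    return bout_list, data


def _mask_runs(mask: np.ndarray):
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask.size and mask[0]:
        starts = np.concatenate([[0], starts])
    if mask.size and mask[-1]:
        ends = np.concatenate([ends, [mask.size]])
    return starts, ends
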