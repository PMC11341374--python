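"""Channel-by-segment artifact grids and the five-step grid algebra.

Event tables are rasterized onto a boolean channels x segments grid
(default segment length 5 s), after which processing proceeds in five
steps: (1) per-detector grids are pooled (logical OR) into the *basic*
grid; (2) *spatial expansion* adds channels surrounded by enough
artifactual neighbors; (3) segments with too many artifactual channels are
marked for *rejection*; (4) *temporal expansion* marks whole channels that
are artifactual in too many non-rejected segments (a bad-channel rule);
(5) the *repair* grid is the union of all artifact grids minus the
rejected segments.

Threshold comparisons for spatial/rejection/temporal use ``>=``; the
per-element rasterization proportion uses a strict ``>`` (so the default
proportion 0 marks any nonzero overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import GLOBAL, EventTable, Scoring

#: Sentinel for a disabled grid-processing step.
OFF = None


@dataclass
class ArtifactGrid:
    """Boolean channels x segments artifact bookkeeping matrix."""

    channel_labels: list[str]
    segment_length_s: float
    duration_s: float
    values: np.ndarray
    origin: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        n_seg = int(np.ceil(self.duration_s / self.segment_length_s))
        if self.values.shape != (len(self.channel_labels), n_seg):
            raise ValueError(
                f"grid shape {self.values.shape} != "
                f"({len(self.channel_labels)}, {n_seg})")

    @property
    def n_segments(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def segment_bounds(self, s: int) -> tuple[float, float]:
        """Time span of segment *s*; the final segment may be partial."""
        start = s * self.segment_length_s
        return start, min(self.duration_s, start + self.segment_length_s)

    def fraction_true(self) -> float:
        return float(self.values.mean()) if self.values.size else 0.0

    def copy_with(self, values: np.ndarray, origin: str) -> "ArtifactGrid":
        return ArtifactGrid(list(self.channel_labels), self.segment_length_s,
                            self.duration_s, values, origin)

    def empty_like(self, origin: str) -> "ArtifactGrid":
        return self.copy_with(np.zeros_like(self.values), origin)


@dataclass
class GridParams:
    """Parameters of grid conversion and the five processing steps.

    ``spatial_threshold`` / ``rejection_threshold`` / ``temporal_threshold``
    are fractions in [0, 1], or ``None`` (OFF, the default) to disable the
    step. OFF differs from 1.0: a fully artifactual segment still rejects
    at threshold 1.0 when the step is enabled.
    """

    segment_length_s: float = 5.0
    element_min_proportion: float = 0.0
    pool_mode: str = "OR"
    pool_subset: list[str] | None = None
    spatial_threshold: float | None = OFF
    rejection_threshold: float | None = OFF
    temporal_threshold: float | None = OFF
    rejection_input: str = "combined"  # "combined" (basic|spatial) or "basic"

    def __post_init__(self) -> None:
        for nm in ("spatial_threshold", "rejection_threshold",
                   "temporal_threshold"):
            v = getattr(self, nm)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{nm} must be in [0, 1] or None")
        if not self.segment_length_s > 0:
            raise ValueError("segment_length_s must be positive")


@dataclass
class GridSet:
    """All grids produced by one cleaning run (shapes identical)."""

    detector_grids: dict[str, ArtifactGrid]
    basic: ArtifactGrid
    spatial: ArtifactGrid
    rejection: np.ndarray  # boolean per segment
    temporal: ArtifactGrid
    repair: ArtifactGrid
    params: GridParams = field(default_factory=GridParams)

    def __post_init__(self) -> None:
        shape = self.basic.values.shape
        for g in (self.spatial, self.temporal, self.repair,
                  *self.detector_grids.values()):
            if g.values.shape != shape:
                raise ValueError("all grids in a GridSet must share shape")
        self.rejection = np.asarray(self.rejection, dtype=bool)
        if self.rejection.shape != (shape[1],):
            raise ValueError("rejection vector length must equal n_segments")
        if np.any(self.repair.values & self.rejection[None, :]):
            raise AssertionError("repair grid overlaps rejected segments")


# ---------------------------------------------------------------------------
# Grid construction and algebra
# ---------------------------------------------------------------------------

def events_to_grid(events: EventTable, channels: list[str], duration_s: float,
                   params: GridParams | None = None,
                   origin: str = "") -> ArtifactGrid:
    """Rasterize an event table onto a channels x segments boolean grid.

    Element (c, s) is true iff the summed overlap of channel c's events
    with segment s strictly exceeds ``element_min_proportion`` times the
    segment's actual duration (the final partial segment uses its true,
    shorter duration). Events on the GLOBAL channel mark every channel.
    """
    params = params or GridParams()
    seg = params.segment_length_s
    n_seg = int(np.ceil(duration_s / seg))
    overlap = np.zeros((len(channels), n_seg))
    idx = {lb: i for i, lb in enumerate(channels)}
    for row in events.df.itertuples(index=False):
        if row.channel == GLOBAL:
            targets = range(len(channels))
        elif row.channel in idx:
            targets = [idx[row.channel]]
        else:
            raise ValueError(f"event channel {row.channel!r} not in grid "
                             "channel list")
        s, e = max(0.0, row.start_s), min(duration_s, row.end_s)
        if e <= s:
            continue
        first, last = int(s // seg), int(np.ceil(e / seg)) - 1
        for k in range(first, min(last, n_seg - 1) + 1):
            ks, ke = k * seg, min((k + 1) * seg, duration_s)
            ov = min(e, ke) - max(s, ks)
            if ov > 0:
                for t in targets:
                    overlap[t, k] += ov
    seg_dur = np.minimum(seg, duration_s - np.arange(n_seg) * seg)
    values = overlap > params.element_min_proportion * seg_dur[None, :]
    return ArtifactGrid(list(channels), seg, duration_s, values, origin)


def pool_grids(grid_map: dict[str, ArtifactGrid], mode: str = "OR",
               subset: list[str] | None = None) -> ArtifactGrid:
    """Element-wise OR over the selected detector grids."""
    if mode != "OR":
        raise ValueError(f"unknown pool mode {mode!r}")
    names = list(grid_map) if subset is None else list(subset)
    missing = [n for n in names if n not in grid_map]
    if missing:
        raise KeyError(f"pool subset names not present: {missing}")
    if not names:
        raise ValueError("cannot pool an empty set of grids")
    first = grid_map[names[0]]
    out = np.zeros_like(first.values)
    for n in names:
        out |= grid_map[n].values
    return first.copy_with(out, origin="basic")


def spatial_expand(basic: ArtifactGrid, neighbor_map: dict[str, set[str]],
                   threshold: float | None) -> ArtifactGrid:
    """Additions grid: clean channels surrounded by artifactual neighbors.

    At each segment, a channel false in *basic* becomes true iff the
    fraction of its neighbors that are artifactual is >= *threshold*.
    Channels already true in basic are false here (the grid holds only the
    additions); channels with no neighbors are never added. Single pass.
    """
    out = np.zeros_like(basic.values)
    if threshold is OFF:
        return basic.copy_with(out, origin="spatial")
    if not neighbor_map or not any(neighbor_map.values()):
        raise ValueError("spatial expansion enabled but neighbor map is empty")
    idx = {lb: i for i, lb in enumerate(basic.channel_labels)}
    for lb, i in idx.items():
        nbrs = [idx[n] for n in neighbor_map.get(lb, ()) if n in idx]
        if not nbrs:
            continue
        frac = basic.values[nbrs].mean(axis=0)
        out[i] = (~basic.values[i]) & (frac >= threshold)
    return basic.copy_with(out, origin="spatial")


def reject_segments(combined: ArtifactGrid, threshold: float | None) -> np.ndarray:
    """Boolean per-segment rejection vector.

    A segment is rejected iff the fraction of artifactual channels
    (over all channels of *combined*) is >= *threshold*; OFF rejects none.
    """
    if threshold is OFF:
        return np.zeros(combined.n_segments, dtype=bool)
    frac = combined.values.mean(axis=0)
    return frac >= threshold


def temporal_expand(combined: ArtifactGrid, rejection: np.ndarray,
                    threshold: float | None) -> ArtifactGrid:
    """Additions grid: whole-channel (bad channel) expansion.

    Per channel, the artifactual fraction is computed over NON-rejected
    segments only; channels at/above *threshold* become true at ALL
    segments (minus elements already true in *combined*).
    """
    out = np.zeros_like(combined.values)
    if threshold is OFF:
        return combined.copy_with(out, origin="temporal")
    keep = ~np.asarray(rejection, dtype=bool)
    if keep.sum() == 0:
        return combined.copy_with(out, origin="temporal")
    frac = combined.values[:, keep].mean(axis=1)
    bad = frac >= threshold
    out[bad, :] = True
    out &= ~combined.values
    return combined.copy_with(out, origin="temporal")


def compose_repair(basic: ArtifactGrid, spatial: ArtifactGrid,
                   temporal: ArtifactGrid, rejection: np.ndarray) -> ArtifactGrid:
    """repair = (basic | spatial | temporal) & ~rejection (per segment)."""
    vals = (basic.values | spatial.values | temporal.values) \
        & ~np.asarray(rejection, dtype=bool)[None, :]
    return basic.copy_with(vals, origin="repair")


def build_grid_set(event_tables: dict[str, EventTable], channels: list[str],
                   duration_s: float, params: GridParams | None = None,
                   neighbor_map: dict[str, set[str]] | None = None) -> GridSet:
    """Run the full five-step grid pipeline from per-detector event tables."""
    params = params or GridParams()
    det = {name: events_to_grid(tab, channels, duration_s, params, origin=name)
           for name, tab in event_tables.items()}
    if det:
        basic = pool_grids(det, params.pool_mode, params.pool_subset)
    else:
        n_seg = int(np.ceil(duration_s / params.segment_length_s))
        basic = ArtifactGrid(list(channels), params.segment_length_s,
                             duration_s,
                             np.zeros((len(channels), n_seg), dtype=bool),
                             origin="basic")
    spatial = spatial_expand(basic, neighbor_map or {}, params.spatial_threshold)
    combined = basic.copy_with(basic.values | spatial.values, origin="combined")
    rej_input = basic if params.rejection_input == "basic" else combined
    rejection = reject_segments(rej_input, params.rejection_threshold)
    temporal = temporal_expand(combined, rejection, params.temporal_threshold)
    repair = compose_repair(basic, spatial, temporal, rejection)
    return GridSet(det, basic, spatial, rejection, temporal, repair, params)


# ---------------------------------------------------------------------------
# Summaries and conversion back to events
# ---------------------------------------------------------------------------

def _segment_stages(grid: ArtifactGrid, scoring: Scoring | None) -> np.ndarray:
    """Stage of each segment = stage of the epoch containing its midpoint."""
    mids = (np.arange(grid.n_segments) + 0.5) * grid.segment_length_s
    mids = np.minimum(mids, grid.duration_s - 1e-9)
    if scoring is None:
        return np.full(grid.n_segments, "unknown", dtype=object)
    return np.array([scoring.stage_at(t) for t in mids], dtype=object)


def summarize(grid_set: GridSet, scoring: Scoring | None = None) -> dict:
    """Percentages of data marked per detector, for repair and rejection.

    Channel-segment percentages for detector/basic/repair grids; segment
    percentages for rejection; each overall and broken down by sleep stage
    (a segment's stage is the stage of the epoch containing its midpoint).
    """
    any_grid = grid_set.basic
    stages = _segment_stages(any_grid, scoring)
    present = list(dict.fromkeys(stages))

    def pct_elements(values: np.ndarray, mask=None) -> float:
        v = values if mask is None else values[:, mask]
        return float(v.mean() * 100.0) if v.size else 0.0

    def pct_segments(vec: np.ndarray, mask=None) -> float:
        v = vec if mask is None else vec[mask]
        return float(v.mean() * 100.0) if v.size else 0.0

    out: dict = {
        "segment_length_s": any_grid.segment_length_s,
        "n_channels": any_grid.n_channels,
        "n_segments": any_grid.n_segments,
        "detectors": {},
        "overall": {
            "basic_pct": pct_elements(grid_set.basic.values),
            "repair_pct": pct_elements(grid_set.repair.values),
            "rejection_pct": pct_segments(grid_set.rejection),
        },
        "by_stage": {},
    }
    for name, g in grid_set.detector_grids.items():
        out["detectors"][name] = pct_elements(g.values)
    for st in present:
        m = stages == st
        out["by_stage"][st] = {
            "n_segments": int(m.sum()),
            "basic_pct": pct_elements(grid_set.basic.values, m),
            "repair_pct": pct_elements(grid_set.repair.values, m),
            "rejection_pct": pct_segments(grid_set.rejection, m),
            "detectors": {name: pct_elements(g.values, m)
                          for name, g in grid_set.detector_grids.items()},
        }
    return out


def grid_to_events(grid: ArtifactGrid, event_type: str | None = None,
                   detector: str | None = None) -> EventTable:
    """Per channel, one event per maximal run of true segments."""
    event_type = event_type or (grid.origin or "artifact")
    detector = detector or event_type
    rows = []
    for i, lb in enumerate(grid.channel_labels):
        v = grid.values[i]
        d = np.diff(v.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if v.size and v[0]:
            starts = [0] + starts
        if v.size and v[-1]:
            ends = ends + [v.size]
        for s, e in zip(starts, ends):
            t0 = s * grid.segment_length_s
            t1 = min(e * grid.segment_length_s, grid.duration_s)
            rows.append((lb, t0, t1, event_type, detector))
    return EventTable(rows)
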