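"""Segment-wise channel repair.

Artifactual channel-segment elements (the *repair grid*) are reconstructed
from the clean channels of the same segment via weighted spherical-spline
interpolation (Perrin-style), or replaced with a fixed value (zero / NaN).

The spline kernel on the unit sphere is

    g(cos t) = (1 / 4 pi) * sum_{n>=1} (2n+1) / (n (n+1))^m  P_n(cos t),

truncated at ``n_legendre_terms`` terms, with P_n the Legendre polynomials
and m the spline order (stiffness). Interpolation solves the regularized
system on the good channels,

    [ G_gg + lambda I   1 ] [ c  ]   [ z ]
    [ 1^T               0 ] [ c0 ] = [ 0 ],

per time sample, and evaluates ``c0 + G_bg c`` at the bad electrode
positions. The constant term reproduces spatially constant fields exactly.

Discontinuities at segment boundaries are smoothed with a linear crossfade
(default 0.1 s) centered on each boundary where a channel's repaired
status (or repaired version) changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

from .grids import ArtifactGrid
from .model_io import ElectrodeLayout, Recording


@dataclass
class SplineParams:
    """Spherical-spline constants.

    order_m : spline stiffness (>= 2); 4 is the common EEG default.
    n_legendre_terms : series truncation (>= order_m).
    regularization_lambda : ridge term added to G_gg.
    """

    order_m: int = 4
    n_legendre_terms: int = 20
    regularization_lambda: float = 1e-5

    def __post_init__(self) -> None:
        if self.order_m < 2:
            raise ValueError("order_m must be >= 2")
        if self.n_legendre_terms < self.order_m:
            raise ValueError("n_legendre_terms must be >= order_m")
        if self.regularization_lambda < 0:
            raise ValueError("regularization_lambda must be nonnegative")


class NotRepairable(RuntimeError):
    """Too few clean channels to interpolate from (< 3)."""


def _unit(positions: np.ndarray) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm electrode position cannot be projected "
                         "to the unit sphere")
    return pos / norms


def spline_g_matrix(positions_a: np.ndarray, positions_b: np.ndarray,
                    params: SplineParams | None = None) -> np.ndarray:
    """Kernel matrix g(cos angle) between two electrode sets.

    Positions are projected to the unit sphere; the series is evaluated
    with Clenshaw recurrence (``numpy.polynomial.legendre.legval``).
    Symmetric when the two sets coincide; coincident electrodes (cos = 1)
    are allowed.
    """
    params = params or SplineParams()
    a, b = _unit(positions_a), _unit(positions_b)
    cosang = np.clip(a @ b.T, -1.0, 1.0)
    n = np.arange(1, params.n_legendre_terms + 1, dtype=float)
    coef = np.zeros(params.n_legendre_terms + 1)
    coef[1:] = (2 * n + 1) / (n * (n + 1)) ** params.order_m
    return npleg.legval(cosang, coef) / (4 * np.pi)


def center_and_normalize(layout: ElectrodeLayout) -> np.ndarray:
    """Electrode positions centered on their centroid, unit-normalized."""
    pos = layout.positions - layout.positions.mean(axis=0)
    return _unit(pos)


def interpolate_channels(segment_data: np.ndarray, good_idx, bad_idx,
                         positions: np.ndarray,
                         params: SplineParams | None = None) -> np.ndarray:
    """Return *segment_data* with the bad rows replaced by spline estimates.

    Parameters
    ----------
    segment_data : ndarray (n_channels, n_times)
    good_idx, bad_idx : disjoint index sequences into the channel axis.
    positions : (n_channels, 3) electrode positions (any origin/scale;
        centered and projected internally).

    Good rows are returned bit-identical. Raises :class:`NotRepairable`
    when fewer than 3 good channels are available.
    """
    params = params or SplineParams()
    good_idx = np.asarray(good_idx, dtype=int)
    bad_idx = np.asarray(bad_idx, dtype=int)
    if np.intersect1d(good_idx, bad_idx).size:
        raise ValueError("good and bad channel sets must be disjoint")
    if good_idx.size < 3:
        raise NotRepairable(f"only {good_idx.size} clean channels available")
    if bad_idx.size == 0:
        return segment_data.copy()

    pos = np.asarray(positions, dtype=float)
    pos = pos - pos.mean(axis=0)
    pg, pb = pos[good_idx], pos[bad_idx]
    g_gg = spline_g_matrix(pg, pg, params)
    g_bg = spline_g_matrix(pb, pg, params)

    ng = good_idx.size
    lhs = np.zeros((ng + 1, ng + 1))
    lhs[:ng, :ng] = g_gg + params.regularization_lambda * np.eye(ng)
    lhs[:ng, ng] = 1.0
    lhs[ng, :ng] = 1.0
    rhs = np.zeros((ng + 1, segment_data.shape[1]))
    rhs[:ng] = segment_data[good_idx]
    sol = np.linalg.solve(lhs, rhs)
    c, c0 = sol[:ng], sol[ng]

    out = segment_data.copy()
    out[bad_idx] = g_bg @ c + c0[None, :]
    return out


# ---------------------------------------------------------------------------
# Grid-driven repair
# ---------------------------------------------------------------------------

def repair_by_grid(recording: Recording, repair_grid: ArtifactGrid,
                   layout: ElectrodeLayout | None = None,
                   method: str = "spline", crossfade_s: float = 0.1,
                   params: SplineParams | None = None):
    """Repair the recording at grid-true channel-segment elements.

    method='spline'
        Per segment, flagged channels are spherical-spline interpolated
        from the unflagged channels of that segment. Each segment's
        repaired signal is extended by ``crossfade_s / 2`` beyond its
        bounds and blended with the surroundings by a linear (trapezoidal)
        overlap-add crossfade centered on every status boundary, including
        boundaries between two repaired segments with different clean
        sets. Segments with fewer than 3 clean channels are left
        unmodified and reported.
    method='nan' / method='zero'
        Flagged sample spans are set to NaN / 0, no crossfade.

    Returns
    -------
    (repaired : Recording, residual : list of (channel_label, segment))
        *residual* lists the channel-segment elements that could not be
        repaired.
    """
    if repair_grid.values.shape[0] != recording.n_channels:
        raise ValueError("grid channel count does not match recording")
    if list(repair_grid.channel_labels) != list(recording.channel_labels):
        raise ValueError("grid channel labels do not match recording")
    fs = recording.sample_rate_hz
    n = recording.n_samples
    residual: list[tuple[str, int]] = []

    if method in ("nan", "zero"):
        fill = np.nan if method == "nan" else 0.0
        out = recording.data.copy()
        for s in range(repair_grid.n_segments):
            t0, t1 = repair_grid.segment_bounds(s)
            i0, i1 = int(round(t0 * fs)), min(n, int(round(t1 * fs)))
            bad = np.flatnonzero(repair_grid.values[:, s])
            out[np.ix_(bad, range(i0, i1))] = fill
        return Recording(list(recording.channel_labels), fs, out,
                         recording.start_time_s), residual
    if method != "spline":
        raise ValueError(f"unknown repair method {method!r}")
    if layout is None:
        raise ValueError("spline repair requires an electrode layout")

    positions = np.array([layout.position_of(lb)
                          for lb in recording.channel_labels])
    half = crossfade_s / 2.0
    orig = recording.data
    acc = np.zeros_like(orig)          # weighted sum of repaired versions
    wsum = np.zeros_like(orig)         # summed repair weights, per sample

    all_idx = np.arange(recording.n_channels)
    for s in range(repair_grid.n_segments):
        bad = np.flatnonzero(repair_grid.values[:, s])
        if bad.size == 0:
            continue
        good = np.setdiff1d(all_idx, bad)
        t0, t1 = repair_grid.segment_bounds(s)
        # extend by half a crossfade so the blend is centered on boundaries
        i0 = max(0, int(round((t0 - half) * fs)))
        i1 = min(n, int(round((t1 + half) * fs)))
        if good.size < 3:
            residual += [(recording.channel_labels[b], s) for b in bad]
            continue
        seg = orig[:, i0:i1]
        rep = interpolate_channels(seg, good, bad, positions, params)
        w = _trapezoid_weights(i0, i1, t0, t1, half, fs, n)
        acc[bad, i0:i1] += rep[bad] * w[None, :]
        wsum[bad, i0:i1] += w[None, :]

    # where repair weight sums to w < 1 the original keeps weight 1 - w;
    # at boundaries between two repaired segments the ramps sum to 1 and
    # the two repaired versions blend into each other
    weff = np.minimum(wsum, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_rep = np.where(wsum > 0, acc / np.where(wsum > 0, wsum, 1.0), 0.0)
    out = orig * (1.0 - weff) + mean_rep * weff
    out[wsum == 0] = orig[wsum == 0]  # bit-identical where untouched
    return Recording(list(recording.channel_labels), fs, out,
                     recording.start_time_s), residual


def _trapezoid_weights(i0: int, i1: int, t0: float, t1: float,
                       half: float, fs: float, n: int) -> np.ndarray:
    """Per-sample blend weight for one repaired segment.

    1 inside the segment core, ramping linearly 0 -> 1 over the crossfade
    window centered on each segment boundary; boundaries clamped at the
    recording edges get full weight.
    """
    t = (np.arange(i0, i1) + 0.5) / fs
    w = np.ones(i1 - i0)
    if half > 0:
        up = (t - (t0 - half)) / (2 * half)
        down = ((t1 + half) - t) / (2 * half)
        if i0 > 0:  # no ramp at the recording start
            w = np.minimum(w, np.clip(up, 0.0, 1.0))
        if i1 < n:  # no ramp at the recording end
            w = np.minimum(w, np.clip(down, 0.0, 1.0))
    return w
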