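"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with naive per-element loops, kept
separate from the library's vectorized implementations.
"""

import numpy as np


def rle_intervals(mask, fs, min_dur):
    """Per-sample scan: maximal True runs as half-open [start, end) seconds."""
    out, start = [], None
    for i, m in enumerate(list(mask) + [False]):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if min_dur == 0 or (i - start) / fs >= min_dur:
                out.append((start / fs, i / fs))
            start = None
    return out


def pad_merge_naive(intervals, pad, gap, duration):
    """Quadratic pad-then-merge on interval lists."""
    iv = sorted((max(0.0, s - pad), min(duration, e + pad))
                for s, e in intervals)
    changed = True
    while changed:
        changed = False
        for i in range(len(iv) - 1):
            if iv[i + 1][0] - iv[i][1] < gap:
                iv[i] = (iv[i][0], max(iv[i][1], iv[i + 1][1]))
                del iv[i + 1]
                changed = True
                break
    return [t for t in iv if t[1] > t[0]]


def grid_steps_naive(basic, nbrs, thr_spatial, thr_reject, thr_temporal):
    """Loop re-implementation of the five grid-processing steps.

    basic : boolean (n_channels, n_segments); nbrs : list of neighbor index
    lists per channel; thresholds: fraction or None (step disabled).
    Returns (spatial, rejection, temporal, repair).
    """
    n_ch, n_seg = basic.shape
    spatial = np.zeros_like(basic)
    if thr_spatial is not None:
        for s in range(n_seg):
            for c in range(n_ch):
                if basic[c, s] or not nbrs[c]:
                    continue
                frac = sum(bool(basic[m, s]) for m in nbrs[c]) / len(nbrs[c])
                if frac >= thr_spatial:
                    spatial[c, s] = True
    combined = basic | spatial
    rejection = np.zeros(n_seg, dtype=bool)
    if thr_reject is not None:
        for s in range(n_seg):
            if sum(bool(combined[c, s]) for c in range(n_ch)) / n_ch >= thr_reject:
                rejection[s] = True
    temporal = np.zeros_like(basic)
    if thr_temporal is not None:
        keep = [s for s in range(n_seg) if not rejection[s]]
        for c in range(n_ch):
            if keep and sum(bool(combined[c, s]) for s in keep) / len(keep) \
                    >= thr_temporal:
                for s in range(n_seg):
                    if not combined[c, s]:
                        temporal[c, s] = True
    repair = (basic | spatial | temporal) & ~rejection[None, :]
    return spatial, rejection, temporal, repair


def legendre_series(cosang, m, n_terms):
    """Term-by-term spline kernel via the three-term Legendre recursion."""
    x = np.asarray(cosang, dtype=float)
    p_prev = np.ones_like(x)
    p_cur = x.copy()
    total = np.zeros_like(x)
    for n in range(1, n_terms + 1):
        total += (2 * n + 1) / (n * (n + 1)) ** m * p_cur
        p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        p_prev, p_cur = p_cur, p_next
    return total / (4 * np.pi)
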