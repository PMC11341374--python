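"""Low-level per-channel signal primitives shared by all artifact detectors.

Every operation maps a :class:`~somnoclean.model_io.Recording` to a new
recording of identical shape and is independent across channels; interval
helpers convert boolean sample criteria into half-open time intervals.
"""

from __future__ import annotations

import numpy as np
import scipy.fft
import scipy.signal

from .model_io import Recording

#: One channel's artifact intervals: sorted, disjoint, half-open, seconds.
IntervalList = list[tuple[float, float]]


def _butter_sos(low_hz, high_hz, fs, btype):
    nyq = fs / 2.0
    for edge, name in ((low_hz, "low"), (high_hz, "high")):
        if edge is not None and edge >= nyq:
            raise ValueError(
                f"{name} band edge {edge} Hz is at or above Nyquist ({nyq} Hz)")
    if btype == "bandpass":
        wn = [low_hz / nyq, high_hz / nyq]
    else:
        wn = low_hz / nyq
    return scipy.signal.butter(4, wn, btype=btype, output="sos")


def bandpass(recording: Recording, low_hz: float, high_hz: float) -> Recording:
    """Zero-phase (forward-backward) 4th-order Butterworth bandpass."""
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    sos = _butter_sos(low_hz, high_hz, recording.sample_rate_hz, "bandpass")
    out = scipy.signal.sosfiltfilt(sos, recording.data, axis=1)
    return Recording(list(recording.channel_labels), recording.sample_rate_hz,
                     out, recording.start_time_s)


def highpass(recording: Recording, low_hz: float) -> Recording:
    """Zero-phase 4th-order Butterworth highpass."""
    if not low_hz > 0:
        raise ValueError("highpass edge must be > 0")
    sos = _butter_sos(low_hz, None, recording.sample_rate_hz, "highpass")
    out = scipy.signal.sosfiltfilt(sos, recording.data, axis=1)
    return Recording(list(recording.channel_labels), recording.sample_rate_hz,
                     out, recording.start_time_s)


def envelope(recording: Recording, smooth_s: float = 0.2) -> Recording:
    """Amplitude envelope: |analytic signal|, then moving-average smoothed.

    ``smooth_s=0`` disables smoothing. The moving average uses a centered
    window of ``round(smooth_s * fs)`` samples with shrinking edges.
    """
    n = recording.n_samples
    nfft = scipy.fft.next_fast_len(n)
    analytic = scipy.signal.hilbert(recording.data, N=nfft, axis=1)[:, :n]
    env = np.abs(analytic)
    if smooth_s > 0:
        w = max(1, int(round(smooth_s * recording.sample_rate_hz)))
        env = _moving_average(env, w)
    return Recording(list(recording.channel_labels), recording.sample_rate_hz,
                     env, recording.start_time_s)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average along axis 1; edge windows shrink."""
    if w <= 1:
        return x
    csum = np.cumsum(np.pad(x, ((0, 0), (1, 0))), axis=1, dtype=np.float64)
    n = x.shape[1]
    idx = np.arange(n)
    left = np.maximum(0, idx - (w - 1) // 2)
    right = np.minimum(n, idx + w // 2 + 1)
    return (csum[:, right] - csum[:, left]) / (right - left)


def zscore_per_channel(recording: Recording, robust: bool = False) -> Recording:
    """Per-channel standardization over all samples.

    Default: subtract mean, divide by population SD. ``robust=True`` uses
    median and 1.4826*MAD instead. Channels with zero spread become all
    zeros (no detections possible downstream).
    """
    x = recording.data
    if robust:
        center = np.median(x, axis=1, keepdims=True)
        spread = 1.4826 * np.median(np.abs(x - center), axis=1, keepdims=True)
    else:
        center = x.mean(axis=1, keepdims=True)
        spread = x.std(axis=1, keepdims=True)
    out = np.zeros_like(x)
    ok = spread[:, 0] > 0
    out[ok] = (x[ok] - center[ok]) / spread[ok]
    return Recording(list(recording.channel_labels), recording.sample_rate_hz,
                     out, recording.start_time_s)


def rectify(recording: Recording) -> Recording:
    """Absolute value, sample-wise."""
    return Recording(list(recording.channel_labels), recording.sample_rate_hz,
                     np.abs(recording.data), recording.start_time_s)


def gradient_abs(recording: Recording) -> Recording:
    """|x[i+1] - x[i]| per sample (uV per sample); last value repeated."""
    d = np.abs(np.diff(recording.data, axis=1))
    if d.shape[1]:
        d = np.concatenate([d, d[:, -1:]], axis=1)
    else:
        d = np.zeros_like(recording.data)
    return Recording(list(recording.channel_labels), recording.sample_rate_hz,
                     d, recording.start_time_s)


def median_filter(recording: Recording, order: int) -> Recording:
    """Running median of odd *order*; edge windows shrink symmetrically."""
    if order < 1 or order % 2 == 0:
        raise ValueError("median filter order must be odd and positive")
    if order == 1:
        return recording.copy()
    x = recording.data
    out = scipy.signal.medfilt(x, kernel_size=(1, order))
    # medfilt zero-pads; recompute the edge samples with shrinking windows
    h = order // 2
    n = x.shape[1]
    for i in range(min(h, n)):
        out[:, i] = np.median(x[:, :min(n, i + h + 1)], axis=1)
        j = n - 1 - i
        if j >= 0:
            out[:, j] = np.median(x[:, max(0, j - h):], axis=1)
    return Recording(list(recording.channel_labels), recording.sample_rate_hz,
                     out, recording.start_time_s)


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def threshold_intervals(signal: np.ndarray, fs: float, cmp: str,
                        threshold: float, min_duration_s: float = 0.0,
                        valid: np.ndarray | None = None) -> IntervalList:
    """Half-open time intervals where one channel satisfies a comparison.

    Maximal runs of samples with ``signal > threshold`` (``cmp='gt'``) or
    ``signal < threshold`` (``cmp='lt'``) are converted to seconds (sample
    ``i`` covering ``[i/fs, (i+1)/fs)``); runs shorter than
    *min_duration_s* are dropped. *valid*, when given, is a boolean mask of
    samples eligible for detection (others never satisfy the criterion).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if cmp == "gt":
        mask = signal > threshold
    elif cmp == "lt":
        mask = signal < threshold
    else:
        raise ValueError(f"cmp must be 'gt' or 'lt', got {cmp!r}")
    if valid is not None:
        mask = mask & valid
    starts, ends = _runs(mask)
    out: IntervalList = []
    for s, e in zip(starts, ends):
        if (e - s) / fs >= min_duration_s or min_duration_s == 0:
            out.append((s / fs, e / fs))
    return out


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end sample indices (half-open) of True runs in a 1-D mask."""
    m = np.asarray(mask, dtype=bool)
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m.size and m[0]:
        starts = np.concatenate([[0], starts])
    if m.size and m[-1]:
        ends = np.concatenate([ends, [m.size]])
    return starts, ends


def pad_and_merge(intervals: IntervalList, padding_s: float, merge_gap_s: float,
                  recording_duration_s: float) -> IntervalList:
    """Pad intervals on both sides, clip to the recording, merge close ones.

    Each interval is extended by *padding_s* on both sides and clipped to
    ``[0, recording_duration_s]``; intervals whose gap is strictly smaller
    than *merge_gap_s* (or that overlap) are then merged. Output is sorted
    and disjoint.
    """
    if padding_s < 0 or merge_gap_s < 0:
        raise ValueError("padding and merge gap must be nonnegative")
    if not intervals:
        return []
    padded = sorted((max(0.0, s - padding_s),
                     min(recording_duration_s, e + padding_s))
                    for s, e in intervals)
    out: IntervalList = []
    cur_s, cur_e = padded[0]
    for s, e in padded[1:]:
        if s - cur_e < merge_gap_s:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return [(s, e) for s, e in out if e > s]
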