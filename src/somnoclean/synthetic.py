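"""Seedable synthetic sleep-EEG generator with ground-truth artifacts.

The generator emulates the statistical features the artifact detectors and
grid pipeline react to — not physiologically realistic EEG. It produces:

* spatially correlated 1/f background noise (independent pink sources
  mixed through a distance-decaying kernel, per-channel RMS normalized),
* stage-locked oscillations (slow waves in N3, spindle bursts in N2,
  alpha in W) coherent across channels,
* injected artifacts of each default detector's target class, with a
  ground-truth event table.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .model_io import ElectrodeLayout, EventTable, Recording, Scoring

#: default detector name -> injected artifact class it targets
DETECTOR_TARGETS = {
    "highamp": "highamp",
    "lowamp": "lowamp",
    "lowfreq": "lowfreq",
    "highfreq": "highfreq",
    "jump": "jump",
    "flatline": "flatline",
    "deviant": "deviant",
    "similar": "bridged",
    "similar2": "common_ref",
}

ARTIFACT_TYPES = tuple(DETECTOR_TARGETS.values())

#: default severity per artifact class (units depend on the class)
DEFAULT_SEVERITY = {
    "highamp": 700.0,     # burst amplitude, uV
    "lowamp": 3.0,        # max residual amplitude, uV
    "lowfreq": 400.0,     # drift amplitude, uV
    "highfreq": 60.0,     # burst RMS, uV
    "jump": 250.0,        # step offset, uV
    "flatline": 0.0,      # (no free parameter: signal held constant)
    "deviant": 1.0,       # replacement RMS as a fraction of the original
    "bridged": 0.0,       # (copy is exact)
    "common_ref": 40.0,   # common source RMS, uV
}


@dataclass
class ArtifactSpec:
    """One planned injection: type, target channel(s), span, severity."""

    type: str
    channels: list[str]
    start_s: float
    duration_s: float
    severity: float | None = None

    def __post_init__(self) -> None:
        if self.type not in ARTIFACT_TYPES:
            raise ValueError(f"unknown artifact type {self.type!r}")
        if self.duration_s <= 0:
            raise ValueError("artifact duration must be positive")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic recording."""

    n_channels: int = 16
    sample_rate_hz: float = 250.0
    duration_s: float = 600.0
    #: hypnogram as (stage, n_epochs) blocks; None derives proportional
    #: blocks (10% W, 10% N1, 30% N2, 30% N3, 20% R) filling the recording
    hypnogram: list | None = None
    epoch_length_s: float = 30.0
    background_alpha: float = 1.0
    background_rms_uv: float = 20.0
    #: per-stage (freq_hz, amplitude_uv); spindles/alpha are burst-gated
    oscillations: dict = field(default_factory=lambda: {
        "N3": (0.75, 50.0), "N2": (13.0, 20.0), "W": (10.0, 15.0)})
    artifacts: list = None  # None -> default_artifact_plan(...)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hypnogram is None:
            self.hypnogram = _proportional_hypnogram(
                self.duration_s, self.epoch_length_s)
        scored = sum(n for _, n in self.hypnogram) * self.epoch_length_s
        if scored > self.duration_s + 1e-9:
            raise ValueError("hypnogram longer than recording")
        if self.artifacts is None:
            self.artifacts = default_artifact_plan(self.n_channels,
                                                   self.duration_s)
        labels = set(channel_labels(self.n_channels))
        for a in self.artifacts:
            if a.start_s < 0 or a.start_s + a.duration_s > self.duration_s:
                raise ValueError(f"artifact {a} outside the recording")
            for ch in a.channels:
                if ch != "ALL" and ch not in labels:
                    raise ValueError(f"artifact channel {ch!r} invalid")


def channel_labels(n: int) -> list[str]:
    return [f"E{i + 1:02d}" for i in range(n)]


def _proportional_hypnogram(duration_s: float, epoch_length_s: float) -> list:
    """Stage blocks W/N1/N2/N3/R at 10/10/30/30/20% of the scored epochs."""
    n = int(duration_s // epoch_length_s)
    if n < 5:
        return [("N2", max(1, n))]
    counts = {"W": round(0.1 * n), "N1": round(0.1 * n),
              "N2": round(0.3 * n), "N3": round(0.3 * n)}
    counts["R"] = n - sum(counts.values())
    return [(st, c) for st, c in counts.items() if c > 0]


def gen_layout(n_channels: int) -> ElectrodeLayout:
    """Quasi-uniform unit-sphere electrodes on the upper hemisphere.

    Fibonacci lattice over z in (0, 1]; deterministic in n.
    """
    i = np.arange(n_channels)
    z = 1.0 - i / n_channels  # (0, 1], upper hemisphere
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z ** 2))
    pos = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return ElectrodeLayout(channel_labels(n_channels), pos)


def default_artifact_plan(n_channels: int = 16,
                          duration_s: float = 600.0) -> list[ArtifactSpec]:
    """The stock 40-event injection schedule (16 channels, 10 min).

    Classes are placed on mostly disjoint channels, and window-based
    classes (deviant, bridged, common_ref) are aligned to the pairwise
    detectors' window boundaries. For other geometries the schedule is
    rescaled in time and wrapped over the available channels.
    """
    lb = channel_labels(n_channels)

    def ch(i):
        return [lb[i % n_channels]]

    plan = [
        # highamp: 2 s bursts
        *[ArtifactSpec("highamp", ch(0), t, 2.0) for t in (35, 155, 275, 395)],
        *[ArtifactSpec("highamp", ch(1), t, 2.0) for t in (95, 215, 335, 575)],
        # lowamp: 40 s attenuations
        ArtifactSpec("lowamp", ch(2), 60.0, 40.0),
        ArtifactSpec("lowamp", ch(2), 400.0, 40.0),
        # lowfreq: 5 s drift excursions (one per channel: z-scoring caps
        # the attainable z at ~sqrt(1/f) for event fraction f)
        ArtifactSpec("lowfreq", ch(3), 130.0, 5.0),
        ArtifactSpec("lowfreq", ch(4), 260.0, 5.0),
        ArtifactSpec("lowfreq", ch(13), 355.0, 5.0),
        ArtifactSpec("lowfreq", ch(14), 545.0, 5.0),
        # highfreq: 4 s muscle-like bursts
        *[ArtifactSpec("highfreq", ch(5), t, 4.0) for t in (50, 230, 370)],
        *[ArtifactSpec("highfreq", ch(6), t, 4.0) for t in (140, 310, 520)],
        # jump: 0.6 s rectangular offsets (a step up and back down)
        *[ArtifactSpec("jump", ch(7), t, 0.6) for t in (70, 190, 330, 450)],
        *[ArtifactSpec("jump", ch(8), t, 0.6) for t in (110, 250, 430, 560)],
        # flatline: 3 s holds
        *[ArtifactSpec("flatline", ch(9), t, 3.0) for t in (45, 165, 285, 405)],
        *[ArtifactSpec("flatline", ch(10), t, 3.0) for t in (85, 205, 325, 525)],
        # deviant: replace with independent noise, 30 s-window aligned
        ArtifactSpec("deviant", ch(11), 120.0, 90.0),
        ArtifactSpec("deviant", ch(11), 390.0, 60.0),
        # bridged: copy the nearest neighbor, window aligned
        ArtifactSpec("bridged", ch(12), 240.0, 60.0),
        # common-reference failure: one high-frequency source everywhere
        ArtifactSpec("common_ref", ["ALL"], 480.0, 30.0),
    ]
    if duration_s != 600.0:
        f = duration_s / 600.0
        plan = [replace(a, start_s=a.start_s * f, duration_s=a.duration_s * f)
                for a in plan]
    return plan


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n_sources: int, n_samples: int,
                alpha: float, fs: float) -> np.ndarray:
    """Unit-RMS 1/f^alpha Gaussian noise, shaped in the frequency domain."""
    nf = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros(nf)
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = (rng.standard_normal((n_sources, nf))
            + 1j * rng.standard_normal((n_sources, nf))) * shape[None, :]
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x / rms


def _mixing_matrix(layout: ElectrodeLayout, decay: float = 0.7) -> np.ndarray:
    """Distance-decaying source-to-channel weights exp(-d / (decay*radius))."""
    pos = layout.positions
    radius = np.median(np.linalg.norm(pos - pos.mean(axis=0), axis=1))
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    return np.exp(-d / (decay * radius))


def _trapezoid(n: int, ramp_frac: float = 0.15) -> np.ndarray:
    """Flat-topped envelope with linear ramps at both ends."""
    w = np.ones(n)
    r = max(1, int(round(ramp_frac * n)))
    ramp = np.linspace(0.0, 1.0, r, endpoint=False)
    w[:r] = ramp
    w[-r:] = ramp[::-1]
    return w


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                low: float, high: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    high = min(high, 0.99 * fs / 2.0)
    sos = scipy.signal.butter(4, [low / (fs / 2), high / (fs / 2)],
                              btype="bandpass", output="sos")
    pad = int(fs)
    x = scipy.signal.sosfilt(sos, rng.standard_normal(n + 2 * pad))[pad:-pad]
    return x / np.sqrt(np.mean(x ** 2))


def _scoring_from_config(cfg: SynthConfig) -> Scoring:
    stages: list[str] = []
    for stage, count in cfg.hypnogram:
        stages += [stage] * int(count)
    return Scoring(stages, epoch_length_s=cfg.epoch_length_s)


def _oscillations(cfg: SynthConfig, scoring: Scoring, layout: ElectrodeLayout,
                  rng: np.random.Generator, n: int) -> np.ndarray:
    """Stage-locked coherent oscillations, per-channel gain in [0.6, 1]."""
    fs = cfg.sample_rate_hz
    t = np.arange(n) / fs
    stage_of = scoring.sample_stages(n, fs)
    gains = 0.6 + 0.4 * rng.random(cfg.n_channels)
    total = np.zeros(n)
    for stage, (freq, amp) in cfg.oscillations.items():
        mask = stage_of == stage
        if not mask.any():
            continue
        carrier = np.sin(2 * np.pi * freq * t)
        if stage in ("N2", "W"):
            # burst-gated (spindle/alpha trains): 1 s Hann bursts every 4 s
            gate = np.zeros(n)
            period = int(4 * fs)
            blen = int(1 * fs)
            for start in range(0, n - blen, period):
                gate[start:start + blen] = np.hanning(blen)
            carrier = carrier * gate
        total += amp * carrier * mask
    return gains[:, None] * total[None, :]


# ---------------------------------------------------------------------------
# Artifact injectors
# ---------------------------------------------------------------------------

def _inject(data: np.ndarray, spec: ArtifactSpec, cfg: SynthConfig,
            layout: ElectrodeLayout, rng: np.random.Generator,
            gt_rows: list) -> None:
    fs = cfg.sample_rate_hz
    labels = channel_labels(cfg.n_channels)
    i0 = int(round(spec.start_s * fs))
    i1 = min(data.shape[1], int(round((spec.start_s + spec.duration_s) * fs)))
    nspan = i1 - i0
    sev = spec.severity
    if sev is None:
        sev = DEFAULT_SEVERITY[spec.type]
    chans = labels if spec.channels == ["ALL"] else spec.channels
    idx = [labels.index(c) for c in chans]
    t = np.arange(nspan) / fs

    if spec.type == "highamp":
        burst = sev * _trapezoid(nspan) * np.sin(2 * np.pi * 4.0 * t)
        for c in idx:
            data[c, i0:i1] += burst
    elif spec.type == "lowamp":
        # scale the composite signal so its peak stays below `sev` uV,
        # with raised-cosine transitions to avoid spurious jumps
        ramp = int(round(0.5 * fs))
        for c in idx:
            peak = np.max(np.abs(data[c, i0:i1]))
            target = sev / peak if peak > 0 else 1.0
            factor = np.full(nspan, target)
            if nspan > 2 * ramp:
                cos = 0.5 * (1 + np.cos(np.linspace(0, np.pi, ramp)))
                factor[:ramp] = target + (1 - target) * cos
                factor[-ramp:] = target + (1 - target) * cos[::-1]
            data[c, i0:i1] *= factor
    elif spec.type == "lowfreq":
        drift = sev * _trapezoid(nspan) * np.sin(2 * np.pi * 0.5 * t)
        for c in idx:
            data[c, i0:i1] += drift
    elif spec.type == "highfreq":
        for c in idx:
            burst = sev * _trapezoid(nspan) * _band_noise(rng, nspan, fs, 60, 120)
            data[c, i0:i1] += burst
    elif spec.type == "jump":
        for c in idx:
            data[c, i0:i1] += sev
    elif spec.type == "flatline":
        for c in idx:
            data[c, i0:i1] = data[c, i0]
    elif spec.type == "deviant":
        for c in idx:
            rms = float(np.sqrt(np.mean(data[c, i0:i1] ** 2)))
            data[c, i0:i1] = sev * rms * _pink_noise(
                rng, 1, nspan, cfg.background_alpha, fs)[0]
    elif spec.type == "bridged":
        for c in idx:
            partner = _nearest_neighbor(layout, labels[c])
            p = labels.index(partner)
            data[c, i0:i1] = data[p, i0:i1]
            gt_rows.append((partner, spec.start_s,
                            spec.start_s + spec.duration_s, "bridged",
                            "injected"))
    elif spec.type == "common_ref":
        src = sev * _band_noise(rng, nspan, fs, 60, 120)
        data[:, i0:i1] += src[None, :]

    for c in idx:
        gt_rows.append((labels[c], spec.start_s,
                        spec.start_s + spec.duration_s, spec.type, "injected"))


def _nearest_neighbor(layout: ElectrodeLayout, label: str) -> str:
    i = layout.labels.index(label)
    d = np.linalg.norm(layout.positions - layout.positions[i], axis=1)
    d[i] = np.inf
    return layout.labels[int(np.argmin(d))]


# ---------------------------------------------------------------------------
# Top-level generation
# ---------------------------------------------------------------------------

def gen_background(cfg: SynthConfig, rng: np.random.Generator,
                   layout: ElectrodeLayout, n: int) -> np.ndarray:
    """Spatially mixed 1/f background, per-channel RMS = target exactly."""
    sources = _pink_noise(rng, cfg.n_channels, n, cfg.background_alpha,
                          cfg.sample_rate_hz)
    mixed = _mixing_matrix(layout) @ sources
    rms = np.sqrt(np.mean(mixed ** 2, axis=1, keepdims=True))
    return cfg.background_rms_uv * mixed / rms


def gen_recording(cfg: SynthConfig):
    """Generate one recording.

    Returns
    -------
    (Recording, Scoring, EventTable, ElectrodeLayout)
        The signal, its hypnogram, the ground-truth artifact table, and
        the electrode layout (positions only; callers build neighbor maps
        with the threshold suiting their montage density).
    """
    rng = np.random.default_rng(cfg.seed)
    layout = gen_layout(cfg.n_channels)
    scoring = _scoring_from_config(cfg)
    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    data = gen_background(cfg, rng, layout, n)
    data += _oscillations(cfg, scoring, layout, rng, n)
    gt_rows: list = []
    for spec in cfg.artifacts:
        _inject(data, spec, cfg, layout, rng, gt_rows)
    recording = Recording(channel_labels(cfg.n_channels), cfg.sample_rate_hz,
                          data)
    return recording, scoring, EventTable(gt_rows), layout
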