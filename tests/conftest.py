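import numpy as np
import pytest

from somnoclean import (
    ArtifactSpec,
    Recording,
    SynthConfig,
    build_neighbors,
    gen_recording,
)


@pytest.fixture(scope="session")
def small_synth():
    """8-channel, 2-min recording with a handful of injected artifacts."""
    cfg = SynthConfig(
        n_channels=8, duration_s=120.0, seed=7,
        artifacts=[
            ArtifactSpec("highamp", ["E01"], 20.0, 2.0),
            ArtifactSpec("flatline", ["E03"], 50.0, 3.0),
            ArtifactSpec("jump", ["E05"], 80.0, 0.6),
        ])
    return gen_recording(cfg)


@pytest.fixture(scope="session")
def default_synth():
    """The stock 16-channel, 10-min fixture with the 40-artifact plan."""
    rec, scoring, truth, layout = gen_recording(SynthConfig(seed=1))
    layout = build_neighbors(layout, threshold=0.9)
    return rec, scoring, truth, layout


@pytest.fixture()
def sine_recording():
    fs = 250.0
    t = np.arange(int(20 * fs)) / fs
    data = np.vstack([np.sin(2 * np.pi * 1.0 * t),
                      np.sin(2 * np.pi * 40.0 * t)])
    return Recording(["slow", "fast"], fs, data)
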