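# somnoclean

Automated, channel- and time-resolved artifact cleaning for multichannel
sleep EEG.

Overnight polysomnography produces hours of multichannel signal in which
artifacts — movement, muscle activity, sweat drift, electrode pops,
flatlines, gel bridges, reference failures — appear on different channels
at different times. Rejecting whole channels or whole 30-s epochs wastes
data; marking artifacts manually per channel is impractically slow.
somnoclean is for sleep researchers who want a reproducible, fully
automated alternative: it detects artifacts per channel, books them on a
channel × segment grid, repairs what can be repaired by spherical-spline
interpolation, rejects what cannot, and hands back analysis-ready bouts of
clean data by sleep stage.

## Method

Cleaning proceeds in five stages:

1. **Detection.** A *detector set* — nine detectors by default — runs over
   the continuous recording. Channel-wise detectors apply a chain of
   signal primitives (Butterworth filtering, Hilbert envelope, smoothing,
   per-channel z-scoring, median filtering, absolute gradient) and
   threshold the result with minimum-duration, padding and merging rules:
   `highamp` (|x| > 300 µV), `lowamp` (|x| < 5 µV for ≥ 30 s), `lowfreq`
   (0.3–15 Hz envelope, z > 8), `highfreq` (60–120 Hz envelope, z > 3),
   `jump` (median-filtered absolute gradient, z > 25), `flatline`
   (gradient < 1 µV for ≥ 1 s). Pairwise detectors compare windows across
   channels: `deviant` (r < 0.3 with a majority of spatial neighbors, 30-s
   windows), `similar` (max |difference| < 0.5 µV with a neighbor — gel
   bridging), `similar2` (r > 0.9 with a majority of all channels after
   2 Hz high-pass — reference failure). Every parameter is data; detector
   sets serialize to YAML and can be edited without code.
2. **Grid bookkeeping.** Each detector's event table is rasterized onto a
   boolean channels × 5-s-segments grid; grids are OR-pooled into a
   *basic* grid, then optionally: *spatial expansion* (mark a clean
   channel when ≥ 75% of its neighbors are artifactual), *segment
   rejection* (drop a segment when ≥ 25% of channels are artifactual),
   and *temporal expansion* (mark a whole channel artifactual when ≥ 25%
   of its non-rejected segments are — a bad-channel rule). The *repair*
   grid is the union of artifact grids minus rejected segments.
3. **Repair.** Per segment, flagged channels are reconstructed from the
   clean channels via spherical-spline interpolation
   (g(cos θ) = Σₙ (2n+1)/(n(n+1))ᵐ Pₙ(cos θ)/4π, m = 4, 20 terms, ridge
   λ = 10⁻⁵), with a linear crossfade across segment boundaries; NaN/zero
   replacement is available as an alternative.
4. **Selection.** Clean data is extracted as maximal uninterrupted bouts
   of requested sleep stages with a minimum duration (e.g. all ≥ 1-min
   bouts of clean N2), as separate trials or pseudocontinuous.
5. **Evaluation.** Automatic grids can be scored against reference
   (manual) annotations: accuracy, Cohen's κ, sensitivity, specificity,
   precision, F1 — from grids directly or reconstructed from published
   summary values.

A seedable synthetic-data generator (`somnoclean.synthetic`) produces
stage-structured multichannel EEG with injected, ground-truth-labeled
artifacts of every detector's target class, so the whole pipeline is
testable without real recordings.

## Worked example

```python
from somnoclean import (SynthConfig, gen_recording, build_neighbors,
                        default_detector_set, run_detector_set,
                        build_grid_set, GridParams, summarize,
                        repair_by_grid, select_clean)

# a 16-channel, 10-min synthetic recording with 40 injected artifacts
rec, scoring, truth, layout = gen_recording(SynthConfig(seed=1))
layout = build_neighbors(layout, threshold=0.9)

events = run_detector_set(rec, default_detector_set(rec.sample_rate_hz),
                          scoring, layout)
params = GridParams(spatial_threshold=0.75, rejection_threshold=0.25,
                    temporal_threshold=0.25)
grids = build_grid_set(events, rec.channel_labels, rec.duration_s,
                       params, layout.neighbor_map)

s = summarize(grids, scoring)
print(f"basic {s['overall']['basic_pct']:.1f}% | "
      f"repair {s['overall']['repair_pct']:.1f}% | "
      f"reject {s['overall']['rejection_pct']:.1f}% of segments")
for name, pct in s["detectors"].items():
    print(f"  {name:9s} {pct:5.2f}%")

repaired, residual = repair_by_grid(rec, grids.repair, layout)
bouts, blocks = select_clean(repaired, grids.rejection, 5.0, scoring,
                             stages=["N2"], min_duration_s=60.0)
print(f"{len(bouts)} clean N2 bouts >= 60 s, "
      f"total {bouts.total_duration():.0f} s")
```

prints

```
basic 15.5% | repair 11.5% | reject 14.2% of segments
  highamp    0.62%
  lowamp     0.83%
  lowfreq    2.29%
  highfreq   6.15%
  jump       0.94%
  flatline   1.46%
  deviant    5.62%
  similar    1.25%
  similar2   5.00%
1 clean N2 bouts >= 60 s, total 120 s
```

The percentages are the fraction of channel-segment elements each
detector flagged; `basic` is their union, `repair` is what will be
interpolated, and `reject` is the fraction of 5-s segments dropped
entirely (the injected reference-failure block plus the fully deviant
channel spans drive rejection here). The final line is the payload: the
N2 sleep that survives cleaning in uninterrupted ≥ 60-s stretches.

The same pipeline runs from the shell:

```
somnoclean simulate -o data --seed 1          # synthetic EDF + hypnogram + layout
somnoclean run -c config.yaml                 # detect -> grids -> repair -> select
somnoclean evaluate --test out/grids.npz --ref manual/grids.npz
```

`somnoclean run` writes per-detector event CSVs, the grid bundle
(`grids.npz` + JSON sidecar), `summary.json` (percentages overall and per
sleep stage), a bout table, an optional repaired EDF, and a data-quality
figure (hypnogram strip, channel × segment raster — gray basic artifact,
magenta spatial expansion, gold temporal expansion, red rejected segments
— and marginal artifact fractions).

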