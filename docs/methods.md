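# Methods

This note records how somnoclean's cleaning procedure is defined, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic test bed does and does not show
about real recordings.

## Conventions

Time is seconds from recording start; all intervals are half-open
`[start, end)`; sample indices are 0-based and sample `i` covers
`[i/fs, (i+1)/fs)`. Hypnogram epoch `e` covers
`[offset + e·epoch_length, …)`; samples beyond the last scored epoch are
stage `unknown`. Signal is stored in microvolts at 64-bit precision.
Event tables, grids and summaries follow directly from these conventions,
so event ↔ sample ↔ segment conversions are exact.

## Detection

A detector is declarative: scope (channel-wise or pairwise), an optional
stage and channel restriction, a chain of signal primitives, a criterion,
and padding/merging post-processing. The primitives are deliberately
cheap — an 8-h high-density recording must be processable in minutes —
and all per-channel:

* **Filtering** — zero-phase (forward–backward) Butterworth, order 4 per
  pass. The filter family is a design choice; zero-phase matters because
  detected intervals must align with the artifacts that caused them.
* **Envelope** — magnitude of the analytic (Hilbert) signal, then a
  centered moving average over 0.2 s (default; 0 disables). 0.2 s is long
  enough to suppress within-cycle ripple above ~10 Hz and short enough
  not to smear burst edges.
* **z-scoring** — per channel over all samples, population SD; a channel
  with zero spread maps to all zeros so nothing can be detected on it.
  Whether z-statistics should come from all stages or only the stages a
  detector inspects is not obvious; the stage mask is applied *before*
  z-scoring (excluded samples contribute neither statistics nor events),
  and the default detectors inspect all stages. A median/MAD variant
  exists behind a flag but is not the default.
* **Gradient** — `|x[i+1] − x[i]|` (µV per sample), last value repeated
  to preserve length. **Median filter** — running median, odd order, edge
  windows shrink.

Thresholding emits maximal runs satisfying the comparison; runs shorter
than the minimum duration are dropped (minimum 0 keeps single-sample
runs). Padding extends events symmetrically and clips to the recording;
events whose gap is strictly smaller than the merge interval are merged —
a gap exactly equal to the merge interval stays split.

Pairwise detectors cut the recording into consecutive non-overlapping
windows anchored at time 0, discarding the final partial window. Per
window and target channel, the pair metric (Pearson r or maximum absolute
difference) is evaluated against each partner — spatial neighbors for
local scope, all other channels for global scope. The target is flagged
for the whole window when the fraction of valid partners meeting the
criterion strictly exceeds `neighbor_fraction`. Partners whose window has
zero variance are excluded from the denominator (their correlation is
undefined), and a window with no valid partner is never flagged. For the
bridging detector (`similar`) the fraction is 0 with strict inequality,
i.e. *any* near-identical neighbor flags both members of the pair — a
bridged pair should be flagged even when the other neighbors look normal.

Sample-rate adjustments of the default set: the jump detector's median
filter order scales as the nearest odd integer to `9·fs/250`; the
flatline gradient threshold scales as `1 µV · 250/fs` (the per-sample
gradient of a fixed-slope signal halves when the rate doubles); the
highfreq band's upper edge is `min(120, 0.95·Nyquist)` and the detector
is omitted, with a warning, once that edge reaches 80 Hz — below that the
band no longer measures muscle-band activity.

Neighborhoods are distance-based: channels are neighbors when their
Euclidean distance is at most a threshold (infinity gives all-to-all).
The default threshold, 0.35 × the layout's median head radius, suits
high-density montages; sparse montages need a larger value (the 16-channel
test fixture uses 0.9 on a unit-sphere layout, giving 3–6 neighbors per
channel). Triangulation-based neighborhoods are out of scope.

## Grid processing

Events are rasterized onto a boolean channels × segments grid (segment
length 5 s — fine enough that little granularity is lost, coarse enough
that grid algebra is trivial). An element is artifactual when the summed
event overlap strictly exceeds `element_min_proportion` of the segment's
actual duration (the final partial segment uses its true length); the
default proportion 0 marks any nonzero overlap.

The five processing steps — OR-pooling, spatial expansion, segment
rejection, temporal expansion, repair composition — are defined in
`somnoclean.grids`. Three comparisons deserve explicit statement:

* spatial/rejection/temporal thresholds compare with `>=`;
* disabled steps are an OFF sentinel, not threshold 1.0 — a fully
  artifactual segment must still reject at an enabled threshold of 1.0;
* spatial expansion is a single pass over channels clean in the basic
  grid (no cascade), and the expansion grids hold only their *additions*.

Temporal expansion computes each channel's artifactual fraction over
non-rejected segments only, so a block of globally bad data does not turn
every channel into a "bad channel". Whether segment rejection should see
the basic grid alone or basic ∨ spatial is ambiguous; the default is
basic ∨ spatial (spatially expanded elements describe genuinely suspect
data), switchable via `GridParams.rejection_input`. The repair grid is
`(basic ∨ spatial ∨ temporal) ∧ ¬rejection`; the disjointness of repair
and rejection is asserted on every `GridSet`.

Summary statistics report percentages per detector grid, for basic and
repair (channel-segment elements) and rejection (segments), overall and
by sleep stage; a segment's stage is the stage of the epoch containing
its midpoint.

## Repair

Spherical-spline interpolation uses the kernel
`g(cosθ) = (1/4π) Σ_{n=1..N} (2n+1)/(n(n+1))^m P_n(cosθ)` with m = 4 and
N = 20 terms, solved with a ridge term λ = 10⁻⁵ on the good-channel block
and a constant-term row/column. These constants follow common EEG
practice for spline interpolation of scalp potentials; all are exposed in
`SplineParams`. Electrode positions are centered on their centroid and
projected to the unit sphere before kernel evaluation. The constant term
makes spatially uniform fields reproduce exactly (to solver precision,
~10⁻¹⁴ in the tests); as λ → 0 the spline reproduces its knots, so a
duplicated electrode position recovers its twin's signal.

Repair is segment-wise: at each segment only the flagged channels are
replaced, using exclusively that segment's clean channels. Each repaired
segment is computed over its span extended by half a crossfade (default
crossfade 0.1 s) and blended in with trapezoidal overlap-add weights:
ramps centered on each boundary where the channel's repaired status
changes, including boundaries between two repaired segments with
different clean sets (the two repaired versions crossfade into each
other). Samples outside every extended span are bit-identical to the
input. Segments with fewer than 3 clean channels are not interpolable;
they are left unmodified and reported in a residual table rather than
NaN-filled, so no data is silently destroyed. Fixed-value replacement
(zero or NaN) replaces exactly the flagged sample spans, without
crossfade.

## Selection

Samples are kept when their stage is requested and their grid segment is
not rejected; maximal kept runs become bouts, and bouts shorter than the
minimum duration are dropped (`>=` by default, strict via a flag). A
change between two *requested* stages does not break a bout by default
(an N2→N3 transition is continuous sleep); a flag makes stage changes
break bouts for stage-pure trials. Trials mode returns one block per
bout; pseudocontinuous concatenates them, with the bout table recording
the boundaries — both contain identical samples.

## Agreement evaluation

`confusion_from_grids` counts channel-segment elements; Cohen's κ uses
chance agreement `pe = p_t·p_r + (1−p_t)(1−p_r)`. Ratios with zero
denominators are NaN rather than 0 — an all-clean reference has no
sensitivity. `metrics_from_summary` reconstructs real-valued counts
(TP = sens·prev_ref·N etc.) from published summary values without
rounding to integers, so the tolerance of any downstream comparison is
transparently the rounding of the inputs: with 3-decimal inputs the
derived metrics carry about ±0.006 of input-rounding slack, which is the
tolerance the reconstruction tests use.

Event-level recovery (`injection_recovery`) scores a detector against
injected ground truth: a truth event is recovered when the detector's
events on that channel cover ≥ 50% of the injected span; a detection is
true when it overlaps *any* injected artifact on its channel, regardless
of class. The asymmetric class handling is deliberate: a high-amplitude
burst legitimately trips the low-frequency detector too, and counting
that as a false positive would measure cross-talk, not false detection.

## Synthetic data

The generator emulates the statistical features the pipeline reacts to,
not physiology:

* **Background**: per-channel 1/f^α Gaussian noise (α = 1), mixed
  spatially through `exp(−d/(0.7·radius))` weights and normalized to
  20 µV RMS per channel. The kernel width was chosen so that neighboring
  channels correlate at r ≈ 0.5–0.7 in 30-s windows — comfortably above
  the deviant detector's r < 0.3 criterion, as in real EEG where volume
  conduction keeps neighbors well correlated; a narrower kernel leaves
  healthy channels hovering near the criterion.
* **Stage oscillations**: coherent across channels with per-channel gains
  in [0.6, 1] — 0.75 Hz slow waves (50 µV) in N3, 1-s 13 Hz spindle
  bursts every 4 s (20 µV) in N2, 10 Hz alpha bursts (15 µV) in W.
* **Artifacts**: each default detector's target class has an injector —
  high-amplitude 4 Hz bursts (700 µV, trapezoidal envelope), attenuation
  below 3 µV peak, 0.5 Hz drift excursions (400 µV), 60–120 Hz noise
  bursts (60 µV RMS), rectangular step offsets (250 µV), sample-exact
  flatlines, replacement by independent noise (deviant), copying the
  nearest neighbor (bridging, ground truth recorded for both channels),
  and a high-frequency common source added to all channels (reference
  failure, 40 µV RMS).

The default plan injects 40 artifacts into a 16-channel, 10-min
recording. Three scheduling rules make the plan a fair test rather than a
trivial one. First, classes sit on mostly disjoint channels: several
detectors threshold per-channel z-scores, and a large artifact of one
class on a channel inflates that channel's SD, silently raising every
z-threshold on it. Second, low-frequency drifts are one ~5-s event per
channel: for an event occupying fraction f of a channel, the attainable
z-score is capped near `sqrt((1−f)/f)` no matter how large the drift, so
z > 8 requires f ≲ 1%. Third, deviant/bridged/reference-failure events
are aligned to the pairwise detectors' window boundaries, since a window
only half-covered by an artifact dilutes its pair metric.

What the generator does *not* emulate: non-stationary background,
arousals, ECG/EOG crosstalk, realistic artifact morphology, electrode
drift that evolves over hours, or any forward head model. Passing the
recovery test therefore shows that each detector recognizes a clean
instance of its target signature at realistic amplitude over realistic
background — not that the default thresholds are optimal for any real
dataset, which is why every threshold is configurable.

## Problem sizes and tolerances in the test suite

The test suite and the acceptance script run the full nine-detector
pipeline on the 16-channel, 10-min fixture (the size at which every
artifact class fits several times over while the whole suite stays in the
range of seconds), check the grid algebra against a loop-based oracle on
1,000 random 8 × 20 grids at thresholds {0, ¼, ½, ¾, 1}, the interval
algebra against a run-length-encoding oracle on 1,000 random signals, and
the spline kernel against a term-by-term Legendre recursion at 10⁻¹²
(identical series, independent evaluation; the implementation uses
Clenshaw summation). Leave-one-out recovery of a smooth dipolar field at
32 electrodes must stay within 10% RMS in the median — the median is the
right summary because electrodes at the hemisphere rim are extrapolated,
which spline interpolation is legitimately bad at.

## Known limitations

* EDF writing quantizes to 16 bits over each channel's physical range
  (the format's native encoding); round trips are exact only to that
  quantization. Only continuous EDF is written, with 1-s records.
* Pairwise detectors build a full correlation matrix per window; at 250+
  channels the `similar` detector's pairwise max-difference loop is the
  slowest component, mirroring its cost profile at high density.
* Spatial expansion assumes a meaningful neighbor map; on montages of a
  handful of channels it should stay disabled (the default).
* The repair changes data rank segment-wise; analyses sensitive to rank
  (e.g. source decomposition) should use rejection rather than repair.
* ICA-based pre-cleaning is deliberately out of scope.
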