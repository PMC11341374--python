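import logging

import numpy as np
import pytest

from somnoclean import (
    DetectorSet,
    Recording,
    Scoring,
    build_neighbors,
    default_detector_set,
    run_detector,
    run_detector_set,
)
from somnoclean.model_io import ElectrodeLayout


def spec_of(ds, name):
    return next(d for d in ds if d.name == name)


class TestDefaultSet:
    def test_nine_detectors_at_250(self):
        ds = default_detector_set(250.0)
        assert len(ds) == 9
        assert ds.names() == ["highamp", "lowamp", "lowfreq", "highfreq",
                              "jump", "flatline", "deviant", "similar",
                              "similar2"]

    def test_stock_parameters(self):
        ds = default_detector_set(250.0)
        ha = spec_of(ds, "highamp")
        assert (ha.cmp, ha.threshold, ha.padding_s, ha.merge_gap_s) == \
            ("gt", 300.0, 0.1, 1.0)
        la = spec_of(ds, "lowamp")
        assert (la.cmp, la.threshold, la.min_duration_s) == ("lt", 5.0, 30.0)
        lf = spec_of(ds, "lowfreq")
        assert lf.chain[0] == ("bandpass", {"low_hz": 0.3, "high_hz": 15.0})
        assert (lf.threshold, lf.padding_s) == (8.0, 3.0)
        hf = spec_of(ds, "highfreq")
        assert hf.chain[0][1]["high_hz"] == 118.75  # 0.95 * Nyquist < 120
        jp = spec_of(ds, "jump")
        assert jp.chain[0] == ("median_filter", {"order": 9})
        assert jp.threshold == 25.0
        fl = spec_of(ds, "flatline")
        assert (fl.threshold, fl.min_duration_s) == (1.0, 1.0)
        dv = spec_of(ds, "deviant")
        assert (dv.window_s, dv.pair_threshold, dv.neighbor_fraction,
                dv.merge_gap_s, dv.min_channels) == (30.0, 0.3, 0.5, 60.0, 3)
        sm = spec_of(ds, "similar")
        assert (sm.pair_metric, sm.pair_threshold) == ("max_abs_difference", 0.5)
        s2 = spec_of(ds, "similar2")
        assert (s2.scope, s2.window_s, s2.pair_threshold, s2.merge_gap_s) == \
            ("pairwise_global", 5.0, 0.9, 5.0)

    def test_flatline_threshold_scales_with_rate(self):
        assert spec_of(default_detector_set(125.0), "flatline").threshold == 2.0

    def test_jump_order_scales_with_rate(self):
        assert spec_of(default_detector_set(500.0), "jump").chain[0][1]["order"] == 19

    def test_highfreq_omitted_below_168(self, caplog):
        # 0.95 * Nyquist <= 80 Hz once fs <= ~168 Hz
        with caplog.at_level(logging.WARNING):
            ds = default_detector_set(150.0)
        assert len(ds) == 8
        assert "highfreq" not in ds.names()
        assert "omitted" in caplog.text

    def test_serialization_round_trip(self):
        ds = default_detector_set(250.0)
        back = DetectorSet.from_dict(ds.to_dict())
        assert back.to_dict() == ds.to_dict()

    def test_unique_names_enforced(self):
        ds = default_detector_set(250.0)
        with pytest.raises(ValueError, match="unique"):
            DetectorSet(list(ds) + [spec_of(ds, "highamp")])


class TestChannelwise:
    def test_highamp_zero_signal(self):
        rec = Recording(["a"], 100.0, np.zeros((1, 1000)))
        spec = spec_of(default_detector_set(100.0), "highamp")
        assert len(run_detector(rec, spec)) == 0

    def test_highamp_block_with_padding(self):
        x = np.zeros((1, 1000))
        x[0, 100:150] = 400.0
        rec = Recording(["a"], 100.0, x)
        spec = spec_of(default_detector_set(100.0), "highamp")
        tab = run_detector(rec, spec)
        assert len(tab) == 1
        row = tab.df.iloc[0]
        assert (row.channel, row.event_type) == ("a", "highamp")
        np.testing.assert_allclose([row.start_s, row.end_s], [0.9, 1.6])

    def test_commutes_with_channel_subsetting(self, small_synth):
        rec, scoring, _, layout = small_synth
        spec = spec_of(default_detector_set(rec.sample_rate_hz), "highamp")
        full = run_detector(rec, spec, scoring)
        sub = run_detector(rec.subset(["E01", "E02"]), spec, scoring)
        expect = full.df[full.df.channel.isin(["E01", "E02"])].reset_index(drop=True)
        assert sub.df.equals(expect)

    def test_raising_threshold_monotone(self, small_synth):
        rec, scoring, _, _ = small_synth
        ds = default_detector_set(rec.sample_rate_hz)
        spec = spec_of(ds, "highamp")
        lo = run_detector(rec, spec, scoring).total_duration()
        spec_hi = type(spec)(**{**spec.to_dict(),
                                "chain": spec.chain, "threshold": 500.0})
        hi = run_detector(rec, spec_hi, scoring).total_duration()
        assert hi <= lo

    def test_stage_restriction_masks_events(self):
        fs = 100.0
        x = np.zeros((1, int(90 * fs)))
        x[0, 1000:1200] = 400.0   # within epoch 0 (W)
        x[0, 4000:4200] = 400.0   # within epoch 1 (N2)
        rec = Recording(["a"], fs, x)
        scoring = Scoring(["W", "N2", "N2"], epoch_length_s=30.0)
        ds = default_detector_set(fs)
        spec = spec_of(ds, "highamp")
        spec.stages = ["N2"]
        tab = run_detector(rec, spec, scoring)
        assert len(tab) == 1
        assert 30.0 <= tab.df.iloc[0].start_s < 60.0


class TestPairwise:
    def _bridged_fixture(self):
        rng = np.random.default_rng(0)
        fs = 100.0
        n = int(90 * fs)
        data = 10.0 * rng.standard_normal((4, n))
        data[1] = data[0]  # exact duplicate pair
        labels = ["a", "b", "c", "d"]
        # neighbor sets where the bridged partner is the majority
        layout = ElectrodeLayout(labels, np.eye(4, 3) * 2,
                                 {"a": {"b"}, "b": {"a"},
                                  "c": {"d"}, "d": {"c"}})
        return Recording(labels, fs, data), layout

    def test_similar_flags_both_duplicates_every_window(self):
        rec, layout = self._bridged_fixture()
        spec = spec_of(default_detector_set(rec.sample_rate_hz), "similar")
        spec.min_channels = 3
        tab = run_detector(rec, spec, layout=layout)
        # three 30 s windows, merged into one event per bridged channel
        assert sorted(tab.channels) == ["a", "b"]
        for ch in ("a", "b"):
            ev = tab.for_channel(ch)
            assert len(ev) == 1
            assert (ev.iloc[0].start_s, ev.iloc[0].end_s) == (0.0, 90.0)

    def test_deviant_flags_uncorrelated_channel(self, default_synth):
        rec, scoring, truth, layout = default_synth
        spec = spec_of(default_detector_set(rec.sample_rate_hz), "deviant")
        tab = run_detector(rec, spec, scoring, layout)
        dev = truth.df[truth.df.event_type == "deviant"]
        for row in dev.itertuples(index=False):
            ev = tab.for_channel(row.channel)
            cov = sum(max(0.0, min(row.end_s, r.end_s) - max(row.start_s, r.start_s))
                      for r in ev.itertuples(index=False))
            assert cov >= 0.99 * (row.end_s - row.start_s)

    def test_too_few_channels_skipped_with_warning(self, caplog):
        rec = Recording(["a", "b"], 100.0,
                        np.random.default_rng(0).standard_normal((2, 6000)))
        layout = ElectrodeLayout(["a", "b"], [[0, 0, 1], [0, 1, 0]],
                                 {"a": {"b"}, "b": {"a"}})
        ds = default_detector_set(100.0)
        with caplog.at_level(logging.WARNING):
            out = run_detector_set(rec, ds, layout=layout)
        assert "deviant" not in out and "similar" not in out
        assert "skipping detector" in caplog.text


class TestDetectorSetExecution:
    def test_empty_set(self, small_synth):
        rec, scoring, _, layout = small_synth
        assert run_detector_set(rec, DetectorSet([]), scoring, layout) == {}

    def test_single_detector_equals_run_detector(self, small_synth):
        rec, scoring, _, layout = small_synth
        spec = spec_of(default_detector_set(rec.sample_rate_hz), "highamp")
        alone = run_detector(rec, spec, scoring, layout)
        in_set = run_detector_set(rec, DetectorSet([spec]), scoring, layout)
        assert in_set["highamp"] == alone

    def test_order_invariance_and_determinism(self, small_synth):
        rec, scoring, _, layout = small_synth
        ds = default_detector_set(rec.sample_rate_hz)
        fwd = run_detector_set(rec, ds, scoring, layout)
        rev = run_detector_set(
            rec, DetectorSet(list(ds)[::-1], name="rev"), scoring, layout)
        again = run_detector_set(rec, ds, scoring, layout)
        assert set(fwd) == set(rev)
        for name in fwd:
            assert fwd[name] == rev[name] == again[name]
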