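import numpy as np
import pytest

from somnoclean import (
    ArtifactGrid,
    EventTable,
    GridParams,
    Scoring,
    build_grid_set,
    compose_repair,
    events_to_grid,
    grid_to_events,
    pool_grids,
    reject_segments,
    spatial_expand,
    summarize,
    temporal_expand,
)

CH4 = ["a", "b", "c", "d"]


def grid_of(values, seg=5.0, labels=None, origin=""):
    values = np.asarray(values, dtype=bool)
    labels = labels or [f"c{i}" for i in range(values.shape[0])]
    return ArtifactGrid(labels, seg, values.shape[1] * seg, values, origin)


class TestEventsToGrid:
    def test_empty_events(self):
        g = events_to_grid(EventTable(), CH4, 20.0)
        assert not g.values.any()
        assert g.values.shape == (4, 4)

    def test_single_segment_event(self):
        g = events_to_grid(EventTable([("a", 0.0, 5.0, "x", "x")]), CH4, 20.0)
        assert g.values[0, 0]
        assert g.values.sum() == 1

    def test_boundary_straddle(self):
        g = events_to_grid(EventTable([("a", 4.9, 5.1, "x", "x")]), CH4, 20.0)
        assert g.values[0, 0] and g.values[0, 1]
        assert g.values.sum() == 2

    def test_proportion_threshold_strict(self):
        tab = EventTable([("a", 0.0, 2.5, "x", "x")])
        g = events_to_grid(tab, CH4, 20.0,
                           GridParams(element_min_proportion=0.5))
        assert not g.values[0, 0]  # overlap 2.5 s is not > 0.5 * 5 s
        g2 = events_to_grid(tab, CH4, 20.0,
                            GridParams(element_min_proportion=0.49))
        assert g2.values[0, 0]

    def test_partial_final_segment_uses_true_duration(self):
        # duration 12 s -> final segment spans [10, 12); a 1.2 s event is
        # 60% of that short segment
        tab = EventTable([("a", 10.0, 11.2, "x", "x")])
        g = events_to_grid(tab, CH4, 12.0,
                           GridParams(element_min_proportion=0.5))
        assert g.values[0, 2]

    def test_unknown_channel(self):
        with pytest.raises(ValueError, match="not in grid"):
            events_to_grid(EventTable([("zz", 0, 1, "x", "x")]), CH4, 20.0)


class TestGridAlgebraExamples:
    def test_pool_identity_and_monotone(self):
        g1 = grid_of(np.eye(3, 4))
        empty = grid_of(np.zeros((3, 4)))
        assert np.array_equal(pool_grids({"g": g1}).values, g1.values)
        both = pool_grids({"g": g1, "e": empty})
        assert np.array_equal(both.values, g1.values)
        g2 = grid_of(np.ones((3, 4)))
        assert pool_grids({"g": g1, "h": g2}).values.all()

    def test_spatial_off_is_all_false(self):
        basic = grid_of(np.ones((3, 4)))
        assert not spatial_expand(basic, {}, None).values.any()

    def test_spatial_three_of_four_neighbors(self):
        vals = np.zeros((5, 1), dtype=bool)
        vals[1:4, 0] = True  # 3 of target's 4 neighbors artifactual
        basic = grid_of(vals, labels=list("tabcd"))
        nbr = {"t": {"a", "b", "c", "d"}}
        nbr.update({k: {"t"} for k in "abcd"})
        out = spatial_expand(basic, nbr, 0.75)
        assert out.values[0, 0]
        assert out.values.sum() == 1  # already-true channels are additions-only

    def test_spatial_isolated_channel_never_added(self):
        vals = np.ones((3, 2), dtype=bool)
        vals[0] = False
        basic = grid_of(vals, labels=list("xyz"))
        out = spatial_expand(basic, {"y": {"z"}, "z": {"y"}, "x": set()}, 0.5)
        assert not out.values[0].any()

    def test_rejection_threshold_inclusive(self):
        vals = np.zeros((64, 1), dtype=bool)
        vals[:16, 0] = True
        assert reject_segments(grid_of(vals), 0.25)[0]
        assert not reject_segments(grid_of(vals), 0.26)[0]
        assert not reject_segments(grid_of(vals), None)[0]

    def test_temporal_fraction_over_non_rejected(self):
        vals = np.zeros((2, 100), dtype=bool)
        vals[0, :30] = True
        rejection = np.zeros(100, dtype=bool)
        out = temporal_expand(grid_of(vals), rejection, 0.25)
        assert out.values[0].sum() == 70  # additions exclude existing elements
        assert not out.values[1].any()

    def test_temporal_ignores_rejected_segments(self):
        vals = np.zeros((2, 10), dtype=bool)
        vals[0, :3] = True
        rejection = np.zeros(10, dtype=bool)
        rejection[:3] = True  # all artifact falls in rejected segments
        out = temporal_expand(grid_of(vals), rejection, 0.25)
        assert not out.values.any()

    def test_compose_repair(self):
        basic = grid_of([[1, 0, 0], [0, 0, 0]], seg=5.0)
        spatial = grid_of([[0, 1, 0], [0, 0, 0]], seg=5.0)
        temporal = grid_of([[0, 0, 0], [0, 0, 1]], seg=5.0)
        rej = np.array([False, True, False])
        rep = compose_repair(basic, spatial, temporal, rej)
        assert np.array_equal(rep.values,
                              [[True, False, False], [False, False, True]])
        again = compose_repair(rep, rep.empty_like("s"), rep.empty_like("t"), rej)
        assert np.array_equal(again.values, rep.values)


class TestBruteForceOracle:
    """The five grid steps against an independent loop implementation."""

    N_GRIDS = 150
    THRESHOLDS = [0.0, 0.25, 0.5, 0.75, 1.0]

    @staticmethod
    def oracle(basic, nbrs, thr_s, thr_r, thr_t):
        n_ch, n_seg = basic.shape
        spatial = np.zeros_like(basic)
        if thr_s is not None:
            for s in range(n_seg):
                for c in range(n_ch):
                    if basic[c, s] or not nbrs[c]:
                        continue
                    frac = sum(basic[m, s] for m in nbrs[c]) / len(nbrs[c])
                    if frac >= thr_s:
                        spatial[c, s] = True
        combined = basic | spatial
        rej = np.zeros(n_seg, dtype=bool)
        if thr_r is not None:
            for s in range(n_seg):
                if sum(combined[c, s] for c in range(n_ch)) / n_ch >= thr_r:
                    rej[s] = True
        temporal = np.zeros_like(basic)
        if thr_t is not None:
            keep = [s for s in range(n_seg) if not rej[s]]
            for c in range(n_ch):
                if keep and sum(combined[c, s] for s in keep) / len(keep) >= thr_t:
                    for s in range(n_seg):
                        if not combined[c, s]:
                            temporal[c, s] = True
        repair = (basic | spatial | temporal) & ~rej[None, :]
        return spatial, rej, temporal, repair

    def test_random_grids_match_oracle(self):
        rng = np.random.default_rng(42)
        labels = [f"c{i}" for i in range(8)]
        for k in range(self.N_GRIDS):
            basic_vals = rng.random((8, 20)) < rng.uniform(0.05, 0.6)
            basic = grid_of(basic_vals, labels=labels)
            adj = rng.random((8, 8)) < 0.4
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            nbrs = [list(np.flatnonzero(adj[i])) for i in range(8)]
            nbr_map = {labels[i]: {labels[j] for j in nbrs[i]}
                       for i in range(8)}
            thr = self.THRESHOLDS[k % 5]
            spatial = spatial_expand(basic, nbr_map, thr)
            combined = basic.copy_with(basic.values | spatial.values, "c")
            rej = reject_segments(combined, thr)
            temporal = temporal_expand(combined, rej, thr)
            repair = compose_repair(basic, spatial, temporal, rej)
            o_sp, o_rej, o_tmp, o_rep = self.oracle(
                basic_vals, nbrs, thr, thr, thr)
            assert np.array_equal(spatial.values, o_sp)
            assert np.array_equal(rej, o_rej)
            assert np.array_equal(temporal.values, o_tmp)
            assert np.array_equal(repair.values, o_rep)
            assert not np.any(repair.values & rej[None, :])


class TestGridSetPipeline:
    def test_monotone_in_events(self):
        ev1 = EventTable([("a", 0.0, 10.0, "x", "d1")])
        ev2 = EventTable([("a", 0.0, 10.0, "x", "d1"),
                          ("b", 5.0, 20.0, "x", "d1")])
        params = GridParams(rejection_threshold=0.5)
        gs1 = build_grid_set({"d1": ev1}, CH4, 20.0, params)
        gs2 = build_grid_set({"d1": ev2}, CH4, 20.0, params)
        assert gs2.basic.values.sum() >= gs1.basic.values.sum()
        assert gs2.rejection.sum() >= gs1.rejection.sum()

    def test_empty_detector_map(self):
        gs = build_grid_set({}, CH4, 20.0)
        assert not gs.basic.values.any()
        assert not gs.repair.values.any()


class TestSummarize:
    def test_all_false_zeros(self):
        gs = build_grid_set({}, CH4, 60.0)
        s = summarize(gs, Scoring(["N2", "N2"]))
        assert s["overall"] == {"basic_pct": 0.0, "repair_pct": 0.0,
                                "rejection_pct": 0.0}

    def test_one_channel_fully_artifactual(self):
        ev = EventTable([("a", 0.0, 60.0, "x", "d")])
        gs = build_grid_set({"d": ev}, CH4, 60.0)
        s = summarize(gs, Scoring(["N2", "N3"]))
        assert s["overall"]["basic_pct"] == 25.0
        assert s["detectors"]["d"] == 25.0

    def test_stagewise_averages_to_overall(self):
        ev = EventTable([("a", 0.0, 25.0, "x", "d"),
                         ("b", 30.0, 47.5, "x", "d")])
        gs = build_grid_set({"d": ev}, CH4, 60.0)
        s = summarize(gs, Scoring(["W", "N2"]))
        total = sum(st["basic_pct"] * st["n_segments"]
                    for st in s["by_stage"].values())
        assert total / gs.basic.n_segments == pytest.approx(
            s["overall"]["basic_pct"])


class TestGridToEvents:
    def test_round_trip(self):
        rng = np.random.default_rng(0)
        g = grid_of(rng.random((4, 12)) < 0.3, labels=CH4)
        back = events_to_grid(grid_to_events(g), CH4, g.duration_s)
        assert np.array_equal(back.values, g.values)

    def test_all_false_empty(self):
        assert len(grid_to_events(grid_of(np.zeros((2, 5))))) == 0

    def test_adjacent_segments_coalesce(self):
        g = grid_of([[0, 1, 1, 0, 1]], labels=["a"])
        tab = grid_to_events(g)
        assert len(tab) == 2
        np.testing.assert_allclose(
            tab.df[["start_s", "end_s"]].to_numpy(),
            [[5.0, 15.0], [20.0, 25.0]])
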