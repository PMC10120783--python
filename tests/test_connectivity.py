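"""Node extraction, dF/F%, sliding windows, Fisher z, homolog averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from widefc import connectivity as conn
from widefc import synth
from widefc.behavior import BehaviorTrace, PeriodInstance
from widefc.parcellate import NodeDomain


def _period(label, t0, t1):
    return PeriodInstance(label, t0, t1, 0.0, 0.0, 0.0)


def _domain(weights):
    return NodeDomain(weights > 0, weights.astype(float), 0, node_id=1)


class TestNodeExtraction:
    def test_uniform_frame_gives_frame_value(self, rng):
        frames = np.full((3, 4, 4), 7.0)
        w = rng.random((4, 4))
        out = conn.extract_node_timeseries(frames, [_domain(w)])
        np.testing.assert_allclose(out, 7.0)

    def test_point_weight_selects_pixel(self, rng):
        frames = rng.normal(size=(10, 4, 4))
        w = np.zeros((4, 4))
        w[2, 3] = 5.0
        out = conn.extract_node_timeseries(frames, [_domain(w)])
        np.testing.assert_allclose(out[:, 0], frames[:, 2, 3])

    def test_zero_weight_rejected(self, rng):
        with pytest.raises(ValueError):
            conn.extract_node_timeseries(np.zeros((2, 4, 4)), [_domain(np.zeros((4, 4)))])

    def test_extracted_series_tracks_known_source(self, rendered_trial):
        from widefc import preprocess as pre
        from widefc.parcellate import reference_footprints

        parc = rendered_trial["parcellation"]
        corr = pre.hemodynamic_correction(
            pre.lowpass_stack(rendered_trial["blue"]),
            pre.lowpass_stack(rendered_trial["violet"]))
        # vessel pixels are excluded before extraction, as in the pipeline
        foots = reference_footprints(parc.node_maps) & ~parc.vessel_mask
        domains = [NodeDomain(foots[k], np.where(foots[k], parc.node_maps[k], 0.0), k,
                              node_id=k + 1) for k in range(parc.n_nodes)]
        series = conn.extract_node_timeseries(corr.frames, domains)
        # the 7 Hz filter shapes both paths identically, so the oracle is
        # the equally filtered ground-truth source
        src = pre.lowpass_filter(rendered_trial["sources"], fps=20.0)
        cs = np.array([np.corrcoef(series[:, k], src[:, k])[0, 1]
                       for k in range(parc.n_nodes)])
        raw_foots = reference_footprints(parc.node_maps)
        vessel_frac = np.array([(raw_foots[k] & parc.vessel_mask).sum() / raw_foots[k].sum()
                                for k in range(parc.n_nodes)])
        # vessel-dominated nodes lose most of their pixels and degrade;
        # the artifact-rejection stage handles those
        assert cs[vessel_frac < 0.3].min() > 0.95
        assert cs.min() > 0.8


class TestDff:
    def test_baseline_gives_zero(self):
        raw = np.full((10, 3), 50.0)
        np.testing.assert_allclose(conn.to_dff(raw, np.full(3, 50.0)), 0.0)

    def test_ten_percent_change(self):
        out = conn.to_dff(np.array([[110.0]]), np.array([100.0]))
        assert out[0, 0] == pytest.approx(10.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            conn.to_dff(np.ones((2, 1)), np.array([0.0]))

    def test_all_session_mean_centers_dff(self, rng):
        raw = 100.0 + rng.normal(size=(500, 4))
        baseline = raw.mean(axis=0)
        assert np.abs(conn.to_dff(raw, baseline).mean(axis=0)).max() < 1e-10


class TestWindows:
    def test_twenty_second_period_yields_77_windows(self):
        wins = conn.make_windows(_period("walk", 0.0, 20.0), 20.0)
        assert len(wins) == 77

    def test_single_window_period(self):
        wins = conn.make_windows(_period("walk", 4.0, 5.0), 20.0)
        assert len(wins) == 1
        assert wins[0]["duration"] == pytest.approx(0.5)

    def test_window_holds_twenty_samples(self):
        wins = conn.make_windows(_period("rest", 0.0, 5.0), 20.0)
        assert all(w["frame_stop"] - w["frame_start"] == 20 for w in wins)

    def test_short_period_yields_empty(self):
        assert conn.make_windows(_period("rest", 0.0, 0.8), 20.0) == []

    @pytest.mark.parametrize("length", [1.0, 2.5, 7.75, 30.0])
    def test_window_count_formula(self, length):
        wins = conn.make_windows(_period("walk", 0.0, length), 20.0)
        assert len(wins) == int((length - 1.0) / 0.25) + 1


class TestWindowCorrelations:
    def test_duplicated_node_hits_clip_path(self, rng):
        x = rng.normal(size=(20, 1))
        dff = np.hstack([x, x, rng.normal(size=(20, 1))])
        z = conn.window_correlations(dff, [{"frame_start": 0, "frame_stop": 20,
                                            "center_time": 0.5}])
        assert z[0, 0] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_independent_noise_mean_z_near_zero(self, rng):
        dff = rng.normal(size=(4000, 4))
        wins = conn.make_windows(_period("rest", 0.0, 200.0), 20.0)
        z = conn.window_correlations(dff, wins)
        se = 1.0 / np.sqrt(17) / np.sqrt(len(wins))
        assert np.abs(z.mean(axis=0)).max() < 3 * se * 2

    def test_edge_count_for_32_nodes(self, rng):
        dff = rng.normal(size=(20, 32))
        z = conn.window_correlations(dff, [{"frame_start": 0, "frame_stop": 20,
                                            "center_time": 0.5}])
        assert z.shape == (1, 496)

    def test_zero_variance_node_marks_edges_missing(self, rng):
        dff = rng.normal(size=(20, 3))
        dff[:, 1] = 4.2
        z = conn.window_correlations(dff, [{"frame_start": 0, "frame_stop": 20,
                                            "center_time": 0.5}])
        edges = conn.edge_index(3)
        for e, (i, j) in enumerate(edges):
            assert np.isnan(z[0, e]) == (2 in (i, j))

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(min_value=2, max_value=40))
    def test_edge_enumeration_matches_brute_force(self, n):
        edges = conn.edge_index(n)
        brute = {(i, j) for i in range(1, n + 1) for j in range(1, n + 1) if i < j}
        assert len(edges) == n * (n - 1) // 2
        assert set(edges) == brute


class TestHomologAveraging:
    def _meta16(self):
        return synth.make_ground_truth_parcellation(16, (64, 64), seed=0).node_meta()

    def test_256_reduced_groups_for_16_pairs(self, rng):
        meta = self._meta16()
        z = rng.normal(size=(3, 496))
        reduced = conn.average_homologs(z, meta, mode="reduced")
        assert reduced.shape == (3, 256)

    def test_symmetric_input_unchanged_by_broadcast(self, rng):
        meta = synth.make_ground_truth_parcellation(2, (16, 16), seed=0).node_meta()
        keys, groups = conn.homolog_edge_groups(meta)
        group_vals = rng.normal(size=len(keys))
        z = group_vals[groups]  # mirrored-symmetric by construction
        out = conn.average_homologs(z, meta, mode="broadcast")
        np.testing.assert_allclose(out, z)

    def test_broadcast_equalizes_mirrored_edges(self, rng):
        meta = self._meta16()
        keys, groups = conn.homolog_edge_groups(meta)
        out = conn.average_homologs(rng.normal(size=496), meta, mode="broadcast")
        assert out.shape == (496,)
        for g in range(len(keys)):
            members = out[groups == g]
            np.testing.assert_allclose(members, members[0])

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(st.integers(min_value=0, max_value=1000))
    def test_symmetric_global_mean_preserved(self, seed):
        meta = synth.make_ground_truth_parcellation(4, (32, 32), seed=0).node_meta()
        keys, groups = conn.homolog_edge_groups(meta)
        z = np.random.default_rng(seed).normal(size=len(groups))
        sym = conn.average_homologs(z, meta, mode="broadcast")
        resym = conn.average_homologs(sym, meta, mode="broadcast")
        np.testing.assert_allclose(sym.mean(), resym.mean())
        np.testing.assert_allclose(sym, resym)

    def test_unmapped_node_rejected(self, rng):
        meta = self._meta16().iloc[:-1]
        with pytest.raises(ValueError):
            conn.average_homologs(rng.normal(size=(1, 496)), meta)


class TestWindowBehavior:
    def _trace(self, speed, pupil=None):
        return BehaviorTrace(speed, np.gradient(speed) * 20.0, pupil, 20.0)

    def test_constant_speed_mean(self):
        wins = conn.make_windows(_period("walk", 0.0, 2.0), 20.0)
        out = conn.window_behavior(self._trace(np.full(40, 3.33)), wins)
        np.testing.assert_allclose(out["mean_speed"], 3.33)

    def test_fully_missing_pupil_propagates(self):
        wins = conn.make_windows(_period("walk", 0.0, 1.0), 20.0)
        out = conn.window_behavior(self._trace(np.zeros(20), np.full(20, np.nan)), wins)
        assert np.isnan(out["mean_pupil"]).all()

    def test_ramp_mean_is_midpoint(self):
        speed = np.linspace(0, 1, 20, endpoint=False)
        wins = [{"frame_start": 0, "frame_stop": 20, "center_time": 0.5}]
        out = conn.window_behavior(self._trace(speed), wins)
        assert out.loc[0, "mean_speed"] == pytest.approx(0.5, abs=0.03)

    def test_acceleration_averaged_after_abs(self):
        speed = np.r_[np.linspace(0, 1, 20), np.linspace(1, 0, 20)]
        trace = self._trace(speed)
        wins = [{"frame_start": 0, "frame_stop": 40, "center_time": 1.0}]
        out = conn.window_behavior(trace, wins)
        assert out.loc[0, "mean_abs_accel"] > 0.5

    def test_misaligned_trace_rejected(self):
        wins = [{"frame_start": 0, "frame_stop": 20, "center_time": 0.5}]
        with pytest.raises(ValueError):
            conn.window_behavior(self._trace(np.zeros(10)), wins)
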