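"""Segmentation algorithm tests: partitioning, thresholds, grouping,
classification and population fractions, each against a brute-force oracle."""

import numpy as np
import pytest

from sptkit.msd import Trajectory
from sptkit.segmentation import (
    SpeedThresholds,
    classify_domains,
    derive_thresholds,
    group_sequences,
    partition_segments,
    population_fractions,
    segment_ensemble,
    segment_track,
)
from sptkit.synthetic import (
    MotionDomainSpec,
    iter_ensemble,
    simulate_stop_and_go,
)


def drift_track(n=30, v_um_min=2.0, heading=0.3, dt=1.0, track_id="drift"):
    t = simulate_stop_and_go(
        [MotionDomainSpec("flow", n, D=0.0, v=v_um_min, heading=heading)],
        dt=dt, noise_sd=0.0, seed=0)
    return Trajectory(track_id, t.positions, dt)


def random_track(n=30, seed=0, dt=1.0):
    rng = np.random.default_rng(seed)
    return Trajectory(f"r{seed}", rng.normal(size=(n, 2)), dt)


class TestPartitionSegments:
    def test_nine_frames_give_three_segments(self):
        segs = partition_segments(random_track(9), m=3)
        assert len(segs) == 3
        assert [(s.start, s.stop) for s in segs] == [(0, 3), (3, 6), (6, 9)]

    def test_remainder_attached_to_last_segment(self):
        segs = partition_segments(random_track(11), m=3)
        assert [(s.start, s.stop) for s in segs] == [(0, 3), (3, 6), (6, 11)]

    def test_pure_drift_segment_speeds_exact(self):
        v, h = 1.2, 0.8
        segs = partition_segments(drift_track(12, v, h), m=3)
        vx, vy = (v / 60.0) * np.cos(h), (v / 60.0) * np.sin(h)
        for s in segs:
            assert s.v_x == pytest.approx(vx, rel=1e-9)
            assert s.v_y == pytest.approx(vy, rel=1e-9)

    def test_speeds_match_finite_difference_oracle(self):
        track = random_track(10, seed=5, dt=0.5)
        segs = partition_segments(track, m=3)
        for s in segs:
            span = track.positions[s.start:s.stop]
            diffs = np.diff(span, axis=0) / 0.5
            assert s.v_x == pytest.approx(diffs[:, 0].mean(), rel=1e-12)
            assert s.v_y == pytest.approx(diffs[:, 1].mean(), rel=1e-12)

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            partition_segments(random_track(5), m=3)


class TestDeriveThresholds:
    def test_identical_segments_give_07_of_abs_speed(self):
        track = drift_track(36, v_um_min=3.0, heading=0.5)
        segs = partition_segments(track, m=3)
        thr = derive_thresholds(segs)
        assert thr.v_x_thr == pytest.approx(0.7 * abs(segs[0].v_x), rel=1e-9)
        assert thr.v_y_thr == pytest.approx(0.7 * abs(segs[0].v_y), rel=1e-9)

    def test_equals_brute_force_mean_over_segment_table(self):
        segs = []
        for seed in range(4):
            segs += partition_segments(random_track(30, seed=seed), m=3)
        thr = derive_thresholds(segs, factor=0.7)
        assert thr.v_x_thr == pytest.approx(
            0.7 * np.mean([abs(s.v_x) for s in segs]), rel=1e-12)
        assert thr.v_y_thr == pytest.approx(
            0.7 * np.mean([abs(s.v_y) for s in segs]), rel=1e-12)

    def test_factor_configurable(self):
        segs = partition_segments(random_track(60, seed=1), m=3)
        half = derive_thresholds(segs, factor=0.5)
        full = derive_thresholds(segs, factor=1.0)
        assert half.v_x_thr == pytest.approx(0.5 * full.v_x_thr, rel=1e-12)

    def test_too_few_segments_rejected(self):
        segs = partition_segments(random_track(9), m=3)
        with pytest.raises(ValueError):
            derive_thresholds(segs)


class TestGroupSequences:
    def test_all_below_is_one_run(self):
        segs = partition_segments(random_track(30, seed=2), m=3)
        thr = SpeedThresholds(v_x_thr=1e9, v_y_thr=1e9)
        runs = group_sequences(segs, thr)
        assert len(runs) == 1 and not runs[0].above
        assert (runs[0].start, runs[0].stop) == (0, 30)

    def test_alternating_segments_yield_unit_runs(self):
        # alternate drift-like and stationary 3-frame stretches
        pos = []
        x = 0.0
        for k in range(6):
            for i in range(3):
                pos.append([x, 0.0])
                if k % 2 == 0:
                    x += 1.0
        track = Trajectory("alt", np.array(pos[:18]))
        segs = partition_segments(track, m=3)
        thr = SpeedThresholds(v_x_thr=0.3, v_y_thr=1e9)
        runs = group_sequences(segs, thr)
        above_runs = [r for r in runs if r.above]
        assert all(r.n_segments <= 2 for r in runs)
        assert len(runs) >= 4

    def test_run_boundaries_match_linear_scan(self):
        segs = partition_segments(random_track(60, seed=3), m=3)
        thr = derive_thresholds(segs)
        runs = group_sequences(segs, thr)
        # oracle: independent linear scan over the above/below flags
        flags = [abs(s.v_x) >= thr.v_x_thr or abs(s.v_y) >= thr.v_y_thr
                 for s in segs]
        expected = []
        start = 0
        for i in range(1, len(flags) + 1):
            if i == len(flags) or flags[i] != flags[start]:
                expected.append((flags[start], segs[start].start, segs[i - 1].stop))
                start = i
        got = [(r.above, r.start, r.stop) for r in runs]
        assert got == expected
        assert runs[0].start == 0 and runs[-1].stop == 60


class TestClassifyDomains:
    def test_pure_drift_is_one_flow_domain_with_alpha_one(self):
        track = drift_track(30, v_um_min=3.0)
        thr = SpeedThresholds(v_x_thr=1e-4, v_y_thr=1e-4)
        seg = segment_track(track, thr)
        assert set(seg.labels) == {"flow"}
        assert len(seg.domains) == 1
        assert seg.domains[0].alpha_local == pytest.approx(1.0, abs=1e-9)

    def test_impossible_alpha_threshold_gives_all_diffusion(self):
        track = drift_track(30, v_um_min=3.0)
        thr = SpeedThresholds(v_x_thr=0.0, v_y_thr=0.0)
        seg = segment_track(track, thr, alpha_thr=1.0)
        assert set(seg.labels) == {"diffusion"}

    def test_zero_thresholds_and_zero_alpha_make_long_runs_flow(self):
        track = random_track(30, seed=7)
        thr = SpeedThresholds(v_x_thr=0.0, v_y_thr=0.0)
        seg = segment_track(track, thr, alpha_thr=0.0)
        # every segment is above zero thresholds -> one >= 2-segment run
        assert set(seg.labels) == {"flow"}

    def test_labels_tile_track_and_domains_partition(self):
        track = random_track(64, seed=9)
        thr = SpeedThresholds(v_x_thr=0.5, v_y_thr=0.5)
        seg = segment_track(track, thr)
        assert seg.n_frames == 64
        spans = [(d.start, d.stop) for d in seg.domains]
        assert spans[0][0] == 0 and spans[-1][1] == 64
        for (a, b), (c, _) in zip(spans[:-1], spans[1:]):
            assert b == c
        for d in seg.domains:
            assert np.all(seg.labels[d.start:d.stop] == d.kind)

    def test_no_flow_domain_shorter_than_two_segments(self):
        for seed in range(5):
            mk = lambda s: simulate_stop_and_go(
                [MotionDomainSpec("brownian", 40, 1e-3),
                 MotionDomainSpec("flow", 20, 1e-4, v=3.0, heading=0.2),
                 MotionDomainSpec("brownian", 40, 1e-3)],
                noise_sd=0.0, seed=s)
            tracks = [t.to_trajectory(i) for i, t in
                      enumerate(iter_ensemble(mk, 5, seed=seed))]
            segmented, _ = segment_ensemble(tracks, m=3)
            for seg in segmented:
                for d in seg.domains:
                    if d.kind == "flow":
                        assert d.stop - d.start >= 2 * 3

    def test_deterministic_relabeling(self):
        tracks = [random_track(50, seed=s) for s in range(5)]
        a, thr_a = segment_ensemble(tracks)
        b, thr_b = segment_ensemble(tracks)
        assert thr_a == thr_b
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.labels, y.labels)

    def test_scale_equivariance_leaves_labels_unchanged(self):
        tracks = [random_track(50, seed=s) for s in range(5)]
        scaled = [Trajectory(t.track_id, 3.7 * t.positions, t.frame_interval)
                  for t in tracks]
        a, thr_a = segment_ensemble(tracks)
        b, thr_b = segment_ensemble(scaled)
        assert thr_b.v_x_thr == pytest.approx(3.7 * thr_a.v_x_thr, rel=1e-9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.labels, y.labels)

    def test_ground_truth_recovery_on_stop_and_go(self):
        # strong drift against slow diffusion: frame-level agreement with
        # the generator's labels should be high
        mk = lambda s: simulate_stop_and_go(
            [MotionDomainSpec("brownian", 60, 2e-4),
             MotionDomainSpec("flow", 30, 2e-4, v=3.0, heading=0.9),
             MotionDomainSpec("brownian", 60, 2e-4)],
            noise_sd=0.01, seed=s)
        sims = list(iter_ensemble(mk, 20, seed=11))
        tracks = [t.to_trajectory(i) for i, t in enumerate(sims)]
        segmented, _ = segment_ensemble(tracks, m=3)
        agree = np.concatenate([
            (seg.labels == "flow") == (sim.labels == "flow")
            for seg, sim in zip(segmented, sims)])
        assert agree.mean() > 0.8


class TestPopulationFractions:
    def test_all_diffusion_ensemble(self):
        tracks = [random_track(30, seed=s) for s in range(3)]
        thr = SpeedThresholds(v_x_thr=1e9, v_y_thr=1e9)
        segmented = [segment_track(t, thr) for t in tracks]
        summary = population_fractions(segmented)
        assert summary.time_fractions == {"diffusion": 1.0, "flow": 0.0}
        assert summary.track_fractions == {"diffusion": 1.0, "flow": 0.0}

    def test_fractions_match_frame_counting_oracle(self):
        mk = lambda s: simulate_stop_and_go(
            [MotionDomainSpec("brownian", 30, 2e-4),
             MotionDomainSpec("flow", 30, 2e-4, v=3.0, heading=0.4)],
            noise_sd=0.0, seed=s)
        tracks = [t.to_trajectory(i) for i, t in
                  enumerate(iter_ensemble(mk, 8, seed=13))]
        segmented, _ = segment_ensemble(tracks)
        summary = population_fractions(segmented)
        flow_frames = sum(int(np.sum(s.labels == "flow")) for s in segmented)
        total = sum(s.n_frames for s in segmented)
        assert summary.time_fractions["flow"] == pytest.approx(flow_frames / total)
        dom_flow = sum(np.mean(s.labels == "flow") > 0.5 for s in segmented)
        assert summary.track_fractions["flow"] == pytest.approx(dom_flow / len(segmented))
        for fr in (summary.time_fractions, summary.track_fractions):
            assert fr["diffusion"] + fr["flow"] == pytest.approx(1.0)
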