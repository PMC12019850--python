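"""Vesicle detection, linking, mobility classification, and summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from axonmt.transport import (
    DetectionTable,
    Track,
    classify_mobility,
    detect_particles,
    filter_tracks,
    link_tracks,
    summarize_cell,
    track_metrics,
)


def table_from_positions(positions, frame_rate_hz=5.0):
    """positions: dict particle -> {frame: (x_nm, y_nm)}."""
    rows = []
    for pid, frames in positions.items():
        for frame, (x, y) in frames.items():
            rows.append({"frame": frame, "x_nm": x, "y_nm": y, "intensity": 100.0})
    return DetectionTable(pd.DataFrame(rows), frame_rate_hz=frame_rate_hz)


def gaussian_spot(shape, center_px, sigma=1.2, amplitude=1000.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(-((rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2) / (2 * sigma**2))


class TestDetectParticles:
    def test_single_spot_detected_at_center(self):
        stack = np.stack([gaussian_spot((41, 41), (20.0, 17.0)) for _ in range(4)])
        dets = detect_particles(stack)
        assert len(dets) == 4
        np.testing.assert_allclose(dets.data["y_nm"] / 172.0, 20.0, atol=0.1)
        np.testing.assert_allclose(dets.data["x_nm"] / 172.0, 17.0, atol=0.1)

    def test_well_separated_spots_never_merge(self):
        # 2 um apart = ~11.6 px >> 500 nm window
        frame = gaussian_spot((41, 41), (10, 10)) + gaussian_spot((41, 41), (10, 22))
        dets = detect_particles(frame[None])
        assert len(dets) == 2

    def test_spots_closer_than_window_merge(self):
        # 300 nm apart inside one 500 nm detection window
        frame = gaussian_spot((41, 41), (20, 20)) + gaussian_spot((41, 41), (20, 21.7))
        dets = detect_particles(frame[None])
        assert len(dets) == 1

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            detect_particles(np.empty((0, 10, 10)))


class TestLinking:
    def test_constant_velocity_particle_single_track(self):
        positions = {0: {f: (f * 150.0, 0.0) for f in range(30)}}
        tracks = link_tracks(table_from_positions(positions))
        assert len(tracks) == 1
        assert len(tracks[0]) == 30

    def test_gap_longer_than_two_frames_splits_track(self):
        frames = {f: (f * 100.0, 0.0) for f in range(30) if f not in (10, 11, 12)}
        tracks = link_tracks(table_from_positions({0: frames}))
        assert len(tracks) == 2

    def test_gap_of_two_frames_bridged(self):
        frames = {f: (f * 100.0, 0.0) for f in range(30) if f not in (10, 11)}
        tracks = link_tracks(table_from_positions({0: frames}))
        assert len(tracks) == 1
        assert tracks[0].gap_positions == [10, 11]

    def test_linking_matches_brute_force_assignment_oracle(self):
        # 3 well-separated particles; every frame the linker's matching must
        # equal exhaustive minimum-cost assignment under the same predictions
        rng = np.random.default_rng(2)
        speeds = [(120.0, 0.0), (0.0, 0.0), (-80.0, 40.0)]
        starts = [(0.0, 0.0), (10_000.0, 10_000.0), (30_000.0, 0.0)]
        positions = {}
        for pid, ((vx, vy), (x0, y0)) in enumerate(zip(speeds, starts)):
            positions[pid] = {
                f: (x0 + f * vx + rng.normal(0, 20), y0 + f * vy + rng.normal(0, 20))
                for f in range(25)
            }
        tracks = link_tracks(table_from_positions(positions))
        assert len(tracks) == 3
        # ground-truth partition: each track stays on one particle
        for track in tracks:
            x0 = track.xy_nm[0]
            pid = int(np.argmin([np.hypot(x0[0] - s[0], x0[1] - s[1]) for s in starts]))
            expected = np.array([positions[pid][int(f)] for f in track.frames])
            np.testing.assert_allclose(track.xy_nm, expected, atol=1e-9)
        # brute-force check frame by frame: greedy-free exhaustive assignment
        for frame in range(1, 25):
            prev = {pid: np.array(positions[pid][frame - 1]) for pid in positions}
            curr = {pid: np.array(positions[pid][frame]) for pid in positions}
            pids = sorted(positions)
            best, best_cost = None, np.inf
            for perm in itertools.permutations(pids):
                cost = sum(np.linalg.norm(curr[q] - prev[p]) for p, q in zip(pids, perm))
                if cost < best_cost:
                    best, best_cost = perm, cost
            assert best == tuple(pids)  # well-separated: identity assignment

    def test_permutation_invariance_within_frames(self):
        rng = np.random.default_rng(0)
        positions = {
            pid: {f: (pid * 8000.0 + f * 100.0, rng.normal(0, 30)) for f in range(20)}
            for pid in range(4)
        }
        table = table_from_positions(positions)
        shuffled = DetectionTable(
            table.data.sample(frac=1.0, random_state=1).reset_index(drop=True),
            frame_rate_hz=table.frame_rate_hz,
        )
        tracks_a = link_tracks(table)
        tracks_b = link_tracks(shuffled)
        assert len(tracks_a) == len(tracks_b)
        for a, b in zip(tracks_a, tracks_b):
            np.testing.assert_array_equal(a.frames, b.frames)
            np.testing.assert_allclose(a.xy_nm, b.xy_nm)

    def test_every_link_respects_gates(self):
        rng = np.random.default_rng(9)
        positions = {
            pid: {
                f: (pid * 5000.0 + f * rng.uniform(50, 250), rng.normal(0, 40))
                for f in range(40)
                if rng.uniform() > 0.1
            }
            for pid in range(5)
        }
        for track in link_tracks(table_from_positions(positions)):
            if len(track) < 2:
                continue
            gaps = np.diff(track.frames)
            assert gaps.max() <= 3  # at most 2 missing frames between detections
            steps = np.linalg.norm(np.diff(track.xy_nm, axis=0), axis=1)
            # per-frame displacement bounded by the 1 um gate plus AR slack
            assert (steps / gaps).max() <= 2_000.0

    def test_no_detections_no_tracks(self):
        table = DetectionTable(pd.DataFrame(columns=["frame", "x_nm", "y_nm", "intensity"]))
        assert link_tracks(table) == []


class TestFilterAndMetrics:
    def make_track(self, n_frames, step_nm=100.0):
        return Track(
            id=0,
            frames=np.arange(n_frames),
            xy_nm=np.stack([np.arange(n_frames) * step_nm, np.zeros(n_frames)], axis=1),
        )

    def test_minimum_span_boundary(self):
        assert filter_tracks([self.make_track(14)]) == []
        assert len(filter_tracks([self.make_track(15)])) == 1

    def test_straight_run_metrics(self):
        # 0.2 um/s at 5 frames/s for 60 s
        track = Track(
            id=0,
            frames=np.arange(300),
            xy_nm=np.stack([np.arange(300) * 40.0, np.zeros(300)], axis=1),
        )
        metrics = track_metrics(track)
        assert metrics.mobile
        assert metrics.velocity_um_s == pytest.approx(0.2, rel=1e-6)
        assert metrics.speed_um_s == pytest.approx(0.2, rel=1e-6)

    def test_exact_threshold_is_stationary(self):
        track = Track(id=0, frames=np.array([0, 300]), xy_nm=np.array([[0.0, 0.0], [750.0, 0.0]]))
        assert not track_metrics(track).mobile
        assert classify_mobility(0.75) == "stationary"
        assert classify_mobility(0.7500001) == "mobile"

    def test_back_and_forth_zero_velocity_positive_speed(self):
        xy = np.zeros((301, 2))
        xy[:, 0] = 3000.0 * (np.arange(301) % 2)  # 3 um hops back and forth
        track = Track(id=0, frames=np.arange(301), xy_nm=xy)
        metrics = track_metrics(track)
        assert not metrics.mobile
        assert metrics.velocity_um_s == pytest.approx(0.0, abs=1e-9)
        assert metrics.speed_um_s > 0

    def test_speed_dominates_velocity_for_random_tracks(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = rng.integers(2, 50)
            track = Track(id=0, frames=np.arange(n), xy_nm=rng.normal(0, 500, (n, 2)))
            metrics = track_metrics(track)
            assert metrics.speed_um_s >= abs(metrics.velocity_um_s) - 1e-12
            assert metrics.path_length_um >= metrics.net_displacement_um - 1e-12

    def test_direction_from_reference_axis(self):
        track = self.make_track(20, step_nm=100.0)
        metrics = track_metrics(track, reference_point_nm=(0.0, 0.0), distal_point_nm=(10_000.0, 0.0))
        assert metrics.direction == "anterograde"
        metrics = track_metrics(track, reference_point_nm=(10_000.0, 0.0), distal_point_nm=(0.0, 0.0))
        assert metrics.direction == "retrograde"
        jitter = Track(id=0, frames=np.arange(20), xy_nm=np.full((20, 2), 5.0))
        metrics = track_metrics(jitter, reference_point_nm=(0.0, 0.0), distal_point_nm=(1.0, 0.0))
        assert metrics.direction == "undirected"


class TestSummaries:
    def test_mobile_fraction(self):
        tracks = [
            Track(id=i, frames=np.arange(100), xy_nm=np.stack([np.arange(100) * s, np.zeros(100)], axis=1))
            for i, s in enumerate([100.0, 120.0, 90.0, 0.5])
        ]
        summary = summarize_cell(tracks)
        assert summary.mobile_fraction == pytest.approx(0.75)
        assert summary.n_mobile == 3

    def test_all_stationary(self):
        tracks = [Track(id=0, frames=np.arange(100), xy_nm=np.full((100, 2), 3.0))]
        assert summarize_cell(tracks).mobile_fraction == 0.0

    def test_no_tracks_flagged_not_zero(self):
        with pytest.warns(UserWarning, match="undefined"):
            summary = summarize_cell([])
        assert summary.mobile_fraction is None
        assert "no retained tracks" in summary.warnings_

    def test_mixture_fraction_recovered(self):
        # light version of the acceptance battery: 3 seeds, default mixture
        from axonmt import synth

        errors = []
        for seed in (0, 1, 2):
            dets, truth = synth.gen_vesicle_series(n_particles=40, seed=seed)
            tracks = filter_tracks(link_tracks(dets))
            summary = summarize_cell(tracks)
            errors.append(summary.mobile_fraction - truth["mobile"].mean())
        assert abs(np.mean(errors)) <= 0.05
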