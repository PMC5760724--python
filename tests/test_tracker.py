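import math

import numpy as np
import pytest

from dimtrack import (
    AutomaticPolicy,
    MotionModel,
    OraclePolicy,
    ParticleSpec,
    SyntheticMovieSpec,
    Track,
    TrackingConfig,
    TrackPoint,
    calibrate_noise_for_snr,
    define_scan_region,
    detect_local_maxima,
    predict_linear_motion,
    render_spot,
    simulate_movie,
    step_frame,
    track_movie,
)
from dimtrack.tracker import IllegalDecisionError, InterventionDecision, gap_point


def _track_from(points):
    t = Track(track_id=0)
    for p in points:
        t.points.append(p)
    return t


def pt(frame, x, y, status="detected", intensity=1.0):
    return TrackPoint(frame=frame, x=x, y=y, intensity=intensity, status=status)


class TestTrackPointInvariants:
    def test_gap_requires_all_nan(self):
        with pytest.raises(ValueError):
            TrackPoint(frame=0, x=1.0, y=math.nan, intensity=math.nan, status="gap")

    def test_non_gap_requires_coordinates(self):
        with pytest.raises(ValueError):
            TrackPoint(frame=0, x=math.nan, y=math.nan, intensity=math.nan, status="detected")

    def test_append_enforces_consecutive_frames_and_stop(self):
        t = _track_from([pt(0, 1, 1)])
        with pytest.raises(ValueError):
            t.append(pt(2, 1, 1))
        t.append(TrackPoint(frame=1, x=1.0, y=1.0, intensity=math.nan, status="stopped"))
        with pytest.raises(ValueError):
            t.append(pt(2, 1, 1))


class TestDetectLocalMaxima:
    def test_single_bright_pixel(self, config):
        img = np.zeros((64, 64))
        img[30, 28] = 100.0
        region = define_scan_region((28, 30), config, img.shape)
        cands = detect_local_maxima(img, region, config)
        assert len(cands) == 1
        assert (cands[0].row, cands[0].col) == (30, 28)

    def test_flat_image_yields_nothing(self, config):
        img = np.full((64, 64), 50.0)
        region = define_scan_region((30, 30), config, img.shape)
        assert detect_local_maxima(img, region, config) == []

    def test_two_spots_give_two_candidates(self):
        cfg = TrackingConfig(scan_rows=21, scan_cols=21, window_size=5, min_separation=5)
        img = np.zeros((64, 64))
        render_spot(img, 100, 25.0, 30.0, 1.5, 1.5)
        render_spot(img, 90, 35.0, 30.0, 1.5, 1.5)
        region = define_scan_region((30, 30), cfg, img.shape)
        cands = detect_local_maxima(img, region, cfg)
        assert len(cands) == 2
        found = sorted((c.col, c.row) for c in cands)
        assert abs(found[0][0] - 25) <= 1 and abs(found[0][1] - 30) <= 1
        assert abs(found[1][0] - 35) <= 1 and abs(found[1][1] - 30) <= 1
        # brightest first
        assert cands[0].window_mean >= cands[1].window_mean

    def test_close_candidates_suppressed(self):
        cfg = TrackingConfig(scan_rows=21, scan_cols=21, window_size=5, min_separation=9)
        img = np.zeros((64, 64))
        render_spot(img, 100, 27.0, 30.0, 1.5, 1.5)
        render_spot(img, 90, 33.0, 30.0, 1.5, 1.5)  # 6 px apart < min_separation
        region = define_scan_region((30, 30), cfg, img.shape)
        assert len(detect_local_maxima(img, region, cfg)) == 1

    def test_region_smaller_than_window_yields_nothing(self):
        cfg = TrackingConfig(scan_rows=9, scan_cols=9, window_size=9)
        img = np.zeros((64, 64))
        img[1, 1] = 100.0
        region = define_scan_region((1, 1), cfg, img.shape)  # clipped below 9x9
        assert detect_local_maxima(img, region, cfg) == []


class TestPredictLinearMotion:
    def test_constant_velocity_extrapolation(self):
        t = _track_from([pt(0, 1, 1), pt(1, 2, 3)])
        assert predict_linear_motion(t, 2) == (3.0, 5.0)

    def test_zero_velocity(self):
        t = _track_from([pt(0, 4, 4), pt(1, 4, 4)])
        assert predict_linear_motion(t, 2) == (4.0, 4.0)

    def test_velocity_bridges_gaps(self):
        t = _track_from([pt(0, 0, 0), gap_point(1), pt(2, 2, 0)])
        assert predict_linear_motion(t, 3) == (3.0, 0.0)

    def test_insufficient_history_raises(self):
        t = _track_from([pt(0, 1, 1)])
        with pytest.raises(ValueError, match="fall back"):
            predict_linear_motion(t, 1)


class TestStepFrame:
    def test_bright_spot_detected_subpixel(self, config, spot_movie):
        sigma = calibrate_noise_for_snr(100, 1.5, 1.5, 5, 10)
        stack, truth = spot_movie(n_frames=2, start=(30.3, 25.6), noise_sigma=sigma, seed=5)
        t = _track_from([pt(0, 30.3, 25.6, status="manual")])
        point = step_frame(t, stack[1], config, AutomaticPolicy())
        assert point.status == "detected"
        assert math.hypot(point.x - 30.3, point.y - 25.6) < 0.2

    def test_blank_frame_gap_policy(self, config):
        t = _track_from([pt(0, 30, 25, status="manual")])
        blank = np.full((64, 64), 100.0)
        point = step_frame(t, blank, config, AutomaticPolicy(no_maximum_action="gap"))
        assert point.status == "gap" and math.isnan(point.x)

    def test_blank_frame_stop_policy_terminates(self, config):
        t = _track_from([pt(0, 30, 25, status="manual")])
        blank = np.full((64, 64), 100.0)
        point = step_frame(t, blank, config, AutomaticPolicy(no_maximum_action="stop"))
        assert point.status == "stopped"
        assert (point.x, point.y) == (30.0, 25.0)
        assert t.stopped

    def test_overlap_linear_motion_continues_line(self):
        cfg = TrackingConfig(scan_rows=21, scan_cols=21, window_size=5)
        img = np.zeros((64, 64))
        render_spot(img, 100, 30.0, 28.0, 1.5, 1.5)  # intruder
        render_spot(img, 100, 26.0, 24.0, 1.5, 1.5)  # our particle, on its line
        t = _track_from([pt(0, 24, 22), pt(1, 25, 23)])  # velocity (1, 1)
        point = step_frame(t, img, cfg, AutomaticPolicy(overlap_action="linear_motion"))
        assert point.status == "predicted"
        assert math.hypot(point.x - 26, point.y - 24) < 0.5

    def test_illegal_action_for_request_kind(self, config):
        class BadPolicy:
            def decide(self, request):
                return InterventionDecision(action="linear_motion")  # illegal for no_maximum

        t = _track_from([pt(0, 30, 25, status="manual")])
        blank = np.full((64, 64), 100.0)
        with pytest.raises(IllegalDecisionError, match="no_maximum"):
            step_frame(t, blank, config, BadPolicy())


class RecordingImage:
    """2D image proxy that records every slice handed to the engine."""

    def __init__(self, arr):
        self.arr = np.asarray(arr)
        self.accesses = []

    @property
    def shape(self):
        return self.arr.shape

    def __getitem__(self, idx):
        self.accesses.append(idx)
        return self.arr[idx]


class TestEngineAccessDiscipline:
    def test_detection_reads_only_the_scan_region(self, config, spot_movie):
        stack, _ = spot_movie(n_frames=2, start=(30.0, 25.0), noise_sigma=0.0)
        t = _track_from([pt(0, 30, 25, status="manual")])
        proxy = RecordingImage(stack[1])
        region = define_scan_region((30, 25), config, stack[1].shape)
        step_frame(t, proxy, config, AutomaticPolicy())
        assert proxy.accesses, "engine should slice the frame"
        for idx in proxy.accesses:
            rs, cs = idx
            assert rs.start >= region.row_min and rs.stop - 1 <= region.row_max
            assert cs.start >= region.col_min and cs.stop - 1 <= region.col_max


class TestTrackMovie:
    def test_stationary_high_snr_recovery(self, spot_movie, config):
        sigma = calibrate_noise_for_snr(100, 1.5, 1.5, 5, 10)
        stack, truth = spot_movie(n_frames=50, start=(30.3, 25.7), noise_sigma=sigma, seed=3)
        result = track_movie(stack, [(30.3, 25.7)], config, AutomaticPolicy())
        (track,) = result.tracks
        assert len(track.points) == 50
        errs = [
            math.hypot(p.x - truth.positions[0, p.frame, 0], p.y - truth.positions[0, p.frame, 1])
            for p in track.points
        ]
        assert math.sqrt(np.mean(np.square(errs))) < 0.1

    def test_two_separated_spots_no_interventions(self, config):
        spec = SyntheticMovieSpec(
            n_frames=20, height=64, width=64,
            particles=(ParticleSpec(start=(15, 15)), ParticleSpec(start=(45, 45))),
            noise_sigma=2.0, seed=4,
        )
        stack, _ = simulate_movie(spec)
        result = track_movie(stack, [(15, 15), (45, 45)], config, AutomaticPolicy())
        assert len(result.tracks) == 2
        assert all(len(t.points) == 20 for t in result.tracks)
        assert result.interventions == []

    def test_blink_produces_exact_gap_run_then_resumes(self, spot_movie, config):
        stack, truth = spot_movie(
            n_frames=40, start=(30, 25), noise_sigma=2.0, seed=2,
            blink_frames=range(20, 25),
        )
        result = track_movie(stack, [(30, 25)], config, AutomaticPolicy())
        (track,) = result.tracks
        gaps = [p.frame for p in track.points if p.status == "gap"]
        assert gaps == [20, 21, 22, 23, 24]
        p25 = track.points[25]
        assert p25.status == "detected"
        assert math.hypot(p25.x - 30, p25.y - 25) < 0.5

    def test_statuses_partition_and_frames_contiguous(self, spot_movie, config):
        stack, _ = spot_movie(n_frames=25, noise_sigma=2.0, blink_frames=range(10, 13))
        result = track_movie(stack, [(30, 25)], config, AutomaticPolicy())
        from dimtrack.tracker import STATUSES

        for t in result.tracks:
            assert [p.frame for p in t.points] == list(range(len(t.points)))
            assert all(p.status in STATUSES for p in t.points)
            assert not t.points[0].is_gap

    def test_empty_annotations_rejected(self, config):
        with pytest.raises(ValueError):
            track_movie(np.zeros((2, 32, 32)), [], config, AutomaticPolicy())

    def test_annotation_outside_frame_names_particle(self, config):
        with pytest.raises(ValueError, match="position 1"):
            track_movie(np.zeros((2, 32, 32)), [(5, 5), (99, 5)], config, AutomaticPolicy())

    def test_deterministic_tracks(self, spot_movie, config):
        stack, _ = spot_movie(n_frames=20, noise_sigma=3.0, seed=8)
        from dimtrack.io import tracks_to_dataframe

        r1 = track_movie(stack, [(30, 25)], config, AutomaticPolicy())
        r2 = track_movie(stack, [(30, 25)], config, AutomaticPolicy())
        assert tracks_to_dataframe(r1.tracks).equals(tracks_to_dataframe(r2.tracks))

    def test_raising_brightness_threshold_never_adds_detections(self, spot_movie):
        sigma = calibrate_noise_for_snr(100, 1.5, 1.5, 5, 2)
        stack, _ = spot_movie(n_frames=30, noise_sigma=sigma, seed=6)
        counts = []
        for k in (0.5, 2.0, 4.0, 8.0):
            cfg = TrackingConfig(brightness_k=k)
            res = track_movie(stack, [(30, 25)], cfg, AutomaticPolicy())
            counts.append(
                sum(p.status == "detected" for t in res.tracks for p in t.points)
            )
        assert counts == sorted(counts, reverse=True)


class TestOracleCrossing:
    def test_oracle_assignment_on_crossing_particles(self):
        """Frame-wise assignment >= 95% correct at SNR 2 with two crossing
        particles when ground truth answers every intervention."""
        cfg = TrackingConfig(scan_rows=21, scan_cols=21, window_size=5)
        sigma = calibrate_noise_for_snr(100, 1.5, 1.5, 5, 2)
        correct = total = 0
        for seed in range(3):
            mover = ParticleSpec(
                start=(10.0, 20.0), motion=MotionModel(kind="directed", velocity=(1.3, 0.0))
            )
            stationary = ParticleSpec(start=(32.0, 26.0))
            spec = SyntheticMovieSpec(
                n_frames=40, height=48, width=72, particles=(mover, stationary),
                noise_sigma=sigma, seed=seed,
            )
            stack, truth = simulate_movie(spec)
            res = track_movie(stack, [(10, 20), (32, 26)], cfg, OraclePolicy(truth))
            for tid, track in enumerate(res.tracks):
                for p in track.points:
                    if p.is_gap or p.status == "stopped":
                        continue
                    d = np.hypot(
                        truth.positions[:, p.frame, 0] - p.x,
                        truth.positions[:, p.frame, 1] - p.y,
                    )
                    total += 1
                    correct += int(np.argmin(d) == tid)
        assert correct / total >= 0.95
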