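"""Displacement reduction, valley detection, drift and irregularity checks."""

import numpy as np
import pytest

from pillartrack import (
    BeatSegments,
    RunConfig,
    SyntheticMovieSpec,
    TrackedTrajectories,
    adjust_start,
    analyze_movie,
    detect_drift,
    detect_irregular,
    find_valleys,
    generate_movie,
    mean_displacement,
    split_beats,
)
from pillartrack.beat_analysis import contraction_signal, slice_beats
from pillartrack.errors import BeatAnalysisError


def _traj(coords, pillar="left"):
    coords = np.asarray(coords, dtype=float)
    return TrackedTrajectories(
        coords=coords, status=np.ones(coords.shape[0], dtype=bool), pillar=pillar
    )


def _segments(valleys):
    valleys = list(valleys)
    return BeatSegments(
        valley_frames=np.asarray(valleys),
        beats=[(valleys[i], valleys[i + 1]) for i in range(len(valleys) - 1)],
    )


class TestMeanDisplacement:
    def test_three_four_five(self):
        """Two markers displaced identically by (3, 4) give abs = 5."""
        base = np.array([[10.0, 10.0], [20.0, 20.0]])
        coords = np.stack([base, base + [3.0, 4.0]], axis=1)
        s = mean_displacement(_traj(coords))
        assert s.d_row[1] == pytest.approx(3.0)
        assert s.d_col[1] == pytest.approx(4.0)
        assert s.d_abs[1] == pytest.approx(5.0)

    def test_directional_cancellation(self):
        """Markers moving (+d, 0) and (-d, 0): directional mean 0, abs d."""
        base = np.array([[10.0, 10.0], [20.0, 10.0]])
        moved = base + np.array([[2.5, 0.0], [-2.5, 0.0]])
        s = mean_displacement(_traj(np.stack([base, moved], axis=1)))
        assert s.d_row[1] == pytest.approx(0.0)
        assert s.d_abs[1] == pytest.approx(2.5)

    def test_baseline_frame_is_zero(self):
        coords = np.cumsum(np.ones((3, 5, 2)), axis=1)
        s = mean_displacement(_traj(coords), baseline_frame=3)
        assert s.d_abs[3] == 0.0

    def test_marker_permutation_invariance(self, rng):
        coords = rng.normal(50, 5, size=(8, 20, 2)).cumsum(axis=1) / 5
        a = mean_displacement(_traj(coords))
        b = mean_displacement(_traj(coords[rng.permutation(8)]))
        np.testing.assert_allclose(a.d_abs, b.d_abs)


class TestFindValleys:
    def test_cosine_closed_form(self):
        """A(1-cos(2πt/30))/2 over 120 frames: valleys 0,30,60,90 -> 3 beats."""
        t = np.arange(120)
        seg = find_valleys(3 * (1 - np.cos(2 * np.pi * t / 30)) / 2, fps=30)
        assert np.abs(seg.valley_frames - [0, 30, 60, 90]).max() <= 1
        assert seg.n_beats == 3

    def test_single_beat_rejected(self):
        t = np.arange(40)
        with pytest.raises(BeatAnalysisError, match="2 complete beats"):
            find_valleys(3 * (1 - np.cos(2 * np.pi * t / 30)) / 2, fps=30)

    def test_noise_robustness(self, rng):
        t = np.arange(120)
        clean = 3 * (1 - np.cos(2 * np.pi * t / 30)) / 2
        noisy = clean + rng.normal(0, 0.02 * 3, size=t.size)
        seg = find_valleys(noisy, fps=30)
        assert len(seg.valley_frames) == 4
        assert np.abs(seg.valley_frames - [0, 30, 60, 90]).max() <= 1

    def test_flat_series_rejected(self):
        with pytest.raises(BeatAnalysisError, match="flat"):
            find_valleys(np.zeros(100), fps=30)

    def test_valley_recovery_across_periods(self):
        """Noiseless waveforms: valleys within ±1 frame for periods >= 10."""
        for period in (10, 20, 45):
            t = np.arange(4 * period + period // 3)
            sig = (1 - np.cos(2 * np.pi * t / period)) / 2
            seg = find_valleys(sig, fps=30)
            expected = np.arange(0, 4 * period + 1, period)
            found = seg.valley_frames
            assert len(found) == len(expected)
            assert np.abs(found - expected).max() <= 1


class TestAdjustStart:
    def test_movie_already_at_valley(self, std_movie):
        movie, _ = std_movie
        out, retrack = adjust_start(movie, _segments([0, 30, 60, 90]))
        assert retrack is False
        assert out is movie

    def test_phase_shifted_movie_is_truncated(self):
        movie, truth = generate_movie(
            SyntheticMovieSpec(amplitude=3.0, phase=np.pi, n_beats=4, noise_sd=0.0, seed=5)
        )
        seg = _segments(list(truth.valley_frames))
        out, retrack = adjust_start(movie, seg)
        assert retrack is True
        assert out.n_frames == movie.n_frames - truth.valley_frames[0]
        np.testing.assert_array_equal(out.frames[0], movie.frames[truth.valley_frames[0]])

    def test_retracked_series_starts_at_zero(self, type1_config):
        movie, _ = generate_movie(
            SyntheticMovieSpec(amplitude=3.0, phase=np.pi, n_beats=4, noise_sd=0.01, seed=5)
        )
        result = analyze_movie(movie, type1_config)
        assert result.reanchored_at > 0
        assert result.combined_abs_px[0] == pytest.approx(0.0, abs=1e-9)


class TestDrift:
    def test_drift_free_not_detected(self):
        sig = (1 - np.cos(2 * np.pi * np.arange(91) / 30)) / 2
        report = detect_drift(sig, _segments([0, 30, 60, 90]))
        assert report.detected is False

    def test_linear_ramp_detected_with_expected_baselines(self):
        """0.05 px/frame ramp: valley baselines 1.5, 3.0, 4.5 px > 0.5 px."""
        t = np.arange(91)
        sig = 3 * (1 - np.cos(2 * np.pi * t / 30)) / 2 + 0.05 * t
        report = detect_drift(sig, _segments([0, 30, 60, 90]), tol_px=0.5)
        assert report.detected is True
        np.testing.assert_allclose(report.valley_baselines_px, [1.5, 3.0, 4.5])

    def test_infinite_tolerance_never_detects(self):
        t = np.arange(91)
        sig = 3 * (1 - np.cos(2 * np.pi * t / 30)) / 2 + 0.05 * t
        report = detect_drift(sig, _segments([0, 30, 60, 90]), tol_px=np.inf)
        assert report.detected is False


@pytest.fixture(scope="module")
def drifting_run():
    movie, truth = generate_movie(
        SyntheticMovieSpec(amplitude=3.0, n_beats=4, drift_rate=0.05, noise_sd=0.0, seed=14)
    )
    config = RunConfig(
        data_type="type1", fps=30, length_scale=4, stiffness=2.677,
        tissue_depth=350, split=True,
    )
    return movie, truth, analyze_movie(movie, config)


class TestSplitBeats:
    def test_two_beats_cannot_be_split(self):
        coords = np.zeros((6, 61, 2))
        with pytest.raises(BeatAnalysisError, match="at least 3"):
            split_beats(_traj(coords), _segments([0, 30, 60]))

    def test_per_beat_amplitudes_recovered_under_drift(self, drifting_run):
        """Re-baselining keeps per-beat peaks within 5% of truth while
        whole-movie baselining inflates the later peaks."""
        movie, truth, result = drifting_run
        true_peak = float(np.hypot(truth.amplitude, 0.05 * 15))
        split_peaks = np.array(
            [b.peak_displacement_um / 4.0 for b in result.report.per_beat]
        )
        np.testing.assert_allclose(split_peaks, true_peak, rtol=0.05)
        whole_peaks = [s.max() for s in slice_beats(result.combined_abs_px, result.segments)]
        assert whole_peaks[-1] > 1.5 * true_peak  # accumulated ramp error

    def test_split_is_noop_without_drift(self, clean_movie, type1_config):
        movie, _ = clean_movie
        result = analyze_movie(movie, type1_config)
        split = split_beats(result.trajectories["left"], result.segments)
        whole = slice_beats(result.series["left"].d_abs, result.segments)
        for s, w in zip(split, whole):
            assert s.d_abs.max() == pytest.approx(w.max(), rel=0.01)


class TestIrregular:
    def test_regular_beats_pass(self):
        sig = (1 - np.cos(2 * np.pi * np.arange(121) / 30)) / 2
        assert detect_irregular(_segments([0, 30, 60, 90, 120]), sig) is False

    def test_alternating_periods_flagged(self):
        """Periods alternating 30/60 frames: CV ≈ 33% > 20%."""
        valleys = [0, 30, 90, 120, 180]
        t = np.arange(181)
        sig = np.abs(np.sin(2 * np.pi * t / 60))
        assert detect_irregular(_segments(valleys), sig) is True

    def test_single_weak_beat_flagged(self):
        t = np.arange(181)
        sig = (1 - np.cos(2 * np.pi * t / 30)) / 2
        sig[60:90] *= 0.5  # one beat at half amplitude among five normal
        assert detect_irregular(_segments([0, 30, 60, 90, 120, 150, 180]), sig) is True


def test_contraction_signal_is_baseline_free():
    """The separation-based signal is zero at relaxed frames no matter
    which frame the trajectories start on."""
    t = np.arange(91)
    defl = 3 * (1 - np.cos(2 * np.pi * (t + 15) / 30)) / 2  # starts contracted
    left = np.zeros((1, 91, 2))
    left[0, :, 1] = 50 + defl
    right = np.zeros((1, 91, 2))
    right[0, :, 1] = 150 - defl
    signal = contraction_signal(_traj(left), _traj(right, "right"))
    np.testing.assert_allclose(signal, 2 * defl, atol=1e-9)
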