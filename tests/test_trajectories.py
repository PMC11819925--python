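import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.interpolate import InterpolatedUnivariateSpline

import run2d as r
from run2d.trajectories import (
    CONFIDENCE_FLOOR,
    FilterSpec,
    TrajectoryError,
    fill_gaps,
    lowpass,
    read_markers_trc,
)


def _csv(tmp_path, text, name="kp.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestKeypointIO:
    def test_image_coordinates_are_flipped_to_y_up(self, tmp_path):
        path = _csv(
            tmp_path,
            "frame,landmark,x,y,confidence\n"
            "0,ankle,10,700,0.9\n1,ankle,11,700,0.9\n2,ankle,12,700,0.9\n",
        )
        series = r.read_keypoints(path, "csv", image_height=720)
        np.testing.assert_allclose(
            series.points["ankle"], [[10, 20], [11, 20], [12, 20]]
        )

    def test_zero_confidence_detection_is_missing(self, tmp_path):
        kps = [0.0] * 63
        idx = 13 * 3  # left knee in COCO WholeBody ordering
        frames = []
        for i in range(3):
            row = list(kps)
            row[idx : idx + 3] = [100.0, 200.0, 0.0 if i == 2 else 0.9]
            frames.append({"predictions": [{"keypoints": row}]})
        path = tmp_path / "pred.json"
        path.write_text(json.dumps(frames))
        series = r.read_keypoints(path, "openpifpaf_json", image_height=720)
        assert not np.isnan(series.points["knee"][0]).any()
        assert np.isnan(series.points["knee"][2]).all()

    def test_low_confidence_below_floor_is_missing(self, tmp_path):
        path = _csv(
            tmp_path,
            "frame,landmark,x,y,confidence\n"
            f"0,knee,1,2,0.9\n1,knee,1,2,{CONFIDENCE_FLOOR / 2}\n2,knee,1,2,0.9\n",
        )
        series = r.read_keypoints(path, "csv")
        assert np.isnan(series.points["knee"][1]).all()

    def test_csv_round_trip_is_bit_exact(self, tmp_path, model25):
        noise = r.NoiseSpec(pixel_noise_sd=2.0, gap_probability=0.05, seed=3)
        _, keypoints, _ = r.render_streams(model25, noise, 5.0)
        out = tmp_path / "round.csv"
        r.write_keypoints_csv(keypoints, out)
        back = r.read_keypoints(out, "csv", frame_rate=keypoints.frame_rate)
        for name in keypoints.points:
            np.testing.assert_array_equal(
                keypoints.points[name], back.points[name][: keypoints.n_frames]
            )

    def test_unknown_landmarks_rejected_with_names(self, tmp_path):
        path = _csv(
            tmp_path,
            "frame,landmark,x,y,confidence\n0,elbow,1,2,0.9\n0,wrist,1,2,0.9\n",
        )
        with pytest.raises(TrajectoryError, match="elbow.*wrist"):
            r.read_keypoints(path, "csv")

    def test_non_monotone_frames_rejected(self, tmp_path):
        path = _csv(
            tmp_path,
            "frame,landmark,x,y,confidence\n2,knee,1,2,0.9\n1,knee,1,2,0.9\n",
        )
        with pytest.raises(TrajectoryError, match="monotone"):
            r.read_keypoints(path, "csv")


class TestMarkerIO:
    def test_marker_csv_round_trip(self, tmp_path, model25):
        markers, _, _ = r.render_streams(model25, r.NoiseSpec(seed=0), 5.0)
        out = tmp_path / "markers.csv"
        r.write_markers_csv(markers, out)
        back = r.read_markers_csv(out, frame_rate=100.0)
        for name in markers.markers:
            np.testing.assert_array_equal(markers.markers[name], back.markers[name])

    def test_trc_reader(self, tmp_path):
        text = (
            "PathFileType\t4\t(X/Y/Z)\ttrial.trc\n"
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\n"
            "100.0\t100.0\t2\t2\tmm\n"
            "Frame#\tTime\tLKNE\t\t\tLANK\t\t\n"
            "\t\tX1\tY1\tZ1\tX2\tY2\tZ2\n"
            "1\t0.00\t1.0\t2.0\t3.0\t4.0\t5.0\t6.0\n"
            "2\t0.01\t1.5\t2.5\t3.5\t4.5\t5.5\t6.5\n"
        )
        path = tmp_path / "trial.trc"
        path.write_text(text)
        series = read_markers_trc(path)
        assert series.frame_rate == 100.0
        np.testing.assert_allclose(series.markers["LANK"][1], [4.5, 5.5, 6.5])


class TestFillGaps:
    def test_collinear_gap_fills_linearly(self):
        filled = fill_gaps(np.array([0.0, np.nan, 2.0, 3.0]))
        np.testing.assert_allclose(filled, [0, 1, 2, 3], atol=1e-12)

    def test_cubic_signal_reproduced_exactly(self):
        t = np.arange(6.0)
        x = t**3
        x[2] = x[3] = np.nan
        filled = fill_gaps(x)
        assert abs(filled[2] - 8.0) < 1e-6
        assert abs(filled[3] - 27.0) < 1e-6

    def test_matches_independent_spline_oracle(self, rng):
        x = np.cumsum(rng.normal(size=200))
        gaps = rng.choice(np.arange(1, 199), 20, replace=False)
        xm = x.copy()
        xm[gaps] = np.nan
        filled = fill_gaps(xm)
        idx = np.arange(200)
        present = ~np.isnan(xm)
        oracle = InterpolatedUnivariateSpline(idx[present], x[present], k=3)(idx[gaps])
        np.testing.assert_allclose(filled[gaps], oracle, atol=1e-9)

    def test_present_samples_unchanged(self, rng):
        x = rng.normal(size=50)
        xm = x.copy()
        xm[10:13] = np.nan
        filled = fill_gaps(xm)
        present = ~np.isnan(xm)
        np.testing.assert_array_equal(filled[present], x[present])

    def test_missing_endpoint_instructs_to_trim(self):
        with pytest.raises(TrajectoryError, match="trim"):
            fill_gaps(np.array([np.nan, 1.0, 2.0, 3.0, 4.0]))

    def test_too_few_present_samples(self):
        with pytest.raises(TrajectoryError, match=">= 3"):
            fill_gaps(np.array([0.0, np.nan, np.nan, 3.0]))

    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=50))
    def test_idempotent_on_complete_tracks(self, values):
        x = np.asarray(values)
        np.testing.assert_array_equal(fill_gaps(x), x)


class TestLowpass:
    spec = FilterSpec(cutoff_hz=6.0, order=4)

    def test_dc_gain_is_one(self):
        out = lowpass(np.full(200, 5.0), 100.0, self.spec)
        np.testing.assert_allclose(out, 5.0, atol=1e-9)

    @pytest.mark.parametrize(
        "freq",
        [2.0, 30.0],
        ids=["passband", "stopband"],
    )
    def test_gain_matches_two_pass_butterworth_magnitude(self, freq):
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        y = lowpass(np.sin(2 * np.pi * freq * t), fs, self.spec)
        central = slice(len(t) // 10, -len(t) // 10)
        amplitude = np.sqrt(2 * np.mean(y[central] ** 2))
        expected = 1.0 / (1.0 + (freq / 6.0) ** 8)
        assert abs(amplitude / expected - 1) < 0.01

    def test_zero_phase(self):
        fs, freq = 100.0, 2.0
        t = np.arange(0, 20, 1 / fs)
        y = lowpass(np.sin(2 * np.pi * freq * t), fs, self.spec)
        central = slice(len(t) // 10, -len(t) // 10)
        gain = 1.0 / (1.0 + (freq / 6.0) ** 8)
        np.testing.assert_allclose(
            y[central], gain * np.sin(2 * np.pi * freq * t)[central], atol=1e-3
        )

    @given(
        st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        st.integers(0, 2**31 - 1),
    )
    def test_linearity(self, a, b, seed):
        g = np.random.default_rng(seed)
        x, y = g.normal(size=(2, 100))
        lhs = lowpass(a * x + b * y, 60.0, self.spec)
        rhs = a * lowpass(x, 60.0, self.spec) + b * lowpass(y, 60.0, self.spec)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-9)

    def test_time_reversal_symmetry(self, rng):
        x = rng.normal(size=300)
        np.testing.assert_allclose(
            lowpass(x[::-1], 100.0, self.spec),
            lowpass(x, 100.0, self.spec)[::-1],
            atol=1e-12,
        )

    def test_short_track_reports_minimum_length(self):
        with pytest.raises(TrajectoryError, match="12"):
            lowpass(np.zeros(12), 100.0, self.spec)

    def test_missing_samples_rejected(self):
        x = np.zeros(100)
        x[5] = np.nan
        with pytest.raises(TrajectoryError, match="fill_gaps"):
            lowpass(x, 100.0, self.spec)

    def test_cutoff_must_be_below_nyquist(self):
        with pytest.raises(TrajectoryError, match="Nyquist"):
            lowpass(np.zeros(100), 10.0, self.spec)


class TestSpecValidation:
    def test_odd_filter_order_rejected(self):
        with pytest.raises(TrajectoryError):
            FilterSpec(order=3)

    def test_unequal_track_lengths_rejected(self):
        with pytest.raises(TrajectoryError, match="unequal"):
            r.KeypointSeries(60.0, {"knee": np.zeros((5, 2)), "ankle": np.zeros((4, 2))})

    def test_identical_lab_axes_rejected(self):
        with pytest.raises(TrajectoryError, match="distinct"):
            r.LabAxes(anterior="x", vertical="x")
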