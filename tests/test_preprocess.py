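import numpy as np
import pytest

from oxydyn import (
    RawChannel,
    Segment,
    SensorFrame,
    build_feature_matrix,
    delta_hr,
    load_participant,
    lowpass_001,
    synchronize_resample,
)
from oxydyn.preprocess import FEATURE_ORDER, PreprocessError


def make_frame(n=100, pid="P0"):
    t = np.arange(n)
    channels = {
        "HR": 60 + np.sin(t / 30),
        "VE": 10 + 0.1 * t,
        "BF": np.full(n, 15.0),
        "Hacc": 0.1 + 0.001 * t,
        "CAD": np.full(n, 105.0),
        "VO2": 5 + 0.05 * t,
    }
    return SensorFrame(time=t, channels=channels, participant_id=pid)


class TestRawChannel:
    def test_rejects_non_monotone_timestamps(self):
        with pytest.raises(PreprocessError, match="HR"):
            RawChannel("HR", [0, 5, 3], [1, 2, 3])

    def test_rejects_unknown_name(self):
        with pytest.raises(PreprocessError, match="unknown channel"):
            RawChannel("EKG", [0, 1], [1, 2])

    def test_rejects_single_sample(self):
        with pytest.raises(PreprocessError):
            RawChannel("HR", [0], [60])


class TestLoadParticipant:
    def test_wide_csv_roundtrip(self, tmp_path):
        import pandas as pd

        t = np.arange(10.0)
        df = pd.DataFrame({"time_s": t, "HR": 60 + t, "VE": 10 + t, "BF": 15 + t,
                           "Hacc": 0.1 + t, "CAD": 100 + t, "VO2": 5 + t})
        p = tmp_path / "wide.csv"
        df.to_csv(p, index=False)
        channels, segments = load_participant(p)
        assert set(channels) == {"HR", "VE", "BF", "Hacc", "CAD", "VO2"}
        np.testing.assert_allclose(channels["HR"].values, 60 + t)
        assert segments == []

    def test_unknown_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_s,HR,XX\n0,60,1\n1,61,2\n")
        with pytest.raises(PreprocessError, match="XX"):
            load_participant(p)

    def test_segment_annotations_parsed(self, tmp_path):
        p = tmp_path / "wide.csv"
        p.write_text("time_s,HR\n0,60\n1,61\n2,62\n")
        ann = tmp_path / "seg.csv"
        ann.write_text("label,start_s,end_s\nREST,0,2\n")
        _, segments = load_participant(p, ann)
        assert segments == [Segment("REST", 0, 2)]


class TestSynchronizeResample:
    def test_integer_grid_is_identity(self):
        t = np.arange(20.0)
        ch = {"HR": RawChannel("HR", t, 60 + t)}
        frame = synchronize_resample(ch)
        np.testing.assert_allclose(frame.channels["HR"], 60 + t)

    def test_breathwise_linear_interpolation(self):
        # hand-computed: breaths at 0/2.5/5 s with values 10/12/14
        ch = {"VO2": RawChannel("VO2", [0, 2.5, 5], [10, 12, 14])}
        frame = synchronize_resample(ch)
        np.testing.assert_allclose(
            frame.channels["VO2"][1:5], [10.8, 11.6, 12.4, 13.2]
        )

    def test_window_is_support_intersection(self):
        ch = {
            "HR": RawChannel("HR", np.arange(0, 101.0), np.ones(101)),
            "VO2": RawChannel("VO2", np.arange(50, 151.0), np.ones(101)),
        }
        frame = synchronize_resample(ch)
        assert frame.time[0] == 50 and frame.time[-1] == 100

    def test_short_overlap_rejected(self):
        ch = {
            "HR": RawChannel("HR", [0.0, 10.0], [1, 1]),
            "VO2": RawChannel("VO2", [9.0, 20.0], [1, 1]),
        }
        with pytest.raises(PreprocessError, match="overlap"):
            synchronize_resample(ch)


class TestDeltaHR:
    def test_lagged_difference_with_zero_start(self):
        np.testing.assert_allclose(delta_hr([60, 63, 61]), [0, 3, -2])

    def test_constant_series_gives_zeros(self):
        np.testing.assert_allclose(delta_hr(np.full(10, 70.0)), np.zeros(10))

    def test_single_sample_boundary(self):
        np.testing.assert_allclose(delta_hr([70.0]), [0.0])

    def test_empty_rejected(self):
        with pytest.raises(PreprocessError):
            delta_hr([])

    def test_telescoping_sum(self, rng):
        hr = rng.normal(70, 5, size=500)
        d = delta_hr(hr)
        assert np.isclose(d[1:].sum(), hr[-1] - hr[0])


class TestLowpass:
    def test_dc_preserved(self):
        x = np.full(2000, 3.3)
        np.testing.assert_allclose(lowpass_001(x), x, atol=1e-9)

    def test_stopband_attenuation(self):
        # 0.05 Hz = 5x cutoff; forward-backward 4th-order Butterworth
        # attenuates |H|^2 to ~2.6e-6 there
        t = np.arange(2000)
        y = lowpass_001(np.sin(2 * np.pi * 0.05 * t))
        assert np.abs(y[300:-300]).max() < 0.01

    def test_passband_amplitude(self):
        t = np.arange(5000)
        y = lowpass_001(np.sin(2 * np.pi * 0.001 * t))
        assert np.abs(y).max() > 0.99

    def test_idempotent_in_deep_passband(self):
        t = np.arange(5000)
        x = np.sin(2 * np.pi * 0.002 * t)
        once = lowpass_001(x)
        twice = lowpass_001(once)
        ratio = np.abs(twice[500:-500]).max() / np.abs(once[500:-500]).max()
        assert abs(ratio - 1) < 0.01

    def test_zero_phase(self):
        t = np.arange(5000)
        x = np.sin(2 * np.pi * 0.002 * t)
        y = lowpass_001(x)
        lags = np.arange(-20, 21)
        xc = [np.dot(x[500:-500], np.roll(y, k)[500:-500]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_too_short_rejected(self):
        with pytest.raises(PreprocessError, match="too short"):
            lowpass_001(np.ones(10))


class TestFeatureMatrix:
    def test_shape_and_column_order(self):
        fm = build_feature_matrix(make_frame(100), filtered=False)
        assert fm.X.shape == (100, 6)
        assert fm.columns == FEATURE_ORDER

    def test_missing_channel_rejected(self):
        frame = make_frame(50)
        del frame.channels["VE"]
        with pytest.raises(PreprocessError, match="VE"):
            build_feature_matrix(frame, filtered=False)

    def test_segment_restriction_half_open(self):
        frame = make_frame(100)
        frame.segments = [Segment("ADL", 10, 20)]
        frame._check_segments()
        fm = build_feature_matrix(frame, restrict_to=("ADL",), filtered=False)
        assert fm.X.shape[0] == 10

    def test_non_finite_reported_with_row(self):
        frame = make_frame(50)
        frame.channels["HR"][7] = np.nan
        with pytest.raises(PreprocessError, match="row 7"):
            build_feature_matrix(frame, filtered=False)
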