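import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from collareffects import accel, synthdata


def make_stream(x, y=None, z=None):
    x = np.asarray(x, dtype=float)
    y = x if y is None else np.asarray(y, dtype=float)
    z = x if z is None else np.asarray(z, dtype=float)
    return pd.DataFrame({"ax": x, "ay": y, "az": z})


def brute_force_moving(x, window, fn):
    """O(n*w) oracle with the package's centered-shrunken convention."""
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - window // 2)
        hi = min(n, i + (window + 1) // 2)
        out[i] = fn(x[lo:hi])
    return out


class TestStaticAcceleration:
    def test_constant_stream(self):
        s = make_stream(np.full(100, 2.5))
        static = accel.static_acceleration(s)
        np.testing.assert_allclose(static["static_x"], 2.5)

    def test_zero_mean_sinusoid_suppressed(self):
        # 4 Hz sinusoid sampled at 8 Hz: 2-s moving average (16 samples,
        # 8 full cycles) has near-zero frequency response
        t = np.arange(400) / 8.0
        s = make_stream(np.sin(2 * np.pi * 4.0 * t))
        static = accel.static_acceleration(s)
        interior = static["static_x"].to_numpy()[16:-16]
        assert np.max(np.abs(interior)) < 0.02

    def test_single_sample(self):
        s = make_stream([1.25])
        static = accel.static_acceleration(s)
        assert static["static_x"].iloc[0] == pytest.approx(1.25)

    def test_empty_stream_raises(self):
        with pytest.raises(ValueError):
            accel.static_acceleration(make_stream([]))

    def test_matches_brute_force(self, rng):
        x = rng.standard_normal(200)
        s = make_stream(x)
        static = accel.static_acceleration(s)
        expected = brute_force_moving(x, 16, np.mean)
        np.testing.assert_allclose(static["static_x"], expected)


class TestDynamicAcceleration:
    def test_identity_gives_zeros(self):
        s = make_stream([1.0, 2.0, 3.0])
        static = accel.static_acceleration(s)
        dyn = accel.dynamic_acceleration(
            make_stream(static["static_x"].to_numpy()), static
        )
        np.testing.assert_allclose(dyn["dynamic_x"], 0.0, atol=1e-15)

    def test_direct_subtraction(self):
        raw = make_stream([1.0, 0.5])
        static = pd.DataFrame(
            {"static_x": [0.8, 0.5], "static_y": [0.8, 0.5], "static_z": [0.8, 0.5]}
        )
        dyn = accel.dynamic_acceleration(raw, static)
        np.testing.assert_allclose(dyn["dynamic_x"], [0.2, 0.0])

    def test_length_mismatch(self):
        raw = make_stream([1.0, 2.0])
        static = pd.DataFrame({"static_x": [1.0], "static_y": [1.0], "static_z": [1.0]})
        with pytest.raises(ValueError):
            accel.dynamic_acceleration(raw, static)

    def test_exact_reconstruction(self, rng):
        x = rng.standard_normal(300)
        s = make_stream(x)
        static = accel.static_acceleration(s)
        dyn = accel.dynamic_acceleration(s, static)
        np.testing.assert_allclose(
            dyn["dynamic_x"].to_numpy() + static["static_x"].to_numpy(), x,
            rtol=0, atol=1e-14,
        )


class TestVedba:
    def test_zero(self):
        d = pd.DataFrame({"dynamic_x": [0.0], "dynamic_y": [0.0], "dynamic_z": [0.0]})
        assert accel.vedba(d)[0] == 0.0

    def test_pythagorean(self):
        d = pd.DataFrame({"dynamic_x": [0.3], "dynamic_y": [0.4], "dynamic_z": [0.0]})
        assert accel.vedba(d)[0] == pytest.approx(0.5)

    @given(
        dx=st.floats(-10, 10),
        dy=st.floats(-10, 10),
        dz=st.floats(-10, 10),
        signs=st.tuples(
            st.sampled_from([-1.0, 1.0]),
            st.sampled_from([-1.0, 1.0]),
            st.sampled_from([-1.0, 1.0]),
        ),
    )
    @hyp_settings(max_examples=50, deadline=None)
    def test_axis_permutation_and_sign_invariance(self, dx, dy, dz, signs):
        def v(a, b, c):
            return accel.vedba(
                pd.DataFrame({"dynamic_x": [a], "dynamic_y": [b], "dynamic_z": [c]})
            )[0]

        base = v(dx, dy, dz)
        assert v(dz, dx, dy) == pytest.approx(base)
        assert v(signs[0] * dx, signs[1] * dy, signs[2] * dz) == pytest.approx(base)


class TestRunningMinmax:
    def test_constant(self):
        mm = accel.running_minmax(make_stream(np.full(50, 1.5)))
        np.testing.assert_allclose(mm["runmin_x"], 1.5)
        np.testing.assert_allclose(mm["runmax_x"], 1.5)

    def test_monotone_interior(self):
        x = np.arange(100, dtype=float)
        mm = accel.running_minmax(make_stream(x))
        i = 50
        assert mm["runmin_x"].iloc[i] == x[i - 8]
        assert mm["runmax_x"].iloc[i] == x[i + 7]

    def test_matches_brute_force(self, rng):
        x = rng.standard_normal(137)
        mm = accel.running_minmax(make_stream(x))
        np.testing.assert_array_equal(
            mm["runmin_x"], brute_force_moving(x, 16, np.min)
        )
        np.testing.assert_array_equal(
            mm["runmax_x"], brute_force_moving(x, 16, np.max)
        )

    def test_short_stream_matches_brute_force(self, rng):
        x = rng.standard_normal(7)  # shorter than the window
        mm = accel.running_minmax(make_stream(x))
        np.testing.assert_array_equal(
            mm["runmin_x"], brute_force_moving(x, 16, np.min)
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            accel.running_minmax(make_stream([]))


class TestBuildFeatures:
    def test_constant_stream(self):
        feats = accel.build_features(make_stream(np.full(60, 0.7)))
        np.testing.assert_allclose(feats["dynamic_x"], 0.0, atol=1e-14)
        np.testing.assert_allclose(feats["vedba"], 0.0, atol=1e-13)

    def test_feature_count(self, rng):
        feats = accel.build_features(make_stream(rng.standard_normal(40)))
        assert feats.shape[1] == 13
        assert list(feats.columns) == list(accel.FEATURE_COLUMNS)

    def test_reconstruction_and_bounds(self, rng):
        x = rng.standard_normal(250)
        s = make_stream(x)
        feats = accel.build_features(s)
        np.testing.assert_allclose(
            feats["static_x"] + feats["dynamic_x"], x, atol=1e-12
        )
        # moving mean bounded by moving extrema
        assert (feats["runmin_x"] <= feats["static_x"] + 1e-12).all()
        assert (feats["static_x"] <= feats["runmax_x"] + 1e-12).all()
        assert (feats["vedba"] >= 0).all()
        # raw bounded by running extrema
        assert (feats["runmin_x"] <= x + 1e-12).all()
        assert (x <= feats["runmax_x"] + 1e-12).all()


class TestClassifier:
    def test_separable_two_class(self, rng):
        n = 600
        X = pd.DataFrame(
            {f: rng.standard_normal(n) for f in ["a", "b", "c"]}
        )
        y = np.where(X["a"] > 0, "pos", "neg")
        X["a"] += np.where(y == "pos", 5.0, -5.0)  # widen the margin
        clf = accel.train_classifier(X.iloc[:400], y[:400], seed=0, n_estimators=100)
        acc = (clf.predict(X.iloc[400:].to_numpy()) == y[400:]).mean()
        assert acc >= 0.99

    def test_permuted_labels_chance(self, rng):
        n = 800
        X = pd.DataFrame({f: rng.standard_normal(n) for f in ["a", "b"]})
        y = np.array(["u", "v"])[rng.integers(0, 2, n)]
        perm = rng.permutation(y[:600])
        clf = accel.train_classifier(X.iloc[:600], perm, seed=0, n_estimators=100)
        acc = (clf.predict(X.iloc[600:].to_numpy()) == y[600:]).mean()
        majority = max(np.mean(y[600:] == "u"), np.mean(y[600:] == "v"))
        assert abs(acc - majority) < 0.1

    def test_determinism(self, rng):
        X = pd.DataFrame({f: rng.standard_normal(300) for f in ["a", "b"]})
        y = np.where(X["a"] + rng.standard_normal(300) > 0, "p", "n")
        c1 = accel.train_classifier(X, y, seed=9, n_estimators=50)
        c2 = accel.train_classifier(X, y, seed=9, n_estimators=50)
        np.testing.assert_array_equal(c1.predict(X.to_numpy()), c2.predict(X.to_numpy()))

    def test_single_class_raises(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(50)})
        with pytest.raises(ValueError):
            accel.train_classifier(X, np.full(50, "only"), seed=0)


class TestBuildTrainingSet:
    def test_five_minute_segment_is_2400_records(self):
        # 8 Hz x 300 s
        stream = synthdata.simulate_accel_stream(
            synthdata.AccelSimConfig(duration_h=0.25, seed=0)
        )
        five_min = stream[
            pd.to_datetime(stream["timestamp"])
            < pd.to_datetime(stream["timestamp"]).iloc[0] + pd.Timedelta(minutes=5)
        ]
        assert len(five_min) == 2400

    def test_split_composition(self, rng):
        labels = np.array(
            ["rest"] * 5000 + ["feed"] * 4000 + ["headshake"] * 300
        )
        feats = pd.DataFrame({"f": rng.standard_normal(labels.size)})
        tr, te = accel.build_training_set(feats, labels, seed=1)
        tr_labels = labels[tr]
        assert (tr_labels == "rest").sum() == 2400
        assert (tr_labels == "feed").sum() == 2400
        assert (tr_labels == "headshake").sum() == 100
        assert len(set(tr) & set(te)) == 0
        assert len(tr) + len(te) == labels.size


class TestEvaluateClassifier:
    def test_perfect(self):
        rep = accel.evaluate_classifier(["a", "b", "a"], ["a", "b", "a"])
        assert rep.overall_accuracy == 1.0
        assert all(v == 1.0 for v in rep.precision.values())
        assert all(v == 1.0 for v in rep.recall.values())

    def test_formula_arithmetic(self):
        # TP=9, FP=1, FN=0, TN=90 for class "x"
        truth = ["x"] * 9 + ["y"] * 91
        pred = ["x"] * 10 + ["y"] * 90
        rep = accel.evaluate_classifier(pred, truth)
        assert rep.precision["x"] == pytest.approx(0.90)
        assert rep.recall["x"] == pytest.approx(1.00)
        assert rep.accuracy["x"] == pytest.approx(0.99)

    def test_degenerate_predictor(self):
        truth = ["a", "a", "b", "b"]
        pred = ["a", "a", "a", "a"]
        rep = accel.evaluate_classifier(pred, truth)
        assert rep.recall["a"] == 1.0
        assert rep.recall["b"] == 0.0

    def test_confusion_row_sums(self):
        truth = ["a", "a", "b", "b", "b"]
        pred = ["a", "b", "b", "b", "a"]
        rep = accel.evaluate_classifier(pred, truth)
        assert rep.confusion.loc["a"].sum() == 2
        assert rep.confusion.loc["b"].sum() == 3

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            accel.evaluate_classifier([], [])


class TestAggregateHourly:
    @staticmethod
    def _stream(n, rate=8.0, labels=None, start="2015-11-03 10:00:00"):
        ts = pd.to_datetime(start) + pd.to_timedelta(np.arange(n) / rate, unit="s")
        return pd.DataFrame(
            {
                "timestamp": ts,
                "label": labels if labels is not None else ["rest"] * n,
            }
        )

    def test_full_hour_trial_count(self):
        s = self._stream(28_800)
        hourly = accel.aggregate_hourly(s, "2015-11-03 10:00:00")
        assert hourly["N"].iloc[0] == 28_800

    def test_all_headshake(self):
        s = self._stream(1000, labels=["headshake"] * 1000)
        hourly = accel.aggregate_hourly(s, "2015-11-03 10:00:00")
        assert hourly["y"].iloc[0] == hourly["N"].iloc[0] == 1000

    def test_no_headshake(self):
        s = self._stream(1000)
        hourly = accel.aggregate_hourly(s, "2015-11-03 10:00:00")
        assert hourly["y"].iloc[0] == 0

    def test_partial_trailing_hour(self):
        s = self._stream(28_800 + 100)
        hourly = accel.aggregate_hourly(s, "2015-11-03 10:00:00")
        assert list(hourly["N"]) == [28_800, 100]

    def test_count_conservation(self, rng):
        n = 40_000
        labels = np.where(rng.random(n) < 0.03, "headshake", "rest")
        s = self._stream(n, labels=list(labels))
        hourly = accel.aggregate_hourly(s, "2015-11-03 10:00:00")
        assert hourly["y"].sum() == (labels == "headshake").sum()
        assert hourly["N"].sum() == n

    def test_day_flag(self):
        # collar at 07:00: hour 0 starts 07 (night), hour 1 starts 08 (day)
        s = self._stream(3 * 28_800, start="2015-11-03 07:00:00")
        hourly = accel.aggregate_hourly(s, "2015-11-03 07:00:00")
        assert list(hourly["is_day"]) == [False, True, True]

    def test_records_before_collar_rejected(self):
        s = self._stream(100)
        with pytest.raises(ValueError):
            accel.aggregate_hourly(s, "2015-11-03 11:00:00")


class TestEndToEnd:
    def test_synthetic_pipeline_accuracy(self):
        # default archetypes must be separable at >= 0.95 held-out accuracy
        cfg = synthdata.AccelSimConfig(
            duration_h=1.0, seed=7, baseline_headshake_logit=-4.0, initial_effect=1.5
        )
        stream = synthdata.simulate_accel_stream(cfg)
        feats = accel.build_features(stream)
        tr, te = accel.build_training_set(
            feats, stream["label"], seed=0, per_class_records=1200
        )
        clf = accel.train_classifier(
            feats.iloc[tr], stream["label"].iloc[tr], seed=0, n_estimators=200
        )
        preds = clf.predict(feats.iloc[te].to_numpy())
        rep = accel.evaluate_classifier(preds, stream["label"].iloc[te])
        assert rep.overall_accuracy >= 0.95
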