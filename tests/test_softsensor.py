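import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fermfuse.faults import FaultInterval, FaultKind, FaultReport
from fermfuse.model import BatchMeta, FusedFrame, RangeError
from fermfuse.softsensor import (
    FeatureSpec,
    assemble_samples,
    fit_soft_sensor,
    load_model,
    make_regressor,
    predict_stream,
    save_model,
    split_train_val,
)


def linear_frame(n=100, seed=0, batch_id="b1", noise=0.0):
    """Frame where biomass is an exact (optionally noisy) linear map of features."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 10, n)
    f1 = np.sin(t) + rng.normal(0, 0.1, n)
    f2 = t + rng.normal(0, 0.1, n)
    y = 2.0 * f1 - 0.5 * f2 + 3.0 + rng.normal(0, noise, n)
    return FusedFrame(times=t, data=pd.DataFrame({"f1": f1, "f2": f2, "biomass": y}),
                      meta=BatchMeta(batch_id=batch_id))


SPEC = FeatureSpec(features=["f1", "f2"], target="biomass")


class TestAssemble:
    def test_one_sample_per_grid_point(self):
        s = assemble_samples(linear_frame(100), SPEC)
        assert len(s) == 100 and s.dropped == 0

    def test_missing_feature_rows_dropped_and_counted(self):
        frame = linear_frame(100)
        frame.data.loc[3:7, "f1"] = np.nan  # pandas label slice: 5 rows
        s = assemble_samples(frame, SPEC)
        assert len(s) == 95 and s.dropped == 5

    def test_target_among_features_rejected(self):
        with pytest.raises(RangeError):
            FeatureSpec(features=["f1", "biomass"], target="biomass")

    def test_fault_intervals_excluded(self):
        frame = linear_frame(100)
        rep = FaultReport(intervals=[FaultInterval(2.0, 4.0, FaultKind.MEAN_BAND, 0.9)])
        s = assemble_samples(frame, SPEC, fault_reports={"b1": rep})
        assert not np.any((s.times >= 2.0) & (s.times <= 4.0))

    def test_multi_frame_batch_labels(self):
        s = assemble_samples([linear_frame(50, batch_id="A"),
                              linear_frame(60, seed=1, batch_id="B")], SPEC)
        assert len(s) == 110
        assert set(s.batch_labels) == {"A", "B"}


class TestSplit:
    def test_ten_samples_split_eight_two(self):
        s = assemble_samples(linear_frame(10), SPEC)
        train, val = split_train_val(s, seed=0)
        assert (len(train), len(val)) == (8, 2)

    @given(st.integers(min_value=5, max_value=500))
    def test_sizes_follow_rounded_ratio(self, n):
        s = assemble_samples(linear_frame(max(n, 5)), SPEC)
        train, val = split_train_val(s, seed=1)
        assert len(train) == round(0.8 * n)
        assert len(val) == round(0.2 * n)

    def test_partition_exact(self):
        s = assemble_samples(linear_frame(57), SPEC)
        train, val = split_train_val(s, seed=2)
        t_all = np.concatenate([train.times, val.times])
        assert np.unique(t_all).size == 57

    def test_same_seed_same_split(self):
        s = assemble_samples(linear_frame(40), SPEC)
        t1, _ = split_train_val(s, seed=9)
        t2, _ = split_train_val(s, seed=9)
        np.testing.assert_array_equal(t1.times, t2.times)

    def test_batch_blocked_mode_keeps_batches_whole(self):
        s = assemble_samples([linear_frame(50, batch_id="A"),
                              linear_frame(50, seed=1, batch_id="B"),
                              linear_frame(50, seed=2, batch_id="C"),
                              linear_frame(50, seed=3, batch_id="D"),
                              linear_frame(50, seed=4, batch_id="E")], SPEC)
        train, val = split_train_val(s, seed=0, by_batch=True)
        assert set(train.batch_labels).isdisjoint(set(val.batch_labels))

    def test_too_few_samples_rejected(self):
        s = assemble_samples(linear_frame(6), SPEC).subset(np.arange(4))
        with pytest.raises(RangeError):
            split_train_val(s)


class TestFitPredict:
    def test_linear_model_realizes_linear_target(self):
        s = assemble_samples(linear_frame(200), SPEC)
        train, val = split_train_val(s, seed=0)
        sensor = fit_soft_sensor(train, make_regressor("linear"), val=val)
        rmse = float(np.sqrt(np.mean((sensor.predict(val.X) - val.y) ** 2)))
        assert rmse < 1e-6

    def test_rmse_approaches_noise_floor_with_n(self):
        sigma = 0.5
        rmses = {}
        for n in (200, 2000):
            s = assemble_samples(linear_frame(n, noise=sigma, seed=4), SPEC)
            train, val = split_train_val(s, seed=0)
            sensor = fit_soft_sensor(train, make_regressor("linear"))
            rmses[n] = float(np.sqrt(np.mean((sensor.predict(val.X) - val.y) ** 2)))
        assert rmses[2000] <= 1.5 * sigma
        assert rmses[2000] <= rmses[200] * 1.5  # no degradation as n grows

    def test_constant_target_predicted_everywhere(self):
        frame = linear_frame(50)
        frame.data["biomass"] = 4.2
        s = assemble_samples(frame, SPEC)
        sensor = fit_soft_sensor(s, make_regressor("linear"))
        np.testing.assert_allclose(sensor.predict(s.X), 4.2, atol=1e-8)

    def test_loss_curve_recorded(self):
        s = assemble_samples(linear_frame(300, noise=0.2), SPEC)
        train, val = split_train_val(s, seed=0)
        sensor = fit_soft_sensor(train, make_regressor("mlp", seed=0, max_iter=50), val=val)
        assert len(sensor.train_loss) > 1
        assert np.isfinite(sensor.train_loss).all()
        assert sensor.val_loss and np.isfinite(sensor.val_loss[-1])

    def test_predict_stream_grid_and_units(self):
        frame = linear_frame(120)
        s = assemble_samples(frame, SPEC)
        sensor = fit_soft_sensor(s, make_regressor("linear"))
        pred = predict_stream(sensor, frame, SPEC)
        np.testing.assert_array_equal(pred.times, frame.times)
        # de-standardized units: matches the actual biomass scale
        assert np.sqrt(np.mean((pred.values - frame.column("biomass")) ** 2)) < 1e-6

    def test_predictions_order_invariant(self):
        frame = linear_frame(60)
        s = assemble_samples(frame, SPEC)
        sensor = fit_soft_sensor(s, make_regressor("linear"))
        perm = np.random.default_rng(0).permutation(60)
        shuffled = FusedFrame(times=frame.times[perm],
                              data=frame.data.iloc[perm].reset_index(drop=True),
                              meta=frame.meta)
        pred = predict_stream(sensor, shuffled, SPEC)
        direct = predict_stream(sensor, frame, SPEC)
        np.testing.assert_array_equal(np.sort(pred.values), np.sort(direct.values))

    def test_feature_mismatch_rejected(self):
        s = assemble_samples(linear_frame(30), SPEC)
        sensor = fit_soft_sensor(s, make_regressor("linear"))
        with pytest.raises(RangeError):
            predict_stream(sensor, linear_frame(30), FeatureSpec(features=["f2", "f1"]))


class TestSerialization:
    def test_round_trip_predictions_bitwise_identical(self, tmp_path):
        frame = linear_frame(150, noise=0.1)
        s = assemble_samples(frame, SPEC)
        train, _ = split_train_val(s, seed=0)
        sensor = fit_soft_sensor(train, make_regressor("mlp", seed=0, max_iter=30))
        before = predict_stream(sensor, frame, SPEC).values
        save_model(sensor, tmp_path / "m.pkl")
        after = predict_stream(load_model(tmp_path / "m.pkl"), frame, SPEC).values
        np.testing.assert_array_equal(before, after)

    def test_loading_non_model_rejected(self, tmp_path):
        import pickle

        with open(tmp_path / "x.pkl", "wb") as fh:
            pickle.dump({"not": "a model"}, fh)
        with pytest.raises(RangeError):
            load_model(tmp_path / "x.pkl")
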