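"""Window preprocessing, the burst-overlap score, and the parameter
model's training/prediction contracts."""

import numpy as np
import pytest

from meaburst.io import TrainingSample, WINDOW_LEN
from meaburst.maxinterval import MaxIntervalParams
from meaburst.model import (ArchitectureSpec, ParamModel, TrainConfig,
                            build_model, burst_occupancy, burst_overlap_error,
                            custom_accuracy, predict_reverberations,
                            preprocess_window, train_model)

FAST = TrainConfig(epochs=3, batch_size=16, seed=0)


class TestPreprocessing:
    @pytest.mark.parametrize("variant,length", [
        ("spikes30", 1667), ("signal30", 1667), ("signal100", 500)])
    def test_binned_lengths(self, variant, length):
        window = np.zeros(WINDOW_LEN)
        window[100] = 1.0
        assert preprocess_window(window, variant).values.shape == (length,)

    def test_signal_normalized_to_unit_interval(self, rng):
        out = preprocess_window(rng.normal(0, 30, WINDOW_LEN), "signal30")
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_constant_signal_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="dynamic range"):
            out = preprocess_window(np.full(WINDOW_LEN, 3.3), "signal100")
        assert not out.values.any()

    def test_single_spike_lands_in_its_bin(self):
        spikes = np.zeros(WINDOW_LEN)
        spikes[7 * 30 + 3] = 1
        out = preprocess_window(spikes, "spikes30")
        assert out.values[7] == 1.0
        assert out.values.sum() == 1.0

    def test_spike_mean_binning_mode(self):
        spikes = np.zeros(WINDOW_LEN)
        spikes[:30] = 1
        out = preprocess_window(spikes, "spikes30", spikes_binarize=False)
        assert out.values[0] == pytest.approx(1.0)
        spikes[:30] = 0
        spikes[0] = 1
        out = preprocess_window(spikes, "spikes30", spikes_binarize=False)
        assert out.values[0] == pytest.approx(1 / 30)

    def test_short_window_right_padded(self):
        out = preprocess_window(np.ones(10_000), "signal100")
        assert out.values.shape == (500,)
        assert not out.values[101:].any()

    def test_final_bin_of_factor_30_averages_20_samples(self):
        x = np.zeros(WINDOW_LEN)
        x[-20:] = 1.0  # exactly the 20 samples of the last bin
        out = preprocess_window(x, "spikes30", spikes_binarize=False)
        assert out.values[-1] == pytest.approx(1.0)


class TestBurstOverlapError:
    def test_identical_arrays_score_zero(self, rng):
        b = (rng.random(1000) < 0.1).astype(int)
        b[0] = 1
        assert burst_overlap_error(b, b) == 0.0
        assert custom_accuracy(b, b) == 1.0

    def test_all_zero_prediction_scores_one(self):
        target = np.zeros(100, int)
        target[10:20] = 1
        assert burst_overlap_error(np.zeros(100, int), target) == 1.0
        assert custom_accuracy(np.zeros(100, int), target) == 0.0

    def test_hand_case_four_target_ones_two_mismatches(self):
        target = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        pred = np.array([1, 1, 0, 1, 1, 0, 0, 0])  # 2 differing positions
        assert burst_overlap_error(pred, target) == 0.5
        assert custom_accuracy(pred, target) == 0.5

    def test_all_zero_target_is_undefined(self):
        with pytest.raises(ValueError, match="no active"):
            burst_overlap_error(np.ones(10, int), np.zeros(10, int))

    def test_error_can_exceed_one_and_accuracy_clips_at_zero(self):
        target = np.array([1, 0, 0, 0, 0, 0])
        pred = np.array([0, 1, 1, 1, 0, 0])
        assert burst_overlap_error(pred, target) == 4.0
        assert custom_accuracy(pred, target) == 0.0

    def test_asymmetry_unless_mass_matches(self):
        # two mismatches normalized by 2 target ones vs by 4
        target = np.array([1, 1, 0, 0])
        pred = np.array([1, 1, 1, 1])
        assert burst_overlap_error(pred, target) == 1.0
        assert burst_overlap_error(target, pred) == 0.5
        # equal mass: symmetric
        a = np.array([1, 1, 0, 0])
        b = np.array([0, 1, 1, 0])
        assert burst_overlap_error(a, b) == burst_overlap_error(b, a)


class TestBuildModel:
    def test_variant_lengths_accepted_and_output_is_three(self, rng):
        for variant, length in (("signal100", 500), ("signal30", 1667)):
            model = build_model(TrainConfig(), variant)
            out = model.net.forward(rng.random((2, length, 1)))
            assert out.shape == (2, 3)

    def test_output_width_override_rejected(self):
        cfg = TrainConfig(architecture=ArchitectureSpec(output_width=5))
        with pytest.raises(ValueError, match="exactly 3"):
            build_model(cfg, "signal100")

    def test_same_seed_gives_identical_initialization(self):
        a = build_model(TrainConfig(seed=3), "signal100")
        b = build_model(TrainConfig(seed=3), "signal100")
        for wa, wb in zip(a.net.get_weights(), b.net.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_incompatible_architecture_rejected(self):
        cfg = TrainConfig(architecture=ArchitectureSpec(
            conv_blocks=((8, 7, 30), (8, 7, 30))))
        with pytest.raises(ValueError, match="incompatible"):
            build_model(cfg, "signal100")


def constant_target_samples(n=12):
    """Identical windows with identical targets (15, 20, 25)."""
    rng = np.random.default_rng(0)
    signal = rng.normal(0, 3, WINDOW_LEN)
    spikes = np.zeros(WINDOW_LEN)
    idx = np.arange(10_000, 10_000 + 5 * 100, 100)
    spikes[idx] = 1
    bursts = np.zeros(WINDOW_LEN)
    bursts[idx[0]:idx[-1] + 1] = 1
    return [TrainingSample(signal=signal, spikes=spikes, bursts=bursts,
                           params_ms=np.array([15.0, 20.0, 25.0]))
            for _ in range(n)]


class TestTraining:
    def test_overfits_constant_dataset_to_within_1ms(self):
        samples = constant_target_samples()
        cfg = TrainConfig(epochs=150, batch_size=4, learning_rate=3e-3,
                          seed=1, split=(0.5, 0.25, 0.25),
                          track_accuracy=False)
        model, _ = train_model(samples, cfg, "signal30")
        pred = model.predict_params(samples[0])
        np.testing.assert_allclose(pred.params_ms, (15, 20, 25), atol=1.0)

    def test_zero_epochs_returns_initialization_with_empty_curves(self,
                                                                  training_samples):
        cfg = TrainConfig(epochs=0, seed=2)
        model, curves = train_model(training_samples, cfg, "signal30")
        init = build_model(cfg, "signal30")
        for wa, wb in zip(model.net.get_weights(), init.net.get_weights()):
            np.testing.assert_array_equal(wa, wb)
        assert curves.train_mse == [] and curves.val_mse == []

    def test_training_deterministic_given_seed(self, training_samples):
        m1, c1 = train_model(training_samples, FAST, "signal100")
        m2, c2 = train_model(training_samples, FAST, "signal100")
        assert c1.val_mse == c2.val_mse
        for wa, wb in zip(m1.net.get_weights(), m2.net.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_shuffled_targets_hurt_validation_mse(self, training_samples):
        cfg = TrainConfig(epochs=8, seed=3, track_accuracy=False)
        _, true_curves = train_model(training_samples, cfg, "signal100")
        rng = np.random.default_rng(0)
        shuffled = [TrainingSample(signal=s.signal, spikes=s.spikes,
                                   bursts=s.bursts, params_ms=p)
                    for s, p in zip(training_samples,
                                    rng.permutation(
                                        [s.params_ms for s in
                                         training_samples]))]
        _, bad_curves = train_model(shuffled, cfg, "signal100")
        assert bad_curves.val_mse[-1] > true_curves.val_mse[-1]

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            train_model(constant_target_samples(5), FAST, "signal30")


class TestPrediction:
    def test_prediction_has_three_clipped_values_plus_fixed(self,
                                                            training_samples):
        model = build_model(TrainConfig(seed=5), "signal30")
        pred = model.predict_params(training_samples[0])
        assert len(pred.params_ms) == 3
        for v, (lo, hi) in zip(pred.params_ms, model.config.clip_bounds):
            assert lo <= v <= hi
        mi = pred.as_maxinterval()
        assert mi.min_duration_ms == 20.0 and mi.min_spikes == 5

    def test_raw_output_below_bound_is_clipped_up(self):
        model = build_model(TrainConfig(seed=6), "signal100")
        for layer in model.net.layers:
            for p in layer.params:
                p[...] = 0.0
        model.net.layers[-1].b[...] = [-5.0, 1000.0, 50.0]
        pred = model.predict_params(np.zeros(WINDOW_LEN))
        assert pred.params_ms == (2.0, 200.0, 50.0)

    def test_variant_mismatch_rejected(self, training_samples):
        model = build_model(TrainConfig(seed=7), "signal100")
        mi = preprocess_window(training_samples[0].signal, "signal30")
        with pytest.raises(ValueError, match="variant"):
            model.predict_params(mi)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, training_samples):
        model, _ = train_model(training_samples, FAST, "signal100")
        model.save(tmp_path / "ckpt")
        back = ParamModel.load(tmp_path / "ckpt")
        a = model.predict_params(training_samples[0])
        b = back.predict_params(training_samples[0])
        assert a == b

    def test_load_refuses_variant_mismatch(self, tmp_path):
        model = build_model(TrainConfig(seed=8), "signal100")
        model.save(tmp_path / "ckpt")
        with pytest.raises(ValueError, match="variant"):
            ParamModel.load(tmp_path / "ckpt", expect_variant="spikes30")


class ConstantModel(ParamModel):
    """Predicts a fixed parameter triple for every window."""

    def __init__(self, params_ms, variant="spikes30"):
        super().__init__(build_model(TrainConfig(), variant).net, variant,
                         TrainConfig())
        self._params = np.asarray(params_ms, float)

    def predict_raw(self, inputs):
        return np.tile(self._params, (inputs.shape[0], 1))


class TestWindowedAnalysis:
    def test_constant_default_predictor_matches_default_analysis(self):
        # concatenated 5-s windows whose events sit away from the window
        # boundaries: per-window prediction of the default parameters must
        # reproduce whole-train default detection exactly
        from meaburst.io import SpikeTrainSet
        from meaburst.maxinterval import detect_reverberations
        from meaburst.simulate import generate_training_dataset

        windows = generate_training_dataset(
            6, param_ranges={"max_start_ms": (15, 15),
                             "max_end_ms": (20, 20),
                             "min_between_ms": (25, 25)}, seed=3)
        times = np.concatenate([np.flatnonzero(w.spikes) / 1e4 + 5.0 * k
                                for k, w in enumerate(windows)])
        trains = SpikeTrainSet("w", {"a": times})
        model = ConstantModel((15, 20, 25))
        windowed = predict_reverberations(trains, model, 30.0)
        direct = detect_reverberations(times, MaxIntervalParams(),
                                       channel="a")
        assert [(e.start_s, e.end_s, e.spike_count)
                for e in windowed["a"]] == \
            [(e.start_s, e.end_s, e.spike_count) for e in direct]

    def test_events_merge_across_window_boundary(self):
        from meaburst.io import SpikeTrainSet

        # two 8-spike clusters either side of the 5-s boundary, 11 ms apart
        left = 4.999 - 0.007 * np.arange(8)[::-1]
        right = 5.010 + 0.007 * np.arange(8)
        trains = SpikeTrainSet("w", {"a": np.concatenate([left, right])})
        model = ConstantModel((15, 20, 25))
        (event,) = predict_reverberations(trains, model, 10.0)["a"]
        assert event.spike_count == 16
        assert event.start_s == pytest.approx(left[0])
        assert event.end_s == pytest.approx(right[-1])

    def test_empty_channel_produces_no_events(self):
        from meaburst.io import SpikeTrainSet

        trains = SpikeTrainSet("w", {"a": np.empty(0)})
        model = ConstantModel((15, 20, 25))
        assert predict_reverberations(trains, model, 10.0) == {"a": []}

    def test_short_recording_processed_with_warning(self):
        from meaburst.io import SpikeTrainSet

        trains = SpikeTrainSet("w", {"a": np.array([0.5, 0.51, 0.52,
                                                    0.53, 0.54])})
        model = ConstantModel((15, 20, 25))
        with pytest.warns(UserWarning, match="shorter than one window"):
            revs = predict_reverberations(trains, model, 1.0)
        assert len(revs["a"]) == 1
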