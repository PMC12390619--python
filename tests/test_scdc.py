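"""Trigger classifier: threshold sweeps, trainers, CV, metrics, decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuroreach.scdc import (
    DegenerateDataError,
    EnsembleConfig,
    FBPStream,
    N_FEATURES,
    NetworkConfig,
    ThresholdRule,
    ci95_upper,
    classification_metrics,
    coefficient_of_variation,
    decode_stream,
    f1_from_precision_recall,
    five_fold_cv,
    percent_change,
    staged_exponential_loss,
    sweep_single_feature_thresholds,
    train_boosted_ensemble,
    train_network,
)


def brute_force_best_accuracy(values, labels):
    """Independent oracle: try every rule built from the observed values."""
    values, labels = np.asarray(values, float), np.asarray(labels, int)
    cuts = np.unique(values)
    best = 0.0
    for lo in cuts:
        for hi in cuts:
            if lo > hi:
                continue
            for mode in ("above", "below", "band"):
                if mode == "above":
                    pred = values >= lo
                elif mode == "below":
                    pred = values <= hi
                else:
                    pred = (values >= lo) & (values <= hi)
                best = max(best, float(np.mean(pred.astype(int) == labels)))
    return 100.0 * best


class TestThresholdSweep:
    def test_matches_brute_force_oracle(self):
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([1, 0, 1, 0, 0, 0])
        rule, acc = sweep_single_feature_thresholds(
            (values.reshape(-1, 1), labels), 0
        )
        assert acc == pytest.approx(brute_force_best_accuracy(values, labels))

    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(10):
            values = rng.choice(np.arange(10.0), size=30)
            labels = rng.integers(0, 2, 30)
            if len(np.unique(labels)) < 2:
                continue
            _, acc = sweep_single_feature_thresholds(
                (values.reshape(-1, 1), labels), 0, grid=400
            )
            assert acc == pytest.approx(brute_force_best_accuracy(values, labels))

    def test_perfect_separation_reaches_full_accuracy(self):
        values = np.concatenate([np.zeros(10), np.ones(10) * 5])
        labels = np.concatenate([np.ones(10, int), np.zeros(10, int)])
        _, acc = sweep_single_feature_thresholds((values.reshape(-1, 1), labels), 0)
        assert acc == pytest.approx(100.0)

    def test_uninformative_feature_stays_near_base_rate(self, rng):
        values = rng.normal(0, 1, 4000)
        labels = (rng.random(4000) < 0.4).astype(int)
        _, acc = sweep_single_feature_thresholds((values.reshape(-1, 1), labels), 0)
        majority = 100.0 * max(labels.mean(), 1 - labels.mean())
        assert acc < majority + 4.0  # small in-sample lift only

    def test_single_class_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            sweep_single_feature_thresholds(
                (np.arange(10.0).reshape(-1, 1), np.zeros(10, int)), 0
            )

    def test_rule_prediction_modes(self):
        X = np.array([[0.5], [1.5], [2.5]])
        assert ThresholdRule(0, "above", 1.0, np.inf).predict(X).tolist() == [0, 1, 1]
        assert ThresholdRule(0, "below", -np.inf, 1.0).predict(X).tolist() == [1, 0, 0]
        assert ThresholdRule(0, "band", 1.0, 2.0).predict(X).tolist() == [0, 1, 0]


def _blob_data(rng, n=400, flip=0.0):
    X = rng.normal(0, 1, (n, 4))
    y = (X[:, 0] + 0.8 * X[:, 1] > 0).astype(int)
    if flip:
        sel = rng.random(n) < flip
        y[sel] = 1 - y[sel]
    return X, y


class TestBoostedEnsemble:
    def test_deterministic_given_seed(self, rng):
        X, y = _blob_data(rng)
        cfg = EnsembleConfig(n_estimators=25, max_depth=3)
        p1 = train_boosted_ensemble((X, y), cfg, seed=7).predict(X)
        p2 = train_boosted_ensemble((X, y), cfg, seed=7).predict(X)
        assert np.array_equal(p1, p2)

    def test_single_stump_reduction(self, rng):
        X, y = _blob_data(rng)
        cfg = EnsembleConfig(n_estimators=1, max_depth=1)
        model = train_boosted_ensemble((X, y), cfg, seed=0)
        assert len(model.estimators_) == 1
        assert np.array_equal(model.predict(X), model.estimators_[0].predict(X))

    def test_beats_best_stump_on_xor_data(self, rng):
        n = 600
        X = rng.uniform(-1, 1, (n, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        stump_acc = max(
            brute_force_best_accuracy(X[:, j], y) for j in range(2)
        )
        model = train_boosted_ensemble(
            (X, y), EnsembleConfig(n_estimators=60, max_depth=2), seed=0
        )
        ens_acc = 100.0 * float(np.mean(model.predict(X) == y))
        assert ens_acc > stump_acc

    def test_staged_surrogate_loss_non_increasing(self, rng):
        for flip in (0.0, 0.15):
            X, y = _blob_data(rng, flip=flip)
            model = train_boosted_ensemble(
                (X, y), EnsembleConfig(n_estimators=40, max_depth=1), seed=1
            )
            losses = staged_exponential_loss(model, (X, y))
            assert np.all(np.diff(losses) <= 1e-10)

    def test_degenerate_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            train_boosted_ensemble((np.zeros((10, 2)), np.zeros(10, int)))


class TestNetwork:
    def test_separable_data_high_accuracy(self, rng):
        n = 2000
        X = rng.normal(0, 1, (n, 6))
        y = (X[:, 0] - X[:, 1] > 0).astype(int)
        model = train_network((X, y), NetworkConfig(epochs=30, seed=0))
        acc = float(np.mean(model.predict(X) == y))
        assert acc > 0.95

    def test_scores_are_probabilities(self, rng):
        X, y = _blob_data(rng)
        model = train_network((X, y), NetworkConfig(epochs=10, seed=0))
        proba = model.predict_proba(X)[:, 1]
        assert np.all((proba >= 0.0) & (proba <= 1.0))

    def test_deterministic_given_seed(self, rng):
        X, y = _blob_data(rng, n=200)
        cfg = NetworkConfig(epochs=10, seed=3)
        m1, m2 = train_network((X, y), cfg), train_network((X, y), cfg)
        w1 = m1.named_steps["mlp"].coefs_
        w2 = m2.named_steps["mlp"].coefs_
        assert all(np.array_equal(a, b) for a, b in zip(w1, w2))
        assert np.array_equal(m1.predict(X), m2.predict(X))


class TestMetrics:
    def test_validation_counts_worked_example(self):
        m = classification_metrics(tp=26, fp=3, fn=1, tn=5)
        assert m.precision == pytest.approx(100 * 26 / 29, abs=1e-9)
        assert m.recall == pytest.approx(100 * 26 / 27, abs=1e-9)
        # printed (truncated) study values agree to 0.02 percentage points
        assert abs(m.precision - 89.65) < 0.02
        assert abs(m.recall - 96.29) < 0.02

    def test_f1_from_printed_precision_recall(self):
        assert f1_from_precision_recall(85.88, 75.26) == pytest.approx(
            0.8022, abs=5e-5
        )

    def test_degenerate_counts_give_undefined_markers(self):
        m = classification_metrics(tp=0, fp=0, fn=0, tn=10)
        assert m.accuracy == pytest.approx(100.0)
        assert m.precision is None and m.recall is None and m.f1 is None

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(0, 0, 0, 0)

    @settings(derandomize=True, max_examples=500)
    @given(
        tp=st.integers(0, 1000),
        fp=st.integers(0, 1000),
        fn=st.integers(0, 1000),
        tn=st.integers(0, 1000),
    )
    def test_f1_identity_between_formulations(self, tp, fp, fn, tn):
        """Direct-count F1 equals the precision/recall harmonic mean."""
        if tp + fp + fn + tn == 0 or tp + fp == 0 or tp + fn == 0:
            return
        m = classification_metrics(tp, fp, fn, tn)
        direct = tp / (tp + (fp + fn) / 2)
        assert m.f1 == pytest.approx(direct, abs=1e-12)
        if m.precision + m.recall > 0:
            hm = f1_from_precision_recall(m.precision, m.recall)
            assert m.f1 == pytest.approx(hm, abs=1e-12)

    def test_percent_change_and_cov(self):
        assert percent_change(75.26, 92.78) == pytest.approx(23.28, abs=5e-3)
        assert -percent_change(85.16, 84.95) == pytest.approx(0.25, abs=5e-3)
        assert coefficient_of_variation(84.95, 1.26) == pytest.approx(
            0.015, abs=5e-4
        )


class TestCI95:
    @pytest.mark.parametrize(
        "mean, std, n, expected",
        [
            (12.4704, 0.6921, 30, 12.7181),
            (12.9060, 1.3820, 30, 13.4005),
        ],
    )
    def test_upper_bound_worked_examples(self, mean, std, n, expected):
        assert ci95_upper(mean, std, n) == pytest.approx(expected, abs=5e-5)

    def test_zero_std_returns_mean(self):
        assert ci95_upper(3.5, 0.0, 12) == 3.5

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            ci95_upper(1.0, 1.0, 0)


class TestFiveFoldCV:
    def _trainer(self, X, y, seed):
        return train_boosted_ensemble(
            (X, y), EnsembleConfig(n_estimators=10, max_depth=2), seed=seed
        )

    def test_folds_partition_data(self, rng):
        X, y = _blob_data(rng, n=100)
        from sklearn.model_selection import KFold

        seen = np.zeros(100, dtype=int)
        for _, te in KFold(5, shuffle=True, random_state=0).split(X):
            seen[te] += 1
        assert np.all(seen == 1)
        result = five_fold_cv((X, y), self._trainer, seed=0)
        assert len(result.folds) == 5
        assert sum(m.tp + m.fp + m.fn + m.tn for m in result.folds) == 100

    def test_reproducible_for_same_seed(self, rng):
        X, y = _blob_data(rng, n=150)
        r1 = five_fold_cv((X, y), self._trainer, seed=4)
        r2 = five_fold_cv((X, y), self._trainer, seed=4)
        assert r1.mean_accuracy == r2.mean_accuracy
        assert r1.std_accuracy == r2.std_accuracy

    def test_cov_matches_hand_arithmetic(self):
        accs = np.array([84.0, 85.0, 86.0, 85.0, 85.0])
        mean, std = accs.mean(), accs.std(ddof=1)
        assert coefficient_of_variation(mean, std) == pytest.approx(
            std / mean, abs=1e-15
        )
        assert mean == pytest.approx(85.0)
        assert std == pytest.approx(np.sqrt(0.5))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            five_fold_cv((np.zeros((3, 2)), np.array([0, 1, 0])), self._trainer)


class _ConstantModel:
    def __init__(self, predictions):
        self._p = np.asarray(predictions, int)

    def predict(self, X):
        return self._p[: len(X)]


class TestDecodeStream:
    def _stream(self, n):
        ts = np.arange(n) / 8.0
        X = np.zeros((n, N_FEATURES))
        return FBPStream.from_arrays(ts, X, np.zeros(n, int))

    def test_debounce_three_fires_on_third_consecutive_positive(self):
        preds = [0, 1, 1, 1, 0]
        result = decode_stream(_ConstantModel(preds), self._stream(5), debounce_k=3)
        assert result.events == [3 / 8.0]

    def test_debounce_one_fires_every_positive(self):
        preds = [0, 1, 0, 1, 1]
        result = decode_stream(_ConstantModel(preds), self._stream(5), debounce_k=1)
        assert result.events == [1 / 8.0, 3 / 8.0, 4 / 8.0]

    def test_quiet_stream_emits_nothing(self):
        result = decode_stream(_ConstantModel([0] * 8), self._stream(8), debounce_k=3)
        assert result.events == []
        assert result.latency_per_sample_s >= 0.0

    def test_counter_resets_after_emission(self):
        preds = [1, 1, 1, 1, 1, 1]
        result = decode_stream(_ConstantModel(preds), self._stream(6), debounce_k=3)
        assert result.events == [2 / 8.0, 5 / 8.0]


class TestStreamContainer:
    def test_csv_round_trip(self, tmp_path, rng):
        ts = np.arange(16) / 8.0
        X = rng.lognormal(1.0, 0.5, (16, N_FEATURES))
        y = rng.integers(0, 2, 16)
        stream = FBPStream.from_arrays(ts, X, y)
        path = tmp_path / "stream.csv"
        stream.to_csv(path)
        back = FBPStream.from_csv(path)
        assert np.allclose(back.X, stream.X)
        assert np.array_equal(back.y, stream.y)

    def test_wrong_feature_count_rejected(self):
        with pytest.raises(ValueError):
            FBPStream.from_arrays([0.0], np.zeros((1, 10)), [0])

    def test_non_increasing_timestamps_rejected(self):
        with pytest.raises(ValueError):
            FBPStream.from_arrays(
                [0.0, 0.0], np.zeros((2, N_FEATURES)), [0, 1]
            )
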