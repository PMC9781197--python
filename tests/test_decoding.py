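"""Detector training, epoch scoring, evidence aggregation, trial decoding."""

import numpy as np
import pytest

from p300home import (
    DetectorConfig,
    DetectorModel,
    make_schedule,
    run_trial,
    score_epochs,
    select_symbol,
    simulate_recording,
    train_detector,
)
from p300home.preprocess import EpochSet

RNG = np.random.default_rng(123)


def _synthetic_epochs(n_blocks=5, n_symbols=12, separation=4.0, seed=0):
    """Toy epoch set: target rows shifted by `separation` along one axis."""
    rng = np.random.default_rng(seed)
    rows, labels, syms, blocks = [], [], [], []
    for b in range(n_blocks):
        for s in range(n_symbols):
            x = rng.normal(0, 1, 20)
            is_target = s == 3
            if is_target:
                x[5:10] += separation
            rows.append(x)
            labels.append(is_target)
            syms.append(s)
            blocks.append(b)
    return EpochSet(
        features=np.array(rows),
        labels=np.array(labels, dtype=bool),
        symbol_indices=np.array(syms),
        block_indices=np.array(blocks),
        n_channels=1,
        samples_per_epoch=20,
        sampling_rate=25.0,
    )


class TestTrainAndScore:
    @pytest.mark.parametrize("method", ["random_forest", "svm", "lda", "knn"])
    def test_separable_epochs_learned_perfectly(self, method):
        epochs = _synthetic_epochs(separation=8.0)
        model = train_detector(epochs, DetectorConfig(method=method, seed=0))
        scores = score_epochs(model, epochs)
        assert scores.shape == (epochs.n_epochs,)
        assert scores[epochs.labels].min() > scores[~epochs.labels].max()

    def test_single_class_training_rejected(self):
        epochs = _synthetic_epochs()
        epochs.labels[:] = False
        with pytest.raises(ValueError):
            train_detector(epochs, DetectorConfig())

    def test_training_deterministic_under_seed(self):
        epochs = _synthetic_epochs(separation=1.0)
        s = [
            score_epochs(train_detector(epochs, DetectorConfig(seed=5)), epochs)
            for _ in range(2)
        ]
        assert np.array_equal(s[0], s[1])

    def test_dimension_mismatch_rejected(self):
        epochs = _synthetic_epochs()
        model = train_detector(epochs, DetectorConfig())
        other = _synthetic_epochs()
        other.features = other.features[:, :10]
        other.samples_per_epoch = 10
        with pytest.raises(ValueError, match="dimension"):
            score_epochs(model, other)

    def test_empty_epoch_set_scores_empty(self):
        epochs = _synthetic_epochs()
        model = train_detector(epochs, DetectorConfig())
        empty = EpochSet(
            features=np.empty((0, 20)),
            labels=np.empty(0, dtype=bool),
            symbol_indices=np.empty(0, dtype=int),
            block_indices=np.empty(0, dtype=int),
            n_channels=1,
            samples_per_epoch=20,
            sampling_rate=25.0,
        )
        assert score_epochs(model, empty).shape == (0,)

    def test_null_labels_collapse_to_majority_class(self):
        """With shuffled labels and no class weighting, held-out epoch
        accuracy sits at the majority-class rate (11/12)."""
        rng = np.random.default_rng(1)
        train = _synthetic_epochs(n_blocks=10, separation=0.0, seed=1)
        model = train_detector(
            train, DetectorConfig(class_weighting="none", seed=1)
        )
        held = _synthetic_epochs(n_blocks=10, separation=0.0, seed=2)
        pred = score_epochs(model, held) > 0.5
        acc = np.mean(pred == held.labels)
        assert acc == pytest.approx(11 / 12, abs=0.05)

    def test_model_file_round_trip(self, tmp_path):
        epochs = _synthetic_epochs()
        model = train_detector(epochs, DetectorConfig(seed=2))
        path = tmp_path / "detector.pkl"
        model.save(path)
        loaded = DetectorModel.load(path)
        assert np.array_equal(score_epochs(loaded, epochs), score_epochs(model, epochs))


class TestSelectSymbol:
    def test_forced_argmax(self):
        epochs = _synthetic_epochs()
        scores = np.where(epochs.symbol_indices == 7, 1.0, 0.0)
        res = select_symbol(scores, epochs, 5)
        assert res.selected_symbol == 7
        assert res.symbol_scores[7] == 1.0

    def test_all_equal_scores_tie_break_to_lowest_index(self):
        epochs = _synthetic_epochs()
        res = select_symbol(np.ones(epochs.n_epochs), epochs, 5)
        assert res.selected_symbol == 0

    def test_single_repetition_matches_brute_force(self):
        """For one repetition, aggregation reduces to the argmax over the
        first block's 12 epoch scores, computed here by direct enumeration."""
        epochs = _synthetic_epochs(n_blocks=3)
        rng = np.random.default_rng(42)
        scores = rng.normal(size=epochs.n_epochs)
        res = select_symbol(scores, epochs, 1)
        first_block = epochs.block_indices == 0
        by_symbol = {
            s: scores[first_block & (epochs.symbol_indices == s)].item()
            for s in range(12)
        }
        assert res.selected_symbol == max(by_symbol, key=by_symbol.get)

    def test_mean_aggregation_over_repetitions(self):
        epochs = _synthetic_epochs(n_blocks=4)
        scores = np.arange(epochs.n_epochs, dtype=float)
        res = select_symbol(scores, epochs, 4)
        for s in range(12):
            mask = epochs.symbol_indices == s
            assert res.symbol_scores[s] == pytest.approx(scores[mask].mean())

    def test_requesting_more_repetitions_than_available_rejected(self):
        epochs = _synthetic_epochs(n_blocks=3)
        with pytest.raises(ValueError):
            select_symbol(np.zeros(epochs.n_epochs), epochs, 4)


class TestRunTrial:
    def test_high_snr_trial_recovers_target(
        self, default_model, paradigm, sim_config, preproc
    ):
        rng = np.random.default_rng(77)
        schedule = make_schedule(paradigm, rng)
        rec = simulate_recording(schedule, 9, sim_config, rng)
        res = run_trial(rec, preproc, default_model)
        assert res.selected_symbol == 9
        assert res.n_repetitions_used == 15

    @pytest.mark.parametrize("method", ["svm", "lda", "knn"])
    def test_all_comparator_classifiers_decode_the_same_path(
        self, method, paradigm, sim_config, preproc
    ):
        from p300home.sessions import training_epochs

        train = training_epochs(paradigm, sim_config, preproc, rng=21, n_selections=3)
        model = train_detector(train, DetectorConfig(method=method, seed=21))
        rng = np.random.default_rng(22)
        rec = simulate_recording(make_schedule(paradigm, rng), 4, sim_config, rng)
        res = run_trial(rec, preproc, model)
        assert res.symbol_scores.shape == (12,)
        assert np.isfinite(res.symbol_scores).all()
        assert res.selected_symbol == 4  # high SNR: every method recovers it
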