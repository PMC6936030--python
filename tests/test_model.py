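import numpy as np
import pytest

from pseusite.model import (ForestConfig, GridSpec, ModelLoadError,
                            PredictionError, TrainingError, evaluate,
                            grid_search_cv, load_model, predict, save_model,
                            scan_sequence, train_final)
from pseusite.sequence_io import FragmentDataset, RnaSequence, UCenteredFragment
from pseusite.synthetic import SignalSpec, simulate_dataset

SMALL_GRID = GridSpec(depth_values=(2, 4), fraction_values=(0.3, 0.6),
                      folds=3, n_trees=30, seed=2)


@pytest.fixture(scope="module")
def small_cv(signal_dataset):
    return grid_search_cv(signal_dataset, grid=SMALL_GRID)


class TestGridSearch:
    def test_folds_partition_and_stratify(self, small_cv, signal_dataset):
        folds = small_cv.fold_assignments
        assert len(folds) == len(signal_dataset)
        labels = np.array(signal_dataset.labels())
        for fold in range(SMALL_GRID.folds):
            mask = folds == fold
            assert mask.sum() > 0
            n_pos = int(labels[mask].sum())
            n_neg = int(mask.sum() - n_pos)
            assert abs(n_pos - n_neg) <= 1  # stratified on a balanced set
        assert set(folds) == set(range(SMALL_GRID.folds))

    def test_every_combination_on_every_fold(self, small_cv):
        fm = small_cv.fold_metrics
        combos = fm.groupby(["max_depth", "max_features_fraction"])
        assert len(combos) == 4
        for _, group in combos:
            assert sorted(group["fold"]) == list(range(SMALL_GRID.folds))

    def test_heatmap_shape_and_range(self, small_cv):
        table = small_cv.mean_accuracy
        assert table.shape == (2, 2)
        assert ((table >= 0) & (table <= 1)).all().all()
        best = table.loc[small_cv.best_depth, small_cv.best_fraction]
        assert best == pytest.approx(small_cv.best_score)

    def test_single_class_rejected(self):
        frags = [UCenteredFragment("AAUAA", label=1) for _ in range(10)]
        with pytest.raises(TrainingError, match="both"):
            grid_search_cv(FragmentDataset(fragments=frags), grid=SMALL_GRID)

    def test_unlabeled_rejected(self, signal_dataset):
        frags = [UCenteredFragment(f.residues) for f in signal_dataset]
        with pytest.raises(TrainingError, match="labeled"):
            grid_search_cv(FragmentDataset(fragments=frags), grid=SMALL_GRID)

    def test_deterministic_given_seed(self, signal_dataset, small_cv):
        again = grid_search_cv(signal_dataset, grid=SMALL_GRID)
        assert again.mean_accuracy.equals(small_cv.mean_accuracy)
        assert (again.fold_assignments == small_cv.fold_assignments).all()


class TestTrainFinal:
    def test_importances_normalized(self, signal_dataset):
        model = train_final(signal_dataset,
                            config=ForestConfig(n_trees=60, max_depth=4, seed=0))
        assert model.importances.shape == (63,)
        assert (model.importances >= 0).all()
        assert model.importances.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_constant_center_block_zero_importance(self, signal_dataset, seed):
        model = train_final(signal_dataset,
                            config=ForestConfig(n_trees=60, max_depth=5,
                                                seed=seed))
        assert (model.importances[30:33] == 0.0).all()

    def test_single_position_signal_recovered(self, single_signal_dataset):
        model = train_final(single_signal_dataset,
                            config=ForestConfig(n_trees=100, max_depth=4,
                                                seed=3))
        # signal planted at position 16 -> NCP feature block 48..50
        assert int(np.argmax(model.importances)) in (48, 49, 50)


@pytest.fixture(scope="module")
def deep_model(signal_dataset):
    return train_final(signal_dataset,
                       config=ForestConfig(n_trees=80, max_depth=8, seed=1))


@pytest.fixture(scope="module")
def shallow_model(signal_dataset):
    return train_final(signal_dataset,
                       config=ForestConfig(n_trees=40, max_depth=4, seed=6))


class TestPredictEvaluate:

    def test_scores_are_vote_fractions(self, deep_model, signal_dataset):
        scores, calls = predict(deep_model, list(signal_dataset)[:20])
        assert ((scores >= 0) & (scores <= 1)).all()
        assert (calls == (scores >= 0.5)).all()
        # vote fractions are multiples of 1/n_trees
        assert np.allclose(scores * 80, np.round(scores * 80))

    def test_prediction_deterministic(self, deep_model, signal_dataset):
        frags = list(signal_dataset)[:10]
        s1, _ = predict(deep_model, frags)
        s2, _ = predict(deep_model, frags)
        assert (s1 == s2).all()

    def test_length_mismatch_names_window(self, deep_model):
        frag31 = UCenteredFragment("A" * 15 + "U" + "G" * 15)
        with pytest.raises(PredictionError, match="21"):
            predict(deep_model, [frag31])

    def test_overfit_on_training_data(self, deep_model, signal_dataset):
        result = evaluate(deep_model, signal_dataset)
        assert result.acc > 0.95  # deep forest memorizes its training set

    def test_no_signal_gives_near_zero_mcc(self, null_dataset):
        model = train_final(null_dataset,
                            config=ForestConfig(n_trees=60, max_depth=4,
                                                seed=2))
        fresh = simulate_dataset(SignalSpec(window_length=21, n_positive=150,
                                            n_negative=150, seed=99))
        result = evaluate(model, fresh)
        assert abs(result.mcc) < 0.2

    def test_generalizes_to_fresh_signal_draw(self, signal_dataset):
        from conftest import STRONG_BIASES
        model = train_final(signal_dataset,
                            config=ForestConfig(n_trees=200, max_depth=6,
                                                max_features_fraction=0.5,
                                                seed=4))
        test = simulate_dataset(SignalSpec(window_length=21, n_positive=150,
                                           n_negative=150,
                                           biases=STRONG_BIASES, seed=101))
        assert evaluate(model, test).acc > 0.85


class TestPersistence:
    def test_roundtrip_identical_scores(self, tmp_path, signal_dataset):
        model = train_final(signal_dataset,
                            config=ForestConfig(n_trees=40, max_depth=4,
                                                seed=5))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        frags = list(signal_dataset)[:25]
        s1, _ = predict(model, frags)
        s2, _ = predict(loaded, frags)
        assert (s1 == s2).all()
        assert loaded.encoder_id == "NCP"
        assert loaded.window_length == 21
        assert loaded.config == model.config

    def test_version_mismatch_rejected(self, tmp_path):
        import joblib
        path = tmp_path / "old.joblib"
        joblib.dump({"format_version": 99}, path)
        with pytest.raises(ModelLoadError, match="version"):
            load_model(path)

    def test_corrupted_file_rejected(self, tmp_path):
        path = tmp_path / "junk.joblib"
        path.write_text("not a model")
        with pytest.raises(ModelLoadError):
            load_model(path)


class TestScan:
    def test_reported_positions_carry_u(self, shallow_model):
        rng = np.random.default_rng(8)
        residues = "".join(rng.choice(list("ACGU"), size=80))
        seq = RnaSequence("scan", residues)
        for record in scan_sequence(shallow_model, seq):
            assert residues[record["position"] - 1] == "U"

    def test_no_u_yields_empty(self, shallow_model):
        assert scan_sequence(shallow_model, RnaSequence("g", "G" * 50)) == []

    def test_short_sequence_skip_policy_empty(self, shallow_model):
        assert scan_sequence(shallow_model, RnaSequence("short", "AAUAA")) == []
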