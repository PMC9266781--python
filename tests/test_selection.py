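"""Recursive entropy-based selection: scheduling, training, pruning,
ensembles and co-selection statistics."""

import numpy as np
import pytest

from ramanflim import selection as sel
from ramanflim.nnet import MLP


class TestMLP:
    def test_softmax_rows_are_probabilities(self):
        m = MLP(350, (32, 16), 3, seed=0)
        probs = m.predict_proba(np.random.default_rng(0).normal(size=(8, 350)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_identical_seed_identical_parameters(self):
        a = MLP(20, (8,), 3, seed=5)
        b = MLP(20, (8,), 3, seed=5)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_zero_inputs_rejected(self):
        with pytest.raises(ValueError):
            MLP(0, (8,), 3)

    def test_empty_architecture_rejected(self):
        with pytest.raises(ValueError):
            sel.build_selection_classifier(10, architecture=())

    def test_learns_linearly_separable_blobs(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(c, 0.3, size=(50, 4))
                       for c in ((-2, 0, 0, 0), (2, 0, 0, 0), (0, 2, 0, 0))])
        y = np.repeat([0, 1, 2], 50)
        m = MLP(4, (8,), 3, seed=0)
        for _ in range(60):
            m.train_epoch(X, y, 32)
        assert m.accuracy(X, y) == 1.0


class TestPruneSchedule:
    def test_paper_schedule_350_to_10(self):
        sched = sel.prune_schedule(350, 0.2, 10)
        assert sched == [280, 224, 179, 143, 114, 91, 73, 58, 46, 37, 30, 24,
                         19, 15, 12, 10]
        assert len(sched) == 16

    def test_start_at_target_is_empty(self):
        assert sel.prune_schedule(10, 0.2, 10) == []

    def test_round_half_up_dialect(self):
        assert sel.prune_schedule(20, 0.2, 10) == [16, 13, 10]

    def test_vanishing_reduction_rejected(self):
        with pytest.raises(ValueError):
            sel.prune_schedule(1000, 1e-9, 10)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            sel.prune_schedule(5, 0.2, 10)


class TestPruneStep:
    def test_keeps_highest_scores(self):
        mask = np.ones(6, dtype=bool)
        scores = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        out = sel.prune_step(mask, scores, 3)
        np.testing.assert_array_equal(out, [1, 1, 1, 0, 0, 0])

    def test_ties_break_to_lower_wavenumber(self):
        mask = np.ones(5, dtype=bool)
        out = sel.prune_step(mask, np.ones(5), 2)
        np.testing.assert_array_equal(out, [1, 1, 0, 0, 0])

    def test_single_drop_removes_argmin(self):
        mask = np.ones(4, dtype=bool)
        scores = np.array([2.0, 0.5, 3.0, 1.0])
        out = sel.prune_step(mask, scores, 3)
        np.testing.assert_array_equal(out, [1, 0, 1, 1])

    def test_new_mask_nested_in_old(self):
        rng = np.random.default_rng(0)
        mask = rng.uniform(size=20) > 0.4
        scores = rng.normal(size=mask.sum())
        out = sel.prune_step(mask, scores, 5)
        assert not np.any(out & ~mask)

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            sel.prune_step(np.ones(4, dtype=bool), np.ones(4), 0)


class TestTrainUntilThreshold:
    def blobs(self, seed=0, n=100):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(c, 0.3, size=(n, 4))
                       for c in ((-2, 0, 0, 0), (2, 0, 0, 0), (0, 2, 0, 0))])
        return X, np.repeat([0, 1, 2], n)

    def test_separable_data_reaches_threshold(self):
        X, y = self.blobs()
        cfg = sel.SelectorConfig(monitor="val")
        m = sel.build_selection_classifier(4, cfg.architecture, seed=0)
        hist = sel.train_until_threshold(m, X, y, X, y, cfg)
        assert hist.reached

    def test_vacuous_threshold_returns_after_first_evaluation(self):
        X, y = self.blobs()
        cfg = sel.SelectorConfig(accuracy_threshold=0.0, consecutive_hits=1)
        m = sel.build_selection_classifier(4, cfg.architecture, seed=0)
        hist = sel.train_until_threshold(m, X, y, X, y, cfg)
        assert hist.reached and hist.epochs == 1

    def test_single_class_rejected(self):
        X, _ = self.blobs()
        y = np.zeros(X.shape[0], dtype=int)
        cfg = sel.SelectorConfig()
        m = sel.build_selection_classifier(4, cfg.architecture, seed=0)
        with pytest.raises(ValueError):
            sel.train_until_threshold(m, X, y, X, y, cfg)


class TestFeatureEntropy:
    def test_zero_column_scores_baseline_loss(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        X[:, 2] = 0.0
        y = rng.integers(0, 3, size=50)
        m = MLP(4, (8,), 3, seed=0)
        mask = np.ones(4, dtype=bool)
        scores = sel.feature_entropy(m, X, y, mask)
        assert scores[2] == pytest.approx(m.loss(X, y), abs=1e-12)

    def test_informative_feature_outranks_noise(self):
        """On a model trained so class = sign of feature 0, masking feature 0
        must cost more loss than masking a pure-noise feature."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 2))
            y = (X[:, 0] > 0).astype(int)
            m = MLP(2, (8,), 3, seed=seed)
            for _ in range(60):
                m.train_epoch(X, y, 64)
            scores = sel.feature_entropy(m, X, y, np.ones(2, dtype=bool))
            wins += scores[0] > scores[1]
        assert wins >= 9

    def test_duplicated_feature_is_redundant(self):
        """Masking one copy of a duplicated informative feature costs less
        than masking a unique informative feature in a matched design, for a
        network whose weights split evenly across the copies."""
        n = 300
        rng = np.random.default_rng(0)
        x = rng.normal(size=n)
        y = (x > 0).astype(int)
        dup = np.column_stack([x, x])        # two identical copies
        uniq = np.column_stack([x, rng.normal(size=n)])  # one copy + noise
        m_dup = MLP(2, (8,), 3, seed=1)
        m_uniq = MLP(2, (8,), 3, seed=1)
        for _ in range(80):
            m_dup.train_epoch(dup, y, 64)
            m_uniq.train_epoch(uniq, y, 64)
        s_dup = sel.feature_entropy(m_dup, dup, y, np.ones(2, dtype=bool))
        s_uniq = sel.feature_entropy(m_uniq, uniq, y, np.ones(2, dtype=bool))
        assert s_dup[0] < s_uniq[0]

    def test_empty_evaluation_rejected(self):
        m = MLP(3, (4,), 3, seed=0)
        with pytest.raises(ValueError):
            sel.feature_entropy(m, np.empty((0, 3)), np.empty(0, dtype=int),
                                np.ones(3, dtype=bool))


class TestRunSelection:
    def test_full_run_nested_masks(self, five_marker_data):
        run = sel.run_selection(five_marker_data, sel.SelectorConfig(), seed=0)
        assert len(run.mask_history) == 16
        assert run.final_mask.sum() == 10
        prev = np.ones_like(run.final_mask)
        for mask in run.mask_history:
            assert not np.any(mask & ~prev)
            assert mask.sum() < prev.sum()
            prev = mask

    def test_shuffled_labels_never_reach_threshold(self, five_marker_data):
        rng = np.random.default_rng(0)
        data = sel.TrainingData(five_marker_data.X,
                                rng.permutation(five_marker_data.y),
                                five_marker_data.wavenumbers)
        cfg = sel.SelectorConfig(max_epochs_per_stage=60)
        with pytest.raises(sel.SelectionStageError, match="stage 0"):
            sel.run_selection(data, cfg, seed=0)


class TestEnsemble:
    @pytest.fixture(scope="class")
    def ensemble(self, five_marker_data):
        return sel.ensemble_selection(five_marker_data,
                                      sel.SelectorConfig(n_runs=10),
                                      base_seed=0)

    def test_uniform_baseline_value(self, ensemble):
        cfg50 = sel.SelectorConfig(n_runs=50)
        assert 50 * 10 / 350 == pytest.approx(1.4286, abs=1e-4)
        assert ensemble.uniform_baseline == pytest.approx(10 * 10 / 350)

    def test_frequency_conservation(self, ensemble):
        assert ensemble.frequency.sum() == ensemble.n_runs * 10

    def test_top_table_recovers_markers(self, ensemble):
        top = list(ensemble.top_table(5)["wavenumber"])
        markers = (702, 815, 1250, 1321, 1455)
        hits = sum(any(abs(w - m) <= 8 for w in top) for m in markers)
        assert hits >= 4

    def test_single_run_frequencies_binary(self, five_marker_data):
        ens = sel.ensemble_selection(five_marker_data,
                                     sel.SelectorConfig(n_runs=1), base_seed=3)
        assert set(np.unique(ens.frequency)) <= {0.0, 1.0}
        assert set(ens.top_table(5)["percent"]) <= {0.0, 100.0}

    def test_reproducible_from_base_seed(self, five_marker_data, ensemble):
        again = sel.ensemble_selection(five_marker_data,
                                       sel.SelectorConfig(n_runs=10),
                                       base_seed=0)
        np.testing.assert_array_equal(again.frequency, ensemble.frequency)


class TestWeightedJaccard:
    @staticmethod
    def toy_ensemble(masks, wavenumbers):
        runs = [sel.SelectionRun(mask_history=[m], final_mask=np.asarray(m),
                                 entropy_history=[], seed=i)
                for i, m in enumerate(masks)]
        freq = np.sum(masks, axis=0).astype(float)
        return sel.SelectionEnsemble(runs=runs, frequency=freq,
                                     wavenumbers=np.asarray(wavenumbers,
                                                            dtype=float),
                                     n_runs=len(masks))

    def test_hand_enumerated_three_run_toy(self):
        # masks {a, b}, {a}, {b} over features (a, b, c)
        masks = np.array([[1, 1, 0], [1, 0, 0], [0, 1, 0]], dtype=bool)
        ens = self.toy_ensemble(masks, [400, 404, 408])
        W, wn = sel.weighted_jaccard(ens, top_m=2)
        # c_a = c_b = 2, J(a,b) = 1/3, W = (1/3) * (4/6) = 2/9
        assert W[0, 1] == pytest.approx(2 / 9)
        np.testing.assert_allclose(np.diag(W), [2 / 3, 2 / 3])

    def test_always_selected_feature_has_unit_diagonal(self):
        masks = np.array([[1, 0], [1, 1], [1, 0]], dtype=bool)
        ens = self.toy_ensemble(masks, [400, 404])
        W, _ = sel.weighted_jaccard(ens, top_m=2)
        assert W[0, 0] == pytest.approx(1.0)

    def test_never_coselected_features_zero_off_diagonal(self):
        masks = np.array([[1, 0], [0, 1]], dtype=bool)
        ens = self.toy_ensemble(masks, [400, 404])
        W, _ = sel.weighted_jaccard(ens, top_m=2)
        assert W[0, 1] == 0.0

    def test_symmetry_and_range(self, five_marker_data):
        ens = sel.ensemble_selection(five_marker_data,
                                     sel.SelectorConfig(n_runs=5), base_seed=0)
        W, _ = sel.weighted_jaccard(ens, top_m=8)
        np.testing.assert_allclose(W, W.T)
        assert (W >= 0).all() and (W <= 1).all()

    def test_invalid_top_m_rejected(self, five_marker_data):
        ens = sel.ensemble_selection(five_marker_data,
                                     sel.SelectorConfig(n_runs=2), base_seed=0)
        with pytest.raises(ValueError):
            sel.weighted_jaccard(ens, top_m=0)


class TestPCALoadingSelection:
    def test_returns_five_distinct_wavenumbers(self, five_marker_data):
        feats = sel.pca_loading_selection(five_marker_data, 5)
        assert len(set(feats)) == 5

    def test_overlaps_planted_markers(self, five_marker_data):
        feats = sel.pca_loading_selection(five_marker_data, 5)
        markers = (702, 815, 1250, 1321, 1455)
        hits = sum(any(abs(w - m) <= 8 for w in feats) for m in markers)
        assert hits >= 2
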