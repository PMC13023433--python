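"""Training regimen, evaluation metrics, protocol splits, and the
comparison statistics."""

import numpy as np
import pytest

from mibci import training as tr
from mibci.model import CBTNet, desk_scale_config
from mibci.preprocessing import TrialSet
from mibci.synthetic import SimConfig, generate_dataset
from mibci.training import (
    AdamW,
    Metrics,
    PlateauState,
    TrainConfig,
    audit_disjoint,
    clip_gradients,
    cohens_d,
    desk_scale_train_config,
    evaluate,
    lr_schedule,
    paired_ttest,
    stratified_split,
    train_supervised,
    wilcoxon_signed_rank,
)


class TestLRSchedule:
    def test_warmup_endpoint_reaches_base_lr(self):
        cfg = TrainConfig()
        assert lr_schedule(10, cfg) == pytest.approx(3e-4)

    def test_warmup_midpoint(self):
        cfg = TrainConfig()
        assert lr_schedule(5, cfg) == pytest.approx(1.5e-4)

    def test_plateau_halves(self):
        cfg = TrainConfig()
        state = PlateauState(patience=2, decay=0.5)
        state.update(1.0)
        state.update(1.1)
        state.update(1.2)  # two bad epochs -> decay
        assert state.factor == 0.5
        assert lr_schedule(20, cfg, state) == pytest.approx(1.5e-4)

    def test_epoch_zero_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(0, TrainConfig())


class TestOptimizer:
    def test_clip_rescales_to_max_norm(self):
        from mibci import _autodiff as ad

        grads = {"a": ad.tensor(np.array([3.0, 4.0]))}
        total = clip_gradients(grads, 1.0)
        assert total == pytest.approx(5.0)
        assert np.linalg.norm(grads["a"].data) == pytest.approx(1.0, rel=1e-6)

    def test_adamw_decay_only_on_matrices(self):
        from mibci import _autodiff as ad

        params = {"W": ad.parameter(np.ones((2, 2))), "b": ad.parameter(np.ones(2))}
        opt = AdamW(params, weight_decay=0.5)
        zero = {"W": ad.tensor(np.zeros((2, 2))), "b": ad.tensor(np.zeros(2))}
        opt.step(zero, lr=0.1)
        assert np.all(params["W"].data < 1.0)  # decayed
        assert np.allclose(params["b"].data, 1.0)  # exempt


def _toy_set(n_per_class=6, n_classes=3, seed=0):
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    return TrialSet(
        trials=rng.normal(size=(n, 3, 64)),
        labels=np.repeat(np.arange(n_classes), n_per_class),
        subject_ids=np.zeros(n, dtype=int),
        rate=250.0,
        classes=("a", "b", "c"),
    )


class TestTrainSupervised:
    def test_early_stop_after_patience_epochs(self, tiny_config, monkeypatch):
        """Strictly rising validation loss stops at patience + 1 epochs."""
        losses = iter(np.arange(1.0, 100.0))
        monkeypatch.setattr(tr, "_mean_loss", lambda *a, **k: float(next(losses)))
        model = CBTNet(tiny_config, seed=0)
        cfg = TrainConfig(max_epochs=100, early_stop_patience=10, batch_size=18)
        _, history = train_supervised(model, _toy_set(), _toy_set(seed=1), cfg)
        assert len(history) == 11

    def test_history_entries_carry_losses_and_lr(self, tiny_config):
        model = CBTNet(tiny_config, seed=0)
        cfg = TrainConfig(max_epochs=3, early_stop_patience=3)
        _, history = train_supervised(model, _toy_set(), _toy_set(seed=1), cfg)
        assert len(history) == 3
        for entry in history:
            assert {"epoch", "train_loss", "val_loss", "lr"} <= set(entry)

    def test_empty_split_rejected(self, tiny_model):
        empty = _toy_set().subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            train_supervised(tiny_model, empty, _toy_set())

    def test_learns_separable_synthetic_data(self):
        """Deep ERD (0.8), two subjects: near-perfect training accuracy."""
        data = generate_dataset(
            SimConfig(n_subjects=2, trials_per_class=10, erd_depth=0.8,
                      master_seed=17)
        )
        accs = []
        for seed in range(3):
            tr_idx, val_idx = stratified_split(data, 0.8, seed)
            model = CBTNet(desk_scale_config(), seed=seed)
            model, _ = train_supervised(
                model, data.subset(tr_idx), data.subset(val_idx),
                desk_scale_train_config(seed=seed, early_stop_patience=30,
                                        restore_best=False),
            )
            accs.append(evaluate(model, data.subset(tr_idx)).accuracy)
        assert np.mean(accs) >= 0.95


class TestMetrics:
    def test_perfect_predictions(self):
        m = Metrics.from_predictions([0, 1, 2, 3], [0, 1, 2, 3], 4)
        assert m.accuracy == 1.0 and m.macro_f1 == 1.0
        assert np.array_equal(m.confusion, np.eye(4, dtype=int))

    def test_hand_computed_confusion(self):
        """Confusion [[8,2],[4,6]]: accuracy 0.7, macro-F1 ~ 0.697."""
        y_true = [0] * 10 + [1] * 10
        y_pred = [0] * 8 + [1] * 2 + [0] * 4 + [1] * 6
        m = Metrics.from_predictions(y_true, y_pred, 2)
        assert m.accuracy == pytest.approx(0.7)
        assert m.macro_f1 == pytest.approx((8 / 11 + 2 / 3) / 2, abs=1e-9)
        assert np.array_equal(m.confusion, [[8, 2], [4, 6]])

    def test_single_class_predictor_on_balanced_data(self):
        y_true = np.repeat(np.arange(4), 5)
        m = Metrics.from_predictions(y_true, np.zeros(20, dtype=int), 4)
        assert m.accuracy == pytest.approx(0.25)

    def test_confusion_total_equals_trials(self, rng):
        y_true = rng.integers(0, 4, 57)
        y_pred = rng.integers(0, 4, 57)
        m = Metrics.from_predictions(y_true, y_pred, 4)
        assert m.confusion.sum() == 57
        assert np.array_equal(m.confusion.sum(axis=1), np.bincount(y_true, minlength=4))


class TestSplits:
    def test_stratified_split_disjoint_and_balanced(self, small_dataset):
        a, b = stratified_split(small_dataset, 0.5, seed=3)
        audit_disjoint(a, b)
        assert len(a) + len(b) == len(small_dataset)
        counts = np.bincount(small_dataset.labels[a])
        assert np.all(counts == counts[0])

    def test_audit_detects_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            audit_disjoint([1, 2, 3], [3, 4])


class TestStatistics:
    def test_ttest_identical_samples(self):
        t, p = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_ttest_hand_computed(self):
        """d = [1,2,3]: t = 2*sqrt(3), p ~ 0.0742 with 2 df."""
        t, p = paired_ttest([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        assert p == pytest.approx(0.0742, abs=2e-4)

    def test_ttest_antisymmetric(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        t1, p1 = paired_ttest(a, b)
        t2, p2 = paired_ttest(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_wilcoxon_hand_ranked(self):
        """Differences [1,-2,3,-4,5]: W = min(9, 6) = 6."""
        b = np.zeros(5)
        a = np.array([1.0, -2.0, 3.0, -4.0, 5.0])
        W, _ = wilcoxon_signed_rank(a, b)
        assert W == 6.0

    def test_wilcoxon_exact_p_matches_enumeration(self):
        """Exact p for small n equals brute-force sign-pattern enumeration."""
        import itertools

        a = np.array([1.2, -0.4, 2.2, 0.7, -1.5, 0.9])
        b = np.zeros(6)
        W_obs, p = wilcoxon_signed_rank(a, b)
        ranks = np.argsort(np.argsort(np.abs(a))) + 1.0
        count = 0
        total = 0
        for signs in itertools.product([0, 1], repeat=6):
            w_plus = sum(r for r, s in zip(ranks, signs) if s)
            w = min(w_plus, ranks.sum() - w_plus)
            total += 1
            if w <= W_obs:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_wilcoxon_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_cohens_d_examples(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
        assert cohens_d([2.0, 4.0], [1.0, 3.0]) == pytest.approx(1 / np.sqrt(2))
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 20000)
        b = rng.normal(0.0, 1.0, 20000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.05)
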