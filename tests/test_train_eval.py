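"""Training loop, metrics, random search, and nested CV bookkeeping."""

import numpy as np
import pytest

from spikescreen.chem_encode import FingerprintDataset
from spikescreen.snn_model import init_network
from spikescreen.synthetic_data import SyntheticSpec, generate
from spikescreen.train_eval import (
    HyperParamPoint,
    SearchGrid,
    SearchRecord,
    auc,
    balanced_accuracy,
    default_grid,
    holdout_split,
    make_optimizer,
    nested_cv,
    random_search,
    rank_models,
    spec_for,
    train,
)


def brute_force_auc(y, scores):
    """Pairwise positive-vs-negative comparison with half credit for ties."""
    y, scores = np.asarray(y), np.asarray(scores)
    pos, neg = scores[y == 1], scores[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
        pos[:, None] == neg[None, :]
    ).sum()
    return wins / (len(pos) * len(neg))


class TestMakeOptimizer:
    def test_published_best_row_settings(self):
        point = HyperParamPoint(
            n_hidden=1000, beta=0.8, slope=75.0, optimizer="Adam",
            lr=1e-4, wd=0.0, gc=True,
        )
        net = init_network(spec_for(point, n_inputs=8), 0)
        opt = make_optimizer(point, net)
        assert type(opt).__name__ == "Adam"
        assert opt.lr == 1e-4 and opt.wd == 0.0

    def test_unknown_optimizer_rejected_at_point_construction(self):
        with pytest.raises(ValueError):
            HyperParamPoint(optimizer="bogus")


class TestTrain:
    def test_one_batch_per_epoch_on_64_samples(self, monkeypatch):
        from spikescreen import optimizers

        calls = []
        orig = optimizers.Optimizer.step

        def counting(self, grads):
            calls.append(1)
            return orig(self, grads)

        monkeypatch.setattr(optimizers.Optimizer, "step", counting)
        ds = generate(
            SyntheticSpec(n_per_class=(32, 32), n_bits=16, n_informative=8, seed=0)
        )
        point = HyperParamPoint(n_hidden=8, epochs=1)
        net = init_network(spec_for(point, 16, n_steps=5), 0)
        train(net, ds, point, seed=1)
        assert len(calls) == 1

    def test_zero_learning_rate_is_a_null_update(self):
        ds = generate(
            SyntheticSpec(n_per_class=(20, 20), n_bits=16, n_informative=8, seed=1)
        )
        point = HyperParamPoint(n_hidden=8, optimizer="SGO", lr=0.0, epochs=2)
        net = init_network(spec_for(point, 16, n_steps=5), 0)
        W1_before = net.W1.copy()
        train(net, ds, point, seed=1)
        assert np.array_equal(net.W1, W1_before)

    def test_loss_drops_on_easy_data(self, easy_dataset):
        point = HyperParamPoint(n_hidden=32, lr=2e-3, epochs=6)
        net = init_network(spec_for(point, easy_dataset.n_bits, n_steps=10), 3)
        _, history = train(net, easy_dataset, point, seed=4)
        assert len(history) == 6
        assert history[-1] < history[0]

    def test_reproducible_from_seed(self, easy_dataset):
        point = HyperParamPoint(n_hidden=16, epochs=2)
        nets = []
        for _ in range(2):
            net = init_network(spec_for(point, easy_dataset.n_bits, n_steps=8), 7)
            train(net, easy_dataset, point, seed=9)
            nets.append(net)
        assert np.array_equal(nets[0].W1, nets[1].W1)

    def test_empty_dataset_rejected(self):
        ds = FingerprintDataset(np.zeros((0, 4), np.int8), np.zeros(0, int))
        point = HyperParamPoint(n_hidden=4, epochs=1)
        net = init_network(spec_for(point, 4, n_steps=3), 0)
        with pytest.raises(ValueError):
            train(net, ds, point, seed=0)


class TestMetrics:
    def test_perfect_predictions(self):
        assert balanced_accuracy([0, 0, 1, 1], [0, 0, 1, 1]) == 100.0

    def test_constant_predictor_is_chance(self):
        assert balanced_accuracy([0, 0, 1, 1], [1, 1, 1, 1]) == 50.0

    def test_hand_computed_confusion(self):
        # TP=9, FN=1, TN=8, FP=2 -> (0.9 + 0.8)/2 = 85%
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 9 + [0] + [0] * 8 + [1] * 2
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(85.0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([1, 1], [0, 1])
        with pytest.raises(ValueError):
            auc([0, 0], [0.1, 0.9])

    def test_auc_perfect_and_tied(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auc([0, 0, 1, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_auc_textbook_example(self):
        assert auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_midrank_auc_equals_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(4, 21)
            y = np.zeros(n, int)
            y[rng.choice(n, rng.integers(1, n), replace=False)] = 1
            if y.sum() in (0, n):
                continue
            scores = rng.integers(0, 5, n) / 4.0  # coarse grid forces ties
            assert auc(y, scores) == pytest.approx(
                brute_force_auc(y, scores), abs=1e-12
            )


class TestRandomSearch:
    def test_single_draw_returned(self, easy_dataset, tiny_grid):
        point, records = random_search(easy_dataset, tiny_grid, n_draws=1, seed=0)
        assert point == records[0].point
        assert len(records) == 1

    def test_same_seed_same_draw_sequence(self, easy_dataset, tiny_grid):
        grid = SearchGrid(**{**tiny_grid.__dict__, "lr": (2e-3, 1e-3), "beta": (0.8, 0.9)})
        _, rec_a = random_search(easy_dataset, grid, n_draws=4, seed=5)
        _, rec_b = random_search(easy_dataset, grid, n_draws=4, seed=5)
        assert [r.point for r in rec_a] == [r.point for r in rec_b]

    def test_superior_configuration_selected(self, easy_dataset, tiny_grid):
        # lr=1e-12 cannot learn anything; enough draws cover both levels
        grid = SearchGrid(**{**tiny_grid.__dict__, "lr": (2e-3, 1e-12)})
        point, records = random_search(easy_dataset, grid, n_draws=8, seed=3)
        assert {r.point.lr for r in records} == {2e-3, 1e-12}
        assert point.lr == 2e-3

    def test_zero_draws_rejected(self, easy_dataset, tiny_grid):
        with pytest.raises(ValueError):
            random_search(easy_dataset, tiny_grid, n_draws=0)


class TestNestedCV:
    def test_fold_accounting(self, easy_dataset, tiny_grid):
        summary = nested_cv(
            easy_dataset, tiny_grid, k_outer=2, k_inner=2,
            n_repeats=1, seed=0, n_draws=1, balance="none", n_steps=8,
        )
        assert summary.rep_fold_ba.shape == (1, 2)
        assert summary.rep_fold_auc.shape == (1, 2)
        assert len(summary.bookkeeping) == 2

    def test_no_outer_test_index_in_inner_training(self, easy_dataset, tiny_grid):
        summary = nested_cv(
            easy_dataset, tiny_grid, k_outer=3, k_inner=2,
            n_repeats=2, seed=1, n_draws=1, balance="safe", n_steps=8,
        )
        for entry in summary.bookkeeping:
            overlap = set(entry["outer_test_rows"]) & set(entry["inner_train_rows"])
            assert not overlap

    def test_safe_mode_keeps_original_records_disjoint(self, tiny_grid):
        ds = generate(
            SyntheticSpec(n_per_class=(80, 20), n_bits=32, n_informative=8,
                          p_on_active=0.8, p_background=0.05, seed=6)
        )
        summary = nested_cv(
            ds, tiny_grid, k_outer=2, k_inner=2, n_repeats=1,
            seed=2, n_draws=1, balance="safe", n_steps=8,
        )
        for entry in summary.bookkeeping:
            assert not set(entry["outer_test_orig"]) & set(entry["inner_train_orig"])

    def test_paper_mode_lets_duplicates_straddle_folds(self, tiny_grid):
        # heavy imbalance: oversampled duplicates must straddle the 2 folds
        ds = generate(
            SyntheticSpec(n_per_class=(80, 10), n_bits=32, n_informative=8,
                          p_on_active=0.8, p_background=0.05, seed=7)
        )
        summary = nested_cv(
            ds, tiny_grid, k_outer=2, k_inner=2, n_repeats=1,
            seed=3, n_draws=1, balance="paper", n_steps=8,
        )
        overlaps = [
            len(set(e["outer_test_orig"]) & set(e["inner_train_orig"]))
            for e in summary.bookkeeping
        ]
        assert any(o > 0 for o in overlaps)
        # row-level disjointness still holds even in the leaky mode
        for e in summary.bookkeeping:
            assert not set(e["outer_test_rows"]) & set(e["inner_train_rows"])

    def test_deterministic_given_seed(self, easy_dataset, tiny_grid):
        kwargs = dict(k_outer=2, k_inner=2, n_repeats=1, seed=4,
                      n_draws=1, balance="none", n_steps=8)
        a = nested_cv(easy_dataset, tiny_grid, **kwargs)
        b = nested_cv(easy_dataset, tiny_grid, **kwargs)
        assert np.array_equal(a.rep_fold_ba, b.rep_fold_ba)
        assert a.mean_auc == b.mean_auc

    def test_separable_data_scores_high(self):
        ds = generate(
            SyntheticSpec(n_per_class=(100, 100), n_bits=64, n_informative=24,
                          p_on_active=1.0, p_background=0.25, seed=8)
        )
        grid = SearchGrid(
            n_hidden=(128,), beta=(0.9,), slope=(25.0,), optimizer=("Adamax",),
            lr=(5e-3,), wd=(0.0,), gc=(False,), epochs=(20,),
        )
        summary = nested_cv(
            ds, grid, k_outer=2, k_inner=2, n_repeats=1,
            seed=5, n_draws=1, balance="none", n_steps=10,
        )
        assert summary.mean_ba > 95.0


class TestRankModels:
    def _records(self, means):
        return [
            SearchRecord(point=HyperParamPoint(n_hidden=500 + i), mean_ba=m)
            for i, m in enumerate(means)
        ]

    def test_truncates_to_top_five(self):
        df = rank_models(self._records([60, 70, 80, 90, 65, 75, 85]))
        assert len(df) == 5
        assert df["mean_ba"].iloc[0] == 90

    def test_sorted_descending_with_stable_ties(self):
        df = rank_models(self._records([80.0, 80.0, 90.0]), top_k=3)
        assert df["mean_ba"].tolist() == [90.0, 80.0, 80.0]
        assert df["hidden"].tolist() == [502, 500, 501]  # insertion order on ties

    def test_columns_mirror_result_tables(self):
        df = rank_models(self._records([50.0]))
        assert list(df.columns) == [
            "hidden", "beta", "slope", "optimizer", "lr", "wd", "gc",
            "mean_ba", "std_ba",
        ]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_models([])


class TestDefaultGrid:
    def test_axes_match_published_search_ranges(self):
        grid = default_grid()
        assert grid.n_hidden == (500, 800, 1000, 1200, 1500, 2000)
        assert len(grid.beta) == 6
        assert grid.beta[0] == 0.6 and grid.beta[-1] == 0.95
        assert grid.slope == (25.0, 50.0, 75.0)
        assert len(grid.lr) == 15
        assert min(grid.lr) == 1e-5 and max(grid.lr) <= 0.5
        assert 0.0 in grid.wd
        assert len(grid.optimizer) == 7

    def test_draws_come_from_the_levels(self):
        grid = default_grid()
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = grid.draw(rng)
            assert p.n_hidden in grid.n_hidden
            assert p.lr in grid.lr
            assert p.optimizer in grid.optimizer


def test_holdout_split_is_stratified_and_disjoint(easy_dataset):
    tr, te = holdout_split(easy_dataset, test_frac=0.25, seed=0)
    assert tr.n_samples + te.n_samples == easy_dataset.n_samples
    assert te.labels.sum() == 30  # 25% of 120 positives
    assert (te.labels == 0).sum() == 30
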