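"""Cross-validation, Bayesian search, winner selection and voting."""

import numpy as np
import pytest

from fetalvol.net import NetworkConfig
from fetalvol.train import (
    HyperparameterSpace,
    SearchEntry,
    SearchResult,
    bayes_opt_search,
    kfold_split,
    majority_vote,
    select_fold_winner,
)
from fetalvol.volumes import BinaryMask, VolumeGrid


class TestKFold:
    def test_partition_laws(self):
        items = list(range(9))
        subjects = [f"s{i}" for i in range(9)]
        folds = kfold_split(items, 3, subjects, seed=0)
        all_val = [i for _, val in folds for i in val]
        assert sorted(all_val) == items
        for train, val in folds:
            assert len(val) == 3
            assert set(train) | set(val) == set(items)
            assert set(train) & set(val) == set()

    def test_subject_scans_stay_together(self):
        items = list(range(8))
        subjects = ["a", "a", "b", "b", "c", "d", "e", "f"]
        folds = kfold_split(items, 3, subjects, seed=1)
        for _, val in folds:
            val = set(val)
            assert (0 in val) == (1 in val)  # subject a
            assert (2 in val) == (3 in val)  # subject b

    def test_deterministic_under_seed(self):
        items = list(range(20))
        subjects = [f"s{i // 2}" for i in range(20)]
        assert kfold_split(items, 4, subjects, seed=7) == kfold_split(
            items, 4, subjects, seed=7
        )

    def test_fewer_subjects_than_k_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            kfold_split([0, 1], 3, ["a", "a"], seed=0)


class TestBayesOpt:
    def test_toy_quadratic_objective_lands_near_optimum(self):
        """With a deterministic quadratic in log-lr, 8 iterations find a
        point in the top decile of an exhaustive 1000-point grid."""
        space = HyperparameterSpace(n_iterations=8)
        opt_log_lr = np.log(2e-3)

        def objective(config, fold):
            val = 1.0 - (np.log(config.learning_rate) - opt_log_lr) ** 2 / 10.0
            return [val]

        base = NetworkConfig(input_shape=(8, 8, 8), depth=2, kernel_sizes=(3, 3))
        result = bayes_opt_search(
            space, folds=[None], budget=8, base_config=base, seed=4,
            evaluate=objective,
        )
        best = max(e.mean_dsc for e in result.entries)
        grid = np.exp(np.linspace(*np.log(space.lr_range), 1000))
        grid_vals = np.sort(1.0 - (np.log(grid) - opt_log_lr) ** 2 / 10.0)
        decile = grid_vals[int(0.9 * len(grid_vals))]
        assert best >= decile

    def test_bookkeeping_counts(self):
        space = HyperparameterSpace(n_iterations=5)

        def objective(config, fold):
            return [0.5]

        base = NetworkConfig(input_shape=(8, 8, 8), depth=2, kernel_sizes=(3, 3))
        result = bayes_opt_search(
            space, folds=[None, None, None], budget=5, base_config=base,
            seed=0, evaluate=objective,
        )
        assert len(result.entries) == 15
        # one shared config per iteration across folds
        for it in range(5):
            cfgs = {e.config for e in result.entries if e.iteration == it}
            assert len(cfgs) == 1

    def test_budget_one_single_fold(self):
        def objective(config, fold):
            return [0.1]

        base = NetworkConfig(input_shape=(8, 8, 8), depth=2, kernel_sizes=(3, 3))
        result = bayes_opt_search(
            HyperparameterSpace(), folds=[None], budget=1, base_config=base,
            seed=0, evaluate=objective,
        )
        assert len(result.entries) == 1

    def test_proposals_respect_bounds(self):
        space = HyperparameterSpace(n_iterations=8)
        seen = []

        def objective(config, fold):
            seen.append(config)
            return [float(np.sin(config.learning_rate * 1000))]

        base = NetworkConfig(input_shape=(8, 8, 8), depth=2, kernel_sizes=(3, 3))
        bayes_opt_search(space, [None], budget=8, base_config=base, seed=2,
                         evaluate=objective)
        for c in seen:
            assert space.f_range[0] <= c.base_filters <= space.f_range[1]
            assert space.batch_range[0] <= c.batch_size <= space.batch_range[1]
            assert space.lr_range[0] <= c.learning_rate <= space.lr_range[1]


def _entry(fold, it, dsc_list):
    cfg = NetworkConfig(input_shape=(8, 8, 8), depth=2, kernel_sizes=(3, 3))
    return SearchEntry(fold, it, cfg, list(dsc_list), [], network=None)


class TestWinnerSelection:
    def test_single_candidate_selected_without_tests(self):
        result = SearchResult(entries=[_entry(0, 0, [0.8, 0.9])], n_folds=1,
                              n_iterations=1)
        w = select_fold_winner(result, 0)
        assert w.entry.iteration == 0
        assert w.signed_rank_p == {}

    def test_uniformly_better_candidate_wins_significantly(self, rng):
        base = rng.uniform(0.7, 0.9, size=10)
        entries = [
            _entry(0, 0, base + 0.05),
            _entry(0, 1, base),
            _entry(0, 2, base - 0.01),
        ]
        result = SearchResult(entries=entries, n_folds=1, n_iterations=3)
        w = select_fold_winner(result, 0)
        assert w.entry.iteration == 0
        # exact one-sided signed-rank tail for n=10 all-positive: 2/2^10
        exact_two_sided = 2.0 * (1.0 / 2**10)
        for p in w.signed_rank_p.values():
            assert p == pytest.approx(exact_two_sided, rel=1e-6)
            assert p < 0.05

    def test_mean_tie_breaks_to_lower_iteration(self):
        entries = [_entry(0, 0, [0.8, 0.8]), _entry(0, 1, [0.9, 0.7])]
        result = SearchResult(entries=entries, n_folds=1, n_iterations=2)
        assert select_fold_winner(result, 0).entry.iteration == 0


class TestMajorityVote:
    def _mask(self, bits, grid):
        data = np.array(bits, dtype=np.uint8).reshape(1, 1, len(bits))
        return BinaryMask(data, grid)

    def test_all_eight_vote_patterns(self):
        grid = VolumeGrid((1, 1, 8), 1.0)
        patterns = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
        m1 = self._mask([p[0] for p in patterns], grid)
        m2 = self._mask([p[1] for p in patterns], grid)
        m3 = self._mask([p[2] for p in patterns], grid)
        out = majority_vote([m1, m2, m3])
        expected = [1 if sum(p) >= 2 else 0 for p in patterns]
        np.testing.assert_array_equal(out.data.ravel(), expected)

    def test_identical_masks_pass_through(self, random_mask):
        out = majority_vote([random_mask] * 3)
        np.testing.assert_array_equal(out.data, random_mask.data)

    def test_three_empty_masks(self, small_grid):
        empty = BinaryMask(np.zeros(small_grid.shape, dtype=np.uint8), small_grid)
        assert majority_vote([empty] * 3).n_voxels == 0

    def test_wrong_member_count_rejected(self, random_mask):
        with pytest.raises(ValueError, match="exactly 3"):
            majority_vote([random_mask, random_mask])

    def test_grid_mismatch_rejected(self, random_mask):
        other = BinaryMask(
            np.zeros((8, 8, 8), dtype=np.uint8), VolumeGrid((8, 8, 8), 1.0)
        )
        with pytest.raises(ValueError, match="mismatch"):
            majority_vote([random_mask, random_mask, other])

    def test_output_always_binary_no_ties_possible(self, rng):
        grid = VolumeGrid((6, 6, 6), 1.0)
        masks = [
            BinaryMask((rng.random(grid.shape) > 0.5).astype(np.uint8), grid)
            for _ in range(3)
        ]
        out = majority_vote(masks)
        assert set(np.unique(out.data)) <= {0, 1}
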