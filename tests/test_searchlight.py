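"""Sphere geometry, CV schemes, calibrated decoding, chance pairing."""

import numpy as np
import pytest

from socialmap import searchlight
from socialmap.volume import VolumeGrid, default_grid


def _brute_force_offsets(spacing, radius):
    out = []
    r = int(np.ceil(radius / spacing)) + 1
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            for k in range(-r, r + 1):
                if spacing * np.sqrt(i * i + j * j + k * k) <= radius:
                    out.append((i, j, k))
    return set(out)


class TestSphereGeometry:
    def test_19_voxels_at_4mm_on_24mm_grid(self):
        """Interior sphere: enumeration of offsets with ||2.4(i,j,k)|| <= 4."""
        offs = searchlight.sphere_offsets(np.diag([2.4, 2.4, 2.4, 1.0]), 4.0)
        oracle = _brute_force_offsets(2.4, 4.0)
        assert set(map(tuple, offs)) == oracle
        assert len(offs) == 19
        grid = default_grid(12)
        center = np.array(grid.shape) // 2
        s = searchlight.sphere_members(center, grid, 4.0)
        assert len(s.member_columns) == 19

    def test_radius_below_spacing_gives_center_only(self):
        grid = default_grid(12)
        s = searchlight.sphere_members(np.array(grid.shape) // 2, grid, 1.0)
        assert len(s.member_columns) == 1

    def test_boundary_sphere_is_truncated(self):
        grid = default_grid(12)
        edge = grid.mask_indices()[0]  # first in-mask voxel is at the rim
        s = searchlight.sphere_members(edge, grid, 4.0)
        assert 1 <= len(s.member_columns) < 19

    def test_center_outside_mask_refused(self):
        grid = default_grid(12)
        with pytest.raises(ValueError, match="outside"):
            searchlight.sphere_members(np.array([0, 0, 0]), grid, 4.0)

    def test_anisotropic_affine_uses_mm_distance(self):
        mask = np.ones((9, 9, 9), dtype=bool)
        grid = VolumeGrid((9, 9, 9), np.diag([1.0, 2.0, 4.0, 1.0]), mask)
        s = searchlight.sphere_members(np.array([4, 4, 4]), grid, 2.0)
        got = set(map(tuple, grid.mask_indices()[s.member_columns] - 4))
        assert got == {(0, 0, 0), (1, 0, 0), (-1, 0, 0), (2, 0, 0), (-2, 0, 0), (0, 1, 0), (0, -1, 0)}


def _full_design_metadata(n_runs=8):
    labels = np.tile(np.repeat([0, 1], 18), n_runs)
    run_ids = np.repeat(np.arange(n_runs), 36)
    concept_ids = np.tile(np.arange(36), n_runs)
    return labels, run_ids, concept_ids


class TestCvSchemes:
    def test_leave_one_run_out_shape(self):
        labels, run_ids, concept_ids = _full_design_metadata()
        folds = searchlight.make_cv_splits("leave_one_run_out", labels, run_ids, concept_ids)
        assert len(folds) == 8
        assert all(len(te) == 36 for _, te in folds)

    def test_leave_two_concepts_out_enumeration(self):
        """18 low x 18 high concepts -> 324 folds of 2 concepts x 8 runs."""
        labels, run_ids, concept_ids = _full_design_metadata()
        folds = searchlight.make_cv_splits(
            "leave_two_concepts_out", labels, run_ids, concept_ids
        )
        assert len(folds) == 18 * 18
        assert all(len(te) == 16 for _, te in folds)
        for _, te in folds[:10]:
            held = np.unique(concept_ids[te])
            assert len(held) == 2
            assert {labels[concept_ids == c][0] for c in held} == {0, 1}

    def test_stratified_shuffle_counts(self):
        labels, *_ = _full_design_metadata(2)
        folds = searchlight.make_cv_splits("stratified_shuffle", labels, n_splits=25)
        assert len(folds) == 25
        for tr, te in folds:
            assert len(te) == int(np.ceil(0.2 * len(labels)))
            counts = np.bincount(labels[te])
            assert abs(int(counts[0]) - int(counts[1])) <= 1

    @pytest.mark.parametrize(
        "scheme", ["stratified_shuffle", "leave_one_run_out", "leave_two_concepts_out"]
    )
    def test_train_test_disjoint_and_both_classes(self, scheme):
        labels, run_ids, concept_ids = _full_design_metadata(4)
        folds = searchlight.make_cv_splits(
            scheme, labels, run_ids, concept_ids, seed=1, n_splits=10, max_folds=20
        )
        for tr, te in folds:
            assert len(np.intersect1d(tr, te)) == 0
            assert len(np.unique(labels[te])) == 2

    def test_nonbinary_labels_refused(self):
        with pytest.raises(ValueError, match="binary"):
            searchlight.make_cv_splits("leave_one_run_out", np.array([0, 1, 2]), np.arange(3))


class TestDecodeAuc:
    def test_separable_data_decodes_perfectly(self, rng):
        X = np.vstack([rng.normal(-5, 0.2, (20, 4)), rng.normal(5, 0.2, (20, 4))])
        y = np.repeat([0, 1], 20)
        folds = searchlight.make_cv_splits("stratified_shuffle", y, seed=0, n_splits=10)
        assert searchlight.decode_auc(X, y, folds) == 1.0

    def test_auc_equals_rank_statistic_oracle(self, rng):
        """On a 1D monotone problem the pipeline's AUC equals the
        Mann-Whitney pair-count statistic computed directly on the feature."""
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.8, 1, 20)])
        y = np.repeat([0, 1], 20)
        tr = np.arange(0, 40, 2)
        te = np.arange(1, 40, 2)
        auc = searchlight.decode_auc(x[:, None], y, [(tr, te)], seed=0)
        pos, neg = x[te][y[te] == 1], x[te][y[te] == 0]
        pairs = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = pairs / (len(pos) * len(neg))
        assert auc == pytest.approx(oracle, abs=1e-12)

    def test_null_labels_give_chance_auc(self, rng):
        aucs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.normal(size=(40, 5))
            y = np.repeat([0, 1], 20)
            folds = searchlight.make_cv_splits("stratified_shuffle", y, seed=seed, n_splits=20)
            aucs.append(searchlight.decode_auc(X, y, folds, seed=seed))
        assert abs(np.mean(aucs) - 0.5) < 0.08

    def test_single_class_fold_skipped(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.repeat([0, 1], 5)
        bad = (np.arange(5), np.arange(5, 10))  # single-class train AND test
        good = (np.array([0, 1, 5, 6]), np.array([2, 3, 7, 8]))
        with pytest.warns(UserWarning, match="single class"):
            searchlight.decode_auc(X, y, [bad, good])


class TestChanceAuc:
    def test_features_are_ignored(self, rng):
        y = np.repeat([0, 1], 20)
        folds = searchlight.make_cv_splits("stratified_shuffle", y, seed=3, n_splits=10)
        a = searchlight.chance_auc(rng.normal(size=(40, 5)), y, folds, seed=9)
        b = searchlight.chance_auc(rng.normal(size=(40, 50)) * 100, y, folds, seed=9)
        assert a == b

    def test_centered_on_half_with_shrinking_variance(self):
        """Monte-Carlo: the fold-mean is unbiased at 0.5 and its variance
        shrinks roughly like 1/n_folds."""
        y = np.repeat([0, 1], 20)
        means_few, means_many = [], []
        for seed in range(60):
            f1 = searchlight.make_cv_splits("stratified_shuffle", y, seed=seed, n_splits=4)
            f2 = searchlight.make_cv_splits("stratified_shuffle", y, seed=seed, n_splits=64)
            means_few.append(searchlight.chance_auc(np.zeros((40, 1)), y, f1, seed=seed))
            means_many.append(searchlight.chance_auc(np.zeros((40, 1)), y, f2, seed=seed))
        assert abs(np.mean(means_many) - 0.5) < 0.02
        assert np.var(means_many) < np.var(means_few) / 4


class TestRunSearchlight:
    def test_recovery_at_implant_and_null_far_away(self, example_set, signal_spec):
        roi = next(r for r in signal_spec.rois if r.dimension == "affect")
        far = next(r for r in signal_spec.rois if r.dimension == "desirability")
        centers = np.vstack([roi.voxel_ijk[:5], far.voxel_ijk[:5]])
        m = searchlight.run_searchlight(
            example_set, "affect", scheme="leave_one_run_out", seed=0, centers=centers
        )
        at_roi = [m.data[tuple(c)] for c in roi.voxel_ijk[:5]]
        at_far = [m.data[tuple(c)] for c in far.voxel_ijk[:5]]
        assert np.median(at_roi) > 0.1
        assert abs(np.median(at_far)) < 0.12

    def test_values_bounded(self, example_set, signal_spec):
        centers = signal_spec.rois[0].voxel_ijk[:4]
        m = searchlight.run_searchlight(
            example_set, "desirability", scheme="leave_one_run_out", seed=1, centers=centers
        )
        vals = m.data[np.isfinite(m.data)]
        assert ((vals >= -1) & (vals <= 1)).all()

    def test_single_sphere_composes_decode_minus_chance(self, example_set):
        """The map value equals standalone decode - chance on the same
        features with the same fanned-out sub-seed."""
        center = example_set.grid.mask_indices()[len(example_set.voxel_ijk) // 2]
        m = searchlight.run_searchlight(
            example_set, "affect", scheme="leave_one_run_out", seed=4,
            centers=center[None, :],
        )
        lookup = {tuple(ijk): i for i, ijk in enumerate(example_set.voxel_ijk)}
        s = searchlight.sphere_members(center, example_set.grid, 4.0, column_lookup=lookup)
        sub_seed = searchlight.sphere_seed(4, center, example_set.grid.shape)
        y = example_set.binary_labels("affect")
        folds = searchlight.make_cv_splits(
            "leave_one_run_out", y, example_set.labels["run_id"].to_numpy(),
            example_set.labels["concept_id"].to_numpy(), seed=sub_seed,
        )
        Xs = example_set.X[:, s.member_columns]
        expected = searchlight.decode_auc(Xs, y, folds, seed=sub_seed) - searchlight.chance_auc(
            Xs, y, folds, seed=sub_seed
        )
        assert m.data[tuple(center)] == pytest.approx(expected, abs=1e-12)

    def test_traversal_order_invariance(self, example_set):
        centers = example_set.grid.mask_indices()[[40, 80, 120]]
        m1 = searchlight.run_searchlight(
            example_set, "affect", scheme="leave_one_run_out", seed=2, centers=centers
        )
        m2 = searchlight.run_searchlight(
            example_set, "affect", scheme="leave_one_run_out", seed=2, centers=centers[::-1]
        )
        for c in centers:
            assert m1.data[tuple(c)] == m2.data[tuple(c)]
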