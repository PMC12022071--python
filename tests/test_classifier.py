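"""Classifier: preprocessing, augmentation, splits, metrics, ensembling."""

import numpy as np
import pytest

from plaquemap import classifier as clf
from plaquemap.classifier import (
    CLASS_ORDER,
    ClassifierEnsemble,
    TrainConfig,
    augment_patch,
    classification_metrics,
    predict_ensemble,
    preprocess_patch,
    reconstruct_confusion,
    split_train_test,
    stratified_folds,
    train_crossval,
)

# confusion matrix consistent with every printed evaluation metric
PRINTED_CONFUSION = np.array([[9, 1, 0], [2, 41, 0], [0, 3, 22]])


class TestPreprocess:
    def test_constant_patch_maps_to_zeros(self):
        out = preprocess_patch(np.full((120, 120), 9.0))
        assert out.shape == (120, 120)
        assert np.all(out == 0)

    def test_downsampling_preserves_mean(self):
        ramp = np.outer(np.linspace(0, 1, 240), np.linspace(0, 1, 240))
        out = preprocess_patch(ramp)
        assert out.shape == (120, 120)
        # compare on the stretched scale: renormalise the input identically
        lo, hi = np.percentile(ramp, [1, 99])
        ref = np.clip((ramp - lo) / (hi - lo), 0, 1)
        assert out.mean() == pytest.approx(ref.mean(), rel=0.02)

    def test_output_bounded(self, rng):
        out = preprocess_patch(rng.normal(50, 20, (90, 150)))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_multichannel_reduced_by_mean(self, rng):
        stack = rng.uniform(0, 1, (120, 120, 3))
        out = preprocess_patch(stack)
        ref = preprocess_patch(stack.mean(axis=2))
        np.testing.assert_allclose(out, ref)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            preprocess_patch(np.empty((0, 0)))


class TestAugment:
    def test_pinned_identity(self, rng):
        patch = rng.uniform(0, 1, (120, 120)).astype(np.float32)
        out = augment_patch(patch, rng, angle=0.0, flip_h=False,
                            flip_v=False, scale=1.0)
        np.testing.assert_array_equal(out, patch)

    def test_double_flip_is_identity(self, rng):
        patch = rng.uniform(0, 1, (120, 120)).astype(np.float32)
        once = augment_patch(patch, rng, angle=0.0, flip_h=True,
                             flip_v=False, scale=1.0)
        twice = augment_patch(once, rng, angle=0.0, flip_h=True,
                              flip_v=False, scale=1.0)
        np.testing.assert_array_equal(twice, patch)

    def test_quarter_turn_matches_index_permutation(self, rng):
        """90-degree rotation equals transpose followed by a flip."""
        patch = rng.uniform(0, 1, (120, 120)).astype(np.float32)
        out = augment_patch(patch, rng, angle=90.0, flip_h=False,
                            flip_v=False, scale=1.0)
        np.testing.assert_allclose(out, patch.T[::-1, :], atol=1e-5)

    def test_shape_preserved_under_scaling(self, rng):
        patch = rng.uniform(0, 1, (120, 120)).astype(np.float32)
        for s in (0.9, 1.1):
            out = augment_patch(patch, rng, angle=0.0, flip_h=False,
                                flip_v=False, scale=s)
            assert out.shape == (120, 120)


class TestSplits:
    def test_study_sized_split_rounding(self, rng):
        """Class counts 42/208/135: round-half-up gives 8+42+27 = 77 test."""
        labels = np.array(["CGP"] * 42 + ["CP"] * 208 + ["DP"] * 135)
        patches = np.zeros((385, 4, 4))
        _, ytr, _, yte = split_train_test(patches, labels, 0.2, seed=1)
        assert len(yte) == 77
        assert len(ytr) == 308
        counts = {c: (yte == c).sum() for c in ("CGP", "CP", "DP")}
        assert counts == {"CGP": 8, "CP": 42, "DP": 27}

    def test_partition_disjoint_and_exhaustive(self, rng):
        labels = rng.choice(["A", "B"], 50)
        patches = np.arange(50).reshape(50, 1, 1).astype(float)
        xtr, _, xte, _ = split_train_test(patches, labels, 0.2, seed=3)
        seen = np.concatenate([xtr.ravel(), xte.ravel()])
        assert sorted(seen.tolist()) == list(range(50))

    def test_same_seed_same_split(self):
        labels = np.array(["A"] * 20 + ["B"] * 20)
        patches = np.arange(40).reshape(40, 1, 1).astype(float)
        a = split_train_test(patches, labels, 0.2, seed=9)
        b = split_train_test(patches, labels, 0.2, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[2], b[2])

    def test_tiny_class_rejected(self):
        labels = np.array(["A"] * 20 + ["B"] * 2)
        with pytest.raises(ValueError, match="members"):
            split_train_test(np.zeros((22, 2, 2)), labels)

    def test_fold_sizes_balanced_307(self):
        """307 samples in 3 stratified folds -> sizes 103/102/102."""
        labels = np.array(["CGP"] * 34 + ["CP"] * 166 + ["DP"] * 107)
        folds = stratified_folds(labels, 3, seed=0)
        sizes = sorted(np.bincount(folds).tolist(), reverse=True)
        assert sizes == [103, 102, 102]
        assert folds.size == 307  # every sample validates exactly once


class TestMetrics:
    def test_printed_metrics_from_reconstructed_matrix(self):
        """The reconstructed confusion reproduces every printed number."""
        report = classification_metrics(PRINTED_CONFUSION)
        assert report.n_test == 78
        assert report.n_correct == 72
        assert round(100 * report.accuracy, 1) == 92.3
        assert round(report.recall["CGP"], 2) == 0.90
        assert round(report.recall["CP"], 2) == 0.95
        assert round(report.recall["DP"], 2) == 0.88
        assert round(report.precision["CGP"], 2) == 0.82
        assert round(report.precision["CP"], 2) == 0.91
        assert round(report.precision["DP"], 2) == 1.00
        assert round(report.f1["CGP"], 2) == 0.86
        assert round(report.f1["CP"], 2) == 0.93
        assert round(report.f1["DP"], 2) == 0.94

    def test_diagonal_matrix_perfect_scores(self):
        report = classification_metrics(np.diag([5, 7, 9]))
        assert report.accuracy == 1.0
        assert all(v == 1.0 for v in report.precision.values())
        assert all(v == 1.0 for v in report.f1.values())

    def test_zero_row_gives_zero_recall(self):
        M = np.array([[0, 2, 0], [0, 5, 0], [0, 0, 4]])
        with pytest.warns(UserWarning, match="never predicted"):
            report = classification_metrics(M)
        assert report.recall["CGP"] == 0.0

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.ones((2, 3)))
        with pytest.raises(ValueError):
            classification_metrics(np.array([[1, -1], [0, 2]]))


class TestReconstruction:
    def test_integer_search_finds_consistent_matrix(self):
        found = reconstruct_confusion()
        assert len(found) >= 1
        assert any(np.array_equal(M, PRINTED_CONFUSION) for M in found)

    def test_all_found_matrices_reproduce_metrics(self):
        for M in reconstruct_confusion():
            rep = classification_metrics(M)
            assert M.sum() == 78 and np.trace(M) == 72
            assert round(rep.f1["CGP"], 2) == 0.86


class _StubModel:
    input_size = 8

    def __init__(self, probs):
        self._p = np.asarray(probs, dtype=float)

    def predict_proba(self, x, batch_size=64):
        return np.tile(self._p, (len(x), 1))


class TestEnsemble:
    def test_identical_members_equal_single(self):
        ens = ClassifierEnsemble(members=[_StubModel([0.7, 0.2, 0.1])] * 3)
        out = predict_ensemble(ens, np.zeros((8, 8)))
        np.testing.assert_allclose(out, [0.7, 0.2, 0.1])

    def test_one_hot_members_average_and_tie_to_cgp(self):
        members = [_StubModel([1, 0, 0]), _StubModel([0, 1, 0]),
                   _StubModel([0, 0, 1])]
        ens = ClassifierEnsemble(members=members)
        out = predict_ensemble(ens, np.zeros((8, 8)))
        np.testing.assert_allclose(out, [1 / 3, 1 / 3, 1 / 3])
        assert ens.predict(np.zeros((1, 8, 8)))[0] == "CGP"

    def test_simplex_property(self, rng):
        members = [_StubModel(p / p.sum())
                   for p in rng.uniform(0.1, 1, (3, 3))]
        ens = ClassifierEnsemble(members=members)
        out = predict_ensemble(ens, np.zeros((8, 8)))
        assert out.sum() == pytest.approx(1.0)
        assert (out >= 0).all()

    def test_shape_mismatch_rejected(self):
        ens = ClassifierEnsemble(members=[_StubModel([1, 0, 0])])
        with pytest.raises(ValueError, match="input"):
            ens.predict_proba(np.zeros((1, 16, 16)))


class TestTraining:
    def _constant_intensity_problem(self):
        """Each class one constant intensity: linearly separable."""
        rng = np.random.default_rng(0)
        patches, labels = [], []
        for value, cls in zip((0.1, 0.5, 0.9), CLASS_ORDER):
            for _ in range(12):
                patches.append(np.full((24, 24), value, dtype=np.float32)
                               + rng.normal(0, 0.01, (24, 24)).astype(np.float32))
                labels.append(cls)
        return np.stack(patches), np.array(labels)

    def test_degenerate_problem_learned_within_five_epochs(self):
        patches, labels = self._constant_intensity_problem()
        cfg = TrainConfig(epochs=5, patience=5, filters=(4, 8), dense_units=16,
                          dropout=0.0, augment=False, seed=0,
                          learning_rate=0.01, batch_size=6)
        ens = train_crossval(patches, labels, cfg)
        acc = (ens.predict(patches) == labels).mean()
        assert acc == 1.0

    def test_seeded_training_reproducible(self):
        patches, labels = self._constant_intensity_problem()
        cfg = TrainConfig(epochs=2, filters=(4,), dense_units=8,
                          dropout=0.0, augment=False, seed=7)
        p1 = train_crossval(patches, labels, cfg).predict_proba(patches[:5])
        p2 = train_crossval(patches, labels, cfg).predict_proba(patches[:5])
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_save_load_roundtrip(self, tmp_path):
        patches, labels = self._constant_intensity_problem()
        cfg = TrainConfig(epochs=2, filters=(4,), dense_units=8,
                          dropout=0.0, augment=False, seed=1)
        ens = train_crossval(patches, labels, cfg)
        clf.save_ensemble(ens, tmp_path / "model")
        back = clf.load_ensemble(tmp_path / "model")
        np.testing.assert_allclose(back.predict_proba(patches[:4]),
                                   ens.predict_proba(patches[:4]), atol=1e-6)
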