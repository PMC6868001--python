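"""Adversarial model: construction, losses, splits, training behavior."""

import numpy as np
import pytest

from erdscope import model
from erdscope.model import ArchConfig, TrainConfig
from erdscope.tfmaps import PairDataset

from conftest import SMALL_ARCH


def zero_head(layers, bias=None):
    for i, (w, b) in enumerate(layers):
        w.data[:] = 0.0
        b.data[:] = 0.0
    if bias is not None:
        layers[-1][1].data[:] = bias


class TestConstruction:
    def test_same_seed_identical_parameters(self):
        b1 = model.build_models(SMALL_ARCH, 5, seed=3, input_shape=(8, 55))
        b2 = model.build_models(SMALL_ARCH, 5, seed=3, input_shape=(8, 55))
        for p1, p2 in zip(b1.theta_f + b1.theta_t + b1.theta_s,
                          b2.theta_f + b2.theta_t + b2.theta_s):
            assert np.array_equal(p1.data, p2.data)

    def test_tf_mode_rejects_electrode_kernels(self):
        with pytest.raises(ValueError, match="electrode"):
            ArchConfig(mode="tf", kernel_electrode=3)
        # frequency-extent-5 kernels are the accepted tf-mode shape
        assert ArchConfig(mode="tf", kernel_freq=5).kernel_electrode == 1

    def test_topo_mode_forward_smoke(self):
        arch = ArchConfig(mode="topo", conv_channels=(4,), pool=2,
                          embed=(16,), head_hidden=(8,))
        b = model.build_models(arch, 4, seed=0, input_shape=(3, 64, 64))
        rng = np.random.default_rng(0)
        gp, sp, d = model.forward_pair(b, rng.random((2, 3, 64, 64)),
                                       rng.random((2, 3, 64, 64)))
        assert np.all(np.isfinite(gp)) and gp.shape == (2, 2)
        assert sp.shape == (2, 4)


class TestForwardPair:
    def setup_method(self):
        self.bundle = model.build_models(SMALL_ARCH, 4, seed=1,
                                         input_shape=(8, 55))
        self.rng = np.random.default_rng(2)

    def test_probabilities_normalize(self):
        B = self.rng.random((3, 8, 55))
        A = self.rng.random((3, 8, 55))
        gp, sp, _ = model.forward_pair(self.bundle, B, A)
        assert np.allclose(gp.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(sp.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_pair_gives_zero_difference(self):
        X = self.rng.random((2, 8, 55))
        _, _, d = model.forward_pair(self.bundle, X, X)
        assert np.allclose(d, 0.0)

    def test_swapping_sessions_negates_difference(self):
        B = self.rng.random((2, 8, 55))
        A = self.rng.random((2, 8, 55))
        _, _, d1 = model.forward_pair(self.bundle, B, A)
        _, _, d2 = model.forward_pair(self.bundle, A, B)
        assert np.allclose(d1, -d2, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            model.forward_pair(self.bundle, np.ones((2, 8, 54)),
                               np.ones((2, 8, 54)))


class TestLosses:
    def make_batch(self, bundle, n=6):
        rng = np.random.default_rng(3)
        B = rng.random((n, 8, 55))
        A = rng.random((n, 8, 55))
        y_g = rng.integers(0, 2, n)
        y_s = rng.integers(0, bundle.S, n)
        return (B, A, y_g, y_s)

    def test_lambda_zero_makes_objective_equal_group_loss(self):
        bundle = model.build_models(SMALL_ARCH, 4, seed=4, lam=0.0,
                                    input_shape=(8, 55))
        J_g, J_s, J_f, kl = model.losses(bundle, self.make_batch(bundle))
        assert np.isclose(float(J_f.data), float(J_g.data))

    def test_uniform_adversary_head_sits_at_confusion_equilibrium(self):
        # zeroed subject head -> uniform probabilities over S: KL vanishes,
        # the objective reduces to the group loss, and J_s = ln(S)
        bundle = model.build_models(SMALL_ARCH, 13, seed=5, lam=7.0,
                                    input_shape=(8, 55))
        zero_head(bundle.sub_layers)
        J_g, J_s, J_f, kl = model.losses(bundle, self.make_batch(bundle))
        assert np.isclose(float(kl.data), 0.0, atol=1e-7)
        assert np.isclose(float(J_f.data), float(J_g.data), atol=1e-6)
        assert np.isclose(float(J_s.data), np.log(13), atol=1e-6)

    def test_kl_from_uniform_nonnegative_and_zero_iff_uniform(self):
        from erdscope.autodiff import Tensor, log_softmax

        rng = np.random.default_rng(6)
        logits = Tensor(rng.standard_normal((20, 7)) * 3)
        kl = model.kl_from_uniform(log_softmax(logits), 7)
        assert np.all(kl.data >= -1e-12)
        uniform = model.kl_from_uniform(log_softmax(Tensor(np.zeros((4, 7)))), 7)
        assert np.allclose(uniform.data, 0.0, atol=1e-12)

    def test_group_head_gradient_independent_of_kl_term(self):
        # the domain-confusion term carries no dependence on the group head,
        # so dJ_f/dtheta_t must equal dJ_g/dtheta_t for any lambda
        bundle = model.build_models(SMALL_ARCH, 4, seed=7, lam=5.0,
                                    input_shape=(8, 55))
        batch = self.make_batch(bundle)
        J_g, _, _, _ = model.losses(bundle, batch)
        for p in bundle.theta_t:
            p.grad = None
        J_g.backward()
        g_only = [p.grad.copy() for p in bundle.theta_t]
        _, _, J_f, _ = model.losses(bundle, batch)
        for p in bundle.theta_t:
            p.grad = None
        J_f.backward()
        for g1, p in zip(g_only, bundle.theta_t):
            assert np.allclose(g1, p.grad, atol=1e-6)

    def test_empty_batch_rejected(self):
        bundle = model.build_models(SMALL_ARCH, 4, seed=8, input_shape=(8, 55))
        with pytest.raises(ValueError, match="empty"):
            model.losses(bundle, (np.zeros((0, 8, 55)), np.zeros((0, 8, 55)),
                                  np.zeros(0, int), np.zeros(0, int)))


class TestSplits:
    def make_dataset(self, n_con=3, n_exe=3, T=10):
        S = n_con + n_exe
        rng = np.random.default_rng(9)
        arr = rng.random((S, 2, 55, T)) + 0.5
        y = np.array([0] * n_con + [1] * n_exe)
        return PairDataset(arr, arr + 0.1, y, [f"s{i}" for i in range(S)])

    def test_timepoint_split_sizes(self):
        ds = self.make_dataset()
        plan = model.make_split(ds, "timepoint_80_20", seed=0)
        train, val = plan.folds[0]
        assert train.size == int(np.floor(0.8 * ds.m))
        assert train.size + val.size == ds.m
        assert np.intersect1d(train, val).size == 0

    def test_leave_two_out_holds_one_subject_per_group(self):
        ds = self.make_dataset()
        plan = model.make_split(ds, "subject_leave2out_10fold", seed=0)
        assert len(plan.folds) == 3  # min(10, 3, 3)
        for train, val in plan.folds:
            held = np.unique(ds.subject_of(val))
            assert held.size == 2
            assert sorted(ds.y_group[held]) == [0, 1]

    def test_subject_shuffle_preserves_group_sizes(self):
        ds = self.make_dataset(4, 2)
        plan = model.make_split(ds, "shuffle_subject_labels", seed=1)
        assert plan.y_group_subject.sum() == 2
        # shuffled labels drive training labels
        idx = np.arange(ds.m)
        labels = plan.labels_for(ds, idx)
        assert labels.size == ds.m

    def test_timepoint_shuffle_is_a_permutation(self):
        ds = self.make_dataset()
        plan = model.make_split(ds, "shuffle_timepoint_labels", seed=2)
        orig = ds.y_group[ds.subject_of(np.arange(ds.m))]
        assert plan.y_group_tuple.sum() == orig.sum()
        assert not np.array_equal(plan.y_group_tuple, orig)

    def test_split_deterministic_per_seed(self):
        ds = self.make_dataset()
        p1 = model.make_split(ds, "subject_leave2out_10fold", seed=5)
        p2 = model.make_split(ds, "subject_leave2out_10fold", seed=5)
        for (a, b), (c, d) in zip(p1.folds, p2.folds):
            assert np.array_equal(a, c) and np.array_equal(b, d)

    def test_too_few_subjects_rejected(self):
        ds = self.make_dataset(1, 3)
        with pytest.raises(ValueError, match="2 subjects"):
            model.make_split(ds, "subject_leave2out_10fold", seed=0)


class TestEvaluate:
    def test_constant_majority_prediction_on_13_12_cohort(self):
        rng = np.random.default_rng(10)
        arr = rng.random((25, 2, 55, 2)) + 0.5
        y = np.array([0] * 13 + [1] * 12)
        ds = PairDataset(arr, arr + 0.1, y, [f"s{i}" for i in range(25)])
        bundle = model.build_models(SMALL_ARCH, 25, seed=0, input_shape=(2, 55))
        zero_head(bundle.top_layers, bias=np.array([1.0, 0.0]))  # always CON
        acc, (acc_con, acc_exe) = model.evaluate(bundle, ds, np.arange(ds.m))
        assert np.isclose(acc, 13 / 25)
        assert acc_con == 1.0 and acc_exe == 0.0

    def test_empty_evaluation_rejected(self):
        bundle = model.build_models(SMALL_ARCH, 4, seed=0, input_shape=(2, 55))
        ds = PairDataset(np.ones((4, 2, 55, 2)), np.ones((4, 2, 55, 2)),
                         np.array([0, 0, 1, 1]), list("abcd"))
        with pytest.raises(ValueError, match="empty"):
            model.evaluate(bundle, ds, np.array([], dtype=int))


class TestTraining:
    def test_planted_effect_learned_above_chance(self, trained_tiny_bundle):
        _, history, _ = trained_tiny_bundle
        assert history.val_acc[-1] > 0.85
        assert history.val_acc[-1] >= history.val_acc[0]
        assert all(np.isfinite(v) for v in history.J_g)

    def test_training_reproducible(self, tiny_dataset):
        split = model.make_split(tiny_dataset, "timepoint_80_20", seed=11)
        runs = []
        for _ in range(2):
            b = model.build_models(SMALL_ARCH, tiny_dataset.n_subjects, seed=11,
                                   lam=0.5, input_shape=(64, 55))
            _, h = model.train(b, tiny_dataset, split,
                               TrainConfig(epochs=2, batch_size=64))
            runs.append(h)
        assert runs[0].J_g == runs[1].J_g
        assert runs[0].val_acc == runs[1].val_acc

    def test_timepoint_label_shuffle_stays_near_chance(self, tiny_dataset):
        split = model.make_split(tiny_dataset, "shuffle_timepoint_labels", seed=11)
        b = model.build_models(SMALL_ARCH, tiny_dataset.n_subjects, seed=11,
                               lam=0.0, input_shape=(64, 55))
        _, h = model.train(b, tiny_dataset, split,
                           TrainConfig(epochs=3, batch_size=64, val_eval_cap=200))
        assert h.val_acc[-1] < 0.65

    def test_extreme_adversary_weight_destroys_discrimination(
            self, tiny_dataset, trained_tiny_bundle):
        split = model.make_split(tiny_dataset, "timepoint_80_20", seed=11)
        b = model.build_models(SMALL_ARCH, tiny_dataset.n_subjects, seed=11,
                               lam=200.0, input_shape=(64, 55))
        _, h = model.train(b, tiny_dataset, split,
                           TrainConfig(epochs=4, batch_size=64, lr=3e-3,
                                       val_eval_cap=200))
        _, ref_history, _ = trained_tiny_bundle
        assert h.val_acc[-1] < ref_history.val_acc[-1] - 0.1


class TestSelectLambda:
    def test_singleton_grid(self, tiny_dataset):
        split = model.make_split(tiny_dataset, "timepoint_80_20", seed=11)
        lam, rows = model.select_lambda([0.0], tiny_dataset, split, SMALL_ARCH,
                                        TrainConfig(epochs=2, batch_size=64,
                                                    val_eval_cap=200),
                                        seed=11, acc_floor=0.5)
        assert lam == 0.0
        assert len(rows) == 1 and rows[0]["val_acc"] > 0.5

    def test_infeasible_floor_returns_none_with_warning(self, tiny_dataset):
        split = model.make_split(tiny_dataset, "timepoint_80_20", seed=11)
        with pytest.warns(RuntimeWarning, match="floor"):
            lam, rows = model.select_lambda([0.0], tiny_dataset, split,
                                            SMALL_ARCH,
                                            TrainConfig(epochs=1, batch_size=64,
                                                        val_eval_cap=200),
                                            seed=11, acc_floor=1.01)
        assert lam is None


class TestFeatures:
    def test_extracted_features_shape_and_determinism(self, trained_tiny_bundle,
                                                      tiny_dataset):
        bundle, _, _ = trained_tiny_bundle
        f1 = model.extract_features(bundle, tiny_dataset, "feature")
        f2 = model.extract_features(bundle, tiny_dataset, "feature")
        assert f1.shape[0] == tiny_dataset.n_subjects
        assert np.array_equal(f1, f2)

    def test_head_layer_tags(self, trained_tiny_bundle, tiny_dataset):
        bundle, _, _ = trained_tiny_bundle
        logits = model.extract_features(bundle, tiny_dataset, "top.1")
        assert logits.shape == (tiny_dataset.n_subjects, 2)
        with pytest.raises(ValueError, match="layer"):
            model.extract_features(bundle, tiny_dataset, "top.9")
        with pytest.raises(ValueError, match="tag"):
            model.extract_features(bundle, tiny_dataset, "bogus")

    def test_identity_pairs_give_constant_features(self, trained_tiny_bundle,
                                                   tiny_dataset):
        bundle, _, _ = trained_tiny_bundle
        same = PairDataset(tiny_dataset.baseline, tiny_dataset.baseline,
                           tiny_dataset.y_group, tiny_dataset.subject_ids)
        feats = model.extract_features(bundle, same, "feature")
        assert np.allclose(feats - feats[0], 0.0, atol=1e-6)


class TestBehaviorCorrelation:
    def test_perfect_correlation_signs(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        feats = scores[:, None]
        assert np.isclose(model.feature_behavior_correlation(feats, scores, 0), 1.0)
        assert np.isclose(
            model.feature_behavior_correlation(-feats, scores, 0), -1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            model.feature_behavior_correlation(np.ones((2, 1)), np.ones(2), 0)
        with pytest.raises(ValueError, match="variance"):
            model.feature_behavior_correlation(np.ones((4, 1)),
                                               np.arange(4.0), 0)
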