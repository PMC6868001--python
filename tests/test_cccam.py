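"""Cue-combination attribution: ablation, precisions, CAM geometry, BSR."""

import numpy as np
import pytest

from erdscope import cccam, model

from conftest import SMALL_ARCH


class GaussianCueStub:
    """Classifier whose correct-class NLL is the Gaussian-cue quadratic.

    This is the generative model the cue-combination derivation assumes
    (cue i ~ N(+/-m_i, sigma_i^2) given the class, independent cues), so it
    serves as the analytic oracle for the precision estimator.
    """

    trained = True

    class arch:
        mode = "tf"

    def __init__(self, m, s2):
        self.m = np.asarray(m, float)
        self.s2 = np.asarray(s2, float)

    def group_nll_from_block(self, block, y):
        c = block.reshape(block.shape[0], -1)
        sign = np.where(np.asarray(y) == 1, 1.0, -1.0)[:, None]
        return ((c - sign * self.m) ** 2 / (2 * self.s2)).sum(axis=1)


def gaussian_cue_data(m, s2, n, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    sign = np.where(y == 1, 1.0, -1.0)
    c = sign[:, None] * np.asarray(m) + rng.standard_normal((n, len(m))) \
        * np.sqrt(s2)
    return c.reshape(n, len(m), 1, 1), y


class TestAblation:
    def test_zero_channel_ablation_is_noop(self):
        stub = GaussianCueStub([1.0, 1.0], [1.0, 1.0])
        mu, y = gaussian_cue_data([2.0, 2.0], [1.0, 1.0], 50, seed=1)
        mu[:, 1] = 0.0  # channel already zero
        eps = cccam.ablation_nll(stub, mu, y, None)
        eps1 = cccam.ablation_nll(stub, mu, y, 1)
        assert np.allclose(eps, eps1)

    def test_untrained_bundle_rejected(self):
        bundle = model.build_models(SMALL_ARCH, 4, seed=0, input_shape=(8, 55))
        with pytest.raises(ValueError, match="trained"):
            cccam.ablation_nll(bundle, np.ones((2, 2, 8, 26)), np.zeros(2, int))

    def test_out_of_range_cue_rejected(self):
        stub = GaussianCueStub([1.0], [1.0])
        with pytest.raises(ValueError, match="range"):
            cccam.ablation_nll(stub, np.ones((2, 1, 1, 1)), np.zeros(2, int), 5)


class TestPrecisions:
    def test_gaussian_oracle_ratio(self):
        # confident regime (means >> sd): the NLL-ablation estimator recovers
        # the analytic reliability ratio 1/sigma_1^2 : 1/sigma_2^2
        m, s2 = (10.0, 10.0), (1.0, 2.0)
        mu, y = gaussian_cue_data(m, s2, 5000, seed=0)
        cs = cccam.estimate_precisions_from_blocks(GaussianCueStub(m, s2), mu, y)
        ratio = cs.precisions[0] / cs.precisions[1]
        assert abs(ratio - 2.0) / 2.0 < 0.10
        assert np.isclose(cs.weights.sum(), 1.0, atol=1e-12)

    def test_duplicated_cues_get_equal_precisions(self):
        m, s2 = (5.0, 5.0), (1.5, 1.5)
        mu, y = gaussian_cue_data(m, s2, 400, seed=2)
        mu[:, 1] = mu[:, 0]
        cs = cccam.estimate_precisions_from_blocks(GaussianCueStub(m, s2), mu, y)
        assert np.isclose(cs.precisions[0], cs.precisions[1], rtol=1e-9)

    def test_uninformative_cue_gets_zero_precision(self):
        # a cue whose removal never changes the loss: weight it out entirely
        class IgnoreSecond(GaussianCueStub):
            def group_nll_from_block(self, block, y):
                c = block.reshape(block.shape[0], -1)[:, :1]
                sign = np.where(np.asarray(y) == 1, 1.0, -1.0)[:, None]
                return ((c - sign * self.m[:1]) ** 2 / (2 * self.s2[:1])).sum(axis=1)

        m, s2 = (5.0, 5.0), (1.0, 1.0)
        mu, y = gaussian_cue_data(m, s2, 300, seed=3)
        cs = cccam.estimate_precisions_from_blocks(IgnoreSecond(m, s2), mu, y)
        assert cs.precisions[1] == 0.0
        assert cs.weights[1] == 0.0


class TestCombination:
    def make_cueset(self, precisions, n=3, shape=(2, 4)):
        rng = np.random.default_rng(4)
        C = len(precisions)
        mu = rng.standard_normal((n, C) + shape)
        prec = np.asarray(precisions, float)
        w = prec / prec.sum() if prec.sum() > 0 else np.full(C, 1 / C)
        return cccam.CueSet(mu=mu, y=np.zeros(n, int), eps_full=np.zeros(n),
                            eps_removed=np.zeros((n, C)), precisions=prec,
                            weights=w)

    def test_equal_precisions_average_cues(self):
        cs = self.make_cueset([2.0, 2.0])
        cstar = cccam.combine_cues(cs)
        assert np.allclose(cstar, cs.mu.mean(axis=1))

    def test_inverse_variance_weights(self):
        # sigma^2 = (1, 3) -> weights (0.75, 0.25)
        cs = self.make_cueset([1.0, 1.0 / 3.0])
        assert np.allclose(cs.weights, [0.75, 0.25])
        cstar = cccam.combine_cues(cs)
        assert np.allclose(cstar, 0.75 * cs.mu[:, 0] + 0.25 * cs.mu[:, 1])

    def test_single_cue_is_identity(self):
        cs = self.make_cueset([5.0])
        assert np.allclose(cccam.combine_cues(cs), cs.mu[:, 0])

    def test_scale_robustness_of_weights(self):
        # rescaling a cue map and its likelihood variance together (what a
        # linear head absorbs) leaves the combined map invariant
        m, s2 = (8.0, 8.0), (1.0, 2.0)
        mu, y = gaussian_cue_data(m, s2, 2000, seed=5)
        cs1 = cccam.estimate_precisions_from_blocks(GaussianCueStub(m, s2), mu, y)
        k = 10.0
        mu2 = mu.copy()
        mu2[:, 0] *= k
        stub2 = GaussianCueStub((m[0] * k, m[1]), (s2[0] * k * k, s2[1]))
        cs2 = cccam.estimate_precisions_from_blocks(stub2, mu2, y)
        c1 = cccam.combine_cues(cs1)
        c2 = cccam.combine_cues(cs2)
        # cue 0 contribution scaled by k but weighted by 1/k^2-scaled
        # precision: weights adapt so the maps stay proportional
        assert np.allclose(cs1.weights[1] * c1[:, 0] + 0, c1[:, 0] * cs1.weights[1])
        assert np.allclose(cs2.weights[0], cs1.weights[0] / (k * k)
                           / (cs1.weights[0] / (k * k) + cs1.weights[1]), rtol=0.05)


class TestCamGeometry:
    def test_identity_when_no_pooling_or_convolution(self):
        arch = model.ArchConfig(conv_channels=(3,), kernel_freq=1, pool=1,
                                embed=(8,), head_hidden=(4,))
        bundle = model.build_models(arch, 3, seed=0, input_shape=(4, 55))
        cstar = np.random.default_rng(6).standard_normal((2, 4, 55))
        cam = cccam.cam_at_input_resolution(bundle, cstar)
        assert np.allclose(cam.values, cstar)

    def test_upsampled_to_55_columns(self):
        arch = model.ArchConfig(conv_channels=(2,), kernel_freq=5, pool=2,
                                embed=(8,), head_hidden=(4,))
        bundle = model.build_models(arch, 3, seed=0, input_shape=(4, 55))
        Fp = bundle.feature_shape[-1]
        cstar = np.random.default_rng(7).standard_normal((3, 4, Fp))
        cam = cccam.cam_at_input_resolution(bundle, cstar)
        assert cam.values.shape == (3, 4, 55)

    def test_constant_map_stays_constant(self):
        arch = model.ArchConfig(conv_channels=(2,), kernel_freq=5, pool=2,
                                embed=(8,), head_hidden=(4,))
        bundle = model.build_models(arch, 3, seed=0, input_shape=(4, 55))
        Fp = bundle.feature_shape[-1]
        cam = cccam.cam_at_input_resolution(bundle, np.full((1, 4, Fp), 3.3))
        assert np.allclose(cam.values, 3.3)

    def test_geometry_mismatch_rejected(self):
        arch = model.ArchConfig(conv_channels=(2,), kernel_freq=5, pool=2,
                                embed=(8,), head_hidden=(4,))
        bundle = model.build_models(arch, 3, seed=0, input_shape=(4, 55))
        with pytest.raises(ValueError, match="geometry"):
            cccam.cam_at_input_resolution(bundle, np.ones((1, 4, 7)))


class TestImportanceAndBSR:
    def test_frequency_importance_averages_electrodes(self):
        cam = cccam.CAMMap(values=np.full((2, 8, 55), 1.7), mode="tf")
        assert np.allclose(cccam.frequency_importance(cam), 1.7)

    def test_importance_is_column_local(self):
        v = np.zeros((1, 4, 55))
        v[0, :, 20] = 1.0
        imp = cccam.frequency_importance(cccam.CAMMap(values=v, mode="tf"))
        assert imp[0, 20] == 1.0 and np.allclose(np.delete(imp[0], 20), 0.0)

    def test_sign_balanced_electrodes_cancel(self):
        v = np.ones((1, 64, 55))
        v[0, ::2] = -1.0
        imp = cccam.frequency_importance(cccam.CAMMap(values=v, mode="tf"))
        assert np.allclose(imp, 0.0)

    def test_topo_mode_rejected(self):
        with pytest.raises(ValueError, match="tf"):
            cccam.frequency_importance(cccam.CAMMap(values=np.ones((1, 8, 8)),
                                                    mode="topo"))

    def test_bsr_is_mean_over_sd(self):
        rng = np.random.default_rng(8)
        series = 2.0 + rng.standard_normal((400, 3))  # mean 2, sd 1
        out = cccam.bsr(series, np.zeros(400, int), 1)
        assert np.allclose(out, 2.0, atol=0.3)

    def test_zero_mean_series_gives_near_zero_bsr(self):
        rng = np.random.default_rng(9)
        out = cccam.bsr(rng.standard_normal((500, 2)), np.zeros(500, int), 1)
        assert np.all(np.abs(out) < 0.2)

    def test_constant_series_hits_epsilon_guard(self):
        series = np.full((5, 2), 1.5)
        with pytest.warns(RuntimeWarning, match="guard"):
            out = cccam.bsr(series, np.zeros(5, int), 1)
        assert np.all(np.isfinite(out))

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError, match="2 timepoints"):
            cccam.bsr(np.ones((1, 2)), np.zeros(1, int), 1)


def test_end_to_end_pipeline_shapes(trained_tiny_bundle, tiny_dataset):
    bundle, _, _ = trained_tiny_bundle
    bsr_map, cueset = cccam.frequency_bsr_pipeline(bundle, tiny_dataset)
    assert bsr_map.per_subject.shape == (tiny_dataset.n_subjects, 55)
    assert np.isclose(cueset.weights.sum(), 1.0)
    assert set(bsr_map.group_mean) == {"CON", "EXE"}
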