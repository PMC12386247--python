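"""Cross-modal attention fusion: histograms, KL, attention, gating."""

import math

import numpy as np
import pytest

from pestfusion.autodiff import Tensor
from pestfusion.cma import (CMAFusion, ProbHistogram, alignment_attention,
                            cross_attention, estimate_distribution,
                            kl_divergence)
from pestfusion.config import ModelConfig
from pestfusion.encoders import FeatureMap
from pestfusion.nn import Linear

from conftest import assert_gradcheck


def _hist(probs):
    probs = np.asarray(probs, dtype=float)
    return ProbHistogram(probs, np.linspace(0, 1, len(probs) + 1))


class TestHistograms:
    def test_constant_map_concentrates_then_smooths(self):
        fmap = np.full((4, 16, 16), 0.7)
        hists = estimate_distribution(fmap, grid=4, bins=8)
        h = hists[0][0]
        assert (h.probs > 0).all()
        assert h.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert h.probs.max() > 2.0 / 8      # mass still concentrated vs uniform

    def test_uniform_activations_fill_bins_binomially(self):
        """Large uniform sample: each of 4 bins holds ~1/4 of the mass."""
        rng = np.random.default_rng(0)
        fmap = rng.uniform(0, 1, (1, 64, 64))
        hists = estimate_distribution(fmap, grid=1, bins=4)
        n = 64 * 64
        tol = 5 * math.sqrt(0.25 * 0.75 / n)
        # smoothing pulls toward uniform, so the binomial band is conservative
        np.testing.assert_allclose(hists[0][0].probs, 0.25, atol=tol + 0.05)

    def test_identical_regions_identical_histograms(self):
        tile = np.random.default_rng(1).uniform(size=(2, 8, 8))
        fmap = np.concatenate([np.concatenate([tile, tile], axis=2)] , axis=1)
        fmap = np.concatenate([fmap, fmap], axis=1)
        hists = estimate_distribution(fmap, grid=2, bins=8)
        np.testing.assert_array_equal(hists[0][0].probs, hists[0][1].probs)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            estimate_distribution(np.zeros((1, 8, 8)), grid=2, bins=1)


class TestKL:
    def test_identity_of_indiscernibles(self):
        p = _hist([0.25, 0.25, 0.25, 0.25])
        assert kl_divergence(p, p) == 0.0

    def test_hand_computed_value(self):
        # 0.5 ln 2 + 0.5 ln(2/3) = 0.143841...
        p, q = _hist([0.5, 0.5]), _hist([0.25, 0.75])
        expected = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
        assert kl_divergence(p, q) == pytest.approx(expected, abs=1e-12)
        assert kl_divergence(p, q) == pytest.approx(0.14384, abs=1e-5)

    def test_asymmetry(self):
        p, q = _hist([0.5, 0.5]), _hist([0.25, 0.75])
        assert kl_divergence(p, q) != kl_divergence(q, p)

    def test_nonnegativity_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a = rng.dirichlet(np.ones(8))
            b = rng.dirichlet(np.ones(8))
            assert kl_divergence(_hist(a), _hist(b)) >= -1e-12

    def test_bin_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(_hist([0.5, 0.5]), _hist([0.3, 0.3, 0.4]))


class TestAlignment:
    def test_zero_kl_gives_unit_weights(self):
        amap = alignment_attention(np.zeros((4, 4)))
        assert (amap.weights == 1.0).all()

    def test_monotone_decreasing_in_kl(self):
        amap = alignment_attention(np.array([[0.1, 0.5], [1.0, 2.0]]))
        flat = amap.weights.ravel()
        assert (np.diff(flat) < 0).all()

    def test_weights_never_amplify_features(self):
        rng = np.random.default_rng(3)
        fmap = rng.normal(size=(4, 8, 8))
        amap = alignment_attention(rng.uniform(0, 3, (8, 8)))
        weighted = fmap * amap.weights
        assert (np.abs(weighted) <= np.abs(fmap) + 1e-12).all()

    def test_non_finite_kl_rejected(self):
        with pytest.raises(ValueError):
            alignment_attention(np.array([np.inf]))


class TestCrossAttention:
    def _projs(self, d, rng):
        return (Linear(d, d, rng) for _ in range(3))

    def test_uniform_softmax_when_keys_equal(self):
        rng = np.random.default_rng(4)
        d = 4
        q_p, k_p, v_p = self._projs(d, rng)
        q_tok = Tensor(rng.normal(size=(3, d)))
        kv = Tensor(np.tile(rng.normal(size=(1, d)), (5, 1)))
        out = cross_attention(q_p, k_p, v_p, q_tok, kv).numpy()
        v = v_p(kv).numpy()
        np.testing.assert_allclose(out, np.tile(v.mean(0), (3, 1)), atol=1e-10)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_double_loop(self, trial):
        """Attention equals the explicit softmax-weighted double sum."""
        rng = np.random.default_rng(100 + trial)
        d = int(rng.integers(2, 6))
        nq, nk = int(rng.integers(1, 6)), int(rng.integers(2, 6))
        q_p = Linear(d, d, rng)
        k_p = Linear(d, d, rng)
        v_p = Linear(d, d, rng)
        q_tok = rng.normal(size=(nq, d))
        kv_tok = rng.normal(size=(nk, d))
        out = cross_attention(q_p, k_p, v_p, Tensor(q_tok), Tensor(kv_tok)).numpy()
        q = q_p(Tensor(q_tok)).numpy()
        k = k_p(Tensor(kv_tok)).numpy()
        v = v_p(Tensor(kv_tok)).numpy()
        ref = np.zeros((nq, d))
        for i in range(nq):
            logits = np.array([q[i] @ k[j] / math.sqrt(d) for j in range(nk)])
            weights = np.exp(logits - logits.max())
            weights /= weights.sum()
            for j in range(nk):
                ref[i] += weights[j] * v[j]
        np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        scores = Tensor(rng.normal(size=(7, 7)))
        rows = scores.softmax(axis=-1).numpy().sum(axis=1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-6)


class TestCMAForward:
    def _feature(self, cfg, seed, modality):
        rng = np.random.default_rng(seed)
        return FeatureMap(Tensor(rng.normal(size=(
            1, cfg.enc_channels, cfg.enc_spatial, cfg.enc_spatial))), modality)

    def test_output_shapes_tiny_and_paper(self):
        tiny = ModelConfig.tiny()
        cma = CMAFusion(tiny, np.random.default_rng(0))
        fused, g_rgb, g_ir = cma(self._feature(tiny, 1, "rgb"),
                                 self._feature(tiny, 2, "thermal"))
        assert fused.tensor.shape == (1, 8, 16, 16)
        assert g_rgb.shape == g_ir.shape == (1, 8, 16, 16)

        paper = ModelConfig()
        cma_p = CMAFusion(paper, np.random.default_rng(0))
        from pestfusion.autodiff import no_grad
        with no_grad():
            fused_p, _, _ = cma_p(self._feature(paper, 1, "rgb"),
                                  self._feature(paper, 2, "thermal"))
        assert fused_p.tensor.shape == (1, 32, 64, 64)

    def test_identical_modalities_give_unit_alignment(self):
        cfg = ModelConfig.tiny()
        cma = CMAFusion(cfg, np.random.default_rng(1))
        fmap = np.random.default_rng(2).normal(size=(
            cfg.enc_channels, cfg.enc_spatial, cfg.enc_spatial))
        amap = cma.alignment_weights(fmap, fmap)
        np.testing.assert_allclose(amap.weights, 1.0, atol=1e-12)

    def test_project_reduce_is_pointwise_in_space(self):
        """1x1 path: perturbing one pixel only changes that position."""
        cfg = ModelConfig.tiny()
        cma = CMAFusion(cfg, np.random.default_rng(3))
        x = np.random.default_rng(4).normal(size=(
            1, cfg.enc_channels, cfg.enc_spatial, cfg.enc_spatial))
        base = cma.reduce_rgb(Tensor(x)).numpy()
        x2 = x.copy()
        x2[0, :, 5, 7] += 1.0
        pert = cma.reduce_rgb(Tensor(x2)).numpy()
        diff = np.abs(pert - base).sum(axis=1)[0]
        assert diff[5, 7] > 0
        diff[5, 7] = 0
        assert diff.sum() == 0

    def test_zero_input_projects_to_bias(self):
        cfg = ModelConfig.tiny()
        cma = CMAFusion(cfg, np.random.default_rng(5))
        z = np.zeros((1, cfg.enc_channels, cfg.enc_spatial, cfg.enc_spatial))
        out = cma.reduce_rgb(Tensor(z)).numpy()
        np.testing.assert_allclose(
            out, cma.reduce_rgb.bias.data.reshape(1, -1, 1, 1)
            * np.ones_like(out), atol=1e-12)

    def test_residual_gate_limits(self):
        cfg = ModelConfig.tiny()
        cma = CMAFusion(cfg, np.random.default_rng(6))
        rng = np.random.default_rng(7)
        orig = Tensor(rng.normal(size=(1, cfg.cma_channels, 4, 4)))
        enh = Tensor(rng.normal(size=(1, cfg.cma_channels, 4, 4)))
        cma.gate_rgb.gamma.data[:] = -40.0      # gate -> 0
        np.testing.assert_allclose(cma.gate_rgb(orig, enh).numpy(),
                                   orig.numpy(), atol=1e-12)
        cma.gate_rgb.gamma.data[:] = 40.0       # gate -> 1
        np.testing.assert_allclose(cma.gate_rgb(orig, enh).numpy(),
                                   (orig + enh).numpy(), atol=1e-12)

    def test_residual_gate_bounded_update(self):
        cfg = ModelConfig.tiny()
        cma = CMAFusion(cfg, np.random.default_rng(8))
        rng = np.random.default_rng(9)
        orig = Tensor(rng.normal(size=(1, cfg.cma_channels, 4, 4)))
        enh = Tensor(rng.normal(size=(1, cfg.cma_channels, 4, 4)))
        out = cma.gate_rgb(orig, enh).numpy()
        assert (np.abs(out - orig.numpy()) <= np.abs(enh.numpy()) + 1e-12).all()

    def test_permutation_equivariance_without_positions(self):
        """Permuting both inputs spatially permutes the attention output.

        The KL-weight path is tied to a fixed region grid, so it is
        disabled for this check (weights are permutation-covariant only
        per region).
        """
        cfg = ModelConfig.tiny(use_reweighting=False)
        cma = CMAFusion(cfg, np.random.default_rng(10))
        rng = np.random.default_rng(11)
        s = cfg.enc_spatial
        a = rng.normal(size=(1, cfg.enc_channels, s, s))
        b = rng.normal(size=(1, cfg.enc_channels, s, s))
        t_rgb = cma._tokens(cma.spatial_rgb(cma.project_reduce(Tensor(a), "rgb")))
        t_ir = cma._tokens(cma.spatial_ir(cma.project_reduce(Tensor(b), "ir")))
        out = cross_attention(cma.q_rgb, cma.k_ir, cma.v_ir, t_rgb, t_ir).numpy()
        perm = rng.permutation(s * s)
        out_p = cross_attention(cma.q_rgb, cma.k_ir, cma.v_ir,
                                Tensor(t_rgb.data[:, perm]),
                                Tensor(t_ir.data[:, perm])).numpy()
        np.testing.assert_allclose(out_p, out[:, perm], atol=1e-10)

    def test_end_to_end_gradcheck_reduced(self):
        cfg = ModelConfig.tiny(enc_spatial=4, enc_channels=4, cma_channels=2,
                               cma_grid=2, gate_hw=4, gate_channels=2, head_hw=4)
        cma = CMAFusion(cfg, np.random.default_rng(12))
        rng = np.random.default_rng(13)
        a = rng.normal(size=(1, 4, 4, 4))
        b = rng.normal(size=(1, 4, 4, 4))

        def f(x, y):
            fused, _, _ = cma(FeatureMap(x, "rgb"), FeatureMap(y, "thermal"))
            return fused.tensor.mean()

        assert_gradcheck(f, a, b, tol=1e-4)
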