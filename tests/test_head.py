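"""Set-prediction head: transformer oracles, matching, and loss algebra."""

import itertools
import math

import numpy as np
import pytest

from pestfusion.autodiff import Tensor, no_grad
from pestfusion.boxes import giou_tensor, giou_xyxy, iou_xyxy
from pestfusion.config import ModelConfig
from pestfusion.head import (DetectionHead, DetectionOutput, MatchAssignment,
                             class_weights, contrastive_loss, hungarian_assign,
                             match_cost, total_loss, weighted_ce)
from pestfusion.nn import Linear, MultiHeadAttention

from conftest import assert_gradcheck


def brute_force_assignment(cost: np.ndarray) -> float:
    """Minimum assignment total over all permutations (oracle)."""
    n, m = cost.shape
    k = min(n, m)
    best = math.inf
    if n <= m:
        for perm in itertools.permutations(range(m), k):
            best = min(best, sum(cost[i, perm[i]] for i in range(k)))
    else:
        for perm in itertools.permutations(range(n), k):
            best = min(best, sum(cost[perm[j], j] for j in range(k)))
    return best


def rasterized_giou(box_a, box_b, resolution: int = 200) -> float:
    """Pixel-counting GIoU oracle on a normalized canvas."""
    boxes = np.array([box_a, box_b], dtype=float)
    lo = boxes[:, :2].min() - 0.1
    hi = boxes[:, 2:].max() + 0.1
    grid = np.linspace(lo, hi, resolution)
    xs, ys = np.meshgrid(grid, grid)

    def mask(b):
        return (xs >= b[0]) & (xs < b[2]) & (ys >= b[1]) & (ys < b[3])

    ma, mb = mask(box_a), mask(box_b)
    inter = (ma & mb).sum()
    union = (ma | mb).sum()
    hull_box = [min(box_a[0], box_b[0]), min(box_a[1], box_b[1]),
                max(box_a[2], box_b[2]), max(box_a[3], box_b[3])]
    hull = mask(hull_box).sum()
    return inter / union - (hull - union) / hull


class TestTransformer:
    def test_token_count_matches_spatial_size(self, tiny_cfg, rng):
        head = DetectionHead(tiny_cfg, tiny_cfg.gate_channels,
                             np.random.default_rng(0))
        fused = Tensor(rng.normal(size=(1, tiny_cfg.gate_channels, 8, 8)))
        with no_grad():
            memory = head.encoder(fused)
        assert memory.shape == (1, 64, tiny_cfg.d_model)

    @pytest.mark.parametrize("trial", range(10))
    def test_single_head_attention_matches_brute_force(self, trial):
        """MHA with one head equals the explicit double-loop softmax sum."""
        rng = np.random.default_rng(500 + trial)
        d = 4
        mha = MultiHeadAttention(d, 1, rng)
        ntok = int(rng.integers(2, 6))
        x = rng.normal(size=(ntok, d))
        out = mha(Tensor(x), Tensor(x), Tensor(x)).numpy()
        q = x @ mha.wq.weight.data + mha.wq.bias.data
        k = x @ mha.wk.weight.data + mha.wk.bias.data
        v = x @ mha.wv.weight.data + mha.wv.bias.data
        ref = np.zeros_like(q)
        for i in range(ntok):
            logits = np.array([q[i] @ k[j] / math.sqrt(d) for j in range(ntok)])
            w = np.exp(logits - logits.max())
            w /= w.sum()
            for j in range(ntok):
                ref[i] += w[j] * v[j]
        ref = ref @ mha.wo.weight.data + mha.wo.bias.data
        np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_token_permutation_equivariance_with_positions(self, rng):
        """Permuting tokens together with their PE permutes the output."""
        cfg = ModelConfig.tiny()
        head = DetectionHead(cfg, cfg.gate_channels, np.random.default_rng(1))
        layer = head.encoder.layers[0]
        x = rng.normal(size=(1, 10, cfg.d_model))
        with no_grad():
            out = layer(Tensor(x)).numpy()
            perm = rng.permutation(10)
            out_p = layer(Tensor(x[:, perm])).numpy()
        np.testing.assert_allclose(out_p, out[:, perm], atol=1e-9)

    def test_decoder_ignores_zeroed_memory_content(self, tiny_cfg, rng):
        """With zero memory, outputs depend only on the queries."""
        head = DetectionHead(tiny_cfg, tiny_cfg.gate_channels,
                             np.random.default_rng(2))
        decoder = head.decoder_pest
        queries = head.queries_pest
        zero_mem = Tensor(np.zeros((1, 16, tiny_cfg.d_model)))
        with no_grad():
            out1 = decoder(zero_mem, queries).numpy()
            out2 = decoder(Tensor(np.zeros((1, 16, tiny_cfg.d_model))),
                           queries).numpy()
        np.testing.assert_array_equal(out1, out2)

    def test_branch_outputs_shapes_paper_config(self):
        cfg = ModelConfig(enc_layers=1, dec_layers=1)   # depth-reduced for speed
        head = DetectionHead(cfg, 64, np.random.default_rng(3))
        fused = Tensor(np.random.default_rng(4).normal(size=(1, 64, 32, 32)))
        with no_grad():
            out = head(fused)
        assert set(out) == {"pest", "predator"}
        det = out["pest"][0]
        assert det.boxes.shape == (100, 4)
        assert det.class_probs.shape == (100, 9)
        assert det.embeddings.shape == (100, 256)

    def test_prediction_ranges(self, tiny_cfg, rng):
        head = DetectionHead(tiny_cfg, tiny_cfg.gate_channels,
                             np.random.default_rng(5))
        emb = Tensor(rng.normal(size=(tiny_cfg.n_queries, tiny_cfg.d_model)))
        det = head.mlps_pest(emb, "pest")
        b = det.boxes.numpy()
        assert (b >= 0).all() and (b <= 1).all()
        np.testing.assert_allclose(det.class_probs.numpy().sum(axis=1), 1.0,
                                   atol=1e-6)
        det2 = head.mlps_pest(emb, "pest")
        np.testing.assert_array_equal(det.boxes.numpy(), det2.boxes.numpy())

    def test_decoder_gradcheck_reduced(self):
        cfg = ModelConfig.tiny(d_model=8, n_heads=2, dec_layers=1, ffn_dim=8,
                               n_queries=2)
        head = DetectionHead(cfg, cfg.gate_channels, np.random.default_rng(6))
        mem = np.random.default_rng(7).normal(size=(1, 3, 8))
        assert_gradcheck(lambda m: head.decoder_pest(m, head.queries_pest)
                         .sum(), mem, tol=1e-4)


class TestHungarian:
    def test_diagonal_zero_cost_gives_identity(self):
        cost = np.ones((3, 3)) - np.eye(3)
        assert hungarian_assign(cost).pairs == [(0, 0), (1, 1), (2, 2)]

    def test_single_element(self):
        assert hungarian_assign(np.array([[3.0]])).pairs == [(0, 0)]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            hungarian_assign(np.array([[np.inf]]))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 8))
        m = int(rng.integers(1, 8))
        cost = rng.uniform(0, 10, (n, m))
        assign = hungarian_assign(cost)
        total = sum(cost[q, t] for q, t in assign.pairs)
        assert len(assign.pairs) == min(n, m)
        assert total == pytest.approx(brute_force_assignment(cost), abs=1e-9)


class TestMatchCost:
    def _perfect_pred(self, cfg, gt_boxes, gt_labels):
        nq = len(gt_boxes)
        probs = np.full((nq, cfg.n_classes + 1), 1e-9)
        for i, l in enumerate(gt_labels):
            probs[i, l] = 1.0 - 1e-9 * cfg.n_classes
        return DetectionOutput(boxes=Tensor(np.asarray(gt_boxes, dtype=float)),
                               class_probs=Tensor(probs),
                               embeddings=Tensor(np.zeros((nq, 4))),
                               branch="pest")

    def test_perfect_prediction_zero_cost(self, tiny_cfg):
        gt = np.array([[0.5, 0.5, 0.2, 0.2]])
        pred = self._perfect_pred(tiny_cfg, gt, [2])
        cost = match_cost(pred, gt, np.array([2]), tiny_cfg)
        assert cost[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_l1_distance(self, tiny_cfg):
        gt = np.array([[0.5, 0.5, 0.2, 0.2]])
        probs = np.full((2, tiny_cfg.n_classes + 1), 1.0 / (tiny_cfg.n_classes + 1))
        boxes = np.array([[0.52, 0.5, 0.2, 0.2], [0.6, 0.5, 0.2, 0.2]])
        pred = DetectionOutput(boxes=Tensor(boxes), class_probs=Tensor(probs),
                               embeddings=Tensor(np.zeros((2, 4))), branch="pest")
        cost = match_cost(pred, gt, np.array([0]), tiny_cfg)
        assert cost[0, 0] < cost[1, 0]

    def test_hand_computed_two_by_two(self, tiny_cfg):
        """Term-by-term check of the 2x2 cost matrix."""
        gt_boxes = np.array([[0.3, 0.3, 0.2, 0.2], [0.7, 0.7, 0.2, 0.2]])
        gt_labels = np.array([1, 6])
        boxes = np.array([[0.3, 0.3, 0.2, 0.2], [0.6, 0.6, 0.2, 0.2]])
        probs = np.zeros((2, tiny_cfg.n_classes + 1))
        probs[0, 1] = 0.8
        probs[0, 8] = 0.2
        probs[1, 6] = 0.6
        probs[1, 8] = 0.4
        pred = DetectionOutput(boxes=Tensor(boxes), class_probs=Tensor(probs),
                               embeddings=Tensor(np.zeros((2, 4))), branch="pest")
        cost = match_cost(pred, gt_boxes, gt_labels, tiny_cfg)
        from pestfusion.boxes import cxcywh_to_xyxy
        for q in range(2):
            for t in range(2):
                l1 = np.abs(boxes[q] - gt_boxes[t]).sum()
                g = giou_xyxy(cxcywh_to_xyxy(boxes[q]), cxcywh_to_xyxy(gt_boxes[t]))
                expected = (tiny_cfg.lambda_cls * (1 - probs[q, gt_labels[t]])
                            + tiny_cfg.lambda_bbox * l1
                            + tiny_cfg.lambda_giou * (1 - g))
                assert cost[q, t] == pytest.approx(expected, abs=1e-12)

    def test_empty_gt_yields_empty_matrix(self, tiny_cfg):
        pred = self._perfect_pred(tiny_cfg, np.array([[0.5, 0.5, 0.2, 0.2]]), [0])
        cost = match_cost(pred, np.zeros((0, 4)), np.zeros(0, int), tiny_cfg)
        assert cost.shape == (1, 0)


class TestClassWeightsAndCE:
    def test_balanced_counts_unit_weights(self):
        np.testing.assert_allclose(class_weights(np.full(8, 10)), 1.0)

    def test_hand_computed_two_class(self):
        # counts (3,1): omega = (4/6, 4/2)
        np.testing.assert_allclose(class_weights(np.array([3, 1])),
                                   [4 / 6, 2.0], atol=1e-12)

    def test_scale_invariance(self):
        a = class_weights(np.array([2, 5, 9]))
        b = class_weights(np.array([20, 50, 90]))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_count_class_capped(self):
        w = class_weights(np.array([10, 10, 0]))
        assert np.isfinite(w).all()
        assert w[2] == pytest.approx(10 * np.median(w[:2] * [1, 1]), rel=0.5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            class_weights(np.zeros(3))

    def test_ce_correct_prediction_zero_loss(self):
        p = Tensor(np.array([0.0, 1.0, 0.0]))
        assert weighted_ce(p, 1, np.ones(3)).item() == pytest.approx(0.0)

    def test_ce_hand_value(self):
        # true class 1, p = 0.5, omega = 2 -> -2 ln 0.5 = 1.3863
        p = Tensor(np.array([0.5, 0.5]))
        got = weighted_ce(p, 0, np.array([2.0, 1.0])).item()
        assert got == pytest.approx(-2 * math.log(0.5), abs=1e-12)
        assert got == pytest.approx(1.3863, abs=1e-4)

    def test_unit_weights_reduce_to_standard_ce(self, rng):
        probs = rng.dirichlet(np.ones(5))
        for y in range(5):
            got = weighted_ce(Tensor(probs), y, np.ones(5)).item()
            assert got == pytest.approx(-math.log(probs[y]), abs=1e-9)

    def test_zero_probability_clamped_with_warning(self):
        p = Tensor(np.array([0.0, 1.0]))
        with pytest.warns(UserWarning):
            val = weighted_ce(p, 0, np.ones(2)).item()
        assert np.isfinite(val)


class TestGIoU:
    def test_identical_boxes(self):
        box = np.array([1.0, 1.0, 3.0, 4.0])
        assert giou_xyxy(box, box) == pytest.approx(1.0)

    def test_hand_geometry_corner_boxes(self):
        # (0,0,2,2)/(1,1,3,3): IoU=1/7, hull=9, union=7, GIoU=1/7-2/9
        a, b = np.array([0.0, 0, 2, 2]), np.array([1.0, 1, 3, 3])
        assert iou_xyxy(a, b) == pytest.approx(1 / 7)
        assert giou_xyxy(a, b) == pytest.approx(1 / 7 - 2 / 9, abs=1e-12)
        assert giou_xyxy(a, b) == pytest.approx(-0.0794, abs=1e-4)

    def test_separation_limit_approaches_minus_one(self):
        a = np.array([0.0, 0, 1, 1])
        vals = [giou_xyxy(a, np.array([d, 0.0, d + 1, 1.0]))
                for d in (10, 100, 1000)]
        assert vals[0] > vals[1] > vals[2] > -1.0
        assert vals[2] == pytest.approx(-1.0, abs=2e-3)

    @pytest.mark.parametrize("seed", range(25))
    def test_rasterization_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        def rand_box():
            x0, y0 = rng.uniform(0, 0.6, 2)
            w, h = rng.uniform(0.1, 0.4, 2)
            return [x0, y0, x0 + w, y0 + h]
        a, b = rand_box(), rand_box()
        exact = giou_xyxy(np.array(a), np.array(b))
        approx = rasterized_giou(a, b, resolution=400)
        assert exact == pytest.approx(approx, abs=2 / 400 * 10)

    def test_tensor_giou_matches_numpy_and_differentiates(self, rng):
        from pestfusion.boxes import xyxy_to_cxcywh, cxcywh_to_xyxy
        pred = rng.uniform(0.3, 0.7, (3, 4))
        gt = rng.uniform(0.2, 0.8, (3, 4))
        pred[:, 2:] = np.maximum(pred[:, 2:], 0.1)
        gt[:, 2:] = np.maximum(gt[:, 2:], 0.1)
        gt_xyxy = cxcywh_to_xyxy(gt)
        t = giou_tensor(Tensor(pred), gt_xyxy).numpy()
        ref = giou_xyxy(cxcywh_to_xyxy(pred), gt_xyxy)
        np.testing.assert_allclose(t, ref, atol=1e-12)
        assert_gradcheck(lambda p: giou_tensor(p, gt_xyxy).sum(), pred, tol=1e-5)


class TestContrastive:
    def test_orthogonal_clusters_beat_shuffled_labels(self):
        emb = np.zeros((4, 8))
        emb[:2, 0] = 1.0
        emb[2:, 1] = 1.0
        good = contrastive_loss(Tensor(emb),
                                ["pest", "pest", "predator", "predator"]).item()
        bad = contrastive_loss(Tensor(emb),
                               ["pest", "predator", "pest", "predator"]).item()
        assert good < bad

    def test_rotation_invariance(self, rng):
        emb = rng.normal(size=(5, 4))
        groups = ["pest", "pest", "predator", "pest", "predator"]
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        a = contrastive_loss(Tensor(emb), groups).item()
        b = contrastive_loss(Tensor(emb @ q.T), groups).item()
        assert a == pytest.approx(b, abs=1e-9)

    def test_identical_same_group_embeddings_at_minimum(self):
        emb = np.tile(np.array([1.0, 0, 0, 0]), (3, 1))
        val = contrastive_loss(Tensor(emb), ["pest"] * 3).item()
        # every positive has maximal similarity: -log(1/(m-1) normalizer limit)
        rng = np.random.default_rng(0)
        for _ in range(10):
            other = rng.normal(size=(3, 4))
            assert val <= contrastive_loss(Tensor(other), ["pest"] * 3).item() + 1e-9

    def test_single_embedding_contributes_zero(self):
        assert contrastive_loss(Tensor(np.ones((1, 4))), ["pest"]).item() == 0.0


class TestTotalLoss:
    def _random_pred(self, cfg, seed, branch):
        rng = np.random.default_rng(seed)
        logits = Tensor(rng.normal(size=(cfg.n_queries, cfg.n_classes + 1)),
                        requires_grad=True)
        boxes = Tensor(rng.normal(size=(cfg.n_queries, 4)), requires_grad=True)
        emb = Tensor(rng.normal(size=(cfg.n_queries, cfg.d_model)),
                     requires_grad=True)
        return DetectionOutput(boxes=boxes.sigmoid(),
                               class_probs=logits.softmax(axis=-1),
                               embeddings=emb, branch=branch)

    def _gts(self):
        return {"pest": (np.array([[0.3, 0.3, 0.2, 0.25], [0.6, 0.6, 0.22, 0.2]]),
                         np.array([1, 4])),
                "predator": (np.array([[0.5, 0.4, 0.3, 0.3]]), np.array([7]))}

    def test_breakdown_identity(self, tiny_cfg):
        preds = {"pest": self._random_pred(tiny_cfg, 1, "pest"),
                 "predator": self._random_pred(tiny_cfg, 2, "predator")}
        omega = np.append(np.ones(8), 0.1)
        bd = total_loss(preds, self._gts(), tiny_cfg, omega)
        lhs = bd.l_total.item()
        rhs = (tiny_cfg.lambda_cls * bd.l_cls.item()
               + tiny_cfg.lambda_bbox * bd.l_bbox.item()
               + tiny_cfg.lambda_giou * bd.l_giou.item()
               + tiny_cfg.mu_contrastive * bd.l_contrastive.item())
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_gt_permutation_invariance(self, tiny_cfg):
        preds = {"pest": self._random_pred(tiny_cfg, 3, "pest"),
                 "predator": self._random_pred(tiny_cfg, 4, "predator")}
        omega = np.append(np.ones(8), 0.1)
        gts = self._gts()
        flipped = {"pest": (gts["pest"][0][::-1].copy(), gts["pest"][1][::-1].copy()),
                   "predator": gts["predator"]}
        a = total_loss(preds, gts, tiny_cfg, omega).l_total.item()
        b = total_loss(preds, flipped, tiny_cfg, omega).l_total.item()
        assert a == pytest.approx(b, abs=1e-9)

    def test_doubling_lambda_bbox_doubles_contribution(self, tiny_cfg):
        import dataclasses
        preds = {"pest": self._random_pred(tiny_cfg, 5, "pest"),
                 "predator": self._random_pred(tiny_cfg, 6, "predator")}
        omega = np.append(np.ones(8), 0.1)
        bd1 = total_loss(preds, self._gts(), tiny_cfg, omega)
        cfg2 = dataclasses.replace(tiny_cfg, lambda_bbox=2 * tiny_cfg.lambda_bbox)
        bd2 = total_loss(preds, self._gts(), cfg2, omega)
        delta = bd2.l_total.item() - bd1.l_total.item()
        # matching may shift; if it does not, the delta is exactly lambda*l_bbox
        assert delta <= tiny_cfg.lambda_bbox * bd1.l_bbox.item() + 1e-9

    def test_perfect_prediction_minimizes_box_terms(self, tiny_cfg):
        gt_boxes = np.array([[0.3, 0.3, 0.2, 0.25]])
        gt_labels = np.array([2])
        nq = tiny_cfg.n_queries
        probs = np.full((nq, tiny_cfg.n_classes + 1), 1e-12)
        probs[:, tiny_cfg.n_classes] = 1.0       # all queries no-object...
        probs[0, tiny_cfg.n_classes] = 1e-12
        probs[0, 2] = 1.0                        # ...except a perfect one
        probs /= probs.sum(axis=1, keepdims=True)
        boxes = np.tile(np.array([0.1, 0.1, 0.05, 0.05]), (nq, 1))
        boxes[0] = gt_boxes[0]
        pred = DetectionOutput(boxes=Tensor(boxes), class_probs=Tensor(probs),
                               embeddings=Tensor(np.zeros((nq, 4))),
                               branch="pest")
        omega = np.append(np.ones(8), 0.1)
        bd = total_loss({"pest": pred}, {"pest": (gt_boxes, gt_labels)},
                        tiny_cfg, omega)
        assert bd.l_bbox.item() == pytest.approx(0.0, abs=1e-9)
        assert bd.l_giou.item() == pytest.approx(0.0, abs=1e-9)
        assert bd.l_cls.item() == pytest.approx(0.0, abs=1e-6)

    def test_branch_decoupling_gradient_isolation(self, tiny_cfg):
        """The pest loss must not touch predator MLP parameters."""
        head = DetectionHead(tiny_cfg, tiny_cfg.gate_channels,
                             np.random.default_rng(7))
        fused = Tensor(np.random.default_rng(8).normal(
            size=(1, tiny_cfg.gate_channels, tiny_cfg.gate_hw, tiny_cfg.gate_hw)))
        out = head(fused)
        omega = np.append(np.ones(8), 0.1)
        gts = {"pest": (np.array([[0.4, 0.4, 0.3, 0.3]]), np.array([0]))}
        bd = total_loss({"pest": out["pest"][0]}, gts, tiny_cfg, omega)
        head.zero_grad()
        bd.l_total.backward()
        for name, p in head.mlps_predator.named_parameters():
            assert p.grad is None or np.all(p.grad == 0), name
        for name, p in head.decoder_predator.named_parameters():
            assert p.grad is None or np.all(p.grad == 0), name
        assert any(p.grad is not None and np.abs(p.grad).sum() > 0
                   for p in head.mlps_pest.parameters())
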