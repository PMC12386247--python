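"""Decoupled dual-target set-prediction head.

A DETR-style head with two independent branches: pest queries and
predator queries are decoded separately against a shared encoder
memory, each with its own box/class MLPs, so gradients from one task
never touch the other's prediction parameters.  Matching between
queries and ground truth is a Hungarian assignment per branch; the
training loss is

    L = lambda_cls * L_cls + lambda_bbox * L_bbox + lambda_giou * L_giou
        + mu * L_contrastive,

where ``L_cls`` is inverse-frequency-weighted cross entropy over all
queries (matched ones supervised with their target class, the rest with
a down-weighted no-object class), ``L_bbox`` the L1 distance and
``L_giou`` the generalized-IoU loss over matched pairs, and
``L_contrastive`` a supervised-contrastive pull/push between pest and
predator embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .autodiff import Tensor, concat, stack
from .boxes import cxcywh_to_xyxy, giou_tensor, giou_xyxy
from .config import ModelConfig
from .nn import (Conv2d, LayerNorm, Linear, Module, MultiHeadAttention,
                 Parameter, sinusoidal_positions_2d)

__all__ = [
    "DetectionOutput", "MatchAssignment", "LossBreakdown", "TransformerEncoder",
    "TransformerDecoder", "PredictionMLPs", "DetectionHead", "match_cost",
    "hungarian_assign", "weighted_ce", "class_weights", "contrastive_loss",
    "giou_loss_value",
]

BRANCHES = ("pest", "predator")


@dataclass
class DetectionOutput:
    """Per-branch set prediction: normalized cxcywh boxes + class simplex rows."""

    boxes: Tensor        # (N_q, 4) in [0,1] (sigmoid)
    class_probs: Tensor  # (N_q, C+1), rows sum to 1 (softmax); last = no-object
    embeddings: Tensor   # (N_q, d_model) decoder outputs
    branch: str

    def __post_init__(self):
        if self.branch not in BRANCHES + ("joint",):
            raise ValueError(f"unknown branch tag {self.branch!r}")


@dataclass
class MatchAssignment:
    """Injective query<->target pairing; unmatched queries are no-object."""

    pairs: list[tuple[int, int]]
    n_queries: int

    def __post_init__(self):
        qs = [q for q, _ in self.pairs]
        ts = [t for _, t in self.pairs]
        if len(set(qs)) != len(qs) or len(set(ts)) != len(ts):
            raise ValueError("assignment must be injective on both sides")

    @property
    def unmatched_queries(self) -> list[int]:
        matched = {q for q, _ in self.pairs}
        return [q for q in range(self.n_queries) if q not in matched]


@dataclass
class LossBreakdown:
    l_cls: Tensor
    l_bbox: Tensor
    l_giou: Tensor
    l_contrastive: Tensor
    l_total: Tensor
    weights: dict = field(default_factory=dict)

    def scalars(self) -> dict[str, float]:
        return {k: float(getattr(self, k).item()) for k in
                ("l_cls", "l_bbox", "l_giou", "l_contrastive", "l_total")}


class FeedForward(Module):
    def __init__(self, d_model: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d_model, hidden, rng)
        self.fc2 = Linear(hidden, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class EncoderLayer(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ffn = FeedForward(cfg.d_model, cfg.ffn_dim, rng)
        self.norm1 = LayerNorm(cfg.d_model)
        self.norm2 = LayerNorm(cfg.d_model)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x, x, x))
        return self.norm2(x + self.ffn(x))


class DecoderLayer(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.self_attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.cross_attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ffn = FeedForward(cfg.d_model, cfg.ffn_dim, rng)
        self.norm1 = LayerNorm(cfg.d_model)
        self.norm2 = LayerNorm(cfg.d_model)
        self.norm3 = LayerNorm(cfg.d_model)

    def forward(self, queries: Tensor, memory: Tensor) -> Tensor:
        q = self.norm1(queries + self.self_attn(queries, queries, queries))
        q = self.norm2(q + self.cross_attn(q, memory, memory))
        return self.norm3(q + self.ffn(q))


class TransformerEncoder(Module):
    """Project the fused map to d_model tokens (+2-D sinusoidal PE), N layers."""

    def __init__(self, cfg: ModelConfig, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.input_proj = Conv2d(in_channels, cfg.d_model, 1, rng)
        # unit-scale tokens before the PE is added, so image content and
        # position information start at comparable magnitude
        self.input_norm = LayerNorm(cfg.d_model)
        self.layers = [EncoderLayer(cfg, rng) for _ in range(cfg.enc_layers)]

    def forward(self, fused: Tensor) -> Tensor:
        if fused.ndim == 3:
            fused = fused.reshape(1, *fused.shape)
        x = self.input_proj(fused)
        n, d, h, w = x.shape
        tokens = self.input_norm(x.reshape(n, d, h * w).transpose(0, 2, 1))
        tokens = tokens + Tensor(sinusoidal_positions_2d(h, w, d))
        for layer in self.layers:
            tokens = layer(tokens)
        return tokens


class TransformerDecoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.layers = [DecoderLayer(cfg, rng) for _ in range(cfg.dec_layers)]

    def forward(self, memory: Tensor, queries: Tensor,
                return_intermediate: bool = False):
        q = queries
        if q.ndim == 2 and memory.ndim == 3:
            q = stack([queries] * memory.shape[0], axis=0)
        intermediate = []
        for layer in self.layers:
            q = layer(q, memory)
            if return_intermediate:
                intermediate.append(q)
        return (q, intermediate) if return_intermediate else q


class PredictionMLPs(Module):
    """Three-layer MLPs: boxes d->d->4 (sigmoid), classes d->d->C+1 (softmax)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.d_model
        self.box1 = Linear(d, d, rng)
        self.box2 = Linear(d, 4, rng)
        self.cls1 = Linear(d, d, rng)
        self.cls2 = Linear(d, cfg.n_classes + 1, rng)

    def forward(self, embeddings: Tensor, branch: str) -> DetectionOutput:
        boxes = self.box2(self.box1(embeddings).relu()).sigmoid()
        logits = self.cls2(self.cls1(embeddings).relu())
        return DetectionOutput(boxes=boxes, class_probs=logits.softmax(axis=-1),
                               embeddings=embeddings, branch=branch)


class DetectionHead(Module):
    """Encoder + per-branch decoders/queries/MLPs (shared memory)."""

    def __init__(self, cfg: ModelConfig, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.encoder = TransformerEncoder(cfg, in_channels, rng)
        self.branches = BRANCHES if cfg.decoupled_head else ("joint",)
        scale = 1.0 / np.sqrt(cfg.d_model)
        for branch in self.branches:
            setattr(self, f"queries_{branch}",
                    Parameter(rng.normal(0, scale, (cfg.n_queries, cfg.d_model))))
            setattr(self, f"decoder_{branch}", TransformerDecoder(cfg, rng))
            setattr(self, f"mlps_{branch}", PredictionMLPs(cfg, rng))

    def forward(self, fused: Tensor, with_aux: bool = False):
        """fused: (N, C, H, W) -> per-branch list of per-image outputs.

        ``with_aux`` additionally returns deep-supervision predictions
        from every decoder layer (shared prediction MLPs, per DETR).
        """
        memory = self.encoder(fused)
        batch = memory.shape[0]
        out: dict[str, list[DetectionOutput]] = {}
        aux: dict[str, list[list[DetectionOutput]]] = {}
        for branch in self.branches:
            queries = getattr(self, f"queries_{branch}")
            decoder = getattr(self, f"decoder_{branch}")
            mlps = getattr(self, f"mlps_{branch}")
            decoded, intermediate = decoder(memory, queries,
                                            return_intermediate=True)
            out[branch] = [mlps(decoded[i], branch) for i in range(batch)]
            if with_aux:
                aux[branch] = [[mlps(layer_q[i], branch) for i in range(batch)]
                               for layer_q in intermediate[:-1]]
        return (out, aux) if with_aux else out


# ----------------------------------------------------------------- matching

def match_cost(pred: DetectionOutput, gt_boxes: np.ndarray, gt_labels: np.ndarray,
               cfg: ModelConfig) -> np.ndarray:
    """DETR-convention cost matrix (N_q x n_gt).

    cost[q,t] = l_cls*(1 - p_q(label_t)) + l_bbox*||b_q - b_t||_1
                + l_giou*(1 - GIoU(b_q, b_t)); boxes normalized cxcywh.
    """
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    gt_labels = np.asarray(gt_labels, dtype=int)
    nq = pred.boxes.shape[0]
    if len(gt_labels) == 0:
        return np.zeros((nq, 0))
    p = pred.class_probs.data[:, gt_labels]                       # (N_q, n_gt)
    l1 = np.abs(pred.boxes.data[:, None, :] - gt_boxes[None]).sum(-1)
    giou = giou_xyxy(cxcywh_to_xyxy(pred.boxes.data)[:, None, :],
                     cxcywh_to_xyxy(gt_boxes)[None])
    return (cfg.lambda_cls * (1.0 - p) + cfg.lambda_bbox * l1
            + cfg.lambda_giou * (1.0 - giou))


def hungarian_assign(cost: np.ndarray) -> MatchAssignment:
    """Minimum-total-cost one-to-one assignment (Hungarian algorithm)."""
    cost = np.asarray(cost, dtype=float)
    if not np.isfinite(cost).all():
        raise ValueError("cost matrix must be finite")
    rows, cols = linear_sum_assignment(cost)
    pairs = sorted(zip(rows.tolist(), cols.tolist()))
    return MatchAssignment(pairs=pairs, n_queries=cost.shape[0])


# ------------------------------------------------------------------- losses

def class_weights(counts: np.ndarray, cap_factor: float = 10.0) -> np.ndarray:
    """Inverse-frequency weights omega_i = N_total / (C * n_i), capped.

    Zero-count classes receive the cap (10x the median finite weight).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("all class counts are zero")
    c = len(counts)
    with np.errstate(divide="ignore"):
        raw = counts.sum() / (c * counts)
    finite = raw[np.isfinite(raw)]
    cap = cap_factor * float(np.median(finite))
    return np.minimum(raw, cap)


def weighted_ce(probs: Tensor, label: int, weights: np.ndarray) -> Tensor:
    """-omega_y * log(p_y) for one probability row, natural log."""
    p = float(probs.data[label])
    if p <= 0:
        warnings.warn("clamping zero predicted probability in cross entropy")
    return Tensor(-weights[label]) * probs[label].clip_min(1e-12).log()


def contrastive_loss(embeddings: Tensor, groups: list[str],
                     temperature: float = 0.1) -> Tensor:
    """Supervised-contrastive pull/push on L2-normalized embeddings.

    Same-group pairs are positives.  Anchors without positives are
    skipped; with fewer than 2 embeddings the loss is 0.
    """
    m = embeddings.shape[0]
    if m < 2:
        return Tensor(0.0)
    norm = (embeddings ** 2).sum(axis=1, keepdims=True).sqrt().clip_min(1e-12)
    z = embeddings / norm
    sim = (z @ z.transpose(1, 0)) * (1.0 / temperature)
    groups_arr = np.asarray(groups)
    eye = np.eye(m, dtype=bool)
    pos_mask = (groups_arr[:, None] == groups_arr[None, :]) & ~eye
    # log-sum-exp over non-self similarities per anchor
    offdiag = Tensor(np.where(eye, -np.inf, 0.0))
    logits = sim + offdiag
    lse = (logits - Tensor(logits.data.max(axis=1, keepdims=True))).exp() \
        .sum(axis=1, keepdims=True).log() + Tensor(logits.data.max(axis=1, keepdims=True))
    log_prob = sim - lse           # (m, m): log p(j | anchor i)
    terms = []
    for i in range(m):
        pos = np.where(pos_mask[i])[0]
        if len(pos) == 0:
            continue
        terms.append(log_prob[i, list(pos)].mean() * -1.0)
    if not terms:
        return Tensor(0.0)
    return stack(terms).mean()


def giou_loss_value(pred_boxes: Tensor, gt_boxes: np.ndarray) -> Tensor:
    """Mean (1 - GIoU) over matched pairs; pred cxcywh, gt cxcywh (fixed)."""
    gt_xyxy = cxcywh_to_xyxy(np.asarray(gt_boxes, dtype=float))
    return (1.0 - giou_tensor(pred_boxes, gt_xyxy)).mean()


def total_loss(preds: dict[str, DetectionOutput],
               gts: dict[str, tuple[np.ndarray, np.ndarray]],
               cfg: ModelConfig, omega: np.ndarray) -> LossBreakdown:
    """Composite set-prediction loss for one image.

    ``preds``: branch -> DetectionOutput; ``gts``: branch -> (boxes
    cxcywh normalized, labels).  ``omega`` is the length-(C+1) class
    weight vector (no-object last).  Classification averages over all
    queries of all branches; box terms over matched pairs only.
    """
    no_obj = cfg.n_classes
    ce_sum, n_queries_total = None, 0
    bbox_terms, giou_terms = [], []
    matched_embeddings, matched_groups = [], []
    for branch, pred in preds.items():
        gt_boxes, gt_labels = gts.get(branch, (np.zeros((0, 4)), np.zeros(0, int)))
        gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
        gt_labels = np.asarray(gt_labels, dtype=int)
        cost = match_cost(pred, gt_boxes, gt_labels, cfg)
        assign = hungarian_assign(cost) if cost.size else \
            MatchAssignment([], pred.boxes.shape[0])
        nq = pred.boxes.shape[0]
        target_class = np.full(nq, no_obj, dtype=int)
        for q, t in assign.pairs:
            target_class[q] = gt_labels[t]
        # -omega_y log p_y for every query, vectorized (== weighted_ce per row)
        p_rows = pred.class_probs[np.arange(nq), target_class]
        ce = (Tensor(omega[target_class])
              * p_rows.clip_min(1e-12).log()).sum() * -1.0
        ce_sum = ce if ce_sum is None else ce_sum + ce
        n_queries_total += nq
        if assign.pairs:
            qs = [q for q, _ in assign.pairs]
            ts = [t for _, t in assign.pairs]
            pb = pred.boxes[qs]
            gb = gt_boxes[ts]
            bbox_terms.append((pb - Tensor(gb)).abs().sum(axis=1))
            giou_terms.append(1.0 - giou_tensor(pb, cxcywh_to_xyxy(gb)))
            matched_embeddings.append(pred.embeddings[qs])
            matched_groups.extend(
                ["pest" if gl < 6 else "predator" for gl in gt_labels[ts]])
    l_cls = ce_sum * (1.0 / n_queries_total)
    if bbox_terms:
        n_matched = sum(t.shape[0] for t in bbox_terms)
        l_bbox = concat(bbox_terms).sum() * (1.0 / n_matched)
        l_giou = concat(giou_terms).sum() * (1.0 / n_matched)
    else:
        l_bbox = Tensor(0.0)
        l_giou = Tensor(0.0)
    if matched_embeddings and sum(t.shape[0] for t in matched_embeddings) >= 2:
        l_con = contrastive_loss(concat(matched_embeddings, axis=0),
                                 matched_groups, cfg.tau_contrastive)
    else:
        l_con = Tensor(0.0)
    l_total = (cfg.lambda_cls * l_cls + cfg.lambda_bbox * l_bbox
               + cfg.lambda_giou * l_giou + cfg.mu_contrastive * l_con)
    return LossBreakdown(
        l_cls=l_cls, l_bbox=l_bbox, l_giou=l_giou, l_contrastive=l_con,
        l_total=l_total,
        weights={"lambda_cls": cfg.lambda_cls, "lambda_bbox": cfg.lambda_bbox,
                 "lambda_giou": cfg.lambda_giou, "mu": cfg.mu_contrastive})
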