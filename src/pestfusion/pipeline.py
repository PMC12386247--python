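"""Dataset loading, training, evaluation and inference orchestration.

Everything here is deterministic given (config, seed): one
``numpy.random.Generator`` derived from the run seed drives weight
initialization, batch sampling and augmentation.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import no_grad
from .boxes import cxcywh_to_xyxy, xyxy_to_cxcywh
from .config import RunConfig
from .head import total_loss
from .metrics import (DetectionRecord, GroundTruthRecord, MetricsReport,
                      evaluate_detections)
from .model import PestPredatorDetector, load_checkpoint, save_checkpoint
from .nn import AdamW, clip_grad_norm
from .preprocess import (NormalizationStats, assemble_sample,
                         perturb_brightness, sample_occlusion_region,
                         apply_occlusion, stats_from_series)
from .head import class_weights as compute_class_weights
from .synthetic import (DatasetManifest, EnvSeries, SceneSpec, generate_dataset,
                        load_coco_annotations, load_image)

__all__ = ["Sample", "load_samples", "env_history", "train", "evaluate",
           "infer", "RunLog"]


@dataclass
class Sample:
    rgb: np.ndarray
    thermal: np.ndarray
    env: EnvSeries
    boxes: np.ndarray        # (n, 4) xyxy pixels
    labels: np.ndarray       # (n,)
    timestamp: float
    image_id: int
    image_size: int
    time_of_day: str
    weather: str


def load_samples(manifest: DatasetManifest) -> list[Sample]:
    root = Path(manifest.root)
    anns = load_coco_annotations(root / manifest.annotations_path)
    samples = []
    for i, (rgb_p, th_p, env_p) in enumerate(zip(
            manifest.rgb_paths, manifest.thermal_paths, manifest.env_paths)):
        record = anns[i + 1]
        cond = manifest.conditions[i] if manifest.conditions else \
            {"time_of_day": "noon", "weather": "sunny"}
        samples.append(Sample(
            rgb=load_image(root / rgb_p), thermal=load_image(root / th_p),
            env=EnvSeries.from_csv(root / env_p),
            boxes=np.asarray(record["boxes"], dtype=float).reshape(-1, 4),
            labels=np.asarray(record["labels"], dtype=int),
            timestamp=float(manifest.timestamps[i]), image_id=i + 1,
            image_size=record["width"],
            time_of_day=cond["time_of_day"], weather=cond["weather"]))
    return samples


def env_history(series: EnvSeries, t_frame: float, stats: NormalizationStats,
                length: int) -> np.ndarray:
    """Last ``length`` 1 Hz env vectors before the frame, normalized (T,3)."""
    times = np.arange(length - 1, -1, -1, dtype=float)
    rows = []
    for dt in times:
        t = max(t_frame - dt, float(series.timestamps[0]))
        sample = assemble_sample(np.empty((3, 1, 1)), np.empty((1, 1, 1)),
                                 series, t, stats)
        rows.append(sample.env)
    return np.asarray(rows)


def _branch_targets(sample: Sample, decoupled: bool
                    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    size = sample.image_size
    norm_boxes = xyxy_to_cxcywh(sample.boxes / size) if len(sample.boxes) else \
        np.zeros((0, 4))
    if not decoupled:
        return {"joint": (norm_boxes, sample.labels)}
    out = {}
    for branch, mask in (("pest", sample.labels < 6), ("predator", sample.labels >= 6)):
        out[branch] = (norm_boxes[mask] if len(sample.boxes) else norm_boxes,
                       sample.labels[mask])
    return out


@dataclass
class RunLog:
    path: Path

    def append(self, record: dict) -> None:
        with open(self.path, "a") as fh:
            fh.write(json.dumps(record) + "\n")


def _augment(rgb: np.ndarray, thermal: np.ndarray, cfg, rng: np.random.Generator):
    sigma = cfg.sigma_brightness
    seed = int(rng.integers(0, 2 ** 31))
    rgb = perturb_brightness(rgb, sigma, seed)
    if rng.uniform() < cfg.p_occlusion:
        region = sample_occlusion_region(rgb.shape[-2:], rng)
        rgb = apply_occlusion(rgb, region)
        thermal = apply_occlusion(thermal, region)
    return rgb, thermal


def train(run_config: RunConfig, manifest: DatasetManifest, out_dir: str | Path,
          log_every: int = 25) -> tuple[Path, list[dict]]:
    """Train a detector on the manifest; returns (checkpoint path, log records)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = run_config.model
    samples = load_samples(manifest)
    stats = stats_from_series([s.env for s in samples])

    counts = np.bincount(np.concatenate([s.labels for s in samples] or
                                        [np.zeros(0, int)]),
                         minlength=cfg.n_classes)[:cfg.n_classes]
    omega = np.append(compute_class_weights(np.maximum(counts, 0)),
                      cfg.no_object_weight)

    model = PestPredatorDetector(cfg, seed=run_config.seed)
    params = [p for p in model.parameters() if p.requires_grad]
    opt = AdamW(params, lr=run_config.train.lr,
                weight_decay=run_config.train.weight_decay)
    rng = np.random.default_rng(run_config.seed)
    log = RunLog(out / "train_log.jsonl")
    records = []
    histories = [env_history(s.env, s.timestamp, stats, cfg.ema_history)
                 for s in samples]
    def lr_at(step: int) -> float:
        tc = run_config.train
        if tc.warmup_steps > 0 and step < tc.warmup_steps:
            return tc.lr * (step + 1) / tc.warmup_steps
        span = max(run_config.train.steps - tc.warmup_steps, 1)
        progress = (step - tc.warmup_steps) / span
        floor = tc.min_lr_frac * tc.lr
        return floor + (tc.lr - floor) * 0.5 * (1 + np.cos(np.pi * progress))

    t0 = time.time()
    for step in range(run_config.train.steps):
        opt.lr = lr_at(step)
        idx = rng.choice(len(samples), size=min(run_config.train.batch_size,
                                                len(samples)), replace=False)
        rgbs, thermals, hists, gts = [], [], [], []
        for i in idx:
            s = samples[i]
            rgb, thermal = (s.rgb, s.thermal)
            if run_config.train.augment:
                rgb, thermal = _augment(rgb, thermal, run_config.train, rng)
            rgbs.append(rgb)
            thermals.append(thermal)
            hists.append(histories[i])
            gts.append(_branch_targets(s, cfg.decoupled_head))
        if cfg.aux_loss:
            outputs, aux = model(np.stack(rgbs), np.stack(thermals),
                                 np.stack(hists), with_aux=True)
        else:
            outputs = model(np.stack(rgbs), np.stack(thermals), np.stack(hists))
            aux = {}
        losses = []
        breakdowns = []
        for b, gt in enumerate(gts):
            preds = {branch: outs[b] for branch, outs in outputs.items()}
            breakdown = total_loss(preds, gt, cfg, omega)
            image_loss = breakdown.l_total
            if cfg.aux_loss:
                n_aux = len(next(iter(aux.values()), []))
                for layer in range(n_aux):
                    aux_preds = {branch: layers[layer][b]
                                 for branch, layers in aux.items()}
                    image_loss = image_loss + total_loss(
                        aux_preds, gt, cfg, omega).l_total
            losses.append(image_loss)
            breakdowns.append(breakdown)
        batch_loss = losses[0]
        for l in losses[1:]:
            batch_loss = batch_loss + l
        batch_loss = batch_loss * (1.0 / len(losses))
        model.zero_grad()
        batch_loss.backward()
        clip_grad_norm(params, run_config.train.grad_clip)
        opt.step()
        if step % log_every == 0 or step == run_config.train.steps - 1:
            mean = {k: float(np.mean([bd.scalars()[k] for bd in breakdowns]))
                    for k in ("l_cls", "l_bbox", "l_giou", "l_contrastive")}
            # l_total is the final-layer composite loss (aux terms excluded)
            final_total = float(np.mean([bd.l_total.item() for bd in breakdowns]))
            record = {"step": step, "l_total": final_total,
                      "l_optimized": float(batch_loss.item()),
                      **mean, "elapsed_s": round(time.time() - t0, 2),
                      "seed": run_config.seed,
                      "config_hash": run_config.config_hash()}
            log.append(record)
            records.append(record)
    ckpt = out / "checkpoint.npz"
    save_checkpoint(ckpt, model, run_config,
                    extra={"norm_stats": stats.to_dict(),
                           "class_weights": omega.tolist()})
    return ckpt, records


def _outputs_to_records(outputs, sample: Sample, cfg,
                        score_threshold: float = 0.0) -> list[DetectionRecord]:
    records = []
    size = sample.image_size
    for branch, outs in outputs.items():
        det = outs if not isinstance(outs, list) else outs[0]
        probs = det.class_probs.data[:, :cfg.n_classes]
        labels = probs.argmax(axis=1)
        scores = probs[np.arange(len(labels)), labels]
        boxes = cxcywh_to_xyxy(det.boxes.data) * size
        for q in range(len(labels)):
            if scores[q] < score_threshold:
                continue
            x0, y0, x1, y1 = boxes[q]
            if x1 <= x0 or y1 <= y0:
                continue
            records.append(DetectionRecord(
                image_id=sample.image_id, label=int(labels[q]),
                score=float(scores[q]),
                box=(float(x0), float(y0), float(x1), float(y1))))
    return records


def evaluate(checkpoint: str | Path, manifest: DatasetManifest,
             group_map: dict[int, int] | None = None,
             score_threshold: float = 0.5, iou_threshold: float = 0.5,
             by_condition: bool = True
             ) -> tuple[MetricsReport, dict[str, MetricsReport]]:
    """Evaluate a checkpoint; returns (overall report, per-condition reports)."""
    model, run_config, meta = load_checkpoint(checkpoint)
    cfg = run_config.model
    stats = NormalizationStats.from_dict(meta["norm_stats"])
    samples = load_samples(manifest)
    all_dets: list[DetectionRecord] = []
    all_gts: list[GroundTruthRecord] = []
    condition_sets: dict[str, list[int]] = {}
    for s in samples:
        hist = env_history(s.env, s.timestamp, stats, cfg.ema_history)[None]
        with no_grad():
            outputs = model(s.rgb[None], s.thermal[None], hist)
        all_dets.extend(_outputs_to_records(outputs, s, cfg, score_threshold))
        for box, label in zip(s.boxes, s.labels):
            all_gts.append(GroundTruthRecord(s.image_id, int(label),
                                             tuple(float(v) for v in box)))
        for key in (s.time_of_day, s.weather):
            condition_sets.setdefault(key, []).append(s.image_id)
    overall = evaluate_detections(all_dets, all_gts, iou_threshold, group_map)
    per_condition: dict[str, MetricsReport] = {}
    if by_condition:
        for key, ids in sorted(condition_sets.items()):
            idset = set(ids)
            dets = [d for d in all_dets if d.image_id in idset]
            gts = [g for g in all_gts if g.image_id in idset]
            if gts:
                per_condition[key] = evaluate_detections(
                    dets, gts, iou_threshold, group_map)
    return overall, per_condition


def infer(checkpoint: str | Path, rgb_path: str | Path, thermal_path: str | Path,
          env_csv: str | Path, t_frame: float, out_json: str | Path,
          score_threshold: float = 0.5, overlay_path: str | Path | None = None
          ) -> list[dict]:
    """Run one frame through a checkpoint; writes COCO-results JSON."""
    model, run_config, meta = load_checkpoint(checkpoint)
    cfg = run_config.model
    stats = NormalizationStats.from_dict(meta["norm_stats"])
    rgb = load_image(rgb_path)
    thermal = load_image(thermal_path) if thermal_path else None
    series = EnvSeries.from_csv(env_csv)
    hist = env_history(series, t_frame, stats, cfg.ema_history)[None]
    sample = Sample(rgb=rgb, thermal=thermal if thermal is not None else
                    np.zeros((1, *rgb.shape[1:])), env=series,
                    boxes=np.zeros((0, 4)), labels=np.zeros(0, int),
                    timestamp=t_frame, image_id=1, image_size=rgb.shape[-1],
                    time_of_day="noon", weather="sunny")
    with no_grad():
        outputs = model(rgb[None], None if thermal is None else thermal[None], hist)
    records = _outputs_to_records(outputs, sample, cfg, score_threshold)
    results = [{"image_id": r.image_id, "category_id": r.label + 1,
                "bbox": [r.box[0], r.box[1], r.box[2] - r.box[0],
                         r.box[3] - r.box[1]],
                "score": r.score} for r in records]
    Path(out_json).write_text(json.dumps(results, indent=1))
    if overlay_path is not None:
        _draw_overlay(rgb, records, overlay_path)
    return results


def _draw_overlay(rgb: np.ndarray, records: list[DetectionRecord],
                  path: str | Path) -> None:
    from PIL import Image, ImageDraw
    from .synthetic import CLASS_NAMES
    img = Image.fromarray((np.clip(rgb, 0, 1).transpose(1, 2, 0) * 255)
                          .astype(np.uint8))
    draw = ImageDraw.Draw(img)
    for r in records:
        draw.rectangle(r.box, outline=(255, 255, 0), width=2)
        draw.text((r.box[0] + 2, r.box[1] + 2),
                  f"{CLASS_NAMES[r.label]} {r.score:.2f}", fill=(255, 255, 0))
    img.save(path)


def generate_from_config(run_config: RunConfig, out_dir: str | Path
                         ) -> tuple[DatasetManifest, DatasetManifest]:
    """Generate the train and val splits the run config describes."""
    d = run_config.data
    template = SceneSpec(image_size=d.image_size, n_targets=d.n_targets,
                         class_distribution=d.class_distribution,
                         seed=run_config.seed)
    out = Path(out_dir)
    train_m = generate_dataset(d.n_train, template, out / "train", split="train",
                               env_duration=d.env_duration)
    val_template = SceneSpec(image_size=d.image_size, n_targets=d.n_targets,
                             class_distribution=d.class_distribution,
                             seed=run_config.seed + 50000)
    val_m = generate_dataset(d.n_val, val_template, out / "val", split="val",
                             env_duration=d.env_duration)
    return train_m, val_m
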