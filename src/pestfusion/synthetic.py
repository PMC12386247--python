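"""Synthetic paired RGB/thermal field scenes with environmental streams.

Real multimodal pest-monitoring data (hardware-synchronized RGB and
thermal frames, 1 Hz temperature/humidity/light streams, box
annotations over 6 pest + 2 predator classes) is not available at desk
scale, so this module fabricates scenes with the same statistical
structure: insects are rendered as textured ellipses with
class-specific hue and shape on a foliage-like background, each at
least 20x20 px; the thermal channel shows targets as warm blobs on a
cooler background; time-of-day and weather knobs modulate brightness,
contrast and the sensor series exactly the way the detector is expected
to exploit them (evening is darker, fog kills contrast, light readings
drop).  Generation is fully deterministic given the spec's seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "TIMES_OF_DAY", "WEATHERS", "CLASS_NAMES", "PEST_CLASSES",
    "PREDATOR_CLASSES", "MIN_TARGET_PX", "SceneSpec", "AnnotatedScene",
    "EnvSeries", "DatasetManifest", "CapacityError", "class_group",
    "generate_scene", "generate_env_series", "generate_dataset",
    "load_manifest", "load_coco_annotations",
]

TIMES_OF_DAY = ("morning", "noon", "evening")
WEATHERS = ("sunny", "cloudy", "foggy")

# 6 pest classes (indices 0-5) and 2 predator classes: lady beetles and
# lacewings (indices 6-7).
CLASS_NAMES = tuple(f"pest_{i}" for i in range(6)) + ("lady_beetle", "lacewing")
PEST_CLASSES = tuple(range(6))
PREDATOR_CLASSES = (6, 7)
MIN_TARGET_PX = 20

# class appearance: hue in [0,1), aspect ratio, spot density
_CLASS_HUE = np.array([0.02, 0.10, 0.55, 0.72, 0.85, 0.30, 0.98, 0.45])
_CLASS_ASPECT = np.array([1.0, 1.6, 0.7, 1.3, 0.9, 2.0, 1.0, 1.8])
_CLASS_SPOTS = np.array([0, 2, 0, 4, 1, 0, 6, 0])

_BRIGHTNESS = {"morning": 0.8, "noon": 1.0, "evening": 0.4}
_WEATHER_BRIGHT = {"sunny": 1.0, "cloudy": 0.85, "foggy": 0.9}


class CapacityError(ValueError):
    """Too many non-overlapping >=20x20 targets requested for the canvas."""


def class_group(label: int) -> str:
    """Pest/predator super-class as a pure function of the class index."""
    if label in PEST_CLASSES:
        return "pest"
    if label in PREDATOR_CLASSES:
        return "predator"
    raise ValueError(f"unknown class index {label}")


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic scene."""

    image_size: int = 256
    n_targets: int = 3
    class_distribution: tuple[float, ...] = tuple([1.0 / 8] * 8)
    time_of_day: str = "noon"
    weather: str = "sunny"
    seed: int = 0
    max_overlap_iou: float = 0.3

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.n_targets < 0:
            raise ValueError("n_targets must be >= 0")
        dist = np.asarray(self.class_distribution, dtype=float)
        if dist.shape != (8,) or (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError("class_distribution must be 8 nonnegative "
                             "probabilities summing to 1")
        if self.time_of_day not in TIMES_OF_DAY:
            raise ValueError(f"time_of_day must be one of {TIMES_OF_DAY}")
        if self.weather not in WEATHERS:
            raise ValueError(f"weather must be one of {WEATHERS}")


@dataclass
class AnnotatedScene:
    """One synchronized RGB/thermal/annotation sample.

    ``rgb`` is 3xHxW and ``thermal`` 1xHxW, both float in [0,1]; boxes
    are (x_min, y_min, x_max, y_max) in pixels.
    """

    rgb: np.ndarray
    thermal: np.ndarray
    boxes: list[tuple[float, float, float, float]]
    labels: list[int]
    group: list[str]
    timestamp: float
    time_of_day: str = "noon"
    weather: str = "sunny"

    def validate(self) -> None:
        _, h, w = self.rgb.shape
        if self.thermal.shape != (1, h, w):
            raise ValueError("thermal/rgb shape mismatch")
        if not (len(self.boxes) == len(self.labels) == len(self.group)):
            raise ValueError("boxes/labels/group length mismatch")
        for (x0, y0, x1, y1), lab, grp in zip(self.boxes, self.labels, self.group):
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(f"box {(x0, y0, x1, y1)} out of bounds for {w}x{h}")
            if x1 - x0 < MIN_TARGET_PX or y1 - y0 < MIN_TARGET_PX:
                raise ValueError(f"box smaller than {MIN_TARGET_PX}px: {(x0, y0, x1, y1)}")
            if class_group(lab) != grp:
                raise ValueError(f"label {lab} inconsistent with group {grp}")


@dataclass
class EnvSeries:
    """1 Hz environmental sensor stream."""

    timestamps: np.ndarray      # seconds, strictly increasing
    temperature: np.ndarray     # deg C
    humidity: np.ndarray        # % RH
    light: np.ndarray           # normalized LDR reading in [0,1]

    def validate(self) -> None:
        n = len(self.timestamps)
        if not (len(self.temperature) == len(self.humidity) == len(self.light) == n):
            raise ValueError("channel length mismatch")
        if n >= 2 and not (np.diff(self.timestamps) > 0).all():
            raise ValueError("timestamps must be strictly increasing")

    def channel(self, name: str) -> np.ndarray:
        return {"temperature": self.temperature, "humidity": self.humidity,
                "light": self.light}[name]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["timestamp", "temperature", "humidity", "light"])
            for row in zip(self.timestamps, self.temperature, self.humidity, self.light):
                writer.writerow([repr(float(v)) for v in row])

    @classmethod
    def from_csv(cls, path: str | Path) -> "EnvSeries":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            expected = ["timestamp", "temperature", "humidity", "light"]
            if header != expected:
                missing = [c for c in expected if c not in header]
                raise ValueError(f"env CSV schema error: expected columns {expected}, "
                                 f"missing {missing or 'none (order differs)'}")
            rows = [[float(v) for v in row] for row in reader if row]
        arr = np.asarray(rows)
        series = cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])
        series.validate()
        return series


@dataclass
class DatasetManifest:
    """File inventory of a generated dataset split."""

    root: str
    rgb_paths: list[str]
    thermal_paths: list[str]
    env_paths: list[str]
    annotations_path: str
    timestamps: list[float]
    conditions: list[dict] = field(default_factory=list)
    split: str = "train"

    def validate(self) -> None:
        root = Path(self.root)
        for rel in (*self.rgb_paths, *self.thermal_paths, *self.env_paths,
                    self.annotations_path):
            if not (root / rel).exists():
                raise FileNotFoundError(root / rel)

    def save(self, path: str | Path) -> None:
        payload = {k: getattr(self, k) for k in
                   ("root", "rgb_paths", "thermal_paths", "env_paths",
                    "annotations_path", "timestamps", "conditions", "split")}
        Path(path).write_text(json.dumps(payload, indent=1))


def load_manifest(path: str | Path) -> DatasetManifest:
    payload = json.loads(Path(path).read_text())
    manifest = DatasetManifest(**payload)
    manifest.validate()
    return manifest


# --------------------------------------------------------------- rendering

def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    return np.array([(v, t, p), (q, v, p), (p, v, t),
                     (p, q, v), (t, p, v), (v, p, q)][i])


def _smooth_noise(rng: np.random.Generator, size: int, scale: int) -> np.ndarray:
    coarse = rng.uniform(0, 1, (scale, scale))
    reps = int(np.ceil(size / scale))
    fine = np.kron(coarse, np.ones((reps, reps)))[:size, :size]
    return fine


def _iou_xyxy(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return inter / union if union > 0 else 0.0


def _place_boxes(rng: np.random.Generator, spec: SceneSpec) -> list[tuple[int, int, int, int]]:
    size = spec.image_size
    max_extent = max(MIN_TARGET_PX, min(48, size // 3))
    boxes: list[tuple[int, int, int, int]] = []
    attempts = 0
    limit = 400 * max(spec.n_targets, 1)
    while len(boxes) < spec.n_targets:
        if attempts > limit:
            raise CapacityError(
                f"could not place {spec.n_targets} non-overlapping "
                f">= {MIN_TARGET_PX}x{MIN_TARGET_PX} targets on a {size}px canvas")
        attempts += 1
        aspect = _CLASS_ASPECT[rng.integers(0, 8)]
        w = int(rng.integers(MIN_TARGET_PX, max_extent + 1))
        h = int(np.clip(round(w / aspect), MIN_TARGET_PX, max_extent))
        x0 = int(rng.integers(0, size - w + 1))
        y0 = int(rng.integers(0, size - h + 1))
        cand = (x0, y0, x0 + w, y0 + h)
        if all(_iou_xyxy(cand, b) <= spec.max_overlap_iou for b in boxes):
            boxes.append(cand)
    return boxes


def _render_target(rgb: np.ndarray, thermal: np.ndarray, box, label: int,
                   rng: np.random.Generator) -> None:
    x0, y0, x1, y1 = box
    h, w = y1 - y0, x1 - x0
    ys, xs = np.mgrid[0:h, 0:w]
    # normalized elliptical coordinate; 1 at the inscribed ellipse boundary
    u = (xs - (w - 1) / 2) / (w / 2)
    v = (ys - (h - 1) / 2) / (h / 2)
    r2 = u ** 2 + v ** 2
    body = r2 <= 0.92
    color = _hsv_to_rgb(float(_CLASS_HUE[label]), 0.85, 0.8)
    texture = 0.75 + 0.25 * rng.uniform(0, 1, (h, w))
    patch = rgb[:, y0:y1, x0:x1]
    for c in range(3):
        patch[c][body] = (color[c] * texture)[body]
    for _ in range(int(_CLASS_SPOTS[label])):
        sx, sy = rng.uniform(-0.5, 0.5, 2)
        spot = (u - sx) ** 2 + (v - sy) ** 2 <= 0.04
        for c in range(3):
            patch[c][spot & body] = 0.05
    # warm body: smooth elevation peaking at the center
    falloff = np.clip(1.0 - r2, 0.0, 1.0)
    thermal[0, y0:y1, x0:x1] += 0.45 * falloff + 0.15 * body


def generate_scene(spec: SceneSpec) -> AnnotatedScene:
    """Render one synchronized RGB/thermal pair with annotations.

    Deterministic given ``spec`` (including its seed).  Raises
    :class:`CapacityError` when the requested target count cannot be
    packed without exceeding the overlap budget.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size

    # foliage-like background: green-dominated smooth noise
    base = _smooth_noise(rng, size, max(4, size // 16))
    rgb = np.stack([0.15 + 0.10 * base,
                    0.35 + 0.25 * base,
                    0.10 + 0.08 * base])
    rgb += rng.normal(0, 0.015, rgb.shape)
    thermal = 0.25 + 0.10 * _smooth_noise(rng, size, max(4, size // 8))[None]
    thermal += rng.normal(0, 0.01, thermal.shape)

    boxes = _place_boxes(rng, spec)
    dist = np.asarray(spec.class_distribution)
    labels = [int(rng.choice(8, p=dist)) for _ in boxes]
    for box, label in zip(boxes, labels):
        _render_target(rgb, thermal, box, label, rng)

    # condition effects on the visible channel
    brightness = _BRIGHTNESS[spec.time_of_day] * _WEATHER_BRIGHT[spec.weather]
    rgb *= brightness
    if spec.weather == "foggy":
        rgb = 0.5 * rgb + 0.5 * rgb.mean() + 0.15   # contrast loss + haze
        thermal = thermal + 0.02 * rng.normal(0, 1, thermal.shape)

    rgb = np.clip(rgb, 0.0, 1.0)
    thermal = np.clip(thermal, 0.0, 1.0)
    timestamp = float(np.round(8.0 + 4.0 * rng.uniform(), 3))
    scene = AnnotatedScene(
        rgb=rgb, thermal=thermal,
        boxes=[tuple(float(v) for v in b) for b in boxes],
        labels=labels, group=[class_group(l) for l in labels],
        timestamp=timestamp, time_of_day=spec.time_of_day, weather=spec.weather)
    scene.validate()
    return scene


# ------------------------------------------------------------- env series

_TEMP_BASE = {"morning": 18.0, "noon": 28.0, "evening": 20.0}
_HUM_BASE = {"sunny": 45.0, "cloudy": 62.0, "foggy": 88.0}
_LIGHT_BASE = {"morning": 0.55, "noon": 0.90, "evening": 0.15}
_LIGHT_WEATHER = {"sunny": 1.0, "cloudy": 0.7, "foggy": 0.45}


def generate_env_series(duration: float, time_of_day: str = "noon",
                        weather: str = "sunny", seed: int = 0,
                        start: float = 0.0) -> EnvSeries:
    """Simulate a 1 Hz sensor stream of the given duration (seconds)."""
    if duration < 2:
        raise ValueError("duration must be >= 2 s")
    if time_of_day not in TIMES_OF_DAY or weather not in WEATHERS:
        raise ValueError("unknown condition")
    rng = np.random.default_rng(seed)
    t = start + np.arange(0.0, np.floor(duration) + 1.0)
    n = len(t)
    drift = np.cumsum(rng.normal(0, 0.02, n))
    temperature = np.clip(_TEMP_BASE[time_of_day] + drift
                          + rng.normal(0, 0.1, n), -10.0, 50.0)
    humidity = np.clip(_HUM_BASE[weather] - 0.3 * drift
                       + rng.normal(0, 0.5, n), 0.0, 100.0)
    light = np.clip(_LIGHT_BASE[time_of_day] * _LIGHT_WEATHER[weather]
                    + 0.01 * np.sin(2 * np.pi * t / 60.0)
                    + rng.normal(0, 0.01, n), 0.0, 1.0)
    series = EnvSeries(t, temperature, humidity, light)
    series.validate()
    return series


# ---------------------------------------------------------------- dataset

def _coco_categories() -> list[dict]:
    return [{"id": i + 1, "name": name,
             "supercategory": class_group(i)} for i, name in enumerate(CLASS_NAMES)]


def _save_png(path: Path, array: np.ndarray) -> None:
    """array is CxHxW float in [0,1]; written as 8-bit PNG."""
    img = np.round(np.clip(array, 0, 1) * 255).astype(np.uint8)
    if img.shape[0] == 1:
        Image.fromarray(img[0], mode="L").save(path)
    else:
        Image.fromarray(img.transpose(1, 2, 0), mode="RGB").save(path)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG back into CxHxW float in [0,1]."""
    img = np.asarray(Image.open(path), dtype=np.float64) / 255.0
    if img.ndim == 2:
        return img[None]
    return img.transpose(2, 0, 1)


def load_coco_annotations(path: str | Path) -> dict[int, dict]:
    """COCO-style JSON -> {image_id: {'boxes': [...xyxy...], 'labels': [...]}}."""
    payload = json.loads(Path(path).read_text())
    out: dict[int, dict] = {img["id"]: {"boxes": [], "labels": [],
                                        "file_name": img["file_name"],
                                        "width": img["width"], "height": img["height"]}
                            for img in payload["images"]}
    for ann in payload["annotations"]:
        x, y, w, h = ann["bbox"]
        out[ann["image_id"]]["boxes"].append((x, y, x + w, y + h))
        out[ann["image_id"]]["labels"].append(ann["category_id"] - 1)
    return out


def generate_dataset(n_scenes: int, spec_template: SceneSpec, out_dir: str | Path,
                     split: str = "train", env_duration: float = 20.0,
                     vary_conditions: bool = True) -> DatasetManifest:
    """Write ``n_scenes`` scenes (PNG pairs + env CSVs + one COCO JSON).

    Scene ``i`` uses seed ``spec_template.seed + i``; when
    ``vary_conditions`` the nine time-of-day x weather combinations are
    cycled so every condition stratum is populated.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    combos = [(t, w) for t in TIMES_OF_DAY for w in WEATHERS]
    images, annotations = [], []
    rgb_paths, thermal_paths, env_paths, timestamps, conditions = [], [], [], [], []
    ann_id = 1
    for i in range(n_scenes):
        tod, weather = ((spec_template.time_of_day, spec_template.weather)
                        if not vary_conditions else combos[i % len(combos)])
        spec = SceneSpec(
            image_size=spec_template.image_size, n_targets=spec_template.n_targets,
            class_distribution=spec_template.class_distribution,
            time_of_day=tod, weather=weather, seed=spec_template.seed + i,
            max_overlap_iou=spec_template.max_overlap_iou)
        scene = generate_scene(spec)
        env = generate_env_series(env_duration, tod, weather,
                                  seed=spec_template.seed + 90000 + i)
        rgb_name, th_name = f"rgb_{i:04d}.png", f"thermal_{i:04d}.png"
        env_name = f"env_{i:04d}.csv"
        _save_png(out / rgb_name, scene.rgb)
        _save_png(out / th_name, scene.thermal)
        env.to_csv(out / env_name)
        images.append({"id": i + 1, "file_name": rgb_name,
                       "width": spec.image_size, "height": spec.image_size,
                       "time_of_day": tod, "weather": weather,
                       "timestamp": scene.timestamp})
        for box, label in zip(scene.boxes, scene.labels):
            x0, y0, x1, y1 = box
            annotations.append({
                "id": ann_id, "image_id": i + 1, "category_id": label + 1,
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "area": (x1 - x0) * (y1 - y0), "iscrowd": 0})
            ann_id += 1
        rgb_paths.append(rgb_name)
        thermal_paths.append(th_name)
        env_paths.append(env_name)
        timestamps.append(scene.timestamp)
        conditions.append({"time_of_day": tod, "weather": weather})
    ann_path = f"annotations_{split}.json"
    (out / ann_path).write_text(json.dumps(
        {"images": images, "annotations": annotations,
         "categories": _coco_categories()}, indent=1))
    manifest = DatasetManifest(
        root=str(out), rgb_paths=rgb_paths, thermal_paths=thermal_paths,
        env_paths=env_paths, annotations_path=ann_path, timestamps=timestamps,
        conditions=conditions, split=split)
    manifest.validate()
    manifest.save(out / f"manifest_{split}.json")
    return manifest
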