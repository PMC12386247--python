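"""Image augmentation and sensor-to-frame alignment.

Four small, exactly-specified transforms feed the multimodal model:

* occlusion simulation ``I'(x,y) = 0`` inside a rectangular region,
  mimicking vegetation blockage;
* brightness perturbation ``I'' = I + N(0, sigma^2)``, clipped back to
  [0,1] since images are stored normalized;
* linear interpolation of 1 Hz sensor streams onto image-frame
  timestamps, ``s_hat = s_k + (s_{k+1}-s_k)/(t_{k+1}-t_k) * (t'-t_k)``
  with the bracketing condition ``t_k <= t' < t_{k+1}`` enforced
  literally (no extrapolation);
* min-max normalization against training-set extrema, with
  out-of-range values clipped to [0,1].

``assemble_sample`` composes the last two into the 3-channel
(temperature, humidity, light) environment vector aligned with a frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import EnvSeries

__all__ = [
    "OcclusionRegion", "NormalizationStats", "AlignedSample",
    "apply_occlusion", "sample_occlusion_region", "perturb_brightness",
    "interpolate_sensor", "normalize", "denormalize", "assemble_sample",
    "stats_from_series",
]

ENV_CHANNELS = ("temperature", "humidity", "light")


@dataclass(frozen=True)
class OcclusionRegion:
    """Rectangle (top-left x,y + extent) to be zeroed out."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w < 1 or self.h < 1:
            raise ValueError("occlusion extent must be >= 1 px")


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel training-set extrema for min-max scaling."""

    s_min: tuple[float, ...]
    s_max: tuple[float, ...]

    def __post_init__(self):
        if len(self.s_min) != len(self.s_max):
            raise ValueError("s_min/s_max length mismatch")
        for lo, hi in zip(self.s_min, self.s_max):
            if not hi > lo:
                raise ValueError(f"degenerate channel: s_max={hi} <= s_min={lo}")

    def to_dict(self) -> dict:
        return {"s_min": list(self.s_min), "s_max": list(self.s_max)}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(tuple(d["s_min"]), tuple(d["s_max"]))


@dataclass
class AlignedSample:
    """Images plus the normalized env vector interpolated at the frame time."""

    rgb: np.ndarray
    thermal: np.ndarray
    env: np.ndarray          # 3 channels, each in [0,1]
    timestamp: float

    def __post_init__(self):
        self.env = np.asarray(self.env, dtype=np.float64)
        if self.env.shape != (3,):
            raise ValueError("env vector must have exactly 3 channels")
        if ((self.env < 0) | (self.env > 1)).any():
            raise ValueError("env vector components must lie in [0,1]")


def apply_occlusion(image: np.ndarray, region: OcclusionRegion) -> np.ndarray:
    """Zero all pixels inside ``region``; everything else is untouched."""
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape[-2:]
    x0, y0 = max(region.x, 0), max(region.y, 0)
    x1, y1 = min(region.x + region.w, w), min(region.y + region.h, h)
    if x0 >= x1 or y0 >= y1:
        raise ValueError("occlusion region does not intersect the image domain")
    out = image.copy()
    out[..., y0:y1, x0:x1] = 0.0
    return out


def sample_occlusion_region(image_hw: tuple[int, int], rng: np.random.Generator,
                            area_range: tuple[float, float] = (0.02, 0.20),
                            aspect_range: tuple[float, float] = (0.3, 3.0),
                            ) -> OcclusionRegion:
    """Draw a random region: area uniform in 2-20% of the image, aspect in [0.3, 3]."""
    h, w = image_hw
    for _ in range(100):
        area = rng.uniform(*area_range) * h * w
        aspect = rng.uniform(*aspect_range)
        rw = int(np.clip(round(np.sqrt(area * aspect)), 1, w))
        rh = int(np.clip(round(np.sqrt(area / aspect)), 1, h))
        if rw <= w and rh <= h:
            x = int(rng.integers(0, w - rw + 1))
            y = int(rng.integers(0, h - rh + 1))
            return OcclusionRegion(x, y, rw, rh)
    raise RuntimeError("failed to sample an occlusion region")


def perturb_brightness(image: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add zero-mean Gaussian noise of std ``sigma``, then clip to [0,1]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    return np.clip(image + rng.normal(0.0, sigma, image.shape), 0.0, 1.0)


def interpolate_sensor(times: np.ndarray, values: np.ndarray,
                       t_prime: float) -> float:
    """Linearly interpolate the series at ``t_prime``.

    Requires a bracketing pair ``t_k <= t' < t_{k+1}``; querying outside
    ``[t_first, t_last)`` raises rather than extrapolating or clamping.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least 2 samples to interpolate")
    if not (np.diff(times) > 0).all():
        raise ValueError("timestamps must be strictly increasing")
    if not (times[0] <= t_prime < times[-1]):
        raise ValueError(f"t'={t_prime} outside [{times[0]}, {times[-1]}) — "
                         "extrapolation is not supported")
    k = int(np.searchsorted(times, t_prime, side="right") - 1)
    t_k, t_k1 = times[k], times[k + 1]
    s_k, s_k1 = values[k], values[k + 1]
    return float(s_k + (s_k1 - s_k) / (t_k1 - t_k) * (t_prime - t_k))


def normalize(value, stats: NormalizationStats, channel: int = 0):
    """(s - s_min) / (s_max - s_min), clipped to [0,1] outside the extrema."""
    lo, hi = stats.s_min[channel], stats.s_max[channel]
    return np.clip((np.asarray(value, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def denormalize(value, stats: NormalizationStats, channel: int = 0):
    lo, hi = stats.s_min[channel], stats.s_max[channel]
    return np.asarray(value, dtype=float) * (hi - lo) + lo


def stats_from_series(series_list: list[EnvSeries]) -> NormalizationStats:
    """Training-set extrema over the three env channels."""
    mins, maxs = [], []
    for name in ENV_CHANNELS:
        chans = np.concatenate([s.channel(name) for s in series_list])
        lo, hi = float(chans.min()), float(chans.max())
        if hi <= lo:                      # constant channel: widen symmetrically
            lo, hi = lo - 0.5, hi + 0.5
        mins.append(lo)
        maxs.append(hi)
    return NormalizationStats(tuple(mins), tuple(maxs))


def assemble_sample(rgb: np.ndarray, thermal: np.ndarray, env_series: EnvSeries,
                    t_frame: float, stats: NormalizationStats) -> AlignedSample:
    """Interpolate each env channel at ``t_frame`` and normalize it."""
    env = np.array([
        normalize(interpolate_sensor(env_series.timestamps,
                                     env_series.channel(name), t_frame),
                  stats, channel=i)
        for i, name in enumerate(ENV_CHANNELS)])
    return AlignedSample(rgb=rgb, thermal=thermal, env=env, timestamp=t_frame)
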