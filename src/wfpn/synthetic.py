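"""Synthetic 4-class skin-lesion-like image generator.

The four classes emulate the visual logic of pressure-injury staging:
all share one background distribution (procedurally textured skin tone)
and differ *only* in the parameters of a central elliptical lesion —

* class 1: diffuse reddish patch with a wide feathered edge, skin
  texture left intact (non-blanchable erythema);
* class 2: small, sharp-edged pale break in the skin;
* class 3: crater with a dark inner core and a granular, noisy ring;
* class 4: large dark region with a high-contrast rim.

A ``separability`` scalar in [0, 1] linearly interpolates every
class-specific lesion parameter toward the across-class mean: at 1 the
classes are maximally distinct, at 0 all four draw from one shared
distribution, so any classifier must fall to chance.  Because the
background generator is shared, classifiers can only exploit lesion
features.

This is a test fixture with controllable difficulty, not a clinical
simulator: lesions are parametric ellipses/annuli with seeded value
noise, chosen for determinism and speed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

STAGE_NAMES = ("stage1", "stage2", "stage3", "stage4")

# per-class lesion parameters at separability 1; identical keys per class
_CLASS_PARAMS: Dict[int, Dict[str, np.ndarray | float]] = {
    0: dict(  # diffuse reddish patch, intact texture
        color=np.array([0.80, 0.30, 0.28]),
        core_color=np.array([0.80, 0.30, 0.28]),
        rim_color=np.array([0.80, 0.35, 0.30]),
        radius=0.30, edge_sharpness=3.0, alpha=0.45,
        texture_amp=0.02, core_frac=0.0, rim_strength=0.0, rim_width=0.10,
    ),
    1: dict(  # small sharp-edged pale break
        color=np.array([0.90, 0.82, 0.74]),
        core_color=np.array([0.92, 0.86, 0.78]),
        rim_color=np.array([0.85, 0.55, 0.48]),
        radius=0.12, edge_sharpness=25.0, alpha=0.90,
        texture_amp=0.03, core_frac=0.0, rim_strength=0.25, rim_width=0.08,
    ),
    2: dict(  # crater: dark core, granular ring
        color=np.array([0.72, 0.38, 0.30]),
        core_color=np.array([0.35, 0.14, 0.12]),
        rim_color=np.array([0.78, 0.45, 0.38]),
        radius=0.24, edge_sharpness=12.0, alpha=0.85,
        texture_amp=0.18, core_frac=0.45, rim_strength=0.30, rim_width=0.10,
    ),
    3: dict(  # large dark region, high-contrast rim
        color=np.array([0.16, 0.09, 0.09]),
        core_color=np.array([0.10, 0.06, 0.06]),
        rim_color=np.array([0.88, 0.52, 0.45]),
        radius=0.38, edge_sharpness=18.0, alpha=0.95,
        texture_amp=0.05, core_frac=0.60, rim_strength=0.80, rim_width=0.07,
    ),
}


@dataclass
class SyntheticSpec:
    """Study conditions for one generated dataset."""

    per_class: Sequence[int] = (100, 100, 100, 100)
    image_size: int = 224
    skin_tone_base: Tuple[float, float, float] = (0.76, 0.57, 0.49)
    skin_tone_jitter: float = 0.06
    noise_sigma: float = 0.05
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.per_class) != 4:
            raise ValueError("exactly 4 classes are modelled")
        if any(n < 0 for n in self.per_class):
            raise ValueError("per-class counts must be non-negative")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")
        if self.image_size < 16:
            raise ValueError("image_size too small")

    @property
    def total(self) -> int:
        return int(sum(self.per_class))


def _bilinear_resize(grid: np.ndarray, size: int) -> np.ndarray:
    """Upsample a small 2-D grid to size x size bilinearly."""
    gh, gw = grid.shape
    ys = np.linspace(0, gh - 1, size)
    xs = np.linspace(0, gw - 1, size)
    y0 = np.clip(ys.astype(int), 0, gh - 2)
    x0 = np.clip(xs.astype(int), 0, gw - 2)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    a = grid[y0][:, x0]
    b = grid[y0][:, x0 + 1]
    c = grid[y0 + 1][:, x0]
    d = grid[y0 + 1][:, x0 + 1]
    return a * (1 - wy) * (1 - wx) + b * (1 - wy) * wx + c * wy * (1 - wx) + d * wy * wx


def _value_noise(rng: np.random.Generator, size: int, octaves: Sequence[int] = (4, 8, 16)) -> np.ndarray:
    """Zero-mean multi-octave value noise in roughly [-1, 1]."""
    out = np.zeros((size, size))
    amp, total = 1.0, 0.0
    for cells in octaves:
        out += amp * _bilinear_resize(rng.standard_normal((cells, cells)), size)
        total += amp
        amp *= 0.5
    return out / total


def _interp_params(c: int, s: float) -> Dict[str, np.ndarray | float]:
    """Shrink class ``c``'s parameters toward the across-class mean by 1-s."""
    keys = _CLASS_PARAMS[0].keys()
    out = {}
    for k in keys:
        vals = [np.asarray(_CLASS_PARAMS[i][k], dtype=float) for i in range(4)]
        mean = np.mean(vals, axis=0)
        v = mean + s * (vals[c] - mean)
        out[k] = v if v.ndim else float(v)
    return out


def render_image(spec: SyntheticSpec, cls: int, rng: np.random.Generator) -> Tuple[np.ndarray, dict]:
    """Render one image of class ``cls``; returns (3 x H x W in [0,1], params)."""
    size = spec.image_size
    p = _interp_params(cls, spec.separability)

    # shared background: jittered skin tone with smooth texture
    base = np.asarray(spec.skin_tone_base) + rng.uniform(
        -spec.skin_tone_jitter, spec.skin_tone_jitter, 3
    )
    shading = _value_noise(rng, size)
    img = np.clip(base[:, None, None] * (1.0 + 0.10 * shading[None]), 0, 1)

    # lesion geometry: ellipse with jittered centre/radii/orientation
    cy, cx = rng.uniform(0.38, 0.62, 2) * size
    r = float(p["radius"]) * size
    ry = r * rng.uniform(0.8, 1.2)
    rx = r * rng.uniform(0.8, 1.2)
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    yr = (yy - cy) * np.cos(theta) - (xx - cx) * np.sin(theta)
    xr = (yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    d = np.sqrt((yr / ry) ** 2 + (xr / rx) ** 2)

    sharp = float(p["edge_sharpness"])
    inside = 1.0 / (1.0 + np.exp(np.clip(sharp * (d - 1.0), -60, 60)))

    # lesion colour field: body colour, optional dark core, granular texture
    lesion = np.broadcast_to(np.asarray(p["color"])[:, None, None], img.shape).copy()
    core_frac = float(p["core_frac"])
    if core_frac > 0:
        core_mask = 1.0 / (1.0 + np.exp(np.clip(sharp * (d - core_frac), -60, 60)))
        lesion = lesion * (1 - core_mask[None]) + np.asarray(p["core_color"])[:, None, None] * core_mask[None]
    tex = _value_noise(rng, size, octaves=(16, 32))
    lesion = np.clip(lesion + float(p["texture_amp"]) * tex[None], 0, 1)

    alpha = float(p["alpha"]) * inside
    img = img * (1 - alpha[None]) + lesion * alpha[None]

    # optional high-contrast rim in a band around d = 1
    rim_w = float(p["rim_width"])
    rim = float(p["rim_strength"]) * np.exp(-((d - 1.0) ** 2) / (2 * rim_w**2))
    img = img * (1 - rim[None]) + np.asarray(p["rim_color"])[:, None, None] * rim[None]

    img = np.clip(img + rng.normal(0, spec.noise_sigma, img.shape), 0, 1)
    params = dict(cy=cy, cx=cx, ry=ry, rx=rx, theta=theta)
    return img, params


def generate_arrays(spec: SyntheticSpec) -> Tuple[np.ndarray, np.ndarray]:
    """All images as one (N, 3, H, W) array in [0,1] plus integer labels.

    Fully determined by ``spec.seed``; images are in class-major order.
    """
    if spec.total == 0:
        raise ValueError("zero total images requested")
    children = np.random.SeedSequence(spec.seed).spawn(spec.total)
    images, labels = [], []
    i = 0
    for cls, count in enumerate(spec.per_class):
        for _ in range(count):
            img, _ = render_image(spec, cls, np.random.default_rng(children[i]))
            images.append(img)
            labels.append(cls)
            i += 1
    return np.stack(images), np.array(labels, dtype=np.int64)


def generate_dataset(spec: SyntheticSpec, out_dir) -> Path:
    """Write a class-per-folder PNG tree plus a manifest CSV; returns the root."""
    if spec.total == 0:
        raise ValueError("zero total images requested")
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(spec.seed).spawn(spec.total)
    rows = []
    i = 0
    for cls, count in enumerate(spec.per_class):
        stage_dir = root / STAGE_NAMES[cls]
        stage_dir.mkdir(exist_ok=True)
        for j in range(count):
            img, params = render_image(spec, cls, np.random.default_rng(children[i]))
            arr = (img.transpose(1, 2, 0) * 255).round().astype(np.uint8)
            rel = f"{STAGE_NAMES[cls]}/img_{j:04d}.png"
            Image.fromarray(arr).save(root / rel)
            rows.append(
                dict(
                    path=rel,
                    label=cls,
                    stage=STAGE_NAMES[cls],
                    separability=spec.separability,
                    noise_sigma=spec.noise_sigma,
                    **{k: f"{v:.4f}" for k, v in params.items()},
                )
            )
            i += 1
    with open(root / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return root


def channel_stats(images: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and std over an (N, 3, H, W) stack."""
    mean = images.mean(axis=(0, 2, 3))
    std = images.std(axis=(0, 2, 3))
    return mean, std
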