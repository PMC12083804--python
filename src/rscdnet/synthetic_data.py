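"""Deterministic synthetic fine-grained grain-image dataset.

Each image shows a single elongated, pointed-ended grain on a dark
background.  Classes differ subtly in morphology (length, width), husk
hue and stripe-texture frequency — deliberately less than typical
intra-class jitter for many class pairs, so the classification problem is
fine-grained.  Nuisance factors (dust specks, global illumination shift,
sensor noise) are applied per image.  Everything derives from a single
master seed: regeneration is bit-exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from PIL import Image

__all__ = [
    "ClassParams",
    "SyntheticSeedSpec",
    "DatasetLayout",
    "sample_class_params",
    "render_seed_image",
    "generate_dataset",
    "simple_features",
    "fine_grained_fraction",
]

SPLITS = ("train", "val", "test")


@dataclass
class ClassParams:
    """Generative parameters of one grain class (relative image units)."""

    name: str
    class_seed: int
    length_mean: float
    length_sd: float
    width_mean: float
    width_sd: float
    hue: Tuple[float, float, float]  # mean husk RGB in [0, 1]
    hue_sd: float
    texture_freq_mean: float  # stripes per grain
    texture_freq_sd: float
    awn_prob: float
    pointiness: float = 1.7


@dataclass
class SyntheticSeedSpec:
    num_classes: int = 4
    per_class: Tuple[int, int, int] = (10, 2, 2)  # (train, val, test)
    image_size: int = 224
    master_seed: int = 0
    dust_rate: float = 2.0  # mean specks per image
    illumination_range: Tuple[float, float] = (0.92, 1.08)
    background_level: float = 0.06
    noise_sd: float = 0.012

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2")
        if len(self.per_class) != 3 or any(n < 0 for n in self.per_class):
            raise ValueError("per_class must be three non-negative counts")
        if self.image_size < 16:
            raise ValueError("image_size too small to render a grain")


@dataclass
class DatasetLayout:
    root: Path
    manifest: Path
    class_names: Tuple[str, ...]
    counts: dict  # split -> per-class count


def sample_class_params(num_classes: int, master_seed: int) -> list[ClassParams]:
    """Draw per-class generative parameters, deterministically.

    Class-level offsets are drawn at a scale comparable to the intra-class
    jitter, which is what makes neighbouring classes hard to separate.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be at least 2")
    rng = np.random.default_rng([int(master_seed), 0xC1A55])
    base_hue = np.array([0.72, 0.60, 0.38])
    params = []
    for i in range(num_classes):
        hue = np.clip(base_hue + rng.normal(0.0, 0.060, size=3), 0.15, 0.95)
        params.append(ClassParams(
            name=f"class{i:02d}",
            class_seed=int(rng.integers(0, 2**31 - 1)),
            length_mean=float(np.clip(0.55 + rng.normal(0.0, 0.050), 0.35, 0.8)),
            length_sd=0.035,
            width_mean=float(np.clip(0.16 + rng.normal(0.0, 0.018), 0.08, 0.3)),
            width_sd=0.013,
            hue=tuple(float(h) for h in hue),
            hue_sd=0.040,
            texture_freq_mean=float(np.clip(9.0 + rng.normal(0.0, 2.0), 4.0, 16.0)),
            texture_freq_sd=1.3,
            awn_prob=float(rng.uniform(0.0, 0.35)),
        ))
    return params


def _instance_rng(cp: ClassParams, instance_seed: int) -> np.random.Generator:
    return np.random.default_rng([cp.class_seed, int(instance_seed)])


def render_seed_image(cp: ClassParams, instance_seed: int, image_size: int = 224,
                      dust_rate: float = 2.0,
                      illumination_range: Tuple[float, float] = (0.85, 1.15),
                      background_level: float = 0.06,
                      noise_sd: float = 0.012) -> np.ndarray:
    """Render one grain image as a (H, W, 3) uint8 array.

    Deterministic per (class params, instance seed).
    """
    rng = _instance_rng(cp, instance_seed)
    n = image_size
    yy, xx = np.mgrid[0:n, 0:n]
    x = (xx - (n - 1) / 2) / (n / 2)
    y = (yy - (n - 1) / 2) / (n / 2)

    # per-instance morphology jitter
    length = max(rng.normal(cp.length_mean, cp.length_sd), 0.2)
    width = max(rng.normal(cp.width_mean, cp.width_sd), 0.05)
    freq = max(rng.normal(cp.texture_freq_mean, cp.texture_freq_sd), 2.0)
    # grains are roughly aligned, as on an arranged acquisition board
    theta = rng.uniform(-0.35, 0.35)
    cx, cy = rng.uniform(-0.10, 0.10, size=2)
    phase = rng.uniform(0.0, 2 * np.pi)
    hue = np.clip(np.asarray(cp.hue) + rng.normal(0.0, cp.hue_sd, size=3), 0.0, 1.0)

    ct, st = np.cos(theta), np.sin(theta)
    u = ct * (x - cx) + st * (y - cy)
    v = -st * (x - cx) + ct * (y - cy)
    a, b = length / 2, width / 2

    # pointed-ended superellipse body with a soft edge
    s = (np.abs(u) / a) ** cp.pointiness + (np.abs(v) / b) ** 2
    body = np.clip((1.0 - s) / 0.10, 0.0, 1.0)

    # husk stripes along the major axis + mild lateral shading
    stripes = 1.0 - 0.30 * 0.5 * (1.0 + np.sin(np.pi * freq * u / a + phase))
    shading = 1.0 - 0.35 * (np.abs(v) / b) ** 2
    intensity = body * stripes * np.clip(shading, 0.0, 1.0)

    img = background_level * (0.8 + 0.4 * rng.random()) * np.ones((n, n, 3))
    img += intensity[:, :, None] * hue[None, None, :]

    # optional awn: a thin bright filament extending from one tip
    if rng.random() < cp.awn_prob:
        awn_len = 0.35 * length
        ua = np.abs(u - (a + awn_len / 2)) / (awn_len / 2)
        va = np.abs(v - 0.02 * np.sin(12 * u)) / 0.015
        awn = np.clip(1.0 - (ua**2 + va**2), 0.0, 1.0)
        img += 0.8 * awn[:, :, None] * hue[None, None, :]

    # dust specks
    n_dust = rng.poisson(dust_rate)
    for _ in range(n_dust):
        dx, dy = rng.uniform(-0.95, 0.95, size=2)
        r = rng.uniform(0.004, 0.015)
        lum = rng.uniform(0.25, 0.7)
        blob = np.exp(-(((x - dx) ** 2 + (y - dy) ** 2) / (2 * r * r)))
        img += lum * blob[:, :, None]

    gain = rng.uniform(*illumination_range)
    img *= gain
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def generate_dataset(spec: SyntheticSeedSpec, root,
                     overwrite: bool = False,
                     image_format: str = "png") -> DatasetLayout:
    """Write split/class/NNN image files plus a manifest CSV.

    PNG (lossless) keeps regeneration bit-exact; JPG export is available
    but not bit-stable across encoders.
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{root} is not empty; pass overwrite=True to regenerate"
            )
    if image_format not in ("png", "jpg"):
        raise ValueError("image_format must be 'png' or 'jpg'")
    params = sample_class_params(spec.num_classes, spec.master_seed)
    rows = []
    counts = {}
    for split, n_split in zip(SPLITS, spec.per_class):
        counts[split] = n_split
        for ci, cp in enumerate(params):
            outdir = root / split / cp.name
            outdir.mkdir(parents=True, exist_ok=True)
            for k in range(n_split):
                # disjoint instance seeds across splits
                inst = {"train": 0, "val": 1_000_000, "test": 2_000_000}[split] + k
                img = render_seed_image(
                    cp, inst, spec.image_size, spec.dust_rate,
                    spec.illumination_range, spec.background_level, spec.noise_sd,
                )
                fname = outdir / f"{k:04d}.{image_format}"
                Image.fromarray(img).save(fname)
                rows.append({
                    "file": str(fname.relative_to(root)),
                    "split": split,
                    "class": cp.name,
                    "instance_seed": inst,
                })
    manifest = root / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["file", "split", "class", "instance_seed"])
        writer.writeheader()
        writer.writerows(rows)
    return DatasetLayout(
        root=root, manifest=manifest,
        class_names=tuple(cp.name for cp in params), counts=counts,
    )


def simple_features(img: np.ndarray, background_margin: float = 0.18) -> np.ndarray:
    """Hand-crafted morphology/colour/texture features for baselines.

    Returns (area, mean R, mean G, mean B, elongation, texture sd).
    """
    f = img.astype(float) / 255.0
    lum = f.mean(axis=2)
    fg = lum > background_margin
    if fg.sum() < 10:
        return np.zeros(6)
    area = fg.mean()
    rgb = f[fg].mean(axis=0)
    ys, xs = np.nonzero(fg)
    cov = np.cov(np.stack([xs, ys]))
    evals = np.sort(np.linalg.eigvalsh(cov))
    elong = np.sqrt(evals[1] / max(evals[0], 1e-9))
    tex = lum[fg].std()
    return np.array([area, rgb[0], rgb[1], rgb[2], elong, tex])


def fine_grained_fraction(params: Sequence[ClassParams]) -> float:
    """Fraction of adjacent class pairs whose normalized parameter
    separation is below 2 intra-class standard deviations."""
    close = 0
    pairs = 0
    for p1, p2 in zip(params[:-1], params[1:]):
        sep = np.array([
            abs(p1.length_mean - p2.length_mean) / p1.length_sd,
            abs(p1.width_mean - p2.width_mean) / p1.width_sd,
            np.linalg.norm(np.subtract(p1.hue, p2.hue)) / p1.hue_sd,
            abs(p1.texture_freq_mean - p2.texture_freq_mean) / p1.texture_freq_sd,
        ])
        pairs += 1
        if np.median(sep) < 2.0:
            close += 1
    return close / pairs
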