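"""Synthetic dermoscopy-like dataset generator.

Emulates the structure of a 9-class, class-imbalanced skin-lesion archive
(2239 images across classes of 114, 376, 95, 438, 357, 462, 77, 181 and 139
images) without any download: each image is an elliptical lesion blob on a
skin-tone background with class-dependent hue, eccentricity, size, border
irregularity and texture noise.

A single ``separability`` knob in [0, 1] scales the between-class parameter
distances: at 1.0 the class appearances are maximally distinct, at 0.0 all
classes share one appearance distribution and are exchangeable, so any
classifier's expected accuracy is 1/K.  Everything is reproducible from
(spec, seed).

These images exercise the full pipeline (cipher, feature fusion, classifier,
metrics) but are not photorealistic dermoscopy: passing tests demonstrate the
machinery, not clinical performance.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image import RasterImage, load_image, save_image

#: Per-class image counts of the emulated 9-class archive (total 2239).
ARCHIVE_CLASS_COUNTS = (114, 376, 95, 438, 357, 462, 77, 181, 139)


@dataclass
class DatasetSpec:
    """Generation recipe; defaults mirror the emulated archive's imbalance
    scaled by ``count_factor`` (0.1 keeps desk-scale runs fast)."""

    n_classes: int = 9
    class_counts: tuple[int, ...] | None = None
    count_factor: float = 0.1
    image_size: int = 64
    separability: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_counts is None:
            base = ARCHIVE_CLASS_COUNTS[: self.n_classes]
            if len(base) < self.n_classes:
                base = base + ARCHIVE_CLASS_COUNTS * (self.n_classes // 9 + 1)
                base = tuple(base[: self.n_classes])
            self.class_counts = tuple(
                max(1, int(round(c * self.count_factor))) for c in base
            )
        self.class_counts = tuple(int(c) for c in self.class_counts)
        if len(self.class_counts) != self.n_classes:
            raise ValueError(
                f"got {len(self.class_counts)} counts for {self.n_classes} classes"
            )
        if any(c < 1 for c in self.class_counts):
            raise ValueError("every class needs at least one image")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")

    @property
    def total(self) -> int:
        return sum(self.class_counts)


@dataclass
class LabelledImage:
    image: RasterImage
    label: int
    params: dict = field(default_factory=dict)


def _class_appearance(k: int, n_classes: int, separability: float) -> dict:
    """Deterministic parametric appearance for class ``k``.

    Base (shared) appearance plus a class-specific offset scaled by the
    separability; at separability 0 every class collapses onto the base.
    """
    phi = 2.0 * np.pi * k / max(n_classes, 1)
    s = separability
    return {
        "hue_rgb": np.array([
            0.45 + 0.35 * s * np.cos(phi),
            0.30 + 0.20 * s * np.sin(phi),
            0.25 + 0.18 * s * np.cos(2 * phi),
        ]),
        "radius": 0.28 + 0.10 * s * np.sin(phi + 0.7),
        "eccentricity": 0.15 + 0.55 * s * (k / max(n_classes - 1, 1)),
        "border_amp": 0.05 + 0.25 * s * ((k * 7 % n_classes) / max(n_classes, 1)),
        "texture_sigma": 0.02 + 0.06 * s * ((k * 3 % n_classes) / max(n_classes, 1)),
    }


def _render(size: int, app: dict, rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    skin = np.array([0.87, 0.72, 0.60]) + rng.normal(0, 0.02, 3)
    img = np.ones((size, size, 3)) * skin
    cy, cx = (rng.uniform(0.4, 0.6, 2) * size)
    radius = app["radius"] * size * rng.uniform(0.85, 1.15)
    ecc = np.clip(app["eccentricity"] + rng.normal(0, 0.03), 0.0, 0.9)
    theta0 = rng.uniform(0, np.pi)
    amp = app["border_amp"] * rng.uniform(0.7, 1.3)
    freq = rng.integers(3, 7)
    phase = rng.uniform(0, 2 * np.pi)

    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame
    ry = dy * np.cos(theta0) + dx * np.sin(theta0)
    rx = -dy * np.sin(theta0) + dx * np.cos(theta0)
    a, b = radius, radius * (1.0 - ecc)
    ang = np.arctan2(ry, rx)
    wobble = 1.0 + amp * np.sin(freq * ang + phase)
    d = np.sqrt((rx / a) ** 2 + (ry / b) ** 2)
    mask = (d < wobble).astype(float)
    soft = np.clip((wobble - d) / 0.15, 0, 1)  # soft edge
    mask = np.maximum(mask * 0.6, soft * 0.6) + 0.4 * mask

    lesion = app["hue_rgb"] + rng.normal(0, 0.02, 3)
    img = img * (1 - mask[..., None]) + lesion * mask[..., None]
    img += rng.normal(0, app["texture_sigma"], img.shape)
    pixels = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
    params = {
        "center": [float(cy), float(cx)],
        "radius": float(radius),
        "eccentricity": float(ecc),
        "border_amp": float(amp),
    }
    return pixels, params


def generate_dataset(spec: DatasetSpec) -> list[LabelledImage]:
    """Generate the labelled image list; class ``k`` appears
    ``spec.class_counts[k]`` times, in class order."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    out: list[LabelledImage] = []
    for k, count in enumerate(spec.class_counts):
        app = _class_appearance(k, spec.n_classes, spec.separability)
        for _ in range(count):
            pixels, params = _render(spec.image_size, app, rng)
            out.append(LabelledImage(RasterImage(pixels), k, params))
    return out


def split(
    dataset: list[LabelledImage], train_fraction: float, seed: int = 0
) -> tuple[list[LabelledImage], list[LabelledImage]]:
    """Stratified train/test partition: disjoint, exhaustive, seed-reproducible.

    Each class keeps ``round(train_fraction * n_k)`` members in train, at
    least one on each side.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train fraction must lie strictly between 0 and 1")
    labels = np.array([d.label for d in dataset])
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for k in np.unique(labels):
        members = np.flatnonzero(labels == k)
        if members.size < 2:
            raise ValueError(
                f"class {k} has {members.size} member(s); need >= 2 to stratify"
            )
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx.sort()
    test_idx.sort()
    return [dataset[i] for i in train_idx], [dataset[i] for i in test_idx]


def write_fixtures(dataset: list[LabelledImage], outdir: str | Path, spec: DatasetSpec | None = None) -> Path:
    """Write PNG images, a ``labels.csv`` (filename,label) and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, item in enumerate(dataset):
        name = f"img_{i:05d}_c{item.label}.png"
        save_image(item.image, outdir / name)
        rows.append((name, item.label))
    with open(outdir / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        writer.writerows(rows)
    manifest = {
        "n_images": len(dataset),
        "spec": None
        if spec is None
        else {
            "n_classes": spec.n_classes,
            "class_counts": list(spec.class_counts),
            "image_size": spec.image_size,
            "separability": spec.separability,
            "seed": spec.seed,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_fixtures(datadir: str | Path) -> list[LabelledImage]:
    """Read a PNG + labels.csv directory back into labelled images."""
    datadir = Path(datadir)
    out = []
    with open(datadir / "labels.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            img = load_image(datadir / row["filename"])
            out.append(LabelledImage(img, int(row["label"])))
    return out
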