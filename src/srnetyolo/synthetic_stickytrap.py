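"""Seeded generator of synthetic yellow-sticky-trap scenes.

Real trap photographs are dominated by pests no larger than 40 px per
side: in the motivating survey 80.4% of labelled pests were tiny (both
sides <= 32 px) and 28.7% very tiny (<= 16 px).  The generator emulates
that statistical structure so every pipeline stage — tiling, training,
size-stratified evaluation — can be exercised without the original
photographs: a yellow textured background with a mild illumination
gradient, two classes of dark insect-like blobs (an elongated thrips-like
shape and a rounder aphid-like shape) rendered as anti-aliased ellipses,
and unlabeled distractor specks so precision is non-trivially exercised.

Rendering is parametric, not learned; photorealism is a non-goal.  Every
scene is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .boxes import BBox
from .data.annotations import AnnotatedImage, write_voc_xml, write_yolo_txt
from .data.sizes import SizeClass, size_class

__all__ = ["SceneConfig", "generate_scene", "generate_dataset", "dataset_size_stats"]

# default class styles: (elongation range, RGB base colour)
_CLASS_STYLES = {
    0: ((1.8, 3.2), (60, 45, 25)),    # cotton-thrips-like: elongated, dark brown
    1: ((1.0, 1.5), (35, 50, 30)),    # myzus-persicae-like: round, dark green
}


@dataclass
class SceneConfig:
    image_size: int = 640
    classes: tuple = ("cotton_thrips", "myzus_persicae")
    n_pests_mean: float = 12.0         # Poisson mean per scene
    # partition probabilities over (very_tiny, tiny-but-not-very-tiny, large)
    size_mixture: tuple = (0.287, 0.517, 0.196)
    max_side: int = 40                 # hard cap on any object side
    min_side: int = 4
    background_rgb: tuple = (212, 180, 40)
    background_noise: float = 8.0
    gradient_strength: float = 18.0
    clutter_mean: float = 10.0         # Poisson mean of unlabeled specks
    max_place_tries: int = 100

    def validate(self):
        if abs(sum(self.size_mixture) - 1.0) > 1e-9:
            raise ValueError("size mixture must sum to 1")
        if not 0 < self.min_side <= self.max_side:
            raise ValueError("need 0 < min_side <= max_side")
        if self.max_side > self.image_size:
            raise ValueError("objects cannot exceed the image")
        return self


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.image_size
    base = np.array(cfg.background_rgb, dtype=np.float32)
    img = np.tile(base, (n, n, 1))
    # smooth illumination gradient with random direction
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float32) / max(n - 1, 1)
    ramp = (np.cos(theta) * xx + np.sin(theta) * yy) - 0.5
    img += cfg.gradient_strength * ramp[..., None]
    # fine texture noise
    img += rng.normal(0.0, cfg.background_noise, size=(n, n, 3)).astype(np.float32)
    return img


def _sample_box_size(cfg: SceneConfig, rng: np.random.Generator) -> tuple[int, int, int]:
    """Sample (class_id, w, h) honouring the size-class mixture."""
    cls = int(rng.integers(len(cfg.classes)))
    stratum = rng.choice(3, p=np.asarray(cfg.size_mixture) / sum(cfg.size_mixture))
    lo = cfg.min_side
    if stratum == 0:        # very tiny: both sides <= 16
        long_side = int(rng.integers(max(lo, 6), 17))
        hi_cap = 16
    elif stratum == 1:      # tiny but not very tiny: both <= 32, max side > 16
        long_side = int(rng.integers(17, 33))
        hi_cap = 32
    else:                   # large: max side in (32, max_side]
        long_side = int(rng.integers(33, cfg.max_side + 1))
        hi_cap = cfg.max_side
    elong_rng, _ = _CLASS_STYLES[cls % 2]
    elong = rng.uniform(*elong_rng)
    short_side = int(np.clip(round(long_side / elong), lo, min(long_side, hi_cap)))
    if rng.random() < 0.5:
        w, h = long_side, short_side
    else:
        w, h = short_side, long_side
    return cls, w, h


def _render_ellipse(img: np.ndarray, box: BBox, color, rng, ss: int = 4):
    """Anti-aliased filled ellipse inscribed in ``box`` (supersampled)."""
    x0, y0 = int(box.x), int(box.y)
    w, h = int(box.w), int(box.h)
    yy, xx = np.mgrid[0 : h * ss, 0 : w * ss].astype(np.float32)
    cx, cy = w * ss / 2.0, h * ss / 2.0
    nx = (xx + 0.5 - cx) / (w * ss / 2.0)
    ny = (yy + 0.5 - cy) / (h * ss / 2.0)
    inside = (nx**2 + ny**2) <= 1.0
    cov = inside.reshape(h, ss, w, ss).mean(axis=(1, 3)).astype(np.float32)
    jitter = rng.normal(0, 6, size=3).astype(np.float32)
    col = np.asarray(color, dtype=np.float32) + jitter
    patch = img[y0 : y0 + h, x0 : x0 + w]
    patch[:] = patch * (1 - cov[..., None]) + col * cov[..., None]


def generate_scene(cfg: SceneConfig, seed: int, render: bool = True) -> AnnotatedImage:
    """Render one deterministic scene with exact ground-truth boxes.

    Layout (box sizes, classes, placements) and texture (background noise,
    colour jitter) are drawn from two independent child streams of the
    seed, so ``render=False`` produces the identical annotation set with
    ``pixels=None`` at a fraction of the cost.
    """
    cfg.validate()
    ss_layout, ss_texture = np.random.SeedSequence(int(seed)).spawn(2)
    rng = np.random.default_rng(ss_layout)       # layout stream
    rng_tex = np.random.default_rng(ss_texture)  # texture stream
    img = _background(cfg, rng_tex) if render else None
    n = cfg.image_size
    n_pests = int(rng.poisson(cfg.n_pests_mean))
    boxes: list[BBox] = []
    for _ in range(n_pests):
        cls, w, h = _sample_box_size(cfg, rng)
        placed = False
        for _try in range(cfg.max_place_tries):
            x = int(rng.integers(0, n - w + 1))
            y = int(rng.integers(0, n - h + 1))
            cand = BBox(cls, x, y, w, h)
            # avoid overlapping existing pests: boxes must not intersect
            if all(cand.x >= b.x2 or b.x >= cand.x2 or cand.y >= b.y2 or b.y >= cand.y2
                   for b in boxes):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place pest after {cfg.max_place_tries} tries "
                f"(scene too crowded: {len(boxes)} placed)"
            )
        if render:
            _, color = _CLASS_STYLES[cls % 2]
            _render_ellipse(img, cand, color, rng_tex)
        boxes.append(cand)
    # unlabeled clutter: small grey/dark specks, kept clear of real pests
    n_clutter = int(rng.poisson(cfg.clutter_mean))
    for _ in range(n_clutter):
        s = int(rng.integers(1, 4))
        x = int(rng.integers(0, n - s))
        y = int(rng.integers(0, n - s))
        speck = BBox(0, x, y, max(s, 1), max(s, 1))
        if any(not (speck.x >= b.x2 + 2 or b.x >= speck.x2 + 2
                    or speck.y >= b.y2 + 2 or b.y >= speck.y2 + 2) for b in boxes):
            continue
        if render:
            grey = rng_tex.uniform(60, 150)
            _render_ellipse(img, speck, (grey, grey * 0.95, grey * 0.8), rng_tex)
    pixels = np.clip(img, 0, 255).astype(np.uint8) if render else None
    return AnnotatedImage(
        image_id=f"scene_{seed}", width=n, height=n, boxes=boxes,
        pixels=pixels, class_names=tuple(cfg.classes),
        source={"generator": "synthetic_stickytrap", "seed": int(seed)},
    ).validate()


def _image_seed(dataset_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=int(dataset_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_scenes(cfg: SceneConfig, n_images: int, seed: int,
                    render: bool = True):
    """In-memory dataset: list of scenes with per-image derived seeds."""
    return [generate_scene(cfg, _image_seed(seed, i), render)
            for i in range(n_images)]


def generate_dataset(cfg: SceneConfig, n_images: int, seed: int, out_dir: str,
                     split_fractions: tuple = (0.7, 0.15, 0.15),
                     force: bool = False) -> dict:
    """Write images (PNG), VOC XML, YOLO txt and a JSON manifest.

    Splits follow the floor rule: n_train = floor(n * f_train),
    n_val = floor(n * f_val), remainder to test.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    os.makedirs(out_dir, exist_ok=True)
    if os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} is not empty (use force=True to overwrite)")
    n_train = int(np.floor(n_images * split_fractions[0]))
    n_val = int(np.floor(n_images * split_fractions[1]))
    records = []
    for i in range(n_images):
        s = _image_seed(seed, i)
        scene = generate_scene(cfg, s)
        scene.image_id = f"img_{i:05d}"
        split = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
        png = os.path.join(out_dir, f"{scene.image_id}.png")
        xml = os.path.join(out_dir, f"{scene.image_id}.xml")
        txt = os.path.join(out_dir, f"{scene.image_id}.txt")
        scene.save_image(png)
        write_voc_xml(scene, xml, image_filename=os.path.basename(png))
        write_yolo_txt(scene, txt)
        records.append({
            "id": scene.image_id, "split": split, "seed": s,
            "png": os.path.basename(png), "xml": os.path.basename(xml),
            "txt": os.path.basename(txt), "n_boxes": len(scene.boxes),
        })
    manifest = {
        "classes": list(cfg.classes),
        "image_size": cfg.image_size,
        "dataset_seed": int(seed),
        "n_images": n_images,
        "split_fractions": list(split_fractions),
        "images": records,
    }
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def dataset_size_stats(manifest_path: str) -> dict:
    """Per-class and per-size-class counts/fractions for a written dataset."""
    from .data.annotations import read_voc_xml

    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = os.path.dirname(os.path.abspath(manifest_path))
    by_class = {name: 0 for name in manifest["classes"]}
    by_size = {s.value: 0 for s in SizeClass}
    total = 0
    for rec in manifest["images"]:
        img = read_voc_xml(os.path.join(root, rec["xml"]), load_image=False,
                           class_names=tuple(manifest["classes"]))
        for b in img.boxes:
            by_class[manifest["classes"][b.class_id]] += 1
            by_size[size_class(b).value] += 1
            total += 1
    frac_size = {k: (v / total if total else 0.0) for k, v in by_size.items()}
    tiny_overall = (frac_size["very_tiny"] + frac_size["tiny"])
    return {
        "total_boxes": total,
        "by_class": by_class,
        "by_size": by_size,
        "fractions": frac_size,
        "tiny_overall_fraction": tiny_overall,
    }
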