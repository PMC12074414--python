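"""Seeded synthetic crown-scene generator in PASCAL-VOC2012 layout.

Emulates the structure of the study imagery — 1:1 RGB orthophoto tiles of a
planted mixed forest with two target species over a soil/grass background,
occasionally crossed by a road — so that training, inference, quantisation
and evaluation can all be exercised without the original UAV data.  The
generator makes no claim of radiometric realism: crowns are irregular
quasi-circular blobs (unions of jittered disks) with class-specific colour
and texture, which is enough to pose a learnable three-class segmentation
problem with the right dataset shape.

Dataset conventions mirror the study: 100-tile datasets split 7:3 into
train/validation with the two species equally represented (each tile is
dominated by one species, and some conifer tiles carry a road stripe), plus
an independent, disjointly seeded hold-out test set.  Everything is fully
deterministic under a master seed: one seed sequence spawns per-tile child
seeds, so regenerating a dataset — or extending it — never reshuffles
existing tiles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import voc

__all__ = [
    "CrownColorModel",
    "BackgroundModel",
    "SceneConfig",
    "generate_scene",
    "generate_dataset",
    "holdout_testset",
]

_TRAINVAL_STREAM = 0
_TEST_STREAM = 1


@dataclass(frozen=True)
class CrownColorModel:
    """Mean RGB of a species' crowns plus per-crown jitter and texture.

    ``texture_scale`` is the side (pixels) of the blocks of the blocky
    per-pixel noise: 1 gives fine, high-frequency texture (conifer), larger
    values a smoother canopy (broadleaf).
    """

    mean_rgb: tuple[float, float, float]
    jitter: float = 12.0  # sd of the per-crown mean-colour offset
    texture_amp: float = 14.0  # sd of per-pixel texture noise
    texture_scale: int = 1
    edge_darkening: float = 0.35  # radial brightness falloff toward the rim


@dataclass(frozen=True)
class BackgroundModel:
    """Soil/grass base with low-frequency patchiness and an optional road."""

    mean_rgb: tuple[float, float, float] = (136.0, 122.0, 96.0)
    patch_amp: float = 10.0
    patch_scale: int = 16
    pixel_noise: float = 4.0
    road_rgb: tuple[float, float, float] = (168.0, 166.0, 160.0)
    road_prob: float = 0.25
    road_width_frac: float = 0.12


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic crown-scene simulator."""

    tile_size: int = 512
    crowns_per_class: tuple[int, int] = (4, 9)  # inclusive range per tile
    radius_range: Optional[tuple[float, float]] = None  # pixels; default 8–18% of tile
    conifer: CrownColorModel = field(
        default_factory=lambda: CrownColorModel(
            mean_rgb=(38.0, 74.0, 40.0), texture_amp=16.0, texture_scale=1
        )
    )
    broadleaf: CrownColorModel = field(
        default_factory=lambda: CrownColorModel(
            mean_rgb=(118.0, 152.0, 62.0), texture_amp=10.0, texture_scale=4
        )
    )
    background: BackgroundModel = field(default_factory=BackgroundModel)
    #: learnability guarantee: minimum Euclidean distance between the two
    #: species' mean colours
    min_class_color_distance: float = 60.0
    #: distribution-shift knob: scales all jitter/texture amplitudes
    jitter_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.tile_size < 16:
            raise ValueError("tile_size must be at least 16")
        lo, hi = self.crowns_per_class
        if lo < 0 or hi < lo:
            raise ValueError("crowns_per_class must be a (lo, hi) range, 0 <= lo <= hi")
        r = self.radii
        if r[0] <= 0 or r[1] < r[0]:
            raise ValueError("radius_range must be positive and ordered")
        if r[1] >= self.tile_size:
            raise ValueError(
                f"crown radius {r[1]} does not fit in a {self.tile_size}px tile"
            )
        d = float(
            np.linalg.norm(
                np.subtract(self.conifer.mean_rgb, self.broadleaf.mean_rgb)
            )
        )
        if d < self.min_class_color_distance:
            raise ValueError(
                f"class mean colours only {d:.1f} apart; "
                f"minimum is {self.min_class_color_distance}"
            )

    @property
    def radii(self) -> tuple[float, float]:
        if self.radius_range is not None:
            return self.radius_range
        return (0.08 * self.tile_size, 0.18 * self.tile_size)

    def shifted(self, jitter_scale: float) -> "SceneConfig":
        """Config with all colour jitter scaled — a domain-shift test knob."""
        return replace(self, jitter_scale=jitter_scale)


def _block_noise(rng: np.random.Generator, size: int, scale: int, amp: float) -> np.ndarray:
    """Blocky noise field: iid normal cells of side ``scale`` pixels."""
    if amp == 0:
        return np.zeros((size, size))
    n = -(-size // scale)  # ceil
    coarse = rng.normal(0.0, amp, size=(n, n))
    return np.kron(coarse, np.ones((scale, scale)))[:size, :size]


def _paint_crown(
    rng: np.random.Generator,
    img: np.ndarray,
    mask: np.ndarray,
    label: int,
    model: CrownColorModel,
    radius: float,
    jitter_scale: float,
) -> None:
    size = mask.shape[0]
    cx, cy = rng.uniform(0, size, size=2)
    # union of jittered disks -> irregular quasi-circular blob
    n_disks = rng.integers(3, 8)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    inside = np.zeros((size, size), dtype=bool)
    dist = np.full((size, size), np.inf)
    for _ in range(n_disks):
        ox, oy = rng.normal(0.0, 0.30 * radius, size=2)
        r = radius * rng.uniform(0.45, 0.85)
        d = np.hypot(xx - (cx + ox), yy - (cy + oy))
        inside |= d <= r
        dist = np.minimum(dist, d / r)
    if not inside.any():
        return
    base = np.asarray(model.mean_rgb) + rng.normal(
        0.0, model.jitter * jitter_scale, size=3
    )
    texture = np.stack(
        [
            _block_noise(rng, size, model.texture_scale, model.texture_amp * jitter_scale)
            for _ in range(3)
        ],
        axis=-1,
    )
    shade = 1.0 - model.edge_darkening * np.clip(dist, 0.0, 1.0)
    colors = base[None, None, :] * shade[:, :, None] + texture
    img[inside] = colors[inside]
    mask[inside] = label  # later crowns occlude earlier ones


def _paint_background(
    rng: np.random.Generator, cfg: SceneConfig, with_road: bool
) -> np.ndarray:
    size = cfg.tile_size
    bg = cfg.background
    img = np.empty((size, size, 3), dtype=np.float64)
    patches = _block_noise(rng, size, bg.patch_scale, bg.patch_amp)
    for ch in range(3):
        img[:, :, ch] = (
            bg.mean_rgb[ch]
            + patches
            + rng.normal(0.0, bg.pixel_noise, size=(size, size))
        )
    if with_road:
        width = max(2, int(bg.road_width_frac * size))
        pos = rng.integers(0, size - width + 1)
        horizontal = rng.random() < 0.5
        road = slice(pos, pos + width)
        noise = rng.normal(0.0, bg.pixel_noise, size=(width, size, 3))
        if horizontal:
            img[road, :, :] = np.asarray(bg.road_rgb)[None, None, :] + noise
        else:
            img[:, road, :] = np.asarray(bg.road_rgb)[None, None, :] + noise.transpose(1, 0, 2)
    return img


def generate_scene(
    cfg: SceneConfig,
    seed,
    species: Optional[int] = None,
    with_road: Optional[bool] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One (RGB uint8 tile, label mask) pair, deterministic under (cfg, seed).

    ``species`` restricts the tile to one crown class (1 conifer,
    2 broadleaf) as in the study's single-species plots; ``None`` mixes
    both.  ``with_road`` forces the road stripe on or off; ``None`` draws it
    with the configured probability.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    if with_road is None:
        with_road = rng.random() < cfg.background.road_prob
    else:
        rng.random()  # keep the stream aligned either way
    img = _paint_background(rng, cfg, with_road)
    mask = np.zeros((cfg.tile_size, cfg.tile_size), dtype=np.uint8)

    lo, hi = cfg.crowns_per_class
    classes = [species] if species in (1, 2) else [1, 2]
    plan: list[tuple[int, float]] = []
    for label in classes:
        count = int(rng.integers(lo, hi + 1))
        radii = rng.uniform(*cfg.radii, size=count)
        plan.extend((label, float(r)) for r in radii)
    rng.shuffle(plan)  # interleave so occlusion is not biased by class
    for label, radius in plan:
        model = cfg.conifer if label == 1 else cfg.broadleaf
        _paint_crown(rng, img, mask, label, model, radius, cfg.jitter_scale)

    return np.clip(img, 0, 255).astype(np.uint8), mask


def _tile_plan(n_tiles: int, prefix: str) -> list[tuple[str, int]]:
    """(tile id, species) for a class-balanced dataset."""
    return [
        (f"{prefix}_{i:04d}", 1 + i % 2)
        for i in range(n_tiles)
    ]


def _child_seeds(master_seed: int, stream: int, n: int) -> list[int]:
    ss = np.random.SeedSequence([int(master_seed), stream])
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tiles(
    cfg: SceneConfig, out_dir: Path, plan, seeds, splits: dict[str, list[str]]
) -> dict:
    img_dir = out_dir / "JPEGImages"
    mask_dir = out_dir / "SegmentationClass"
    split_dir = out_dir / "ImageSets" / "Segmentation"
    for d in (img_dir, mask_dir, split_dir):
        d.mkdir(parents=True, exist_ok=True)

    tiles = []
    for (tile_id, species), seed in zip(plan, seeds):
        rgb, mask = generate_scene(cfg, seed, species=species)
        jpg = img_dir / f"{tile_id}.jpg"
        png = mask_dir / f"{tile_id}.png"
        voc.write_image(rgb, jpg)
        voc.write_mask(mask, png)
        tiles.append(
            {
                "id": tile_id,
                "seed": seed,
                "species": species,
                "image_sha256": _sha256(jpg),
                "mask_sha256": _sha256(png),
            }
        )
    for name, ids in splits.items():
        voc.write_split(ids, split_dir / f"{name}.txt")

    manifest = {
        "config": asdict(cfg),
        "tiles": tiles,
        "splits": {k: len(v) for k, v in splits.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def generate_dataset(
    cfg: SceneConfig, n_tiles: int, out_dir: Path | str, seed: int, train_frac: float = 0.7
) -> dict:
    """Write a class-balanced train/validation dataset in VOC2012 layout.

    Tiles alternate between the two species; within each species the first
    ``train_frac`` of tiles go to the training split, giving the study's 7:3
    partition (100 tiles -> 70 train / 30 val, 50 tiles per species).
    """
    if n_tiles < 10:
        raise ValueError("need at least 10 tiles for a meaningful split")
    out_dir = Path(out_dir)
    plan = _tile_plan(n_tiles, "tile")
    seeds = _child_seeds(seed, _TRAINVAL_STREAM, n_tiles)

    train, val = [], []
    per_class: dict[int, int] = {1: 0, 2: 0}
    counts = {1: sum(1 for _, s in plan if s == 1), 2: sum(1 for _, s in plan if s == 2)}
    for tile_id, species in plan:
        k = per_class[species]
        per_class[species] += 1
        (train if k < int(counts[species] * train_frac) else val).append(tile_id)

    return _write_tiles(cfg, out_dir, plan, seeds, {"train": train, "val": val})


def holdout_testset(cfg: SceneConfig, n_tiles: int, out_dir: Path | str, seed: int) -> dict:
    """Write an independent test set from a disjoint child-seed stream.

    The test stream never shares RNG state with the train/validation stream
    derived from the same master seed, mirroring the study's geographically
    separate test plot.
    """
    if n_tiles < 10:
        raise ValueError("need at least 10 tiles")
    out_dir = Path(out_dir)
    plan = _tile_plan(n_tiles, "test")
    seeds = _child_seeds(seed, _TEST_STREAM, n_tiles)
    return _write_tiles(cfg, out_dir, plan, seeds, {"test": [tid for tid, _ in plan]})
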