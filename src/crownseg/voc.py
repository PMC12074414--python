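"""PASCAL-VOC2012-style dataset I/O: indexed-colour masks, JPEG tiles, splits.

A dataset directory follows the VOC layout exactly::

    <root>/JPEGImages/<id>.jpg
    <root>/SegmentationClass/<id>.png      (palette PNG, pixel value = label)
    <root>/ImageSets/Segmentation/train.txt / val.txt / test.txt

Label masks are 8-bit palette PNGs whose pixel values are the class labels
themselves, so reading a mask back is lossless.  The palette renders class 1
(conifer) green and class 2 (broadleaf) red in any image viewer; the
remaining entries follow the standard VOC palette generator so third-party
VOC tooling displays the files sensibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from PIL import Image

__all__ = [
    "voc_palette",
    "write_mask",
    "read_mask",
    "write_image",
    "read_image",
    "write_split",
    "read_split",
    "VocDataset",
]


def voc_palette() -> list[int]:
    """768-entry flat RGB palette; indices 0/1/2 are black/green/red."""
    pal = np.zeros((256, 3), dtype=np.uint8)
    for i in range(256):
        c, v = i, 0
        for bit in range(8):
            pal[i, 0] |= ((c >> 0) & 1) << (7 - bit)
            pal[i, 1] |= ((c >> 1) & 1) << (7 - bit)
            pal[i, 2] |= ((c >> 2) & 1) << (7 - bit)
            c >>= 3
            v += 1
    pal[1] = (0, 128, 0)  # conifer: green overlay
    pal[2] = (128, 0, 0)  # broadleaf: red overlay
    return pal.ravel().tolist()


_PALETTE = None


def _palette() -> list[int]:
    global _PALETTE
    if _PALETTE is None:
        _PALETTE = voc_palette()
    return _PALETTE


def write_mask(mask: np.ndarray, path: Path | str) -> None:
    """Write a label mask as an indexed-colour (palette) PNG."""
    arr = np.asarray(mask, dtype=np.uint8)
    img = Image.fromarray(arr, mode="P")
    img.putpalette(_palette())
    img.save(path, format="PNG")


def read_mask(path: Path | str) -> np.ndarray:
    """Read a palette PNG back into a label array (uint8)."""
    with Image.open(path) as img:
        if img.mode != "P":
            raise ValueError(f"{path}: expected an indexed-colour mask")
        return np.asarray(img, dtype=np.uint8)


def write_image(rgb: np.ndarray, path: Path | str, quality: int = 95) -> None:
    """Write an (H, W, 3) uint8 RGB tile as JPEG."""
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(
        path, format="JPEG", quality=quality
    )


def read_image(path: Path | str) -> np.ndarray:
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"), dtype=np.uint8)


def write_split(ids: Iterable[str], path: Path | str) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def read_split(path: Path | str) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


@dataclass
class VocDataset:
    """In-memory view of a VOC-layout segmentation dataset."""

    root: Path
    splits: dict[str, list[str]]

    @classmethod
    def load(cls, root: Path | str) -> "VocDataset":
        root = Path(root)
        split_dir = root / "ImageSets" / "Segmentation"
        if not split_dir.is_dir():
            raise FileNotFoundError(f"{root} is not a VOC-layout dataset")
        splits = {
            p.stem: read_split(p) for p in sorted(split_dir.glob("*.txt"))
        }
        return cls(root, splits)

    def ids(self, split: str) -> list[str]:
        if split not in self.splits:
            raise KeyError(f"no split {split!r}; have {sorted(self.splits)}")
        if not self.splits[split]:
            raise ValueError(f"split {split!r} is empty")
        return self.splits[split]

    def image(self, tile_id: str) -> np.ndarray:
        return read_image(self.root / "JPEGImages" / f"{tile_id}.jpg")

    def mask(self, tile_id: str) -> np.ndarray:
        return read_mask(self.root / "SegmentationClass" / f"{tile_id}.png")

    def pair(self, tile_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(image as float32 CHW in [0,1], label mask) ready for the engines."""
        img = self.image(tile_id).astype(np.float32) / 255.0
        return np.ascontiguousarray(img.transpose(2, 0, 1)), self.mask(tile_id)

    def manifest(self) -> dict:
        path = self.root / "manifest.json"
        return json.loads(path.read_text()) if path.exists() else {}
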