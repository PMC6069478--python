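"""Imagery and label-map I/O, frame tiling, and dataset splitting.

Full survey frames (e.g. 4000 x 3000) are cut into non-overlapping square
tiles in row-major order, dropping partial border regions, so a 4000 x 3000
frame yields 12 tiles of 1000 x 1000 and 91 frames yield 1092.  Label maps
travel as single-channel indexed PNG with palette 0 = others, 1 = rice,
2 = weeds; imagery as 8-bit RGB PNG or TIFF.  Both round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

N_CLASSES = 3
GT_PALETTE = [0, 0, 0, 0, 200, 0, 220, 40, 40]  # others black, rice green, weeds red


class ImageFormatError(ValueError):
    """Raised when a file does not match the expected 8-bit RGB / indexed layout."""


@dataclass
class Tile:
    image: np.ndarray                 # (side, side, 3) uint8
    gt: np.ndarray | None             # (side, side) labels, or None
    origin: tuple[int, int]           # (row, col) pixel offset in the source frame
    source_id: str = ""


@dataclass
class DatasetSplit:
    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    seed: int = 0


def tile_image(
    image: np.ndarray,
    gt: np.ndarray | None = None,
    tile_side: int = 1000,
    source_id: str = "",
) -> list[Tile]:
    """Cut a frame into non-overlapping tile_side x tile_side regions.

    Tiles enumerate in row-major order; partial border strips are dropped, so
    the count is floor(H / s) * floor(W / s).  A frame smaller than one tile
    in either dimension yields an empty list.
    """
    if tile_side < 1:
        raise ValueError(f"tile_side must be >= 1, got {tile_side}")
    h, w = image.shape[:2]
    if gt is not None and gt.shape[:2] != (h, w):
        raise ValueError(f"gt shape {gt.shape[:2]} does not match image {image.shape[:2]}")
    tiles = []
    for r in range(h // tile_side):
        for c in range(w // tile_side):
            r0, c0 = r * tile_side, c * tile_side
            tiles.append(
                Tile(
                    image=image[r0 : r0 + tile_side, c0 : c0 + tile_side],
                    gt=None if gt is None else gt[r0 : r0 + tile_side, c0 : c0 + tile_side],
                    origin=(r0, c0),
                    source_id=source_id,
                )
            )
    return tiles


def split_dataset(ids: list, validation_fraction: float, seed: int) -> DatasetSplit:
    """Random unstratified train/validation split, deterministic given seed.

    The validation size is round(n * fraction): a 200/1092 fraction on 1092
    samples reproduces the canonical 892/200 partition exactly.
    """
    n = len(ids)
    if n < 2:
        raise ValueError(f"need at least 2 samples to split, got {n}")
    if not (0.0 < validation_fraction < 1.0):
        raise ValueError(f"validation_fraction must be in (0, 1), got {validation_fraction}")
    n_val = int(round(n * validation_fraction))
    n_val = min(max(n_val, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    val_idx = set(perm[:n_val].tolist())
    return DatasetSplit(
        train=[ids[i] for i in range(n) if i not in val_idx],
        validation=[ids[i] for i in sorted(val_idx)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# file round-trips
# ---------------------------------------------------------------------------

def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an (H, W, 3) uint8 array as PNG or TIFF (by extension)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ImageFormatError(f"expected (H, W, 3) uint8 image, got {image.shape} {image.dtype}")
    Image.fromarray(image, mode="RGB").save(str(path))


def read_image(path: str | Path) -> np.ndarray:
    with Image.open(str(path)) as im:
        if im.mode != "RGB":
            if im.mode in ("I", "I;16", "I;16B", "F"):
                raise ImageFormatError(f"{path}: not 8-bit (mode {im.mode})")
            raise ImageFormatError(f"{path}: expected 3-channel RGB, got mode {im.mode}")
        arr = np.asarray(im)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"{path}: expected 3 channels, got shape {arr.shape}")
    return arr


def write_gt(path: str | Path, gt: np.ndarray) -> None:
    """Write a label map as single-channel indexed PNG (palette 0/1/2)."""
    gt = np.asarray(gt)
    if gt.ndim != 2:
        raise ImageFormatError(f"label map must be 2-D, got shape {gt.shape}")
    if gt.min() < 0 or gt.max() >= N_CLASSES:
        raise ImageFormatError(
            f"label values outside {{0..{N_CLASSES - 1}}}: range [{gt.min()}, {gt.max()}]"
        )
    im = Image.fromarray(gt.astype(np.uint8), mode="P")
    im.putpalette(GT_PALETTE + [0] * (768 - len(GT_PALETTE)))
    im.save(str(path))


def read_gt(path: str | Path) -> np.ndarray:
    with Image.open(str(path)) as im:
        if im.mode not in ("P", "L"):
            raise ImageFormatError(f"{path}: expected indexed/grayscale label map, got mode {im.mode}")
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: label map must be single-channel, got shape {arr.shape}")
    bad = np.unique(arr[(arr < 0) | (arr >= N_CLASSES)])
    if bad.size:
        raise ImageFormatError(f"{path}: out-of-range label values {bad.tolist()} (allowed 0..{N_CLASSES - 1})")
    return arr.astype(np.uint8)
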