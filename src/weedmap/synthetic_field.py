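"""Synthetic paddy-field scenes with exact pixel-level ground truth.

Emulates early-tillering rice sown in rows and naturally infested with grassy
weeds, as seen from a low-altitude UAV: three classes (0 = others — soil and
water between rows, 1 = rice, 2 = weeds), row-structured crop canopy,
irregular weed patches from large blobs down to a few pixels, green color
distributions that overlap between rice and weeds, low-frequency canopy
texture and per-pixel sensor noise.

Geometry is desk-scaled: the default 256 x 256 tile with a 42-pixel row
period corresponds to 50 cm row spacing at roughly 1.2 cm ground sampling
distance (a 4x coarsening of a 0.3 cm/px survey, where the same rows repeat
every ~167 px on a 1000 x 1000 tile).

All randomness flows from ``SceneConfig.seed`` — two calls with the same
config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as _draw_ellipse


class SceneConfigError(ValueError):
    """Raised when a scene configuration violates its invariants."""


@dataclass(frozen=True)
class SceneConfig:
    height: int = 256
    width: int = 256
    n_classes: int = 3
    row_period: int = 42
    row_width: int = 16
    weed_patch_count_range: tuple[int, int] = (6, 14)
    weed_patch_radius_range: tuple[float, float] = (2.0, 18.0)
    class_color_means: tuple[tuple[int, int, int], ...] = (
        (96, 78, 58),   # others: wet soil / water
        (62, 112, 54),  # rice canopy
        (80, 128, 48),  # weeds: greener / yellower, overlapping rice
    )
    color_noise_sd: float = 8.0
    texture_scale: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 16 or self.width < 16:
            raise SceneConfigError(f"tile must be at least 16 x 16, got {self.height} x {self.width}")
        if not (self.row_period > self.row_width > 0):
            raise SceneConfigError(
                f"need row_period > row_width > 0, got period {self.row_period}, width {self.row_width}"
            )
        if self.n_classes != 3:
            raise SceneConfigError("exactly 3 classes (others, rice, weeds) are supported")
        lo, hi = self.weed_patch_count_range
        if lo < 0 or hi < lo:
            raise SceneConfigError(f"bad weed_patch_count_range {self.weed_patch_count_range}")
        rlo, rhi = self.weed_patch_radius_range
        if hi > 0 and (rlo <= 0 or rhi < rlo):
            raise SceneConfigError(f"bad weed_patch_radius_range {self.weed_patch_radius_range}")
        if len(self.class_color_means) != 3:
            raise SceneConfigError("class_color_means must give 3 RGB triplets")
        means = [tuple(m) for m in self.class_color_means]
        if len(set(means)) != 3:
            raise SceneConfigError("class color means must be pairwise distinct")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class SceneSample:
    """An RGB tile with its pixel-aligned ground-truth label map.

    ``meta`` records provenance (seed, config hash) plus the weed-patch
    placement log: one entry per placed patch listing its ellipse primitives,
    so tests can re-rasterize individual patches.
    """

    image: np.ndarray  # (H, W, 3) uint8
    gt: np.ndarray     # (H, W) uint8 in {0, 1, 2}
    meta: dict = field(default_factory=dict)


def _rasterize_patch(patch: dict, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of one weed patch from its logged ellipse primitives."""
    mask = np.zeros(shape, dtype=bool)
    for e in patch["ellipses"]:
        rr, cc = _draw_ellipse(
            e["r"], e["c"], e["r_radius"], e["c_radius"], shape=shape, rotation=e["rotation"]
        )
        mask[rr, cc] = True
    # close small concavities so the blob reads as one organic patch
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3)), iterations=2)
    return mask


def _rice_mask(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Vertical periodic crop rows with smooth lateral jitter."""
    h, w = cfg.height, cfg.width
    phase = rng.uniform(0, cfg.row_period)
    # smooth per-scanline jitter of the row centers (sub-row-width amplitude)
    jitter = ndimage.gaussian_filter1d(rng.normal(0, 1, h), sigma=12, mode="reflect")
    amp = jitter.std() or 1.0
    jitter = jitter / amp * (cfg.row_width / 5.0)
    xx = np.arange(w)[None, :] - phase - jitter[:, None]
    frac = np.mod(xx, cfg.row_period)
    return frac < cfg.row_width


def _weed_patches(
    cfg: SceneConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[dict]]:
    h, w = cfg.height, cfg.width
    lo, hi = cfg.weed_patch_count_range
    n_patches = int(rng.integers(lo, hi + 1))
    mask = np.zeros((h, w), dtype=bool)
    log: list[dict] = []
    for _ in range(n_patches):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        radius = rng.uniform(*cfg.weed_patch_radius_range)
        n_ell = int(rng.integers(2, 6))
        ellipses = []
        for _ in range(n_ell):
            ellipses.append(
                {
                    "r": float(cy + rng.normal(0, radius / 3)),
                    "c": float(cx + rng.normal(0, radius / 3)),
                    "r_radius": float(rng.uniform(0.45, 1.0) * radius),
                    "c_radius": float(rng.uniform(0.45, 1.0) * radius),
                    "rotation": float(rng.uniform(-np.pi / 2, np.pi / 2)),
                }
            )
        patch = {"center": (float(cy), float(cx)), "radius": float(radius), "ellipses": ellipses}
        pmask = _rasterize_patch(patch, (h, w))
        if not pmask.any():
            continue  # fully outside the tile
        mask |= pmask
        log.append(patch)
    return mask, log


def generate_scene(config: SceneConfig) -> SceneSample:
    """Render one labeled tile; deterministic given ``config.seed``.

    Rice rows are painted first; weed patches are unions of random ellipses
    (morphologically closed) and overwrite whatever they cover, so weeds occur
    both between and inside the rows.  The label map is exact by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width

    gt = np.zeros((h, w), dtype=np.uint8)
    gt[_rice_mask(config, rng)] = 1
    weed_mask, patch_log = _weed_patches(config, rng)
    gt[weed_mask] = 2

    means = np.asarray(config.class_color_means, dtype=np.float64)
    image = means[gt]  # (H, W, 3)
    # low-frequency canopy/soil texture, then white sensor noise
    texture = ndimage.gaussian_filter(
        rng.normal(0, 1, (h, w, 3)), sigma=(config.texture_scale, config.texture_scale, 0)
    )
    tsd = texture.std(axis=(0, 1), keepdims=True)
    tsd[tsd == 0] = 1.0
    image = image + texture / tsd * config.color_noise_sd
    image = image + rng.normal(0, config.color_noise_sd / 2, (h, w, 3))
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    meta = {
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "patch_log": patch_log,
    }
    return SceneSample(image=image, gt=gt, meta=meta)


def generate_dataset(
    n: int,
    config: SceneConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[SceneSample], pd.DataFrame]:
    """Generate ``n`` scenes with per-sample seeds derived from a master seed.

    Returns the samples and a manifest (path_image, path_gt, seed).  If
    ``out_dir`` is given, images and label maps are written there as PNG and
    the manifest as ``manifest.csv``; otherwise the path columns hold the
    would-be file names.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 samples, got {n}")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    samples = []
    rows = []
    from . import imagery_io  # local import to avoid a cycle at import time

    for i, child in enumerate(child_seeds):
        cfg_i = SceneConfig(**{**asdict(config), "seed": child})
        sample = generate_scene(cfg_i)
        samples.append(sample)
        img_name = f"scene_{i:04d}.png"
        gt_name = f"scene_{i:04d}_gt.png"
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            imagery_io.write_image(out / img_name, sample.image)
            imagery_io.write_gt(out / gt_name, sample.gt)
        rows.append({"path_image": img_name, "path_gt": gt_name, "seed": child})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return samples, manifest
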