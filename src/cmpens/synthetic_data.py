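"""Synthetic micrographs, ground-truth masks, CMP stacks and patch datasets.

The generator emulates the statistical shape of H&E nucleus-segmentation
data without attempting photorealism: compact elliptical "cells" (nucleus
purple) sparse on a textured pinkish background, so that true negatives
dominate (|TP| << |TN|), plus per-pixel ensembles of class-membership
probabilities whose histograms are narrow away from object boundaries and
may be skewed or heavy-tailed, as real ensemble CMP histograms are.

Per-pixel CMP ensembles are built from a base probability map p0 — a
sigmoid of the signed distance to the nearest object boundary (p0 = 0.5 on
the boundary, -> 1 inside, -> 0 outside) — plus independent per-member noise
from a configurable family, clipped to [0, 1].  The clipped fraction is
recorded per pixel so distribution-shape checks can exclude saturated pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .aggregation import CMPStack

__all__ = [
    "SceneConfig",
    "NoiseConfig",
    "PatchDataset",
    "generate_micrograph",
    "generate_cmp_stack",
    "make_patch_dataset",
    "valid_center_bounds",
]


@dataclass(frozen=True)
class SceneConfig:
    """Recipe for one synthetic micrograph.

    ``fg_fraction_target`` drives placement: cells are added (up to
    ``max_cells``, rejecting overlaps) until the realized foreground fraction
    reaches the target.  The target must stay below 0.5 to preserve the
    background-dominated regime of real micrographs.
    """

    height: int = 128
    width: int = 128
    max_cells: int = 400
    radius_range: tuple[float, float] = (5.0, 11.0)
    fg_fraction_target: float = 0.15
    texture_amplitude: float = 0.035
    cell_color: tuple[float, float, float] = (0.42, 0.28, 0.55)  # nucleus purple
    background_color: tuple[float, float, float] = (0.87, 0.74, 0.83)  # eosin pink
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fg_fraction_target < 0.5):
            raise ValueError("fg_fraction_target must be in (0, 0.5)")
        if self.radius_range[0] <= 1.0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("invalid radius_range")


@dataclass(frozen=True)
class NoiseConfig:
    """Recipe for a synthetic CMP stack on top of a ground-truth mask.

    ``sharpness`` is the logistic slope (per pixel of signed boundary
    distance) of the base probability map; larger values mean better-trained
    members with narrower boundary bands.  ``scale`` is the per-member noise
    standard deviation (for the alpha_stable family, its scale parameter).
    """

    n_members: int = 100
    sharpness: float = 1.0
    family: str = "gaussian"  # gaussian | skewed | alpha_stable
    scale: float = 0.08
    skew_direction: int = 1
    stable_alpha: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.family not in ("gaussian", "skewed", "alpha_stable"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.skew_direction not in (-1, 1):
            raise ValueError("skew_direction must be -1 or +1")


@dataclass
class PatchDataset:
    """Center positions + labels for patch classification.

    ``patches`` is n x P x P x 3 (float32), ``labels`` the binary class of
    each patch's center pixel.  ``source_image`` records which scene each
    patch came from, for per-tissue bookkeeping.
    """

    patches: np.ndarray
    labels: np.ndarray
    positions: np.ndarray
    source_image: np.ndarray
    split: str = "train"

    def __post_init__(self) -> None:
        if len(self.patches) != len(self.labels):
            raise ValueError("patches and labels length mismatch")

    def __len__(self) -> int:
        return len(self.patches)

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def generate_micrograph(cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate one synthetic H&E-like image and its binary cell mask.

    Non-overlapping ellipses are placed by rejection sampling until the
    foreground-fraction target is met; deterministic given ``cfg.seed``.
    Raises if the packing target cannot be reached in a bounded number of
    attempts (too many / too large cells for the canvas).
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    mask = np.zeros((h, w), dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    placed: list[tuple[float, float, float]] = []  # (cy, cx, bounding radius)
    target_px = cfg.fg_fraction_target * h * w
    attempts, max_attempts = 0, 200 * cfg.max_cells
    n_cells = 0
    while mask.sum() < target_px and n_cells < cfg.max_cells:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "infeasible packing: could not reach foreground fraction "
                f"{cfg.fg_fraction_target} after {max_attempts} attempts"
            )
        ra, rb = rng.uniform(*cfg.radius_range, size=2)
        theta = rng.uniform(0, np.pi)
        rmax = max(ra, rb)
        cy = rng.uniform(rmax, h - rmax)
        cx = rng.uniform(rmax, w - rmax)
        if any((cy - py) ** 2 + (cx - px) ** 2 < (rmax + pr + 1.0) ** 2 for py, px, pr in placed):
            continue
        ct, st = np.cos(theta), np.sin(theta)
        u = (yy - cy) * ct + (xx - cx) * st
        v = -(yy - cy) * st + (xx - cx) * ct
        mask[(u / ra) ** 2 + (v / rb) ** 2 <= 1.0] = 1
        placed.append((cy, cx, rmax))
        n_cells += 1

    image = np.empty((h, w, 3), dtype=np.float32)
    fg = mask.astype(np.float32)[..., None]
    base = fg * np.asarray(cfg.cell_color, dtype=np.float32) + (1.0 - fg) * np.asarray(
        cfg.background_color, dtype=np.float32
    )
    texture = rng.normal(0.0, 1.0, size=(h, w, 3)).astype(np.float32)
    texture = ndimage.gaussian_filter(texture, sigma=(1.2, 1.2, 0.0))
    texture *= cfg.texture_amplitude / max(texture.std(), 1e-9)
    image[:] = np.clip(base + texture, 0.0, 1.0)
    return image, mask


def base_probability_map(mask: np.ndarray, sharpness: float) -> np.ndarray:
    """Sigmoid of signed boundary distance: 0.5 on the object boundary."""
    m = np.asarray(mask).astype(bool)
    if m.any() and not m.all():
        d_in = ndimage.distance_transform_edt(m)
        d_out = ndimage.distance_transform_edt(~m)
        signed = np.where(m, d_in - 0.5, -(d_out - 0.5))
    else:
        signed = np.where(m, 6.0, -6.0).astype(float)
    return 1.0 / (1.0 + np.exp(-sharpness * signed))


def generate_cmp_stack(mask: np.ndarray, cfg: NoiseConfig, image_id: str = "synthetic") -> CMPStack:
    """Simulate an M-member CMP stack for a ground-truth mask.

    Member values are clip(p0 + e_i, 0, 1) with e_i i.i.d. from the configured
    family (zero-centered; the ``skewed`` family is a shifted-scaled Beta with
    controllable skew sign).  The per-pixel clipped fraction is stored on the
    returned stack.
    """
    rng = np.random.default_rng(cfg.seed)
    p0 = base_probability_map(mask, cfg.sharpness)
    h, w = p0.shape
    shape = (h, w, cfg.n_members)
    if cfg.scale == 0.0:
        noise = np.zeros(shape)
    elif cfg.family == "gaussian":
        noise = rng.normal(0.0, cfg.scale, size=shape)
    elif cfg.family == "skewed":
        a_, b_ = 2.0, 5.0
        mean_b = a_ / (a_ + b_)
        std_b = np.sqrt(a_ * b_ / ((a_ + b_) ** 2 * (a_ + b_ + 1.0)))
        noise = cfg.skew_direction * (rng.beta(a_, b_, size=shape) - mean_b) * (cfg.scale / std_b)
    else:  # alpha_stable
        noise = (
            stats.levy_stable.rvs(cfg.stable_alpha, 0.0, size=shape, random_state=rng) * cfg.scale
        )
    raw = p0[..., None] + noise
    values = np.clip(raw, 0.0, 1.0)
    clip_fraction = (raw != values).mean(axis=2)
    return CMPStack(
        values=values.astype(np.float64),
        image_id=image_id,
        clip_fraction=clip_fraction,
    )


def valid_center_bounds(shape: tuple[int, int], patch_size: int) -> tuple[int, int, int, int]:
    """Inclusive row/col bounds (r0, r1, c0, c1) of valid patch centers."""
    half = patch_size // 2
    h, w = shape[:2]
    r1, c1 = h - 1 - half, w - 1 - half
    if r1 < half or c1 < half:
        raise ValueError(f"image {h}x{w} smaller than patch size {patch_size}")
    return half, r1, half, c1


def make_patch_dataset(
    images,
    masks,
    n: int,
    balance: str = "fg_bg",
    seed: int = 0,
    patch_size: int = 51,
) -> PatchDataset:
    """Sample n labeled patches without replacement across images.

    ``balance='per_image'`` spreads the draw as evenly as possible across the
    source images (the stand-in for equal tissue-class frequency);
    ``'fg_bg'`` additionally balances foreground- vs background-centered
    patches within each image; ``'none'`` samples uniformly.  Deterministic
    given ``seed``; raises (naming the available count) if n is too large.
    """
    if balance not in ("none", "per_image", "fg_bg"):
        raise ValueError(f"unknown balance policy {balance!r}")
    images = list(images)
    masks = list(masks)
    if len(images) != len(masks):
        raise ValueError("images and masks length mismatch")
    rng = np.random.default_rng(seed)
    n_img = len(images)
    per_img = [n // n_img + (1 if k < n % n_img else 0) for k in range(n_img)]

    all_patches, all_labels, all_pos, all_src = [], [], [], []
    for k, (img, msk) in enumerate(zip(images, masks)):
        r0, r1, c0, c1 = valid_center_bounds(msk.shape, patch_size)
        rows = np.arange(r0, r1 + 1)
        cols = np.arange(c0, c1 + 1)
        quota = per_img[k] if balance in ("per_image", "fg_bg") else None
        labels_grid = np.asarray(msk)[r0 : r1 + 1, c0 : c1 + 1]
        flat_labels = labels_grid.ravel()
        n_avail = flat_labels.size

        def _pick(pool: np.ndarray, count: int) -> np.ndarray:
            if count > pool.size:
                raise ValueError(
                    f"requested {count} patches from image {k} but only {pool.size} available"
                )
            return rng.choice(pool, size=count, replace=False)

        if balance == "fg_bg":
            fg_pool = np.flatnonzero(flat_labels == 1)
            bg_pool = np.flatnonzero(flat_labels == 0)
            n_fg = quota // 2
            n_bg = quota - n_fg
            chosen = np.concatenate([_pick(fg_pool, n_fg), _pick(bg_pool, n_bg)])
        elif balance == "per_image":
            chosen = _pick(np.arange(n_avail), quota)
        else:
            chosen = None  # handled globally below
        if chosen is not None:
            rr = rows[chosen // cols.size]
            cc = cols[chosen % cols.size]
            for r, c in zip(rr, cc):
                all_patches.append(_window(img, r, c, patch_size))
            all_labels.append(flat_labels[chosen])
            all_pos.append(np.stack([rr, cc], axis=1))
            all_src.append(np.full(chosen.size, k))

    if balance == "none":
        # one global pool over all images
        pools = []
        for k, msk in enumerate(masks):
            r0, r1, c0, c1 = valid_center_bounds(msk.shape, patch_size)
            n_avail = (r1 - r0 + 1) * (c1 - c0 + 1)
            pools.append(np.stack([np.full(n_avail, k), np.arange(n_avail)], axis=1))
        pool = np.concatenate(pools)
        if n > len(pool):
            raise ValueError(f"requested {n} patches but only {len(pool)} available")
        sel = rng.choice(len(pool), size=n, replace=False)
        for k, flat in pool[sel]:
            img, msk = images[k], masks[k]
            r0, r1, c0, c1 = valid_center_bounds(msk.shape, patch_size)
            ncols = c1 - c0 + 1
            r, c = r0 + flat // ncols, c0 + flat % ncols
            all_patches.append(_window(img, r, c, patch_size))
            all_labels.append(np.array([msk[r, c]]))
            all_pos.append(np.array([[r, c]]))
            all_src.append(np.array([k]))

    return PatchDataset(
        patches=np.stack(all_patches).astype(np.float32),
        labels=np.concatenate(all_labels).astype(np.int64),
        positions=np.concatenate(all_pos),
        source_image=np.concatenate(all_src),
    )


def _window(img: np.ndarray, r: int, c: int, patch_size: int) -> np.ndarray:
    half = patch_size // 2
    return np.asarray(img)[r - half : r + half + 1, c - half : c + half + 1]
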