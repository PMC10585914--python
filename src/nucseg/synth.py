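"""Synthetic H&E-like nuclei scenes with exact ground-truth instance masks.

Scenes emulate the structure of 256x256 H&E tiles: rotated elliptical
nuclei of varying size and eccentricity, optionally touching, rendered
through a two-stain Beer-Lambert model (high hematoxylin concentration
inside nuclei, an eosin-dominated textured background) with additive
Gaussian pixel noise.  Everything is a pure function of (config, seed), so
fixtures are regenerated identically at test time instead of being stored.

Also provides the training augmentations (horizontal/vertical flips,
random rotations, color jitter) applied consistently to image and label
map, and a fixture writer (PNG images, 16-bit TIFF label masks, JSON
manifest).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .stain import CANONICAL_HE_BASIS, od_to_rgb

__all__ = [
    "SceneConfig",
    "LabeledScene",
    "AugmentSpec",
    "DEFAULT_STAIN_BASIS",
    "generate_scene",
    "generate_dataset",
    "augment",
    "write_fixture_set",
    "load_fixture_set",
]

# unit-norm H&E optical-density directions (hematoxylin row, eosin row)
DEFAULT_STAIN_BASIS = CANONICAL_HE_BASIS.copy()


@dataclass(frozen=True)
class SceneConfig:
    """Generation parameters for one scene family.

    Defaults describe a 64x64 tile with 3-7 nuclei of 5-9 px radius, about
    a quarter of them placed touching a neighbour, and mild pixel noise --
    small but structurally faithful stand-ins for 256x256 H&E tiles.
    """

    height: int = 64
    width: int = 64
    n_nuclei: tuple[int, int] = (3, 7)
    radius_range: tuple[float, float] = (5.0, 9.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    min_center_distance: float = 16.0
    touch_fraction: float = 0.25
    noise_sd: float = 4.0
    hematoxylin_nucleus: float = 0.85
    hematoxylin_background: float = 0.06
    eosin_background: float = 0.35
    n_classes: int = 1
    stain_basis: tuple = tuple(map(tuple, DEFAULT_STAIN_BASIS))
    max_tries: int = 2000

    def __post_init__(self):
        if self.radius_range[0] <= 0:
            raise ValueError("radii must be positive")
        if not 0.0 <= self.touch_fraction <= 1.0:
            raise ValueError("touch_fraction must be a probability")
        ecc = self.eccentricity_range
        if not (0.0 <= ecc[0] <= ecc[1] < 1.0):
            raise ValueError("eccentricity_range must lie in [0, 1)")


@dataclass
class LabeledScene:
    image: np.ndarray                 # [H,W,3] uint8
    labels: np.ndarray                # [H,W] int32, 0 = background
    class_of: dict[int, int]


def _ellipse_mask(h, w, cy, cx, ry, rx, theta):
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_scene(config: SceneConfig, seed: int = 0) -> LabeledScene:
    """Render one scene; bit-identical for identical (config, seed)."""
    rng = np.random.default_rng(seed)
    h, w = config.height, config.width
    lo, hi = config.n_nuclei
    n = int(rng.integers(lo, hi + 1)) if hi > lo else int(lo)

    centers: list[tuple[float, float]] = []
    shapes = []
    tries = 0
    while len(shapes) < n:
        tries += 1
        if tries > config.max_tries:
            raise RuntimeError(
                "could not place all nuclei; use fewer or smaller nuclei "
                "or a lower min_center_distance"
            )
        r = rng.uniform(*config.radius_range)
        ecc = rng.uniform(*config.eccentricity_range)
        rx = r
        ry = r * np.sqrt(1.0 - ecc**2)
        theta = rng.uniform(0, np.pi)
        touching = centers and rng.random() < config.touch_fraction
        if touching:
            idx = int(rng.integers(len(centers)))
            base = centers[idx]
            ang = rng.uniform(0, 2 * np.pi)
            dist = (r + shapes[idx][3]) * 0.95  # adjacent, slight overlap
            cy = base[0] + dist * np.sin(ang)
            cx = base[1] + dist * np.cos(ang)
        else:
            cy = rng.uniform(r, h - r)
            cx = rng.uniform(r, w - r)
        if not (0 <= cy < h and 0 <= cx < w):
            continue
        if not touching:
            ok = all(
                np.hypot(cy - oy, cx - ox) >= config.min_center_distance
                for oy, ox in centers
            )
            if not ok:
                continue
        centers.append((cy, cx))
        shapes.append((cy, cx, ry, rx, theta))

    labels = np.zeros((h, w), dtype=np.int32)
    for i, (cy, cx, ry, rx, theta) in enumerate(shapes, start=1):
        labels[_ellipse_mask(h, w, cy, cx, ry, rx, theta)] = i  # later wins

    # drop fully occluded nuclei, force contiguous ids
    from .clustering import relabel_contiguous

    labels = relabel_contiguous(labels)
    k = int(labels.max())
    class_of = {i: 1 + (i - 1) % config.n_classes for i in range(1, k + 1)}

    # two-stain concentration fields
    fg = labels > 0
    hema = np.full((h, w), config.hematoxylin_background)
    hema[fg] = config.hematoxylin_nucleus * rng.uniform(0.85, 1.15, int(fg.sum()))
    eosin = config.eosin_background * (
        0.7 + 0.3 * _smooth_noise(rng, h, w)
    )
    eosin[fg] *= 0.35  # nuclei displace cytoplasm

    basis = np.asarray(config.stain_basis, dtype=float)
    od = np.stack([hema, eosin], axis=-1) @ basis  # [H,W,3]
    img = od_to_rgb(od)
    img = img + rng.normal(0.0, config.noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return LabeledScene(image=img, labels=labels, class_of=class_of)


def _smooth_noise(rng, h, w, scale=8):
    coarse = rng.random((h // scale + 2, w // scale + 2))
    sm = ndimage.zoom(coarse, scale, order=3)[:h, :w]
    sm = sm - sm.min()
    return sm / max(sm.max(), 1e-9)


def generate_dataset(config: SceneConfig, n_scenes: int, seed: int = 0):
    """n_scenes independent scenes with per-scene seeds spawned from seed."""
    root = np.random.default_rng(seed)
    scene_seeds = root.integers(0, 2**31 - 1, size=n_scenes)
    return [generate_scene(config, int(s)) for s in scene_seeds]


# ----------------------------------------------------------------------
# augmentation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentSpec:
    """Training augmentations: flips, rotations and color jitter."""

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_rot90: float = 0.5
    p_rotate: float = 0.25
    max_angle: float = 30.0
    p_color_jitter: float = 0.5
    brightness: float = 0.1
    per_channel: float = 0.05


def augment(image: np.ndarray, labels: np.ndarray, spec: AugmentSpec,
            seed: int = 0):
    """Apply one random augmentation draw; geometric transforms hit image
    and labels identically (labels nearest-neighbour), color jitter hits
    the image only."""
    rng = np.random.default_rng(seed)
    img = np.asarray(image).astype(float)
    lab = np.asarray(labels).copy()
    if rng.random() < spec.p_hflip:
        img = img[:, ::-1].copy()
        lab = lab[:, ::-1].copy()
    if rng.random() < spec.p_vflip:
        img = img[::-1].copy()
        lab = lab[::-1].copy()
    if rng.random() < spec.p_rot90:
        k = int(rng.integers(1, 4))
        img = np.rot90(img, k, axes=(0, 1)).copy()
        lab = np.rot90(lab, k).copy()
    if rng.random() < spec.p_rotate:
        angle = rng.uniform(-spec.max_angle, spec.max_angle)
        # reflect-pad the image, nearest-neighbour the labels, keep shape
        img = ndimage.rotate(img, angle, axes=(1, 0), reshape=False,
                             order=1, mode="reflect")
        lab = ndimage.rotate(lab, angle, axes=(1, 0), reshape=False,
                             order=0, mode="constant", cval=0)
    if rng.random() < spec.p_color_jitter:
        gain = 1.0 + rng.uniform(-spec.brightness, spec.brightness)
        ch = 1.0 + rng.uniform(-spec.per_channel, spec.per_channel, 3)
        img = img * gain * ch[None, None, :]
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, lab.astype(np.int32)


# ----------------------------------------------------------------------
# fixture writer
# ----------------------------------------------------------------------

def _config_hash(config: SceneConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_fixture_set(config: SceneConfig, n_images: int, out_dir,
                      seed: int = 0) -> dict:
    """Write PNG images + 16-bit TIFF masks + a JSON manifest; re-running
    with the same arguments reproduces identical files."""
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    scene_seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=n_images)]
    entries = []
    for i, s in enumerate(scene_seeds):
        scene = generate_scene(config, s)
        img_path = out / "images" / f"scene_{i:04d}.png"
        mask_path = out / "masks" / f"scene_{i:04d}.tiff"
        iio.imwrite(img_path, scene.image)
        tifffile.imwrite(mask_path, scene.labels.astype(np.uint16))
        entries.append(
            {
                "image": str(img_path.relative_to(out)),
                "mask": str(mask_path.relative_to(out)),
                "seed": s,
                "n_instances": int(scene.labels.max()),
            }
        )
    manifest = {
        "config_hash": _config_hash(config),
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "seed": seed,
        "entries": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_array_dataset(images_path, masks_path) -> list[LabeledScene]:
    """Adapter for PanNuke-style array containers (optional input route).

    images: .npy stack [N,H,W,3]; masks: either [N,H,W] integer instance
    maps or [N,H,W,C] per-class instance-id channels (merged, later class
    wins on overlap; the class index becomes the instance's class id).
    """
    from .clustering import relabel_contiguous

    images = np.load(images_path)
    masks = np.load(masks_path)
    if images.ndim != 4 or images.shape[-1] != 3:
        raise ValueError(f"expected images [N,H,W,3], got {images.shape}")
    if images.shape[0] != masks.shape[0]:
        raise ValueError("images and masks stacks differ in length")
    scenes = []
    for img, mask in zip(images, masks):
        img8 = np.clip(np.round(img), 0, 255).astype(np.uint8)
        if mask.ndim == 2:
            labels = mask.astype(np.int32)
            class_src = {int(i): 1 for i in np.unique(labels) if i > 0}
        else:
            labels = np.zeros(mask.shape[:2], dtype=np.int32)
            class_src = {}
            next_id = 1
            for ch in range(mask.shape[-1]):
                for inst in np.unique(mask[..., ch]):
                    if inst == 0:
                        continue
                    labels[mask[..., ch] == inst] = next_id
                    class_src[next_id] = ch + 1
                    next_id += 1
        relabeled = relabel_contiguous(labels)
        # carry classes across the relabeling
        class_of = {}
        for new_id in np.unique(relabeled):
            if new_id == 0:
                continue
            old = int(labels[relabeled == new_id][0])
            class_of[int(new_id)] = class_src.get(old, 1)
        scenes.append(LabeledScene(img8, relabeled, class_of))
    return scenes


def load_fixture_set(out_dir):
    """Read back a fixture set written by :func:`write_fixture_set`."""
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    scenes = []
    for e in manifest["entries"]:
        img = iio.imread(out / e["image"])
        lab = tifffile.imread(out / e["mask"]).astype(np.int32)
        k = int(lab.max())
        scenes.append(LabeledScene(img, lab, {i: 1 for i in range(1, k + 1)}))
    return scenes, manifest
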