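"""Synthetic H&E-like nuclei patches with full ground truth.

Generates square RGB patches of overlapping elliptical nuclei on a pink
eosin-like background: each nucleus carries an instance label, a type in
{1..n_types}, and a type-dependent haematoxylin-ish colour, so the same
patches serve segmentation and classification training.  Later-drawn
nuclei occlude earlier ones, mirroring the single-label ground-truth
rasters of public nuclei datasets; a configurable fraction of nuclei is
seeded adjacent to an existing one to produce touching instances — the
hard case HV-map regression exists to solve.

The whole dataset is a pure function of :class:`SynthConfig` (one seed
sequence split per image index), so fixtures regenerate bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import label as cc_label

__all__ = ["SynthConfig", "LabeledPatch", "generate_dataset", "augment",
           "center_crop", "save_dataset", "load_dataset", "has_touching_pair"]

# haematoxylin-stained chromatin tones per nucleus type (RGB, [0,1])
_TYPE_COLORS = np.array([
    (0.36, 0.22, 0.53),   # dark purple
    (0.22, 0.28, 0.58),   # blue-violet
    (0.52, 0.26, 0.36),   # maroon
])
_BACKGROUND = np.array((0.88, 0.76, 0.85))

AUGMENT_OPS = ("zoom", "channel_shift", "shear", "rotate", "hflip", "vflip")


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; defaults emulate dense colorectal tissue
    patches with three nucleus categories plus background."""

    image_size: int = 80
    n_images: int = 16
    n_types: int = 3
    nuclei_per_image: tuple[int, int] = (4, 10)
    radius_range: tuple[float, float] = (6.0, 13.0)
    overlap_prob: float = 0.3
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.nuclei_per_image[0] > self.nuclei_per_image[1]:
            raise ValueError("nuclei_per_image min exceeds max")
        if self.nuclei_per_image[0] < 0:
            raise ValueError("nuclei_per_image must be non-negative")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range min exceeds max")
        if self.radius_range[1] >= self.image_size / 4:
            raise ValueError("radius max must be < image_size / 4")
        if not (0.0 <= self.overlap_prob <= 1.0):
            raise ValueError("overlap_prob must lie in [0, 1]")
        if not (0.0 <= self.noise_sd <= 1.0):
            raise ValueError("noise_sd must lie in [0, 1]")
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")


@dataclass
class LabeledPatch:
    """One training example: image in [0,1], instance raster (0 =
    background, labels consecutive 1..N), and per-pixel type raster."""

    image: np.ndarray      # (H, W, 3) float32
    instances: np.ndarray  # (H, W) int32
    types: np.ndarray      # (H, W) int16


def _type_color(t: int, n_types: int, rng: np.random.Generator) -> np.ndarray:
    if t <= len(_TYPE_COLORS):
        base = _TYPE_COLORS[t - 1]
    else:
        # deterministic extra hues for n_types > 3
        hue = (t - 1) / n_types
        base = np.array([0.25 + 0.3 * np.cos(2 * np.pi * hue),
                         0.25 + 0.2 * np.sin(2 * np.pi * hue),
                         0.45 + 0.15 * np.cos(2 * np.pi * hue + 1.0)])
    return np.clip(base + rng.uniform(-0.04, 0.04, size=3), 0.05, 0.95)


def _generate_patch(cfg: SynthConfig, rng: np.random.Generator) -> LabeledPatch:
    size = cfg.image_size
    image = np.empty((size, size, 3), dtype=np.float32)
    image[:] = np.clip(_BACKGROUND + rng.uniform(-0.02, 0.02, size=3), 0, 1)
    instances = np.zeros((size, size), dtype=np.int32)
    types = np.zeros((size, size), dtype=np.int16)

    n = int(rng.integers(cfg.nuclei_per_image[0], cfg.nuclei_per_image[1] + 1))
    centers: list[tuple[float, float, float]] = []  # (cy, cx, mean radius)
    inst_type: dict[int, int] = {}
    for k in range(n):
        a = rng.uniform(*cfg.radius_range)
        b = rng.uniform(*cfg.radius_range)
        r = 0.5 * (a + b)
        adjacent = bool(centers) and rng.random() < cfg.overlap_prob
        margin = min(r + 1, size / 2 - 1)
        cy = cx = None
        for _ in range(40):
            if adjacent:
                cy0, cx0, r0 = centers[int(rng.integers(len(centers)))]
                theta = rng.uniform(0, 2 * np.pi)
                # near-tangent contact: nuclei abut or slightly overlap, as
                # in tissue; deep interpenetration would carve concave
                # crescents no convex-nucleus representation can describe
                d = (r0 + r) * rng.uniform(0.85, 1.05)
                ty = cy0 + d * np.sin(theta)
                tx = cx0 + d * np.cos(theta)
                if not (margin <= ty <= size - 1 - margin
                        and margin <= tx <= size - 1 - margin):
                    continue
            else:
                ty = rng.uniform(margin, size - 1 - margin)
                tx = rng.uniform(margin, size - 1 - margin)
            if all(np.hypot(ty - cy0, tx - cx0) >= 0.8 * (r + r0)
                   for cy0, cx0, r0 in centers):
                cy, cx = float(ty), float(tx)
                break
        if cy is None:  # crowded patch: give up on this nucleus
            continue
        rot = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, b, a, shape=(size, size), rotation=rot)
        if rr.size == 0:
            continue
        label = len(centers) + 1
        t = int(rng.integers(1, cfg.n_types + 1))
        instances[rr, cc] = label
        types[rr, cc] = t
        color = _type_color(t, cfg.n_types, rng)
        shade = rng.uniform(0.92, 1.08)
        image[rr, cc] = np.clip(color * shade, 0, 1)
        centers.append((cy, cx, r))
        inst_type[label] = t

    # occlusion may fragment or erase earlier nuclei: keep the largest
    # connected piece of each survivor and relabel consecutively
    out = np.zeros_like(instances)
    next_label = 1
    for label in range(1, len(centers) + 1):
        mask = instances == label
        if mask.sum() < 8:
            if mask.any():
                types[mask] = 0
                image[mask] = np.clip(
                    _BACKGROUND + rng.uniform(-0.02, 0.02, size=3), 0, 1)
            continue
        pieces = cc_label(mask, connectivity=2)
        if pieces.max() > 1:
            sizes = np.bincount(pieces.ravel())[1:]
            keep = int(np.argmax(sizes)) + 1
            drop = mask & (pieces != keep)
            types[drop] = 0
            image[drop] = np.clip(
                _BACKGROUND + rng.uniform(-0.02, 0.02, size=3), 0, 1)
            mask = pieces == keep
        out[mask] = next_label
        types[mask] = inst_type[label]
        next_label += 1

    if cfg.noise_sd > 0:
        image = np.clip(image + rng.normal(0, cfg.noise_sd, image.shape), 0, 1)
    return LabeledPatch(image.astype(np.float32), out, types)


def generate_dataset(cfg: SynthConfig) -> list[LabeledPatch]:
    """Generate ``cfg.n_images`` labelled patches, reproducibly.

    One seed sequence is spawned per image index, so patch *i* of a
    dataset can be regenerated without generating its predecessors.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_images)
    return [_generate_patch(cfg, np.random.default_rng(s)) for s in streams]


def center_crop(patch: LabeledPatch, size: int) -> LabeledPatch:
    """Centre-crop a labelled patch to ``size`` x ``size`` (the network
    input convention: large sampled tiles are cropped to the training
    window); instance labels are re-made consecutive after the crop."""
    h, w = patch.instances.shape
    if size > h or size > w:
        raise ValueError("crop size exceeds patch size")
    y0 = (h - size) // 2
    x0 = (w - size) // 2
    inst = patch.instances[y0:y0 + size, x0:x0 + size].copy()
    relabel = np.zeros(inst.max() + 1, dtype=inst.dtype)
    relabel[np.unique(inst[inst > 0])] = \
        np.arange(1, np.unique(inst[inst > 0]).size + 1, dtype=inst.dtype)
    return LabeledPatch(
        patch.image[y0:y0 + size, x0:x0 + size].copy(),
        relabel[inst],
        patch.types[y0:y0 + size, x0:x0 + size].copy(),
    )


def has_touching_pair(instances: np.ndarray) -> bool:
    """True if two distinct instance labels share an 8-adjacent pixel pair."""
    inst = np.asarray(instances)
    h, w = inst.shape
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        y0, y1 = max(0, -dy), h - max(0, dy)
        x0, x1 = max(0, -dx), w - max(0, dx)
        a = inst[y0:y1, x0:x1]
        b = inst[y0 + dy:y1 + dy, x0 + dx:x1 + dx]
        if ((a > 0) & (b > 0) & (a != b)).any():
            return True
    return False


# -- augmentation ---------------------------------------------------------

def _geometric(patch: LabeledPatch, matrix: np.ndarray) -> LabeledPatch:
    """Apply a 2x2 affine map about the image centre; bilinear for the
    image, nearest for the label rasters, output size preserved."""
    h, w = patch.instances.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - matrix @ center
    image = np.stack([
        ndi.affine_transform(patch.image[..., c], matrix, offset=offset,
                             order=1, mode="nearest")
        for c in range(3)], axis=-1)
    inst = ndi.affine_transform(patch.instances, matrix, offset=offset,
                                order=0, mode="constant", cval=0)
    typ = ndi.affine_transform(patch.types, matrix, offset=offset,
                               order=0, mode="constant", cval=0)
    return LabeledPatch(np.clip(image, 0, 1).astype(np.float32),
                        inst.astype(np.int32), typ.astype(np.int16))


def augment(patch: LabeledPatch, ops: list[str], seed: int) -> LabeledPatch:
    """Apply augmentation ops in order; geometry is applied identically to
    image and label rasters (nearest-neighbour for labels).

    Supported ops: zoom, channel_shift, shear, rotate (quarter turns),
    hflip, vflip.
    """
    rng = np.random.default_rng(seed)
    out = LabeledPatch(patch.image.copy(), patch.instances.copy(),
                       patch.types.copy())
    for op in ops:
        if op == "hflip":
            out = LabeledPatch(out.image[:, ::-1].copy(),
                               out.instances[:, ::-1].copy(),
                               out.types[:, ::-1].copy())
        elif op == "vflip":
            out = LabeledPatch(out.image[::-1].copy(),
                               out.instances[::-1].copy(),
                               out.types[::-1].copy())
        elif op == "rotate":
            k = int(rng.integers(1, 4))
            out = LabeledPatch(np.rot90(out.image, k, axes=(0, 1)).copy(),
                               np.rot90(out.instances, k).copy(),
                               np.rot90(out.types, k).copy())
        elif op == "zoom":
            f = float(rng.uniform(0.8, 1.2))
            out = _geometric(out, np.diag([1.0 / f, 1.0 / f]))
        elif op == "shear":
            s = float(rng.uniform(-0.2, 0.2))
            out = _geometric(out, np.array([[1.0, s], [0.0, 1.0]]))
        elif op == "channel_shift":
            shift = rng.uniform(-0.08, 0.08, size=3).astype(np.float32)
            out = LabeledPatch(np.clip(out.image + shift, 0, 1),
                               out.instances, out.types)
        else:
            raise ValueError(f"unknown augmentation op: {op!r}")
    return out


# -- disk format ----------------------------------------------------------

def save_dataset(patches: list[LabeledPatch], cfg: SynthConfig,
                 out_dir: str | Path) -> Path:
    """Write images as 8-bit RGB PNG, instance and type rasters as 16-bit
    single-channel PNG, plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, p in enumerate(patches):
        names = {"image": f"img_{i:04d}.png",
                 "instances": f"inst_{i:04d}.png",
                 "types": f"type_{i:04d}.png"}
        iio.imwrite(out_dir / names["image"],
                    (p.image * 255).round().astype(np.uint8))
        iio.imwrite(out_dir / names["instances"], p.instances.astype(np.uint16))
        iio.imwrite(out_dir / names["types"], p.types.astype(np.uint16))
        entries.append(names)
    manifest = {"config": asdict(cfg), "patches": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def load_dataset(in_dir: str | Path) -> tuple[list[LabeledPatch], SynthConfig]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    raw = manifest["config"]
    for key in ("nuclei_per_image", "radius_range"):
        raw[key] = tuple(raw[key])
    cfg = SynthConfig(**raw)
    patches = []
    for names in manifest["patches"]:
        image = iio.imread(in_dir / names["image"]).astype(np.float32) / 255.0
        inst = iio.imread(in_dir / names["instances"]).astype(np.int32)
        typ = iio.imread(in_dir / names["types"]).astype(np.int16)
        patches.append(LabeledPatch(image, inst, typ))
    return patches, cfg
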