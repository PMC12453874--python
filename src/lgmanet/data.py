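"""Dataset I/O, the 80/20 split convention, augmentation, and the synthetic
lesion-image generator.

The generator emulates the qualitative character of dermoscopy/endoscopy
style benchmarks at desk scale: smooth irregular foreground blobs (unions
of radially perturbed ellipses) on a textured background, with pixel-exact
binary masks, optionally corrupted by hair-like curvilinear streaks,
rectangular patch occluders, multiplicative speckle, or blurred boundaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from .config import DatasetSpec, SynthSpec, config_to_dict

IMAGE_EXTS = (".png", ".jpg", ".jpeg")


@dataclass
class SamplePair:
    """One image (3,R,R) in [0,1] and its binary mask (1,R,R) in {0,1}."""
    image: np.ndarray
    mask: np.ndarray
    stem: str = ""

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[0] != 3:
            raise ValueError(f"image must be (3,H,W), got {self.image.shape}")
        if self.mask.ndim != 3 or self.mask.shape[0] != 1:
            raise ValueError(f"mask must be (1,H,W), got {self.mask.shape}")
        if self.image.shape[1:] != self.mask.shape[1:]:
            raise ValueError("image and mask spatial dims differ")


# ---------------------------------------------------------------------
# split convention
# ---------------------------------------------------------------------

def split_counts(n: int, ratio: float = 0.8) -> tuple[int, int]:
    """Train/test sizes under the 80/20 convention.

    Nearest-integer rounding with the half-up tie rule (612 * 0.8 = 489.6
    -> 490 train), both parts kept non-empty.
    """
    if n < 2:
        raise ValueError(f"need at least 2 images to split, got {n}")
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"split ratio must lie in (0, 1), got {ratio}")
    n_train = math.floor(n * ratio + 0.5)
    n_train = min(max(n_train, 1), n - 1)
    return n_train, n - n_train


def split_stems(stems: list[str], ratio: float, seed: int) -> tuple[list[str], list[str]]:
    """Seeded random permutation, then partition by :func:`split_counts`."""
    n_train, _ = split_counts(len(stems), ratio)
    order = np.random.default_rng(seed).permutation(len(stems))
    shuffled = [stems[i] for i in order]
    return shuffled[:n_train], shuffled[n_train:]


# ---------------------------------------------------------------------
# folder reading
# ---------------------------------------------------------------------

def _open_image(path: Path, mode: str) -> Image.Image:
    try:
        return Image.open(path).convert(mode)
    except UnidentifiedImageError as exc:
        raise ValueError(f"not a readable image file: {path}") from exc


def load_pair(image_path, mask_path, resolution: int) -> SamplePair:
    """Load one image/mask pair, resized to ``resolution`` square.

    The image is bilinearly resized and scaled to [0,1]; the mask is
    nearest-neighbour resized and re-binarised at the 8-bit midpoint
    (values > 127 map to 1), so it stays strictly binary.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    if not mask_path.exists():
        raise FileNotFoundError(f"image {image_path.name} has no paired mask at {mask_path}")
    img = _open_image(image_path, "RGB").resize((resolution, resolution), Image.BILINEAR)
    msk = _open_image(mask_path, "L").resize((resolution, resolution), Image.NEAREST)
    image = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
    mask = (np.asarray(msk) > 127).astype(np.float32)[None]
    return SamplePair(image, mask, stem=image_path.stem)


def list_pairs(spec: DatasetSpec) -> list[tuple[str, Path, Path]]:
    """(stem, image path, mask path) for every image file, sorted by stem.
    Every image must have exactly one mask with a matching stem."""
    images_dir, masks_dir = Path(spec.images_dir), Path(spec.masks_dir)
    out = []
    for p in sorted(images_dir.iterdir()):
        if p.suffix.lower() not in IMAGE_EXTS:
            continue
        candidates = [masks_dir / (p.stem + ext) for ext in IMAGE_EXTS]
        hits = [c for c in candidates if c.exists()]
        if not hits:
            raise FileNotFoundError(f"image {p.name} has no paired mask in {masks_dir}")
        out.append((p.stem, p, hits[0]))
    if not out:
        raise ValueError(f"no images found in {images_dir}")
    return out


def read_split_file(path) -> list[str]:
    """Plain-text split file: one image stem per line."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def load_split(spec: DatasetSpec,
               split_files: tuple | None = None) -> tuple[list[SamplePair], list[SamplePair]]:
    """Load the whole folder and split it into train/test sample lists.

    By default the split is a seeded random permutation partitioned by
    :func:`split_counts`; pass ``split_files=(train_list, test_list)`` to use
    an explicit stem-list partition instead.
    """
    pairs = {stem: (ip, mp) for stem, ip, mp in list_pairs(spec)}
    if split_files is not None:
        train_stems = read_split_file(split_files[0])
        test_stems = read_split_file(split_files[1])
        missing = [s for s in train_stems + test_stems if s not in pairs]
        if missing:
            raise FileNotFoundError(f"split file names unknown stems: {missing[:5]}")
    else:
        train_stems, test_stems = split_stems(sorted(pairs), spec.split_ratio, spec.seed)
    load = lambda stems: [load_pair(*pairs[s], spec.resolution) for s in stems]
    return load(train_stems), load(test_stems)


# ---------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------

def flip(sample: SamplePair, axis: str) -> SamplePair:
    """Horizontal ('h') or vertical ('v') flip of image and mask together."""
    ax = 2 if axis == "h" else 1
    return SamplePair(np.flip(sample.image, axis=ax).copy(),
                      np.flip(sample.mask, axis=ax).copy(), sample.stem)


def rotate(sample: SamplePair, angle: float) -> SamplePair:
    """Rotate image (bilinear) and mask (nearest) by `angle` degrees
    counter-clockwise about the image centre, keeping the frame size.

    Exact multiples of 90 degrees are lossless: a pixel at (r, c) moves to
    (R-1-c, r) under a 90-degree rotation of an R x R frame.
    """
    if angle % 360 == 0:
        return sample
    if angle % 90 == 0:
        k = int(angle // 90) % 4
        img = np.rot90(sample.image, k, axes=(1, 2)).copy()
        msk = np.rot90(sample.mask, k, axes=(1, 2)).copy()
        return SamplePair(img, msk, sample.stem)
    img = ndimage.rotate(sample.image, angle, axes=(2, 1), reshape=False,
                         order=1, mode="constant", cval=0.0)
    msk = ndimage.rotate(sample.mask, angle, axes=(2, 1), reshape=False,
                         order=0, mode="constant", cval=0.0)
    return SamplePair(np.clip(img, 0.0, 1.0).astype(np.float32),
                      (msk > 0.5).astype(np.float32), sample.stem)


def normalize(sample: SamplePair, mode: str = "unit",
              mean=None, std=None) -> SamplePair:
    """'unit': clamp the image into [0,1] (loading already scales by 255);
    'standardize': per-channel (x - mean) / std with given statistics."""
    if mode == "unit":
        img = np.clip(sample.image, 0.0, 1.0).astype(np.float32)
    elif mode == "standardize":
        mean = np.asarray(mean, np.float32).reshape(3, 1, 1)
        std = np.asarray(std, np.float32).reshape(3, 1, 1)
        img = (sample.image - mean) / std
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return SamplePair(img, sample.mask, sample.stem)


def augment(sample: SamplePair, rng: np.random.Generator,
            rot_prob: float = 0.5, flip_prob: float = 0.5,
            norm_mode: str = "unit") -> SamplePair:
    """Random rotation (uniform in [-180, 180), probability ``rot_prob``)
    and random horizontal/vertical flips (each with ``flip_prob``), applied
    identically to image and mask; normalisation is applied last."""
    out = sample
    if rng.random() < rot_prob:
        out = rotate(out, float(rng.uniform(-180.0, 180.0)))
    if rng.random() < flip_prob:
        out = flip(out, "h")
    if rng.random() < flip_prob:
        out = flip(out, "v")
    return normalize(out, norm_mode)


# ---------------------------------------------------------------------
# synthetic lesion-image generator
# ---------------------------------------------------------------------

def _blob_mask(size: int, rng: np.random.Generator) -> np.ndarray:
    """One smooth irregular blob: an ellipse whose radius is modulated by a
    low-order Fourier series in polar angle."""
    cy, cx = rng.uniform(0.3, 0.7, size=2) * size
    r0 = rng.uniform(0.13, 0.26) * size
    aspect = rng.uniform(0.7, 1.4)
    theta0 = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame
    ry = dy * np.cos(theta0) - dx * np.sin(theta0)
    rx = dy * np.sin(theta0) + dx * np.cos(theta0)
    dist = np.hypot(ry / aspect, rx * aspect)
    ang = np.arctan2(ry, rx)
    radius = np.full_like(dist, r0)
    for k in range(2, 6):
        radius += r0 * (0.18 / k) * np.cos(k * ang + rng.uniform(0, 2 * np.pi))
    return dist <= radius


def synth_mask(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Binary mask: union of deformed ellipses with foreground fraction
    inside ``spec.fg_fraction`` (resampled until the bound holds)."""
    lo, hi = spec.fg_fraction
    for _ in range(64):
        n = int(rng.integers(spec.n_blobs[0], spec.n_blobs[1] + 1))
        mask = np.zeros((spec.size, spec.size), dtype=bool)
        for _ in range(n):
            mask |= _blob_mask(spec.size, rng)
        frac = mask.mean()
        if lo <= frac <= hi:
            return mask
    raise RuntimeError("could not draw a mask within the foreground bounds")


def _texture(size: int, rng: np.random.Generator, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)


def synth_pair(spec: SynthSpec, index: int) -> SamplePair:
    """Deterministically generate pair `index` of the fixture."""
    rng = np.random.default_rng([spec.seed, index])
    size = spec.size
    mask = synth_mask(spec, rng)

    bg_level, fg_level = 0.35, 0.35 + spec.contrast
    base = np.where(mask, fg_level, bg_level).astype(np.float32)
    base += 0.05 * _texture(size, rng, size / 24)       # large-scale shading
    base += 0.03 * _texture(size, rng, 1.5)             # fine texture
    tint = rng.uniform(-0.04, 0.04, size=3).astype(np.float32)
    image = base[None] + tint[:, None, None]
    image += 0.01 * rng.standard_normal((3, size, size)).astype(np.float32)

    if "speckle" in spec.noise_profile:
        image = image * (1.0 + 0.15 * rng.standard_normal((1, size, size)))
    if "hair_streaks" in spec.noise_profile:
        image = _draw_hairs(image, rng)
    if "patch_artifacts" in spec.noise_profile:
        image = _draw_patches(image, rng)
    if "blur_boundary" in spec.noise_profile:
        image = ndimage.gaussian_filter(image, (0, 1.8, 1.8))

    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SamplePair(image, mask.astype(np.float32)[None], stem=f"img_{index:04d}")


def _draw_hairs(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dark curvilinear streaks crossing the frame (quadratic Bezier)."""
    size = image.shape[-1]
    out = image.copy()
    for _ in range(int(rng.integers(3, 9))):
        p = rng.uniform(0, size, size=(3, 2))
        t = np.linspace(0, 1, 4 * size)[:, None]
        curve = ((1 - t) ** 2 * p[0] + 2 * (1 - t) * t * p[1] + t ** 2 * p[2])
        rr, cc = curve[:, 0].astype(int), curve[:, 1].astype(int)
        keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        shade = rng.uniform(0.02, 0.18)
        out[:, rr[keep], cc[keep]] = shade
    return out


def _draw_patches(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rectangular occluders blended over the image."""
    size = image.shape[-1]
    out = image.copy()
    for _ in range(int(rng.integers(1, 4))):
        h, w = rng.integers(size // 10, size // 4, size=2)
        r = int(rng.integers(0, size - h))
        c = int(rng.integers(0, size - w))
        level = rng.uniform(0.1, 0.9)
        alpha = rng.uniform(0.5, 0.9)
        out[:, r:r + h, c:c + w] = (1 - alpha) * out[:, r:r + h, c:c + w] + alpha * level
    return out


def synth_pairs(spec: SynthSpec) -> list[SamplePair]:
    """Generate the whole fixture in memory."""
    return [synth_pair(spec, i) for i in range(spec.n_images)]


def generate_synthetic(spec: SynthSpec, out_dir) -> Path:
    """Write the fixture to ``out_dir/images`` and ``out_dir/masks`` as 8-bit
    PNGs ({0,255} masks), with a JSON manifest recording the spec. Returns
    the output directory. Bitwise-deterministic for a fixed spec."""
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    masks_dir = out_dir / "masks"
    images_dir.mkdir(parents=True, exist_ok=True)
    masks_dir.mkdir(parents=True, exist_ok=True)
    stems = []
    for i in range(spec.n_images):
        pair = synth_pair(spec, i)
        img8 = (pair.image.transpose(1, 2, 0) * 255.0).round().astype(np.uint8)
        msk8 = (pair.mask[0] * 255.0).astype(np.uint8)
        Image.fromarray(img8).save(images_dir / f"{pair.stem}.png")
        Image.fromarray(msk8, mode="L").save(masks_dir / f"{pair.stem}.png")
        stems.append(pair.stem)
    manifest = {"spec": config_to_dict(spec), "stems": stems}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
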