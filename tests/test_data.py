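"""Folder I/O, split convention, augmentation and the synthetic generator."""

import hashlib
import json

import numpy as np
import pytest
from PIL import Image

from lgmanet.config import DatasetSpec, SynthSpec
from lgmanet.data import (SamplePair, augment, flip, generate_synthetic,
                          load_pair, load_split, normalize, rotate,
                          split_counts, split_stems, synth_pair, synth_pairs)


# ---------------------------------------------------------------------
# split convention
# ---------------------------------------------------------------------

@pytest.mark.parametrize("n, expected", [
    (612, (490, 122)),     # endoscopy benchmark row
    (2594, (2075, 519)),   # dermoscopy row
    (210, (168, 42)),      # ultrasound row
    (165, (132, 33)),      # gland histology row
    (10, (8, 2)),
])
def test_split_counts_reproduces_published_rows(n, expected):
    assert split_counts(n, 0.8) == expected


def test_split_counts_half_up_and_validation():
    assert split_counts(5, 0.5) == (3, 2)  # 2.5 rounds up
    with pytest.raises(ValueError):
        split_counts(1, 0.8)
    with pytest.raises(ValueError):
        split_counts(10, 1.0)


def test_split_counts_conserves_n():
    for n in range(2, 3000):
        tr, te = split_counts(n, 0.8)
        assert tr + te == n and tr >= 1 and te >= 1


def test_split_stems_is_seeded_partition():
    stems = [f"s{i}" for i in range(20)]
    tr1, te1 = split_stems(stems, 0.8, seed=5)
    tr2, te2 = split_stems(stems, 0.8, seed=5)
    assert (tr1, te1) == (tr2, te2)
    assert len(tr1) == 16 and len(te1) == 4
    assert sorted(tr1 + te1) == sorted(stems)


# ---------------------------------------------------------------------
# pair loading
# ---------------------------------------------------------------------

@pytest.fixture
def disk_pair(tmp_path):
    gen = np.random.default_rng(0)
    img = (gen.random((45, 60, 3)) * 255).astype(np.uint8)
    msk = np.zeros((45, 60), np.uint8)
    msk[10:30, 20:50] = 255
    ip = tmp_path / "case1.png"
    mp = tmp_path / "case1_mask.png"
    Image.fromarray(img).save(ip)
    Image.fromarray(msk, "L").save(mp)
    return ip, mp


def test_load_pair_contract(disk_pair):
    ip, mp = disk_pair
    pair = load_pair(ip, mp, 384)
    assert pair.image.shape == (3, 384, 384)
    assert pair.mask.shape == (1, 384, 384)
    assert pair.image.min() >= 0 and pair.image.max() <= 1
    assert set(np.unique(pair.mask)) <= {0.0, 1.0}
    again = load_pair(ip, mp, 384)
    np.testing.assert_array_equal(pair.image, again.image)
    np.testing.assert_array_equal(pair.mask, again.mask)


def test_load_pair_missing_mask_and_bad_format(tmp_path, disk_pair):
    ip, _ = disk_pair
    with pytest.raises(FileNotFoundError, match="mask"):
        load_pair(ip, tmp_path / "nope.png", 64)
    bad = tmp_path / "bad.png"
    bad.write_text("not an image")
    with pytest.raises(ValueError, match="image"):
        load_pair(bad, ip, 64)


def test_load_split_pairs_files_by_stem(tmp_path):
    spec = SynthSpec(n_images=6, size=32, seed=3)
    root = generate_synthetic(spec, tmp_path / "ds")
    ds = DatasetSpec(str(root / "images"), str(root / "masks"),
                     resolution=32, seed=0)
    train, test = load_split(ds)
    assert len(train) == 5 and len(test) == 1
    assert all(isinstance(p, SamplePair) for p in train + test)


# ---------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------

def _toy_pair():
    img = np.random.default_rng(0).random((3, 9, 9)).astype(np.float32)
    msk = np.zeros((1, 9, 9), np.float32)
    msk[0, 2, 6] = 1.0
    return SamplePair(img, msk)


def test_flip_is_involution():
    pair = _toy_pair()
    for axis in ("h", "v"):
        twice = flip(flip(pair, axis), axis)
        np.testing.assert_array_equal(twice.image, pair.image)
        np.testing.assert_array_equal(twice.mask, pair.mask)


def test_rotate_90_moves_pixel_to_expected_coordinate():
    pair = _toy_pair()  # single on-pixel at (r, c) = (2, 6), R = 9
    rot = rotate(pair, 90.0)
    r, c = np.argwhere(rot.mask[0])[0]
    assert (r, c) == (9 - 1 - 6, 2)  # (r,c) -> (R-1-c, r) counter-clockwise


def test_rotate_arbitrary_angle_keeps_mask_binary_and_shape():
    pair = _toy_pair()
    rot = rotate(pair, 37.5)
    assert rot.image.shape == pair.image.shape
    assert set(np.unique(rot.mask)) <= {0.0, 1.0}


def test_augment_probability_zero_is_identity():
    pair = _toy_pair()
    out = augment(pair, np.random.default_rng(0), rot_prob=0.0, flip_prob=0.0)
    np.testing.assert_array_equal(out.image, pair.image)
    np.testing.assert_array_equal(out.mask, pair.mask)


def test_augment_preserves_mask_binarity_and_shapes():
    pair = _toy_pair()
    gen = np.random.default_rng(7)
    for _ in range(20):
        out = augment(pair, gen)
        assert out.image.shape == pair.image.shape
        assert out.mask.shape == pair.mask.shape
        assert set(np.unique(out.mask)) <= {0.0, 1.0}


def test_normalize_standardize_mode():
    pair = _toy_pair()
    out = normalize(pair, "standardize", mean=[0.5] * 3, std=[2.0] * 3)
    np.testing.assert_allclose(out.image, (pair.image - 0.5) / 2.0, atol=1e-6)
    with pytest.raises(ValueError):
        normalize(pair, "weird")


# ---------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------

def _tree_digest(root):
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def test_generate_synthetic_bitwise_deterministic(tmp_path):
    spec = SynthSpec(n_images=5, size=48, seed=7,
                     noise_profile=("hair_streaks", "speckle"))
    d1 = generate_synthetic(spec, tmp_path / "a")
    d2 = generate_synthetic(spec, tmp_path / "b")
    assert _tree_digest(d1) == _tree_digest(d2)
    manifest = json.loads((d1 / "manifest.json").read_text())
    assert manifest["spec"]["seed"] == 7 and len(manifest["stems"]) == 5


def test_synthetic_masks_respect_foreground_bounds():
    spec = SynthSpec(n_images=12, size=64, seed=2)
    for pair in synth_pairs(spec):
        frac = pair.mask.mean()
        assert spec.fg_fraction[0] <= frac <= spec.fg_fraction[1]
        assert set(np.unique(pair.mask)) <= {0.0, 1.0}


def test_clean_synthetic_recovered_by_midpoint_threshold():
    """Brute-force oracle: with no artifacts and the default contrast,
    thresholding the grey level halfway between the two intensity modes
    recovers the mask at IoU > 0.95."""
    spec = SynthSpec(n_images=6, size=96, seed=11, noise_profile=())
    for pair in synth_pairs(spec):
        grey = pair.image.mean(axis=0)
        thr = 0.35 + spec.contrast / 2  # midpoint of bg/fg levels
        pred = grey > thr
        truth = pair.mask[0].astype(bool)
        iou = (pred & truth).sum() / (pred | truth).sum()
        assert iou > 0.95


def test_noise_profiles_change_pixels_but_not_masks():
    clean = synth_pair(SynthSpec(n_images=1, size=64, seed=5), 0)
    for kind in ("hair_streaks", "patch_artifacts", "speckle", "blur_boundary"):
        noisy = synth_pair(SynthSpec(n_images=1, size=64, seed=5,
                                     noise_profile=(kind,)), 0)
        assert not np.array_equal(noisy.image, clean.image), kind
        np.testing.assert_array_equal(noisy.mask, clean.mask)
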