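"""Preprocessing and augmentation behaviour."""

from __future__ import annotations

import numpy as np
import pytest
from PIL import Image

from bonecnn import (
    AugmentationPolicy,
    NormalizationSpec,
    clahe,
    load_and_standardize,
    materialize_augmented_set,
    normalize,
    plan_class_balancing,
    random_augment,
)
from bonecnn.data import DatasetManifest, ImageRecord
from bonecnn.errors import ConfigurationError, ContractViolationError, InputError
from bonecnn.imaging import load_grayscale


def _identity_policy(**overrides):
    base = dict(
        rotation_degrees=0.0,
        translation_fraction=0.0,
        hflip_probability=0.0,
        gamma_range=(1.0, 1.0),
        clahe_enabled=False,
    )
    base.update(overrides)
    return AugmentationPolicy(**base)


# ---------------------------------------------------------------------------
# Loading and normalisation
# ---------------------------------------------------------------------------


def test_load_resizes_rectangles_and_replicates_channels(tmp_path):
    arr = (np.linspace(0, 255, 64 * 128).reshape(64, 128)).astype(np.uint8)
    p = tmp_path / "rect.png"
    Image.fromarray(arr).save(p)
    out = load_and_standardize(p, input_size=32)
    assert out.shape == (3, 32, 32)
    assert (out[0] == out[1]).all() and (out[1] == out[2]).all()
    assert 0.0 <= out.min() and out.max() <= 1.0


def test_load_identity_resize_preserves_values(tmp_path):
    arr = np.arange(16 * 16, dtype=np.uint8).reshape(16, 16)
    p = tmp_path / "same.png"
    Image.fromarray(arr).save(p)
    out = load_and_standardize(p, input_size=16)
    assert out[0] == pytest.approx(arr / 255.0, abs=1e-6)


def test_load_constant_image_stays_constant(tmp_path):
    p = tmp_path / "const.png"
    Image.fromarray(np.full((40, 80), 128, dtype=np.uint8)).save(p)
    out = load_and_standardize(p, input_size=24)
    assert out == pytest.approx(np.full((3, 24, 24), 128 / 255.0), abs=1e-6)


def test_load_scales_16bit_and_rgb(tmp_path):
    p16 = tmp_path / "deep.png"
    Image.fromarray(np.full((20, 20), 65535, dtype=np.uint16)).save(p16)
    assert load_grayscale(p16) == pytest.approx(np.ones((20, 20)))
    prgb = tmp_path / "rgb.png"
    Image.fromarray(np.full((20, 20, 3), 255, dtype=np.uint8)).save(prgb)
    assert load_grayscale(prgb) == pytest.approx(np.ones((20, 20)))


def test_unreadable_file_raises_with_path(tmp_path):
    p = tmp_path / "broken.png"
    p.write_bytes(b"this is not a png")
    with pytest.raises(OSError, match="broken.png"):
        load_grayscale(p)


def test_normalize_centres_and_scales():
    spec = NormalizationSpec()
    x = np.zeros((3, 2, 2))
    x[0], x[1], x[2] = 0.485, 0.456, 0.406
    assert normalize(x, spec) == pytest.approx(np.zeros((3, 2, 2)), abs=1e-12)
    x[0] = 1.0
    assert normalize(x, spec)[0, 0, 0] == pytest.approx(2.2489, abs=1e-4)
    with pytest.raises(InputError):
        normalize(np.zeros((2, 4, 4)), spec)


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------


def test_clahe_constant_image_maps_to_constant():
    out = clahe(np.full((32, 32), 0.7), clip_limit=2.0, tile_grid=(4, 4))
    assert out == pytest.approx(np.full((32, 32), out[0, 0]))


def test_clahe_output_stays_in_unit_interval():
    rng = np.random.default_rng(0)
    for _ in range(3):
        out = clahe(rng.random((24, 24)), clip_limit=2.0, tile_grid=(3, 3))
        assert out.min() >= 0.0 and out.max() <= 1.0


def test_clahe_single_tile_equals_global_equalization():
    """With one tile and no clipping, CLAHE must reduce to brute-force
    global histogram equalisation (inclusive CDF at 256 levels)."""
    rng = np.random.default_rng(42)
    for _ in range(10):
        img = rng.random((16, 16))
        out = clahe(img, clip_limit=None, tile_grid=(1, 1))
        q = np.minimum((img * 256).astype(int), 255)
        n = img.size
        oracle = np.empty_like(img)
        for i in range(16):
            for j in range(16):
                oracle[i, j] = (q <= q[i, j]).sum() / n
        assert out == pytest.approx(oracle, abs=1e-12)


def test_clahe_rejects_oversized_tile_grid():
    with pytest.raises(InputError, match="tile grid"):
        clahe(np.zeros((8, 8)), 2.0, (16, 16))


# ---------------------------------------------------------------------------
# Random augmentation
# ---------------------------------------------------------------------------


def test_identity_policy_returns_input_exactly():
    img = np.random.default_rng(1).random((32, 32))
    out = random_augment(img, _identity_policy(), np.random.default_rng(0))
    assert (out == img).all()


def test_same_seed_reproduces_bitwise():
    img = np.random.default_rng(2).random((32, 32))
    policy = AugmentationPolicy(seed=5)
    a = random_augment(img, policy, np.random.default_rng(99))
    b = random_augment(img, policy, np.random.default_rng(99))
    assert (a == b).all()


def test_gamma_two_squares_intensities():
    out = random_augment(
        np.full((16, 16), 0.5), _identity_policy(gamma_range=(2.0, 2.0)), np.random.default_rng(0)
    )
    assert out == pytest.approx(np.full((16, 16), 0.25), abs=1e-12)


def test_augment_output_stays_in_unit_interval():
    rng = np.random.default_rng(3)
    policy = AugmentationPolicy()
    for _ in range(3):
        out = random_augment(rng.random((24, 24)), policy, rng)
        assert out.min() >= 0.0 and out.max() <= 1.0


@pytest.mark.parametrize(
    "kwargs",
    [
        {"rotation_degrees": 13.0},
        {"translation_fraction": 0.05},
        {"hflip_probability": 1.5},
        {"gamma_range": (0.0, 1.2)},
    ],
)
def test_policy_invariants_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        AugmentationPolicy(**kwargs)


# ---------------------------------------------------------------------------
# Class balancing
# ---------------------------------------------------------------------------


def test_plan_exact_division_gives_uniform_copies():
    plan = plan_class_balancing({"a": 100}, {"a": 600})
    cur, tgt, mult = plan.per_class["a"]
    assert (cur, tgt) == (100, 600)
    assert mult == [5] * 100


def test_plan_equal_counts_is_noop():
    plan = plan_class_balancing({"a": 100}, {"a": 100})
    assert plan.per_class["a"][2] == [0] * 100
    assert plan.total_new() == 0


def test_plan_table_targets_reach_full_dataset_size():
    targets = dict(zip(
        [f"c{i}" for i in range(9)], [600, 1403, 984, 626, 600, 672, 482, 600, 664]
    ))
    current = {c: 60 for c in targets}  # arbitrary originals below target
    plan = plan_class_balancing(current, targets, seed=0)
    assert plan.planned_total() == 6631
    for cls, (cur, tgt, mult) in plan.per_class.items():
        assert sum(mult) == tgt - cur
        assert max(mult) - min(mult) <= 1


def test_plan_rejects_target_below_current():
    with pytest.raises(ConfigurationError, match="below current"):
        plan_class_balancing({"a": 10}, {"a": 5})


# ---------------------------------------------------------------------------
# Materialisation
# ---------------------------------------------------------------------------


def _tiny_split_manifest(tmp_path, n=4):
    rng = np.random.default_rng(0)
    records = []
    for cls_idx, cls in enumerate(["ca", "cb"]):
        d = tmp_path / cls
        d.mkdir()
        for i in range(n):
            p = d / f"img{i}.png"
            Image.fromarray((rng.random((20, 20)) * 255).astype(np.uint8)).save(p)
            split = "train" if i < n - 2 else ("val" if i == n - 2 else "test")
            records.append(ImageRecord(str(p), cls_idx, cls, split=split))
    return DatasetManifest(records=records, class_names=["ca", "cb"])


def test_materialize_empty_plan_keeps_manifest(tmp_path):
    manifest = _tiny_split_manifest(tmp_path)
    plan = plan_class_balancing({"ca": 2, "cb": 2}, {"ca": 2, "cb": 2})
    out = materialize_augmented_set(manifest, plan, AugmentationPolicy(seed=0), tmp_path / "aug")
    assert len(out.records) == len(manifest.records)


def test_materialize_grows_by_planned_copies_and_spares_val_test(tmp_path):
    manifest = _tiny_split_manifest(tmp_path)
    plan = plan_class_balancing({"ca": 2, "cb": 2}, {"ca": 5, "cb": 4})
    policy = AugmentationPolicy(seed=1)
    out = materialize_augmented_set(manifest, plan, policy, tmp_path / "aug")
    assert len(out.records) == len(manifest.records) + 5
    for split in ("val", "test"):
        assert len(out.by_split(split)) == len(manifest.by_split(split))
    for r in out.records:
        if r.origin == "augmented":
            assert r.split == "train" and r.source_image


def test_materialize_is_byte_deterministic(tmp_path):
    manifest = _tiny_split_manifest(tmp_path)
    plan = plan_class_balancing({"ca": 2, "cb": 2}, {"ca": 4, "cb": 4})
    policy = AugmentationPolicy(seed=3)
    out1 = materialize_augmented_set(manifest, plan, policy, tmp_path / "aug1")
    out2 = materialize_augmented_set(
        DatasetManifest(records=manifest.records, class_names=manifest.class_names),
        plan, policy, tmp_path / "aug2",
    )
    aug1 = sorted(r.path for r in out1.records if r.origin == "augmented")
    aug2 = sorted(r.path for r in out2.records if r.origin == "augmented")
    for p1, p2 in zip(aug1, aug2):
        with open(p1, "rb") as f1, open(p2, "rb") as f2:
            assert f1.read() == f2.read()


def test_materialize_rejects_plan_touching_val_test(tmp_path):
    manifest = _tiny_split_manifest(tmp_path)
    plan = plan_class_balancing({"ca": 3, "cb": 2}, {"ca": 6, "cb": 2})  # ca has only 2 train
    with pytest.raises(ContractViolationError):
        materialize_augmented_set(manifest, plan, AugmentationPolicy(seed=0), tmp_path / "aug")
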