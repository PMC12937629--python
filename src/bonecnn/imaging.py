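"""Radiograph preprocessing and class-balancing augmentation.

Preprocessing standardises every radiograph to a square float image in
[0, 1], replicated across three channels and normalised with the
ImageNet statistics, so the network sees the same input contract
regardless of source bit depth or aspect ratio.  Resizing is anisotropic
(plain bilinear to the square target) by default; an aspect-preserving
pad-then-resize variant is available behind a flag.

Augmentation is the class-balancing family applied to the training
split only: CLAHE, small rotation, horizontal flip, slight translation,
and gamma correction, each with bounded ranges chosen to perturb
appearance without destroying diagnostic structure (mineralisation,
cortical margins).  The fixed application order is
CLAHE -> rotate -> flip -> translate -> gamma: contrast equalisation
first, geometric ops after, photometric gamma last.  Every augmented
copy draws all transforms from a seeded stream, so a manifest + policy
+ seed reproduces byte-identical augmented files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError, ContractViolationError, InputError

CLAHE_BINS = 256  # histogram resolution; part of the CLAHE contract


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-channel standardisation constants (ImageNet defaults)."""

    mean: tuple[float, float, float] = (0.485, 0.456, 0.406)
    std: tuple[float, float, float] = (0.229, 0.224, 0.225)

    def __post_init__(self) -> None:
        if len(self.mean) != 3 or len(self.std) != 3:
            raise ConfigurationError("NormalizationSpec: mean and std must have three channels")
        if any(s <= 0 for s in self.std):
            raise ConfigurationError("NormalizationSpec: std must be strictly positive")


@dataclass
class AugmentationPolicy:
    """The bounded transform family used for class balancing.

    rotation_degrees : symmetric rotation range, at most +/-12 degrees
    translation_fraction : per-axis shift bound, strictly below 0.05
    hflip_probability : probability of a horizontal flip
    gamma_range : interval for the gamma exponent on [0,1] intensities
    clahe_* : contrast-limited adaptive histogram equalisation settings
    seed : identifier of the random stream used when materialising
    """

    rotation_degrees: float = 12.0
    translation_fraction: float = 0.04
    hflip_probability: float = 0.5
    gamma_range: tuple[float, float] = (0.8, 1.2)
    clahe_enabled: bool = True
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rotation_degrees <= 12.0:
            raise ConfigurationError(
                f"rotation_degrees must lie in [0, 12], got {self.rotation_degrees}"
            )
        if not 0.0 <= self.translation_fraction < 0.05:
            raise ConfigurationError(
                f"translation_fraction must lie in [0, 0.05), got {self.translation_fraction}"
            )
        if not 0.0 <= self.hflip_probability <= 1.0:
            raise ConfigurationError("hflip_probability must be a probability")
        lo, hi = self.gamma_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"gamma_range must be positive and ordered, got {self.gamma_range}")
        if min(self.clahe_tile_grid) < 1:
            raise ConfigurationError("clahe_tile_grid entries must be >= 1")


@dataclass
class AugmentationPlan:
    """Per-class replication targets.

    ``per_class`` maps class name -> (current_count, target_count,
    multiplicities), where multiplicities has one entry per existing
    training image of that class, entries differing by at most one, and
    summing to target - current.
    """

    per_class: dict[str, tuple[int, int, list[int]]] = field(default_factory=dict)
    seed: int = 0

    def total_new(self) -> int:
        return sum(sum(mult) for _, _, mult in self.per_class.values())

    def planned_total(self) -> int:
        return sum(t for _, t, _ in self.per_class.values())

    def validate(self) -> None:
        for cls, (cur, tgt, mult) in self.per_class.items():
            if tgt < cur:
                raise ConfigurationError(f"class {cls}: target {tgt} below current {cur}")
            if len(mult) != cur or sum(mult) != tgt - cur:
                raise ConfigurationError(f"class {cls}: multiplicities inconsistent with counts")
            if mult and max(mult) - min(mult) > 1:
                raise ConfigurationError(f"class {cls}: multiplicities differ by more than 1")


# ---------------------------------------------------------------------------
# Loading and standardisation
# ---------------------------------------------------------------------------


def load_grayscale(path: str | Path) -> np.ndarray:
    """Read a PNG as a single-channel float image in [0, 1].

    8-bit inputs are scaled by 1/255, 16-bit by 1/65535; RGB inputs are
    converted to luminance first.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("RGB", "RGBA", "P"):
                im = im.convert("L")
                arr = np.asarray(im, dtype=np.float64) / 255.0
            elif im.mode == "L":
                arr = np.asarray(im, dtype=np.float64) / 255.0
            elif im.mode in ("I;16", "I;16B", "I"):
                arr = np.asarray(im, dtype=np.float64) / 65535.0
            else:
                im = im.convert("L")
                arr = np.asarray(im, dtype=np.float64) / 255.0
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.ndim != 2 or arr.size == 0 or min(arr.shape) == 0:
        raise InputError(f"zero-area or non-2D image: {path}")
    return np.clip(arr, 0.0, 1.0)


def resize_square(image: np.ndarray, size: int, preserve_aspect: bool = False) -> np.ndarray:
    """Bilinear resize to ``size x size``.

    By default the resize is anisotropic (each axis scaled
    independently).  With ``preserve_aspect`` the image is first padded
    to square with edge replication, then scaled isotropically.
    """
    if image.shape == (size, size):
        return image.astype(np.float64)
    if preserve_aspect:
        h, w = image.shape
        side = max(h, w)
        py, px = side - h, side - w
        image = np.pad(
            image,
            ((py // 2, py - py // 2), (px // 2, px - px // 2)),
            mode="edge",
        )
    return _sk_resize(image, (size, size), order=1, anti_aliasing=False, preserve_range=True)


def load_and_standardize(
    path: str | Path, input_size: int = 224, preserve_aspect: bool = False
) -> np.ndarray:
    """Load, resize, and replicate to three identical channels.

    Returns a (3, input_size, input_size) float array in [0, 1].
    """
    gray = resize_square(load_grayscale(path), input_size, preserve_aspect)
    return np.repeat(gray[None].astype(np.float32), 3, axis=0)


def normalize(image: np.ndarray, spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    """Channel-wise standardisation: out[c] = (in[c] - mean[c]) / std[c]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[0] != 3:
        raise InputError(f"expected a (3, H, W) image, got shape {image.shape}")
    mean = np.asarray(spec.mean, dtype=image.dtype)[:, None, None]
    std = np.asarray(spec.std, dtype=image.dtype)[:, None, None]
    return (image - mean) / std


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------


def clahe(
    image: np.ndarray,
    clip_limit: float | None = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
    nbins: int = CLAHE_BINS,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on a [0,1] image.

    The image is divided into a ``tile_grid`` of tiles; each tile's
    histogram (``nbins`` levels) is clipped at
    ``clip_limit * tile_pixels / nbins`` with the clipped mass
    redistributed uniformly, and the per-tile equalisation mappings
    (cumulative histogram / tile pixel count) are blended with bilinear
    interpolation between tile centres.  ``clip_limit=None`` disables
    clipping; with a single tile and no clipping this reduces exactly to
    global histogram equalisation at the same quantisation.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise InputError(f"clahe expects a single-channel image, got shape {image.shape}")
    h, w = image.shape
    gh, gw = tile_grid
    if gh > h or gw > w:
        raise InputError(f"tile grid {tile_grid} larger than image {image.shape}")
    q = np.minimum((np.clip(image, 0.0, 1.0) * nbins).astype(np.int64), nbins - 1)

    # per-tile lookup tables
    luts = np.empty((gh, gw, nbins))
    cy = np.empty(gh)
    cx = np.empty(gw)
    for ti in range(gh):
        r0, r1 = (ti * h) // gh, ((ti + 1) * h) // gh
        cy[ti] = (r0 + r1 - 1) / 2.0
        for tj in range(gw):
            c0, c1 = (tj * w) // gw, ((tj + 1) * w) // gw
            if ti == 0:
                cx[tj] = (c0 + c1 - 1) / 2.0
            hist = np.bincount(q[r0:r1, c0:c1].ravel(), minlength=nbins).astype(np.float64)
            npix = (r1 - r0) * (c1 - c0)
            if clip_limit is not None and np.isfinite(clip_limit):
                limit = max(clip_limit * npix / nbins, 1.0)
                excess = np.clip(hist - limit, 0.0, None).sum()
                hist = np.minimum(hist, limit) + excess / nbins
            luts[ti, tj] = np.cumsum(hist) / npix

    # bilinear interpolation between tile-centre mappings
    ty = np.interp(np.arange(h), cy, np.arange(gh)) if gh > 1 else np.zeros(h)
    tx = np.interp(np.arange(w), cx, np.arange(gw)) if gw > 1 else np.zeros(w)
    t0y = np.floor(ty).astype(int)
    t0x = np.floor(tx).astype(int)
    t1y = np.minimum(t0y + 1, gh - 1)
    t1x = np.minimum(t0x + 1, gw - 1)
    wy = (ty - t0y)[:, None]
    wx = (tx - t0x)[None, :]
    a = luts[t0y[:, None], t0x[None, :], q]
    b = luts[t0y[:, None], t1x[None, :], q]
    c = luts[t1y[:, None], t0x[None, :], q]
    d = luts[t1y[:, None], t1x[None, :], q]
    out = (1 - wy) * ((1 - wx) * a + wx * b) + wy * ((1 - wx) * c + wx * d)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Random augmentation
# ---------------------------------------------------------------------------


def random_augment(
    image: np.ndarray, policy: AugmentationPolicy, draw: np.random.Generator
) -> np.ndarray:
    """Apply one random draw of the full transform family.

    Order is fixed: CLAHE -> rotation -> horizontal flip -> translation
    -> gamma.  Geometric borders use edge replication so no synthetic
    black wedges appear.  Identical seed implies identical output.
    """
    image = np.asarray(image, dtype=np.float64)
    multi = image.ndim == 3
    chans = list(image) if multi else [image]

    if policy.clahe_enabled:
        chans = [clahe(c, policy.clahe_clip_limit, policy.clahe_tile_grid) for c in chans]

    angle = float(draw.uniform(-policy.rotation_degrees, policy.rotation_degrees))
    if angle != 0.0:
        chans = [
            ndimage.rotate(c, angle, reshape=False, order=1, mode="nearest") for c in chans
        ]

    if policy.hflip_probability > 0 and draw.random() < policy.hflip_probability:
        chans = [c[:, ::-1] for c in chans]

    h, w = chans[0].shape
    dy = float(draw.uniform(-policy.translation_fraction, policy.translation_fraction)) * h
    dx = float(draw.uniform(-policy.translation_fraction, policy.translation_fraction)) * w
    if dy != 0.0 or dx != 0.0:
        chans = [ndimage.shift(c, (dy, dx), order=1, mode="nearest") for c in chans]

    lo, hi = policy.gamma_range
    gamma = float(draw.uniform(lo, hi))
    chans = [np.clip(c, 0.0, 1.0) for c in chans]
    if gamma != 1.0:
        chans = [np.power(c, gamma) for c in chans]

    out = np.stack(chans) if multi else chans[0]
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Class balancing
# ---------------------------------------------------------------------------


def plan_class_balancing(
    current_counts: dict[str, int], target_counts: dict[str, int], seed: int = 0
) -> AugmentationPlan:
    """Distribute ``target - current`` augmented copies as evenly as
    possible over each class's original training images.

    Every image receives ``deficit // current`` copies; the remainder is
    assigned one extra copy each to a seeded random subset of images, so
    multiplicities differ by at most one.
    """
    plan = AugmentationPlan(seed=seed)
    rng = np.random.default_rng(seed)
    for cls in sorted(current_counts):
        cur = current_counts[cls]
        tgt = target_counts.get(cls, cur)
        if tgt < cur:
            raise ConfigurationError(f"class {cls}: target {tgt} is below current count {cur}")
        deficit = tgt - cur
        base, rem = divmod(deficit, cur) if cur else (0, 0)
        mult = [base] * cur
        for idx in rng.choice(cur, size=rem, replace=False) if rem else []:
            mult[idx] += 1
        plan.per_class[cls] = (cur, tgt, mult)
    plan.validate()
    return plan


def records_to_tensors(
    records, input_size: int, spec: NormalizationSpec = NormalizationSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Load manifest records into network-ready tensors.

    Returns ``(x, y)`` with x of shape (n, 3, input_size, input_size),
    standardised with ``spec``, and integer labels y."""
    xs, ys = [], []
    for r in records:
        img = load_and_standardize(r.path, input_size)
        xs.append(normalize(img, spec).astype(np.float32))
        ys.append(r.class_index)
    if not xs:
        return (np.zeros((0, 3, input_size, input_size), dtype=np.float32),
                np.zeros(0, dtype=np.int64))
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


def materialize_augmented_set(manifest, plan: AugmentationPlan, policy: AugmentationPolicy,
                              out_dir: str | Path | None = None):
    """Write augmented PNGs and return an extended manifest.

    Only ``split == train`` records are eligible; validation and test
    records are never touched.  Each copy's random stream is derived
    from (policy seed, class index, image index, copy index), so outputs
    are independent of traversal order and byte-identical across runs.
    """
    from .data import DatasetManifest, ImageRecord  # local import to avoid a cycle

    plan.validate()
    new_records = list(manifest.records)
    for cls, (cur, _tgt, mult) in plan.per_class.items():
        train_recs = [r for r in manifest.records if r.class_name == cls and r.split == "train"]
        eligible = [r for r in manifest.records if r.class_name == cls]
        if len(train_recs) != cur:
            if len(eligible) >= cur and len(train_recs) < cur:
                raise ContractViolationError(
                    f"class {cls}: plan covers {cur} images but only {len(train_recs)} "
                    f"are in the train split; augmentation must not touch val/test records"
                )
            raise ContractViolationError(
                f"class {cls}: plan expects {cur} train images, manifest has {len(train_recs)}"
            )
        for i, (rec, m) in enumerate(zip(train_recs, mult)):
            if m == 0:
                continue
            src = Path(rec.path)
            gray = load_grayscale(src)
            dest_dir = Path(out_dir) / cls if out_dir is not None else src.parent
            dest_dir.mkdir(parents=True, exist_ok=True)
            for j in range(m):
                rng = np.random.default_rng(
                    np.random.SeedSequence([policy.seed, rec.class_index, i, j])
                )
                aug = random_augment(gray, policy, rng)
                dest = dest_dir / f"{src.stem}__aug{j}.png"
                Image.fromarray((np.clip(aug, 0, 1) * 255).round().astype(np.uint8)).save(dest)
                new_records.append(
                    ImageRecord(
                        path=str(dest),
                        class_index=rec.class_index,
                        class_name=rec.class_name,
                        split="train",
                        origin="augmented",
                        source_image=rec.path,
                    )
                )
    return DatasetManifest(
        records=new_records,
        class_names=list(manifest.class_names),
        created_seed=manifest.created_seed,
    )
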