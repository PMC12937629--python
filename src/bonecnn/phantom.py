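"""Synthetic bone-radiograph phantoms with class-conditional lesions.

Each phantom renders a vertical long-bone band — bright cortical
stripes flanking a darker medullary cavity with faint trabecular
texture — over a soft-tissue background, then stamps one lesion motif
keyed to the class label, echoing the radiographic vocabulary that
distinguishes tumour families (lysis, matrix, periosteal reaction):

=====  ==========================================================
class  motif
=====  ==========================================================
0      sharply marginated lytic disc with a sclerotic rim
1      moth-eaten cluster of small lucencies
2      ground-glass textured patch (intentionally confusable with 1)
3      exostotic protrusion off the cortex
4      radiating sunburst spicules
5      concentric onion-skin laminations
6      expansile segment with thinned cortex
7      punctate calcifications inside a lucent patch
8      horizontal trabecular striations
=====  ==========================================================

A Gaussian point-spread blur and additive Gaussian noise finish the
image, clipped to [0, 1].  Everything is driven by a seeded generator,
so a (class, spec, seed) triple maps to one exact image.  The phantoms
make no claim of radiological realism; they exist so the full pipeline
is exercisable and its tests meaningful without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .data import DatasetManifest, ImageRecord
from .errors import ConfigurationError, InputError

MEDULLA = 0.55
CORTEX = 0.85
SOFT_TISSUE = 0.18
TRABECULAR_AMP = 0.04  # kept well under contrast/2 so lesions dominate


@dataclass
class PhantomSpec:
    image_size: int = 224
    num_classes: int = 9
    noise_sd: float = 0.03
    contrast: float = 0.35
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ConfigurationError(f"image_size must be >= 32, got {self.image_size}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 < self.contrast <= 1:
            raise ConfigurationError(f"contrast must lie in (0, 1], got {self.contrast}")
        if self.num_classes < 1:
            raise ConfigurationError("num_classes must be >= 1")


def _disc(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, r: float) -> np.ndarray:
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def generate_phantom(
    class_index: int,
    spec: PhantomSpec,
    draw: np.random.Generator | None = None,
    return_meta: bool = False,
):
    """Render one phantom for ``class_index``; grayscale in [0, 1].

    ``draw`` supplies all randomness; when omitted it is derived from
    ``(spec.seed, class_index)`` so the call is reproducible on its own.
    """
    if not 0 <= class_index < spec.num_classes:
        raise InputError(f"class_index {class_index} outside 0..{spec.num_classes - 1}")
    rng = draw if draw is not None else np.random.default_rng(
        np.random.SeedSequence([spec.seed, class_index])
    )
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    # soft tissue with a gentle vertical exposure gradient
    img = SOFT_TISSUE + 0.04 * (yy / s)

    # bone band geometry
    cx = s * (0.5 + rng.uniform(-0.05, 0.05))
    bw = s * (0.17 + rng.uniform(-0.02, 0.02))  # half-width
    ct = max(2.0, s * 0.045)  # cortical thickness
    band = np.abs(xx - cx) <= bw
    medulla = np.abs(xx - cx) <= bw - ct
    img[band] = CORTEX
    img[medulla] = MEDULLA

    # faint trabecular texture inside the medulla (bounded amplitude)
    f1, f2 = rng.uniform(4, 9), rng.uniform(4, 9)
    p1, p2 = rng.uniform(0, 2 * np.pi, 2)
    tex = TRABECULAR_AMP * np.sin(2 * np.pi * f1 * yy / s + p1) * np.sin(2 * np.pi * f2 * xx / s + p2)
    img[medulla] += tex[medulla]

    # lesion placement inside the medulla
    ly = s * rng.uniform(0.30, 0.70)
    lx = cx + rng.uniform(-0.5, 0.5) * (bw - ct)
    r = s * rng.uniform(0.075, 0.11)
    c = spec.contrast
    k = class_index

    if k == 0:  # lytic disc with sclerotic rim
        rim = _disc(yy, xx, ly, lx, r + max(2.0, 0.02 * s)) & ~_disc(yy, xx, ly, lx, r)
        img[rim & medulla] = MEDULLA + 0.25
        img[_disc(yy, xx, ly, lx, r) & medulla] = MEDULLA - c
    elif k == 1:  # moth-eaten lucency cluster
        for _ in range(int(rng.integers(6, 11))):
            oy, ox = rng.uniform(-1.1 * r, 1.1 * r, 2)
            img[_disc(yy, xx, ly + oy, lx + ox, r * rng.uniform(0.2, 0.38)) & medulla] = MEDULLA - c
    elif k == 2:  # ground-glass patch
        patch = _disc(yy, xx, ly, lx, 1.2 * r) & medulla
        g1, g2 = rng.uniform(10, 18, 2)
        q1, q2 = rng.uniform(0, 2 * np.pi, 2)
        gg = 0.10 * np.sin(2 * np.pi * g1 * yy / s + q1) * np.cos(2 * np.pi * g2 * xx / s + q2)
        img[patch] = MEDULLA - 0.5 * c + gg[patch]
    elif k == 3:  # exostotic protrusion off the cortex
        side = 1 if rng.random() < 0.5 else -1
        ex = cx + side * bw
        img[_disc(yy, xx, ly, ex, 1.1 * r)] = CORTEX
    elif k == 4:  # sunburst spicules radiating from the cortex
        side = 1 if rng.random() < 0.5 else -1
        ox = cx + side * (bw - ct / 2)
        ang = np.arctan2(yy - ly, xx - ox)
        dist = np.hypot(yy - ly, xx - ox)
        n_rays = int(rng.integers(9, 15))
        phase = rng.uniform(0, 2 * np.pi)
        rays = (np.cos(n_rays * ang + phase) > 0.82) & (dist <= 1.8 * r) & (dist >= 2)
        img[rays] = 0.92
    elif k == 5:  # onion-skin laminations
        side = 1 if rng.random() < 0.5 else -1
        ox = cx + side * bw
        dist = np.hypot(yy - ly, xx - ox)
        period = max(3.0, 0.028 * s)
        rings = (np.cos(2 * np.pi * dist / period) > 0.55) & (dist <= 1.9 * r)
        img[rings] = 0.82
    elif k == 6:  # expansile segment with thinned cortex
        span = np.abs(yy - ly) <= 1.4 * r
        img[span & medulla] = MEDULLA - 0.6 * c
        img[span & band & ~medulla] = 0.62
    elif k == 7:  # punctate calcifications in a lucent patch
        patch = _disc(yy, xx, ly, lx, 1.15 * r) & medulla
        img[patch] = MEDULLA - 0.7 * c
        for _ in range(int(rng.integers(8, 14))):
            oy, ox = rng.uniform(-0.9 * r, 0.9 * r, 2)
            img[_disc(yy, xx, ly + oy, lx + ox, max(1.2, 0.008 * s)) & patch] = 0.95
    elif k == 8:  # horizontal trabecular striations
        region = _disc(yy, xx, ly, lx, 1.3 * r) & medulla
        period = max(4.0, 0.03 * s)
        stripes = np.sin(2 * np.pi * yy / period) > 0.1
        img[region & stripes] = MEDULLA + 0.2

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    if return_meta:
        meta = {
            "band_center": cx,
            "band_half_width": bw,
            "cortex_thickness": ct,
            "medulla_level": MEDULLA,
            "lesion_center": (ly, lx),
            "lesion_radius": r,
            "class_index": k,
        }
        return img, meta
    return img


def generate_dataset(
    n_per_class: int, spec: PhantomSpec, out_dir: str | Path
) -> DatasetManifest:
    """Write ``n_per_class`` phantoms per class as 8-bit PNGs.

    Layout is ``out_dir/class_<k>/img_<i>.png``; the returned manifest
    has all splits unassigned.  Per-image streams derive from
    ``(spec.seed, class, index)``, so two runs with the same seed write
    identical bytes.
    """
    if n_per_class < 1:
        raise InputError(f"n_per_class must be >= 1, got {n_per_class}")
    out_dir = Path(out_dir)
    records: list[ImageRecord] = []
    class_names = [f"class_{k}" for k in range(spec.num_classes)]
    for k in range(spec.num_classes):
        d = out_dir / class_names[k]
        try:
            d.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {d}: {exc}") from exc
        for i in range(n_per_class):
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, k, i]))
            img = generate_phantom(k, spec, draw=rng)
            path = d / f"img_{i:04d}.png"
            Image.fromarray((img * 255).round().astype(np.uint8)).save(path)
            records.append(ImageRecord(path=str(path), class_index=k, class_name=class_names[k]))
    return DatasetManifest(records=records, class_names=class_names, created_seed=spec.seed)


def phantom_tensor_dataset(
    n_per_class: int, spec: PhantomSpec, normalized: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """In-memory phantom batch: (n, 3, S, S) float32 tensors + labels.

    Uses the same per-image seeding as :func:`generate_dataset` (without
    the 8-bit quantisation round trip).  With ``normalized`` the
    three-channel replication is followed by ImageNet standardisation.
    """
    from .imaging import NormalizationSpec, normalize

    xs, ys = [], []
    for k in range(spec.num_classes):
        for i in range(n_per_class):
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, k, i]))
            img = generate_phantom(k, spec, draw=rng)
            t = np.repeat(img[None].astype(np.float32), 3, axis=0)
            if normalized:
                t = normalize(t, NormalizationSpec()).astype(np.float32)
            xs.append(t)
            ys.append(k)
    return np.stack(xs), np.asarray(ys, dtype=np.int64)
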