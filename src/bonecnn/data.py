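"""Dataset manifests, stratified splitting, and k-fold planning.

A manifest is the single source of truth for what the pipeline trains
and evaluates on: one record per PNG with its class, split assignment
(train/val/test), and provenance (original vs augmented).  Splitting is
image-level and stratified: within every class the records are shuffled
with the split seed and partitioned so each subset's size is within one
image of ``n * fraction`` (floor allocation plus largest-remainder
correction).  Augmented records may only ever carry ``split=train``, so
validation and test sets contain original images only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, InputError

SPLIT_TOKENS = ("train", "val", "test", "unassigned")
ORIGIN_TOKENS = ("original", "augmented")
MANIFEST_COLUMNS = ["path", "class_index", "class_name", "split", "origin", "source_image", "seed"]


@dataclass
class ImageRecord:
    path: str
    class_index: int
    class_name: str
    split: str = "unassigned"
    origin: str = "original"
    source_image: str | None = None

    def __post_init__(self) -> None:
        if self.split not in SPLIT_TOKENS:
            raise FormatError(f"unknown split token {self.split!r} for {self.path}")
        if self.origin not in ORIGIN_TOKENS:
            raise FormatError(f"unknown origin token {self.origin!r} for {self.path}")
        if self.origin == "augmented" and (self.split != "train" or not self.source_image):
            raise ConfigurationError(
                f"augmented record {self.path} must have split=train and a source_image"
            )


@dataclass
class DatasetManifest:
    records: list[ImageRecord] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)
    created_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        paths = [r.path for r in self.records]
        if len(set(paths)) != len(paths):
            dupes = sorted({p for p in paths if paths.count(p) > 1})
            raise ConfigurationError(f"duplicate record paths in manifest: {dupes[:3]}")
        k = len(self.class_names)
        for r in self.records:
            if not 0 <= r.class_index < k:
                raise ConfigurationError(
                    f"record {r.path}: class_index {r.class_index} outside 0..{k - 1}"
                )
            if self.class_names[r.class_index] != r.class_name:
                raise ConfigurationError(
                    f"record {r.path}: class_name {r.class_name!r} does not match index"
                )
        used = {r.class_index for r in self.records}
        if self.records and used != set(range(k)):
            missing = sorted(set(range(k)) - used)
            warnings.warn(f"classes with no records: {[self.class_names[i] for i in missing]}")

    def by_split(self, split: str) -> list[ImageRecord]:
        return [r for r in self.records if r.split == split]

    def class_counts(self, split: str | None = None) -> dict[str, int]:
        counts = {c: 0 for c in self.class_names}
        for r in self.records:
            if split is None or r.split == split:
                counts[r.class_name] += 1
        return counts


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions):
            raise ConfigurationError("split fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigurationError(f"split fractions must sum to 1, got {self.fractions}")


@dataclass
class FoldPlan:
    k: int
    assignments: list[int]  # fold id per manifest record, aligned by index
    seed: int = 0

    def val_indices(self, fold: int) -> list[int]:
        return [i for i, f in enumerate(self.assignments) if f == fold]

    def train_indices(self, fold: int) -> list[int]:
        return [i for i, f in enumerate(self.assignments) if f != fold]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_manifest(root: str | Path, seed: int = 0) -> DatasetManifest:
    """Scan ``root/<class_name>/*.png`` into a manifest.

    Class order is the sorted directory names; all splits start
    unassigned.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise InputError(f"no class directories under {root}")
    records: list[ImageRecord] = []
    class_names = [d.name for d in class_dirs]
    for idx, d in enumerate(class_dirs):
        files = sorted(d.glob("*.png"))
        if not files:
            warnings.warn(f"class directory {d} contains no PNG files")
        for f in files:
            records.append(ImageRecord(path=str(f), class_index=idx, class_name=d.name))
    return DatasetManifest(records=records, class_names=class_names, created_seed=seed)


def _largest_remainder_sizes(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Subset sizes summing to n with |size - n*f| <= 1 for every subset."""
    exact = [n * f for f in fractions]
    sizes = [math.floor(e) for e in exact]
    leftover = n - sum(sizes)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in order[:leftover]:
        sizes[i] += 1
    return sizes


def stratified_split(manifest: DatasetManifest, spec: SplitSpec) -> DatasetManifest:
    """Assign train/val/test per class, stratified and seeded.

    Within each class the records are shuffled with ``spec.seed`` and
    cut into subsets sized by floor allocation plus largest-remainder
    correction, so every subset is within one image of its exact share.
    """
    if any(r.split != "unassigned" for r in manifest.records):
        raise InputError("stratified_split expects a manifest with all splits unassigned")
    rng = np.random.default_rng(spec.seed)
    n_subsets = sum(1 for f in spec.fractions if f > 0)
    names = ("train", "val", "test")
    for cls in manifest.class_names:
        idxs = [i for i, r in enumerate(manifest.records) if r.class_name == cls]
        if not idxs:
            continue
        if len(idxs) < n_subsets:
            raise InputError(
                f"class {cls!r} has {len(idxs)} records, fewer than the {n_subsets} subsets"
            )
        rng.shuffle(idxs)
        sizes = _largest_remainder_sizes(len(idxs), spec.fractions)
        pos = 0
        for name, size in zip(names, sizes):
            for i in idxs[pos : pos + size]:
                manifest.records[i].split = name
            pos += size
    return manifest


def kfold_plan(manifest: DatasetManifest, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k-fold assignment over all manifest records.

    Per class the records are shuffled with ``seed`` and dealt to folds
    cyclically, so per-class fold sizes differ by at most one and the
    folds partition the record set.
    """
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    assignments = [-1] * len(manifest.records)
    cursor = int(rng.integers(k))  # rotates which folds receive the extras
    for cls in manifest.class_names:
        idxs = [i for i, r in enumerate(manifest.records) if r.class_name == cls]
        if 0 < len(idxs) < k:
            raise InputError(f"class {cls!r} has {len(idxs)} records, fewer than k={k}")
        rng.shuffle(idxs)
        # deal cyclically, continuing the cursor across classes so both
        # per-class and overall fold sizes stay within one of each other
        for pos, i in enumerate(idxs):
            assignments[i] = (cursor + pos) % k
        cursor = (cursor + len(idxs)) % k
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Serialise to the documented CSV layout (UTF-8, header required)."""
    rows = [
        {
            "path": r.path,
            "class_index": r.class_index,
            "class_name": r.class_name,
            "split": r.split,
            "origin": r.origin,
            "source_image": r.source_image or "",
            "seed": manifest.created_seed,
        }
        for r in manifest.records
    ]
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Parse a manifest CSV; the inverse of :func:`write_manifest`."""
    try:
        df = pd.read_csv(path, dtype={"source_image": "string"}, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse manifest {path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} is missing columns: {missing}")
    records: list[ImageRecord] = []
    class_map: dict[int, str] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.split not in SPLIT_TOKENS:
            raise FormatError(f"{path} line {line_no}: unknown split token {row.split!r}")
        if row.origin not in ORIGIN_TOKENS:
            raise FormatError(f"{path} line {line_no}: unknown origin token {row.origin!r}")
        src = str(row.source_image) if str(row.source_image) else None
        records.append(
            ImageRecord(
                path=str(row.path),
                class_index=int(row.class_index),
                class_name=str(row.class_name),
                split=str(row.split),
                origin=str(row.origin),
                source_image=src,
            )
        )
        class_map[int(row.class_index)] = str(row.class_name)
    if records:
        k = max(class_map) + 1
        class_names = [class_map.get(i, f"class_{i}") for i in range(k)]
    else:
        class_names = []
    seed = int(df["seed"].iloc[0]) if len(df) else 0
    return DatasetManifest(records=records, class_names=class_names, created_seed=seed)
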