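"""Intensity normalization, ROI cropping, resizing, augmentation and dataset
partitioning.

Z-score normalization maps a pixel population to zero mean and unit variance.
Statistics are computed either over the pooled pixels of a whole record
collection (``dataset`` scope — the default pipeline computes them on the
training split only and applies them everywhere, which avoids test-set
leakage) or per image (``per_image`` scope, which additionally removes
per-acquisition brightness/contrast offsets).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage import transform as sktransform

from .records import SliceRecord

__all__ = [
    "DatasetStats",
    "SplitPlan",
    "FoldAssignment",
    "AugmentSpec",
    "compute_dataset_stats",
    "zscore_normalize",
    "normalize_records",
    "crop_to_roi",
    "resize_to",
    "augment",
    "augment_to_count",
    "split_dataset",
    "assign_patient_folds",
]

MASK_BINARIZE_THRESHOLD = 0.5


@dataclass
class DatasetStats:
    """Mean/standard deviation of a pixel population (population std, ddof=0)."""

    mean: float
    std: float

    @property
    def valid(self) -> bool:
        return self.std > 0.0


@dataclass
class SplitPlan:
    train_indices: np.ndarray
    val_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self):
        sets = [set(map(int, s)) for s in (self.train_indices, self.val_indices, self.test_indices)]
        n = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != n:
            raise ValueError("split partitions must be pairwise disjoint")


@dataclass
class FoldAssignment:
    fold_of_patient: dict[str, int]
    k: int

    def patients_in_fold(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.fold_of_patient.items() if f == fold)

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.fold_of_patient.values():
            sizes[f] += 1
        return sizes


def compute_dataset_stats(
    records: Sequence[SliceRecord],
    scope: Literal["dataset", "per_image"] = "dataset",
):
    """Pooled-pixel statistics (``dataset``) or one DatasetStats per record
    (``per_image``)."""
    if len(records) == 0:
        raise ValueError("cannot compute statistics of an empty record collection")
    for r in records:
        if r.image.size == 0:
            raise ValueError("records contain an empty image")
    if scope == "per_image":
        return [
            DatasetStats(float(r.image.mean()), float(r.image.std())) for r in records
        ]
    if scope != "dataset":
        raise ValueError(f"unknown scope {scope!r}")
    # Two accumulator pooled pass; exact for the population mean/std.
    n = sum(r.image.size for r in records)
    total = sum(float(r.image.sum()) for r in records)
    mean = total / n
    ss = sum(float(((r.image - mean) ** 2).sum()) for r in records)
    return DatasetStats(mean, float(np.sqrt(ss / n)))


def zscore_normalize(image: np.ndarray, stats: DatasetStats) -> np.ndarray:
    """Map `image` to (image - mean)/std using the supplied statistics."""
    if not stats.valid:
        raise ValueError(
            "cannot z-score normalize: the pixel population is constant "
            f"(mean {stats.mean}, std 0)"
        )
    return (np.asarray(image, dtype=np.float64) - stats.mean) / stats.std


def normalize_records(
    records: Sequence[SliceRecord],
    stats: DatasetStats | None = None,
    scope: Literal["dataset", "per_image"] = "dataset",
) -> list[SliceRecord]:
    """Z-score every record; with ``dataset`` scope, `stats` may be passed in
    (e.g. computed on the training split)."""
    if scope == "per_image":
        per = compute_dataset_stats(records, "per_image")
        return [r.copy_with(zscore_normalize(r.image, s), r.mask) for r, s in zip(records, per)]
    if stats is None:
        stats = compute_dataset_stats(records, "dataset")
    return [r.copy_with(zscore_normalize(r.image, stats), r.mask) for r in records]


def crop_to_roi(record: SliceRecord, margin: int = 0) -> SliceRecord:
    """Crop image and mask to the mask bounding box expanded by `margin`
    pixels, clipped to the image bounds (half-open windows, row-major)."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    coords = np.argwhere(record.mask)
    if coords.size == 0:
        raise ValueError(
            f"record {record.patient_id}/{record.slice_index} has an empty mask; "
            "only lesion-containing slices are kept"
        )
    (r0, c0), (r1, c1) = coords.min(axis=0), coords.max(axis=0) + 1
    h, w = record.mask.shape
    r0, c0 = max(0, r0 - margin), max(0, c0 - margin)
    r1, c1 = min(h, r1 + margin), min(w, c1 + margin)
    return record.copy_with(record.image[r0:r1, c0:c1], record.mask[r0:r1, c0:c1])


def resize_to(record: SliceRecord, side: int) -> SliceRecord:
    """Resample to side x side: bilinear for the image, nearest-neighbour +
    re-binarization for the mask."""
    if side < 8:
        raise ValueError("side must be >= 8")
    if record.image.shape == (side, side):
        return record.copy_with(record.image.copy(), record.mask.copy())
    image = sktransform.resize(
        record.image.astype(np.float64),
        (side, side),
        order=1,
        preserve_range=True,
        anti_aliasing=False,
    )
    mask = sktransform.resize(
        record.mask.astype(np.float64),
        (side, side),
        order=0,
        preserve_range=True,
        anti_aliasing=False,
    )
    return record.copy_with(image, (mask > MASK_BINARIZE_THRESHOLD).astype(np.uint8))


@dataclass
class AugmentSpec:
    """Which geometric transforms to apply and their magnitudes.

    Magnitudes stay mild to preserve anatomical plausibility: small in-plane
    rotations, horizontal mirroring, and gentle affine scale/shear.
    """

    transforms: tuple[str, ...] = ("mirror", "rotate", "affine")
    rotation_degrees: tuple[float, ...] = (-10.0, -5.0, 5.0, 10.0)
    scale_range: tuple[float, float] = (0.9, 1.1)
    max_shear_degrees: float = 5.0

    KNOWN = ("mirror", "rotate", "affine")


def _apply_transform(
    record: SliceRecord, name: str, spec: AugmentSpec, rng: np.random.Generator
) -> SliceRecord:
    if name == "mirror":
        return record.copy_with(record.image[:, ::-1].copy(), record.mask[:, ::-1].copy())
    if name == "rotate":
        angle = float(rng.choice(spec.rotation_degrees))
        image = sktransform.rotate(
            record.image.astype(np.float64), angle, order=1, preserve_range=True
        )
        mask = sktransform.rotate(
            record.mask.astype(np.float64), angle, order=0, preserve_range=True
        )
        return record.copy_with(image, (mask > MASK_BINARIZE_THRESHOLD).astype(np.uint8))
    if name == "affine":
        scale = float(rng.uniform(*spec.scale_range))
        shear = float(np.deg2rad(rng.uniform(-spec.max_shear_degrees, spec.max_shear_degrees)))
        h, w = record.image.shape
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        tf = (
            sktransform.AffineTransform(translation=-center)
            + sktransform.AffineTransform(scale=scale, shear=shear)
            + sktransform.AffineTransform(translation=center)
        )
        image = sktransform.warp(
            record.image.astype(np.float64), tf.inverse, order=1, preserve_range=True
        )
        mask = sktransform.warp(
            record.mask.astype(np.float64), tf.inverse, order=0, preserve_range=True
        )
        return record.copy_with(image, (mask > MASK_BINARIZE_THRESHOLD).astype(np.uint8))
    raise ValueError(f"unknown transform {name!r}; known: {AugmentSpec.KNOWN}")


def augment(
    record: SliceRecord, spec: AugmentSpec | None = None, seed: int = 0
) -> list[SliceRecord]:
    """Return the original record plus one transformed copy per named
    transform; image and mask receive the identical geometric transform."""
    spec = spec or AugmentSpec()
    rng = np.random.default_rng(seed)
    out = [record]
    for name in spec.transforms:
        out.append(_apply_transform(record, name, spec, rng))
    return out


def augment_to_count(
    records: Sequence[SliceRecord],
    target_count: int,
    spec: AugmentSpec | None = None,
    seed: int = 0,
) -> list[SliceRecord]:
    """Grow a record list to an explicit target size by sampling (record,
    transform) pairs; the originals are always retained."""
    if target_count < len(records):
        raise ValueError("target_count must be >= the number of records")
    spec = spec or AugmentSpec()
    rng = np.random.default_rng(seed)
    out = list(records)
    while len(out) < target_count:
        rec = records[int(rng.integers(len(records)))]
        name = str(rng.choice(spec.transforms))
        out.append(_apply_transform(rec, name, spec, rng))
    return out


def split_dataset(
    n: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1), seed: int = 0
) -> SplitPlan:
    """Seeded shuffle then an 80/10/10-style partition: train and validation
    take the floored counts, the remainder goes to the test set."""
    if n < 3:
        raise ValueError("need at least 3 items to form three non-empty-capable splits")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    return SplitPlan(
        train_indices=perm[:n_train],
        val_indices=perm[n_train : n_train + n_val],
        test_indices=perm[n_train + n_val :],
    )


def assign_patient_folds(
    patient_ids: Sequence[str], k: int, seed: int = 0
) -> FoldAssignment:
    """Seeded shuffle of the distinct patients, then round-robin fold
    assignment; fold sizes differ by at most one."""
    distinct = sorted(set(map(str, patient_ids)))
    if len(distinct) < k:
        raise ValueError(f"need at least {k} distinct patients, got {len(distinct)}")
    rng = np.random.default_rng(seed)
    order = [distinct[i] for i in rng.permutation(len(distinct))]
    return FoldAssignment({p: i % k for i, p in enumerate(order)}, k=k)
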