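"""The per-slice data unit and dataset I/O.

A dataset on disk is a directory of paired grayscale files
``<patient>_<slice>_img.png`` / ``<patient>_<slice>_mask.png`` (8- or 16-bit
PNG; TIFF accepted) plus a manifest CSV with columns
``patient_id,slice_index,image_path,mask_path``. A minimal DICOM ingestion
hook converts pixel data + the PatientID tag to records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SliceRecord",
    "save_dataset",
    "load_dataset",
    "dicom_to_slice_records",
]


@dataclass
class SliceRecord:
    """One 2-D grayscale slice with its binary lesion mask."""

    patient_id: str
    slice_index: int
    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.image.shape}")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image/mask shape mismatch: {self.image.shape} vs {self.mask.shape}"
            )
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")

    def copy_with(self, image: np.ndarray, mask: np.ndarray) -> "SliceRecord":
        return SliceRecord(self.patient_id, self.slice_index, image, mask)


def _to_uint(image: np.ndarray) -> np.ndarray:
    if image.dtype in (np.uint8, np.uint16):
        return image
    lo, hi = float(image.min()), float(image.max())
    if hi <= 1.0 and lo >= 0.0:
        return np.round(image * 255).astype(np.uint8)
    span = hi - lo if hi > lo else 1.0
    return np.round((image - lo) / span * 255).astype(np.uint8)


def save_dataset(records: Iterable[SliceRecord], out_dir: str | Path) -> Path:
    """Write paired PNGs plus manifest.csv; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        stem = f"{rec.patient_id}_{rec.slice_index:04d}"
        img_path = out_dir / f"{stem}_img.png"
        mask_path = out_dir / f"{stem}_mask.png"
        Image.fromarray(_to_uint(rec.image)).save(img_path)
        Image.fromarray((rec.mask.astype(np.uint8) * 255)).save(mask_path)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "slice_index": rec.slice_index,
                "image_path": img_path.name,
                "mask_path": mask_path.name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(path: str | Path) -> list[SliceRecord]:
    """Read a dataset from a manifest CSV (or a directory containing one)."""
    path = Path(path)
    manifest = path / "manifest.csv" if path.is_dir() else path
    base = manifest.parent
    df = pd.read_csv(manifest)
    records = []
    for row in df.itertuples(index=False):
        image = np.asarray(Image.open(base / row.image_path), dtype=np.float64)
        raw_mask = np.asarray(Image.open(base / row.mask_path))
        mask = (raw_mask > (raw_mask.max() / 2 if raw_mask.max() else 0)).astype(np.uint8)
        records.append(
            SliceRecord(str(row.patient_id), int(row.slice_index), image, mask)
        )
    return records


def dicom_to_slice_records(
    files: Sequence[str | Path],
    masks: Optional[Sequence[np.ndarray]] = None,
) -> list[SliceRecord]:
    """Convert a DICOM series to records (pixel data + PatientID tag only).

    Masks, when not supplied, default to all-background; annotation is
    external to the imaging files.
    """
    import pydicom

    records = []
    for i, f in enumerate(files):
        ds = pydicom.dcmread(str(f))
        image = ds.pixel_array.astype(np.float64)
        mask = (
            np.zeros_like(image, dtype=np.uint8)
            if masks is None
            else np.asarray(masks[i], dtype=np.uint8)
        )
        records.append(SliceRecord(str(ds.PatientID), i, image, mask))
    return records
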