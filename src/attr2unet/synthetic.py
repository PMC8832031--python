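"""Synthetic MRI-phantom cohorts for benchmarking the segmentation pipeline.

Real head-and-neck tumor data are rarely shareable, so every experiment in
this package can run on generated phantoms that reproduce the statistical
difficulties of the task rather than its anatomy:

* a single connected lesion whose area, shape irregularity and laterality
  vary widely from slice to slice;
* distractor structures at lesion-like intensity (thin arcs and small blobs)
  that defeat naive intensity thresholding;
* strong per-"scanner" brightness/contrast variation, assigned per patient,
  so pooled intensity statistics cluster by patient the way acquisition
  differences make them cluster in practice.

Generation is fully deterministic per (root seed, patient, slice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from .records import SliceRecord, save_dataset

__all__ = [
    "ScannerProfile",
    "PhantomSpec",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class ScannerProfile:
    """Affine intensity transform + noise applied to a finished slice:
    ``out = gain * (img - 0.5) + 0.5 + offset + noise``. Intensities are in
    [0, 1] units."""

    brightness_offset: float
    contrast_gain: float
    noise_sd: float


DEFAULT_PROFILES = (
    ScannerProfile(-0.15, 0.80, 0.020),
    ScannerProfile(0.00, 1.00, 0.010),
    ScannerProfile(+0.15, 1.25, 0.030),
)


@dataclass
class PhantomSpec:
    image_side: int = 256
    lesion_area_fraction: tuple[float, float] = (0.002, 0.06)
    lesion_irregularity: float = 0.3
    laterality_bias: float = 0.7
    n_distractors: int = 6
    scanner_profiles: tuple[ScannerProfile, ...] = DEFAULT_PROFILES
    quantize_8bit: bool = True
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_area_fraction
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("lesion area fraction range must lie within (0, 1)")
        if len(self.scanner_profiles) == 0:
            raise ValueError("at least one scanner profile is required")
        if self.lesion_irregularity < 0:
            raise ValueError("lesion_irregularity must be >= 0")


@dataclass
class CohortSpec:
    n_patients: int = 20
    slices_per_patient: tuple[int, int] = (3, 12)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.slices_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("slices_per_patient range is empty")


def _rng_for(spec: PhantomSpec, patient_seed: int, slice_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(patient_seed, slice_index))
    )


def _star_blob(rng, side: int, center, r0: float, irregularity: float) -> np.ndarray:
    """Fill a star-convex radial polygon; irregularity 0 gives an ellipse."""
    n_vert = 48
    theta = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
    ecc = rng.uniform(0.7, 1.3)
    rr_base = r0 * np.sqrt(ecc)
    cc_base = r0 / np.sqrt(ecc)
    if irregularity > 0:
        # Smooth periodic radial perturbation from a few random harmonics.
        pert = np.zeros(n_vert)
        for k in range(2, 6):
            pert += rng.normal(0, 1) * np.cos(k * theta) + rng.normal(0, 1) * np.sin(k * theta)
        pert = 1.0 + irregularity * pert / np.max(np.abs(pert))
        pert = np.clip(pert, 0.2, None)
    else:
        pert = np.ones(n_vert)
    rot = rng.uniform(0, np.pi)
    rows = center[0] + rr_base * pert * np.sin(theta + rot)
    cols = center[1] + cc_base * pert * np.cos(theta + rot)
    rr, cc = skdraw.polygon(rows, cols, shape=(side, side))
    out = np.zeros((side, side), dtype=np.uint8)
    out[rr, cc] = 1
    return out


def _head_ellipse(side: int, rng) -> np.ndarray:
    out = np.zeros((side, side), dtype=bool)
    rr, cc = skdraw.ellipse(
        side / 2,
        side / 2,
        side * rng.uniform(0.40, 0.45),
        side * rng.uniform(0.42, 0.47),
        shape=(side, side),
    )
    out[rr, cc] = True
    return out


def generate_phantom(
    spec: PhantomSpec,
    patient_seed: int,
    slice_index: int,
    profile_index: int | None = None,
) -> SliceRecord:
    """Render one slice: background field + ring "anatomy" + distractors +
    a single star-convex lesion, then the scanner intensity transform."""
    rng = _rng_for(spec, patient_seed, slice_index)
    side = spec.image_side
    head = _head_ellipse(side, rng)

    # Smoothed random background inside the head.
    field_ = ndimage.gaussian_filter(rng.standard_normal((side, side)), sigma=side / 16)
    field_ = (field_ - field_.min()) / (field_.max() - field_.min() + 1e-12)
    img = np.where(head, 0.25 + 0.2 * field_, 0.02)

    # Concentric elliptical "anatomy" rings of moderate intensity.
    yy, xx = np.mgrid[0:side, 0:side]
    cy, cx = side / 2 + rng.normal(0, side / 64), side / 2 + rng.normal(0, side / 64)
    radial = np.sqrt(((yy - cy) / (0.45 * side)) ** 2 + ((xx - cx) / (0.48 * side)) ** 2)
    rings = 0.18 * np.maximum(0.0, np.sin(radial * rng.uniform(8, 14))) ** 4
    img = np.where(head, img + rings, img)

    lesion_band = (0.70, 0.85)  # lesion and distractors share this band

    # Distractors: thin arcs and small elongated blobs at lesion intensity.
    for _ in range(spec.n_distractors):
        kind = rng.random()
        c = (rng.uniform(0.2, 0.8) * side, rng.uniform(0.2, 0.8) * side)
        intensity = rng.uniform(*lesion_band)
        if kind < 0.5:
            r_out = rng.uniform(0.03, 0.10) * side
            rr, cc = skdraw.ellipse(c[0], c[1], r_out, r_out * rng.uniform(0.6, 1.4), shape=(side, side))
            outer = np.zeros((side, side), dtype=bool)
            outer[rr, cc] = True
            rr, cc = skdraw.ellipse(c[0], c[1], r_out * 0.7, r_out * 0.7 * rng.uniform(0.6, 1.4), shape=(side, side))
            inner = np.zeros((side, side), dtype=bool)
            inner[rr, cc] = True
            shape_mask = outer & ~inner
        else:
            r = rng.uniform(0.015, 0.05) * side
            rr, cc = skdraw.ellipse(c[0], c[1], r, r * rng.uniform(0.25, 0.6), rotation=rng.uniform(0, np.pi), shape=(side, side))
            shape_mask = np.zeros((side, side), dtype=bool)
            shape_mask[rr, cc] = True
        shape_mask &= head
        img[shape_mask] = intensity

    # Lesion: placed per the laterality bias, retried until its area fraction
    # lands in range and it sits inside the head.
    lo, hi = spec.lesion_area_fraction
    target_frac = rng.uniform(lo, hi)
    target_r = np.sqrt(target_frac * side * side / np.pi)
    mask = None
    for _attempt in range(100):
        left = rng.random() < spec.laterality_bias
        col = rng.uniform(0.18, 0.45) * side if left else rng.uniform(0.55, 0.82) * side
        row = rng.uniform(0.25, 0.75) * side
        cand = _star_blob(rng, side, (row, col), target_r, spec.lesion_irregularity)
        cand &= head.astype(np.uint8)
        frac = cand.sum() / (side * side)
        if lo <= frac <= hi and cand.sum() >= 4:
            mask = cand
            break
    if mask is None:
        raise RuntimeError("could not place a lesion within bounds after 100 attempts")
    lesion_tex = rng.uniform(*lesion_band) + 0.03 * rng.standard_normal((side, side))
    img = np.where(mask.astype(bool), lesion_tex, img)

    # Scanner profile: affine intensity transform + additive noise.
    profiles = spec.scanner_profiles
    if profile_index is None:
        profile_index = patient_seed % len(profiles)
    prof = profiles[profile_index % len(profiles)]
    img = prof.contrast_gain * (img - 0.5) + 0.5 + prof.brightness_offset
    img = img + prof.noise_sd * rng.standard_normal((side, side))
    img = np.clip(img, 0.0, 1.0)
    if spec.quantize_8bit:
        img = np.round(img * 255) / 255.0
    return SliceRecord(f"P{patient_seed:03d}", slice_index, img, mask)


def generate_cohort(spec: CohortSpec) -> tuple[list[SliceRecord], pd.DataFrame]:
    """Generate all patients' slices plus a manifest of patient metadata.

    Each patient draws a slice count from the configured range and is bound
    to one scanner profile, so intensity statistics cluster by patient.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.phantom.seed, spawn_key=(99,)))
    records: list[SliceRecord] = []
    rows = []
    n_profiles = len(spec.phantom.scanner_profiles)
    for p in range(spec.n_patients):
        lo, hi = spec.slices_per_patient
        n_slices = int(rng.integers(lo, hi + 1))
        profile_index = int(rng.integers(n_profiles))
        for s in range(n_slices):
            records.append(generate_phantom(spec.phantom, p, s, profile_index))
        rows.append(
            {
                "patient_id": f"P{p:03d}",
                "n_slices": n_slices,
                "profile_index": profile_index,
            }
        )
    return records, pd.DataFrame(rows)


def write_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Generate a cohort and write the PNG/manifest dataset layout."""
    records, patients = generate_cohort(spec)
    manifest = save_dataset(records, out_dir)
    patients.to_csv(Path(out_dir) / "patients.csv", index=False)
    return manifest
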