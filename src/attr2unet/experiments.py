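"""Experiment harnesses: single runs, the recurrence-step sweep, the ablation
table, patient-wise k-fold cross-validation, and the scaled-down synthetic
benchmark used for acceptance checks.

All harnesses share one split and one root seed so comparisons between models
are paired: every variant sees identical training, validation and test data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import MetricsReport, fold_summary, kruskal_wallis
from .network import (
    VARIANT_NAMES,
    AttR2UNet,
    NetworkConfig,
    build_model,
    count_parameters,
    make_variant,
)
from .preprocessing import (
    AugmentSpec,
    assign_patient_folds,
    augment_to_count,
    compute_dataset_stats,
    normalize_records,
    split_dataset,
)
from .records import SliceRecord
from .synthetic import CohortSpec, PhantomSpec, generate_cohort
from .training import TrainConfig, TrainHistory, evaluate, train

__all__ = [
    "ExperimentConfig",
    "prepare_splits",
    "run_single",
    "run_ablation",
    "run_t_sweep",
    "run_crossval",
    "run_synthetic_benchmark",
    "FULL_MODEL",
]

FULL_MODEL = "Att+Rec+Res"


@dataclass
class ExperimentConfig:
    """Everything needed to re-execute a run."""

    variant: str = FULL_MODEL
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    augment_factor: float = 3.0  # training-split growth via geometric augmentation
    norm_scope: str = "dataset"  # "dataset" (train-split stats) or "per_image"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "network": dataclasses.asdict(self.network),
            "training": dataclasses.asdict(self.training),
            "augment_factor": self.augment_factor,
            "norm_scope": self.norm_scope,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(
            variant=d.get("variant", FULL_MODEL),
            network=NetworkConfig(**d.get("network", {})),
            training=TrainConfig(**d.get("training", {})),
            augment_factor=float(d.get("augment_factor", 3.0)),
            norm_scope=str(d.get("norm_scope", "dataset")),
            seed=int(d.get("seed", 0)),
        )


def prepare_splits(
    records: Sequence[SliceRecord],
    seed: int,
    normalize: bool = True,
    augment_factor: float = 1.0,
    norm_scope: str = "dataset",
) -> tuple[list[SliceRecord], list[SliceRecord], list[SliceRecord]]:
    """80/10/10 split; when `normalize`, z-score all splits — with pooled
    statistics computed on the training split only (``dataset`` scope) or
    image by image (``per_image`` scope).

    ``augment_factor > 1`` grows the training split by sampled geometric
    transforms (rotation, mirroring, mild affine). Augmentation happens after
    the split so no transformed copy of a held-out slice can leak into
    training.
    """
    plan = split_dataset(len(records), seed=seed)
    train_r = [records[i] for i in plan.train_indices]
    val_r = [records[i] for i in plan.val_indices]
    test_r = [records[i] for i in plan.test_indices]
    if augment_factor > 1.0:
        target = int(round(augment_factor * len(train_r)))
        train_r = augment_to_count(train_r, target, AugmentSpec(), seed=seed + 1)
    if normalize:
        if norm_scope == "per_image":
            train_r = normalize_records(train_r, scope="per_image")
            val_r = normalize_records(val_r, scope="per_image")
            test_r = normalize_records(test_r, scope="per_image")
        else:
            stats = compute_dataset_stats(train_r, "dataset")
            train_r = normalize_records(train_r, stats)
            val_r = normalize_records(val_r, stats)
            test_r = normalize_records(test_r, stats)
    return train_r, val_r, test_r


def run_single(
    records: Sequence[SliceRecord],
    config: ExperimentConfig,
) -> tuple[AttR2UNet, TrainHistory, MetricsReport]:
    """Train one variant on a shared split and evaluate on the test split."""
    spec = make_variant(config.variant, base=config.network)
    tr, va, te = prepare_splits(
        records,
        config.seed,
        normalize=spec.config.use_normalization,
        augment_factor=config.augment_factor,
        norm_scope=config.norm_scope,
    )
    model = build_model(spec.config, seed=config.seed)
    model, history = train(model, tr, va, config.training)
    report = evaluate(model, te, threshold=config.training.threshold)
    return model, history, report


def _report_row(name: str, report: MetricsReport) -> dict:
    row: dict = {"model": name}
    for k in ("dsc", "jaccard", "precision", "specificity", "sensitivity"):
        row[k] = report.mean[k]
        row[f"{k}_std"] = report.std[k]
    row["auc"] = report.auc
    return row


def run_ablation(
    records: Sequence[SliceRecord],
    config: ExperimentConfig,
    variants: Sequence[str] = VARIANT_NAMES,
) -> pd.DataFrame:
    """Train/evaluate every ablation variant on identical splits and seeds;
    appends the Kruskal–Wallis p-value of each variant's per-slice DSC
    distribution against the full model's."""
    reports: dict[str, MetricsReport] = {}
    rows = []
    for name in variants:
        cfg = dataclasses.replace(config, variant=name)
        try:
            _, _, report = run_single(records, cfg)
        except Exception as exc:
            raise RuntimeError(f"ablation variant {name!r} failed: {exc}") from exc
        reports[name] = report
        rows.append(_report_row(name, report))
    df = pd.DataFrame(rows)
    if FULL_MODEL in reports:
        full_dsc = list(reports[FULL_MODEL].per_slice["dsc"])
        pvals = []
        for name in df["model"]:
            if name == FULL_MODEL:
                pvals.append(np.nan)
            else:
                _, p = kruskal_wallis([full_dsc, list(reports[name].per_slice["dsc"])])
                pvals.append(p)
        df["kw_p_vs_full"] = pvals
    return df


def run_t_sweep(
    records: Sequence[SliceRecord],
    config: ExperimentConfig,
    t_values: Sequence[int] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """One trained model per recurrence-step count t, on identical splits."""
    if len(t_values) == 0:
        raise ValueError("t_values must be non-empty")
    rows = []
    for t in t_values:
        if t < 1:
            raise ValueError("t values must be >= 1")
        cfg = dataclasses.replace(config, network=dataclasses.replace(config.network, t=int(t)))
        model, _, report = run_single(records, cfg)
        row = _report_row(f"t={t}", report)
        row["t"] = int(t)
        row["n_parameters"] = count_parameters(model)
        rows.append(row)
    return pd.DataFrame(rows)


def run_crossval(
    records: Sequence[SliceRecord],
    config: ExperimentConfig,
    k: int = 5,
    val_fraction: float = 0.1,
) -> pd.DataFrame:
    """Patient-wise k-fold cross-validation of the configured variant.

    Folds come from a seeded round-robin over distinct patients; per fold the
    held-out patients form the test set and a slice-level fraction of the
    remaining data is carved off for validation-based model selection.
    """
    patient_ids = [r.patient_id for r in records]
    folds = assign_patient_folds(patient_ids, k, seed=config.seed)
    spec = make_variant(config.variant, base=config.network)
    rows = []
    fold_dsc = []
    for fold in range(k):
        test_r = [r for r in records if folds.fold_of_patient[r.patient_id] == fold]
        rest = [r for r in records if folds.fold_of_patient[r.patient_id] != fold]
        rng = np.random.default_rng(config.seed + fold)
        perm = rng.permutation(len(rest))
        n_val = max(1, int(val_fraction * len(rest)))
        val_r = [rest[i] for i in perm[:n_val]]
        train_r = [rest[i] for i in perm[n_val:]]
        if spec.config.use_normalization:
            stats = compute_dataset_stats(train_r, "dataset")
            train_r = normalize_records(train_r, stats)
            val_r = normalize_records(val_r, stats)
            test_r = normalize_records(test_r, stats)
        model = build_model(spec.config, seed=config.seed + fold)
        model, _ = train(model, train_r, val_r, config.training)
        report = evaluate(model, test_r, threshold=config.training.threshold)
        fold_dsc.append(report.mean["dsc"])
        rows.append(
            {
                "fold": fold,
                "n_test_patients": len(folds.patients_in_fold(fold)),
                "n_test_slices": len(test_r),
                "dsc": report.mean["dsc"],
            }
        )
    mean, std = fold_summary(fold_dsc)
    df = pd.DataFrame(rows)
    df.attrs["mean_dsc"] = mean
    df.attrs["std_dsc"] = std
    return df


def benchmark_cohort(seed: int, n_patients: int = 20, image_side: int = 64) -> list[SliceRecord]:
    """The reduced-scale phantom cohort used by the synthetic benchmark:
    ~200 64x64 slices across 20 patients."""
    spec = CohortSpec(
        n_patients=n_patients,
        slices_per_patient=(6, 14),
        phantom=PhantomSpec(image_side=image_side, seed=seed),
    )
    records, _ = generate_cohort(spec)
    return records


def benchmark_config(seed: int, variant: str = FULL_MODEL) -> ExperimentConfig:
    """Reduced model + training budget for CPU-scale benchmark runs."""
    return ExperimentConfig(
        variant=variant,
        network=NetworkConfig(base_channels=4, t=2, dropout_rate=0.0, per_step_bn=True),
        training=TrainConfig(epochs=30, batch_size=8, initial_lr=1e-3, seed=seed),
        augment_factor=3.0,
        norm_scope="per_image",
        seed=seed,
    )


def run_synthetic_benchmark(
    seed: int,
    variants: Sequence[str] = (FULL_MODEL, "Skeleton"),
    epochs: int | None = None,
) -> dict[str, MetricsReport]:
    """Train the reduced full-mechanism model (and comparators) on a phantom
    cohort and report held-out metrics, all from one root seed."""
    records = benchmark_cohort(seed)
    out = {}
    for name in variants:
        cfg = benchmark_config(seed, variant=name)
        if epochs is not None:
            cfg = dataclasses.replace(cfg, training=dataclasses.replace(cfg.training, epochs=epochs))
        _, _, report = run_single(records, cfg)
        out[name] = report
    return out
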