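"""End-to-end experiments: phantom cohorts through training to metrics files.

A single :class:`ExperimentConfig` (YAML-serializable) describes the whole
run. One master seed fans out to every random stage through a fixed
derivation — ``SeedSequence((master_seed, stage_code[, index]))`` — so a
partial rerun (one lesion, one fold) reproduces exactly what the full run
produced:

========  ==========================
code  1   cohort generation
code  2   dataset subsampling
code  3   model initialization (per fold: + fold index)
code  4   training shuffle
code  5   augmentation
code  6   training-label permutation (null calibration)
========  ==========================

Outputs land in a config-named directory: the echoed config, per-unit
metrics CSV, ROC points CSV, a JSON summary, and four-colour
classification maps per lesion.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import __version__
from .cube_io import CohortManifest, render_rgb, write_cube, write_mask
from .evaluation import (
    ClassificationMapSpec,
    FoldSummary,
    MetricsRecord,
    aggregate_folds,
    auc,
    confusion_at_threshold,
    metrics_from_confusion,
    render_classification_map,
    roc_curve,
    youden_threshold,
)
from .model import ModelConfig, TrainConfig, build_model, predict_pixelwise, train_model
from .sampling import (
    AugmentationPolicy,
    DatasetSpec,
    SplitSpec,
    build_patch_dataset,
    loo_folds,
    vertical_half_split,
)
from .synthetic import CohortVariability, Phantom, PhantomParams, generate_cohort

logger = logging.getLogger(__name__)

_STAGE_COHORT, _STAGE_DATASET, _STAGE_MODEL = 1, 2, 3
_STAGE_SHUFFLE, _STAGE_AUGMENT, _STAGE_PERMUTE = 4, 5, 6


def derive_seed(master_seed: int, *codes: int) -> int:
    """Deterministic sub-seed (< 2**31) for one pipeline stage."""
    ss = np.random.SeedSequence((master_seed, *codes))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    n_lesions: int = 6
    phantom: dict = field(default_factory=dict)       # PhantomParams overrides
    variability: dict = field(default_factory=dict)   # CohortVariability overrides
    guard_band_px: int = 12
    samples_per_class_per_lesion: int | None = 2000
    validation_fraction: float = 0.2
    spectral_mode: str = "patch_mean"
    model: dict = field(default_factory=dict)         # ModelConfig overrides
    train: dict = field(default_factory=dict)         # TrainConfig overrides
    augment: bool = True
    threshold: float = 0.5
    master_seed: int = 0
    permute_labels: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    # -- derived objects ----------------------------------------------------

    def phantom_params(self) -> PhantomParams:
        return PhantomParams(**self.phantom)

    def cohort_variability(self) -> CohortVariability:
        kw = dict(self.variability)
        if "n_lobes_range" in kw:
            kw["n_lobes_range"] = tuple(kw["n_lobes_range"])
        return CohortVariability(**kw)

    def dataset_spec(self) -> DatasetSpec:
        return DatasetSpec(
            samples_per_class_per_lesion=self.samples_per_class_per_lesion,
            validation_fraction=self.validation_fraction,
            seed=derive_seed(self.master_seed, _STAGE_DATASET),
            spectral_mode=self.spectral_mode,
        )

    def model_config(self) -> ModelConfig:
        kw = dict(self.model)
        for key in ("spatial_channels", "head_hidden_dims"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "spectral_conv_layers" in kw:
            kw["spectral_conv_layers"] = tuple(
                tuple(v) for v in kw["spectral_conv_layers"]
            )
        return ModelConfig(**kw)

    def train_config(self, fold: int = 0) -> TrainConfig:
        return TrainConfig(
            weight_seed=derive_seed(self.master_seed, _STAGE_MODEL, fold),
            shuffle_seed=derive_seed(self.master_seed, _STAGE_SHUFFLE, fold),
            augment_seed=derive_seed(self.master_seed, _STAGE_AUGMENT, fold),
            augmentation=AugmentationPolicy() if self.augment else None,
            **self.train,
        )


def _generate(config: ExperimentConfig) -> list[Phantom]:
    cohort = generate_cohort(
        config.n_lesions,
        base_params=config.phantom_params(),
        variability=config.cohort_variability(),
        seed=derive_seed(config.master_seed, _STAGE_COHORT),
    )
    logger.info("generated cohort of %d phantoms", len(cohort))
    return cohort


def _maybe_permute(dataset, config: ExperimentConfig):
    """Null-calibration switch: shuffle training/validation labels in place."""
    if not config.permute_labels:
        return dataset
    rng = np.random.default_rng(
        np.random.SeedSequence((derive_seed(config.master_seed, _STAGE_PERMUTE), 0))
    )
    for arrays in (dataset.train, dataset.validation):
        arrays.labels = rng.permutation(arrays.labels)
    logger.info("training labels permuted (null calibration)")
    return dataset


def _write_metrics_csv(path: Path, rows: list[dict]) -> None:
    keys = ["unit", "accuracy", "sensitivity", "specificity", "auc",
            "n_pixels", "n_positive", "tp", "tn", "fp", "fn"]
    lines = [",".join(keys)]
    for row in rows:
        lines.append(",".join(_fmt(row.get(k)) for k in keys))
    path.write_text("\n".join(lines) + "\n")


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)


def _write_roc_csv(path: Path, curve) -> None:
    lines = ["fpr,tpr,threshold"]
    for f, t, thr in zip(curve.fpr, curve.tpr, curve.thresholds):
        lines.append(f"{f:.10g},{t:.10g},{thr:.10g}")
    path.write_text("\n".join(lines) + "\n")


@dataclass
class HalfSplitResult:
    metrics: MetricsRecord
    per_lesion: list[MetricsRecord]
    pooled_probs: np.ndarray
    pooled_labels: np.ndarray
    youden: float
    model: object
    prob_maps: dict[str, np.ndarray]
    truth: dict[str, np.ndarray]


def run_halfsplit_experiment(
    config: ExperimentConfig, outdir: str | Path | None = None,
    cohort: list[Phantom] | None = None,
) -> HalfSplitResult:
    """Train one model on the pooled left halves, test on the right halves.

    Pixels from all lesions' test halves are pooled for the headline
    metrics; per-lesion rows and maps are emitted alongside.
    """
    if config.n_lesions < 1:
        raise ValueError("half-split experiment needs at least one lesion")
    phantoms = cohort if cohort is not None else _generate(config)
    images = [p.image for p in phantoms]

    splits = [vertical_half_split(img, config.guard_band_px) for img in images]
    combined = SplitSpec(
        kind="half_split",
        train_cols={k: v for s in splits for k, v in s.train_cols.items()},
        test_cols={k: v for s in splits for k, v in s.test_cols.items()},
        guard_band_px=config.guard_band_px,
    )
    dataset = build_patch_dataset(images, combined, config.dataset_spec())
    dataset = _maybe_permute(dataset, config)
    logger.info(
        "dataset: %d train / %d validation samples, %d test streams",
        len(dataset.train), len(dataset.validation), len(dataset.test),
    )

    model = build_model(config.model_config(),
                        seed=derive_seed(config.master_seed, _STAGE_MODEL))
    train_model(model, dataset.train, dataset.validation, config.train_config())

    cache: dict = {}
    by_id = {img.lesion_id: img for img in images}
    probs_parts, label_parts, per_lesion, rows = [], [], [], []
    prob_maps, truths = {}, {}
    for stream in dataset.test:
        image = by_id[stream.lesion_id]
        region = np.zeros((image.cube.height, image.cube.width), dtype=bool)
        region[stream.centres[:, 0], stream.centres[:, 1]] = True
        pm = predict_pixelwise(model, image, region, feature_cache=cache)
        truth = image.mask.binary_tumour
        prob_maps[stream.lesion_id], truths[stream.lesion_id] = pm, truth
        probs = pm[stream.centres[:, 0], stream.centres[:, 1]]
        probs_parts.append(probs)
        label_parts.append(stream.labels)
        c = confusion_at_threshold(pm, truth, region, config.threshold)
        rec = metrics_from_confusion(c, unit=stream.lesion_id)
        if np.unique(stream.labels).size == 2:
            rec.auc = auc(roc_curve(probs, stream.labels))
        per_lesion.append(rec)
        rows.append({**rec.as_dict(), "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn})

    pooled_probs = np.concatenate(probs_parts)
    pooled_labels = np.concatenate(label_parts).astype(int)
    call = pooled_probs >= config.threshold
    from .evaluation import ConfusionCounts  # local to avoid cycle at import time

    pooled_c = ConfusionCounts(
        tp=int(np.sum(call & (pooled_labels == 1))),
        tn=int(np.sum(~call & (pooled_labels == 0))),
        fp=int(np.sum(call & (pooled_labels == 0))),
        fn=int(np.sum(~call & (pooled_labels == 1))),
    )
    pooled = metrics_from_confusion(pooled_c, unit="pooled")
    curve = roc_curve(pooled_probs, pooled_labels)
    pooled.auc = auc(curve)
    yj = youden_threshold(curve)
    rows.append({**pooled.as_dict(), "tp": pooled_c.tp, "tn": pooled_c.tn,
                 "fp": pooled_c.fp, "fn": pooled_c.fn})

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        _write_metrics_csv(outdir / "metrics.csv", rows)
        _write_roc_csv(outdir / "roc.csv", curve)
        (outdir / "summary.json").write_text(json.dumps(
            {
                "experiment": "half_split",
                "version": __version__,
                "pooled": pooled.as_dict(),
                "youden_threshold": yj,
                "split": combined.to_json(),
                "best_epoch": model.best_epoch,
            }, indent=2, sort_keys=True) + "\n")
        map_spec = ClassificationMapSpec(threshold=config.threshold)
        maps_dir = outdir / "maps"
        maps_dir.mkdir(exist_ok=True)
        for lesion_id, pm in prob_maps.items():
            img = render_classification_map(pm, truths[lesion_id], map_spec)
            Image.fromarray(img).save(maps_dir / f"{lesion_id}.png")

    return HalfSplitResult(
        metrics=pooled, per_lesion=per_lesion, pooled_probs=pooled_probs,
        pooled_labels=pooled_labels, youden=yj, model=model,
        prob_maps=prob_maps, truth=truths,
    )


@dataclass
class LooResult:
    folds: list[MetricsRecord]
    summary: FoldSummary


def run_loo_experiment(
    config: ExperimentConfig, outdir: str | Path | None = None,
    cohort: list[Phantom] | None = None,
) -> LooResult:
    """Image-level leave-one-out: one model per fold, mean +/- SD across folds."""
    if config.n_lesions < 2:
        raise ValueError("leave-one-out needs a cohort of >= 2 lesions")
    phantoms = cohort if cohort is not None else _generate(config)
    images = [p.image for p in phantoms]
    folds = loo_folds(images)
    by_id = {img.lesion_id: img for img in images}

    records, rows = [], []
    for fold in folds:
        dataset = build_patch_dataset(images, fold, config.dataset_spec())
        dataset = _maybe_permute(dataset, config)
        model = build_model(
            config.model_config(),
            seed=derive_seed(config.master_seed, _STAGE_MODEL, fold.fold_index),
        )
        train_model(model, dataset.train, dataset.validation,
                    config.train_config(fold.fold_index))
        (stream,) = dataset.test
        image = by_id[stream.lesion_id]
        pm = predict_pixelwise(model, image)
        truth = image.mask.binary_tumour
        c = confusion_at_threshold(pm, truth, threshold=config.threshold)
        rec = metrics_from_confusion(c, unit="per-fold")
        probs = pm[stream.centres[:, 0], stream.centres[:, 1]]
        if np.unique(stream.labels).size == 2:
            rec.auc = auc(roc_curve(probs, stream.labels))
        records.append(rec)
        rows.append({**rec.as_dict(), "unit": f"fold-{fold.fold_index}:{stream.lesion_id}",
                     "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn})
        logger.info("fold %d (%s): %s", fold.fold_index, stream.lesion_id, rec.as_dict())

    summary = aggregate_folds(records)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        _write_metrics_csv(outdir / "fold_metrics.csv", rows)
        (outdir / "summary.json").write_text(json.dumps(
            {
                "experiment": "leave_one_out",
                "version": __version__,
                "n_folds": len(records),
                "mean": summary.mean,
                "sd": summary.sd,
            }, indent=2, sort_keys=True) + "\n")
    return LooResult(folds=records, summary=summary)


def run_phantom_demo(config: ExperimentConfig, outdir: str | Path) -> CohortManifest:
    """Write a phantom cohort to disk: ENVI cubes, mask PNGs, RGB previews,
    and annotation overlays (clinical region vs subclinical lobes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    phantoms = _generate(config)
    entries = []
    for p in phantoms:
        lid = p.image.lesion_id
        write_cube(p.image.cube, outdir / f"{lid}.raw")
        write_mask(p.image.mask, outdir / f"{lid}_mask.png")
        rgb = render_rgb(p.image.cube)
        Image.fromarray(rgb).save(outdir / f"{lid}_rgb.png")
        overlay = rgb.copy()
        clinical = p.image.mask.labels == 1
        subclinical = p.image.mask.labels == 2
        overlay[clinical] = (0.5 * overlay[clinical] + 0.5 * np.array([220, 40, 40])).astype(np.uint8)
        overlay[subclinical] = (0.5 * overlay[subclinical] + 0.5 * np.array([250, 220, 40])).astype(np.uint8)
        Image.fromarray(overlay).save(outdir / f"{lid}_overlay.png")
        entries.append({
            "lesion_id": lid,
            "cube": f"{lid}.raw",
            "mask": f"{lid}_mask.png",
            "files": [f"{lid}.raw", f"{lid}.raw.hdr", f"{lid}_mask.png",
                      f"{lid}_rgb.png", f"{lid}_overlay.png"],
            "metadata": {
                "size_mm": p.image.metadata["size_mm"],
                "subclinical_extension": p.image.metadata["subclinical_extension"],
            },
        })
    manifest = CohortManifest(entries=entries)
    manifest.save(outdir / "manifest.json")
    return manifest
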