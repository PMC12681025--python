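"""Dual-branch spatial/spectral pixel classifier.

The classifier sees each pixel through two branches:

* a **spatial branch** — a compact strided 2-D convolution stack over the
  25x25x3 slab of selected wavelengths, ending in global average pooling;
* a **spectral branch** — a 1-D convolution stack along the 120-band
  normalized mean spectrum, also globally pooled.

The pooled features are concatenated and passed through a small
fully-connected head producing one logit; ``sigmoid(logit)`` is the tumour
probability of the central pixel. Training minimizes binary cross-entropy
with logits using Adam, with early stopping on validation loss. Either
branch can be switched off (ablation), in which case the head consumes the
remaining branch alone.

Everything runs on CPU in NumPy and is bit-deterministic given the seeds.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import nn
from .cube_io import LesionImage
from .sampling import (
    AugmentationPolicy,
    SampleArrays,
    augment_batch,
    pixel_features,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the dual-branch network."""

    spatial_backbone: str = "compact-2d"  # the only supported backbone
    spatial_channels: tuple[int, ...] = (8, 16)
    spatial_kernel: int = 3
    spatial_stride: int = 2
    spectral_conv_layers: tuple[tuple[int, int, int], ...] = ((8, 7, 2), (16, 5, 2))
    head_hidden_dims: tuple[int, ...] = (32,)
    dropout: float = 0.0
    use_spatial: bool = True
    use_spectral: bool = True
    n_bands: int = 120
    patch_channels: int = 3

    def __post_init__(self):
        if self.spatial_backbone != "compact-2d":
            raise ValueError(
                f"spatial backbone {self.spatial_backbone!r} is not available in "
                "this build; only the compact 2-D stack is supported (a "
                "pretrained EfficientNet branch would require a GPU deep-"
                "learning runtime and downloaded weights)"
            )
        if not (self.use_spatial or self.use_spectral):
            raise ValueError("at least one branch must be enabled")
        if self.dropout < 0 or self.dropout >= 1:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def spatial_feature_dim(self) -> int:
        return self.spatial_channels[-1] if self.use_spatial else 0

    @property
    def spectral_feature_dim(self) -> int:
        return self.spectral_conv_layers[-1][0] if self.use_spectral else 0


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 5
    weight_seed: int = 0
    shuffle_seed: int = 0
    positive_class_weight: float | str | None = None  # number | "auto" | None
    augmentation: AugmentationPolicy | None = None
    augment_seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


class TwoBranchModel:
    """Built (possibly trained) dual-branch network."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0x2B)))
        c = config

        if c.use_spatial:
            layers, c_in = [], c.patch_channels
            for c_out in c.spatial_channels:
                layers += [
                    nn.Conv2D(c_in, c_out, c.spatial_kernel, c.spatial_stride, rng),
                    nn.ReLU(),
                ]
                c_in = c_out
            layers.append(nn.GlobalAvgPool())
            self.spatial_branch = nn.Sequential(layers)
        else:
            self.spatial_branch = None

        if c.use_spectral:
            layers, c_in = [], 1
            for c_out, kernel, stride in c.spectral_conv_layers:
                layers += [nn.Conv1D(c_in, c_out, kernel, stride, rng), nn.ReLU()]
                c_in = c_out
            layers.append(nn.GlobalAvgPool())
            self.spectral_branch = nn.Sequential(layers)
        else:
            self.spectral_branch = None

        d_in = c.spatial_feature_dim + c.spectral_feature_dim
        head_layers: list[nn.Layer] = []
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD0)))
        for d_out in c.head_hidden_dims:
            head_layers += [nn.Dense(d_in, d_out, rng), nn.ReLU()]
            if c.dropout > 0:
                head_layers.append(nn.Dropout(c.dropout, self._dropout_rng))
            d_in = d_out
        head_layers.append(nn.Dense(d_in, 1, rng))
        self.head = nn.Sequential(head_layers)

        self.train_config: TrainConfig | None = None
        self.training_log: list[dict] = []
        self.best_epoch: int | None = None

    # -- parameter plumbing -------------------------------------------------

    @property
    def parameters(self) -> list[np.ndarray]:
        out = []
        for branch in (self.spatial_branch, self.spectral_branch, self.head):
            if branch is not None:
                out += branch.all_params
        return out

    @property
    def gradients(self) -> list[np.ndarray]:
        out = []
        for branch in (self.spatial_branch, self.spectral_branch, self.head):
            if branch is not None:
                out += branch.all_grads
        return out

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def load_state_dict(self, state: Sequence[np.ndarray]) -> None:
        for p, s in zip(self.parameters, state, strict=True):
            p[...] = s

    # -- forward / backward -------------------------------------------------

    def forward(
        self, spatial: np.ndarray | None, spectral: np.ndarray | None,
        train: bool = False,
    ) -> np.ndarray:
        feats = []
        if self.spatial_branch is not None:
            feats.append(self.spatial_branch.forward(
                np.asarray(spatial, dtype=np.float32), train=train))
        if self.spectral_branch is not None:
            x = np.asarray(spectral, dtype=np.float32)[:, :, None]  # (N, B, 1)
            feats.append(self.spectral_branch.forward(x, train=train))
        self._feat_dims = [f.shape[1] for f in feats]
        fused = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)
        logits = self.head.forward(fused, train=train)[:, 0]
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite logits in forward pass")
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits[:, None])
        splits = np.cumsum(self._feat_dims)[:-1]
        parts = np.split(dfused, splits, axis=1)
        i = 0
        if self.spatial_branch is not None:
            self.spatial_branch.backward(parts[i]); i += 1
        if self.spectral_branch is not None:
            self.spectral_branch.backward(parts[i])

    def predict_proba(self, spatial, spectral, batch_size: int = 4096) -> np.ndarray:
        n = (spatial if spatial is not None else spectral).shape[0]
        out = np.empty(n, dtype=np.float64)
        for lo in range(0, n, batch_size):
            hi = min(lo + batch_size, n)
            logits = self.forward(
                None if spatial is None else spatial[lo:hi],
                None if spectral is None else spectral[lo:hi],
            )
            out[lo:hi] = nn.sigmoid(logits)
        return out


def build_model(config: ModelConfig | None = None, seed: int = 0) -> TwoBranchModel:
    """Construct an untrained model with seeded He initialization."""
    return TwoBranchModel(config or ModelConfig(), seed=seed)


def forward_logit(model: TwoBranchModel, sample) -> float:
    """Single-sample logit; ``sigmoid`` of it is the tumour probability."""
    return float(
        model.forward(sample.spatial[None, ...], sample.spectral[None, ...])[0]
    )


def _epoch_loss(model, arrays: SampleArrays, pos_weight: float, batch: int) -> float:
    total, n = 0.0, len(arrays)
    for lo in range(0, n, batch):
        hi = min(lo + batch, n)
        logits = model.forward(arrays.spatial[lo:hi], arrays.spectral[lo:hi])
        loss, _ = nn.bce_with_logits(logits, arrays.labels[lo:hi], pos_weight)
        total += loss * (hi - lo)
    return total / n


def train_model(
    model: TwoBranchModel,
    train: SampleArrays,
    validation: SampleArrays,
    tc: TrainConfig,
) -> TwoBranchModel:
    """Adam / BCE-with-logits training with early stopping on validation loss.

    Stops once the validation loss has not improved for ``patience`` epochs
    (or at ``max_epochs``) and restores the parameters of the best epoch.
    """
    if len(train) == 0 or len(validation) == 0:
        raise ValueError("training and validation streams must be non-empty")
    classes = np.unique(train.labels)
    if classes.size < 2:
        raise ValueError(f"training data contains a single class {classes.tolist()}")

    if tc.positive_class_weight == "auto":
        n_pos = int((train.labels == 1).sum())
        pos_weight = (len(train) - n_pos) / n_pos
    else:
        pos_weight = float(tc.positive_class_weight or 1.0)

    opt = nn.Adam(model.parameters, lr=tc.learning_rate)
    best_loss, best_state, best_epoch = np.inf, model.state_dict(), -1
    model.training_log = []

    for epoch in range(tc.max_epochs):
        rng = np.random.default_rng(np.random.SeedSequence((tc.shuffle_seed, epoch)))
        order = rng.permutation(len(train))
        spatial = train.spatial[order]
        spectral = train.spectral[order]
        labels = train.labels[order]
        if tc.augmentation is not None:
            aug_rng = np.random.default_rng(
                np.random.SeedSequence((tc.augment_seed, epoch, 0xA6))
            )
            spatial = augment_batch(spatial, tc.augmentation, aug_rng)

        running, seen = 0.0, 0
        for lo in range(0, len(train), tc.batch_size):
            hi = min(lo + tc.batch_size, len(train))
            logits = model.forward(spatial[lo:hi], spectral[lo:hi], train=True)
            loss, dlogits = nn.bce_with_logits(logits, labels[lo:hi], pos_weight)
            model.backward(dlogits)
            opt.step(model.gradients)
            running += loss * (hi - lo)
            seen += hi - lo

        val_loss = _epoch_loss(model, validation, pos_weight, 4096)
        train_loss = running / seen
        model.training_log.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        logger.info(
            "epoch %d train_loss=%.4f val_loss=%.4f", epoch, train_loss, val_loss
        )
        if val_loss < best_loss:
            best_loss, best_state, best_epoch = val_loss, model.state_dict(), epoch
        elif epoch - best_epoch >= tc.patience:
            logger.info("early stop at epoch %d (best epoch %d)", epoch, best_epoch)
            break

    model.load_state_dict(best_state)
    model.train_config = tc
    model.best_epoch = best_epoch
    return model


def predict_pixelwise(
    model: TwoBranchModel,
    image: LesionImage,
    region: np.ndarray | None = None,
    batch_size: int = 4096,
    feature_cache: dict | None = None,
) -> np.ndarray:
    """Tumour-probability map over a region; NaN marks unevaluated pixels.

    Batched evaluation is exact: each batch goes through the same forward
    pass as a single sample would.
    """
    h, w = image.cube.height, image.cube.width
    if region is None:
        region = np.ones((h, w), dtype=bool)
    if region.shape != (h, w):
        raise ValueError("region shape does not match image")
    prob_map = np.full((h, w), np.nan)
    rr, cc = np.nonzero(region)
    centres = np.column_stack([rr, cc])
    for lo in range(0, centres.shape[0], batch_size):
        sub = centres[lo : lo + batch_size]
        spatial, spectral = pixel_features(image, sub, _cache=feature_cache)
        probs = model.predict_proba(
            spatial if model.config.use_spatial else None,
            spectral if model.config.use_spectral else None,
            batch_size=batch_size,
        )
        prob_map[sub[:, 0], sub[:, 1]] = probs
    return prob_map


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: TwoBranchModel, path: str | Path) -> None:
    """Single-archive checkpoint: parameters + configs + training log."""
    meta = {
        "model_config": asdict(model.config),
        "train_config": None if model.train_config is None else asdict(model.train_config),
        "training_log": model.training_log,
        "best_epoch": model.best_epoch,
    }
    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters)}
    np.savez(path, meta=json.dumps(meta, default=list), **arrays)


def load_model(path: str | Path, seed: int = 0) -> TwoBranchModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        mc = meta["model_config"]
        for key in ("spatial_channels", "head_hidden_dims"):
            mc[key] = tuple(mc[key])
        mc["spectral_conv_layers"] = tuple(tuple(v) for v in mc["spectral_conv_layers"])
        model = TwoBranchModel(ModelConfig(**mc), seed=seed)
        n = len(model.parameters)
        model.load_state_dict([archive[f"param_{i}"] for i in range(n)])
    model.training_log = meta["training_log"]
    model.best_epoch = meta["best_epoch"]
    if meta["train_config"] is not None:
        tcd = dict(meta["train_config"])
        aug = tcd.pop("augmentation", None)
        policy = None
        if aug is not None:
            aug["rotations"] = tuple(aug["rotations"])
            policy = AugmentationPolicy(**aug)
        model.train_config = TrainConfig(augmentation=policy, **tcd)
    return model


# ---------------------------------------------------------------------------
# Hyperparameter search (generic seeded random search)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperparamSearchSpec:
    """Random-search space: field name -> list of candidate values.

    Names matching a :class:`TrainConfig` field override the training
    config, anything else overrides :class:`ModelConfig`.
    """

    space: dict[str, list] = field(default_factory=dict)
    budget: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("trial budget must be >= 1")


def hyperparameter_search(
    spec: HyperparamSearchSpec,
    train: SampleArrays,
    validation: SampleArrays,
    base_model_config: ModelConfig | None = None,
    base_train_config: TrainConfig | None = None,
) -> tuple[ModelConfig, TrainConfig, list[dict]]:
    """Seeded random search minimizing best validation loss; returns the
    winning configs and the full trial table."""
    base_mc = base_model_config or ModelConfig()
    base_tc = base_train_config or TrainConfig()
    tc_fields = set(asdict(base_tc))
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x45)))
    table: list[dict] = []
    for trial in range(spec.budget):
        draw = {k: v[int(rng.integers(len(v)))] for k, v in spec.space.items()}
        mc = replace(base_mc, **{k: v for k, v in draw.items() if k not in tc_fields})
        tc = replace(base_tc, **{k: v for k, v in draw.items() if k in tc_fields})
        model = build_model(mc, seed=int(rng.integers(2**31 - 1)))
        train_model(model, train, validation, tc)
        objective = min(rec["val_loss"] for rec in model.training_log)
        table.append({"trial": trial, "params": draw, "val_loss": objective})
        logger.info("trial %d %s -> val_loss %.4f", trial, draw, objective)
    best = min(table, key=lambda rec: rec["val_loss"])
    draw = best["params"]
    best_mc = replace(base_mc, **{k: v for k, v in draw.items() if k not in tc_fields})
    best_tc = replace(base_tc, **{k: v for k, v in draw.items() if k in tc_fields})
    return best_mc, best_tc, table
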