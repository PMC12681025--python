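"""Per-pixel sample construction: patches, band selection, normalization,
augmentation, and the two validation splits.

Every pixel is treated as an independent classification sample described by
two views of its 25x25 neighbourhood:

* **spatial** — the 25x25x3 slab at three informative wavelengths
  (defaults 487, 604 and 795 nm), consumed by the 2-D branch;
* **spectral** — the neighbourhood's mean spectrum over all bands, z-scored
  by its own band mean and standard deviation, consumed by the 1-D branch.

Patches reaching past the image border are completed by reflection
(column -1 maps to column 1), so no out-of-gamut constants enter training.

Two splits mirror the study design: a vertical half-split (left half of
every lesion trains, right half tests, with a guard band wide enough that
no training patch can read a test-half pixel) and image-level
leave-one-out folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .cube_io import LesionImage, SpectralCube, WavelengthGrid, nearest_band_index

logger = logging.getLogger(__name__)

PATCH_SIZE = 25
PATCH_HALF = PATCH_SIZE // 2  # 12
DEFAULT_BAND_TARGETS = (487.0, 604.0, 795.0)
#: Default guard half-width: ceil(25/2) - 1, the widest patch reach.
DEFAULT_GUARD_BAND = PATCH_HALF


@dataclass
class PatchSample:
    """One pixel's classification sample."""

    spatial: np.ndarray  # 25 x 25 x 3
    spectral: np.ndarray  # n_bands, z-scored
    centre: tuple[int, int]
    label: int  # 1 = tumour
    lesion_id: str

    def __post_init__(self):
        if self.spatial.shape[:2] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"spatial slab must be {PATCH_SIZE}x{PATCH_SIZE}xC")


@dataclass(frozen=True)
class SplitSpec:
    """Pixel membership for one train/test split.

    ``train_cols``/``test_cols`` are half-open [start, stop) column ranges
    per lesion for the half-split; for leave-one-out folds whole lesions are
    assigned instead and the ranges span the full width.
    """

    kind: str  # "half_split" | "loo"
    train_cols: dict[str, tuple[int, int]]
    test_cols: dict[str, tuple[int, int]]
    guard_band_px: int = 0
    fold_index: int | None = None

    def to_json(self) -> dict:
        return {
            "kind": self.kind,
            "train_cols": {k: list(v) for k, v in self.train_cols.items()},
            "test_cols": {k: list(v) for k, v in self.test_cols.items()},
            "guard_band_px": self.guard_band_px,
            "fold_index": self.fold_index,
        }


def vertical_half_split(
    image: LesionImage, guard_band_px: int = DEFAULT_GUARD_BAND
) -> SplitSpec:
    """Left half trains, right half tests, guard columns excluded from both.

    The split column is ``floor(W/2)``; a patch belongs to a side by its
    centre. With ``guard_band_px >= 12`` no 25-wide training patch can touch
    a test column.
    """
    w = image.cube.width
    mid = w // 2
    if w < 2 * (guard_band_px + PATCH_HALF + 1):
        raise ValueError(
            f"image width {w} too narrow for guard band {guard_band_px}"
        )
    return SplitSpec(
        kind="half_split",
        train_cols={image.lesion_id: (0, mid - guard_band_px)},
        test_cols={image.lesion_id: (mid + guard_band_px, w)},
        guard_band_px=guard_band_px,
    )


def loo_folds(cohort: Sequence[LesionImage]) -> list[SplitSpec]:
    """Image-level leave-one-out: fold i tests lesion i, trains on the rest."""
    if len(cohort) < 2:
        raise ValueError("leave-one-out needs a cohort of >= 2 lesions")
    ids = [img.lesion_id for img in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate lesion_ids in cohort")
    widths = {img.lesion_id: img.cube.width for img in cohort}
    folds = []
    for i, test_id in enumerate(ids):
        folds.append(
            SplitSpec(
                kind="loo",
                train_cols={k: (0, widths[k]) for k in ids if k != test_id},
                test_cols={test_id: (0, widths[test_id])},
                fold_index=i,
            )
        )
    return folds


def extract_patch(
    cube: SpectralCube, centre: tuple[int, int], size: int = PATCH_SIZE
) -> np.ndarray:
    """``size x size x B`` slab centred on a pixel, reflect-padded at borders."""
    r, c = centre
    if not (0 <= r < cube.height and 0 <= c < cube.width):
        raise ValueError(f"centre {centre} outside image")
    half = size // 2
    padded = np.pad(
        cube.data, ((half, half), (half, half), (0, 0)), mode="reflect"
    )
    return padded[r : r + size, c : c + size, :]


def select_bands(
    slab: np.ndarray,
    grid: WavelengthGrid,
    targets: Sequence[float] = DEFAULT_BAND_TARGETS,
) -> np.ndarray:
    """Pick wavelength channels from a slab, ordered as given in ``targets``."""
    if slab.shape[-1] != grid.n_bands:
        raise ValueError("slab band dimension does not match grid")
    idx = [nearest_band_index(grid, t) for t in targets]
    if len(set(idx)) != len(idx):
        warnings.warn(f"band targets {targets} resolve to duplicate indices {idx}")
    return slab[..., idx]


def band_indices(
    grid: WavelengthGrid, targets: Sequence[float] = DEFAULT_BAND_TARGETS
) -> list[int]:
    return [nearest_band_index(grid, t) for t in targets]


def spectral_input(slab: np.ndarray) -> np.ndarray:
    """Mean spectrum over the slab's spatial window, z-scored over bands.

    A constant (zero-variance) mean spectrum returns all zeros with a
    logged degenerate-input warning instead of dividing by zero.
    """
    mean_spec = slab.mean(axis=(0, 1))
    mu, sd = mean_spec.mean(), mean_spec.std()
    if sd < 1e-12:
        logger.warning("degenerate constant spectrum; returning zero vector")
        return np.zeros_like(mean_spec)
    return (mean_spec - mu) / sd


@dataclass(frozen=True)
class AugmentationPolicy:
    """Spatial-slab augmentations; every transform maps the 25x25 grid onto itself."""

    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotations: tuple[int, ...] = (0, 90, 180, 270)

    def __post_init__(self):
        if any(r % 90 for r in self.rotations):
            raise ValueError(
                "only multiples of 90 degrees keep the square grid invariant; "
                "use arbitrary-angle rotation via augment_patch(..., arbitrary=True)"
            )


def augment_patch(
    sample: PatchSample,
    policy: AugmentationPolicy,
    seed: int,
    arbitrary: bool = False,
) -> PatchSample:
    """Random flip/rotation of the spatial slab; spectral and label unchanged."""
    rng = np.random.default_rng(seed)
    spatial = _augment_slab(sample.spatial, policy, rng, arbitrary)
    return PatchSample(
        spatial=spatial,
        spectral=sample.spectral,
        centre=sample.centre,
        label=sample.label,
        lesion_id=sample.lesion_id,
    )


def _augment_slab(
    slab: np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
    arbitrary: bool = False,
) -> np.ndarray:
    out = slab
    if policy.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1, :]
    if policy.vertical_flip and rng.random() < 0.5:
        out = out[::-1, :, :]
    if arbitrary:
        angle = rng.uniform(0.0, 360.0)
        out = ndimage.rotate(out, angle, axes=(0, 1), reshape=False, mode="reflect")
    elif policy.rotations:
        k = int(rng.choice(np.asarray(policy.rotations))) // 90
        out = np.rot90(out, k=k, axes=(0, 1))
    return np.ascontiguousarray(out)


def augment_batch(
    spatial: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator
) -> np.ndarray:
    """Independently augment each slab of a (N, 25, 25, C) batch in place-cost."""
    out = np.empty_like(spatial)
    for i in range(spatial.shape[0]):
        out[i] = _augment_slab(spatial[i], policy, rng)
    return out


# ---------------------------------------------------------------------------
# Vectorized per-pixel feature maps
# ---------------------------------------------------------------------------

def mean_spectrum_map(cube: SpectralCube, size: int = PATCH_SIZE) -> np.ndarray:
    """H x W x B map of each pixel's 25x25-window mean spectrum.

    Box mean with mirrored boundary, identical to averaging
    :func:`extract_patch` output (scipy "mirror" == numpy "reflect").
    """
    return ndimage.uniform_filter(
        cube.data, size=(size, size, 1), mode="mirror"
    )


def zscore_spectra(spectra: np.ndarray) -> np.ndarray:
    """Z-score each row (last axis = bands) by its own mean and sd."""
    mu = spectra.mean(axis=-1, keepdims=True)
    sd = spectra.std(axis=-1, keepdims=True)
    out = np.where(sd < 1e-12, 0.0, (spectra - mu) / np.where(sd < 1e-12, 1.0, sd))
    return out


def pixel_features(
    image: LesionImage,
    centres: np.ndarray,
    band_targets: Sequence[float] = DEFAULT_BAND_TARGETS,
    _cache: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched (spatial, spectral) inputs for an array of (row, col) centres.

    Equivalent to looping extract_patch -> select_bands and
    extract_patch -> spectral_input per pixel, but computed through one
    reflect-padded sliding-window view and one box filter per image.
    A caller-held ``_cache`` dict reuses the per-image precomputation across
    calls (training and prediction on the same lesion).
    """
    cube = image.cube
    key = (id(cube), tuple(band_targets))
    if _cache is not None and key in _cache:
        padded, spec_map = _cache[key]
    else:
        sel = select_bands(cube.data, cube.grid, band_targets).astype(np.float32)
        padded = np.pad(
            sel, ((PATCH_HALF, PATCH_HALF), (PATCH_HALF, PATCH_HALF), (0, 0)),
            mode="reflect",
        )
        spec_map = zscore_spectra(mean_spectrum_map(cube)).astype(np.float32)
        if _cache is not None:
            _cache[key] = (padded, spec_map)

    centres = np.asarray(centres)
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (PATCH_SIZE, PATCH_SIZE), axis=(0, 1)
    )  # (H, W, C, 25, 25)
    spatial = windows[centres[:, 0], centres[:, 1]]  # (N, C, 25, 25)
    spatial = np.ascontiguousarray(np.moveaxis(spatial, 1, -1))  # (N, 25, 25, C)
    spectral = spec_map[centres[:, 0], centres[:, 1]]
    return spatial, spectral


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSpec:
    """Training subsample sizes and seeding."""

    samples_per_class_per_lesion: int | None = 2000  # None = all pixels
    validation_fraction: float = 0.2
    seed: int = 0
    stratified: bool = True
    spectral_mode: str = "patch_mean"  # or "half_mean": literal half-image spectrum

    def __post_init__(self):
        if self.spectral_mode not in ("patch_mean", "half_mean"):
            raise ValueError(f"unknown spectral_mode {self.spectral_mode!r}")


@dataclass
class SampleArrays:
    """Columnar batch of patch samples (what the trainer consumes)."""

    spatial: np.ndarray  # (N, 25, 25, 3) float32
    spectral: np.ndarray  # (N, B) float32
    labels: np.ndarray  # (N,) int8
    centres: np.ndarray  # (N, 2)
    lesion_ids: np.ndarray  # (N,) object/str

    def __len__(self) -> int:
        return self.labels.size

    @staticmethod
    def concatenate(parts: Sequence["SampleArrays"]) -> "SampleArrays":
        return SampleArrays(
            spatial=np.concatenate([p.spatial for p in parts]),
            spectral=np.concatenate([p.spectral for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            centres=np.concatenate([p.centres for p in parts]),
            lesion_ids=np.concatenate([p.lesion_ids for p in parts]),
        )


@dataclass
class TestStream:
    """Enumeration of every eligible test pixel of one lesion."""

    lesion_id: str
    centres: np.ndarray  # (N, 2)
    labels: np.ndarray  # (N,)


@dataclass
class PatchDataset:
    train: SampleArrays
    validation: SampleArrays
    test: list[TestStream]


def _eligible_centres(
    image: LesionImage, cols: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    h = image.cube.height
    rr, cc = np.mgrid[0:h, cols[0] : cols[1]]
    centres = np.column_stack([rr.ravel(), cc.ravel()])
    labels = image.mask.binary_tumour[centres[:, 0], centres[:, 1]].astype(np.int8)
    return centres, labels


def _half_mean_spectral(image: LesionImage, cols: tuple[int, int]) -> np.ndarray:
    """Literal reading: one z-scored mean spectrum for the whole half."""
    half = image.cube.data[:, cols[0] : cols[1], :]
    return zscore_spectra(half.mean(axis=(0, 1))[None, :])[0].astype(np.float32)


def build_patch_dataset(
    images: Sequence[LesionImage],
    split: SplitSpec,
    spec: DatasetSpec,
    band_targets: Sequence[float] = DEFAULT_BAND_TARGETS,
) -> PatchDataset:
    """Assemble train/validation/test streams for one split.

    Training pixels are a stratified seeded subsample per lesion; validation
    is a seeded fraction of the training samples (used only for early
    stopping); the test stream enumerates every eligible test pixel exactly
    once, as centres (features are computed lazily at prediction time).
    """
    by_id = {img.lesion_id: img for img in images}
    missing = set(split.train_cols) - set(by_id)
    if missing:
        raise ValueError(f"split references unknown lesions {sorted(missing)}")

    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xD5)))
    train_parts: list[SampleArrays] = []
    for lesion_id in sorted(split.train_cols):
        image = by_id[lesion_id]
        centres, labels = _eligible_centres(image, split.train_cols[lesion_id])
        picks = []
        if spec.stratified:
            for cls in (0, 1):
                idx = np.nonzero(labels == cls)[0]
                if idx.size == 0:
                    raise ValueError(
                        f"lesion {lesion_id!r} has no class-{cls} pixels on the "
                        "training side"
                    )
                k = spec.samples_per_class_per_lesion
                if k is None or k >= idx.size:
                    picks.append(idx)
                else:
                    picks.append(rng.choice(idx, size=k, replace=False))
        else:
            k = spec.samples_per_class_per_lesion
            idx = np.arange(labels.size)
            picks.append(
                idx if k is None or 2 * k >= idx.size
                else rng.choice(idx, size=2 * k, replace=False)
            )
        sel = np.sort(np.concatenate(picks))
        spatial, spectral = pixel_features(image, centres[sel], band_targets)
        if spec.spectral_mode == "half_mean":
            spectral = np.tile(
                _half_mean_spectral(image, split.train_cols[lesion_id]),
                (sel.size, 1),
            )
        train_parts.append(
            SampleArrays(
                spatial=spatial,
                spectral=spectral,
                labels=labels[sel],
                centres=centres[sel],
                lesion_ids=np.array([lesion_id] * sel.size, dtype=object),
            )
        )
    full = SampleArrays.concatenate(train_parts)

    # seeded validation carve-out from the training samples
    n = len(full)
    n_val = int(round(spec.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx, train_idx = np.sort(perm[:n_val]), np.sort(perm[n_val:])
    take = lambda idx: SampleArrays(
        spatial=full.spatial[idx],
        spectral=full.spectral[idx],
        labels=full.labels[idx],
        centres=full.centres[idx],
        lesion_ids=full.lesion_ids[idx],
    )

    test_streams = []
    for lesion_id in sorted(split.test_cols):
        centres, labels = _eligible_centres(by_id[lesion_id], split.test_cols[lesion_id])
        test_streams.append(TestStream(lesion_id, centres, labels))

    return PatchDataset(train=take(train_idx), validation=take(val_idx), test=test_streams)
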