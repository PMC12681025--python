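"""Synthetic hyperspectral skin phantoms with known lateral tumour margins.

A phantom emulates the structure of an in-vivo hyperspectral lesion image:
an elliptical tumour core (the part a dermatologist would demarcate with
dermoscopy), irregular subclinical lobes growing laterally out of the core
(the part only histopathology reveals), a smooth illumination field, and
multiplicative per-pixel-per-band Gaussian noise.

Tissue spectra are modelled as a baseline reflectance carved by Gaussian
absorption dips, the simplest parametric family that gives each tissue a
distinct spectral signature with controllable class separation:

    R(lambda) = baseline * prod_k (1 - depth_k * exp(-(lambda-c_k)^2 / (2 w_k^2)))

Pixels mix the tumour and healthy endmembers linearly through a per-pixel
tumour fraction ``alpha`` derived from the signed distance to the tumour
boundary, so the lateral margin is band-limited rather than a hard edge:

    cube(x,y,:) = illum(x,y) * [alpha*T + (1-alpha)*H] * (1 + eps),  eps ~ N(0, sd)

Everything is generated from a seed; identical parameters and seed give
bit-identical phantoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .cube_io import (
    AnnotationMask,
    LesionImage,
    SpectralCube,
    WavelengthGrid,
    make_wavelength_grid,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EndmemberSpec:
    """Parametric tissue reflectance: baseline with Gaussian absorption dips.

    ``features`` is a list of (centre_nm, width_nm, depth) triples; each dip
    multiplies the spectrum by ``1 - depth * exp(-(lambda-centre)^2/(2 width^2))``.
    Depth must stay below 1 so reflectance remains positive.
    """

    baseline: float
    features: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self):
        if not 0 < self.baseline <= 1.5:
            raise ValueError(f"baseline must be in (0, 1.5], got {self.baseline}")
        for c, w, d in self.features:
            if w <= 0:
                raise ValueError(f"feature width must be positive, got {w}")
            if not 0 <= d < 1:
                raise ValueError(f"feature depth must be in [0, 1), got {d}")
        object.__setattr__(self, "features", tuple(map(tuple, self.features)))


def endmember_spectrum(spec: EndmemberSpec, grid: WavelengthGrid) -> np.ndarray:
    """Evaluate the endmember reflectance on a wavelength grid."""
    lam = grid.wavelengths_nm
    r = np.full(lam.shape, spec.baseline, dtype=float)
    for centre, width, depth in spec.features:
        r *= 1.0 - depth * np.exp(-((lam - centre) ** 2) / (2.0 * width**2))
    return r


# Default endmembers. Healthy skin: bright, with a broad oxyhaemoglobin-like
# absorption around 575 nm. Tumour: darker, deeper 575 nm dip plus an extra
# dip near 690 nm — one clearly distinguishing feature in the red/NIR where
# healthy tissue is flat.
DEFAULT_HEALTHY = EndmemberSpec(baseline=0.65, features=((575.0, 35.0, 0.20),))
DEFAULT_TUMOUR = EndmemberSpec(
    baseline=0.52, features=((575.0, 35.0, 0.38), (690.0, 45.0, 0.22))
)

#: Patch half-width of the downstream classifier; core geometry must keep
#: at least this margin from the image border.
_CORE_MARGIN_PX = 13


@dataclass(frozen=True)
class PhantomParams:
    """Full description of one phantom; every field is deterministic given seed."""

    height: int = 200
    width: int = 200
    grid: WavelengthGrid = field(default_factory=make_wavelength_grid)
    healthy: EndmemberSpec = DEFAULT_HEALTHY
    tumour: EndmemberSpec = DEFAULT_TUMOUR
    core_centre: tuple[float, float] = (100.0, 100.0)  # (row, col)
    core_semi_axes: tuple[float, float] = (55.0, 42.0)
    core_rotation_deg: float = 0.0
    n_lobes: int = 3
    lobe_scale: float = 18.0  # px
    boundary_blur_px: float = 3.0
    illum_amplitude: float = 0.1
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.illum_amplitude < 0.5:
            raise ValueError("illum_amplitude must be in [0, 0.5)")
        r, c = self.core_centre
        a, b = self.core_semi_axes
        reach = max(a, b)
        if (
            r - reach < _CORE_MARGIN_PX
            or c - reach < _CORE_MARGIN_PX
            or r + reach > self.height - _CORE_MARGIN_PX
            or c + reach > self.width - _CORE_MARGIN_PX
        ):
            raise ValueError(
                "core ellipse must lie inside the image with a "
                f">= {_CORE_MARGIN_PX}-pixel margin"
            )


@dataclass
class Phantom:
    """A generated lesion image plus the knowledge only a simulator has."""

    image: LesionImage
    clinical_mask: np.ndarray  # bool, the dermoscopy-visible (code-1) region
    truth_alpha: np.ndarray  # per-pixel tumour fraction in [0, 1]

    @property
    def params(self) -> PhantomParams:
        return self.image.metadata["phantom_params"]


def _ellipse_mask(
    shape: tuple[int, int],
    centre: tuple[float, float],
    semi_axes: tuple[float, float],
    rotation_deg: float,
) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dr, dc = rows - centre[0], cols - centre[1]
    t = np.deg2rad(rotation_deg)
    u = np.cos(t) * dr + np.sin(t) * dc
    v = -np.sin(t) * dr + np.cos(t) * dc
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def make_lesion_mask(params: PhantomParams) -> tuple[AnnotationMask, np.ndarray]:
    """Tumour geometry: elliptical core plus boundary-seeded subclinical lobes.

    Returns the 3-class annotation mask (code 1 core, code 2 lobes minus
    core) and the per-pixel tumour fraction ``truth_alpha`` obtained by
    ramping the signed boundary distance over ``boundary_blur_px``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0xA5)))
    shape = (params.height, params.width)
    core = _ellipse_mask(
        shape, params.core_centre, params.core_semi_axes, params.core_rotation_deg
    )

    tumour = core.copy()
    a, b = params.core_semi_axes
    t0 = np.deg2rad(params.core_rotation_deg)
    for _ in range(params.n_lobes):
        # seed the lobe on the core boundary, push its centre slightly
        # outward so it straddles the margin and stays connected to the core
        phi = rng.uniform(0, 2 * np.pi)
        br = params.core_centre[0] + a * np.cos(phi) * np.cos(t0) - b * np.sin(phi) * np.sin(t0)
        bc = params.core_centre[1] + a * np.cos(phi) * np.sin(t0) + b * np.sin(phi) * np.cos(t0)
        radial = np.array([br - params.core_centre[0], bc - params.core_centre[1]])
        radial /= max(np.linalg.norm(radial), 1e-9)
        scale = params.lobe_scale * rng.uniform(0.7, 1.3)
        centre = (br + 0.45 * scale * radial[0], bc + 0.45 * scale * radial[1])
        axes = (scale * rng.uniform(0.6, 1.1), scale * rng.uniform(0.6, 1.1))
        lobe = _ellipse_mask(shape, centre, axes, rng.uniform(0, 180))
        if not (lobe & core).any():
            # grow the lobe toward the core so connectivity always holds
            lobe = _ellipse_mask(shape, ((br + centre[0]) / 2, (bc + centre[1]) / 2), axes, 0.0)
        clipped = lobe.sum()
        tumour |= lobe
        if clipped and (
            centre[0] - max(axes) < 0
            or centre[1] - max(axes) < 0
            or centre[0] + max(axes) > params.height
            or centre[1] + max(axes) > params.width
        ):
            logger.warning("lobe at %s extends beyond image bounds; clipped", centre)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[tumour] = 2
    labels[core] = 1

    if params.boundary_blur_px > 0:
        inside = ndimage.distance_transform_edt(tumour)
        outside = ndimage.distance_transform_edt(~tumour)
        signed = inside - outside
        alpha = np.clip(0.5 + signed / (2.0 * params.boundary_blur_px), 0.0, 1.0)
    else:
        alpha = tumour.astype(float)
    return AnnotationMask(labels), alpha


def _illumination_field(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field with mean 1 and peak deviation illum_amplitude."""
    if params.illum_amplitude == 0:
        return np.ones((params.height, params.width))
    rows, cols = np.mgrid[0 : params.height, 0 : params.width].astype(float)
    cr = rng.uniform(0.25, 0.75) * params.height
    cc = rng.uniform(0.25, 0.75) * params.width
    sigma = 0.6 * max(params.height, params.width)
    bump = np.exp(-((rows - cr) ** 2 + (cols - cc) ** 2) / (2 * sigma**2))
    bump -= bump.mean()
    bump /= np.abs(bump).max()
    return 1.0 + params.illum_amplitude * bump


def generate_phantom(params: PhantomParams, lesion_id: str = "phantom-000") -> Phantom:
    """Generate one seeded phantom: cube, 3-class mask, clinical mask, alpha."""
    mask, alpha = make_lesion_mask(params)
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0xC3)))

    healthy = endmember_spectrum(params.healthy, params.grid)
    tumour = endmember_spectrum(params.tumour, params.grid)
    mixed = alpha[:, :, None] * tumour + (1.0 - alpha[:, :, None]) * healthy

    illum = _illumination_field(params, rng)
    data = illum[:, :, None] * mixed
    if params.noise_sd > 0:
        data = data * (1.0 + rng.normal(0.0, params.noise_sd, size=data.shape))
    data = np.clip(data, 0.0, None)

    cube = SpectralCube(data=data, grid=params.grid)
    image = LesionImage(
        cube=cube,
        mask=mask,
        lesion_id=lesion_id,
        metadata={
            "phantom_params": params,
            "size_mm": round(2 * max(params.core_semi_axes) * 0.015, 1),  # ~15 um/px
            "subclinical_extension": bool((mask.labels == 2).any()),
        },
    )
    return Phantom(image=image, clinical_mask=mask.labels == 1, truth_alpha=alpha)


@dataclass(frozen=True)
class CohortVariability:
    """Per-lesion jitter applied on top of the base phantom parameters."""

    centre_jitter_px: float = 8.0
    semi_axis_jitter: float = 0.15  # relative
    rotation_range_deg: float = 90.0
    baseline_jitter: float = 0.03  # absolute, both endmembers
    n_lobes_range: tuple[int, int] = (2, 4)


def _jitter_params(
    base: PhantomParams, var: CohortVariability, rng: np.random.Generator
) -> PhantomParams:
    a, b = base.core_semi_axes
    jit = lambda s: 1.0 + rng.uniform(-var.semi_axis_jitter, var.semi_axis_jitter)
    healthy = replace(
        base.healthy,
        baseline=float(
            np.clip(base.healthy.baseline + rng.uniform(-1, 1) * var.baseline_jitter, 0.05, 1.5)
        ),
    )
    tumour = replace(
        base.tumour,
        baseline=float(
            np.clip(base.tumour.baseline + rng.uniform(-1, 1) * var.baseline_jitter, 0.05, 1.5)
        ),
    )
    return replace(
        base,
        core_centre=(
            base.core_centre[0] + rng.uniform(-1, 1) * var.centre_jitter_px,
            base.core_centre[1] + rng.uniform(-1, 1) * var.centre_jitter_px,
        ),
        core_semi_axes=(a * jit(rng), b * jit(rng)),
        core_rotation_deg=rng.uniform(0, var.rotation_range_deg),
        n_lobes=int(rng.integers(var.n_lobes_range[0], var.n_lobes_range[1] + 1)),
        healthy=healthy,
        tumour=tumour,
    )


def generate_cohort(
    n: int,
    base_params: PhantomParams | None = None,
    variability: CohortVariability | None = None,
    seed: int = 0,
) -> list[Phantom]:
    """Generate ``n`` phantoms with jittered geometry and endmembers.

    Each phantom is reproducible in isolation: lesion ``i`` depends only on
    ``(seed, i)``, so regenerating a single lesion matches the cohort run.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base = base_params if base_params is not None else PhantomParams()
    var = variability if variability is not None else CohortVariability()
    phantoms = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        params = _jitter_params(base, var, rng)
        params = replace(params, seed=sub_seed)
        phantoms.append(generate_phantom(params, lesion_id=f"phantom-{i:03d}"))
    return phantoms


def class_mean_separation(
    phantom: Phantom, n_sample: int = 2000, seed: int = 0
) -> float:
    """Bhattacharyya-style distance between sampled class mean spectra.

    Used to verify that added noise cannot increase the apparent spectral
    separation between tumour and healthy pixels.
    """
    rng = np.random.default_rng(seed)
    labels = phantom.image.mask.binary_tumour
    data = phantom.image.cube.data
    out = []
    for cls in (True, False):
        rr, cc = np.nonzero(labels == cls)
        idx = rng.choice(rr.size, size=min(n_sample, rr.size), replace=False)
        out.append(data[rr[idx], cc[idx], :])
    t, h = out
    mu_t, mu_h = t.mean(0), h.mean(0)
    var = 0.5 * (t.var(0, ddof=1) + h.var(0, ddof=1)) + 1e-12
    return float(np.mean((mu_t - mu_h) ** 2 / (8.0 * var)))
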