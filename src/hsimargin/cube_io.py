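"""Hyperspectral cube containers and file I/O.

The in-memory model mirrors what a snapshot hyperspectral skin imager
produces: a reflectance cube indexed ``[row, col, band]`` (0-based,
row-major, origin top-left), a wavelength grid of band centres in
nanometres, and a per-pixel annotation mask distinguishing healthy skin,
dermoscopically visible tumour, and histopathologically verified
subclinical extension.

On disk, cubes use the de facto hyperspectral interchange format: an ENVI
text header (``.hdr``) next to a band-sequential (BSQ) raw binary payload.
Masks are stored as indexed-colour PNGs with codes {0, 1, 2}.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

#: Annotation codes.
HEALTHY = 0
TUMOUR_CLINICAL = 1  # dermoscopically visible tumour
TUMOUR_SUBCLINICAL = 2  # extension verified only by histopathology

#: Default acquisition geometry: 120 bands spanning 460-830 nm.
DEFAULT_N_BANDS = 120
DEFAULT_MIN_NM = 460.0
DEFAULT_MAX_NM = 830.0

# ENVI numeric type codes <-> numpy dtypes (subset we read/write).
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


class FormatError(ValueError):
    """Raised when an on-disk cube or mask violates its format contract."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-centre wavelengths in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("grid needs at least 2 bands")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", w)

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def spacing_nm(self) -> float:
        """Mean band spacing (exact for uniform grids)."""
        w = self.wavelengths_nm
        return float((w[-1] - w[0]) / (w.size - 1))


def make_wavelength_grid(
    n_bands: int = DEFAULT_N_BANDS,
    min_nm: float = DEFAULT_MIN_NM,
    max_nm: float = DEFAULT_MAX_NM,
) -> WavelengthGrid:
    """Uniform wavelength grid including both endpoints."""
    if n_bands < 2:
        raise ValueError(f"n_bands must be >= 2, got {n_bands}")
    if not min_nm < max_nm:
        raise ValueError(f"need min_nm < max_nm, got {min_nm} >= {max_nm}")
    return WavelengthGrid(np.linspace(min_nm, max_nm, n_bands))


def nearest_band_index(grid: WavelengthGrid, target_nm: float) -> int:
    """Index of the band centre closest to ``target_nm``.

    Ties break toward the lower index. Targets slightly outside the grid
    (within one band spacing) clamp to the nearest endpoint; anything
    farther raises a warning and still clamps.
    """
    w = grid.wavelengths_nm
    if target_nm < w[0] - grid.spacing_nm or target_nm > w[-1] + grid.spacing_nm:
        warnings.warn(
            f"target {target_nm} nm outside grid [{w[0]}, {w[-1]}] nm; "
            "clamping to nearest endpoint",
            stacklevel=2,
        )
    # argmin returns the first (lowest) index on exact ties
    return int(np.argmin(np.abs(w - target_nm)))


@dataclass
class SpectralCube:
    """Reflectance cube ``data[row, col, band]`` with its wavelength grid."""

    data: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ValueError(f"cube must be 3-D [row, col, band], got ndim={d.ndim}")
        if d.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"band dimension {d.shape[2]} != grid n_bands {self.grid.n_bands}"
            )
        if not np.all(np.isfinite(d)):
            raise ValueError("cube contains non-finite values")
        if d.min() < 0:
            raise ValueError("reflectance must be non-negative")
        self.data = d

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]


@dataclass
class AnnotationMask:
    """Per-pixel 3-class annotation: 0 healthy, 1 clinical tumour, 2 subclinical."""

    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(lab, (HEALTHY, TUMOUR_CLINICAL, TUMOUR_SUBCLINICAL)).all():
            bad = sorted(set(np.unique(lab)) - {0, 1, 2})
            raise FormatError(f"mask contains illegal codes {bad}")
        self.labels = lab.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def binary_tumour(self) -> np.ndarray:
        """Boolean tumour-vs-healthy ground truth (codes 1 and 2 merged)."""
        return self.labels > 0


@dataclass
class LesionImage:
    """A lesion's cube, its annotation, and cohort metadata."""

    cube: SpectralCube
    mask: AnnotationMask
    lesion_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.cube.height, self.cube.width) != (self.mask.height, self.mask.width):
            raise ValueError(
                f"cube shape {(self.cube.height, self.cube.width)} != "
                f"mask shape {(self.mask.height, self.mask.width)}"
            )


# ---------------------------------------------------------------------------
# ENVI header + BSQ binary I/O
# ---------------------------------------------------------------------------

def _format_header(cube: SpectralCube, dtype: np.dtype) -> str:
    wl = ", ".join(f"{v:.6f}" for v in cube.grid.wavelengths_nm)
    return (
        "ENVI\n"
        "description = {hsimargin spectral cube}\n"
        f"samples = {cube.width}\n"
        f"lines = {cube.height}\n"
        f"bands = {cube.grid.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        "wavelength = {" + wl + "}\n"
    )


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    key, buf, in_braces = None, [], False
    for raw in text.splitlines()[1:]:
        line = raw.strip()
        if not line:
            continue
        if in_braces:
            buf.append(line)
            if line.endswith("}"):
                fields[key] = " ".join(buf).strip("{} ")
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, val = (p.strip() for p in line.partition("="))
        key = key.lower()
        if val.startswith("{") and not val.endswith("}"):
            buf, in_braces = [val.lstrip("{")], True
        else:
            fields[key] = val.strip("{} ")
    return fields


def write_cube(cube: SpectralCube, path: str | Path, dtype=np.float64) -> None:
    """Write an ENVI ``.hdr`` + band-sequential raw binary pair.

    ``path`` names the binary payload; the header is written next to it
    with a ``.hdr`` suffix. float64 (the default) round-trips bit-exactly.
    """
    path = Path(path)
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"unsupported dtype {dtype}")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.with_suffix(path.suffix + ".hdr").write_text(_format_header(cube, dtype))
    # BSQ: band-major layout on disk
    bsq = np.ascontiguousarray(np.moveaxis(cube.data.astype(dtype, copy=False), 2, 0))
    bsq.tofile(path)


def read_cube(path: str | Path) -> SpectralCube:
    """Read an ENVI header + BSQ binary pair written by :func:`write_cube`."""
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        raise FormatError(f"missing header {hdr_path}")
    fields = _parse_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"header missing required field {exc}") from exc
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise FormatError(f"unsupported interleave {fields.get('interleave')!r}")
    if "wavelength" not in fields:
        raise FormatError("header has no wavelength list")
    wavelengths = np.array(
        [float(v) for v in fields["wavelength"].split(",") if v.strip()]
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"wavelength list length {wavelengths.size} != bands {bands}"
        )
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    expected = samples * lines * bands * dtype.itemsize
    actual = path.stat().st_size
    if expected != actual:
        raise FormatError(
            f"payload size {actual} B does not match header "
            f"({lines}x{samples}x{bands} {dtype.name} = {expected} B)"
        )
    bsq = np.fromfile(path, dtype=dtype).reshape(bands, lines, samples)
    data = np.moveaxis(bsq, 0, 2)
    return SpectralCube(data=data, grid=WavelengthGrid(wavelengths))


# ---------------------------------------------------------------------------
# Mask PNG I/O
# ---------------------------------------------------------------------------

#: Display palette for annotation PNGs (healthy grey, clinical red,
#: subclinical yellow — matching the usual dermoscopy/histopathology overlay).
_MASK_PALETTE = [200, 200, 200, 220, 40, 40, 250, 220, 40]


def write_mask(mask: AnnotationMask, path: str | Path) -> None:
    """Write an indexed-colour PNG whose pixel values are the codes 0/1/2."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = Image.fromarray(mask.labels, mode="P")
    img.putpalette(_MASK_PALETTE + [0] * (768 - len(_MASK_PALETTE)))
    img.save(path)


def read_mask(path: str | Path) -> AnnotationMask:
    with Image.open(path) as img:
        if img.mode not in ("P", "L"):
            raise FormatError(f"mask PNG must be indexed, got mode {img.mode!r}")
        labels = np.asarray(img, dtype=np.uint8)
    return AnnotationMask(labels)  # code validation happens in the constructor


# ---------------------------------------------------------------------------
# RGB rendering
# ---------------------------------------------------------------------------

#: Default rendering bands (nm): near-infrared, orange, blue-green — the
#: three bands the classifier's spatial branch also consumes.
DEFAULT_RENDER_BANDS = (795.0, 604.0, 487.0)


def render_rgb(
    cube: SpectralCube, bands: Sequence[float] = DEFAULT_RENDER_BANDS
) -> np.ndarray:
    """8-bit colour rendering from three wavelengths.

    Channels are ordered (R, G, B) by descending wavelength and each is
    min-max scaled to [0, 255]; a constant channel maps to 0.
    """
    if len(bands) != 3:
        raise ValueError("need exactly 3 wavelengths")
    ordered = sorted(bands, reverse=True)
    out = np.zeros((cube.height, cube.width, 3), dtype=np.uint8)
    for ch, nm in enumerate(ordered):
        plane = cube.data[:, :, nearest_band_index(cube.grid, nm)].astype(float)
        lo, hi = plane.min(), plane.max()
        if hi > lo:
            out[:, :, ch] = np.round(255.0 * (plane - lo) / (hi - lo)).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

@dataclass
class CohortManifest:
    """List of (lesion_id, cube path, mask path, metadata) entries."""

    entries: list[dict]

    def __post_init__(self):
        ids = [e["lesion_id"] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate lesion_id in manifest")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"entries": self.entries}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CohortManifest":
        manifest = cls(**json.loads(Path(path).read_text()))
        root = Path(path).parent
        for e in manifest.entries:
            for key in ("cube", "mask"):
                p = root / e[key]
                if not p.exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")
        return manifest


def load_lesion(manifest_path: str | Path, entry: dict) -> LesionImage:
    root = Path(manifest_path).parent
    return LesionImage(
        cube=read_cube(root / entry["cube"]),
        mask=read_mask(root / entry["mask"]),
        lesion_id=entry["lesion_id"],
        metadata=entry.get("metadata", {}),
    )
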