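"""Voxel dose grids and ROI masks: the lattice every computation runs on.

A :class:`DoseGrid` is a 3-D scalar field (dose or dose rate) on a regular
lattice with a physical voxel size and a mandatory units tag; a
:class:`ROIMask` is a boolean field naming a structure on the same lattice.
Grids and masks are written to disk in a portable two-file format: a JSON
header (shape, voxel size, units, storage order, dtype, metadata) next to a
raw little-endian payload.  Storage order is x-fastest, voxel indexing is
0-based; round-trips are byte-exact at float32 precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Recognised units tags for dose / dose-rate grids.
UNITS = (
    "Gy_absorbed",
    "Gy_IsoE_BNCT",
    "Gy_IsoE_C12",
    "Gy_IsoE_C12_BED",
    "Gy_per_min",
)

_FORMAT_ORDER = "x-fastest"
_GRID_DTYPE = "float32-le"
_MASK_DTYPE = "uint8-le"


class GridError(ValueError):
    """Base class for grid model errors."""


class GridFormatError(GridError):
    """Malformed header or header/payload inconsistency on disk."""


class UnitsError(GridError):
    """Unknown units tag, or arithmetic across mismatched units."""


class LatticeMismatchError(GridError):
    """Operation across grids/masks that do not share one lattice."""


class EmptyMaskError(GridError):
    """Statistics requested on a mask with no selected voxel."""


def _validate_lattice(shape, voxel_size):
    if len(shape) != 3 or any(int(s) <= 0 for s in shape):
        raise GridError(f"shape must be 3 positive integers, got {shape!r}")
    if len(voxel_size) != 3 or any(not (float(v) > 0) for v in voxel_size):
        raise GridError(f"voxel_size must be 3 positive lengths (mm), got {voxel_size!r}")


@dataclass
class DoseGrid:
    """3-D dose (or dose-rate) field with voxel size [mm] and a units tag.

    ``values`` has shape ``(nx, ny, nz)``; all entries must be finite and
    non-negative.  Arithmetic across grids is only defined on identical
    lattices with identical units.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (10.0, 10.0, 10.0)
    units: str = "Gy_absorbed"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GridError(f"values must be 3-D, got ndim={self.values.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        _validate_lattice(self.values.shape, self.voxel_size)
        if self.units not in UNITS:
            raise UnitsError(f"unknown units tag {self.units!r}; expected one of {UNITS}")
        if not np.all(np.isfinite(self.values)):
            raise GridError("dose values must all be finite")
        if np.any(self.values < 0):
            raise GridError("dose values must all be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz / 1000.0  # mm^3 -> cm^3

    def same_lattice(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_size, other.voxel_size)

    def _check_arithmetic(self, other: "DoseGrid"):
        if not self.same_lattice(other):
            raise LatticeMismatchError(
                f"lattice mismatch: {self.shape}/{self.voxel_size} vs {other.shape}/{other.voxel_size}"
            )
        if self.units != other.units:
            raise UnitsError(f"units mismatch: {self.units!r} vs {other.units!r}")

    def __add__(self, other: "DoseGrid") -> "DoseGrid":
        self._check_arithmetic(other)
        return DoseGrid(self.values + other.values, self.voxel_size, self.units, dict(self.meta))

    def scaled(self, factor: float, units: str | None = None) -> "DoseGrid":
        """Return a copy with values scaled by ``factor``; optionally retag units
        (e.g. Gy_per_min -> Gy_absorbed after multiplying by a time)."""
        if factor < 0:
            raise GridError("scale factor must be non-negative")
        return DoseGrid(self.values * factor, self.voxel_size, units or self.units, dict(self.meta))


@dataclass
class ROIMask:
    """Boolean structure mask on a dose-grid lattice."""

    name: str
    values: np.ndarray
    voxel_size: tuple[float, float, float] = (10.0, 10.0, 10.0)

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise GridError(f"mask values must be 3-D, got ndim={self.values.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        _validate_lattice(self.values.shape, self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.values))

    def same_lattice(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_size, other.voxel_size)


@dataclass
class Phantom:
    """A named collection of ROI masks on one lattice with declared containments.

    ``containments`` lists pairs ``(inner, outer)`` that must hold voxelwise,
    e.g. GTV within PTV-HD within PTV-LD.
    """

    masks: dict[str, ROIMask]
    containments: tuple[tuple[str, str], ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        names = list(self.masks)
        if not names:
            raise GridError("phantom needs at least one mask")
        first = self.masks[names[0]]
        for m in self.masks.values():
            if not first.same_lattice(m):
                raise LatticeMismatchError("all phantom masks must share one lattice")
        for inner, outer in self.containments:
            a, b = self.masks[inner], self.masks[outer]
            if np.any(a.values & ~b.values):
                raise GridError(f"containment violated: {inner} not within {outer}")

    @property
    def shape(self):
        return next(iter(self.masks.values())).shape

    @property
    def voxel_size(self):
        return next(iter(self.masks.values())).voxel_size


# ---------------------------------------------------------------------------
# ROI statistics plumbing
# ---------------------------------------------------------------------------

def mask_volume(mask: ROIMask) -> float:
    """Structure volume in cm^3 = (number of selected voxels) x voxel volume."""
    n = mask.n_voxels
    if n == 0:
        raise EmptyMaskError(f"mask {mask.name!r} selects no voxel")
    return n * mask.voxel_volume_cm3


def extract_roi_doses(grid: DoseGrid, mask: ROIMask) -> np.ndarray:
    """Per-voxel doses inside a mask, in lexicographic (ix, iy, iz) order."""
    if not grid.same_lattice(mask):
        raise LatticeMismatchError(
            f"grid lattice {grid.shape} does not match mask {mask.name!r} lattice {mask.shape}"
        )
    if mask.n_voxels == 0:
        raise EmptyMaskError(f"mask {mask.name!r} selects no voxel")
    # boolean indexing of a C-ordered array enumerates voxels lexicographically
    return grid.values[mask.values]


# ---------------------------------------------------------------------------
# Portable grid format I/O
# ---------------------------------------------------------------------------

def _paths(path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix == ".json":
        return p, p.with_suffix(".raw")
    return p.with_suffix(p.suffix + ".json"), p.with_suffix(p.suffix + ".raw")


def _write_header(header: dict, header_path: Path):
    header_path.write_text(json.dumps(header, sort_keys=True, separators=(",", ":")) + "\n")


def write_grid(grid: DoseGrid, path) -> None:
    """Write a grid as JSON header + raw float32 little-endian payload.

    Byte output is deterministic for identical input.
    """
    header_path, payload_path = _paths(path)
    header = {
        "shape": list(grid.shape),
        "voxel_size_mm": list(grid.voxel_size),
        "units": grid.units,
        "order": _FORMAT_ORDER,
        "dtype": _GRID_DTYPE,
        "meta": grid.meta,
    }
    payload = np.ascontiguousarray(grid.values.ravel(order="F"), dtype="<f4")
    _write_header(header, header_path)
    payload_path.write_bytes(payload.tobytes())


def read_grid(path) -> DoseGrid:
    """Read a grid written by :func:`write_grid`.

    Raises :class:`GridFormatError` on malformed headers or payload-size
    mismatch and :class:`UnitsError` on unknown units tags.
    """
    header_path, payload_path = _paths(path)
    try:
        header = json.loads(header_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise GridFormatError(f"cannot parse grid header {header_path}: {exc}") from exc
    for key in ("shape", "voxel_size_mm", "units", "order", "dtype"):
        if key not in header:
            raise GridFormatError(f"grid header {header_path} missing key {key!r}")
    if header["order"] != _FORMAT_ORDER or header["dtype"] != _GRID_DTYPE:
        raise GridFormatError(
            f"unsupported order/dtype {header['order']!r}/{header['dtype']!r} in {header_path}"
        )
    units = header["units"]
    if units not in UNITS:
        raise UnitsError(f"unknown units tag {units!r} in {header_path}")
    shape = tuple(int(s) for s in header["shape"])
    raw = np.frombuffer(payload_path.read_bytes(), dtype="<f4")
    if raw.size != int(np.prod(shape)):
        raise GridFormatError(
            f"payload size {raw.size} does not match header shape {shape} "
            f"({int(np.prod(shape))} voxels) for {payload_path}"
        )
    values = raw.reshape(shape, order="F").astype(np.float64)
    return DoseGrid(values, tuple(header["voxel_size_mm"]), units, dict(header.get("meta", {})))


def write_mask(mask: ROIMask, path) -> None:
    """Write a mask in the same format with uint8 payload."""
    header_path, payload_path = _paths(path)
    header = {
        "shape": list(mask.shape),
        "voxel_size_mm": list(mask.voxel_size),
        "name": mask.name,
        "order": _FORMAT_ORDER,
        "dtype": _MASK_DTYPE,
        "meta": {},
    }
    payload = np.ascontiguousarray(mask.values.ravel(order="F"), dtype=np.uint8)
    _write_header(header, header_path)
    payload_path.write_bytes(payload.tobytes())


def read_mask(path) -> ROIMask:
    header_path, payload_path = _paths(path)
    try:
        header = json.loads(header_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise GridFormatError(f"cannot parse mask header {header_path}: {exc}") from exc
    if header.get("dtype") != _MASK_DTYPE or header.get("order") != _FORMAT_ORDER:
        raise GridFormatError(f"unsupported mask order/dtype in {header_path}")
    shape = tuple(int(s) for s in header["shape"])
    raw = np.frombuffer(payload_path.read_bytes(), dtype=np.uint8)
    if raw.size != int(np.prod(shape)):
        raise GridFormatError(f"mask payload size mismatch for {payload_path}")
    values = raw.reshape(shape, order="F").astype(bool)
    return ROIMask(header.get("name", header_path.stem), values, tuple(header["voxel_size_mm"]))
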