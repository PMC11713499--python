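"""Volumes, masks and grid geometry shared by every stage of the QA pipeline.

All grids are axis-aligned: ``world = origin + index * spacing`` per axis,
with 0-based voxel indices and the origin at the *center* of voxel
``(0, 0, 0)``.  Array axis ``a`` of :attr:`ScalarVolume.values` maps to world
axis ``a`` (an ``"ijk"`` convention); oblique orientations must be
normalised to this convention at load time (see :mod:`sctqa.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
from scipy.ndimage import map_coordinates

#: absolute tolerance (mm) for declaring two grids geometrically identical
GRID_TOL_MM = 1e-6

#: Hounsfield floor used for CT resampling and out-of-extent fill
HU_AIR = -1000.0


class GridMismatchError(ValueError):
    """Two objects that must share a grid do not."""


class OutsideVolumeError(ValueError):
    """A world point falls outside the physical extent of a volume."""


def _as_triple(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).reshape(3)
    return arr


@dataclass
class ScalarVolume:
    """A 3D scalar field (HU for CT, Gy for dose) on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (ni, nj, nk)
        Voxel values; stored as float64.
    spacing : (3,) float
        Physical voxel size per axis, mm; strictly positive.
    origin : (3,) float
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    axes_order : str
        Axis convention label; only ``"ijk"`` is supported.
    allow_non_finite : bool
        CT and dose volumes must be finite everywhere (the default);
        derived fields that carry NaN sentinels (e.g. a gamma map outside
        the analysed region) set this flag.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axes_order: str = "ijk"
    allow_non_finite: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3D array")
        if not self.allow_non_finite and not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive on all axes")
        if self.axes_order != "ijk":
            raise ValueError(f"unsupported axes_order {self.axes_order!r}")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of a (possibly fractional) voxel index."""
        idx = np.asarray(index, dtype=float)
        return self.origin + idx * self.spacing

    def world_to_index(self, point) -> np.ndarray:
        """Continuous voxel index of a world point; may be fractional or
        out of bounds (the caller decides how to treat out-of-bounds)."""
        pt = np.asarray(point, dtype=float)
        return (pt - self.origin) / self.spacing

    def contains(self, point) -> bool:
        """True if the world point lies within the volume's physical extent
        (the convex hull of voxel centers)."""
        idx = self.world_to_index(point)
        upper = np.asarray(self.shape, dtype=float) - 1
        return bool(np.all(idx >= 0) and np.all(idx <= upper))

    def interpolate(self, points) -> np.ndarray:
        """Trilinear interpolation at one or more world points.

        Exact at voxel centers.  Raises :class:`OutsideVolumeError` if any
        point falls outside the volume extent.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = (pts - self.origin) / self.spacing
        upper = np.asarray(self.shape, dtype=float) - 1
        if np.any(idx < -GRID_TOL_MM) or np.any(idx > upper + GRID_TOL_MM):
            raise OutsideVolumeError("point outside volume extent")
        out = map_coordinates(self.values, idx.T, order=1, mode="nearest")
        if np.asarray(points).ndim == 1:
            return out[0]
        return out

    def same_grid(self, other, tol: float = GRID_TOL_MM) -> bool:
        """Whether self and other share shape, spacing and origin."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_values(self, values: np.ndarray) -> "ScalarVolume":
        """A copy of this volume carrying new values on the same grid."""
        return replace(self, values=np.asarray(values, dtype=np.float64))


@dataclass
class VectorField:
    """Per-voxel displacement vectors (mm) on a reference grid.

    ``displacements`` has shape ``(ni, nj, nk, 3)``; component ``c`` is the
    world-axis-``c`` displacement added to the reference-grid world point to
    find the sampling location in the moving volume (pull/backward warping).
    """

    displacements: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise ValueError("displacements must have shape (ni, nj, nk, 3)")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacements must be finite")

    @property
    def grid_shape(self) -> tuple:
        return self.displacements.shape[:3]

    def matches_grid(self, volume: ScalarVolume, tol: float = GRID_TOL_MM) -> bool:
        return (
            self.grid_shape == volume.shape
            and np.allclose(self.spacing, volume.spacing, atol=tol)
            and np.allclose(self.origin, volume.origin, atol=tol)
        )

    @classmethod
    def identity(cls, reference: ScalarVolume) -> "VectorField":
        return cls(
            displacements=np.zeros(reference.shape + (3,)),
            spacing=reference.spacing.copy(),
            origin=reference.origin.copy(),
        )


@dataclass
class BinaryMask:
    """A named boolean structure volume on a companion grid."""

    name: str
    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if self.values.ndim != 3:
            raise ValueError("mask values must be 3D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def check_compatible(self, volume: ScalarVolume, tol: float = GRID_TOL_MM):
        ok = (
            self.shape == volume.shape
            and np.allclose(self.spacing, volume.spacing, atol=tol)
            and np.allclose(self.origin, volume.origin, atol=tol)
        )
        if not ok:
            raise GridMismatchError(
                f"mask {self.name!r} is not grid-compatible with volume"
            )


@dataclass
class CaseBundle:
    """One 'patient': paired CTs, paired doses, structures, prescription."""

    planning_ct: ScalarVolume
    synthetic_ct: ScalarVolume
    dose_reference: ScalarVolume
    dose_evaluated: ScalarVolume
    structures: dict
    prescription_dose: float
    prescription_isodose_fraction: float = 1.0
    case_id: str = "case"
    group: str = ""

    def __post_init__(self):
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be > 0")
        if not (0 < self.prescription_isodose_fraction <= 1):
            raise ValueError("prescription_isodose_fraction must be in (0, 1]")
        for vol in (self.synthetic_ct, self.dose_reference, self.dose_evaluated):
            if not self.planning_ct.same_grid(vol):
                raise GridMismatchError("all bundle members must share one grid")
        for mask in self.structures.values():
            mask.check_compatible(self.planning_ct)


def resample_to_reference(
    moving: ScalarVolume,
    reference: ScalarVolume,
    dvf: Optional[VectorField] = None,
    fill_value: float = HU_AIR,
    floor: Optional[float] = HU_AIR,
) -> ScalarVolume:
    """Resample ``moving`` onto the grid of ``reference``.

    Each output voxel is sampled (trilinearly) from ``moving`` at the
    reference voxel's world position plus the DVF displacement there
    (pull warping); identity warp when ``dvf`` is None.  Samples falling
    outside ``moving``'s extent are set to ``fill_value``; values below
    ``floor`` are clamped to ``floor`` (pass ``floor=None`` to disable, e.g.
    for dose grids where ``fill_value=0``).
    """
    if dvf is not None and not dvf.matches_grid(reference):
        raise GridMismatchError("DVF must be defined on the reference grid")

    ii, jj, kk = np.meshgrid(
        *[np.arange(n, dtype=float) for n in reference.shape], indexing="ij"
    )
    world = np.stack([ii, jj, kk], axis=-1) * reference.spacing + reference.origin
    if dvf is not None:
        world = world + dvf.displacements

    idx = (world - moving.origin) / moving.spacing  # (ni,nj,nk,3)
    coords = np.moveaxis(idx, -1, 0)
    sampled = map_coordinates(
        moving.values, coords.reshape(3, -1), order=1, mode="constant",
        cval=fill_value,
    ).reshape(reference.shape)

    upper = np.asarray(moving.shape, dtype=float) - 1
    outside = np.zeros(reference.shape, dtype=bool)
    for a in range(3):
        outside |= (idx[..., a] < -GRID_TOL_MM) | (idx[..., a] > upper[a] + GRID_TOL_MM)
    sampled[outside] = fill_value
    if floor is not None:
        np.maximum(sampled, floor, out=sampled)
    return ScalarVolume(values=sampled, spacing=reference.spacing.copy(),
                        origin=reference.origin.copy())
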