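"""Volume I/O and voxel-grid geometry.

Every other module consumes :class:`VoxelGrid` and :class:`LabeledVolume`
from here. The conventions are the dominant neuroimaging ones: RAS+ world
coordinates in millimetres, 0-based voxel indices, and a 4x4 voxel-to-world
affine that is authoritative (grids are never assumed axis-aligned except
where an operation's precondition says so). 1 mm^3 == 1 microlitre, so the
voxel volume in ul is simply the product of the spacings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("atlasforge")

KINDS = ("binary", "probability", "intensity", "index")

#: absolute tolerance for probability values outside [0, 1] that are clipped
#: (B-spline interpolation overshoot) rather than rejected at load time
PROB_LOAD_TOL = 1e-6


class AtlasForgeError(Exception):
    """Base class for all errors raised by this package."""


class GeometryError(AtlasForgeError):
    """Grid mismatch or unsupported geometry (e.g. oblique where axis-aligned is required)."""


class FormatError(AtlasForgeError):
    """File does not parse as the expected on-disk format."""


class ValidationError(AtlasForgeError):
    """Data violate the declared kind (e.g. probabilities far outside [0, 1])."""


# ---------------------------------------------------------------------------
# Voxel grid
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class VoxelGrid:
    """A 3-D sampling grid: shape plus a 4x4 voxel-to-world affine (RAS+, mm).

    Parameters
    ----------
    shape
        Grid dimensions, three positive integers.
    affine
        Voxel-index -> world-coordinate homogeneous matrix. Its 3x3 block
        must be invertible; column norms define the voxel spacing.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise GeometryError(f"shape must be 3 positive integers, got {self.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine 3x3 block is singular")

    @classmethod
    def create(
        cls,
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float],
        origin: tuple[float, float, float] | None = None,
        centered: bool = False,
    ) -> "VoxelGrid":
        """Build an axis-aligned grid.

        With ``centered=True`` the world origin is placed at the grid centre,
        so the mid-sagittal plane x=0 bisects the field of view.
        """
        spacing = np.asarray(spacing, dtype=float)
        if np.any(spacing <= 0):
            raise GeometryError("spacing must be positive")
        affine = np.eye(4)
        affine[:3, :3] = np.diag(spacing)
        if centered:
            if origin is not None:
                raise GeometryError("give either origin or centered, not both")
            origin = -(np.asarray(shape, dtype=float) - 1) / 2.0 * spacing
        if origin is not None:
            affine[:3, 3] = origin
        return cls(tuple(shape), affine)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm (column norms of the affine's 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_ul(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to (..., 3) world coordinates in mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm coordinates to (..., 3) fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (n_voxels, 3), C order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.index_to_world(idx)

    def world_axis_coords(self, axis: int) -> np.ndarray:
        """World coordinate along one axis for every voxel, shaped like the grid.

        Requires the grid to be axis-aligned on that world axis.
        """
        if not self.is_axis_aligned():
            raise GeometryError("grid is not axis-aligned")
        i = np.arange(self.shape[axis], dtype=float)
        coords = self.affine[axis, axis] * i + self.affine[axis, 3]
        reshape = [1, 1, 1]
        reshape[axis] = self.shape[axis]
        return np.broadcast_to(coords.reshape(reshape), self.shape)

    def is_axis_aligned(self, tol: float = 1e-9) -> bool:
        """True when each voxel axis maps to a single world axis (diagonal 3x3 block)."""
        block = self.affine[:3, :3]
        off = block - np.diag(np.diag(block))
        return bool(np.max(np.abs(off)) <= tol * max(1.0, np.max(np.abs(block))))

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def __eq__(self, other: object) -> bool:  # geometric equality
        return isinstance(other, VoxelGrid) and self.same_geometry(other)


def voxel_volume_ul(grid: VoxelGrid) -> float:
    """Volume of one voxel in microlitres (product of spacings in mm)."""
    return grid.voxel_volume_ul


# ---------------------------------------------------------------------------
# Labeled volume
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class LabeledVolume:
    """A scalar volume on a :class:`VoxelGrid` with a declared kind.

    kind ``binary``      -- values in {0, 1}
    kind ``probability`` -- values in [0, 1]
    kind ``intensity``   -- any finite scalar
    kind ``index``       -- non-negative integers (multi-region label map)
    """

    grid: VoxelGrid
    data: np.ndarray
    kind: str = "intensity"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown kind {self.kind!r}; expected one of {KINDS}")
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise GeometryError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        validate_kind(self.data, self.kind)

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "LabeledVolume":
        """New volume on the same grid."""
        return LabeledVolume(self.grid, data, self.kind if kind is None else kind)

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.data))


def validate_kind(data: np.ndarray, kind: str) -> None:
    if not np.all(np.isfinite(data)):
        raise ValidationError("volume contains non-finite values")
    if kind == "binary":
        if not np.isin(data, (0, 1)).all():
            raise ValidationError("binary volume has values outside {0, 1}")
    elif kind == "probability":
        lo, hi = float(data.min()), float(data.max())
        if lo < 0.0 or hi > 1.0:
            raise ValidationError(
                f"probability volume has values in [{lo:g}, {hi:g}] outside [0, 1]"
            )
    elif kind == "index":
        if np.any(data < 0) or not np.allclose(data, np.round(data)):
            raise ValidationError("index volume must hold non-negative integers")


# ---------------------------------------------------------------------------
# NIfTI-1 read / write
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, expected_kind: str = "intensity") -> LabeledVolume:
    """Load a NIfTI-1 volume and validate it against ``expected_kind``.

    Binary maps stored with a single non-zero id k (ITK-SNAP style) are
    normalized to {0, 1}. Probability values overshooting [0, 1] by at most
    ``PROB_LOAD_TOL`` (B-spline ringing) are clipped with a logged warning;
    larger excursions raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
    except Exception as exc:  # nibabel raises a zoo of types for bad headers
        raise FormatError(f"{path} does not parse as NIfTI-1: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    grid = VoxelGrid(data.shape, affine)

    if expected_kind == "binary":
        vals = np.unique(data)
        nz = vals[vals != 0]
        if nz.size == 1 and nz[0] != 1:  # single label id -> {0,1}
            data = (data != 0).astype(float)
        data = data.astype(np.uint8) if np.isin(data, (0, 1)).all() else data
    elif expected_kind == "probability":
        lo, hi = float(data.min()), float(data.max())
        if lo < -PROB_LOAD_TOL or hi > 1.0 + PROB_LOAD_TOL:
            raise ValidationError(
                f"{path}: probability values in [{lo:g}, {hi:g}] exceed [0, 1] "
                f"beyond tolerance {PROB_LOAD_TOL:g}"
            )
        if lo < 0.0 or hi > 1.0:
            logger.warning(
                "%s: clipping probability overshoot (min %g, max %g) into [0, 1]",
                path, lo, hi,
            )
            data = np.clip(data, 0.0, 1.0)
    elif expected_kind == "index":
        data = np.round(data).astype(np.int32)
    return LabeledVolume(grid, data, expected_kind)


def write_volume(vol: LabeledVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with the grid affine in the header.

    Probability and intensity volumes are stored as 32-bit float; binary as
    uint8 and index as uint16, so the integer kinds round-trip bit-exactly.
    """
    path = Path(path)
    if not path.parent.exists():
        raise OSError(f"parent directory does not exist: {path.parent}")
    if vol.kind == "binary":
        data = vol.data.astype(np.uint8)
    elif vol.kind == "index":
        data = vol.data.astype(np.uint16)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.grid.affine)
    img.header.set_zooms(tuple(vol.grid.spacing))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Affine transform and displacement field (world -> world, mm)
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class AffineTransform:
    """Homogeneous 4x4 world-to-world map in mm.

    By package convention this is a *forward* map (it sends source-space
    points to target-space points); resampling pulls values back through
    its inverse (see :mod:`atlasforge.xform`).
    """

    matrix: np.ndarray
    converged: bool = True  # set false by register_affine on iteration-budget exhaustion

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValidationError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], (0, 0, 0, 1), atol=1e-12):
            raise ValidationError("affine last row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValidationError("affine 3x3 block is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.converged)

    @classmethod
    def read(cls, path: str | Path) -> "AffineTransform":
        """Read a 4-line whitespace-delimited text matrix."""
        mat = np.loadtxt(path)
        if mat.shape != (4, 4):
            raise FormatError(f"{path}: expected a 4x4 text matrix, got {mat.shape}")
        return cls(mat)

    def write(self, path: str | Path) -> None:
        np.savetxt(path, self.matrix, fmt="%.12g")


@dataclass(eq=False)
class DisplacementField:
    """Dense displacement field: per-voxel 3-vector in mm, world space.

    Forward action is p -> p + u(p); u is evaluated by trilinear
    interpolation on the field's own grid and taken as 0 outside it.
    """

    grid: VoxelGrid
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != self.grid.shape + (3,):
            raise GeometryError(
                f"vectors shape {self.vectors.shape} != grid shape + (3,)"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("displacement field contains non-finite vectors")

    @classmethod
    def read(cls, path: str | Path) -> "DisplacementField":
        """Read a 4-D NIfTI with the vector dimension last (mm, world space)."""
        path = Path(path)
        try:
            img = nib.load(str(path))
            data = np.asarray(img.dataobj, dtype=float)
        except Exception as exc:
            raise FormatError(f"{path} does not parse as NIfTI-1: {exc}") from exc
        data = np.squeeze(data)  # tolerate the NIfTI (x,y,z,1,3) vector convention
        if data.ndim != 4 or data.shape[-1] != 3:
            raise FormatError(
                f"{path}: displacement field must be 4-D with vector dim last"
            )
        return cls(VoxelGrid(data.shape[:3], img.affine), data)

    def write(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.vectors.astype(np.float32), self.grid.affine)
        nib.save(img, str(path))
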