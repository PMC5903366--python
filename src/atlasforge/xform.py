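"""Spatial transforms and resampling.

A left-hemisphere label is carried to the right hemisphere by a "reflection
warp": a reflection about the mid-sagittal plane, followed by an affine and
optionally a dense displacement field. The chain stores *forward* world->world
maps; resampling uses pull-back semantics (each output voxel centre is mapped
through the chain inverse and the input is interpolated there). Probabilistic
labels are interpolated with third-order B-splines and clipped back into
[0, 1], since cubic interpolation overshoots at sharp label edges.

The diffeomorphic leg is deliberately not optimized here: the chain *applies*
an externally computed displacement field (SyN/ANTs or similar); the
published registration parameters are shipped verbatim as the preset
``syn_cit168.json`` for users driving such a backend.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Union

import numpy as np
from scipy import ndimage, optimize

from .volio import (
    AffineTransform,
    DisplacementField,
    GeometryError,
    LabeledVolume,
    ValidationError,
    VoxelGrid,
)

logger = logging.getLogger("atlasforge")

_INTERP_ORDER = {"bspline3": 3, "linear": 1, "nearest": 0}

#: fixed-point inversion of displacement fields: tolerance in voxels, max iterations
FIELD_INV_TOL_VOX = 0.01
FIELD_INV_MAX_ITER = 20


# ---------------------------------------------------------------------------
# Chain steps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reflection:
    """Mirror about the plane x = plane_x (world mm). Its own inverse."""

    plane_x: float = 0.0

    def apply(self, pts: np.ndarray) -> np.ndarray:
        out = np.array(pts, dtype=float, copy=True)
        out[..., 0] = 2.0 * self.plane_x - out[..., 0]
        return out


ChainStep = Union[Reflection, AffineTransform, DisplacementField]


def _evaluate_field(fld: DisplacementField, pts: np.ndarray) -> np.ndarray:
    """Trilinear displacement lookup at world points; 0 outside the field FOV."""
    idx = fld.grid.world_to_index(pts)
    u = np.empty_like(pts)
    for c in range(3):
        u[:, c] = ndimage.map_coordinates(
            fld.vectors[..., c], idx.T, order=1, mode="constant", cval=0.0
        )
    return u


def _invert_field(fld: DisplacementField, pts: np.ndarray) -> np.ndarray:
    """Solve q + u(q) = p for q by fixed-point iteration q <- p - u(q)."""
    tol_mm = FIELD_INV_TOL_VOX * float(fld.grid.spacing.min())
    q = pts - _evaluate_field(fld, pts)
    for _ in range(FIELD_INV_MAX_ITER):
        q_new = pts - _evaluate_field(fld, q)
        step = np.max(np.linalg.norm(q_new - q, axis=1)) if len(q) else 0.0
        q = q_new
        if step <= tol_mm:
            break
    else:
        logger.warning(
            "displacement-field inversion did not reach %.3g voxel tolerance "
            "in %d iterations (last step %.3g mm)",
            FIELD_INV_TOL_VOX, FIELD_INV_MAX_ITER, step,
        )
    return q


@dataclass
class TransformChain:
    """Ordered forward composition: optional reflection first, then affines/fields."""

    steps: list[ChainStep]
    interpolation: str = "bspline3"

    def __post_init__(self) -> None:
        if self.interpolation not in _INTERP_ORDER:
            raise ValidationError(
                f"interpolation must be one of {tuple(_INTERP_ORDER)}"
            )
        for i, step in enumerate(self.steps):
            if isinstance(step, Reflection) and i != 0:
                raise ValidationError(
                    "a reflection may appear at most once and only as the first step"
                )

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        """Apply the forward chain to (N, 3) world points."""
        pts = np.asarray(pts, dtype=float)
        for step in self.steps:
            if isinstance(step, Reflection):
                pts = step.apply(pts)
            elif isinstance(step, AffineTransform):
                pts = step.apply(pts)
            else:
                pts = pts + _evaluate_field(step, pts)
        return pts

    def inverse_map_points(self, pts: np.ndarray) -> np.ndarray:
        """Map (N, 3) world points through the chain inverse (for pull-back)."""
        pts = np.asarray(pts, dtype=float)
        for step in reversed(self.steps):
            if isinstance(step, Reflection):
                pts = step.apply(pts)
            elif isinstance(step, AffineTransform):
                pts = step.inverse().apply(pts)
            else:
                pts = _invert_field(step, pts)
        return pts


# ---------------------------------------------------------------------------
# Mid-sagittal reflection of volumes
# ---------------------------------------------------------------------------

def reflect_midsagittal(vol: LabeledVolume, plane_x: float = 0.0) -> LabeledVolume:
    """Mirror a volume about the world plane x = plane_x, output on the same grid.

    Requires a grid that is axis-aligned in world x. When the reflected voxel
    centres land exactly on grid positions the flip is exact (and hence an
    exact involution); otherwise binary and index maps are flipped to the
    nearest voxel (a deterministic snap, logged) and continuous maps are
    resampled with the B-spline pathway.
    """
    if not vol.grid.is_axis_aligned():
        raise GeometryError("reflect_midsagittal requires an axis-aligned grid")
    a = vol.grid.affine
    sx, x0 = a[0, 0], a[0, 3]
    # voxel i sits at world x0 + i*sx; its mirror sits at fractional index c - i
    c = (2.0 * plane_x - 2.0 * x0) / sx
    if abs(c - round(c)) > 1e-6 and vol.kind in ("intensity", "probability"):
        chain = TransformChain([Reflection(plane_x)], interpolation="bspline3")
        return apply_chain(vol, chain, vol.grid)
    k = int(round(c))
    if abs(c - round(c)) > 1e-6:
        logger.warning(
            "reflection plane x=%g is off-lattice by %.3g voxels; snapping "
            "binary/index flip to the nearest voxel", plane_x, abs(c - round(c)),
        )
    nx = vol.grid.shape[0]
    out = np.zeros_like(vol.data)
    src = k - np.arange(nx)          # input index feeding each output slice
    ok = (src >= 0) & (src < nx)
    out[ok] = vol.data[src[ok]]
    return vol.with_data(out)


# ---------------------------------------------------------------------------
# Chain application (pull-back resampling)
# ---------------------------------------------------------------------------

def apply_chain(
    vol: LabeledVolume,
    chain: TransformChain,
    out_grid: VoxelGrid,
    clip: bool = True,
) -> LabeledVolume:
    """Resample ``vol`` through ``chain`` onto ``out_grid``.

    Each output voxel centre is mapped through the chain inverse and the
    input is interpolated there; points falling outside the input field of
    view read as 0. Binary inputs are promoted to probability unless the
    chain interpolates with ``nearest``; index inputs require ``nearest``.
    With ``clip=False`` probability outputs keep any interpolation overshoot
    (useful for inspecting B-spline ringing); by default they are clipped to
    [0, 1] and the overshoot is logged.
    """
    order = _INTERP_ORDER[chain.interpolation]
    kind = vol.kind
    if kind == "index" and order != 0:
        raise ValidationError("index volumes must be resampled with nearest interpolation")
    if kind == "binary" and order != 0:
        kind = "probability"  # smooth interpolation of a mask yields fractions

    pts = chain.inverse_map_points(out_grid.voxel_centers())
    idx = vol.grid.world_to_index(pts)
    data = ndimage.map_coordinates(
        vol.data.astype(float), idx.T, order=order, mode="constant", cval=0.0,
        prefilter=(order > 1),
    ).reshape(out_grid.shape)

    if kind == "probability":
        lo, hi = float(data.min()), float(data.max())
        if clip and (lo < 0.0 or hi > 1.0):
            logger.info(
                "clipping B-spline overshoot into [0, 1] (pre-clip range [%g, %g])",
                lo, hi,
            )
            data = np.clip(data, 0.0, 1.0)
        if not clip:
            kind = "intensity"  # may legitimately overshoot [0, 1]
    if kind in ("binary", "index"):
        data = data.astype(vol.data.dtype)
    return LabeledVolume(out_grid, data, kind)


# ---------------------------------------------------------------------------
# Intensity-driven affine registration (the affine leg of the reflection warp)
# ---------------------------------------------------------------------------

@dataclass
class RegistrationConfig:
    """Multi-resolution affine registration settings.

    ``levels`` are downsampling factors (strictly decreasing, finest last);
    ``iterations`` is the optimizer budget per level. The optimizer is
    deterministic (identity initialization, derivative-free Powell descent
    on the chosen similarity), so repeated runs give identical transforms.
    """

    levels: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (60, 60, 40)
    step_size: float = 0.25
    similarity: str = "mean-squares"
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if any(a <= b for a, b in zip(self.levels, self.levels[1:])):
            raise ValidationError("levels must be strictly decreasing")
        if len(self.iterations) != len(self.levels) or any(
            i <= 0 for i in self.iterations
        ):
            raise ValidationError("iterations must be positive, one per level")
        if self.similarity not in ("mean-squares", "cross-correlation"):
            raise ValidationError("similarity must be mean-squares or cross-correlation")


def _params_to_matrix(p: np.ndarray, center: np.ndarray) -> np.ndarray:
    """9-DOF parameters (tx ty tz, rx ry rz, log sx sy sz) -> 4x4, about ``center``."""
    t, ang, logs = p[:3], p[3:6], p[6:9]
    cx, sx_ = np.cos(ang[0]), np.sin(ang[0])
    cy, sy_ = np.cos(ang[1]), np.sin(ang[1])
    cz, sz_ = np.cos(ang[2]), np.sin(ang[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx_], [0, sx_, cx]])
    ry = np.array([[cy, 0, sy_], [0, 1, 0], [-sy_, 0, cy]])
    rz = np.array([[cz, -sz_, 0], [sz_, cz, 0], [0, 0, 1]])
    lin = rz @ ry @ rx @ np.diag(np.exp(logs))
    m = np.eye(4)
    m[:3, :3] = lin
    m[:3, 3] = t + center - lin @ center
    return m


def _coarse_grid(grid: VoxelGrid, factor: int) -> VoxelGrid:
    if factor == 1:
        return grid
    shape = tuple(int(np.ceil(s / factor)) for s in grid.shape)
    affine = grid.affine.copy()
    affine[:3, :3] *= factor
    return VoxelGrid(shape, affine)


def register_affine(
    moving: LabeledVolume,
    fixed: LabeledVolume,
    cfg: RegistrationConfig | None = None,
) -> AffineTransform:
    """Estimate the forward affine map (moving world -> fixed world).

    The returned transform, applied to ``moving`` via :func:`apply_chain`,
    approximately minimizes the configured similarity against ``fixed``.
    9 DOF: translation, rotation and anisotropic scale about the fixed-image
    centre; multi-resolution with Gaussian pre-smoothing per level. On
    iteration-budget exhaustion the best-so-far transform is returned with
    ``converged=False``.
    """
    if cfg is None:
        cfg = RegistrationConfig()
    if moving.kind not in ("intensity", "probability") or fixed.kind not in (
        "intensity", "probability",
    ):
        raise ValidationError("register_affine needs intensity or probability volumes")

    center = fixed.grid.index_to_world((np.asarray(fixed.grid.shape, float) - 1) / 2)
    mov_data = moving.data.astype(float)
    fix_data = fixed.data.astype(float)

    params = np.zeros(9)
    # optimizer works in comparable units: mm, and mm-equivalent angle/scale
    scale_units = np.array([1.0, 1.0, 1.0, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02])
    converged = True
    for factor, max_iter in zip(cfg.levels, cfg.iterations):
        sigma = factor / 2.0 if factor > 1 else 0.0
        mov_s = ndimage.gaussian_filter(mov_data, sigma) if sigma else mov_data
        fix_s = ndimage.gaussian_filter(fix_data, sigma) if sigma else fix_data
        cgrid = _coarse_grid(fixed.grid, factor)
        fix_c = fix_s[::factor, ::factor, ::factor]
        pts = cgrid.voxel_centers()
        fix_flat = fix_c.ravel()
        mov_grid = moving.grid

        def cost(u: np.ndarray) -> float:
            mat = _params_to_matrix(u * scale_units, center)
            src = pts @ np.linalg.inv(mat)[:3, :3].T + np.linalg.inv(mat)[:3, 3]
            samp = ndimage.map_coordinates(
                mov_s, mov_grid.world_to_index(src).T, order=1,
                mode="constant", cval=0.0,
            )
            if cfg.similarity == "mean-squares":
                return float(np.mean((samp - fix_flat) ** 2))
            a = samp - samp.mean()
            b = fix_flat - fix_flat.mean()
            denom = np.sqrt((a @ a) * (b @ b))
            return 1.0 - float(a @ b / denom) if denom > 0 else 1.0

        res = optimize.minimize(
            cost,
            params / scale_units,
            method="Powell",
            options={
                "maxiter": max_iter,
                "xtol": cfg.tolerance,
                "ftol": cfg.tolerance,
            },
        )
        params = res.x * scale_units
        converged = bool(res.success)
    return AffineTransform(_params_to_matrix(params, center), converged=converged)


# ---------------------------------------------------------------------------
# Reflection warp
# ---------------------------------------------------------------------------

def reflection_warp(
    left_prob: LabeledVolume,
    affine: AffineTransform | None = None,
    fld: DisplacementField | None = None,
    plane_x: float = 0.0,
    out_grid: VoxelGrid | None = None,
    overlap_warn_fraction: float = 0.05,
) -> LabeledVolume:
    """Carry a left-hemisphere probabilistic label to the right hemisphere.

    Composes reflection -> affine -> displacement field (forward), resamples
    the label through the chain with third-order B-splines and clips to
    [0, 1]. The input is not modified; the union (voxel-wise maximum) of
    input and output is the bilateral label. If more than
    ``overlap_warn_fraction`` of the output's probability mass remains in
    the source hemisphere (x < plane_x) a warning is logged, which usually
    indicates a bad transform.
    """
    steps: list[ChainStep] = [Reflection(plane_x)]
    if affine is not None:
        steps.append(affine)
    if fld is not None:
        steps.append(fld)
    chain = TransformChain(steps, interpolation="bspline3")
    grid = out_grid if out_grid is not None else left_prob.grid
    out = apply_chain(left_prob, chain, grid, clip=True)
    if out.kind != "probability":
        out = LabeledVolume(grid, out.data.astype(float), "probability")

    total = float(out.data.sum())
    if total > 0:
        x = grid.voxel_centers()[:, 0].reshape(grid.shape)
        source_mass = float(out.data[x < plane_x].sum())
        if source_mass / total > overlap_warn_fraction:
            logger.warning(
                "reflection warp output keeps %.1f%% of its mass in the source "
                "hemisphere (x < %g); the transform may be wrong",
                100 * source_mass / total, plane_x,
            )
    return out


def bilateral_label(left: LabeledVolume, right: LabeledVolume) -> LabeledVolume:
    """Union of the two hemisphere labels (voxel-wise maximum probability)."""
    if not left.grid.same_geometry(right.grid):
        raise GeometryError("hemisphere labels are on different grids")
    return LabeledVolume(left.grid, np.maximum(left.data, right.data), "probability")


# ---------------------------------------------------------------------------
# Registration preset for external diffeomorphic backends
# ---------------------------------------------------------------------------

def load_syn_preset() -> dict:
    """Published SyN registration parameters for the CIT168 template build.

    The diffeomorphic optimizer itself is external (ANTs/SyN); this preset
    records the settings verbatim for users driving such a backend.
    """
    with resources.files("atlasforge.data").joinpath("syn_cit168.json").open() as fh:
        return json.load(fh)
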