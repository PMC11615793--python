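"""Reorientation, cropping and template construction.

Raw volumes are aligned to a gestational-age-specific template by an affine
registration (12 degrees of freedom) from which only the rigid part
(rotation + translation, 6 degrees of freedom) is applied — anatomy must be
reoriented, not rescaled, because the voxel count of the segmentation *is*
the measurement.  The reoriented volume is cropped to the head and resampled
to a fixed isotropic spacing.

Registration is implemented internally: an intensity-centroid initialization
followed by multi-resolution, gradient-free (Powell) maximization of the
normalized cross-correlation, warping with trilinear interpolation.  No
external registration binary is required.

Transform convention
--------------------
A transform ``T`` maps *reference/fixed* physical coordinates into *moving*
physical coordinates: ``T(x) = A (x - c) + c + t`` with ``c`` the centre of
the reference grid.  Resampling a moving image under ``T`` produces an image
on the reference grid with ``out(x) = moving(T(x))``; registration finds the
``T`` for which this matches the fixed image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .volumes import BinaryMask, Volume, VolumeGrid, resample_isotropic

__all__ = [
    "AffineTransform",
    "RigidTransform",
    "AgeTemplate",
    "register_affine",
    "rigid_part",
    "apply_transform",
    "reorient_and_crop",
    "build_template",
]

DEFAULT_TARGET_SPACING_MM = 0.40
FOREGROUND_THRESHOLD = 0.1


class AffineTransform:
    """12-DOF affine map of reference physical coords into moving coords."""

    def __init__(self, linear, translation, centre=(0.0, 0.0, 0.0)) -> None:
        self.linear = np.asarray(linear, dtype=float).reshape(3, 3)
        self.translation = np.asarray(translation, dtype=float).reshape(3)
        self.centre = np.asarray(centre, dtype=float).reshape(3)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("linear part is singular")
        #: similarity objective (normalized cross-correlation) if produced
        #: by registration; None otherwise
        self.objective: float | None = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x - self.centre) @ self.linear.T + self.centre + self.translation

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4×4 matrix equivalent to this transform."""
        m = np.eye(4)
        m[:3, :3] = self.linear
        m[:3, 3] = self.centre + self.translation - self.linear @ self.centre
        return m

    def inverse(self) -> "AffineTransform":
        m = np.linalg.inv(self.as_matrix())
        return AffineTransform(m[:3, :3], m[:3, 3], centre=(0.0, 0.0, 0.0))

    # -- plain-text serialization (4x4 matrix, one row per line) ------------
    def to_text(self, path) -> None:
        np.savetxt(path, self.as_matrix(), fmt="%.10g")

    @classmethod
    def from_text(cls, path) -> "AffineTransform":
        m = np.loadtxt(path)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got {m.shape}")
        return cls(m[:3, :3], m[:3, 3], centre=(0.0, 0.0, 0.0))

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}(t={np.round(self.translation, 3)})"


class RigidTransform(AffineTransform):
    """6-DOF rigid map: orthonormal rotation (det +1) plus translation."""

    def __init__(self, linear, translation, centre=(0.0, 0.0, 0.0)) -> None:
        linear = np.asarray(linear, dtype=float).reshape(3, 3)
        if not np.allclose(linear @ linear.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal within 1e-6")
        if np.linalg.det(linear) < 0:
            raise ValueError("rotation must have det +1 (no reflection)")
        super().__init__(linear, translation, centre)


@dataclass(frozen=True)
class AgeTemplate:
    """Gestational-age-specific template volume and intracranial mask."""

    wave: str
    template_volume: Volume
    template_mask: BinaryMask

    def __post_init__(self) -> None:
        if tuple(self.template_volume.shape) != tuple(self.template_mask.shape):
            raise ValueError("template volume and mask must share a grid")
        if self.template_mask.n_voxels == 0:
            raise ValueError("template mask is empty")


# ---------------------------------------------------------------------------
# Parameterization and warping
# ---------------------------------------------------------------------------

def _euler_matrix(angles_deg) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _params_to_linear(p: np.ndarray, dof: int) -> np.ndarray:
    rot = _euler_matrix(p[3:6])
    if dof == 6:
        return rot
    scales = np.exp(p[6:9])
    shear = np.eye(3)
    shear[0, 1], shear[0, 2], shear[1, 2] = p[9:12]
    return rot @ shear @ np.diag(scales)


def _params_to_transform(p: np.ndarray, centre, dof: int) -> AffineTransform:
    linear = _params_to_linear(p, dof)
    if dof == 6:
        return RigidTransform(linear, p[:3], centre)
    return AffineTransform(linear, p[:3], centre)


def _grid_centre_mm(grid: VolumeGrid) -> np.ndarray:
    return (np.array(grid.shape, dtype=float) - 1.0) / 2.0 * grid.spacing_mm


def _warp(data, spacing_moving, t: AffineTransform, out_grid: VolumeGrid, order):
    """Resample ``data`` (moving) under ``t`` onto ``out_grid``."""
    m4 = t.as_matrix()
    s_f = out_grid.spacing_mm
    matrix = m4[:3, :3] * (s_f / spacing_moving)
    offset = m4[:3, 3] / spacing_moving
    return ndimage.affine_transform(
        np.asarray(data, dtype=np.float64),
        matrix,
        offset=offset,
        output_shape=out_grid.shape,
        order=order,
        mode="constant",
        cval=0.0,
    )


def apply_transform(obj, t: AffineTransform, reference_grid: VolumeGrid | None = None):
    """Resample a Volume or BinaryMask under transform ``t`` onto
    ``reference_grid`` (default: the object's own grid)."""
    out_grid = reference_grid or obj.grid
    if isinstance(obj, BinaryMask):
        warped = _warp(obj.data, obj.spacing_mm, t, out_grid, order=1)
        return BinaryMask((warped > 0.5).astype(np.uint8), out_grid)
    warped = _warp(obj.data, obj.spacing_mm, t, out_grid, order=1)
    return Volume(warped, out_grid)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    return ndimage.zoom(data, 1.0 / factor, order=1)


def _centroid_mm(data: np.ndarray, spacing: float) -> np.ndarray:
    w = np.clip(data, 0.0, None)
    total = w.sum()
    if total == 0:
        return (np.array(data.shape, dtype=float) - 1.0) / 2.0 * spacing
    com = np.array(ndimage.center_of_mass(w))
    return com * spacing


def register_affine(
    moving: Volume,
    fixed: Volume,
    dof: int = 12,
    levels: tuple[int, ...] = (4, 2, 1),
    maxiter: tuple[int, ...] = (30, 12, 4),
) -> AffineTransform:
    """Register ``moving`` to ``fixed``; returns the transform ``T`` for
    which ``moving(T(x)) ≈ fixed(x)``.

    Multi-resolution Powell maximization of normalized cross-correlation,
    initialized from the intensity centroids.  The final objective value is
    stored on the returned transform (``.objective``); a non-finite
    objective raises ``RuntimeError`` rather than returning silently.
    """
    if dof not in (6, 12):
        raise ValueError("dof must be 6 or 12")
    centre = _grid_centre_mm(fixed.grid)
    t0 = _centroid_mm(moving.data, moving.spacing_mm) - _centroid_mm(
        fixed.data, fixed.spacing_mm
    )
    n_par = 6 if dof == 6 else 12
    params = np.zeros(n_par)
    params[:3] = t0

    if np.isscalar(maxiter):
        maxiter = (int(maxiter),) * len(levels)
    for level, level_maxiter in zip(levels, maxiter):
        if min(fixed.grid.shape) // level < 8:
            continue
        f_data = _downsample(fixed.data, level)
        m_data = _downsample(moving.data, level)
        f_grid = VolumeGrid(f_data.shape, fixed.spacing_mm * level)
        m_spacing = moving.spacing_mm * level

        def neg_ncc(p):
            t = _params_to_transform_raw(p, centre, dof)
            warped = _warp(m_data, m_spacing, t, f_grid, order=1)
            return -_ncc(warped, f_data)

        res = optimize.minimize(
            neg_ncc,
            params,
            method="Powell",
            options={"maxiter": level_maxiter, "xtol": 1e-3, "ftol": 1e-6},
        )
        params = res.x

    final = _params_to_transform_raw(params, centre, dof)
    t = _params_to_transform(params, centre, dof)
    warped = apply_transform(moving, final, fixed.grid)
    score = _ncc(warped.data, fixed.data)
    if not np.isfinite(score):
        raise RuntimeError("registration failed: non-finite objective")
    t.objective = score
    return t


def _params_to_transform_raw(p, centre, dof) -> AffineTransform:
    # optimizer-internal: skip the orthonormality validation cost
    linear = _params_to_linear(np.asarray(p, dtype=float), dof)
    t = AffineTransform.__new__(AffineTransform)
    t.linear = linear
    t.translation = np.asarray(p[:3], dtype=float)
    t.centre = np.asarray(centre, dtype=float)
    t.objective = None
    return t


def rigid_part(t: AffineTransform) -> RigidTransform:
    """Extract the rigid (rotation + translation) component of an affine
    transform via the orthogonal polar factor of its linear part.

    A reflecting affine (negative determinant) is an error: mirrored
    anatomy must not be silently rectified.
    """
    if np.linalg.det(t.linear) < 0:
        raise ValueError("affine contains a reflection (det < 0)")
    u, _, vt = np.linalg.svd(t.linear)
    rot = u @ vt
    if np.linalg.det(rot) < 0:  # guard: flip smallest singular direction
        u[:, -1] = -u[:, -1]
        rot = u @ vt
    return RigidTransform(rot, t.translation, t.centre)


# ---------------------------------------------------------------------------
# Reorient / crop / template
# ---------------------------------------------------------------------------

def reorient_and_crop(
    v: Volume,
    r: RigidTransform,
    margin_mm: float = 2.0,
    target_spacing_mm: float = DEFAULT_TARGET_SPACING_MM,
    foreground_threshold: float = FOREGROUND_THRESHOLD,
) -> Volume:
    """Apply the rigid transform, crop to the above-threshold foreground
    (largest connected component) plus a margin, and resample isotropically.

    Raises ``ValueError`` if no voxel exceeds the foreground threshold.
    """
    warped = apply_transform(v, r)
    fg = warped.data > foreground_threshold
    if not fg.any():
        raise ValueError("empty foreground after threshold; nothing to crop")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    margin_vox = int(np.ceil(margin_mm / v.spacing_mm))
    idx = np.nonzero(fg)
    lo = [max(0, int(i.min()) - margin_vox) for i in idx]
    hi = [min(s, int(i.max()) + 1 + margin_vox) for i, s in zip(idx, warped.shape)]
    cropped = warped.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    out = Volume(cropped, VolumeGrid(cropped.shape, v.spacing_mm))
    if np.isclose(target_spacing_mm, v.spacing_mm):
        return out
    return resample_isotropic(out, target_spacing_mm)


def build_template(
    aligned: list[tuple[Volume, BinaryMask]], wave: str
) -> AgeTemplate:
    """Voxel-wise mean volume and majority-vote mask over aligned pairs
    (ties count as inside the mask)."""
    if not aligned:
        raise ValueError("need at least one aligned pair")
    grid = aligned[0][0].grid
    for v, m in aligned:
        if tuple(v.shape) != tuple(grid.shape) or tuple(m.shape) != tuple(grid.shape):
            raise ValueError("all inputs must share a common grid")
    mean_vol = np.mean([v.data for v, _ in aligned], axis=0)
    votes = np.sum([m.data.astype(np.int32) for _, m in aligned], axis=0)
    majority = (2 * votes >= len(aligned)).astype(np.uint8)
    return AgeTemplate(
        wave=wave,
        template_volume=Volume(mean_vol, grid),
        template_mask=BinaryMask(majority, grid),
    )
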