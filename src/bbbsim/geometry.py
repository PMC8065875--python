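"""Rigid-body transforms and grid resampling.

Conventions used throughout the package:

* Array axes are (x, y, z) = (frequency-encode, phase-encode,
  slice/partition-encode).
* Each volume lives on a regular grid described by its ``shape`` and
  ``spacing`` (mm); the voxel->world affine is "centred": the world origin
  sits at the centre of the field of view.  Two grids with the same FOV
  therefore share world coordinates regardless of resolution, which is what
  central k-space extraction assumes.
* A :class:`RigidTransform` moves the *object*.  Resampling an image of the
  moved object pulls values through the inverse map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RigidTransform",
    "centered_affine",
    "apply_rigid",
    "resample_to_grid",
]


def centered_affine(shape, spacing) -> np.ndarray:
    """Voxel->world affine with the world origin at the FOV centre."""
    shape = np.asarray(shape, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = -spacing * (shape - 1) / 2.0
    return aff


def _euler_zyx_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """R = Rz @ Ry @ Rx, angles in degrees (extrinsic x, then y, then z)."""
    rx, ry, rz = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _euler_zyx_angles(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`_euler_zyx_matrix`; gimbal lock resolved with rz=0."""
    sy = -R[2, 0]
    sy = np.clip(sy, -1.0, 1.0)
    ry = np.arcsin(sy)
    if abs(sy) < 1.0 - 1e-12:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:  # cos(ry) == 0
        rz = 0.0
        rx = np.arctan2(-R[0, 1], R[1, 1]) * np.sign(sy)
    return tuple(np.rad2deg([rx, ry, rz]))


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid-body transform: rotate about ``centre`` then translate.

    World map: ``p' = R (p - c) + c + t`` with ``R = Rz @ Ry @ Rx`` (Euler
    order ZYX, degrees) and translations in mm.
    """

    rotations_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    centre_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @property
    def is_identity(self) -> bool:
        return not (np.any(self.rotations_deg) or np.any(self.translations_mm))

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous world-coordinate matrix."""
        R = _euler_zyx_matrix(*self.rotations_deg)
        c = np.asarray(self.centre_mm, dtype=float)
        t = np.asarray(self.translations_mm, dtype=float)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray, centre_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        R = M[:3, :3]
        b = M[:3, 3]
        c = np.asarray(centre_mm, dtype=float)
        rot = _euler_zyx_angles(R)
        t = b - c + R @ c
        return cls(tuple(rot), tuple(t), tuple(c))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        return RigidTransform.from_matrix(
            self.matrix() @ other.matrix(), self.centre_mm
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(
            np.linalg.inv(self.matrix()), self.centre_mm
        )

    def params(self) -> np.ndarray:
        """(rx, ry, rz, tx, ty, tz) vector, degrees and mm."""
        return np.asarray(self.rotations_deg + self.translations_mm, dtype=float)

    @classmethod
    def from_params(cls, p, centre_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        p = np.asarray(p, dtype=float)
        return cls(tuple(p[:3]), tuple(p[3:6]), tuple(centre_mm))


def _lanczos(x: np.ndarray, a: int = 3) -> np.ndarray:
    out = np.sinc(x) * np.sinc(x / a)
    out[np.abs(x) >= a] = 0.0
    return out


def _lanczos_resample(volume: np.ndarray, coords: np.ndarray, a: int = 3) -> np.ndarray:
    """Windowed-sinc (Lanczos) interpolation at fractional voxel coordinates.

    ``coords`` has shape (3, ...); out-of-grid samples evaluate to 0.
    """
    shape = volume.shape
    base = np.floor(coords).astype(np.int64)
    frac = coords - base
    out = np.zeros(coords.shape[1:], dtype=np.float64)
    wsum = np.zeros_like(out)
    offsets = range(1 - a, a + 1)
    # pad once so gathers never index out of bounds
    pad = a + 1
    vol = np.pad(volume.astype(np.float64, copy=False), pad, mode="constant")
    bx, by, bz = base[0] + pad, base[1] + pad, base[2] + pad
    for ox in offsets:
        wx = _lanczos(frac[0] - ox, a)
        ix = np.clip(bx + ox, 0, vol.shape[0] - 1)
        for oy in offsets:
            wy = wx * _lanczos(frac[1] - oy, a)
            iy = np.clip(by + oy, 0, vol.shape[1] - 1)
            for oz in offsets:
                w = wy * _lanczos(frac[2] - oz, a)
                iz = np.clip(bz + oz, 0, vol.shape[2] - 1)
                out += w * vol[ix, iy, iz]
                wsum += w
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(wsum) > 1e-8, out / wsum, 0.0)
    # zero anything whose support lies fully outside the source grid
    inside = (
        (coords[0] > -a) & (coords[0] < shape[0] - 1 + a)
        & (coords[1] > -a) & (coords[1] < shape[1] - 1 + a)
        & (coords[2] > -a) & (coords[2] < shape[2] - 1 + a)
    )
    return np.where(inside, out, 0.0)


_SPLINE_ORDER = {"nearest": 0, "trilinear": 1, "cubic": 3}


def _fourier_shift(volume: np.ndarray, shift_vox: np.ndarray) -> np.ndarray:
    """Exact sinc interpolation for a pure (fractional) translation."""
    k = np.fft.fftn(volume)
    k = ndimage.fourier_shift(k, shift_vox)
    return np.fft.ifftn(k).real


def resample_to_grid(
    volume: np.ndarray,
    src_shape,
    src_spacing,
    dst_shape,
    dst_spacing,
    transform: RigidTransform | None = None,
    interpolation: str = "trilinear",
) -> np.ndarray:
    """Sample an image of the object moved by ``transform`` on the dst grid.

    Both grids use centred affines, so equal FOVs align in world space.
    """
    T = transform if transform is not None else RigidTransform.identity()
    A_src = centered_affine(src_shape, src_spacing)
    A_dst = centered_affine(dst_shape, dst_spacing)
    # dst voxel -> world -> (object frame) -> src voxel
    M = np.linalg.inv(A_src) @ np.linalg.inv(T.matrix()) @ A_dst

    if interpolation == "sinc":
        same_grid = tuple(src_shape) == tuple(dst_shape) and np.allclose(
            src_spacing, dst_spacing
        )
        if same_grid and not np.any(T.rotations_deg):
            shift_vox = np.asarray(T.translations_mm) / np.asarray(
                src_spacing, dtype=float
            )
            return _fourier_shift(volume, shift_vox)
        idx = np.indices(tuple(dst_shape), dtype=np.float64)
        coords = np.einsum("ij,j...->i...", M[:3, :3], idx) + M[:3, 3].reshape(
            3, 1, 1, 1
        )
        return _lanczos_resample(volume, coords)

    order = _SPLINE_ORDER[interpolation]
    return ndimage.affine_transform(
        volume,
        M[:3, :3],
        offset=M[:3, 3],
        output_shape=tuple(dst_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=order > 1,
    )


def apply_rigid(
    volume: np.ndarray,
    transform: RigidTransform,
    spacing,
    interpolation: str = "trilinear",
) -> np.ndarray:
    """Resample ``volume`` after moving the imaged object by ``transform``.

    Out-of-grid voxels are filled with 0.  ``interpolation`` is one of
    ``nearest``, ``trilinear``, ``cubic`` (spline) or ``sinc`` (Lanczos-3;
    exact Fourier shift for pure translations).
    """
    if transform.is_identity and interpolation in ("nearest", "trilinear"):
        return volume.copy()
    return resample_to_grid(
        volume, volume.shape, spacing, volume.shape, spacing, transform, interpolation
    )
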