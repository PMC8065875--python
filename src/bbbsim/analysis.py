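"""Measurement pipeline: realignment, concentration, Patlak fitting.

The acquired dynamic series is (optionally) rigidly realigned to its first
frame, each voxel's signal is converted to contrast-agent concentration by
inverting the SPGR signal equation at the nominal flip angle with a regional
T10 map, and the concentration curves are fitted to the Patlak model by
ordinary least squares on the regressors {c_p[t], ∫c_p dt'} — the same
quadrature as the forward model.  Following common in-vivo practice the
first three post-contrast frames are excluded from the fit by default, and
the T2* contribution at the echo time is neglected in the inversion (the
forward model retains it, so the mismatch is a real, documented error
source).  Negative PS and vP estimates are possible and are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .acquisition import MotionTrajectory
from .geometry import RigidTransform, apply_rigid
from .kinetics import AIF, DynamicVolume, Protocol

__all__ = [
    "ParameterMap",
    "register_rigid",
    "realign_frames",
    "signal_to_concentration",
    "patlak_fit",
    "patlak_design_matrix",
    "default_excluded_frames",
    "fit_parameter_maps",
]


# --------------------------------------------------------------------------
# rigid registration (intensity-based, normalised cross-correlation)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def register_rigid(
    fixed: np.ndarray,
    moving: np.ndarray,
    spacing,
    init: RigidTransform | None = None,
    xtol: float = 1e-3,
) -> RigidTransform:
    """Estimate the 6-DOF transform T such that moving(T) matches fixed.

    Powell search maximising normalised cross-correlation, two resolution
    levels (coarse grid smoothed and decimated by 2, then full resolution).
    Both images must share one grid.
    """
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving images must share a grid")
    spacing = np.asarray(spacing, dtype=float)
    p0 = (init or RigidTransform.identity()).params()

    # two passes at full grid resolution: a smoothed pass to regularise the
    # similarity surface (interpolation ripple creates spurious local
    # optima), then a refinement on the raw images
    levels = [
        (ndimage.gaussian_filter(fixed, 1.0), ndimage.gaussian_filter(moving, 1.0), spacing),
        (fixed, moving, spacing),
    ]

    p = p0
    # soft trust region around the initialisation (gross head motion stays
    # well inside +/-15 deg, 12 mm): a quadratic penalty outside the region
    # stops Powell drifting along near-flat cost directions (e.g. axial
    # rotation of a nearly axisymmetric object) while keeping the line
    # searches unconstrained, which scipy's Powell handles far better than
    # hard bounds
    limits = np.array([15.0] * 3 + [12.0] * 3)
    for fx, mv, sp in levels:
        centre = p.copy()

        def cost(params):
            T = RigidTransform.from_params(params)
            resampled = apply_rigid(mv, T, sp, "trilinear")
            excess = np.maximum(np.abs(params - centre) - limits, 0.0)
            return -_ncc(fx, resampled) + 0.01 * float((excess**2).sum())

        res = optimize.minimize(
            cost, p, method="Powell",
            options={"xtol": xtol, "ftol": 1e-6, "maxfev": 3000},
        )
        p = res.x
    return RigidTransform.from_params(p)


def realign_frames(
    series: DynamicVolume,
    mode: str = "registration",
    interpolation: str = "trilinear",
    trajectory: "MotionTrajectory | list[RigidTransform] | None" = None,
) -> tuple[DynamicVolume, list[RigidTransform]]:
    """Rigidly realign every frame to frame 0.

    ``registration`` estimates a 6-DOF transform per frame by maximising
    normalised cross-correlation with frame 0; ``oracle`` inverts the known
    simulation positions (``trajectory`` = the true per-frame object
    positions, e.g. ``SimulationRecord.positions``).  Returns the realigned
    series and the transform applied to each frame.
    """
    data = series.data
    n = series.n_frames
    transforms: list[RigidTransform] = []
    out = np.empty_like(data)
    out[..., 0] = data[..., 0]
    ref = np.asarray(data[..., 0], dtype=np.float64)

    if mode == "oracle":
        if trajectory is None:
            raise ValueError("oracle realignment requires the true trajectory")
        poses = list(trajectory.transforms if isinstance(trajectory, MotionTrajectory) else trajectory)
        if len(poses) != n:
            raise ValueError("trajectory length must equal the frame count")
        rels = [poses[0].compose(poses[t].inverse()) for t in range(n)]
    elif mode == "registration":
        rels = [None] * n
    else:
        raise ValueError("mode must be 'registration' or 'oracle'")

    transforms.append(RigidTransform.identity())
    prev = RigidTransform.identity()
    for t in range(1, n):
        frame = np.asarray(data[..., t], dtype=np.float64)
        if mode == "oracle":
            T = rels[t]
        else:
            try:
                # moving frame shows object at pos_t; we search for the map
                # that brings it back onto frame 0 (warm start = previous)
                T = register_rigid(ref, frame, series.spacing, init=prev)
                prev = T
            except Exception as exc:  # pragma: no cover - optimizer failure path
                warnings.warn(f"registration failed for frame {t}: {exc}; using identity")
                T = RigidTransform.identity()
        transforms.append(T)
        out[..., t] = (
            frame if T.is_identity else apply_rigid(frame, T, series.spacing, interpolation)
        )
    realigned = DynamicVolume(out, series.spacing, series.frame_times_s, series.affine)
    return realigned, transforms


# --------------------------------------------------------------------------
# concentration and Patlak fit


def signal_to_concentration(
    series: DynamicVolume,
    T10_map: np.ndarray,
    proto: Protocol,
    linear: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert the dynamic signal to concentration (mM) per voxel.

    Enhancement is taken relative to the mean of the pre-contrast frames;
    the SPGR equation is inverted for T1[t] at the nominal flip angle given
    the regional T10; C = (1/T1[t] - 1/T10) / r1.  Enhancement beyond the
    SPGR ceiling cannot be inverted: such samples are clamped and flagged.
    ``linear=True`` selects a diagnostic fast path where concentration is
    proportional to relative enhancement.

    Returns ``(C, clamped)`` with C shaped like the series and ``clamped``
    a boolean volume marking voxels with any clamped frame.
    """
    data = np.asarray(series.data, dtype=np.float64)
    n_pre = proto.n_pre
    pre = data[..., :n_pre].mean(axis=-1)
    T10 = np.asarray(T10_map, dtype=np.float64)
    valid = (pre > 0) & np.isfinite(T10) & (T10 > 0)
    safe_pre = np.where(valid, pre, 1.0)
    E = data / safe_pre[..., None]

    th = np.deg2rad(proto.flip_deg)
    sin_t, cos_t = np.sin(th), np.cos(th)
    x0 = np.exp(-proto.tr_s / np.where(valid, T10, 1.0))
    g0 = (1.0 - x0) * sin_t / (1.0 - x0 * cos_t)

    if linear:
        # dS/S ~ proportional-to-C small-signal approximation
        dR1_dC = proto.r1_per_mM_s
        slope = (
            proto.tr_s * x0 * (1.0 - cos_t) / ((1.0 - x0) * (1.0 - x0 * cos_t))
        )
        C = (E - 1.0) / np.where(valid, slope, 1.0)[..., None] / dR1_dC
        clamped = np.zeros(C.shape[:-1], dtype=bool)
    else:
        y = E * g0[..., None]
        eps = 1e-9
        ceiling = sin_t - eps
        clamped_frames = y >= ceiling
        y = np.minimum(y, ceiling)
        x = (sin_t - y) / (sin_t - y * cos_t)
        x = np.clip(x, eps, 1.0 - eps)
        R1 = -np.log(x) / proto.tr_s
        C = (R1 - 1.0 / np.where(valid, T10, 1.0)[..., None]) / proto.r1_per_mM_s
        clamped = clamped_frames.any(axis=-1)

    C = np.where(valid[..., None], C, 0.0)
    return C, clamped & valid


def default_excluded_frames(proto: Protocol, n_excluded_post: int = 3) -> list[int]:
    """Indices of the first ``n_excluded_post`` post-contrast frames."""
    return list(range(proto.n_pre, min(proto.n_pre + n_excluded_post, proto.n_frames)))


def patlak_design_matrix(aif: AIF) -> np.ndarray:
    """Regressors {c_p[t], ∫c_p dt'} (n_frames x 2); shared with the forward model."""
    return np.column_stack([aif.cp_mM, aif.integral_mM_min()])


def patlak_fit(
    C: np.ndarray, aif: AIF, exclude: "list[int] | None" = None
) -> tuple[float, float]:
    """Patlak estimates (vP, PS_per_min) by OLS without intercept.

    ``C`` is one concentration-time curve; ``exclude`` lists frame indices
    omitted from the fit (default: none).
    """
    C = np.asarray(C, dtype=np.float64)
    X = patlak_design_matrix(aif)
    keep = np.ones(len(C), dtype=bool)
    if exclude:
        keep[list(exclude)] = False
    if keep.sum() < 3:
        raise ValueError("need at least 3 frames after exclusion")
    Xk = X[keep]
    if np.linalg.matrix_rank(Xk) < 2:
        raise ValueError("rank-deficient Patlak design (degenerate AIF)")
    beta, *_ = np.linalg.lstsq(Xk, C[keep], rcond=None)
    return float(beta[0]), float(beta[1])


@dataclass
class ParameterMap:
    """Voxelwise Patlak estimates with fit diagnostics.

    Negative values are possible (and observed under artefacts) and are
    preserved.  ``flags`` marks voxels whose concentration conversion
    clamped at the SPGR ceiling.
    """

    PS: np.ndarray  # min^-1
    vP: np.ndarray
    residual: np.ndarray  # RMS concentration residual, mM
    frames_used: list[int]
    mask: np.ndarray
    flags: np.ndarray


def fit_parameter_maps(
    series: DynamicVolume,
    T10_map: np.ndarray,
    aif: AIF,
    proto: Protocol,
    mask: np.ndarray | None = None,
    n_excluded_post: int = 3,
    linear: bool = False,
) -> ParameterMap:
    """Voxelwise composition of concentration conversion and Patlak OLS.

    The design matrix is shared across voxels (one AIF), so the whole map is
    one pseudo-inverse product.  Background (``mask`` False or missing T10)
    is zeroed, never fitted.
    """
    if mask is None:
        mask = np.isfinite(T10_map) & (np.asarray(T10_map) > 0)
    C, clamped = signal_to_concentration(series, T10_map, proto, linear=linear)
    exclude = default_excluded_frames(proto, n_excluded_post)
    keep = np.ones(series.n_frames, dtype=bool)
    keep[exclude] = False
    X = patlak_design_matrix(aif)[keep]
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("rank-deficient Patlak design (degenerate AIF)")
    pinv = np.linalg.pinv(X)

    flat = C.reshape(-1, series.n_frames)[:, keep]
    beta = flat @ pinv.T  # (n_voxels, 2)
    resid = flat - beta @ X.T
    rms = np.sqrt((resid**2).mean(axis=1))

    shape = series.data.shape[:-1]
    vP = np.where(mask, beta[:, 0].reshape(shape), 0.0)
    PS = np.where(mask, beta[:, 1].reshape(shape), 0.0)
    residual = np.where(mask, rms.reshape(shape), 0.0)
    return ParameterMap(
        PS=PS,
        vP=vP,
        residual=residual,
        frames_used=[int(i) for i in np.flatnonzero(keep)],
        mask=np.asarray(mask, dtype=bool),
        flags=clamped & mask,
    )
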