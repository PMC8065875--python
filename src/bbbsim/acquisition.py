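"""Measurement simulation.

Five steps turn the high-resolution ground-truth object into "acquired"
images: (1) a randomised starting head position, (2) per-frame gross rigid
motion, (3) 3D Cartesian k-space sampling at the acquired field of view and
resolution (central k-space extraction — the source of Gibbs ringing and
partial-volume averaging), (4) composite-k-space motion artefacts in which a
random proportion of phase-encode planes is acquired at the previous head
position, and (5) complex Gaussian k-space noise followed by magnitude
reconstruction, which makes the image noise Rician.

FFTs use the unitary (orthonormal) convention with the DC sample at index
``floor(N/2)``, so image-domain noise sigma maps 1:1 through the transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import RigidTransform, apply_rigid, resample_to_grid
from .kinetics import AIF, DynamicVolume, Protocol, class_signal_curves
from .phantom import LabelVolume, TissueParameterTable

__all__ = [
    "KSpaceFrame",
    "MotionTrajectory",
    "SEVERITY_SCALES",
    "random_start_position",
    "generate_trajectory",
    "mean_frame_displacement_mm",
    "fft3c",
    "ifft3c",
    "sample_kspace",
    "composite_motion_kspace",
    "add_noise_and_reconstruct",
    "reconstruct",
    "calibrate_noise_sigma",
    "simulate_acquisition",
    "SimulationRecord",
]


# --------------------------------------------------------------------------
# motion


def random_start_position(
    rng: np.random.Generator,
    rot_range_deg: float = 5.0,
    trans_range_mm: float = 2.5,
    centre_mm=(0.0, 0.0, 0.0),
) -> RigidTransform:
    """Uniform random starting position: ±5 deg rotations, ±2.5 mm translations."""
    rot = rng.uniform(-rot_range_deg, rot_range_deg, size=3)
    tra = rng.uniform(-trans_range_mm, trans_range_mm, size=3)
    return RigidTransform(tuple(rot), tuple(tra), tuple(centre_mm))


#: Random-walk step scales (rotation sd in degrees, translation sd in mm)
#: per severity class.  Classes are defined by mean frame-to-frame brain
#: displacement: low < 0.5 mm, moderate 0.5–1.5 mm, high > 1.5 mm.
SEVERITY_SCALES: dict[str, tuple[float, float]] = {
    "none": (0.0, 0.0),
    "low": (0.05, 0.10),
    "moderate": (0.30, 0.45),
    "high": (0.80, 1.40),
}


@dataclass
class MotionTrajectory:
    """One rigid transform per frame (absolute position, random walk)."""

    transforms: list[RigidTransform]
    severity_class: str = "none"

    def __len__(self) -> int:
        return len(self.transforms)

    def __getitem__(self, i: int) -> RigidTransform:
        return self.transforms[i]

    def to_params(self) -> np.ndarray:
        return np.stack([T.params() for T in self.transforms])


def generate_trajectory(
    severity: str,
    n_frames: int,
    rng: np.random.Generator,
    centre_mm=(0.0, 0.0, 0.0),
) -> MotionTrajectory:
    """Random-walk rigid trajectory with severity-dependent step scale."""
    if severity not in SEVERITY_SCALES:
        raise ValueError(f"severity must be one of {sorted(SEVERITY_SCALES)}")
    s_rot, s_tra = SEVERITY_SCALES[severity]
    transforms = [RigidTransform(centre_mm=tuple(centre_mm))]
    for _ in range(1, n_frames):
        delta = RigidTransform(
            tuple(rng.normal(0.0, s_rot, size=3)) if s_rot else (0.0, 0.0, 0.0),
            tuple(rng.normal(0.0, s_tra, size=3)) if s_tra else (0.0, 0.0, 0.0),
            tuple(centre_mm),
        )
        transforms.append(delta.compose(transforms[-1]))
    return MotionTrajectory(transforms, severity)


def mean_frame_displacement_mm(
    trajectory: MotionTrajectory, points_mm: np.ndarray
) -> float:
    """Mean frame-to-frame displacement of the given points (e.g. brain voxels)."""
    pts = np.asarray(points_mm, dtype=float)
    h = np.c_[pts, np.ones(len(pts))]
    disp = []
    for prev, nxt in zip(trajectory.transforms[:-1], trajectory.transforms[1:]):
        d = (h @ nxt.matrix().T - h @ prev.matrix().T)[:, :3]
        disp.append(np.linalg.norm(d, axis=1).mean())
    return float(np.mean(disp)) if disp else 0.0


# --------------------------------------------------------------------------
# k-space


@dataclass
class KSpaceFrame:
    """Complex 3D k-space array; axes (frequency, phase, partition) encode."""

    data: np.ndarray
    fov_mm: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def fft3c(x: np.ndarray) -> np.ndarray:
    """Unitary centred 3D FFT (DC at floor(N/2))."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x), norm="ortho"))


def ifft3c(k: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(k), norm="ortho"))


def _central_block(k: np.ndarray, out_shape) -> np.ndarray:
    slices = []
    for n, m in zip(k.shape, out_shape):
        if m > n:
            raise ValueError(f"acquired matrix {tuple(out_shape)} exceeds source {k.shape}")
        c = n // 2
        start = c - m // 2
        slices.append(slice(start, start + m))
    return k[tuple(slices)]


def sample_kspace(
    highres_frame: np.ndarray,
    src_spacing,
    proto: Protocol,
) -> KSpaceFrame:
    """Cartesian k-space sampling of a high-resolution frame.

    The object is masked to the acquired FOV along the frequency- (x) and
    partition- (z) encode axes (band filtering and slab-selective
    excitation); the k-space of the result is truncated to the acquired
    matrix by central extraction.  Source and acquired FOV must agree so the
    k-space sample spacing matches (the phase-encode axis would otherwise
    wrap, which the simulator does not model because the source grid itself
    bounds the object).
    """
    src_shape = np.asarray(highres_frame.shape)
    src_spacing = np.asarray(src_spacing, dtype=float)
    src_fov = src_shape * src_spacing
    acq_shape = np.asarray(proto.acquired_matrix)
    acq_fov = np.asarray(proto.fov_mm, dtype=float)
    if not np.allclose(src_fov, acq_fov, rtol=1e-3):
        raise ValueError(
            f"source FOV {tuple(src_fov)} must match acquired FOV {tuple(acq_fov)}"
        )
    img = np.asarray(highres_frame, dtype=np.float64)
    # FOV suppression along frequency- and partition-encode axes
    for ax in (0, 2):
        coords = (np.arange(src_shape[ax]) - (src_shape[ax] - 1) / 2) * src_spacing[ax]
        keep = np.abs(coords) <= acq_fov[ax] / 2
        if not keep.all():
            sl = [None, None, None]
            sl[ax] = slice(None)
            img = img * keep[tuple(sl)]
    k = fft3c(img)
    k = _central_block(k, acq_shape)
    # unitary-convention scaling so image intensities are resolution-invariant
    k = k * np.sqrt(np.prod(acq_shape) / np.prod(src_shape))
    return KSpaceFrame(np.ascontiguousarray(k), tuple(acq_fov))


def composite_motion_kspace(
    k_initial: KSpaceFrame,
    k_next: KSpaceFrame,
    split_fraction: float,
    axis: int = 2,
) -> KSpaceFrame:
    """Mix two k-spaces of the same scene at two head positions.

    Phase-encode planes are acquired sequentially bottom-to-top along
    ``axis`` (default: the slowest, partition-encode axis); the first
    ``split_fraction`` of planes comes from the initial-position k-space and
    the remainder from the subsequent position.
    """
    if k_initial.shape != k_next.shape:
        raise ValueError("k-space shapes differ")
    if not 0.0 <= split_fraction <= 1.0:
        raise ValueError("split_fraction must lie in [0, 1]")
    n = k_next.shape[axis]
    n_init = int(round(split_fraction * n))
    out = k_next.data.copy()
    sl = [slice(None)] * out.ndim
    sl[axis] = slice(0, n_init)
    out[tuple(sl)] = k_initial.data[tuple(sl)]
    return KSpaceFrame(out, k_next.fov_mm)


def reconstruct(k: KSpaceFrame) -> np.ndarray:
    """Magnitude image from k-space."""
    return np.abs(ifft3c(k.data))


def add_noise_and_reconstruct(
    k: KSpaceFrame, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Add complex Gaussian k-space noise and reconstruct the magnitude.

    ``sigma`` is the per-channel image-domain noise standard deviation
    (identical in k-space under the unitary FFT).  Background voxels follow
    a Rayleigh law with scale sigma; bright voxels are approximately
    Gaussian (Rician in general).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    noisy = k.data
    if sigma > 0:
        noise = rng.normal(0.0, sigma, size=k.shape + (2,))
        noisy = k.data + noise[..., 0] + 1j * noise[..., 1]
    return np.abs(ifft3c(noisy))


# --------------------------------------------------------------------------
# orchestration


def _label_mask_acquired(
    labels: LabelVolume, class_name: str, proto: Protocol, position: RigidTransform
) -> np.ndarray:
    """Nearest-neighbour resampling of one class mask onto the acquired grid."""
    m = labels.mask(class_name).astype(np.float64)
    res = resample_to_grid(
        m, m.shape, labels.spacing, proto.acquired_matrix,
        proto.acquired_spacing_mm, position, "trilinear",
    )
    return res > 0.5


def calibrate_noise_sigma(
    labels: LabelVolume,
    table: TissueParameterTable,
    aif: AIF,
    proto: Protocol,
    position: RigidTransform | None = None,
) -> float:
    """Noise sigma giving the target NAWM spatial SNR on the pre-contrast frame.

    sigma = mean noise-free pre-contrast NAWM signal / proto.snr_nawm, with
    the mean taken over an eroded NAWM mask at acquired resolution.
    """
    pos = position or RigidTransform.identity()
    curves = class_signal_curves(table, aif, proto)
    img = curves[:, 0][labels.labels]
    if not pos.is_identity:
        img = apply_rigid(img, pos, labels.spacing)
    frame0 = reconstruct(sample_kspace(img, labels.spacing, proto))
    mask = _label_mask_acquired(labels, "nawm", proto, pos)
    mask = ndimage.binary_erosion(mask, _ball(1))
    if not mask.any():
        raise ValueError("eroded NAWM mask is empty at acquired resolution")
    return float(frame0[mask].mean() / proto.snr_nawm)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    z = np.arange(-r, r + 1)
    x, y, zz = np.meshgrid(z, z, z, indexing="ij")
    return (x**2 + y**2 + zz**2) <= r**2


@dataclass
class SimulationRecord:
    """Everything needed to reproduce or invert one simulated acquisition."""

    positions: list[RigidTransform]
    split_fractions: list[float]
    sigma: float
    artefact_flags: dict[str, bool] = field(default_factory=dict)


def simulate_acquisition(
    labels: LabelVolume,
    table: TissueParameterTable,
    aif: AIF,
    proto: Protocol,
    start: RigidTransform | None = None,
    trajectory: MotionTrajectory | None = None,
    rng: np.random.Generator | None = None,
    artefact_flags: dict[str, bool] | None = None,
    sigma: float | None = None,
    interpolation: str = "trilinear",
) -> tuple[DynamicVolume, SimulationRecord]:
    """Run the five acquisition steps for every frame.

    ``artefact_flags`` toggles ``gross_motion``, ``motion_artefacts`` and
    ``noise`` (k-space sampling is the acquisition itself and always on).
    Returns the acquired-resolution 4D series and a record of the true
    positions, the per-frame k-space split fractions and the noise sigma.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    flags = {"gross_motion": True, "motion_artefacts": True, "noise": True}
    flags.update(artefact_flags or {})
    start = start or RigidTransform.identity()
    curves = class_signal_curves(table, aif, proto)
    n_frames = proto.n_frames
    if trajectory is not None and len(trajectory) != n_frames:
        raise ValueError("trajectory length must equal the frame count")

    if flags["gross_motion"] and trajectory is not None:
        positions = [trajectory[t].compose(start) for t in range(n_frames)]
    else:
        positions = [start] * n_frames

    if flags["noise"]:
        if sigma is None:
            sigma = calibrate_noise_sigma(labels, table, aif, proto, positions[0])
    else:
        sigma = 0.0

    acq = np.empty(tuple(proto.acquired_matrix) + (n_frames,), dtype=np.float32)
    splits: list[float] = []
    lab = labels.labels
    for t in range(n_frames):
        img = curves[:, t][lab]
        pos = positions[t]
        moved = img if pos.is_identity else apply_rigid(img, pos, labels.spacing, interpolation)
        k = sample_kspace(moved, labels.spacing, proto)
        split = float("nan")
        if flags["motion_artefacts"] and t > 0 and positions[t - 1] != pos:
            prev_pos = positions[t - 1]
            moved_prev = (
                img if prev_pos.is_identity
                else apply_rigid(img, prev_pos, labels.spacing, interpolation)
            )
            k_init = sample_kspace(moved_prev, labels.spacing, proto)
            split = float(rng.uniform())
            k = composite_motion_kspace(k_init, k, split)
        splits.append(split)
        acq[..., t] = (
            add_noise_and_reconstruct(k, sigma, rng) if flags["noise"] else reconstruct(k)
        )

    from .geometry import centered_affine

    series = DynamicVolume(
        data=acq,
        spacing=proto.acquired_spacing_mm,
        frame_times_s=aif.frame_times_s,
        affine=centered_affine(proto.acquired_matrix, proto.acquired_spacing_mm),
    )
    return series, SimulationRecord(positions, splits, float(sigma), dict(flags))
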