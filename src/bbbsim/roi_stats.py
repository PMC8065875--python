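"""Segmentation propagation, post-processing and summary estimators.

Tissue masks defined on the high-resolution object are propagated into the
acquired image space by rigid registration of the pre-contrast images, each
mask resampled with cubic interpolation into a soft probability and voxels
labelled by the most probable class.  From the propagated labels a regional
T10 map is built, and per-tissue PS and vP are summarised four ways: mean or
median over the parametric maps, or a single Patlak fit of the mean or
median ROI signal curve.  Mask erosion (spherical kernel) and a Bessel
low-pass filter applied to the acquired k-space are the two artefact
mitigation strategies studied; a Monte-Carlo driver repeats the whole
simulate-analyse-summarise loop with fresh randomness and reports median and
IQR of the relative errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from . import acquisition as acq
from .analysis import (
    ParameterMap,
    default_excluded_frames,
    fit_parameter_maps,
    patlak_fit,
    realign_frames,
    register_rigid,
    signal_to_concentration,
)
from .geometry import RigidTransform, resample_to_grid
from .kinetics import AIF, DynamicVolume, Protocol, class_signal_curves
from .phantom import LabelVolume, TissueParameterTable

__all__ = [
    "ESTIMATORS",
    "propagate_segmentation",
    "build_T10_map",
    "erode_mask",
    "ball",
    "lowpass_filter_kspace",
    "summarize_roi",
    "run_monte_carlo",
    "aggregate_monte_carlo",
]

ESTIMATORS = ("mean_signal", "median_signal", "mean_parameter", "median_parameter")

#: Brain tissue classes whose Patlak parameters are quantified.
BRAIN_CLASSES = ("nawm", "wmh", "stroke", "cortical_gm", "deep_gm")


def ball(radius: int = 1) -> np.ndarray:
    """Spherical structuring element (radius in voxels)."""
    r = int(radius)
    z = np.arange(-r, r + 1)
    x, y, zz = np.meshgrid(z, z, z, indexing="ij")
    return (x**2 + y**2 + zz**2) <= r**2


def erode_mask(mask: np.ndarray, radius_voxels: int = 1) -> np.ndarray:
    """Morphological erosion with a spherical kernel; may return empty."""
    return ndimage.binary_erosion(np.asarray(mask, dtype=bool), ball(radius_voxels))


def propagate_segmentation(
    labels: LabelVolume,
    acquired_frame0: np.ndarray,
    proto: Protocol,
    mode: str = "register",
    highres_t1w: np.ndarray | None = None,
    transform: RigidTransform | None = None,
    background_threshold: float = 0.5,
) -> tuple[np.ndarray, RigidTransform]:
    """Propagate the high-resolution tissue masks to the acquired grid.

    ``register`` estimates the rigid map from the high-resolution
    pre-contrast T1w image to the acquired frame 0; ``oracle`` uses the
    known simulation transform.  Each class mask is resampled with cubic
    interpolation into a soft probability; each voxel takes the argmax
    class, or background where the best probability falls below
    ``background_threshold``.

    Returns ``(label_map, transform)`` at acquired resolution.
    """
    acq_shape = tuple(proto.acquired_matrix)
    acq_spacing = proto.acquired_spacing_mm
    if mode == "oracle":
        T = transform or RigidTransform.identity()
    elif mode == "register":
        if highres_t1w is None:
            raise ValueError("register mode needs the high-resolution T1w image")
        # search on the acquired grid: resample the high-res image under
        # candidate transforms and compare with the acquired frame
        moving = resample_to_grid(
            np.asarray(highres_t1w, dtype=np.float64),
            highres_t1w.shape, labels.spacing,
            acq_shape, acq_spacing, None, "trilinear",
        )
        T = register_rigid(
            np.asarray(acquired_frame0, dtype=np.float64), moving, acq_spacing,
            init=transform,
        )
    else:
        raise ValueError("mode must be 'register' or 'oracle'")

    class_ids = sorted(set(np.unique(labels.labels)) - {0})
    probs = np.zeros((len(class_ids),) + acq_shape, dtype=np.float32)
    for j, cid in enumerate(class_ids):
        m = (labels.labels == cid).astype(np.float64)
        p = resample_to_grid(
            m, m.shape, labels.spacing, acq_shape, acq_spacing, T, "cubic"
        )
        probs[j] = np.clip(p, 0.0, 1.0)
    best = probs.argmax(axis=0)
    label_map = np.asarray(class_ids, dtype=np.uint16)[best]
    label_map[probs.max(axis=0) < background_threshold] = 0
    return label_map, T


def build_T10_map(label_map: np.ndarray, table: TissueParameterTable) -> np.ndarray:
    """Piecewise-constant regional T10 map; background voxels are NaN."""
    present = sorted(set(int(i) for i in np.unique(label_map)) - {0})
    lut = np.full(max(present, default=0) + 1, np.nan)
    for cid in present:
        lut[cid] = table.by_id(cid)["T10_s"]
    return lut[label_map]


def lowpass_filter_kspace(
    series: DynamicVolume, order: int = 4, cutoff: float = 0.7
) -> DynamicVolume:
    """Bessel low-pass filter applied to the acquired k-space of each frame.

    The magnitude response of an analog Bessel filter of the given order is
    applied separably per axis at ``cutoff`` (fraction of Nyquist); the
    response is unity at DC, so the image mean is preserved.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    data = series.data
    if order == 0:  # flat (all-pass) response
        b, a = np.array([1.0]), np.array([1.0])
    else:
        b, a = signal.bessel(order, 1.0, btype="low", analog=True, norm="mag")

    def axis_response(n: int) -> np.ndarray:
        # normalised frequency of each centred k-space sample, 1.0 = Nyquist
        f = (np.arange(n) - n // 2) / (n / 2.0)
        _, h = signal.freqs(b, a, worN=np.abs(f) / cutoff + 1e-12)
        return np.abs(h)

    H = (
        axis_response(data.shape[0])[:, None, None]
        * axis_response(data.shape[1])[None, :, None]
        * axis_response(data.shape[2])[None, None, :]
    )
    out = np.empty_like(data)
    for t in range(series.n_frames):
        k = acq.fft3c(np.asarray(data[..., t], dtype=np.float64))
        out[..., t] = np.abs(acq.ifft3c(k * H))
    return DynamicVolume(out, series.spacing, series.frame_times_s, series.affine)


def _fit_roi_signal(
    series: DynamicVolume,
    mask: np.ndarray,
    T10_s: float,
    aif: AIF,
    proto: Protocol,
    reducer,
    n_excluded_post: int = 3,
) -> tuple[float, float]:
    """Patlak fit of the reduced (mean/median) ROI signal time curve."""
    curves = series.data[mask]  # (n_voxels, n_frames)
    s = reducer(np.asarray(curves, dtype=np.float64), axis=0)
    roi_series = DynamicVolume(
        s.reshape(1, 1, 1, -1), series.spacing, series.frame_times_s, series.affine
    )
    T10 = np.full((1, 1, 1), T10_s)
    C, _ = signal_to_concentration(roi_series, T10, proto)
    vP, PS = patlak_fit(
        C[0, 0, 0], aif, default_excluded_frames(proto, n_excluded_post)
    )
    return vP, PS


def summarize_roi(
    pmap: ParameterMap,
    series: DynamicVolume,
    label_map: np.ndarray,
    table: TissueParameterTable,
    aif: AIF,
    proto: Protocol,
    estimators=ESTIMATORS,
    erode: bool = False,
    erosion_radius: int = 1,
    tissues=BRAIN_CLASSES,
    n_excluded_post: int = 3,
) -> pd.DataFrame:
    """Per-tissue PS and vP point estimates with relative errors (%).

    ``*_parameter`` estimators reduce the parametric maps inside the
    (optionally eroded) tissue mask; ``*_signal`` estimators reduce the
    signal time curve inside the mask and run a single Patlak fit.  Relative
    error is 100*(estimate - truth)/truth with truth from ``table``.
    """
    rows = []
    for name in tissues:
        row = table.row(name)
        cid = int(row["class_id"])
        mask = label_map == cid
        if erode:
            mask = erode_mask(mask, erosion_radius)
        if not mask.any():
            for est in estimators:
                rows.append(
                    dict(tissue=name, estimator=est, eroded=erode,
                         PS_est=np.nan, vP_est=np.nan,
                         rel_err_PS_pct=np.nan, rel_err_vP_pct=np.nan,
                         n_voxels=0)
                )
            continue
        for est in estimators:
            if est == "mean_parameter":
                ps, vp = pmap.PS[mask].mean(), pmap.vP[mask].mean()
            elif est == "median_parameter":
                ps, vp = np.median(pmap.PS[mask]), np.median(pmap.vP[mask])
            elif est in ("mean_signal", "median_signal"):
                reducer = np.mean if est == "mean_signal" else np.median
                vp, ps = _fit_roi_signal(
                    series, mask, float(row["T10_s"]), aif, proto, reducer,
                    n_excluded_post,
                )
            else:
                raise ValueError(f"unknown estimator {est!r}")
            ps_true, vp_true = float(row["PS_per_min"]), float(row["vP"])
            rows.append(
                dict(
                    tissue=name,
                    estimator=est,
                    eroded=erode,
                    PS_est=float(ps),
                    vP_est=float(vp),
                    rel_err_PS_pct=100.0 * (ps - ps_true) / ps_true if ps_true else np.nan,
                    rel_err_vP_pct=100.0 * (vp - vp_true) / vp_true if vp_true else np.nan,
                    n_voxels=int(mask.sum()),
                )
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Monte Carlo


def _brain_points_mm(labels: LabelVolume, n: int = 400, seed: int = 0) -> np.ndarray:
    brain_ids = [
        cid for cid, nm in labels.class_names.items() if nm in BRAIN_CLASSES + ("csf",)
    ]
    brain = np.isin(labels.labels, brain_ids)
    idx = np.argwhere(brain)
    rng = np.random.default_rng(seed)
    idx = idx[rng.choice(len(idx), size=min(n, len(idx)), replace=False)]
    shape = np.asarray(labels.labels.shape)
    return (idx - (shape - 1) / 2.0) * np.asarray(labels.spacing)


def run_monte_carlo(
    labels: LabelVolume,
    table: TissueParameterTable,
    aif: AIF,
    proto: Protocol,
    n_runs: int = 25,
    seed: int = 0,
    severity: str = "moderate",
    artefact_flags: dict[str, bool] | None = None,
    realign: str | None = "oracle",
    realign_interpolation: str = "trilinear",
    erode_conditions=(False, True),
    segmentation_mode: str = "oracle",
    estimators=ESTIMATORS,
    n_excluded_post: int = 3,
) -> pd.DataFrame:
    """Repeat the full simulate-analyse-summarise loop with fresh randomness.

    Each run draws a new starting position, motion trajectory and noise from
    a child seed of ``seed``.  ``realign`` is None (skip), ``oracle`` (invert
    the known positions) or ``registration``.  Returns a tidy DataFrame with
    one row per run x tissue x estimator x erosion condition; failures are
    recorded (``ok=False``), never fatal.
    """
    flags = {"gross_motion": True, "motion_artefacts": True, "noise": True}
    flags.update(artefact_flags or {})
    children = np.random.SeedSequence(seed).spawn(n_runs)
    frames = []
    for run, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        try:
            start = acq.random_start_position(rng)
            trajectory = (
                acq.generate_trajectory(severity, proto.n_frames, rng)
                if flags["gross_motion"]
                else None
            )
            series, record = acq.simulate_acquisition(
                labels, table, aif, proto,
                start=start, trajectory=trajectory, rng=rng,
                artefact_flags=flags,
            )
            if realign is not None:
                series, _ = realign_frames(
                    series, mode=realign, interpolation=realign_interpolation,
                    trajectory=record.positions,
                )
            ref_pos = record.positions[0]
            label_map, _ = propagate_segmentation(
                labels, series.frame(0), proto,
                mode=segmentation_mode, transform=ref_pos,
                highres_t1w=None if segmentation_mode == "oracle" else _t1w(labels, table, aif, proto),
            )
            T10_map = build_T10_map(label_map, table)
            pmap = fit_parameter_maps(
                series, T10_map, aif, proto, n_excluded_post=n_excluded_post
            )
            for erode in erode_conditions:
                df = summarize_roi(
                    pmap, series, label_map, table, aif, proto,
                    estimators=estimators, erode=erode,
                    n_excluded_post=n_excluded_post,
                )
                df.insert(0, "run", run)
                df["severity"] = severity
                df["ok"] = True
                frames.append(df)
        except Exception as exc:
            frames.append(
                pd.DataFrame([dict(run=run, tissue="", estimator="", eroded=False,
                                   severity=severity, ok=False, error=str(exc))])
            )
    return pd.concat(frames, ignore_index=True)


def _t1w(labels, table, aif, proto):
    curves = class_signal_curves(table, aif, proto)
    return curves[:, 0][labels.labels]


def aggregate_monte_carlo(results: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of estimates and relative errors per condition."""
    ok = results[results.get("ok", True) == True]  # noqa: E712

    def iqr(x):
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if x.size == 0:
            return np.nan
        q75, q25 = np.percentile(x, [75, 25])
        return q75 - q25

    g = ok.groupby(["tissue", "estimator", "eroded", "severity"])
    out = g.agg(
        PS_median=("PS_est", "median"),
        PS_iqr=("PS_est", iqr),
        vP_median=("vP_est", "median"),
        vP_iqr=("vP_est", iqr),
        rel_err_PS_median_pct=("rel_err_PS_pct", "median"),
        rel_err_PS_iqr_pct=("rel_err_PS_pct", iqr),
        rel_err_vP_median_pct=("rel_err_vP_pct", "median"),
        rel_err_vP_iqr_pct=("rel_err_vP_pct", iqr),
        n_runs=("run", "nunique"),
    )
    return out.reset_index()
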