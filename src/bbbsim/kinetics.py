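"""Forward signal model.

Contrast-agent kinetics in brain tissue follow the Patlak model for
irreversible slow leakage,

    C_t[t] = vP * c_p[t] + PS * ∫_0^t c_p dt',

where ``c_p`` is the arterial input function (plasma concentration, mM),
``vP`` the fractional plasma volume and ``PS`` the permeability-surface-area
product (min^-1).  Concentration modulates the relaxation rates linearly,
``1/Ti[t] = 1/Ti0 + ri * C_t[t]`` for i in {1, 2*}, and the measured signal
is the spoiled-gradient-echo (SPGR) steady state

    S = S0 (1 - E1) sin(th) / (1 - E1 cos(th)) * exp(-TE/T2*),  E1 = e^{-TR/T1}.

Tissues without a blood-brain barrier (muscle, skin, meninges, ...) enhance
far more than brain and are modelled by empirical multiplier curves applied
to their pre-contrast SPGR signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .phantom import LabelVolume, TissueParameterTable

__all__ = [
    "AIF",
    "Protocol",
    "DynamicVolume",
    "patlak_concentration",
    "extracerebral_enhancement",
    "relaxation_rates",
    "spgr_signal",
    "class_signal_curves",
    "synthesize_dro",
]


@dataclass(frozen=True)
class Protocol:
    """MR protocol parameters (SI units internally: seconds, mm, mM)."""

    tr_s: float = 0.00824
    te_s: float = 0.0031
    flip_deg: float = 12.0
    fov_mm: tuple[float, float, float] = (240.0, 240.0, 184.0)
    acquired_matrix: tuple[int, int, int] = (256, 192, 46)
    temporal_resolution_s: float = 73.0
    n_pre: int = 1
    n_post: int = 20
    r1_per_mM_s: float = 3.9
    r2star_per_mM_s: float = 4.5
    snr_nawm: float = 91.5

    def __post_init__(self):
        if not (self.tr_s > self.te_s > 0):
            raise ValueError("require TR > TE > 0")
        if not (0 < self.flip_deg < 90):
            raise ValueError("flip angle must lie in (0, 90) degrees")
        if self.n_pre < 1:
            raise ValueError("need at least one pre-contrast frame")

    @property
    def n_frames(self) -> int:
        return self.n_pre + self.n_post

    def frame_times_s(self) -> np.ndarray:
        """Mid-frame acquisition times from scan start."""
        return (np.arange(self.n_frames) + 0.5) * self.temporal_resolution_s

    @property
    def injection_time_s(self) -> float:
        """Bolus injection at the start of the first post-contrast frame."""
        return self.n_pre * self.temporal_resolution_s

    @property
    def acquired_spacing_mm(self) -> tuple[float, float, float]:
        return tuple(
            f / n for f, n in zip(self.fov_mm, self.acquired_matrix)
        )


# Weinmann population parameters for a gadolinium bolus: plasma
# concentration D*(a1 e^{-m1 t} + a2 e^{-m2 t}), t in minutes post injection.
_WEINMANN = dict(a1_kg_per_l=3.99, a2_kg_per_l=4.78, m1_per_min=0.144, m2_per_min=0.0111)


@dataclass(frozen=True)
class AIF:
    """Arterial input function sampled at the frame times.

    ``frame_times_s`` are measured from scan start; ``cp_mM`` must be zero on
    pre-contrast frames.
    """

    frame_times_s: np.ndarray
    cp_mM: np.ndarray
    model: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.frame_times_s, dtype=float)
        c = np.asarray(self.cp_mM, dtype=float)
        if t.shape != c.shape:
            raise ValueError("frame_times_s and cp_mM must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("plasma concentration must be non-negative")
        object.__setattr__(self, "frame_times_s", t)
        object.__setattr__(self, "cp_mM", c)

    @classmethod
    def population(
        cls,
        frame_times_s,
        injection_time_s: float,
        dose_mmol_per_kg: float = 0.1,
        **params,
    ) -> "AIF":
        """Biexponential population AIF (Weinmann form) for a standard bolus."""
        p = {**_WEINMANN, **params}
        t = np.asarray(frame_times_s, dtype=float)
        tau_min = (t - injection_time_s) / 60.0
        cp = dose_mmol_per_kg * (
            p["a1_kg_per_l"] * np.exp(-p["m1_per_min"] * tau_min)
            + p["a2_kg_per_l"] * np.exp(-p["m2_per_min"] * tau_min)
        )
        cp[tau_min < 0] = 0.0
        return cls(t, cp, model={"form": "population_biexponential",
                                 "dose_mmol_per_kg": dose_mmol_per_kg,
                                 "injection_time_s": injection_time_s, **p})

    def integral_mM_min(self) -> np.ndarray:
        """Cumulative trapezoidal ∫c_p dt in mM*min at each frame time."""
        return cumulative_trapezoid(
            self.cp_mM, self.frame_times_s / 60.0, initial=0.0
        )

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.frame_times_s, self.cp_mM]),
            delimiter=",",
            header="time_s,cp_mM",
            comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "AIF":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(arr[:, 0], arr[:, 1], model={"form": "tabulated"})


@dataclass
class DynamicVolume:
    """4D (x, y, z, t) real-valued image series with frame timing."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    frame_times_s: np.ndarray
    affine: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    def frame(self, i: int) -> np.ndarray:
        return self.data[..., i]


def patlak_concentration(vP: float, PS_per_min: float, aif: AIF) -> np.ndarray:
    """Tissue concentration C_t[t] (mM) under the Patlak forward model."""
    if vP < 0 or PS_per_min < 0:
        raise ValueError("forward model requires vP >= 0 and PS >= 0")
    return vP * aif.cp_mM + PS_per_min * aif.integral_mM_min()


def extracerebral_enhancement(curve_params: dict, frame_times_s, injection_time_s: float) -> np.ndarray:
    """Relative signal multiplier E[t] for tissues without a BBB.

    ``form`` selects the template: ``constant`` (all ones), exponential
    saturation ``1 + a (1 - e^{-tau/tau_s})`` or power law
    ``1 + a (tau/tref_s)^b``; E = 1 before injection.
    """
    t = np.asarray(frame_times_s, dtype=float)
    tau = t - injection_time_s
    form = curve_params.get("form", "constant")
    numeric = [v for k, v in curve_params.items() if k != "form"]
    if not np.all(np.isfinite(numeric)):
        raise ValueError(f"non-finite enhancement curve parameters: {curve_params}")
    if form == "constant":
        E = np.ones_like(t)
    elif form == "exponential":
        a, tau_s = float(curve_params["a"]), float(curve_params["tau_s"])
        E = 1.0 + a * (1.0 - np.exp(-np.maximum(tau, 0.0) / tau_s))
    elif form == "power":
        a, b = float(curve_params["a"]), float(curve_params["b"])
        tref = float(curve_params["tref_s"])
        E = 1.0 + a * (np.maximum(tau, 0.0) / tref) ** b
    else:
        raise ValueError(f"unknown enhancement curve form: {form!r}")
    if not np.all(np.isfinite(E)):
        raise ValueError("enhancement curve produced non-finite values")
    E[tau < 0] = 1.0
    return E


def relaxation_rates(
    C_mM: np.ndarray, T10_s: float, T20star_s: float, r1_per_mM_s: float, r2star_per_mM_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Concentration-modulated T1[t] and T2*[t] via linear relaxivity."""
    if T10_s <= 0 or T20star_s <= 0:
        raise ValueError("pre-contrast relaxation times must be positive")
    C = np.asarray(C_mM, dtype=float)
    T1 = 1.0 / (1.0 / T10_s + r1_per_mM_s * C)
    T2s = 1.0 / (1.0 / T20star_s + r2star_per_mM_s * C)
    return T1, T2s


def spgr_signal(S0, T1_s, T2star_s, proto: Protocol) -> np.ndarray:
    """Spoiled gradient-echo steady-state signal (arbitrary units)."""
    th = np.deg2rad(proto.flip_deg)
    E1 = np.exp(-proto.tr_s / np.asarray(T1_s, dtype=float))
    return (
        np.asarray(S0, dtype=float)
        * (1.0 - E1) * np.sin(th) / (1.0 - E1 * np.cos(th))
        * np.exp(-proto.te_s / np.asarray(T2star_s, dtype=float))
    )


def class_signal_curves(
    table: TissueParameterTable, aif: AIF, proto: Protocol
) -> np.ndarray:
    """Per-class signal-time curves, shape (max_class_id + 1, n_frames).

    Row 0 (background) is zero.  Ground-truth parameters are
    piecewise-constant per class, so these curves fully determine the
    high-resolution 4D object.
    """
    n_frames = len(aif.frame_times_s)
    max_id = int(table.frame["class_id"].max())
    curves = np.zeros((max_id + 1, n_frames))
    for _, row in table.frame.iterrows():
        cid = int(row["class_id"])
        mode = row["enhancement_mode"]
        if mode == "patlak":
            C = patlak_concentration(row["vP"], row["PS_per_min"], aif)
            T1, T2s = relaxation_rates(
                C, row["T10_s"], row["T2star0_s"], proto.r1_per_mM_s, proto.r2star_per_mM_s
            )
            curves[cid] = spgr_signal(row["S0"], T1, T2s, proto)
        else:
            pre = spgr_signal(row["S0"], row["T10_s"], row["T2star0_s"], proto)
            if mode == "extracerebral_curve":
                E = extracerebral_enhancement(
                    table.curve_params(row["name"]), aif.frame_times_s, proto.injection_time_s
                )
            else:  # none
                E = np.ones(n_frames)
            curves[cid] = pre * E
    return curves


def synthesize_dro(
    labels: LabelVolume,
    table: TissueParameterTable,
    aif: AIF,
    proto: Protocol,
    frames: "list[int] | None" = None,
    dtype=np.float32,
) -> DynamicVolume:
    """Paint the high-resolution ground-truth 4D signal object.

    Because every parameter is piecewise-constant per tissue class, each
    frame is a lookup of the per-class curve; ``frames`` restricts synthesis
    to a subset to bound memory.
    """
    curves = class_signal_curves(table, aif, proto)
    t = aif.frame_times_s
    if len(t) != proto.n_frames:
        raise ValueError("AIF frame count does not match the protocol")
    idx = list(range(proto.n_frames)) if frames is None else list(frames)
    out = np.empty(labels.labels.shape + (len(idx),), dtype=dtype)
    for j, i in enumerate(idx):
        out[..., j] = curves[:, i][labels.labels]
    return DynamicVolume(
        data=out, spacing=labels.spacing, frame_times_s=t[idx], affine=labels.affine
    )
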