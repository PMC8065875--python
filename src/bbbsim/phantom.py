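"""Labelled ground-truth head object.

The simulator needs a high-resolution labelled head in which every voxel
belongs to one of 16 tissue classes (brain tissues with known plasma volume
``vP`` and leakage rate ``PS``, plus the extra-cerebral structures whose
strong contrast enhancement drives ringing artefacts into the brain).  A
synthetic nested-ellipsoid phantom is the default so no external atlas is
required; :func:`load_label_volume` accepts any labelled NIfTI with the same
class IDs for users who have a real atlas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import centered_affine

__all__ = [
    "CLASS_NAMES",
    "LabelVolume",
    "TissueParameterTable",
    "ParameterVolumes",
    "PhantomSpec",
    "build_synthetic_head",
    "load_label_volume",
    "save_label_volume",
    "assign_parameters",
]

#: Canonical tissue-class IDs.  0 is background everywhere in the package.
CLASS_NAMES: dict[int, str] = {
    1: "csf",
    2: "nawm",
    3: "wmh",
    4: "stroke",
    5: "cortical_gm",
    6: "deep_gm",
    7: "meninges",
    8: "muscle",
    9: "mandible_vertebrae",
    10: "skull_diploe",
    11: "skull_inner_table",
    12: "skull_outer_table",
    13: "vessels",
    14: "skin",
    15: "adipose",
    16: "eyes",
}

NAME_TO_ID = {v: k for k, v in CLASS_NAMES.items()}


@dataclass
class LabelVolume:
    """Integer-labelled 3D grid with voxel spacing and a voxel->world affine."""

    labels: np.ndarray  # uint16, 0 = background
    spacing: tuple[float, float, float]
    affine: np.ndarray
    class_names: dict[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint16)
        if np.any(np.asarray(self.spacing) <= 0):
            raise ValueError("spacing must be strictly positive")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.class_names)
        if unknown:
            raise ValueError(f"labels contain IDs without class names: {sorted(unknown)}")

    def mask(self, class_id_or_name) -> np.ndarray:
        cid = (
            NAME_TO_ID[class_id_or_name]
            if isinstance(class_id_or_name, str)
            else int(class_id_or_name)
        )
        return self.labels == cid

    def voxel_counts(self) -> dict[str, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {
            self.class_names.get(int(i), "background"): int(c)
            for i, c in zip(ids, counts)
        }


@dataclass
class PhantomSpec:
    """Geometry of the synthetic head.

    ``shape``/``spacing`` give the source grid (default 96 voxels at 1 mm —
    a desk-scale stand-in for a 0.5 mm atlas).  ``classes`` selects which of
    the 16 tissue classes to paint; omitted classes are simply not drawn.
    ``jitter`` adds a small seeded displacement (fraction of the head
    semi-axes) to the internal structures so distinct seeds give distinct
    anatomies.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    classes: tuple[str, ...] = tuple(NAME_TO_ID)
    head_fraction: float = 0.46
    jitter: float = 0.02


def _ellipsoid(u, centre, semi):
    return (
        ((u[0] - centre[0]) / semi[0]) ** 2
        + ((u[1] - centre[1]) / semi[1]) ** 2
        + ((u[2] - centre[2]) / semi[2]) ** 2
    ) < 1.0


def build_synthetic_head(spec: PhantomSpec | None = None, seed: int = 0) -> LabelVolume:
    """Deterministic nested-ellipsoid head phantom.

    Outside-in: skin and adipose shells, three-layer skull (outer table,
    diploe, inner table), meninges, subarachnoid CSF, cortical grey-matter
    ribbon and white-matter interior; inside: CSF ventricles, periventricular
    WMH caps, deep grey-matter nuclei, one basal-ganglia stroke lesion; plus
    tubular vessels crossing the brain surface, eyes, and a lower muscle /
    vertebrae block.  Raises if a requested class ends up empty (grid too
    small to host it).
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    want = set(spec.classes)
    unknown = want - set(NAME_TO_ID)
    if unknown:
        raise ValueError(f"unknown tissue classes requested: {sorted(unknown)}")

    shape = np.asarray(spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    fov = shape * spacing
    a = spec.head_fraction * fov  # head ellipsoid semi-axes, mm

    idx = np.indices(tuple(shape), dtype=np.float64)
    world = (idx - ((shape - 1) / 2.0).reshape(3, 1, 1, 1)) * spacing.reshape(3, 1, 1, 1)
    u = world / a.reshape(3, 1, 1, 1)  # normalised head coordinates
    r = np.sqrt((u**2).sum(axis=0))  # ellipsoidal radius, 1.0 = skin surface

    jit = lambda: rng.uniform(-spec.jitter, spec.jitter, size=3)  # noqa: E731

    labels = np.zeros(tuple(shape), dtype=np.uint16)

    def paint(name, mask):
        if name in want:
            labels[mask] = NAME_TO_ID[name]

    # concentric shells (fractions of the head radius)
    shells = [
        ("skin", 0.96, 1.00),
        ("adipose", 0.92, 0.96),
        ("skull_outer_table", 0.88, 0.92),
        ("skull_diploe", 0.84, 0.88),
        ("skull_inner_table", 0.80, 0.84),
        ("meninges", 0.77, 0.80),
        ("csf", 0.74, 0.77),
        ("cortical_gm", 0.64, 0.74),
        ("nawm", 0.00, 0.64),
    ]
    for name, lo, hi in shells:
        paint(name, (r >= lo) & (r < hi))

    interior = r < 0.64
    for sgn in (+1.0, -1.0):
        vent_c = np.array([sgn * 0.10, 0.0, 0.02]) + jit()
        for dy, name, semi in [
            (0.0, "csf", (0.07, 0.25, 0.10)),  # lateral ventricle
            (+0.30, "wmh", (0.09, 0.10, 0.12)),  # periventricular caps
            (-0.30, "wmh", (0.09, 0.10, 0.12)),
        ]:
            m = _ellipsoid(u, vent_c + [0.0, dy, 0.0], semi)
            if name == "wmh":
                m &= labels == NAME_TO_ID.get("nawm", 0)
            paint(name, m & interior)
        paint("deep_gm", _ellipsoid(u, np.array([sgn * 0.28, 0.02, 0.0]) + jit(),
                                    (0.10, 0.13, 0.12)) & interior)
    paint("stroke", _ellipsoid(u, np.array([0.22, 0.12, -0.06]) + jit(),
                               (0.08, 0.09, 0.09)) & interior)

    # vessels: superior sagittal sinus along y plus two penetrating vessels
    # along z; all restricted to r < 0.86 so they cross the brain surface
    vr = max(2.5, 1.5 * spacing.max())  # mm radius, >= voxel scale
    sinus = np.sqrt(world[0] ** 2 + (world[2] - 0.70 * a[2]) ** 2) < vr
    vessels = sinus & (r < 0.86)
    for sx in (+1.0, -1.0):
        pen = np.sqrt(
            (world[0] - sx * 0.30 * a[0]) ** 2 + (world[1] + 0.15 * a[1]) ** 2
        ) < vr * 0.8
        vessels |= pen & (r < 0.86) & (u[2] > -0.1)
    paint("vessels", vessels)

    # eyes: two spheres in the anterior face region
    eye_r = 0.12 * a.min()
    for sx in (+1.0, -1.0):
        c = np.array([sx * 0.30 * a[0], -0.80 * a[1], -0.05 * a[2]])
        paint("eyes", ((world - c.reshape(3, 1, 1, 1)) ** 2).sum(axis=0) < eye_r**2)

    # lower muscle block with embedded vertebrae/mandible column
    lower = (u[2] < -0.62) & (r < 1.0)
    paint("muscle", lower)
    spine = np.sqrt(world[0] ** 2 + (world[1] - 0.20 * a[1]) ** 2) < 0.10 * a.min()
    paint("mandible_vertebrae", lower & spine)

    missing = [n for n in spec.classes if not np.any(labels == NAME_TO_ID[n])]
    if missing:
        raise ValueError(
            f"grid {tuple(spec.shape)} too small to host classes: {missing}"
        )

    return LabelVolume(
        labels=labels,
        spacing=tuple(spacing),
        affine=centered_affine(shape, spacing),
        class_names=dict(CLASS_NAMES),
    )


def save_label_volume(vol: LabelVolume, path) -> None:
    img = nib.Nifti1Image(vol.labels.astype(np.uint16), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_label_volume(path, class_map: dict[int, str] | None = None) -> LabelVolume:
    """Read an integer-labelled NIfTI volume (e.g. an external atlas).

    ``class_map`` maps label IDs to tissue names; IDs present in the file but
    absent from the map raise with the offending IDs listed.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: label volume contains non-integer data")
        data = np.round(data).astype(np.uint16)
    class_map = dict(class_map) if class_map is not None else dict(CLASS_NAMES)
    present = set(int(i) for i in np.unique(data)) - {0}
    unknown = sorted(present - set(class_map))
    if unknown:
        raise ValueError(f"{path}: label IDs not in class_map: {unknown}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(
        labels=data.astype(np.uint16),
        spacing=spacing,
        affine=np.asarray(img.affine),
        class_names=class_map,
    )


# ---------------------------------------------------------------------------
# tissue parameters


@dataclass
class TissueParameterTable:
    """Per-class MR and pharmacokinetic ground truth.

    Columns: ``class_id, name, S0, T10_s, T2star0_s, vP, PS_per_min,
    enhancement_mode, curve_params`` (JSON).  ``enhancement_mode`` is one of
    ``patlak`` (brain tissues and vessels), ``extracerebral_curve`` (signal
    multiplier template) or ``none`` (no enhancement).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        if np.any(df["T10_s"] <= 0):
            raise ValueError("T10 must be positive")
        if np.any((df["vP"] < 0) | (df["vP"] > 1)):
            raise ValueError("vP must lie in [0, 1]")
        if np.any(df["PS_per_min"] < 0):
            raise ValueError("ground-truth PS must be non-negative")
        bad = df[~df["enhancement_mode"].isin(["patlak", "extracerebral_curve", "none"])]
        if len(bad):
            raise ValueError(f"invalid enhancement_mode for {list(bad['name'])}")
        self.frame = df.set_index("name", drop=False) if df.index.name != "name" else df

    def row(self, name: str) -> pd.Series:
        return self.frame.loc[name]

    def __getitem__(self, name: str) -> pd.Series:
        return self.row(name)

    def by_id(self, class_id: int) -> pd.Series:
        hit = self.frame[self.frame["class_id"] == class_id]
        if not len(hit):
            raise KeyError(f"no tissue-parameter row for class id {class_id}")
        return hit.iloc[0]

    def curve_params(self, name: str) -> dict:
        raw = self.row(name)["curve_params"]
        if isinstance(raw, dict):
            return raw
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
            return {}
        return json.loads(raw)

    @classmethod
    def from_csv(cls, path) -> "TissueParameterTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class ParameterVolumes:
    """Voxelwise ground-truth parameter maps, piecewise-constant per class."""

    S0: np.ndarray
    T10: np.ndarray
    T2star0: np.ndarray
    vP: np.ndarray
    PS: np.ndarray  # min^-1


def assign_parameters(vol: LabelVolume, table: TissueParameterTable) -> ParameterVolumes:
    """Expand the per-class table to voxelwise parameter volumes.

    Background voxels get S0 = PS = vP = 0 and nominal relaxation times.
    Raises naming the class if a label present in the volume has no row.
    """
    present = sorted(set(np.unique(vol.labels)) - {0})
    rows = {}
    for cid in present:
        name = vol.class_names[cid]
        try:
            rows[cid] = table.row(name)
        except KeyError:
            raise KeyError(f"tissue-parameter table has no row for class '{name}'")
    n = max(present, default=0) + 1
    luts = {k: np.zeros(n) for k in ("S0", "T10", "T2star0", "vP", "PS")}
    luts["T10"][0] = luts["T2star0"][0] = 1.0  # background placeholders, S0=0
    for cid, row in rows.items():
        luts["S0"][cid] = row["S0"]
        luts["T10"][cid] = row["T10_s"]
        luts["T2star0"][cid] = row["T2star0_s"]
        luts["vP"][cid] = row["vP"]
        luts["PS"][cid] = row["PS_per_min"]
    lab = vol.labels
    return ParameterVolumes(
        S0=luts["S0"][lab],
        T10=luts["T10"][lab],
        T2star0=luts["T2star0"][lab],
        vP=luts["vP"][lab],
        PS=luts["PS"][lab],
    )
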