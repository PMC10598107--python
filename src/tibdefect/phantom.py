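"""Digital periprosthetic tibial CT phantoms with full ground truth.

The phantom emulates a proximal tibia after total knee arthroplasty as seen
on a metal-artifact-reduced CT: tibia and fibula bone, a cemented tibial
component (tray + stem), and optional ellipsoidal osteolytic defects, on a
regular HU grid with configurable noise and radial streak artifacts.

Geometry is deliberately simple — stacked elliptical tibial cross-sections
with a wide epiphyseal flare tapering linearly into a cylindrical shaft, and
a separate fibula (thin cylinder with an ellipsoidal head, never voxel-
connected to the tibia) — but it exposes every landmark the downstream
pipeline needs: the tibial cut, the fibular tip and widest-head planes, the
tubercle level, and the mediolateral midline.

Noise-free class HU values sit at the midpoints of the segmentation threshold
intervals (defect -400, bone 1000, cement 850, implant 2500, air -1000), so
a noise-free phantom is exactly re-segmentable. The cement mantle is built
with the same Euclidean-distance rule the segmenter uses.

A separate cohort simulator draws per-knee (intraoperative, CT, X-ray) grade
triples from an intraoperative grade distribution and per-method confusion
matrices, defaulting to the row-normalized published 99-knee counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from . import reference
from .aori import AORIGrade, grade_defect
from .image import CTVolume, Label, LabelMap, DEFAULT_AXIS_TAGS
from .volumetrics import VolumeReport, compute_volumes
from .zones import Landmarks, partition_zones

# noise-free HU per class: midpoint of each threshold interval
HU_AIR = -1000
HU_DEFECT = -400
HU_BONE = 1000
HU_CEMENT = 850
HU_IMPLANT = 2500

Side = Literal["medial", "lateral", "both", "central"]
Zone = Literal["epiphysis", "metaphysis", "diaphysis"]


@dataclass(frozen=True)
class DefectSpec:
    """An ellipsoidal void carved out of tibial bone.

    ``centre_mm`` is the ellipsoid centre in physical coordinates
    (index * spacing). For ``side='both'`` a second ellipsoid is carved at
    the mediolateral mirror position about the tibial axis. If
    ``target_volume_cm3`` is given, the semi-axes are scaled uniformly so the
    analytic volume 4/3*pi*a*b*c matches it.
    """

    zone_target: Zone
    side: Side
    semi_axes_mm: tuple[float, float, float]
    centre_mm: tuple[float, float, float]
    target_volume_cm3: float | None = None

    def __post_init__(self):
        if self.side not in ("medial", "lateral", "both", "central"):
            raise ValueError(f"invalid side {self.side!r}")
        if self.zone_target not in ("epiphysis", "metaphysis", "diaphysis"):
            raise ValueError(f"invalid zone_target {self.zone_target!r}")
        if any(s <= 0 for s in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")
        if self.target_volume_cm3 is not None and self.target_volume_cm3 <= 0:
            raise ValueError("target_volume_cm3 must be positive")

    @property
    def scaled_semi_axes_mm(self) -> tuple[float, float, float]:
        a, b, c = self.semi_axes_mm
        if self.target_volume_cm3 is None:
            return (a, b, c)
        v0 = 4.0 / 3.0 * np.pi * a * b * c / 1000.0
        s = (self.target_volume_cm3 / v0) ** (1.0 / 3.0)
        return (a * s, b * s, c * s)

    @property
    def analytic_volume_cm3(self) -> float:
        a, b, c = self.scaled_semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


@dataclass(frozen=True)
class FibulaSpec:
    """Fibular geometry: thin shaft with an ellipsoidal head."""

    present: bool = True
    gap_mm: float = 4.5  # clearance between epiphyseal edge and fibular head
    head_radius_mm: float = 8.0
    shaft_radius_mm: float = 4.5
    tip_below_cut_mm: float = 18.0


@dataclass(frozen=True)
class ImplantSpec:
    """Cemented tibial component: elliptical tray plus a central stem."""

    tray_thickness_mm: float = 4.0
    tray_coverage: float = 0.85  # fraction of the plateau ellipse covered
    stem_length_mm: float = 30.0
    stem_radius_mm: float = 6.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom parameterization. Defaults give a realistic adult tibia."""

    grid_shape: tuple[int, int, int] = (160, 112, 224)
    spacing_mm: tuple[float, float, float] = (0.625, 0.625, 0.625)
    epiphysis_width_mm: float = 75.0
    epiphysis_ap_mm: float = 55.0
    flare_length_mm: float = 50.0
    shaft_radius_mm: float = 12.5
    cut_below_top_mm: float = 10.0
    total_length_mm: float | None = None  # None: tibia runs to the grid bottom
    tubercle_below_cut_mm: float = 50.0
    fibula: FibulaSpec = field(default_factory=FibulaSpec)
    implant: ImplantSpec = field(default_factory=ImplantSpec)
    cement_thickness_mm: float = 3.0
    defects: tuple[DefectSpec, ...] = ()
    noise_sd_hu: float = 0.0
    streak_artifacts: bool = False
    streak_amplitude_hu: float = 150.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "epiphysis_width_mm", "epiphysis_ap_mm", "flare_length_mm",
            "shaft_radius_mm", "cut_below_top_mm", "tubercle_below_cut_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cement_thickness_mm < 0 or self.noise_sd_hu < 0:
            raise ValueError("cement_thickness_mm and noise_sd_hu must be non-negative")
        object.__setattr__(self, "defects", tuple(self.defects))

    @property
    def tibia_centre_mm(self) -> tuple[float, float]:
        # centred at 40% mediolaterally to leave lateral room for the fibula
        nx, ny, _ = self.grid_shape
        return (0.40 * nx * self.spacing_mm[0], 0.5 * ny * self.spacing_mm[1])


@dataclass
class GroundTruth:
    """Exact per-voxel labels, landmarks, zone volumes and grade of a phantom."""

    true_labels: LabelMap
    landmarks: Landmarks
    true_zone_volumes: VolumeReport
    true_grade: AORIGrade


def _ellipsoid_mask(shape, spacing, centre_mm, semi_axes_mm) -> np.ndarray:
    nx, ny, nz = shape
    x = np.arange(nx) * spacing[0]
    y = np.arange(ny) * spacing[1]
    z = np.arange(nz) * spacing[2]
    dx = (x - centre_mm[0]) / semi_axes_mm[0]
    dy = (y - centre_mm[1]) / semi_axes_mm[1]
    dz = (z - centre_mm[2]) / semi_axes_mm[2]
    return (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    ) <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Build the HU volume and its exact ground truth.

    Deterministic given ``spec.seed``; the seed feeds only the additive noise,
    so two noise-free phantoms with different seeds are voxel-identical.
    Raises ``ValueError`` for a tray thinner than one slice or a defect that
    extends outside the tibial bone.
    """
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.spacing_mm
    if spec.implant.tray_thickness_mm < sz:
        raise ValueError(
            f"implant tray ({spec.implant.tray_thickness_mm} mm) thinner than one "
            f"slice ({sz} mm): grid too coarse"
        )
    cx, cy = spec.tibia_centre_mm
    cut_z = round(spec.cut_below_top_mm / sz)
    if spec.total_length_mm is None:
        end_z = nz
    else:
        end_z = min(nz, cut_z + round(spec.total_length_mm / sz))

    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    z = np.arange(nz) * sz

    # tibia: elliptical sections, linear flare from the plateau to the shaft
    a_epi, b_epi = spec.epiphysis_width_mm / 2.0, spec.epiphysis_ap_mm / 2.0
    r_shaft = spec.shaft_radius_mm
    t = np.clip((z - cut_z * sz) / spec.flare_length_mm, 0.0, 1.0)
    a_z = a_epi + (r_shaft - a_epi) * t
    b_z = b_epi + (r_shaft - b_epi) * t
    in_roi = (np.arange(nz) >= cut_z) & (np.arange(nz) < end_z)
    tibia = (
        ((x[:, None, None] - cx) / a_z[None, None, :]) ** 2
        + ((y[None, :, None] - cy) / b_z[None, None, :]) ** 2
    ) <= 1.0
    tibia &= in_roi[None, None, :]

    # fibula: ellipsoidal head + distal shaft, strictly lateral of the tibia
    fibula = np.zeros_like(tibia)
    fib = spec.fibula
    if fib.present:
        fx = cx + a_epi + fib.gap_mm + fib.head_radius_mm
        if fx + fib.head_radius_mm >= nx * sx:
            raise ValueError("fibula does not fit inside the grid laterally")
        tip_mm = (cut_z * sz) + fib.tip_below_cut_mm
        head_cz = tip_mm + fib.head_radius_mm
        fibula |= _ellipsoid_mask(
            spec.grid_shape, spec.spacing_mm, (fx, cy, head_cz),
            (fib.head_radius_mm, fib.head_radius_mm, fib.head_radius_mm),
        )
        shaft = (
            ((x[:, None, None] - fx) ** 2 + (y[None, :, None] - cy) ** 2)
            <= fib.shaft_radius_mm**2
        ) & (z[None, None, :] >= head_cz)
        fibula |= shaft
        fibula &= (np.arange(nz) < end_z)[None, None, :]
        if (fibula & tibia).any():
            raise ValueError("fibula intersects the tibia; increase fibula gap")

    # implant: tray covering most of the plateau, stem below it
    imp = spec.implant
    tray_z1 = cut_z + max(1, round(imp.tray_thickness_mm / sz))
    tray_xy = (
        ((x[:, None] - cx) / (imp.tray_coverage * a_epi)) ** 2
        + ((y[None, :] - cy) / (imp.tray_coverage * b_epi)) ** 2
    ) <= 1.0
    zi = np.arange(nz)
    tray = tray_xy[:, :, None] & ((zi >= cut_z) & (zi < tray_z1))[None, None, :]
    stem_z1 = tray_z1 + round(imp.stem_length_mm / sz)
    stem_xy = ((x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2) <= imp.stem_radius_mm**2
    stem = stem_xy[:, :, None] & ((zi >= tray_z1) & (zi < stem_z1))[None, None, :]
    implant = (tray | stem) & tibia

    # cement: bone-region voxels within the mantle thickness of the implant,
    # built with the same Euclidean distance rule the segmenter applies
    bone_region = tibia & ~implant
    if spec.cement_thickness_mm > 0:
        dist = ndimage.distance_transform_edt(~implant, sampling=spec.spacing_mm)
        cement = bone_region & (dist <= spec.cement_thickness_mm)
    else:
        cement = np.zeros_like(bone_region)
    bone = bone_region & ~cement

    # defects: ellipsoidal voids carved strictly out of tibial bone
    defect = np.zeros_like(bone)
    for d in spec.defects:
        centres = [d.centre_mm]
        if d.side == "both":
            mx = 2 * cx - d.centre_mm[0]
            centres.append((mx, d.centre_mm[1], d.centre_mm[2]))
        for c_mm in centres:
            ix = (round(c_mm[0] / sx), round(c_mm[1] / sy), round(c_mm[2] / sz))
            if not tibia[ix]:
                raise ValueError(f"defect centre {c_mm} lies outside the tibia")
            ell = _ellipsoid_mask(
                spec.grid_shape, spec.spacing_mm, c_mm, d.scaled_semi_axes_mm
            )
            if (ell & ~bone).any():
                raise ValueError(
                    f"defect at {c_mm} extends outside the tibial bone envelope"
                )
            defect |= ell
    bone = bone & ~defect

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[bone] = Label.BONE_TIBIA
    labels[fibula] = Label.BONE_FIBULA
    labels[cement] = Label.CEMENT
    labels[implant] = Label.IMPLANT
    labels[defect] = Label.DEFECT

    hu = np.full(spec.grid_shape, HU_AIR, dtype=np.float64)
    hu[bone | fibula] = HU_BONE
    hu[cement] = HU_CEMENT
    hu[implant] = HU_IMPLANT
    hu[defect] = HU_DEFECT

    if spec.streak_artifacts:
        hu += _streak_field(spec, implant, x, y)
        hu[implant] = HU_IMPLANT  # streaks corrupt the surroundings, not the metal

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu += rng.normal(0.0, spec.noise_sd_hu, size=hu.shape)

    hu = np.clip(np.rint(hu), -1024, 3071).astype(np.int16)
    ct = CTVolume(hu, spec.spacing_mm, DEFAULT_AXIS_TAGS)
    label_map = LabelMap(labels, spec.spacing_mm, DEFAULT_AXIS_TAGS)

    # ground-truth landmarks from the constructed masks themselves
    if fib.present:
        fib_slices = np.flatnonzero(fibula.any(axis=(0, 1)))
        tip_z_idx = int(fib_slices[0])
        widths = np.zeros(nz)
        for k in fib_slices:
            xs = np.flatnonzero(fibula[:, :, k].any(axis=1))
            widths[k] = (xs[-1] - xs[0] + 1) * sx
        widest_z_idx = int(np.argmax(widths))
    else:
        # virtual landmarks at the configured fibular positions
        tip_z_idx = cut_z + round(fib.tip_below_cut_mm / sz)
        widest_z_idx = tip_z_idx + round(fib.head_radius_mm / sz)
    landmarks = Landmarks(
        tibial_cut_z=cut_z,
        fibular_tip_z=tip_z_idx,
        fibular_widest_z=widest_z_idx,
        tubercle_z=cut_z + round(spec.tubercle_below_cut_mm / sz),
        midline_x=cx / sx,
        distal_end_z=end_z,
    ).validate()

    partition = partition_zones(landmarks, spec.epiphysis_width_mm, sz)
    truth = GroundTruth(
        true_labels=label_map,
        landmarks=landmarks,
        true_zone_volumes=compute_volumes(label_map, partition),
        true_grade=grade_defect(label_map, landmarks),
    )
    return ct, truth


def _streak_field(spec: PhantomSpec, implant: np.ndarray, x, y) -> np.ndarray:
    """Radial high/low-HU streaks emanating from the implant, per slice."""
    nx, ny, nz = spec.grid_shape
    cx, cy = spec.tibia_centre_mm
    theta = np.arctan2(y[None, :] - cy, x[:, None] - cx)
    r = np.hypot(x[:, None] - cx, y[None, :] - cy)
    pattern = spec.streak_amplitude_hu * np.cos(12 * theta) * np.exp(-r / 40.0)
    field3d = np.zeros(spec.grid_shape)
    has_implant = implant.any(axis=(0, 1))
    field3d[:, :, has_implant] = pattern[:, :, None]
    return field3d


# ---------------------------------------------------------------------------
# scenario grid: 12 canonical defect configurations spanning all four grades

def scenario_grid(base: PhantomSpec | None = None) -> list[tuple[str, PhantomSpec, AORIGrade]]:
    """Twelve defect scenarios: 3 zones x {medial, lateral, both, central}.

    Epiphyseal defects stay proximal to the fibular-tip plane (grade I);
    metaphyseal defects cross it on one condyle (IIa) or on both — either as
    two mirrored voids ('both') or as one midline-spanning anterior void
    ('central'), both IIb; diaphyseal defects extend distal to the tubercle
    plane (III).
    """
    base = base or PhantomSpec()
    sx, sy, sz = base.spacing_mm
    cx, cy = base.tibia_centre_mm
    cut_mm = round(base.cut_below_top_mm / sz) * sz

    def at(dx, dy, dz_below_cut):
        # generic sub-voxel offset: a defect centre exactly on the lattice with
        # integer-voxel semi-axes is the worst case for voxel-centre inclusion
        # (undercounts ~3% at 5 mm semi-axes); real lesions are never aligned
        g = (0.3 * sx, 0.3 * sy, 0.3 * sz)
        return (cx + dx + g[0], cy + dy + g[1], cut_mm + dz_below_cut + g[2])

    defs: list[tuple[str, DefectSpec, AORIGrade]] = [
        # epiphysis: between the cement under the tray (ends 7 mm below the
        # cut) and the fibular tip plane (18 mm below the cut) -> grade I
        ("epi-medial", DefectSpec("epiphysis", "medial", (8, 8, 4.5), at(-18, 0, 12.5)), AORIGrade.I),
        ("epi-lateral", DefectSpec("epiphysis", "lateral", (8, 8, 4.5), at(+18, 0, 12.5)), AORIGrade.I),
        ("epi-both", DefectSpec("epiphysis", "both", (8, 8, 4.5), at(-18, 0, 12.5)), AORIGrade.I),
        ("epi-central", DefectSpec("epiphysis", "central", (8, 4.5, 4.5), at(0, -14, 12.5)), AORIGrade.I),
        # metaphysis: crossing the fibular-tip plane, above the tubercle
        ("meta-medial", DefectSpec("metaphysis", "medial", (5, 8, 6), at(-15, 0, 26)), AORIGrade.IIA),
        ("meta-lateral", DefectSpec("metaphysis", "lateral", (5, 8, 6), at(+15, 0, 26)), AORIGrade.IIA),
        ("meta-both", DefectSpec("metaphysis", "both", (5, 8, 6), at(-15, 0, 26)), AORIGrade.IIB),
        ("meta-central", DefectSpec("metaphysis", "central", (14, 4.5, 5), at(0, -14, 22)), AORIGrade.IIB),
        # diaphysis: distal to the tubercle plane -> grade III
        ("dia-medial", DefectSpec("diaphysis", "medial", (5, 5, 8), at(-5, 0, 85)), AORIGrade.III),
        ("dia-lateral", DefectSpec("diaphysis", "lateral", (5, 5, 8), at(+5, 0, 85)), AORIGrade.III),
        ("dia-both", DefectSpec("diaphysis", "both", (5, 5, 8), at(-5, 0, 85)), AORIGrade.III),
        ("dia-central", DefectSpec("diaphysis", "central", (5, 5, 8), at(0, 0, 85)), AORIGrade.III),
    ]
    return [
        (name, replace(base, defects=(d,)), expected)
        for name, d, expected in defs
    ]


def demo_spec(noise_sd_hu: float = 0.0, seed: int = 0) -> PhantomSpec:
    """The canonical single-defect phantom: a medial metaphyseal void (IIa)."""
    base = PhantomSpec(noise_sd_hu=noise_sd_hu, seed=seed)
    _, spec, _ = scenario_grid(base)[4]  # meta-medial
    return spec


# ---------------------------------------------------------------------------
# grading-cohort simulator

@dataclass(frozen=True)
class CohortSpec:
    """Statistical model of a grading cohort.

    Per knee, the intraoperative grade is drawn from ``intraop_distribution``
    and the CT / X-ray grades conditionally from the corresponding row of the
    per-method confusion matrix. Defaults are the row-normalized published
    99-knee counts.
    """

    n_knees: int
    intraop_distribution: np.ndarray = field(
        default_factory=reference.intraop_distribution
    )
    ct_confusion: np.ndarray = field(default_factory=reference.ct_confusion)
    xray_confusion: np.ndarray = field(default_factory=reference.xray_confusion)
    seed: int = 0

    def __post_init__(self):
        if self.n_knees <= 0:
            raise ValueError("n_knees must be positive")
        p = np.asarray(self.intraop_distribution, dtype=float)
        if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-12 or (p < 0).any():
            raise ValueError("intraop_distribution must be a probability vector over 4 grades")
        for name in ("ct_confusion", "xray_confusion"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (4, 4) or (m < 0).any():
                raise ValueError(f"{name} must be a non-negative 4x4 matrix")
            if np.abs(m.sum(axis=1) - 1.0).max() > 1e-12:
                raise ValueError(f"rows of {name} must sum to 1")
        object.__setattr__(self, "intraop_distribution", p)
        object.__setattr__(self, "ct_confusion", np.asarray(self.ct_confusion, float))
        object.__setattr__(self, "xray_confusion", np.asarray(self.xray_confusion, float))


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a cohort table with columns knee_id, intraop, ct, xray (grades 1-4)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_knees
    intraop = rng.choice(4, size=n, p=spec.intraop_distribution)
    u_ct = rng.random(n)
    u_xr = rng.random(n)
    ct_cdf = np.cumsum(spec.ct_confusion, axis=1)
    xr_cdf = np.cumsum(spec.xray_confusion, axis=1)
    ct = (u_ct[:, None] > ct_cdf[intraop]).sum(axis=1)
    xray = (u_xr[:, None] > xr_cdf[intraop]).sum(axis=1)
    return pd.DataFrame(
        {
            "knee_id": np.arange(1, n + 1),
            "intraop": intraop + 1,
            "ct": ct + 1,
            "xray": xray + 1,
        }
    )
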