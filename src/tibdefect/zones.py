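"""Zonal partition of the tibial region of interest.

The region of interest runs from the tibial resection plane (the flat cut
under the tibial component) to the most distal depicted tibial slice. It is
split into the three zones of the zonal-fixation concept:

* **epiphysis** — from the tibial cut down to the level where the fibular
  head is at its widest mediolateral extent;
* **metaphysis** — from that level down to the metaphyseal–diaphyseal
  junction placed by the *rule of the square*: a square whose side equals
  the widest mediolateral width of the epiphysis, anchored with its top edge
  at the tibial cut;
* **diaphysis** — everything distal to the square.

Zone boundaries are transverse planes (slice indices); each zone is the full
cross-section of the bone between its planes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .image import Label, LabelMap, TIBIAL_CLASSES


@dataclass
class Landmarks:
    """Anatomical landmark slice indices along the superior–inferior axis.

    ``midline_x`` is a voxel index on the medial–lateral axis splitting the
    medial (index < midline) and lateral condyles. ``distal_end_z`` is the
    half-open end of the region of interest.
    """

    tibial_cut_z: int
    fibular_tip_z: int
    fibular_widest_z: int
    tubercle_z: int
    midline_x: float
    distal_end_z: int

    def validate(self) -> "Landmarks":
        if not (self.tibial_cut_z < self.fibular_widest_z < self.distal_end_z):
            raise ValueError(
                "landmarks must be ordered tibial_cut_z < fibular_widest_z < distal_end_z, "
                f"got {self.tibial_cut_z}, {self.fibular_widest_z}, {self.distal_end_z}"
            )
        if self.fibular_tip_z > self.fibular_widest_z:
            raise ValueError("fibular tip must be at or proximal to the widest fibular slice")
        return self

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Landmarks":
        d = json.loads(Path(path).read_text())
        return cls(**d).validate()


@dataclass
class ZonePartition:
    """Half-open slice intervals of the three zones, plus the square side W."""

    epiphysis_range: tuple[int, int]
    metaphysis_range: tuple[int, int]
    diaphysis_range: tuple[int, int]
    square_side_mm: float

    def validate(self) -> "ZonePartition":
        e, m, d = self.epiphysis_range, self.metaphysis_range, self.diaphysis_range
        if not (e[0] <= e[1] == m[0] <= m[1] == d[0] <= d[1]):
            raise ValueError(f"zone intervals must be contiguous and ordered: {e}, {m}, {d}")
        if self.square_side_mm <= 0:
            raise ValueError("square_side_mm must be positive")
        return self

    @property
    def roi_range(self) -> tuple[int, int]:
        return (self.epiphysis_range[0], self.diaphysis_range[1])

    def zone_of_slice(self, z: int) -> str | None:
        for name, (a, b) in self.items():
            if a <= z < b:
                return name
        return None

    def items(self):
        return [
            ("epiphysis", self.epiphysis_range),
            ("metaphysis", self.metaphysis_range),
            ("diaphysis", self.diaphysis_range),
        ]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ZonePartition":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["epiphysis_range"]),
            tuple(d["metaphysis_range"]),
            tuple(d["diaphysis_range"]),
            d["square_side_mm"],
        ).validate()


def detect_tibial_cut(labels: LabelMap) -> int:
    """Most proximal slice of the implant tray, or of tibial bone if no implant.

    The tibial cut is the proximal boundary of the region of interest; with a
    component in place its tray sits on the cut, so the first implant slice
    marks it.
    """
    implant = labels.mask(Label.IMPLANT)
    target = implant if implant.any() else labels.mask(Label.BONE_TIBIA)
    if not target.any():
        raise ValueError("volume contains neither implant nor tibial bone")
    return int(np.flatnonzero(target.any(axis=(0, 1)))[0])


def detect_fibular_landmarks(labels: LabelMap) -> tuple[int, int]:
    """Locate the fibular head: (most proximal slice, widest mediolateral slice).

    The widest slice maximizes the physical mediolateral extent
    ``(max_index - min_index + 1) * spacing``; ties go to the most proximal
    qualifying slice.
    """
    fib = labels.mask(Label.BONE_FIBULA)
    per_slice = fib.any(axis=(0, 1))
    if not per_slice.any():
        raise ValueError(
            "no fibula in the label map; supply landmarks explicitly "
            "(fibular_tip_z / fibular_widest_z)"
        )
    slices = np.flatnonzero(per_slice)
    tip_z = int(slices[0])
    sx = labels.spacing_mm[0]
    widths = np.zeros(labels.shape[2])
    for z in slices:
        xs = np.flatnonzero(fib[:, :, z].any(axis=1))
        widths[z] = (xs[-1] - xs[0] + 1) * sx
    widest_z = int(np.argmax(widths))  # argmax returns the first (most proximal) maximum
    return tip_z, widest_z


def measure_epiphysis_width(labels: LabelMap, cut_z: int, widest_z: int) -> float:
    """Widest mediolateral extent (mm) of the tibial foreground in [cut_z, widest_z).

    The tibial foreground is bone + cement + implant + defect; fibular bone is
    excluded. This width is the side of the square in the rule of the square.
    """
    if widest_z <= cut_z:
        raise ValueError(f"empty epiphyseal range [{cut_z}, {widest_z})")
    fg = labels.mask(*TIBIAL_CLASSES)[:, :, cut_z:widest_z]
    if not fg.any():
        raise ValueError("no tibial foreground in the epiphyseal range")
    sx = labels.spacing_mm[0]
    width = 0.0
    for k in range(fg.shape[2]):
        xs = np.flatnonzero(fg[:, :, k].any(axis=1))
        if xs.size:
            width = max(width, (xs[-1] - xs[0] + 1) * sx)
    return float(width)


def partition_zones(
    landmarks: Landmarks, width_mm: float, slice_spacing_mm: float
) -> ZonePartition:
    """Partition the region of interest by the rule of the square.

    The metaphyseal–diaphyseal junction lies ``round(W / spacing)`` slices
    below the tibial cut, where ``W`` is the widest epiphyseal width; the
    epiphyseal–metaphyseal junction is the widest fibular-head slice. Both
    boundaries are clamped into the region of interest.
    """
    landmarks.validate()
    if width_mm <= 0:
        raise ValueError("width_mm must be positive")
    cut = landmarks.tibial_cut_z
    end = landmarks.distal_end_z
    epi_meta = min(landmarks.fibular_widest_z, end)
    meta_dia = min(cut + round(width_mm / slice_spacing_mm), end)
    if meta_dia <= epi_meta:
        warnings.warn(
            "rule-of-the-square junction lies at or above the fibular widest plane; "
            "metaphysis is empty",
            stacklevel=2,
        )
        meta_dia = epi_meta
    return ZonePartition(
        epiphysis_range=(cut, epi_meta),
        metaphysis_range=(epi_meta, meta_dia),
        diaphysis_range=(meta_dia, end),
        square_side_mm=float(width_mm),
    ).validate()


def detect_landmarks(
    labels: LabelMap,
    tubercle_z: int,
    overrides: dict | None = None,
) -> Landmarks:
    """Detect all image-derived landmarks, with explicit overrides.

    The tibial tubercle level is not detectable from image content and must be
    supplied. ``midline_x`` defaults to the mediolateral centroid of the
    tibial bone in the distal half of the region of interest (a shaft-based
    estimate robust to plateau defects).
    """
    overrides = dict(overrides or {})
    cut_z = overrides.pop("tibial_cut_z", None)
    if cut_z is None:
        cut_z = detect_tibial_cut(labels)
    if "fibular_tip_z" in overrides or "fibular_widest_z" in overrides:
        tip_z = overrides.pop("fibular_tip_z")
        widest_z = overrides.pop("fibular_widest_z")
    else:
        tip_z, widest_z = detect_fibular_landmarks(labels)
    tibia = labels.mask(*TIBIAL_CLASSES)
    distal_slices = np.flatnonzero(tibia.any(axis=(0, 1)))
    end_z = overrides.pop("distal_end_z", None)
    if end_z is None:
        end_z = int(distal_slices[-1]) + 1
    midline = overrides.pop("midline_x", None)
    if midline is None:
        half = (cut_z + end_z) // 2
        shaft = labels.mask(Label.BONE_TIBIA)[:, :, half:end_z]
        xs = np.nonzero(shaft)[0]
        midline = float(xs.mean()) if xs.size else labels.shape[0] / 2
    if overrides:
        raise ValueError(f"unknown landmark overrides: {sorted(overrides)}")
    return Landmarks(
        tibial_cut_z=int(cut_z),
        fibular_tip_z=int(tip_z),
        fibular_widest_z=int(widest_z),
        tubercle_z=int(tubercle_z),
        midline_x=float(midline),
        distal_end_z=int(end_z),
    ).validate()
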