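"""Hounsfield-unit threshold segmentation of periprosthetic tibial CT.

Each voxel is classified into defect / bone / cement / implant / background
from standard HU threshold intervals for a cemented tibial component:
defect [-1024, 200], bone [200, 1800], cement [300, 1400], implant
[2000, 3071]. The intervals overlap (cement is inside the bone range) and
leave a gap (1800, 2000); resolution rules:

* a voxel at exactly 200 HU goes to bone, not defect — conservative, so
  boundary artifacts never inflate the defect;
* cement wins over bone only within a configurable Euclidean distance of the
  implant (a cement mantle sits at the bone–implant interface by definition);
* the unassigned gap (1800, 2000) is a partial-volume rim: it goes to the
  implant when touching it (within one voxel), otherwise to bone;
* defect-range voxels count as defect only inside the bone envelope —
  the hole-filled morphological closing of the bone + cement + implant union
  (closing bridges surface-breaking voids, hole-filling captures enclosed
  osteolytic cavities); exterior air is background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import Label, LabelMap, CTVolume

DEFAULT_CEMENT_ADJACENCY_MM = 3.0
DEFAULT_CLOSING_RADIUS_VOX = 3


@dataclass(frozen=True)
class ThresholdSet:
    """Closed HU intervals per tissue class."""

    defect_range: tuple[int, int] = (-1024, 200)
    bone_range: tuple[int, int] = (200, 1800)
    cement_range: tuple[int, int] = (300, 1400)
    implant_range: tuple[int, int] = (2000, 3071)

    def __post_init__(self):
        for name in ("defect_range", "bone_range", "cement_range", "implant_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: [{lo}, {hi}]")
        if self.implant_range[0] <= self.bone_range[1]:
            raise ValueError("implant_range must be disjoint from bone_range")

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        kw = {f"{k}_range": tuple(v) for k, v in d.items()}
        return cls(**kw)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return X**2 + Y**2 + Z**2 <= r**2


def segment_hu(
    ct: CTVolume,
    thresholds: ThresholdSet | None = None,
    cement_adjacency_mm: float = DEFAULT_CEMENT_ADJACENCY_MM,
    closing_radius_voxels: int = DEFAULT_CLOSING_RADIUS_VOX,
) -> LabelMap:
    """Classify every voxel of ``ct`` by HU thresholds and the resolution rules.

    Returns a :class:`LabelMap` whose bone voxels are all ``BONE_TIBIA``;
    use :func:`split_tibia_fibula` to separate the fibula.
    """
    thr = thresholds or ThresholdSet()
    if cement_adjacency_mm < 0:
        raise ValueError("cement_adjacency_mm must be non-negative")
    hu = ct.voxels
    labels = np.zeros(hu.shape, dtype=np.uint8)

    implant = (hu >= thr.implant_range[0]) & (hu <= thr.implant_range[1])
    # gap rule: HU between bone top and implant bottom is a partial-volume rim
    gap = (hu > thr.bone_range[1]) & (hu < thr.implant_range[0])
    if gap.any():
        near_implant = ndimage.binary_dilation(implant, _ball(1))
        implant = implant | (gap & near_implant)
        gap_bone = gap & ~implant
    else:
        gap_bone = np.zeros_like(gap)

    if not implant.any():
        warnings.warn("no implant voxels found; cement class will be empty", stacklevel=2)
        cement = np.zeros_like(implant)
    else:
        dist = ndimage.distance_transform_edt(~implant, sampling=ct.spacing_mm)
        shell = dist <= cement_adjacency_mm
        cement = (
            (hu >= thr.cement_range[0]) & (hu <= thr.cement_range[1]) & shell & ~implant
        )

    # exact 200 HU is shared by the defect and bone ranges: bone wins
    bone = ((hu >= thr.bone_range[0]) & (hu <= thr.bone_range[1]) & ~cement & ~implant) | gap_bone
    solid = bone | cement | implant
    if not solid.any():
        raise ValueError("no foreground: volume contains no bone, cement or implant")

    envelope = ndimage.binary_fill_holes(
        ndimage.binary_closing(solid, _ball(closing_radius_voxels), border_value=0)
    )
    defect = (hu < thr.bone_range[0]) & (hu >= thr.defect_range[0]) & envelope & ~solid

    labels[bone] = Label.BONE_TIBIA
    labels[cement] = Label.CEMENT
    labels[implant] = Label.IMPLANT
    labels[defect] = Label.DEFECT
    return LabelMap(labels, ct.spacing_mm, ct.axis_tags, ct.origin)


def split_tibia_fibula(labels: LabelMap) -> LabelMap:
    """Separate tibial from fibular bone by connected components (26-connectivity).

    The largest bone component is the tibia. Among the remaining components,
    the largest one whose centroid lies lateral to the tibial centroid is the
    fibula. Other small components are merged into the tibia when within two
    voxels of it, else discarded as background. When the two largest
    components tie in size, the one with more voxels in the proximal half of
    the volume is the tibia.
    """
    bone = labels.mask(Label.BONE_TIBIA, Label.BONE_FIBULA)
    if not bone.any():
        raise ValueError("no bone voxels to split")
    structure = np.ones((3, 3, 3), dtype=bool)
    comp, n = ndimage.label(bone, structure=structure)
    out = labels.labels.copy()
    if n == 1:
        out[bone] = Label.BONE_TIBIA
        return LabelMap(out, labels.spacing_mm, labels.axis_tags, labels.origin)

    sizes = ndimage.sum_labels(bone, comp, index=np.arange(1, n + 1)).astype(int)
    order = np.argsort(sizes)[::-1] + 1  # component ids, largest first
    tibia_id = int(order[0])
    if len(order) > 1 and sizes[order[1] - 1] == sizes[tibia_id - 1]:
        half = labels.shape[2] // 2
        cand = [int(order[0]), int(order[1])]
        proximal = [np.count_nonzero(comp[:, :, :half] == c) for c in cand]
        tibia_id = cand[int(np.argmax(proximal))]

    centroids = ndimage.center_of_mass(bone, comp, index=np.arange(1, n + 1))
    tibia_cx = centroids[tibia_id - 1][0]
    fibula_id = 0
    best = 0
    for cid in range(1, n + 1):
        if cid == tibia_id:
            continue
        if centroids[cid - 1][0] > tibia_cx and sizes[cid - 1] > best:
            best = sizes[cid - 1]
            fibula_id = cid

    tibia_mask = comp == tibia_id
    out[bone] = Label.BACKGROUND
    out[tibia_mask] = Label.BONE_TIBIA
    if fibula_id:
        out[comp == fibula_id] = Label.BONE_FIBULA

    # stray fragments: merge into tibia if within 2 voxels, else background
    strays = [c for c in range(1, n + 1) if c not in (tibia_id, fibula_id)]
    if strays:
        near = ndimage.binary_dilation(tibia_mask, _ball(2))
        for cid in strays:
            frag = comp == cid
            if (frag & near).any():
                out[frag] = Label.BONE_TIBIA
    return LabelMap(out, labels.spacing_mm, labels.axis_tags, labels.origin)
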