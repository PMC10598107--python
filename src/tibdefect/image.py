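"""In-memory containers for CT volumes and voxel label maps, with NIfTI-1 I/O.

Axis convention used throughout the package (recorded in the NIfTI header
description and in JSON sidecars):

* axis 0 — medial -> lateral (index increases laterally),
* axis 1 — anterior -> posterior,
* axis 2 — superior -> inferior (slice index increases distally).

Voxel indices are 0-based; physical position of voxel ``i`` along an axis is
``i * spacing_mm`` for that axis. All intervals over slice indices are
half-open ``[start, stop)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import nibabel as nib
import numpy as np

HU_MIN = -1024
HU_MAX = 3071

#: canonical axis tags, in axis order
DEFAULT_AXIS_TAGS = ("medial-lateral", "anterior-posterior", "superior-inferior")


class Label(IntEnum):
    """Voxel tissue classes produced by segmentation."""

    BACKGROUND = 0
    BONE_TIBIA = 1
    BONE_FIBULA = 2
    CEMENT = 3
    IMPLANT = 4
    DEFECT = 5


#: classes counted as tibial material (fibula deliberately excluded)
TIBIAL_CLASSES = (Label.BONE_TIBIA, Label.CEMENT, Label.IMPLANT, Label.DEFECT)


def _check_spacing(spacing_mm) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths, got {spacing_mm}")
    return spacing


@dataclass
class CTVolume:
    """A 3D grid of Hounsfield-unit values with physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Integer HU values in ``[-1024, 3071]``.
    spacing_mm : tuple of float
        Per-axis voxel size in millimetres.
    axis_tags : tuple of str
        Anatomical direction of each array axis.
    origin : tuple of float
        Physical position (mm) of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    axis_tags: tuple[str, str, str] = DEFAULT_AXIS_TAGS
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume requires a 3D array")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        vmin, vmax = self.voxels.min(), self.voxels.max()
        if vmin < HU_MIN or vmax > HU_MAX:
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: range [{vmin}, {vmax}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class LabelMap:
    """Per-voxel tissue classes on the same lattice as the source CT volume."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    axis_tags: tuple[str, str, str] = DEFAULT_AXIS_TAGS
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("LabelMap requires a 3D array")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        valid = {int(v) for v in Label}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"unknown label values: {sorted(present - valid)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def mask(self, *classes: Label) -> np.ndarray:
        """Boolean mask of voxels belonging to any of ``classes``."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for c in classes:
            out |= self.labels == int(c)
        return out

    def volume_cm3(self, *classes: Label) -> float:
        """Total volume of the given classes in cm^3."""
        return float(self.mask(*classes).sum()) * self.voxel_volume_mm3 / 1000.0


def _affine(spacing_mm, origin) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_ct(ct: CTVolume, path: str | Path) -> None:
    """Write a CT volume as NIfTI-1 with int16 HU values."""
    img = nib.Nifti1Image(ct.voxels.astype(np.int16), _affine(ct.spacing_mm, ct.origin))
    img.header["descrip"] = ("axes=" + ",".join(ct.axis_tags))[:79].encode()
    nib.save(img, str(path))


def load_ct(path: str | Path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int16)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(data, spacing, origin=origin)


def save_labels(lm: LabelMap, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a label map as NIfTI-1 uint8, plus an optional JSON label dictionary."""
    img = nib.Nifti1Image(lm.labels.astype(np.uint8), _affine(lm.spacing_mm, lm.origin))
    img.header["descrip"] = ("axes=" + ",".join(lm.axis_tags))[:79].encode()
    nib.save(img, str(path))
    if sidecar is not None:
        mapping = {l.name.lower(): int(l) for l in Label}
        Path(sidecar).write_text(json.dumps({"labels": mapping, "axes": lm.axis_tags}, indent=2))


def load_labels(path: str | Path) -> LabelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.uint8)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return LabelMap(data, spacing, origin=origin)
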