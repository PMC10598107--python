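"""AORI grading of segmented tibial bone defects.

The Anderson Orthopaedic Research Institute (AORI) scale grades tibial bone
loss on an ordinal scale (I = 1, IIa = 2, IIb = 3, III = 4):

* **I** — metaphyseal bone intact: no meaningful defect crosses the plane
  through the tip of the fibular head;
* **IIa / IIb** — metaphyseal bone loss of one / both condyles, i.e. defect
  volume crossing the fibular-tip plane on one / both sides of the sagittal
  midline;
* **III** — bone loss extending distal to the tibial tubercle level.

The clinical criteria that are not visible in a static preoperative image
(component subsidence, patellar tendon or collateral ligament damage) are not
modelled; grade III is triggered purely by defect extent below the tubercle
plane.
"""

from __future__ import annotations

from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

from .image import Label, LabelMap
from .zones import Landmarks

#: default minimal defect volume (cm^3) for a plane crossing / condyle to count.
#: A small positive volume suppresses single-voxel noise; configurable.
DEFAULT_MIN_INVOLVEMENT_CM3 = 0.5


class AORIGrade(IntEnum):
    """Ordinal AORI grade with clinical display names."""

    I = 1
    IIA = 2
    IIB = 3
    III = 4

    @property
    def display(self) -> str:
        return {1: "I", 2: "IIa", 3: "IIb", 4: "III"}[int(self)]


def grade_defect(
    labels: LabelMap,
    landmarks: Landmarks,
    min_involvement_cm3: float = DEFAULT_MIN_INVOLVEMENT_CM3,
) -> AORIGrade:
    """Grade the defect in a label map on the AORI scale.

    Only the ``DEFECT`` class counts (implant and cement voxels are occupied,
    not lost, for grading purposes). Rule order: any supra-threshold defect
    volume distal to the tubercle plane gives grade III regardless of condyle
    pattern; otherwise supra-threshold volume distal to the fibular-tip plane
    gives IIb when both condyles are involved past that plane and IIa when
    exactly one is; otherwise grade I.
    """
    if min_involvement_cm3 < 0:
        raise ValueError("min_involvement_cm3 must be non-negative")
    landmarks.validate()
    vv = labels.voxel_volume_mm3 / 1000.0  # cm^3 per voxel
    defect = labels.mask(Label.DEFECT)

    below_tubercle = defect[:, :, landmarks.tubercle_z:]
    if below_tubercle.sum() * vv > min_involvement_cm3:
        return AORIGrade.III

    crossing = defect[:, :, landmarks.fibular_tip_z:]
    if crossing.sum() * vv > min_involvement_cm3:
        xs = np.nonzero(crossing)[0]
        v_medial = np.count_nonzero(xs < landmarks.midline_x) * vv
        v_lateral = np.count_nonzero(xs >= landmarks.midline_x) * vv
        if v_medial > min_involvement_cm3 and v_lateral > min_involvement_cm3:
            return AORIGrade.IIB
        return AORIGrade.IIA
    return AORIGrade.I


def grade_cohort(
    label_maps: Iterable[LabelMap],
    landmark_list: Sequence[Landmarks],
    min_involvement_cm3: float = DEFAULT_MIN_INVOLVEMENT_CM3,
) -> list[AORIGrade]:
    """Element-wise :func:`grade_defect` over matched label maps and landmarks."""
    label_maps = list(label_maps)
    if len(label_maps) != len(landmark_list):
        raise ValueError(
            f"{len(label_maps)} label maps but {len(landmark_list)} landmark sets"
        )
    grades = []
    for i, (lm, lms) in enumerate(zip(label_maps, landmark_list)):
        try:
            grades.append(grade_defect(lm, lms, min_involvement_cm3))
        except Exception as exc:  # re-raise with the knee identifier
            raise RuntimeError(f"grading failed for item {i}: {exc}") from exc
    return grades
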