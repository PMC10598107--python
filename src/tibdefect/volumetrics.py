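"""Volume accounting of the segmented tibia, overall and per zone.

For each scope (whole region of interest, epiphysis, metaphysis, diaphysis)
the tally is: bone, cement, implant and void-defect volumes in cm^3, the
*total defect* (implant + cement + defect: everything that is not remaining
bone after component removal), the *total tibial volume* (bone + total
defect), and the remaining-bone ratio bone / total tibial volume. Fibular
bone never enters any tibial tally. The implant volume is the implant within
the region of interest only, not the whole component.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .image import Label, LabelMap
from .zones import ZonePartition

SCOPES = ("total", "epiphysis", "metaphysis", "diaphysis")


@dataclass
class ScopeVolumes:
    """Class volumes (cm^3) within one scope."""

    v_bone: float
    v_cement: float
    v_implant: float
    v_defect: float

    @property
    def v_total_defect(self) -> float:
        return self.v_cement + self.v_implant + self.v_defect

    @property
    def v_total_tibial(self) -> float:
        return self.v_bone + self.v_total_defect

    @property
    def remaining_ratio(self) -> float | None:
        """Bone / total tibial volume; ``None`` when the scope is empty."""
        if self.v_total_tibial == 0:
            return None
        return self.v_bone / self.v_total_tibial

    def as_row(self) -> dict:
        ratio = self.remaining_ratio
        return {
            "v_bone_cm3": round(self.v_bone, 3),
            "v_cement_cm3": round(self.v_cement, 3),
            "v_implant_cm3": round(self.v_implant, 3),
            "v_defect_cm3": round(self.v_defect, 3),
            "v_total_defect_cm3": round(self.v_total_defect, 3),
            "v_total_tibial_cm3": round(self.v_total_tibial, 3),
            "remaining_ratio": None if ratio is None else round(ratio, 4),
        }


@dataclass
class VolumeReport:
    """Per-scope volume tallies for one knee."""

    scopes: dict[str, ScopeVolumes]

    def __getitem__(self, scope: str) -> ScopeVolumes:
        return self.scopes[scope]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({s: v.as_row() for s, v in self.scopes.items()}, indent=2)
        )

    def to_csv(self, path: str | Path) -> None:
        rows = [{"scope": s, **v.as_row()} for s, v in self.scopes.items()]
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            w.writeheader()
            w.writerows(rows)


def compute_volumes(labels: LabelMap, partition: ZonePartition) -> VolumeReport:
    """Tally class volumes per zone and over the whole region of interest.

    Volumes are voxel counts times the voxel volume; zone tallies sum exactly
    to the region-of-interest totals because zones partition its slices.
    """
    vv = labels.voxel_volume_mm3 / 1000.0
    arr = labels.labels

    def tally(z0: int, z1: int) -> ScopeVolumes:
        sub = arr[:, :, z0:z1]
        counts = np.bincount(sub.reshape(-1), minlength=6)
        return ScopeVolumes(
            v_bone=counts[Label.BONE_TIBIA] * vv,
            v_cement=counts[Label.CEMENT] * vv,
            v_implant=counts[Label.IMPLANT] * vv,
            v_defect=counts[Label.DEFECT] * vv,
        )

    scopes = {name: tally(a, b) for name, (a, b) in partition.items()}
    roi = partition.roi_range
    scopes = {"total": tally(*roi), **scopes}
    return VolumeReport(scopes)


def summarize_cohort(
    reports: Sequence[VolumeReport], grades: Sequence[int]
) -> pd.DataFrame:
    """Per-grade, per-zone summary (mean, SEM, median) of remaining-bone ratios.

    Undefined ratios (empty scopes) are excluded; empty grade/zone groups are
    omitted with a warning. SEM of a single observation is reported as NaN.
    """
    if len(reports) != len(grades):
        raise ValueError("reports and grades must have equal length")
    rows = []
    n_missing = 0
    for rep, g in zip(reports, grades):
        for scope in SCOPES:
            ratio = rep[scope].remaining_ratio
            if ratio is None:
                n_missing += 1
                continue
            rows.append({"grade": int(g), "zone": scope, "ratio": ratio})
    if n_missing:
        warnings.warn(f"excluded {n_missing} undefined ratios from the summary", stacklevel=2)
    if not rows:
        warnings.warn("no defined ratios; empty summary", stacklevel=2)
        return pd.DataFrame(columns=["grade", "zone", "n", "mean", "sem", "median"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["grade", "zone"], sort=True)["ratio"]
        .agg(n="count", mean="mean", sem="sem", median="median")
        .reset_index()
    )
    return out
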