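"""End-to-end pipeline: CT volume -> labels -> zones -> volumes -> grade.

Chains the stages for a manifest of knees and writes per-knee artifacts plus
cohort-level tables. Failures on individual knees are logged and skipped; the
run summary reports the count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aori import DEFAULT_MIN_INVOLVEMENT_CM3, AORIGrade, grade_defect
from .image import CTVolume, LabelMap, load_ct, save_labels
from .segmentation import (
    DEFAULT_CEMENT_ADJACENCY_MM,
    DEFAULT_CLOSING_RADIUS_VOX,
    ThresholdSet,
    segment_hu,
    split_tibia_fibula,
)
from .volumetrics import VolumeReport, compute_volumes, summarize_cohort
from .zones import Landmarks, ZonePartition, detect_landmarks, measure_epiphysis_width, partition_zones

log = logging.getLogger("tibdefect")

_CONFIG_KEYS = {
    "thresholds",
    "cement_adjacency_mm",
    "closing_radius_voxels",
    "min_involvement_cm3",
    "landmarks",
    "output_dir",
    "log_level",
    "seed",
}


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline."""

    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    cement_adjacency_mm: float = DEFAULT_CEMENT_ADJACENCY_MM
    closing_radius_voxels: int = DEFAULT_CLOSING_RADIUS_VOX
    min_involvement_cm3: float = DEFAULT_MIN_INVOLVEMENT_CM3
    landmarks: dict = field(default_factory=dict)  # per-knee or global overrides
    output_dir: str = "out"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self):
        if self.cement_adjacency_mm < 0 or self.min_involvement_cm3 < 0:
            raise ValueError("lengths and volumes must be non-negative")
        if self.closing_radius_voxels < 0:
            raise ValueError("closing_radius_voxels must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in raw:
            raw["thresholds"] = ThresholdSet.from_dict(raw["thresholds"])
        return cls(**raw)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ManifestEntry:
    knee_id: str
    ct_path: str
    landmarks_path: str | None = None


@dataclass
class RunManifest:
    """Per-knee input files plus provenance."""

    entries: list[ManifestEntry]

    def validate(self) -> "RunManifest":
        if not self.entries:
            raise ValueError("no inputs: manifest is empty")
        ids = [e.knee_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("knee identifiers must be unique")
        for e in self.entries:
            if not Path(e.ct_path).exists():
                raise FileNotFoundError(e.ct_path)
            if e.landmarks_path and not Path(e.landmarks_path).exists():
                raise FileNotFoundError(e.landmarks_path)
        return self

    @classmethod
    def from_csv(cls, path: str | Path) -> "RunManifest":
        df = pd.read_csv(path, dtype=str)
        entries = [
            ManifestEntry(
                knee_id=row["knee_id"],
                ct_path=row["ct_path"],
                landmarks_path=row.get("landmarks_path") or None,
            )
            for _, row in df.iterrows()
        ]
        return cls(entries).validate()


@dataclass
class KneeResult:
    knee_id: str
    labels: LabelMap
    landmarks: Landmarks
    partition: ZonePartition
    volumes: VolumeReport
    grade: AORIGrade


def analyze_ct(
    ct: CTVolume,
    config: PipelineConfig | None = None,
    landmark_overrides: dict | None = None,
) -> KneeResult:
    """Run segmentation, landmarking, zoning, volumetrics and grading on one CT.

    ``landmark_overrides`` must supply at least ``tubercle_z`` (the tubercle
    level is not detectable from image content); fibular landmarks must be
    supplied when no fibula is depicted.
    """
    cfg = config or PipelineConfig()
    overrides = dict(cfg.landmarks)
    overrides.update(landmark_overrides or {})
    if "tubercle_z" not in overrides:
        raise ValueError("landmark override 'tubercle_z' is required")
    tubercle_z = overrides.pop("tubercle_z")
    labels = segment_hu(
        ct, cfg.thresholds, cfg.cement_adjacency_mm, cfg.closing_radius_voxels
    )
    labels = split_tibia_fibula(labels)
    lm = detect_landmarks(labels, tubercle_z=tubercle_z, overrides=overrides)
    width = measure_epiphysis_width(labels, lm.tibial_cut_z, lm.fibular_widest_z)
    partition = partition_zones(lm, width, ct.spacing_mm[2])
    volumes = compute_volumes(labels, partition)
    grade = grade_defect(labels, lm, cfg.min_involvement_cm3)
    return KneeResult("", labels, lm, partition, volumes, grade)


def run_pipeline(manifest: RunManifest, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Process every manifest entry; write artifacts; return the cohort table.

    The cohort table has one row per successfully processed knee with its
    grade and per-zone remaining-bone ratios, and is written as
    ``cohort.csv`` under the configured output directory together with a
    run summary (config hash, version, failure count) and per-knee label
    maps, landmark/partition JSONs and volume reports.
    """
    cfg = config or PipelineConfig()
    manifest.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    rows = []
    reports, grades = [], []
    failures = 0
    for e in manifest.entries:
        try:
            ct = load_ct(e.ct_path)
            lm_over = {}
            if e.landmarks_path:
                lm = Landmarks.from_json(e.landmarks_path)
                lm_over = dataclasses.asdict(lm)
            res = analyze_ct(ct, cfg, lm_over)
            res.knee_id = e.knee_id
        except Exception as exc:
            failures += 1
            log.warning("knee %s failed: %s", e.knee_id, exc)
            continue
        kdir = out / e.knee_id
        kdir.mkdir(exist_ok=True)
        save_labels(res.labels, kdir / "labels.nii.gz", kdir / "labels.json")
        res.landmarks.to_json(kdir / "landmarks.json")
        res.partition.to_json(kdir / "partition.json")
        res.volumes.to_json(kdir / "volumes.json")
        (kdir / "grade.json").write_text(
            json.dumps({"grade": int(res.grade), "display": res.grade.display})
        )
        row = {"knee_id": e.knee_id, "grade": int(res.grade)}
        for scope in ("total", "epiphysis", "metaphysis", "diaphysis"):
            r = res.volumes[scope].remaining_ratio
            row[f"ratio_{scope}"] = None if r is None else round(r, 4)
        rows.append(row)
        reports.append(res.volumes)
        grades.append(int(res.grade))
        log.info("knee %s -> grade %s", e.knee_id, res.grade.display)

    cohort = pd.DataFrame(rows)
    cohort.to_csv(out / "cohort.csv", index=False)
    if grades:
        summarize_cohort(reports, grades).to_csv(out / "grade_zone_summary.csv", index=False)
    (out / "run.json").write_text(
        json.dumps(
            {
                "version": __version__,
                "config_hash": cfg.digest(),
                "n_processed": len(rows),
                "n_failed": failures,
            },
            indent=2,
        )
    )
    log.info("processed %d knees, %d failures", len(rows), failures)
    return cohort
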