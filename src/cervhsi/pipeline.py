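"""End-to-end orchestration: register annotations into the HSI frame, build
consensus reference masks, extract tissue indices and run the paired tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import consensus as cons
from . import io as chio
from .registration import (
    Homography,
    LandmarkSet,
    backprojection_error,
    estimate_homography,
    warp_mask,
)
from .spectral import (
    DEFAULT_INDEX_DEFS,
    BandRatioIndexDef,
    Hypercube,
    compute_all_indices,
    mean_spectrum,
    region_mean_index,
    zscore_spectrum,
)
from .stats import PairedIndexTable, PairedStatResult, StatsConfig, run_paired_analysis

logger = logging.getLogger("cervhsi")

__all__ = [
    "AnalysisConfig",
    "SubjectData",
    "SubjectRecord",
    "CohortResult",
    "run_subject",
    "run_cohort",
    "run_sensitivity",
    "load_cohort_manifest",
    "write_cohort_results",
]


@dataclass
class AnalysisConfig:
    """All analysis knobs in one place; defaults follow the reference protocol."""

    tau: float = 0.5
    index_defs: dict[str, BandRatioIndexDef] = field(
        default_factory=lambda: dict(DEFAULT_INDEX_DEFS)
    )
    wavelength_window: tuple[float, float] | None = None
    zscore_ddof: int = 0
    #: mean-reflectance cutoff separating tissue from dark background; only
    #: the tissue area of the HSI image enters the analysis (None disables)
    tissue_threshold: float | None = 0.15
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self) -> None:
        if not 0 < self.tau <= 1:
            raise ValueError("tau must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        index_defs = None
        if "index_defs" in d:
            index_defs = {
                name: BandRatioIndexDef(
                    name=name,
                    numerator_band=tuple(v["numerator_band"]),
                    denominator_band=tuple(v["denominator_band"]),
                    scale=tuple(v.get("scale", (-1.0, 1.0))),
                    mode=v.get("mode", "difference"),
                )
                for name, v in d.pop("index_defs").items()
            }
        stats = StatsConfig(**d.pop("stats", {}))
        window = d.pop("wavelength_window", None)
        cfg = cls(
            tau=d.pop("tau", 0.5),
            wavelength_window=tuple(window) if window else None,
            zscore_ddof=d.pop("zscore_ddof", 0),
            tissue_threshold=d.pop("tissue_threshold", 0.15),
            stats=stats,
        )
        if index_defs is not None:
            cfg.index_defs = index_defs
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def summary(self) -> dict:
        return {
            "tau": self.tau,
            "wavelength_window": self.wavelength_window,
            "zscore_ddof": self.zscore_ddof,
            "tissue_threshold": self.tissue_threshold,
            "indices": sorted(self.index_defs),
            "stats": {
                "B": self.stats.B,
                "level": self.stats.level,
                "seed": self.stats.seed,
                "zero_policy": self.stats.zero_policy,
            },
        }


@dataclass
class SubjectData:
    """Inputs for one subject: cube (HSI frame), examiner annotations
    (colposcope frame) and the colposcope->HSI landmark pairs."""

    subject_id: str
    cube: Hypercube
    examiner_annotations: list[cons.AnnotationSet]
    landmarks: LandmarkSet


@dataclass
class SubjectRecord:
    """Per-subject analysis outcome."""

    subject_id: str
    homography: Homography | None = None
    backprojection_residual: float | None = None
    cin_mask: np.ndarray | None = None
    healthy_mask: np.ndarray | None = None
    consensus: cons.ConsensusMap | None = None
    region_means: dict[str, dict[str, float]] = field(default_factory=dict)
    mean_spectra: dict[str, list[float]] = field(default_factory=dict)
    zscored_spectra: dict[str, list[float]] = field(default_factory=dict)
    flagged: bool = False
    flag_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "homography": None
            if self.homography is None
            else [float(v) for v in self.homography.h.ravel()],
            "backprojection_residual": self.backprojection_residual,
            "cin_area_px": None if self.cin_mask is None else int(self.cin_mask.sum()),
            "healthy_area_px": None
            if self.healthy_mask is None
            else int(self.healthy_mask.sum()),
            "region_means": self.region_means,
            "mean_spectra": self.mean_spectra,
            "zscored_spectra": self.zscored_spectra,
            "flagged": self.flagged,
            "flag_reason": self.flag_reason,
        }


def run_subject(data: SubjectData, config: AnalysisConfig) -> SubjectRecord:
    """Full single-subject analysis.

    Steps: estimate the homography from landmarks; warp every examiner's
    masks into the HSI frame; build the union-of-lesion-classes consensus map;
    threshold it at ``tau``; take the healthy union (made disjoint from the
    lesion mask); compute the four index maps and per-class region means plus
    mean/z-scored spectra.  Subjects whose thresholded lesion mask (or healthy
    reference) is empty are flagged instead of producing region means.
    """
    rec = SubjectRecord(subject_id=data.subject_id)
    H = estimate_homography(data.landmarks)
    rec.homography = H
    rec.backprojection_residual = backprojection_error(H, data.landmarks)

    hsi_shape = data.cube.spatial_shape
    warped_sets = []
    for s in data.examiner_annotations:
        warped_sets.append(
            cons.AnnotationSet(
                subject_id=s.subject_id,
                examiner_id=s.examiner_id,
                masks={cls: warp_mask(H, m, hsi_shape) for cls, m in s.masks.items()},
                frame="hsi",
            )
        )

    cmap = cons.consensus_map(cons.union_cin_masks(warped_sets))
    rec.consensus = cmap
    cin_mask = cons.threshold_consensus(cmap, config.tau)
    healthy_mask = cons.healthy_union(warped_sets, cin_mask=cin_mask)
    if config.tissue_threshold is not None:
        # only the tissue area of the HSI image is analyzed; annotations
        # spilling onto dark background are clipped away
        tissue = data.cube.reflectance.mean(axis=2) > config.tissue_threshold
        cin_mask &= tissue
        healthy_mask &= tissue
    rec.cin_mask = cin_mask
    rec.healthy_mask = healthy_mask

    if not cin_mask.any():
        rec.flagged = True
        rec.flag_reason = f"empty lesion mask after consensus threshold tau={config.tau}"
        logger.warning("subject %s flagged: %s", data.subject_id, rec.flag_reason)
        return rec
    if not healthy_mask.any():
        rec.flagged = True
        rec.flag_reason = "empty healthy reference mask"
        logger.warning("subject %s flagged: %s", data.subject_id, rec.flag_reason)
        return rec

    cube = data.cube
    if config.wavelength_window is not None:
        cube = cube.restrict_window(*config.wavelength_window)
    index_maps = compute_all_indices(cube, config.index_defs)
    for name, imap in index_maps.items():
        rec.region_means[name] = {
            "cin": region_mean_index(imap, cin_mask),
            "healthy": region_mean_index(imap, healthy_mask),
        }
    for cls, mask in (("cin", cin_mask), ("healthy", healthy_mask)):
        spec = mean_spectrum(cube, mask)
        rec.mean_spectra[cls] = [float(v) for v in spec]
        try:
            rec.zscored_spectra[cls] = [
                float(v) for v in zscore_spectrum(spec, ddof=config.zscore_ddof)
            ]
        except ValueError:
            rec.zscored_spectra[cls] = []
    return rec


@dataclass
class CohortResult:
    config: AnalysisConfig
    records: list[SubjectRecord]
    paired_table: PairedIndexTable | None
    stat_results: list[PairedStatResult]
    iou: cons.IoUMatrix | None

    def results_payload(self) -> dict:
        return {
            "config": self.config.summary(),
            "n_subjects": len(self.records),
            "n_flagged": sum(r.flagged for r in self.records),
            "subjects": [r.to_dict() for r in self.records],
            "stats": [s.to_dict() for s in self.stat_results],
            "iou_union_mean": None
            if self.iou is None
            else _nanmean_offdiag(self.iou.values),
        }


def _nanmean_offdiag(values: np.ndarray) -> float | None:
    v = values[~np.eye(values.shape[0], dtype=bool)]
    v = v[~np.isnan(v)]
    return float(v.mean()) if v.size else None


def run_cohort(
    subjects: Sequence[SubjectData], config: AnalysisConfig | None = None
) -> CohortResult:
    """Analyze every subject, aggregate the paired index table and test it."""
    config = config or AnalysisConfig()
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("subject_ids must be unique")
    records = [run_subject(s, config) for s in subjects]
    usable = [r for r in records if not r.flagged]
    if not usable:
        raise RuntimeError(
            "all subjects were flagged; no paired analysis possible "
            f"({[r.flag_reason for r in records]})"
        )
    rows = []
    for r in usable:
        for name, means in r.region_means.items():
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "index": name,
                    "cin_mean": means["cin"],
                    "healthy_mean": means["healthy"],
                }
            )
    table = PairedIndexTable(pd.DataFrame(rows))
    stat_results = run_paired_analysis(table, config.stats)

    iou = None
    if len({a.examiner_id for s in subjects for a in s.examiner_annotations}) >= 2:
        iou = cons.iou_matrix(
            {s.subject_id: s.examiner_annotations for s in subjects}
        )
    return CohortResult(
        config=config, records=records, paired_table=table, stat_results=stat_results, iou=iou
    )


def run_sensitivity(
    subjects: Sequence[SubjectData],
    config: AnalysisConfig | None = None,
    tau_list: Sequence[float] = (0.5, 0.75),
) -> dict[float, CohortResult]:
    """Repeat the cohort analysis across consensus thresholds."""
    config = config or AnalysisConfig()
    out: dict[float, CohortResult] = {}
    for tau in tau_list:
        cfg = AnalysisConfig(
            tau=tau,
            index_defs=config.index_defs,
            wavelength_window=config.wavelength_window,
            zscore_ddof=config.zscore_ddof,
            stats=config.stats,
        )
        out[tau] = run_cohort(subjects, cfg)
    return out


def load_cohort_manifest(path: str | Path) -> list[SubjectData]:
    """Load subjects from a JSON manifest.

    Layout::

        {"subjects": [{"subject_id": ..., "cube": <path>,
                       "annotations": <manifest json>, "landmarks": <csv>}]}

    Paths are resolved relative to the manifest file.
    """
    path = Path(path)
    manifest = json.loads(path.read_text())
    root = path.parent
    subjects = []
    seen = set()
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        if sid in seen:
            raise ValueError(f"duplicate subject_id {sid!r} in manifest")
        seen.add(sid)
        subjects.append(
            SubjectData(
                subject_id=sid,
                cube=chio.read_cube(root / entry["cube"]),
                examiner_annotations=chio.read_annotation_manifest(root / entry["annotations"]),
                landmarks=chio.read_landmarks_csv(root / entry["landmarks"]),
            )
        )
    return subjects


def write_cohort_results(result: CohortResult, out_dir: str | Path) -> Path:
    """Write results.json (+ CSV side tables).  Deterministic byte-for-byte
    for identical inputs: keys sorted, plain-float serialization."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results_path = out_dir / "results.json"
    results_path.write_text(
        json.dumps(result.results_payload(), indent=2, sort_keys=True) + "\n"
    )
    if result.paired_table is not None:
        result.paired_table.frame.to_csv(out_dir / "paired_table.csv", index=False)
    if result.iou is not None:
        result.iou.to_frame().to_csv(out_dir / "iou_union.csv")
    pd.DataFrame([s.to_dict() for s in result.stat_results]).to_csv(
        out_dir / "stats.csv", index=False
    )
    return results_path
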