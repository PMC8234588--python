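"""End-to-end day-3/14/30 workflow: simulate → fit → segment → ROI → quantify → stats.

`run_pipeline` drives a whole synthetic cohort through the analysis exactly
as a patient cohort would flow through it: per subject, the lesion is
segmented from the baseline (first acquired) b=0 image, the analysis sphere
is placed on the lesion centroid with a radius that encloses the lesion,
and that sphere — center and radius — is then held fixed across the
subject's remaining timepoints, so longitudinal changes are measured in a
constant volume. The contralateral sphere is the midsagittal mirror image.

Every stage failure aborts with the stage name and the offending
subject/day; outputs (cohort CSV, per-subject JSON, manifest, statistics
report) are byte-reproducible given the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ich_io
from .cohort import CohortDesign, PhantomLayout, iter_cohort
from .dti import compute_scalar_maps
from .gradients import default_scheme
from .quantify import cohort_table, quantify_subject_timepoint
from .roi import Grid, LesionMask, mirror_sphere, place_ipsilateral_sphere
from .stats import (
    bonferroni_threshold,
    linear_regression,
    mixed_model_location_time,
    summarize_by_location_day,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and subject/day context."""

    def __init__(self, stage: str, subject: str, day, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject} day {day}: {cause}")
        self.stage = stage
        self.subject = subject
        self.day = day
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    out_dir: str = "ichwm_run"
    seed: int = 0
    n_subjects: int = 13
    days: tuple[int, ...] = (3, 14, 30)
    layout: str = "standard"              # "standard" | "small"
    hematoma_volume_range_ml: tuple[float, float] | None = None
    noise_sigma: float = 50.0
    sphere_radius_band_mm: tuple[float, float] | None = None
    fa_threshold: float = 0.5
    segmentation_threshold_fraction: float = 0.5
    segmentation_min_component_ml: float = 0.3
    nan_in_denominator: bool = True       # NaN voxels stay in compartment volumes
    use_true_lesion: bool = False         # bypass segmentation with ground truth
    lesion_mask_policy: str = "per_day"   # "per_day" | "baseline" (frozen day-3 mask)
    write_images: bool = True

    _HARD_RADIUS_LIMITS = (5.0, 40.0)

    def __post_init__(self):
        if not (0.0 < self.fa_threshold < 1.0):
            raise ValueError("FA threshold must lie in (0, 1)")
        if self.layout not in ("standard", "small"):
            raise ValueError("layout must be 'standard' or 'small'")
        if self.lesion_mask_policy not in ("per_day", "baseline"):
            raise ValueError("lesion_mask_policy must be 'per_day' or 'baseline'")
        band = self.radius_band
        lo, hi = self._HARD_RADIUS_LIMITS
        if not (lo <= band[0] <= band[1] <= hi):
            raise ValueError(f"radius band {band} outside hard limits [{lo}, {hi}] mm")

    @property
    def phantom_layout(self) -> PhantomLayout:
        return PhantomLayout.standard() if self.layout == "standard" else PhantomLayout.small()

    @property
    def radius_band(self) -> tuple[float, float]:
        if self.sphere_radius_band_mm is not None:
            return tuple(self.sphere_radius_band_mm)
        r = self.phantom_layout.sphere_radius_mm
        return (r, min(r + 3.0, self._HARD_RADIUS_LIMITS[1]))

    def design(self) -> CohortDesign:
        layout = self.phantom_layout
        vol_range = self.hematoma_volume_range_ml
        if vol_range is None:
            vol_range = (0.3, layout.max_hematoma_volume_ml)
        return CohortDesign(
            n_subjects=self.n_subjects, days=tuple(self.days),
            hematoma_volume_range_ml=tuple(vol_range),
            seed=self.seed, layout=layout, noise_sigma=self.noise_sigma,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = ich_io.load_yaml_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("days", "hematoma_volume_range_ml", "sphere_radius_band_mm"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        for key in ("days", "hematoma_volume_range_ml", "sphere_radius_band_mm"):
            if d.get(key) is not None:
                d[key] = list(d[key])
        return ich_io.dump_yaml_config(d, path)


@dataclass
class PipelineResult:
    cohort: pd.DataFrame              # long-format cohort table
    manifest: pd.DataFrame
    quantifications: list
    stats_report: dict
    out_dir: Path


def _stats_report(table: pd.DataFrame, days) -> dict:
    """Cohort statistics: summaries, mixed model, loss-vs-size regressions."""
    report: dict = {"bonferroni": dataclasses.asdict(bonferroni_threshold(0.05, 6))}
    report["summary"] = summarize_by_location_day(table).to_dict(orient="records")

    try:
        mm = mixed_model_location_time(table, include_day=True, include_interaction=False)
        report["mixed_model"] = {
            "tests": mm.tests,
            "contrasts": mm.contrasts.to_dict(orient="records"),
            "random_intercept_sd": mm.random_intercept_sd,
            "residual_sd": mm.residual_sd,
            "singular": mm.singular,
        }
    except ValueError as e:
        report["mixed_model"] = {"error": str(e)}

    regressions = {}
    per_day = table[table["location"] == "perilesion"]
    for day in days:
        sub = per_day[per_day["day"] == day].dropna(
            subset=["hematoma_volume_ml_day3", "loss_ml"])
        if len(sub) >= 3 and np.ptp(sub["hematoma_volume_ml_day3"].to_numpy()) > 0:
            r = linear_regression(sub["hematoma_volume_ml_day3"], sub["loss_ml"])
            regressions[str(day)] = dataclasses.asdict(r)
    report["loss_vs_hematoma_size"] = regressions
    return report


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full synthetic-cohort analysis described by `config`."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    scheme = default_scheme()
    design = config.design()
    grid = Grid(design.layout.grid_shape, design.layout.voxel_spacing)

    quants = []
    manifest_rows = []
    true_day3: dict[str, float] = {}
    sphere_state: dict[str, tuple] = {}    # subject -> (ipsi_roi, contra_roi)
    baseline_lesion: dict[str, LesionMask] = {}

    for rec in iter_cohort(design, scheme):
        sid, day = rec.subject_id, rec.day
        true_day3.setdefault(sid, 4.0 / 3.0 * np.pi
                             * rec.timecourse.radius_baseline_mm ** 3 / 1000.0)
        paths = {}
        try:
            if config.write_images:
                prefix = out / "images" / f"{sid}_day{day:02d}"
                paths.update({k: str(v) for k, v in ich_io.save_dwi(rec.dwi, prefix).items()})
                paths["lesion_true"] = str(ich_io.save_mask(
                    rec.ground_truth.lesion_mask_true, rec.dwi.voxel_spacing,
                    out / "images" / f"{sid}_day{day:02d}_lesion_true.nii.gz"))
        except Exception as e:              # pragma: no cover - disk errors
            raise StageError("write-images", sid, day, e)

        try:
            maps = compute_scalar_maps(rec.dwi, kinds=("FA",))
            fa_map, b0_map = maps["FA"], maps["b0"]
            if config.write_images:
                paths["fa"] = str(ich_io.save_scalar_map(
                    fa_map, out / "maps" / f"{sid}_day{day:02d}_fa.nii.gz"))
        except Exception as e:
            raise StageError("fit-dti", sid, day, e)

        try:
            if config.use_true_lesion:
                lesion = LesionMask(rec.ground_truth.lesion_mask_true, rec.dwi.voxel_spacing)
            else:
                from .roi import segment_lesion
                lesion = segment_lesion(b0_map, config.segmentation_threshold_fraction,
                                        config.segmentation_min_component_ml)
            if config.lesion_mask_policy == "baseline":
                lesion = baseline_lesion.setdefault(sid, lesion)
        except Exception as e:
            raise StageError("segment", sid, day, e)

        try:
            if sid not in sphere_state:
                if lesion.n_voxels > 0:
                    ipsi = place_ipsilateral_sphere(lesion, grid, config.radius_band)
                else:
                    # hematoma resolved below the segmentation floor: anchor the
                    # sphere at the known lesion site, as an operator would
                    from .roi import SphericalROI
                    ipsi = SphericalROI(rec.spec.hematoma.center_mm,
                                        config.radius_band[0], side="ipsilateral")
                contra = mirror_sphere(ipsi, grid)
                sphere_state[sid] = (ipsi, contra)
            ipsi, contra = sphere_state[sid]
        except Exception as e:
            raise StageError("roi", sid, day, e)

        try:
            q = quantify_subject_timepoint(
                fa_map, ipsi, contra, lesion,
                threshold=config.fa_threshold,
                nan_in_denominator=config.nan_in_denominator,
                subject_id=sid, day=day)
            quants.append(q)
        except Exception as e:
            raise StageError("quantify", sid, day, e)

        row = {"subject_id": sid, "day": day,
               "true_hematoma_ml": rec.ground_truth.true_hematoma_volume_ml,
               "segmented_lesion_ml": lesion.volume_ml,
               "sphere_radius_mm": ipsi.radius_mm, **paths}
        if config.write_images:
            row["dwi_sha256"] = ich_io.sha256_of(paths["dwi"])
        manifest_rows.append(row)

    table = cohort_table(quants, hematoma_day3_ml=true_day3)
    manifest = pd.DataFrame(manifest_rows)
    report = _stats_report(table, design.days)

    table.to_csv(out / "cohort.csv", index=False)
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "stats_report.json").write_text(json.dumps(report, indent=2, default=float))
    for q in quants:
        p = out / "quant" / f"{q.subject_id}_day{q.day:02d}.json"
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(dataclasses.asdict(q), indent=2, default=float))

    logger.info("pipeline: %d records, NaN policy nan_in_denominator=%s, "
                "lesion policy %s, loss sign positive-is-loss",
                len(quants), config.nan_in_denominator, config.lesion_mask_policy)
    return PipelineResult(table, manifest, quants, report, out)
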