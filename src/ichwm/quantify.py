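"""FA>0.5 volumetry per compartment and the perilesional deficit.

The white-matter index is deliberately simple: the volume (mL) of voxels
whose FA strictly exceeds a threshold (default 0.5), computed over four
compartments — the contralateral analysis sphere, the ipsilateral sphere,
the lesion, and the perilesional zone (ipsilateral sphere minus lesion).
The lesion, ipsilateral and contralateral values are measured directly;
perilesional values are obtained by subtraction.

The perilesional deficit compares the measured perilesional FA>0.5 volume
with the amount *expected* if the perilesional zone were as white-matter
rich as the contralateral sphere:

    deficit = (ipsi FA>0.5 mL − lesion FA>0.5 mL)
              − perilesion volume mL × (contra FA>0.5 mL / contra sphere mL)

This raw expression is negative when tissue is missing; the package also
reports its negation as ``loss_ml`` so that positive numbers mean white
matter lost, which is how the quantity reads in a disease context. Both are
always emitted.

NaN voxels (ill-defined tensor fits) never count toward a suprathreshold
volume. By default they still count toward compartment *volumes*, keeping
denominators purely geometric; ``nan_in_denominator=False`` excludes them
there too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dti import ScalarMap
from .roi import Grid, LesionMask, SphericalROI, check_midline, sphere_voxel_mask

logger = logging.getLogger(__name__)

COMPARTMENTS = ("contralateral_sphere", "ipsilateral_sphere", "lesion", "perilesion")


class CompartmentError(ValueError):
    """Raised when the compartment geometry is inconsistent."""


@dataclass
class SubjectQuantification:
    """Per-subject × timepoint FA-threshold volumetry."""

    subject_id: str = ""
    day: int | None = None
    threshold: float = 0.5
    sphere_radius_mm: float = float("nan")
    sphere_volume_ml: float = float("nan")           # ipsilateral sphere
    contra_sphere_volume_ml: float = float("nan")
    lesion_volume_ml: float = float("nan")
    perilesion_volume_ml: float = float("nan")
    fa_ml: dict = field(default_factory=dict)        # compartment -> mL with FA > thr
    fa_pct: dict = field(default_factory=dict)       # compartment -> % of compartment
    nan_count: dict = field(default_factory=dict)    # compartment -> NaN voxels
    deficit_printed_ml: float = float("nan")         # measured − expected (raw expression)
    loss_ml: float = float("nan")                    # −deficit: positive = tissue lost
    perilesion_floored: bool = False


@dataclass(frozen=True)
class DeficitResult:
    measured_ml: float    # perilesional FA>0.5 volume
    expected_ml: float    # perilesion volume × contralateral FA>0.5 fraction
    deficit_printed_ml: float  # measured − expected
    loss_ml: float        # expected − measured (positive = loss)


def fa_suprathreshold_volume(fa_map: ScalarMap, mask: np.ndarray,
                             threshold: float = 0.5) -> tuple[float, int]:
    """Volume (mL) of masked voxels with finite FA strictly above threshold.

    Returns ``(ml, nan_count)``; NaN voxels are counted separately and can
    never contribute to the suprathreshold volume.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fa_map.data.shape:
        raise CompartmentError(
            f"mask shape {mask.shape} does not match FA map {fa_map.data.shape}"
        )
    finite = np.isfinite(fa_map.data)
    n_supra = int(np.count_nonzero(mask & finite & (fa_map.data > threshold)))
    n_nan = int(np.count_nonzero(mask & ~finite))
    return n_supra * fa_map.voxel_volume_ml, n_nan


def quantify_subject_timepoint(fa_map: ScalarMap,
                               ipsi_roi: SphericalROI,
                               contra_roi: SphericalROI,
                               lesion: LesionMask,
                               threshold: float = 0.5,
                               nan_in_denominator: bool = True,
                               subject_id: str = "",
                               day: int | None = None) -> SubjectQuantification:
    """Measure all four compartments for one FA map.

    Direct measurement for the contralateral sphere, ipsilateral sphere and
    lesion; perilesional values by subtraction. The lesion must be wholly
    inside the ipsilateral sphere and both spheres must respect the
    midline.
    """
    grid = Grid.of_map(fa_map)
    for roi in (ipsi_roi, contra_roi):
        chk = check_midline(roi, grid)
        if not chk.passed:
            raise CompartmentError(
                f"{roi.side} sphere crosses the midline by {-chk.margin_mm:.2f} mm"
            )

    ipsi_mask, ipsi_vol = sphere_voxel_mask(ipsi_roi, grid)
    contra_mask, contra_vol = sphere_voxel_mask(contra_roi, grid)
    les_mask = np.asarray(lesion.mask, dtype=bool)
    if les_mask.shape != grid.shape:
        raise CompartmentError("lesion mask grid does not match the FA map")
    overflow = int(np.count_nonzero(les_mask & ~ipsi_mask))
    if overflow:
        raise CompartmentError(
            f"lesion escapes the ipsilateral sphere by {overflow} voxels"
        )

    vox = grid.voxel_volume_ml
    les_vol = float(les_mask.sum()) * vox
    peri_mask = ipsi_mask & ~les_mask
    peri_vol = ipsi_vol - les_vol

    q = SubjectQuantification(
        subject_id=subject_id, day=day, threshold=threshold,
        sphere_radius_mm=ipsi_roi.radius_mm,
        sphere_volume_ml=ipsi_vol, contra_sphere_volume_ml=contra_vol,
        lesion_volume_ml=les_vol, perilesion_volume_ml=peri_vol,
    )

    measured = {}
    for name, mask in (("contralateral_sphere", contra_mask),
                       ("ipsilateral_sphere", ipsi_mask),
                       ("lesion", les_mask)):
        ml, n_nan = fa_suprathreshold_volume(fa_map, mask, threshold)
        measured[name] = ml
        q.fa_ml[name] = ml
        q.nan_count[name] = n_nan

    peri_ml = measured["ipsilateral_sphere"] - measured["lesion"]
    if peri_ml < 0:
        logger.warning("%s day %s: perilesional FA volume %.3f mL floored at 0",
                       subject_id, day, peri_ml)
        peri_ml = 0.0
        q.perilesion_floored = True
    q.fa_ml["perilesion"] = peri_ml
    q.nan_count["perilesion"] = int(np.count_nonzero(peri_mask & ~np.isfinite(fa_map.data)))

    denominators = {
        "contralateral_sphere": contra_vol,
        "ipsilateral_sphere": ipsi_vol,
        "lesion": les_vol,
        "perilesion": peri_vol,
    }
    if not nan_in_denominator:
        denominators = {k: denominators[k] - q.nan_count[k] * vox for k in denominators}
    for name in COMPARTMENTS:
        denom = denominators[name]
        q.fa_pct[name] = 100.0 * q.fa_ml[name] / denom if denom > 0 else float("nan")

    d = perilesional_deficit(q)
    q.deficit_printed_ml = d.deficit_printed_ml
    q.loss_ml = d.loss_ml
    return q


def perilesional_deficit(q: SubjectQuantification) -> DeficitResult:
    """Expected-versus-measured perilesional FA>0.5 volume.

    The raw expression ``(ipsi − lesion) − perilesion_volume ×
    contra/contra_sphere_volume`` is negative when white matter is missing;
    ``loss_ml`` is its negation (positive = loss).
    """
    if not (q.contra_sphere_volume_ml > 0):
        raise ValueError("contralateral sphere volume must be positive")
    measured = q.fa_ml["ipsilateral_sphere"] - q.fa_ml["lesion"]
    expected = q.perilesion_volume_ml * (
        q.fa_ml["contralateral_sphere"] / q.contra_sphere_volume_ml
    )
    printed = measured - expected
    return DeficitResult(measured_ml=measured, expected_ml=expected,
                         deficit_printed_ml=printed, loss_ml=-printed)


@dataclass(frozen=True)
class LongitudinalChange:
    """Late-minus-early change for one subject."""

    subject_id: str
    day_early: int
    day_late: int
    delta_ml: dict       # compartment -> Δ mL of FA>threshold tissue
    delta_pct: dict      # compartment -> Δ percentage points
    declined: dict       # compartment -> True if Δ mL < 0


def longitudinal_change(q_early: SubjectQuantification,
                        q_late: SubjectQuantification) -> LongitudinalChange:
    """Per-compartment change between two timepoints of the same subject.

    Requires the same subject and an unchanged sphere radius (the constant
    diameter is what makes the longitudinal comparison meaningful).
    """
    if q_early.subject_id != q_late.subject_id:
        raise ValueError("longitudinal change requires the same subject")
    if q_early.day is None or q_late.day is None or not q_early.day < q_late.day:
        raise ValueError("q_early must precede q_late")
    if abs(q_early.sphere_radius_mm - q_late.sphere_radius_mm) > 1e-9:
        raise ValueError(
            f"sphere radius changed between timepoints "
            f"({q_early.sphere_radius_mm} vs {q_late.sphere_radius_mm} mm)"
        )
    delta_ml = {c: q_late.fa_ml[c] - q_early.fa_ml[c] for c in COMPARTMENTS}
    delta_pct = {c: q_late.fa_pct[c] - q_early.fa_pct[c] for c in COMPARTMENTS}
    declined = {c: delta_ml[c] < 0 for c in COMPARTMENTS}
    return LongitudinalChange(q_early.subject_id, q_early.day, q_late.day,
                              delta_ml, delta_pct, declined)


def cohort_table(quantifications, hematoma_day3_ml: dict | None = None):
    """Long-format cohort table feeding the statistics layer.

    One row per subject × day × compartment with the FA>threshold volume,
    percentage and per-timepoint loss. ``hematoma_day3_ml`` maps subject to
    baseline hematoma volume; when omitted it is taken from each subject's
    day-3 lesion volume (NaN if day 3 was not acquired — mirroring cohorts
    where a baseline size is simply unavailable).
    """
    import pandas as pd

    if hematoma_day3_ml is None:
        hematoma_day3_ml = {q.subject_id: q.lesion_volume_ml
                            for q in quantifications if q.day == 3}
    rows = []
    for q in quantifications:
        for loc in COMPARTMENTS:
            rows.append({
                "subject_id": q.subject_id,
                "day": q.day,
                "location": loc,
                "fa_gt_ml": q.fa_ml[loc],
                "fa_gt_pct": q.fa_pct[loc],
                "loss_ml": q.loss_ml,
                "deficit_printed_ml": q.deficit_printed_ml,
                "lesion_volume_ml": q.lesion_volume_ml,
                "hematoma_volume_ml_day3": hematoma_day3_ml.get(q.subject_id, float("nan")),
                "sphere_radius_mm": q.sphere_radius_mm,
                "threshold": q.threshold,
            })
    return pd.DataFrame(rows)
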