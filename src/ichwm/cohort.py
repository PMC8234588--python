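"""Longitudinal synthetic cohorts of hemorrhage phantoms.

A cohort design mirrors the study structure the analysis expects: subjects
scanned at days 3, 14 and 30 with a realistic missing-timepoint pattern,
baseline hematoma volumes spanning 0.3–39 mL, and heterogeneous per-subject
recovery. Each emitted record carries the simulated DWI plus its ground
truth, so every downstream stage can be validated against the generator.

Two phantom layouts are provided. The *standard* layout uses a 96×96×44
grid at 1×1×2.3 mm (≈ 95×95×99 mm field of view) with 22 mm analysis
spheres, roughly hemispheric scale; the *small* layout is a geometrically
similar miniature (56×56×26 grid, 11 mm spheres, hematomas up to 5 mL) used
where many cohorts must be simulated quickly. White matter is a
mirror-symmetric lattice of thin cranio-caudal tubes filling each
hemisphere at a packing fraction of ≈ 17% (tube radius / lattice spacing
chosen so πr²/s² = 0.17), so an analysis sphere anywhere in a hemisphere
holds ≈ 17% white matter by volume and — crucially — destroyed or disrupted
white matter scales with the *volume* of the lesion and its shell rather
than with the chance geometry of a single central tract.

The disruption shell around each subject's hematoma has thickness 0.4× the
baseline hematoma radius (attenuation factor 0.35 at day 3), so the volume
of sub-threshold perilesional white matter — the measured loss — grows in
proportion to hematoma volume until the shell outgrows the analysis sphere,
the dependence the deficit-versus-volume regression is meant to detect.

The module also hosts table-level simulators (`simulate_loss_table`,
`simulate_location_table`) that generate cohort *measurement tables*
directly, without images, for statistical calibration experiments that need
hundreds of replicate cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .dti import DiffusionVolume, GradientScheme
from .phantom import (
    Bundle,
    GroundTruth,
    Hematoma,
    PerilesionalShell,
    PhantomSpec,
    SubjectTimecourse,
    evolve_timepoint,
    generate_tensor_field,
    s0_map,
    simulate_dwi,
)

#: white-matter packing fraction of the tube lattice (πr²/s²)
WM_PACKING_FRACTION = 0.17
#: tube radius as a fraction of the sphere radius; lattice spacing follows
_TUBE_SPHERE_RATIO = 2.4 / 22.0

#: baseline (day-3) shell attenuation factor and shell geometry
_BASELINE_ATTENUATION = 0.35
_SHELL_RADIUS_FRACTION = 0.4      # shell thickness = 0.4 × baseline hematoma radius
_MIN_SHELL_THICKNESS_MM = 2.0

#: median longitudinal rates (1/day); per-subject values are lognormal
_MEDIAN_RECOVERY_RATE = 0.04
_MEDIAN_RESOLUTION_RATE = 0.015
_RESOLUTION_RATE_SD = 0.5


def volume_to_radius_mm(volume_ml: float) -> float:
    """Radius of a sphere of the given volume (mL → mm)."""
    return float((3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass(frozen=True)
class PhantomLayout:
    """Geometry shared by every subject of a cohort."""

    grid_shape: tuple[int, int, int]
    voxel_spacing: tuple[float, float, float]
    sphere_radius_mm: float
    max_hematoma_volume_ml: float

    @classmethod
    def standard(cls) -> "PhantomLayout":
        return cls((96, 96, 44), (1.0, 1.0, 2.3), 22.0, 39.0)

    @classmethod
    def small(cls) -> "PhantomLayout":
        return cls((56, 56, 26), (1.0, 1.0, 2.3), 11.0, 5.0)

    @property
    def tube_radius_mm(self) -> float:
        return _TUBE_SPHERE_RATIO * self.sphere_radius_mm

    @property
    def lattice_spacing_mm(self) -> float:
        return float(self.tube_radius_mm * np.sqrt(np.pi / WM_PACKING_FRACTION))

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.voxel_spacing)

    @property
    def midplane_x_mm(self) -> float:
        return float(self.extent_mm[0] / 2.0)

    def hemisphere_center_x(self, side: str) -> float:
        ext = self.extent_mm[0]
        return float(0.75 * ext if side == "ipsilateral" else 0.25 * ext)

    def bundles(self, side: str) -> tuple[Bundle, ...]:
        """Square lattice of cranio-caudal tubes filling one hemisphere.

        The lattice is centered on the hemisphere center (so the hematoma
        sits on a tube) and mirror-symmetric across the midsagittal plane;
        tubes never reach past the midplane or the grid edge.
        """
        cx = self.hemisphere_center_x(side)
        cy = float(self.extent_mm[1] / 2.0)
        s = self.lattice_spacing_mm
        rt = self.tube_radius_mm
        ext = self.extent_mm
        mid = self.midplane_x_mm
        x_lo, x_hi = (mid, ext[0]) if cx > mid else (0.0, mid)
        tubes = []
        n = int(np.ceil(max(ext[:2]) / s))
        for i in range(-n, n + 1):
            x = cx + i * s
            if x - rt < x_lo or x + rt > x_hi:
                continue
            for j in range(-n, n + 1):
                y = cy + j * s
                if y - rt < 0 or y + rt > ext[1]:
                    continue
                tubes.append(Bundle((x, y, 0.0), (x, y, float(ext[2])), rt))
        return tuple(tubes)

    def hematoma_center(self) -> tuple[float, float, float]:
        return (self.hemisphere_center_x("ipsilateral"),
                float(self.extent_mm[1] / 2.0),
                float(self.extent_mm[2] / 2.0))


def shell_thickness_for(radius_mm: float) -> float:
    """Disruption-shell thickness for a given baseline hematoma radius."""
    return max(_SHELL_RADIUS_FRACTION * radius_mm, _MIN_SHELL_THICKNESS_MM)


def phantom_spec(layout: PhantomLayout | None = None,
                 hematoma_volume_ml: float | None = 5.0,
                 attenuation: float = _BASELINE_ATTENUATION,
                 shell_thickness_mm: float | None = None,
                 core_fa: float = 0.15,
                 noise_sigma: float = 50.0,
                 seed: int = 0) -> PhantomSpec:
    """A single-subject phantom on the given layout.

    ``hematoma_volume_ml=None`` builds a lesion-free (control) phantom;
    the shell thickness defaults to 0.4× the hematoma radius.
    """
    layout = layout or PhantomLayout.standard()
    hem = None
    thickness = shell_thickness_mm if shell_thickness_mm is not None else _MIN_SHELL_THICKNESS_MM
    if hematoma_volume_ml is not None:
        radius = volume_to_radius_mm(hematoma_volume_ml)
        hem = Hematoma(layout.hematoma_center(), radius, core_fa=core_fa)
        if shell_thickness_mm is None:
            thickness = shell_thickness_for(radius)
    return PhantomSpec(
        grid_shape=layout.grid_shape,
        voxel_spacing=layout.voxel_spacing,
        wm_bundles=layout.bundles("ipsilateral") + layout.bundles("contralateral"),
        hematoma=hem,
        perilesional_shell=PerilesionalShell(thickness, attenuation),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def paper_like_missingness(days: Sequence[int] = (3, 14, 30)) -> list[frozenset[int]]:
    """Acquisition pattern of a 13-subject cohort: 11/10/9 scans per day, 7 complete."""
    d3, d14, d30 = days
    pattern = [
        {d3, d14, d30}, {d3, d14, d30}, {d3, d14, d30}, {d3, d14, d30},
        {d3, d14, d30}, {d3, d14, d30}, {d3, d14, d30},
        {d3, d14}, {d3, d14}, {d3, d30}, {d3}, {d14}, {d30},
    ]
    return [frozenset(s) for s in pattern]


@dataclass(frozen=True)
class CohortDesign:
    """Design of a longitudinal synthetic cohort."""

    n_subjects: int = 13
    days: tuple[int, ...] = (3, 14, 30)
    missingness: tuple[frozenset[int], ...] | None = None
    hematoma_volume_range_ml: tuple[float, float] = (0.3, 39.0)
    recovery_heterogeneity: float = 0.6   # SD of log per-subject recovery rate
    seed: int = 0
    layout: PhantomLayout = field(default_factory=PhantomLayout.standard)
    noise_sigma: float = 50.0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")
        lo, hi = self.hematoma_volume_range_ml
        if not (0 < lo < hi):
            raise ValueError("hematoma volume range must be positive and increasing")
        if hi > self.layout.max_hematoma_volume_ml:
            raise ValueError(
                f"max hematoma volume {hi} mL exceeds layout capacity "
                f"{self.layout.max_hematoma_volume_ml} mL"
            )
        if self.missingness is not None:
            if len(self.missingness) != self.n_subjects:
                raise ValueError("missingness must list one day-set per subject")
            for s in self.missingness:
                if not set(s) <= set(self.days):
                    raise ValueError(f"missingness {set(s)} not a subset of days {self.days}")

    def acquired_days(self) -> list[frozenset[int]]:
        if self.missingness is not None:
            return list(self.missingness)
        if self.n_subjects == 13 and tuple(self.days) == (3, 14, 30):
            return paper_like_missingness(self.days)
        return [frozenset(self.days)] * self.n_subjects


@dataclass
class CohortRecord:
    """One subject × acquisition day, with full ground truth retained."""

    subject_id: str
    day: int
    dwi: DiffusionVolume
    ground_truth: GroundTruth
    spec: PhantomSpec
    timecourse: SubjectTimecourse
    hematoma_volume_ml_day3: float      # designed baseline (analytic) volume


def _subject_draws(design: CohortDesign) -> list[dict]:
    """Per-subject baseline volume, attenuation and longitudinal rates."""
    lo, hi = design.hematoma_volume_range_ml
    n = design.n_subjects
    root = np.random.SeedSequence(design.seed)
    design_rng = np.random.default_rng(root.spawn(1)[0])
    # baseline volumes: log-uniform (hematoma sizes are right-skewed),
    # stratified so every cohort spans the range, then shuffled
    strata = (np.arange(n) + design_rng.uniform(0.0, 1.0, n)) / n
    volumes = np.exp(np.log(lo) + strata * (np.log(hi) - np.log(lo)))
    design_rng.shuffle(volumes)

    subject_seeds = root.spawn(n + 1)[1:]
    draws = []
    for i in range(n):
        rng = np.random.default_rng(subject_seeds[i])
        v = float(volumes[i])
        a3 = _BASELINE_ATTENUATION
        recovery = float(rng.lognormal(np.log(_MEDIAN_RECOVERY_RATE),
                                       design.recovery_heterogeneity))
        resolution = float(rng.lognormal(np.log(_MEDIAN_RESOLUTION_RATE),
                                         _RESOLUTION_RATE_SD))
        draws.append({
            "volume_ml": v,
            "attenuation": a3,
            "recovery_rate": recovery,
            "resolution_rate": resolution,
            "noise_seed_seq": subject_seeds[i].spawn(len(design.days)),
        })
    return draws


def subject_timecourse(design: CohortDesign, draw: dict) -> SubjectTimecourse:
    return SubjectTimecourse(
        baseline_day=design.days[0],
        allowed_days=tuple(design.days),
        attenuation_baseline=draw["attenuation"],
        recovery_rate=draw["recovery_rate"],
        radius_baseline_mm=volume_to_radius_mm(draw["volume_ml"]),
        resolution_rate=draw["resolution_rate"],
    )


def iter_cohort(design: CohortDesign, scheme: GradientScheme | None = None) -> Iterator[CohortRecord]:
    """Yield cohort records one at a time (memory-friendly for large grids).

    Fully reproducible: the record stream is a pure function of the design
    (including its seed) and the gradient scheme.
    """
    if scheme is None:
        from .gradients import default_scheme
        scheme = default_scheme()

    draws = _subject_draws(design)
    acquired = design.acquired_days()
    base = phantom_spec(design.layout, hematoma_volume_ml=None,
                        noise_sigma=design.noise_sigma)

    for i, (draw, days_present) in enumerate(zip(draws, acquired)):
        tc = subject_timecourse(design, draw)
        subject_id = f"S{i + 1:02d}"
        baseline = dataclasses.replace(
            base,
            hematoma=Hematoma(design.layout.hematoma_center(), tc.radius_baseline_mm),
            perilesional_shell=PerilesionalShell(
                shell_thickness_for(tc.radius_baseline_mm), draw["attenuation"]),
            seed=design.seed,
        )
        for j, day in enumerate(design.days):
            if day not in days_present:
                continue
            spec = evolve_timepoint(baseline, tc, day)
            tensor_field, gt = generate_tensor_field(spec)
            rng = np.random.default_rng(draw["noise_seed_seq"][j])
            dwi = simulate_dwi(tensor_field, scheme, s0_map(spec, gt),
                               spec.noise_sigma, rng)
            yield CohortRecord(subject_id, day, dwi, gt, spec, tc, draw["volume_ml"])


def generate_cohort(design: CohortDesign, scheme: GradientScheme | None = None) -> list[CohortRecord]:
    """Materialise the whole cohort as a list (use iter_cohort for big grids)."""
    return list(iter_cohort(design, scheme))


# ---------------------------------------------------------------------------
# Table-level simulators for statistical calibration
# ---------------------------------------------------------------------------

def simulate_loss_table(n_subjects: int = 11,
                        slope: float = 0.15,
                        noise_sd: float = 1.25,
                        volume_range_ml: tuple[float, float] = (0.3, 39.0),
                        intercept: float = 0.0,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Day-3 loss-versus-hematoma-volume table, loss ∝ volume plus noise.

    Defaults model a perilesional white-matter loss of ≈ 0.15 mL per mL of
    hematoma (≈ 6 mL lost for the largest bleeds) with 1.25 mL of
    measurement scatter — the scale of effect the deficit regression is
    designed around.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = volume_range_ml
    vol = rng.uniform(lo, hi, n_subjects)
    loss = intercept + slope * vol + rng.normal(0.0, noise_sd, n_subjects)
    return pd.DataFrame({
        "subject_id": [f"S{i + 1:02d}" for i in range(n_subjects)],
        "hematoma_volume_ml_day3": vol,
        "loss_ml": loss,
    })


LOCATIONS = ("contralateral_sphere", "ipsilateral_sphere", "perilesion", "lesion")


def simulate_location_table(n_subjects: int = 12,
                            days: Sequence[int] = (3, 14, 30),
                            location_effects: dict[str, float] | None = None,
                            day_effects: dict[int, float] | None = None,
                            grand_mean: float = 12.0,
                            subject_sd: float = 2.0,
                            resid_sd: float = 3.0,
                            seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Long-format FA>0.5 percentage table from an additive mixed model.

    ``fa_gt_pct = grand_mean + location effect + day effect + subject
    intercept + residual`` — the generating model matched to the
    random-intercept analysis. With all effects at zero this is the null
    model used for type-I-error calibration.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    location_effects = location_effects or {}
    day_effects = day_effects or {}
    rows = []
    for i in range(n_subjects):
        b = rng.normal(0.0, subject_sd)
        for day in days:
            for loc in LOCATIONS:
                rows.append({
                    "subject_id": f"S{i + 1:02d}",
                    "day": int(day),
                    "location": loc,
                    "fa_gt_pct": grand_mean + location_effects.get(loc, 0.0)
                    + day_effects.get(int(day), 0.0) + b
                    + rng.normal(0.0, resid_sd),
                })
    return pd.DataFrame(rows)
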