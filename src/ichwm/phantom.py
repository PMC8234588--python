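"""Ground-truthed digital DTI phantoms of intracerebral hemorrhage.

A phantom is a 3D tensor field on a regular voxel grid emulating the
features the downstream analysis relies on:

* anisotropic white-matter bundles — straight tubes carrying a cigar-shaped
  tensor aligned with the tube axis (defaults λ = (1.7, 0.3, 0.3)×10⁻³
  mm²/s, typical deep white matter);
* isotropic background tissue (default 0.8×10⁻³ mm²/s);
* a spherical hematoma core whose tensor is tuned to an exact target FA in
  the 0.1–0.2 band measured for clotting blood in vitro, and whose b=0
  signal is attenuated (subacute blood is dark on T2-weighted EPI) so the
  lesion can be segmented from the b=0 image alone;
* a perilesional shell in which bundle tensors are shrunk toward isotropy
  by an attenuation factor f ∈ [0, 1] (f = 1 intact, f = 0 fully
  isotropic), the model of perihematomal white-matter disruption.

The first voxel axis is left–right; the midsagittal plane sits at the
geometric center of that axis. Voxel centers are at ``index × spacing``
(0-based), so all geometry below is in those world millimetres.

From a phantom the module simulates single-shell diffusion-weighted
volumes, ``S = S0 · exp(−b gᵀDg)`` with Rician (two-channel Gaussian
magnitude) noise, and longitudinal evolution: monotone hematoma shrinkage
and exponential relaxation of the shell attenuation toward 1 at a
per-subject recovery rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .dti import (
    DiffusionVolume,
    GradientScheme,
    TensorField,
    eigenvalues_descending,
    fractional_anisotropy,
)

#: typical deep-white-matter eigenvalues, mm²/s
WM_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)
#: isotropic background (gray matter-like) diffusivity, mm²/s
BACKGROUND_DIFFUSIVITY = 0.8e-3


class PhantomError(ValueError):
    """Raised for an invalid phantom specification."""


@dataclass(frozen=True)
class Bundle:
    """A straight white-matter tube: segment endpoints (mm) + radius + eigenvalues."""

    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    radius_mm: float
    eigenvalues: tuple[float, float, float] = WM_EIGENVALUES

    def axis(self) -> np.ndarray:
        a = np.asarray(self.end_mm, float) - np.asarray(self.start_mm, float)
        n = np.linalg.norm(a)
        if n == 0:
            raise PhantomError("bundle with coincident endpoints")
        return a / n


@dataclass(frozen=True)
class Hematoma:
    """Spherical hematoma: center/radius in mm plus core tissue properties."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    core_fa: float = 0.15          # target FA of the clot, in [0.1, 0.2]
    core_md: float = 0.8e-3        # mean diffusivity of the clot, mm²/s
    b0_fraction: float = 0.4       # hypointensity of the clot on the b=0 image


@dataclass(frozen=True)
class PerilesionalShell:
    """Disruption shell around the hematoma: thickness + attenuation factor."""

    thickness_mm: float = 8.0
    attenuation: float = 1.0       # 1 = intact, 0 = fully isotropic

    def __post_init__(self):
        if not (0.0 <= self.attenuation <= 1.0):
            raise PhantomError(f"attenuation factor {self.attenuation} outside [0, 1]")
        if self.thickness_mm < 0:
            raise PhantomError("negative shell thickness")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic subject at one timepoint."""

    grid_shape: tuple[int, int, int]
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 2.3)
    wm_bundles: tuple[Bundle, ...] = ()
    background_diffusivity: float = BACKGROUND_DIFFUSIVITY
    hematoma: Hematoma | None = None
    perilesional_shell: PerilesionalShell = field(default_factory=PerilesionalShell)
    s0: float = 1000.0
    noise_sigma: float = 50.0      # default SNR₀ = 20
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise PhantomError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise PhantomError("voxel spacing must be positive")
        for b in self.wm_bundles:
            if any(e < 0 for e in b.eigenvalues):
                raise PhantomError("negative white-matter eigenvalue")
        if self.background_diffusivity < 0:
            raise PhantomError("negative background diffusivity")
        if self.noise_sigma < 0:
            raise PhantomError("negative noise sigma")
        if self.hematoma is not None:
            self._validate_hematoma()

    def _validate_hematoma(self):
        h = self.hematoma
        if not (0.0 < h.core_fa < 1.0):
            raise PhantomError("hematoma core FA must lie strictly in (0, 1)")
        c = np.asarray(h.center_mm, float)
        extent = self.extent_mm
        lo = c - h.radius_mm
        hi = c + h.radius_mm
        if np.any(lo < 0) or np.any(hi > extent):
            raise PhantomError(
                f"hematoma (center {tuple(c)}, radius {h.radius_mm} mm) overlaps the grid boundary"
            )
        if c[0] == self.midplane_x_mm:
            raise PhantomError("hematoma center lies on the midsagittal plane")

    @property
    def extent_mm(self) -> np.ndarray:
        """World coordinate of the last voxel center along each axis."""
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.voxel_spacing)

    @property
    def midplane_x_mm(self) -> float:
        return (self.grid_shape[0] - 1) * self.voxel_spacing[0] / 2.0

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.voxel_spacing
        return sx * sy * sz / 1000.0


@dataclass
class GroundTruth:
    """Oracle geometry and FA for one phantom."""

    wm_mask: np.ndarray                 # true bundle voxels (outside the lesion)
    lesion_mask_true: np.ndarray
    perilesional_shell_mask: np.ndarray
    true_fa_map: np.ndarray
    true_hematoma_volume_ml: float


def hematoma_eigenvalues(target_fa: float, mean_diffusivity: float) -> tuple[float, float, float]:
    """Axially symmetric eigenvalues (a, b, b) with exact FA and MD.

    For λ = (a, b, b) the FA formula reduces to (r−1)/√(r²+2) with r = a/b,
    which inverts in closed form; b then follows from MD = (a + 2b)/3.
    """
    t = float(target_fa)
    if not (0.0 < t < 1.0):
        raise PhantomError("target FA must lie strictly in (0, 1)")
    disc = 1.0 - (1.0 - t * t) * (1.0 - 2.0 * t * t)
    r = (1.0 + np.sqrt(disc)) / (1.0 - t * t)
    b = 3.0 * mean_diffusivity / (r + 2.0)
    return (r * b, b, b)


def _voxel_coords_mm(spec: PhantomSpec):
    ax = [np.arange(n) * s for n, s in zip(spec.grid_shape, spec.voxel_spacing)]
    return np.meshgrid(*ax, indexing="ij")


def _distance_to_segment(xx, yy, zz, start, end):
    p = np.stack([xx, yy, zz], axis=-1)
    a = np.asarray(start, float)
    d = np.asarray(end, float) - a
    L2 = float(d @ d)
    t = np.clip(((p - a) @ d) / L2, 0.0, 1.0)
    closest = a + t[..., None] * d
    return np.linalg.norm(p - closest, axis=-1)


def _rotation_aligning_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix whose third column is `axis` (unit)."""
    z = np.asarray(axis, float)
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def generate_tensor_field(spec: PhantomSpec) -> tuple[TensorField, GroundTruth]:
    """Paint the phantom tensor field and its ground truth.

    Painting order: isotropic background → bundles → perilesional
    attenuation of bundle voxels inside the shell → hematoma core. The true
    FA map is computed analytically from the painted eigenvalues, so it is
    exact (no fitting involved).
    """
    if not spec.wm_bundles:
        raise PhantomError("at least one white-matter bundle is required")

    xx, yy, zz = _voxel_coords_mm(spec)
    shape = spec.grid_shape

    tensors = np.zeros(shape + (3, 3), dtype=float)
    tensors[...] = spec.background_diffusivity * np.eye(3)

    spacing = np.asarray(spec.voxel_spacing)
    wm_mask = np.zeros(shape, dtype=bool)
    for b in spec.wm_bundles:
        # restrict the distance computation to the tube's bounding box
        pts = np.vstack([b.start_mm, b.end_mm])
        lo = np.maximum(np.floor((pts.min(axis=0) - b.radius_mm) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((pts.max(axis=0) + b.radius_mm) / spacing).astype(int) + 1,
                        np.asarray(shape))
        box = tuple(slice(l, h) for l, h in zip(lo, hi))
        dist = _distance_to_segment(xx[box], yy[box], zz[box], b.start_mm, b.end_mm)
        mask = dist <= b.radius_mm
        R = _rotation_aligning_z(b.axis())
        # eigenvalues ordered (λ2, λ3, λ1) so λ1 rides the tube axis (3rd column)
        lam = np.diag([b.eigenvalues[1], b.eigenvalues[2], b.eigenvalues[0]])
        tensors[box][mask] = R @ lam @ R.T
        wm_mask[box] |= mask

    lesion = np.zeros(shape, dtype=bool)
    shell = np.zeros(shape, dtype=bool)
    if spec.hematoma is not None:
        h = spec.hematoma
        r = np.sqrt((xx - h.center_mm[0]) ** 2 + (yy - h.center_mm[1]) ** 2
                    + (zz - h.center_mm[2]) ** 2)
        lesion = r <= h.radius_mm
        shell = (r > h.radius_mm) & (r <= h.radius_mm + spec.perilesional_shell.thickness_mm)

        f = spec.perilesional_shell.attenuation
        if f < 1.0:
            target = wm_mask & shell
            if target.any():
                d = tensors[target]
                iso = (np.trace(d, axis1=-2, axis2=-1) / 3.0)[:, None, None] * np.eye(3)
                tensors[target] = f * d + (1.0 - f) * iso

        core = hematoma_eigenvalues(h.core_fa, h.core_md)
        tensors[lesion] = np.diag(core)
        wm_mask &= ~lesion

    field = TensorField.from_matrices(tensors, voxel_spacing=spec.voxel_spacing)
    true_fa = fractional_anisotropy(eigenvalues_descending(field))

    gt = GroundTruth(
        wm_mask=wm_mask,
        lesion_mask_true=lesion,
        perilesional_shell_mask=shell,
        true_fa_map=true_fa,
        true_hematoma_volume_ml=float(lesion.sum()) * spec.voxel_volume_ml,
    )
    return field, gt


def s0_map(spec: PhantomSpec, ground_truth: GroundTruth) -> np.ndarray:
    """Per-voxel baseline (b=0) signal: uniform except the hypointense clot."""
    s0 = np.full(spec.grid_shape, float(spec.s0))
    if spec.hematoma is not None:
        s0[ground_truth.lesion_mask_true] = spec.s0 * spec.hematoma.b0_fraction
    return s0


def simulate_dwi(tensor_field: TensorField, scheme: GradientScheme,
                 s0: float | np.ndarray, noise_sigma: float,
                 seed: int | np.random.Generator | None = 0) -> DiffusionVolume:
    """Simulate magnitude DWI from a tensor field.

    Noiseless signal per voxel and volume is ``s0 · exp(−b gᵀDg)``; Rician
    noise is applied as the magnitude of ``(signal + N(0, σ), N(0, σ))``.
    σ = 0 reproduces the noiseless signal exactly. Reproducible for a fixed
    integer seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    comps = tensor_field.components
    w = np.linalg.eigvalsh(tensor_field.as_matrices()[tensor_field.valid])
    if np.any(w < -1e-12):
        raise ValueError("tensor field contains negative eigenvalues")

    g = scheme.directions
    b = scheme.b_values
    # per-volume b·gᵀDg from the packed components in one contraction
    M = b[:, None] * np.column_stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ])                                               # (nvol, 6)
    signal = np.einsum("...i,ji->...j", comps, M)    # b·gᵀDg
    np.exp(np.negative(signal, out=signal), out=signal)
    signal *= np.asarray(s0, dtype=float)[..., None]

    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        signal += rng.normal(0.0, noise_sigma, signal.shape)
        im = rng.normal(0.0, noise_sigma, signal.shape)
        np.square(signal, out=signal)
        signal += np.square(im, out=im)
        np.sqrt(signal, out=signal)
    return DiffusionVolume(signal, scheme, tensor_field.voxel_spacing)


@dataclass(frozen=True)
class SubjectTimecourse:
    """Per-subject longitudinal parameters, drawn once per subject.

    The shell attenuation relaxes exponentially toward 1 (intact) at
    ``recovery_rate`` per day and the hematoma radius shrinks exponentially
    at ``resolution_rate`` per day, both anchored at the baseline day.
    """

    baseline_day: int
    allowed_days: tuple[int, ...]
    attenuation_baseline: float
    recovery_rate: float           # 1/day, ≥ 0
    radius_baseline_mm: float
    resolution_rate: float         # 1/day, ≥ 0

    def attenuation_at(self, day: int) -> float:
        dt = day - self.baseline_day
        return 1.0 - (1.0 - self.attenuation_baseline) * np.exp(-self.recovery_rate * dt)

    def radius_at(self, day: int) -> float:
        dt = day - self.baseline_day
        return self.radius_baseline_mm * float(np.exp(-self.resolution_rate * dt))


def evolve_timepoint(spec: PhantomSpec, subject_params: SubjectTimecourse, day: int) -> PhantomSpec:
    """Phantom spec of `subject_params` at `day`: shrunken hematoma, relaxed shell.

    Deterministic given the subject parameters; the hematoma radius is
    non-increasing in day and the attenuation factor is non-decreasing.
    """
    if day not in subject_params.allowed_days:
        raise ValueError(f"day {day} not in the cohort design days {subject_params.allowed_days}")
    if spec.hematoma is None:
        raise PhantomError("cannot evolve a phantom without a hematoma")
    hem = dataclasses.replace(spec.hematoma, radius_mm=subject_params.radius_at(day))
    shell = dataclasses.replace(spec.perilesional_shell,
                                attenuation=float(np.clip(subject_params.attenuation_at(day), 0.0, 1.0)))
    return dataclasses.replace(spec, hematoma=hem, perilesional_shell=shell)
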