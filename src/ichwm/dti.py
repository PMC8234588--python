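"""Diffusion tensor estimation and scalar anisotropy maps.

Implements the standard single-shell DTI chain: per-voxel log-linear
least-squares fit of the symmetric diffusion tensor D from
``S(g, b) = S0 · exp(−b · gᵀ D g)``, the eigen-decomposition
λ1 ≥ λ2 ≥ λ3, and the derived scalar maps used as white-matter indices —
fractional anisotropy (FA), the Westin linear/planar/spherical shape
measures, and mean diffusivity (the ADC trace / 3).

FA is the normalised eigenvalue dispersion

    FA = sqrt(3/2) · sqrt(Σ(λi − λ̄)²) / sqrt(Σ λi²),

0 for isotropic diffusion and 1 when a single eigenvalue carries all the
diffusivity. Voxels where the fit is ill-defined (non-positive signal) are
flagged invalid and carry NaN in every derived map, so that a threshold
count over a region never picks them up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_TENSOR_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


class SchemeError(ValueError):
    """Raised for an unusable gradient scheme / DWI combination."""


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion gradient table: one b-value and one unit direction per volume."""

    b_values: np.ndarray
    directions: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float).ravel()
        g = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        if b.shape[0] != g.shape[0]:
            raise SchemeError(
                f"{b.shape[0]} b-values but {g.shape[0]} directions"
            )
        if np.any(b < 0):
            raise SchemeError("negative b-value")
        dw = b > 0
        norms = np.linalg.norm(g[dw], axis=1)
        if dw.any() and np.any(np.abs(norms - 1.0) > 1e-6):
            raise SchemeError("non-unit direction for a diffusion-weighted volume")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    def __len__(self) -> int:
        return self.b_values.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values == 0

    @property
    def dw_mask(self) -> np.ndarray:
        return self.b_values > 0

    def design_matrix(self) -> np.ndarray:
        """Rows b·(gx², gy², gz², 2gxgy, 2gxgz, 2gygz) for the weighted volumes."""
        g = self.directions[self.dw_mask]
        b = self.b_values[self.dw_mask]
        return b[:, None] * np.column_stack([
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ])

    def validate_for_fit(self) -> None:
        if not self.b0_mask.any():
            raise SchemeError("at least one b=0 volume is required")
        B = self.design_matrix()
        if B.shape[0] < 6 or np.linalg.matrix_rank(B) < 6:
            raise SchemeError(
                "fewer than 6 usable (non-collinear) diffusion-weighted directions"
            )


@dataclass
class DiffusionVolume:
    """4D diffusion-weighted image: (x, y, z, volume) + its gradient scheme."""

    data: np.ndarray
    scheme: GradientScheme
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 2.3)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D (x, y, z, volume)")
        if self.data.shape[3] != len(self.scheme):
            raise SchemeError(
                f"DWI has {self.data.shape[3]} volumes, scheme has {len(self.scheme)}"
            )
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor, packed (xx, yy, zz, xy, xz, yz)."""

    components: np.ndarray          # (..., 6), mm²/s
    valid: np.ndarray               # (...,) bool
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 2.3)

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape[-1] != 6:
            raise ValueError("tensor components must have trailing dimension 6")
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.components.shape[:-1]:
            raise ValueError("validity mask shape mismatch")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.components.shape[:-1]

    def as_matrices(self) -> np.ndarray:
        """Expand packed components to (..., 3, 3) symmetric matrices."""
        c = self.components
        m = np.empty(c.shape[:-1] + (3, 3), dtype=float)
        m[..., 0, 0] = c[..., 0]
        m[..., 1, 1] = c[..., 1]
        m[..., 2, 2] = c[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
        return m

    @classmethod
    def from_matrices(cls, m: np.ndarray, valid: np.ndarray | None = None,
                      voxel_spacing=(1.0, 1.0, 2.3)) -> "TensorField":
        m = np.asarray(m, dtype=float)
        c = np.stack([m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
                      m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]], axis=-1)
        if valid is None:
            valid = np.ones(m.shape[:-2], dtype=bool)
        return cls(c, valid, voxel_spacing)


@dataclass
class ScalarMap:
    """A single per-voxel scalar (FA, cl, cp, cs, MD or b0) with its geometry."""

    data: np.ndarray
    kind: str
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 2.3)

    _KINDS = ("FA", "cl", "cp", "cs", "MD", "b0")

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; expected one of {self._KINDS}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def voxel_volume_ml(self) -> float:
        sx, sy, sz = self.voxel_spacing
        return sx * sy * sz / 1000.0


def fit_tensor(dwi: DiffusionVolume, scheme: GradientScheme | None = None) -> TensorField:
    """Fit the diffusion tensor voxelwise by ordinary log-linear least squares.

    The model ``log(S/S0) = −b gᵀDg`` is solved with the Moore–Penrose
    pseudo-inverse of the b-matrix design, identical for every voxel. When
    several b=0 volumes are present their mean serves as S0. Voxels with
    S0 ≤ 0 or any non-positive weighted signal are marked invalid.
    """
    scheme = dwi.scheme if scheme is None else scheme
    if dwi.data.shape[3] != len(scheme):
        raise SchemeError("DWI / scheme length mismatch")
    scheme.validate_for_fit()

    s = dwi.data
    s0 = s[..., scheme.b0_mask].mean(axis=-1)
    sdw = s[..., scheme.dw_mask]

    valid = (s0 > 0) & np.all(sdw > 0, axis=-1) & np.isfinite(s0) \
        & np.all(np.isfinite(sdw), axis=-1)
    n_invalid = int(valid.size - valid.sum())
    if n_invalid:
        logger.info("tensor fit: %d voxels marked invalid (non-positive signal)", n_invalid)

    B = scheme.design_matrix()                       # (ndw, 6)
    Binv = np.linalg.pinv(B)                         # (6, ndw)

    y = np.zeros_like(sdw)
    np.log(sdw, out=y, where=valid[..., None] & (sdw > 0))
    logs0 = np.zeros_like(s0)
    np.log(s0, out=logs0, where=valid & (s0 > 0))
    y = logs0[..., None] - y                         # −log(S/S0)

    comps = np.einsum("ij,...j->...i", Binv, y)
    comps[~valid] = np.nan
    return TensorField(comps, valid, dwi.voxel_spacing)


def eigen_spectrum(tensor: np.ndarray, clamp_negative: bool = True):
    """Eigenvalues sorted descending plus the principal eigenvector.

    Accepts a packed 6-vector, a 3×3 matrix, or arrays thereof. Negative
    eigenvalues (possible below the noise floor) are clamped to zero before
    scalar-map computation; the number of clamped values is logged.

    Returns ``(eigvals, principal)`` with eigvals ``(..., 3)`` in descending
    order and principal the unit eigenvector of λ1, shape ``(..., 3)``.
    Non-finite tensors yield NaN eigenvalues.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape[-1] == 6 and (t.ndim == 1 or t.shape[-2:] != (3, 3)):
        m = TensorField(t.reshape(-1, 6) if t.ndim == 1 else t,
                        np.ones(t.shape[:-1] if t.ndim > 1 else (1,), bool)).as_matrices()
        if t.ndim == 1:
            m = m[0]
    elif t.shape[-2:] == (3, 3):
        m = t
    else:
        raise ValueError("tensor must be packed 6-vector(s) or 3×3 matrix/matrices")

    finite = np.all(np.isfinite(m), axis=(-2, -1))
    safe = np.where(finite[..., None, None], m, np.eye(3))
    w, v = np.linalg.eigh(safe)                      # ascending
    w = w[..., ::-1]
    principal = v[..., ::-1][..., :, 0]
    if clamp_negative:
        n_neg = int(np.count_nonzero(w[finite] < 0))
        if n_neg:
            logger.info("eigen spectrum: clamped %d negative eigenvalues to 0", n_neg)
        w = np.clip(w, 0.0, None)
    w = np.where(finite[..., None], w, np.nan)
    principal = np.where(finite[..., None], principal, np.nan)
    return w, principal


def fractional_anisotropy(l1, l2=None, l3=None):
    """FA from eigenvalues; accepts three arrays or one stacked (..., 3) array.

    All-zero triples (and any non-finite input) map to NaN: a voxel with no
    diffusivity at all has no defined anisotropy.
    """
    if l2 is None and l3 is None:
        lam = np.asarray(l1, dtype=float)
    elif l2 is None or l3 is None:
        raise TypeError("pass either one stacked (..., 3) array or three eigenvalues")
    else:
        lam = np.stack([np.asarray(l1, float), np.asarray(l2, float),
                        np.asarray(l3, float)], axis=-1)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam ** 2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, np.nan)
    fa = np.where(np.all(np.isfinite(lam), axis=-1), fa, np.nan)
    fa = np.clip(fa, 0.0, 1.0)  # NaN propagates through clip
    return float(fa) if np.ndim(fa) == 0 else fa


def westin_measures(l1, l2, l3):
    """Westin shape decomposition (cl, cp, cs), normalised by the trace.

    cl = (λ1−λ2)/T, cp = 2(λ2−λ3)/T, cs = 3λ3/T with T = λ1+λ2+λ3, so that
    cl + cp + cs = 1 wherever the trace is positive; a zero trace yields a
    NaN triple. Requires λ1 ≥ λ2 ≥ λ3 ≥ 0.
    """
    l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
    t = l1 + l2 + l3
    with np.errstate(invalid="ignore", divide="ignore"):
        cl = (l1 - l2) / t
        cp = 2.0 * (l2 - l3) / t
        cs = 3.0 * l3 / t
    bad = ~(t > 0)
    cl = np.where(bad, np.nan, cl)
    cp = np.where(bad, np.nan, cp)
    cs = np.where(bad, np.nan, cs)
    return cl, cp, cs


def mean_diffusivity(l1, l2, l3):
    """MD = (λ1 + λ2 + λ3) / 3, the ADC trace over three."""
    return (np.asarray(l1, float) + np.asarray(l2, float) + np.asarray(l3, float)) / 3.0


def eigenvalues_descending(field: TensorField, clamp_negative: bool = True) -> np.ndarray:
    """(..., 3) eigenvalues λ1 ≥ λ2 ≥ λ3 of a tensor field (no eigenvectors).

    Cheaper than `eigen_spectrum` for scalar-map pipelines; same clamping
    policy for negative eigenvalues.
    """
    m = field.as_matrices()
    finite = np.all(np.isfinite(m), axis=(-2, -1))
    safe = np.where(finite[..., None, None], m, np.eye(3))
    w = np.linalg.eigvalsh(safe)[..., ::-1]
    if clamp_negative:
        n_neg = int(np.count_nonzero(w[finite] < 0))
        if n_neg:
            logger.info("eigenvalues: clamped %d negative eigenvalues to 0", n_neg)
        w = np.clip(w, 0.0, None)
    return np.where(finite[..., None], w, np.nan)


def _scalar_from_tensor(field: TensorField, kind: str) -> ScalarMap:
    w = eigenvalues_descending(field)
    l1, l2, l3 = w[..., 0], w[..., 1], w[..., 2]
    if kind == "FA":
        data = fractional_anisotropy(w)
    elif kind == "MD":
        data = mean_diffusivity(l1, l2, l3)
    elif kind in ("cl", "cp", "cs"):
        data = westin_measures(l1, l2, l3)[("cl", "cp", "cs").index(kind)]
    else:
        raise ValueError(f"cannot derive map kind {kind!r} from a tensor field")
    data = np.where(field.valid, data, np.nan)
    return ScalarMap(data, kind, field.voxel_spacing)


def fa_map_from_tensor(field: TensorField) -> ScalarMap:
    """FA map of an existing tensor field (NaN where the field is invalid)."""
    return _scalar_from_tensor(field, "FA")


def compute_fa_map(dwi: DiffusionVolume, scheme: GradientScheme | None = None) -> ScalarMap:
    """Fit tensors and return the FA map in one step.

    Composition fit → eigen spectrum → FA; invalid voxels carry NaN and the
    map inherits the voxel spacing of the input volume.
    """
    return fa_map_from_tensor(fit_tensor(dwi, scheme))


def compute_scalar_maps(dwi: DiffusionVolume, kinds=("FA", "MD", "cl", "cp", "cs")) -> dict[str, ScalarMap]:
    """All requested scalar maps from one tensor fit, plus the mean b0 image."""
    field = fit_tensor(dwi)
    maps = {k: _scalar_from_tensor(field, k) for k in kinds}
    maps["b0"] = ScalarMap(dwi.data[..., dwi.scheme.b0_mask].mean(axis=-1),
                           "b0", dwi.voxel_spacing)
    return maps
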