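"""Built-in diffusion gradient scheme.

The acquisition emulated throughout this package is a single-shell DTI
protocol: one unweighted (b = 0) volume followed by 32 diffusion-weighted
volumes at b = 800 s/mm². The 32 unit directions below were spread over the
half-sphere by minimising an antipodally symmetric electrostatic (Coulomb)
energy, the standard way clinical DTI direction tables are designed; the
resulting 6-parameter tensor design matrix has condition number ≈ 1.6.
"""

from __future__ import annotations

import numpy as np

from .dti import GradientScheme

DEFAULT_B_VALUE = 800.0  # s/mm²

# 32 electrostatically spread unit vectors (antipodal energy minimised).
_DIRECTIONS_32 = np.array([
    (-0.99999681, +0.00121827, +0.00221112),
    (-0.89057569, +0.13761335, +0.43351761),
    (-0.88438257, +0.45971850, +0.08078600),
    (-0.88079375, -0.33173793, +0.33786435),
    (-0.67219814, -0.21361912, +0.70888400),
    (-0.67203638, +0.54250210, +0.50404224),
    (-0.61458662, -0.77979581, +0.11917118),
    (-0.57077535, +0.18957862, +0.79892142),
    (-0.56507292, +0.81267008, +0.14233740),
    (-0.56299333, -0.63735927, +0.52612895),
    (-0.30394108, -0.38156597, +0.87294171),
    (-0.27563222, +0.80680683, +0.52257978),
    (-0.26858570, +0.50201377, +0.82209725),
    (-0.19410809, -0.95038016, +0.24310408),
    (-0.17172212, +0.02665186, +0.98478485),
    (-0.14799129, -0.75591465, +0.63772378),
    (-0.08108110, +0.97960182, +0.18386445),
    (+0.13519955, +0.39214888, +0.90991227),
    (+0.13787617, -0.42740610, +0.89348430),
    (+0.18191108, +0.75892717, +0.62525027),
    (+0.27363680, -0.93966203, +0.20532453),
    (+0.28672147, -0.75567904, +0.58884632),
    (+0.29709271, -0.02831507, +0.95442872),
    (+0.34053888, +0.91480294, +0.21718392),
    (+0.53683844, +0.40607021, +0.73953463),
    (+0.57476312, -0.43670488, +0.69205217),
    (+0.63736218, +0.65580480, +0.40458561),
    (+0.67587877, -0.67759195, +0.28992592),
    (+0.68281473, -0.02228853, +0.73025151),
    (+0.87851355, +0.47296421, +0.06722203),
    (+0.88428489, +0.20913232, +0.41749720),
    (+0.89234916, -0.27201461, +0.36016807),
], dtype=float)


def default_scheme(b_value: float = DEFAULT_B_VALUE, n_b0: int = 1) -> GradientScheme:
    """Return the built-in 1×b0 + 32-direction single-shell scheme.

    Parameters
    ----------
    b_value : diffusion weighting of the shell, s/mm².
    n_b0 : number of leading unweighted volumes.
    """
    dirs = _DIRECTIONS_32 / np.linalg.norm(_DIRECTIONS_32, axis=1, keepdims=True)
    b = np.concatenate([np.zeros(n_b0), np.full(len(dirs), float(b_value))])
    g = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(b_values=b, directions=g)
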