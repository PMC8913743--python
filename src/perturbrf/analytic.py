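"""Closed-form vacuum fields used as independent validation oracles."""

from __future__ import annotations

import numpy as np

from .constants import EPS0, MU0


def hertzian_dipole_field(points: np.ndarray, current_moment: float, k_b: float, axis: int = 0) -> np.ndarray:
    """Exact E-field of a Hertzian dipole at the origin (e^{+iωt}, e^{-ikr}).

    Parameters
    ----------
    points : (..., 3) observation positions [m]; must exclude the origin.
    current_moment : I·l [A·m] of the infinitesimal element along ``axis``.
    k_b : vacuum wavenumber [rad/m].

    Returns the complex E vector, shape (..., 3):

        E_r  = η Il cosθ / (2π r²) (1 + 1/(ikr)) e^{-ikr}
        E_θ  = iη k Il sinθ / (4π r) (1 + 1/(ikr) - 1/(kr)²) e^{-ikr}
    """
    eta = np.sqrt(MU0 / EPS0)
    pts = np.asarray(points, dtype=float)
    r = np.linalg.norm(pts, axis=-1)
    if np.any(r == 0):
        raise ValueError("observation point at the dipole position")
    rhat = pts / r[..., None]
    zhat = np.zeros(3)
    zhat[axis] = 1.0
    cos = rhat @ zhat
    sin = np.sqrt(np.clip(1.0 - cos**2, 0.0, None))
    phase = np.exp(-1j * k_b * r)
    kr = k_b * r
    Er = eta * current_moment * cos / (2 * np.pi * r**2) * (1 + 1 / (1j * kr)) * phase
    Eth = 1j * eta * k_b * current_moment * sin / (4 * np.pi * r) * (1 + 1 / (1j * kr) - 1 / kr**2) * phase
    with np.errstate(invalid="ignore", divide="ignore"):
        thetahat = (cos[..., None] * rhat - zhat) / sin[..., None]
    thetahat = np.where(sin[..., None] > 1e-12, thetahat, 0.0)
    return Er[..., None] * rhat + Eth[..., None] * thetahat
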