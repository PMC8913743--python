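"""Physical constants and unit helpers (SI, e^{+iωt} time convention)."""

import numpy as np

MU0 = 4e-7 * np.pi  # vacuum permeability [H/m]
EPS0 = 8.8541878128e-12  # vacuum permittivity [F/m]
C0 = 1.0 / np.sqrt(MU0 * EPS0)  # speed of light [m/s]
ETA0 = np.sqrt(MU0 / EPS0)  # vacuum impedance [ohm]


def db_to_linear(db: float) -> float:
    """Convert a convergence level in dB to a linear relative-residual tolerance.

    A stopping rule of, e.g., -50 dB corresponds to a relative residual of
    10**(-50/20) ≈ 3.16e-3 (amplitude convention).
    """
    if db >= 0:
        raise ValueError(f"convergence level must be negative dB, got {db}")
    return 10.0 ** (db / 20.0)
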