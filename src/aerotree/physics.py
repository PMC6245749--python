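"""Shared aerosol-mechanics primitives and air properties (room conditions)."""

from __future__ import annotations

import numpy as np

AIR_VISCOSITY = 1.81e-5          # Pa s, dynamic viscosity of air
AIR_KINEMATIC_VISCOSITY = 1.5e-5  # m^2/s
MEAN_FREE_PATH = 6.6e-8          # m, air at room conditions
GRAVITY = 9.81                   # m/s^2

__all__ = ["AIR_VISCOSITY", "AIR_KINEMATIC_VISCOSITY", "MEAN_FREE_PATH",
           "GRAVITY", "slip_correction", "settling_velocity"]


def slip_correction(dp, lambda_mfp: float = MEAN_FREE_PATH):
    """Cunningham slip correction Cc = 1 + Kn (1.257 + 0.4 exp(-1.1/Kn)).

    Kn = 2 lambda / dp.  Corrects Stokes drag for particles whose size
    approaches the gas mean free path; Cc -> 1 in the continuum limit.
    Accepts scalars or arrays of diameters in meters.
    """
    dp = np.asarray(dp, dtype=float)
    if np.any(dp <= 0):
        raise ValueError("particle diameter must be positive")
    kn = 2.0 * lambda_mfp / dp
    cc = 1.0 + kn * (1.257 + 0.4 * np.exp(-1.1 / kn))
    return float(cc) if cc.ndim == 0 else cc


def settling_velocity(dp, rho_p: float = 1000.0,
                      mu: float = AIR_VISCOSITY,
                      lambda_mfp: float = MEAN_FREE_PATH,
                      g: float = GRAVITY):
    """Terminal gravitational settling speed under Stokes drag (m/s)."""
    cc = slip_correction(dp, lambda_mfp)
    dp = np.asarray(dp, dtype=float)
    v = rho_p * dp ** 2 * g * cc / (18.0 * mu)
    return float(v) if v.ndim == 0 else v
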