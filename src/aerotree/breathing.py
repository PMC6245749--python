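"""Age- and device-specific inhalation waveforms.

Two maneuver families are modelled, each parameterized by tidal volume VT,
peak inspiratory flow rate (PIFR) and inspiration time t_insp:

* **Nebulizer** (relaxed tidal breathing): half-sine inspiratory flow
  Q(t) = PIFR * sin(pi t / t_insp), whose closed-form volume is
  (2/pi) * PIFR * t_insp.
* **DPI** (forceful single inhalation): quarter-sine rise to PIFR at
  t_peak (0.45 s), plateau at PIFR until t_plateau_end (0.6 s), then a
  volume-constrained cos^gamma decay to zero at t_insp.  The exponent
  gamma is solved by bisection so the waveform integrates exactly to VT.

Default parameter sets for ages 5, 10 and 25 years are tabulated in
``MANEUVER_TABLE``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "Device", "ManeuverParams", "InhalationProfile", "MANEUVER_TABLE",
    "maneuver_defaults", "nebulizer_profile", "dpi_profile", "build_profile",
    "inhaled_volume", "characteristic_velocity", "write_waveform_csv",
    "InfeasibleManeuverError",
]

DEFAULT_DT = 1.0e-3      # s
_L_TO_M3 = 1.0e-3
_LPM_TO_M3S = 1.0 / 60.0e3


class Device(str, Enum):
    DPI = "DPI"
    NEBULIZER = "NEBULIZER"


class InfeasibleManeuverError(ValueError):
    """Tidal volume cannot be met by any decay exponent."""


@dataclass(frozen=True)
class ManeuverParams:
    """One (age, device) breathing maneuver.

    ``tidal_volume`` in liters, ``pifr`` in l/min, times in seconds.
    """

    age: float
    device: Device
    tidal_volume: float
    pifr: float
    t_insp: float
    t_peak: float = 0.45          # DPI: time PIFR is reached
    t_plateau_end: float = 0.6    # DPI: end of the PIFR plateau

    def __post_init__(self) -> None:
        if min(self.tidal_volume, self.pifr, self.t_insp) <= 0:
            raise ValueError("maneuver parameters must be positive")
        if self.device is Device.DPI and not (
                0 < self.t_peak < self.t_plateau_end < self.t_insp):
            raise ValueError("DPI requires 0 < t_peak < t_plateau_end < t_insp")

    @property
    def pifr_m3s(self) -> float:
        return self.pifr * _LPM_TO_M3S

    @property
    def tidal_volume_m3(self) -> float:
        return self.tidal_volume * _L_TO_M3


#: Default inhalation parameters (VT in l, PIFR in l/min, t_insp in s).
MANEUVER_TABLE: dict[tuple[float, Device], ManeuverParams] = {
    (5.0, Device.DPI): ManeuverParams(5.0, Device.DPI, 0.89, 40.0, 2.0),
    (10.0, Device.DPI): ManeuverParams(10.0, Device.DPI, 1.33, 60.0, 2.0),
    (25.0, Device.DPI): ManeuverParams(25.0, Device.DPI, 2.95, 90.0, 3.0),
    (5.0, Device.NEBULIZER): ManeuverParams(5.0, Device.NEBULIZER, 0.108, 8.14, 1.25),
    (10.0, Device.NEBULIZER): ManeuverParams(10.0, Device.NEBULIZER, 0.168, 10.0, 1.58),
    (25.0, Device.NEBULIZER): ManeuverParams(25.0, Device.NEBULIZER, 0.5, 22.0, 2.14),
}


def maneuver_defaults(age: float, device: Device | str) -> ManeuverParams:
    device = Device(device)
    try:
        return MANEUVER_TABLE[(float(age), device)]
    except KeyError:
        raise ValueError(
            f"no default maneuver for age {age} y with {device.value}") from None


@dataclass(frozen=True)
class InhalationProfile:
    """Sampled flow waveform Q(t) on a uniform time grid (m^3/s)."""

    times: np.ndarray
    flow: np.ndarray
    params: ManeuverParams

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def flow_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation; zero outside the inspiration window."""
        return np.interp(t, self.times, self.flow, left=0.0, right=0.0)

    def volume(self) -> float:
        """Inhaled volume in m^3 (trapezoidal integral)."""
        return float(np.trapezoid(self.flow, self.times))


def inhaled_volume(profile: InhalationProfile) -> float:
    """Inhaled volume in liters."""
    return profile.volume() / _L_TO_M3


def nebulizer_profile(params: ManeuverParams,
                      dt: float = DEFAULT_DT) -> InhalationProfile:
    """Half-sine tidal inspiration Q(t) = PIFR sin(pi t / t_insp)."""
    if params.device is not Device.NEBULIZER:
        raise ValueError("nebulizer_profile requires a NEBULIZER maneuver")
    if dt > 1.0e-3:
        raise ValueError("dt must be <= 1e-3 s")
    closed_form = (2.0 / math.pi) * params.pifr_m3s * params.t_insp
    vt = params.tidal_volume_m3
    if abs(closed_form - vt) / vt > 0.02:
        warnings.warn(
            f"half-sine volume {closed_form / _L_TO_M3:.4f} l deviates >2% from "
            f"tabulated VT {params.tidal_volume:.4f} l; using the integral",
            stacklevel=2)
    times = _grid(params.t_insp, dt)
    flow = params.pifr_m3s * np.sin(math.pi * times / params.t_insp)
    return InhalationProfile(times=times, flow=np.maximum(flow, 0.0),
                             params=params)


def _cos_power_mean(gamma: float) -> float:
    """Mean of cos^gamma(x) over x in [0, pi/2] (exact, via the Beta function)."""
    # integral_0^{pi/2} cos^g = sqrt(pi)/2 * Gamma((g+1)/2) / Gamma(g/2 + 1)
    log_int = (0.5 * math.log(math.pi) - math.log(2.0)
               + gammaln((gamma + 1.0) / 2.0) - gammaln(gamma / 2.0 + 1.0))
    return math.exp(log_int) / (math.pi / 2.0)


def solve_decay_exponent(params: ManeuverParams,
                         tol: float = 1.0e-6) -> float:
    """Bisection for the DPI decay exponent gamma.

    The decay phase contributes PIFR * (t_insp - t_plateau_end) * m(gamma)
    with m(gamma) the mean of cos^gamma over a quarter period; gamma is
    chosen so rise + plateau + decay volumes equal the tidal volume.
    ``tol`` is relative on the volume.
    """
    q = params.pifr_m3s
    v_rise = (2.0 / math.pi) * q * params.t_peak
    v_plateau = q * (params.t_plateau_end - params.t_peak)
    t_decay = params.t_insp - params.t_plateau_end
    v_target = params.tidal_volume_m3 - v_rise - v_plateau
    lo, hi = 0.05, 20.0
    v_lo = q * t_decay * _cos_power_mean(lo)   # largest achievable
    v_hi = q * t_decay * _cos_power_mean(hi)   # smallest achievable
    if not v_hi <= v_target <= v_lo:
        raise InfeasibleManeuverError(
            f"tidal volume {params.tidal_volume} l incompatible with "
            f"PIFR {params.pifr} l/min over t_insp {params.t_insp} s "
            f"(decay phase can hold {v_hi / _L_TO_M3:.3f}-{v_lo / _L_TO_M3:.3f} l, "
            f"needs {v_target / _L_TO_M3:.3f} l)")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        v_mid = q * t_decay * _cos_power_mean(mid)
        if abs(v_mid - v_target) <= tol * params.tidal_volume_m3:
            return mid
        if v_mid > v_target:     # volume decreases with gamma
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def dpi_profile(params: ManeuverParams,
                dt: float = DEFAULT_DT) -> InhalationProfile:
    """Piecewise DPI inhalation: quarter-sine rise, plateau, cos^gamma decay."""
    if params.device is not Device.DPI:
        raise ValueError("dpi_profile requires a DPI maneuver")
    gamma = solve_decay_exponent(params)
    times = _grid(params.t_insp, dt)
    q = params.pifr_m3s
    flow = np.empty_like(times)
    rise = times < params.t_peak
    flow[rise] = q * np.sin(0.5 * math.pi * times[rise] / params.t_peak)
    plateau = (times >= params.t_peak) & (times <= params.t_plateau_end)
    flow[plateau] = q
    decay = times > params.t_plateau_end
    phase = (0.5 * math.pi * (times[decay] - params.t_plateau_end)
             / (params.t_insp - params.t_plateau_end))
    flow[decay] = q * np.cos(phase) ** gamma
    flow[-1] = 0.0
    return InhalationProfile(times=times, flow=flow, params=params)


def build_profile(params: ManeuverParams,
                  dt: float = DEFAULT_DT) -> InhalationProfile:
    if params.device is Device.DPI:
        return dpi_profile(params, dt)
    return nebulizer_profile(params, dt)


def characteristic_velocity(params: ManeuverParams, mouth_area: float) -> float:
    """Characteristic mouth-inlet velocity Um (m/s) for the Stokes number.

    DPI: mean inlet velocity over the PIFR plateau (the particle-release
    window), which equals PIFR / area since the plateau is constant.
    Nebulizer: mean inhalation velocity over the whole inspiration,
    VT / (t_insp * area), since release spans the full breath.
    """
    if mouth_area <= 0:
        raise ValueError("mouth area must be positive")
    if params.device is Device.DPI:
        return params.pifr_m3s / mouth_area
    return params.tidal_volume_m3 / (params.t_insp * mouth_area)


def _grid(t_end: float, dt: float) -> np.ndarray:
    n = int(round(t_end / dt))
    return np.linspace(0.0, t_end, n + 1)


def write_waveform_csv(profile: InhalationProfile, path: str | Path) -> None:
    pd.DataFrame({"t_s": profile.times, "Q_m3_per_s": profile.flow}).to_csv(
        path, index=False)
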