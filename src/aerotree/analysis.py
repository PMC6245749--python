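"""Dimensionless deposition analysis on the Stokes-number axis.

The central quantity is the mouth-inlet Stokes number

    Stk = rho_p dp^2 Um Cc / (18 mu Do),

with Um a device-specific characteristic velocity (mean inlet velocity
during the PIFR release window for DPI, mean inhalation velocity over the
whole inspiration for nebulizers) and Do the mouth hydraulic diameter.
Plotting regional deposition efficiency against Stk pools the three age
points onto master curves; the conducting-airway curve has an interior
Gaussian-like peak whose location Stk* inverts — per age and device —
into an optimal aerosol diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from aerotree import physics
from aerotree.airway_model import AirwayTree
from aerotree.breathing import Device, ManeuverParams, characteristic_velocity
from aerotree.physics import slip_correction
from aerotree.transport import DepositionResult

__all__ = [
    "StokesContext", "EfficiencyCurve", "GaussianFit", "OptimalSize",
    "slip_correction", "stokes_number", "reynolds_number", "make_context",
    "efficiency_curve", "fit_gaussian", "optimal_diameter",
    "collapse_diagnostic", "NoInteriorPeakError",
]


class NoInteriorPeakError(ValueError):
    """The efficiency curve is monotone over the sampled Stk range."""


@dataclass(frozen=True)
class StokesContext:
    """Fixed quantities entering the Stokes number for one (age, device)."""

    um: float                     # m/s
    do: float                     # m, mouth hydraulic diameter
    rho_p: float = 1000.0
    mu: float = physics.AIR_VISCOSITY
    lambda_mfp: float = physics.MEAN_FREE_PATH
    age: float | None = None
    device: Device | None = None

    def __post_init__(self) -> None:
        if min(self.um, self.do, self.rho_p, self.mu) <= 0:
            raise ValueError("Stokes-context quantities must be positive")


def make_context(tree: AirwayTree, params: ManeuverParams,
                 rho_p: float = 1000.0) -> StokesContext:
    """Context from a scaled tree and its maneuver (Um per device convention)."""
    um = characteristic_velocity(params, tree.mouth_inlet_area)
    return StokesContext(um=um, do=tree.mouth_hydraulic_diameter, rho_p=rho_p,
                         age=tree.age_label, device=params.device)


def stokes_number(dp, ctx: StokesContext):
    """Mouth-inlet Stokes number Stk = rho_p dp^2 Um Cc / (18 mu Do)."""
    dp = np.asarray(dp, dtype=float)
    cc = np.where(dp > 0, slip_correction(np.where(dp > 0, dp, 1.0),
                                          ctx.lambda_mfp), 1.0)
    stk = ctx.rho_p * dp ** 2 * ctx.um * cc / (18.0 * ctx.mu * ctx.do)
    return float(stk) if stk.ndim == 0 else stk


def reynolds_number(q: float, d: float,
                    nu: float = physics.AIR_KINEMATIC_VISCOSITY) -> float:
    """Mouth-inlet Reynolds number Re = 4Q/(pi D nu) (circular inlet)."""
    if d <= 0 or nu <= 0:
        raise ValueError("diameter and kinematic viscosity must be positive")
    return 4.0 * q / (math.pi * d * nu)


@dataclass(frozen=True)
class EfficiencyCurve:
    """Deposition efficiency vs Stk, possibly pooled over age points."""

    stk: np.ndarray
    efficiency: np.ndarray
    dp: np.ndarray                # m
    age: np.ndarray               # years
    region: str
    device: Device

    def __post_init__(self) -> None:
        if np.any(self.stk <= 0):
            raise ValueError("Stokes numbers must be strictly positive")
        if np.any((self.efficiency < 0) | (self.efficiency > 1)):
            raise ValueError("efficiencies must lie in [0, 1]")
        if np.any(np.diff(self.stk) < 0):
            raise ValueError("curve points must be sorted by Stk")

    def __len__(self) -> int:
        return len(self.stk)


def efficiency_curve(results: Sequence[DepositionResult], region: str,
                     contexts: dict[float, StokesContext]) -> EfficiencyCurve:
    """Pool (age, dp) deposition results onto one Stk-indexed curve.

    ``contexts`` maps each age to its StokesContext; pooling all ages on a
    common Stk axis is exactly the master-curve (collapse) construction.
    """
    if not results:
        raise ValueError("no deposition results supplied")
    devices = {r.device for r in results}
    if len(devices) > 1:
        raise ValueError(f"mixed devices in one curve: {devices}")
    rows = []
    for r in results:
        ctx = contexts[r.age]
        rows.append((float(stokes_number(r.dp, ctx)), r.efficiency(region),
                     r.dp, r.age))
    rows.sort()
    stk, eff, dp, age = (np.array(x) for x in zip(*rows))
    return EfficiencyCurve(stk=stk, efficiency=eff, dp=dp, age=age,
                           region=region, device=devices.pop())


@dataclass(frozen=True)
class GaussianFit:
    """Fitted conducting-airway peak: eta = A exp(-(Stk - Stk*)^2 / 2 sigma^2)."""

    amplitude: float
    peak_stk: float
    sigma_stk: float
    rmse: float

    def __post_init__(self) -> None:
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be in (0, 1]")
        if self.peak_stk <= 0 or self.sigma_stk <= 0:
            raise ValueError("peak and width must be positive")

    def __call__(self, stk):
        return self.amplitude * np.exp(
            -((np.asarray(stk) - self.peak_stk) ** 2)
            / (2.0 * self.sigma_stk ** 2))


def fit_gaussian(curve: EfficiencyCurve, max_iter: int = 500) -> GaussianFit:
    """Nonlinear least-squares Gaussian fit of efficiency vs Stk.

    Requires an interior maximum: a curve whose largest efficiency sits at
    either end of the sampled Stk range (e.g. the monotone mouth-throat
    sigmoid) raises :class:`NoInteriorPeakError`.
    """
    if len(curve) < 5:
        raise ValueError("need at least 5 points to fit a peak")
    i_max = int(np.argmax(curve.efficiency))
    if i_max == 0 or i_max == len(curve) - 1:
        raise NoInteriorPeakError(
            f"{curve.region} efficiency is maximal at the edge of the "
            "sampled Stk range; no interior peak to fit")
    q1, q3 = np.percentile(curve.stk, [25, 75])
    p0 = [float(curve.efficiency[i_max]), float(curve.stk[i_max]),
          max(0.5 * (q3 - q1), 1e-6)]

    def model(stk, a, mu, sigma):
        return a * np.exp(-((stk - mu) ** 2) / (2.0 * sigma ** 2))

    popt, _ = curve_fit(model, curve.stk, curve.efficiency, p0=p0,
                        maxfev=max_iter * (len(curve) + 4))
    a, mu, sigma = popt
    resid = curve.efficiency - model(curve.stk, *popt)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return GaussianFit(amplitude=float(np.clip(a, 1e-12, 1.0)),
                       peak_stk=float(mu), sigma_stk=float(abs(sigma)),
                       rmse=rmse)


@dataclass(frozen=True)
class OptimalSize:
    """Optimal aerosol diameter (and spread) for one age and device."""

    age: float
    device: Device
    dp_opt: float                 # m
    dp_spread: float              # m, half-width mapped through the inversion


def optimal_diameter(peak_stk: float, ctx: StokesContext,
                     rel_tol: float = 1.0e-4, max_iter: int = 50) -> float:
    """Invert the Stokes number for dp at a target Stk.

    Fixed-point iteration on the slip correction: starting from Cc = 1,
    dp = sqrt(18 mu Do Stk / (rho_p Um Cc(dp))) until dp is stable to
    ``rel_tol``; converges in a few steps for micron-sized particles.
    """
    if peak_stk < 0:
        raise ValueError("Stokes number must be non-negative")
    if peak_stk == 0:
        return 0.0
    base = 18.0 * ctx.mu * ctx.do * peak_stk / (ctx.rho_p * ctx.um)
    cc = 1.0
    dp = math.sqrt(base)
    for _ in range(max_iter):
        cc = slip_correction(dp, ctx.lambda_mfp)
        dp_new = math.sqrt(base / cc)
        if abs(dp_new - dp) <= rel_tol * dp:
            return dp_new
        dp = dp_new
    raise RuntimeError(
        f"slip-correction fixed point did not converge for Stk={peak_stk}")


def optimal_sizes(fit: GaussianFit,
                  contexts: Iterable[StokesContext]) -> list[OptimalSize]:
    """Map the fitted peak (and width) into per-age optimal diameters."""
    out = []
    for ctx in contexts:
        dp_opt = optimal_diameter(fit.peak_stk, ctx)
        hi = optimal_diameter(fit.peak_stk + fit.sigma_stk, ctx)
        lo = optimal_diameter(max(fit.peak_stk - fit.sigma_stk, 1e-12), ctx)
        out.append(OptimalSize(age=ctx.age, device=ctx.device, dp_opt=dp_opt,
                               dp_spread=0.5 * (hi - lo)))
    return out


def collapse_diagnostic(per_age_curves: Sequence[EfficiencyCurve],
                        n_grid: int = 50) -> float:
    """Maximum across-age spread of efficiency at matched Stk.

    Curves are linearly interpolated onto a common Stk grid spanning the
    overlap of their ranges; the diagnostic is the largest (max - min)
    efficiency across ages at any grid point.  Zero means perfect
    collapse onto a single master curve.
    """
    if len(per_age_curves) < 2:
        raise ValueError("need at least two age curves to compare")
    regions = {c.region for c in per_age_curves}
    devices = {c.device for c in per_age_curves}
    if len(regions) > 1 or len(devices) > 1:
        raise ValueError("curves must share region and device")
    lo = max(c.stk.min() for c in per_age_curves)
    hi = min(c.stk.max() for c in per_age_curves)
    if lo >= hi:
        raise ValueError("curves have no overlapping Stk range")
    grid = np.geomspace(lo, hi, n_grid)
    interp = np.array([np.interp(grid, c.stk, c.efficiency)
                       for c in per_age_curves])
    return float(np.max(interp.max(axis=0) - interp.min(axis=0)))
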