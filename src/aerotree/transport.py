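"""Quasi-steady particle transport through the airway tree.

This module stands in for a full unsteady CFD + Lagrangian tracking
computation with a mechanistic surrogate: the instantaneous inhalation flow
is distributed through the tree with fixed lobar weighting, each particle
transits mouth -> outlet as a plug along a flow-weighted random path, and
deposition is decided segment-by-segment by Bernoulli trials with

* a sigmoidal Stokes-number filter for the lumped mouth-throat
  (inertial filtering by the oral cavity, pharynx and laryngeal jet),
* an exponential inertial-impaction closure at each bifurcation,
  P_I = 1 - exp(-k * theta * Stk_seg), and
* a tube gravitational-sedimentation closure,
  P_S = 1 - exp(-4 v_ts L cos(phi) / (pi d U)).

A closed-form companion (:func:`expected_deposition`) sums the same
probabilities over all 64 root-to-outlet paths and serves as the exact
oracle for the Monte-Carlo sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from aerotree.airway_model import AirwayTree, AirwaySegment, Lobe, Region, path_to_outlet
from aerotree.breathing import Device, InhalationProfile, ManeuverParams
from aerotree import physics

__all__ = [
    "ParticleSpec", "ParticleEnsemble", "MechanismParams", "FlowField",
    "DepositionResult", "LOBAR_FRACTIONS", "distribute_flow",
    "mouth_throat_efficiency", "impaction_probability",
    "sedimentation_probability", "sample_release_times",
    "simulate_deposition", "expected_deposition",
]

#: Physiological partition of inspiratory flow among the five lung lobes.
LOBAR_FRACTIONS: dict[Lobe, float] = {
    Lobe.LU: 0.15, Lobe.LL: 0.31, Lobe.RU: 0.14, Lobe.RM: 0.07, Lobe.RL: 0.33,
}

REGIONS = ("mouth_throat", "trachea", "conducting", "escaped")


@dataclass(frozen=True)
class ParticleSpec:
    """One spherical aerosol particle (diameter in m, density in kg/m^3)."""

    dp: float
    rho_p: float = 1000.0
    release_time: float = 0.0

    def __post_init__(self) -> None:
        if self.dp < 1.0e-6:
            raise ValueError(
                "dp must be >= 1 micron: Brownian motion is neglected by the "
                "default mechanism set")
        if self.rho_p <= 0:
            raise ValueError("particle density must be positive")


@dataclass(frozen=True)
class ParticleEnsemble:
    """A monodisperse ensemble with individual release times."""

    dp: float
    release_times: np.ndarray
    rho_p: float = 1000.0

    def __post_init__(self) -> None:
        ParticleSpec(self.dp, self.rho_p)  # reuse the validation

    @property
    def n(self) -> int:
        return len(self.release_times)


@dataclass(frozen=True)
class MechanismParams:
    """Physical constants and surrogate closure coefficients.

    ``mt_stk50``/``mt_slope`` shape the mouth-throat sigmoid (Stk at 50%
    capture and its sharpness); ``k_impact`` scales the per-bifurcation
    impaction probability.  All three are calibration knobs of the
    reduced-order model, not first-principles predictions.
    """

    mu_air: float = physics.AIR_VISCOSITY
    lambda_mfp: float = physics.MEAN_FREE_PATH
    g: float = physics.GRAVITY
    mt_stk50: float = 0.075
    mt_slope: float = 9.0
    k_impact: float = 6.0

    def __post_init__(self) -> None:
        if min(self.mu_air, self.lambda_mfp, self.g, self.mt_stk50,
               self.mt_slope, self.k_impact) <= 0:
            raise ValueError("all mechanism parameters must be positive")


@dataclass(frozen=True)
class FlowField:
    """Instantaneous flow split of the inlet waveform through the tree.

    ``fractions[i]`` is the (time-independent) fraction of the mouth-inlet
    flow carried by segment ``i``; the trachea carries 1 and outlet
    fractions sum to 1 per lobe weighting.
    """

    fractions: dict[int, float]
    lobar_fractions: dict[Lobe, float]
    profile: InhalationProfile | None = None


def distribute_flow(tree: AirwayTree,
                    lobar_fractions: Mapping[Lobe, float] | None = None,
                    profile: InhalationProfile | None = None) -> FlowField:
    """Flow-rate weighting: split the inlet flow among lobes, then equally
    among each lobe's outlets, and sum fractions back up the tree."""
    lobar = dict(LOBAR_FRACTIONS if lobar_fractions is None else lobar_fractions)
    total = sum(lobar.values())
    if abs(total - 1.0) > 1.0e-9:
        raise ValueError(f"lobar fractions must sum to 1, got {total}")
    counts: dict[Lobe, int] = tree.lobe_counts()
    missing = [l.value for l in lobar if counts.get(l, 0) == 0]
    if missing:
        raise ValueError(f"tree has no outlets for lobes: {missing}")

    fractions: dict[int, float] = {}

    def fill(seg: AirwaySegment) -> float:
        if seg.is_terminal:
            f = lobar[seg.lobe] / counts[seg.lobe]
        else:
            f = sum(fill(tree.segments[c]) for c in seg.child_ids)
        fractions[seg.id] = f
        return f

    fill(tree.mouth)
    return FlowField(fractions=fractions, lobar_fractions=lobar,
                     profile=profile)


def mouth_throat_efficiency(stk, params: MechanismParams = MechanismParams()):
    """Sigmoidal oral/laryngeal capture efficiency vs Stokes number.

    eta = Stk^s / (Stk^s + Stk50^s): zero at Stk=0, 1/2 at Stk50,
    saturating to 1 for strongly inertial particles.
    """
    stk = np.asarray(stk, dtype=float)
    if np.any(stk < 0):
        raise ValueError("Stokes number must be non-negative")
    x = (stk / params.mt_stk50) ** params.mt_slope
    eta = x / (1.0 + x)
    return float(eta) if eta.ndim == 0 else eta


def _segment_stokes(dp: float, rho_p: float, cc: float, velocity,
                    diameter, params: MechanismParams):
    return rho_p * dp * dp * cc * velocity / (18.0 * params.mu_air * diameter)


def impaction_probability(segment: AirwaySegment, local_velocity: float,
                          particle: ParticleSpec,
                          params: MechanismParams = MechanismParams()) -> float:
    """Inertial-impaction probability at a bifurcation entry.

    P_I = 1 - exp(-k * theta * Stk_seg) with the segment-scale Stokes
    number; zero for straight entry (theta = 0, i.e. the trachea).
    """
    if segment.branching_angle == 0.0:
        return 0.0
    cc = physics.slip_correction(particle.dp, params.lambda_mfp)
    stk = _segment_stokes(particle.dp, particle.rho_p, cc, local_velocity,
                          segment.diameter, params)
    return 1.0 - math.exp(-params.k_impact * segment.branching_angle * stk)


def sedimentation_probability(segment: AirwaySegment, local_velocity: float,
                              particle: ParticleSpec,
                              params: MechanismParams = MechanismParams()) -> float:
    """Gravitational-sedimentation probability for a quasi-steady tube transit.

    P_S = 1 - exp(-4 v_ts L cos(phi) / (pi d U)); vanishes for vertical
    tubes (cos(phi)=0) and in the fast-transit limit.
    """
    if local_velocity <= 0:
        raise ValueError("quasi-steady transit requires positive velocity")
    v_ts = physics.settling_velocity(particle.dp, particle.rho_p,
                                     params.mu_air, params.lambda_mfp, params.g)
    x = (4.0 * v_ts * segment.length * math.cos(segment.gravity_angle)
         / (math.pi * segment.diameter * local_velocity))
    return 1.0 - math.exp(-x)


def sample_release_times(params: ManeuverParams, profile: InhalationProfile,
                         n: int, seed) -> np.ndarray:
    """Release times per injection protocol.

    DPI: a short bolus, uniform over the PIFR plateau
    [t_peak, t_plateau_end].  Nebulizer: continuous injection at constant
    number rate over the whole inspiration [0, t_insp].
    """
    if n <= 0:
        raise ValueError("need at least one particle")
    rng = np.random.default_rng(seed)
    if params.device is Device.DPI:
        lo, hi = params.t_peak, params.t_plateau_end
    else:
        lo, hi = 0.0, params.t_insp
    return rng.uniform(lo, hi, size=n)


# ---------------------------------------------------------------------------
# results container

@dataclass(frozen=True)
class DepositionResult:
    """Regional deposition bookkeeping for one (age, device, dp) run."""

    age: float
    device: Device
    dp: float
    counts: dict[str, int]                 # keys: REGIONS + "injected"
    escaped_by_lobe: dict[Lobe, int]
    segment_deposits: dict[int, int]
    seed: object = None

    def __post_init__(self) -> None:
        total = sum(self.counts[r] for r in REGIONS)
        if total != self.counts["injected"]:
            raise ValueError("regional counts do not conserve the injected total")

    @property
    def efficiencies(self) -> dict[str, float]:
        n = self.counts["injected"]
        return {r: self.counts[r] / n for r in REGIONS}

    def efficiency(self, region: str) -> float:
        return self.counts[region] / self.counts["injected"]


class _TreeArrays:
    """Flat per-segment arrays for vectorized transport."""

    def __init__(self, tree: AirwayTree, flowfield: FlowField):
        n = max(tree.segments) + 1
        self.diameter = np.zeros(n)
        self.length = np.zeros(n)
        self.branching_angle = np.zeros(n)
        self.cos_gravity = np.zeros(n)
        self.fraction = np.zeros(n)
        # region codes: 0 mouth-throat, 1 trachea, 2 conducting
        self.region_code = np.zeros(n, dtype=np.int64)
        codes = {Region.MOUTH_THROAT: 0, Region.TRACHEA: 1, Region.CONDUCTING: 2}
        for s in tree.segments.values():
            self.diameter[s.id] = s.diameter
            self.length[s.id] = s.length
            self.branching_angle[s.id] = s.branching_angle
            self.cos_gravity[s.id] = math.cos(s.gravity_angle)
            self.fraction[s.id] = flowfield.fractions[s.id]
            self.region_code[s.id] = codes[s.region]
        self.area = math.pi * self.diameter ** 2 / 4.0
        outlets = tree.outlets
        self.outlet_ids = np.array([s.id for s in outlets])
        self.outlet_lobes = [s.lobe for s in outlets]
        self.outlet_p = self.fraction[self.outlet_ids]
        self.outlet_p = self.outlet_p / self.outlet_p.sum()
        self.paths = np.array(
            [[seg.id for seg in path_to_outlet(tree, s.id)] for s in outlets])


def simulate_deposition(tree: AirwayTree, flowfield: FlowField,
                        particles: ParticleEnsemble,
                        params: MechanismParams = MechanismParams(),
                        seed=0,
                        device: Device | None = None) -> DepositionResult:
    """Monte-Carlo transport of one monodisperse ensemble.

    Each particle samples a root-to-outlet path with probability equal to
    the outlet's flow fraction, then transits segment by segment: a
    Bernoulli capture trial at the mouth-throat (sigmoid at the
    instantaneous release-time Stokes number) and at every downstream
    segment (combined impaction + sedimentation), with arrival times
    advanced by the quasi-steady residence time L/U.  Particles still in
    flight when the inspiratory flow reaches zero are tallied as escaped.
    """
    if particles.n == 0:
        raise ValueError("empty particle ensemble")
    profile = flowfield.profile
    if profile is None:
        raise ValueError("flowfield must carry an inhalation profile")
    if not np.any(profile.flow > 0):
        raise ValueError("zero-flow inhalation profile")
    device = device or profile.params.device

    arrays = _TreeArrays(tree, flowfield)
    rng = np.random.default_rng(seed)
    n = particles.n
    dp, rho_p = particles.dp, particles.rho_p
    cc = physics.slip_correction(dp, params.lambda_mfp)
    v_ts = physics.settling_velocity(dp, rho_p, params.mu_air,
                                     params.lambda_mfp, params.g)
    mouth = tree.mouth
    mouth_area = tree.mouth_inlet_area

    t = np.asarray(particles.release_times, dtype=float).copy()
    alive = np.ones(n, dtype=bool)
    dep_segment = np.full(n, -1, dtype=np.int64)
    escaped_in_flight = np.zeros(n, dtype=bool)
    outlet_idx = rng.choice(len(arrays.outlet_ids), size=n, p=arrays.outlet_p)

    # --- mouth-throat: sigmoidal Stk filter at the release-time velocity
    q = np.asarray(profile.flow_at(t))
    stalled = alive & (q <= 0)
    escaped_in_flight |= stalled
    alive &= ~stalled
    u_mouth = np.where(q > 0, q / mouth_area, np.nan)
    stk = _segment_stokes(dp, rho_p, cc, u_mouth, mouth.diameter, params)
    eta = np.where(alive, mouth_throat_efficiency(np.nan_to_num(stk), params), 0.0)
    captured = alive & (rng.random(n) < eta)
    dep_segment[captured] = mouth.id
    alive &= ~captured
    t[alive] += mouth.length / u_mouth[alive]

    # --- trachea + 6 bronchial levels along each particle's sampled path
    for step in range(1, arrays.paths.shape[1]):
        if not alive.any():
            break
        seg = arrays.paths[outlet_idx, step]
        q = np.asarray(profile.flow_at(t))
        stalled = alive & (q <= 0)
        escaped_in_flight |= stalled
        alive &= ~stalled
        u = np.where(q > 0,
                     arrays.fraction[seg] * q / arrays.area[seg], np.nan)
        stk_seg = _segment_stokes(dp, rho_p, cc, u, arrays.diameter[seg], params)
        p_imp = -np.expm1(-params.k_impact * arrays.branching_angle[seg] * stk_seg)
        p_sed = -np.expm1(-4.0 * v_ts * arrays.length[seg]
                          * arrays.cos_gravity[seg]
                          / (math.pi * arrays.diameter[seg] * u))
        p = 1.0 - (1.0 - p_imp) * (1.0 - p_sed)
        captured = alive & (rng.random(n) < np.nan_to_num(p))
        dep_segment[captured] = seg[captured]
        alive &= ~captured
        t[alive] += (arrays.length[seg] / u)[alive]

    # --- bookkeeping
    counts = {r: 0 for r in REGIONS}
    counts["injected"] = n
    deposited = dep_segment >= 0
    region_hits = np.bincount(arrays.region_code[dep_segment[deposited]],
                              minlength=3)
    counts["mouth_throat"] = int(region_hits[0])
    counts["trachea"] = int(region_hits[1])
    counts["conducting"] = int(region_hits[2])
    escaped = alive | escaped_in_flight
    counts["escaped"] = int(escaped.sum())

    lobe_hits = np.bincount(outlet_idx[escaped],
                            minlength=len(arrays.outlet_lobes))
    escaped_by_lobe: dict[Lobe, int] = {}
    for i, c in enumerate(lobe_hits):
        if c:
            lobe = arrays.outlet_lobes[i]
            escaped_by_lobe[lobe] = escaped_by_lobe.get(lobe, 0) + int(c)

    seg_counts = np.bincount(dep_segment[deposited],
                             minlength=max(tree.segments) + 1)
    segment_deposits = {int(i): int(c) for i, c in enumerate(seg_counts) if c}

    return DepositionResult(
        age=tree.age_label, device=device, dp=dp, counts=counts,
        escaped_by_lobe=escaped_by_lobe, segment_deposits=segment_deposits,
        seed=seed)


def expected_deposition(tree: AirwayTree, flowfield: FlowField,
                        particle: ParticleSpec,
                        params: MechanismParams = MechanismParams()
                        ) -> dict[str, float]:
    """Exact expected regional probabilities for one release time.

    Sums P(path) * (per-segment deposit/survive products) over all 64
    root-to-outlet paths with deterministic quasi-steady arrival times —
    the closed-form oracle for :func:`simulate_deposition`.
    """
    profile = flowfield.profile
    if profile is None:
        raise ValueError("flowfield must carry an inhalation profile")
    probs = {r: 0.0 for r in REGIONS}
    cc = physics.slip_correction(particle.dp, params.lambda_mfp)
    mouth = tree.mouth
    mouth_area = tree.mouth_inlet_area

    t0 = particle.release_time
    q0 = float(profile.flow_at(t0))
    if q0 <= 0:
        return {**probs, "escaped": 1.0}
    u_mouth = q0 / mouth_area
    stk = _segment_stokes(particle.dp, particle.rho_p, cc, u_mouth,
                          mouth.diameter, params)
    eta = float(mouth_throat_efficiency(stk, params))
    probs["mouth_throat"] = eta
    surv0 = 1.0 - eta
    t_after_mouth = t0 + mouth.length / u_mouth

    counts = tree.lobe_counts()
    for outlet in tree.outlets:
        p_path = flowfield.lobar_fractions[outlet.lobe] / counts[outlet.lobe]
        s = surv0
        t = t_after_mouth
        for seg in path_to_outlet(tree, outlet.id)[1:]:
            q = float(profile.flow_at(t))
            if q <= 0:
                break  # stalled in flight: remaining probability escapes
            u = flowfield.fractions[seg.id] * q / (math.pi * seg.diameter ** 2 / 4)
            p_imp = impaction_probability(seg, u, particle, params)
            p_sed = sedimentation_probability(seg, u, particle, params)
            p = 1.0 - (1.0 - p_imp) * (1.0 - p_sed)
            key = ("trachea" if seg.region is Region.TRACHEA else "conducting")
            probs[key] += p_path * s * p
            s *= 1.0 - p
            t += seg.length / u
        probs["escaped"] += p_path * s
    return probs
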