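# Methods

## Scope and intent

`aerotree` estimates regional deposition of inhaled micron-sized aerosols
(mouth-throat, trachea, conducting airways, or escape into the deeper lung)
in an idealized upper-airway geometry representative of ages 5, 10 and 25
years, under dry-powder-inhaler (DPI) and nebulizer breathing maneuvers.
It is a *reduced-order surrogate*: the unsteady three-dimensional airflow
(turbulence, laryngeal jet, secondary flows) is not resolved. Instead, the
model exploits the empirical observation that upper-airway deposition
organizes on the mouth-inlet Stokes number, and represents each deposition
mechanism by a bounded per-segment probability closure. The package's
outputs are therefore trend- and scaling-faithful (how deposition shifts
with age, device, and particle size) rather than pointwise CFD
replacements.

## Airway geometry

The tree is a lumped mouth-throat compartment feeding a trachea and six
dichotomous bifurcation levels (64 terminal outlets). Anchor dimensions at
adult scale: mouth hydraulic diameter 19 mm, trachea 16 mm, main bronchi
10.8 mm. Children's anatomy is produced by homothetic scaling — every
length and diameter multiplied by 0.578 (5 y) or 0.743 (10 y), factors
chosen to match tracheal-diameter growth. Scaling is exact by
construction: any length-dimension-n quantity transforms as factor^n, which
the property tests verify.

Distal morphometry (levels 2–6) is not anchored to measurements anywhere;
defaults are a Weibel-like taper with mild asymmetry (major child/parent
diameter ratio 0.86, minor 0.72, the major side alternating
deterministically), L/d = 3 for conducting segments, trachea length
6.25 × diameter, mouth-throat path length 0.17 m, branching angle 35° at
every bifurcation. Orientation relative to gravity is a deterministic rule:
trachea vertical, conducting levels alternating 20°/50° from horizontal by
level parity. These are knobs (all exposed through `TreeConfig` and the
`geometry:` YAML block), not anatomical claims; they produce a physiologic
taper and reproducible runs.

The 64 outlets are partitioned into the five lung lobes by contiguous
blocks within each main-bronchus subtree, defaults
RU 10 / RM 6 / RL 16 / LU 12 / LL 20. Only the *flow* split per lobe is
physiologically anchored; the outlet counts are a modelling choice and
configurable.

One representational note: the mouth-throat compartment has a single child
(the trachea) — the dichotomy constraint applies from the trachea down.

## Breathing maneuvers

Tabulated per age: tidal volume VT, peak inspiratory flow rate PIFR, and
inspiration time t_insp (DPI: 0.89 l / 40 l·min⁻¹ / 2 s at 5 y,
1.33 / 60 / 2 at 10 y, 2.95 / 90 / 3 at 25 y; nebulizer:
0.108 / 8.14 / 1.25, 0.168 / 10 / 1.58, 0.5 / 22 / 2.14).

* **Nebulizer**: Q(t) = PIFR · sin(π t / t_insp). The closed-form volume
  (2/π) · PIFR · t_insp matches the tabulated VT within 0.3% for all three
  ages; if a user supplies inconsistent parameters (>2% mismatch) the
  generator warns and the integral wins.
* **DPI**: quarter-sine rise to PIFR at t_peak = 0.45 s, plateau at PIFR to
  t_plateau_end = 0.6 s, then Q(t) = PIFR · cos^γ(·) decaying to zero at
  t_insp. The reference device waveform's decay shape is not published in a
  reusable form, so the decay is a surrogate: γ is solved by bisection
  (volume tolerance 10⁻⁶ relative, using the exact Beta-function expression
  for the cos^γ mean) so the waveform integrates exactly to VT. A plain
  cosine (γ = 1) already closes the volume budget to ~1% for all three
  ages, so γ stays near unity; infeasible (VT, PIFR, t_insp) combinations
  raise an explicit error.

Waveforms are sampled at dt = 10⁻³ s; halving dt moves integrals by
< 0.1%.

The characteristic velocity U_m entering the Stokes number follows the
release protocol: for DPI it is the mean inlet velocity over the PIFR
plateau (equal to PIFR/A since the plateau is flat), for nebulizers the
mean inhalation velocity VT/(t_insp · A), with A = π D_h²/4 the
circular-equivalent mouth-inlet area.

## Transport surrogate

The instantaneous inlet flow Q(t) is distributed through the tree with
fixed fractions: each lobe receives its physiological share
(LU 15 / LL 31 / RU 14 / RM 7 / RL 33 %), divided equally among that
lobe's outlets and summed back up the junctions (conservation is exact and
tested). Segment velocity is quasi-steady plug flow,
U_seg(t) = fraction · Q(t) / (π d²/4).

Each particle samples a root-to-outlet path with probability equal to the
outlet's flow fraction, then transits segment by segment; arrival times
advance by the residence L/U. Deposition is decided by Bernoulli trials:

* **Mouth-throat**: η_MT(Stk) = Stk^s / (Stk^s + Stk50^s) with s = 9 and
  Stk50 = 0.075, evaluated at the instantaneous release-time inlet
  velocity. The lumped sigmoid stands in for oral impaction and the
  laryngeal jet; the constants are calibrated so η_MT(0.06) ≈ 0.12 and
  η_MT(0.1) ≈ 0.93, consistent with near-total filtering beyond
  Stk ≈ 0.1 while leaving most of the conducting-peak window untouched.
  They are calibration knobs, not predictions.
* **Impaction** at each bifurcation: P_I = 1 − exp(−k θ Stk_seg), with
  θ the branching angle, Stk_seg the segment-scale Stokes number
  (ρ_p d_p² C_c U_seg / 18 μ d_seg) and k = 6 a single tuned constant
  that places an interior conducting-airway maximum in the observed Stk
  window. P_I = 0 for straight entry (trachea).
* **Sedimentation**: P_S = 1 − exp(−4 v_ts L cos φ / (π d U)), the
  standard quasi-steady tube closure with terminal settling velocity
  v_ts = ρ_p d_p² g C_c / 18μ; zero for vertical tubes.

The two mechanisms combine independently,
P = 1 − (1 − P_I)(1 − P_S). Particles reaching an outlet escape (tallied
per lobe); particles still in flight when Q(t) reaches zero are also
counted as escaped, since exhalation is outside the model.

Release protocols: DPI particles are released uniformly over the PIFR
plateau (a short 0.15 s bolus); nebulizer particles uniformly (constant
number rate) over the whole inspiration. A flow-proportional nebulizer
release would be an alternative reading of "continuous injection"; the
constant-rate choice is the default because the device aerosolizes at a
fixed rate independent of the breath.

**Oracle.** `expected_deposition` computes the exact expected regional
probabilities for a single release time by summing, over all 64 paths,
P(path) × the product of per-segment deposit/survive factors with the same
deterministic arrival-time recursion. The Monte-Carlo sampler is tested
against it at n = 10³–10⁵ (agreement within 4 binomial standard errors),
which pins the sampler to the model's closed form rather than to itself.

Default ensemble sizes follow the study protocol: 28,500 particles per
size, sizes 1–12 µm (DPI) or 1–20 µm (nebulizer) in 1 µm steps, particle
density 1000 kg/m³, spherical, one-way coupled; Brownian motion is
neglected (enforced d_p ≥ 1 µm), as are hygroscopic growth and
electrostatics. At these counts the binomial standard error of any
regional efficiency is ≤ 0.3 percentage points and the observed
run-to-run spread across seeds is ≈ 0.5–0.7 pp.

## Dimensionless analysis

Air properties (not tied to a stated temperature anywhere): dynamic
viscosity μ = 1.81·10⁻⁵ Pa·s, kinematic viscosity ν = 1.5·10⁻⁵ m²/s, mean
free path λ = 0.066 µm. The Cunningham slip correction uses the standard
form C_c = 1 + Kn(1.257 + 0.4 e^(−1.1/Kn)), Kn = 2λ/d_p.

Efficiency curves pool all ages for one device on the Stk axis. The
conducting-airway curve is fitted with an unweighted Gaussian
A·exp(−(Stk−Stk*)²/2σ*²) in linear Stk (initialization: A = max η,
Stk* = argmax, σ* = half the Stk IQR; fit quality reported as RMSE; the
amplitude is clipped into (0, 1] after the unconstrained fit). Curves
whose maximum sits at the boundary of the sampled range (the monotone
mouth-throat sigmoid) raise a "no interior peak" error instead of a
meaningless fit. Optimal diameters invert
Stk* = ρ_p d_p² U_m C_c(d_p)/(18 μ D_o) per age by fixed-point iteration
on C_c (tolerance 10⁻⁴ relative; converges in a handful of steps for
d_p > 1 µm).

Collapse is quantified two ways. `collapse_diagnostic` interpolates
per-age curves onto a common Stk grid and reports the worst across-age
spread; on the integer-µm sampling grid this includes linear-interpolation
bias, which is visible (~7 pp) for the steep mouth-throat sigmoid even
though the underlying filter is a pure function of Stk. The sharper test
therefore compares ages *at matched Stk* — inverting d_p per age so all
three simulate the same abscissa — where the DPI mouth-throat efficiencies
agree to Monte-Carlo noise (≪ 5 pp), because the DPI release window sits
on the constant-PIFR plateau.

## What the synthetic conditions do and do not show

The geometry/waveform generators *are* the study conditions: idealized
scaled anatomy, representative maneuvers, protocol ensemble sizes. Passing
tests demonstrate internal consistency (conservation, oracle equivalence,
determinism, scale similarity) and the mechanism-level orderings the
surrogate was built to reproduce: a monotone mouth-throat sigmoid
saturating beyond Stk ≈ 0.1; interior conducting-airway peaks for both
devices with the DPI peak at higher Stk and higher amplitude than the
nebulizer peak; optimal diameters increasing with age and smaller for DPI
than for nebulizer at fixed age. They do not validate the surrogate
against real airways: the absolute peak amplitudes and widths inherit the
closure calibration (the default constants put the fitted DPI conducting
peak near Stk* ≈ 0.044 with amplitude ≈ 0.99, higher and slightly left of
cluster-scale CFD values), secondary-flow and turbulence effects are
lumped, intersubject anatomical variation is absent, and nothing below
generation 7 is modelled.

## Numerical and reproducibility choices

* One master seed per scenario; per-size streams derived as
  `SeedSequence([seed, size_nm])`, so adding a size never perturbs the
  others. Release-time and transport draws use separate spawned streams.
* Identical config + seed reproduce byte-identical output files; every
  output records the seed and a SHA-256 config hash.
* Default problem sizes (28,500 particles/size; oracle comparisons at
  10⁵; three seeds for repeatability) run a full six-scenario study in a
  few seconds on one core.
* Degenerate inputs fail loudly: empty ensembles, zero-flow profiles,
  non-positive scale factors, infeasible DPI volume budgets, lobar
  fractions not summing to 1, untabulated ages (no interpolation between
  age points in this version).

## Known limitations

* Deposition closures are calibrated, not predictive; absolute
  efficiencies should be read as model output under stated calibration.
* The trachea deposits almost nothing in the surrogate (straight vertical
  tube: no impaction by construction, no sedimentation when vertical);
  real tracheal deposition driven by the laryngeal jet is folded into the
  mouth-throat filter.
* Quasi-steady plug transit ignores velocity profiles, secondary flows
  and turbulent dispersion; residence times are L/U at arrival.
* The tabulated trachea diameters (9, 11.6 mm) differ slightly from
  factor × 16 mm (9.25, 11.9 mm) because the scale factors were fitted to
  external growth data; the factors are treated as authoritative.
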