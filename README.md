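# aerotree

Reduced-order modelling of inhaled aerosol deposition in age-scaled upper
airways, for researchers in respiratory drug delivery who want fast,
reproducible estimates of where micron-sized particles land — mouth-throat,
trachea, or conducting airways — as a function of patient age (5, 10, 25
years) and delivery device (dry powder inhaler vs. nebulizer).

## What it computes

The package replaces a full CFD + Lagrangian-tracking computation with a
mechanistic quasi-steady surrogate built from four pieces:

1. **Airway geometry** — a procedurally generated idealized tree: a lumped
   mouth-throat compartment (hydraulic diameter 19 mm in the adult) feeding
   a trachea (16 mm) and six dichotomous, mildly asymmetric bronchial
   levels ending in 64 lobe-labelled outlets. Pediatric anatomy is obtained
   by homothetic scaling (factors 0.578 at 5 y and 0.743 at 10 y, chosen to
   match tracheal diameter growth).
2. **Breathing maneuvers** — half-sine tidal waveforms for nebulizer use
   and rapid-rise/plateau/volume-constrained-decay waveforms for DPI use,
   parameterized per age by tidal volume, peak inspiratory flow rate (PIFR)
   and inspiration time.
3. **Particle transport** — Monte-Carlo ensembles (28,500 particles per
   size; 1–12 µm for DPI, 1–20 µm for nebulizer) routed along flow-weighted
   paths (lobar split LU 15 / LL 31 / RU 14 / RM 7 / RL 33 %), with
   Bernoulli deposition trials per segment: a sigmoidal Stokes-number
   filter in the mouth-throat, `P_I = 1 − exp(−k θ Stk_seg)` for inertial
   impaction at bifurcations, and
   `P_S = 1 − exp(−4 v_ts L cos φ / (π d U))` for gravitational
   sedimentation. A closed-form path-sum oracle validates the sampler.
4. **Stokes-number analysis** — regional efficiencies collapse across ages
   when plotted against

   ```
   Stk = ρ_p d_p² U_m C_c / (18 μ D_o)
   ```

   (ρ_p particle density, d_p diameter, C_c Cunningham slip correction,
   μ air viscosity, D_o mouth hydraulic diameter, U_m the device-specific
   characteristic velocity). The conducting-airway master curve has an
   interior Gaussian-like peak; fitting it and inverting Stk at the peak
   yields the optimal aerosol diameter per age and device.

## Worked example

```python
import aerotree as at
from aerotree.runner import RunConfig, run_scenario, run_analysis

scenarios = {}
for age in (5, 10, 25):
    cfg = RunConfig(age=age, device=at.Device.DPI, n_per_size=28_500, seed=1)
    scenarios[age] = run_scenario(cfg)

r5 = scenarios[5]
print(f"age-5 DPI: Um = {r5.context.um:.2f} m/s, Do = {r5.context.do*1e3:.1f} mm")
for r in r5.results[3:8]:
    stk = at.stokes_number(r.dp, r5.context)
    print(f"  dp = {r.dp*1e6:4.1f} um  Stk = {stk:.3f}  "
          f"mouth-throat = {r.efficiency('mouth_throat'):.3f}  "
          f"conducting = {r.efficiency('conducting'):.3f}")

summary = run_analysis([r for s in scenarios.values() for r in s.results],
                       {a: s.context for a, s in scenarios.items()})
g = summary["gaussian_fit"]
print(f"conducting-airway peak: A = {g['amplitude']:.2f} at Stk* = {g['peak_stk']:.3f}")
for o in summary["optimal_sizes"]:
    print(f"  age {o['age_yr']:4.0f} y: dp_opt = {o['dp_opt_um']:.1f} "
          f"+/- {o['dp_spread_um']:.1f} um")
```

prints

```
age-5 DPI: Um = 7.04 m/s, Do = 11.0 mm
  dp =  4.0 um  Stk = 0.033  mouth-throat = 0.001  conducting = 0.873
  dp =  5.0 um  Stk = 0.051  mouth-throat = 0.031  conducting = 0.921
  dp =  6.0 um  Stk = 0.073  mouth-throat = 0.434  conducting = 0.555
  dp =  7.0 um  Stk = 0.099  mouth-throat = 0.922  conducting = 0.078
  dp =  8.0 um  Stk = 0.129  mouth-throat = 0.992  conducting = 0.008
conducting-airway peak: A = 0.99 at Stk* = 0.044
  age    5 y: dp_opt = 4.6 +/- 1.5 um
  age   10 y: dp_opt = 5.5 +/- 1.7 um
  age   25 y: dp_opt = 7.1 +/- 2.2 um
```

Reading: at age 5 under DPI inhalation, particles around 4–5 µm deposit
overwhelmingly in the conducting airways, while by 7 µm the mouth-throat
filter captures >90% before they get there. The optimal size for
conducting-airway delivery shrinks from ~7 µm in the adult to ~4.6 µm in
the 5-year-old — smaller children need smaller particles.

The same workflow is scriptable from a shell:

```bash
aerotree run --age 5 --device dpi --seed 1 --out runs/dpi5
aerotree run --age 10 --device dpi --seed 1 --out runs/dpi10
aerotree run --age 25 --device dpi --seed 1 --out runs/dpi25
aerotree analyze --device dpi runs/dpi5 runs/dpi10 runs/dpi25
aerotree geometry --age 5 --out tree5.csv
aerotree waveform --age 10 --device neb --out wave10.csv
```

## Layout

| Path | Contents |
|---|---|
| `src/aerotree/airway_model.py` | procedural tree builder, homothetic scaling, segment-table I/O |
| `src/aerotree/breathing.py` | DPI and nebulizer waveform generators, characteristic velocities |
| `src/aerotree/transport.py` | lobar flow split, deposition closures, Monte-Carlo sampler + oracle |
| `src/aerotree/analysis.py` | Stokes/Reynolds numbers, master curves, Gaussian peak, optimal size |
| `src/aerotree/runner.py`, `cli.py` | scenario orchestration, YAML config, `aerotree` CLI |
| `docs/methods.md` | model description, assumptions, calibration and limitations |
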