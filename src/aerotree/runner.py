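"""Scenario orchestration, configuration and reproducible outputs.

A *scenario* is one (age, device) pair: build the scaled tree, generate the
maneuver waveform, distribute flow through the tree, then run the
Monte-Carlo transport for every particle size in the protocol (1-12 um for
DPI, 1-20 um for nebulizer, ~28,500 particles per size).  The analysis
stage pools >= 2 age points per device into master curves, fits the
conducting-airway Gaussian peak and inverts it into per-age optimal sizes.

Reproducibility: one master seed per run; per-size sub-streams are derived
with ``SeedSequence([master_seed, size_in_nm])`` so adding or removing a
size never perturbs the others.  Every output records the seed and a hash
of the full configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from aerotree.airway_model import AirwayTree, Lobe, TreeConfig, build_tree
from aerotree.analysis import (
    EfficiencyCurve, GaussianFit, NoInteriorPeakError, StokesContext,
    collapse_diagnostic, efficiency_curve, fit_gaussian, make_context,
    optimal_sizes, stokes_number,
)
from aerotree.breathing import (
    Device, InhalationProfile, ManeuverParams, build_profile,
    maneuver_defaults,
)
from aerotree.transport import (
    REGIONS, DepositionResult, FlowField, MechanismParams, ParticleEnsemble,
    distribute_flow, sample_release_times, simulate_deposition,
)

__all__ = ["RunConfig", "ScenarioOutput", "run_scenario", "run_analysis",
           "load_scenario_dir", "load_run_config", "default_sizes_um"]

DEFAULT_N_PER_SIZE = 28500


def default_sizes_um(device: Device) -> list[float]:
    """Protocol particle-size grids: 1-12 um (DPI) or 1-20 um (nebulizer)."""
    top = 12 if device is Device.DPI else 20
    return [float(d) for d in range(1, top + 1)]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one scenario."""

    age: float
    device: Device
    sizes_um: tuple[float, ...] = ()
    n_per_size: int = DEFAULT_N_PER_SIZE
    seed: int = 0
    dt: float = 1.0e-3
    tree_config: TreeConfig = field(default_factory=TreeConfig)
    maneuver: ManeuverParams | None = None
    mechanisms: MechanismParams = field(default_factory=MechanismParams)

    def __post_init__(self) -> None:
        self.device  # Device(...) coercion happens in load_run_config
        if not self.sizes_um:
            object.__setattr__(self, "sizes_um",
                               tuple(default_sizes_um(self.device)))
        if any(s <= 0 for s in self.sizes_um):
            raise ValueError("particle sizes must be positive")
        if self.n_per_size <= 0:
            raise ValueError("n_per_size must be positive")

    def resolved_maneuver(self) -> ManeuverParams:
        return self.maneuver or maneuver_defaults(self.age, self.device)

    def hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in sorted(
                    obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (Device, Lobe)):
                return obj.value
            return obj

        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class ScenarioOutput:
    config: RunConfig
    tree: AirwayTree
    profile: InhalationProfile
    flowfield: FlowField
    context: StokesContext
    results: list[DepositionResult]

    @property
    def total_injected(self) -> int:
        return sum(r.counts["injected"] for r in self.results)


def _size_seeds(master_seed: int, size_um: float):
    """Counter-based per-size streams keyed by the size in nanometers."""
    ss = np.random.SeedSequence([int(master_seed), int(round(size_um * 1000))])
    return ss.spawn(2)  # (release-time stream, transport stream)


def run_scenario(config: RunConfig,
                 output_dir: str | Path | None = None) -> ScenarioOutput:
    """Simulate every particle size of one (age, device) scenario.

    When ``output_dir`` is given, writes ``deposition.csv`` (regional
    counts/efficiencies per size), ``segment_deposits.csv`` (per-segment
    hit counts) and ``summary.json`` (full bookkeeping incl. seed and
    config hash).  Identical config + seed produce byte-identical files.
    """
    maneuver = config.resolved_maneuver()
    tree = build_tree(config.age, config.tree_config)
    profile = build_profile(maneuver, config.dt)
    flowfield = distribute_flow(tree, profile=profile)
    ctx = make_context(tree, maneuver)

    results: list[DepositionResult] = []
    for size_um in config.sizes_um:
        dp = size_um * 1.0e-6
        release_ss, transport_ss = _size_seeds(config.seed, size_um)
        release = sample_release_times(maneuver, profile, config.n_per_size,
                                       release_ss)
        ensemble = ParticleEnsemble(dp=dp, release_times=release)
        results.append(simulate_deposition(
            tree, flowfield, ensemble, config.mechanisms, seed=transport_ss,
            device=config.device))

    out = ScenarioOutput(config=config, tree=tree, profile=profile,
                         flowfield=flowfield, context=ctx, results=results)
    if output_dir is not None:
        write_scenario(out, output_dir)
    return out


def write_scenario(out: ScenarioOutput, output_dir: str | Path) -> None:
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    cfg = out.config

    rows = []
    for r in out.results:
        stk = float(stokes_number(r.dp, out.context))
        for region in REGIONS:
            rows.append(dict(
                age_yr=cfg.age, device=cfg.device.value, dp_um=r.dp * 1e6,
                stk=stk, region=region, count=r.counts[region],
                efficiency=r.efficiency(region), seed=cfg.seed))
    pd.DataFrame(rows).to_csv(output_dir / "deposition.csv", index=False)

    seg_rows = [dict(segment_id=sid, dp_um=r.dp * 1e6, count=c)
                for r in out.results
                for sid, c in sorted(r.segment_deposits.items())]
    pd.DataFrame(seg_rows, columns=["segment_id", "dp_um", "count"]).to_csv(
        output_dir / "segment_deposits.csv", index=False)

    summary = {
        "age_yr": cfg.age,
        "device": cfg.device.value,
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
        "n_per_size": cfg.n_per_size,
        "sizes_um": list(cfg.sizes_um),
        "total_injected": out.total_injected,
        "context": {"um_m_per_s": out.context.um, "do_m": out.context.do,
                    "rho_p": out.context.rho_p, "mu": out.context.mu},
        "results": [
            {
                "dp_um": r.dp * 1e6,
                "stk": float(stokes_number(r.dp, out.context)),
                "counts": r.counts,
                "escaped_by_lobe": {l.value: c
                                    for l, c in sorted(r.escaped_by_lobe.items(),
                                                       key=lambda kv: kv[0].value)},
            }
            for r in out.results
        ],
    }
    (output_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")


def load_scenario_dir(path: str | Path
                      ) -> tuple[list[DepositionResult], StokesContext]:
    """Rebuild deposition results + Stokes context from a scenario directory."""
    summary = json.loads((Path(path) / "summary.json").read_text())
    device = Device(summary["device"])
    age = float(summary["age_yr"])
    ctx = StokesContext(um=summary["context"]["um_m_per_s"],
                        do=summary["context"]["do_m"],
                        rho_p=summary["context"]["rho_p"],
                        mu=summary["context"]["mu"],
                        age=age, device=device)
    results = []
    for rec in summary["results"]:
        results.append(DepositionResult(
            age=age, device=device, dp=rec["dp_um"] * 1e-6,
            counts={k: int(v) for k, v in rec["counts"].items()},
            escaped_by_lobe={Lobe(k): int(v)
                             for k, v in rec["escaped_by_lobe"].items()},
            segment_deposits={}, seed=summary["seed"]))
    return results, ctx


def run_analysis(results: Sequence[DepositionResult],
                 contexts: dict[float, StokesContext]) -> dict:
    """Pooled master-curve analysis for one device across >= 2 age points.

    Returns a JSON-ready summary: pooled curves per region, the
    conducting-airway Gaussian fit (or the reason it was not possible),
    per-age optimal diameters and the across-age collapse diagnostics.
    """
    ages = sorted({r.age for r in results})
    if len(ages) < 2:
        raise ValueError("analysis needs results for at least two age points")
    devices = {r.device for r in results}
    if len(devices) != 1:
        raise ValueError(f"analysis requires a single device, got {devices}")
    device = devices.pop()

    summary: dict = {"device": device.value, "ages_yr": ages}
    curves = {region: efficiency_curve(list(results), region, contexts)
              for region in ("total", "conducting", "mouth_throat")
              if region != "total"}
    # total = 1 - escaped
    total_results = results
    curves["total"] = _total_curve(total_results, contexts)

    summary["curves"] = {
        region: {"stk": c.stk.tolist(), "efficiency": c.efficiency.tolist(),
                 "dp_um": (c.dp * 1e6).tolist(), "age_yr": c.age.tolist()}
        for region, c in curves.items()
    }

    try:
        fit = fit_gaussian(curves["conducting"])
        ctx_by_age = [contexts[a] for a in ages]
        opts = optimal_sizes(fit, ctx_by_age)
        summary["gaussian_fit"] = {
            "amplitude": fit.amplitude, "peak_stk": fit.peak_stk,
            "sigma_stk": fit.sigma_stk, "rmse": fit.rmse}
        summary["optimal_sizes"] = [
            {"age_yr": o.age, "dp_opt_um": o.dp_opt * 1e6,
             "dp_spread_um": o.dp_spread * 1e6}
            for o in opts]
    except NoInteriorPeakError as err:
        summary["gaussian_fit"] = None
        summary["gaussian_fit_error"] = str(err)

    summary["collapse"] = {}
    for region, pooled in curves.items():
        per_age = []
        for a in ages:
            mask = pooled.age == a
            per_age.append(EfficiencyCurve(
                stk=pooled.stk[mask], efficiency=pooled.efficiency[mask],
                dp=pooled.dp[mask], age=pooled.age[mask],
                region=pooled.region, device=pooled.device))
        summary["collapse"][region] = collapse_diagnostic(per_age)
    return summary


def _total_curve(results: Sequence[DepositionResult],
                 contexts: dict[float, StokesContext]) -> EfficiencyCurve:
    rows = []
    for r in results:
        stk = float(stokes_number(r.dp, contexts[r.age]))
        rows.append((stk, 1.0 - r.efficiency("escaped"), r.dp, r.age))
    rows.sort()
    stk, eff, dp, age = (np.array(x) for x in zip(*rows))
    device = results[0].device
    return EfficiencyCurve(stk=stk, efficiency=eff, dp=dp, age=age,
                           region="total", device=device)


# ---------------------------------------------------------------------------
# YAML configuration

def parse_device(value: str | Device) -> Device:
    if isinstance(value, Device):
        return value
    name = str(value).strip().upper()
    if name in ("NEB", "NEBULIZER"):
        return Device.NEBULIZER
    if name == "DPI":
        return Device.DPI
    raise ValueError(f"unknown device {value!r} (expected 'dpi' or 'neb')")


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file with blocks
    ``geometry`` / ``maneuver`` / ``mechanisms`` / ``run``."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    run = {**raw.get("run", {}), **overrides}
    geometry = raw.get("geometry", {})
    if "lobe_counts" in geometry:
        geometry["lobe_counts"] = {Lobe(k): int(v)
                                   for k, v in geometry["lobe_counts"].items()}
    mechanisms = raw.get("mechanisms", {})

    age = float(run.pop("age"))
    device = parse_device(run.pop("device"))
    maneuver_over = raw.get("maneuver", {})
    maneuver = None
    if maneuver_over:
        base = maneuver_defaults(age, device)
        maneuver = dataclasses.replace(base, **maneuver_over)
    return RunConfig(
        age=age, device=device,
        sizes_um=tuple(run.pop("sizes_um", ())),
        n_per_size=int(run.pop("n_per_size", DEFAULT_N_PER_SIZE)),
        seed=int(run.pop("seed", 0)),
        dt=float(run.pop("dt", 1.0e-3)),
        tree_config=TreeConfig(**geometry),
        maneuver=maneuver,
        mechanisms=MechanismParams(**mechanisms),
    )
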