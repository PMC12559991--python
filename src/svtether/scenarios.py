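"""Named experimental conditions and batch execution.

A :class:`Scenario` fully determines one simulated condition: copy numbers
(knockouts are pure copy-number removals, ``n_total = 0``), rate constants,
the SNARE height interval (for tether-elongation experiments), the
membrane-repulsion toggle and the simulation settings.  The builtin
catalogue covers the control model, single and double tether removals,
SNARE elongations, single-species models, the no-tether control and the
realistic-stoichiometry variants (35/9/7 copies, with and without the
mean-preserving rate compensation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import occupancy_histogram, summarize
from .dynamics import SimConfig, run_replicates
from .errors import ConfigError
from .model import DockingModel
from .presets import MOBILITY_RATE, default_specs

__all__ = ["Scenario", "builtin_scenarios", "load_scenario", "build_model",
           "run_scenario", "sensitivity_sweep"]


@dataclass(frozen=True)
class Scenario:
    """One fully resolved experimental condition."""

    name: str
    description: str = ""
    n_total: tuple[int, int, int] = (9, 9, 9)
    kon_max: tuple[float, float, float] = (40.0, 40.0, 40.0)
    koff: tuple[float, float, float] = (50.0, 100.0, 100.0)
    snare_height: tuple[float, float] = (2.0, 8.0)
    energetics_enabled: bool = True
    mobility_rate: float = MOBILITY_RATE
    d_start: float = 100.0
    d_max: float = 100.0
    t_end: float = 50.0
    n_reps: int = 100


def builtin_scenarios() -> dict[str, Scenario]:
    """Catalogue of the named conditions studied with this model."""
    c = Scenario("control", "nine copies of each tether species")
    scenarios = [
        c,
        replace(c, name="snare_ko", n_total=(0, 9, 9),
                description="SNARE complex removed"),
        replace(c, name="munc13_ko", n_total=(9, 0, 9),
                description="Munc13 tethers removed"),
        replace(c, name="munc13_snare_ko", n_total=(0, 0, 9),
                description="Munc13 and SNARE tethers removed"),
        replace(c, name="syt_ko", n_total=(9, 9, 0),
                description="Syt tethers removed"),
        replace(c, name="snare_ext5", snare_height=(7.0, 13.0),
                description="SNARE tether elongated by 5 nm"),
        replace(c, name="snare_ext10", snare_height=(12.0, 18.0),
                description="SNARE tether elongated by 10 nm"),
        replace(c, name="snare_only_9", n_total=(9, 0, 0),
                description="nine SNAREs, no other tethers"),
        replace(c, name="snare_only_27", n_total=(27, 0, 0),
                description="27 SNAREs, no other tethers"),
        replace(c, name="syt_only_9", n_total=(0, 0, 9),
                description="nine Syts, no other tethers"),
        replace(c, name="syt_only_27", n_total=(0, 0, 27),
                description="27 Syts, no other tethers"),
        replace(c, name="no_tethers", n_total=(0, 0, 0),
                description="no tethers; membrane repulsion only"),
        replace(c, name="realistic_stoichiometry", n_total=(35, 9, 7),
                description="35 SNAREs / 9 Munc13 / 7 Syts, base rates"),
        # Rate constants of the rescaled variant are the published rounded
        # values; see the rescaling module for the exact transform.
        replace(c, name="realistic_stoichiometry_rescaled", n_total=(35, 9, 7),
                kon_max=(10.3, 40.0, 51.4), koff=(76.7, 100.0, 88.6),
                description="35/9/7 copies with mean-preserving rate compensation"),
    ]
    return {s.name: s for s in scenarios}


def load_scenario(path) -> Scenario:
    """Read a scenario from a YAML file, inheriting control defaults.

    Unknown keys are rejected with the offending key path.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: scenario file must be a mapping")
    allowed = set(Scenario.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown scenario keys {sorted(unknown)}")
    for key in ("n_total", "kon_max", "koff", "snare_height"):
        if key in raw:
            raw[key] = tuple(raw[key])
    base = builtin_scenarios()["control"]
    try:
        return replace(base, **raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def build_model(scenario: Scenario) -> DockingModel:
    """Resolve a scenario to its :class:`DockingModel`."""
    from .energetics import EnergeticsConfig
    from .geometry import GeometryConfig

    specs = default_specs(n_total=scenario.n_total, kon_max=scenario.kon_max,
                          koff=scenario.koff, snare_height=scenario.snare_height)
    return DockingModel(
        specs,
        GeometryConfig(d_max=scenario.d_max),
        EnergeticsConfig(enabled=scenario.energetics_enabled),
    )


def sim_config(scenario: Scenario, base_seed: int = 0,
               t_end: float | None = None, n_reps: int | None = None) -> SimConfig:
    return SimConfig(mobility_rate=scenario.mobility_rate,
                     d_start=scenario.d_start, d_max=scenario.d_max,
                     t_end=t_end if t_end is not None else scenario.t_end,
                     n_reps=n_reps if n_reps is not None else scenario.n_reps,
                     base_seed=base_seed)


def run_scenario(scenario: Scenario, out_dir=None, base_seed: int = 0,
                 t_end: float | None = None, n_reps: int | None = None,
                 progress: bool = False):
    """Simulate a scenario and (optionally) write its artifact bundle.

    Writes, under ``out_dir``: the resolved config snapshot (JSON), a tidy
    per-replicate metrics table (CSV), the pooled summary (JSON) and the
    pooled occupancy histogram (CSV).  An existing output directory is only
    reused if its snapshot matches the requested configuration exactly.

    Returns ``(trajectories, SummaryMetrics)``.
    """
    model = build_model(scenario)
    cfg = sim_config(scenario, base_seed, t_end, n_reps)
    snapshot = {"scenario": {**scenario.__dict__,
                             "n_total": list(scenario.n_total),
                             "kon_max": list(scenario.kon_max),
                             "koff": list(scenario.koff),
                             "snare_height": list(scenario.snare_height)},
                "base_seed": base_seed, "t_end": cfg.t_end, "n_reps": cfg.n_reps}

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        snap_file = out / "config_snapshot.json"
        if snap_file.exists():
            if json.loads(snap_file.read_text()) != json.loads(json.dumps(snapshot)):
                raise ConfigError(
                    f"{out} holds results for a different configuration; refusing")
        out.mkdir(parents=True, exist_ok=True)
        snap_file.write_text(json.dumps(snapshot, indent=1))

    trajs = []
    from .analysis import (first_passage_below, median_distance,
                           time_below, time_to_first_tether)
    from .dynamics import simulate
    rows = []
    for rep in range(cfg.n_reps):
        traj = simulate(model, cfg, rep)
        trajs.append(traj)
        if progress:
            print(f"  rep {rep + 1}/{cfg.n_reps}: {traj.n_events} events")
        for metric, value in (
                ("median_d", median_distance(traj)),
                ("time_below_5", time_below(traj, 5.0)),
                ("time_below_10", time_below(traj, 10.0)),
                ("t_first_below_5", first_passage_below(traj, 5.0)),
                ("t_first_tether", time_to_first_tether(traj))):
            rows.append({"scenario": scenario.name, "replicate": rep,
                         "metric": metric, "value": value})
    summary = summarize(trajs)

    if out is not None:
        pd.DataFrame(rows).to_csv(out / "replicate_metrics.csv", index=False)
        pooled = {**summary.__dict__, "pooled_median_d": summary.median_d}
        (out / "summary.json").write_text(json.dumps(pooled, indent=1))
        edges, props = occupancy_histogram(trajs, d_max=scenario.d_max)
        pd.DataFrame({"bin_left_nm": edges[:-1], "bin_right_nm": edges[1:],
                      "proportion": props}).to_csv(
            out / "occupancy_histogram.csv", index=False)
    return trajs, summary


def sensitivity_sweep(scenarios, kon_values, mode: str = "vary-kon",
                      base_seed: int = 0, t_end: float | None = None,
                      n_reps: int | None = None) -> pd.DataFrame:
    """Rate-constant sensitivity grid.

    Modes: ``vary-kon`` changes only the maximal assembly rates,
    ``vary-both-fixed-ratio`` scales the disassembly rates along with them so
    every species keeps its k_off/k_on ratio, and ``vary-koff`` scales only
    the disassembly rates (``kon_values`` are then multipliers on each
    species' k_off).  Per grid point and scenario the table reports the
    pooled median gap, time below 10 nm and mean first passage below 5 nm.
    """
    from .analysis import first_passage_below, median_distance, time_below

    if mode not in {"vary-kon", "vary-both-fixed-ratio", "vary-koff"}:
        raise ConfigError(f"unknown sweep mode {mode!r}")
    rows = []
    for scenario in scenarios:
        for v in kon_values:
            if mode == "vary-kon":
                mod = replace(scenario, kon_max=(v, v, v))
            elif mode == "vary-both-fixed-ratio":
                scale = tuple(v / k for k in scenario.kon_max)
                mod = replace(scenario, kon_max=(v, v, v),
                              koff=tuple(k * s for k, s in
                                         zip(scenario.koff, scale)))
            else:
                mod = replace(scenario,
                              koff=tuple(k * v for k in scenario.koff))
            model = build_model(mod)
            cfg = sim_config(mod, base_seed, t_end, n_reps)
            trajs = run_replicates(model, cfg)
            fp = [first_passage_below(t, 5.0) for t in trajs]
            fp_ok = [x for x in fp if x is not None]
            rows.append({
                "scenario": scenario.name, "mode": mode, "grid_value": v,
                "kon_max": mod.kon_max, "koff": mod.koff,
                "median_d": median_distance(trajs),
                "time_below_10": time_below(trajs, 10.0) / len(trajs),
                "t_first_below_5": (float(np.mean(fp_ok)) if fp_ok else None),
            })
    return pd.DataFrame(rows)
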