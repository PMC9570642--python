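"""Configuration files, trajectory CSVs and schedule reports.

Configs are YAML (or JSON — YAML is a superset) with one block per
parameter group. Unknown keys are rejected with the offending name; range
violations raise errors naming the field. Trajectory output is a tidy daily
CSV, one row per field per day.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .costs import season_costs, truncate4
from .model import Scenario, ScenarioSeries, SimulationResult
from .optimize import OptimizationConfig, SolutionReport
from .params import CostParams, CropParams, FieldParams, LeakageNetwork
from .scenarios import (
    Instance,
    default_single_field,
    default_three_field_chain,
    generate_dtr,
    generate_lai,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "write_trajectories",
    "read_trajectories",
    "read_series_csv",
    "write_series_csv",
    "render_schedule_report",
    "schedule_report_frame",
]

log = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = [
    "day", "field", "soil_n", "nni", "dose", "b",
    "growth", "potential_growth", "cum_biomass",
]


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending key."""


@dataclass(frozen=True)
class RunConfig:
    """A validated run configuration: the solvable instance plus run options."""

    instance: Instance
    out_dir: Optional[str] = None
    verbosity: str = "INFO"


_TOP_KEYS = {"scenario", "crop", "fields", "leakage", "costs", "optimization",
             "output", "verbosity"}
_SCENARIO_KEYS = {"preset", "n_days", "dtr", "lai", "series_csv", "series_inline"}
_DTR_KEYS = {"model", "mean", "amplitude", "period", "sigma", "seed"}
_LAI_KEYS = {"lai0", "lai_max", "rate"}
_LEAK_KEYS = {"sign", "entries"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def _build(cls, block: dict, where: str):
    fields = {f for f in cls.__dataclass_fields__}
    _check_keys(block, fields, where)
    return cls(**block)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON config into a ready-to-solve instance.

    A ``scenario.preset`` of ``single_field`` or ``three_field_chain`` seeds
    every block with the corresponding reference instance; explicit blocks
    override it. A missing ``costs`` block falls back to the default prices
    (labor 0.2, fertilizer 0.8 €/kg) with a logged notice.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(data, _TOP_KEYS, "config")

    scen_block = dict(data.get("scenario") or {})
    _check_keys(scen_block, _SCENARIO_KEYS, "scenario")
    preset_name = scen_block.get("preset")
    n_days = int(scen_block.get("n_days", 100))

    base: Optional[Instance] = None
    if preset_name is not None:
        presets = {
            "single_field": default_single_field,
            "three_field_chain": default_three_field_chain,
        }
        if preset_name not in presets:
            raise ConfigError(
                f"scenario.preset: unknown preset {preset_name!r} "
                f"(choose from {sorted(presets)})"
            )
        base = presets[preset_name](n_days=n_days)

    if "crop" in data:
        crop = _build(CropParams, dict(data["crop"]), "crop")
    elif base is not None:
        crop = base.scenario.crop
    else:
        crop = CropParams()

    if "fields" in data:
        fields = tuple(
            _build(FieldParams, dict(fb), f"fields[{j}]")
            for j, fb in enumerate(data["fields"])
        )
    elif base is not None:
        fields = base.scenario.fields
    else:
        fields = (FieldParams(),)
    nf = len(fields)

    if "leakage" in data:
        lb = dict(data["leakage"])
        _check_keys(lb, _LEAK_KEYS, "leakage")
        zeta = np.zeros((nf, nf))
        for e in lb.get("entries") or []:
            _check_keys(dict(e), {"from", "to", "zeta"}, "leakage.entries[]")
            zeta[int(e["from"]) - 1, int(e["to"]) - 1] = float(e["zeta"])
        leakage = LeakageNetwork(zeta=zeta, sign=lb.get("sign", "subtract"))
    elif base is not None:
        leakage = base.scenario.leakage
    else:
        leakage = LeakageNetwork.none(nf)

    if "series_inline" in scen_block:
        inline = scen_block["series_inline"]
        series = ScenarioSeries(
            dtr=np.asarray(inline["dtr"], float), lai=np.asarray(inline["lai"], float)
        )
        n_days = series.n_days
    elif "series_csv" in scen_block:
        series = read_series_csv(scen_block["series_csv"])
        n_days = series.n_days
    elif base is not None and "dtr" not in scen_block and "lai" not in scen_block:
        series = base.scenario.series
    else:
        dtr_b = dict(scen_block.get("dtr") or {})
        _check_keys(dtr_b, _DTR_KEYS, "scenario.dtr")
        lai_b = dict(scen_block.get("lai") or {})
        _check_keys(lai_b, _LAI_KEYS, "scenario.lai")
        dtr = generate_dtr(n_days, **dtr_b)
        lai = generate_lai(n_days, **lai_b)
        series = ScenarioSeries(
            dtr=np.tile(dtr, (nf, 1)), lai=np.tile(lai, (nf, 1))
        )
    if series.n_fields == 1 and nf > 1:
        series = ScenarioSeries(
            dtr=np.tile(series.dtr, (nf, 1)), lai=np.tile(series.lai, (nf, 1))
        )

    if "costs" in data:
        costs = _build(CostParams, dict(data["costs"]), "costs")
    elif base is not None:
        costs = base.costs
    else:
        costs = CostParams()
        log.info("no costs block: using default prices alpha=0.2, beta=0.8 eur/kg")

    if "optimization" in data:
        opt = _build(OptimizationConfig, dict(data["optimization"]), "optimization")
    elif base is not None:
        opt = base.opt
    else:
        opt = OptimizationConfig()

    scenario = Scenario(crop=crop, fields=fields, series=series, leakage=leakage)
    out = data.get("output") or {}
    return RunConfig(
        instance=Instance(scenario=scenario, costs=costs, opt=opt),
        out_dir=out.get("dir") if isinstance(out, dict) else None,
        verbosity=str(data.get("verbosity", "INFO")),
    )


def save_config(run: RunConfig | Instance, path: str | Path) -> None:
    """Serialize an instance to YAML (or JSON by .json suffix); round-trips
    through load_config bit-identically for generated series."""
    inst = run.instance if isinstance(run, RunConfig) else run
    scen = inst.scenario
    entries = [
        {"from": int(k) + 1, "to": int(i) + 1, "zeta": float(scen.leakage.zeta[k, i])}
        for k, i in zip(*np.nonzero(scen.leakage.zeta))
    ]
    doc = {
        "scenario": {
            "n_days": int(scen.n_days),
            "series_inline": {
                "dtr": scen.series.dtr.tolist(),
                "lai": scen.series.lai.tolist(),
            },
        },
        "crop": asdict(scen.crop),
        "fields": [asdict(f) for f in scen.fields],
        "leakage": {"sign": scen.leakage.sign, "entries": entries},
        "costs": asdict(inst.costs),
        "optimization": asdict(inst.opt),
    }
    path = Path(path)
    if path.suffix == ".json":
        import json

        path.write_text(json.dumps(doc, indent=1))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# trajectory and series CSV
# ---------------------------------------------------------------------------

def trajectories_frame(sim: SimulationResult) -> pd.DataFrame:
    """Tidy daily frame: one row per field per day; cum_biomass is the
    running biomass total up to that day."""
    nf, nd = sim.soil_n.shape
    day = np.tile(np.arange(1, nd + 1), nf)
    fld = np.repeat(np.arange(1, nf + 1), nd)
    cum = np.cumsum(sim.growth, axis=1)
    return pd.DataFrame(
        {
            "day": day,
            "field": fld,
            "soil_n": sim.soil_n.ravel(),
            "nni": sim.nni.ravel(),
            "dose": sim.schedule.u.ravel(),
            "b": sim.schedule.b.ravel(),
            "growth": sim.growth.ravel(),
            "potential_growth": sim.potential_growth.ravel(),
            "cum_biomass": cum.ravel(),
        }
    )[TRAJECTORY_COLUMNS]


def write_trajectories(sim: SimulationResult, path: str | Path) -> None:
    trajectories_frame(sim).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def read_series_csv(path: str | Path) -> ScenarioSeries:
    """Exogenous daily series from CSV with columns day, field, dtr, lai
    (1-based inclusive day index)."""
    df = pd.read_csv(path, float_precision="round_trip")
    need = {"day", "field", "dtr", "lai"}
    if not need.issubset(df.columns):
        raise ConfigError(f"series csv must have columns {sorted(need)}")
    fields = np.sort(df["field"].unique())
    days = np.sort(df["day"].unique())
    nd = int(days.max())
    if not np.array_equal(days, np.arange(1, nd + 1)):
        raise ConfigError("series csv: day must cover 1..D for every field")
    piv_d = df.pivot(index="field", columns="day", values="dtr").loc[fields]
    piv_l = df.pivot(index="field", columns="day", values="lai").loc[fields]
    if piv_d.isna().any().any() or piv_l.isna().any().any():
        raise ConfigError("series csv: missing (field, day) entries")
    return ScenarioSeries(dtr=piv_d.to_numpy(), lai=piv_l.to_numpy())


def write_series_csv(series: ScenarioSeries, path: str | Path) -> None:
    nf, nd = series.dtr.shape
    pd.DataFrame(
        {
            "day": np.tile(np.arange(1, nd + 1), nf),
            "field": np.repeat(np.arange(1, nf + 1), nd),
            "dtr": series.dtr.ravel(),
            "lai": series.lai.ravel(),
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# schedule report
# ---------------------------------------------------------------------------

def schedule_report_frame(report: SolutionReport, costs: CostParams) -> pd.DataFrame:
    """One row per field: initial N, ON days, per-day doses, fertilizer and
    labor cost (truncated at 4 decimals), season biomass."""
    sched = report.schedule
    nf = sched.u.shape[0]
    rows = []
    for i in range(nf):
        days = report.on_days(i)
        fert, labor = season_costs(sched.u[i], costs)
        rows.append(
            {
                "field": i + 1,
                "initial_n": float(report.sim.soil_n[i, 0]),
                "on_days": ", ".join(str(d) for d in days),
                "doses": "; ".join(
                    f"D{d}: {sched.u[i, d - 1]:.3f}" for d in days
                ),
                "fertilizer_cost": fert,
                "labor_cost": labor,
                "biomass_growth": float(report.cum_biomass[i]),
            }
        )
    return pd.DataFrame(rows)


def render_schedule_report(
    report: SolutionReport, costs: CostParams, fmt: str = "text"
) -> str:
    df = schedule_report_frame(report, costs)
    if fmt == "csv":
        return df.to_csv(index=False)
    lines = [
        "Field | Initial N (g/m2) | ON days | Doses (g/m2) | "
        "Fertilizer cost (eur/m2) | Labor cost (eur/m2) | Biomass (g/m2)"
    ]
    for _, r in df.iterrows():
        lines.append(
            f"{r['field']} | {r['initial_n']:.1f} | {r['on_days'] or '-'} | "
            f"{r['doses'] or '-'} | {truncate4(r['fertilizer_cost']):.4f} | "
            f"{truncate4(r['labor_cost']):.4f} | {r['biomass_growth']:.1f}"
        )
    return "\n".join(lines)
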