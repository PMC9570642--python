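"""Scenario generators: reference instances and randomized test instances.

The reference presets encode a 100-day flood-irrigated rice season. The
exogenous drivers the growth model needs but that no standard source fixes
per-day — radiation and canopy LAI — are generated here: constant or
sinusoidal/noisy radiation around 20 MJ m⁻² d⁻¹ and a logistic canopy
closure from LAI 0.1 to 6. The crop uptake-capacity curve is scaled to a
peak of about 0.55 gN m⁻² d⁻¹ at full canopy (uptake_scale=0.005), the
order of magnitude of measured daily rice N uptake; at the curve's nominal
scale the daily capacity would exceed any plausible soil stock and the soil
pool would empty every day. The calibration also keeps every preset —
including the leaky three-field chain — feasible under the 10-day
candidate-day rule; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import Scenario, ScenarioSeries
from .optimize import OptimizationConfig
from .params import CostParams, CropParams, FieldParams, LeakageNetwork

__all__ = [
    "Instance",
    "generate_lai",
    "generate_dtr",
    "default_single_field",
    "default_three_field_chain",
    "random_tiny_instance",
]

#: uptake-capacity scale used by all presets (see module docstring)
PRESET_UPTAKE_SCALE = 0.005


@dataclass(frozen=True)
class Instance:
    """A scenario bundled with its economic and optimization settings —
    everything a solver call needs."""

    scenario: Scenario
    costs: CostParams
    opt: OptimizationConfig


def generate_lai(
    n_days: int, lai0: float = 0.1, lai_max: float = 6.0, rate: float = 0.12
) -> np.ndarray:
    """Logistic canopy development evaluated at days 1..n_days:
    LAI(d) = lai_max / (1 + ((lai_max−lai0)/lai0)·exp(−rate·d)).

    rate=0 gives a constant series at lai0; the curve rises monotonically
    toward lai_max.
    """
    if lai0 <= 0:
        raise ValueError("lai0 must be > 0")
    if lai_max < lai0:
        raise ValueError("lai_max must be >= lai0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    d = np.arange(1, n_days + 1, dtype=float)
    return lai_max / (1.0 + ((lai_max - lai0) / lai0) * np.exp(-rate * d))


def generate_dtr(
    n_days: int,
    model: str = "constant",
    mean: float = 20.0,
    amplitude: float = 5.0,
    period: float = 100.0,
    sigma: float = 0.1,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Daily total radiation series (MJ m⁻² d⁻¹), all entries ≥ 0.

    model: 'constant' (all = mean); 'sinusoidal' (mean + amplitude·sin);
    'noise' (lognormal multiplicative noise around mean, reproducible for a
    fixed seed).
    """
    d = np.arange(1, n_days + 1, dtype=float)
    if model == "constant":
        out = np.full(n_days, float(mean))
    elif model == "sinusoidal":
        out = mean + amplitude * np.sin(2.0 * np.pi * d / period)
    elif model == "noise":
        rng = np.random.default_rng(seed)
        out = mean * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_days)
    else:
        raise ValueError(f"unknown dtr model {model!r}")
    if np.any(out < 0):
        raise ValueError("dtr model produced negative radiation")
    return out


def _series(n_fields: int, n_days: int, dtr: np.ndarray, lai: np.ndarray) -> ScenarioSeries:
    return ScenarioSeries(
        dtr=np.tile(dtr, (n_fields, 1)), lai=np.tile(lai, (n_fields, 1))
    )


def default_crop() -> CropParams:
    return CropParams(lue=3.0, k=0.6, eps=0.6, uptake_scale=PRESET_UPTAKE_SCALE)


def default_single_field(n_days: int = 100) -> Instance:
    """Reference single-field season: 100 days, initial soil N 5 gN m⁻²,
    labor €0.2/kg and fertilizer €0.8/kg, objective weights ω₁=100, ω₂=1,
    doses in [10, 25] gN m⁻² on day 1 plus days spaced 10 apart."""
    scenario = Scenario(
        crop=default_crop(),
        fields=(FieldParams(field_id=1, eta=0.9, gamma=0.0, n0=5.0),),
        series=_series(1, n_days, generate_dtr(n_days), generate_lai(n_days)),
        leakage=LeakageNetwork.none(1),
    )
    return Instance(scenario=scenario, costs=CostParams(), opt=OptimizationConfig())


def default_three_field_chain(n_days: int = 100) -> Instance:
    """Reference three-field season with downslope nitrogen leakage.

    Field 1 sits highest: its stock leaks into field 2's balance
    (coefficient 0.01) and field 2's into field 3's (0.015); self-loss
    rates gamma are (0.015, 0.015, 0.01). Initial soil N is (5, 5, 0) —
    field 3 starts depleted and must be fertilized on day 1.
    """
    scenario = Scenario(
        crop=default_crop(),
        fields=(
            FieldParams(field_id=1, eta=0.9, gamma=0.015, n0=5.0),
            FieldParams(field_id=2, eta=0.9, gamma=0.015, n0=5.0),
            FieldParams(field_id=3, eta=0.9, gamma=0.010, n0=0.0),
        ),
        series=_series(3, n_days, generate_dtr(n_days), generate_lai(n_days)),
        leakage=LeakageNetwork.chain([0.01, 0.015]),
    )
    return Instance(scenario=scenario, costs=CostParams(), opt=OptimizationConfig())


def random_tiny_instance(
    seed: int,
    n_fields: Optional[int] = None,
    n_days: int = 20,
    n_candidates: int = 2,
    u_max: float = 25.0,
) -> Instance:
    """Small randomized instance for solver validation: 1–2 fields, a short
    horizon, and at most ``n_candidates`` candidate application days, sized
    so exhaustive enumeration over a dose grid is cheap.

    Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    nf = int(n_fields) if n_fields is not None else int(rng.integers(1, 3))
    lai = generate_lai(n_days, lai0=float(rng.uniform(0.3, 0.8)), lai_max=6.0,
                       rate=float(rng.uniform(0.08, 0.2)))
    dtr = generate_dtr(n_days, "noise", mean=20.0, sigma=0.1,
                       seed=int(rng.integers(0, 2**31 - 1)))
    crop = CropParams(
        lue=float(rng.uniform(2.5, 3.5)),
        k=0.6,
        eps=float(rng.uniform(0.3, 0.8)),
        uptake_scale=PRESET_UPTAKE_SCALE,
    )
    fields = tuple(
        FieldParams(
            field_id=i + 1,
            eta=float(rng.uniform(0.88, 0.97)),
            gamma=float(rng.uniform(0.0, 0.02)),
            n0=float(rng.uniform(4.0, 8.0)),
        )
        for i in range(nf)
    )
    if nf == 2 and rng.random() < 0.5:
        leak = LeakageNetwork.chain([float(rng.uniform(0.0, 0.01))])
    else:
        leak = LeakageNetwork.none(nf)
    scenario = Scenario(
        crop=crop, fields=fields, series=_series(nf, n_days, dtr, lai), leakage=leak
    )
    gap = max(1, n_days // n_candidates) if n_candidates > 1 else n_days
    opt = OptimizationConfig(
        u_min=10.0,
        u_max=float(u_max),
        delta=float(rng.uniform(0.1, 0.25)),
        candidate_gap_days=gap,
        force_day1=True,
    )
    return Instance(
        scenario=scenario,
        costs=CostParams(omega1=float(rng.uniform(10.0, 200.0)), omega2=1.0),
        opt=opt,
    )
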