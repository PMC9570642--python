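"""Deterministic forward simulation of the nitrogen-limited crop growth model.

The state of each field on day d is its soil nitrogen stock N (gN m⁻²).
Within a day the model proceeds: dose is added to the stock, the nitrogen
nutrition index (NNI) is the dosed stock over the critical concentration
NCR(LAI), biomass growth is the potential (light-limited) increment reduced
by the stress factor exp(-eps*(1-min(NNI,1))), crop uptake removes
min(available, capacity), and the next-day stock is retention times the
dosed stock minus uptake, self-loss and inter-field exchange, clamped at 0.

Doses enter the same day's NNI: a day-1 application can lift a depleted
soil over the stress floor on day 1 itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import CropParams, FieldParams, LeakageNetwork

__all__ = [
    "ScenarioSeries",
    "DoseSchedule",
    "Scenario",
    "SimulationResult",
    "nitrogen_uptake",
    "uptake_capacity",
    "critical_n",
    "nni",
    "step_soil_n_single",
    "step_soil_n_multi",
    "biomass_increment",
    "potential_increment",
    "stress_factor",
    "simulate",
]


class DimensionError(ValueError):
    """Structural mismatch between schedule, series and field sets."""


@dataclass(frozen=True, eq=False)
class ScenarioSeries:
    """Exogenous daily drivers: total radiation and leaf area index.

    Arrays have shape (n_fields, n_days); index d=0 is calendar day 1.
    """

    dtr: np.ndarray
    lai: np.ndarray

    def __post_init__(self) -> None:
        dtr = np.atleast_2d(np.asarray(self.dtr, dtype=float))
        lai = np.atleast_2d(np.asarray(self.lai, dtype=float))
        object.__setattr__(self, "dtr", dtr)
        object.__setattr__(self, "lai", lai)
        if dtr.shape != lai.shape:
            raise DimensionError(f"dtr shape {dtr.shape} != lai shape {lai.shape}")
        if np.any(dtr < 0):
            raise ValueError("dtr must be nonnegative")
        if np.any(lai <= 0):
            raise ValueError("lai must be strictly positive")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ScenarioSeries)
            and np.array_equal(self.dtr, other.dtr)
            and np.array_equal(self.lai, other.lai)
        )

    @property
    def n_fields(self) -> int:
        return self.dtr.shape[0]

    @property
    def n_days(self) -> int:
        return self.dtr.shape[1]


@dataclass
class DoseSchedule:
    """Fertilization decision: binary on/off flags b and dose amounts u
    (gN m⁻²), shape (n_fields, n_days)."""

    b: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.b = np.atleast_2d(np.asarray(self.b, dtype=int))
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        if self.b.shape != self.u.shape:
            raise DimensionError(f"b shape {self.b.shape} != u shape {self.u.shape}")

    @classmethod
    def zeros(cls, n_fields: int, n_days: int) -> "DoseSchedule":
        return cls(b=np.zeros((n_fields, n_days), int), u=np.zeros((n_fields, n_days)))

    @classmethod
    def from_events(
        cls, n_fields: int, n_days: int, events: dict[int, dict[int, float]]
    ) -> "DoseSchedule":
        """events[field_id][day] = dose, with 1-based field ids and days."""
        sched = cls.zeros(n_fields, n_days)
        for fid, byday in events.items():
            for day, dose in byday.items():
                sched.b[fid - 1, day - 1] = 1
                sched.u[fid - 1, day - 1] = dose
        return sched

    def coupling_violations(self, u_min: float, u_max: float, tol: float = 1e-9) -> list[str]:
        """Check b=0 ⇒ u=0 and b=1 ⇒ u_min ≤ u ≤ u_max; returns messages."""
        out = []
        off = (self.b == 0) & (np.abs(self.u) > tol)
        on_bad = (self.b == 1) & ((self.u < u_min - tol) | (self.u > u_max + tol))
        for i, d in zip(*np.nonzero(off)):
            out.append(f"field {i + 1} day {d + 1}: u={self.u[i, d]:.6g} with b=0")
        for i, d in zip(*np.nonzero(on_bad)):
            out.append(
                f"field {i + 1} day {d + 1}: u={self.u[i, d]:.6g} outside "
                f"[{u_min}, {u_max}] with b=1"
            )
        return out

    def total_n(self) -> np.ndarray:
        """Total N supplied per field (gN m⁻²)."""
        return self.u.sum(axis=1)


@dataclass(frozen=True)
class Scenario:
    """A complete problem instance: crop, per-field soil parameters, exogenous
    series and the inter-field leakage network."""

    crop: CropParams
    fields: tuple[FieldParams, ...]
    series: ScenarioSeries
    leakage: LeakageNetwork = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fields", tuple(self.fields))
        if self.leakage is None:
            object.__setattr__(self, "leakage", LeakageNetwork.none(len(self.fields)))
        nf = len(self.fields)
        if self.series.n_fields != nf:
            raise DimensionError(
                f"series has {self.series.n_fields} fields, parameters have {nf}"
            )
        if self.leakage.n_fields != nf:
            raise DimensionError(
                f"leakage network has {self.leakage.n_fields} fields, parameters have {nf}"
            )

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    @property
    def n_days(self) -> int:
        return self.series.n_days

    @property
    def eta(self) -> np.ndarray:
        return np.array([f.eta for f in self.fields])

    @property
    def gamma(self) -> np.ndarray:
        return np.array([f.gamma for f in self.fields])

    @property
    def n0(self) -> np.ndarray:
        return np.array([f.n0 for f in self.fields])


# ---------------------------------------------------------------------------
# elementary model operations
# ---------------------------------------------------------------------------

def _check_lai(lai) -> np.ndarray:
    lai = np.asarray(lai, dtype=float)
    if np.any(lai <= 0):
        raise ValueError("LAI must be strictly positive")
    return lai


def uptake_capacity(lai, params: CropParams | None = None):
    """Daily crop N uptake capacity (gN m⁻² d⁻¹) at the given LAI."""
    p = params or CropParams()
    return p.uptake_scale * p.uptake_coef * _check_lai(lai) ** p.uptake_exp


def nitrogen_uptake(lai, n_available, params: CropParams | None = None):
    """Daily N uptake: the lesser of the available soil stock and the
    LAI-driven crop capacity. Never negative, never exceeds the stock."""
    n_available = np.asarray(n_available, dtype=float)
    if np.any(n_available < 0):
        raise ValueError("n_available must be >= 0")
    return np.minimum(n_available, uptake_capacity(lai, params))


def critical_n(lai, params: CropParams | None = None):
    """Critical nitrogen concentration NCR (gN m⁻²) below which growth is
    N-limited; a decreasing power law of LAI (dilution curve)."""
    p = params or CropParams()
    return p.ncr_coef * _check_lai(lai) ** p.ncr_exp


def nni(soil_n, lai, params: CropParams | None = None):
    """Nitrogen nutrition index: soil N over the critical concentration.
    0 = maximum shortage, 1 = no shortage; exceeds 1 in N-rich soil."""
    soil_n = np.asarray(soil_n, dtype=float)
    if np.any(soil_n < 0):
        raise ValueError("soil_n must be >= 0")
    return soil_n / critical_n(lai, params)


def step_soil_n_single(state_n, dose, eta, uptake):
    """One-day soil N balance for an isolated field:
    next N = max(0, (N + u)·eta − uptake)."""
    return np.maximum(0.0, (np.asarray(state_n, float) + dose) * eta - uptake)


def step_soil_n_multi(
    all_states,
    doses,
    field_params: Sequence[FieldParams],
    leakage: LeakageNetwork,
    uptakes,
):
    """One-day balance for coupled fields: the single-field step minus the
    self-loss gamma_i·N_i and the exchange sum over donors k of zeta[k,i]·N_k."""
    n = np.asarray(all_states, dtype=float)
    u = np.asarray(doses, dtype=float)
    nu = np.asarray(uptakes, dtype=float)
    nf = len(field_params)
    if not (n.shape[-1] == u.shape[-1] == nu.shape[-1] == nf == leakage.n_fields):
        raise DimensionError("field sets of states, doses, uptakes, params, leakage differ")
    eta = np.array([f.eta for f in field_params])
    gamma = np.array([f.gamma for f in field_params])
    exchange = n @ leakage.signed()  # sum_k sign*zeta[k, i] * N_k
    return np.maximum(0.0, (n + u) * eta - nu - gamma * n - exchange)


def stress_factor(eps: float, nni_val):
    """Growth reduction multiplier exp(-eps*(1-min(NNI,1))) ∈ (0, 1]."""
    capped = np.minimum(np.asarray(nni_val, dtype=float), 1.0)
    return np.exp(-eps * (1.0 - capped))


def potential_increment(params: CropParams, dtr, lai):
    """Potential (N-unlimited) daily biomass increment:
    ½·η_LUE·DTR·(1−exp(−k·LAI)) (g m⁻² d⁻¹)."""
    return 0.5 * params.lue * np.asarray(dtr, float) * (1.0 - np.exp(-params.k * _check_lai(lai)))


def biomass_increment(params: CropParams, dtr, lai, nni_val):
    """Actual daily biomass increment under N stress: the potential increment
    times the stress factor. Equals the potential when NNI ≥ 1 or eps = 0."""
    if np.any(np.asarray(nni_val, float) < 0):
        raise ValueError("nni_val must be >= 0")
    return potential_increment(params, dtr, lai) * stress_factor(params.eps, nni_val)


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Daily trajectories, shape (n_fields, n_days). ``soil_n`` is the
    start-of-day stock before the day's dose; ``available_n`` includes it.
    ``final_n`` is the stock carried past the last day."""

    soil_n: np.ndarray
    available_n: np.ndarray
    nni: np.ndarray
    uptake: np.ndarray
    growth: np.ndarray
    potential_growth: np.ndarray
    final_n: np.ndarray
    schedule: DoseSchedule

    @property
    def cum_biomass(self) -> np.ndarray:
        """Season biomass per field (g m⁻²)."""
        return self.growth.sum(axis=1)

    @property
    def total_gap(self) -> float:
        """Season growth gap Σ|G* − G| over all fields and days."""
        return float(np.abs(self.potential_growth - self.growth).sum())

    def min_nni(self) -> float:
        return float(self.nni.min())


def simulate(scenario: Scenario, schedule: DoseSchedule) -> SimulationResult:
    """Run the day-by-day recursion for every field under the given schedule.

    Deterministic: identical inputs give identical trajectories.
    """
    nf, nd = scenario.n_fields, scenario.n_days
    if schedule.u.shape != (nf, nd):
        raise DimensionError(
            f"schedule shape {schedule.u.shape} does not match scenario ({nf}, {nd})"
        )
    crop = scenario.crop
    dtr, lai = scenario.series.dtr, scenario.series.lai

    soil = np.empty((nf, nd))
    avail = np.empty((nf, nd))
    nni_tr = np.empty((nf, nd))
    nu_tr = np.empty((nf, nd))

    ncr = critical_n(lai, crop)
    cap = uptake_capacity(lai, crop)
    gpot = potential_increment(crop, dtr, lai)

    n = scenario.n0.astype(float).copy()
    for d in range(nd):
        soil[:, d] = n
        a = n + schedule.u[:, d]
        avail[:, d] = a
        nni_tr[:, d] = a / ncr[:, d]
        nu = np.minimum(a, cap[:, d])
        nu_tr[:, d] = nu
        n = step_soil_n_multi(
            n, schedule.u[:, d], scenario.fields, scenario.leakage, nu
        )

    growth = gpot * stress_factor(crop.eps, nni_tr)
    return SimulationResult(
        soil_n=soil,
        available_n=avail,
        nni=nni_tr,
        uptake=nu_tr,
        growth=growth,
        potential_growth=gpot.copy(),
        final_n=n,
        schedule=schedule,
    )
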