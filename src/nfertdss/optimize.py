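"""Fertilizer-schedule optimization.

Two objectives over binary on/off flags and continuous doses on a restricted
set of candidate days:

* max-growth — minimize the season sum of growth gaps G* − G;
* cost-aware — minimize ω₁·(application cost) + ω₂·(growth gap).

The daily growth model is nonlinear in the decision (an exponential stress
factor of NNI and a min() in the uptake), so the solver works on a mixed-
integer linear reformulation:

* the stress factor exp(-eps*(1-m)), m = min(NNI, 1), is replaced by its
  piecewise-linear interpolant on m ∈ [1−δ, 1] (the NNI floor constraint
  confines every feasible m to that interval), encoded with lambda weights
  plus one binary per segment enforcing SOS2-style adjacency;
* the uptake min(stock, capacity) and the nonnegativity clamp on soil N get
  big-M binaries only on days where interval propagation of the dynamics
  cannot decide the branch — for realistic parameterisations that is almost
  never, and the reformulation is exact there;
* everything else (balance, NNI floor, dose coupling) is linear already.

Every returned schedule is re-simulated through the exact nonlinear model;
the report carries both the solver's linearized objective and the exact one,
and flags any stress-floor violation beyond tolerance.

A brute-force enumeration oracle (exact dynamics, discretized doses) is
provided for validation, and ``run_dss`` wraps the solver in the daily
receding-horizon loop: observe the state, re-solve the remaining season,
commit today's decision, step the simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from . import costs as costs_mod
from .model import (
    DoseSchedule,
    Scenario,
    ScenarioSeries,
    SimulationResult,
    critical_n,
    potential_increment,
    simulate,
    stress_factor,
    uptake_capacity,
)
from .params import CostParams, coerce_numeric_fields

__all__ = [
    "OptimizationConfig",
    "SolutionReport",
    "DssResult",
    "InfeasibleError",
    "SolverError",
    "OracleGuardError",
    "build_candidate_days",
    "linearize_stress_factor",
    "PiecewiseLinear",
    "solve_max_growth",
    "solve_cost_aware",
    "brute_force_oracle",
    "run_dss",
]

log = logging.getLogger(__name__)


class InfeasibleError(RuntimeError):
    """No schedule can keep every field above the nitrogen-stress floor."""

    def __init__(self, message: str, day: Optional[int] = None):
        super().__init__(message)
        self.day = day


class SolverError(RuntimeError):
    """The MILP solver failed for a reason other than proven infeasibility."""


class OracleGuardError(RuntimeError):
    """Enumeration oracle refused: combination count exceeds the guard."""


@dataclass(frozen=True)
class OptimizationConfig:
    """Solver settings.

    u_min/u_max bound any nonzero dose (gN m⁻²); delta is the stress
    tolerance in the floor constraint NNI ≥ 1−delta; candidate days are day 1
    (if force_day1) plus days spaced candidate_gap_days apart; n_breakpoints
    is the number of piecewise-linear segments for the stress factor.
    """

    u_min: float = 10.0
    u_max: float = 25.0
    delta: float = 0.1
    candidate_gap_days: int = 10
    force_day1: bool = True
    n_breakpoints: int = 16
    solver_gap_tol: float = 1e-6
    nni_tol: float = 1e-6
    tie_break_weight: float = 1e-6

    def __post_init__(self) -> None:
        coerce_numeric_fields(self)
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        if not 0.0 <= self.u_min <= self.u_max:
            raise ValueError("need 0 <= u_min <= u_max")
        if self.candidate_gap_days < 1:
            raise ValueError("candidate_gap_days must be >= 1")
        if self.n_breakpoints < 2:
            raise ValueError("n_breakpoints must be >= 2")


@dataclass
class SolutionReport:
    """Outcome of a solve: the schedule, objectives, per-field season totals
    and the exact re-simulation used to validate it."""

    schedule: DoseSchedule
    mode: str
    status: str
    objective_value: float
    objective_linearized: Optional[float]
    total_gap: float
    total_cost: float
    total_n: np.ndarray
    fert_cost: np.ndarray
    labor_cost: np.ndarray
    cum_biomass: np.ndarray
    sim: SimulationResult
    candidate_days: tuple[int, ...]
    nni_floor: float
    max_floor_violation: float
    nni_ok: bool
    coupling_violations: list[str] = field(default_factory=list)

    def on_days(self, field_index: int = 0) -> list[int]:
        """1-based days with b=1 for one field."""
        return [int(d) + 1 for d in np.nonzero(self.schedule.b[field_index])[0]]

    def summary(self) -> str:
        lines = [
            f"mode: {self.mode}   status: {self.status}",
            f"objective (exact dynamics): {self.objective_value:.4f}"
            + (
                f"   (linearized: {self.objective_linearized:.4f})"
                if self.objective_linearized is not None
                else ""
            ),
            f"stress floor 1-delta = {self.nni_floor:.3f}: "
            + ("satisfied" if self.nni_ok else f"VIOLATED by {self.max_floor_violation:.3g}"),
        ]
        for i in range(self.schedule.u.shape[0]):
            days = self.on_days(i)
            doses = ", ".join(
                f"D{d}: {self.schedule.u[i, d - 1]:.3f}" for d in days
            )
            lines.append(
                f"field {i + 1}: ON days {days or '-'}; doses [{doses}]; "
                f"N supplied {self.total_n[i]:.3f} g/m2; "
                f"fertilizer cost {costs_mod.truncate4(self.fert_cost[i]):.4f} "
                f"labor cost {costs_mod.truncate4(self.labor_cost[i]):.4f} eur/m2; "
                f"biomass {self.cum_biomass[i]:.1f} g/m2"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# candidate days and piecewise linearization
# ---------------------------------------------------------------------------

def build_candidate_days(n_days: int, gap: int, force_day1: bool = True) -> tuple[int, ...]:
    """Days (1-based) on which fertilization may be switched on: day 1 plus
    days spaced ``gap`` apart. With force_day1=False the day-1 anchor is
    dropped and the progression starts at 1+gap. gap=1 allows every day."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    start = 1 if force_day1 else 1 + gap
    return tuple(range(start, n_days + 1, gap))


@dataclass(frozen=True)
class PiecewiseLinear:
    """Piecewise-linear interpolant of the stress factor on [lo, hi]:
    exact at every breakpoint, chordal in between. For the convex stress
    exponential the chords overestimate, by at most ``max_error()``."""

    x: np.ndarray
    y: np.ndarray

    def __call__(self, v):
        return np.interp(np.asarray(v, dtype=float), self.x, self.y)

    def max_error(self, eps: float, n_grid: int = 10_000) -> float:
        """Max |interpolant − exp(-eps*(1-x))| on a dense grid of the domain."""
        g = np.linspace(self.x[0], self.x[-1], n_grid)
        return float(np.max(np.abs(self(g) - np.exp(-eps * (1.0 - g)))))


def linearize_stress_factor(
    eps: float, n_breakpoints: int = 16, lo: float = 0.0, hi: float = 1.0
) -> PiecewiseLinear:
    """Interpolate f(m) = exp(-eps*(1-m)) at n_breakpoints+1 evenly spaced
    points of [lo, hi]. eps=0 gives the constant 1 exactly."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if not lo < hi:
        raise ValueError("need lo < hi")
    x = np.linspace(lo, hi, n_breakpoints + 1)
    return PiecewiseLinear(x=x, y=np.exp(-eps * (1.0 - x)))


# ---------------------------------------------------------------------------
# interval presolve
# ---------------------------------------------------------------------------

_BRANCH_CAP = 0  # uptake = capacity (stock provably ample)
_BRANCH_STOCK = 1  # uptake = stock (capacity provably ample)
_BRANCH_FREE = 2  # needs a binary


@dataclass
class _Presolve:
    ncr: np.ndarray
    cap: np.ndarray
    gpot: np.ndarray
    floor: np.ndarray
    n_lb: np.ndarray
    n_ub: np.ndarray
    a_lb: np.ndarray
    a_ub: np.ndarray
    branch: np.ndarray
    expr_lb: np.ndarray  # (F, D-1) lower bound of pre-clamp next-day stock
    clamp: np.ndarray  # (F, D-1) bool: clamp binary required


def _presolve(scenario: Scenario, opt: OptimizationConfig, cand0: np.ndarray) -> _Presolve:
    """Propagate interval bounds on the soil stock through the season,
    classify the uptake min() branch per day, and detect days whose stress
    floor is unreachable even at maximal dosing."""
    crop = scenario.crop
    F, D = scenario.n_fields, scenario.n_days
    lai, dtr = scenario.series.lai, scenario.series.dtr
    ncr = critical_n(lai, crop)
    cap = uptake_capacity(lai, crop)
    gpot = potential_increment(crop, dtr, lai)
    floor = (1.0 - opt.delta) * ncr
    eta, gamma = scenario.eta, scenario.gamma
    sm = scenario.leakage.signed()

    umax_day = np.where(cand0[None, :], opt.u_max, 0.0)
    n_lb = np.zeros((F, D))
    n_ub = np.zeros((F, D))
    a_lb = np.zeros((F, D))
    a_ub = np.zeros((F, D))
    branch = np.full((F, D), _BRANCH_FREE, dtype=int)
    expr_lb_arr = np.zeros((F, max(D - 1, 0)))
    clamp = np.zeros((F, max(D - 1, 0)), dtype=bool)

    n_lb[:, 0] = n_ub[:, 0] = scenario.n0
    for d in range(D):
        a_ub[:, d] = n_ub[:, d] + umax_day[:, d]
        bad = a_ub[:, d] < floor[:, d] - 1e-9
        if np.any(bad):
            i = int(np.nonzero(bad)[0][0])
            raise InfeasibleError(
                f"stress floor unreachable: field {i + 1}, day {d + 1} needs "
                f"available N >= {floor[i, d]:.3f} g/m2 but at most "
                f"{a_ub[i, d]:.3f} is attainable even at u_max",
                day=d + 1,
            )
        a_lb[:, d] = np.maximum(floor[:, d], n_lb[:, d])
        nu_lb = np.minimum(a_lb[:, d], cap[:, d])
        nu_ub = np.minimum(a_ub[:, d], cap[:, d])
        branch[:, d] = np.where(
            a_lb[:, d] >= cap[:, d] - 1e-12,
            _BRANCH_CAP,
            np.where(a_ub[:, d] <= cap[:, d] + 1e-12, _BRANCH_STOCK, _BRANCH_FREE),
        )
        if d < D - 1:
            # balance: N' = eta*(N+u) - NU - gamma*N - sum_k sm[k,i]*N_k
            coef_pos = np.clip(sm, 0.0, None)  # loses with donor stock
            coef_neg = np.clip(sm, None, 0.0)
            ex_ub = (
                eta * a_ub[:, d]
                - nu_lb
                - gamma * n_lb[:, d]
                - n_lb[:, d] @ coef_pos
                - n_ub[:, d] @ coef_neg
            )
            ex_lb = (
                eta * n_lb[:, d]
                - nu_ub
                - gamma * n_ub[:, d]
                - n_ub[:, d] @ coef_pos
                - n_lb[:, d] @ coef_neg
            )
            expr_lb_arr[:, d] = ex_lb
            n_ub[:, d + 1] = np.maximum(0.0, ex_ub)
            floor_lb = floor[:, d + 1] - umax_day[:, d + 1]
            n_lb[:, d + 1] = np.maximum.reduce(
                [np.zeros(F), ex_lb, floor_lb]
            )
            # clamp binary needed only if the pre-clamp stock can go negative
            # while a zero stock is still admissible (dose can cover the floor)
            clamp[:, d] = (ex_lb < -1e-12) & (floor_lb <= 1e-12)
    return _Presolve(
        ncr=ncr, cap=cap, gpot=gpot, floor=floor,
        n_lb=n_lb, n_ub=n_ub, a_lb=a_lb, a_ub=a_ub,
        branch=branch, expr_lb=expr_lb_arr, clamp=clamp,
    )


# ---------------------------------------------------------------------------
# MILP construction and solve
# ---------------------------------------------------------------------------

class _Rows:
    """Sparse constraint accumulator."""

    def __init__(self) -> None:
        self.r: list[int] = []
        self.c: list[int] = []
        self.v: list[float] = []
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.n = 0

    def add(self, cols: Sequence[int], coefs: Sequence[float], lb: float, ub: float) -> None:
        self.r.extend([self.n] * len(cols))
        self.c.extend(cols)
        self.v.extend(coefs)
        self.lb.append(lb)
        self.ub.append(ub)
        self.n += 1

    def constraint(self, n_vars: int) -> LinearConstraint:
        A = sp.coo_matrix((self.v, (self.r, self.c)), shape=(self.n, n_vars))
        return LinearConstraint(A.tocsc(), np.array(self.lb), np.array(self.ub))


def _weights(mode: str, costs: CostParams) -> tuple[float, float]:
    if mode == "max_growth":
        return 0.0, 1.0
    if mode == "cost_aware":
        return costs.omega1, costs.omega2
    raise ValueError(f"unknown mode {mode!r}")


def _solve_milp(
    scenario: Scenario,
    costs: CostParams,
    opt: OptimizationConfig,
    mode: str,
    cand_days: tuple[int, ...],
) -> tuple[DoseSchedule, float, object]:
    """Build and solve the linearized scheduling MILP; returns the cleaned
    schedule, the linearized objective (tie-break terms removed) and the raw
    solver result."""
    F, D = scenario.n_fields, scenario.n_days
    cand0 = np.zeros(D, dtype=bool)
    cand0[[d - 1 for d in cand_days]] = True
    pre = _presolve(scenario, opt, cand0)
    w1, w2 = _weights(mode, costs)
    eta, gamma = scenario.eta, scenario.gamma
    sm = scenario.leakage.signed()
    price = (costs.alpha + costs.beta) / costs_mod.G_PER_KG

    pwl = linearize_stress_factor(
        scenario.crop.eps, opt.n_breakpoints, lo=max(0.0, 1.0 - opt.delta), hi=1.0
    )
    S = len(pwl.x) - 1  # segments

    lb: list[float] = []
    ub: list[float] = []
    integ: list[int] = []
    obj: list[float] = []

    def add_var(lo_, hi_, integer=False, c=0.0) -> int:
        lb.append(lo_)
        ub.append(hi_)
        integ.append(1 if integer else 0)
        obj.append(c)
        return len(lb) - 1

    n_cand = len(cand_days)
    wtb = opt.tie_break_weight
    tb_u = wtb / (10.0 * D * max(opt.u_max, 1.0) * max(n_cand, 1))

    N_idx = np.empty((F, D), dtype=int)
    u_idx = np.full((F, D), -1, dtype=int)
    b_idx = np.full((F, D), -1, dtype=int)
    m_idx = np.empty((F, D), dtype=int)
    lam_idx = np.empty((F, D, S + 1), dtype=int)
    y_idx = np.empty((F, D, S), dtype=int)
    nu_idx = np.full((F, D), -1, dtype=int)
    s_idx = np.full((F, D), -1, dtype=int)

    const_obj = float(w2 * pre.gpot.sum())
    m_lo = max(0.0, 1.0 - opt.delta)

    for i in range(F):
        for d in range(D):
            fix = scenario.n0[i] if d == 0 else None
            N_idx[i, d] = add_var(
                fix if fix is not None else pre.n_lb[i, d],
                fix if fix is not None else pre.n_ub[i, d],
            )
            if cand0[d]:
                u_idx[i, d] = add_var(0.0, opt.u_max, c=w1 * price + tb_u)
                b_idx[i, d] = add_var(0.0, 1.0, integer=True, c=wtb * (d + 1) / D)
            m_idx[i, d] = add_var(m_lo, 1.0)
            for j in range(S + 1):
                lam_idx[i, d, j] = add_var(0.0, 1.0, c=-w2 * pre.gpot[i, d] * pwl.y[j])
            for j in range(S):
                y_idx[i, d, j] = add_var(0.0, 1.0, integer=True)
            if pre.branch[i, d] == _BRANCH_FREE:
                nu_idx[i, d] = add_var(0.0, min(pre.a_ub[i, d], pre.cap[i, d]))
                s_idx[i, d] = add_var(0.0, 1.0, integer=True)

    c_idx = np.full((F, max(D - 1, 0)), -1, dtype=int)
    for i in range(F):
        for d in range(D - 1):
            if pre.clamp[i, d]:
                c_idx[i, d] = add_var(0.0, 1.0, integer=True)

    rows = _Rows()
    INF = np.inf
    for i in range(F):
        for d in range(D):
            nv, uv, bv, mv = N_idx[i, d], u_idx[i, d], b_idx[i, d], m_idx[i, d]
            a_cols, a_coefs = [nv], [1.0]
            if uv >= 0:
                a_cols.append(uv)
                a_coefs.append(1.0)
            # stress floor: N + u >= (1-delta)*NCR
            rows.add(a_cols, a_coefs, pre.floor[i, d], INF)
            # dose coupling
            if uv >= 0:
                rows.add([uv, bv], [1.0, -opt.u_max], -INF, 0.0)
                rows.add([uv, bv], [1.0, -opt.u_min], 0.0, INF)
            # m <= NNI  <=>  ncr*m - N - u <= 0
            rows.add([mv] + a_cols, [pre.ncr[i, d]] + [-x for x in a_coefs], -INF, 0.0)
            # lambda rows
            lam = list(lam_idx[i, d])
            yy = list(y_idx[i, d])
            rows.add(lam, [1.0] * (S + 1), 1.0, 1.0)
            rows.add(lam + [mv], list(pwl.x) + [-1.0], 0.0, 0.0)
            rows.add(yy, [1.0] * S, 1.0, 1.0)
            rows.add([lam[0], yy[0]], [1.0, -1.0], -INF, 0.0)
            for j in range(1, S):
                rows.add([lam[j], yy[j - 1], yy[j]], [1.0, -1.0, -1.0], -INF, 0.0)
            rows.add([lam[S], yy[S - 1]], [1.0, -1.0], -INF, 0.0)
            # ambiguous uptake branch: NU = min(N+u, cap) via indicator s
            if pre.branch[i, d] == _BRANCH_FREE:
                nuv, sv = nu_idx[i, d], s_idx[i, d]
                cap_d = pre.cap[i, d]
                m_a = pre.a_ub[i, d]
                nu_lo = min(pre.a_lb[i, d], cap_d)
                # NU <= N+u ; NU <= cap (bound) ; NU >= N+u - M*s ; NU >= cap - (cap-lo)*(1-s)
                rows.add([nuv] + a_cols, [1.0] + [-x for x in a_coefs], -INF, 0.0)
                rows.add([nuv], [1.0], -INF, cap_d)
                rows.add([nuv, sv] + a_cols, [1.0, m_a] + [-x for x in a_coefs], 0.0, INF)
                rows.add([nuv, sv], [1.0, -(cap_d - nu_lo)], nu_lo, INF)

    # dynamics
    for i in range(F):
        for d in range(D - 1):
            # expr = eta*(N+u) - NU - gamma*N - sum_k sm[k,i]*N_k
            cols = [N_idx[i, d]]
            coefs = [eta[i] - gamma[i]]
            if u_idx[i, d] >= 0:
                cols.append(u_idx[i, d])
                coefs.append(eta[i])
            rhs = 0.0
            br = pre.branch[i, d]
            if br == _BRANCH_CAP:
                rhs -= pre.cap[i, d]
            elif br == _BRANCH_STOCK:
                coefs[0] -= 1.0
                if u_idx[i, d] >= 0:
                    coefs[1] -= 1.0
            else:
                cols.append(nu_idx[i, d])
                coefs.append(-1.0)
            for k in range(F):
                if k != i and sm[k, i] != 0.0:
                    cols.append(N_idx[k, d])
                    coefs.append(-sm[k, i])
            nxt = N_idx[i, d + 1]
            if c_idx[i, d] < 0:
                # N' = expr
                rows.add([nxt] + cols, [1.0] + [-x for x in coefs], rhs, rhs)
            else:
                cv = c_idx[i, d]
                m_c = -pre.expr_lb[i, d]
                # N' >= expr ; N' <= expr + Mc*c ; N' <= ub*(1-c)
                rows.add([nxt] + cols, [1.0] + [-x for x in coefs], rhs, INF)
                rows.add([nxt, cv] + cols, [1.0, -m_c] + [-x for x in coefs], -INF, rhs)
                nb = pre.n_ub[i, d + 1]
                rows.add([nxt, cv], [1.0, nb], -INF, nb)

    n_vars = len(lb)
    res = milp(
        c=np.array(obj),
        constraints=[rows.constraint(n_vars)],
        integrality=np.array(integ),
        bounds=Bounds(np.array(lb), np.array(ub)),
        options={"mip_rel_gap": opt.solver_gap_tol, "presolve": True},
    )
    if res.status == 2:
        raise InfeasibleError(_infeasibility_message(scenario, opt, cand_days), day=None)
    if not res.success:
        raise SolverError(f"solver failed: status {res.status} ({res.message})")

    x = res.x
    b = np.zeros((F, D), dtype=int)
    u = np.zeros((F, D))
    for i in range(F):
        for d in range(D):
            if b_idx[i, d] >= 0:
                bi = int(round(x[b_idx[i, d]]))
                b[i, d] = bi
                if bi:
                    u[i, d] = float(np.clip(x[u_idx[i, d]], opt.u_min, opt.u_max))
    schedule = DoseSchedule(b=b, u=u)

    tb = sum(
        x[b_idx[i, d]] * wtb * (d + 1) / D + x[u_idx[i, d]] * tb_u
        for i in range(F)
        for d in range(D)
        if b_idx[i, d] >= 0
    )
    lin_obj = float(res.fun + const_obj - tb)
    return schedule, lin_obj, res


def _infeasibility_message(
    scenario: Scenario, opt: OptimizationConfig, cand_days: tuple[int, ...]
) -> str:
    """Diagnose a proven-infeasible model: simulate maximal dosing and name
    the first day whose stress floor is missed."""
    F, D = scenario.n_fields, scenario.n_days
    sched = DoseSchedule.zeros(F, D)
    for d in cand_days:
        sched.b[:, d - 1] = 1
        sched.u[:, d - 1] = opt.u_max
    sim = simulate(scenario, sched)
    viol = sim.nni < (1.0 - opt.delta) - 1e-12
    if viol.any():
        d0 = int(np.nonzero(viol.any(axis=0))[0][0])
        i0 = int(np.nonzero(viol[:, d0])[0][0])
        return (
            f"no feasible schedule: even applying u_max on every candidate day, "
            f"field {i0 + 1} falls below the stress floor on day {d0 + 1} "
            f"(NNI {sim.nni[i0, d0]:.3f} < {1 - opt.delta:.3f})"
        )
    return "solver proved the linearized model infeasible"


def _make_report(
    scenario: Scenario,
    costs: CostParams,
    opt: OptimizationConfig,
    schedule: DoseSchedule,
    mode: str,
    cand_days: tuple[int, ...],
    status: str,
    lin_obj: Optional[float],
    sim: Optional[SimulationResult] = None,
) -> SolutionReport:
    if sim is None:
        sim = simulate(scenario, schedule)
    w1, w2 = _weights(mode, costs)
    price = (costs.alpha + costs.beta) / costs_mod.G_PER_KG
    total_n = schedule.total_n()
    total_cost = float(price * total_n.sum())
    total_gap = sim.total_gap
    fert = costs.beta * total_n / costs_mod.G_PER_KG
    labor = costs.alpha * total_n / costs_mod.G_PER_KG
    floor = 1.0 - opt.delta
    viol = float(np.max(floor - sim.nni))
    return SolutionReport(
        schedule=schedule,
        mode=mode,
        status=status,
        objective_value=float(w1 * total_cost + w2 * total_gap),
        objective_linearized=lin_obj,
        total_gap=total_gap,
        total_cost=total_cost,
        total_n=total_n,
        fert_cost=fert,
        labor_cost=labor,
        cum_biomass=sim.cum_biomass,
        sim=sim,
        candidate_days=tuple(cand_days),
        nni_floor=floor,
        max_floor_violation=max(0.0, viol),
        nni_ok=viol <= opt.nni_tol,
        coupling_violations=schedule.coupling_violations(opt.u_min, opt.u_max),
    )


def _solve(
    scenario: Scenario,
    costs: CostParams,
    opt: OptimizationConfig,
    mode: str,
    candidate_days: Optional[Sequence[int]] = None,
) -> SolutionReport:
    cand = (
        tuple(sorted(candidate_days))
        if candidate_days is not None
        else build_candidate_days(scenario.n_days, opt.candidate_gap_days, opt.force_day1)
    )
    schedule, lin_obj, _ = _solve_milp(scenario, costs, opt, mode, cand)
    report = _make_report(scenario, costs, opt, schedule, mode, cand, "optimal", lin_obj)
    if not report.nni_ok:
        log.warning(
            "linearization discrepancy: re-simulated schedule misses the stress "
            "floor by %.3g", report.max_floor_violation,
        )
    return report


def solve_max_growth(
    scenario: Scenario,
    costs: CostParams,
    opt: OptimizationConfig,
    candidate_days: Optional[Sequence[int]] = None,
) -> SolutionReport:
    """Minimize the season growth gap Σ(G* − G) subject to the nitrogen
    balance, the stress floor and the dose coupling."""
    return _solve(scenario, costs, opt, "max_growth", candidate_days)


def solve_cost_aware(
    scenario: Scenario,
    costs: CostParams,
    opt: OptimizationConfig,
    candidate_days: Optional[Sequence[int]] = None,
) -> SolutionReport:
    """Minimize ω₁·(application cost) + ω₂·(growth gap)."""
    return _solve(scenario, costs, opt, "cost_aware", candidate_days)


# ---------------------------------------------------------------------------
# brute-force enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_oracle(
    scenario: Scenario,
    costs: CostParams,
    opt: OptimizationConfig,
    mode: str = "max_growth",
    dose_grid_step: float = 0.5,
    candidate_days: Optional[Sequence[int]] = None,
    guard: int = 1_000_000,
) -> SolutionReport:
    """Exhaustively enumerate every (b, u) combination on a dose grid over
    the candidate days, simulate each through the exact nonlinear dynamics,
    discard stress-floor violators and return the best feasible schedule.

    Independent of the MILP path: no linearization, no solver. Refuses
    (OracleGuardError) when the combination count exceeds ``guard``.
    """
    F, D = scenario.n_fields, scenario.n_days
    cand = (
        tuple(sorted(candidate_days))
        if candidate_days is not None
        else build_candidate_days(D, opt.candidate_gap_days, opt.force_day1)
    )
    grid = np.concatenate(
        [[0.0], np.arange(opt.u_min, opt.u_max + 1e-9, dose_grid_step)]
    )
    slots = [(i, d - 1) for i in range(F) for d in cand]
    n_opt = len(grid)
    n_comb = n_opt ** len(slots)
    if n_comb > guard:
        raise OracleGuardError(
            f"{n_comb} combinations exceed the enumeration guard of {guard}"
        )

    # mixed-radix decode of every combination into a dose per slot
    combo = np.arange(n_comb)
    u_slot = np.empty((n_comb, len(slots)))
    rem = combo.copy()
    for s in range(len(slots) - 1, -1, -1):
        u_slot[:, s] = grid[rem % n_opt]
        rem //= n_opt

    crop = scenario.crop
    ncr = critical_n(scenario.series.lai, crop)
    cap = uptake_capacity(scenario.series.lai, crop)
    gpot = potential_increment(crop, scenario.series.dtr, scenario.series.lai)
    eta, gamma = scenario.eta, scenario.gamma
    sm = scenario.leakage.signed()
    floor = (1.0 - opt.delta) * ncr
    w1, w2 = _weights(mode, costs)
    price = (costs.alpha + costs.beta) / costs_mod.G_PER_KG

    u_day = np.zeros((n_comb, F, D))
    for s, (i, d0) in enumerate(slots):
        u_day[:, i, d0] = u_slot[:, s]

    n = np.tile(scenario.n0, (n_comb, 1))
    feasible = np.ones(n_comb, dtype=bool)
    obj = np.zeros(n_comb)
    for d in range(D):
        a = n + u_day[:, :, d]
        nni_d = a / ncr[:, d]
        feasible &= np.all(a >= floor[:, d] - 1e-9, axis=1)
        growth = gpot[:, d] * stress_factor(crop.eps, nni_d)
        obj += w2 * (gpot[:, d] - growth).sum(axis=1)
        nu = np.minimum(a, cap[:, d])
        n = np.maximum(0.0, a * eta - nu - gamma * n - n @ sm)
    obj += w1 * price * u_day.sum(axis=(1, 2))

    if not feasible.any():
        raise InfeasibleError(
            "enumeration oracle: empty feasible set over the dose grid"
        )
    obj_f = np.where(feasible, obj, np.inf)
    # deterministic tie-break: objective, then earliest/fewest ON days, then total N
    days_key = (u_day > 0) * (np.arange(1, D + 1) / D)
    best = np.lexsort(
        (u_day.sum(axis=(1, 2)), days_key.sum(axis=(1, 2)), np.round(obj_f, 12))
    )[0]
    sched = DoseSchedule(b=(u_day[best] > 0).astype(int), u=u_day[best])
    return _make_report(
        scenario, costs, opt, sched, mode, cand, "optimal (enumeration)", None
    )


# ---------------------------------------------------------------------------
# receding-horizon decision support loop
# ---------------------------------------------------------------------------

@dataclass
class DssResult:
    """Day-by-day committed decisions plus the final season report."""

    decisions: list[tuple[int, np.ndarray, np.ndarray]]
    report: SolutionReport

    @property
    def schedule(self) -> DoseSchedule:
        return self.report.schedule


def run_dss(
    scenario: Scenario,
    costs: CostParams,
    opt: OptimizationConfig,
    mode: str = "max_growth",
    perturb: Optional[Callable[[int, np.ndarray], np.ndarray]] = None,
    resolve_daily: bool = False,
) -> DssResult:
    """Daily decision-support loop: observe the current soil state, re-solve
    the remaining-season problem, commit today's decision, advance one day.

    ``perturb(day, n)`` (1-based day) may return a modified state vector
    before that day's solve — the hook for sensor feedback or disturbances.
    By default the solve is repeated only on candidate days (on other days
    the committed decision is forced to b=0 and the plan cannot change on a
    deterministic scenario); ``resolve_daily=True`` re-solves every day.
    On a deterministic scenario the committed schedule coincides with the
    one-shot full-horizon optimum.
    """
    F, D = scenario.n_fields, scenario.n_days
    cand_all = build_candidate_days(D, opt.candidate_gap_days, opt.force_day1)
    crop = scenario.crop
    ncr = critical_n(scenario.series.lai, crop)
    cap = uptake_capacity(scenario.series.lai, crop)
    gpot = potential_increment(crop, scenario.series.dtr, scenario.series.lai)

    b = np.zeros((F, D), dtype=int)
    u = np.zeros((F, D))
    soil = np.empty((F, D))
    avail = np.empty((F, D))
    nni_tr = np.empty((F, D))
    nu_tr = np.empty((F, D))
    decisions: list[tuple[int, np.ndarray, np.ndarray]] = []

    n = scenario.n0.astype(float).copy()
    for d in range(D):
        day = d + 1
        if perturb is not None:
            n = np.asarray(perturb(day, n.copy()), dtype=float)
        is_cand = day in cand_all
        if is_cand or resolve_daily:
            tail = tuple(c - d for c in cand_all if c > d)
            sub = Scenario(
                crop=crop,
                fields=tuple(
                    replace(f, n0=float(max(n[i], 0.0)))
                    for i, f in enumerate(scenario.fields)
                ),
                series=ScenarioSeries(
                    dtr=scenario.series.dtr[:, d:], lai=scenario.series.lai[:, d:]
                ),
                leakage=scenario.leakage,
            )
            try:
                sched_tail, _, _ = _solve_milp(sub, costs, opt, mode, tail)
            except (InfeasibleError, SolverError) as err:
                raise type(err)(f"day {day}: {err}") from err
            if is_cand:
                b[:, d] = sched_tail.b[:, 0]
                u[:, d] = sched_tail.u[:, 0]
        decisions.append((day, b[:, d].copy(), u[:, d].copy()))
        log.info("day %d: b=%s u=%s", day, b[:, d], np.round(u[:, d], 3))

        soil[:, d] = n
        a = n + u[:, d]
        avail[:, d] = a
        nni_tr[:, d] = a / ncr[:, d]
        nu = np.minimum(a, cap[:, d])
        nu_tr[:, d] = nu
        n = np.maximum(
            0.0,
            a * scenario.eta - nu - scenario.gamma * n - n @ scenario.leakage.signed(),
        )

    schedule = DoseSchedule(b=b, u=u)
    sim = SimulationResult(
        soil_n=soil,
        available_n=avail,
        nni=nni_tr,
        uptake=nu_tr,
        growth=gpot * stress_factor(crop.eps, nni_tr),
        potential_growth=gpot.copy(),
        final_n=n,
        schedule=schedule,
    )
    report = _make_report(
        scenario, costs, opt, schedule, mode, cand_all, "optimal (receding horizon)",
        None, sim=sim,
    )
    return DssResult(decisions=decisions, report=report)
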