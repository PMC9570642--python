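"""Cost, objective and yield arithmetic.

Doses live in gN m⁻²; prices in € per kg N, so monetary terms carry a fixed
1/1000 conversion. Season totals are reported truncated (not rounded) to
four decimals, matching how per-m² money amounts are conventionally tabled.
"""

from __future__ import annotations

import math

import numpy as np

from .params import CostParams

__all__ = [
    "daily_cost",
    "growth_gap",
    "weighted_objective_term",
    "harvest_yield",
    "season_costs",
    "truncate4",
]

G_PER_KG = 1000.0


def daily_cost(dose_g_per_m2, alpha: float, beta: float):
    """Cost of one day's application, € m⁻²: (alpha + beta) · dose/1000."""
    dose = np.asarray(dose_g_per_m2, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    return (alpha + beta) * dose / G_PER_KG


def growth_gap(g_pot, g_act):
    """Absolute gap |G* − G| between potential and actual daily growth."""
    return np.abs(np.asarray(g_pot, float) - np.asarray(g_act, float))


def weighted_objective_term(cost, gap, omega1: float, omega2: float):
    """Daily objective integrand ω₁·cost + ω₂·gap."""
    return omega1 * np.asarray(cost, float) + omega2 * np.asarray(gap, float)


def harvest_yield(biomass, hi: float):
    """Grain yield from season biomass via the harvest index (0.46–0.50 for
    rice): yield = HI · biomass."""
    if not 0.0 <= hi <= 1.0:
        raise ValueError("harvest index must lie in [0, 1]")
    return hi * np.asarray(biomass, float)


def truncate4(x: float) -> float:
    """Truncate a monetary value toward zero at four decimals (reporting
    convention: 0.0069602 € m⁻² is tabled as 0.0069)."""
    return math.trunc(x * 1e4) / 1e4


def season_costs(doses_g_per_m2, costs: CostParams, truncated: bool = True):
    """Season fertilizer (beta) and labor (alpha) cost components, € m⁻².

    Parameters
    ----------
    doses_g_per_m2 : array-like
        Doses for one field over the season (any shape; summed).
    truncated : bool
        Apply the 4-decimal truncation reporting convention.

    Returns
    -------
    (fertilizer_cost, labor_cost) : tuple of float
    """
    total = float(np.sum(np.asarray(doses_g_per_m2, dtype=float)))
    fert = costs.beta * total / G_PER_KG
    labor = costs.alpha * total / G_PER_KG
    if truncated:
        return truncate4(fert), truncate4(labor)
    return fert, labor
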