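"""Parameter containers for the nitrogen-limited rice growth and scheduling model.

All nitrogen quantities are in gN m⁻², radiation in MJ m⁻² d⁻¹, biomass in
g m⁻², money in € m⁻² (prices in € per kg of nitrogen).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CropParams",
    "FieldParams",
    "CostParams",
    "LeakageNetwork",
    "ParameterError",
]


class ParameterError(ValueError):
    """Raised when a parameter violates its documented range; names the field."""


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{name}: {msg}")


def coerce_numeric_fields(obj) -> None:
    """Cast dataclass fields annotated float/int/bool to their type in place.

    Config files may deliver numbers as strings (YAML parses '1e-06' as a
    string); a non-castable value raises ParameterError naming the field.
    """
    for name, fld in obj.__dataclass_fields__.items():
        typ = {"float": float, "int": int, "bool": bool}.get(str(fld.type).strip())
        if typ is None:
            continue
        val = getattr(obj, name)
        if isinstance(val, typ):
            continue
        try:
            cast = typ(float(val)) if typ is not bool else bool(val)
        except (TypeError, ValueError) as err:
            raise ParameterError(f"{name}: not a {typ.__name__}: {val!r}") from err
        object.__setattr__(obj, name, cast)


@dataclass(frozen=True)
class CropParams:
    """Crop-specific constants of the light-use-efficiency growth model.

    Parameters
    ----------
    lue : float
        Light-use efficiency η_LUE (g biomass per MJ intercepted radiation).
    k : float
        Canopy light attenuation coefficient (m² m⁻²).
    eps : float
        LUE reduction factor ε under nitrogen stress (dimensionless);
        the stress multiplier on growth is exp(-eps * (1 - min(NNI, 1))).
    uptake_coef, uptake_exp : float
        Daily crop N uptake capacity is uptake_scale * uptake_coef * LAI**uptake_exp.
    ncr_coef, ncr_exp : float
        Critical N dilution curve NCR = ncr_coef * LAI**ncr_exp.
    uptake_scale : float
        Dimensionless multiplier on the uptake capacity curve; 1.0 uses the
        curve exactly as parameterised.
    """

    lue: float = 3.0
    k: float = 0.6
    eps: float = 0.6
    uptake_coef: float = 35.7
    uptake_exp: float = 0.63
    ncr_coef: float = 3.7
    ncr_exp: float = -0.35
    uptake_scale: float = 1.0

    def __post_init__(self) -> None:
        coerce_numeric_fields(self)
        _require(self.lue > 0, "lue", "must be > 0")
        _require(self.k > 0, "k", "must be > 0")
        _require(self.eps >= 0, "eps", "must be >= 0")
        _require(self.uptake_coef > 0, "uptake_coef", "must be > 0")
        _require(self.ncr_coef > 0, "ncr_coef", "must be > 0")
        _require(self.uptake_scale >= 0, "uptake_scale", "must be >= 0")


@dataclass(frozen=True)
class FieldParams:
    """Per-field soil nitrogen balance parameters.

    eta is the retention factor applied to (soil N + dose) each day — the
    complement of the daily denitrification/leaching loss fraction. gamma is
    an additional self-loss rate used in the multi-field balance; n0 the
    initial soil nitrogen stock.
    """

    field_id: int = 1
    eta: float = 0.9
    gamma: float = 0.0
    n0: float = 5.0

    def __post_init__(self) -> None:
        coerce_numeric_fields(self)
        _require(0.0 <= self.eta <= 1.0, "eta", "must lie in [0, 1]")
        _require(self.gamma >= 0.0, "gamma", "must be >= 0")
        _require(self.n0 >= 0.0, "n0", "must be >= 0")


@dataclass(frozen=True)
class CostParams:
    """Economic parameters: spreading (alpha) and fertilizer (beta) prices in
    €/kg N, objective weights, and the grain harvest index."""

    alpha: float = 0.2
    beta: float = 0.8
    omega1: float = 100.0
    omega2: float = 1.0
    harvest_index: float = 0.5

    def __post_init__(self) -> None:
        coerce_numeric_fields(self)
        _require(self.alpha >= 0, "alpha", "must be >= 0")
        _require(self.beta >= 0, "beta", "must be >= 0")
        _require(self.omega1 > 0, "omega1", "must be > 0")
        _require(self.omega2 > 0, "omega2", "must be > 0")
        _require(0.0 <= self.harvest_index <= 1.0, "harvest_index", "must lie in [0, 1]")


@dataclass(frozen=True, eq=False)
class LeakageNetwork:
    """Directed nitrogen exchange between fields.

    ``zeta[k, i]`` is the coefficient with which field i's balance loses
    (default sign) an amount zeta[k, i] * N_k each day, i.e. the exchange is
    driven by the donor field k's stock. The diagonal is zero. ``sign`` is
    'subtract' (as in the source balance) or 'add' (treat the exchanged
    amount as an input to the receiving field).
    """

    zeta: np.ndarray = field(default_factory=lambda: np.zeros((1, 1)))
    sign: str = "subtract"

    def __post_init__(self) -> None:
        z = np.asarray(self.zeta, dtype=float)
        object.__setattr__(self, "zeta", z)
        _require(z.ndim == 2 and z.shape[0] == z.shape[1], "zeta", "must be square")
        _require(np.all(z >= 0), "zeta", "entries must be >= 0")
        _require(np.all(np.diag(z) == 0), "zeta", "diagonal must be zero")
        _require(self.sign in ("subtract", "add"), "sign", "must be 'subtract' or 'add'")

    @property
    def n_fields(self) -> int:
        return self.zeta.shape[0]

    @property
    def is_zero(self) -> bool:
        return bool(np.all(self.zeta == 0))

    @classmethod
    def none(cls, n_fields: int) -> "LeakageNetwork":
        return cls(zeta=np.zeros((n_fields, n_fields)))

    @classmethod
    def chain(cls, coeffs: Sequence[float], sign: str = "subtract") -> "LeakageNetwork":
        """Downslope chain: field 1 → field 2 → … with coeffs[j] the
        coefficient from field j+1 into field j+2 (1-based labels)."""
        n = len(coeffs) + 1
        z = np.zeros((n, n))
        for j, c in enumerate(coeffs):
            z[j, j + 1] = c
        return cls(zeta=z, sign=sign)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LeakageNetwork)
            and self.sign == other.sign
            and np.array_equal(self.zeta, other.zeta)
        )

    def signed(self) -> np.ndarray:
        """Coefficient matrix with the configured sign folded in (subtract → +zeta
        appears with minus in the balance)."""
        return self.zeta if self.sign == "subtract" else -self.zeta
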