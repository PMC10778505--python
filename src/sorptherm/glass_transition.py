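"""Glass-transition plasticization: Gordon--Taylor fitting and critical
storage conditions.

The mixture glass-transition temperature is

    Tg(xw) = [(1 - xw)*Tgs + k*xw*Tgw] / [(1 - xw) + k*xw]

with ``xw`` the wet-basis water mass fraction and ``Tgw`` fixed (water,
-135 degC).  All temperatures here are Celsius — the ratio form is affine
invariant, so Celsius inputs give the same Tg in Celsius as kelvin inputs
would in kelvin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .data_model import GlassTransitionPoint, wet_to_db_fraction
from .errors import DomainError, RangeError, ValidationError
from .isotherm_models import ModelParams, invert

__all__ = [
    "TGW_WATER_C",
    "GlassTransitionFit",
    "CriticalMoisture",
    "gordon_taylor",
    "fit_gordon_taylor",
    "critical_moisture",
    "critical_aw",
]

#: Glass-transition temperature of pure water, degrees Celsius.
TGW_WATER_C = -135.0


@dataclass(frozen=True)
class GlassTransitionFit:
    """Fitted Gordon--Taylor parameters (temperatures in Celsius)."""

    Tgs: float
    k: float
    Tgw: float = TGW_WATER_C
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValidationError(f"k must be > 0, got {self.k}")
        if self.Tgw >= self.Tgs:
            raise ValidationError("Tgw must be below Tgs")


@dataclass(frozen=True)
class CriticalMoisture:
    """Critical water content at a storage temperature.

    ``flag`` is None for an interior solution; 'rubbery_even_dry' when the
    storage temperature exceeds Tgs (xw = 0), 'glassy_even_saturated' when
    it is at or below Tgw (xw = 1).
    """

    xw: float
    x_db: float
    storage_T: float
    flag: Optional[str] = None


def gordon_taylor(fit: GlassTransitionFit, xw) -> float | np.ndarray:
    """Mixture glass-transition temperature (degC) at water fraction xw."""
    x = np.asarray(xw, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise DomainError("xw must lie in [0, 1]")
    num = (1.0 - x) * fit.Tgs + fit.k * x * fit.Tgw
    den = (1.0 - x) + fit.k * x
    out = num / den
    return float(out) if out.ndim == 0 else out


def fit_gordon_taylor(
    data: Sequence[GlassTransitionPoint],
    tgw_fixed: float = TGW_WATER_C,
) -> GlassTransitionFit:
    """Nonlinear least squares over (Tgs, k) with Tgw held fixed."""
    xw = np.asarray([p.xw for p in data], dtype=float)
    tg = np.asarray([p.tg_c for p in data], dtype=float)
    if xw.size < 3:
        raise ValidationError("need >= 3 glass-transition points")
    if np.unique(np.round(xw, 12)).size < 2:
        raise ValidationError("need >= 2 distinct water fractions")

    def resid(theta):
        tgs, k = theta
        num = (1.0 - xw) * tgs + k * xw * tgw_fixed
        den = (1.0 - xw) + k * xw
        return tg - num / den

    init = np.array([float(tg.max()), 0.3])
    lower = np.array([tgw_fixed + 1e-6, 1e-6])
    upper = np.array([500.0, 100.0])
    res = least_squares(
        resid, np.clip(init, lower + 1e-9, upper - 1e-9), bounds=(lower, upper),
        method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
    )
    tgs, k = res.x
    pred = tg - resid(res.x)
    ss_tot = float(np.sum((tg - tg.mean()) ** 2))
    ss_res = float(np.sum((tg - pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GlassTransitionFit(Tgs=float(tgs), k=float(k), Tgw=tgw_fixed, r2=r2)


def critical_moisture(fit: GlassTransitionFit, storage_T: float) -> CriticalMoisture:
    """Water fraction at which Tg equals the storage temperature (degC).

    Closed form: xw = (Tgs - T) / [(Tgs - T) + k*(T - Tgw)].  Outside
    (Tgw, Tgs] the boundary value is returned with an explanatory flag.
    """
    if storage_T > fit.Tgs:
        return CriticalMoisture(0.0, 0.0, storage_T, flag="rubbery_even_dry")
    if storage_T <= fit.Tgw:
        return CriticalMoisture(1.0, float("inf"), storage_T, flag="glassy_even_saturated")
    xw = (fit.Tgs - storage_T) / ((fit.Tgs - storage_T) + fit.k * (storage_T - fit.Tgw))
    x_db = wet_to_db_fraction(xw) if xw < 1 else float("inf")
    return CriticalMoisture(float(xw), float(x_db), storage_T)


def critical_aw(xw_critical: float, isotherm_params: ModelParams) -> float:
    """Water activity matching the critical moisture on a fitted isotherm.

    Converts the wet-basis critical fraction to dry basis and inverts the
    (typically adsorption-branch, best-ranked) isotherm at the storage
    temperature.
    """
    if xw_critical < 0 or xw_critical >= 1:
        raise RangeError(f"xw_critical must lie in [0, 1), got {xw_critical}")
    if xw_critical == 0:
        return 0.0
    x_db = wet_to_db_fraction(xw_critical)
    return invert(isotherm_params, x_db)
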