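"""Sorption thermodynamics from fitted isotherms at three or more temperatures.

Isosteres are built by inverting one fitted isotherm per temperature at a
fixed moisture content; ordinary least squares of ln(aw) on 1/T then yields
the net isosteric heat (qst = -slope*R) and the differential entropy
(dS = intercept*R).  The integral heat adds the latent heat of pure-water
vaporization, the Gibbs energy is -R*T*ln(aw), and enthalpy--entropy
compensation regresses qst on dS to obtain the isokinetic temperature,
compared against the harmonic mean of the experiment temperatures.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import R_GAS
from .data_model import Branch
from .errors import DomainError, RangeError, ValidationError
from .isotherm_models import AW_MAX, invert
from .model_fitting import IsothermFit

__all__ = [
    "ThermoProfile",
    "TrendFamily",
    "TrendFit",
    "CompensationResult",
    "Verdict",
    "build_isosteres",
    "default_xe_grid",
    "fit_isostere",
    "latent_heat",
    "integral_heat",
    "gibbs_energy",
    "fit_trend",
    "harmonic_mean_temperature",
    "compensation",
    "thermo_profile",
]

logger = logging.getLogger(__name__)


class TrendFamily(str, enum.Enum):
    POWER = "power"        # y = a * x**b
    LOG = "log"            # y = a * ln(x) + c
    EXP = "exp"            # y = a * exp(b*x)
    LINEAR = "linear"      # y = a * x + c


class Verdict(str, enum.Enum):
    ENTHALPY_DRIVEN = "enthalpy_driven"
    ENTROPY_DRIVEN = "entropy_driven"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class TrendFit:
    family: TrendFamily
    coefficients: dict[str, float]
    r2: float


@dataclass(frozen=True)
class CompensationResult:
    T_beta: float           # isokinetic temperature, K (regression slope)
    dG_beta: float          # Gibbs energy at T_beta, J/mol (intercept)
    r2: float
    T_h: float              # harmonic mean temperature, K
    verdict: Verdict


@dataclass
class ThermoProfile:
    """Per-moisture thermodynamic arrays for one branch."""

    branch: Branch
    xe_grid: np.ndarray
    qst: np.ndarray                  # net isosteric heat, J/mol
    Qst: np.ndarray                  # integral isosteric heat, J/mol
    dS: np.ndarray                   # differential entropy, J/(mol K)
    r2_per_xe: np.ndarray
    dG: pd.DataFrame                 # columns: xe, T, aw, dG (J/mol)
    T_ref: float                     # temperature used for the latent heat


# ---------------------------------------------------------------------------
# isosteres
# ---------------------------------------------------------------------------

def default_xe_grid(
    fits: Sequence[IsothermFit],
    n: int = 12,
    aw_range: tuple[float, float] = (0.05, 0.95),
) -> np.ndarray:
    """Moisture grid on the common invertible support of all fits.

    Spans from the maximum of the per-temperature minimum fitted moisture to
    the minimum of the per-temperature maximum, shrunk 1% inward so every
    value inverts at every temperature.
    """
    lo = max(float(f.predict(aw_range[0])) for f in fits)
    hi = min(float(f.predict(aw_range[1])) for f in fits)
    if not (hi > lo > 0):
        raise ValidationError(
            f"fitted curves share no common moisture support ({lo:.4g}..{hi:.4g})"
        )
    span = hi - lo
    return np.linspace(lo + 0.01 * span, hi - 0.01 * span, n)


def build_isosteres(
    fits: Sequence[IsothermFit],
    xe_grid: Sequence[float],
    aw_bracket: tuple[float, float] = (1e-6, AW_MAX),
) -> pd.DataFrame:
    """Invert one fitted isotherm per temperature at each grid moisture.

    Returns a dataframe with columns ``xe, T, aw, ln_aw, inv_T``.  Grid
    values that fail to invert at any temperature are dropped (logged).
    Requires at least three distinct temperatures.
    """
    temps = sorted({f.T for f in fits})
    if len(temps) < 3:
        raise ValidationError(
            f"isosteres need fits at >= 3 temperatures, got {len(temps)}"
        )
    by_T = {f.T: f for f in fits}
    if len(by_T) != len(fits):
        raise ValidationError("expected exactly one fit per temperature")

    rows = []
    for xe in np.asarray(xe_grid, dtype=float):
        entry = []
        try:
            for T in temps:
                aw = invert(by_T[T].params, float(xe), aw_bracket=aw_bracket)
                entry.append((float(xe), T, aw, float(np.log(aw)), 1.0 / T))
        except (RangeError, DomainError, Exception) as exc:
            logger.warning("dropping xe=%.5g from isostere table: %s", xe, exc)
            continue
        rows.extend(entry)
    if not rows:
        raise ValidationError("no xe grid value was invertible at all temperatures")
    return pd.DataFrame(rows, columns=["xe", "T", "aw", "ln_aw", "inv_T"])


def fit_isostere(lnaw: Sequence[float], invT: Sequence[float]) -> tuple[float, float, float]:
    """OLS of ln(aw) on 1/T: returns (qst [J/mol], dS [J/(mol K)], r2).

    qst = -slope * R, dS = intercept * R.
    """
    y = np.asarray(lnaw, dtype=float)
    x = np.asarray(invT, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValidationError("need >= 3 aligned (ln aw, 1/T) pairs")
    if np.ptp(x) <= 0:
        raise ValidationError("1/T values are degenerate (all equal)")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(-slope * R_GAS), float(intercept * R_GAS), float(r2)


# ---------------------------------------------------------------------------
# heats, entropy, Gibbs energy
# ---------------------------------------------------------------------------

def latent_heat(T: float) -> float:
    """Latent heat of vaporization of pure water, J/mol: R*(6687 - 5.31*T)."""
    if not (250.0 <= T <= 400.0):
        logger.warning("latent_heat called at T=%.2f K outside 250-400 K", T)
    return R_GAS * (6687.0 - 5.31 * T)


def integral_heat(qst, T_ref: float):
    """Integral isosteric heat: Qst = qst + latent_heat(T_ref)."""
    return np.asarray(qst, dtype=float) + latent_heat(T_ref)


def gibbs_energy(T: float, aw) -> float | np.ndarray:
    """Gibbs free energy of sorption, J/mol: dG = -R*T*ln(aw)."""
    aw_arr = np.asarray(aw, dtype=float)
    if np.any(aw_arr <= 0) or np.any(aw_arr > 1):
        raise DomainError("aw must lie in (0, 1]")
    out = -R_GAS * T * np.log(aw_arr)
    return float(out) if out.ndim == 0 else out


def harmonic_mean_temperature(temps: Sequence[float]) -> float:
    """Harmonic mean temperature: n / sum(1/T)."""
    t = np.asarray(temps, dtype=float)
    if t.size == 0 or np.any(t <= 0):
        raise ValidationError("temperatures must be positive and non-empty")
    return float(t.size / np.sum(1.0 / t))


# ---------------------------------------------------------------------------
# trend fits
# ---------------------------------------------------------------------------

def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - pred) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_trend(x: Sequence[float], y: Sequence[float], family: TrendFamily | str) -> TrendFit:
    """Fit one of the trend families to (x, y).

    Power and exponential fits are nonlinear least squares in the original
    space (not log-linearized); the log family is linear regression on
    ln(x).  Power and log require x > 0.
    """
    family = TrendFamily(family)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 aligned (x, y) points")
    if family in (TrendFamily.POWER, TrendFamily.LOG) and np.any(x <= 0):
        raise ValidationError(f"{family.value} family requires x > 0")

    if family is TrendFamily.LINEAR:
        a, c = np.polyfit(x, y, 1)
        pred = a * x + c
        return TrendFit(family, {"a": float(a), "c": float(c)}, _r2(y, pred))

    if family is TrendFamily.LOG:
        a, c = np.polyfit(np.log(x), y, 1)
        pred = a * np.log(x) + c
        return TrendFit(family, {"a": float(a), "c": float(c)}, _r2(y, pred))

    if family is TrendFamily.POWER:
        # init from log-log regression when possible
        if np.all(y > 0):
            b0, loga = np.polyfit(np.log(x), np.log(y), 1)
            init = np.array([np.exp(loga), b0])
        else:
            init = np.array([y[np.argmin(x)], -0.1])

        def resid(theta):
            a, b = theta
            return y - a * x**b

    else:  # EXP
        if np.all(y > 0):
            b0, loga = np.polyfit(x, np.log(y), 1)
            init = np.array([np.exp(loga), b0])
        else:
            init = np.array([y[0] if y[0] != 0 else 1.0, 0.0])

        def resid(theta):
            a, b = theta
            with np.errstate(over="ignore"):
                return y - a * np.exp(np.clip(b * x, -700, 700))

    res = least_squares(resid, init, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    a, b = res.x
    pred = y - resid(res.x)
    return TrendFit(family, {"a": float(a), "b": float(b)}, _r2(y, pred))


# ---------------------------------------------------------------------------
# compensation
# ---------------------------------------------------------------------------

def compensation(
    dH: Sequence[float],
    dS: Sequence[float],
    temps: Sequence[float],
    r2_min: float = 0.9,
) -> CompensationResult:
    """Enthalpy--entropy compensation: OLS of dH on dS.

    Slope = isokinetic temperature T_beta (K), intercept = dG_beta (J/mol).
    Verdict: indeterminate when the fit r2 < ``r2_min``; otherwise
    enthalpy-driven iff T_beta > T_h (harmonic mean of ``temps``), else
    entropy-driven.
    """
    h = np.asarray(dH, dtype=float)
    s = np.asarray(dS, dtype=float)
    if h.size != s.size or h.size < 3:
        raise ValidationError("dH and dS must be aligned with >= 3 entries")
    if np.ptp(s) <= 0 or np.var(s) == 0:
        raise ValidationError("dS has zero variance; compensation slope undefined")
    t_beta, dg_beta = np.polyfit(s, h, 1)
    pred = t_beta * s + dg_beta
    r2 = _r2(h, pred)
    t_h = harmonic_mean_temperature(temps)
    if r2 < r2_min:
        verdict = Verdict.INDETERMINATE
    elif t_beta > t_h:
        verdict = Verdict.ENTHALPY_DRIVEN
    else:
        verdict = Verdict.ENTROPY_DRIVEN
    return CompensationResult(
        T_beta=float(t_beta), dG_beta=float(dg_beta), r2=float(r2),
        T_h=t_h, verdict=verdict,
    )


# ---------------------------------------------------------------------------
# full profile
# ---------------------------------------------------------------------------

def thermo_profile(
    fits: Sequence[IsothermFit],
    xe_grid: Sequence[float] | None = None,
    T_ref: Optional[float] = None,
) -> ThermoProfile:
    """Compute qst, Qst, dS and dG profiles from one fit per temperature.

    ``T_ref`` for the latent-heat term defaults to the harmonic mean of the
    fit temperatures.
    """
    branches = {f.branch for f in fits}
    if len(branches) != 1:
        raise ValidationError("thermo_profile expects fits for one branch")
    branch = branches.pop()
    temps = sorted({f.T for f in fits})
    if xe_grid is None:
        xe_grid = default_xe_grid(fits)
    table = build_isosteres(fits, xe_grid)

    qst_list, ds_list, r2_list, kept_xe = [], [], [], []
    dg_rows = []
    for xe, sub in table.groupby("xe", sort=True):
        q, s, r2 = fit_isostere(sub["ln_aw"].to_numpy(), sub["inv_T"].to_numpy())
        kept_xe.append(xe)
        qst_list.append(q)
        ds_list.append(s)
        r2_list.append(r2)
        for _, row in sub.iterrows():
            dg_rows.append(
                (xe, row["T"], row["aw"], float(gibbs_energy(row["T"], row["aw"])))
            )

    t_ref = harmonic_mean_temperature(temps) if T_ref is None else T_ref
    qst = np.asarray(qst_list)
    return ThermoProfile(
        branch=branch,
        xe_grid=np.asarray(kept_xe),
        qst=qst,
        Qst=integral_heat(qst, t_ref),
        dS=np.asarray(ds_list),
        r2_per_xe=np.asarray(r2_list),
        dG=pd.DataFrame(dg_rows, columns=["xe", "T", "aw", "dG"]),
        T_ref=t_ref,
    )
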