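"""Spreading pressure of the sorbed water film via the Dent isotherm.

The Dent model is fitted with its monolayer fixed to the BET anchor, and the
spreading pressure is computed two ways: a closed form,

    phi(aw) = (kB*T/Am) * ln[(1 + b0*aw - b*aw) / (1 - b*aw)],

and direct adaptive quadrature of (kB*T/Am) * integral of theta(a)/a da with
theta = Xe/Xm, whose integrand has the finite limit b0 at a -> 0.  The two
routes agree to quadrature tolerance and serve as mutual oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import least_squares

from .constants import A_WATER_MOLECULE, K_BOLTZMANN
from .data_model import Branch, SorptionDataset
from .errors import DomainError, NumericError, ValidationError
from .isotherm_models import ModelParams, evaluate_raw
from .model_fitting import DEFAULT_SEED, goodness_of_fit

__all__ = ["DentFit", "SpreadingPressureCurve", "fit_dent", "phi_closed", "phi_numeric"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DentFit:
    """Dent constants (b, b0) with a fixed BET monolayer anchor."""

    b: float
    b0: float
    Xm_anchor: float
    r2: float
    branch: Branch
    T: float
    pole_warning: bool = False

    def params(self) -> ModelParams:
        return ModelParams("dent", (self.Xm_anchor, self.b, self.b0), T_for_eval=self.T)


@dataclass(frozen=True)
class SpreadingPressureCurve:
    """Spreading pressure phi(aw) in J/m^2 on a water-activity grid.

    ``phi_reduced`` is the dimensionless form phi*Am/(kB*T).
    """

    aw: np.ndarray
    phi: np.ndarray
    phi_reduced: np.ndarray
    T: float
    branch: Branch


def fit_dent(
    group: SorptionDataset,
    xm_anchor: float,
    n_starts: int = 8,
    seed: int = DEFAULT_SEED,
) -> DentFit:
    """Estimate (b, b0) by least squares in Xe-space with Xm fixed.

    Fitting in moisture space (rather than the aw/X linearization) keeps the
    error structure consistent with the other model fits.  If the fitted
    pole 1/b falls inside the observed activity range a warning flag is set
    but the fit is still returned.
    """
    if xm_anchor <= 0:
        raise ValidationError(f"xm_anchor must be > 0, got {xm_anchor}")
    branches = group.branches()
    temps = group.temperatures()
    if len(branches) != 1 or len(temps) != 1:
        raise ValidationError("fit_dent expects a single (branch, T) slice")
    aw = group.aw_values()
    xe = group.xe_values()
    if aw.size < 3:
        raise ValidationError("fit_dent requires at least 3 points")

    def residuals(theta: np.ndarray) -> np.ndarray:
        b, b0 = theta
        den1 = 1.0 - b * aw
        den1 = np.where(den1 <= 1e-12, 1e-12, den1)
        pred = xm_anchor * b0 * aw / (den1 * (den1 + b0 * aw))
        return xe - pred

    rng = np.random.default_rng(seed)
    lower = np.array([0.0, 1e-9])
    upper = np.array([0.9999, 1e6])
    starts = [np.array([0.3, 10.0])]
    while len(starts) < n_starts:
        starts.append(
            np.array([rng.uniform(0.0, 0.95), 10.0 ** rng.uniform(-1.0, 3.0)])
        )

    best = None
    for x0 in starts:
        res = least_squares(
            residuals, np.clip(x0, lower + 1e-12, upper - 1e-12),
            bounds=(lower, upper), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res

    b, b0 = best.x
    pole = bool(b * aw.max() >= 1.0)
    if pole:
        logger.warning("Dent pole inside data range: b*max(aw) = %.4f >= 1", b * aw.max())
    stats = goodness_of_fit(xe, xe - residuals(best.x))
    return DentFit(
        b=float(b), b0=float(b0), Xm_anchor=float(xm_anchor),
        r2=stats.r2_standard, branch=branches[0], T=temps[0], pole_warning=pole,
    )


def _check_pole(b: float, aw: float) -> None:
    if b * aw >= 1.0:
        raise DomainError(f"b*aw = {b * aw:.6g} >= 1: spreading pressure undefined")


def phi_closed(dent: DentFit, aw) -> float | np.ndarray:
    """Closed-form spreading pressure, J/m^2."""
    aw_arr = np.asarray(aw, dtype=float)
    scalar = aw_arr.ndim == 0
    aw_arr = np.atleast_1d(aw_arr)
    if np.any(aw_arr < 0):
        raise DomainError("aw must be >= 0")
    _check_pole(dent.b, float(aw_arr.max(initial=0.0)))
    pref = K_BOLTZMANN * dent.T / A_WATER_MOLECULE
    val = pref * np.log((1.0 + dent.b0 * aw_arr - dent.b * aw_arr) / (1.0 - dent.b * aw_arr))
    return float(val[0]) if scalar else val


def phi_numeric(dent: DentFit, aw_upper: float, tol: float = 1e-10) -> float:
    """Spreading pressure by adaptive quadrature of theta(a)/a.

    theta(a)/a = b0 / [(1 - b*a)(1 - b*a + b0*a)], a smooth integrand whose
    a -> 0 limit is b0, so no lower-bound offset is needed.
    """
    if aw_upper < 0:
        raise DomainError("aw_upper must be >= 0")
    if aw_upper == 0:
        return 0.0
    _check_pole(dent.b, aw_upper)
    b, b0 = dent.b, dent.b0

    def integrand(a: float) -> float:
        den1 = 1.0 - b * a
        return b0 / (den1 * (den1 + b0 * a))

    value, abserr = quad(integrand, 0.0, aw_upper, epsabs=0.0, epsrel=tol, limit=200)
    if not np.isfinite(value) or (value != 0 and abserr / abs(value) > max(tol * 100, 1e-8)):
        raise NumericError(
            f"quadrature did not converge (value={value}, abserr={abserr})"
        )
    pref = K_BOLTZMANN * dent.T / A_WATER_MOLECULE
    return float(pref * value)


def spreading_curve(
    dent: DentFit, aw_grid=None
) -> SpreadingPressureCurve:
    """Evaluate the closed-form spreading pressure on a grid (default
    0.05..0.80 step 0.05)."""
    if aw_grid is None:
        aw_grid = np.arange(0.05, 0.8001, 0.05)
    aw_grid = np.asarray(aw_grid, dtype=float)
    phi = np.asarray(phi_closed(dent, aw_grid), dtype=float)
    pref = K_BOLTZMANN * dent.T / A_WATER_MOLECULE
    return SpreadingPressureCurve(
        aw=aw_grid, phi=phi, phi_reduced=phi / pref, T=dent.T, branch=dent.branch
    )
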