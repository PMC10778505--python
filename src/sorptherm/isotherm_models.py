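"""Registry of sorption isotherm models.

Ten models are registered: Peleg, GAB, BET, Halsey, Oswin, Smith,
Adam--Shove, modified Oswin, modified Halsey and Dent.  Each exposes a
forward evaluation ``Xe = f(aw[, T])`` and a bracketed numeric inversion
``aw = f^-1(Xe[, T])``.

The two modified models consume temperature through an ``A + B*T`` prefactor
or exponent; ``T`` there is in **degrees Celsius** (the choice is recorded in
output metadata — the printed per-temperature parameter magnitudes only make
sense on the Celsius scale).  All other models ignore temperature.

Water activity is clamped to ``aw <= AW_MAX = 0.999`` because several models
are singular at ``aw = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import k_to_c
from .errors import DomainError, InversionError, RangeError, ValidationError

__all__ = [
    "AW_MAX",
    "ModelSpec",
    "ModelParams",
    "registry",
    "get_spec",
    "evaluate",
    "invert",
    "MODEL_IDS",
]

#: Upper clamp of the water-activity domain (many models diverge at aw -> 1).
AW_MAX = 0.999


@dataclass(frozen=True)
class ModelSpec:
    """Static description of one registered model."""

    model_id: str
    param_names: tuple[str, ...]
    uses_temperature: bool
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    default_init: tuple[float, ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


@dataclass(frozen=True)
class ModelParams:
    """A concrete parameter vector for one model.

    ``T_for_eval`` (kelvin) is consumed only by temperature-dependent models
    and may be ``None`` for the others.
    """

    model_id: str
    values: tuple[float, ...]
    T_for_eval: Optional[float] = None

    def __post_init__(self) -> None:
        spec = get_spec(self.model_id)
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) != spec.n_params:
            raise ValidationError(
                f"model {self.model_id!r} expects {spec.n_params} parameters "
                f"({', '.join(spec.param_names)}), got {len(self.values)}"
            )

    def as_dict(self) -> dict[str, float]:
        spec = get_spec(self.model_id)
        return dict(zip(spec.param_names, self.values))


# ---------------------------------------------------------------------------
# model functions: f(aw, values, t_c) -> Xe
# aw arrives as a validated ndarray within [0, AW_MAX]; t_c is Celsius or None
# ---------------------------------------------------------------------------

def _peleg(aw, v, t_c):
    c1, c2, c3, c4 = v
    return c1 * aw**c2 + c3 * aw**c4


def _gab(aw, v, t_c):
    xm, c, k = v
    den1 = 1.0 - k * aw
    if np.any(den1 <= 0):
        raise DomainError(f"GAB pole: 1 - K*aw <= 0 at K={k}")
    den2 = den1 + c * k * aw
    if np.any(den2 <= 0):
        raise DomainError("GAB pole: 1 - K*aw + C*K*aw <= 0")
    return xm * c * k * aw / (den1 * den2)


def _bet(aw, v, t_c):
    xm, c = v
    den = (1.0 - aw) * (1.0 + (c - 1.0) * aw)
    if np.any(den <= 0):
        raise DomainError("BET pole: (1-aw)(1+(C-1)aw) <= 0")
    return xm * c * aw / den


def _halsey(aw, v, t_c):
    a, b = v
    with np.errstate(divide="ignore"):
        neg_ln = -np.log(aw)
    # aw = 0 -> -ln aw = +inf -> Xe = 0 (continuous limit)
    return np.where(neg_ln > 0, (a / np.where(neg_ln > 0, neg_ln, 1.0)) ** (1.0 / b), 0.0)


def _oswin(aw, v, t_c):
    k, n = v
    return k * (aw / (1.0 - aw)) ** n


def _smith(aw, v, t_c):
    a, b = v
    return a - b * np.log1p(-aw)


def _adam_shove(aw, v, t_c):
    a, b, c, d = v
    return a + b * aw + c * aw**2 + d * aw**3


def _mod_oswin(aw, v, t_c):
    a, b, c = v
    pref = a + b * t_c
    return pref * (aw / (1.0 - aw)) ** c


def _mod_halsey(aw, v, t_c):
    a, b, c = v
    with np.errstate(divide="ignore", over="ignore"):
        neg_ln = -np.log(aw)
        expo = np.exp(np.clip(a + b * t_c, -700.0, 700.0))
    return np.where(neg_ln > 0, (expo / np.where(neg_ln > 0, neg_ln, 1.0)) ** (1.0 / c), 0.0)


def _dent(aw, v, t_c):
    xm, b, b0 = v
    den1 = 1.0 - b * aw
    if np.any(den1 <= 0):
        raise DomainError(f"Dent pole: 1 - b*aw <= 0 at b={b}")
    den2 = den1 + b0 * aw
    return xm * b0 * aw / (den1 * den2)


_MODEL_FUNCS: dict[str, Callable] = {
    "peleg": _peleg,
    "gab": _gab,
    "bet": _bet,
    "halsey": _halsey,
    "oswin": _oswin,
    "smith": _smith,
    "adam_shove": _adam_shove,
    "mod_oswin": _mod_oswin,
    "mod_halsey": _mod_halsey,
    "dent": _dent,
}


_REGISTRY: tuple[ModelSpec, ...] = (
    ModelSpec(
        "peleg", ("C1", "C2", "C3", "C4"), False,
        lower=(1e-12, 1e-3, 1e-12, 1e-3), upper=(1e3, 100.0, 1e3, 100.0),
        default_init=(0.3, 5.0, 0.05, 1.5),
    ),
    ModelSpec(
        "gab", ("Xm", "C", "K"), False,
        lower=(1e-6, 1e-6, 1e-6), upper=(10.0, 1e10, 1.2),
        default_init=(0.05, 10.0, 0.8),
    ),
    ModelSpec(
        "bet", ("Xm", "C"), False,
        lower=(1e-6, 1e-6), upper=(10.0, 1e12),
        default_init=(0.05, 10.0),
    ),
    ModelSpec(
        "halsey", ("A", "B"), False,
        lower=(1e-9, 0.01), upper=(100.0, 20.0),
        default_init=(0.05, 1.5),
    ),
    ModelSpec(
        "oswin", ("K", "n"), False,
        lower=(1e-9, 0.01), upper=(100.0, 10.0),
        default_init=(0.05, 0.5),
    ),
    ModelSpec(
        "smith", ("A", "B"), False,
        lower=(-10.0, -10.0), upper=(10.0, 10.0),
        default_init=(0.01, 0.1),
    ),
    ModelSpec(
        "adam_shove", ("A", "B", "C", "D"), False,
        lower=(-100.0,) * 4, upper=(100.0,) * 4,
        default_init=(0.01, 0.1, 0.1, 0.1),
    ),
    ModelSpec(
        "mod_oswin", ("A", "B", "C"), True,
        lower=(-1e3, -100.0, 0.01), upper=(1e3, 100.0, 10.0),
        default_init=(0.05, 1e-3, 0.5),
    ),
    ModelSpec(
        "mod_halsey", ("A", "B", "C"), True,
        lower=(-1e3, -100.0, 0.01), upper=(1e3, 100.0, 20.0),
        default_init=(-3.0, 1e-3, 1.5),
    ),
    ModelSpec(
        "dent", ("Xm", "b", "b0"), False,
        lower=(1e-6, 0.0, 1e-9), upper=(10.0, 0.999, 1e6),
        default_init=(0.05, 0.3, 10.0),
    ),
)

MODEL_IDS: tuple[str, ...] = tuple(s.model_id for s in _REGISTRY)
_SPEC_BY_ID = {s.model_id: s for s in _REGISTRY}


def registry() -> list[ModelSpec]:
    """All registered model specs, in stable order."""
    return list(_REGISTRY)


def get_spec(model_id: str) -> ModelSpec:
    try:
        return _SPEC_BY_ID[model_id]
    except KeyError:
        raise ValidationError(
            f"unknown model {model_id!r}; known: {', '.join(MODEL_IDS)}"
        ) from None


def evaluate_raw(model_id: str, values: Sequence[float], aw, T=None):
    """Evaluate a model from raw parameter values.

    ``T`` is in kelvin and may be an array aligned with ``aw`` for
    temperature-dependent models; ignored otherwise.
    """
    spec = get_spec(model_id)
    aw_arr = np.asarray(aw, dtype=float)
    scalar = aw_arr.ndim == 0
    aw_arr = np.atleast_1d(aw_arr)
    if np.any(aw_arr < 0) or np.any(aw_arr > AW_MAX):
        raise DomainError(f"aw must lie in [0, {AW_MAX}]")
    t_c = None
    if spec.uses_temperature:
        if T is None:
            raise ValidationError(f"model {model_id!r} requires a temperature")
        t_c = k_to_c(np.asarray(T, dtype=float))
    out = np.asarray(_MODEL_FUNCS[model_id](aw_arr, tuple(values), t_c), dtype=float)
    return float(out[0]) if scalar else out


def evaluate(params: ModelParams, aw):
    """Evaluate ``Xe = f(aw)`` for a parameter set.

    Returns a float for scalar ``aw``, an ndarray otherwise.
    """
    return evaluate_raw(params.model_id, params.values, aw, T=params.T_for_eval)


def invert(
    params: ModelParams,
    xe_target: float,
    aw_bracket: tuple[float, float] = (1e-6, AW_MAX),
    n_monotone_check: int = 64,
) -> float:
    """Solve ``evaluate(params, aw) = xe_target`` for ``aw`` on a bracket.

    The curve must be strictly monotone on the bracket (checked by sampling)
    and the target must lie inside the bracket's image.  Root finding is
    bracketed (Brent), never derivative-based, so flat low-activity regions
    (e.g. Peleg with large exponents) are handled robustly.
    """
    if xe_target < 0:
        raise RangeError(f"xe_target must be >= 0, got {xe_target}")
    lo, hi = aw_bracket
    if not (0 <= lo < hi <= AW_MAX):
        raise ValidationError(f"invalid bracket {aw_bracket}")

    grid = np.linspace(lo, hi, n_monotone_check)
    values = evaluate(params, grid)
    diffs = np.diff(values)
    if np.all(diffs > 0):
        increasing = True
    elif np.all(diffs < 0):
        increasing = False
    else:
        raise InversionError(
            f"model {params.model_id!r} is not strictly monotone on "
            f"[{lo}, {hi}]; try a narrower bracket"
        )

    f_lo, f_hi = values[0], values[-1]
    y_min, y_max = (f_lo, f_hi) if increasing else (f_hi, f_lo)
    if not (y_min <= xe_target <= y_max):
        raise RangeError(
            f"xe_target={xe_target} outside attainable range "
            f"[{y_min:.6g}, {y_max:.6g}] on bracket [{lo}, {hi}]"
        )

    def objective(aw: float) -> float:
        return evaluate(params, aw) - xe_target

    root = brentq(objective, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    resid = abs(objective(root))
    if resid > 1e-10 * max(1.0, abs(xe_target)):
        raise InversionError(
            f"inversion residual {resid:.3g} exceeds tolerance for "
            f"model {params.model_id!r}"
        )
    return float(root)
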