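"""Nonlinear least-squares fitting of isotherm models and model ranking.

Fitting is multi-start (default 32 starts: the registry's default init plus
log-uniform perturbations drawn from a caller-supplied seed) and therefore
deterministic for a given seed.  Goodness of fit reports both R-squared
variants, the per-point mean squared error ("sse", which carries a 1/N
factor) and the mean relative percent error E%.

Selection rule: a model passes when, at every temperature, the conventional
R-squared is at least 0.90 and E% is below 10; passing models are ordered by
total sse ascending, ties broken by mean E% then by parameter count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .data_model import Branch, FitStatistics, SorptionDataset
from .errors import NonConvergenceError, ValidationError
from .isotherm_models import (
    ModelParams,
    ModelSpec,
    evaluate_raw,
    get_spec,
    registry,
)

__all__ = [
    "DEFAULT_SEED",
    "IsothermFit",
    "ModelRanking",
    "goodness_of_fit",
    "fit_isotherm",
    "fit_all_models",
    "rank_models",
]

logger = logging.getLogger(__name__)

#: Default seed for multi-start perturbations.
DEFAULT_SEED = 20231226

#: Relative-error floor: observations at or below this moisture content are
#: excluded from the E% average (the relative error is undefined at zero).
E_PERCENT_FLOOR = 1e-6

#: Selection thresholds.
R2_THRESHOLD = 0.90
E_PERCENT_THRESHOLD = 10.0


@dataclass(frozen=True)
class IsothermFit:
    """Result of fitting one model to one (branch, temperature) group."""

    model_id: str
    branch: Branch
    T: float
    params: ModelParams
    stats: FitStatistics
    converged: bool
    n_starts_used: int

    def predict(self, aw):
        from .isotherm_models import evaluate

        return evaluate(self.params, aw)


@dataclass(frozen=True)
class ModelRanking:
    """Aggregate ranking of all models for one branch."""

    branch: Branch
    model_ids: tuple[str, ...]            # ordered best -> worst
    mean_r2: dict[str, float]
    mean_e_percent: dict[str, float]
    total_sse: dict[str, float]
    passes_criteria: dict[str, bool]
    best_model_id: str
    no_model_passed: bool = False


def goodness_of_fit(
    observed: Sequence[float],
    predicted: Sequence[float],
    floor: float = E_PERCENT_FLOOR,
) -> FitStatistics:
    """Compute the fit statistics for one curve.

    ``sse`` is the mean squared error ``(1/N) * sum((obs - pred)^2)``;
    ``e_percent`` is ``(100/N') * sum(|obs - pred| / obs)`` over the N'
    observations exceeding ``floor``.  Both R-squared variants are returned:
    the regression-SS ratio (``r2_regression``) and the conventional
    ``1 - SSres/SStot`` (``r2_standard``, which drives model selection).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValidationError(
            f"observed and predicted must be equal-length 1-D vectors, "
            f"got shapes {obs.shape} and {pred.shape}"
        )
    n = obs.size
    if n < 2:
        raise ValidationError("at least 2 points required")

    resid = obs - pred
    sse = float(np.mean(resid**2))

    admissible = obs > floor
    n_excluded = int(n - admissible.sum())
    if admissible.any():
        e_percent = float(
            100.0 * np.mean(np.abs(resid[admissible]) / obs[admissible])
        )
    else:
        e_percent = 0.0
    if n_excluded:
        logger.warning(
            "E%% computed over %d of %d points (observations <= %g excluded)",
            n - n_excluded, n, floor,
        )

    mean_obs = obs.mean()
    ss_tot = float(np.sum((obs - mean_obs) ** 2))
    ss_reg = float(np.sum((pred - mean_obs) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot > 0:
        r2_regression = ss_reg / ss_tot
        r2_standard = 1.0 - ss_res / ss_tot
    else:  # constant observations
        r2_regression = 1.0 if ss_reg == 0 else np.inf
        r2_standard = 1.0 if ss_res == 0 else 0.0

    return FitStatistics(
        r2_regression=r2_regression,
        r2_standard=r2_standard,
        sse=sse,
        e_percent=e_percent,
        n_points=n,
        n_excluded_e=n_excluded,
    )


def _initial_points(
    spec: ModelSpec, n_starts: int, rng: np.random.Generator,
    aw: np.ndarray, xe: np.ndarray, T: np.ndarray,
) -> list[np.ndarray]:
    """Build the multi-start initial parameter vectors.

    Start 0 is the registry default (or an exact linear least-squares
    solution for models linear in their parameters); the remaining starts
    perturb it by elementwise log-uniform multipliers in [0.1, 10].
    """
    lower = np.asarray(spec.lower)
    upper = np.asarray(spec.upper)
    base = np.asarray(spec.default_init, dtype=float)

    starts = []
    linear = _linear_init(spec.model_id, aw, xe)
    if linear is not None:
        starts.append(np.clip(linear, lower, upper))
    starts.append(np.clip(base, lower, upper))

    while len(starts) < n_starts:
        mult = 10.0 ** rng.uniform(-1.0, 1.0, size=base.size)
        cand = base * mult
        # parameters with zero/near-zero default: draw additively instead
        tiny = np.abs(base) < 1e-8
        if tiny.any():
            cand[tiny] = rng.uniform(-0.5, 0.5, size=int(tiny.sum()))
        # occasionally flip signs where the bounds allow negatives
        flip = (rng.random(base.size) < 0.25) & (lower < 0)
        cand[flip] = -cand[flip]
        starts.append(np.clip(cand, lower, upper))
    return starts[:n_starts]


def _linear_init(model_id: str, aw: np.ndarray, xe: np.ndarray) -> Optional[np.ndarray]:
    """Exact linear LS solution for models linear in their parameters."""
    if model_id == "smith":
        design = np.column_stack([np.ones_like(aw), -np.log1p(-aw)])
        coef, *_ = np.linalg.lstsq(design, xe, rcond=None)
        return np.asarray(coef)
    if model_id == "adam_shove":
        design = np.column_stack([np.ones_like(aw), aw, aw**2, aw**3])
        coef, *_ = np.linalg.lstsq(design, xe, rcond=None)
        return np.asarray(coef)
    return None


def fit_isotherm(
    group: SorptionDataset,
    model_id: str,
    n_starts: int = 32,
    seed: int = DEFAULT_SEED,
) -> IsothermFit:
    """Fit one model to one (branch, temperature) group.

    For temperature-dependent models (modified Oswin/Halsey) the group may
    span several temperatures of one branch — the ``A + B*T`` term is only
    jointly identifiable across temperatures.  For all other models the
    group must be a single (branch, T) slice.

    Deterministic for fixed (group, model_id, n_starts, seed).
    """
    spec = get_spec(model_id)
    branches = group.branches()
    if len(branches) != 1:
        raise ValidationError("fit group must contain exactly one branch")
    temps = group.temperatures()
    if not spec.uses_temperature and len(temps) != 1:
        raise ValidationError(
            f"model {model_id!r} fits a single temperature; group has {len(temps)}"
        )

    aw = group.aw_values()
    xe = group.xe_values()
    T = np.asarray([p.T for p in group.points], dtype=float)
    n_min = max(3, spec.n_params)
    if aw.size < n_min:
        raise ValidationError(
            f"{aw.size} points insufficient for {spec.n_params}-parameter "
            f"model {model_id!r} (need >= {n_min})"
        )
    group.require_fittable()

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            pred = evaluate_raw(model_id, theta, aw, T=T if spec.uses_temperature else None)
        except Exception:
            return np.full_like(xe, 1e6)
        pred = np.asarray(pred, dtype=float)
        bad = ~np.isfinite(pred)
        if bad.any():
            pred = np.where(bad, 1e6, pred)
        return xe - pred

    rng = np.random.default_rng(seed)
    lower = np.asarray(spec.lower)
    upper = np.asarray(spec.upper)
    # keep starts strictly inside the box for the trf algorithm
    eps = 1e-12
    starts = _initial_points(spec, n_starts, rng, aw, xe, T)

    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        x0 = np.minimum(np.maximum(x0, lower + eps), upper - eps)
        try:
            res = least_squares(
                residuals, x0, bounds=(lower, upper), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=4000,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None or not np.isfinite(best.cost):
        raise NonConvergenceError(
            f"no start converged for model {model_id!r}",
            best_residual_norm=None if best is None else float(np.sqrt(2 * best.cost)),
        )

    t_eval = temps[0] if len(temps) == 1 else float(np.mean(temps))
    params = ModelParams(model_id=model_id, values=tuple(best.x), T_for_eval=t_eval)
    pred = evaluate_raw(model_id, best.x, aw, T=T if spec.uses_temperature else None)
    stats = goodness_of_fit(xe, pred)
    return IsothermFit(
        model_id=model_id,
        branch=branches[0],
        T=t_eval,
        params=params,
        stats=stats,
        converged=bool(best.status > 0),
        n_starts_used=n_used,
    )


def fit_all_models(
    dataset: SorptionDataset,
    model_ids: Sequence[str] | None = None,
    n_starts: int = 32,
    seed: int = DEFAULT_SEED,
) -> list[IsothermFit]:
    """Fit every requested model to every (branch, T) group of the dataset.

    Temperature-dependent models are fitted once per branch on the pooled
    multi-temperature slice and reported once per temperature with the same
    parameters (matching per-temperature reporting conventions).
    """
    if model_ids is None:
        model_ids = [s.model_id for s in registry()]
    fits: list[IsothermFit] = []
    for branch in dataset.branches():
        temps = dataset.temperatures(branch)
        for model_id in model_ids:
            spec = get_spec(model_id)
            if spec.uses_temperature and len(temps) > 1:
                pooled = SorptionDataset(
                    points=[p for p in dataset.points if p.branch is branch],
                    label=dataset.label,
                )
                pooled_fit = fit_isotherm(pooled, model_id, n_starts=n_starts, seed=seed)
                for T in temps:
                    grp = dataset.group(branch, T)
                    params = ModelParams(model_id, pooled_fit.params.values, T_for_eval=T)
                    pred = evaluate_raw(model_id, params.values, grp.aw_values(), T=T)
                    stats = goodness_of_fit(grp.xe_values(), pred)
                    fits.append(
                        IsothermFit(
                            model_id=model_id, branch=branch, T=T, params=params,
                            stats=stats, converged=pooled_fit.converged,
                            n_starts_used=pooled_fit.n_starts_used,
                        )
                    )
            else:
                for T in temps:
                    grp = dataset.group(branch, T)
                    fits.append(fit_isotherm(grp, model_id, n_starts=n_starts, seed=seed))
    return fits


def rank_models(fits: Sequence[IsothermFit]) -> ModelRanking:
    """Rank all models of one branch by the selection criteria.

    Pass filter: ``r2_standard >= 0.90`` and ``E% < 10`` at every
    temperature.  Passing models are ordered by total sse ascending, ties by
    mean E% then by fewer parameters.  If no model passes, the best model by
    total sse is reported with a warning flag.
    """
    if not fits:
        raise ValidationError("no fits supplied")
    branches = {f.branch for f in fits}
    if len(branches) != 1:
        raise ValidationError("rank_models expects fits for exactly one branch")
    branch = branches.pop()

    by_model: dict[str, list[IsothermFit]] = {}
    for f in fits:
        by_model.setdefault(f.model_id, []).append(f)

    mean_r2, mean_e, total_sse, passes = {}, {}, {}, {}
    for mid, group in by_model.items():
        mean_r2[mid] = float(np.mean([f.stats.r2_standard for f in group]))
        mean_e[mid] = float(np.mean([f.stats.e_percent for f in group]))
        total_sse[mid] = float(np.sum([f.stats.sse for f in group]))
        passes[mid] = all(
            f.stats.r2_standard >= R2_THRESHOLD
            and f.stats.e_percent < E_PERCENT_THRESHOLD
            for f in group
        )

    def sort_key(mid: str):
        return (total_sse[mid], mean_e[mid], get_spec(mid).n_params)

    passing = sorted([m for m in by_model if passes[m]], key=sort_key)
    failing = sorted([m for m in by_model if not passes[m]], key=sort_key)
    ordered = tuple(passing + failing)

    if passing:
        best, warn = passing[0], False
    else:
        best, warn = ordered[0], True
        logger.warning(
            "no model passed the selection criteria for branch %s; "
            "falling back to lowest total sse (%s)", branch.value, best,
        )

    return ModelRanking(
        branch=branch,
        model_ids=ordered,
        mean_r2=mean_r2,
        mean_e_percent=mean_e,
        total_sse=total_sse,
        passes_criteria=passes,
        best_model_id=best,
        no_model_passed=warn,
    )
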