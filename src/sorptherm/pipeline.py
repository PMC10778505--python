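"""Orchestration of the full analysis: fit -> rank -> spreading pressure ->
thermodynamics -> glass transition -> report.

The report is a plain JSON-serializable dict; serialization uses sorted keys
so that identical configs and seeds give byte-identical documents.  Stage
failures degrade to a partial report with the failure recorded under
``failures``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .constants import k_to_c
from .data_model import (
    Branch,
    GlassTransitionPoint,
    SorptionDataset,
    db_to_wet_fraction,
    read_sorption_csv,
    read_tg_csv,
)
from .errors import SorpthermError, ValidationError
from .glass_transition import (
    TGW_WATER_C,
    critical_aw,
    critical_moisture,
    fit_gordon_taylor,
)
from .isotherm_models import get_spec
from .model_fitting import (
    DEFAULT_SEED,
    IsothermFit,
    fit_all_models,
    rank_models,
)
from .spreading_pressure import fit_dent, phi_closed, spreading_curve
from .synthetic_data import default_scenario, generate_sorption
from .thermodynamics import TrendFamily, compensation, fit_trend, thermo_profile

__all__ = ["AnalysisConfig", "run_pipeline", "hysteresis_report", "report_to_json"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Configuration for one pipeline run."""

    input_csv: Optional[str] = None          # None -> default synthetic scenario
    tg_csv: Optional[str] = None
    temperature_unit: str = "C"
    seed: int = DEFAULT_SEED
    models: Optional[Sequence[str]] = None   # None -> all registered
    n_starts: int = 32
    storage_temp_c: float = 25.0
    tgw_c: float = TGW_WATER_C
    compensation_mode: str = "qst"           # or "Qst"
    aw_grid_spread: Sequence[float] = field(
        default_factory=lambda: [round(0.05 * i, 2) for i in range(1, 17)]
    )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["aw_grid_spread"] = [float(v) for v in self.aw_grid_spread]
        if d["models"] is not None:
            d["models"] = list(d["models"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _round_floats(obj, ndigits: int = 10):
    """Round floats recursively so report serialization is stable."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_round_floats(float(v), ndigits) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return _round_floats(float(obj), ndigits)
    return obj


def hysteresis_report(
    fits: Sequence[IsothermFit],
    aw_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Desorption-minus-adsorption moisture difference on a common grid.

    ``fits`` holds one best fit per (branch, T).  Returns rows
    ``(T, aw, delta_xe)`` plus a trapezoidal ``loop_area`` per temperature
    (stored on the frame's attrs).  Temperatures missing a branch are
    skipped with a warning.
    """
    if aw_grid is None:
        aw_grid = np.linspace(0.09, 0.83, 25)
    aw_grid = np.asarray(aw_grid, dtype=float)
    by_key = {(f.branch, round(f.T, 6)): f for f in fits}
    temps = sorted({round(f.T, 6) for f in fits})
    rows, areas = [], {}
    for T in temps:
        ads = by_key.get((Branch.ADSORPTION, T))
        des = by_key.get((Branch.DESORPTION, T))
        if ads is None or des is None:
            logger.warning("hysteresis at T=%.2f skipped: missing a branch", T)
            continue
        diff = np.asarray(des.predict(aw_grid)) - np.asarray(ads.predict(aw_grid))
        for a, d in zip(aw_grid, diff):
            rows.append((T, float(a), float(d)))
        areas[T] = float(np.trapezoid(diff, aw_grid))
    frame = pd.DataFrame(rows, columns=["T", "aw", "delta_xe"])
    frame.attrs["loop_area"] = areas
    return frame


def _best_fits_per_T(
    fits: Sequence[IsothermFit], branch: Branch, model_id: str
) -> list[IsothermFit]:
    return sorted(
        (f for f in fits if f.branch is branch and f.model_id == model_id),
        key=lambda f: f.T,
    )


def run_pipeline(config: AnalysisConfig) -> dict[str, Any]:
    """Execute the full analysis and return the report dict."""
    report: dict[str, Any] = {
        "provenance": {
            "package": "sorptherm",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "modified_model_temperature_unit": "C",
        },
        "failures": [],
    }

    def fail(stage: str, exc: Exception) -> None:
        logger.warning("stage %s failed: %s", stage, exc)
        report["failures"].append({"stage": stage, "error": str(exc)})

    # ---- load or synthesize data -------------------------------------
    if config.input_csv is not None:
        dataset = read_sorption_csv(config.input_csv, temperature_unit=config.temperature_unit)
    else:
        dataset = generate_sorption(default_scenario(seed=config.seed))
    report["data"] = {
        "label": dataset.label,
        "n_points": len(dataset),
        "branches": [b.value for b in dataset.branches()],
        "temperatures_K": dataset.temperatures(),
    }

    # ---- fit all models ----------------------------------------------
    fits = fit_all_models(
        dataset, model_ids=config.models, n_starts=config.n_starts, seed=config.seed
    )
    parameters: dict[str, Any] = {}
    criteria: dict[str, Any] = {}
    for f in fits:
        t_key = f"{k_to_c(f.T):.2f}C"
        parameters.setdefault(f.branch.value, {}).setdefault(f.model_id, {})[t_key] = (
            f.params.as_dict()
        )
        criteria.setdefault(f.branch.value, {}).setdefault(f.model_id, {})[t_key] = {
            "sse": f.stats.sse,
            "r2_standard": f.stats.r2_standard,
            "r2_regression": f.stats.r2_regression,
            "e_percent": f.stats.e_percent,
            "n_points": f.stats.n_points,
        }
    report["parameters"] = parameters
    report["criteria"] = criteria

    # ---- ranking ------------------------------------------------------
    rankings: dict[Branch, Any] = {}
    report["ranking"] = {}
    for branch in dataset.branches():
        branch_fits = [f for f in fits if f.branch is branch]
        ranking = rank_models(branch_fits)
        rankings[branch] = ranking
        report["ranking"][branch.value] = {
            "order": list(ranking.model_ids),
            "best_model_id": ranking.best_model_id,
            "passes_criteria": ranking.passes_criteria,
            "total_sse": ranking.total_sse,
            "mean_e_percent": ranking.mean_e_percent,
            "mean_r2": ranking.mean_r2,
            "no_model_passed": ranking.no_model_passed,
        }

    # ---- hysteresis ----------------------------------------------------
    try:
        best_fits = []
        for branch, ranking in rankings.items():
            best_fits.extend(_best_fits_per_T(fits, branch, ranking.best_model_id))
        hyst = hysteresis_report(best_fits)
        report["hysteresis"] = {
            "loop_area": {f"{k_to_c(T):.2f}C": a for T, a in hyst.attrs["loop_area"].items()},
            "rows": hyst.to_dict(orient="list"),
        }
    except SorpthermError as exc:
        fail("hysteresis", exc)

    # ---- spreading pressure (Dent anchored on BET monolayer) ----------
    dent_block: dict[str, Any] = {}
    for branch in dataset.branches():
        for T in dataset.temperatures(branch):
            try:
                bet = next(
                    f for f in fits
                    if f.branch is branch and f.model_id == "bet" and abs(f.T - T) < 1e-6
                )
                grp = dataset.group(branch, T)
                dent = fit_dent(grp, xm_anchor=bet.params.values[0], seed=config.seed)
                curve = spreading_curve(dent, np.asarray(config.aw_grid_spread))
                dent_block.setdefault(branch.value, {})[f"{k_to_c(T):.2f}C"] = {
                    "b": dent.b,
                    "b0": dent.b0,
                    "xm_anchor": dent.Xm_anchor,
                    "r2": dent.r2,
                    "pole_warning": dent.pole_warning,
                    "aw": list(curve.aw),
                    "phi_J_per_m2": list(curve.phi),
                    "phi_reduced": list(curve.phi_reduced),
                }
            except (SorpthermError, StopIteration) as exc:
                fail(f"spreading_pressure[{branch.value}, {T:.2f}K]", exc)
    report["spreading_pressure"] = dent_block

    # ---- thermodynamics ----------------------------------------------
    report["thermodynamics"] = {}
    for branch, ranking in rankings.items():
        temps = dataset.temperatures(branch)
        if len(temps) < 3:
            fail(f"thermodynamics[{branch.value}]",
                 ValidationError("fewer than 3 temperatures; isosteres not possible"))
            continue
        try:
            branch_best = _best_fits_per_T(fits, branch, ranking.best_model_id)
            profile = thermo_profile(branch_best)
            dH = profile.qst if config.compensation_mode == "qst" else profile.Qst
            comp = compensation(dH, profile.dS, temps)
            trends = {
                "Qst_vs_xe": dataclasses.asdict(
                    fit_trend(profile.xe_grid, profile.Qst / 1000.0, TrendFamily.POWER)
                ),
                "dS_vs_xe": dataclasses.asdict(
                    fit_trend(profile.xe_grid, profile.dS, TrendFamily.LOG)
                ),
                "dG_vs_xe": dataclasses.asdict(
                    fit_trend(
                        profile.dG.groupby("xe")["dG"].mean().index.to_numpy(),
                        profile.dG.groupby("xe")["dG"].mean().to_numpy() / 1000.0,
                        TrendFamily.POWER if branch is Branch.ADSORPTION else TrendFamily.EXP,
                    )
                ),
            }
            report["thermodynamics"][branch.value] = {
                "model_id": ranking.best_model_id,
                "xe_grid": list(profile.xe_grid),
                "qst_J_per_mol": list(profile.qst),
                "Qst_J_per_mol": list(profile.Qst),
                "dS_J_per_molK": list(profile.dS),
                "isostere_r2": list(profile.r2_per_xe),
                "T_ref_K": profile.T_ref,
                "gibbs": profile.dG.to_dict(orient="list"),
                "trends": trends,
                "compensation": {
                    "mode": config.compensation_mode,
                    "T_beta_K": comp.T_beta,
                    "dG_beta_J_per_mol": comp.dG_beta,
                    "r2": comp.r2,
                    "T_h_K": comp.T_h,
                    "verdict": comp.verdict.value,
                },
            }
        except SorpthermError as exc:
            fail(f"thermodynamics[{branch.value}]", exc)

    # ---- glass transition ---------------------------------------------
    if config.tg_csv is not None:
        try:
            tg_points = read_tg_csv(config.tg_csv)
            gt = fit_gordon_taylor(tg_points, tgw_fixed=config.tgw_c)
            crit = critical_moisture(gt, config.storage_temp_c)
            block: dict[str, Any] = {
                "Tgs_C": gt.Tgs,
                "k": gt.k,
                "Tgw_C": gt.Tgw,
                "r2": gt.r2,
                "critical": {
                    "storage_T_C": crit.storage_T,
                    "xw": crit.xw,
                    "x_db": crit.x_db,
                    "flag": crit.flag,
                },
            }
            # link to activity through the adsorption best model at the
            # temperature closest to storage
            try:
                ads_rank = rankings.get(Branch.ADSORPTION)
                if ads_rank is not None and 0 < crit.xw < 1:
                    ads_fits = _best_fits_per_T(fits, Branch.ADSORPTION, ads_rank.best_model_id)
                    closest = min(
                        ads_fits, key=lambda f: abs(k_to_c(f.T) - config.storage_temp_c)
                    )
                    block["critical"]["aw"] = critical_aw(crit.xw, closest.params)
            except SorpthermError as exc:
                fail("glass_transition.critical_aw", exc)
            report["glass_transition"] = block
        except SorpthermError as exc:
            fail("glass_transition", exc)

    return report


def report_to_json(report: Mapping[str, Any]) -> str:
    """Deterministic JSON serialization of a report."""
    return json.dumps(_round_floats(dict(report)), sort_keys=True, indent=2)
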