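"""Synthetic sorption and glass-transition datasets.

Stands in for vapor-sorption and calorimetry measurements: model-generated
equilibrium curves with additive Gaussian noise, a multiplicative hysteresis
offset lifting the desorption branch, duplicate replicates per point, and a
thermodynamically consistent generator whose isosteric-heat profile is known
exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .constants import R_GAS
from .data_model import Branch, GlassTransitionPoint, SorptionDataset, SorptionPoint
from .errors import ScenarioError, ValidationError
from .glass_transition import TGW_WATER_C, GlassTransitionFit, gordon_taylor
from .isotherm_models import evaluate_raw, get_spec

__all__ = [
    "DEFAULT_TEMPERATURES_K",
    "default_aw_grid",
    "SorptionScenario",
    "TgScenario",
    "default_scenario",
    "generate_sorption",
    "generate_clausius_consistent",
    "generate_tg",
]

#: Default experiment temperatures (25, 35, 45 degC in kelvin).
DEFAULT_TEMPERATURES_K = (298.15, 308.15, 318.15)


def default_aw_grid(n: int = 15) -> np.ndarray:
    """Water-activity grid spanning the measured range 0.09..0.83."""
    return np.linspace(0.09, 0.83, n)


@dataclass
class SorptionScenario:
    """Ground truth for a synthetic sorption experiment.

    ``params_by_T`` maps each temperature (K) to the generating model's
    parameter vector.  The desorption branch is the adsorption equilibrium
    surface multiplied by ``hysteresis_offset`` (>= 1).
    """

    model_id: str
    params_by_T: Mapping[float, Sequence[float]]
    aw_grid: np.ndarray = field(default_factory=default_aw_grid)
    noise_sd: float = 0.002
    hysteresis_offset: float = 1.25
    seed: int = 0
    n_replicates: int = 2
    label: str = "synthetic"

    def __post_init__(self) -> None:
        get_spec(self.model_id)
        self.aw_grid = np.asarray(self.aw_grid, dtype=float)
        temps = list(self.params_by_T)
        if len(set(temps)) != len(temps) or not temps:
            raise ScenarioError("temperatures must be distinct and non-empty")
        if self.noise_sd < 0:
            raise ScenarioError("noise_sd must be >= 0")
        if self.hysteresis_offset < 1:
            raise ScenarioError("hysteresis_offset must be >= 1")
        if self.n_replicates < 1:
            raise ScenarioError("n_replicates must be >= 1")


@dataclass
class TgScenario:
    """Ground truth for a synthetic glass-transition experiment (degC)."""

    Tgs: float = 3.4
    k: float = 0.33
    Tgw: float = TGW_WATER_C
    xw_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 0.30, 10)
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ScenarioError("k must be > 0")
        if self.noise_sd < 0:
            raise ScenarioError("noise_sd must be >= 0")
        self.xw_grid = np.asarray(self.xw_grid, dtype=float)


def default_scenario(seed: int = 0) -> SorptionScenario:
    """A three-temperature GAB scenario with mild temperature shift.

    The curves move slightly down with temperature, so at fixed moisture the
    activity increases with temperature and the implied isosteric heat is
    positive.
    """
    return SorptionScenario(
        model_id="gab",
        params_by_T={
            298.15: (0.065, 12.0, 0.90),
            308.15: (0.060, 12.0, 0.88),
            318.15: (0.056, 12.0, 0.86),
        },
        seed=seed,
    )


def generate_sorption(scenario: SorptionScenario) -> SorptionDataset:
    """Generate both branches of a sorption dataset from a scenario.

    Adsorption: ``Xe = model(aw, T) + N(0, noise_sd)``, clipped at zero.
    Desorption: the same surface scaled by ``hysteresis_offset``.  Each grid
    point is emitted ``n_replicates`` times (mirroring duplicate runs).
    Deterministic for a fixed scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    spec = get_spec(scenario.model_id)
    dataset = SorptionDataset(label=scenario.label)
    for T, values in sorted(scenario.params_by_T.items()):
        try:
            base = evaluate_raw(
                scenario.model_id, values, scenario.aw_grid,
                T=T if spec.uses_temperature else None,
            )
        except Exception as exc:
            raise ScenarioError(
                f"model {scenario.model_id!r} undefined on the aw grid at T={T}: {exc}"
            ) from exc
        base = np.asarray(base, dtype=float)
        if not np.all(np.isfinite(base)):
            raise ScenarioError(f"model pole inside aw grid at T={T}")
        for branch, surface in (
            (Branch.ADSORPTION, base),
            (Branch.DESORPTION, scenario.hysteresis_offset * base),
        ):
            for _ in range(scenario.n_replicates):
                noise = rng.normal(0.0, scenario.noise_sd, size=surface.size) \
                    if scenario.noise_sd > 0 else np.zeros(surface.size)
                xe = np.clip(surface + noise, 0.0, None)
                for a, x in zip(scenario.aw_grid, xe):
                    dataset.add(SorptionPoint(aw=float(a), xe=float(x), T=float(T), branch=branch))
    return dataset


def generate_clausius_consistent(
    qst_profile: Callable[[float], float],
    dS_profile: Callable[[float], float],
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES_K,
    xe_grid: Sequence[float] | None = None,
    branch: Branch = Branch.ADSORPTION,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "clausius-consistent",
) -> SorptionDataset:
    """Dataset whose true isosteric heat is ``qst_profile`` by construction.

    Emits points ``(aw(xe, T), xe, T)`` with

        aw = exp(-qst(xe)/(R*T) + dS(xe)/R),

    so an isostere regression of ln(aw) on 1/T recovers the profiles
    exactly.  Note the profiles must vary with moisture for the result to be
    a function ``Xe(aw)``; constant profiles put every moisture at the same
    activity.  Optional Gaussian noise is added to ``xe``.
    """
    if xe_grid is None:
        xe_grid = np.linspace(0.05, 0.40, 12)
    xe_grid = np.asarray(xe_grid, dtype=float)
    temps = list(temperatures)
    if len(set(temps)) < 3:
        raise ScenarioError("need >= 3 distinct temperatures")
    rng = np.random.default_rng(seed)
    dataset = SorptionDataset(label=label)
    for T in sorted(temps):
        for xe in xe_grid:
            q = float(qst_profile(float(xe)))
            s = float(dS_profile(float(xe)))
            aw = float(np.exp(-q / (R_GAS * T) + s / R_GAS))
            if not (0.0 < aw < 1.0):
                raise ScenarioError(
                    f"aw={aw:.4g} outside (0,1) at xe={xe:.4g}, T={T} "
                    "(check the qst/dS profiles)"
                )
            x_obs = float(xe + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
            dataset.add(SorptionPoint(aw=aw, xe=max(x_obs, 0.0), T=float(T), branch=branch))
    return dataset


def generate_tg(scenario: TgScenario) -> list[GlassTransitionPoint]:
    """Gordon--Taylor curve plus Gaussian noise; seeded and reproducible."""
    rng = np.random.default_rng(scenario.seed)
    fit = GlassTransitionFit(Tgs=scenario.Tgs, k=scenario.k, Tgw=scenario.Tgw)
    tg = np.asarray(gordon_taylor(fit, scenario.xw_grid), dtype=float)
    if scenario.noise_sd > 0:
        tg = tg + rng.normal(0.0, scenario.noise_sd, size=tg.size)
    return [
        GlassTransitionPoint(xw=float(x), tg_c=float(t))
        for x, t in zip(scenario.xw_grid, tg)
    ]
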