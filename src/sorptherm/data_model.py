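"""Domain types and CSV input/output for sorption and glass-transition data.

Units policy
------------
* Moisture content ``Xe`` is always grams of water per gram of dry matter
  (a fraction, not per-100 g), everywhere inside the package.
* Temperatures are stored in kelvin.  CSV files may declare Celsius via the
  ``temperature_unit`` argument and are converted on read.
* Glass-transition work uses wet-basis water mass fraction ``Xw``;
  :func:`db_to_wet_fraction` converts between the two bases.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

import numpy as np
import pandas as pd

from .constants import c_to_k, k_to_c
from .errors import FormatError, ValidationError

__all__ = [
    "Branch",
    "SorptionPoint",
    "SorptionDataset",
    "GlassTransitionPoint",
    "FitStatistics",
    "read_sorption_csv",
    "write_sorption_csv",
    "read_tg_csv",
    "write_tg_csv",
    "db_to_wet_fraction",
    "wet_to_db_fraction",
]


class Branch(str, enum.Enum):
    """Sorption branch: wetting (adsorption) or drying (desorption)."""

    ADSORPTION = "adsorption"
    DESORPTION = "desorption"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


BranchLike = Union[Branch, str]


def _coerce_branch(branch: BranchLike) -> Branch:
    if isinstance(branch, Branch):
        return branch
    try:
        return Branch(str(branch).strip().lower())
    except ValueError:
        raise ValidationError(
            f"unknown branch {branch!r}; expected 'adsorption' or 'desorption'"
        ) from None


@dataclass(frozen=True)
class SorptionPoint:
    """One equilibrium observation.

    Attributes
    ----------
    aw:
        Water activity, dimensionless, ``0 <= aw < 1``.
    xe:
        Equilibrium moisture content, g water / g dry matter, ``>= 0``.
    T:
        Absolute temperature in kelvin.
    branch:
        Sorption branch the point belongs to.
    """

    aw: float
    xe: float
    T: float
    branch: Branch

    def __post_init__(self) -> None:
        object.__setattr__(self, "branch", _coerce_branch(self.branch))
        if not (0.0 <= self.aw < 1.0):
            raise ValidationError(f"aw must satisfy 0 <= aw < 1, got {self.aw}")
        if self.xe < 0.0:
            raise ValidationError(f"xe must be >= 0, got {self.xe}")
        if self.T <= 0.0:
            raise ValidationError(f"T must be > 0 K, got {self.T}")


@dataclass
class SorptionDataset:
    """A collection of sorption points retrievable by (branch, temperature)."""

    points: list[SorptionPoint] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[SorptionPoint]:
        return iter(self.points)

    def add(self, point: SorptionPoint) -> None:
        self.points.append(point)

    def group_keys(self) -> list[tuple[Branch, float]]:
        """Sorted unique (branch, T) keys present in the dataset."""
        keys = {(p.branch, p.T) for p in self.points}
        return sorted(keys, key=lambda k: (k[0].value, k[1]))

    def group(self, branch: BranchLike, T: float, atol: float = 1e-9) -> "SorptionDataset":
        """Return the sub-dataset for one branch and temperature (kelvin)."""
        branch = _coerce_branch(branch)
        pts = [p for p in self.points if p.branch is branch and abs(p.T - T) <= atol]
        return SorptionDataset(points=pts, label=self.label)

    def branches(self) -> list[Branch]:
        return sorted({p.branch for p in self.points}, key=lambda b: b.value)

    def temperatures(self, branch: BranchLike | None = None) -> list[float]:
        if branch is None:
            return sorted({p.T for p in self.points})
        branch = _coerce_branch(branch)
        return sorted({p.T for p in self.points if p.branch is branch})

    def aw_values(self) -> np.ndarray:
        return np.asarray([p.aw for p in self.points], dtype=float)

    def xe_values(self) -> np.ndarray:
        return np.asarray([p.xe for p in self.points], dtype=float)

    def require_fittable(self, min_distinct_aw: int = 3) -> None:
        """Validate every (branch, T) group has enough distinct aw values."""
        for branch, T in self.group_keys():
            grp = self.group(branch, T)
            n = len({round(p.aw, 12) for p in grp.points})
            if n < min_distinct_aw:
                raise ValidationError(
                    f"group ({branch.value}, {T} K) has only {n} distinct aw "
                    f"values; at least {min_distinct_aw} required for fitting"
                )

    def to_frame(self, temperature_unit: str = "K") -> pd.DataFrame:
        """Tidy dataframe with columns branch, temperature, aw, xe."""
        temps = [p.T if temperature_unit == "K" else k_to_c(p.T) for p in self.points]
        return pd.DataFrame(
            {
                "branch": [p.branch.value for p in self.points],
                "temperature": temps,
                "aw": [p.aw for p in self.points],
                "xe": [p.xe for p in self.points],
            }
        )


@dataclass(frozen=True)
class GlassTransitionPoint:
    """One (water mass fraction, glass-transition temperature) observation.

    ``xw`` is wet-basis (mass of water over total mass); ``tg_c`` is the
    transition midpoint in degrees Celsius.
    """

    xw: float
    tg_c: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.xw <= 1.0):
            raise ValidationError(f"xw must lie in [0, 1], got {self.xw}")
        if not math.isfinite(self.tg_c):
            raise ValidationError(f"tg_c must be finite, got {self.tg_c}")


@dataclass(frozen=True)
class FitStatistics:
    """Goodness-of-fit summary for one fitted curve.

    ``r2_regression`` is the regression-sum-of-squares ratio
    ``sum((pred - mean(obs))^2) / sum((obs - mean(obs))^2)``;
    ``r2_standard`` is the conventional ``1 - SSres/SStot``.
    ``sse`` carries a 1/N factor (it is a mean squared error) and
    ``e_percent`` is the mean relative percent error.  ``n_excluded_e``
    counts observations dropped from the E% average because they sat at or
    below the relative-error floor.
    """

    r2_regression: float
    r2_standard: float
    sse: float
    e_percent: float
    n_points: int
    n_excluded_e: int = 0

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValidationError("sse must be >= 0")
        if self.e_percent < 0:
            raise ValidationError("e_percent must be >= 0")
        if self.n_points < 1:
            raise ValidationError("n_points must be >= 1")


# ---------------------------------------------------------------------------
# moisture-basis conversions
# ---------------------------------------------------------------------------

def db_to_wet_fraction(x_db):
    """Convert dry-basis moisture (g/g dry matter) to wet-basis mass fraction.

    ``xw = x_db / (1 + x_db)``; strictly increasing, image ``[0, 1)``.
    """
    x = np.asarray(x_db, dtype=float)
    if np.any(x < 0):
        raise ValidationError("dry-basis moisture must be >= 0")
    out = x / (1.0 + x)
    return float(out) if np.isscalar(x_db) or out.ndim == 0 else out


def wet_to_db_fraction(x_wet):
    """Inverse of :func:`db_to_wet_fraction`: ``x_db = xw / (1 - xw)``."""
    x = np.asarray(x_wet, dtype=float)
    if np.any(x < 0) or np.any(x >= 1):
        raise ValidationError("wet-basis fraction must lie in [0, 1)")
    out = x / (1.0 - x)
    return float(out) if np.isscalar(x_wet) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_SORPTION_COLUMNS = ("branch", "temperature", "aw", "xe")
_TG_COLUMNS = ("xw", "tg_c")


def read_sorption_csv(
    path: str | Path, temperature_unit: str = "C", label: str | None = None
) -> SorptionDataset:
    """Read a sorption dataset from CSV.

    Expected header: ``branch,temperature,aw,xe``; lines starting with ``#``
    are comments.  ``temperature_unit`` is ``"C"`` or ``"K"``; temperatures
    are converted to kelvin on read.  Malformed rows raise
    :class:`ValidationError` naming the offending row.
    """
    path = Path(path)
    if temperature_unit not in ("C", "K"):
        raise ValidationError(f"temperature_unit must be 'C' or 'K', got {temperature_unit!r}")
    try:
        frame = pd.read_csv(path, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas-specific failures
        raise FormatError(f"could not parse {path}: {exc}") from exc

    missing = [c for c in _SORPTION_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    dataset = SorptionDataset(label=label if label is not None else path.stem)
    for idx, row in frame.iterrows():
        try:
            t = float(row["temperature"])
            t_k = c_to_k(t) if temperature_unit == "C" else t
            dataset.add(
                SorptionPoint(
                    aw=float(row["aw"]),
                    xe=float(row["xe"]),
                    T=t_k,
                    branch=_coerce_branch(row["branch"]),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: invalid row {idx}: {exc}") from exc
    return dataset


def write_sorption_csv(
    dataset: SorptionDataset, path: str | Path, temperature_unit: str = "K"
) -> None:
    """Write a dataset to CSV, losslessly at 12 significant digits."""
    if temperature_unit not in ("C", "K"):
        raise ValidationError(f"temperature_unit must be 'C' or 'K', got {temperature_unit!r}")
    frame = dataset.to_frame(temperature_unit=temperature_unit)
    frame.to_csv(path, index=False, float_format="%.12g")


def read_tg_csv(path: str | Path) -> list[GlassTransitionPoint]:
    """Read glass-transition points from CSV with header ``xw,tg_c``."""
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _TG_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    points = []
    for idx, row in frame.iterrows():
        try:
            points.append(GlassTransitionPoint(xw=float(row["xw"]), tg_c=float(row["tg_c"])))
        except (ValidationError, ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: invalid row {idx}: {exc}") from exc
    return points


def write_tg_csv(points: Iterable[GlassTransitionPoint], path: str | Path) -> None:
    frame = pd.DataFrame(
        {"xw": [p.xw for p in points], "tg_c": [p.tg_c for p in points]}
    )
    frame.to_csv(path, index=False, float_format="%.12g")
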