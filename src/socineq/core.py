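"""Closed-form inequality indices for a single stratified population.

A population is described by an ordered set of socio-economic groups
(educational levels, lowest first), each with a population share and an
event rate per 100,000 person-years.  On that input the module computes:

* **ridits** — each group's relative rank, the midpoint of its cumulative
  population-share range on the [0, 1] axis (0 = bottom of the hierarchy);
* **SII**, the slope index of inequality — the slope of the weighted
  least-squares regression of group rates on ridits, with weights
  proportional to group shares (an absolute measure, in rate units);
* **RII**, the relative index of inequality (Kunst–Mackenbach ratio) —
  the fitted rate at rank 0 (the intercept) divided by the fitted rate at
  rank 1 (intercept + slope);
* **PAF**, the population attributable fraction — the fraction of the
  population rate that would be removed if every group had the rate of the
  highest (best-off) group;
* pairwise absolute differences and rate ratios versus a reference group,
  which do not depend on the group shares.

All computation is in full precision; display rounding (RII/PAF to two
decimals, SII to integer) is applied only by the reporting helpers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EducationLevelDistribution",
    "MortalitySchedule",
    "RiditScale",
    "InequalityIndices",
    "PairwiseComparisons",
    "BELGIUM_MALES_2001",
    "compute_ridits",
    "compute_sii",
    "compute_rii",
    "compute_paf",
    "compute_pairwise",
    "compute_all",
    "read_stratified_table",
    "write_stratified_table",
]

_SHARE_SUM_TOL = 1e-9


@dataclass(frozen=True)
class EducationLevelDistribution:
    """Ordered population shares across socio-economic groups.

    ``shares[0]`` is the lowest (most deprived) level.  Shares must be
    strictly positive and sum to 1 within ``1e-9``; at least two levels are
    required for the rank regression to be defined.
    """

    shares: tuple[float, ...]

    def __init__(self, shares: Sequence[float]) -> None:
        shares = tuple(float(s) for s in shares)
        if len(shares) < 2:
            raise ValueError("at least 2 levels are required")
        if any(s <= 0 for s in shares):
            raise ValueError("every share must be > 0")
        if abs(sum(shares) - 1.0) > _SHARE_SUM_TOL:
            raise ValueError(f"shares must sum to 1, got {sum(shares)!r}")
        object.__setattr__(self, "shares", shares)

    @classmethod
    def from_percent(cls, percents: Sequence[float]) -> "EducationLevelDistribution":
        return cls([p / 100.0 for p in percents])

    @property
    def n_levels(self) -> int:
        return len(self.shares)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.shares, dtype=float)


@dataclass(frozen=True)
class MortalitySchedule:
    """Event rates per 100,000 person-years, aligned with a distribution's levels."""

    rates: tuple[float, ...]

    def __init__(self, rates: Sequence[float]) -> None:
        rates = tuple(float(r) for r in rates)
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        object.__setattr__(self, "rates", rates)

    @property
    def n_levels(self) -> int:
        return len(self.rates)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.rates, dtype=float)


#: Belgian male premature (under-75) mortality rates by educational level,
#: census 2001, per 100,000 person-years, lowest level (EL1) first.
BELGIUM_MALES_2001 = MortalitySchedule((733.8, 552.1, 450.1, 313.9))


@dataclass(frozen=True)
class RiditScale:
    """Relative ranks: midpoints of the cumulative share ranges, in (0, 1)."""

    ridits: tuple[float, ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.ridits, dtype=float)


@dataclass(frozen=True)
class InequalityIndices:
    """Summary inequality indices for one (distribution, schedule) pair.

    ``sii`` is in rate units per unit of relative rank (signed; negative when
    rates decline with rising level).  ``rii`` and ``paf`` are dimensionless.
    ``intercept`` and ``fitted_top`` are the fitted rates at ranks 0 and 1,
    so ``rii == intercept / fitted_top`` and ``fitted_top == intercept + sii``.
    """

    sii: float
    rii: float
    paf: float
    intercept: float
    fitted_top: float
    mean_rate: float

    def rounded(self) -> dict[str, float]:
        """Display-rounded values: SII to integer, RII/PAF to 2 decimals."""
        return {
            "sii": round(self.sii),
            "rii": round(self.rii, 2),
            "paf": round(self.paf, 2),
        }

    def to_dict(self) -> dict:
        return {
            "sii": self.sii,
            "rii": self.rii,
            "paf": self.paf,
            "intercept": self.intercept,
            "fitted_top": self.fitted_top,
            "mean_rate": self.mean_rate,
            "display": self.rounded(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class PairwiseComparisons:
    """Per-level rate differences and ratios versus a reference level.

    Independent of the group shares; the reference compared with itself
    gives difference 0 and ratio 1.
    """

    reference_index: int
    differences: tuple[float, ...]
    ratios: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "reference_index": self.reference_index,
            "differences": list(self.differences),
            "ratios": list(self.ratios),
        }


def _check_aligned(
    distribution: EducationLevelDistribution, schedule: MortalitySchedule
) -> None:
    if distribution.n_levels != schedule.n_levels:
        raise ValueError(
            f"distribution has {distribution.n_levels} levels but schedule "
            f"has {schedule.n_levels} rates"
        )


def compute_ridits(distribution: EducationLevelDistribution) -> RiditScale:
    """Relative rank of each level on the cumulative-share axis.

    Level *i* occupies the cumulative-share range ``(cum_{i-1}, cum_i]``;
    its ridit is the midpoint of that range.  The share-weighted mean of the
    ridits is exactly 0.5 for every valid distribution.
    """
    p = distribution.as_array()
    cum = np.cumsum(p)
    ridits = cum - p / 2.0
    return RiditScale(tuple(float(v) for v in ridits))


def _wls_slope_intercept(
    p: np.ndarray, x: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Share-weighted least-squares slope and intercept of rate on rank."""
    x_bar = float(p @ x)
    y_bar = float(p @ y)
    sxx = float(p @ (x - x_bar) ** 2)
    if sxx <= 0:
        raise ZeroDivisionError(
            "degenerate rank variance: all population mass at one ridit"
        )
    sxy = float(p @ ((y - y_bar) * (x - x_bar)))
    slope = sxy / sxx
    return slope, y_bar - slope * x_bar


def compute_sii(
    distribution: EducationLevelDistribution, schedule: MortalitySchedule
) -> float:
    """Slope index of inequality: WLS slope of rates on ridits.

    Equals ``sum(w_i (y_i - ybar_w)(x_i - xbar_w)) / sum(w_i (x_i - xbar_w)^2)``
    with weights w = shares, x = ridits, y = rates.  Negative when rates
    decline with rising socio-economic level.
    """
    _check_aligned(distribution, schedule)
    p = distribution.as_array()
    x = compute_ridits(distribution).as_array()
    slope, _ = _wls_slope_intercept(p, x, schedule.as_array())
    return slope


def compute_rii(
    distribution: EducationLevelDistribution, schedule: MortalitySchedule
) -> float:
    """Relative index of inequality: fitted rate at rank 0 over fitted rate at rank 1.

    Raises ``ArithmeticError`` when the fitted rate at the top of the scale is
    not positive (the extrapolation leaves the admissible range; the value is
    reported as an error, never clamped).
    """
    _check_aligned(distribution, schedule)
    p = distribution.as_array()
    x = compute_ridits(distribution).as_array()
    slope, intercept = _wls_slope_intercept(p, x, schedule.as_array())
    top = intercept + slope
    if top <= 0:
        raise ArithmeticError(
            f"fitted rate at the top of the scale is {top:.6g} <= 0; "
            "RII is undefined for this input"
        )
    return intercept / top


def compute_paf(
    distribution: EducationLevelDistribution, schedule: MortalitySchedule
) -> float:
    """Population attributable fraction relative to the highest level.

    ``(mean_rate - rate_of_highest_level) / mean_rate`` where the mean is
    share-weighted and the highest level is the last entry of the ordered
    lists.
    """
    _check_aligned(distribution, schedule)
    y = schedule.as_array()
    mean_rate = float(distribution.as_array() @ y)
    if mean_rate <= 0:
        raise ZeroDivisionError("mean rate is 0; PAF undefined")
    return float((mean_rate - y[-1]) / mean_rate)


@dataclass(frozen=True)
class IndexBundle:
    """Indices and pairwise comparisons computed in a single pass."""

    indices: InequalityIndices
    pairwise: PairwiseComparisons


def compute_pairwise(
    schedule: MortalitySchedule, reference_level_index: int = -1
) -> PairwiseComparisons:
    """Absolute differences and rate ratios of each level versus a reference.

    These comparisons depend only on the rates, never on the group shares.
    """
    r = schedule.as_array()
    n = len(r)
    ref = reference_level_index if reference_level_index >= 0 else n + reference_level_index
    if not 0 <= ref < n:
        raise IndexError(f"reference level {reference_level_index} out of range")
    ref_rate = r[ref]
    diffs = tuple(float(v) for v in r - ref_rate)
    if ref_rate == 0:
        raise ZeroDivisionError("reference rate is 0; rate ratios undefined")
    ratios = tuple(float(v) for v in r / ref_rate)
    return PairwiseComparisons(ref, diffs, ratios)


def compute_all(
    distribution: EducationLevelDistribution,
    schedule: MortalitySchedule,
    reference_level_index: int = -1,
) -> IndexBundle:
    """All indices and pairwise comparisons for one stratified population.

    The highest level (PAF numerator reference and pairwise reference)
    defaults to the last level but may be overridden.
    """
    _check_aligned(distribution, schedule)
    p = distribution.as_array()
    y = schedule.as_array()
    x = compute_ridits(distribution).as_array()
    slope, intercept = _wls_slope_intercept(p, x, y)
    top = intercept + slope
    if top <= 0:
        raise ArithmeticError(
            f"fitted rate at the top of the scale is {top:.6g} <= 0; "
            "RII is undefined for this input"
        )
    mean_rate = float(p @ y)
    if mean_rate <= 0:
        raise ZeroDivisionError("mean rate is 0; PAF undefined")
    n = len(y)
    ref = reference_level_index if reference_level_index >= 0 else n + reference_level_index
    paf = (mean_rate - y[ref]) / mean_rate
    indices = InequalityIndices(
        sii=slope,
        rii=intercept / top,
        paf=float(paf),
        intercept=intercept,
        fitted_top=top,
        mean_rate=mean_rate,
    )
    return IndexBundle(indices, compute_pairwise(schedule, reference_level_index))


# ---------------------------------------------------------------------------
# Delimited-text I/O


def read_stratified_table(
    path: str | Path,
) -> tuple[list[str], EducationLevelDistribution, MortalitySchedule]:
    """Read a stratified rate table (columns level_label, share, rate).

    Levels must appear in ascending socio-economic order, lowest first.
    Returns (labels, distribution, schedule).
    """
    df = pd.read_csv(path)
    missing = {"level_label", "share", "rate"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty table")
    labels = [str(v) for v in df["level_label"]]
    dist = EducationLevelDistribution(df["share"].tolist())
    sched = MortalitySchedule(df["rate"].tolist())
    return labels, dist, sched


def write_stratified_table(
    path: str | Path,
    labels: Sequence[str],
    distribution: EducationLevelDistribution,
    schedule: MortalitySchedule,
) -> None:
    _check_aligned(distribution, schedule)
    pd.DataFrame(
        {
            "level_label": list(labels),
            "share": list(distribution.shares),
            "rate": list(schedule.rates),
        }
    ).to_csv(path, index=False)
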