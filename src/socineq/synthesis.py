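"""Synthetic stratified populations with person-years and death counts.

Builds populations consistent with a given rate schedule so that
confidence-interval code and stochastic properties can be exercised
without any external data.  Deaths are either deterministic expectations
(``expected_counts``) or Poisson draws around them (``sample_population``);
Poisson is the natural model for rare-event counts accumulated over
person-years.  ``indices_with_ci`` recomputes the summary indices from the
observed rates and attaches Wald-type confidence intervals.

CI strategy.  The SII is a linear statistic of the level rates
(SII = sum c_i y_i with coefficients fixed by the shares and ridits), so
its variance follows from the Poisson plug-in variances of the observed
rates, Var(y_i) = deaths_i * (1e5 / person_years_i)^2.  The RII interval
is a delta-method interval on the log scale, log RII = log(intercept) -
log(intercept + slope), propagating the full intercept/slope covariance.
The strategy is pluggable: any object with the ``CIStrategy`` signature
can be substituted without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy import stats

from .core import (
    EducationLevelDistribution,
    InequalityIndices,
    MortalitySchedule,
    compute_all,
    compute_ridits,
)

__all__ = [
    "SyntheticPopulation",
    "expected_counts",
    "sample_population",
    "indices_with_ci",
    "IndicesWithCI",
    "WaldDeltaStrategy",
]

RATE_SCALE = 100_000.0


@dataclass(frozen=True)
class SyntheticPopulation:
    """Per-level person-years and deaths; rates are observed, not assumed."""

    person_years: tuple[float, ...]
    deaths: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.person_years) != len(self.deaths):
            raise ValueError("person_years and deaths must align")
        if any(py < 0 for py in self.person_years) or any(d < 0 for d in self.deaths):
            raise ValueError("person-years and deaths must be non-negative")

    @property
    def n_levels(self) -> int:
        return len(self.person_years)

    @property
    def total_person_years(self) -> float:
        return float(sum(self.person_years))

    def observed_rates(self) -> np.ndarray:
        """Rates per 100,000 person-years; requires person-years > 0."""
        py = np.asarray(self.person_years, dtype=float)
        d = np.asarray(self.deaths, dtype=float)
        if np.any(py <= 0):
            raise ZeroDivisionError("observed rates need positive person-years")
        return d / py * RATE_SCALE

    def distribution(self) -> EducationLevelDistribution:
        py = np.asarray(self.person_years, dtype=float)
        return EducationLevelDistribution(py / py.sum())

    def schedule(self) -> MortalitySchedule:
        return MortalitySchedule(self.observed_rates())


def expected_counts(
    distribution: EducationLevelDistribution,
    schedule: MortalitySchedule,
    total_person_years: float,
) -> SyntheticPopulation:
    """Deterministic population: expected (real-valued) deaths per level.

    Level person-years are share x total; expected deaths are
    rate x person-years / 100,000.  Indices computed on this population
    reproduce the noise-free indices exactly.
    """
    if total_person_years <= 0:
        raise ValueError("total_person_years must be positive")
    if distribution.n_levels != schedule.n_levels:
        raise ValueError("distribution and schedule must align")
    py = distribution.as_array() * total_person_years
    deaths = schedule.as_array() * py / RATE_SCALE
    return SyntheticPopulation(tuple(py), tuple(deaths))


def sample_population(
    distribution: EducationLevelDistribution,
    schedule: MortalitySchedule,
    total_person_years: float,
    seed: int | np.random.Generator,
) -> SyntheticPopulation:
    """Poisson-sampled population; reproducible for a fixed seed."""
    rng = np.random.default_rng(seed)
    expected = expected_counts(distribution, schedule, total_person_years)
    deaths = rng.poisson(np.asarray(expected.deaths))
    return SyntheticPopulation(expected.person_years, tuple(float(d) for d in deaths))


@dataclass(frozen=True)
class IndicesWithCI:
    """Point estimates plus confidence bounds at the requested level."""

    indices: InequalityIndices
    ci_level: float
    sii_ci: tuple[float, float]
    rii_ci: tuple[float, float]
    sii_se: float

    @property
    def sii(self) -> float:
        return self.indices.sii

    @property
    def rii(self) -> float:
        return self.indices.rii


class CIStrategy(Protocol):
    def __call__(
        self, population: SyntheticPopulation, ci_level: float
    ) -> IndicesWithCI: ...


class WaldDeltaStrategy:
    """Analytic Wald SII interval and log-scale delta-method RII interval.

    Writes slope and intercept as linear combinations of the observed level
    rates and propagates the Poisson plug-in rate variances through those
    coefficients; zero observed deaths in a level fall back to a variance of
    one death so the interval never degenerates to a point by accident.
    """

    def __call__(
        self, population: SyntheticPopulation, ci_level: float = 0.95
    ) -> IndicesWithCI:
        if not 0 < ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        dist = population.distribution()
        y = population.observed_rates()
        bundle = compute_all(dist, MortalitySchedule(y))
        est = bundle.indices

        p = dist.as_array()
        x = compute_ridits(dist).as_array()
        x_bar = float(p @ x)
        sxx = float(p @ (x - x_bar) ** 2)
        c = p * (x - x_bar) / sxx          # slope coefficients
        a = p - c * x_bar                  # intercept coefficients

        py = np.asarray(population.person_years, dtype=float)
        deaths = np.asarray(population.deaths, dtype=float)
        var_y = np.maximum(deaths, 1.0) * (RATE_SCALE / py) ** 2

        var_slope = float(c**2 @ var_y)
        var_int = float(a**2 @ var_y)
        cov_int_slope = float((a * c) @ var_y)

        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        se_slope = np.sqrt(var_slope)
        sii_ci = (est.sii - z * se_slope, est.sii + z * se_slope)

        # log RII = log(intercept) - log(intercept + slope)
        top = est.fitted_top
        var_top = var_int + var_slope + 2.0 * cov_int_slope
        cov_int_top = var_int + cov_int_slope
        var_log_rii = (
            var_int / est.intercept**2
            + var_top / top**2
            - 2.0 * cov_int_top / (est.intercept * top)
        )
        se_log = np.sqrt(max(var_log_rii, 0.0))
        rii_ci = (est.rii * np.exp(-z * se_log), est.rii * np.exp(z * se_log))

        return IndicesWithCI(
            indices=est,
            ci_level=ci_level,
            sii_ci=sii_ci,
            rii_ci=rii_ci,
            sii_se=float(se_slope),
        )


def indices_with_ci(
    population: SyntheticPopulation,
    ci_level: float = 0.95,
    strategy: CIStrategy | None = None,
) -> IndicesWithCI:
    """Summary indices with confidence intervals from observed counts."""
    return (strategy or WaldDeltaStrategy())(population, ci_level)


# ---------------------------------------------------------------------------
# CSV round-trip in the same dialect as the core stratified tables


def write_population_table(
    path,
    labels: Sequence[str],
    population: SyntheticPopulation,
) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "level_label": list(labels),
            "share": list(population.distribution().shares),
            "rate": list(population.observed_rates()),
            "person_years": list(population.person_years),
            "deaths": list(population.deaths),
        }
    ).to_csv(path, index=False)


def read_population_table(path) -> tuple[list[str], SyntheticPopulation]:
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"level_label", "person_years", "deaths"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    pop = SyntheticPopulation(
        tuple(float(v) for v in df["person_years"]),
        tuple(float(v) for v in df["deaths"]),
    )
    return [str(v) for v in df["level_label"]], pop
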