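"""Named scenarios and decomposition of inequality-index changes.

A scenario pairs a mortality schedule with an educational-level
distribution.  Between a baseline and a comparison that changes both the
rates and the composition, the change in each summary index splits into

* a mortality-differential component: change the rates first, keep the
  baseline composition; and
* a composition-shift component: then change the composition, keep the new
  rates;

each expressed as a percent of the baseline index, so the two components
add exactly to the total percent change.  The decomposition is
path-dependent by construction (rates first, then distribution); the
alternative ordering is deliberately not offered.  Components are computed
from full-precision index values; rounding happens only at display.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .core import (
    EducationLevelDistribution,
    IndexBundle,
    MortalitySchedule,
    compute_all,
)

__all__ = [
    "Scenario",
    "DecompositionResult",
    "IndexChange",
    "evaluate_scenarios",
    "decompose",
    "build_scenario_table",
    "read_scenarios_config",
]

INDEX_NAMES = ("sii", "rii", "paf")


@dataclass(frozen=True)
class Scenario:
    label: str
    distribution: EducationLevelDistribution
    schedule: MortalitySchedule

    def __post_init__(self) -> None:
        if self.distribution.n_levels != self.schedule.n_levels:
            raise ValueError(f"scenario {self.label!r}: misaligned levels")


@dataclass(frozen=True)
class IndexChange:
    """Change of one index between scenarios, as percent of baseline."""

    baseline: float
    comparison: float
    total_pct: float
    differential_pct: float
    shift_pct: float


@dataclass(frozen=True)
class DecompositionResult:
    """Per-index decomposition; total = differential + shift exactly."""

    baseline_label: str
    comparison_label: str
    changes: dict[str, IndexChange]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: vars(ch) for name, ch in self.changes.items()}
        ).T[["baseline", "comparison", "total_pct", "differential_pct", "shift_pct"]]


def evaluate_scenarios(
    scenarios: Sequence[Scenario], reference_level_index: int = -1
) -> dict[str, IndexBundle]:
    """Full indices and pairwise comparisons for each scenario, by label."""
    if not scenarios:
        raise ValueError("at least one scenario is required")
    return {
        s.label: compute_all(s.distribution, s.schedule, reference_level_index)
        for s in scenarios
    }


def _index_values(s: Scenario) -> dict[str, float]:
    b = compute_all(s.distribution, s.schedule).indices
    return {"sii": b.sii, "rii": b.rii, "paf": b.paf}


def decompose(
    baseline: Scenario,
    rates_changed: Scenario,
    rates_and_eld_changed: Scenario,
) -> DecompositionResult:
    """Split the baseline -> final index change into its two components.

    ``rates_changed`` must share the baseline's distribution (only the rates
    moved); ``rates_and_eld_changed`` must share ``rates_changed``'s schedule
    (only the composition moved).  For each index I:

    * differential = (I(rates_changed) - I(baseline)) / I(baseline)
    * shift        = (I(final) - I(rates_changed)) / I(baseline)
    * total        = differential + shift = (I(final) - I(baseline)) / I(baseline)

    all in percent of the baseline value.
    """
    if rates_changed.distribution.shares != baseline.distribution.shares:
        raise ValueError("rates_changed must keep the baseline distribution")
    if rates_and_eld_changed.schedule.rates != rates_changed.schedule.rates:
        raise ValueError("rates_and_eld_changed must keep rates_changed's schedule")
    base = _index_values(baseline)
    mid = _index_values(rates_changed)
    final = _index_values(rates_and_eld_changed)
    changes: dict[str, IndexChange] = {}
    for name in INDEX_NAMES:
        b = base[name]
        if b == 0:
            raise ZeroDivisionError(f"baseline {name} is 0; percent change undefined")
        diff_pct = 100.0 * (mid[name] - b) / b
        shift_pct = 100.0 * (final[name] - mid[name]) / b
        changes[name] = IndexChange(
            baseline=b,
            comparison=final[name],
            total_pct=diff_pct + shift_pct,
            differential_pct=diff_pct,
            shift_pct=shift_pct,
        )
    return DecompositionResult(baseline.label, rates_and_eld_changed.label, changes)


def build_scenario_table(
    scenarios: Sequence[Scenario],
    reference_level_index: int = -1,
    baseline_label: str | None = None,
) -> pd.DataFrame:
    """Report table: one column per scenario, rows for inputs and indices.

    Rows cover the per-level rates and shares, the pairwise differences and
    ratios versus the reference level, and the composite indices (display
    rounding: SII to integer, RII/PAF to two decimals).  When a baseline
    label is given, percent-change rows from that baseline are appended for
    the composite indices.  An empty scenario list gives an empty table.
    """
    if not scenarios:
        return pd.DataFrame()
    results = evaluate_scenarios(scenarios, reference_level_index)
    n = scenarios[0].schedule.n_levels
    ref = reference_level_index if reference_level_index >= 0 else n + reference_level_index
    rows: dict[str, dict[str, object]] = {}
    for s in scenarios:
        bundle = results[s.label]
        col: dict[str, object] = {}
        for i in range(n):
            col[f"EL{i + 1} rate"] = s.schedule.rates[i]
            col[f"EL{i + 1} share %"] = round(s.distribution.shares[i] * 100, 6)
        for i in range(n):
            if i == ref:
                continue
            col[f"EL{i + 1} vs EL{ref + 1} diff"] = round(bundle.pairwise.differences[i], 6)
            col[f"EL{i + 1} vs EL{ref + 1} ratio"] = round(bundle.pairwise.ratios[i], 2)
        disp = bundle.indices.rounded()
        col["SII"] = disp["sii"]
        col["RII"] = disp["rii"]
        col["PAF"] = disp["paf"]
        rows[s.label] = col
    table = pd.DataFrame(rows)
    if baseline_label is not None and len(scenarios) > 1:
        base = results[baseline_label].indices
        base_vals = {"SII": base.sii, "RII": base.rii, "PAF": base.paf}
        full = {
            s.label: {
                "SII": results[s.label].indices.sii,
                "RII": results[s.label].indices.rii,
                "PAF": results[s.label].indices.paf,
            }
            for s in scenarios
        }
        for name in ("SII", "RII", "PAF"):
            table.loc[f"{name} change from {baseline_label} %"] = [
                round(100.0 * (full[s.label][name] - base_vals[name]) / base_vals[name])
                if s.label != baseline_label
                else 0
                for s in scenarios
            ]
    return table


def read_scenarios_config(path: str | Path) -> tuple[list[Scenario], str | None]:
    """Load scenarios from a YAML config.

    Schema::

        baseline: A            # optional
        scenarios:
          - label: A
            shares: [40, 25, 25, 10]   # percent (values summing to 100) or fractions
            rates: [750, 550, 450, 300]

    Returns (scenarios, baseline_label).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not cfg or "scenarios" not in cfg:
        raise ValueError(f"{path}: missing 'scenarios' section")
    scenarios = []
    for entry in cfg["scenarios"]:
        shares = entry["shares"]
        if abs(sum(shares) - 100) < 1e-6:
            dist = EducationLevelDistribution.from_percent(shares)
        else:
            dist = EducationLevelDistribution(shares)
        scenarios.append(
            Scenario(str(entry["label"]), dist, MortalitySchedule(entry["rates"]))
        )
    return scenarios, cfg.get("baseline")
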