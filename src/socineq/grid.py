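"""Hypothetical-population grid: index behaviour under composition change.

Enumerates educational-level distributions on an integer-percent lattice
(the shares of the lower levels sweep a bounded range in fixed steps, the
top share takes the complement), evaluates SII/RII/PAF over the grid at a
fixed rate schedule, extracts one-parameter curve families (index versus
the top-level share p4), and characterises their maxima and monotonicity.

Shares are carried as exact integer percents during enumeration and
matching so lattice membership is never subject to floating-point error;
they are converted to fractions only when indices are evaluated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .core import (
    EducationLevelDistribution,
    MortalitySchedule,
    compute_all,
)
from .synthesis import expected_counts, indices_with_ci

__all__ = [
    "GridSpec",
    "GridResult",
    "CurveFamily",
    "FamilyKind",
    "generate_eld_grid",
    "evaluate_grid",
    "extract_family",
    "find_maximum",
    "check_monotone",
    "filter_by_significance",
]


@dataclass(frozen=True)
class GridSpec:
    """Lattice of admissible share combinations, in integer percent.

    The first ``n_levels - 1`` shares sweep ``lower_pct..upper_pct`` in
    ``step_pct`` increments; the last share is the complement to 100 and a
    combination is retained only if every share (complement included) lies
    within the bounds.  Defaults are 4 levels over 5–50% in 5-point steps.
    """

    n_levels: int = 4
    lower_pct: int = 5
    upper_pct: int = 50
    step_pct: int = 5

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not (0 < self.lower_pct <= self.upper_pct < 100):
            raise ValueError("bounds must satisfy 0 < lower <= upper < 100")
        if self.step_pct <= 0 or (self.upper_pct - self.lower_pct) % self.step_pct:
            raise ValueError("step must be positive and divide the bound range")


def generate_eld_grid(spec: GridSpec = GridSpec()) -> list[tuple[int, ...]]:
    """Enumerate admissible share combinations, lexicographic in p1..p(n-1).

    Returns integer-percent tuples summing to 100; every entry lies within
    the spec's bounds.  An infeasible spec yields an empty list.
    """
    values = range(spec.lower_pct, spec.upper_pct + 1, spec.step_pct)
    combos: list[tuple[int, ...]] = []
    for head in itertools.product(values, repeat=spec.n_levels - 1):
        tail = 100 - sum(head)
        if spec.lower_pct <= tail <= spec.upper_pct:
            combos.append(head + (tail,))
    return combos


@dataclass(frozen=True)
class GridResult:
    """Indices evaluated at every admissible share combination.

    ``table`` has one row per combination: integer-percent share columns
    ``p1..pn`` followed by ``sii``, ``rii``, ``paf`` (and CI columns after
    :func:`filter_by_significance` has been applied with ``keep_ci=True``).
    """

    table: pd.DataFrame
    schedule: MortalitySchedule

    def __len__(self) -> int:
        return len(self.table)

    def share_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("p") and c[1:].isdigit()]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=1)


def evaluate_grid(
    grid: Iterable[tuple[int, ...]] | Iterable[EducationLevelDistribution],
    schedule: MortalitySchedule,
) -> GridResult:
    """Compute SII, RII and PAF for every distribution, rates held fixed."""
    rows = []
    for combo in grid:
        if isinstance(combo, EducationLevelDistribution):
            pct = tuple(round(s * 100) for s in combo.shares)
            dist = combo
        else:
            pct = tuple(int(v) for v in combo)
            dist = EducationLevelDistribution.from_percent(pct)
        bundle = compute_all(dist, schedule)
        row = {f"p{i + 1}": v for i, v in enumerate(pct)}
        row.update(
            sii=bundle.indices.sii, rii=bundle.indices.rii, paf=bundle.indices.paf
        )
        rows.append(row)
    n = schedule.n_levels
    cols = [f"p{i + 1}" for i in range(n)] + ["sii", "rii", "paf"]
    table = pd.DataFrame(rows, columns=cols)
    return GridResult(table, schedule)


FamilyKind = Literal["fixed-p1-p3", "fixed-p1-p2", "fixed-p2-p3"]

#: For each family kind (4-level grids): the two share indices held fixed
#: and the one that varies in complement to p4.
_FAMILY_LAYOUT: dict[str, tuple[tuple[int, int], int]] = {
    "fixed-p1-p3": ((1, 3), 2),
    "fixed-p1-p2": ((1, 2), 3),
    "fixed-p2-p3": ((2, 3), 1),
}


@dataclass(frozen=True)
class CurveFamily:
    """An index series along p4 with two shares held fixed.

    ``kind`` names the fixed pair; the remaining lower-level share varies in
    complement to p4.  Points are ordered by increasing p4 and are all drawn
    from the parent grid.
    """

    kind: str
    fixed_values: tuple[int, int]
    index: str
    p4_pct: tuple[int, ...]
    values: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.p4_pct)


def extract_family(
    result: GridResult,
    kind: FamilyKind,
    fixed_values: tuple[int, int],
    index: str = "rii",
) -> CurveFamily:
    """Slice one curve family out of a 4-level grid result.

    ``fixed_values`` are integer percents for the two fixed shares, matched
    exactly on the lattice; off-grid values give an empty family.
    """
    if kind not in _FAMILY_LAYOUT:
        raise ValueError(f"unknown family kind {kind!r}")
    if index not in ("sii", "rii", "paf"):
        raise ValueError(f"unknown index {index!r}")
    (i, j), _ = _FAMILY_LAYOUT[kind]
    t = result.table
    mask = (t[f"p{i}"] == fixed_values[0]) & (t[f"p{j}"] == fixed_values[1])
    sub = t[mask].sort_values("p4")
    return CurveFamily(
        kind=kind,
        fixed_values=(int(fixed_values[0]), int(fixed_values[1])),
        index=index,
        p4_pct=tuple(int(v) for v in sub["p4"]),
        values=tuple(float(v) for v in sub[index]),
    )


def find_maximum(family: CurveFamily) -> tuple[int, float]:
    """(p4, value) at the maximum absolute index value along the family.

    Ties are broken toward the smaller p4.  For a signed index such as the
    SII this locates the extremum of magnitude; the returned value keeps its
    sign.
    """
    if len(family) == 0:
        raise ValueError("empty family has no maximum")
    mags = np.abs(family.values)
    pos = int(np.argmax(mags))  # argmax returns the first of tied maxima
    return family.p4_pct[pos], family.values[pos]


def check_monotone(
    family: CurveFamily, direction: Literal["increasing", "decreasing"]
) -> tuple[bool, int | None]:
    """Whether the series is strictly monotone along p4.

    Returns ``(ok, first_violation)`` where the violation is the position of
    the first offending step (index into the series), or None.
    """
    if len(family) < 2:
        raise ValueError("monotonicity needs at least 2 points")
    diffs = np.diff(family.values)
    bad = diffs <= 0 if direction == "increasing" else diffs >= 0
    if bad.any():
        return False, int(np.argmax(bad))
    return True, None


def filter_by_significance(
    result: GridResult,
    total_person_years: float,
    ci_level: float = 0.95,
    keep_ci: bool = False,
) -> GridResult:
    """Keep combinations whose SII CI excludes 0 and RII CI excludes 1.

    Each combination is treated as a population of ``total_person_years``
    split by its shares, with the grid schedule's expected death counts;
    the intervals come from the analytic strategy in
    :mod:`socineq.synthesis`.  With enormous person-years nothing is
    removed (CI width shrinks to zero around a non-zero slope); with a
    constant-rate schedule everything is removed.
    """
    if total_person_years <= 0:
        raise ValueError("total_person_years must be positive")
    share_cols = result.share_columns()
    keep = []
    ci_rows = []
    for _, row in result.table.iterrows():
        dist = EducationLevelDistribution.from_percent([row[c] for c in share_cols])
        pop = expected_counts(dist, result.schedule, total_person_years)
        est = indices_with_ci(pop, ci_level=ci_level)
        ok = not (est.sii_ci[0] <= 0.0 <= est.sii_ci[1]) and not (
            est.rii_ci[0] <= 1.0 <= est.rii_ci[1]
        )
        keep.append(ok)
        ci_rows.append(
            {
                "sii_lo": est.sii_ci[0],
                "sii_hi": est.sii_ci[1],
                "rii_lo": est.rii_ci[0],
                "rii_hi": est.rii_ci[1],
            }
        )
    table = result.table.copy()
    if keep_ci:
        table = pd.concat([table, pd.DataFrame(ci_rows, index=table.index)], axis=1)
    table = table[np.asarray(keep)].reset_index(drop=True)
    return GridResult(table, result.schedule)


def plot_families(
    result: GridResult,
    kind: FamilyKind,
    fixed_values_list: Sequence[tuple[int, int]],
    out_path,
) -> None:
    """Three-panel figure (|SII|, RII, PAF versus p4) for several families."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    for ax, index, label in zip(axes, ("sii", "rii", "paf"), ("|SII|", "RII", "PAF")):
        for fixed in fixed_values_list:
            fam = extract_family(result, kind, fixed, index)
            if len(fam) == 0:
                continue
            vals = np.abs(fam.values) if index == "sii" else np.asarray(fam.values)
            ax.plot(fam.p4_pct, vals, marker="o", label=f"fixed={fixed}")
        ax.set_xlabel("p4 (%)")
        ax.set_ylabel(label)
        ax.legend(fontsize=7)
    fig.suptitle(f"Index evolution with p4 ({kind})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
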