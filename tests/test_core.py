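"""Closed-form index computations on single stratified populations."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socineq import (
    EducationLevelDistribution,
    MortalitySchedule,
    compute_all,
    compute_pairwise,
    compute_paf,
    compute_ridits,
    compute_rii,
    compute_sii,
    read_stratified_table,
    write_stratified_table,
)

# strategy: valid distributions of 2-6 levels (positive shares normalised to 1)
shares_st = st.lists(
    st.floats(0.01, 1.0, allow_nan=False), min_size=2, max_size=6
).map(lambda raw: EducationLevelDistribution(np.asarray(raw) / np.sum(raw)))

rates_st = st.lists(st.floats(1.0, 2000.0), min_size=2, max_size=6)


def aligned_rates(dist: EducationLevelDistribution, values) -> MortalitySchedule:
    reps = (values * dist.n_levels)[: dist.n_levels]
    return MortalitySchedule(reps)


@pytest.mark.parametrize(
    "shares, expected",
    [
        ([0.40, 0.25, 0.25, 0.10], [0.200, 0.525, 0.775, 0.950]),
        ([0.20, 0.25, 0.25, 0.30], [0.100, 0.325, 0.575, 0.850]),
        ([0.5, 0.5], [0.25, 0.75]),
    ],
)
def test_ridits_are_midpoints_of_cumulative_ranges(shares, expected):
    scale = compute_ridits(EducationLevelDistribution(shares))
    assert scale.as_array() == pytest.approx(expected, abs=1e-12)


@given(shares_st)
@settings(max_examples=100, derandomize=True)
def test_share_weighted_ridit_mean_is_half(dist):
    """Algebraic identity: ridits average to 0.5 under the share weights."""
    x = compute_ridits(dist).as_array()
    assert dist.as_array() @ x == pytest.approx(0.5, abs=1e-12)
    assert np.all(np.diff(x) > 0)
    assert np.all((x > 0) & (x < 1))


@pytest.mark.parametrize(
    "shares_pct, rates, expected_sii",
    [
        ((40, 25, 25, 10), (750, 550, 450, 300), -559.3),
        ((20, 25, 25, 30), (750, 550, 450, 300), -567.1),
        ((40, 25, 25, 10), (630, 500, 400, 290), -423.9),
    ],
)
def test_sii_matches_published_scenarios(shares_pct, rates, expected_sii):
    dist = EducationLevelDistribution.from_percent(shares_pct)
    sii = compute_sii(dist, MortalitySchedule(rates))
    assert sii == pytest.approx(expected_sii, abs=0.05)


@pytest.mark.parametrize(
    "shares_pct, rates, expected_rii",
    [
        ((40, 25, 25, 10), (750, 550, 450, 300), 2.86),
        ((20, 25, 25, 30), (750, 550, 450, 300), 3.75),
    ],
)
def test_rii_matches_published_scenarios(shares_pct, rates, expected_rii):
    dist = EducationLevelDistribution.from_percent(shares_pct)
    rii = compute_rii(dist, MortalitySchedule(rates))
    assert round(rii, 2) == expected_rii


@pytest.mark.parametrize(
    "shares_pct, rates, expected_paf",
    [
        ((40, 25, 25, 10), (750, 550, 450, 300), 0.4828),
        ((20, 25, 25, 30), (630, 500, 400, 290), 0.3379),
    ],
)
def test_paf_matches_published_scenarios(shares_pct, rates, expected_paf):
    dist = EducationLevelDistribution.from_percent(shares_pct)
    paf = compute_paf(dist, MortalitySchedule(rates))
    assert paf == pytest.approx(expected_paf, abs=5e-4)


@given(shares_st, st.floats(10.0, 1000.0))
@settings(max_examples=50, derandomize=True)
def test_constant_rates_give_null_indices(dist, c):
    sched = aligned_rates(dist, [c])
    bundle = compute_all(dist, sched)
    assert bundle.indices.sii == pytest.approx(0.0, abs=1e-9 * c)
    assert bundle.indices.rii == pytest.approx(1.0, abs=1e-9)
    assert bundle.indices.paf == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "rates, el1_diff, el1_ratio",
    [
        ((630, 500, 400, 290), 340, 2.17),
        ((750, 570, 420, 260), 490, 2.88),
    ],
)
def test_pairwise_versus_top_level(rates, el1_diff, el1_ratio):
    cmp = compute_pairwise(MortalitySchedule(rates), -1)
    assert cmp.differences[0] == pytest.approx(el1_diff)
    assert round(cmp.ratios[0], 2) == el1_ratio
    # reference versus itself
    assert cmp.differences[cmp.reference_index] == 0.0
    assert cmp.ratios[cmp.reference_index] == 1.0


def test_compute_all_bundles_consistently():
    dist = EducationLevelDistribution.from_percent((40, 25, 25, 10))
    sched = MortalitySchedule((750, 550, 450, 300))
    bundle = compute_all(dist, sched)
    idx = bundle.indices
    assert idx.fitted_top == pytest.approx(idx.intercept + idx.sii, abs=1e-9)
    assert idx.rii == pytest.approx(idx.intercept / idx.fitted_top, abs=1e-12)
    assert idx.mean_rate == pytest.approx(dist.as_array() @ sched.as_array())
    assert idx.rounded() == {"sii": -559, "rii": 2.86, "paf": 0.48}


@given(shares_st, st.floats(-200.0, 200.0), st.floats(0.1, 10.0))
@settings(max_examples=60, derandomize=True)
def test_translation_and_scaling_of_rates(dist, c, k):
    """Adding c shifts the intercept only; scaling by k scales the SII and
    leaves the RII and PAF unchanged."""
    # declining gradient, affine in the ridits so the fit is exact and the
    # fitted top stays positive for every draw of c and k
    base = 1000.0 - 300.0 * compute_ridits(dist).as_array()
    b0 = compute_all(dist, MortalitySchedule(base))
    b1 = compute_all(dist, MortalitySchedule(base + c))
    assert b1.indices.sii == pytest.approx(b0.indices.sii, rel=1e-9, abs=1e-6)
    assert b1.indices.intercept == pytest.approx(b0.indices.intercept + c, rel=1e-9)
    b2 = compute_all(dist, MortalitySchedule(base * k))
    assert b2.indices.sii == pytest.approx(k * b0.indices.sii, rel=1e-9)
    assert b2.indices.rii == pytest.approx(b0.indices.rii, rel=1e-9)
    assert b2.indices.paf == pytest.approx(b0.indices.paf, rel=1e-9)


@given(shares_st, st.data())
@settings(max_examples=60, derandomize=True, deadline=None)
def test_sii_agrees_with_generic_wls_solver(dist, data):
    """Closed-form covariance ratio versus an independent WLS fit."""
    import statsmodels.api as sm

    rates = data.draw(
        st.lists(
            st.floats(1.0, 2000.0),
            min_size=dist.n_levels,
            max_size=dist.n_levels,
        )
    )
    sched = MortalitySchedule(rates)
    x = compute_ridits(dist).as_array()
    fit = sm.WLS(
        sched.as_array(), sm.add_constant(x), weights=dist.as_array()
    ).fit()
    sii = compute_sii(dist, sched)
    assert sii == pytest.approx(fit.params[1], rel=1e-9, abs=1e-9)
    # RII from the same regression line: fitted rank-0 over fitted rank-1
    top = fit.params[0] + fit.params[1]
    if top > 0:
        assert compute_rii(dist, sched) == pytest.approx(
            fit.params[0] / top, rel=1e-9
        )


def test_paf_bounded_when_top_level_is_best_off():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = rng.integers(2, 6)
        raw = rng.uniform(0.05, 1.0, n)
        dist = EducationLevelDistribution(raw / raw.sum())
        rates = np.sort(rng.uniform(10.0, 1000.0, n))[::-1]
        rates[-1] = rates.min() * 0.9  # strictly lowest positive rate on top
        paf = compute_paf(dist, MortalitySchedule(rates))
        assert 0.0 <= paf < 1.0


class TestValidation:
    def test_rejects_single_level(self):
        with pytest.raises(ValueError, match="2 levels"):
            EducationLevelDistribution([1.0])

    def test_rejects_shares_not_summing_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            EducationLevelDistribution([0.5, 0.4])

    def test_rejects_nonpositive_share(self):
        with pytest.raises(ValueError, match="> 0"):
            EducationLevelDistribution([1.0, 0.0])

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError, match="non-negative"):
            MortalitySchedule([100.0, -1.0])

    def test_rejects_misaligned_lengths(self):
        with pytest.raises(ValueError, match="levels"):
            compute_sii(
                EducationLevelDistribution([0.5, 0.5]),
                MortalitySchedule([1.0, 2.0, 3.0]),
            )

    def test_rii_extrapolation_failure_is_an_error(self):
        # two-point fit whose extension to rank 1 goes negative
        dist = EducationLevelDistribution([0.5, 0.5])
        with pytest.raises(ArithmeticError, match="top of the scale"):
            compute_rii(dist, MortalitySchedule([100.0, 1.0]))

    def test_pairwise_reference_out_of_range(self):
        with pytest.raises(IndexError):
            compute_pairwise(MortalitySchedule([1.0, 2.0]), 5)


def test_stratified_table_round_trip(tmp_path):
    path = tmp_path / "table.csv"
    dist = EducationLevelDistribution.from_percent((40, 25, 25, 10))
    sched = MortalitySchedule((733.8, 552.1, 450.1, 313.9))
    write_stratified_table(path, ["EL1", "EL2", "EL3", "EL4"], dist, sched)
    labels, dist2, sched2 = read_stratified_table(path)
    assert labels == ["EL1", "EL2", "EL3", "EL4"]
    assert dist2.shares == pytest.approx(dist.shares)
    assert sched2.rates == pytest.approx(sched.rates)


def test_indices_json_has_full_and_rounded_fields():
    dist = EducationLevelDistribution.from_percent((40, 25, 25, 10))
    bundle = compute_all(dist, MortalitySchedule((750, 550, 450, 300)))
    payload = json.loads(bundle.indices.to_json())
    assert payload["display"] == {"sii": -559, "rii": 2.86, "paf": 0.48}
    assert payload["sii"] == pytest.approx(-559.3, abs=0.05)
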