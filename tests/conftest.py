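import pytest

from socineq import (
    BELGIUM_MALES_2001,
    EducationLevelDistribution,
    GridSpec,
    MortalitySchedule,
    Scenario,
    evaluate_grid,
    generate_eld_grid,
)

# The six fictive scenarios: three rate schedules (baseline, lower, higher
# mortality and differentials) crossed with two educational distributions
# (left-skewed ELD1 and upward-shifted ELD2).
RATES_1 = (750.0, 550.0, 450.0, 300.0)
RATES_2 = (630.0, 500.0, 400.0, 290.0)
RATES_3 = (750.0, 570.0, 420.0, 260.0)
ELD_1 = (40, 25, 25, 10)
ELD_2 = (20, 25, 25, 30)


def make_scenario(label: str, shares_pct, rates) -> Scenario:
    return Scenario(
        label,
        EducationLevelDistribution.from_percent(shares_pct),
        MortalitySchedule(rates),
    )


@pytest.fixture(scope="session")
def six_scenarios():
    return [
        make_scenario("A", ELD_1, RATES_1),
        make_scenario("B", ELD_2, RATES_1),
        make_scenario("C", ELD_1, RATES_2),
        make_scenario("D", ELD_2, RATES_2),
        make_scenario("E", ELD_1, RATES_3),
        make_scenario("F", ELD_2, RATES_3),
    ]


@pytest.fixture(scope="session")
def belgian_rates():
    return BELGIUM_MALES_2001


@pytest.fixture(scope="session")
def belgian_grid(belgian_rates):
    """Full default grid (5-50% bounds, 5-point step) at the Belgian rates."""
    return evaluate_grid(generate_eld_grid(GridSpec()), belgian_rates)
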