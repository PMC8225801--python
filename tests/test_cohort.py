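"""Cohort entry: starting allocations, screening costs, scenario scaling."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytocea import (
    ParameterError,
    allocate_from_trial,
    base_scenario,
    readminister_scenario,
    scale_uptake,
    screening_cost,
    table1_allocation,
)
from cytocea.cohort import ScreeningScenario
from cytocea.states import DISEASE_STATES, HealthState

H = HealthState

#: Published starting counts (arm, chain) -> state -> persons.
EXPECTED_TABLE = {
    ("intervention", "treatment"): {H.NO_BE: 0, H.NDBE: 123, H.LGD: 1,
                                    H.HGD: 3, H.EARLY_EAC: 4},
    ("intervention", "natural"): {H.NO_BE: 6230.6, H.NDBE: 443.6, H.LGD: 3.6,
                                  H.HGD: 10.8, H.EARLY_EAC: 14.4},
    ("usual", "treatment"): {H.NO_BE: 0, H.NDBE: 11.6, H.LGD: 0,
                             H.HGD: 0, H.EARLY_EAC: 4},
    ("usual", "natural"): {H.NO_BE: 6230.6, H.NDBE: 555.0, H.LGD: 4.6,
                           H.HGD: 13.8, H.EARLY_EAC: 14.4},
}


def test_starting_allocation_reproduces_trial_table(ps):
    alloc = table1_allocation(ps)
    for (arm, chain), expected in EXPECTED_TABLE.items():
        vec = getattr(alloc.arm(arm), chain)
        for state, count in expected.items():
            assert vec[state] == pytest.approx(count, abs=1e-9), (arm, chain, state)
        assert vec[H.LATE_EAC] == 0 and vec[H.DEAD] == 0


def test_intervention_treatment_chain_totals_131_diagnoses(ps):
    alloc = table1_allocation(ps)
    assert alloc.intervention.treatment.sum() == pytest.approx(131.0)


def test_both_arms_total_cohort_size(ps):
    alloc = table1_allocation(ps)
    assert alloc.intervention.total == pytest.approx(6834.0)
    assert alloc.usual.total == pytest.approx(6834.0)


def test_per_state_totals_identical_across_arms(ps):
    alloc = table1_allocation(ps)
    np.testing.assert_allclose(alloc.intervention.per_state_total,
                               alloc.usual.per_state_total, rtol=1e-12)
    # e.g. NDBE: 123 + 443.6 = 11.6 + 555 = 566.6
    assert alloc.intervention.per_state_total[H.NDBE] == pytest.approx(566.6)


def test_implied_be_prevalence_near_nine_percent(ps):
    alloc = table1_allocation(ps)
    diseased = sum(alloc.usual.per_state_total[s] for s in DISEASE_STATES)
    assert diseased / 6834.0 == pytest.approx(0.09, abs=0.005)
    assert ps.prevalence_be == pytest.approx(diseased / 6834.0)


# ----------------------------------------------------------------------


def test_screening_cost_per_person(ps):
    sc = screening_cost(base_scenario(ps), ps.costs)
    assert sc.total_intervention == pytest.approx(524716.0, abs=0.5)
    assert round(sc.per_person_intervention) == 77
    assert sc.per_person_usual == pytest.approx(1.14, abs=0.005)
    assert sc.total_usual == pytest.approx(7808.0)


def test_screening_cost_zero_counts(ps):
    sc = screening_cost(ScreeningScenario(
        n_invited=100.0, n_swallowed=0.0, n_endoscopy_intervention=0.0,
        n_endoscopy_usual=0.0, uptake=0.5), ps.costs)
    assert sc.total_intervention == 0.0
    assert sc.total_usual == 0.0


def test_screening_cost_zero_invited_errors(ps):
    with pytest.raises(ParameterError):
        screening_cost(ScreeningScenario(
            n_invited=0.0, n_swallowed=0.0, n_endoscopy_intervention=0.0,
            n_endoscopy_usual=0.0, uptake=0.5), ps.costs)


def test_detected_cannot_exceed_prevalent(ps):
    detected = {"intervention": {H.HGD: 1e6}, "usual": {}}
    with pytest.raises(ParameterError, match="HGD"):
        allocate_from_trial(ps, detected=detected)


def test_perfect_test_limit(ps):
    # Detecting every prevalent case leaves no diseased natural-history mass.
    n = ps.settings.cohort_size
    detected = {arm: {s: ps.prevalence[s] * n for s in DISEASE_STATES}
                for arm in ("intervention", "usual")}
    alloc = allocate_from_trial(ps, detected=detected)
    for arm in ("intervention", "usual"):
        for s in DISEASE_STATES:
            assert alloc.arm(arm).natural[s] == pytest.approx(0.0, abs=1e-9)


# ----------------------------------------------------------------------


def test_scale_uptake_identity_at_base(ps):
    scenario = base_scenario(ps)
    alloc0 = table1_allocation(ps)
    alloc, sc = scale_uptake(ps, scenario, scenario.uptake)
    assert sc.n_swallowed == pytest.approx(scenario.n_swallowed)
    np.testing.assert_allclose(alloc.intervention.treatment,
                               alloc0.intervention.treatment)


def test_scale_uptake_to_fifty_percent(ps):
    alloc, sc = scale_uptake(ps, base_scenario(ps), 0.50)
    assert sc.n_swallowed == pytest.approx(3417, abs=1.0)
    assert sc.n_endoscopy_intervention == pytest.approx(409, abs=1.0)
    # detections scale with the funnel; usual care unchanged
    assert alloc.intervention.treatment[H.NDBE] == pytest.approx(
        123.0 * 0.50 / base_scenario(ps).uptake)
    assert alloc.usual.treatment[H.NDBE] == pytest.approx(11.6)
    alloc.validate(ps.settings.cohort_size)


def test_scale_uptake_rejects_nonpositive(ps):
    with pytest.raises(ParameterError):
        scale_uptake(ps, base_scenario(ps), 0.0)


def test_screening_cost_linear_monotone_in_uptake(ps):
    costs = []
    for uptake in (0.1, 0.2, 0.3, 0.4, 0.5):
        _, sc = scale_uptake(ps, base_scenario(ps), uptake)
        costs.append(screening_cost(sc, ps.costs).per_person_intervention)
    assert all(b > a for a, b in zip(costs, costs[1:]))
    increments = np.diff(costs)
    np.testing.assert_allclose(increments, increments[0], rtol=1e-9)


def test_readminister_scenario_volumes_and_detections(ps):
    alloc, sc = readminister_scenario(ps, base_scenario(ps))
    assert sc.total_tests == pytest.approx(1654 + 202)
    assert sc.total_endoscopies_intervention == pytest.approx(198 + 23)
    base = table1_allocation(ps)
    delta = alloc.intervention.treatment - base.intervention.treatment
    assert delta[H.LGD] == pytest.approx(0.1)
    assert delta[H.HGD] == pytest.approx(1.0)
    assert delta[H.EARLY_EAC] == pytest.approx(2.0)
    alloc.validate(ps.settings.cohort_size)


# ----------------------------------------------------------------------


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    fractions=st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
    prev_scale=st.floats(0.3, 1.3),
)
def test_allocation_conservation_property(ps, fractions, prev_scale):
    """Any feasible detected/prevalence combination conserves the cohort."""
    n = ps.settings.cohort_size
    prevalence = {s: ps.prevalence[s] * prev_scale for s in DISEASE_STATES}
    detected = {
        "intervention": {s: f * prevalence[s] * n
                         for s, f in zip(DISEASE_STATES, fractions)},
        "usual": {},
    }
    alloc = allocate_from_trial(ps, detected=detected, prevalence=prevalence)
    alloc.validate(n)  # conservation + cross-arm identity + non-negativity
    np.testing.assert_allclose(alloc.intervention.per_state_total,
                               alloc.usual.per_state_total, rtol=1e-9, atol=1e-9)
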