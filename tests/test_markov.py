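"""Markov engine: matrices, half-cycle correction, conservation, oracles."""
import numpy as np
import pytest

from cytocea import (
    LifeTable,
    ParameterError,
    build_transition_matrix,
    half_cycle_correct,
    microsimulate,
    run_cohort,
    table1_allocation,
    treatment_entry,
)
from cytocea.cohort import ArmAllocation
from cytocea.states import ALIVE_STATES, HealthState, N_STATES

H = HealthState


def _natural_only(vector):
    return ArmAllocation(treatment=np.zeros(N_STATES), natural=np.asarray(vector, float))


def test_half_cycle_correction_values():
    assert half_cycle_correct(100.0, 100.0) == 100.0
    assert half_cycle_correct(100.0, 0.0) == 50.0
    with pytest.raises(ParameterError):
        half_cycle_correct(-1.0, 0.0)


def test_matrix_rows_sum_to_one_at_every_age(ps):
    for age in range(ps.settings.start_age, ps.settings.age_cap):
        m = build_transition_matrix(ps, age)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(m >= 0.0)


def test_dead_row_is_identity(ps):
    m = build_transition_matrix(ps, 80)
    expected = np.zeros(N_STATES)
    expected[H.DEAD] = 1.0
    np.testing.assert_array_equal(m[H.DEAD], expected)


def test_zero_disease_matrix_is_pure_mortality(ps):
    p = ps.copy()
    p.transitions.natural_history = {k: 0.0 for k in p.transitions.natural_history}
    p.transitions.eac_mortality = {s: 0.0 for s in p.transitions.eac_mortality}
    q = p.life_table.q(75)
    m = build_transition_matrix(p, 75)
    for s in ALIVE_STATES:
        assert m[s, s] == pytest.approx(1.0 - q)
        assert m[s, H.DEAD] == pytest.approx(q)


def test_composite_incidence_is_rate_times_survival(ps):
    age = 72
    q = ps.life_table.q(age)
    i = ps.transitions.natural_history[(H.NO_BE, H.NDBE)]
    m = build_transition_matrix(ps, age)
    assert m[H.NO_BE, H.NDBE] == pytest.approx(i * (1.0 - q), rel=1e-12)


def test_missing_life_table_age_errors(ps):
    with pytest.raises(ParameterError, match="life table"):
        build_transition_matrix(ps, 200)


# ----------------------------------------------------------------------
# Cohort runs


def test_cohort_mass_conserved_every_cycle(ps):
    alloc = table1_allocation(ps)
    trace = run_cohort(alloc.intervention, ps, arm="intervention")
    totals = trace.occupancy.sum(axis=1)
    np.testing.assert_allclose(totals, ps.settings.cohort_size, rtol=1e-9)


def test_dead_occupancy_non_decreasing(ps):
    trace = run_cohort(table1_allocation(ps).usual, ps)
    dead = trace.occupancy[:, H.DEAD]
    assert np.all(np.diff(dead) >= -1e-9)


def test_no_mortality_keeps_dead_empty(ps):
    p = ps.copy()
    p.life_table = LifeTable(p.life_table.ages,
                             np.zeros_like(p.life_table.qx))
    p.transitions.eac_mortality = {s: 0.0 for s in p.transitions.eac_mortality}
    p.transitions.esophagectomy_90day_mortality = 0.0
    trace = run_cohort(table1_allocation(p).usual, p)
    assert np.all(trace.occupancy[:, H.DEAD] == 0.0)
    assert trace.cumulative_eac_deaths == 0.0


def test_unit_utility_zero_discount_qalys_equal_life_years(ps):
    p = ps.copy()
    p.settings.discount_rate = 0.0
    for s in ALIVE_STATES:
        p.utilities.state_utility[s] = 1.0
    for ev in p.utilities.events.values():
        ev.decrement = 0.0
    trace = run_cohort(table1_allocation(p).intervention, p)
    assert trace.total_qalys == pytest.approx(trace.total_life_years, rel=1e-12)
    np.testing.assert_allclose(trace.qalys, trace.life_years, rtol=1e-12)


def test_two_cycle_hand_oracle(ps):
    """One NoBE person, no disease moves, constant mortality: closed form."""
    p = ps.copy()
    p.settings.cohort_size = 1.0
    p.settings.age_cap = p.settings.start_age + 2
    p.transitions.natural_history = {k: 0.0 for k in p.transitions.natural_history}
    q = 0.1
    p.life_table = LifeTable(p.life_table.ages,
                             np.full_like(p.life_table.qx, q))
    u = p.utilities.state_utility[H.NO_BE]
    r = p.settings.discount_rate
    start = np.zeros(N_STATES)
    start[H.NO_BE] = 1.0
    trace = run_cohort(_natural_only(start), p)
    # hand-computed: survival 1 -> 0.9 -> 0.81; trapezoids 0.95 and 0.855
    expected_ly = 0.95 + 0.855 / (1.0 + r)
    assert trace.total_life_years == pytest.approx(expected_ly, rel=1e-12)
    assert trace.total_qalys == pytest.approx(u * expected_ly, rel=1e-12)


def test_half_cycle_life_years_bracketed_by_riemann_sums(ps):
    trace = run_cohort(table1_allocation(ps).usual, ps)
    alive = [int(s) for s in ALIVE_STATES]
    start_sum = trace.occupancy[:-1, alive].sum()
    end_sum = trace.occupancy[1:, alive].sum()
    total = trace.life_years.sum()
    assert end_sum < total < start_sum


def test_discounting_monotone(ps):
    alloc = table1_allocation(ps).intervention
    base = run_cohort(alloc, ps, arm="intervention")
    p = ps.copy()
    p.settings.discount_rate = 0.07
    heavier = run_cohort(alloc, p, arm="intervention")
    assert heavier.total_qalys < base.total_qalys
    assert heavier.cost_disc[1:].sum() < base.cost_disc[1:].sum()


def test_usual_care_eac_deaths_near_reported(ps):
    trace = run_cohort(table1_allocation(ps).usual, ps)
    assert trace.cumulative_eac_deaths == pytest.approx(173.0, rel=0.10)


# ----------------------------------------------------------------------
# Treatment entry


def test_perfect_treatment_moves_all_detected_to_nobe(ps):
    p = ps.copy()
    p.transitions.treatment_success = {s: 1.0 for s in p.transitions.treatment_success}
    p.transitions.esophagectomy_90day_mortality = 0.0
    alloc = table1_allocation(p).intervention
    entry = treatment_entry(alloc, p)
    expected_nobe = alloc.natural[H.NO_BE] + alloc.treatment.sum()
    assert entry.occupancy[H.NO_BE] == pytest.approx(expected_nobe)
    assert entry.eac_deaths == 0.0


def test_empty_treatment_chain_costs_nothing(ps):
    vec = np.zeros(N_STATES)
    vec[H.NO_BE] = 100.0
    entry = treatment_entry(_natural_only(vec), ps)
    assert entry.cost == 0.0
    assert entry.disutility == 0.0


def test_endotherapy_disutility_four_weeks(ps):
    p = ps.copy()
    for label in ("stricture", "perforation"):
        p.utilities.events[label].probability = 0.0
    tr = np.zeros(N_STATES)
    tr[H.NDBE] = 10.0
    entry = treatment_entry(
        ArmAllocation(treatment=tr, natural=np.zeros(N_STATES)), p)
    ev = p.utilities.events["emr_rfa"]
    assert ev.duration_years == pytest.approx(4.0 / 52.0)
    assert entry.disutility == pytest.approx(10.0 * ev.decrement * 4.0 / 52.0)


def test_late_eac_cannot_enter_treatment(ps):
    tr = np.zeros(N_STATES)
    tr[H.LATE_EAC] = 1.0
    with pytest.raises(ParameterError, match="late EAC"):
        treatment_entry(ArmAllocation(treatment=tr, natural=np.zeros(N_STATES)), ps)


def test_failed_treatment_collapses_arms_to_same_dynamics(ps):
    """With zero treatment success the chains merge: occupancy traces of the
    two arms coincide and they differ only through entry costs."""
    p = ps.copy()
    p.transitions.treatment_success = {s: 0.0 for s in p.transitions.treatment_success}
    p.transitions.esophagectomy_90day_mortality = 0.0
    alloc = table1_allocation(p)
    t_int = run_cohort(alloc.intervention, p, arm="intervention")
    t_usual = run_cohort(alloc.usual, p, arm="usual")
    np.testing.assert_allclose(t_int.occupancy, t_usual.occupancy, rtol=1e-9)
    np.testing.assert_allclose(t_int.life_years, t_usual.life_years, rtol=1e-9)


# ----------------------------------------------------------------------
# Independent microsimulation oracle


def test_cohort_engine_matches_microsimulation(ps):
    """Per-person microsimulation (same matrices, n = 50,000, fixed seed)
    reproduces the cohort engine's mean life years and QALYs within three
    Monte-Carlo standard errors."""
    entry = treatment_entry(table1_allocation(ps).usual, ps)
    trace = run_cohort(_natural_only(entry.occupancy), ps)
    n = entry.occupancy.sum()
    ms = microsimulate(ps, entry.occupancy, n_persons=50_000, seed=20240214 % 2**31)
    assert abs(trace.total_life_years / n - ms.mean_life_years) < 3 * ms.se_life_years
    assert abs(trace.total_qalys / n - ms.mean_qalys) < 3 * ms.se_qalys
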