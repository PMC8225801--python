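"""Yearly-cycle cohort Markov engine with half-cycle correction.

The model iterates one-year cycles from the cohort's starting age to the
age cap.  Disease transitions (from :class:`~cytocea.params.TransitionSet`)
are composited each cycle with age-specific all-cause mortality from the
life table; EAC states additionally carry excess cancer mortality.  Costs
and QALYs accrue on half-cycle-corrected (trapezoidal) occupancy and are
discounted at the annual rate with cycle-0 accruals undiscounted, so that
one-off screening and treatment-entry quantities charged at model start
carry no discount.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import ArmAllocation
from .params import ParameterError, ParameterSet
from .states import ALIVE_STATES, HealthState, N_STATES

_ALIVE = [int(s) for s in ALIVE_STATES]
_DEAD = int(HealthState.DEAD)


def half_cycle_correct(occupancy_start, occupancy_end):
    """Effective person-years over one cycle: the trapezoidal mean."""
    start = np.asarray(occupancy_start, dtype=float)
    end = np.asarray(occupancy_end, dtype=float)
    if np.any(start < 0) or np.any(end < 0):
        raise ParameterError("occupancy must be non-negative")
    return (start + end) / 2.0


def build_transition_matrix(params: ParameterSet, age: int) -> np.ndarray:
    """Row-stochastic one-year transition matrix at a given age.

    Disease moves are conditional on surviving the year; the Dead row is
    the identity.  EAC states combine background mortality with the
    cancer-specific annual death probability.
    """
    q = params.life_table.q(age)
    nh = params.transitions.natural_history
    eac_mort = params.transitions.eac_mortality
    m = np.zeros((N_STATES, N_STATES))
    for s in ALIVE_STATES:
        excess = eac_mort.get(s, 0.0)
        p_dead = q + (1.0 - q) * excess
        survive = (1.0 - q) * (1.0 - excess)
        out = 0.0
        for (f, t), p in nh.items():
            if f is s:
                m[s, t] += survive * p
                out += p
        if out > 1.0 + 1e-12:
            raise ParameterError(
                f"outgoing disease probabilities from {s.label} sum to {out}")
        m[s, s] += survive * (1.0 - out)
        m[s, _DEAD] += p_dead
    m[_DEAD, _DEAD] = 1.0
    if np.any(m < -1e-15):
        raise ParameterError(f"negative composite probability at age {age}")
    rowsum = m.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-12):
        raise ParameterError(f"rows do not sum to 1 at age {age}: {rowsum}")
    return m


def transition_matrices(params: ParameterSet, start_age: int | None = None) -> np.ndarray:
    """Stacked matrices for every cycle of the horizon, shape (T, n, n)."""
    a0 = params.settings.start_age if start_age is None else start_age
    ages = range(a0, params.settings.age_cap)
    return np.stack([build_transition_matrix(params, a) for a in ages])


@dataclass
class EntryResult:
    """Outcome of applying one-off treatment at model entry."""

    occupancy: np.ndarray          # post-entry state vector (whole arm)
    cost: float                    # one-off treatment cost, GBP
    disutility: float              # one-off QALY loss from procedure events
    eac_deaths: float              # 90-day surgical deaths at entry

#: Treatment pathways at entry: state -> (cost fields, disutility events).
_TREATMENT_PATHWAYS = {
    HealthState.NDBE: (("endotherapy_rfa",), ("emr_rfa", "stricture", "perforation")),
    HealthState.LGD: (("endotherapy_rfa",), ("emr_rfa", "stricture", "perforation")),
    HealthState.HGD: (("endotherapy_emr", "endotherapy_rfa"),
                      ("emr_rfa", "stricture", "perforation")),
    HealthState.EARLY_EAC: (("esophagectomy", "chemotherapy"),
                            ("esophagectomy", "chemotherapy")),
}


def treatment_entry(allocation: ArmAllocation, params: ParameterSet) -> EntryResult:
    """Apply one-off treatment to the arm's treatment chain.

    Dysplastic and non-dysplastic BE receive endotherapy (EMR/RFA); early
    EAC follows the resection/chemotherapy pathway with its 90-day
    mortality.  Successes join the natural-history chain's NoBE state,
    failures remain in-state in the natural-history chain; surgical deaths
    move to Dead.  One-off costs and procedure disutilities (decrement x
    duration, weighted by occurrence probability) are charged at entry.
    """
    tr = allocation.treatment
    if tr[HealthState.LATE_EAC] != 0:
        raise ParameterError("late EAC is not a permissible treatment-entry state")
    occupancy = allocation.natural.copy()
    occupancy[HealthState.NO_BE] += tr[HealthState.NO_BE]
    cost = 0.0
    disutility = 0.0
    deaths = 0.0
    success = params.transitions.treatment_success
    for state, (cost_fields, event_labels) in _TREATMENT_PATHWAYS.items():
        n = tr[state]
        if n == 0:
            continue
        cost += n * sum(getattr(params.costs, f) for f in cost_fields)
        disutility += n * sum(params.utilities.events[l].qaly_loss for l in event_labels)
        mortality = (params.transitions.esophagectomy_90day_mortality
                     if state is HealthState.EARLY_EAC else 0.0)
        dead = n * mortality
        survivors = n - dead
        cured = survivors * success[state]
        occupancy[HealthState.NO_BE] += cured
        occupancy[state] += survivors - cured
        occupancy[HealthState.DEAD] += dead
        deaths += dead
    return EntryResult(occupancy=occupancy, cost=cost,
                       disutility=disutility, eac_deaths=deaths)


@dataclass
class TraceResult:
    """Per-cycle trace for one arm, plus discounted totals."""

    arm: str
    start_age: int
    cohort_size: float
    ages: np.ndarray                  # (T,)
    occupancy: np.ndarray             # (T+1, N_STATES), start-of-cycle counts
    life_years: np.ndarray            # (T,) undiscounted person-years
    life_years_disc: np.ndarray
    qalys: np.ndarray
    qalys_disc: np.ndarray
    cost: np.ndarray                  # (T,) undiscounted GBP (incl. one-offs at t=0)
    cost_disc: np.ndarray
    eac_deaths: np.ndarray            # (T,) deaths attributed to EAC per cycle
    inflow: np.ndarray                # (T, N_STATES) entries into each state per cycle
    initial_disease: np.ndarray       # (N_STATES,) pre-entry per-state totals
    entry_eac_deaths: float = 0.0
    screening_cost: float = 0.0       # component memo, GBP (included in cost[0])
    entry_cost: float = 0.0

    @property
    def total_cost(self) -> float:
        return float(self.cost_disc.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qalys_disc.sum())

    @property
    def total_life_years(self) -> float:
        return float(self.life_years_disc.sum())

    @property
    def treatment_cost(self) -> float:
        """Everything that is not the screening programme itself."""
        return self.total_cost - self.screening_cost

    @property
    def cumulative_eac_deaths(self) -> float:
        return float(self.eac_deaths.sum()) + self.entry_eac_deaths

    def incident_count(self, state: HealthState) -> float:
        """Patients who start with or develop a state (entries, not persons)."""
        return float(self.initial_disease[state] + self.inflow[:, state].sum())

    @property
    def censored_alive_fraction(self) -> float:
        """Share of the cohort still alive when the age cap terminates the run."""
        return float(self.occupancy[-1, _ALIVE].sum() / self.cohort_size)

    def to_frame(self):
        """Tidy per-cycle export (cycle, age, state, occupancy, cost, qaly)."""
        import pandas as pd

        rows = []
        for t, age in enumerate(self.ages):
            for s in HealthState:
                rows.append({
                    "cycle": t, "age": int(age), "arm": self.arm,
                    "state": s.label,
                    "occupancy": float(self.occupancy[t, s]),
                })
        df = pd.DataFrame(rows)
        per_cycle = pd.DataFrame({
            "cycle": np.arange(len(self.ages)),
            "cost_disc": self.cost_disc, "qalys_disc": self.qalys_disc,
        })
        return df.merge(per_cycle, on="cycle")


def run_cohort(
    allocation: ArmAllocation,
    params: ParameterSet,
    *,
    arm: str = "",
    oneoff_cost: float = 0.0,
    screening_cost: float = 0.0,
    start_age: int | None = None,
    matrices: np.ndarray | None = None,
) -> TraceResult:
    """Run one arm over the lifetime horizon.

    Treatment entry is applied first; the merged cohort then evolves under
    the natural-history dynamics.  Recurring state costs (acid-suppressant
    drugs for reflux states, annual late-EAC management) accrue on
    half-cycle-corrected occupancy; palliative care is charged once per
    death from late EAC.  ``oneoff_cost`` (screening etc.) is added,
    undiscounted, at cycle 0.
    """
    entry = treatment_entry(allocation, params)
    a0 = params.settings.start_age if start_age is None else start_age
    age_cap = params.settings.age_cap
    T = age_cap - a0
    if T <= 0:
        raise ParameterError(f"start age {a0} must be below age cap {age_cap}")
    if matrices is None:
        matrices = transition_matrices(params, start_age=a0)

    n_states = N_STATES
    occ = np.empty((T + 1, n_states))
    occ[0] = entry.occupancy
    ly = np.zeros(T)
    qaly = np.zeros(T)
    cost = np.zeros(T)
    deaths = np.zeros(T)
    inflow = np.zeros((T, n_states))

    u = np.zeros(n_states)
    for s in ALIVE_STATES:
        u[s] = params.utilities.state_utility[s]
    ppi_mask = np.zeros(n_states)
    for s in params.ppi_states:
        ppi_mask[s] = 1.0
    costs = params.costs
    late = int(HealthState.LATE_EAC)
    early = int(HealthState.EARLY_EAC)
    early_excess = params.transitions.eac_mortality.get(HealthState.EARLY_EAC, 0.0)

    for t in range(T):
        m = matrices[t]
        cur = occ[t]
        nxt = cur @ m
        if np.any(nxt < -1e-9):
            raise ParameterError("negative occupancy: malformed transition matrix")
        occ[t + 1] = nxt
        hcc = half_cycle_correct(cur, nxt)
        alive_hcc = hcc[_ALIVE]
        ly[t] = alive_hcc.sum()
        qaly[t] = float(u[_ALIVE] @ alive_hcc)
        late_deaths = cur[late] * m[late, _DEAD]
        q_bg = params.life_table.q(a0 + t)
        early_deaths = cur[early] * (1.0 - q_bg) * early_excess
        deaths[t] = late_deaths + early_deaths
        cost[t] = (costs.ppi_annual * float(ppi_mask @ hcc)
                   + costs.chemotherapy * hcc[late]
                   + costs.palliative_care * late_deaths)
        inflow[t] = cur @ (m * (1.0 - np.eye(n_states)))

    rate = params.settings.discount_rate
    disc = (1.0 + rate) ** (-np.arange(T, dtype=float))
    cost[0] += oneoff_cost + entry.cost
    qaly[0] -= entry.disutility

    return TraceResult(
        arm=arm,
        start_age=a0,
        cohort_size=params.settings.cohort_size,
        ages=np.arange(a0, age_cap),
        occupancy=occ,
        life_years=ly,
        life_years_disc=ly * disc,
        qalys=qaly,
        qalys_disc=qaly * disc,
        cost=cost,
        cost_disc=cost * disc,
        eac_deaths=deaths,
        inflow=inflow,
        initial_disease=allocation.per_state_total,
        entry_eac_deaths=entry.eac_deaths,
        screening_cost=screening_cost,
        entry_cost=entry.cost,
    )
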