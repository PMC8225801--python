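"""Incremental cost-effectiveness analysis and budget impact.

Compares the screening (intervention) arm against usual care on
discounted per-person costs and QALYs, reports the incremental
cost-effectiveness ratio (ICER = dC/dE on unrounded increments), net
monetary benefit at a willingness-to-pay threshold, and the aggregate
budget impact of offering one screening round to the eligible population.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort as _cohort
from . import markov as _markov
from .params import ParameterError, ParameterSet
from .states import HealthState


@dataclass
class ArmSummary:
    """Discounted per-person means for one arm."""

    arm: str
    screening_cost: float
    treatment_cost: float
    total_cost: float
    qalys: float
    life_years: float


@dataclass
class CEResult:
    intervention: ArmSummary
    usual: ArmSummary
    delta_cost: float
    delta_qalys: float
    delta_life_years: float
    icer: float | None          # None when delta_qalys == 0
    dominance: str | None       # "dominant" | "dominated" | None
    nmb: float
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        """Per-patient breakdown table (units: GBP and QALYs)."""
        rows = [
            ("screening_cost", self.intervention.screening_cost,
             self.usual.screening_cost,
             self.intervention.screening_cost - self.usual.screening_cost),
            ("treatment_cost", self.intervention.treatment_cost,
             self.usual.treatment_cost,
             self.intervention.treatment_cost - self.usual.treatment_cost),
            ("total_cost", self.intervention.total_cost, self.usual.total_cost,
             self.delta_cost),
            ("qalys", self.intervention.qalys, self.usual.qalys, self.delta_qalys),
            ("life_years", self.intervention.life_years, self.usual.life_years,
             self.delta_life_years),
        ]
        df = pd.DataFrame(rows, columns=["quantity", "intervention", "usual",
                                         "difference"])
        icer_label = "dominant" if self.dominance == "dominant" else (
            "undefined" if self.icer is None else self.icer)
        df.loc[len(df)] = ["icer", icer_label, "", ""]
        return df


@dataclass
class BudgetImpact:
    eligible_patients: float
    total_budget: float
    horizon_years: float
    annual_cost: float


# ----------------------------------------------------------------------


def run_arm(
    params: ParameterSet,
    arm: str,
    allocation: _cohort.StartingAllocation | None = None,
    scenario: _cohort.ScreeningScenario | None = None,
    start_age: int | None = None,
    matrices: np.ndarray | None = None,
) -> _markov.TraceResult:
    """Run one arm of the base pipeline: entry, screening cost, Markov trace."""
    if allocation is None:
        allocation = _cohort.table1_allocation(params)
    if scenario is None:
        scenario = _cohort.base_scenario(params)
    sc = _cohort.screening_cost(scenario, params.costs)
    screen_total = (sc.total_intervention if arm == "intervention"
                    else sc.total_usual)
    return _markov.run_cohort(
        allocation.arm(arm), params, arm=arm,
        oneoff_cost=screen_total, screening_cost=screen_total,
        start_age=start_age, matrices=matrices)


def run_base_case(
    params: ParameterSet,
    allocation: _cohort.StartingAllocation | None = None,
    scenario: _cohort.ScreeningScenario | None = None,
    start_age: int | None = None,
) -> tuple[_markov.TraceResult, _markov.TraceResult, CEResult]:
    """Run both arms and the incremental analysis."""
    matrices = _markov.transition_matrices(params, start_age=start_age)
    trace_int = run_arm(params, "intervention", allocation, scenario,
                        start_age=start_age, matrices=matrices)
    trace_usual = run_arm(params, "usual", allocation, scenario,
                          start_age=start_age, matrices=matrices)
    ce = incremental_analysis(trace_int, trace_usual,
                              params.settings.wtp_threshold)
    return trace_int, trace_usual, ce


def _summary(trace: _markov.TraceResult) -> ArmSummary:
    n = trace.cohort_size
    return ArmSummary(
        arm=trace.arm,
        screening_cost=trace.screening_cost / n,
        treatment_cost=trace.treatment_cost / n,
        total_cost=trace.total_cost / n,
        qalys=trace.total_qalys / n,
        life_years=trace.total_life_years / n,
    )


def incremental_analysis(
    trace_int: _markov.TraceResult,
    trace_usual: _markov.TraceResult,
    threshold: float,
) -> CEResult:
    """Per-person increments, ICER with quadrant semantics, and NMB.

    The ICER is undefined (``None``) at zero QALY difference; a strategy
    that saves money while gaining QALYs is flagged ``dominant`` rather
    than reported as a negative ratio headline.
    """
    if trace_int.cohort_size != trace_usual.cohort_size:
        raise ParameterError("traces must come from identical settings")
    s_int = _summary(trace_int)
    s_usual = _summary(trace_usual)
    d_cost = s_int.total_cost - s_usual.total_cost
    d_qaly = s_int.qalys - s_usual.qalys
    d_ly = s_int.life_years - s_usual.life_years
    if d_qaly == 0.0:
        icer, dominance = None, None
    else:
        icer = d_cost / d_qaly
        if d_cost < 0 and d_qaly > 0:
            dominance = "dominant"
        elif d_cost > 0 and d_qaly < 0:
            dominance = "dominated"
        else:
            dominance = None
    nmb = d_qaly * threshold - d_cost
    return CEResult(
        intervention=s_int, usual=s_usual,
        delta_cost=d_cost, delta_qalys=d_qaly, delta_life_years=d_ly,
        icer=icer, dominance=dominance, nmb=nmb, threshold=threshold,
    )


def budget_impact(
    ce: CEResult, eligible: float, horizon: float
) -> BudgetImpact:
    """Aggregate cost of one screening round for the eligible population.

    Uses the unrounded incremental cost per person; the total is spread
    evenly (undiscounted) over the horizon.
    """
    if eligible <= 0:
        raise ParameterError(f"eligible_patients {eligible}: must be > 0")
    if horizon <= 0:
        raise ParameterError(f"horizon_years {horizon}: must be > 0")
    total = eligible * ce.delta_cost
    return BudgetImpact(
        eligible_patients=eligible,
        total_budget=total,
        horizon_years=horizon,
        annual_cost=total / horizon,
    )


def model_outputs_frame(
    traces: dict[str, _markov.TraceResult],
    scenarios: dict[str, _cohort.ScreeningScenario],
) -> pd.DataFrame:
    """Key model outputs per arm: screening volumes, incident disease, deaths."""
    rows = []
    for name, trace in traces.items():
        sc = scenarios[name]
        is_int = name != "usual"
        rows.append({
            "arm": name,
            "invited": sc.n_invited if is_int else 0.0,
            "cytosponge_tests": sc.total_tests if is_int else 0.0,
            "endoscopies": (sc.total_endoscopies_intervention if is_int
                            else sc.n_endoscopy_usual),
            "incident_lgd": trace.incident_count(HealthState.LGD),
            "incident_hgd": trace.incident_count(HealthState.HGD),
            "incident_early_eac": trace.incident_count(HealthState.EARLY_EAC),
            "eac_deaths": trace.cumulative_eac_deaths,
        })
    return pd.DataFrame(rows)


def display_round(ce: CEResult) -> dict:
    """Rounded values for display: costs to nearest GBP, QALYs to 3 d.p."""
    icer = ce.icer
    return {
        "delta_cost": round(ce.delta_cost),
        "delta_qalys": round(ce.delta_qalys, 3),
        "delta_life_years": round(ce.delta_life_years, 3),
        "icer": ("dominant" if ce.dominance == "dominant"
                 else None if icer is None else round(icer)),
        "nmb": round(ce.nmb),
    }
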