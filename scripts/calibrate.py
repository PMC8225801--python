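#!/usr/bin/env python
"""One-time calibration of the packaged base-case parameter set.

The natural-history transition probabilities, state utilities and several
unit costs of the reference analysis were published only in aggregate:
the report prints the model's base-case outputs (per-arm discounted
costs, QALYs and life years, cumulative incident disease and EAC deaths)
but not the full input tables behind them.  This script starts from
values in the style of the antecedent decision model, then tunes a small
set of inputs, in a fixed staged order, so that the packaged base case
reproduces those printed outputs:

  stage 0  life-table level      -> usual-care discounted life years
  stage 1  transitions           -> usual-care incident LGD/HGD/early-EAC
                                    counts and EAC deaths; EAC-death
                                    difference between arms; incremental
                                    life years
  stage 2  utilities             -> usual-care QALYs; incremental QALYs
  stage 3  costs                 -> usual-care treatment cost; incremental
                                    cost

Stages 0-1 are iterated twice (the life-table level and the cancer
mortality interact); stages 2-3 depend on the earlier stages but not
vice versa.  Calibrated parameters are written with provenance
``derived-calibration``.  The script rewrites ``src/cytocea/data/basecase``
and is run once; it is kept for provenance and reproducibility.
"""
from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, least_squares

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

from cytocea import cea, cohort  # noqa: E402
from cytocea.params import (  # noqa: E402
    BudgetSettings, CostSet, DisutilityEvent, LifeTable, ModelSettings,
    ParamMeta, ParameterSet, TestAccuracy, TransitionSet, TrialCounts,
    UtilitySet, write_parameters,
)
from cytocea.states import HealthState as H  # noqa: E402

DATA_DIR = REPO / "src" / "cytocea" / "data" / "basecase"

# Published base-case outputs used as calibration targets (usual-care arm
# unless noted).  Monetary values GBP, discounted at 3.5%.
TARGETS = {
    "life_years_usual": 13.016,
    "qalys_usual": 9.911,
    "treatment_cost_usual": 482.0,
    "incident_lgd_usual": 343.0,
    "incident_hgd_usual": 151.0,
    "incident_early_eac_usual": 177.0,
    "eac_deaths_usual": 173.0,
    "eac_death_difference": 20.0,
    "delta_life_years": 0.011,
    "delta_qalys": 82.29 / 5500.0,  # implied by the unrounded cost difference
    "delta_cost": 82.29,            # budget total / eligible patients
}

#: Cytosponge unit cost derived in closed form from the printed screening
#: total: (524716 - 198 x 488) / 1654.  Endoscopy cost 488 = 7808 / 16.
ENDOSCOPY_COST = 7808.0 / 16.0
CYTOSPONGE_COST = (524716.0 - 198.0 * ENDOSCOPY_COST) / 1654.0

GOMPERTZ_SLOPE = 0.095  # per-year log-slope of adult all-cause mortality


def gompertz_life_table(level: float) -> LifeTable:
    ages = np.arange(50, 101)
    qx = np.minimum(level * np.exp(GOMPERTZ_SLOPE * (ages - 69.0)), 0.7)
    return LifeTable(ages, qx)


def initial_parameter_set() -> ParameterSet:
    """Antecedent-model-style starting values, before calibration."""
    n = 6834.0
    prevalence = {H.NDBE: 566.6 / n, H.LGD: 4.6 / n,
                  H.HGD: 13.8 / n, H.EARLY_EAC: 18.4 / n}
    trial = TrialCounts(
        detected={
            "intervention": {H.NDBE: 123.0, H.LGD: 1.0, H.HGD: 3.0,
                             H.EARLY_EAC: 4.0},
            "usual": {H.NDBE: 11.6, H.LGD: 0.0, H.HGD: 0.0, H.EARLY_EAC: 4.0},
        },
        repeat_detected_delta={H.LGD: 0.1, H.HGD: 1.0, H.EARLY_EAC: 2.0},
    )
    costs = CostSet(
        cytosponge_test=CYTOSPONGE_COST, endoscopy_biopsy=ENDOSCOPY_COST,
        ppi_annual=17.0, endotherapy_emr=2500.0, endotherapy_rfa=2200.0,
        esophagectomy=13000.0, chemotherapy=9000.0, palliative_care=4000.0)
    utilities = UtilitySet(
        state_utility={H.NO_BE: 0.765, H.NDBE: 0.730, H.LGD: 0.720,
                       H.HGD: 0.700, H.EARLY_EAC: 0.670, H.LATE_EAC: 0.450},
        events={
            "stricture": DisutilityEvent("stricture", 0.12, 2.0 / 52.0, 0.08),
            "perforation": DisutilityEvent("perforation", 0.15, 4.0 / 52.0, 0.01),
            "emr_rfa": DisutilityEvent("emr_rfa", 0.10, 4.0 / 52.0, 1.0),
            "chemotherapy": DisutilityEvent("chemotherapy", 0.15, 4.5 / 12.0, 1.0),
            "esophagectomy": DisutilityEvent("esophagectomy", 0.20, 3.0 / 12.0, 1.0),
        })
    transitions = TransitionSet(
        natural_history={
            (H.NO_BE, H.NDBE): 0.002,
            (H.NDBE, H.LGD): 0.030,
            (H.NDBE, H.EARLY_EAC): 0.012,
            (H.LGD, H.NDBE): 0.100,
            (H.LGD, H.HGD): 0.120,
            (H.HGD, H.LGD): 0.050,
            (H.HGD, H.EARLY_EAC): 0.150,
            (H.EARLY_EAC, H.LATE_EAC): 0.600,
        },
        treatment_success={H.NDBE: 0.80, H.LGD: 0.90, H.HGD: 0.85,
                           H.EARLY_EAC: 0.75},
        esophagectomy_90day_mortality=0.04,
        eac_mortality={H.EARLY_EAC: 0.05, H.LATE_EAC: 0.60})
    meta = _build_meta(costs, utilities)
    return ParameterSet(
        settings=ModelSettings(), accuracy=TestAccuracy(), costs=costs,
        utilities=utilities, transitions=transitions,
        life_table=gompertz_life_table(0.0150), prevalence=prevalence,
        trial=trial, budget=BudgetSettings(), meta=meta)


def _build_meta(costs, utilities) -> dict[str, ParamMeta]:
    """Provenance + PSA/DSA metadata for every registered parameter."""
    m: dict[str, ParamMeta] = {}

    def add(name, value, low=None, high=None, dist=None, prov="assumption"):
        m[name] = ParamMeta(name=name, value=value, low=low, high=high,
                            distribution=dist, provenance=prov)

    add("cytosponge_test", costs.cytosponge_test, 144.0, 344.0, "gamma",
        "derived-calibration")
    add("endoscopy_biopsy", costs.endoscopy_biopsy, dist="gamma",
        prov="trial-publication")
    add("ppi_annual", costs.ppi_annual, dist="gamma", prov="derived-calibration")
    add("endotherapy_emr", costs.endotherapy_emr, dist="gamma", prov="literature")
    add("endotherapy_rfa", costs.endotherapy_rfa, dist="gamma",
        prov="derived-calibration")
    add("esophagectomy", costs.esophagectomy, dist="gamma", prov="literature")
    add("chemotherapy", costs.chemotherapy, dist="gamma", prov="literature")
    add("palliative_care", costs.palliative_care, dist="gamma", prov="literature")

    for s, prov in ((H.NO_BE, "derived-calibration"),
                    (H.NDBE, "derived-calibration"), (H.LGD, "literature"),
                    (H.HGD, "literature"), (H.EARLY_EAC, "literature"),
                    (H.LATE_EAC, "literature")):
        add(f"utility_{s.label.lower()}", utilities.state_utility[s],
            dist="beta:0.02", prov=prov)
    for label, ev in utilities.events.items():
        add(f"disutility_{label}", ev.decrement, dist="beta", prov="literature")
        add(f"duration_{label}", ev.duration_years, dist="fixed",
            prov="trial-publication")
    for label in ("stricture", "perforation"):
        add(f"prob_{label}", utilities.events[label].probability, dist="beta",
            prov="literature")

    calibrated_transitions = (
        "nobe_to_ndbe", "ndbe_to_lgd", "ndbe_to_early_eac", "lgd_to_ndbe",
        "lgd_to_hgd", "hgd_to_lgd", "hgd_to_early_eac", "early_to_late_eac",
        "early_eac_mortality", "late_eac_mortality", "treat_success_ndbe")
    for name in ("nobe_to_ndbe", "ndbe_to_lgd", "ndbe_to_early_eac",
                 "lgd_to_ndbe", "lgd_to_hgd", "hgd_to_lgd",
                 "hgd_to_early_eac", "early_to_late_eac",
                 "early_eac_mortality", "late_eac_mortality",
                 "treat_success_ndbe", "treat_success_lgd",
                 "treat_success_hgd", "treat_success_early_eac",
                 "esophagectomy_90day_mortality"):
        prov = ("derived-calibration" if name in calibrated_transitions
                else "literature")
        add(name, 0.0, dist="beta", prov=prov)  # values filled at write time

    add("sensitivity", 0.799, 0.764, 0.830, "beta", "trial-publication")
    add("specificity", 0.924, dist="beta", prov="trial-publication")
    add("uptake", 0.242, 0.10, 0.50, "beta", "trial-publication")
    add("endoscopy_attendance", 198.0 / 221.0, dist="beta",
        prov="trial-publication")
    add("prevalence_be", 603.4 / 6834.0, 0.04, 0.12, "beta",
        prov="trial-publication")
    add("start_age", 69.0, 50.0, 74.0, None, "trial-publication")
    add("discount_rate", 0.035, prov="trial-publication")
    add("wtp_threshold", 20000.0, prov="trial-publication")
    return m


# ----------------------------------------------------------------------


def measure(ps: ParameterSet) -> dict[str, float]:
    trace_int, trace_usual, ce_res = cea.run_base_case(ps)
    n = ps.settings.cohort_size
    return {
        "life_years_usual": trace_usual.total_life_years / n,
        "qalys_usual": trace_usual.total_qalys / n,
        "treatment_cost_usual": trace_usual.treatment_cost / n,
        "incident_lgd_usual": trace_usual.incident_count(H.LGD),
        "incident_hgd_usual": trace_usual.incident_count(H.HGD),
        "incident_early_eac_usual": trace_usual.incident_count(H.EARLY_EAC),
        "eac_deaths_usual": trace_usual.cumulative_eac_deaths,
        "eac_death_difference": (trace_usual.cumulative_eac_deaths
                                 - trace_int.cumulative_eac_deaths),
        "delta_life_years": ce_res.delta_life_years,
        "delta_qalys": ce_res.delta_qalys,
        "delta_cost": ce_res.delta_cost,
        "icer": ce_res.icer if ce_res.icer is not None else float("nan"),
    }


def relative_residuals(ps: ParameterSet, keys, weights=None) -> np.ndarray:
    got = measure(ps)
    weights = weights or {}
    return np.array([
        weights.get(k, 1.0) * (got[k] / TARGETS[k] - 1.0) for k in keys
    ])


def stage_life_table(ps: ParameterSet) -> None:
    def gap(level):
        ps.life_table = gompertz_life_table(level)
        got = measure(ps)
        return got["life_years_usual"] - TARGETS["life_years_usual"]

    level = brentq(gap, 0.005, 0.05, xtol=1e-7)
    ps.life_table = gompertz_life_table(level)
    print(f"  life-table level at age 69: q = {level:.5f}")


TRANSITION_KNOBS = (
    "nobe_to_ndbe", "ndbe_to_lgd", "ndbe_to_early_eac", "lgd_to_ndbe",
    "lgd_to_hgd", "hgd_to_lgd", "hgd_to_early_eac", "early_to_late_eac",
    "early_eac_mortality", "late_eac_mortality", "treat_success_ndbe")
# Bounds keep the cancer-stage dynamics clinically plausible (stage-4
# median survival under two years; early-stage progression not instant).
TRANSITION_BOUNDS = (
    np.array([1e-4, 0.005, 0.001, 0.02, 0.02, 0.00, 0.02, 0.20, 0.00, 0.40, 0.30]),
    np.array([0.02, 0.15, 0.08, 0.30, 0.40, 0.20, 0.50, 0.85, 0.50, 0.90, 0.98]))
TRANSITION_TARGETS = (
    "incident_lgd_usual", "incident_hgd_usual", "incident_early_eac_usual",
    "eac_deaths_usual", "eac_death_difference", "delta_life_years")
TRANSITION_WEIGHTS = {"eac_deaths_usual": 2.0, "eac_death_difference": 2.0,
                      "delta_life_years": 2.0, "incident_early_eac_usual": 1.5}


def stage_transitions(ps: ParameterSet) -> None:
    def residual(x):
        for name, v in zip(TRANSITION_KNOBS, x):
            ps.set_value(name, float(v))
        return relative_residuals(ps, TRANSITION_TARGETS, TRANSITION_WEIGHTS)

    x0 = np.array([ps.get_value(k) for k in TRANSITION_KNOBS])
    fit = least_squares(residual, x0, bounds=TRANSITION_BOUNDS,
                        xtol=1e-10, ftol=1e-10)
    x = np.where(np.abs(fit.x) < 1e-10, 0.0, fit.x)  # snap bound-hugging zeros
    residual(x)
    for name, v in zip(TRANSITION_KNOBS, x):
        print(f"  {name} = {v:.5f}")


def stage_utilities(ps: ParameterSet) -> None:
    def residual(x):
        u0, gap = x
        ps.utilities.state_utility[H.NO_BE] = u0
        ps.utilities.state_utility[H.NDBE] = u0 - gap
        ps.utilities.state_utility[H.LGD] = u0 - gap - 0.01
        ps.utilities.state_utility[H.HGD] = u0 - gap - 0.03
        return relative_residuals(ps, ("qalys_usual", "delta_qalys"))

    fit = least_squares(residual, np.array([0.765, 0.035]),
                        bounds=(np.array([0.5, 0.0]), np.array([0.95, 0.3])),
                        xtol=1e-12, ftol=1e-12)
    residual(fit.x)
    print(f"  utility NoBE = {fit.x[0]:.4f}, NDBE = {fit.x[0] - fit.x[1]:.4f}")


def stage_costs(ps: ParameterSet) -> None:
    def residual(x):
        ps.costs.ppi_annual, ps.costs.endotherapy_rfa = x
        return relative_residuals(ps, ("treatment_cost_usual", "delta_cost"))

    fit = least_squares(residual, np.array([17.0, 2200.0]),
                        bounds=(np.array([1.0, 100.0]),
                                np.array([200.0, 9000.0])),
                        xtol=1e-12, ftol=1e-12)
    residual(fit.x)
    print(f"  ppi_annual = {fit.x[0]:.2f}, endotherapy_rfa = {fit.x[1]:.2f}")


def refresh_meta_values(ps: ParameterSet) -> None:
    for name in list(ps.meta):
        if name in ps.flat_names():
            ps.meta[name] = ParamMeta(
                name=name, value=ps.get_value(name), low=ps.meta[name].low,
                high=ps.meta[name].high, distribution=ps.meta[name].distribution,
                provenance=ps.meta[name].provenance)


def main() -> None:
    ps = initial_parameter_set()
    for sweep in (1, 2):
        print(f"pass {sweep}: life table")
        stage_life_table(ps)
        print(f"pass {sweep}: transitions")
        stage_transitions(ps)
    print("utilities")
    stage_utilities(ps)
    print("costs")
    stage_costs(ps)

    refresh_meta_values(ps)
    ps.validate()
    got = measure(ps)
    print("\ncalibration summary (value | target | rel. error):")
    for key, target in TARGETS.items():
        val = got[key]
        print(f"  {key:28s} {val:12.4f} | {target:12.4f} | "
              f"{val / target - 1.0:+8.2%}")
    print(f"  {'icer':28s} {got['icer']:12.1f} | {5500.0:12.1f} | "
          f"{got['icer'] / 5500.0 - 1.0:+8.2%}")

    write_parameters(ps, DATA_DIR)
    print(f"\nwrote calibrated base case to {DATA_DIR}")


if __name__ == "__main__":
    main()
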