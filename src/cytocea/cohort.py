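"""Cohort entry: from trial screening counts to starting-state allocations.

One round of Cytosponge-TFF3 screening splits each arm's cohort into a
*treatment* chain (true positives confirmed at endoscopy, who receive
treatment at entry) and a *natural-history* chain (everyone else,
including false negatives).  Both arms face the same underlying disease:
per-state totals across the two chains are identical between arms, and
the arms differ only in how many prevalent cases are detected.  False
positives incur the screening and endoscopy cost but enter the
natural-history chain's NoBE state with no treatment cost.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import ParameterSet, CostSet, ParameterError
from .states import DISEASE_STATES, HealthState, N_STATES

ARMS = ("intervention", "usual")
CHAINS = ("treatment", "natural")


@dataclass
class ScreeningScenario:
    """Counts describing one realisation of the screening funnel."""

    n_invited: float
    n_swallowed: float
    n_endoscopy_intervention: float
    n_endoscopy_usual: float
    uptake: float
    n_repeat_tests: float = 0.0
    n_repeat_endoscopies: float = 0.0
    include_repeat: bool = False

    def validate(self) -> None:
        for name in ("n_invited", "n_swallowed", "n_endoscopy_intervention",
                     "n_endoscopy_usual", "n_repeat_tests", "n_repeat_endoscopies"):
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"scenario count {name} = {v}: must be >= 0")
        if self.n_swallowed > self.n_invited:
            raise ParameterError("n_swallowed cannot exceed n_invited")
        if self.n_endoscopy_intervention > self.n_swallowed + self.n_repeat_tests:
            raise ParameterError("endoscopies cannot exceed tests")

    @property
    def total_tests(self) -> float:
        return self.n_swallowed + (self.n_repeat_tests if self.include_repeat else 0.0)

    @property
    def total_endoscopies_intervention(self) -> float:
        return self.n_endoscopy_intervention + (
            self.n_repeat_endoscopies if self.include_repeat else 0.0)


@dataclass
class ArmAllocation:
    """Starting counts for one arm, split by chain (fractional persons)."""

    treatment: np.ndarray  # shape (N_STATES,)
    natural: np.ndarray

    def __post_init__(self):
        self.treatment = np.asarray(self.treatment, dtype=float)
        self.natural = np.asarray(self.natural, dtype=float)

    @property
    def per_state_total(self) -> np.ndarray:
        return self.treatment + self.natural

    @property
    def total(self) -> float:
        return float(self.per_state_total.sum())


@dataclass
class StartingAllocation:
    intervention: ArmAllocation
    usual: ArmAllocation

    def arm(self, name: str) -> ArmAllocation:
        if name not in ARMS:
            raise ValueError(f"unknown arm {name!r}")
        return getattr(self, name)

    def validate(self, cohort_size: float) -> None:
        for arm_name in ARMS:
            arm = self.arm(arm_name)
            if np.any(arm.treatment < -1e-9) or np.any(arm.natural < -1e-9):
                raise ParameterError(f"{arm_name}: negative starting count")
            for chain in (arm.treatment, arm.natural):
                for s in (HealthState.LATE_EAC, HealthState.DEAD):
                    if chain[s] != 0:
                        raise ParameterError(
                            f"{arm_name}: {s.label} must start at 0")
            if not np.isclose(arm.total, cohort_size, rtol=1e-9):
                raise ParameterError(
                    f"{arm_name}: allocation sums to {arm.total}, "
                    f"expected cohort_size {cohort_size}")
        if not np.allclose(self.intervention.per_state_total,
                           self.usual.per_state_total, rtol=1e-9, atol=1e-9):
            raise ParameterError(
                "per-state totals must be identical across arms")

    def to_frame(self):
        """Tidy table (arm, chain, state, count) mirroring the trial layout."""
        import pandas as pd

        rows = []
        for arm_name in ARMS:
            arm = self.arm(arm_name)
            for chain_name, vec in (("treatment", arm.treatment),
                                    ("natural", arm.natural)):
                for s in HealthState:
                    rows.append({"arm": arm_name, "chain": chain_name,
                                 "state": s.label, "count": float(vec[s])})
        return pd.DataFrame(rows)


@dataclass
class ScreeningCost:
    total_intervention: float
    total_usual: float
    per_person_intervention: float
    per_person_usual: float


# ----------------------------------------------------------------------


def base_scenario(params: ParameterSet) -> ScreeningScenario:
    t = params.trial
    sc = ScreeningScenario(
        n_invited=t.n_invited,
        n_swallowed=t.n_swallowed,
        n_endoscopy_intervention=t.n_endoscopy_intervention,
        n_endoscopy_usual=t.n_endoscopy_usual,
        uptake=t.uptake,
        n_repeat_tests=t.n_repeat_tests,
        n_repeat_endoscopies=t.n_repeat_endoscopies,
        include_repeat=False,
    )
    sc.validate()
    return sc


def screening_cost(scenario: ScreeningScenario, costs: CostSet) -> ScreeningCost:
    """Total and per-person screening costs for both arms.

    Intervention: administered Cytosponge tests plus confirmatory
    endoscopies (plus repeat-test volumes when the scenario includes
    them).  Usual care: symptom-driven endoscopies only.
    """
    scenario.validate()
    if scenario.n_invited == 0:
        raise ParameterError("scenario has zero invited patients")
    total_int = (scenario.total_tests * costs.cytosponge_test
                 + scenario.total_endoscopies_intervention * costs.endoscopy_biopsy)
    total_usual = scenario.n_endoscopy_usual * costs.endoscopy_biopsy
    return ScreeningCost(
        total_intervention=total_int,
        total_usual=total_usual,
        per_person_intervention=total_int / scenario.n_invited,
        per_person_usual=total_usual / scenario.n_invited,
    )


def allocate_from_trial(
    params: ParameterSet,
    detected: dict[str, dict[HealthState, float]] | None = None,
    prevalence: dict[HealthState, float] | None = None,
) -> StartingAllocation:
    """Build the per-arm starting allocation from detected counts.

    The treatment chain receives exactly the detected (true-positive,
    endoscopy-confirmed) counts per state; the natural-history chain
    receives the cohort remainder so that per-state totals equal
    prevalence x cohort_size in both arms.  False negatives are therefore
    implicit in the natural-history counts.
    """
    detected = detected if detected is not None else params.trial.detected
    prevalence = prevalence if prevalence is not None else params.prevalence
    n = params.settings.cohort_size
    arms = {}
    for arm_name in ARMS:
        det = detected.get(arm_name, {})
        tr = np.zeros(N_STATES)
        nat = np.zeros(N_STATES)
        for s in DISEASE_STATES:
            prevalent = prevalence.get(s, 0.0) * n
            d = det.get(s, 0.0)
            if d > prevalent + 1e-9:
                raise ParameterError(
                    f"{arm_name}: detected {s.label} count {d} exceeds "
                    f"prevalent {prevalent:.3f}")
            tr[s] = d
            nat[s] = prevalent - d
        nat[HealthState.NO_BE] = n - tr.sum() - nat.sum()
        arms[arm_name] = ArmAllocation(treatment=tr, natural=nat)
    alloc = StartingAllocation(intervention=arms["intervention"], usual=arms["usual"])
    alloc.validate(n)
    return alloc


def table1_allocation(params: ParameterSet) -> StartingAllocation:
    """The base-case starting allocation observed in the trial.

    Equivalent to :func:`allocate_from_trial` at the packaged detected
    counts and prevalence, which reproduce the published starting table
    (e.g. intervention treatment chain NDBE 123, LGD 1, HGD 3, early EAC
    4, summing to the 131 diagnoses reported).
    """
    return allocate_from_trial(params)


def scale_uptake(
    params: ParameterSet,
    scenario: ScreeningScenario,
    new_uptake: float,
) -> tuple[StartingAllocation, ScreeningScenario]:
    """Rescale the screening funnel to a different uptake fraction.

    Test and endoscopy volumes and detected (treatment-chain) counts scale
    proportionally with uptake; the usual-care arm and the underlying
    disease prevalence are unchanged, so per-state cross-arm totals remain
    conserved.
    """
    if not (0.0 < new_uptake <= 1.0):
        raise ParameterError(f"uptake {new_uptake}: must lie in (0, 1]")
    f = new_uptake / scenario.uptake
    new_scenario = replace(
        scenario,
        n_swallowed=scenario.n_swallowed * f,
        n_endoscopy_intervention=scenario.n_endoscopy_intervention * f,
        n_repeat_tests=scenario.n_repeat_tests * f,
        n_repeat_endoscopies=scenario.n_repeat_endoscopies * f,
        uptake=new_uptake,
    )
    detected = {
        "intervention": {s: v * f
                         for s, v in params.trial.detected["intervention"].items()},
        "usual": dict(params.trial.detected["usual"]),
    }
    allocation = allocate_from_trial(params, detected=detected)
    return allocation, new_scenario


def rescaled_allocation(
    params: ParameterSet,
    sensitivity_factor: float = 1.0,
    prevalence_factor: float = 1.0,
) -> StartingAllocation:
    """Allocation with detected counts rescaled for accuracy/prevalence shifts.

    Detected (true-positive) counts scale with both the test sensitivity
    and the underlying prevalence; the prevalence vector itself scales so
    that cross-arm conservation holds.  Used by the sensitivity analyses.
    """
    prevalence = {s: v * prevalence_factor for s, v in params.prevalence.items()}
    detected = {
        arm: {s: v * sensitivity_factor * prevalence_factor for s, v in det.items()}
        for arm, det in params.trial.detected.items()
    }
    return allocate_from_trial(params, detected=detected, prevalence=prevalence)


def readminister_scenario(
    params: ParameterSet, base: ScreeningScenario
) -> tuple[StartingAllocation, ScreeningScenario]:
    """Scenario in which inconclusive tests are re-administered.

    Adds the repeat test and endoscopy volumes to the screening cost and
    moves the additional detected patients (per-state deltas observed in
    the trial) into the treatment chain.
    """
    scenario = replace(base, include_repeat=True)
    detected = {
        "intervention": {
            s: params.trial.detected["intervention"].get(s, 0.0)
            + params.trial.repeat_detected_delta.get(s, 0.0)
            for s in DISEASE_STATES
        },
        "usual": dict(params.trial.detected["usual"]),
    }
    allocation = allocate_from_trial(params, detected=detected)
    return allocation, scenario
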