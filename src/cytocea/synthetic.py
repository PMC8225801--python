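"""Synthetic screening-trial generator.

Simulates the screening funnel the analysis assumes, person by person:
invitation -> uptake (Bernoulli) -> true disease state (multinomial at the
assumed prevalence) -> TFF3 result (sensitivity for diseased, 1 -
specificity otherwise) -> confirmatory endoscopy (perfect accuracy,
attended with a fixed probability) -> treatment entry.  The aggregate
output is a :class:`~cytocea.cohort.ScreeningScenario` plus per-state
detected counts in exactly the form the cohort-entry stage consumes, so
every pipeline stage is testable without external data.  A funnel
inversion (:func:`recover_prevalence`) supports parameter-recovery
experiments.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ScreeningScenario
from .params import ParameterError, TestAccuracy
from .states import DISEASE_STATES, HealthState

#: Default repeat-test behaviour: share of tests with an inadequate sample,
#: and the share of those offered a repeat who attend (trial volumes).
DEFAULT_INADEQUATE_FRACTION = 311.0 / 1654.0
DEFAULT_RETEST_ATTENDANCE = 202.0 / 311.0


@dataclass
class SyntheticTrial:
    seed: int
    n_invited: int
    uptake: float
    endoscopy_attendance: float
    accuracy: TestAccuracy
    prevalence: dict[HealthState, float]
    states: np.ndarray            # (n,) true per-person HealthState values
    attended: np.ndarray          # (n,) bool, swallowed the device
    tff3_positive: np.ndarray     # (n,) bool (False for non-attendees)
    endoscopy: np.ndarray         # (n,) bool, attended confirmatory endoscopy
    detected: dict[HealthState, float]
    scenario: ScreeningScenario

    @property
    def n_swallowed(self) -> int:
        return int(self.attended.sum())

    @property
    def n_detected(self) -> float:
        return float(sum(self.detected.values()))

    def detected_by_arm(self, usual_detected=None) -> dict:
        """Detected counts in the two-arm dict form cohort entry consumes."""
        return {"intervention": dict(self.detected),
                "usual": dict(usual_detected or {})}


def generate_trial(
    seed: int,
    n_invited: int,
    uptake: float,
    prevalence: dict[HealthState, float],
    accuracy: TestAccuracy,
    endoscopy_attendance: float,
    n_endoscopy_usual: float = 0.0,
    repeat_tests: bool = False,
    inadequate_fraction: float = DEFAULT_INADEQUATE_FRACTION,
    retest_attendance: float = DEFAULT_RETEST_ATTENDANCE,
) -> SyntheticTrial:
    """Generate one synthetic screening trial; deterministic for a seed.

    With ``repeat_tests``, a fraction of first tests is inadequate (the
    TFF3 read is forced negative); those patients may attend a repeat test
    which is read normally, adding repeat volumes and extra detections.
    """
    for name, v in (("uptake", uptake),
                    ("endoscopy_attendance", endoscopy_attendance),
                    ("inadequate_fraction", inadequate_fraction),
                    ("retest_attendance", retest_attendance)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} = {v}: must lie in [0, 1]")
    accuracy.validate()
    p_disease = np.array([prevalence.get(s, 0.0) for s in DISEASE_STATES])
    if np.any(p_disease < 0) or p_disease.sum() > 1.0:
        raise ParameterError("invalid prevalence vector")

    rng = np.random.default_rng(seed)
    n = int(n_invited)
    attended = rng.random(n) < uptake
    # true state: NoBE residual, then the four prevalent disease states
    probs = np.concatenate([[1.0 - p_disease.sum()], p_disease])
    choices = np.array([HealthState.NO_BE] + list(DISEASE_STATES), dtype=int)
    states = choices[rng.choice(len(choices), size=n, p=probs)]
    diseased = states != int(HealthState.NO_BE)

    p_pos = np.where(diseased, accuracy.sensitivity, 1.0 - accuracy.specificity)
    tff3 = (rng.random(n) < p_pos) & attended

    n_repeat_tests = 0
    n_repeat_endoscopies = 0.0
    if repeat_tests:
        inadequate = attended & (rng.random(n) < inadequate_fraction)
        tff3 = tff3 & ~inadequate
        retested = inadequate & (rng.random(n) < retest_attendance)
        n_repeat_tests = int(retested.sum())
        repeat_pos = retested & (rng.random(n) < p_pos)
        tff3 = tff3 | repeat_pos

    endoscopy = tff3 & (rng.random(n) < endoscopy_attendance)
    confirmed = endoscopy & diseased  # confirmatory endoscopy is gold-standard
    if repeat_tests:
        n_repeat_endoscopies = float((endoscopy & repeat_pos).sum())

    detected = {s: float(np.sum(states[confirmed] == int(s)))
                for s in DISEASE_STATES}
    first_endoscopies = float(endoscopy.sum()) - n_repeat_endoscopies
    scenario = ScreeningScenario(
        n_invited=float(n),
        n_swallowed=float(attended.sum()),
        n_endoscopy_intervention=first_endoscopies,
        n_endoscopy_usual=float(n_endoscopy_usual),
        uptake=uptake,
        n_repeat_tests=float(n_repeat_tests),
        n_repeat_endoscopies=n_repeat_endoscopies,
        include_repeat=repeat_tests,
    )
    scenario.validate()
    return SyntheticTrial(
        seed=seed, n_invited=n, uptake=uptake,
        endoscopy_attendance=endoscopy_attendance, accuracy=accuracy,
        prevalence=dict(prevalence), states=states, attended=attended,
        tff3_positive=tff3, endoscopy=endoscopy, detected=detected,
        scenario=scenario,
    )


def recover_prevalence(trial: SyntheticTrial,
                       accuracy: TestAccuracy | None = None) -> tuple[float, float]:
    """Estimate true disease prevalence by inverting the screening funnel.

    detected / (attendees x sensitivity x endoscopy attendance) is an
    unbiased estimator of the prevalence of screen-detectable disease;
    returns (estimate, binomial-variance-based standard error).
    """
    accuracy = accuracy or trial.accuracy
    n_att = trial.n_swallowed
    if n_att == 0:
        raise ParameterError("trial has no attendees")
    if accuracy.sensitivity == 0:
        raise ParameterError("cannot invert a zero-sensitivity funnel")
    denom = accuracy.sensitivity * trial.endoscopy_attendance
    if denom == 0:
        raise ParameterError("cannot invert a funnel with zero endoscopy attendance")
    p_det = trial.n_detected / n_att
    estimate = p_det / denom
    se = float(np.sqrt(max(p_det * (1.0 - p_det), 0.0) / n_att) / denom)
    return float(estimate), se


def write_trial(trial: SyntheticTrial, directory: str | Path) -> None:
    """Emit the scenario YAML + detected-counts CSV dialect cohort entry reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sc = trial.scenario
    with open(directory / "scenario.yaml", "w") as fh:
        yaml.safe_dump({
            "n_invited": sc.n_invited,
            "n_swallowed": sc.n_swallowed,
            "n_endoscopy_intervention": sc.n_endoscopy_intervention,
            "n_endoscopy_usual": sc.n_endoscopy_usual,
            "uptake": sc.uptake,
            "n_repeat_tests": sc.n_repeat_tests,
            "n_repeat_endoscopies": sc.n_repeat_endoscopies,
        }, fh, sort_keys=False)
    pd.DataFrame(
        [{"state": s.label, "count": c} for s, c in trial.detected.items()]
    ).to_csv(directory / "detected.csv", index=False)
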