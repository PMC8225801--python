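"""Typed parameter registry for the screening cost-utility model.

Every number the model consumes — transition probabilities, unit costs,
utilities, test accuracy, trial participation counts, analysis settings —
lives in a :class:`ParameterSet` loaded from structured files (one YAML
settings file plus CSV tables for transitions, costs, utilities and the
life table).  Each parameter carries a provenance tag
(``trial-publication`` | ``literature`` | ``assumption`` |
``derived-calibration``) and optional one-way bounds / distribution
metadata used by the sensitivity analyses.

The packaged base case (:func:`base_case`) reproduces the reference
analysis: a cohort of 6834 patients with gastro-esophageal reflux disease,
median age 69, offered one round of Cytosponge-TFF3 screening (sensitivity
79.9%, specificity 92.4%) with confirmatory endoscopy, evaluated over a
lifetime horizon at a 3.5% annual discount rate.
"""
from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .states import ALIVE_STATES, DISEASE_STATES, HealthState, state_from_label

PROVENANCE_TAGS = frozenset(
    {"trial-publication", "literature", "assumption", "derived-calibration"}
)

#: CSV column layout shared by all parameter tables.
CSV_COLUMNS = ["parameter", "value", "low", "high", "distribution", "provenance"]


class ParameterError(ValueError):
    """A parameter failed validation; the message names the parameter."""


def _check(condition: bool, name: str, value, why: str) -> None:
    if not condition:
        raise ParameterError(f"parameter {name!r} = {value!r}: {why}")


@dataclass(frozen=True)
class ParamMeta:
    """Provenance and sensitivity-analysis metadata for one parameter."""

    name: str
    value: float
    low: float | None = None
    high: float | None = None
    distribution: str | None = None  # beta | gamma | fixed
    provenance: str = "assumption"

    def __post_init__(self):
        _check(self.provenance in PROVENANCE_TAGS, self.name, self.provenance,
               f"provenance must be one of {sorted(PROVENANCE_TAGS)}")


@dataclass
class ModelSettings:
    start_age: int = 69
    cohort_size: float = 6834.0
    discount_rate: float = 0.035
    cycle_length: float = 1.0
    age_cap: int = 100
    wtp_threshold: float = 20000.0

    def validate(self) -> None:
        _check(self.discount_rate >= 0, "discount_rate", self.discount_rate, "must be >= 0")
        _check(self.cycle_length == 1.0, "cycle_length", self.cycle_length,
               "the model is defined on yearly cycles")
        _check(self.start_age < self.age_cap, "start_age", self.start_age,
               f"must be below age_cap ({self.age_cap})")
        _check(self.cohort_size > 0, "cohort_size", self.cohort_size, "must be > 0")


@dataclass
class TestAccuracy:
    __test__ = False  # dataclass, not a pytest collection target

    sensitivity: float = 0.799
    specificity: float = 0.924
    endoscopy_sensitivity: float = 1.0
    endoscopy_specificity: float = 1.0

    def validate(self) -> None:
        for name in ("sensitivity", "specificity",
                     "endoscopy_sensitivity", "endoscopy_specificity"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, v, "must lie in [0, 1]")


@dataclass
class CostSet:
    """Unit costs in GBP.

    ``cytosponge_test`` covers the device, centralised laboratory
    processing, the TFF3 antibody, manual pathology reporting and the time
    of the nurse administering the test.  ``chemotherapy`` doubles as the
    annual management cost of the late (stage-4-like) EAC state;
    ``palliative_care`` is charged once at death from late EAC.
    """

    cytosponge_test: float
    endoscopy_biopsy: float
    ppi_annual: float
    endotherapy_emr: float
    endotherapy_rfa: float
    esophagectomy: float
    chemotherapy: float
    palliative_care: float

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            _check(v >= 0, f.name, v, "costs must be >= 0")


@dataclass
class DisutilityEvent:
    """A one-off utility decrement applied for a fixed duration.

    QALY loss per affected person = decrement x duration_years.
    ``probability`` is the chance the event accompanies a course of
    treatment (1 for the procedure itself, <1 for complications).
    """

    label: str
    decrement: float
    duration_years: float
    probability: float = 1.0

    @property
    def qaly_loss(self) -> float:
        return self.probability * self.decrement * self.duration_years

    def validate(self) -> None:
        _check(self.decrement >= 0, f"disutility_{self.label}", self.decrement, "must be >= 0")
        _check(self.duration_years > 0, f"duration_{self.label}", self.duration_years,
               "must be > 0")
        _check(0 <= self.probability <= 1, f"prob_{self.label}", self.probability,
               "must lie in [0, 1]")


@dataclass
class UtilitySet:
    state_utility: dict[HealthState, float]
    events: dict[str, DisutilityEvent]

    def validate(self) -> None:
        for s in ALIVE_STATES:
            _check(s in self.state_utility, f"utility_{s.label}", None, "missing")
            u = self.state_utility[s]
            _check(0.0 <= u <= 1.0, f"utility_{s.label}", u, "must lie in [0, 1]")
        _check(HealthState.DEAD not in self.state_utility, "utility_Dead", None,
               "utilities are defined only for alive states")
        for ev in self.events.values():
            ev.validate()


@dataclass
class TransitionSet:
    """Annual disease-transition probabilities (before all-cause mortality).

    ``natural_history`` maps (from_state, to_state) to the annual
    probability of the move conditional on surviving the year;
    per-state outgoing probabilities must sum to <= 1 (residual = stay).
    ``eac_mortality`` holds annual cancer-specific death probabilities for
    the EAC states; ``treatment_success`` the probability that a treated
    patient returns to NoBE.
    """

    natural_history: dict[tuple[HealthState, HealthState], float]
    treatment_success: dict[HealthState, float]
    esophagectomy_90day_mortality: float
    eac_mortality: dict[HealthState, float]

    def validate(self) -> None:
        for (f, t), p in self.natural_history.items():
            name = f"{f.label}->{t.label}"
            _check(0.0 <= p <= 1.0, name, p, "must lie in [0, 1]")
            _check(f.is_alive and t.is_alive, name, p,
                   "disease transitions are defined between alive states")
        for s in ALIVE_STATES:
            out = sum(p for (f, _), p in self.natural_history.items() if f is s)
            _check(out <= 1.0 + 1e-12, f"outgoing({s.label})", out,
                   "per-state disease probabilities must sum to <= 1")
        for s, p in self.treatment_success.items():
            _check(0.0 <= p <= 1.0, f"treat_success_{s.label}", p, "must lie in [0, 1]")
        _check(0.0 <= self.esophagectomy_90day_mortality <= 1.0,
               "esophagectomy_90day_mortality", self.esophagectomy_90day_mortality,
               "must lie in [0, 1]")
        for s, p in self.eac_mortality.items():
            _check(0.0 <= p <= 1.0, f"eac_mortality_{s.label}", p, "must lie in [0, 1]")


@dataclass
class LifeTable:
    """Annual all-cause death probability q(x) by integer age."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)
        self._lookup = dict(zip(self.ages.tolist(), self.qx.tolist()))

    def q(self, age: int) -> float:
        try:
            return self._lookup[int(age)]
        except KeyError:
            raise ParameterError(f"life table has no entry for age {age}") from None

    def validate(self, start_age: int | None = None, age_cap: int | None = None) -> None:
        _check(np.all((self.qx >= 0) & (self.qx <= 1)), "life_table.qx",
               (self.qx.min(), self.qx.max()), "probabilities must lie in [0, 1]")
        if start_age is not None and age_cap is not None:
            need = set(range(start_age, age_cap))
            missing = need - set(self.ages.tolist())
            _check(not missing, "life_table", sorted(missing)[:5],
                   "missing ages in [start_age, age_cap)")


@dataclass
class TrialCounts:
    """Screening-funnel counts and per-state detected counts from the trial."""

    n_invited: float = 6834.0
    n_swallowed: float = 1654.0
    n_endoscopy_intervention: float = 198.0
    n_endoscopy_usual: float = 16.0
    n_repeat_tests: float = 202.0
    n_repeat_endoscopies: float = 23.0
    uptake: float = 0.242
    endoscopy_attendance: float = 198.0 / 221.0
    detected: dict[str, dict[HealthState, float]] = field(default_factory=dict)
    repeat_detected_delta: dict[HealthState, float] = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("n_invited", "n_swallowed", "n_endoscopy_intervention",
                     "n_endoscopy_usual", "n_repeat_tests", "n_repeat_endoscopies"):
            v = getattr(self, name)
            _check(v >= 0, name, v, "counts must be >= 0")
        _check(self.n_swallowed <= self.n_invited, "n_swallowed", self.n_swallowed,
               "cannot exceed n_invited")
        _check(self.n_endoscopy_intervention <= self.n_swallowed,
               "n_endoscopy_intervention", self.n_endoscopy_intervention,
               "cannot exceed number of tests")
        _check(0.0 < self.uptake <= 1.0, "uptake", self.uptake, "must lie in (0, 1]")
        _check(0.0 <= self.endoscopy_attendance <= 1.0, "endoscopy_attendance",
               self.endoscopy_attendance, "must lie in [0, 1]")
        for arm, counts in self.detected.items():
            for s, v in counts.items():
                _check(v >= 0, f"detected[{arm}][{s.label}]", v, "must be >= 0")


@dataclass
class BudgetSettings:
    eligible_patients: float = 262941.0
    horizon_years: float = 29.0

    def validate(self) -> None:
        _check(self.eligible_patients > 0, "eligible_patients", self.eligible_patients,
               "must be > 0")
        _check(self.horizon_years > 0, "horizon_years", self.horizon_years, "must be > 0")


@dataclass
class ParameterSet:
    settings: ModelSettings
    accuracy: TestAccuracy
    costs: CostSet
    utilities: UtilitySet
    transitions: TransitionSet
    life_table: LifeTable
    prevalence: dict[HealthState, float]
    trial: TrialCounts
    budget: BudgetSettings
    #: States whose occupants accrue the annual acid-suppressant drug cost.
    ppi_states: tuple[HealthState, ...] = tuple(
        s for s in ALIVE_STATES if s is not HealthState.LATE_EAC
    )
    psa_n_draws: int = 1000
    meta: dict[str, ParamMeta] = field(default_factory=dict)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        self.settings.validate()
        self.accuracy.validate()
        self.costs.validate()
        self.utilities.validate()
        self.transitions.validate()
        self.life_table.validate(self.settings.start_age, self.settings.age_cap)
        self.trial.validate()
        self.budget.validate()
        total = 0.0
        for s, p in self.prevalence.items():
            _check(s in DISEASE_STATES, f"prevalence[{s.label}]", p,
                   "prevalence is defined for prevalent disease states only")
            _check(p >= 0, f"prevalence[{s.label}]", p, "must be >= 0")
            total += p
        _check(total <= 1.0, "prevalence", total,
               "entries must sum to <= 1 (residual = NoBE)")

    @property
    def prevalence_be(self) -> float:
        """Total prevalence of Barrett esophagus or cancer in the cohort."""
        return float(sum(self.prevalence.values()))

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- flat registry --------------------------------------------------
    def flat_names(self) -> list[str]:
        return list(_flat_registry())

    def get_value(self, name: str) -> float:
        getter, _ = _flat_registry()[name]
        return getter(self)

    def set_value(self, name: str, value: float) -> None:
        _, setter = _flat_registry()[name]
        setter(self, value)

    def with_value(self, name: str, value: float) -> "ParameterSet":
        ps = self.copy()
        ps.set_value(name, value)
        return ps


# ----------------------------------------------------------------------
# Flat parameter registry: one name per scalar model input, used by the
# sensitivity analyses and by the registry-completeness test.

TRANSITION_KEYS: dict[str, tuple[HealthState, HealthState]] = {
    "nobe_to_ndbe": (HealthState.NO_BE, HealthState.NDBE),
    "ndbe_to_lgd": (HealthState.NDBE, HealthState.LGD),
    "ndbe_to_early_eac": (HealthState.NDBE, HealthState.EARLY_EAC),
    "lgd_to_ndbe": (HealthState.LGD, HealthState.NDBE),
    "lgd_to_hgd": (HealthState.LGD, HealthState.HGD),
    "hgd_to_lgd": (HealthState.HGD, HealthState.LGD),
    "hgd_to_early_eac": (HealthState.HGD, HealthState.EARLY_EAC),
    "early_to_late_eac": (HealthState.EARLY_EAC, HealthState.LATE_EAC),
}
SUCCESS_KEYS: dict[str, HealthState] = {
    "treat_success_ndbe": HealthState.NDBE,
    "treat_success_lgd": HealthState.LGD,
    "treat_success_hgd": HealthState.HGD,
    "treat_success_early_eac": HealthState.EARLY_EAC,
}
EAC_MORT_KEYS: dict[str, HealthState] = {
    "early_eac_mortality": HealthState.EARLY_EAC,
    "late_eac_mortality": HealthState.LATE_EAC,
}
EVENT_LABELS = ("stricture", "perforation", "emr_rfa", "chemotherapy", "esophagectomy")
#: Complication events carry an occurrence probability of their own.
COMPLICATION_EVENTS = ("stricture", "perforation")

_REGISTRY: dict | None = None


def _flat_registry() -> dict:
    global _REGISTRY
    if _REGISTRY is not None:
        return _REGISTRY
    reg: dict[str, tuple] = {}

    def add(name, getter, setter):
        reg[name] = (getter, setter)

    for f in dataclasses.fields(CostSet):
        add(f.name,
            lambda ps, n=f.name: getattr(ps.costs, n),
            lambda ps, v, n=f.name: setattr(ps.costs, n, float(v)))
    for s in ALIVE_STATES:
        add(f"utility_{s.label.lower()}",
            lambda ps, s=s: ps.utilities.state_utility[s],
            lambda ps, v, s=s: ps.utilities.state_utility.__setitem__(s, float(v)))
    for label in EVENT_LABELS:
        add(f"disutility_{label}",
            lambda ps, l=label: ps.utilities.events[l].decrement,
            lambda ps, v, l=label: setattr(ps.utilities.events[l], "decrement", float(v)))
        add(f"duration_{label}",
            lambda ps, l=label: ps.utilities.events[l].duration_years,
            lambda ps, v, l=label: setattr(ps.utilities.events[l], "duration_years", float(v)))
    for label in COMPLICATION_EVENTS:
        add(f"prob_{label}",
            lambda ps, l=label: ps.utilities.events[l].probability,
            lambda ps, v, l=label: setattr(ps.utilities.events[l], "probability", float(v)))
    for name, key in TRANSITION_KEYS.items():
        add(name,
            lambda ps, k=key: ps.transitions.natural_history[k],
            lambda ps, v, k=key: ps.transitions.natural_history.__setitem__(k, float(v)))
    for name, s in SUCCESS_KEYS.items():
        add(name,
            lambda ps, s=s: ps.transitions.treatment_success[s],
            lambda ps, v, s=s: ps.transitions.treatment_success.__setitem__(s, float(v)))
    for name, s in EAC_MORT_KEYS.items():
        add(name,
            lambda ps, s=s: ps.transitions.eac_mortality[s],
            lambda ps, v, s=s: ps.transitions.eac_mortality.__setitem__(s, float(v)))
    add("esophagectomy_90day_mortality",
        lambda ps: ps.transitions.esophagectomy_90day_mortality,
        lambda ps, v: setattr(ps.transitions, "esophagectomy_90day_mortality", float(v)))
    add("sensitivity",
        lambda ps: ps.accuracy.sensitivity,
        lambda ps, v: setattr(ps.accuracy, "sensitivity", float(v)))
    add("specificity",
        lambda ps: ps.accuracy.specificity,
        lambda ps, v: setattr(ps.accuracy, "specificity", float(v)))
    add("uptake",
        lambda ps: ps.trial.uptake,
        lambda ps, v: setattr(ps.trial, "uptake", float(v)))
    add("endoscopy_attendance",
        lambda ps: ps.trial.endoscopy_attendance,
        lambda ps, v: setattr(ps.trial, "endoscopy_attendance", float(v)))
    add("start_age",
        lambda ps: float(ps.settings.start_age),
        lambda ps, v: setattr(ps.settings, "start_age", int(round(v))))
    add("discount_rate",
        lambda ps: ps.settings.discount_rate,
        lambda ps, v: setattr(ps.settings, "discount_rate", float(v)))
    add("wtp_threshold",
        lambda ps: ps.settings.wtp_threshold,
        lambda ps, v: setattr(ps.settings, "wtp_threshold", float(v)))

    def _get_prev(ps):
        return ps.prevalence_be

    def _set_prev(ps, v):
        # Rescale the disease mix proportionally to a new total prevalence.
        old = ps.prevalence_be
        if old <= 0:
            raise ParameterError("cannot rescale a zero prevalence vector")
        f = float(v) / old
        for s in list(ps.prevalence):
            ps.prevalence[s] *= f

    add("prevalence_be", _get_prev, _set_prev)
    _REGISTRY = reg
    return reg


# ----------------------------------------------------------------------
# File I/O

_TABLE_FILES = ("transitions.csv", "costs.csv", "utilities.csv")


def _read_table(path: Path) -> dict[str, ParamMeta]:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"{path.name}: missing columns {sorted(missing)}")
    out: dict[str, ParamMeta] = {}
    for row in df.itertuples(index=False):
        low = None if pd.isna(row.low) else float(row.low)
        high = None if pd.isna(row.high) else float(row.high)
        dist = None if pd.isna(row.distribution) else str(row.distribution)
        out[str(row.parameter)] = ParamMeta(
            name=str(row.parameter), value=float(row.value), low=low, high=high,
            distribution=dist, provenance=str(row.provenance))
    return out


def _known_table_names() -> dict[str, set[str]]:
    util = ({f"utility_{s.label.lower()}" for s in ALIVE_STATES}
            | {f"disutility_{l}" for l in EVENT_LABELS}
            | {f"duration_{l}" for l in EVENT_LABELS}
            | {f"prob_{l}" for l in COMPLICATION_EVENTS})
    return {
        "transitions.csv": (set(TRANSITION_KEYS) | set(SUCCESS_KEYS)
                            | set(EAC_MORT_KEYS) | {"esophagectomy_90day_mortality"}),
        "costs.csv": {f.name for f in dataclasses.fields(CostSet)},
        "utilities.csv": util,
    }


def load_parameters(path: str | Path, allow_defaults: bool = False) -> ParameterSet:
    """Load and validate a :class:`ParameterSet` from a config directory.

    ``path`` is a directory holding ``settings.yaml`` plus the CSV tables
    (``transitions.csv``, ``costs.csv``, ``utilities.csv``,
    ``life_table.csv``).  With ``allow_defaults`` set, files or fields
    missing from ``path`` fall back to the packaged base case; otherwise
    every file must be present.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"config path does not exist: {path}")
    base = _basecase_dir()

    def locate(fname: str) -> Path:
        p = path / fname
        if p.exists():
            return p
        if allow_defaults:
            return base / fname
        raise ParameterError(f"missing required file {fname} in {path}")

    with open(locate("settings.yaml")) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError("settings.yaml must parse to a mapping")

    tables: dict[str, ParamMeta] = {}
    known = _known_table_names()
    for fname in _TABLE_FILES:
        tab = _read_table(locate(fname))
        unknown = set(tab) - known[fname]
        if unknown:
            raise ParameterError(f"{fname}: unknown parameter keys {sorted(unknown)}")
        missing = known[fname] - set(tab)
        if missing and not allow_defaults:
            raise ParameterError(f"{fname}: missing parameters {sorted(missing)}")
        if missing:
            defaults = _read_table(base / fname)
            for name in missing:
                tab[name] = defaults[name]
        tables.update(tab)

    lt = pd.read_csv(locate("life_table.csv"))
    life_table = LifeTable(lt["age"].to_numpy(), lt["qx"].to_numpy())

    def block(name, default=None):
        if name in raw:
            return raw[name]
        if allow_defaults and default is not None:
            return default
        if default is None and allow_defaults:
            return {}
        raise ParameterError(f"settings.yaml: missing block {name!r}")

    settings = ModelSettings(**block("settings"))
    accuracy = TestAccuracy(**block("accuracy"))
    trial_raw = dict(block("trial"))
    detected = {
        arm: {state_from_label(k): float(v) for k, v in counts.items()}
        for arm, counts in trial_raw.pop("detected", {}).items()
    }
    repeat_delta = {state_from_label(k): float(v)
                    for k, v in trial_raw.pop("repeat_detected_delta", {}).items()}
    trial = TrialCounts(detected=detected, repeat_detected_delta=repeat_delta, **trial_raw)
    budget = BudgetSettings(**block("budget", {}))
    prevalence = {state_from_label(k): float(v)
                  for k, v in block("prevalence").items()}
    ppi_states = tuple(state_from_label(k) for k in block(
        "ppi_states", [s.label for s in ALIVE_STATES if s is not HealthState.LATE_EAC]))
    psa_n_draws = int(raw.get("psa", {}).get("n_draws", 1000))

    costs = CostSet(**{f.name: tables[f.name].value
                       for f in dataclasses.fields(CostSet)})
    utilities = UtilitySet(
        state_utility={s: tables[f"utility_{s.label.lower()}"].value for s in ALIVE_STATES},
        events={l: DisutilityEvent(
            label=l,
            decrement=tables[f"disutility_{l}"].value,
            duration_years=tables[f"duration_{l}"].value,
            probability=(tables[f"prob_{l}"].value if l in COMPLICATION_EVENTS else 1.0),
        ) for l in EVENT_LABELS},
    )
    transitions = TransitionSet(
        natural_history={key: tables[name].value for name, key in TRANSITION_KEYS.items()},
        treatment_success={s: tables[name].value for name, s in SUCCESS_KEYS.items()},
        esophagectomy_90day_mortality=tables["esophagectomy_90day_mortality"].value,
        eac_mortality={s: tables[name].value for name, s in EAC_MORT_KEYS.items()},
    )

    meta = dict(tables)
    for name, m in (raw.get("meta") or {}).items():
        reg = _flat_registry()
        if name not in reg:
            raise ParameterError(f"settings.yaml meta: unknown parameter key {name!r}")
        ps_stub = None  # value resolved below once the set is assembled
        meta[name] = ParamMeta(name=name, value=float(m.get("value", np.nan)),
                               low=m.get("low"), high=m.get("high"),
                               distribution=m.get("distribution"),
                               provenance=m.get("provenance", "assumption"))

    ps = ParameterSet(settings=settings, accuracy=accuracy, costs=costs,
                      utilities=utilities, transitions=transitions,
                      life_table=life_table, prevalence=prevalence, trial=trial,
                      budget=budget, ppi_states=ppi_states,
                      psa_n_draws=psa_n_draws, meta=meta)
    # Fill meta values for YAML-sourced scalars from the assembled set.
    for name, m in list(meta.items()):
        if np.isnan(m.value) if isinstance(m.value, float) else False:
            meta[name] = dataclasses.replace(m, value=ps.get_value(name))
    ps.validate()
    return ps


def write_parameters(ps: ParameterSet, directory: str | Path) -> None:
    """Write a :class:`ParameterSet` back to the structured-file layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    known = _known_table_names()
    for fname in _TABLE_FILES:
        rows = []
        for name in sorted(known[fname]):
            m = ps.meta.get(name)
            value = ps.get_value(name) if name in _flat_registry() else (
                m.value if m else None)
            rows.append({
                "parameter": name,
                "value": value,
                "low": m.low if m else None,
                "high": m.high if m else None,
                "distribution": m.distribution if m else None,
                "provenance": m.provenance if m else "assumption",
            })
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(directory / fname, index=False)
    pd.DataFrame({"age": ps.life_table.ages, "qx": ps.life_table.qx}).to_csv(
        directory / "life_table.csv", index=False)

    trial = ps.trial
    raw = {
        "settings": dataclasses.asdict(ps.settings),
        "accuracy": dataclasses.asdict(ps.accuracy),
        "trial": {
            "n_invited": trial.n_invited,
            "n_swallowed": trial.n_swallowed,
            "n_endoscopy_intervention": trial.n_endoscopy_intervention,
            "n_endoscopy_usual": trial.n_endoscopy_usual,
            "n_repeat_tests": trial.n_repeat_tests,
            "n_repeat_endoscopies": trial.n_repeat_endoscopies,
            "uptake": trial.uptake,
            "endoscopy_attendance": trial.endoscopy_attendance,
            "detected": {arm: {s.label: v for s, v in counts.items()}
                         for arm, counts in trial.detected.items()},
            "repeat_detected_delta": {s.label: v
                                      for s, v in trial.repeat_detected_delta.items()},
        },
        "budget": dataclasses.asdict(ps.budget),
        "prevalence": {s.label: v for s, v in ps.prevalence.items()},
        "ppi_states": [s.label for s in ps.ppi_states],
        "psa": {"n_draws": ps.psa_n_draws},
        "meta": {
            name: {k: v for k, v in {
                "low": m.low, "high": m.high,
                "distribution": m.distribution, "provenance": m.provenance,
            }.items() if v is not None}
            for name, m in ps.meta.items()
            if name not in set().union(*known.values())
        },
    }
    with open(directory / "settings.yaml", "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def _basecase_dir() -> Path:
    return Path(resources.files("cytocea") / "data" / "basecase")


def base_case() -> ParameterSet:
    """The packaged base-case parameter set (pure: identical on every call)."""
    return load_parameters(_basecase_dir())
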