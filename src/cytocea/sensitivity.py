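"""Probabilistic and deterministic sensitivity analysis.

PSA: Monte-Carlo over independent per-parameter distributions
(moment-matched beta for probabilities and utilities, gamma for costs),
re-running the whole pipeline per draw; summarised as the CE plane, a
cost-effectiveness acceptability curve (CEAC, from the sign of net
monetary benefit so it is well defined in every quadrant) and a
percentile interval for the ICER.

DSA: one-way variation of every parameter between its low/high bounds
(default mean +/- 20% clipped to the parameter's support), ranked by the
width of the induced ICER range (tornado ordering).  Structural
parameters — uptake, prevalence, test sensitivity, starting age —
re-trigger the cohort-entry rebuild.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cea as _cea
from . import cohort as _cohort
from .params import ParameterError, ParameterSet
from .states import HealthState

#: Parameters that change the starting allocation / screening funnel.
STRUCTURAL_PARAMS = ("uptake", "prevalence_be", "sensitivity", "start_age")
#: Parameters excluded from the one-way DSA (analysis settings, not inputs).
DSA_EXCLUDED = ("wtp_threshold",)

DEFAULT_CEAC_GRID = np.arange(0.0, 50001.0, 1000.0)


@dataclass
class PSAConfig:
    n_draws: int = 1000
    seed: int = 0
    ceac_grid: np.ndarray = field(default_factory=lambda: DEFAULT_CEAC_GRID.copy())

    def validate(self):
        if self.n_draws < 1:
            raise ParameterError(f"n_draws {self.n_draws}: must be >= 1")


@dataclass
class PSAResult:
    draws: pd.DataFrame            # per-draw delta_cost, delta_qalys, per-arm values
    icer_point: float              # ratio of mean increments
    mean_delta_cost: float
    sd_delta_cost: float
    mean_delta_qalys: float
    sd_delta_qalys: float
    ceac_thresholds: np.ndarray
    ceac_probability: np.ndarray
    seed: int
    n_draws: int

    def prob_cost_effective(self, threshold: float) -> float:
        """Share of draws with positive net monetary benefit at a threshold."""
        nmb = (self.draws["delta_qalys"].to_numpy() * threshold
               - self.draws["delta_cost"].to_numpy())
        return float(np.mean(nmb > 0))


@dataclass
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    icer_low: float                # ICER with the parameter at its low bound
    icer_high: float
    range_width: float


# ----------------------------------------------------------------------
# Distribution machinery


def _parse_distribution(spec: str | None) -> tuple[str | None, float | None]:
    """``"beta"`` or ``"beta:0.02"`` (absolute SD override) -> (family, sd)."""
    if spec is None or spec == "fixed":
        return None, None
    if ":" in spec:
        fam, sd = spec.split(":", 1)
        return fam, float(sd)
    return spec, None


def _sample_one(rng: np.random.Generator, family: str, mean: float,
                sd: float | None, name: str) -> float:
    """Moment-matched draw; default SD is 20% of the mean."""
    if mean == 0.0:
        return 0.0
    if sd is None:
        sd = 0.2 * mean
    if family == "gamma":
        shape = (mean / sd) ** 2
        scale = sd ** 2 / mean
        return float(rng.gamma(shape, scale))
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ParameterError(
                f"parameter {name!r}: beta distribution needs mean in (0,1)")
        # keep the SD inside the beta support
        sd = min(sd, 0.9 * np.sqrt(mean * (1.0 - mean)))
        nu = mean * (1.0 - mean) / sd ** 2 - 1.0
        return float(rng.beta(mean * nu, (1.0 - mean) * nu))
    raise ParameterError(f"parameter {name!r}: unknown distribution {family!r}")


def sample_parameter_set(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA draw: independently resample every flagged parameter."""
    draw = params.copy()
    flat = set(params.flat_names())
    for name, meta in params.meta.items():
        if name not in flat:
            continue
        family, sd = _parse_distribution(meta.distribution)
        if family is None:
            continue
        value = _sample_one(rng, family, params.get_value(name), sd, name)
        draw.set_value(name, value)
    return draw


# ----------------------------------------------------------------------
# Structural rebuild shared by PSA and DSA


def _structural_inputs(base: ParameterSet, current: ParameterSet):
    """Allocation + scenario for a parameter set whose structural values moved."""
    f_up = current.trial.uptake / base.trial.uptake
    f_sens = current.accuracy.sensitivity / base.accuracy.sensitivity
    f_prev = current.prevalence_be / base.prevalence_be
    scenario = _cohort.base_scenario(base)
    scenario = replace(
        scenario,
        n_swallowed=scenario.n_swallowed * f_up,
        n_endoscopy_intervention=scenario.n_endoscopy_intervention * f_up,
        n_repeat_tests=scenario.n_repeat_tests * f_up,
        n_repeat_endoscopies=scenario.n_repeat_endoscopies * f_up,
        uptake=current.trial.uptake,
    )
    prevalence = {s: v * f_prev for s, v in base.prevalence.items()}
    n = base.settings.cohort_size
    detected = {}
    for arm, det in base.trial.detected.items():
        f_det = f_prev * (f_up * f_sens if arm == "intervention" else 1.0)
        detected[arm] = {
            s: min(v * f_det, prevalence.get(s, 0.0) * n) for s, v in det.items()
        }
    allocation = _cohort.allocate_from_trial(current, detected=detected,
                                             prevalence=prevalence)
    return allocation, scenario


def _run_pipeline(base: ParameterSet, current: ParameterSet,
                  start_age: int | None = None) -> _cea.CEResult:
    allocation, scenario = _structural_inputs(base, current)
    _, _, ce = _cea.run_base_case(current, allocation=allocation,
                                  scenario=scenario, start_age=start_age)
    return ce


# ----------------------------------------------------------------------
# PSA


def run_psa(params: ParameterSet, config: PSAConfig) -> PSAResult:
    """Monte-Carlo PSA; reproducible bit-for-bit for a given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records = []
    for _ in range(config.n_draws):
        draw = sample_parameter_set(params, rng)
        ce = _run_pipeline(params, draw)
        records.append({
            "delta_cost": ce.delta_cost,
            "delta_qalys": ce.delta_qalys,
            "cost_intervention": ce.intervention.total_cost,
            "cost_usual": ce.usual.total_cost,
            "qalys_intervention": ce.intervention.qalys,
            "qalys_usual": ce.usual.qalys,
        })
    draws = pd.DataFrame.from_records(records)
    mean_dc = float(draws["delta_cost"].mean())
    mean_de = float(draws["delta_qalys"].mean())
    result = PSAResult(
        draws=draws,
        icer_point=(mean_dc / mean_de) if mean_de != 0 else float("nan"),
        mean_delta_cost=mean_dc,
        sd_delta_cost=float(draws["delta_cost"].std()),
        mean_delta_qalys=mean_de,
        sd_delta_qalys=float(draws["delta_qalys"].std()),
        ceac_thresholds=np.asarray(config.ceac_grid, dtype=float),
        ceac_probability=np.empty(0),
        seed=config.seed,
        n_draws=config.n_draws,
    )
    result.ceac_probability = ceac(result, result.ceac_thresholds)
    return result


def ceac(psa: PSAResult, thresholds) -> np.ndarray:
    """P(cost-effective) per threshold: share of draws with dE*lambda - dC > 0."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ParameterError("threshold grid must be nonempty")
    de = psa.draws["delta_qalys"].to_numpy()
    dc = psa.draws["delta_cost"].to_numpy()
    nmb = de[None, :] * thresholds[:, None] - dc[None, :]
    return (nmb > 0).mean(axis=1)


def per_draw_icers(psa: PSAResult) -> np.ndarray:
    """Per-draw ICERs (negative values retained; undefined draws dropped)."""
    de = psa.draws["delta_qalys"].to_numpy()
    dc = psa.draws["delta_cost"].to_numpy()
    mask = de != 0
    return dc[mask] / de[mask]


def icer_interval(psa: PSAResult, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval of the per-draw ICERs (2.5/97.5 at level 0.95)."""
    if not 0.0 < level < 1.0:
        raise ParameterError(f"interval level {level}: must lie in (0, 1)")
    icers = per_draw_icers(psa)
    if icers.size < 2:
        raise ParameterError("need at least 2 draws with nonzero QALY difference")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(icers, [tail, 1.0 - tail])
    return float(lo), float(hi)


# ----------------------------------------------------------------------
# DSA


def _support_bounds(name: str, value: float) -> tuple[float, float]:
    """Default +/-20% band clipped to the parameter's natural support."""
    low, high = 0.8 * value, 1.2 * value
    if value <= 1.0:  # probabilities, utilities and event durations
        high = min(high, 1.0)
    return low, high


def dsa_specs(params: ParameterSet) -> dict[str, tuple[float, float]]:
    """Low/high bounds per parameter: explicit bounds, else +/-20%."""
    specs: dict[str, tuple[float, float]] = {}
    for name in params.flat_names():
        if name in DSA_EXCLUDED:
            continue
        meta = params.meta.get(name)
        if meta is not None and meta.low is not None and meta.high is not None:
            specs[name] = (float(meta.low), float(meta.high))
        else:
            value = params.get_value(name)
            if value == 0.0:
                continue
            specs[name] = _support_bounds(name, value)
    return specs


def icer_at(params: ParameterSet, name: str, value: float) -> float:
    """ICER of the full pipeline with one parameter set to ``value``."""
    current = params.with_value(name, value)
    start_age = current.settings.start_age if name == "start_age" else None
    ce = _run_pipeline(params, current, start_age=start_age)
    return float("nan") if ce.icer is None else ce.icer


def run_dsa(
    params: ParameterSet,
    specs: dict[str, tuple[float, float]] | None = None,
) -> list[TornadoEntry]:
    """One-way DSA over every parameter, tornado-ordered by ICER range."""
    if specs is None:
        specs = dsa_specs(params)
    entries = []
    for name, (low, high) in specs.items():
        if low > high:
            raise ParameterError(f"DSA bounds for {name!r}: low {low} > high {high}")
        icer_low = icer_at(params, name, low)
        icer_high = icer_at(params, name, high)
        entries.append(TornadoEntry(
            parameter=name, low_input=low, high_input=high,
            icer_low=icer_low, icer_high=icer_high,
            range_width=abs(icer_high - icer_low),
        ))
    entries.sort(key=lambda e: (np.isnan(e.range_width), -e.range_width))
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter, "low": e.low_input, "high": e.high_input,
        "icer_low": e.icer_low, "icer_high": e.icer_high,
        "range_width": e.range_width,
    } for e in entries])
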