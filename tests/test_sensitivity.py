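"""PSA and DSA: determinism, CEAC semantics, tornado ordering, monotonicity."""
import numpy as np
import pandas as pd
import pytest

from cytocea import PSAConfig, ceac, icer_interval, run_dsa, run_psa
from cytocea.sensitivity import (
    PSAResult,
    dsa_specs,
    icer_at,
    per_draw_icers,
    sample_parameter_set,
)


@pytest.fixture(scope="module")
def psa_small(ps):
    return run_psa(ps, PSAConfig(n_draws=150, seed=11))


def test_psa_seed_determinism(ps):
    a = run_psa(ps, PSAConfig(n_draws=25, seed=5))
    b = run_psa(ps, PSAConfig(n_draws=25, seed=5))
    pd.testing.assert_frame_equal(a.draws, b.draws)
    np.testing.assert_array_equal(a.ceac_probability, b.ceac_probability)
    c = run_psa(ps, PSAConfig(n_draws=25, seed=6))
    assert not a.draws.equals(c.draws)


def test_zero_dispersion_collapses_to_base_case(ps):
    from cytocea import run_base_case
    import dataclasses

    p = ps.copy()
    p.meta = {name: dataclasses.replace(m, distribution=None)
              for name, m in p.meta.items()}
    psa = run_psa(p, PSAConfig(n_draws=5, seed=3))
    _, _, base = run_base_case(ps)
    np.testing.assert_allclose(psa.draws["delta_cost"], base.delta_cost, rtol=1e-9)
    np.testing.assert_allclose(psa.draws["delta_qalys"], base.delta_qalys, rtol=1e-9)
    assert psa.sd_delta_cost == pytest.approx(0.0, abs=1e-9)
    # CEAC is then a step function located at the base-case ICER
    grid = np.array([base.icer - 1000.0, base.icer + 1000.0])
    lo, hi = ceac(psa, grid)
    assert (lo, hi) == (0.0, 1.0)


def test_draws_respect_parameter_support(ps):
    rng = np.random.default_rng(0)
    for _ in range(20):
        draw = sample_parameter_set(ps, rng)
        draw.validate()


def test_ceac_limits(psa_small):
    de = psa_small.draws["delta_qalys"].to_numpy()
    dc = psa_small.draws["delta_cost"].to_numpy()
    at_zero = ceac(psa_small, [0.0])[0]
    assert at_zero == pytest.approx(np.mean(dc < 0))
    at_inf = ceac(psa_small, [1e12])[0]
    assert at_inf == pytest.approx(np.mean(de > 0))


def test_ceac_monotone_and_cdf_consistent_when_gains_positive():
    draws = pd.DataFrame({
        "delta_qalys": np.full(200, 0.015) + np.linspace(0, 0.01, 200),
        "delta_cost": np.linspace(-50.0, 250.0, 200),
    })
    psa = PSAResult(draws=draws, icer_point=0.0, mean_delta_cost=0.0,
                    sd_delta_cost=0.0, mean_delta_qalys=0.0, sd_delta_qalys=0.0,
                    ceac_thresholds=np.empty(0), ceac_probability=np.empty(0),
                    seed=0, n_draws=200)
    grid = np.arange(0.0, 30001.0, 500.0)
    probs = ceac(psa, grid)
    assert np.all(np.diff(probs) >= 0.0)
    icers = per_draw_icers(psa)
    for lam in (2000.0, 8000.0, 14000.0):
        assert ceac(psa, [lam])[0] == pytest.approx(np.mean(icers < lam))


def test_icer_interval_properties(psa_small):
    lo95, hi95 = icer_interval(psa_small, 0.95)
    lo50, hi50 = icer_interval(psa_small, 0.50)
    assert lo95 < lo50 < hi50 < hi95
    # degenerate draws collapse to the point
    draws = pd.DataFrame({"delta_qalys": [0.01] * 5, "delta_cost": [55.0] * 5})
    degenerate = PSAResult(draws=draws, icer_point=5500.0, mean_delta_cost=55.0,
                           sd_delta_cost=0.0, mean_delta_qalys=0.01,
                           sd_delta_qalys=0.0, ceac_thresholds=np.empty(0),
                           ceac_probability=np.empty(0), seed=0, n_draws=5)
    lo, hi = icer_interval(degenerate, 0.95)
    assert lo == hi == pytest.approx(5500.0)


def test_psa_summary_near_base_case(psa_small, ps):
    from cytocea import run_base_case

    _, _, base = run_base_case(ps)
    # stochastic: the PSA point estimate sits near the deterministic ICER
    assert psa_small.icer_point == pytest.approx(base.icer, rel=0.25)
    assert psa_small.prob_cost_effective(20000.0) > 0.90


# ----------------------------------------------------------------------
# DSA


def test_degenerate_dsa_spec_zero_width(ps):
    base_cost = ps.costs.cytosponge_test
    entries = run_dsa(ps, {"cytosponge_test": (base_cost, base_cost)})
    assert entries[0].range_width == pytest.approx(0.0, abs=1e-6)


def test_dsa_cytosponge_cost_bounds(ps):
    hi = icer_at(ps, "cytosponge_test", 344.0)
    lo = icer_at(ps, "cytosponge_test", 144.0)
    assert hi == pytest.approx(7212.0, rel=0.10)
    assert lo < hi


def test_dsa_monotone_in_prevalence_and_cytosponge_cost(ps):
    prev_icers = [icer_at(ps, "prevalence_be", p)
                  for p in np.linspace(0.04, 0.12, 5)]
    assert all(b < a for a, b in zip(prev_icers, prev_icers[1:])), prev_icers
    cost_icers = [icer_at(ps, "cytosponge_test", c)
                  for c in np.linspace(144.0, 344.0, 5)]
    assert all(b > a for a, b in zip(cost_icers, cost_icers[1:])), cost_icers


def test_dsa_explicit_bounds_used(ps):
    specs = dsa_specs(ps)
    assert specs["cytosponge_test"] == (144.0, 344.0)
    assert specs["uptake"] == (0.10, 0.50)
    assert specs["start_age"] == (50.0, 74.0)
    assert specs["prevalence_be"] == (0.04, 0.12)
    assert specs["sensitivity"] == (0.764, 0.830)
    # default band: mean +/- 20%, probabilities clipped at 1
    lo, hi = specs["treat_success_lgd"]
    assert lo == pytest.approx(0.8 * ps.get_value("treat_success_lgd"))
    assert hi <= 1.0


def test_tornado_sorted_and_ranks_nobe_utility_above_cytosponge_cost(ps):
    entries = run_dsa(ps)
    widths = [e.range_width for e in entries if not np.isnan(e.range_width)]
    assert widths == sorted(widths, reverse=True)
    order = [e.parameter for e in entries]
    assert order.index("utility_nobe") < order.index("cytosponge_test")
    for e in entries:
        assert e.range_width == pytest.approx(abs(e.icer_high - e.icer_low))


def test_dsa_rejects_inverted_bounds(ps):
    with pytest.raises(Exception, match="low"):
        run_dsa(ps, {"cytosponge_test": (344.0, 144.0)})
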