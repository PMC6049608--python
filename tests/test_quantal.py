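"""Quantal-model tests: Poisson pmf, failure-rate and content estimators,
the silent-fraction identity, potency, the quantal-size fit, AMPA/NMDA
ratios, and group summaries."""

import math
from decimal import Decimal, getcontext

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minstim.detection import DetectionParams
from minstim.quantal import (
    QuantalExperimentModel,
    ampa_nmda_ratio,
    compute_potency,
    estimate_failure_rate,
    fit_quantal_size,
    group_silent_fraction,
    mean_quantal_content,
    poisson_pmf,
    silent_fraction_estimate,
    summarize_groups,
)
from minstim.simulate import (
    SimulationConfig,
    biexp_waveform,
    simulate_minstim_experiment,
)
from minstim.sweeps import EventTable, SweepSet


def _events(failures, amplitudes=None, excluded=None):
    n = len(failures)
    amplitudes = amplitudes if amplitudes is not None else [0.0] * n
    frame = pd.DataFrame(
        {
            "sweep_index": np.arange(n),
            "order_index": np.arange(n),
            "timestamp_s": np.arange(n, dtype=float),
            "holding_potential_mv": -60.0,
            "baseline_pa": 0.0,
            "noise_context": "",
            "peak_pa": amplitudes,
            "peak_latency_ms": 2.0,
            "amplitude_pa": amplitudes,
            "charge_pc": 0.0,
            "is_failure": failures,
            "qc_excluded": excluded if excluded is not None else [False] * n,
            "qc_reason": "",
        }
    )
    return EventTable(frame=frame)


# ---------------------------------------------------------------------------
# poisson pmf


def _pmf_decimal(k: int, m: float) -> float:
    """Arbitrary-precision oracle: m^k e^-m / k! via Decimal arithmetic."""
    getcontext().prec = 60
    md = Decimal(repr(m))
    val = md**k * (-md).exp() / Decimal(math.factorial(k))
    return float(val)


def test_poisson_pmf_values_and_normalization():
    assert poisson_pmf(0, 2.0) == pytest.approx(math.exp(-2), abs=1e-15)
    assert poisson_pmf(3, 1.5) == pytest.approx(0.12551, abs=1e-5)
    assert sum(poisson_pmf(k, 2.0) for k in range(51)) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("m", [0.5, 1.0, 2.0, 5.0, 10.0])
def test_poisson_pmf_matches_arbitrary_precision_oracle(m):
    for k in range(31):
        assert poisson_pmf(k, m) == pytest.approx(_pmf_decimal(k, m), abs=1e-12)


def test_poisson_pmf_domain_errors():
    with pytest.raises(ValueError):
        poisson_pmf(-1, 2.0)
    with pytest.raises(ValueError):
        poisson_pmf(1.5, 2.0)
    with pytest.raises(ValueError):
        poisson_pmf(1, 0.0)


# ---------------------------------------------------------------------------
# failure rate and quantal content


def test_failure_rate_simple_ratio():
    est = estimate_failure_rate(_events([True] * 5 + [False] * 15))
    assert est.rf == 0.25 and est.n_events == 20 and est.n_failures == 5
    assert est.ci_low < 0.25 < est.ci_high


def test_zero_failures_exact_binomial_upper_bound():
    """With 0/20 failures the Clopper-Pearson upper bound has the closed
    form 1 - (alpha/2)^(1/n)."""
    est = estimate_failure_rate(_events([False] * 20))
    assert est.rf == 0.0 and est.ci_low == 0.0
    assert est.ci_high == pytest.approx(1 - 0.025 ** (1 / 20), abs=1e-9)


def test_clopper_pearson_bounds_invert_binomial_tails():
    """The interval endpoints satisfy the defining tail equations
    P(X >= k | p = hi) = alpha/2 and P(X <= k | p = lo) = alpha/2."""
    from scipy.stats import binom

    est = estimate_failure_rate(_events([True] * 5 + [False] * 15))
    k, n = 5, 20
    # upper: P(X <= k | hi) = alpha/2; lower: P(X >= k | lo) = alpha/2
    assert binom.cdf(k, n, est.ci_high) == pytest.approx(0.025, abs=1e-6)
    assert 1 - binom.cdf(k - 1, n, est.ci_low) == pytest.approx(0.025, abs=1e-6)


def test_all_excluded_is_an_error():
    with pytest.raises(ValueError):
        estimate_failure_rate(_events([True, False], excluded=[True, True]))


def test_mean_quantal_content_identities():
    assert mean_quantal_content(1.0) == 0.0
    assert mean_quantal_content(math.exp(-1)) == pytest.approx(1.0, abs=1e-12)
    assert mean_quantal_content(0.127) == pytest.approx(2.0636, abs=5e-4)
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            mean_quantal_content(bad)


# ---------------------------------------------------------------------------
# silent fraction


def test_silent_fraction_reproduces_published_knockout_value():
    """The knockout group-mean failure rates (36.3%, 12.7%) give ~51%
    silent synapses."""
    s = silent_fraction_estimate(0.363, 0.127)
    assert s == pytest.approx(0.5089, abs=5e-4)
    assert round(100 * s) == 51


def test_equal_failure_rates_mean_no_silent_synapses():
    for r in (0.05, 0.2, 0.5, 0.9):
        assert silent_fraction_estimate(r, r) == pytest.approx(0.0, abs=1e-14)


def test_silent_fraction_inverts_generative_model_exactly():
    m, s = 1.7, 0.4
    est = silent_fraction_estimate(math.exp(-m * (1 - s)), math.exp(-m))
    assert est == pytest.approx(s, abs=1e-14)


@settings(max_examples=200, derandomize=True)
@given(
    m=st.floats(min_value=0.01, max_value=5.0),
    s=st.floats(min_value=0.0, max_value=0.9),
)
def test_silent_fraction_identity_property(m, s):
    est = silent_fraction_estimate(math.exp(-m * (1 - s)), math.exp(-m))
    assert est == pytest.approx(s, abs=1e-9)


def test_silent_fraction_domain_and_negative_flagging():
    with pytest.raises(ValueError):
        silent_fraction_estimate(0.5, 1.0)
    with pytest.raises(ValueError):
        silent_fraction_estimate(0.0, 0.5)
    # noisy rf_hyper < rf_depol: negative value returned, not clipped
    assert silent_fraction_estimate(0.1, 0.2) < 0


def test_group_silent_fraction_both_aggregations():
    # published group means: KO ~51%, WT back-computes to ~10.4%
    assert group_silent_fraction([0.363], [0.127]) == pytest.approx(0.5089, abs=5e-4)
    assert group_silent_fraction([0.163], [0.132]) == pytest.approx(0.104, abs=5e-3)
    per_exp = group_silent_fraction([0.3, 0.4], [0.1, 0.2], "mean_per_experiment")
    expected = np.mean(
        [silent_fraction_estimate(0.3, 0.1), silent_fraction_estimate(0.4, 0.2)]
    )
    assert per_exp == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# potency


def test_potency_is_mean_of_success_amplitudes():
    ev = _events([False, False, False, True], amplitudes=[-8.0, -10.0, -12.0, 0.0])
    assert compute_potency(ev) == pytest.approx(-10.0)
    single = _events([True, False], amplitudes=[0.0, -7.5])
    assert compute_potency(single) == -7.5
    with pytest.raises(ValueError):
        compute_potency(_events([True, True]))


def test_potency_matches_conditional_poisson_mean():
    """With cv_q = 0 and no noise, potency ~ q * E[k | k >= 1]
    = q * m / (1 - e^-m)."""
    m, q = 1.2, 9.7
    cfg = SimulationConfig(
        n_sweeps_per_potential=3000, m_total=m, cv_q=0.0, noise_sd=0.0, seed=21
    )
    sw_h, _, _ = simulate_minstim_experiment(cfg)
    params = DetectionParams.for_simulation(cfg)
    model = QuantalExperimentModel.from_sweeps(sw_h, sw_h, params, qc=False)
    potency = compute_potency(model.events_hyper)
    expected = -q * m / (1 - math.exp(-m))
    assert potency == pytest.approx(expected, rel=0.03)


# ---------------------------------------------------------------------------
# quantal-size fit


def test_noiseless_fit_recovers_q_exactly():
    rf = np.arange(0.1, 0.95, 0.1)
    points = [(r, -math.log(r) * 5.0) for r in rf]
    fit = fit_quantal_size(points, "published")
    assert fit.q == pytest.approx(5.0, abs=1e-12)
    assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)


def test_variants_differ_systematically_on_same_points():
    rf = np.arange(0.1, 0.95, 0.1)
    points = [(r, -math.log(r) * 5.0) for r in rf]
    corrected = fit_quantal_size(points, "corrected")
    assert corrected.q != pytest.approx(5.0, abs=0.1)
    assert corrected.q < 5.0  # 1/(1-rf) inflates the regressor


def test_fit_contract_errors():
    with pytest.raises(ValueError):
        fit_quantal_size([(0.5, 1.0), (0.6, 1.2)])
    with pytest.raises(ValueError):
        fit_quantal_size([(0.0, 1.0), (0.5, 1.0), (0.6, 1.0)])
    with pytest.raises(ValueError):
        fit_quantal_size([(0.5, 1.0)] * 4, "unknown-variant")


def test_degenerate_identical_points_collapse_ci():
    points = [(0.3, -math.log(0.3) * 4.0)] * 5
    fit = fit_quantal_size(points, "published")
    assert fit.q == pytest.approx(4.0, abs=1e-12)
    assert fit.se == pytest.approx(0.0, abs=1e-12)
    assert fit.ci_low == pytest.approx(fit.ci_high, abs=1e-9)


# ---------------------------------------------------------------------------
# AMPA/NMDA ratio


def _single_sweep(trace, hp):
    return SweepSet(
        data=trace[None, :], sampling_rate_hz=5000.0, stim_time_ms=10.0,
        holding_potential_mv=hp,
    )


def test_ratio_is_simple_division():
    t = np.arange(600) * 0.2
    hyper = _single_sweep(-30.0 * biexp_waveform(t - 10.0, 1.0, 8.0), -60.0)
    depol_trace = np.zeros(600)
    depol_trace[int(11.0 / 0.2) :] = 15.0  # constant 15 pA from 1 ms post-stim
    depol = _single_sweep(depol_trace, +40.0)
    r = ampa_nmda_ratio(hyper, depol)
    assert r.ratio == pytest.approx(2.0, rel=1e-3)


def test_ratio_symmetry_construction_gives_unity():
    """Equal quantal content and q at both potentials, with the depolarized
    25-ms read scaled to equal the hyperpolarized peak, yields ratio 1."""
    t = np.arange(600) * 0.2
    w_slow = biexp_waveform(t - 10.0, 5.0, 60.0)
    read25 = biexp_waveform(np.array([25.0]), 5.0, 60.0)[0]
    hyper = _single_sweep(-12.0 * biexp_waveform(t - 10.0, 1.0, 8.0), -60.0)
    depol = _single_sweep((12.0 / read25) * w_slow, +40.0)
    r = ampa_nmda_ratio(hyper, depol)
    assert r.ratio == pytest.approx(1.0, rel=2e-2)


def test_silent_rich_group_has_lower_ratio():
    def ratio(s, seed):
        cfg = SimulationConfig(n_sweeps_per_potential=150, silent_fraction=s, seed=seed)
        sw_h, sw_d, _ = simulate_minstim_experiment(cfg)
        return ampa_nmda_ratio(
            sw_h, sw_d, params=DetectionParams.for_simulation(cfg)
        ).ratio

    wt = np.mean([ratio(0.1, 30 + i) for i in range(3)])
    ko = np.mean([ratio(0.5, 40 + i) for i in range(3)])
    assert ko < wt


def test_nonpositive_nmda_component_is_an_error():
    t = np.arange(600) * 0.2
    hyper = _single_sweep(-10.0 * biexp_waveform(t - 10.0, 1.0, 8.0), -60.0)
    depol = _single_sweep(np.zeros(600) - 1.0, +40.0)
    with pytest.raises(ValueError):
        ampa_nmda_ratio(hyper, depol)


# ---------------------------------------------------------------------------
# group summaries


def test_parametric_summary():
    s = summarize_groups([1.0, 2.0, 3.0], parametric=True)
    assert s.mean == pytest.approx(2.0)
    assert s.se == pytest.approx(1.0 / math.sqrt(3), abs=1e-6)  # 0.577


def test_nonparametric_summary_uses_linear_interpolation():
    s = summarize_groups([1.0, 2.0, 3.0, 100.0], parametric=False)
    assert s.median == pytest.approx(2.5)
    assert s.q25 == pytest.approx(np.percentile([1, 2, 3, 100], 25))
    assert s.q75 == pytest.approx(np.percentile([1, 2, 3, 100], 75))
    assert s.minimum == 1.0 and s.maximum == 100.0


def test_single_value_and_empty_group():
    s = summarize_groups([5.0], parametric=True)
    assert s.mean == 5.0 and s.se is None
    with pytest.raises(ValueError):
        summarize_groups([], parametric=True)


# ---------------------------------------------------------------------------
# model object


def test_model_fit_is_internally_consistent(default_experiment):
    _, sweeps_hyper, sweeps_depol, _, params = default_experiment
    res = QuantalExperimentModel.from_sweeps(
        sweeps_hyper, sweeps_depol, params, qc=False
    ).fit()
    assert res.m_hyper == pytest.approx(-math.log(res.rf_hyper.rf), abs=1e-12)
    assert res.m_depol == pytest.approx(-math.log(res.rf_depol.rf), abs=1e-12)
    assert res.silent_fraction == pytest.approx(
        1 - res.m_hyper / res.m_depol, abs=1e-12
    )
    assert "silent fraction" in res.summary()
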