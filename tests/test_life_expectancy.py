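"""Quantile inversion, published-table reconstruction, bootstrap intervals."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import gompertzle as gle
from gompertzle.life_expectancy import (
    _QUANTILE_RATIO_TARGET,
    BootstrapResult,
    bootstrap_ci,
    prediction_interval,
    reconstruct_from_quantiles,
)
from gompertzle.published import PREDICTED_QUANTILES


# ---------------------------------------------------------------------------
# quantile inversion
# ---------------------------------------------------------------------------

def test_quantile_closed_forms():
    # exponential limit: median = ln 2 / lambda
    assert gle.quantile(0.5, 0.1, 0.0) == pytest.approx(np.log(2) / 0.1)
    # vanishing mortality fraction -> vanishing time
    assert gle.quantile(1e-12, 0.1, 0.1) == pytest.approx(0.0, abs=1e-9)


def test_quantile_rejects_bad_fractions():
    for p in (0.0, 1.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            gle.quantile(p, 0.1, 0.1)


def test_negative_shape_plateau():
    """A decaying hazard caps total mortality; beyond it the quantile errors."""
    lam, g = 0.05, -0.1  # cumulative hazard plateaus at lam/|g| = 0.5
    attainable = 1.0 - np.exp(-0.5)
    assert np.isfinite(gle.quantile(attainable - 0.01, lam, g))
    with pytest.raises(gle.PlateauError):
        gle.quantile(attainable + 0.01, lam, g)


@given(lam=st.floats(1e-4, 0.3), gamma=st.floats(0.0, 0.4),
       p=st.floats(0.01, 0.99))
@settings(max_examples=300, derandomize=True)
def test_quantile_survival_round_trip(lam, gamma, p):
    t = gle.quantile(p, lam, gamma)
    assert gle.survival(t, lam, gamma) == pytest.approx(1.0 - p, abs=1e-10)


@given(lam=st.floats(1e-4, 0.3), gamma=st.floats(0.0, 0.4),
       p=st.floats(0.02, 0.90))
@settings(max_examples=200, derandomize=True)
def test_quantile_monotone(lam, gamma, p):
    assert gle.quantile(p + 0.05, lam, gamma) > gle.quantile(p, lam, gamma)
    # at fixed shape, a higher rate shortens the median
    assert (gle.quantile(0.5, lam * 1.5, gamma) < gle.quantile(0.5, lam, gamma))


# ---------------------------------------------------------------------------
# published-table values through the reconstructed model
# ---------------------------------------------------------------------------

def test_predicted_medians_match_published(ref_model):
    """Group 11 median 5.9 y and top-group median 3.4 y, as published."""
    assert gle.predict_le(ref_model, 11).t50 == pytest.approx(5.9, abs=0.05)
    assert gle.predict_le(ref_model, 14).t50 == pytest.approx(3.4, abs=0.05)


def test_predicted_third_quartiles_match_published(ref_model):
    """t75 values reproduce the published table within print precision."""
    for g, expected in ((0, 41.5), (10, 11.2)):
        est = gle.predict_le(ref_model, g)
        assert est.t75 == pytest.approx(expected, abs=0.3)
        # quantile/survival identity at the reported median
        assert gle.survival(est.t50, ref_model.rates[g], ref_model.shape) == \
            pytest.approx(0.5, abs=1e-10)


def test_predict_le_flags_extrapolation(ref_model):
    assert gle.predict_le(ref_model, 0, horizon=10.0).extrapolated
    assert not gle.predict_le(ref_model, 14, horizon=10.0).extrapolated
    with pytest.raises(ValueError):
        fit = gle.fit_mle(pd.DataFrame({"group": [0] * 10,
                                        "time_years": np.linspace(1, 9, 10),
                                        "event": [True] * 10}))
        gle.predict_le(fit, 7)


def test_predict_le_table_medians_decrease(ref_model):
    tab = gle.predict_le_table(ref_model)
    assert len(tab) == 15
    assert tab["t50"].is_monotonic_decreasing
    assert (tab["t25"] < tab["t50"]).all() and (tab["t50"] < tab["t75"]).all()


# ---------------------------------------------------------------------------
# reconstruction from a quantile table
# ---------------------------------------------------------------------------

def test_reconstruction_round_trip_exact():
    """Noiseless quantiles from a known model are inverted exactly."""
    gamma, rates = 0.15, {0: 0.002, 3: 0.01, 9: 0.08}
    table = {g: (gle.quantile(0.25, r, gamma), gle.quantile(0.5, r, gamma))
             for g, r in rates.items()}
    fit = reconstruct_from_quantiles(table)
    assert fit.shape == pytest.approx(gamma, abs=1e-8)
    for g, r in rates.items():
        assert fit.rates[g] == pytest.approx(r, rel=1e-8)


def test_shared_shape_agrees_with_bisection_oracle():
    """The least-squares shape sits inside the per-group bisection solutions.

    Each published (t25, t50) pair pins its own shape through
    (e^{g t50}-1)/(e^{g t25}-1) = ln(.5)/ln(.75); root-finding them one by
    one brackets the shared estimate near 0.11.
    """
    per_group = []
    for t25, t50, _ in PREDICTED_QUANTILES.values():
        f = lambda g: np.expm1(g * t50) / np.expm1(g * t25) - _QUANTILE_RATIO_TARGET
        per_group.append(brentq(f, 1e-6, 2.0))
    fit = reconstruct_from_quantiles(PREDICTED_QUANTILES)
    assert min(per_group) <= fit.shape <= max(per_group)
    assert fit.shape == pytest.approx(0.11, abs=0.01)
    assert np.median(per_group) == pytest.approx(fit.shape, abs=0.01)


def test_reconstruction_rejects_disordered_quantiles():
    bad = {0: (27.8, 35.4), 5: (18.0, 17.7)}
    with pytest.raises(ValueError, match="group 5"):
        reconstruct_from_quantiles(bad)
    with pytest.raises(ValueError, match="group 2"):
        reconstruct_from_quantiles({2: (-1.0, 4.0)})


# ---------------------------------------------------------------------------
# bootstrap confidence intervals
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_cohort(dev_probs):
    spec = gle.CohortSpec(n=2000, group_probabilities=dev_probs, horizon=10.0)
    return gle.sample_cohort(spec, seed=21)


def test_bootstrap_deterministic_given_seed(small_cohort):
    a = bootstrap_ci(small_cohort, B=60, seed=9)
    b = bootstrap_ci(small_cohort, B=60, seed=9)
    np.testing.assert_array_equal(a.quantiles, b.quantiles)
    pd.testing.assert_frame_equal(a.ci(), b.ci())


def test_bootstrap_contract_edges(small_cohort):
    with pytest.raises(ValueError):
        bootstrap_ci(small_cohort, B=1)
    with pytest.warns(UserWarning, match="coarse"):
        res = bootstrap_ci(small_cohort, B=2, seed=1)
    ci = res.ci()
    assert (ci["t50_lo"] <= ci["t50_hi"]).all()


def test_bootstrap_ci_width_shrinks_with_n(dev_probs):
    """Median-CI width at n=8000 beats n=2000 in expectation (20 seed pairs)."""
    widths = {2000: [], 8000: []}
    for n in widths:
        for s in range(20):
            spec = gle.CohortSpec(n=n, group_probabilities=dev_probs, horizon=10.0)
            coh = gle.sample_cohort(spec, seed=100 + s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ci = bootstrap_ci(coh, B=40, seed=s).ci()
            widths[n].append(float((ci["t50_hi"] - ci["t50_lo"]).mean()))
    assert np.mean(widths[8000]) < np.mean(widths[2000])


def test_bootstrap_coverage_of_true_median(dev_probs, ref_model):
    """95% percentile CI covers the generating median ~95% of the time.

    60 outer replicates at n=2000, B=120; coverage for the mid-risk group 5
    must sit within 3 binomial standard errors of 0.95.
    """
    true_med = gle.quantile(0.5, ref_model.rates[5], ref_model.shape)
    spec = gle.CohortSpec(n=2000, group_probabilities=dev_probs, horizon=10.0)
    hits = 0
    n_rep = 60
    for s in range(n_rep):
        coh = gle.sample_cohort(spec, seed=7000 + s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ci = bootstrap_ci(coh, B=120, seed=s).ci().set_index("group")
        hits += ci.loc[5, "t50_lo"] <= true_med <= ci.loc[5, "t50_hi"]
    se = np.sqrt(0.95 * 0.05 / n_rep)
    assert abs(hits / n_rep - 0.95) < 3 * se + 1e-9


# ---------------------------------------------------------------------------
# prediction intervals
# ---------------------------------------------------------------------------

def _degenerate_boot(ref_model, B=10):
    groups = tuple(range(15))
    q = np.array([[gle.quantile(p, ref_model.rates[g], ref_model.shape)
                   for p in (0.25, 0.5, 0.75)] for g in groups])
    return BootstrapResult(
        groups=groups,
        quantiles=np.repeat(q[None, :, :], B, axis=0),
        shapes=np.full(B, ref_model.shape),
        rates=np.repeat(ref_model.rates[None, :], B, axis=0),
        n_requested=B, n_failed=0, seed=0)


def test_pi_collapses_to_individual_band_without_sampling_noise(ref_model):
    """Identical replicates: the 50% PI is the model's own (t25, t75) band."""
    boot = _degenerate_boot(ref_model)
    pi = prediction_interval(boot, n_draws=6000, seed=2).set_index("group")
    for g in (5, 11):
        t25 = gle.quantile(0.25, ref_model.rates[g], ref_model.shape)
        t75 = gle.quantile(0.75, ref_model.rates[g], ref_model.shape)
        assert pi.loc[g, "pi_lo"] == pytest.approx(t25, abs=0.35)
        assert pi.loc[g, "pi_hi"] == pytest.approx(t75, abs=0.35)


def test_pi_width_approaches_quartile_band_as_n_grows(dev_probs, ref_model):
    """Sampling noise widens the PI; more data moves it toward t75 - t25."""
    widths = {}
    for n in (300, 8000):
        spec = gle.CohortSpec(n=n, group_probabilities=dev_probs, horizon=10.0)
        coh = gle.sample_cohort(spec, seed=31)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boot = bootstrap_ci(coh, B=60, seed=3)
            pi = prediction_interval(boot, n_draws=400, seed=4).set_index("group")
        widths[n] = float(pi.loc[10, "pi_hi"] - pi.loc[10, "pi_lo"])
    band = (gle.quantile(0.75, ref_model.rates[10], ref_model.shape)
            - gle.quantile(0.25, ref_model.rates[10], ref_model.shape))
    assert abs(widths[8000] - band) < abs(widths[300] - band)


def test_pi_requires_replicates(ref_model):
    boot = _degenerate_boot(ref_model, B=2)
    boot.quantiles = boot.quantiles[:0]
    with pytest.raises(ValueError):
        prediction_interval(boot)


def test_estimate_life_expectancy_pipeline(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = gle.estimate_life_expectancy(small_cohort, B=40, seed=2)
    assert len(tab) == 15
    inside = ((tab["t50_lo"] <= tab["t50"]) & (tab["t50"] <= tab["t50_hi"])).mean()
    assert inside > 0.8
    assert (tab["pi_lo"] < tab["pi_hi"]).all()
    assert tab.loc[tab["group"] == 0, "extrapolated"].item()
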