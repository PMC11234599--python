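import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twinclocks import (
    BivariateSimSpec,
    CholeskyParams,
    TwinDataset,
    Zygosity,
    cholesky_from_summary,
    ctct_observed,
    derive_bivariate_statistics,
    expected_moments_bivariate,
    fit_bivariate,
    fit_saturated_bivariate,
    neg2_loglik_bivariate,
    simulate_bivariate_twins,
)
from twinclocks.bivariate import profile_ci_bivariate, select_model_bivariate

from conftest import make_pair


# ---------------------------------------------------------------------------
# expected moments
# ---------------------------------------------------------------------------

def test_zero_cross_paths_give_block_independence():
    params = CholeskyParams(a=(0.8, 0.0, 0.6), e=(0.5, 0.0, 0.7))
    _, sigma = expected_moments_bivariate(params, "MZ")
    # wave-1 / wave-2 covariance within the same twin is entry (0, 1)
    assert sigma[0, 1] == pytest.approx(0.0, abs=1e-15)
    assert sigma[2, 3] == pytest.approx(0.0, abs=1e-15)


def test_dz_cross_twin_a_block_is_half_of_mz():
    params = CholeskyParams(a=(0.9, 0.4, 0.5), e=(0.4, 0.1, 0.6))
    _, s_mz = expected_moments_bivariate(params, "MZ")
    _, s_dz = expected_moments_bivariate(params, "DZ")
    a_block = params.block("a")
    np.testing.assert_allclose(s_mz[:2, 2:] - s_dz[:2, 2:], 0.5 * a_block,
                               atol=1e-12)


def test_within_twin_cross_wave_covariance_is_a11_a21():
    params = CholeskyParams(a=(1.0, 1.0, 0.0), e=(1.0, 0.0, 1.0))
    _, sigma = expected_moments_bivariate(params, "MZ")
    assert sigma[0, 1] == pytest.approx(1.0)


@settings(derandomize=True, max_examples=30)
@given(
    a=st.tuples(st.floats(0.1, 1.5), st.floats(-1, 1), st.floats(0, 1.5)),
    e=st.tuples(st.floats(0.1, 1.5), st.floats(-1, 1), st.floats(0.1, 1.5)),
)
def test_implied_sigma_symmetric_pd(a, e):
    params = CholeskyParams(a=a, e=e)
    for z in ("MZ", "DZ"):
        _, sigma = expected_moments_bivariate(params, z)
        np.testing.assert_allclose(sigma, sigma.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(sigma) > 0)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _oracle_m2ll(params, dataset):
    """Explicit per-pair 4-variate normal density via inverse and determinant."""
    total = 0.0
    for pair in dataset.pairs:
        y = pair.phenotype.reshape(4)  # (t1w1, t1w2, t2w1, t2w2)
        mean, sigma = expected_moments_bivariate(params, pair.zygosity)
        obs = ~np.isnan(y)
        k = obs.sum()
        if k == 0:
            continue
        sub = sigma[np.ix_(obs, obs)]
        d = y[obs] - mean[obs]
        total += (k * math.log(2 * math.pi)
                  + math.log(np.linalg.det(sub))
                  + d @ np.linalg.inv(sub) @ d)
    return total


@pytest.fixture
def two_wave_dataset():
    params = cholesky_from_summary(0.6, 0.55, ra=0.8, re=0.3)
    return simulate_bivariate_twins(
        BivariateSimSpec(n_mz=12, n_dz=10, params=params, seed=4))


def test_neg2ll_matches_oracle(two_wave_dataset):
    params = CholeskyParams(a=(0.7, 0.3, 0.5), e=(0.6, 0.1, 0.6),
                            mu=(0.05, -0.1))
    assert neg2_loglik_bivariate(params, two_wave_dataset) == pytest.approx(
        _oracle_m2ll(params, two_wave_dataset), rel=1e-12)


def test_neg2ll_fiml_handles_missing_entries(two_wave_dataset):
    pairs = list(two_wave_dataset.pairs)
    pairs[0].phenotype[1, 1] = np.nan   # one twin missing at follow-up
    pairs[1].phenotype[0, :] = np.nan   # one twin entirely missing
    ds = TwinDataset(pairs, n_waves=2)
    params = CholeskyParams(a=(0.7, 0.3, 0.5), e=(0.6, 0.1, 0.6))
    assert neg2_loglik_bivariate(params, ds) == pytest.approx(
        _oracle_m2ll(params, ds), rel=1e-12)


def test_neg2ll_invariant_to_twin_order(two_wave_dataset):
    params = CholeskyParams(a=(0.7, 0.3, 0.5), e=(0.6, 0.1, 0.6))
    assert neg2_loglik_bivariate(params, two_wave_dataset) == pytest.approx(
        neg2_loglik_bivariate(params, two_wave_dataset.swapped()), rel=1e-14)


# ---------------------------------------------------------------------------
# derived statistics
# ---------------------------------------------------------------------------

def test_summary_round_trip_dunedinpace_like():
    params = cholesky_from_summary(0.70, 0.69, ra=0.99, re=0.36)
    d = derive_bivariate_statistics(params)
    assert d.h2_baseline == pytest.approx(0.70, abs=1e-10)
    assert d.h2_followup == pytest.approx(0.69, abs=1e-10)
    assert d.ra == pytest.approx(0.99, abs=1e-10)
    assert d.re == pytest.approx(0.36, abs=1e-10)
    assert d.V1 == pytest.approx(1.0, abs=1e-10)
    assert d.V2 == pytest.approx(1.0, abs=1e-10)


def test_zero_cross_path_zeroes_ra():
    params = CholeskyParams(a=(0.8, 0.0, 0.7), e=(0.5, 0.2, 0.5))
    d = derive_bivariate_statistics(params)
    assert d.ra == 0.0
    assert d.proportions["a"] == 0.0


def test_proportions_sum_to_one_when_rph_nonzero():
    params = cholesky_from_summary(0.6, 0.5, ra=0.9, re=0.4,
                                   c2_baseline=0.1, c2_followup=0.2, rc=0.5)
    d = derive_bivariate_statistics(params)
    assert sum(d.proportions.values()) == pytest.approx(1.0, abs=1e-6)


@settings(derandomize=True, max_examples=40)
@given(
    h2_1=st.floats(0.05, 0.9), h2_2=st.floats(0.05, 0.9),
    ra=st.floats(-0.99, 0.99), re=st.floats(-0.99, 0.99),
)
def test_standardized_rph_identity(h2_1, h2_2, ra, re):
    """Rph = Ra*sqrt(h2_1*h2_2) + Re*sqrt(e2_1*e2_2) on the standardized scale."""
    params = cholesky_from_summary(h2_1, h2_2, ra=ra, re=re)
    d = derive_bivariate_statistics(params)
    e2_1, e2_2 = 1 - h2_1, 1 - h2_2
    expected = ra * math.sqrt(h2_1 * h2_2) + re * math.sqrt(e2_1 * e2_2)
    assert d.rph == pytest.approx(expected, abs=1e-10)


def test_implied_ctct_mz_geq_dz_for_nonnegative_a_cross():
    params = cholesky_from_summary(0.7, 0.6, ra=0.8, re=0.2)
    d = derive_bivariate_statistics(params)
    assert d.ctct_implied["MZ"] >= d.ctct_implied["DZ"]
    assert d.ctct_implied["DZ"] == pytest.approx(
        0.5 * d.cross_cov["a"] / math.sqrt(d.V1 * d.V2))


# ---------------------------------------------------------------------------
# observed CTCT
# ---------------------------------------------------------------------------

def test_ctct_perfect_when_cotwin_followup_equals_baseline():
    pairs = []
    rng = np.random.default_rng(8)
    for i in range(6):
        v1, v2 = rng.normal(size=2)
        # twin1 baseline == twin2 follow-up and vice versa
        pairs.append(make_pair(f"m{i}", "MZ", [[v1, v2], [v2, v1]], n_waves=2))
    ds = TwinDataset(pairs, n_waves=2)
    res = ctct_observed(ds, "MZ")
    assert res.r == pytest.approx(1.0)


def test_ctct_near_zero_for_independent_data():
    params = CholeskyParams(a=None, c=None, e=(1.0, 0.0, 1.0))
    ds = simulate_bivariate_twins(
        BivariateSimSpec(n_mz=20000, n_dz=1, params=params, seed=12))
    res = ctct_observed(ds, "MZ")
    assert res.r == pytest.approx(0.0, abs=0.02)
    assert res.ci[0] < res.r < res.ci[1]


def test_ctct_invariant_to_twin_relabeling(two_wave_dataset):
    r1 = ctct_observed(two_wave_dataset, "MZ")
    r2 = ctct_observed(two_wave_dataset.swapped(), "MZ")
    assert r1.r == pytest.approx(r2.r, rel=1e-12)
    assert r1.n_pairs == r2.n_pairs


def test_ctct_requires_three_pairs():
    pairs = [make_pair(f"m{i}", "MZ", [[0.1, 0.2], [0.3, 0.4]], n_waves=2)
             for i in range(2)]
    ds = TwinDataset(pairs, n_waves=2)
    with pytest.raises(Exception, match="at least 3"):
        ctct_observed(ds, "MZ")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_recovers_generating_correlations():
    params = cholesky_from_summary(0.70, 0.69, ra=0.99, re=0.36)
    ds = simulate_bivariate_twins(
        BivariateSimSpec(n_mz=2000, n_dz=2000, params=params, seed=202))
    fit = fit_bivariate(ds, "AE")
    assert fit.converged
    d = derive_bivariate_statistics(fit.params)
    assert d.ra == pytest.approx(0.99, abs=0.03)
    assert d.re == pytest.approx(0.36, abs=0.05)
    assert d.h2_baseline == pytest.approx(0.70, abs=0.04)
    assert d.h2_followup == pytest.approx(0.69, abs=0.04)


def test_fit_zero_cross_correlation_data():
    params = CholeskyParams(a=(0.8, 0.0, 0.8), e=(0.6, 0.0, 0.6))
    ds = simulate_bivariate_twins(
        BivariateSimSpec(n_mz=1500, n_dz=1500, params=params, seed=6))
    fit = fit_bivariate(ds, "AE")
    assert abs(fit.params.a[1]) < 0.06
    assert abs(fit.params.e[1]) < 0.06


def test_fit_optimum_is_local_minimum_on_cross_path_grid():
    """Grid refinement over (a21, e21) cannot improve on the ML optimum."""
    params = cholesky_from_summary(0.6, 0.55, ra=0.8, re=0.3)
    ds = simulate_bivariate_twins(
        BivariateSimSpec(n_mz=18, n_dz=12, params=params, seed=44))
    fit = fit_bivariate(ds, "AE")
    a11, a21, a22 = fit.params.a
    e11, e21, e22 = fit.params.e
    best = fit.minus2lnL
    for da in np.linspace(-0.3, 0.3, 41):
        for de in np.linspace(-0.3, 0.3, 41):
            trial = CholeskyParams(a=(a11, a21 + da, a22),
                                   e=(e11, e21 + de, e22), mu=fit.params.mu)
            best = min(best, neg2_loglik_bivariate(trial, ds))
    assert fit.minus2lnL <= best + 1e-6


def test_fit_likelihood_invariant_to_twin_order(two_wave_dataset):
    f1 = fit_bivariate(two_wave_dataset, "AE")
    f2 = fit_bivariate(two_wave_dataset.swapped(), "AE")
    assert f1.minus2lnL == pytest.approx(f2.minus2lnL, abs=1e-5)


def test_recovery_bias_over_replicates():
    """Ra, Re, and both wave heritabilities recovered with small mean bias."""
    truth = dict(h2_1=0.7, h2_2=0.69, ra=0.9, re=0.36)
    errs = {k: [] for k in ("ra", "re", "h2_1", "h2_2")}
    for rep in range(10):
        params = cholesky_from_summary(truth["h2_1"], truth["h2_2"],
                                       ra=truth["ra"], re=truth["re"])
        ds = simulate_bivariate_twins(
            BivariateSimSpec(n_mz=2000, n_dz=2000, params=params,
                             seed=3000 + rep))
        d = derive_bivariate_statistics(fit_bivariate(ds, "AE").params)
        errs["ra"].append(d.ra - truth["ra"])
        errs["re"].append(d.re - truth["re"])
        errs["h2_1"].append(d.h2_baseline - truth["h2_1"])
        errs["h2_2"].append(d.h2_followup - truth["h2_2"])
    for k, v in errs.items():
        assert abs(np.mean(v)) < 0.02, k


# ---------------------------------------------------------------------------
# saturated model, selection, CIs
# ---------------------------------------------------------------------------

def test_saturated_bounds_cholesky_likelihood(two_wave_dataset):
    sat = fit_saturated_bivariate(two_wave_dataset)
    fit = fit_bivariate(two_wave_dataset, "ACE")
    assert sat.minus2lnL <= fit.minus2lnL + 1e-6


def test_saturated_recovers_sample_moments():
    params = cholesky_from_summary(0.6, 0.5, ra=0.7, re=0.3)
    ds = simulate_bivariate_twins(
        BivariateSimSpec(n_mz=300, n_dz=250, params=params, seed=21))
    sat = fit_saturated_bivariate(ds)
    y = ds.phenotype_array().reshape(-1, 4)
    mz = ds.zygosity_array()
    for zyg, mask in (("MZ", mz), ("DZ", ~mz)):
        sub = y[mask]
        np.testing.assert_allclose(sat.means[zyg], sub.mean(axis=0), atol=5e-3)
        np.testing.assert_allclose(sat.covariances[zyg],
                                   np.cov(sub.T, ddof=0), atol=2e-2)


def test_select_model_bivariate_prefers_ae_on_ae_data():
    params = cholesky_from_summary(0.6, 0.6, ra=0.9, re=0.4)
    ds = simulate_bivariate_twins(
        BivariateSimSpec(n_mz=1500, n_dz=1500, params=params, seed=66))
    result = select_model_bivariate(ds)
    assert result.selected == "AE"
    assert result.table.selected.sum() == 1


def test_profile_ci_bivariate_brackets_ra():
    params = cholesky_from_summary(0.65, 0.6, ra=0.85, re=0.35)
    ds = simulate_bivariate_twins(
        BivariateSimSpec(n_mz=800, n_dz=800, params=params, seed=91))
    fit = fit_bivariate(ds, "AE")
    d = derive_bivariate_statistics(fit.params)
    lo, hi = profile_ci_bivariate(fit, "ra")
    assert -1.0 <= lo < d.ra < hi <= 1.0
    assert hi - lo < 0.5
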