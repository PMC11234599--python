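import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twinclocks import (
    TwinDataset,
    UnivariateModelSpec,
    UnivariateParams,
    UnivariateSimSpec,
    Zygosity,
    expected_moments_univariate,
    fit_saturated_univariate,
    fit_univariate,
    likelihood_ratio_test,
    neg2_loglik_univariate,
    profile_ci,
    select_model,
    simulate_univariate_twins,
)

from conftest import make_pair


# ---------------------------------------------------------------------------
# expected moments
# ---------------------------------------------------------------------------

def test_ace_moments_follow_sharing_coefficients():
    p = UnivariateParams(a=math.sqrt(0.5), c=math.sqrt(0.2), e=math.sqrt(0.3))
    _, cov_mz = expected_moments_univariate(p, "MZ")
    _, cov_dz = expected_moments_univariate(p, "DZ")
    np.testing.assert_allclose(cov_mz, [[1.0, 0.7], [0.7, 1.0]], atol=1e-12)
    assert cov_dz[0, 1] == pytest.approx(0.45)


def test_ade_moments_follow_sharing_coefficients():
    p = UnivariateParams(a=math.sqrt(0.4), d=math.sqrt(0.2), e=math.sqrt(0.4))
    _, cov_mz = expected_moments_univariate(p, "MZ")
    _, cov_dz = expected_moments_univariate(p, "DZ")
    assert cov_mz[0, 1] == pytest.approx(0.6)
    assert cov_dz[0, 1] == pytest.approx(0.5 * 0.4 + 0.25 * 0.2)


def test_e_only_moments_are_identity():
    p = UnivariateParams(e=1.0)
    for z in ("MZ", "DZ"):
        _, cov = expected_moments_univariate(p, z)
        np.testing.assert_allclose(cov, np.eye(2), atol=1e-15)


@settings(derandomize=True, max_examples=40)
@given(a2=st.floats(0, 2), c2=st.floats(0, 2), e2=st.floats(0.01, 2))
def test_moments_symmetric_positive_definite(a2, c2, e2):
    p = UnivariateParams(a=math.sqrt(a2), c=math.sqrt(c2), e=math.sqrt(e2))
    for z in ("MZ", "DZ"):
        _, cov = expected_moments_univariate(p, z)
        assert cov[0, 1] == cov[1, 0]
        assert np.all(np.linalg.eigvalsh(cov) > 0)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_neg2ll_single_standard_normal_pair():
    ds = TwinDataset([make_pair("m", "MZ", [0.0, 0.0])], n_waves=1)
    p = UnivariateParams(a=0.0, c=0.0, e=1.0, mu=0.0)
    assert neg2_loglik_univariate(p, ds) == pytest.approx(2 * math.log(2 * math.pi),
                                                          abs=1e-10)


def _per_pair_density_oracle(params, dataset):
    """Explicit 2x2 inverse/determinant evaluation, pair by pair."""
    total = 0.0
    for pair in dataset.pairs:
        y = pair.phenotype[:, 0]
        mean, cov = expected_moments_univariate(params, pair.zygosity)
        obs = ~np.isnan(y)
        if obs.sum() == 2:
            d = y - mean
            det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
            inv = np.array([[cov[1, 1], -cov[0, 1]],
                            [-cov[0, 1], cov[0, 0]]]) / det
            total += 2 * math.log(2 * math.pi) + math.log(det) + d @ inv @ d
        elif obs.sum() == 1:
            d = y[obs][0] - mean[obs][0]
            v = cov[0, 0]
            total += math.log(2 * math.pi) + math.log(v) + d * d / v
    return total


def test_neg2ll_matches_per_pair_oracle(small_dataset):
    params = UnivariateParams(a=0.6, c=0.3, e=0.8, mu=0.1)
    expected = _per_pair_density_oracle(params, small_dataset)
    assert neg2_loglik_univariate(params, small_dataset) == pytest.approx(
        expected, rel=1e-12)


def test_neg2ll_with_missing_cotwin_uses_marginal(small_dataset):
    pairs = [p for p in small_dataset.pairs]
    pairs[0].phenotype[1, 0] = np.nan
    ds = TwinDataset(pairs, n_waves=1)
    params = UnivariateParams(a=0.5, e=0.9, mu=-0.2)
    assert neg2_loglik_univariate(params, ds) == pytest.approx(
        _per_pair_density_oracle(params, ds), rel=1e-12)


def test_neg2ll_invariant_to_twin_order(small_dataset):
    params = UnivariateParams(a=0.7, c=0.2, e=0.6, mu=0.05)
    v1 = neg2_loglik_univariate(params, small_dataset)
    v2 = neg2_loglik_univariate(params, small_dataset.swapped())
    assert v1 == pytest.approx(v2, rel=1e-14)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_ae_recovers_generating_shares():
    spec = UnivariateSimSpec(n_mz=4000, n_dz=4000, components="AE",
                             a2=0.45, e2=0.55, seed=101)
    ds = simulate_univariate_twins(spec)
    fit = fit_univariate(ds, "AE", compute_ci=False)
    assert fit.converged
    assert fit.h2 == pytest.approx(0.45, abs=0.03)
    assert sum(fit.standardized_components.values()) == pytest.approx(1.0,
                                                                      abs=1e-6)


def test_no_familial_resemblance_gives_zero_h2():
    spec = UnivariateSimSpec(n_mz=1500, n_dz=1500, components="E", e2=1.0,
                             seed=5)
    ds = simulate_univariate_twins(spec)
    fit = fit_univariate(ds, "AE", compute_ci=False)
    assert fit.h2 == pytest.approx(0.0, abs=0.04)
    assert fit.e2_share == pytest.approx(1.0, abs=0.04)


def test_ace_fit_on_ae_data_drives_c2_to_zero():
    spec = UnivariateSimSpec(n_mz=3000, n_dz=3000, components="AE",
                             a2=0.59, e2=0.41, seed=23)
    ds = simulate_univariate_twins(spec)
    fit = fit_univariate(ds, "ACE", compute_ci=False)
    assert fit.standardized_components["c2"] == pytest.approx(0.0, abs=0.04)


def test_fit_invariant_to_twin_order(ae_dataset):
    f1 = fit_univariate(ae_dataset, "AE", compute_ci=False)
    f2 = fit_univariate(ae_dataset.swapped(), "AE", compute_ci=False)
    assert f1.h2 == pytest.approx(f2.h2, abs=1e-6)
    assert f1.minus2lnL == pytest.approx(f2.minus2lnL, abs=1e-6)


def test_fit_with_covariate_recovers_effect():
    from twinclocks.simulate import CovariateSettings

    spec = UnivariateSimSpec(n_mz=1500, n_dz=1500, components="AE",
                             a2=0.5, e2=0.5, beta={"sex": 0.8},
                             covariates=CovariateSettings(include=("sex",)),
                             seed=31)
    ds = simulate_univariate_twins(spec)
    fit = fit_univariate(ds, UnivariateModelSpec("AE", ["sex"]),
                         compute_ci=False)
    assert fit.params.beta["sex"] == pytest.approx(0.8, abs=0.08)
    assert fit.h2 == pytest.approx(0.5, abs=0.05)


def test_ml_optimum_matches_grid_oracle():
    """Dense (a, e) grid with closed-form GLS mean beats nothing the ML found."""
    spec = UnivariateSimSpec(n_mz=18, n_dz=12, components="AE",
                             a2=0.5, e2=0.5, seed=13)
    ds = simulate_univariate_twins(spec)
    fit = fit_univariate(ds, "AE", compute_ci=False)

    y = ds.phenotype_array()[:, :, 0]
    mz = ds.zygosity_array()

    def m2ll(a, e, mu):
        total = 0.0
        for mask, rho in ((mz, 1.0), (~mz, 0.5)):
            V = a * a + e * e
            cov = rho * a * a
            det = V * V - cov * cov
            d = y[mask] - mu
            q = (V * (d[:, 0] ** 2 + d[:, 1] ** 2)
                 - 2 * cov * d[:, 0] * d[:, 1]) / det
            total += mask.sum() * (2 * math.log(2 * math.pi) + math.log(det)) \
                + q.sum()
        return total

    def mu_hat(a, e):
        num = den = 0.0
        for mask, rho in ((mz, 1.0), (~mz, 0.5)):
            w = 1.0 / (a * a + e * e + rho * a * a)
            num += w * y[mask].sum()
            den += w * 2 * mask.sum()
        return num / den

    grid = np.linspace(0.05, 1.6, 120)
    best = min((m2ll(a, e, mu_hat(a, e)) for a in grid for e in grid))
    assert fit.minus2lnL <= best + 1e-6
    # and the grid should come close to the ML optimum at this resolution
    assert best - fit.minus2lnL < 0.05


def test_falconer_consistency_at_large_n():
    spec = UnivariateSimSpec(n_mz=4000, n_dz=4000, components="AE",
                             a2=0.6, e2=0.4, seed=77)
    ds = simulate_univariate_twins(spec)
    fit = fit_univariate(ds, "AE", compute_ci=False)
    from twinclocks import summarize

    s = summarize(ds)
    falconer = 2 * (s.row("MZ")["r_within"] - s.row("DZ")["r_within"])
    assert fit.h2 == pytest.approx(falconer, abs=0.05)


def test_recovery_bias_small_over_replicates():
    """Mean bias of h-hat-squared under the true AE model stays below 0.01."""
    errs = []
    for rep in range(20):
        spec = UnivariateSimSpec(n_mz=2000, n_dz=2000, components="AE",
                                 a2=0.6, e2=0.4, seed=1000 + rep)
        fit = fit_univariate(simulate_univariate_twins(spec), "AE",
                             compute_ci=False)
        errs.append(fit.h2 - 0.6)
    assert abs(np.mean(errs)) < 0.01


def test_zero_variance_phenotype_errors():
    pairs = [make_pair(f"m{i}", "MZ", [1.0, 1.0]) for i in range(5)]
    pairs += [make_pair(f"d{i}", "DZ", [1.0, 1.0]) for i in range(5)]
    ds = TwinDataset(pairs, n_waves=1)
    with pytest.raises(Exception, match="zero variance"):
        fit_univariate(ds, "AE", compute_ci=False)


# ---------------------------------------------------------------------------
# saturated model and nesting
# ---------------------------------------------------------------------------

def test_saturated_recovers_sample_moments(small_dataset):
    """Covariate-free MVN ML equals per-group sample moments (n denominator)."""
    sat = fit_saturated_univariate(small_dataset)
    y = small_dataset.phenotype_array()[:, :, 0]
    mz = small_dataset.zygosity_array()
    for zyg, mask in (("MZ", mz), ("DZ", ~mz)):
        g = sat.group_stats[zyg]
        sub = y[mask]
        assert g["mean_twin1"] == pytest.approx(sub[:, 0].mean(), abs=1e-4)
        assert g["mean_twin2"] == pytest.approx(sub[:, 1].mean(), abs=1e-4)
        assert g["var_twin1"] == pytest.approx(sub[:, 0].var(), rel=1e-3)
        assert g["cov_within"] == pytest.approx(
            np.mean(sub[:, 0] * sub[:, 1]) - sub[:, 0].mean() * sub[:, 1].mean(),
            abs=1e-3)


def test_likelihood_nesting_chain(ae_dataset):
    sat = fit_saturated_univariate(ae_dataset)
    fits = {m: fit_univariate(ae_dataset, m, compute_ci=False)
            for m in ("ACE", "AE", "E")}
    assert sat.minus2lnL <= fits["ACE"].minus2lnL + 1e-6
    assert fits["ACE"].minus2lnL <= fits["AE"].minus2lnL + 1e-6
    assert fits["AE"].minus2lnL <= fits["E"].minus2lnL + 1e-6


# ---------------------------------------------------------------------------
# LRT and model selection
# ---------------------------------------------------------------------------

class _Stub:
    def __init__(self, label, m2ll, k):
        self.label, self.minus2lnL, self.n_params = label, m2ll, k


def test_lrt_identical_likelihoods_give_p_one():
    stat, df, p = likelihood_ratio_test(_Stub("ACE", 100.0, 5),
                                        _Stub("AE", 100.0, 4))
    assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)


def test_lrt_chi_square_quantile():
    stat, df, p = likelihood_ratio_test(_Stub("ACE", 100.0, 5),
                                        _Stub("AE", 103.841, 4))
    assert p == pytest.approx(0.05, abs=5e-4)
    assert p == pytest.approx(stats.chi2.sf(3.841, 1))


def test_lrt_rejects_bad_nesting():
    with pytest.raises(ValueError):
        likelihood_ratio_test(_Stub("AE", 90.0, 4), _Stub("ACE", 95.0, 5))
    with pytest.raises(ValueError):  # CE not nested in ADE
        likelihood_ratio_test(_Stub("ADE", 90.0, 5), _Stub("CE", 95.0, 4))


def test_select_model_prefers_ae_on_ae_data():
    spec = UnivariateSimSpec(n_mz=2500, n_dz=2500, components="AE",
                             a2=0.6, e2=0.4, seed=9)
    ds = simulate_univariate_twins(spec)
    result = select_model(ds, compute_ci=False)
    assert result.selected == "AE"
    assert result.table.selected.sum() == 1
    assert set(result.table.model) >= {"saturated", "ACE", "ADE", "AE", "E"}
    # statistics are consistent with the dumped likelihoods
    sat_row = result.table[result.table.model == "saturated"].iloc[0]
    ae_row = result.table[result.table.model == "AE"].iloc[0]
    assert ae_row.aic == pytest.approx(ae_row.minus2lnL + 2 * ae_row.n_params)
    assert sat_row.minus2lnL <= ae_row.minus2lnL


# ---------------------------------------------------------------------------
# profile confidence intervals
# ---------------------------------------------------------------------------

def test_profile_ci_brackets_estimate_and_shrinks_with_n():
    widths = []
    for n in (500, 2000):
        spec = UnivariateSimSpec(n_mz=n, n_dz=n, components="AE",
                                 a2=0.5, e2=0.5, seed=55)
        fit = fit_univariate(simulate_univariate_twins(spec), "AE",
                             compute_ci=False)
        lo, hi = profile_ci(fit, "h2")
        assert lo < fit.h2 < hi
        widths.append(hi - lo)
    assert widths[1] < widths[0]


def test_profile_ci_clips_at_zero_for_null_h2():
    spec = UnivariateSimSpec(n_mz=800, n_dz=800, components="E", e2=1.0,
                             seed=3)
    fit = fit_univariate(simulate_univariate_twins(spec), "AE",
                         compute_ci=False)
    lo, hi = profile_ci(fit, "h2")
    assert lo == 0.0
    assert hi < 0.2


def test_profile_ci_close_to_delta_in_quadratic_regime():
    from twinclocks.univariate import _delta_ci

    spec = UnivariateSimSpec(n_mz=3000, n_dz=3000, components="AE",
                             a2=0.5, e2=0.5, seed=88)
    fit = fit_univariate(simulate_univariate_twins(spec), "AE",
                         compute_ci=False)
    plo, phi = profile_ci(fit, "h2")
    dlo, dhi = _delta_ci(fit, "h2", 0.95)
    p_width, d_width = phi - plo, dhi - dlo
    assert abs(p_width - d_width) / d_width < 0.10
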