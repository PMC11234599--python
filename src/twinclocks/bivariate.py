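"""Longitudinal bivariate Cholesky twin models (same trait at two waves).

The trait measured at baseline and follow-up is decomposed per latent source
K in {A, C or D, E} through a lower-triangular 2x2 path matrix

    L_K = [[k11, 0], [k21, k22]]

so that K contributes k11^2 to the baseline variance, k21^2 + k22^2 to the
follow-up variance and k11*k21 to the cross-wave covariance.  The within-twin
2x2 covariance block is the sum of L_K L_K' over included components; the
cross-twin block scales the A block by 1 (MZ) or 0.5 (DZ), the D block by 1
or 0.25 and the C block by 1 for both; E is unshared.

Derived summaries follow the standard bivariate twin algebra: wave-specific
heritabilities, cross-time component correlations (Ra, Rc/Rd, Re), the
phenotypic cross-wave correlation Rph and its decomposition into component
contributions (Pa, Pc, Pe), and model-implied cross-twin cross-trait (CTCT)
correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .twin_data import IntegrityError, TwinDataset, Zygosity
from .univariate import COMPONENT_SETS, LOG_2PI, _BIG

__all__ = [
    "CholeskyParams",
    "BivariateFit",
    "BivariateDerived",
    "SaturatedFit4",
    "CTCTResult",
    "expected_moments_bivariate",
    "neg2_loglik_bivariate",
    "fit_bivariate",
    "fit_saturated_bivariate",
    "derive_bivariate_statistics",
    "ctct_observed",
    "profile_ci_bivariate",
    "select_model_bivariate",
]

#: cross-twin scaling of each component block (MZ, DZ)
_RHO = {"a": (1.0, 0.5), "c": (1.0, 1.0), "d": (1.0, 0.25), "e": (0.0, 0.0)}


@dataclass
class CholeskyParams:
    """Lower-triangular path matrices per component plus the means model.

    Each component entry is ``(k11, k21, k22)``; absent components are None.
    Diagonal entries follow the k11, k22 >= 0 sign convention; k21 is free.
    E is always present with strictly positive diagonal.
    """

    a: tuple[float, float, float] | None = None
    c: tuple[float, float, float] | None = None
    d: tuple[float, float, float] | None = None
    e: tuple[float, float, float] = (1.0, 0.0, 1.0)
    mu: tuple[float, float] = (0.0, 0.0)
    beta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.c is not None and self.d is not None:
            raise ValueError("C and D cannot both be included (not identifiable)")
        if self.e[0] <= 0 or self.e[2] <= 0:
            raise ValueError("E diagonal paths e11, e22 must be strictly positive")

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(k for k in ("a", "c", "d", "e")
                     if getattr(self, k) is not None)

    def matrix(self, comp: str) -> np.ndarray:
        paths = getattr(self, comp)
        if paths is None:
            return np.zeros((2, 2))
        k11, k21, k22 = paths
        return np.array([[k11, 0.0], [k21, k22]])

    def block(self, comp: str) -> np.ndarray:
        """Covariance contribution L_K L_K' of one component."""
        L = self.matrix(comp)
        return L @ L.T


def _sigma4(params: CholeskyParams, zygosity: Zygosity) -> np.ndarray:
    within = np.zeros((2, 2))
    cross = np.zeros((2, 2))
    rho_idx = 0 if zygosity is Zygosity.MZ else 1
    for comp in ("a", "c", "d", "e"):
        if getattr(params, comp) is None:
            continue
        S = params.block(comp)
        within += S
        cross += _RHO[comp][rho_idx] * S
    sigma = np.empty((4, 4))
    sigma[:2, :2] = within
    sigma[2:, 2:] = within
    sigma[:2, 2:] = cross
    sigma[2:, :2] = cross.T
    return sigma


def expected_moments_bivariate(
    params: CholeskyParams,
    zygosity: Zygosity | str,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied 4-vector mean and 4x4 covariance for one pair.

    Variable order is (twin1-wave1, twin1-wave2, twin2-wave1, twin2-wave2).
    ``covariates`` has shape (2, 2, p): twin, wave, covariate, ordered like
    ``params.beta``.
    """
    zyg = Zygosity.parse(zygosity)
    sigma = _sigma4(params, zyg)
    mu1, mu2 = params.mu
    mean = np.array([mu1, mu2, mu1, mu2], dtype=float)
    if params.beta:
        if covariates is None:
            raise ValueError("params include covariate effects but no covariates given")
        bvec = np.array(list(params.beta.values()))
        X = np.asarray(covariates, dtype=float).reshape(2, 2, -1)
        shift = X @ bvec  # (twin, wave)
        mean = mean + shift.reshape(-1)[[0, 1, 2, 3]]
    return mean, sigma


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class _BiData:
    """Two-wave dataset grouped by zygosity and missingness pattern."""

    def __init__(self, dataset: TwinDataset, covariate_names: Sequence[str]):
        if dataset.n_waves != 2:
            raise IntegrityError("bivariate models require two-wave data")
        self.covariate_names = list(covariate_names)
        pheno = dataset.phenotype_array()            # (n, 2, 2)
        y = pheno.reshape(len(pheno), 4)             # (t1w1, t1w2, t2w1, t2w2)
        p = len(self.covariate_names)
        if p:
            X = dataset.covariate_tensor(self.covariate_names).reshape(
                len(pheno), 4, p)
            if (np.isnan(X) & ~np.isnan(y)[:, :, None]).any():
                raise IntegrityError(
                    "covariates missing for an observed measurement")
        else:
            X = np.zeros((len(pheno), 4, 0))
        mz = dataset.zygosity_array()
        self.groups: list[tuple[Zygosity, np.ndarray, np.ndarray, np.ndarray]] = []
        self.n_pairs_used = 0
        for zyg, zmask in ((Zygosity.MZ, mz), (Zygosity.DZ, ~mz)):
            yz, Xz = y[zmask], X[zmask]
            obs = ~np.isnan(yz)
            keep = obs.any(axis=1)
            yz, Xz, obs = yz[keep], Xz[keep], obs[keep]
            self.n_pairs_used += int(keep.sum())
            if not len(yz):
                continue
            codes = obs @ (1 << np.arange(4))
            for code in np.unique(codes):
                sel = codes == code
                idx = np.flatnonzero(obs[sel][0])
                self.groups.append((zyg, idx,
                                    yz[sel][:, idx], Xz[sel][:, idx, :]))
        if self.n_pairs_used == 0:
            raise IntegrityError("no pairs with observed phenotypes")

    def neg2ll(self, sigma_by_zyg, mu4_by_zyg, beta: np.ndarray) -> float:
        total = 0.0
        for zyg, idx, y, X in self.groups:
            sigma = sigma_by_zyg[zyg][np.ix_(idx, idx)]
            try:
                L = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                return _BIG
            logdet = 2.0 * float(np.log(np.diag(L)).sum())
            mean = mu4_by_zyg[zyg][idx]
            d = y - mean
            if beta.size:
                d = d - X @ beta
            z = solve_triangular(L, d.T, lower=True)
            total += len(y) * (len(idx) * LOG_2PI + logdet) + float((z * z).sum())
        return total


def neg2_loglik_bivariate(params: CholeskyParams, dataset: TwinDataset) -> float:
    """-2 log-likelihood under a bivariate Cholesky model (FIML)."""
    data = _BiData(dataset, list(params.beta))
    sigma = {z: _sigma4(params, z) for z in (Zygosity.MZ, Zygosity.DZ)}
    mu1, mu2 = params.mu
    mu4 = np.array([mu1, mu2, mu1, mu2])
    mu4_by_zyg = {Zygosity.MZ: mu4, Zygosity.DZ: mu4}
    beta = np.array(list(params.beta.values()), dtype=float)
    return data.neg2ll(sigma, mu4_by_zyg, beta)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class BivariateFit:
    params: CholeskyParams
    spec: str
    covariate_names: list[str]
    minus2lnL: float
    n_params: int
    aic: float
    converged: bool
    warnings: list[str] = field(default_factory=list)
    _data: "_BiData | None" = field(default=None, repr=False, compare=False)

    @property
    def label(self) -> str:
        return self.spec

    def to_dict(self) -> dict:
        return {
            "model": self.spec,
            "covariates": self.covariate_names,
            "paths": {k: list(getattr(self.params, k))
                      for k in ("a", "c", "d", "e")
                      if getattr(self.params, k) is not None},
            "mu": list(self.params.mu),
            "beta": self.params.beta,
            "minus2lnL": self.minus2lnL,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "warnings": self.warnings,
        }


def _theta_to_chol(theta: np.ndarray, comps: tuple[str, ...],
                   covariate_names: Sequence[str]) -> CholeskyParams:
    kw: dict = {}
    i = 0
    for comp in comps:
        kw[comp] = (float(theta[i]), float(theta[i + 1]), float(theta[i + 2]))
        i += 3
    mu = (float(theta[i]), float(theta[i + 1]))
    beta = {n: float(b) for n, b in zip(covariate_names, theta[i + 2:])}
    for comp in "acd":
        kw.setdefault(comp, None)
    return CholeskyParams(mu=mu, beta=beta, **kw)


def _canonical_sign(paths: tuple[float, float, float]) -> tuple[float, float, float]:
    """Flip latent-factor signs so the diagonal entries are nonnegative."""
    k11, k21, k22 = paths
    if k11 < 0:
        k11, k21 = -k11, -k21
    return (k11, k21, abs(k22))


def _objective_bi(theta, comps, data: "_BiData"):
    i = 0
    blocks = {}
    for comp in comps:
        k11, k21, k22 = theta[i], theta[i + 1], theta[i + 2]
        L = np.array([[k11, 0.0], [k21, k22]])
        blocks[comp] = L @ L.T
        i += 3
    if comps[-1] == "e" and (theta[i - 3] ** 2 < 1e-10 or theta[i - 1] ** 2 < 1e-10):
        return _BIG
    sigma_by_zyg = {}
    for j, zyg in enumerate((Zygosity.MZ, Zygosity.DZ)):
        within = sum(blocks.values())
        cross = sum(_RHO[c][j] * S for c, S in blocks.items())
        sigma = np.empty((4, 4))
        sigma[:2, :2] = within
        sigma[2:, 2:] = within
        sigma[:2, 2:] = cross
        sigma[2:, :2] = cross.T
        sigma_by_zyg[zyg] = sigma
    mu4 = np.array([theta[i], theta[i + 1], theta[i], theta[i + 1]])
    mu4_by_zyg = {Zygosity.MZ: mu4, Zygosity.DZ: mu4}
    return data.neg2ll(sigma_by_zyg, mu4_by_zyg, theta[i + 2:])


def _psd_chol_paths(S: np.ndarray) -> tuple[float, float, float]:
    """Cholesky paths of a (possibly indefinite) 2x2 moment estimate."""
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    floor = max(1e-4, 1e-3 * max(np.trace(S), 1.0))
    w = np.clip(w, floor, None)
    S = V @ np.diag(w) @ V.T
    L = np.linalg.cholesky(S)
    return (float(L[0, 0]), float(L[1, 0]), float(L[1, 1]))


def _moment_blocks(data: "_BiData") -> tuple[np.ndarray, dict, np.ndarray]:
    """Complete-case within-twin covariance, cross-twin covariances, means."""
    full = {z: [] for z in (Zygosity.MZ, Zygosity.DZ)}
    for zyg, idx, y, _X in data.groups:
        if len(idx) == 4:
            full[zyg].append(y)
    all_rows = np.concatenate([v[0] for v in full.values() if v]) \
        if any(full.values()) else np.zeros((0, 4))
    if len(all_rows) < 4:
        raise IntegrityError("too few complete pairs for moment start values")
    mu = 0.5 * (all_rows[:, :2] + all_rows[:, 2:]).mean(axis=0)
    within = np.zeros((2, 2))
    n = 0
    cross = {}
    for zyg, rows_list in full.items():
        rows = rows_list[0] if rows_list else np.zeros((0, 4))
        d1 = rows[:, :2] - mu
        d2 = rows[:, 2:] - mu
        if len(rows):
            within += d1.T @ d1 + d2.T @ d2
            n += 2 * len(rows)
            cz = (d1.T @ d2 + d2.T @ d1) / (2 * len(rows))
            cross[zyg] = 0.5 * (cz + cz.T)
        else:
            cross[zyg] = np.zeros((2, 2))
    within /= max(n, 1)
    return within, cross, mu


def _start_vectors_bi(comps, data: "_BiData", n_starts: int) -> list[np.ndarray]:
    within, cross, mu = _moment_blocks(data)
    c_mz, c_dz = cross[Zygosity.MZ], cross[Zygosity.DZ]
    S: dict[str, np.ndarray] = {}
    if comps == ("a", "c", "e"):
        S["a"] = 2 * (c_mz - c_dz)
        S["c"] = 2 * c_dz - c_mz
    elif comps == ("a", "d", "e"):
        S["a"] = 4 * c_dz - c_mz
        S["d"] = 2 * c_mz - 4 * c_dz
    elif comps == ("a", "e"):
        S["a"] = c_mz
    elif comps == ("c", "e"):
        S["c"] = c_mz
    S["e"] = within - sum(S.values()) if S else within
    base = []
    for comp in comps:
        base.extend(_psd_chol_paths(S[comp]))
    base += [float(mu[0]), float(mu[1])]
    base += [0.0] * len(data.covariate_names)
    base = np.array(base)
    rng = np.random.default_rng(20240710)
    scale = np.maximum(np.abs(base), 0.2 * math.sqrt(max(np.trace(within), 1e-6)))
    starts = [base]
    for _ in range(n_starts - 1):
        starts.append(base + rng.normal(0, 0.3, base.shape) * scale)
    return starts


def _minimize_multistart_bi(fun, starts):
    best = None
    for x0 in starts:
        res = optimize.minimize(fun, x0, method="L-BFGS-B",
                                options={"maxiter": 3000, "ftol": 1e-12,
                                         "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    polish = optimize.minimize(fun, best.x, method="Nelder-Mead",
                               options={"xatol": 1e-9, "fatol": 1e-10,
                                        "maxiter": 8000, "maxfev": 12000})
    if polish.fun < best.fun:
        best = polish
    return best


def fit_bivariate(
    dataset: TwinDataset,
    spec: str = "ACE",
    covariate_names: Sequence[str] = (),
    n_starts: int = 5,
) -> BivariateFit:
    """ML fit of a bivariate Cholesky twin model (four-variate normal FIML)."""
    if spec not in COMPONENT_SETS:
        raise ValueError(f"spec must be one of {sorted(COMPONENT_SETS)}")
    comps = COMPONENT_SETS[spec]
    dataset.require_both_zygosities()
    data = _BiData(dataset, covariate_names)
    starts = _start_vectors_bi(comps, data, n_starts)
    fun = lambda th: _objective_bi(th, comps, data)
    best = _minimize_multistart_bi(fun, starts)

    theta = best.x.copy()
    kw: dict = {}
    i = 0
    for comp in comps:
        kw[comp] = _canonical_sign((theta[i], theta[i + 1], theta[i + 2]))
        i += 3
    for comp in "acd":
        kw.setdefault(comp, None)
    # keep E strictly positive-definite for the CholeskyParams invariant
    e = kw["e"]
    kw["e"] = (max(e[0], 1e-8), e[1], max(e[2], 1e-8))
    params = CholeskyParams(
        mu=(float(theta[i]), float(theta[i + 1])),
        beta={n: float(b) for n, b in zip(covariate_names, theta[i + 2:])},
        **kw,
    )
    grad = optimize.approx_fprime(best.x, fun, 1e-6)
    grad_norm = float(np.linalg.norm(grad))
    converged = bool(np.isfinite(best.fun) and best.fun < _BIG / 2
                     and grad_norm < 1e-2 * max(1.0, abs(best.fun)))
    n_params = 3 * len(comps) + 2 + len(covariate_names)
    fit = BivariateFit(
        params=params,
        spec=spec,
        covariate_names=list(covariate_names),
        minus2lnL=float(best.fun),
        n_params=n_params,
        aic=float(best.fun) + 2 * n_params,
        converged=converged,
        _data=data,
    )
    if not converged:
        fit.warnings.append(
            f"optimizer did not meet convergence criteria (gradient norm {grad_norm:.3g})"
        )
    return fit


@dataclass
class SaturatedFit4:
    """Per-zygosity free 4-vector means and 4x4 covariances."""

    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    beta: dict[str, float]
    minus2lnL: float
    n_params: int
    converged: bool

    label: str = "saturated"

    @property
    def aic(self) -> float:
        return self.minus2lnL + 2 * self.n_params


_TRIL = np.tril_indices(4)


def _sat4_objective(theta: np.ndarray, data: "_BiData") -> float:
    p = len(data.covariate_names)
    beta = theta[28:28 + p]
    mu4_by_zyg, sigma_by_zyg = {}, {}
    for j, zyg in enumerate((Zygosity.MZ, Zygosity.DZ)):
        off = 14 * j
        mu4_by_zyg[zyg] = theta[off: off + 4]
        L = np.zeros((4, 4))
        L[_TRIL] = theta[off + 4: off + 14]
        diag = np.exp(np.clip(np.diag(L), -20, 20))
        np.fill_diagonal(L, diag)
        sigma_by_zyg[zyg] = L @ L.T
    return data.neg2ll(sigma_by_zyg, mu4_by_zyg, beta)


def fit_saturated_bivariate(
    dataset: TwinDataset, covariate_names: Sequence[str] = ()
) -> SaturatedFit4:
    """Saturated two-wave model; -2lnL lower bound for all Cholesky fits."""
    dataset.require_both_zygosities()
    data = _BiData(dataset, list(covariate_names))
    theta0 = []
    for zyg in (Zygosity.MZ, Zygosity.DZ):
        rows = [y for z, idx, y, _ in data.groups
                if z is zyg and len(idx) == 4]
        rows = rows[0] if rows else np.zeros((0, 4))
        if len(rows) >= 5:
            mu = rows.mean(axis=0)
            S = np.cov(rows.T)
        else:
            mu = np.zeros(4)
            S = np.eye(4)
        w, V = np.linalg.eigh(0.5 * (S + S.T))
        w = np.clip(w, 1e-3 * max(np.trace(S), 1.0), None)
        L = np.linalg.cholesky(V @ np.diag(w) @ V.T)
        L = L.copy()
        d = np.diag(L).copy()
        entries = L[_TRIL]
        # store log of the diagonal entries
        diag_pos = [k for k, (r, c) in enumerate(zip(*_TRIL)) if r == c]
        entries = entries.copy()
        entries[diag_pos] = np.log(d)
        theta0 += list(mu) + list(entries)
    theta0 = np.array(theta0 + [0.0] * len(covariate_names))
    fun = lambda th: _sat4_objective(th, data)
    best = _minimize_multistart_bi(fun, [theta0])
    means, covs = {}, {}
    for j, zyg in enumerate((Zygosity.MZ, Zygosity.DZ)):
        off = 14 * j
        means[zyg.value] = best.x[off: off + 4].copy()
        L = np.zeros((4, 4))
        L[_TRIL] = best.x[off + 4: off + 14]
        np.fill_diagonal(L, np.exp(np.clip(np.diag(L), -20, 20)))
        covs[zyg.value] = L @ L.T
    n_params = 28 + len(covariate_names)
    return SaturatedFit4(
        means=means,
        covariances=covs,
        beta={n: float(b) for n, b in zip(covariate_names, best.x[28:])},
        minus2lnL=float(best.fun),
        n_params=n_params,
        converged=bool(np.isfinite(best.fun) and best.fun < _BIG / 2),
    )


# ---------------------------------------------------------------------------
# derived statistics
# ---------------------------------------------------------------------------

@dataclass
class BivariateDerived:
    """Summaries derived from fitted Cholesky paths.

    ``correlations`` holds the cross-time correlation of each component
    (keys 'a', 'c', 'd', 'e') plus 'ph' for the phenotypic cross-wave
    correlation; ``proportions`` holds each component's share of the
    phenotypic cross-wave covariance.
    """

    variance_wave1: dict[str, float]
    shared_wave2: dict[str, float]      # k21^2 per component
    new_wave2: dict[str, float]         # k22^2 per component
    cross_cov: dict[str, float]         # k11 * k21 per component
    V1: float
    V2: float
    h2_baseline: float
    h2_followup: float
    correlations: dict[str, float]
    proportions: dict[str, float]
    ctct_implied: dict[str, float]
    flags: list[str] = field(default_factory=list)

    # convenience aliases used in reports
    @property
    def ra(self) -> float: return self.correlations.get("a", float("nan"))

    @property
    def rc(self) -> float: return self.correlations.get("c", float("nan"))

    @property
    def re(self) -> float: return self.correlations.get("e", float("nan"))

    @property
    def rph(self) -> float: return self.correlations["ph"]

    @property
    def pa(self) -> float: return self.proportions.get("a", float("nan"))

    @property
    def pe(self) -> float: return self.proportions.get("e", float("nan"))


def derive_bivariate_statistics(params: CholeskyParams) -> BivariateDerived:
    """Wave heritabilities, Ra/Rc/Re, Rph, Pa/Pc/Pe and implied CTCT."""
    comps = params.components
    v1, shared, new, cross = {}, {}, {}, {}
    flags: list[str] = []
    for comp in comps:
        k11, k21, k22 = getattr(params, comp)
        v1[comp] = k11 ** 2
        shared[comp] = k21 ** 2
        new[comp] = k22 ** 2
        cross[comp] = k11 * k21
    V1 = sum(v1.values())
    V2 = sum(shared.values()) + sum(new.values())
    if V1 <= 0 or V2 <= 0:
        raise ValueError("total variance is zero at one of the waves")

    h2_1 = (v1.get("a", 0.0) + v1.get("d", 0.0)) / V1
    h2_2 = (shared.get("a", 0.0) + new.get("a", 0.0)
            + shared.get("d", 0.0) + new.get("d", 0.0)) / V2

    correlations: dict[str, float] = {}
    for comp in comps:
        va, vb = v1[comp], shared[comp] + new[comp]
        if va <= 1e-12 or vb <= 1e-12:
            correlations[comp] = 0.0
            flags.append(f"{comp}: zero variance at one wave; correlation set to 0")
        else:
            correlations[comp] = cross[comp] / math.sqrt(va * vb)
    total_cross = sum(cross.values())
    correlations["ph"] = total_cross / math.sqrt(V1 * V2)
    proportions = {}
    for comp in comps:
        proportions[comp] = (cross[comp] / total_cross
                             if abs(total_cross) > 1e-12 else float("nan"))

    genetic_cross = cross.get("a", 0.0)
    shared_env_cross = cross.get("c", 0.0)
    dom_cross = cross.get("d", 0.0)
    denom = math.sqrt(V1 * V2)
    ctct = {
        "MZ": (genetic_cross + shared_env_cross + dom_cross) / denom,
        "DZ": (0.5 * genetic_cross + shared_env_cross + 0.25 * dom_cross) / denom,
    }
    return BivariateDerived(
        variance_wave1=v1, shared_wave2=shared, new_wave2=new, cross_cov=cross,
        V1=V1, V2=V2, h2_baseline=h2_1, h2_followup=h2_2,
        correlations=correlations, proportions=proportions,
        ctct_implied=ctct, flags=flags,
    )


# ---------------------------------------------------------------------------
# observed CTCT correlations
# ---------------------------------------------------------------------------

@dataclass
class CTCTResult:
    zygosity: Zygosity
    r: float
    ci: tuple[float, float]
    n_pairs: int


def ctct_observed(
    dataset: TwinDataset,
    zygosity: Zygosity | str,
    level: float = 0.95,
) -> CTCTResult:
    """Observed cross-twin cross-trait correlation for one zygosity group.

    Each pair is double-entered: (twin1 baseline, twin2 follow-up) and
    (twin2 baseline, twin1 follow-up).  The Fisher-z confidence interval
    conservatively uses the number of contributing pairs, not entries.
    """
    zyg = Zygosity.parse(zygosity)
    if dataset.n_waves != 2:
        raise IntegrityError("CTCT correlations require two-wave data")
    pheno = dataset.phenotype_array()
    mask = dataset.zygosity_array() if zyg is Zygosity.MZ \
        else ~dataset.zygosity_array()
    sub = pheno[mask]
    xs, ys, pair_ids = [], [], set()
    for i, p in enumerate(sub):
        for t in (0, 1):
            x, y = p[t, 0], p[1 - t, 1]
            if not (np.isnan(x) or np.isnan(y)):
                xs.append(x)
                ys.append(y)
                pair_ids.add(i)
    n_pairs = len(pair_ids)
    if n_pairs < 3:
        raise IntegrityError(
            f"CTCT needs at least 3 {zyg.value} pairs with usable entries; "
            f"got {n_pairs}"
        )
    r = float(np.corrcoef(xs, ys)[0, 1])
    if n_pairs > 3 and abs(r) < 1:
        z = math.atanh(r)
        se = 1.0 / math.sqrt(n_pairs - 3)
        zc = stats.norm.ppf(0.5 + level / 2)
        ci = (math.tanh(z - zc * se), math.tanh(z + zc * se))
    else:
        ci = (float("nan"), float("nan"))
    return CTCTResult(zygosity=zyg, r=r, ci=ci, n_pairs=n_pairs)


# ---------------------------------------------------------------------------
# profile CIs for derived correlations
# ---------------------------------------------------------------------------

def _profile_objective_corr(t: float, fit: BivariateFit, comp: str) -> float:
    """min -2lnL with the cross-time correlation of one component fixed at t."""
    comps = COMPONENT_SETS[fit.spec]
    data = fit._data
    others = [c for c in comps if c != comp]
    p = len(fit.covariate_names)

    def fun(psi):
        # psi: [log v1_comp, log v2_comp] + 3 paths per other comp + mu + beta
        v1 = math.exp(min(psi[0], 30))
        v2 = math.exp(min(psi[1], 30))
        k11 = math.sqrt(v1)
        k21 = t * math.sqrt(v2)
        k22 = math.sqrt(max(v2 * (1 - t * t), 0.0))
        theta = []
        j = 2
        for c in comps:
            if c == comp:
                theta += [k11, k21, k22]
            else:
                theta += list(psi[j: j + 3])
                j += 3
        theta += list(psi[j:])
        return _objective_bi(np.array(theta), comps, data)

    k11, k21, k22 = getattr(fit.params, comp)
    v1 = max(k11 ** 2, 1e-6)
    v2 = max(k21 ** 2 + k22 ** 2, 1e-6)
    psi0 = [math.log(v1), math.log(v2)]
    for c in others:
        psi0 += list(getattr(fit.params, c))
    psi0 += list(fit.params.mu)
    psi0 += [fit.params.beta[n] for n in fit.covariate_names]
    res = optimize.minimize(fun, np.array(psi0), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-9,
                                     "maxiter": 6000, "maxfev": 9000})
    return float(res.fun)


def profile_ci_bivariate(
    fit: BivariateFit,
    quantity: str = "ra",
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood CI for Ra/Rc/Rd/Re, clipped to [-1, 1]."""
    comp = {"ra": "a", "rc": "c", "rd": "d", "re": "e"}.get(quantity)
    if comp is None:
        raise ValueError(f"unknown quantity {quantity!r}")
    if getattr(fit.params, comp) is None:
        raise ValueError(f"component {comp!r} absent from the {fit.spec} model")
    if fit._data is None:
        raise ValueError("fit does not carry its data; refit with fit_bivariate")
    derived = derive_bivariate_statistics(fit.params)
    q_hat = derived.correlations[comp]
    cutoff = fit.minus2lnL + stats.chi2.ppf(level, 1)

    def f(t):
        return _profile_objective_corr(t, fit, comp) - cutoff

    eps = 1e-5
    lo_edge, hi_edge = -1.0 + eps, 1.0 - eps
    q0 = float(np.clip(q_hat, lo_edge + eps, hi_edge - eps))
    lower = -1.0 if f(lo_edge) <= 0 else float(
        optimize.brentq(f, lo_edge, q0, xtol=1e-4))
    upper = 1.0 if f(hi_edge) <= 0 else float(
        optimize.brentq(f, q0, hi_edge, xtol=1e-4))
    return (lower, upper)


# ---------------------------------------------------------------------------
# model selection (reuses the univariate lattice against the 4-variate saturated)
# ---------------------------------------------------------------------------

def select_model_bivariate(
    dataset: TwinDataset,
    covariate_names: Sequence[str] = (),
    alpha: float = 0.05,
):
    from .univariate import ModelComparisonTable, likelihood_ratio_test, _SUBMODELS, _PARENTS

    covs = list(covariate_names)
    sat = fit_saturated_bivariate(dataset, covs)
    fits: dict[str, object] = {"saturated": sat}
    for label in ("ACE", "ADE"):
        fits[label] = fit_bivariate(dataset, label, covs)
    family = "ACE" if fits["ACE"].aic <= fits["ADE"].aic else "ADE"
    for label in _SUBMODELS[family]:
        if label not in fits:
            fits[label] = fit_bivariate(dataset, label, covs)

    rows = [{"model": "saturated", "minus2lnL": sat.minus2lnL,
             "n_params": sat.n_params, "lrt_stat": float("nan"), "df": 0,
             "p_value": float("nan"), "aic": sat.aic, "selected": False}]
    admissible = []
    for label in ("ACE", "ADE"):
        stat, df, p = likelihood_ratio_test(sat, fits[label])
        rows.append({"model": label, "minus2lnL": fits[label].minus2lnL,
                     "n_params": fits[label].n_params, "lrt_stat": stat,
                     "df": df, "p_value": p, "aic": fits[label].aic,
                     "selected": False})
        if label == family and p > alpha:
            admissible.append(label)
    for label in _SUBMODELS[family]:
        parent = _PARENTS[label] or family
        fit = fits[label]
        stat, df, p = likelihood_ratio_test(fits[parent], fit)
        _, _, p_sat = likelihood_ratio_test(sat, fit)
        rows.append({"model": label, "minus2lnL": fit.minus2lnL,
                     "n_params": fit.n_params, "lrt_stat": stat, "df": df,
                     "p_value": p, "aic": fit.aic, "selected": False})
        if p > alpha and p_sat > alpha:
            admissible.append(label)
    warning = None
    if admissible:
        selected = min(admissible, key=lambda l: (fits[l].aic, fits[l].n_params))
    else:
        selected = family
        warning = ("no candidate passed both likelihood-ratio tests; the full "
                   f"{family} model is reported")
    table = pd.DataFrame(rows)
    table.loc[table.model == selected, "selected"] = True
    return ModelComparisonTable(table=table, selected=selected, fits=fits,
                                warning=warning)
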