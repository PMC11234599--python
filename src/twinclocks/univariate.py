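"""Univariate twin variance-component models (ACE, ADE, AE, CE, E).

The phenotypic variance of a trait measured in MZ and DZ twin pairs is
decomposed into additive genetic (A), common environmental (C) *or*
dominance genetic (D), and unique environmental (E) latent sources.  With
twins reared together C and D are not jointly identifiable, so models are
drawn from the ACE family (ACE, AE, CE, E) or the ADE family (ADE, AE, E).

Each latent source loads on the phenotype through a path coefficient
(a, c, d, e); squared paths are variance components.  Expected within-pair
covariance follows genetic sharing: MZ twins share A and D fully, DZ twins
share A at 0.5 and D at 0.25, C is shared fully by both, E is unshared.
Pairs are independent, so the likelihood is a product of bivariate-normal
pair densities; pairs with one missing twin contribute their marginal
univariate density (full-information maximum likelihood).

Heritability h² is a²/V in the ACE family and (a²+d²)/V in the ADE family.
Confidence intervals are profile-likelihood based (chi-square(1) cutoff),
with a delta-method fallback that is flagged in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .twin_data import IntegrityError, TwinDataset, Zygosity

__all__ = [
    "COMPONENT_SETS",
    "UnivariateModelSpec",
    "UnivariateParams",
    "UnivariateFit",
    "SaturatedFit",
    "ModelComparisonTable",
    "expected_moments_univariate",
    "neg2_loglik_univariate",
    "fit_univariate",
    "fit_saturated_univariate",
    "likelihood_ratio_test",
    "select_model",
    "profile_ci",
]

LOG_2PI = math.log(2.0 * math.pi)

COMPONENT_SETS: dict[str, tuple[str, ...]] = {
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "E": ("e",),
}

#: cross-twin sharing of each latent source (MZ, DZ)
SHARING = {"a": (1.0, 0.5), "c": (1.0, 1.0), "d": (1.0, 0.25), "e": (0.0, 0.0)}

_BIG = 1e12  # objective value returned for non-positive-definite moments


@dataclass
class UnivariateModelSpec:
    components: str = "ACE"
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.components not in COMPONENT_SETS:
            raise ValueError(
                f"components must be one of {sorted(COMPONENT_SETS)}, "
                f"got {self.components!r}"
            )

    @property
    def paths(self) -> tuple[str, ...]:
        return COMPONENT_SETS[self.components]

    @property
    def family(self) -> str:
        """'ADE' when D is present, else 'ACE'."""
        return "ADE" if "d" in self.paths else "ACE"


@dataclass
class UnivariateParams:
    """Path coefficients plus the means model.

    Absent components have a path fixed at 0; squared paths are the variance
    components.  Sign of a path is not identified, so fitted values are
    reported as absolute values.
    """

    a: float = 0.0
    c: float = 0.0
    d: float = 0.0
    e: float = 1.0
    mu: float = 0.0
    beta: dict[str, float] = field(default_factory=dict)

    @property
    def variance_components(self) -> dict[str, float]:
        return {"a2": self.a ** 2, "c2": self.c ** 2,
                "d2": self.d ** 2, "e2": self.e ** 2}

    @property
    def total_variance(self) -> float:
        return self.a ** 2 + self.c ** 2 + self.d ** 2 + self.e ** 2


def expected_moments_univariate(
    params: UnivariateParams,
    zygosity: Zygosity | str,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean (length 2) and 2x2 covariance for one pair.

    ``covariates`` is a (2, p) array ordered like ``params.beta``; omit it
    for a covariate-free means model.
    """
    zyg = Zygosity.parse(zygosity)
    a2, c2, d2, e2 = (params.a ** 2, params.c ** 2, params.d ** 2, params.e ** 2)
    total = a2 + c2 + d2 + e2
    if zyg is Zygosity.MZ:
        off = a2 + c2 + d2
    else:
        off = 0.5 * a2 + c2 + 0.25 * d2
    cov = np.array([[total, off], [off, total]])
    mean = np.full(2, params.mu)
    if params.beta:
        bvec = np.array(list(params.beta.values()))
        if covariates is None:
            raise ValueError("params include covariate effects but no covariates given")
        X = np.asarray(covariates, dtype=float).reshape(2, -1)
        mean = mean + X @ bvec
    return mean, cov


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class _UniData:
    """Dataset reorganised for fast likelihood evaluation.

    Per zygosity, complete pairs are stored as (m, 2) value and (m, 2, p)
    covariate arrays; pairs with one observed twin as (k,) / (k, p) arrays.
    """

    def __init__(self, dataset: TwinDataset, covariate_names: Sequence[str]):
        if dataset.n_waves != 1:
            raise IntegrityError("univariate models require one-wave data")
        self.covariate_names = list(covariate_names)
        y = dataset.phenotype_array()[:, :, 0]
        X = (dataset.covariate_tensor(self.covariate_names)[:, :, 0, :]
             if self.covariate_names else np.zeros((len(y), 2, 0)))
        mzmask = dataset.zygosity_array()
        self.groups: dict[Zygosity, dict] = {}
        self.n_pairs_used = 0
        for zyg, zmask in ((Zygosity.MZ, mzmask), (Zygosity.DZ, ~mzmask)):
            yz, Xz = y[zmask], X[zmask]
            obs = ~np.isnan(yz)
            if self.covariate_names:
                bad = obs & np.isnan(Xz).any(axis=2)
                if bad.any():
                    raise IntegrityError(
                        "covariates missing for an observed twin; covariates must "
                        "be present wherever the phenotype is"
                    )
            complete = obs.all(axis=1)
            single = obs.sum(axis=1) == 1
            which = np.argmax(obs[single], axis=1) if single.any() else np.empty(0, int)
            self.groups[zyg] = {
                "y": yz[complete],
                "X": Xz[complete],
                "y1": yz[single, :][np.arange(single.sum()), which],
                "X1": Xz[single, :][np.arange(single.sum()), which],
            }
            self.n_pairs_used += int(complete.sum() + single.sum())
        if self.n_pairs_used == 0:
            raise IntegrityError("no pairs with observed phenotypes")

    def neg2ll(self, variance: float, off: dict[Zygosity, float],
               mu: float, beta: np.ndarray) -> float:
        if variance <= 0:
            return _BIG
        total = 0.0
        for zyg, g in self.groups.items():
            cov = off[zyg]
            det = variance * variance - cov * cov
            if det <= 0:
                return _BIG
            y, X = g["y"], g["X"]
            if len(y):
                mean = mu + (X @ beta if beta.size else 0.0)
                d = y - mean
                d1, d2 = d[:, 0], d[:, 1]
                q = (variance * (d1 * d1 + d2 * d2) - 2.0 * cov * d1 * d2) / det
                total += len(y) * (2.0 * LOG_2PI + math.log(det)) + float(q.sum())
            y1, X1 = g["y1"], g["X1"]
            if len(y1):
                mean1 = mu + (X1 @ beta if beta.size else 0.0)
                d = y1 - mean1
                total += len(y1) * (LOG_2PI + math.log(variance)) \
                    + float((d * d).sum()) / variance
        return total


def neg2_loglik_univariate(params: UnivariateParams, dataset: TwinDataset) -> float:
    """-2 log-likelihood of the dataset under the given parameters (FIML)."""
    data = _UniData(dataset, list(params.beta))
    a2, c2, d2, e2 = (params.a ** 2, params.c ** 2, params.d ** 2, params.e ** 2)
    variance = a2 + c2 + d2 + e2
    off = {Zygosity.MZ: a2 + c2 + d2, Zygosity.DZ: 0.5 * a2 + c2 + 0.25 * d2}
    beta = np.array(list(params.beta.values()), dtype=float)
    return data.neg2ll(variance, off, mu=params.mu, beta=beta)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class UnivariateFit:
    spec: UnivariateModelSpec
    params: UnivariateParams
    minus2lnL: float
    n_params: int
    aic: float
    converged: bool
    standardized_components: dict[str, float]
    h2: float
    e2_share: float
    h2_ci: tuple[float, float] | None = None
    e2_share_ci: tuple[float, float] | None = None
    ci_method: str | None = None
    warnings: list[str] = field(default_factory=list)
    grad_norm: float = float("nan")
    _data: "_UniData | None" = field(default=None, repr=False, compare=False)

    @property
    def label(self) -> str:
        return self.spec.components

    def to_dict(self) -> dict:
        return {
            "model": self.label,
            "covariates": self.spec.covariate_names,
            "paths": {k: getattr(self.params, k) for k in ("a", "c", "d", "e")},
            "mu": self.params.mu,
            "beta": self.params.beta,
            "variance_components": self.params.variance_components,
            "standardized_components": self.standardized_components,
            "h2": self.h2,
            "h2_ci": list(self.h2_ci) if self.h2_ci else None,
            "e2_share": self.e2_share,
            "e2_share_ci": list(self.e2_share_ci) if self.e2_share_ci else None,
            "ci_method": self.ci_method,
            "minus2lnL": self.minus2lnL,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "warnings": self.warnings,
        }


@dataclass
class SaturatedFit:
    """Unconstrained per-zygosity means and covariances (likelihood reference)."""

    group_stats: dict[str, dict[str, float]]
    beta: dict[str, float]
    minus2lnL: float
    n_params: int
    converged: bool

    label: str = "saturated"

    @property
    def aic(self) -> float:
        return self.minus2lnL + 2 * self.n_params


def _theta_to_params(theta: np.ndarray, spec: UnivariateModelSpec) -> UnivariateParams:
    paths = spec.paths
    kw = {p: float(theta[i]) for i, p in enumerate(paths)}
    mu = float(theta[len(paths)])
    beta = {n: float(b) for n, b in
            zip(spec.covariate_names, theta[len(paths) + 1:])}
    return UnivariateParams(mu=mu, beta=beta, **{k: kw.get(k, 0.0) for k in "acde"})


def _objective(theta: np.ndarray, spec: UnivariateModelSpec, data: _UniData) -> float:
    paths = spec.paths
    sq = {p: theta[i] ** 2 for i, p in enumerate(paths)}
    a2, c2, d2, e2 = (sq.get("a", 0.0), sq.get("c", 0.0),
                      sq.get("d", 0.0), sq.get("e", 0.0))
    if e2 < 1e-10:
        return _BIG
    variance = a2 + c2 + d2 + e2
    off = {Zygosity.MZ: a2 + c2 + d2, Zygosity.DZ: 0.5 * a2 + c2 + 0.25 * d2}
    mu = theta[len(paths)]
    beta = theta[len(paths) + 1:]
    return data.neg2ll(variance, off, mu, beta)


def _means_start(data: _UniData) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Pooled-individual OLS start for (mu, beta) plus residuals and variance."""
    p = len(data.covariate_names)
    ys, Xs = [], []
    for g in data.groups.values():
        if len(g["y"]):
            ys.append(g["y"].ravel())
            Xs.append(g["X"].reshape(2 * len(g["y"]), p))
        if len(g["y1"]):
            ys.append(g["y1"])
            Xs.append(g["X1"])
    y = np.concatenate(ys)
    X = np.concatenate(Xs) if Xs else np.zeros((len(y), p))
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    var = float(resid.var(ddof=1))
    if var <= 0:
        raise IntegrityError("phenotype has zero variance; nothing to decompose")
    return float(coef[0]), coef[1:], resid, var


def _group_corr(data: _UniData, zyg: Zygosity, mu: float, beta: np.ndarray) -> float:
    g = data.groups[zyg]
    y = g["y"]
    if len(y) < 3:
        return 0.0
    d = y - (mu + (g["X"] @ beta if beta.size else 0.0))
    x1 = np.concatenate([d[:, 0], d[:, 1]])
    x2 = np.concatenate([d[:, 1], d[:, 0]])
    if x1.std() == 0:
        return 0.0
    return float(np.clip(np.corrcoef(x1, x2)[0, 1], -0.95, 0.95))


def _start_vectors(spec: UnivariateModelSpec, data: _UniData,
                   n_starts: int) -> list[np.ndarray]:
    mu0, beta0, _, var = _means_start(data)
    r_mz = _group_corr(data, Zygosity.MZ, mu0, beta0)
    r_dz = _group_corr(data, Zygosity.DZ, mu0, beta0)
    comp = {"e": max((1.0 - r_mz) * var, 0.05 * var)}
    if spec.components == "ACE":
        comp["a"] = np.clip(2 * (r_mz - r_dz), 0.05, 0.9) * var
        comp["c"] = np.clip(2 * r_dz - r_mz, 0.02, 0.9) * var
    elif spec.components == "ADE":
        comp["a"] = np.clip(4 * r_dz - r_mz, 0.05, 0.9) * var
        comp["d"] = np.clip(2 * (r_mz - 2 * r_dz), 0.02, 0.9) * var
    elif spec.components == "AE":
        comp["a"] = np.clip(r_mz, 0.05, 0.95) * var
    elif spec.components == "CE":
        comp["c"] = np.clip(r_mz, 0.05, 0.95) * var
    else:  # E
        comp["e"] = var
    base = np.array([math.sqrt(comp.get(p, 0.0)) for p in spec.paths]
                    + [mu0] + list(beta0))
    rng = np.random.default_rng(20240710)  # fixed jitter seed for reproducibility
    starts = [base]
    scale = np.maximum(np.abs(base), math.sqrt(var) * 0.2)
    for _ in range(n_starts - 1):
        starts.append(base + rng.normal(0, 0.3, base.shape) * scale)
    return starts


def _minimize_multistart(fun, starts: list[np.ndarray]):
    best = None
    for x0 in starts:
        res = optimize.minimize(fun, x0, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-12,
                                         "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    polish = optimize.minimize(fun, best.x, method="Nelder-Mead",
                               options={"xatol": 1e-9, "fatol": 1e-10,
                                        "maxiter": 5000, "maxfev": 8000})
    if polish.fun < best.fun:
        best = polish
    return best


def fit_univariate(
    dataset: TwinDataset,
    spec: UnivariateModelSpec | str = "ACE",
    compute_ci: bool = True,
    ci_level: float = 0.95,
    n_starts: int = 5,
) -> UnivariateFit:
    """Maximum-likelihood fit of a univariate twin model.

    Uses multi-start quasi-Newton optimisation over unconstrained path
    coefficients (moments-based start plus jittered restarts with a fixed
    jitter seed) followed by a simplex polish.  Non-convergence is flagged,
    never silent.
    """
    if isinstance(spec, str):
        spec = UnivariateModelSpec(spec)
    dataset.require_both_zygosities()
    data = _UniData(dataset, spec.covariate_names)
    starts = _start_vectors(spec, data, n_starts)
    fun = lambda th: _objective(th, spec, data)
    best = _minimize_multistart(fun, starts)

    grad = optimize.approx_fprime(best.x, fun, 1e-6)
    grad_norm = float(np.linalg.norm(grad))
    converged = bool(np.isfinite(best.fun) and best.fun < _BIG / 2
                     and grad_norm < 1e-2 * max(1.0, abs(best.fun)))

    theta = best.x.copy()
    theta[: len(spec.paths)] = np.abs(theta[: len(spec.paths)])  # sign convention
    params = _theta_to_params(theta, spec)
    comps = params.variance_components
    total = params.total_variance
    shares = {k: v / total for k, v in comps.items()}
    h2 = shares["a2"] + (shares["d2"] if spec.family == "ADE" else 0.0)
    n_params = len(spec.paths) + 1 + len(spec.covariate_names)
    fit = UnivariateFit(
        spec=spec,
        params=params,
        minus2lnL=float(best.fun),
        n_params=n_params,
        aic=float(best.fun) + 2 * n_params,
        converged=converged,
        standardized_components=shares,
        h2=h2,
        e2_share=shares["e2"],
        grad_norm=grad_norm,
        _data=data,
    )
    if not converged:
        fit.warnings.append(
            f"optimizer did not meet convergence criteria (gradient norm {grad_norm:.3g})"
        )
    if compute_ci:
        if any(p in spec.paths for p in _QUANTITY_GROUPS["h2"](spec.family)):
            fit.h2_ci = profile_ci(fit, "h2", ci_level)
        fit.e2_share_ci = profile_ci(fit, "e2_share", ci_level)
        fit.ci_method = fit.ci_method or "profile"
    return fit


# -- saturated model ---------------------------------------------------------

def _sat_objective(theta: np.ndarray, data: _UniData) -> float:
    total = 0.0
    p = len(data.covariate_names)
    beta = theta[10:10 + p]
    for j, zyg in enumerate((Zygosity.MZ, Zygosity.DZ)):
        m1, m2, ls1, ls2, z = theta[5 * j: 5 * j + 5]
        s1, s2 = math.exp(ls1), math.exp(ls2)
        r = math.tanh(z)
        cov = r * s1 * s2
        g = data.groups[zyg]
        y, X = g["y"], g["X"]
        det = (s1 * s2) ** 2 - cov ** 2
        if det <= 0:
            return _BIG
        if len(y):
            xb = X @ beta if p else 0.0
            d1 = y[:, 0] - m1 - (xb[:, 0] if p else 0.0)
            d2 = y[:, 1] - m2 - (xb[:, 1] if p else 0.0)
            q = (s2 ** 2 * d1 * d1 + s1 ** 2 * d2 * d2 - 2 * cov * d1 * d2) / det
            total += len(y) * (2 * LOG_2PI + math.log(det)) + float(q.sum())
        # singletons: twin order is arbitrary, so the marginal density uses the
        # slot-average mean and variance
        y1, X1 = g["y1"], g["X1"]
        if len(y1):
            m = 0.5 * (m1 + m2)
            v = 0.5 * (s1 ** 2 + s2 ** 2)
            d = y1 - m - (X1 @ beta if p else 0.0)
            total += len(y1) * (LOG_2PI + math.log(v)) + float((d * d).sum()) / v
    return total


def fit_saturated_univariate(
    dataset: TwinDataset, covariate_names: Sequence[str] = ()
) -> SaturatedFit:
    """Fully saturated model: free means/variances/covariance per zygosity.

    Covariate coefficients are shared across zygosity groups and twin order.
    Its -2lnL lower-bounds every constrained twin model on the same data.
    """
    dataset.require_both_zygosities()
    data = _UniData(dataset, list(covariate_names))
    mu0, beta0, _, var = _means_start(data)
    theta0 = []
    for zyg in (Zygosity.MZ, Zygosity.DZ):
        g = data.groups[zyg]
        y = g["y"]
        if len(y) >= 3:
            m1, m2 = y.mean(axis=0)
            s1, s2 = np.maximum(y.std(axis=0, ddof=0), 1e-6)
            r = np.clip(np.corrcoef(y[:, 0], y[:, 1])[0, 1], -0.95, 0.95)
            if not np.isfinite(r):
                r = 0.0
        else:
            m1 = m2 = mu0
            s1 = s2 = math.sqrt(var)
            r = 0.0
        theta0 += [m1, m2, math.log(s1), math.log(s2), math.atanh(r)]
    theta0 = np.array(theta0 + list(beta0))
    fun = lambda th: _sat_objective(th, data)
    best = _minimize_multistart(fun, [theta0])
    stats_out = {}
    for j, zyg in enumerate((Zygosity.MZ, Zygosity.DZ)):
        m1, m2, ls1, ls2, z = best.x[5 * j: 5 * j + 5]
        s1, s2 = math.exp(ls1), math.exp(ls2)
        stats_out[zyg.value] = {
            "mean_twin1": float(m1), "mean_twin2": float(m2),
            "var_twin1": float(s1 ** 2), "var_twin2": float(s2 ** 2),
            "cov_within": float(math.tanh(z) * s1 * s2),
        }
    n_params = 10 + len(covariate_names)
    return SaturatedFit(
        group_stats=stats_out,
        beta={n: float(b) for n, b in zip(covariate_names, best.x[10:])},
        minus2lnL=float(best.fun),
        n_params=n_params,
        converged=bool(np.isfinite(best.fun) and best.fun < _BIG / 2),
    )


# -- model comparison --------------------------------------------------------

def _is_nested(general, nested) -> bool:
    if getattr(general, "label", None) == "saturated":
        return getattr(nested, "label", None) != "saturated"
    if getattr(nested, "label", None) == "saturated":
        return False
    gset = set(COMPONENT_SETS[general.label])
    nset = set(COMPONENT_SETS[nested.label])
    return nset < gset


def likelihood_ratio_test(general, nested) -> tuple[float, int, float]:
    """LRT of a nested model against a more general one.

    Returns ``(statistic, df, p_value)`` with the statistic floored at 0 and
    p from the chi-square upper tail.
    """
    if nested.n_params >= general.n_params:
        raise ValueError(
            f"nested model has {nested.n_params} parameters, not fewer than the "
            f"general model's {general.n_params}"
        )
    if not _is_nested(general, nested):
        raise ValueError(
            f"{getattr(nested, 'label', '?')} is not nested in "
            f"{getattr(general, 'label', '?')}"
        )
    stat = nested.minus2lnL - general.minus2lnL
    if stat < -1e-6:
        raise ValueError(
            f"nested model fits better than the general one by {-stat:.3g}; "
            "likely a convergence failure"
        )
    stat = max(stat, 0.0)
    df = general.n_params - nested.n_params
    return stat, df, float(stats.chi2.sf(stat, df))


@dataclass
class ModelComparisonTable:
    table: pd.DataFrame
    selected: str
    fits: dict[str, object]
    warning: str | None = None

    @property
    def selected_fit(self):
        return self.fits[self.selected]


_SUBMODELS = {"ACE": ["AE", "CE", "E"], "ADE": ["AE", "E"]}
_PARENTS = {"AE": None, "CE": None, "E": "AE"}  # None -> the family head


def select_model(
    dataset: TwinDataset,
    covariate_names: Sequence[str] = (),
    alpha: float = 0.05,
    compute_ci: bool = True,
) -> ModelComparisonTable:
    """Fit saturated, ACE and ADE models, then sub-models of the better family.

    A candidate is admissible when its LRT against its parent and against the
    saturated model are both non-significant; among admissible candidates the
    lowest AIC wins, ties going to the model with fewest parameters.  When no
    candidate is admissible the full family model is selected with a warning.
    """
    covs = list(covariate_names)
    sat = fit_saturated_univariate(dataset, covs)
    fits: dict[str, object] = {"saturated": sat}
    for label in ("ACE", "ADE"):
        fits[label] = fit_univariate(
            dataset, UnivariateModelSpec(label, covs), compute_ci=False)
    family = "ACE" if fits["ACE"].aic <= fits["ADE"].aic else "ADE"
    for label in _SUBMODELS[family]:
        if label not in fits:
            fits[label] = fit_univariate(
                dataset, UnivariateModelSpec(label, covs), compute_ci=False)

    rows = [{
        "model": "saturated", "minus2lnL": sat.minus2lnL,
        "n_params": sat.n_params, "lrt_stat": float("nan"), "df": 0,
        "p_value": float("nan"), "aic": sat.aic, "selected": False,
    }]
    candidates = [family] + _SUBMODELS[family]
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
        parent_label = _PARENTS[label] or family
        fit = fits[label]
        stat, df, p = likelihood_ratio_test(fits[parent_label], fit)
        _, _, p_sat = likelihood_ratio_test(sat, fit)
        rows.append({"model": label, "minus2lnL": fit.minus2lnL,
                     "n_params": fit.n_params, "lrt_stat": stat, "df": df,
                     "p_value": p, "aic": fit.aic, "selected": False})
        if p > alpha and p_sat > alpha:
            admissible.append(label)

    warning = None
    if admissible:
        selected = min(admissible,
                       key=lambda l: (fits[l].aic, fits[l].n_params))
    else:
        selected = family
        warning = ("no candidate passed both likelihood-ratio tests; the full "
                   f"{family} model is reported")
    table = pd.DataFrame(rows)
    table.loc[table.model == selected, "selected"] = True
    if compute_ci and isinstance(fits[selected], UnivariateFit):
        sel = fits[selected]
        if any(p in sel.spec.paths
               for p in _QUANTITY_GROUPS["h2"](sel.spec.family)):
            sel.h2_ci = profile_ci(sel, "h2")
        sel.e2_share_ci = profile_ci(sel, "e2_share")
        sel.ci_method = sel.ci_method or "profile"
    return ModelComparisonTable(table=table, selected=selected, fits=fits,
                                warning=warning)


# -- profile-likelihood confidence intervals ---------------------------------

_QUANTITY_GROUPS = {
    "h2": lambda family: ("a", "d") if family == "ADE" else ("a",),
    "a2_share": lambda family: ("a",),
    "c2_share": lambda family: ("c",),
    "d2_share": lambda family: ("d",),
    "e2_share": lambda family: ("e",),
}


def _profile_objective(t: float, fit: UnivariateFit) -> float:
    """min -2lnL subject to the chosen share equalling t."""
    spec, data = fit.spec, fit._data
    paths = spec.paths
    in_group = [p for p in _QUANTITY_GROUPS_RESOLVED(fit)
                if p in paths]
    out_group = [p for p in paths if p not in in_group]
    p_cov = len(spec.covariate_names)

    def shares_from(phi):
        # phi: [split_in?] + [split_out?]; logistic splits within each group
        idx = 0
        shares = {}
        if len(in_group) == 2:
            w = 1.0 / (1.0 + math.exp(-phi[idx])); idx += 1
            shares[in_group[0]], shares[in_group[1]] = t * w, t * (1 - w)
        elif len(in_group) == 1:
            shares[in_group[0]] = t
        if len(out_group) == 2:
            w = 1.0 / (1.0 + math.exp(-phi[idx])); idx += 1
            shares[out_group[0]], shares[out_group[1]] = (1 - t) * w, (1 - t) * (1 - w)
        elif len(out_group) == 1:
            shares[out_group[0]] = 1 - t
        return shares, idx

    n_split = (len(in_group) == 2) + (len(out_group) == 2)

    def fun(psi):
        logv = psi[0]
        shares, used = shares_from(psi[1:1 + n_split])
        V = math.exp(logv)
        sq = {p: shares.get(p, 0.0) * V for p in "acde"}
        if sq["e"] < 1e-12:
            return _BIG
        variance = sum(sq.values())
        off = {Zygosity.MZ: sq["a"] + sq["c"] + sq["d"],
               Zygosity.DZ: 0.5 * sq["a"] + sq["c"] + 0.25 * sq["d"]}
        mu = psi[1 + n_split]
        beta = psi[2 + n_split:]
        return data.neg2ll(variance, off, mu, beta)

    V_hat = max(fit.params.total_variance, 1e-8)
    psi0 = [math.log(V_hat)]
    # start the splits at the fitted proportions where defined
    comps = fit.standardized_components
    sq_map = {"a": "a2", "c": "c2", "d": "d2", "e": "e2"}
    for group in (in_group, out_group):
        if len(group) == 2:
            s0, s1 = comps[sq_map[group[0]]], comps[sq_map[group[1]]]
            tot = s0 + s1
            w = s0 / tot if tot > 1e-12 else 0.5
            w = min(max(w, 1e-4), 1 - 1e-4)
            psi0.append(math.log(w / (1 - w)))
    psi0.append(fit.params.mu)
    psi0 += [fit.params.beta[n] for n in spec.covariate_names]
    res = optimize.minimize(fun, np.array(psi0), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-9,
                                     "maxiter": 4000, "maxfev": 6000})
    return float(res.fun)


def _QUANTITY_GROUPS_RESOLVED(fit: UnivariateFit):
    return _QUANTITY_GROUPS[fit._quantity](fit.spec.family)


def _delta_ci(fit: UnivariateFit, quantity: str, level: float) -> tuple[float, float]:
    from statsmodels.tools.numdiff import approx_hess

    spec, data = fit.spec, fit._data
    paths = spec.paths
    theta = np.array([getattr(fit.params, p) for p in paths] + [fit.params.mu]
                     + [fit.params.beta[n] for n in spec.covariate_names])
    fun = lambda th: _objective(th, spec, data)
    H = approx_hess(theta, fun)
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = 2.0 * np.linalg.pinv(H)

    def q_of(th):
        sq = {p: th[i] ** 2 for i, p in enumerate(paths)}
        total = sum(sq.values())
        group = _QUANTITY_GROUPS[quantity](spec.family)
        return sum(sq.get(p, 0.0) for p in group) / total

    grad = optimize.approx_fprime(theta, q_of, 1e-6)
    var_q = float(grad @ cov @ grad)
    se = math.sqrt(max(var_q, 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    q_hat = q_of(theta)
    return (max(q_hat - z * se, 0.0), min(q_hat + z * se, 1.0))


def profile_ci(
    fit: UnivariateFit,
    quantity: str = "h2",
    level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for a standardized share.

    The bound is where the profiled -2lnL exceeds the minimum by the
    chi-square(1) quantile (3.841 at 95%); bounds are clipped to [0, 1].
    Falls back to a delta-method interval (flagged via ``fit.ci_method``)
    if profiling fails.
    """
    if quantity not in _QUANTITY_GROUPS:
        raise ValueError(f"unknown quantity {quantity!r}")
    if fit._data is None:
        raise ValueError("fit does not carry its data; refit with fit_univariate")
    group = _QUANTITY_GROUPS[quantity](fit.spec.family)
    if not any(p in fit.spec.paths for p in group):
        raise ValueError(
            f"{quantity} involves components absent from the {fit.label} model"
        )
    comps = fit.standardized_components
    sq_map = {"a": "a2", "c": "c2", "d": "d2", "e": "e2"}
    q_hat = sum(comps[sq_map[p]] for p in group if p in fit.spec.paths)
    cutoff = fit.minus2lnL + stats.chi2.ppf(level, 1)
    fit._quantity = quantity

    try:
        def f(t):
            return _profile_objective(t, fit) - cutoff

        eps = 1e-6
        lo_edge, hi_edge = eps, 1.0 - eps
        # lower bound
        if q_hat <= lo_edge or f(lo_edge) <= 0:
            lower = 0.0
        else:
            lower = float(optimize.brentq(f, lo_edge, q_hat, xtol=1e-5))
        # upper bound
        if q_hat >= hi_edge or f(hi_edge) <= 0:
            upper = 1.0
        else:
            upper = float(optimize.brentq(f, q_hat, hi_edge, xtol=1e-5))
        return (lower, upper)
    except Exception:
        fit.ci_method = "delta"
        return _delta_ci(fit, quantity, level)
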