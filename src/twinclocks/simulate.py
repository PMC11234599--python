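"""Synthetic twin-pair generators with exact ACE/ADE covariance structure.

Cohort data behind twin studies of epigenetic aging are typically restricted,
so these generators produce phenotype-level stand-ins with precisely the
statistical structure the models assume: per pair, the 2-vector (one wave) or
4-vector (two waves) is drawn from the model-implied multivariate normal for
its zygosity.  Drawing from the implied normal is exactly equivalent in
distribution to simulating latent A/C/D/E scores; a latent-draw mode is kept
for didactic traces.

Defaults follow the study design being emulated: covariate effects are zero
(so recovery experiments are clean), sex is a pair-level Bernoulli(0.5) draw
(twin pairs are same-sex), and age is shared within a pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bivariate import CholeskyParams, _sigma4, expected_moments_bivariate
from .twin_data import TwinDataset, TwinPair, Zygosity
from .univariate import UnivariateParams, expected_moments_univariate

__all__ = [
    "UnivariateSimSpec",
    "BivariateSimSpec",
    "simulate_univariate_twins",
    "simulate_bivariate_twins",
    "cholesky_from_summary",
]


@dataclass
class CovariateSettings:
    """Generators for the covariates attached to simulated pairs.

    ``sex_p`` is the probability of the 1-coded sex, drawn once per pair
    (same-sex design); ``age_range`` draws a pair-level uniform age in years.
    """

    sex_p: float = 0.5
    age_range: tuple[float, float] = (19.0, 82.0)
    include: tuple[str, ...] = ()   # subset of ("sex", "age")


@dataclass
class UnivariateSimSpec:
    n_mz: int
    n_dz: int
    components: str = "ACE"
    a2: float = 0.0
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 1.0
    mu: float = 0.0
    beta: dict[str, float] = field(default_factory=dict)
    covariates: CovariateSettings = field(default_factory=CovariateSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.a2, self.c2, self.d2) < 0 or self.e2 <= 0:
            raise ValueError("variance components must be >= 0 with e2 > 0")
        if self.c2 > 0 and self.d2 > 0:
            raise ValueError("C and D cannot both be present")
        if self.n_mz + self.n_dz <= 0:
            raise ValueError("at least one pair must be requested")

    def params(self) -> UnivariateParams:
        return UnivariateParams(
            a=math.sqrt(self.a2), c=math.sqrt(self.c2),
            d=math.sqrt(self.d2), e=math.sqrt(self.e2),
            mu=self.mu, beta=dict(self.beta),
        )


@dataclass
class BivariateSimSpec:
    n_mz: int
    n_dz: int
    params: CholeskyParams
    beta: dict[str, float] = field(default_factory=dict)
    covariates: CovariateSettings = field(default_factory=CovariateSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mz + self.n_dz <= 0:
            raise ValueError("at least one pair must be requested")


def _draw_covariates(rng: np.random.Generator, settings: CovariateSettings,
                     n: int, n_waves: int) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    if "sex" in settings.include:
        sex = rng.binomial(1, settings.sex_p, size=n).astype(float)
        out["sex"] = np.broadcast_to(sex[:, None, None], (n, 2, n_waves)).copy()
    if "age" in settings.include:
        lo, hi = settings.age_range
        age = rng.uniform(lo, hi, size=n)
        out["age"] = np.broadcast_to(age[:, None, None], (n, 2, n_waves)).copy()
    return out


def simulate_univariate_twins(spec: UnivariateSimSpec) -> TwinDataset:
    """Draw one-wave twin pairs from the exact model-implied moments.

    Deterministic given ``spec.seed``: the same spec always yields a
    bit-identical dataset.
    """
    rng = np.random.default_rng(spec.seed)
    params = spec.params()
    cov_names = list(spec.covariates.include)
    pairs: list[TwinPair] = []
    for zyg, n in ((Zygosity.MZ, spec.n_mz), (Zygosity.DZ, spec.n_dz)):
        if n == 0:
            continue
        _, sigma = expected_moments_univariate(
            UnivariateParams(a=params.a, c=params.c, d=params.d, e=params.e,
                             mu=params.mu),
            zyg)
        L = np.linalg.cholesky(sigma)
        z = rng.standard_normal((n, 2))
        y = params.mu + z @ L.T
        covs = _draw_covariates(rng, spec.covariates, n, 1)
        for name, b in spec.beta.items():
            if name in covs:
                y += b * covs[name][:, :, 0]
        for i in range(n):
            pairs.append(TwinPair(
                f"{zyg.value}{i + 1:05d}", zyg, y[i].reshape(2, 1),
                {c: covs[c][i] for c in cov_names},
            ))
    return TwinDataset(pairs, n_waves=1, variable_name="y",
                       covariate_names=cov_names,
                       meta={"generator": "simulate_univariate_twins",
                             "seed": spec.seed})


def simulate_univariate_twins_latent(spec: UnivariateSimSpec) -> TwinDataset:
    """Latent-draw variant: sample A/C/D/E scores explicitly then combine.

    Distributionally identical to :func:`simulate_univariate_twins`; useful
    for inspecting the latent bookkeeping.  Not the default path.
    """
    rng = np.random.default_rng(spec.seed)
    params = spec.params()
    cov_names = list(spec.covariates.include)
    pairs: list[TwinPair] = []
    for zyg, n in ((Zygosity.MZ, spec.n_mz), (Zygosity.DZ, spec.n_dz)):
        if n == 0:
            continue
        rho_a, rho_d = (1.0, 1.0) if zyg is Zygosity.MZ else (0.5, 0.25)
        def shared_pair(rho):
            common = rng.standard_normal((n, 1))
            specific = rng.standard_normal((n, 2))
            return math.sqrt(rho) * common + math.sqrt(1 - rho) * specific
        A = shared_pair(rho_a)
        C = np.repeat(rng.standard_normal((n, 1)), 2, axis=1)
        D = shared_pair(rho_d)
        E = rng.standard_normal((n, 2))
        y = (spec.mu + params.a * A + params.c * C
             + params.d * D + params.e * E)
        covs = _draw_covariates(rng, spec.covariates, n, 1)
        for name, b in spec.beta.items():
            if name in covs:
                y += b * covs[name][:, :, 0]
        for i in range(n):
            pairs.append(TwinPair(
                f"{zyg.value}{i + 1:05d}", zyg, y[i].reshape(2, 1),
                {c: covs[c][i] for c in cov_names},
            ))
    return TwinDataset(pairs, n_waves=1, variable_name="y",
                       covariate_names=cov_names,
                       meta={"generator": "simulate_univariate_twins_latent",
                             "seed": spec.seed})


def simulate_bivariate_twins(spec: BivariateSimSpec) -> TwinDataset:
    """Draw two-wave twin pairs from the exact 4-variate implied moments."""
    rng = np.random.default_rng(spec.seed)
    cov_names = list(spec.covariates.include)
    mu1, mu2 = spec.params.mu
    mean4 = np.array([mu1, mu2, mu1, mu2])
    pairs: list[TwinPair] = []
    for zyg, n in ((Zygosity.MZ, spec.n_mz), (Zygosity.DZ, spec.n_dz)):
        if n == 0:
            continue
        sigma = _sigma4(spec.params, zyg)
        L = np.linalg.cholesky(sigma)
        z = rng.standard_normal((n, 4))
        y = mean4 + z @ L.T
        covs = _draw_covariates(rng, spec.covariates, n, 2)
        for name, b in spec.beta.items():
            if name in covs:
                y += b * covs[name].reshape(n, 4)
        for i in range(n):
            pairs.append(TwinPair(
                f"{zyg.value}{i + 1:05d}", zyg, y[i].reshape(2, 2),
                {c: covs[c][i] for c in cov_names},
            ))
    return TwinDataset(pairs, n_waves=2, variable_name="y",
                       covariate_names=cov_names,
                       meta={"generator": "simulate_bivariate_twins",
                             "seed": spec.seed})


def cholesky_from_summary(
    h2_baseline: float,
    h2_followup: float,
    ra: float,
    re: float,
    c2_baseline: float = 0.0,
    c2_followup: float = 0.0,
    rc: float | None = None,
) -> CholeskyParams:
    """Invert printed summary statistics into standardized Cholesky paths.

    Builds parameters on the standardized scale (total variance 1 at both
    waves) such that the baseline/follow-up heritabilities and the cross-time
    correlations Ra and Re (and Rc if a C component is requested) are exactly
    reproduced by :func:`derive_bivariate_statistics`.

    The E share at each wave is the remainder after A (and C); a negative
    remainder or an out-of-range correlation raises ``ValueError``.
    """
    for name, v in (("h2_baseline", h2_baseline), ("h2_followup", h2_followup),
                    ("c2_baseline", c2_baseline), ("c2_followup", c2_followup)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    for name, v in (("ra", ra), ("re", re)):
        if abs(v) > 1.0:
            raise ValueError(f"|{name}| must be <= 1, got {v}")
    has_c = c2_baseline > 0 or c2_followup > 0
    if has_c:
        if rc is None:
            raise ValueError("rc is required when a C component is requested")
        if abs(rc) > 1.0:
            raise ValueError(f"|rc| must be <= 1, got {rc}")
    e2_1 = 1.0 - h2_baseline - c2_baseline
    e2_2 = 1.0 - h2_followup - c2_followup
    if e2_1 < -1e-12 or e2_2 < -1e-12:
        raise ValueError(
            "variance shares exceed 1 at a wave; the E remainder is negative"
        )
    e2_1, e2_2 = max(e2_1, 0.0), max(e2_2, 0.0)
    if e2_1 <= 0 or e2_2 <= 0:
        raise ValueError("E share must be positive at both waves")

    def paths(v1, v2, r):
        k11 = math.sqrt(v1)
        k21 = r * math.sqrt(v2)
        k22 = math.sqrt(max(v2 * (1.0 - r * r), 0.0))
        return (k11, k21, k22)

    a = paths(h2_baseline, h2_followup, ra) if (h2_baseline > 0 or h2_followup > 0) \
        else None
    c = paths(c2_baseline, c2_followup, rc) if has_c else None
    e = paths(e2_1, e2_2, re)
    return CholeskyParams(a=a, c=c, d=None, e=e, mu=(0.0, 0.0))
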