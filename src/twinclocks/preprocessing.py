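"""Age-acceleration residuals and metric standardization.

Epigenetic age acceleration (AA) is defined as the residual of an epigenetic
clock regressed on the six Houseman blood-cell proportions and chronological
age: what remains after removing the parts of the clock explained by cell
composition and calendar time.  Cell proportions and clock values are inputs;
neither deconvolution nor clock computation happens here.

Metrics are standardized (z-scored, sample-SD convention with the n-1
denominator) before twin modelling so that variance components are on a
comparable scale across clocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ResidualModel",
    "StandardizationParams",
    "compute_age_acceleration",
    "standardize",
    "destandardize",
]


@dataclass
class ResidualModel:
    """OLS fit behind an age-acceleration residualization."""

    intercept: float
    coefficients: dict[str, float]
    n_used: int
    r_squared: float


@dataclass
class StandardizationParams:
    mean: float
    sd: float
    #: denominator convention used for ``sd``
    ddof: int = 1


def compute_age_acceleration(
    clock_values: np.ndarray | pd.Series,
    predictors: pd.DataFrame | np.ndarray,
    predictor_names: list[str] | None = None,
) -> tuple[np.ndarray, ResidualModel]:
    """Residualize clock values on cell proportions and chronological age.

    Fits ordinary least squares of ``clock_values`` on ``predictors`` (with
    intercept) over the rows where the response and every predictor are
    observed; returns the residual vector aligned with the input (NaN where
    any input was missing) and the fitted :class:`ResidualModel`.

    Raises
    ------
    ValueError
        If the design matrix is rank deficient (the collinear columns are
        named) or there are fewer complete rows than parameters.
    """
    y = np.asarray(clock_values, dtype=float)
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        names = predictor_names or [f"x{j+1}" for j in range(X.shape[1])]
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"predictors have {X.shape[0]} rows but clock_values has {y.shape[0]}"
        )

    complete = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    n_used = int(complete.sum())
    n_params = X.shape[1] + 1
    if n_used < n_params:
        raise ValueError(
            f"{n_used} complete observations are too few to fit {n_params} parameters"
        )

    Xc = X[complete]
    # constant predictors carry no information beyond the intercept; they get
    # a zero coefficient instead of tripping the collinearity check
    keep = np.ptp(Xc, axis=0) > 0
    kept_names = [n for n, k in zip(names, keep) if k]
    design = np.column_stack([np.ones(n_used), Xc[:, keep]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        culprits = _collinear_columns(design, kept_names)
        raise ValueError(
            "rank-deficient design for age-acceleration regression; "
            f"collinear columns: {culprits}"
        )

    coef_kept, *_ = np.linalg.lstsq(design, y[complete], rcond=None)
    fitted = design @ coef_kept
    coef = np.zeros(X.shape[1] + 1)
    coef[0] = coef_kept[0]
    coef[1:][keep] = coef_kept[1:]
    resid_used = y[complete] - fitted
    ss_res = float(resid_used @ resid_used)
    ss_tot = float(np.sum((y[complete] - y[complete].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    residuals = np.full_like(y, np.nan)
    residuals[complete] = resid_used
    model = ResidualModel(
        intercept=float(coef[0]),
        coefficients={n: float(b) for n, b in zip(names, coef[1:])},
        n_used=n_used,
        r_squared=r2,
    )
    return residuals, model


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Name the design columns (beyond the intercept) involved in collinearity."""
    labels = ["(intercept)"] + list(names)
    _, r, piv = _pivoted_qr(design)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * abs(r[0, 0])))
    return [labels[j] for j in sorted(piv[rank:])]


def _pivoted_qr(a: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(a, mode="economic", pivoting=True)
    return q, r, piv


def standardize(values: np.ndarray | pd.Series) -> tuple[np.ndarray, StandardizationParams]:
    """Z-score a vector over its non-missing entries (sample SD, ddof=1).

    Missing entries stay missing.  Raises ``ValueError`` on fewer than two
    observed values or zero variance.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValueError("standardize requires at least 2 non-missing values")
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    if sd == 0.0:
        raise ValueError("cannot standardize a zero-variance vector")
    return (x - mean) / sd, StandardizationParams(mean=mean, sd=sd)


def destandardize(values: np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Invert :func:`standardize`."""
    return np.asarray(values, dtype=float) * params.sd + params.mean
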