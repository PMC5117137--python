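"""Normal linear imputation of a single incomplete column, and analysis fits.

Two imputation flavours are provided for the model y_g | y~  ~  N(y~ mu, sigma)
(``sigma`` is the error *variance* throughout):

* **bayesian** — each set of imputations is drawn under an independent draw
  of (mu, sigma) from the Jeffreys-prior posterior given the complete cases;
  this is the proper imputation that Rubin's rules assume.
* **frequentist** — every set of imputations is drawn with (mu, sigma) fixed
  at the complete-case maximum likelihood estimate; this is the scheme the
  Robins-Wang variance estimator and full mechanism bootstrapping require.

The analysis procedure is ordinary least squares with both the model-based
covariance s^2 (X'X)^-1 and the HC1 heteroscedasticity-robust sandwich.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dgp import IncompleteDataset

__all__ = [
    "Theta",
    "ImputedStack",
    "AnalysisFit",
    "DegenerateFitWarning",
    "build_design",
    "subgroup_mask",
    "fit_imputation_mle",
    "draw_posterior_theta",
    "impute",
    "fit_analysis",
]


class DegenerateFitWarning(UserWarning):
    """Raised when a fitted error variance is (numerically) zero."""


@dataclass(frozen=True)
class Theta:
    """Imputation-model parameters: coefficients and error variance."""

    mu: np.ndarray
    sigma: float  # error variance, not SD

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        if self.sigma < 0.0:
            raise ValueError("sigma (error variance) must be nonnegative")


def _get_column(cols, name: str) -> np.ndarray:
    if isinstance(cols, pd.DataFrame):
        return cols[name].to_numpy(dtype=float)
    return np.asarray(cols[name], dtype=float)


def build_design(cols, names) -> np.ndarray:
    """Assemble a design matrix from named columns.

    ``"const"`` yields a column of ones and ``"a:b"`` the elementwise
    product of columns ``a`` and ``b``; there are no implicit intercepts.
    ``cols`` may be a DataFrame or a dict of 1-d arrays.
    """
    arrays = []
    n = None
    for name in names:
        if name == "const":
            arrays.append(None)  # filled once n is known
            continue
        if ":" in name:
            a, b = name.split(":", 1)
            col = _get_column(cols, a) * _get_column(cols, b)
        else:
            col = _get_column(cols, name)
        n = len(col)
        arrays.append(col)
    if n is None:  # design of constants only
        n = len(cols) if isinstance(cols, pd.DataFrame) else len(next(iter(cols.values())))
    ones = np.ones(n)
    return np.column_stack([ones if a is None else a for a in arrays])


def subgroup_mask(cols, subgroup) -> np.ndarray:
    """Boolean row mask for an analysis subgroup (``None``/"all", "men", or array)."""
    if subgroup is None or (isinstance(subgroup, str) and subgroup == "all"):
        n = len(cols) if isinstance(cols, pd.DataFrame) else len(next(iter(cols.values())))
        return np.ones(n, dtype=bool)
    if isinstance(subgroup, str):
        if subgroup == "men":
            return _get_column(cols, "sex") == 0.0
        raise ValueError(f"unknown subgroup {subgroup!r}")
    return np.asarray(subgroup, dtype=bool)


def _checked_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS with an explicit rank check; returns (beta, XtX)."""
    q = X.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < q:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {q} columns)"
        )
    return beta, X.T @ X


def fit_imputation_mle(data: IncompleteDataset, covariates) -> Theta:
    """Complete-case maximum likelihood fit of the imputation model.

    ``mu`` is the OLS coefficient vector on the rows with the incomplete
    column observed and ``sigma`` the ML error variance RSS/(n-t).
    """
    comp = data.r == 1
    nc = int(comp.sum())
    p1 = len(covariates)
    if nc <= p1:
        raise ValueError(
            f"too few complete rows ({nc}) to fit {p1} imputation coefficients"
        )
    X = build_design(data.frame, covariates)[comp]
    y = data.frame[data.missing_col].to_numpy(dtype=float)[comp]
    mu, _ = _checked_ols(X, y)
    resid = y - X @ mu
    sigma = float(resid @ resid) / nc
    if sigma <= np.finfo(float).eps * max(1.0, float(y @ y) / nc):
        warnings.warn(
            "imputation model fits the complete cases exactly (sigma = 0)",
            DegenerateFitWarning,
            stacklevel=2,
        )
    return Theta(mu=mu, sigma=sigma)


def _posterior_state(data: IncompleteDataset, covariates):
    comp = data.r == 1
    nc = int(comp.sum())
    p1 = len(covariates)
    if nc <= p1:
        raise ValueError(
            f"too few complete rows ({nc}) to fit {p1} imputation coefficients"
        )
    X = build_design(data.frame, covariates)[comp]
    y = data.frame[data.missing_col].to_numpy(dtype=float)[comp]
    mu_hat, XtX = _checked_ols(X, y)
    resid = y - X @ mu_hat
    rss = float(resid @ resid)
    dfree = nc - p1
    if dfree <= 2:
        warnings.warn(
            f"only {dfree} residual degrees of freedom for the posterior "
            "variance draw; draws will be heavy tailed",
            UserWarning,
            stacklevel=3,
        )
    # XtX^-1 = L L' with L lower triangular, for correlated mu draws
    L = np.linalg.cholesky(np.linalg.inv(XtX))
    return mu_hat, L, rss, dfree


def _draw_theta(mu_hat, L, rss, dfree, rng: np.random.Generator) -> Theta:
    sigma = rss / rng.chisquare(dfree) if rss > 0.0 else 0.0
    mu = mu_hat + np.sqrt(sigma) * (L @ rng.standard_normal(len(mu_hat)))
    return Theta(mu=mu, sigma=float(sigma))


def draw_posterior_theta(
    data: IncompleteDataset, covariates, rng: np.random.Generator
) -> Theta:
    """One draw of (mu, sigma) from the Jeffreys-prior posterior.

    sigma is drawn as RSS/chisq with (n-t)-(p-1) degrees of freedom and mu
    from N(mu_hat, sigma (X'X)^-1), the standard normal-linear-model
    posterior under the independent Jeffreys prior, using complete cases.
    """
    return _draw_theta(*_posterior_state(data, covariates), rng)


@dataclass
class ImputedStack:
    """m completed copies of an incomplete dataset sharing observed values.

    Imputed values for the ``t`` missing rows are held as an (m, t) array;
    observed cells are identical across copies by construction.  ``mode``
    records the provenance of the parameter values behind the draws.
    """

    data: IncompleteDataset
    covariates: tuple[str, ...]
    mode: str  # "bayesian" | "frequentist"
    imputed: np.ndarray  # (m, t)
    theta_hat: Theta | None = None
    theta_draws: list[Theta] | None = None
    miss_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def m(self) -> int:
        return self.imputed.shape[0]

    @property
    def n(self) -> int:
        return self.data.n

    def completed_column(self, k: int) -> np.ndarray:
        """The missing-column values of copy ``k``, length n."""
        col = self.data.frame[self.data.missing_col].to_numpy(dtype=float, copy=True)
        col[self.miss_idx] = self.imputed[k]
        return col

    def completed_columns(self) -> np.ndarray:
        """(m, n) matrix of the missing column across all copies."""
        base = self.data.frame[self.data.missing_col].to_numpy(dtype=float)
        out = np.tile(base, (self.m, 1))
        out[:, self.miss_idx] = self.imputed
        return out

    def completed(self, k: int) -> pd.DataFrame:
        frame = self.data.frame.copy()
        frame[self.data.missing_col] = self.completed_column(k)
        return frame

    def stacked(self) -> pd.DataFrame:
        """The mn-row stacked dataset with subject and imputation indices."""
        frames = []
        for k in range(self.m):
            f = self.completed(k)
            f["_subject"] = np.arange(self.n)
            f["_imputation"] = k
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def impute(
    data: IncompleteDataset,
    covariates,
    m: int,
    mode: str,
    rng: np.random.Generator,
) -> ImputedStack:
    """Draw ``m`` sets of imputations for the incomplete column.

    ``bayesian`` draws a fresh (mu, sigma) from the posterior for each set;
    ``frequentist`` fixes (mu, sigma) at the complete-case MLE for all sets.
    Observed cells are never touched.
    """
    if mode not in ("bayesian", "frequentist"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    if mode == "bayesian" and m < 2:
        raise ValueError("bayesian imputation needs m >= 2 for Rubin pooling")
    if m < 1:
        raise ValueError("m must be at least 1")
    covariates = tuple(covariates)
    miss_idx = np.flatnonzero(data.r == 0)
    t = len(miss_idx)

    theta_hat = fit_imputation_mle(data, covariates)
    if t == 0:
        return ImputedStack(
            data=data, covariates=covariates, mode=mode,
            imputed=np.empty((m, 0)), theta_hat=theta_hat,
            theta_draws=[theta_hat] * m if mode == "bayesian" else None,
            miss_idx=miss_idx,
        )

    X_mis = build_design(data.frame, covariates)[miss_idx]
    imputed = np.empty((m, t))
    if mode == "frequentist":
        sd = np.sqrt(theta_hat.sigma)
        mean = X_mis @ theta_hat.mu
        for k in range(m):
            imputed[k] = mean + sd * rng.standard_normal(t)
        return ImputedStack(
            data=data, covariates=covariates, mode=mode, imputed=imputed,
            theta_hat=theta_hat, miss_idx=miss_idx,
        )

    state = _posterior_state(data, covariates)
    draws: list[Theta] = []
    for k in range(m):
        th = _draw_theta(*state, rng)
        draws.append(th)
        imputed[k] = X_mis @ th.mu + np.sqrt(th.sigma) * rng.standard_normal(t)
    return ImputedStack(
        data=data, covariates=covariates, mode=mode, imputed=imputed,
        theta_hat=theta_hat, theta_draws=draws, miss_idx=miss_idx,
    )


@dataclass
class AnalysisFit:
    """An OLS fit with model-based and HC1 sandwich covariances."""

    names: tuple[str, ...]
    beta: np.ndarray
    vcov_model: np.ndarray
    vcov_sandwich: np.ndarray
    residuals: np.ndarray
    nu_com: int  # residual degrees of freedom, rows used minus q
    n_used: int

    def se(self, robust: bool = False) -> np.ndarray:
        v = self.vcov_sandwich if robust else self.vcov_model
        return np.sqrt(np.diag(v))


def fit_analysis(obj, outcome: str, covariates, subgroup=None) -> AnalysisFit:
    """Fit the analysis OLS with model-based and HC1 sandwich covariances.

    ``obj`` is a completed DataFrame or an :class:`ImputedStack` (in which
    case the mn stacked rows are used).  ``subgroup`` restricts the rows the
    analysis uses (e.g. ``"men"``).
    """
    frame = obj.stacked() if isinstance(obj, ImputedStack) else obj
    covariates = tuple(covariates)
    mask = subgroup_mask(frame, subgroup)
    if not mask.any():
        raise ValueError("analysis subgroup is empty")
    X = build_design(frame, covariates)[mask]
    y = _get_column(frame, outcome)[mask]
    N, q = X.shape
    if N <= q:
        raise ValueError(f"only {N} rows for {q} analysis coefficients")
    beta, XtX = _checked_ols(X, y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    XtX_inv = np.linalg.inv(XtX)
    s2 = rss / (N - q)
    vcov_model = s2 * XtX_inv
    meat = (X * resid[:, None] ** 2).T @ X
    vcov_sandwich = (N / (N - q)) * XtX_inv @ meat @ XtX_inv
    return AnalysisFit(
        names=covariates, beta=beta, vcov_model=vcov_model,
        vcov_sandwich=0.5 * (vcov_sandwich + vcov_sandwich.T),
        residuals=resid, nu_com=N - q, n_used=N,
    )
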