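"""Rubin's rules for pooling multiply imputed analyses.

Per coefficient j the m completed-data estimates b_jk with within variances
W_jk are pooled as

    b_j   = mean_k b_jk
    Wbar_j = mean_k W_jk
    B_j   = (m-1)^-1 sum_k (b_jk - b_j)^2
    V_j   = Wbar_j + (m+1)/m * B_j

with confidence intervals on the Student t distribution using the
Barnard-Rubin small-sample degrees of freedom.  The *robust* variant feeds
sandwich within-variances into the same rules; the pooled point estimate is
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .imputation import ImputedStack, fit_analysis

__all__ = [
    "MIEstimate",
    "pool_rubin",
    "barnard_rubin_df",
    "rubin_interval",
    "rubin_mi",
]


@dataclass
class MIEstimate:
    """A pooled multiple-imputation inference, one entry per coefficient."""

    names: tuple[str, ...]
    beta: np.ndarray       # pooled point estimates
    Wbar: np.ndarray       # mean within-imputation variance
    B: np.ndarray          # between-imputation variance
    V: np.ndarray          # total variance Wbar + (m+1)/m B
    gamma: np.ndarray      # fraction-of-missing-information statistic
    nu_star: np.ndarray    # Barnard-Rubin adjusted degrees of freedom
    m: int
    nu_com: int

    def se(self) -> np.ndarray:
        return np.sqrt(self.V)


def barnard_rubin_df(B, Wbar, m: int, nu_com: int):
    """Barnard-Rubin adjusted degrees of freedom (vectorized).

    gamma = (1+1/m)B / (Wbar + (1+1/m)B)
    nu    = (m-1) (1 + [m/(m+1)] Wbar/B)^2
    nu_obs = (1-gamma) (nu_com+1)/(nu_com+3) nu_com
    nu*   = (1/nu + 1/nu_obs)^-1

    B = 0 is handled as the exact limit: gamma = 0, nu = inf, nu* = nu_obs.
    """
    if nu_com < 1:
        raise ValueError("nu_com must be at least 1")
    if m < 2:
        raise ValueError("Barnard-Rubin df needs m >= 2")
    B = np.asarray(B, dtype=float)
    Wbar = np.asarray(Wbar, dtype=float)
    if np.any(Wbar <= 0.0):
        raise ValueError("within-imputation variances must be positive")
    if np.any(B < 0.0):
        raise ValueError("between-imputation variance cannot be negative")
    gamma = (1.0 + 1.0 / m) * B / (Wbar + (1.0 + 1.0 / m) * B)
    nu_obs = (1.0 - gamma) * ((nu_com + 1.0) / (nu_com + 3.0)) * nu_com
    with np.errstate(divide="ignore"):
        nu = (m - 1.0) * (1.0 + (m / (m + 1.0)) * Wbar / B) ** 2
        nu_star = np.where(B > 0.0, 1.0 / (1.0 / nu + 1.0 / nu_obs), nu_obs)
    if np.ndim(B) == 0:
        return float(nu_star)
    return nu_star


def pool_rubin(betas, withins, nu_com: int, names=None) -> MIEstimate:
    """Pool an (m, q) matrix of estimates and within-variances by Rubin's rules."""
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    withins = np.atleast_2d(np.asarray(withins, dtype=float))
    if betas.shape != withins.shape:
        raise ValueError("betas and withins must have matching shapes")
    m, q = betas.shape
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 imputations")
    if np.any(withins <= 0.0):
        raise ValueError("within-imputation variances must be positive")
    beta_I = betas.mean(axis=0)
    Wbar = withins.mean(axis=0)
    B = ((betas - beta_I) ** 2).sum(axis=0) / (m - 1)
    V = Wbar + (m + 1.0) / m * B
    gamma = (1.0 + 1.0 / m) * B / (Wbar + (1.0 + 1.0 / m) * B)
    nu_star = np.asarray(barnard_rubin_df(B, Wbar, m, nu_com))
    if names is None:
        names = tuple(f"x{j}" for j in range(q))
    return MIEstimate(
        names=tuple(names), beta=beta_I, Wbar=Wbar, B=B, V=V,
        gamma=gamma, nu_star=nu_star, m=m, nu_com=nu_com,
    )


def rubin_interval(est: MIEstimate, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Student-t confidence interval at the Barnard-Rubin degrees of freedom."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0,1)")
    tq = stats.t.ppf((1.0 + level) / 2.0, est.nu_star)
    half = tq * np.sqrt(est.V)
    return est.beta - half, est.beta + half


def rubin_mi(
    stack: ImputedStack,
    outcome: str,
    analysis_covariates,
    subgroup=None,
    robust: bool = False,
) -> MIEstimate:
    """Analyse each completed copy of ``stack`` and pool by Rubin's rules.

    With ``robust=True`` the within variances come from the HC1 sandwich;
    the pooled point estimate is the same either way.
    """
    if stack.mode != "bayesian":
        raise ValueError(
            "Rubin's rules assume posterior-draw (bayesian) imputations; "
            f"got a {stack.mode!r} stack"
        )
    betas, withins, nu_com, names = _per_imputation_fits(
        stack, outcome, analysis_covariates, subgroup, robust=robust
    )
    return pool_rubin(betas, withins, nu_com, names=names)


def _per_imputation_fits(stack, outcome, covariates, subgroup, robust):
    betas, withins = [], []
    nu_com = None
    names = tuple(covariates)
    for k in range(stack.m):
        fit = fit_analysis(stack.completed(k), outcome, covariates, subgroup)
        betas.append(fit.beta)
        withins.append(np.diag(fit.vcov_sandwich if robust else fit.vcov_model))
        nu_com = fit.nu_com
    return np.array(betas), np.array(withins), nu_com, names
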