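"""Full mechanism bootstrapping (FMB) for imputation inference.

The procedure: (1) singly impute the incomplete dataset with the
imputation-model parameters fixed at the complete-case MLE and take the
analysis estimate on the completed data as the point estimate; then for
each of T replicates (2) resample n rows with replacement from the singly
imputed dataset, (3) re-impose missingness — either the observed missing
data pattern applied positionally, or Bernoulli draws from a fitted
missing-data-mechanism (MDM) model, (4) singly re-impute under the same
imputation model, (5) refit the analysis and store the estimate.  Standard
bootstrap formulae on the T replicates give the variance and normal,
percentile, bias-corrected (BC) and approximate-BCa intervals.

Under MCAR the observed pattern suffices; under MAR the MDM must be
modelled, otherwise the bootstrap variance is biased downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .dgp import IncompleteDataset
from .imputation import (
    AnalysisFit,
    build_design,
    fit_analysis,
    impute,
    subgroup_mask,
)

__all__ = [
    "BootstrapReplicates",
    "MDMModel",
    "fmb_estimate",
    "fit_mdm_model",
    "fmb_bootstrap",
    "bootstrap_variance",
    "bootstrap_interval",
]

INTERVAL_TYPES = ("normal", "percentile", "bc", "bca_approx")


@dataclass
class BootstrapReplicates:
    """T bootstrap estimates of the analysis coefficients."""

    names: tuple[str, ...]
    replicates: np.ndarray      # (T, q)
    beta_I: np.ndarray          # (q,) point estimate from step 1
    T: int
    mdm_mode: str               # "observed_mdp" | "modelled"
    failures: int = 0
    accel: np.ndarray | None = None  # jackknife acceleration constants


@dataclass
class MDMModel:
    """A frozen logistic model for the probability that weight is observed."""

    covariates: tuple[str, ...]
    coef: np.ndarray

    def prob_observed(self, cols) -> np.ndarray:
        return expit(build_design(cols, self.covariates) @ self.coef)


def fit_mdm_model(data: IncompleteDataset, covariates=None) -> MDMModel:
    """Fit the observation-indicator logistic regression on the original data.

    By default the covariates are the constant plus every fully observed
    column (which includes the analysis outcome), so a mechanism depending
    on any observed variable is correctly specified.  The fit is frozen and
    reused across all bootstrap replicates.
    """
    if covariates is None:
        covariates = ("const",) + tuple(
            c for c in data.frame.columns if c != data.missing_col
        )
    covariates = tuple(covariates)
    Z = build_design(data.frame, covariates)
    fit = sm.Logit(data.r.astype(float), Z).fit(disp=0)
    return MDMModel(covariates=covariates, coef=np.asarray(fit.params))


def fmb_estimate(
    data: IncompleteDataset,
    imputation_covariates,
    outcome: str,
    analysis_covariates,
    subgroup=None,
    rng: np.random.Generator | None = None,
):
    """Step 1: singly impute (fixed-MLE draw) and fit the analysis.

    Returns ``(fit, completed_frame)`` where ``fit.beta`` is the FMB point
    estimate.
    """
    if rng is None:
        raise ValueError("an rng is required for the imputation draw")
    stack = impute(data, imputation_covariates, 1, "frequentist", rng)
    completed = stack.completed(0)
    fit = fit_analysis(completed, outcome, analysis_covariates, subgroup)
    return fit, completed


def _jackknife_accel(fit: AnalysisFit, X: np.ndarray) -> np.ndarray:
    """BCa acceleration from exact leave-one-out OLS on the analysis fit.

    Uses the hat-matrix identity beta_(i) = beta - (X'X)^-1 x_i' e_i/(1-h_i),
    so the full jackknife costs one pass.
    """
    XtX_inv_Xt = np.linalg.solve(X.T @ X, X.T)
    h = np.einsum("nq,qn->n", X, XtX_inv_Xt)  # leverages
    adj = XtX_inv_Xt * (fit.residuals / (1.0 - h))  # (q, n) columns = delta_i
    theta_i = fit.beta[:, None] - adj  # (q, n) leave-one-out estimates
    dev = theta_i.mean(axis=1, keepdims=True) - theta_i
    num = (dev**3).sum(axis=1)
    den = 6.0 * ((dev**2).sum(axis=1)) ** 1.5
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(den > 0.0, num / den, 0.0)
    return a


def fmb_bootstrap(
    data: IncompleteDataset,
    imputation_covariates,
    outcome: str,
    analysis_covariates,
    subgroup=None,
    mdm_mode: str = "observed_mdp",
    mdm_model: MDMModel | None = None,
    T: int = 2500,
    rng: np.random.Generator | None = None,
    max_failure_frac: float = 0.05,
) -> BootstrapReplicates:
    """Steps 2-5 repeated T times; returns the bootstrap replicates.

    ``observed_mdp`` re-applies the original missingness pattern
    positionally (bootstrap row j is masked iff original row j was masked);
    ``modelled`` draws fresh indicators from ``mdm_model`` evaluated on the
    bootstrap rows (fitted on the original data if not supplied).
    Replicates whose imputation model cannot be fitted are redrawn, up to
    ``max_failure_frac * T`` discards in total.
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    if mdm_mode not in ("observed_mdp", "modelled"):
        raise ValueError(f"unknown mdm_mode {mdm_mode!r}")
    if rng is None:
        raise ValueError("an rng is required")
    imputation_covariates = tuple(imputation_covariates)
    analysis_covariates = tuple(analysis_covariates)

    fit0, completed = fmb_estimate(
        data, imputation_covariates, outcome, analysis_covariates, subgroup, rng
    )
    if mdm_mode == "modelled" and mdm_model is None:
        mdm_model = fit_mdm_model(data)

    n = data.n
    miss0 = data.r == 0
    cols0 = {c: completed[c].to_numpy(dtype=float) for c in completed.columns}
    X_imp0 = build_design(cols0, imputation_covariates)
    weight0 = cols0[data.missing_col]
    p1 = X_imp0.shape[1]
    q = len(analysis_covariates)

    # acceleration from the singly imputed dataset's analysis design
    w0 = subgroup_mask(completed, subgroup)
    accel = _jackknife_accel(fit0, build_design(cols0, analysis_covariates)[w0])

    mdm_Z0 = None
    if mdm_mode == "modelled":
        mdm_Z0 = build_design(cols0, mdm_model.covariates)

    replicates = np.empty((T, q))
    failures = 0
    max_failures = max(1, int(np.ceil(max_failure_frac * T)))
    t_stored = 0
    while t_stored < T:
        idx = rng.integers(0, n, n)
        if mdm_mode == "observed_mdp":
            miss_b = miss0
        else:
            probs = expit(mdm_Z0[idx] @ mdm_model.coef)
            miss_b = rng.random(n) >= probs
        comp_b = ~miss_b
        nc = int(comp_b.sum())
        X_b = X_imp0[idx]
        y_b = weight0[idx]
        if nc <= p1:
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"more than {max_failures} failed bootstrap replicates"
                )
            continue
        try:
            y_new = y_b.copy()
            if nc < n:  # a modelled MDM draw may leave nothing to impute
                Xc = X_b[comp_b]
                mu = np.linalg.solve(Xc.T @ Xc, Xc.T @ y_b[comp_b])
                resid = y_b[comp_b] - Xc @ mu
                sigma = float(resid @ resid) / nc
                y_new[miss_b] = X_b[miss_b] @ mu + np.sqrt(sigma) * rng.standard_normal(
                    int(miss_b.sum())
                )
            cols_b = {c: v[idx] for c, v in cols0.items()}
            cols_b[data.missing_col] = y_new
            w_b = subgroup_mask(cols_b, subgroup)
            A = build_design(cols_b, analysis_covariates)[w_b]
            if A.shape[0] <= q:
                raise np.linalg.LinAlgError("empty analysis subgroup")
            beta = np.linalg.solve(A.T @ A, A.T @ cols_b[outcome][w_b])
        except np.linalg.LinAlgError:
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"more than {max_failures} failed bootstrap replicates"
                )
            continue
        replicates[t_stored] = beta
        t_stored += 1

    return BootstrapReplicates(
        names=analysis_covariates, replicates=replicates, beta_I=fit0.beta,
        T=T, mdm_mode=mdm_mode, failures=failures, accel=accel,
    )


def bootstrap_variance(reps: BootstrapReplicates) -> np.ndarray:
    """Per-coefficient sample variance of the replicates (divisor T-1)."""
    if reps.T < 2:
        raise ValueError("T must be at least 2")
    return reps.replicates.var(axis=0, ddof=1)


def _order_statistic(sorted_reps: np.ndarray, alpha: float, clip: bool = False) -> float:
    """The floor(alpha (T+1))-th order statistic (Efron's convention).

    With ``clip`` (used for bias-corrected endpoints, whose adjusted alphas
    can be arbitrarily extreme) the index is clamped to [1, T]; otherwise a
    nonexistent order statistic is an error.
    """
    T = len(sorted_reps)
    k = int(np.floor(alpha * (T + 1)))
    if k < 1:
        if not clip:
            raise ValueError(
                f"T={T} is too small for the {alpha:.4g} order statistic"
            )
        k = 1
    k = min(k, T)
    return float(sorted_reps[k - 1])


def bootstrap_interval(
    reps: BootstrapReplicates,
    kind: str = "percentile",
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap confidence interval of the requested type.

    ``normal`` is beta_I +/- z * SD(replicates); ``percentile`` uses
    order-statistic quantiles; ``bc`` corrects for median bias via
    z0 = Phi^-1(#{b* < beta_I}/T); ``bca_approx`` additionally applies the
    jackknife acceleration constant (an approximation, since no exact
    acceleration formula exists for this procedure).
    """
    if kind not in INTERVAL_TYPES:
        raise ValueError(f"unknown interval type {kind!r}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0,1)")
    R = reps.replicates
    q = R.shape[1]
    alpha = (1.0 - level) / 2.0
    if kind == "normal":
        z = stats.norm.ppf(1.0 - alpha)
        sd = R.std(axis=0, ddof=1)
        return reps.beta_I - z * sd, reps.beta_I + z * sd

    lo = np.empty(q)
    hi = np.empty(q)
    for j in range(q):
        r = np.sort(R[:, j])
        if kind == "percentile":
            a_lo, a_hi = alpha, 1.0 - alpha
        else:
            frac = float((R[:, j] < reps.beta_I[j]).mean())
            if frac == 0.0 or frac == 1.0:
                raise ValueError(
                    "bias correction undefined: all replicates fall on one "
                    f"side of the estimate for coefficient {reps.names[j]!r}"
                )
            z0 = stats.norm.ppf(frac)
            a = 0.0
            if kind == "bca_approx":
                if reps.accel is None:
                    raise ValueError("no acceleration constants stored on replicates")
                a = float(reps.accel[j])
            z_lo, z_hi = stats.norm.ppf(alpha), stats.norm.ppf(1.0 - alpha)
            a_lo = stats.norm.cdf(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo)))
            a_hi = stats.norm.cdf(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi)))
        clip = kind != "percentile"
        lo[j] = _order_statistic(r, a_lo, clip=clip)
        hi[j] = _order_statistic(r, a_hi, clip=clip)
    return lo, hi
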