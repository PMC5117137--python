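"""Robins-Wang frequentist multiple imputation inference.

The point estimate solves the analysis estimating equation on the stack of
m imputed datasets (imputations drawn with the imputation-model parameters
fixed at the complete-case MLE theta_hat), treating the mn rows as
independent — for OLS this is simply the stacked regression.

The variance estimator combines imputer-side and analyst-side artifacts.
The imputer supplies, from the imputation-model log likelihood
l_i(theta) = -0.5[log 2 pi + log sigma + (y_i - x_i mu)^2 / sigma]:

* ``s_obs``  — per-subject scores at the observed values (zero rows for
  incomplete subjects),
* ``S_mis`` — per-subject, per-imputation scores at the imputed values
  (zero rows for complete subjects),
* ``D``     — d_i' = -Hbar^-1 s_obs_i', where Hbar is the averaged Hessian
  over complete subjects (divisor n).

The analyst supplies the stacked estimating functions
u_ik = x_ik' (y_ik - x_ik beta) and the derivative matrix
tau = (nm)^-1 sum_ik x_ik' x_ik, then evaluates

    kappa  = (nm)^-1 sum_ik u_ik s_ik^mis
    Lambda = n^-1 sum_i d_i' d_i
    Omega  = n^-1 sum_i ubar_i' ubar_i
    Delta  = Omega + kappa Lambda kappa' + n^-1 sum_i {kappa d_i' ubar_i + (.)'}
    Gamma  = n^-1 tau^-1 Delta tau^-T

whose diagonal provides the coefficient variance estimates.  In a subgroup
analysis, subjects outside the subgroup contribute zero estimating
functions while all n subjects still enter the averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dgp import IncompleteDataset
from .imputation import ImputedStack, Theta, build_design, subgroup_mask

__all__ = [
    "ScoreBundle",
    "RWComponents",
    "build_score_bundle",
    "rw_point_estimate",
    "rw_variance",
    "rw_interval",
    "robins_wang_mi",
    "export_score_bundle",
    "import_score_bundle",
]


@dataclass
class ScoreBundle:
    """Imputer-side artifacts of the variance estimator.

    Score vectors are ordered (mu components..., sigma), dimension
    p = (number of imputation covariates) + 1.
    """

    s_obs: np.ndarray   # (n, p); zero rows for incomplete subjects
    S_mis: np.ndarray   # (m, n, p); zero rows for complete subjects
    H_bar: np.ndarray   # (p, p) averaged Hessian, divisor n
    D: np.ndarray       # (n, p); zero rows for incomplete subjects

    @property
    def n(self) -> int:
        return self.s_obs.shape[0]

    @property
    def p(self) -> int:
        return self.s_obs.shape[1]

    @property
    def m(self) -> int:
        return self.S_mis.shape[0]


@dataclass
class RWComponents:
    """Analyst-side matrices; ``Gamma``'s diagonal holds the variances."""

    names: tuple[str, ...]
    U: np.ndarray        # (m, n, q) estimating functions at beta_I
    u_bar: np.ndarray    # (n, q) per-subject means over imputations
    tau: np.ndarray      # (q, q)
    kappa: np.ndarray    # (q, p)
    Lambda: np.ndarray   # (p, p)
    Omega: np.ndarray    # (q, q)
    Delta: np.ndarray    # (q, q)
    Gamma: np.ndarray    # (q, q)

    def variances(self) -> np.ndarray:
        return np.diag(self.Gamma).copy()


def _score_terms(y: np.ndarray, X: np.ndarray, theta: Theta) -> np.ndarray:
    """Per-row score vectors (d/d mu, d/d sigma) of the imputation model."""
    resid = y - X @ theta.mu
    s_mu = (resid / theta.sigma)[:, None] * X
    s_sigma = 0.5 * (-1.0 / theta.sigma + resid**2 / theta.sigma**2)
    return np.column_stack([s_mu, s_sigma])


def build_score_bundle(
    data: IncompleteDataset,
    stack: ImputedStack,
    theta_hat: Theta | None = None,
    covariates=None,
) -> ScoreBundle:
    """Compute s_obs, S_mis, the averaged Hessian and D from a frequentist stack.

    Incomplete subjects contribute zero rows to s_obs, the Hessian average
    and D; complete subjects contribute zero rows to S_mis.
    """
    if stack.mode != "frequentist":
        raise ValueError("score bundle requires a frequentist (fixed-theta) stack")
    covariates = tuple(covariates) if covariates is not None else stack.covariates
    theta = theta_hat if theta_hat is not None else stack.theta_hat
    n = data.n
    comp = data.r == 1
    miss_idx = stack.miss_idx
    X = build_design(data.frame, covariates)
    p1 = X.shape[1]
    p = p1 + 1
    y = data.frame[data.missing_col].to_numpy(dtype=float)

    s_obs = np.zeros((n, p))
    s_obs[comp] = _score_terms(y[comp], X[comp], theta)

    S_mis = np.zeros((stack.m, n, p))
    if len(miss_idx):
        X_mis = X[miss_idx]
        for k in range(stack.m):
            S_mis[k, miss_idx] = _score_terms(stack.imputed[k], X_mis, theta)

    # Hessian of the log likelihood, averaged over complete subjects with
    # divisor n (incomplete subjects contribute zero).
    Xc = X[comp]
    resid_c = y[comp] - Xc @ theta.mu
    sig = theta.sigma
    H = np.zeros((p, p))
    H[:p1, :p1] = -(Xc.T @ Xc) / sig
    cross = -(Xc.T @ resid_c) / sig**2
    H[:p1, p1] = cross
    H[p1, :p1] = cross
    H[p1, p1] = comp.sum() / (2.0 * sig**2) - float(resid_c @ resid_c) / sig**3
    H /= n

    H_inv = np.linalg.inv(H)
    D = np.zeros((n, p))
    D[comp] = -s_obs[comp] @ H_inv.T  # d_i' = -Hbar^-1 s_obs_i'
    return ScoreBundle(s_obs=s_obs, S_mis=S_mis, H_bar=H, D=D)


def _analysis_arrays(stack: ImputedStack, outcome: str, covariates, subgroup):
    """Per-imputation analysis designs and outcomes, with subgroup mask."""
    covariates = tuple(covariates)
    base = {c: stack.data.frame[c].to_numpy(dtype=float) for c in stack.data.frame.columns}
    w = subgroup_mask(stack.data.frame, subgroup)
    m, n = stack.m, stack.n
    cols = stack.completed_columns()  # (m, n)
    A = np.empty((m, n, len(covariates)))
    Y = np.empty((m, n))
    for k in range(m):
        ck = dict(base)
        ck[stack.data.missing_col] = cols[k]
        A[k] = build_design(ck, covariates)
        Y[k] = ck[outcome]
    return A, Y, w


def rw_point_estimate(
    stack: ImputedStack, outcome: str, covariates, subgroup=None
) -> np.ndarray:
    """OLS on the mn stacked rows (restricted to the analysis subgroup)."""
    if stack.mode != "frequentist":
        raise ValueError(
            "the Robins-Wang estimator requires imputations drawn at a fixed "
            "theta_hat; got a bayesian stack"
        )
    A, Y, w = _analysis_arrays(stack, outcome, covariates, subgroup)
    Aw = A * w[None, :, None]
    q = Aw.shape[2]
    G = np.einsum("kni,knj->ij", Aw, Aw)
    if int(w.sum()) * stack.m <= q:
        raise ValueError("too few subgroup rows for the analysis model")
    b = np.einsum("kni,kn->i", Aw, Y * w[None, :])
    return np.linalg.solve(G, b)


def rw_variance(
    bundle: ScoreBundle,
    stack: ImputedStack,
    beta_I: np.ndarray,
    outcome: str,
    covariates,
    subgroup=None,
) -> RWComponents:
    """Assemble the matrix formulae into the covariance estimate Gamma."""
    A, Y, w = _analysis_arrays(stack, outcome, covariates, subgroup)
    m, n, q = A.shape
    if bundle.n != n or bundle.m != m:
        raise ValueError("score bundle dimensions do not match the stack")
    resid = (Y - np.einsum("knq,q->kn", A, np.asarray(beta_I, float))) * w[None, :]
    U = A * resid[:, :, None]  # rows outside the subgroup are zero
    Aw = A * w[None, :, None]
    tau = np.einsum("kni,knj->ij", Aw, Aw) / (n * m)
    if np.linalg.matrix_rank(tau) < q:
        raise np.linalg.LinAlgError("tau is singular")
    u_bar = U.mean(axis=0)
    kappa = np.einsum("knq,knp->qp", U, bundle.S_mis) / (n * m)
    Lambda = bundle.D.T @ bundle.D / n
    Omega = u_bar.T @ u_bar / n
    cross = kappa @ (bundle.D.T @ u_bar) / n  # n^-1 sum_i kappa d_i' ubar_i
    Delta = Omega + kappa @ Lambda @ kappa.T + cross + cross.T
    tau_inv = np.linalg.inv(tau)
    Gamma = tau_inv @ Delta @ tau_inv.T / n
    Gamma = 0.5 * (Gamma + Gamma.T)
    return RWComponents(
        names=tuple(covariates), U=U, u_bar=u_bar, tau=tau, kappa=kappa,
        Lambda=Lambda, Omega=Omega, Delta=Delta, Gamma=Gamma,
    )


def rw_interval(
    beta_I: np.ndarray, components: RWComponents, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Wald interval on normal quantiles from Gamma's diagonal."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0,1)")
    var = np.diag(components.Gamma)
    if np.any(var < 0.0):
        bad = int(np.argmax(var < 0.0))
        raise ValueError(
            f"negative variance estimate for coefficient "
            f"{components.names[bad]!r} (index {bad})"
        )
    z = stats.norm.ppf((1.0 + level) / 2.0)
    half = z * np.sqrt(var)
    beta_I = np.asarray(beta_I, float)
    return beta_I - half, beta_I + half


def robins_wang_mi(
    data: IncompleteDataset,
    imputation_covariates,
    outcome: str,
    analysis_covariates,
    subgroup=None,
    m: int = 50,
    rng: np.random.Generator | None = None,
    stack: ImputedStack | None = None,
) -> tuple[np.ndarray, RWComponents]:
    """End-to-end Robins-Wang inference; returns (beta_I, components)."""
    from .imputation import impute

    if stack is None:
        if rng is None:
            raise ValueError("either a stack or an rng must be supplied")
        stack = impute(data, imputation_covariates, m, "frequentist", rng)
    beta_I = rw_point_estimate(stack, outcome, analysis_covariates, subgroup)
    bundle = build_score_bundle(data, stack)
    comps = rw_variance(bundle, stack, beta_I, outcome, analysis_covariates, subgroup)
    return beta_I, comps


def export_score_bundle(bundle: ScoreBundle, directory) -> None:
    """Write S_mis and D as provenance-indexed CSVs for hand-off to an analyst.

    ``S_mis.csv`` has one row per (subject i, imputation k) pair and
    ``D.csv`` one row per subject, score components in columns s1..sp.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    m, n, p = bundle.S_mis.shape
    cols = [f"s{j + 1}" for j in range(p)]
    smis = pd.DataFrame(bundle.S_mis.reshape(m * n, p), columns=cols)
    smis.insert(0, "k", np.repeat(np.arange(m), n))
    smis.insert(0, "i", np.tile(np.arange(n), m))
    smis.to_csv(directory / "S_mis.csv", index=False)
    d = pd.DataFrame(bundle.D, columns=cols)
    d.insert(0, "i", np.arange(n))
    d.to_csv(directory / "D.csv", index=False)


def import_score_bundle(directory) -> tuple[np.ndarray, np.ndarray]:
    """Read back (S_mis, D) written by :func:`export_score_bundle`."""
    directory = Path(directory)
    smis = pd.read_csv(directory / "S_mis.csv")
    d = pd.read_csv(directory / "D.csv").sort_values("i")
    p = d.shape[1] - 1
    n = d.shape[0]
    m = smis["k"].max() + 1
    S = np.zeros((m, n, p))
    cols = [f"s{j + 1}" for j in range(p)]
    for k, grp in smis.groupby("k"):
        grp = grp.sort_values("i")
        S[k] = grp[cols].to_numpy()
    return S, d[cols].to_numpy()
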