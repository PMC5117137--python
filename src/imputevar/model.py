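"""Model/Results front end for regression with one incompletely observed variable.

:class:`MIRegression` is built from a data frame in which exactly one
column has missing values, together with the imputation-model and
analysis-model specifications.  Its :meth:`~MIRegression.fit` dispatches to
one of four inference procedures and returns an
:class:`MIRegressionResults` carrying the coefficient estimates, their
variance estimates, confidence intervals and a ``summary()`` table:

``rubin``
    Posterior-draw multiple imputation pooled by Rubin's rules with
    Barnard-Rubin degrees of freedom.
``rubin_robust``
    The same, with HC1 sandwich within-imputation variances.
``rw``
    Robins-Wang: fixed-MLE imputations analysed as one stacked regression,
    with the score-based estimating-equation variance.
``fmb``
    Full mechanism bootstrapping with normal / percentile / BC /
    approximate-BCa intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fmb as fmb_mod
from . import robins_wang as rw_mod
from .dgp import IncompleteDataset
from .imputation import impute
from .rubin import rubin_interval, rubin_mi

__all__ = ["MIRegression", "MIRegressionResults"]


class MIRegression:
    """Regression of an outcome on covariates when one covariate (or the
    outcome) is incompletely observed and must be imputed.

    Parameters
    ----------
    data
        DataFrame with NaN in exactly one column, or an
        :class:`~imputevar.dgp.IncompleteDataset`.
    missing
        Name of the incomplete column (imputation-model response).
    imputation_covariates, analysis_covariates
        Explicit column lists; include ``"const"`` for an intercept and use
        ``"a:b"`` for an interaction.
    outcome
        Analysis-model response column.
    subgroup
        Optional row restriction for the analysis (``"men"`` or a boolean
        mask).
    """

    def __init__(
        self,
        data,
        missing: str,
        imputation_covariates,
        outcome: str,
        analysis_covariates,
        subgroup=None,
    ):
        if isinstance(data, IncompleteDataset):
            self.data = data
        else:
            self.data = IncompleteDataset.from_frame(pd.DataFrame(data), missing)
        self.missing = missing
        self.imputation_covariates = tuple(imputation_covariates)
        self.analysis_covariates = tuple(analysis_covariates)
        self.outcome = outcome
        self.subgroup = subgroup

    @classmethod
    def from_csv(cls, path, missing, imputation_covariates, outcome,
                 analysis_covariates, subgroup=None) -> "MIRegression":
        """Read a delimited file (missing cells empty or ``NA``)."""
        frame = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
        return cls(frame, missing, imputation_covariates, outcome,
                   analysis_covariates, subgroup)

    def fit(
        self,
        method: str = "rubin",
        m: int = 50,
        T: int = 2500,
        level: float = 0.95,
        seed=None,
        mdm_mode: str = "observed_mdp",
        interval: str = "percentile",
    ) -> "MIRegressionResults":
        """Run one inference procedure and return its results object."""
        rng = np.random.default_rng(seed)
        names = self.analysis_covariates
        diag = None
        df = None
        if method in ("rubin", "rubin_robust"):
            stack = impute(self.data, self.imputation_covariates, m, "bayesian", rng)
            est = rubin_mi(stack, self.outcome, names, self.subgroup,
                           robust=(method == "rubin_robust"))
            lo, hi = rubin_interval(est, level)
            params, variances, df, diag = est.beta, est.V, est.nu_star, est
        elif method == "rw":
            beta, comps = rw_mod.robins_wang_mi(
                self.data, self.imputation_covariates, self.outcome, names,
                subgroup=self.subgroup, m=m, rng=rng,
            )
            lo, hi = rw_mod.rw_interval(beta, comps, level)
            params, variances, diag = beta, comps.variances(), comps
        elif method == "fmb":
            reps = fmb_mod.fmb_bootstrap(
                self.data, self.imputation_covariates, self.outcome, names,
                subgroup=self.subgroup, mdm_mode=mdm_mode, T=T, rng=rng,
            )
            lo, hi = fmb_mod.bootstrap_interval(reps, interval, level)
            params, variances, diag = reps.beta_I, fmb_mod.bootstrap_variance(reps), reps
        else:
            raise ValueError(f"unknown method {method!r}")
        return MIRegressionResults(
            model=self, method=method, names=names,
            params=np.asarray(params, float), variances=np.asarray(variances, float),
            ci_lower=np.asarray(lo, float), ci_upper=np.asarray(hi, float),
            level=level, m=m, df=df, diagnostics=diag, interval=interval,
        )


@dataclass
class MIRegressionResults:
    """Estimates, variances and intervals from one inference procedure."""

    model: MIRegression
    method: str
    names: tuple[str, ...]
    params: np.ndarray
    variances: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    level: float
    m: int
    df: np.ndarray | None = None
    diagnostics: object = None
    interval: str = "percentile"

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(self.variances), index=self.names)

    @property
    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.names)

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lower": self.ci_lower, "upper": self.ci_upper}, index=self.names
        )

    def summary(self) -> str:
        d = self.model.data
        head = [
            "Imputation inference for incomplete-data regression",
            "=" * 64,
            f"method: {self.method:<14} outcome: {self.model.outcome}",
            f"n: {d.n:<6} missing {d.missing_col}: {d.t} "
            f"({100.0 * d.t / d.n:.1f}%)",
        ]
        if self.method in ("rubin", "rubin_robust", "rw"):
            head.append(f"imputations (m): {self.m}")
        else:
            head.append(
                f"bootstrap replicates (T): {self.diagnostics.T}, "
                f"interval: {self.interval}, mdm: {self.diagnostics.mdm_mode}"
            )
        a = (1.0 - self.level) / 2.0
        rows = [
            "-" * 64,
            f"{'':<12}{'coef':>10}{'se':>10}"
            f"{f'[{a:.3f}':>10}{f'{1 - a:.3f}]':>9}"
            + (f"{'df':>9}" if self.df is not None else ""),
        ]
        se = np.sqrt(self.variances)
        for j, name in enumerate(self.names):
            line = (
                f"{name:<12}{self.params[j]:>10.4f}{se[j]:>10.4f}"
                f"{self.ci_lower[j]:>10.4f}{self.ci_upper[j]:>9.4f}"
            )
            if self.df is not None:
                line += f"{self.df[j]:>9.1f}"
            rows.append(line)
        rows.append("=" * 64)
        return "\n".join(head + rows)
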