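"""Synthetic anthropometric data generation and missingness mechanisms.

The simulation laboratory draws datasets of five variables — ``sex``
(0 = male, 1 = female), ``age``, ``height``, ``weight`` and ``loginsindex``
(natural log of an insulin index) — from a chained linear model calibrated
to a cohort of young adults:

    sex ~ Bernoulli(pi)
    (age, height) | sex ~ N(alpha0 + alpha1 * sex, Sigma)
    weight      = iota0 + iota1*sex + iota2*age + iota3*height
                  + eta**sex * lambda_w * error_W
    loginsindex = beta0 + beta1*sex + beta2*age + beta3*weight
                  + eta**sex * omega_l * error_L

where ``error_W`` and ``error_L`` are i.i.d. errors standardized to mean 0
and variance 1, and ``eta**sex`` is 1 for men and ``eta`` for women, so
``eta`` scales the female residual standard deviations.

Missingness is imposed on ``weight`` only, under MCAR (everyone, or men
only) or MAR with the observation probability logistic in the analysis
outcome ``loginsindex``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "ScenarioConfig",
    "IncompleteDataset",
    "ERROR_DISTS",
    "SCENARIO_NAMES",
    "scenario_config",
    "sample_standardized_error",
    "generate_complete",
    "apply_mdm",
]

ERROR_DISTS = (
    "normal",
    "uniform",
    "t3",
    "t6",
    "lognormal_mild",
    "lognormal_severe",
)

SCENARIO_NAMES = (
    "subgroup",
    "heteroscedastic",
    "interaction",
    "nonnormal",
    "mar_followup",
)

# Calibrated parameter values of the data model (four significant figures).
_PI = 0.4577
_ALPHA0 = (25.02, 1.774)
_ALPHA1 = (-0.03616, -0.1336)
_SIGMA = ((0.5521, 0.001574), (0.001574, 0.003705))
_IOTA = (-32.98, -2.314, -0.01566, 65.38)
_LAMBDA_W = 12.29
_BETA = (1.854, 0.2908, 0.08003, 0.01119)
_OMEGA_L = 0.7887
_ETA = 0.5

# Slope of the MAR observation model on the standardized outcome.
_MAR_SLOPE = 1.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one simulation scenario.

    Holds the data-model parameters, the error-distribution choices, the
    missing-data mechanism, the imputation/analysis model specifications and
    the simulation sizes.  Covariate lists name columns explicitly; the
    constant term is the explicit column ``"const"`` and an interaction is
    written ``"a:b"``.
    """

    name: str
    pi: float = _PI
    alpha0: tuple[float, float] = _ALPHA0
    alpha1: tuple[float, float] = _ALPHA1
    Sigma: tuple[tuple[float, float], tuple[float, float]] = _SIGMA
    iota: tuple[float, float, float, float] = _IOTA
    lambda_w: float = _LAMBDA_W
    beta_dgp: tuple[float, float, float, float] = _BETA
    omega_l: float = _OMEGA_L
    eta: float = 1.0
    error_w_dist: str = "normal"
    error_l_dist: str = "normal"
    n: int = 1000
    p_obs: float = 0.4
    mdm: str = "mcar_all"
    imputation_covariates: tuple[str, ...] = ()
    analysis_covariates: tuple[str, ...] = ()
    analysis_subgroup: str = "all"
    m: int = 50
    T_boot: int = 2500
    n_reps: int = 2500
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError(f"pi must lie in (0,1), got {self.pi}")
        if not 0.0 < self.p_obs < 1.0:
            raise ValueError(f"p_obs must lie in (0,1), got {self.p_obs}")
        if self.eta <= 0.0:
            raise ValueError("eta must be positive")
        if self.n < 20:
            raise ValueError("n must be at least 20")
        S = np.asarray(self.Sigma, dtype=float)
        if S.shape != (2, 2) or not np.allclose(S, S.T):
            raise ValueError("Sigma must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(S) <= 0.0):
            raise ValueError("Sigma must be positive definite")
        for d in (self.error_w_dist, self.error_l_dist):
            if d not in ERROR_DISTS:
                raise ValueError(f"unknown error distribution {d!r}")
        if self.mdm not in ("mcar_all", "mcar_men_only", "mar_on_loginsindex"):
            raise ValueError(f"unknown missing-data mechanism {self.mdm!r}")
        if self.analysis_subgroup not in ("all", "men"):
            raise ValueError(f"unknown subgroup {self.analysis_subgroup!r}")

    def true_beta(self) -> dict[str, float]:
        """True analysis-model coefficients implied by the data model.

        The weight coefficient equals ``beta3`` in every scenario; an
        interaction term, when present, has true coefficient 0; in a
        men-only subgroup analysis the sex terms are absent.
        """
        b0, b1, b2, b3 = self.beta_dgp
        truth: dict[str, float] = {}
        for name in self.analysis_covariates:
            if name == "const":
                truth[name] = b0
            elif name == "sex":
                truth[name] = b1
            elif name == "age":
                truth[name] = b2
            elif name == "weight":
                truth[name] = b3
            elif name in ("weight:sex", "sex:weight"):
                truth[name] = 0.0
            else:  # pragma: no cover - presets never reach here
                raise KeyError(f"no known true value for column {name!r}")
        return truth


@dataclass
class IncompleteDataset:
    """A complete data frame with the weight column masked for some rows.

    ``frame`` carries NaN in ``missing_col`` where ``r == 0``; ``r`` is the
    observation indicator (1 = observed) and ``t`` the number of missing
    rows.  Only one column is ever incomplete.
    """

    frame: pd.DataFrame
    missing_col: str = "weight"
    r: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    t: int = 0

    def __post_init__(self) -> None:
        n = len(self.frame)
        self.r = np.asarray(self.r, dtype=int)
        if self.r.shape != (n,):
            raise ValueError("observation indicator must have one entry per row")
        if self.t != n - int(self.r.sum()):
            raise ValueError("t inconsistent with observation indicator")
        nan_mask = self.frame[self.missing_col].isna().to_numpy()
        if not np.array_equal(nan_mask, self.r == 0):
            raise ValueError("NaN pattern must match the observation indicator")
        other = self.frame.drop(columns=[self.missing_col])
        if other.isna().any().any():
            raise ValueError("only the designated column may contain missing values")

    @property
    def n(self) -> int:
        return len(self.frame)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, missing_col: str) -> "IncompleteDataset":
        r = (~frame[missing_col].isna()).to_numpy().astype(int)
        return cls(frame=frame, missing_col=missing_col, r=r, t=int((r == 0).sum()))


def scenario_config(
    name: str,
    n: int = 1000,
    p_obs: float = 0.4,
    variant: tuple[str, str] | None = None,
    **overrides,
) -> ScenarioConfig:
    """Return the named scenario preset.

    Parameters
    ----------
    name
        One of ``subgroup`` (null sex effects, weight MCAR-missing in men
        only, men-only analysis), ``heteroscedastic`` (non-null sex effects,
        female residual SDs halved), ``interaction`` (non-null sex effects,
        analysis adds a spurious weight-by-sex interaction), ``nonnormal``
        (null sex effects, configurable error distributions) or
        ``mar_followup`` (correctly specified models, weight missing at
        random dependent on loginsindex).
    variant
        ``(error_w_dist, error_l_dist)`` pair, accepted only by
        ``nonnormal``; defaults there to normal errors.
    overrides
        Passed through to :class:`ScenarioConfig` (e.g. ``m``, ``n_reps``,
        ``seed``).
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    if variant is not None and name != "nonnormal":
        raise ValueError(f"scenario {name!r} does not accept an error-distribution variant")

    null_means = dict(alpha1=(0.0, 0.0), iota=(_IOTA[0], 0.0, _IOTA[2], _IOTA[3]),
                      beta_dgp=(_BETA[0], 0.0, _BETA[2], _BETA[3]))
    imp_full = ("const", "sex", "age", "height", "loginsindex")
    imp_nosex = ("const", "age", "height", "loginsindex")
    ana_full = ("const", "sex", "age", "weight")
    ana_nosex = ("const", "age", "weight")

    if name == "subgroup":
        cfg = ScenarioConfig(
            name=name, n=n, p_obs=p_obs, eta=1.0, mdm="mcar_men_only",
            imputation_covariates=imp_nosex, analysis_covariates=ana_nosex,
            analysis_subgroup="men", **null_means, **overrides,
        )
    elif name == "heteroscedastic":
        cfg = ScenarioConfig(
            name=name, n=n, p_obs=p_obs, eta=_ETA, mdm="mcar_all",
            imputation_covariates=imp_full, analysis_covariates=ana_full,
            **overrides,
        )
    elif name == "interaction":
        cfg = ScenarioConfig(
            name=name, n=n, p_obs=p_obs, eta=1.0, mdm="mcar_all",
            imputation_covariates=imp_full,
            analysis_covariates=ana_full + ("weight:sex",),
            **overrides,
        )
    elif name == "nonnormal":
        err_w, err_l = variant if variant is not None else ("normal", "normal")
        cfg = ScenarioConfig(
            name=name, n=n, p_obs=p_obs, eta=1.0, mdm="mcar_all",
            error_w_dist=err_w, error_l_dist=err_l,
            imputation_covariates=imp_nosex, analysis_covariates=ana_nosex,
            **null_means, **overrides,
        )
    else:  # mar_followup
        cfg = ScenarioConfig(
            name=name, n=n, p_obs=p_obs, eta=1.0, mdm="mar_on_loginsindex",
            imputation_covariates=imp_full, analysis_covariates=ana_full,
            **overrides,
        )
    return cfg


def _lognormal_constants(s: float) -> tuple[float, float]:
    """Mean and SD of exp{N(0, s^2)} in closed form."""
    mean = np.exp(s * s / 2.0)
    sd = np.sqrt((np.exp(s * s) - 1.0) * np.exp(s * s))
    return mean, sd


def sample_standardized_error(dist: str, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. errors from ``dist`` standardized to mean 0, variance 1.

    Standardizing constants are closed-form: the uniform is scaled to
    support [-sqrt(3), sqrt(3)]; Student-t with nu degrees of freedom is
    scaled by sqrt((nu-2)/nu); the lognormal exp{N(0,s^2)} is centred at
    exp(s^2/2) and scaled by its SD, with s = 1/4 (mild) or 1 (severe).
    """
    if size < 1:
        raise ValueError("size must be at least 1")
    if dist == "normal":
        return rng.standard_normal(size)
    if dist == "uniform":
        return rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size)
    if dist in ("t3", "t6"):
        df = 3 if dist == "t3" else 6
        if df <= 2:
            raise ValueError("t-distribution needs df > 2 for a finite variance")
        return rng.standard_t(df, size) * np.sqrt((df - 2.0) / df)
    if dist in ("lognormal_mild", "lognormal_severe"):
        s = 0.25 if dist == "lognormal_mild" else 1.0
        mean, sd = _lognormal_constants(s)
        return (np.exp(rng.normal(0.0, s, size)) - mean) / sd
    raise ValueError(f"unknown error distribution {dist!r}")


def generate_complete(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a complete dataset of ``config.n`` rows from the data model."""
    n = config.n
    sex = (rng.random(n) < config.pi).astype(float)
    mean = np.asarray(config.alpha0, float) + np.outer(sex, np.asarray(config.alpha1, float))
    L = np.linalg.cholesky(np.asarray(config.Sigma, float))
    ah = mean + rng.standard_normal((n, 2)) @ L.T
    age, height = ah[:, 0], ah[:, 1]

    scale = config.eta**sex  # 1 for men, eta for women
    i0, i1, i2, i3 = config.iota
    err_w = sample_standardized_error(config.error_w_dist, n, rng)
    weight = i0 + i1 * sex + i2 * age + i3 * height + scale * config.lambda_w * err_w

    b0, b1, b2, b3 = config.beta_dgp
    err_l = sample_standardized_error(config.error_l_dist, n, rng)
    loginsindex = b0 + b1 * sex + b2 * age + b3 * weight + scale * config.omega_l * err_l

    return pd.DataFrame(
        {"sex": sex, "age": age, "height": height, "weight": weight,
         "loginsindex": loginsindex}
    )


def _mar_observation_probs(loginsindex: np.ndarray, p_obs: float) -> np.ndarray:
    """Logistic-in-outcome observation probabilities calibrated to p_obs.

    P(observed) = expit(psi0 + z) with z the standardized outcome; psi0 is
    solved so the within-sample mean observation probability equals p_obs.
    """
    z = (loginsindex - loginsindex.mean()) / loginsindex.std()
    z = _MAR_SLOPE * z

    def gap(psi0: float) -> float:
        return float(special.expit(psi0 + z).mean() - p_obs)

    psi0 = optimize.brentq(gap, -30.0, 30.0, xtol=1e-12)
    return special.expit(psi0 + z)


def _draw_indicator(data: pd.DataFrame, config: ScenarioConfig,
                    rng: np.random.Generator) -> np.ndarray:
    n = len(data)
    if config.mdm == "mcar_all":
        return (rng.random(n) < config.p_obs).astype(int)
    if config.mdm == "mcar_men_only":
        men = data["sex"].to_numpy() == 0.0
        r = np.ones(n, dtype=int)
        r[men] = (rng.random(int(men.sum())) < config.p_obs).astype(int)
        return r
    probs = _mar_observation_probs(data["loginsindex"].to_numpy(), config.p_obs)
    return (rng.random(n) < probs).astype(int)


def apply_mdm(
    data: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator,
    *,
    resample_degenerate: bool = True,
    max_redraws: int = 100,
) -> IncompleteDataset:
    """Mask the weight column of ``data`` under the configured mechanism.

    A degenerate indicator (no missing rows, or none observed) is redrawn up
    to ``max_redraws`` times when ``resample_degenerate`` is set (simulation
    mode), and is a fatal error otherwise.
    """
    n = len(data)
    for _ in range(max_redraws if resample_degenerate else 1):
        r = _draw_indicator(data, config, rng)
        t = n - int(r.sum())
        if 0 < t < n:
            frame = data.copy()
            col = frame["weight"].to_numpy(dtype=float, copy=True)
            col[r == 0] = np.nan
            frame["weight"] = col
            return IncompleteDataset(frame=frame, missing_col="weight", r=r, t=t)
    raise RuntimeError(
        "degenerate missingness pattern (t=0 or t=n); "
        "cannot proceed with imputation"
    )


def with_config(config: ScenarioConfig, **changes) -> ScenarioConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return replace(config, **changes)


def config_to_dict(config: ScenarioConfig) -> dict:
    d = asdict(config)
    d["Sigma"] = [list(row) for row in config.Sigma]
    for key in ("alpha0", "alpha1", "iota", "beta_dgp",
                "imputation_covariates", "analysis_covariates"):
        d[key] = list(d[key])
    return d


def config_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    d["Sigma"] = tuple(tuple(row) for row in d["Sigma"])
    for key in ("alpha0", "alpha1", "iota", "beta_dgp",
                "imputation_covariates", "analysis_covariates"):
        d[key] = tuple(d[key])
    return ScenarioConfig(**d)


def save_dataset(data, path, config: ScenarioConfig | None = None) -> None:
    """Write a (possibly incomplete) dataset as CSV with a header row.

    Missing weight cells are written as empty fields.  If ``config`` is
    given, a JSON sidecar ``<path>.config.json`` records the scenario
    configuration.
    """
    frame = data.frame if isinstance(data, IncompleteDataset) else data
    frame.to_csv(path, index=False, na_rep="")
    if config is not None:
        with open(f"{path}.config.json", "w") as fh:
            json.dump(config_to_dict(config), fh, indent=2)


def load_dataset(path, missing_col: str = "weight") -> IncompleteDataset:
    """Read a CSV written by :func:`save_dataset` (or any user CSV with
    empty/NA cells in one column)."""
    frame = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    return IncompleteDataset.from_frame(frame, missing_col)
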