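# Methods

This note documents the models, estimators and numerical choices behind
`imputevar`, in the spirit of a statistical package's methods appendix. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Setting

$g$ variables are intended on $n$ i.i.d. subjects; exactly one variable
(here `weight`, generically $Y_g$) is missing for $t$ of them
($0 < t < n$), and the missing-data mechanism is ignorable. The
**imputation model** is the normal linear regression
$y_{ig}\mid \tilde y_i \sim N(\tilde y_i\mu,\ \sigma)$ on $p-1$ fully
observed covariates (including an explicit constant); throughout the
package $\sigma$ is the error **variance**, which is what makes the score
and Hessian formulae below internally consistent. The **analysis
procedure** is OLS of an outcome on $q$ covariates (one of which may be the
imputed variable, and which may include an interaction such as
`weight:sex`), optionally restricted to a subgroup. Multivariate missing
patterns and chained-equations imputation are out of scope: the
stacked-imputation variance theory requires a single imputation model.

## The four inference procedures

**Rubin's MI.** Imputations are proper: for each of $m\ (\ge 2)$ copies a
fresh $(\mu,\sigma)$ is drawn from the complete-case Jeffreys-prior
posterior — $\sigma \sim \mathrm{RSS}/\chi^2_{n-t-(p-1)}$, then
$\mu \sim N(\hat\mu,\ \sigma(X^TX)^{-1})$ — and missing values from
$N(\tilde y_i\mu,\sigma)$. Per-coefficient pooling uses Rubin's rules
($\hat V = \bar W + \frac{m+1}{m}B$) and Student-$t$ intervals on the
Barnard–Rubin degrees of freedom

$$\hat\gamma=\frac{(1+m^{-1})B}{\bar W+(1+m^{-1})B},\quad
\nu=(m-1)\Big(1+\tfrac{m}{m+1}\tfrac{\bar W}{B}\Big)^2,\quad
\hat\nu_{obs}=(1-\hat\gamma)\tfrac{\nu_{com}+1}{\nu_{com}+3}\nu_{com},\quad
\nu^*=(\nu^{-1}+\hat\nu_{obs}^{-1})^{-1},$$

with $\nu_{com}$ the complete-data residual df (analysis rows minus $q$).
$B=0$ is handled as the exact limit ($\nu^*=\hat\nu_{obs}$), no epsilon
fudging. The **robust** variant feeds HC1 sandwich within-variances into
the same rules; the pooled point estimate is unchanged by construction.

**Robins–Wang MI.** All $m$ sets of imputations are drawn at the fixed
complete-case MLE $\hat\theta$ ($\hat\sigma = \mathrm{RSS}/(n-t)$, the ML
divisor). The point estimate is OLS on the $mn$ stacked rows. The variance
estimator combines:

* imputer-side artifacts — per-subject scores of the imputation-model log
  likelihood at the observed values ($s^{obs}_i$, zero rows for incomplete
  subjects), at the imputed values ($S^{mis}$, zero rows for complete
  subjects), the Hessian averaged over complete subjects with divisor $n$
  ($\bar H$), and $d_i^T=-\bar H^{-1}s_i^{obs\,T}$;
* analyst-side artifacts — stacked estimating functions
  $u_{ik}=\ddot y_{ik}^T(y_{igk}-\ddot y_{ik}\beta)$ and
  $\tau=(nm)^{-1}\sum_{ik}\ddot y_{ik}^T\ddot y_{ik}$;

assembled as $\kappa=(nm)^{-1}\sum_{ik}u_{ik}s_i^{mis,k}$,
$\Lambda=n^{-1}\sum_i d_i^Td_i$, $\Omega=n^{-1}\sum_i\bar u_i^T\bar u_i$,
$\Delta=\Omega+\kappa\Lambda\kappa^T+n^{-1}\sum_i\{\kappa d_i^T\bar u_i+
(\cdot)^T\}$ and $\Gamma=n^{-1}\tau^{-1}\Delta\tau^{-T}$, whose diagonal
gives the coefficient variances; intervals are Wald with normal quantiles
(the estimator's justification is asymptotic). Two conventions the printed
formulae leave open are resolved as follows and are covered by tests:

* *Hessian averaging set.* Rows with missing $y_g$ cannot contribute to the
  observed-data Hessian; they contribute zero while the divisor stays $n$.
  This makes $\Lambda$ the asymptotic covariance of
  $\sqrt n(\hat\theta-\theta)$ for the complete-case MLE, matching the role
  of $d_i$, and mirrors the convention already used for $s^{obs}$.
* *Subgroup analyses.* Subjects outside the analysis subgroup contribute
  zero estimating functions to $u$, $\tau$, $\Omega$ and the cross terms,
  while all $n$ subjects remain in every $i$-indexed average (they may
  still carry imputed values and feed $S^{mis}$). The no-missingness
  reduction $\Gamma \to$ HC0 sandwich then holds within the subgroup as
  well. The variance estimates are read off diagonal entries
  $j=1,\dots,q$.

The imputer/analyst division of labour is preserved in the API:
`build_score_bundle` needs only imputer-side knowledge, `rw_variance` only
the bundle, the stack and $\hat\beta_I$; `S_mis` and `D` can be exported
and re-imported as provenance-indexed CSVs.

**Full mechanism bootstrapping.** One fixed-MLE imputation gives the point
estimate; each of $T$ replicates resamples $n$ rows with replacement from
the singly imputed data, re-imposes missingness, re-imputes under the same
model and refits the analysis. Missingness is re-imposed either
positionally from the observed pattern (`observed_mdp`, the literal
"same missing data pattern" — row $j$ of the bootstrap sample is masked iff
original row $j$ was; an indicator-resampling alternative was considered
and rejected as a less literal reading) or by Bernoulli draws from a
logistic model of the observation indicator (`modelled`), fitted once on
the original data — covariates: constant plus every fully observed column,
which includes the analysis outcome, so any mechanism depending on observed
variables is correctly specified — and frozen across replicates. Intervals:
normal, percentile, bias-corrected ($z_0=\Phi^{-1}(\#\{\hat\beta^*<
\hat\beta_I\}/T)$) and approximate BCa, whose acceleration constant comes
from the standard nonparametric jackknife over rows of the singly imputed
dataset (no exact acceleration formula exists for this procedure; the
jackknife is computed by the closed-form leave-one-out OLS identity, so it
costs one pass). Percentile-type endpoints are order statistics, the
$\lfloor\alpha(T+1)\rfloor$-th, so they are monotone in the level and
always members of the replicate set; the BC/BCa adjusted tail
probabilities can be arbitrarily extreme, and are clamped to the first/last
order statistic. Replicates whose imputation model cannot be fitted
(too few complete rows, singular design) are redrawn, with an abort
ceiling of 5% of $T$; a modelled-MDM draw that leaves nothing to impute is
legitimate and analysed directly.

## The synthetic data model

Data are drawn from a chained linear model calibrated to a cohort of young
adults:

    sex ~ Bernoulli(0.4577)                     (1 = female)
    (age, height) | sex ~ N(alpha0 + alpha1*sex, Sigma)
    weight      = iota0 + iota1*sex + iota2*age + iota3*height
                  + eta^sex * 12.29 * errW
    loginsindex = 1.854 + 0.2908*sex + 0.08003*age + 0.01119*weight
                  + eta^sex * 0.7887 * errL

with alpha0=(25.02, 1.774), alpha1=(−0.03616, −0.1336),
Sigma=[[0.5521, 0.001574], [0.001574, 0.003705]],
iota=(−32.98, −2.314, −0.01566, 65.38). `eta^sex` is 1 for men and `eta`
for women, so `eta` scales the **standard deviations** of the female
residuals (eta = 1/2 quarters the variances). λ = 12.29 and ω = 0.7887 are
residual SDs on the natural scales of weight (kg) and log insulin index.
Error distributions are standardized to mean 0, variance 1 in closed form:
uniform on $[-\sqrt3,\sqrt3]$; Student $t_\nu$ scaled by
$\sqrt{(\nu-2)/\nu}$ ($\nu\in\{3,6\}$; $\nu\le2$ is rejected); lognormal
$\exp\{N(0,s^2)\}$ centred at $e^{s^2/2}$ and scaled by
$\sqrt{(e^{s^2}-1)e^{s^2}}$, with $s=1/4$ (mild) or $s=1$ (severe).

Five scenario presets encode canonical failure modes; in each, weight is
the incomplete variable and both models include an explicit constant:

| preset | sex effects | eta | mechanism | incompatibility / misspecification |
|---|---|---|---|---|
| `subgroup` | null | 1 | MCAR, men only | imputer pools sexes; analyst studies men only |
| `heteroscedastic` | non-null | 1/2 | MCAR, all | both models wrongly assume homoscedasticity |
| `interaction` | non-null | 1 | MCAR, all | analyst adds a spurious `weight:sex` term |
| `nonnormal` | null | 1 | MCAR, all | error distributions violate normality |
| `mar_followup` | non-null | 1 | MAR on outcome | models correct; tests FMB's need for an MDM model |

The MAR mechanism is logistic in the standardized outcome with unit slope,
the simplest form depending only on `loginsindex`; its intercept is
calibrated per dataset by Brent root-finding so the within-sample mean
observation probability equals `p_obs`. The DGP parameterization of the
MAR follow-up (not fully pinned down by its description) defaults to the
non-null means with eta = 1 and is configurable. Degenerate masks
($t=0$ or $t=n$) are redrawn up to 100 times in simulation mode and fatal
for user data.

What the generator does *not* emulate: real anthropometric data have
measurement error, non-linear age effects, and missingness in several
variables at once; passing tests show correct behaviour of the estimators
under this stylized model, not robustness to those features.

## Simulation design and metrics

Replication $r$ of a run with master seed $s$ draws all randomness from
substreams keyed $(s, \text{scenario}, r, \text{method-slot})$, so results
are bit-reproducible, independent of which other methods are requested, and
order-independent. The two Rubin variants deliberately share one bayesian
stack (one slot), as in a shared-imputation analysis. Reported metrics per
method × coefficient: mean bias against the analytic truth (the weight
coefficient is 0.01119 in every scenario; an interaction term's truth is
0), empirical variance of the estimates, mean estimated variance, empirical
coverage and mean width of the 95% interval, and the Monte Carlo SE of a
nominal-level coverage estimate $\sqrt{p(1-p)/R}$. For $R=2500$ and
$p=0.95$ this SE is 0.0044 and the 95%-probability band for an estimated
coverage is (0.941, 0.959) — note 0.95 + 1.96·0.0044 rounds to 0.959, not
0.960. FMB's headline interval is the percentile type (its best performer);
all four types are retained.

## Problem sizes and numerical choices

The test suite and the acceptance script run reduced-scale studies chosen
so that each check is decisively powered yet completes in minutes on one
CPU: directional coverage findings use 300–500 replications with $m=10$
and $T=200$; the heteroscedastic Rubin-deficit check keeps the full 2500
replications with $m=50$, because at small $m$ the Barnard–Rubin df
correction itself widens the intervals and attenuates the very deficit
being measured. Hot loops (analysis OLS, sandwich, bootstrap refits) use
direct normal-equation linear algebra; the public `fit_analysis` carries an
explicit rank check, and its model-based and HC1 covariances are verified
against statsmodels in the tests. Noiseless fits (zero residual variance)
warn rather than fail, so exact-fit fixtures run. Negative variance
estimates (possible for $\Gamma$ in principle) raise with the offending
coefficient named.

## Known limitations

* One incomplete variable, normal linear imputation and analysis models
  only; no categorical imputation, no chained equations.
* The Robins–Wang variance is asymptotic: at $n=100$ it is biased downward
  (the small-sample acceptance study measures the resulting undercoverage);
  normal-quantile intervals are used because no finite-sample reference
  distribution is available.
* FMB is markedly more expensive than the MI methods and, under MAR,
  requires the missingness model; with `observed_mdp` under MAR its
  variance is biased downward by design of the check.
* The BCa acceleration is an approximation (jackknife on the singly imputed
  data), as no exact formula exists for the full pipeline.
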