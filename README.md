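# imputevar

Variance estimation for regression when one variable is incompletely
observed and filled in by imputation.

An unbiased point estimate is only half of a valid analysis of incomplete
data: the variance estimator must be unbiased too. Rubin's multiple
imputation (MI) variance estimator — the default in essentially all MI
software — can be badly biased when the imputation model and the analysis
procedure are *incompatible* (they make contradictory assumptions, e.g. the
imputer pools two subgroups while the analyst studies one) or *misspecified*
(e.g. both assume homoscedastic normal errors that the data do not have).
This package implements, and lets you compare head-to-head, four inference
procedures for the normal linear setting with a single incomplete variable:

* **Rubin's MI** — posterior-predictive imputation under the Jeffreys prior,
  pooled by Rubin's rules with the Barnard–Rubin small-sample degrees of
  freedom;
* **robust Rubin's MI** — the same pooling with HC1 sandwich
  within-imputation variances;
* **Robins–Wang MI** — imputations drawn with the imputation-model
  parameters fixed at the complete-case MLE, analysed as one stacked
  regression, with a variance estimator assembled from the imputation-model
  scores and the analysis estimating functions, valid under incompatibility
  and misspecification;
* **full mechanism bootstrapping (FMB)** — bootstrap of the whole
  resample → re-impose missingness → re-impute → re-analyse pipeline, with
  normal, percentile, bias-corrected and approximate-BCa intervals.

A simulation laboratory generates anthropometric data (sex, age, height,
weight, log insulin index) from a calibrated chained linear model, imposes
MCAR or MAR missingness on weight, and scores every method by bias,
empirical variance, mean estimated variance, coverage and interval width.

## The statistics in brief

With estimates $\hat\beta_{jk}$ and within variances $\hat W_{jk}$ from
$m$ completed datasets, Rubin's rules pool

$$\hat\beta_j = m^{-1}\sum_k \hat\beta_{jk},\quad
\bar W_j = m^{-1}\sum_k \hat W_{jk},\quad
B_j = \tfrac{1}{m-1}\sum_k(\hat\beta_{jk}-\hat\beta_j)^2,\quad
\hat V_j = \bar W_j + \tfrac{m+1}{m}B_j,$$

with $t$ intervals on the Barnard–Rubin degrees of freedom
$\nu_j^* = (\nu_j^{-1} + \hat\nu_{j,\mathrm{obs}}^{-1})^{-1}$.

The Robins–Wang estimator solves the analysis estimating equation
$\sum_i m^{-1}\sum_k u_{ik}(\hat\theta,\beta)=0$ on the $mn$ stacked rows
(imputations drawn at the fixed complete-case MLE $\hat\theta$) and
estimates the covariance as
$\Gamma = n^{-1}\tau^{-1}\Delta\,\tau^{-T}$ with
$\Delta = \Omega + \kappa\Lambda\kappa^T + n^{-1}\sum_i\{\kappa d_i^T\bar
u_i + (\kappa d_i^T\bar u_i)^T\}$, where $\kappa$ couples the analyst's
estimating functions to the imputation-model scores at the imputed values,
$\Lambda$ is built from the observed-data scores and averaged Hessian, and
$\Omega$ is the outer product of the per-subject mean estimating functions.
With no missing data $\Gamma$ collapses to the HC0 sandwich.

## Worked example

Simulate one heteroscedastic-errors dataset (n = 1000, 59.5% of weights
missing completely at random), then compare Rubin's MI with Robins–Wang:

```python
import numpy as np
import imputevar as iv
from imputevar.model import MIRegression

cfg = iv.scenario_config("heteroscedastic", n=1000, p_obs=0.4)
rng = np.random.default_rng(7)
inc = iv.apply_mdm(iv.generate_complete(cfg, rng), cfg, rng)

model = MIRegression(
    inc, "weight",
    imputation_covariates=("const", "sex", "age", "height", "loginsindex"),
    outcome="loginsindex",
    analysis_covariates=("const", "sex", "age", "weight"),
)
print(model.fit(method="rubin", m=50, seed=1).summary())
print(model.fit(method="rw", m=50, seed=1).summary())
```

```
Imputation inference for incomplete-data regression
================================================================
method: rubin          outcome: loginsindex
n: 1000   missing weight: 595 (59.5%)
imputations (m): 50
----------------------------------------------------------------
                  coef        se    [0.025   0.975]       df
const           1.4559    0.7253    0.0317   2.8800    686.5
sex             0.3232    0.0505    0.2239   0.4225    449.7
age             0.0949    0.0269    0.0420   0.1477    873.6
weight          0.0112    0.0027    0.0059   0.0165    133.3
================================================================
```

```
Imputation inference for incomplete-data regression
================================================================
method: rw             outcome: loginsindex
n: 1000   missing weight: 595 (59.5%)
imputations (m): 50
----------------------------------------------------------------
                  coef        se    [0.025   0.975]
const           1.4810    0.6839    0.1406   2.8215
sex             0.3247    0.0476    0.2314   0.4181
age             0.0936    0.0253    0.0440   0.1432
weight          0.0112    0.0031    0.0051   0.0174
================================================================
```

Both methods recover the true weight coefficient (0.01119), but they
disagree on its uncertainty: under this heteroscedastic data-generating
model Rubin's standard error (0.0027) is systematically too small —
simulated coverage of its 95% interval is about 0.91 rather than 0.95 —
while the Robins–Wang standard error (0.0031) tracks the actual sampling
variability.

Scenario studies run from the command line:

```sh
imputevar simulate --scenario heteroscedastic --n 1000 --p-obs 0.4 \
    --reps 500 --m 10 --methods rubin,rubin-robust,rw --seed 42 --out results.csv
imputevar analyze --data mydata.csv --missing-col weight \
    --impute-covars sex,age,height,loginsindex \
    --analysis-covars sex,age,weight --outcome loginsindex --method rw --m 50
```

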