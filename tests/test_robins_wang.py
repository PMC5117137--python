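"""Robins-Wang stacked-imputation estimator and its score-based variance."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from imputevar.dgp import IncompleteDataset, apply_mdm, generate_complete, scenario_config
from imputevar.imputation import build_design, fit_analysis, impute
from imputevar.robins_wang import (
    build_score_bundle,
    export_score_bundle,
    import_score_bundle,
    robins_wang_mi,
    rw_interval,
    rw_point_estimate,
    rw_variance,
)

IMP = ("const", "age", "height", "loginsindex")
ANA = ("const", "age", "weight")


def _loglik(y, xrow, theta_vec):
    """Per-row imputation-model log likelihood; theta_vec = (mu..., sigma)."""
    mu, sig = theta_vec[:-1], theta_vec[-1]
    r = y - xrow @ mu
    return 0.5 * (-np.log(2 * np.pi) - np.log(sig) - r * r / sig)


def _fd_grad(f, x, h=1e-6):
    g = np.empty_like(x)
    for j in range(len(x)):
        e = np.zeros_like(x)
        e[j] = h * max(1.0, abs(x[j]))
        g[j] = (f(x + e) - f(x - e)) / (2 * e[j])
    return g


@pytest.fixture
def eight_row_stack(rng):
    frame = pd.DataFrame(
        {
            "sex": [0.0, 1, 0, 1, 0, 1, 0, 1],
            "age": [24.0, 25.5, 26.1, 24.2, 25.0, 23.8, 26.5, 25.2],
            "height": [1.81, 1.62, 1.74, 1.66, 1.79, 1.58, 1.83, 1.69],
            "weight": [83.0, 60.0, np.nan, 59.5, 81.0, np.nan, 88.0, 64.0],
            "loginsindex": [4.8, 4.0, 5.1, 3.8, 4.9, 4.2, 5.3, 4.1],
        }
    )
    data = IncompleteDataset.from_frame(frame, "weight")
    stack = impute(data, ("const", "loginsindex"), 2, "frequentist", rng)
    return data, stack


class TestScoreBundle:
    def test_scores_sum_to_zero_at_mle(self, eight_row_stack):
        data, stack = eight_row_stack
        bundle = build_score_bundle(data, stack)
        np.testing.assert_allclose(bundle.s_obs.sum(axis=0), 0.0, atol=1e-8)

    def test_finite_difference_gradients_and_hessian(self, eight_row_stack):
        data, stack = eight_row_stack
        theta = stack.theta_hat
        tv = np.concatenate([theta.mu, [theta.sigma]])
        bundle = build_score_bundle(data, stack)
        X = build_design(data.frame, stack.covariates)
        y = data.frame["weight"].to_numpy()
        comp = data.r == 1
        n, p = bundle.s_obs.shape
        # observed-row scores
        for i in range(n):
            if comp[i]:
                g = _fd_grad(lambda t: _loglik(y[i], X[i], t), tv)
                np.testing.assert_allclose(bundle.s_obs[i], g, rtol=1e-6, atol=1e-9)
            else:
                assert np.all(bundle.s_obs[i] == 0.0)
        # imputed-row scores
        for k in range(stack.m):
            yk = stack.completed_column(k)
            for i in range(n):
                if comp[i]:
                    assert np.all(bundle.S_mis[k, i] == 0.0)
                else:
                    g = _fd_grad(lambda t: _loglik(yk[i], X[i], t), tv)
                    np.testing.assert_allclose(
                        bundle.S_mis[k, i], g, rtol=1e-6, atol=1e-9
                    )
        # averaged Hessian over complete rows, divisor n, via central second
        # differences of the log likelihood itself (O(h^2) truncation)
        H_fd = np.zeros((p, p))
        for i in np.flatnonzero(comp):
            f = lambda t: _loglik(y[i], X[i], t)  # noqa: E731
            for j in range(p):
                hj = 1e-4 * max(1.0, abs(tv[j]))
                ej = np.zeros(p)
                ej[j] = hj
                for l in range(p):
                    hl = 1e-4 * max(1.0, abs(tv[l]))
                    el = np.zeros(p)
                    el[l] = hl
                    H_fd[j, l] += (
                        f(tv + ej + el) - f(tv + ej - el)
                        - f(tv - ej + el) + f(tv - ej - el)
                    ) / (4 * hj * hl)
        H_fd /= n
        np.testing.assert_allclose(bundle.H_bar, H_fd, rtol=1e-6, atol=1e-6)

    def test_d_rows(self, eight_row_stack):
        data, stack = eight_row_stack
        bundle = build_score_bundle(data, stack)
        Hinv = np.linalg.inv(bundle.H_bar)
        comp = data.r == 1
        for i in range(data.n):
            if comp[i]:
                np.testing.assert_allclose(
                    bundle.D[i], -(Hinv @ bundle.s_obs[i]), rtol=1e-10
                )
            else:
                assert np.all(bundle.D[i] == 0.0)

    def test_requires_frequentist_stack(self, eight_row_stack, rng):
        data, _ = eight_row_stack
        bstack = impute(data, ("const", "loginsindex"), 2, "bayesian", rng)
        with pytest.raises(ValueError):
            build_score_bundle(data, bstack)

    def test_csv_roundtrip(self, eight_row_stack, tmp_path):
        data, stack = eight_row_stack
        bundle = build_score_bundle(data, stack)
        export_score_bundle(bundle, tmp_path)
        S, D = import_score_bundle(tmp_path)
        np.testing.assert_allclose(S, bundle.S_mis, rtol=1e-10)
        np.testing.assert_allclose(D, bundle.D, rtol=1e-10)


class TestPointEstimate:
    def test_single_imputation_equals_ols_on_completed(self, small_incomplete, rng):
        cfg, inc = small_incomplete
        stack = impute(inc, cfg.imputation_covariates, 1, "frequentist", rng)
        beta = rw_point_estimate(stack, "loginsindex", cfg.analysis_covariates, "men")
        ref = fit_analysis(stack.completed(0), "loginsindex",
                           cfg.analysis_covariates, "men")
        np.testing.assert_allclose(beta, ref.beta, rtol=1e-9)

    def test_no_missing_reduces_to_complete_data_ols(self, rng):
        cfg = scenario_config("subgroup", n=100, p_obs=0.5)
        frame = generate_complete(cfg, rng)
        data = IncompleteDataset.from_frame(frame, "weight")
        for m in (1, 4):
            stack = impute(data, cfg.imputation_covariates, m, "frequentist", rng)
            beta = rw_point_estimate(stack, "loginsindex", cfg.analysis_covariates)
            ref = fit_analysis(frame, "loginsindex", cfg.analysis_covariates)
            np.testing.assert_allclose(beta, ref.beta, rtol=1e-9)

    def test_matches_estimating_equation_root(self, eight_row_stack):
        data, stack = eight_row_stack
        covs = ("const", "weight")
        beta = rw_point_estimate(stack, "loginsindex", covs)

        def avg_estimating_eq(b):
            total = np.zeros(2)
            for k in range(stack.m):
                f = stack.completed(k)
                A = build_design(f, covs)
                total += A.T @ (f["loginsindex"].to_numpy() - A @ b) / stack.m
            return total

        root = optimize.fsolve(avg_estimating_eq, np.zeros(2), full_output=False)
        np.testing.assert_allclose(beta, root, rtol=1e-7)

    def test_rejects_bayesian_stack(self, small_incomplete, rng):
        cfg, inc = small_incomplete
        stack = impute(inc, cfg.imputation_covariates, 3, "bayesian", rng)
        with pytest.raises(ValueError):
            rw_point_estimate(stack, "loginsindex", cfg.analysis_covariates, "men")


def _gamma_bruteforce(data, stack, outcome, ana_covs, subgroup=None):
    """Naive nested-loop evaluation of the matrix formulae (independent oracle)."""
    theta = stack.theta_hat
    mu, sig = theta.mu, theta.sigma
    Ximp = build_design(data.frame, stack.covariates)
    y = data.frame[data.missing_col].to_numpy()
    comp = data.r == 1
    n, m = data.n, stack.m
    p = Ximp.shape[1] + 1
    q = len(ana_covs)

    def score(yv, xrow):
        r = yv - xrow @ mu
        return np.concatenate([(r / sig) * xrow, [0.5 * (-1 / sig + r * r / sig**2)]])

    def hess(yv, xrow):
        r = yv - xrow @ mu
        H = np.empty((p, p))
        H[: p - 1, : p - 1] = -np.outer(xrow, xrow) / sig
        H[: p - 1, -1] = H[-1, : p - 1] = -xrow * r / sig**2
        H[-1, -1] = 1.0 / (2 * sig**2) - r * r / sig**3
        return H

    Hbar = np.zeros((p, p))
    for i in range(n):
        if comp[i]:
            Hbar += hess(y[i], Ximp[i])
    Hbar /= n
    Hinv = np.linalg.inv(Hbar)
    d = np.zeros((n, p))
    for i in range(n):
        if comp[i]:
            d[i] = -(Hinv @ score(y[i], Ximp[i]))
    s_mis = np.zeros((m, n, p))
    for k in range(m):
        yk = stack.completed_column(k)
        for i in range(n):
            if not comp[i]:
                s_mis[k, i] = score(yk[i], Ximp[i])

    # analysis-side pieces
    from imputevar.imputation import subgroup_mask

    w = subgroup_mask(data.frame, subgroup)
    beta = rw_point_estimate(stack, outcome, ana_covs, subgroup)
    u = np.zeros((m, n, q))
    tau = np.zeros((q, q))
    for k in range(m):
        f = stack.completed(k)
        A = build_design(f, ana_covs)
        yo = f[outcome].to_numpy()
        for i in range(n):
            if w[i]:
                u[k, i] = A[i] * (yo[i] - A[i] @ beta)
                tau += np.outer(A[i], A[i])
    tau /= n * m
    kappa = np.zeros((q, p))
    for k in range(m):
        for i in range(n):
            kappa += np.outer(u[k, i], s_mis[k, i])
    kappa /= n * m
    Lam = np.zeros((p, p))
    for i in range(n):
        Lam += np.outer(d[i], d[i])
    Lam /= n
    ubar = u.mean(axis=0)
    Om = np.zeros((q, q))
    cross = np.zeros((q, q))
    for i in range(n):
        Om += np.outer(ubar[i], ubar[i])
        kd = kappa @ d[i]
        cross += np.outer(kd, ubar[i]) + np.outer(ubar[i], kd)
    Om /= n
    cross /= n
    Delta = Om + kappa @ Lam @ kappa.T + cross
    tinv = np.linalg.inv(tau)
    return beta, tinv @ Delta @ tinv.T / n


class TestVariance:
    def test_loop_oracle_small_fixture(self, six_row_data, rng):
        stack = impute(six_row_data, ("const", "loginsindex"), 2, "frequentist", rng)
        covs = ("const", "weight")
        beta, G_loop = _gamma_bruteforce(six_row_data, stack, "loginsindex", covs)
        bundle = build_score_bundle(six_row_data, stack)
        comps = rw_variance(bundle, stack, beta, "loginsindex", covs)
        np.testing.assert_allclose(comps.Gamma, G_loop, rtol=1e-10)

    def test_no_missing_reduces_to_hc0_sandwich(self, rng):
        cfg = scenario_config("subgroup", n=150, p_obs=0.5)
        frame = generate_complete(cfg, rng)
        data = IncompleteDataset.from_frame(frame, "weight")
        stack = impute(data, cfg.imputation_covariates, 3, "frequentist", rng)
        beta, comps = robins_wang_mi(
            data, cfg.imputation_covariates, "loginsindex",
            cfg.analysis_covariates, stack=stack,
        )
        assert np.all(comps.kappa == 0.0)
        # independently coded HC0 sandwich on the complete data
        X = build_design(frame, cfg.analysis_covariates)
        y = frame["loginsindex"].to_numpy()
        b = np.linalg.solve(X.T @ X, X.T @ y)
        e = y - X @ b
        XtX_inv = np.linalg.inv(X.T @ X)
        hc0 = XtX_inv @ ((X * e[:, None] ** 2).T @ X) @ XtX_inv
        np.testing.assert_allclose(comps.Gamma, hc0, rtol=1e-8)

    def test_no_missing_within_subgroup_reduction(self, rng):
        # weight missing only in women while the analysis is men-only:
        # the imputer-analyst cross terms vanish and Gamma is the men-only
        # HC0 sandwich of the complete male data.
        cfg = scenario_config("subgroup", n=200, p_obs=0.5)
        frame = generate_complete(cfg, rng)
        women = frame["sex"].to_numpy() == 1.0
        r = np.ones(len(frame), dtype=int)
        r[women] = (rng.random(women.sum()) < 0.5).astype(int)
        masked = frame.copy()
        masked.loc[r == 0, "weight"] = np.nan
        data = IncompleteDataset.from_frame(masked, "weight")
        stack = impute(data, cfg.imputation_covariates, 3, "frequentist", rng)
        beta, comps = robins_wang_mi(
            data, cfg.imputation_covariates, "loginsindex",
            cfg.analysis_covariates, subgroup="men", stack=stack,
        )
        np.testing.assert_allclose(comps.kappa, 0.0, atol=1e-12)
        men = ~women
        X = build_design(frame, cfg.analysis_covariates)[men]
        y = frame["loginsindex"].to_numpy()[men]
        b = np.linalg.solve(X.T @ X, X.T @ y)
        e = y - X @ b
        XtX_inv = np.linalg.inv(X.T @ X)
        hc0 = XtX_inv @ ((X * e[:, None] ** 2).T @ X) @ XtX_inv
        np.testing.assert_allclose(beta, b, rtol=1e-9)
        np.testing.assert_allclose(comps.Gamma, hc0, rtol=1e-8)

    def test_lambda_and_omega_psd(self, rng):
        for seed in range(3):
            cfg = scenario_config("heteroscedastic", n=120, p_obs=0.5)
            r = np.random.default_rng(seed)
            inc = apply_mdm(generate_complete(cfg, r), cfg, r)
            stack = impute(inc, cfg.imputation_covariates, 3, "frequentist", r)
            beta, comps = robins_wang_mi(
                inc, cfg.imputation_covariates, "loginsindex",
                cfg.analysis_covariates, stack=stack,
            )
            assert np.all(np.linalg.eigvalsh(comps.Lambda) > -1e-10)
            assert np.all(np.linalg.eigvalsh(comps.Omega) > -1e-10)
            assert np.all(np.diag(comps.Gamma) > 0.0)

    def test_permutation_invariance(self, small_incomplete, rng):
        cfg, inc = small_incomplete
        stack = impute(inc, cfg.imputation_covariates, 3, "frequentist", rng)
        beta, comps = robins_wang_mi(
            inc, cfg.imputation_covariates, "loginsindex",
            cfg.analysis_covariates, subgroup="men", stack=stack,
        )
        perm = rng.permutation(inc.n)
        frame2 = inc.frame.iloc[perm].reset_index(drop=True)
        inc2 = IncompleteDataset.from_frame(frame2, "weight")
        # carry the same imputed values across the permutation
        col_of_old = {i: j for j, i in enumerate(stack.miss_idx)}
        new_miss = np.flatnonzero(inc2.r == 0)
        imput2 = stack.imputed[:, [col_of_old[perm[j]] for j in new_miss]]
        from imputevar.imputation import ImputedStack

        stack2 = ImputedStack(
            data=inc2, covariates=stack.covariates, mode="frequentist",
            imputed=imput2, theta_hat=stack.theta_hat, miss_idx=new_miss,
        )
        beta2, comps2 = robins_wang_mi(
            inc2, cfg.imputation_covariates, "loginsindex",
            cfg.analysis_covariates, subgroup="men", stack=stack2,
        )
        np.testing.assert_allclose(beta2, beta, rtol=1e-9)
        np.testing.assert_allclose(comps2.Gamma, comps.Gamma, rtol=1e-8)

    def test_variance_stable_in_number_of_imputations(self, small_incomplete):
        cfg, inc = small_incomplete
        vals = {}
        for m in (2, 10, 50):
            r = np.random.default_rng(4)
            stack = impute(inc, cfg.imputation_covariates, m, "frequentist", r)
            _, comps = robins_wang_mi(
                inc, cfg.imputation_covariates, "loginsindex",
                cfg.analysis_covariates, subgroup="men", stack=stack,
            )
            vals[m] = comps.variances()[2]
        for m in (2, 10):
            assert vals[m] == pytest.approx(vals[50], rel=0.5)


class TestInterval:
    def test_normal_quantile_and_degenerate(self, small_incomplete, rng):
        cfg, inc = small_incomplete
        stack = impute(inc, cfg.imputation_covariates, 3, "frequentist", rng)
        beta, comps = robins_wang_mi(
            inc, cfg.imputation_covariates, "loginsindex",
            cfg.analysis_covariates, subgroup="men", stack=stack,
        )
        lo, hi = rw_interval(beta, comps, 0.95)
        half = 1.959964 * np.sqrt(np.diag(comps.Gamma))
        np.testing.assert_allclose(hi - beta, half, rtol=1e-5)
        np.testing.assert_allclose(beta - lo, half, rtol=1e-5)

    def test_negative_variance_reported_with_index(self, small_incomplete, rng):
        cfg, inc = small_incomplete
        stack = impute(inc, cfg.imputation_covariates, 3, "frequentist", rng)
        beta, comps = robins_wang_mi(
            inc, cfg.imputation_covariates, "loginsindex",
            cfg.analysis_covariates, subgroup="men", stack=stack,
        )
        comps.Gamma[1, 1] = -1.0
        with pytest.raises(ValueError, match="age"):
            rw_interval(beta, comps, 0.95)


def test_superefficiency_occurs_in_subgroup_scenario():
    """The imputations carry information the men-only analysis ignores, so the
    stacked-imputation variance can undercut the complete-data variance."""
    cfg = scenario_config("subgroup", n=1000, p_obs=0.4)
    hits = 0
    reps = 200
    for rep in range(reps):
        r = np.random.default_rng((11, rep))
        frame = generate_complete(cfg, r)
        inc = apply_mdm(frame, cfg, r)
        stack = impute(inc, cfg.imputation_covariates, 10, "frequentist", r)
        _, comps = robins_wang_mi(
            inc, cfg.imputation_covariates, "loginsindex",
            cfg.analysis_covariates, subgroup="men", stack=stack,
        )
        full = fit_analysis(frame, "loginsindex", cfg.analysis_covariates, "men")
        if comps.variances()[2] < full.vcov_model[2, 2]:
            hits += 1
    assert hits > 0
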