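"""Penalized IRLS, GCV and power-index selection against oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize

from spatialccc.config import FitConfig
from spatialccc.design import PairDesign
from spatialccc.fit import (
    _model_matrix,
    estimate_power,
    fit_design,
    gcv_score,
    model_aic,
    pirls_fit,
    select_smoothing,
)
from spatialccc.tweedie import sample_tweedie, tweedie_unit_deviance


def make_design(rng, n=60, G=2, n_grid=4, rho=0.5, beta=None, beta0=0.3,
                phi=0.7, p=1.5, response=None):
    """Random small design drawn from the generative model."""
    comp = rng.dirichlet(np.ones(G), size=n)
    dist = rng.uniform(0, 2, size=n)
    w = np.exp(-rho * dist)
    XI = np.stack([np.outer(comp[i], comp[rng.integers(n)]).ravel()
                   for i in range(n)])
    X = np.column_stack([np.ones(n), XI * w[:, None]])
    sg = rng.integers(1, n_grid + 1, size=n)
    rg = rng.integers(1, n_grid + 1, size=n)
    if response is None:
        if beta is None:
            beta = rng.normal(0, 0.5, size=G * G)
        eta = X @ np.concatenate([[beta0], beta])
        response = sample_tweedie(np.exp(eta), phi, p, rng=rng)
        if not (response > 0).any():
            response[0] = 1.0
    return PairDesign(
        sender_idx=np.arange(n),
        receiver_idx=np.arange(n),
        response=response,
        distance=dist,
        X=X,
        sender_grid=sg,
        receiver_grid=rg,
        n_grid=n_grid,
        rho=rho,
        dmax=2.0,
    )


def intercept_only_design(y, n_grid=1):
    """Design whose only informative column is the intercept (the single
    interaction column duplicates it and is dropped as aliased)."""
    n = len(y)
    X = np.ones((n, 2))
    return PairDesign(
        sender_idx=np.arange(n),
        receiver_idx=np.arange(n),
        response=np.asarray(y, dtype=float),
        distance=np.zeros(n),
        X=X,
        sender_grid=np.ones(n, dtype=int),
        receiver_grid=np.ones(n, dtype=int),
        n_grid=n_grid,
        rho=0.0,
        dmax=1.0,
    )


def penalized_objective(design, p, lam_L, lam_R):
    """Independent objective: 1/2 sum deviance + 1/2 lambda ||nu||^2."""
    Xf, ZL, ZR = _model_matrix(design)
    C = np.column_stack([Xf, ZL, ZR])
    nf = Xf.shape[1]
    g = design.n_grid
    s = np.concatenate([np.zeros(nf), np.full(g, lam_L), np.full(g, lam_R)])
    y = design.response

    def obj(theta):
        mu = np.exp(np.clip(C @ theta, -30, 30))
        return 0.5 * np.sum(tweedie_unit_deviance(y, mu, p)) + 0.5 * s @ theta**2

    def grad(theta):
        mu = np.exp(np.clip(C @ theta, -30, 30))
        return -C.T @ ((y - mu) * mu ** (1.0 - p)) + s * theta

    return C, obj, grad


class TestPIRLS:
    def test_intercept_only_mean_fixed_point(self, rng):
        # with the random effects fully shrunk the log-link score equation
        # collapses to sum(y - mu) = 0, i.e. mu = mean(y)
        y = rng.gamma(2.0, 1.0, size=80)
        design = intercept_only_design(y)
        fit = pirls_fit(design, 1.5, 1e9, 1e9)
        assert fit.mu[0] == pytest.approx(y.mean(), rel=1e-6)
        assert 1 in fit.aliased  # duplicated interaction column dropped

    def test_constant_response_exact_fit(self):
        y = np.full(50, 3.7)
        fit = pirls_fit(intercept_only_design(y), 1.4, 1e9, 1e9)
        assert fit.deviance == pytest.approx(0.0, abs=1e-10)
        assert fit.beta0 == pytest.approx(np.log(3.7), rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_numerical_optimizer(self, seed):
        rng = np.random.default_rng(seed)
        design = make_design(rng, n=60, G=2, n_grid=4)
        p, lam = 1.5, (1.0, 1.0)
        fit = pirls_fit(design, p, *lam)
        C, obj, grad = penalized_objective(design, p, *lam)
        x0 = np.zeros(C.shape[1])
        res = minimize(obj, x0, jac=grad, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 2000})
        ours = np.concatenate([[fit.beta0], fit.beta, fit.nu_L, fit.nu_R])
        assert np.abs(ours - res.x).max() < 1e-4

    def test_nonconvergence_flagged(self, rng):
        design = make_design(rng, n=40)
        cfg = FitConfig(max_iter=1)
        fit = pirls_fit(design, 1.5, 1.0, 1.0, config=cfg)
        assert not fit.converged
        assert np.isfinite(fit.deviance)

    def test_shrinkage_monotone_in_lambda(self, rng):
        design = make_design(rng, n=100, G=2, n_grid=5)
        norms = [
            np.linalg.norm(pirls_fit(design, 1.5, lam, 1.0).nu_L)
            for lam in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_rejects_nonpositive_lambda(self, rng):
        design = make_design(rng, n=30)
        with pytest.raises(ValueError):
            pirls_fit(design, 1.5, 0.0, 1.0)


class TestGCV:
    def test_finite_for_positive_lambda(self, rng):
        design = make_design(rng, n=50)
        assert np.isfinite(gcv_score(design, 1.5, 1.0, 1.0))

    def test_heavy_shrinkage_matches_fixed_effects_only_glm(self, rng):
        # lambda -> inf drives nu -> 0; the fit and its GCV must agree with a
        # plain unpenalized Tweedie GLM on the fixed columns (statsmodels)
        design = make_design(rng, n=120, G=2, n_grid=4)
        p = 1.5
        fit = pirls_fit(design, p, 1e10, 1e10)
        assert np.linalg.norm(fit.nu_L) < 1e-6
        glm = sm.GLM(
            design.response,
            design.X,
            family=sm.families.Tweedie(var_power=p,
                                       link=sm.families.links.Log()),
        ).fit(tol=1e-12)
        ours = np.concatenate([[fit.beta0], fit.beta])
        np.testing.assert_allclose(ours, glm.params, atol=1e-4)
        n = design.n_pairs
        gcv_fixed = n * glm.deviance / (n - design.X.shape[1]) ** 2
        assert gcv_score(design, p, 1e10, 1e10, fit=fit) == pytest.approx(
            gcv_fixed, rel=1e-5
        )

    def test_grid_minimum_consistent_under_recomputation(self, rng):
        design = make_design(rng, n=50, G=2, n_grid=3)
        cfg = FitConfig(lambda_grid_size=5, refine_smoothing=False)
        lamL, lamR = select_smoothing(design, 1.5, config=cfg)
        grid = np.logspace(-3, 3, 5)
        scores = {
            (a, b): gcv_score(design, 1.5, a, b) for a in grid for b in grid
        }
        best = min(scores, key=scores.get)
        assert (lamL, lamR) == pytest.approx(best)


class TestSelectSmoothing:
    def test_null_heterogeneity_gets_heavy_shrinkage(self, rng):
        # no sender/receiver heterogeneity planted -> lambdas end up large
        design = make_design(rng, n=150, G=2, n_grid=4, beta=np.zeros(4))
        lamL, lamR = select_smoothing(design, 1.5)
        assert lamL > 1.0 and lamR > 1.0

    def test_planted_sender_effects_reduce_lambda_L(self, rng):
        n, n_grid = 200, 4
        base = make_design(rng, n=n, G=2, n_grid=n_grid, beta=np.zeros(4))
        lam_null = select_smoothing(base, 1.5)
        # replant: strong sender-grid effects in the response
        nu = np.array([1.5, -1.5, 1.0, -1.0])
        eta = 0.3 + nu[base.sender_grid - 1]
        response = sample_tweedie(np.exp(eta), 0.5, 1.5,
                                  rng=np.random.default_rng(99))
        strong = PairDesign(
            sender_idx=base.sender_idx, receiver_idx=base.receiver_idx,
            response=response, distance=base.distance, X=base.X,
            sender_grid=base.sender_grid, receiver_grid=base.receiver_grid,
            n_grid=n_grid, rho=base.rho, dmax=base.dmax,
        )
        lam_strong = select_smoothing(strong, 1.5)
        assert lam_strong[0] < lam_null[0]

    def test_invariant_to_row_permutation(self, rng):
        design = make_design(rng, n=60, G=2, n_grid=3)
        perm = rng.permutation(design.n_pairs)
        shuffled = PairDesign(
            sender_idx=design.sender_idx[perm],
            receiver_idx=design.receiver_idx[perm],
            response=design.response[perm],
            distance=design.distance[perm],
            X=design.X[perm],
            sender_grid=design.sender_grid[perm],
            receiver_grid=design.receiver_grid[perm],
            n_grid=design.n_grid,
            rho=design.rho,
            dmax=design.dmax,
        )
        assert select_smoothing(design, 1.5) == pytest.approx(
            select_smoothing(shuffled, 1.5), rel=1e-6
        )


class TestPowerEstimation:
    def test_recovers_true_power(self):
        # intercept-only data at p = 1.3: selected p within one grid step
        hits = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            y = sample_tweedie(2.0, 1.0, 1.3, n=2000, rng=rng)
            design = intercept_only_design(y)
            p_hat, _ = estimate_power(design, 1e6, 1e6)
            hits += p_hat in (1.2, 1.3, 1.4)
        assert hits >= 0.9 * reps

    def test_degenerate_constant_response_tie_rule(self):
        design = intercept_only_design(np.full(40, 2.0))
        p_hat, _ = estimate_power(design, 1e6, 1e6)
        assert p_hat == 1.5

    def test_selected_p_maximizes_profile(self, rng):
        design = make_design(rng, n=80)
        p_hat, profile = estimate_power(design, 1.0, 1.0)
        finite = {k: v for k, v in profile.items() if np.isfinite(v)}
        assert profile[p_hat] == max(finite.values())


class TestAIC:
    def test_formula(self, rng):
        design = make_design(rng, n=50)
        fit = fit_design(design, FitConfig(lambda_grid_size=3,
                                           refine_smoothing=False,
                                           p_grid=(1.5,)))
        assert model_aic(fit) == pytest.approx(-2 * fit.loglik + 2 * fit.edf,
                                               abs=1e-8)
        assert fit.aic == pytest.approx(model_aic(fit), abs=1e-8)
        assert 1.0 <= fit.edf <= design.X.shape[1] + 2 * design.n_grid

    def test_distance_rescaling_invariance(self, rng):
        # multiplying distances by c and dividing rho by c leaves the design,
        # hence the AIC comparison, unchanged
        from spatialccc.datasets import SpatialDataset
        from spatialccc.design import build_design, build_pair_set

        n, G, c = 40, 2, 7.0
        coords = rng.random((n, 2))
        comp = rng.dirichlet(np.ones(G), size=n)

        def dataset(scale):
            return SpatialDataset(
                expr=np.ones((1, n)), gene_ids=["g"],
                unit_ids=[f"u{i}" for i in range(n)],
                coords=coords * scale, composition=comp,
                type_names=["a", "b"],
            )

        y = rng.gamma(1.0, 1.0, size=None)
        ds1, dsc = dataset(1.0), dataset(c)
        p1 = build_pair_set(ds1.coords, 0.5)
        pc = build_pair_set(dsc.coords, 0.5 * c)
        resp = rng.gamma(1.0, 1.0, size=len(p1[0]))
        cfg = FitConfig(lambda_grid_size=3, refine_smoothing=False,
                        p_grid=(1.5,))
        for rho in (0.5, 2.0):
            d1 = build_design(ds1, None, None, p1, rho, response=resp)
            dc = build_design(dsc, None, None, pc, rho / c, response=resp)
            f1 = fit_design(d1, cfg)
            fc = fit_design(dc, cfg)
            assert f1.aic == pytest.approx(fc.aic, rel=1e-6)
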