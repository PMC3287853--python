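"""GBPLS2: closed-form outer weights and the partially penalized LASSO."""

import numpy as np
import pytest
from scipy.optimize import minimize

from gbpls.errors import ConfigError
from gbpls.gbpls2 import (
    fit_lasso_partial,
    gene_scores,
    pls_outer_weights,
    run_gbpls2,
    snp_ranks_gbpls2,
    supported_dimensions,
)
from gbpls.simulate import SimulationConfig, simulate_cohort

from conftest import make_covariates, make_genotypes, make_gene_map


def test_single_snp_gene_weight_is_sign_of_covariance():
    rng = np.random.default_rng(0)
    x = rng.binomial(2, 0.3, size=40).astype(float)[:, None]
    y = -1.5 * x[:, 0] + rng.normal(size=40)
    w, T, bad = pls_outer_weights(x, y)
    assert not bad
    assert w[0] == pytest.approx(-1.0)
    np.testing.assert_allclose(T, -(x[:, 0] - x[:, 0].mean()), atol=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_two_snp_weight_beats_unit_circle_grid(seed):
    rng = np.random.default_rng(seed)
    X = rng.binomial(2, rng.uniform(0.1, 0.5, size=2), size=(30, 2)).astype(float)
    y = rng.normal(size=30)
    w, T, bad = pls_outer_weights(X, y)
    assert not bad
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    best = (yc @ (Xc @ w)) / 30
    theta = np.linspace(0, 2 * np.pi, 3600, endpoint=False)
    grid = np.column_stack([np.cos(theta), np.sin(theta)])
    grid_best = ((Xc @ grid.T).T @ yc / 30).max()
    assert best >= grid_best - 1e-12
    assert T.mean() == pytest.approx(0.0, abs=1e-12)


def test_degenerate_gene_flagged_and_excluded():
    # y exactly orthogonal to both centered SNP columns
    X = np.array([[0, 0], [0, 2], [2, 0], [2, 2]], dtype=float)
    y = np.array([1.0, -1.0, -1.0, 1.0])
    w, T, bad = pls_outer_weights(X, y)
    assert bad and T is None and (w == 0).all()

    g = make_genotypes(40, 6, seed=1)
    gm = make_gene_map(g.snp_ids, [2, 2, 2])
    rng = np.random.default_rng(2)
    y2 = rng.normal(size=40)
    scores = gene_scores(g, gm, list(gm.genes), y2)
    assert scores.T.shape == (40, len(scores.genes))
    assert not scores.degenerate  # generic trait: no degeneracy


def test_supported_dimensions_presets():
    assert supported_dimensions() == (100, 250, 500, 750)
    g = make_genotypes(30, 8, seed=3)
    gm = make_gene_map(g.snp_ids, [2] * 4)
    cov = make_covariates(g, k_pcs=2)
    y = np.random.default_rng(0).normal(size=30)
    order = list(gm.genes)
    # t=1 accepted; t beyond the screened list rejected
    sel, *_ = run_gbpls2(g, gm, cov, y, order, t=1, folds=3, seed=0)
    assert isinstance(sel, list)
    with pytest.raises(ConfigError, match="exceeds"):
        run_gbpls2(g, gm, cov, y, order, t=5, folds=3, seed=0)


def _lasso_instance(seed, n=40, t=5, k_pcs=3):
    g = make_genotypes(n, 20, seed=seed)
    cov = make_covariates(g, k_pcs=k_pcs)
    rng = np.random.default_rng(seed + 100)
    T = rng.normal(size=(n, t))
    y = T[:, 0] - 0.5 * T[:, 1] + 0.3 * cov.table["Age"].to_numpy() / 10 \
        + rng.normal(size=n)
    genes = [f"g{i}" for i in range(t)]
    return T, cov, y, genes


def _qp_oracle(U, Ts, y, lam):
    """Independent solver: variable splitting + L-BFGS-B on the smooth bound-
    constrained equivalent of the partially penalized LASSO objective."""
    n = len(y)
    X = np.column_stack([U, Ts, -Ts])
    nu, nt = U.shape[1], Ts.shape[1]

    def obj(z):
        r = y - X @ z
        return r @ r / (2 * n) + lam * z[nu:].sum()

    def grad(z):
        gr = -X.T @ (y - X @ z) / n
        gr[nu:] += lam
        return gr

    bounds = [(None, None)] * nu + [(0, None)] * (2 * nt)
    res = minimize(obj, np.zeros(nu + 2 * nt), jac=grad, method="L-BFGS-B",
                   bounds=bounds,
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    z = res.x
    return np.concatenate([z[:nu], z[nu:nu + nt] - z[nu + nt:]])


def _internal_design(fit):
    return fit._X[:, :fit._X.shape[1] - len(fit.genes)], \
        fit._X[:, fit._X.shape[1] - len(fit.genes):]


def test_lasso_zero_penalty_equals_ols():
    T, cov, y, genes = _lasso_instance(0)
    fit = fit_lasso_partial(T, cov, y, genes, lambda_grid=[0.0])
    D = np.column_stack([np.ones(len(y)), cov.design(), T])
    oracle, *_ = np.linalg.lstsq(D, y, rcond=None)
    got = fit.beta[["intercept"] + cov.names + genes].to_numpy()
    np.testing.assert_allclose(got, oracle, atol=1e-6)


def test_lasso_death_point_zeroes_genes_exactly():
    T, cov, y, genes = _lasso_instance(1)
    n = len(y)
    U = np.column_stack([np.ones(n), cov.design()])
    Ts = (T - T.mean(axis=0)) / T.std(axis=0)
    M = lambda A: A - U @ np.linalg.lstsq(U, A, rcond=None)[0]
    lam_max = np.abs(M(Ts).T @ M(y)).max() / n
    fit = fit_lasso_partial(T, cov, y, genes, lambda_grid=[lam_max * 1.0001])
    assert all(fit.beta[g] == 0.0 for g in genes)
    assert fit.selected_genes == []
    # unpenalized block equals plain OLS of y on the covariates
    oracle, *_ = np.linalg.lstsq(U, y, rcond=None)
    got = fit.beta[["intercept"] + cov.names].to_numpy()
    np.testing.assert_allclose(got, oracle, atol=1e-8)


@pytest.mark.parametrize("seed", range(5))
def test_lasso_kkt_and_qp_oracle(seed):
    T, cov, y, genes = _lasso_instance(seed, n=40, t=5)
    n = len(y)
    U = np.column_stack([np.ones(n), cov.design()])
    Ts = (T - T.mean(axis=0)) / T.std(axis=0)
    M = lambda A: A - U @ np.linalg.lstsq(U, A, rcond=None)[0]
    lam = 0.3 * np.abs(M(Ts).T @ M(y)).max() / n
    fit = fit_lasso_partial(T, cov, y, genes, lambda_grid=[lam])
    assert fit.kkt_residual() < 1e-6
    oracle = _qp_oracle(U, Ts, y, lam)
    np.testing.assert_allclose(fit._beta_internal, oracle, atol=1e-5)


def test_lasso_active_set_grows_from_empty():
    T, cov, y, genes = _lasso_instance(2, n=60, t=8)
    fit = fit_lasso_partial(T, cov, y, genes, n_lambda=30)
    grid = fit.cv_curve["lam"].to_numpy()
    first = fit_lasso_partial(T, cov, y, genes, lambda_grid=[grid[0]])
    last = fit_lasso_partial(T, cov, y, genes, lambda_grid=[grid[-1]])
    assert first.selected_genes == []  # empty at lambda_max
    assert len(last.selected_genes) >= len(first.selected_genes)


def test_unpenalized_covariate_shift_changes_only_intercept():
    T, cov, y, genes = _lasso_instance(3)
    fit_a = fit_lasso_partial(T, cov, y, genes, folds=4, seed=9)
    shifted = cov.table.copy()
    shifted["Age"] = shifted["Age"] + 100.0
    from gbpls.cohort import CohortCovariates

    fit_b = fit_lasso_partial(T, CohortCovariates(shifted), y, genes,
                              folds=4, seed=9)
    assert fit_a.lam == pytest.approx(fit_b.lam)
    keep = cov.names + genes
    np.testing.assert_allclose(fit_a.beta[keep].to_numpy(),
                               fit_b.beta[keep].to_numpy(), atol=1e-8)
    assert fit_b.beta["intercept"] == pytest.approx(
        fit_a.beta["intercept"] - 100.0 * fit_a.beta["Age"], abs=1e-6
    )


def test_cv_curve_and_fold_determinism():
    T, cov, y, genes = _lasso_instance(4, n=50, t=6)
    a = fit_lasso_partial(T, cov, y, genes, n_lambda=20, folds=5, seed=3)
    b = fit_lasso_partial(T, cov, y, genes, n_lambda=20, folds=5, seed=3)
    assert a.lam == b.lam
    np.testing.assert_array_equal(a.cv_curve["mean_mse"], b.cv_curve["mean_mse"])
    assert list(a.cv_curve.columns) == ["lam", "mean_mse", "sd_mse"]
    assert (a.cv_curve["lam"].diff().dropna() < 0).all()  # decreasing grid


def test_strong_signal_recovery_across_replicates():
    """5 strongly causal genes out of 500 are all selected in >=90% of the
    seeded trait replicates."""
    cfg = SimulationConfig(
        n=700, n_genes=500, R=20, seed=23,
        causal_h2=[(0.05, 1), (0.05, 2), (0.05, 3), (0.05, 1), (0.05, 2)],
    )
    g, gm, cov, traits, truth = simulate_cohort(cfg)
    genes = list(gm.genes)
    hits = 0
    for r in range(traits.R):
        y = traits.Q[:, r]
        scores = gene_scores(g, gm, genes, y)
        fit = fit_lasso_partial(scores.T, cov, y, scores.genes, n_lambda=50,
                                folds=10, seed=1000 + r)
        if truth.causal_gene_ids <= set(fit.selected_genes):
            hits += 1
    assert hits >= 0.9 * traits.R


def test_snp_ranks_shared_contract():
    g = make_genotypes(50, 6, seed=8)
    gm = make_gene_map(g.snp_ids, [3, 3])
    y = np.random.default_rng(3).normal(size=50)
    scores = gene_scores(g, gm, list(gm.genes), y)
    ranks = snp_ranks_gbpls2(scores, scores.genes)
    for gid in scores.genes:
        vals = sorted(ranks[gid].values())
        assert vals == sorted(
            np.arange(1, len(vals) + 1).astype(float)
        ) or len(set(vals)) < len(vals)
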