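"""GBPLS2: closed-form PLS gene scores and a partially penalized LASSO.

Stage 1 computes, per gene, the first PLS component of the gene's centered
SNP submatrix against the centered trait: the weight vector maximizing
cov(y, X w) over the unit sphere, whose closed form is w = X'y / ||X'y||.
The gene score is the projection T = X w.  A gene whose cross-covariance
with the trait is exactly zero is degenerate: it is flagged and excluded
from the inner model.

Stage 2 fits the trait on all t gene scores plus Age/Sex/Smoke and the
genotype PCs with an L1 penalty applied to the gene-score coefficients
only; covariates, PCs and the intercept are never shrunk.  Because the
unpenalized block enters without a penalty, it can be partialled out
exactly: the LASSO is solved by cyclic coordinate descent on the
residualized, internally standardized gene scores (gram-matrix updates,
warm starts along a log-spaced lambda path from lambda_max down).  The
penalty is chosen per replicate by 10-fold cross-validation, minimizing
mean held-out squared error (a 1-SE variant is available).  Selected genes
are those with a nonzero gene-score coefficient at the chosen lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .cohort import CohortCovariates, GeneMap, GenotypeMatrix
from .errors import ConfigError, NumericalError
from .ranks import snp_ranks as _snp_ranks

__all__ = [
    "PlsGeneScores",
    "LassoInnerFit",
    "pls_outer_weights",
    "gene_scores",
    "fit_lasso_partial",
    "supported_dimensions",
    "snp_ranks_gbpls2",
    "run_gbpls2",
]

T_PRESETS = (100, 250, 500, 750)


def supported_dimensions() -> tuple[int, ...]:
    """Preset gene counts t for the penalized inner model."""
    return T_PRESETS


def pls_outer_weights(Xi: np.ndarray, y: np.ndarray):
    """Closed-form maximizer of cov(y, Xi w) subject to ||w|| = 1.

    Columns of Xi and y are centered internally.  Returns (w, T, degenerate);
    for a degenerate gene (zero cross-covariance) w is the zero vector and
    T is None.
    """
    Xi = np.asarray(Xi, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = Xi - Xi.mean(axis=0)
    yc = y - y.mean()
    c = Xc.T @ yc
    norm = np.linalg.norm(c)
    if norm == 0:
        return np.zeros(Xi.shape[1]), None, True
    w = c / norm
    return w, Xc @ w, False


@dataclass
class PlsGeneScores:
    genes: list[str]  # non-degenerate genes, score column order
    weights: dict[str, np.ndarray]
    snp_ids: dict[str, list[str]]
    T: np.ndarray  # n x len(genes), centered projections
    degenerate: list[str] = field(default_factory=list)


def gene_scores(g: GenotypeMatrix, gene_map: GeneMap, genes: list[str],
                y: np.ndarray) -> PlsGeneScores:
    """Closed-form PLS weights and projection scores for each gene."""
    col = {sid: j for j, sid in enumerate(g.snp_ids)}
    kept, cols, weights, snp_ids, degenerate = [], [], {}, {}, []
    for gid in genes:
        snps = gene_map.snps_of(gid)
        Xi = g.G[:, [col[s] for s in snps]].astype(float)
        w, T, bad = pls_outer_weights(Xi, y)
        weights[gid] = w
        snp_ids[gid] = snps
        if bad:
            degenerate.append(gid)
            continue
        kept.append(gid)
        cols.append(T)
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} degenerate gene(s) excluded from the inner "
            f"model: {degenerate[:5]}",
            stacklevel=2,
        )
    T = np.column_stack(cols) if cols else np.empty((g.n, 0))
    return PlsGeneScores(genes=kept, weights=weights, snp_ids=snp_ids, T=T,
                         degenerate=degenerate)


@dataclass
class LassoInnerFit:
    lam: float
    beta: pd.Series  # original scale: intercept, covariates, gene scores
    selected_genes: list[str]
    cv_curve: pd.DataFrame  # columns: lam, mean_mse, sd_mse
    genes: list[str]
    # internals retained for optimality checks
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _names: list[str] = field(repr=False, default=None)
    _penalized: np.ndarray = field(repr=False, default=None)
    _beta_internal: np.ndarray = field(repr=False, default=None)

    def kkt_residual(self) -> float:
        """Max violation of the LASSO optimality conditions at the solution.

        The objective is ||y - X b||^2 / (2n) + lam * sum over penalized
        coordinates of |b_j|, on the internal (standardized gene score)
        scale.  Unpenalized coordinates must have zero gradient; penalized
        zeros must have |gradient| <= lam; penalized nonzeros must satisfy
        gradient = -lam * sign(b_j).
        """
        X, y, b = self._X, self._y, self._beta_internal
        n = len(y)
        grad = X.T @ (X @ b - y) / n
        viol = 0.0
        for j in range(len(b)):
            if not self._penalized[j]:
                viol = max(viol, abs(grad[j]))
            elif b[j] == 0:
                viol = max(viol, max(0.0, abs(grad[j]) - self.lam))
            else:
                viol = max(viol, abs(grad[j] + self.lam * np.sign(b[j])))
        return float(viol)


def _soft(x: float, lam: float) -> float:
    if x > lam:
        return x - lam
    if x < -lam:
        return x + lam
    return 0.0


def _cd_path(X: np.ndarray, y: np.ndarray, lam_grid: np.ndarray,
             tol: float, max_sweeps: int) -> np.ndarray:
    """Coordinate-descent LASSO path with warm starts and gram updates.

    X columns are the residualized (not necessarily unit-norm) penalized
    predictors; y is the residualized response.  Objective per lambda:
    ||y - X b||^2 / (2n) + lam ||b||_1.  Returns len(grid) x m coefficients.
    """
    n, m = X.shape
    gram = X.T @ X / n
    xy = X.T @ y / n
    diag = np.diag(gram).copy()
    beta = np.zeros(m)
    q = np.zeros(m)  # gram @ beta, maintained incrementally
    out = np.zeros((len(lam_grid), m))
    live = np.where(diag > 0)[0]

    def sweep(idx, lam):
        nonlocal q
        delta = 0.0
        for j in idx:
            rho = xy[j] - q[j] + diag[j] * beta[j]
            bj = _soft(rho, lam) / diag[j]
            d = bj - beta[j]
            if d != 0.0:
                q += gram[:, j] * d
                beta[j] = bj
                ad = abs(d)
                if ad > delta:
                    delta = ad
        return delta

    for k, lam in enumerate(lam_grid):
        # one full pass to refresh the active set, then cycle over the
        # active coordinates only, then re-check the full set
        for _ in range(max_sweeps):
            if sweep(live, lam) < tol:
                break
            active = live[beta[live] != 0.0]
            for _ in range(max_sweeps):
                if sweep(active, lam) < tol:
                    break
        else:
            raise NumericalError(
                f"coordinate descent did not converge at lambda={lam:.3e}"
            )
        out[k] = beta
    return out


def _residualize(U: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project M onto the orthogonal complement of col(U); also return the
    least-squares map so unpenalized coefficients can be recovered."""
    coef, *_ = np.linalg.lstsq(U, M, rcond=None)
    return M - U @ coef, coef


def fit_lasso_partial(T: np.ndarray, cov: CohortCovariates, y: np.ndarray,
                      genes: list[str], lambda_grid=None, n_lambda: int = 100,
                      lambda_min_ratio: float = 1e-3, folds: int = 10,
                      seed: int = 0, one_se: bool = False,
                      tol: float = 1e-10, cv_tol: float = 1e-4,
                      max_sweeps: int = 100000) -> LassoInnerFit:
    """Partially penalized LASSO inner model with cross-validated penalty.

    Gene-score columns are standardized internally (coefficients reported on
    the original scale); intercept, covariates and PCs carry no penalty and
    satisfy exact normal equations given the penalized fit.  ``lambda_grid``
    defaults to ``n_lambda`` log-spaced values from lambda_max down to
    ``lambda_min_ratio * lambda_max``; folds are assigned once by a seeded
    shuffle and reused across the whole grid.
    """
    if folds < 2:
        raise ConfigError("cross-validation needs at least 2 folds")
    y = np.asarray(y, dtype=float)
    n = len(y)
    T = np.asarray(T, dtype=float).reshape(n, -1)
    t = T.shape[1]
    if t != len(genes):
        raise ConfigError(f"{t} score columns vs {len(genes)} gene ids")
    C = cov.design()
    U = np.column_stack([np.ones(n), C])
    unpen_names = ["intercept"] + cov.names

    sd = T.std(axis=0)
    mu = T.mean(axis=0)
    dead = sd == 0
    sd_safe = np.where(dead, 1.0, sd)
    Ts = (T - mu) / sd_safe
    Ts[:, dead] = 0.0

    Xr, _ = _residualize(U, Ts)
    yr, _ = _residualize(U, y)
    grad0 = np.abs(Xr.T @ yr) / n
    lam_max = float(grad0.max()) if t else 0.0
    if lambda_grid is None:
        if lam_max == 0:
            lambda_grid = np.array([0.0])
        else:
            lambda_grid = np.geomspace(lam_max, lam_max * lambda_min_ratio,
                                       n_lambda)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ConfigError("empty lambda grid")

    # cross-validation over a shared fold assignment and lambda grid
    if len(lambda_grid) > 1:
        kf = KFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
        mse = np.zeros((folds, len(lambda_grid)))
        for f, (tr, te) in enumerate(kf.split(y)):
            if y[tr].std() == 0:
                raise NumericalError(f"fold {f}: training trait is constant")
            mu_f = T[tr].mean(axis=0)
            sd_f = T[tr].std(axis=0)
            sd_f = np.where(sd_f == 0, 1.0, sd_f)
            Ttr = (T[tr] - mu_f) / sd_f
            Tte = (T[te] - mu_f) / sd_f
            Xr_f, _ = _residualize(U[tr], Ttr)
            yr_f, _ = _residualize(U[tr], y[tr])
            path = _cd_path(Xr_f, yr_f, lambda_grid, cv_tol, max_sweeps)
            # unpenalized block refit per lambda (multi-RHS lstsq)
            resid = y[tr][:, None] - Ttr @ path.T
            bu, *_ = np.linalg.lstsq(U[tr], resid, rcond=None)
            pred = U[te] @ bu + Tte @ path.T
            mse[f] = ((y[te][:, None] - pred) ** 2).mean(axis=0)
        mean_mse = mse.mean(axis=0)
        sd_mse = mse.std(axis=0, ddof=1)
        best = int(np.argmin(mean_mse))
        if one_se:
            thresh = mean_mse[best] + sd_mse[best] / np.sqrt(folds)
            best = int(np.where(mean_mse <= thresh)[0][0])
        lam = float(lambda_grid[best])
        cv_curve = pd.DataFrame(
            {"lam": lambda_grid, "mean_mse": mean_mse, "sd_mse": sd_mse}
        )
    else:
        lam = float(lambda_grid[0])
        cv_curve = pd.DataFrame({"lam": [lam], "mean_mse": [np.nan],
                                 "sd_mse": [np.nan]})

    # final fit on the full data at the chosen lambda (tight tolerance)
    warm = lambda_grid[lambda_grid >= lam] if len(lambda_grid) > 1 else lambda_grid
    path = _cd_path(Xr, yr, warm, tol, max_sweeps)
    beta_std = path[-1]
    bu, *_ = np.linalg.lstsq(U, y - Ts @ beta_std, rcond=None)

    beta_T = beta_std / sd_safe
    beta_T[dead] = 0.0
    intercept = bu[0] - float((mu / sd_safe * beta_std).sum())
    names = unpen_names + list(genes)
    values = np.concatenate([[intercept], bu[1:], beta_T])
    beta = pd.Series(values, index=names)
    selected = [gid for gid, b in zip(genes, beta_std) if b != 0.0]
    penalized = np.concatenate(
        [np.zeros(U.shape[1], dtype=bool), ~dead]
    )
    return LassoInnerFit(
        lam=lam,
        beta=beta,
        selected_genes=selected,
        cv_curve=cv_curve,
        genes=list(genes),
        _X=np.column_stack([U, Ts]),
        _y=y,
        _names=names,
        _penalized=penalized,
        _beta_internal=np.concatenate([bu, beta_std]),
    )


def snp_ranks_gbpls2(scores: PlsGeneScores,
                     selected: list[str]) -> dict[str, dict[str, float]]:
    """Within each selected gene, rank SNPs by |outer weight| (1 = largest)."""
    return _snp_ranks(scores.weights, scores.snp_ids, selected)


def run_gbpls2(g: GenotypeMatrix, gene_map: GeneMap, cov: CohortCovariates,
               y: np.ndarray, screened_order: list[str], t: int = 250,
               folds: int = 10, seed: int = 0, **lasso_kwargs):
    """Full GBPLS2 pass for one replicate on the first t screened genes.

    Returns (selected gene ids, snp rank map, LassoInnerFit, PlsGeneScores).
    """
    if t > len(screened_order):
        raise ConfigError(
            f"t={t} exceeds the {len(screened_order)} screened genes"
        )
    genes = screened_order[:t]
    scores = gene_scores(g, gene_map, genes, y)
    fit = fit_lasso_partial(scores.T, cov, y, scores.genes, folds=folds,
                            seed=seed, **lasso_kwargs)
    ranks = snp_ranks_gbpls2(scores, fit.selected_genes)
    return fit.selected_genes, ranks, fit, scores
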