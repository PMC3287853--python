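"""GBPLS1: PLS path modeling outer weights, ordinary-least-squares inner model.

Stage 1 builds one latent variable (gene score) per gene with Wold's
alternating PLS path-modeling algorithm on a star-shaped path diagram: every
gene block of standardized SNP columns is connected to a single-indicator
trait block.  Outer estimation is mode A (weights updated by covariance with
the block's inner proxy) and the inner weighting rule is the factor scheme
(proxy = correlation-weighted sum of adjacent latent variables).  For this
topology the algorithm has a closed fixed point — each gene's weight vector
is proportional to its SNPs' marginal correlations with the trait — which is
what the convergence tests check against.

Stage 2 regresses the trait on all t gene scores plus Age, Sex, Smoke and
the genotype PCs by OLS, orders genes by |inner coefficient|, keeps the top
q, and ranks SNPs inside each kept gene by |outer weight|.  The OLS inner
model is what caps this variant at t <= 100 genes: beyond that the design
approaches rank deficiency at the cohort sizes the method targets, which is
precisely the regime the penalized variant (GBPLS2) exists for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortCovariates, GeneMap, GenotypeMatrix
from .errors import ConfigError, NumericalError
from .ranks import snp_ranks as _snp_ranks

__all__ = [
    "OuterModel",
    "InnerFit",
    "gene_blocks",
    "fit_plspm",
    "fit_inner_ols",
    "select_top_q",
    "snp_ranks",
    "run_gbpls1",
]

MAX_GENES = 100  # OLS inner model design limit
Q_PRESETS = (25, 35, 50)


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std(axis=0)
    out = x - x.mean(axis=0)
    if out.ndim == 1:
        return out / s if s > 0 else out
    nz = s > 0
    out[:, nz] = out[:, nz] / s[nz]
    return out


@dataclass
class OuterModel:
    genes: list[str]
    weights: dict[str, np.ndarray]  # unit-norm over each gene's SNPs
    snp_ids: dict[str, list[str]]
    scores: np.ndarray  # n x t, standardized latent variables
    n_iter: int
    final_change: float


@dataclass
class InnerFit:
    params: pd.Series  # intercept, per-gene beta, covariates
    gene_betas: pd.Series
    residual_var: float
    n: int


def gene_blocks(g: GenotypeMatrix, gene_map: GeneMap,
                genes: list[str]) -> list[tuple[str, list[str], np.ndarray]]:
    """Extract (gene_id, snp_ids, genotype submatrix) blocks in order."""
    col = {sid: j for j, sid in enumerate(g.snp_ids)}
    out = []
    for gid in genes:
        snps = gene_map.snps_of(gid)
        out.append((gid, snps, g.G[:, [col[s] for s in snps]].astype(float)))
    return out


def fit_plspm(blocks, y: np.ndarray, tol: float = 1e-6,
              max_iter: int = 300) -> OuterModel:
    """Wold's alternating algorithm (mode A outer, factor scheme inner).

    ``blocks`` is a list of (gene_id, snp_ids, X submatrix).  Manifest
    variables are standardized; the trait forms a single-indicator block
    whose latent variable is the standardized trait.  Initial weights are
    equal; iteration stops when the largest outer-weight change drops below
    ``tol``.  Latent-variable signs are fixed so that r(Z_i, y) >= 0.
    """
    t = len(blocks)
    if t == 0:
        raise ConfigError("no gene blocks to fit")
    if t > MAX_GENES:
        raise ConfigError(
            f"GBPLS1 supports at most {MAX_GENES} genes (got {t}); "
            "use GBPLS2 for higher dimensions"
        )
    y = np.asarray(y, dtype=float)
    n = len(y)
    if y.std() == 0:
        raise NumericalError("trait vector has zero variance")
    zy = _standardize(y)
    Xs, genes, snp_lists = [], [], []
    for gid, snps, X in blocks:
        if X.std(axis=0).max() == 0:
            raise NumericalError(f"gene {gid}: all SNP columns are constant")
        Xs.append(_standardize(np.asarray(X, dtype=float)))
        genes.append(gid)
        snp_lists.append(list(snps))
    W = [np.full(X.shape[1], 1.0 / np.sqrt(X.shape[1])) for X in Xs]
    change = np.inf
    for it in range(1, max_iter + 1):
        change = 0.0
        for i, X in enumerate(Xs):
            z = _standardize(X @ W[i])
            r = float(z @ zy) / n  # correlation: both standardized
            proxy = r * zy  # factor scheme, single neighbour
            w_new = X.T @ proxy / n  # mode A
            norm = np.linalg.norm(w_new)
            if norm == 0:
                raise NumericalError(
                    f"gene {genes[i]}: degenerate outer update (weights -> 0)"
                )
            w_new = w_new / norm
            change = max(change, float(np.abs(w_new - W[i]).max()))
            W[i] = w_new
        if change < tol:
            break
    else:
        raise NumericalError(
            f"PLSPM did not converge in {max_iter} iterations "
            f"(last max weight change {change:.3e})"
        )
    Z = np.empty((n, t))
    for i, X in enumerate(Xs):
        z = _standardize(X @ W[i])
        if float(z @ zy) < 0:
            W[i] = -W[i]
            z = -z
        Z[:, i] = z
    return OuterModel(
        genes=genes,
        weights={gid: W[i] for i, gid in enumerate(genes)},
        snp_ids={gid: snp_lists[i] for i, gid in enumerate(genes)},
        scores=Z,
        n_iter=it,
        final_change=change,
    )


def fit_inner_ols(outer: OuterModel, cov: CohortCovariates,
                  y: np.ndarray) -> InnerFit:
    """OLS of the trait on gene scores plus covariates and PCs."""
    t = len(outer.genes)
    if t > MAX_GENES:
        raise ConfigError(
            f"OLS inner model limited to {MAX_GENES} genes by design (got {t})"
        )
    y = np.asarray(y, dtype=float)
    C = cov.design()
    n = len(y)
    names = ["intercept"] + list(outer.genes) + cov.names
    D = np.column_stack([np.ones(n), outer.scores, C])
    if D.shape[1] > n:
        raise ConfigError(
            f"design has {D.shape[1]} columns for {n} samples; cannot fit OLS"
        )
    _, Rm = np.linalg.qr(D)
    diag = np.abs(np.diag(Rm))
    bad = diag < diag.max() * 1e-10
    if bad.any():
        off = [names[j] for j in np.where(bad)[0]]
        raise NumericalError(f"inner design is rank deficient; collinear columns: {off}")
    beta, res, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    dof = max(n - D.shape[1], 1)
    params = pd.Series(beta, index=names)
    return InnerFit(
        params=params,
        gene_betas=params[list(outer.genes)],
        residual_var=float(resid @ resid) / dof,
        n=n,
    )


def select_top_q(fit: InnerFit, q: int,
                 screening_order: list[str] | None = None) -> list[str]:
    """The q genes with largest |inner coefficient|.

    Ties are broken by screening rank (better-screened gene first), falling
    back to fit order when no screening order is supplied.
    """
    genes = list(fit.gene_betas.index)
    if q > len(genes):
        raise ConfigError(f"q={q} exceeds the {len(genes)} fitted genes")
    if screening_order is not None:
        prio = {gid: k for k, gid in enumerate(screening_order)}
        rank = {gid: prio.get(gid, len(prio) + i) for i, gid in enumerate(genes)}
    else:
        rank = {gid: i for i, gid in enumerate(genes)}
    order = sorted(genes, key=lambda gid: (-abs(fit.gene_betas[gid]), rank[gid]))
    return order[:q]


def snp_ranks(outer: OuterModel, selected: list[str]) -> dict[str, dict[str, float]]:
    """Within each selected gene, rank SNPs by |outer weight| (1 = largest)."""
    return _snp_ranks(outer.weights, outer.snp_ids, selected)


def run_gbpls1(g: GenotypeMatrix, gene_map: GeneMap, cov: CohortCovariates,
               y: np.ndarray, screened_order: list[str], t: int = MAX_GENES,
               q: int = 25, tol: float = 1e-6, max_iter: int = 300):
    """Full GBPLS1 pass for one replicate on the first t screened genes.

    Returns (selected gene ids, snp rank map, InnerFit, OuterModel).
    """
    t = min(t, len(screened_order))
    if q > t:
        raise ConfigError(f"q={q} exceeds t={t}")
    genes = screened_order[:t]
    blocks = gene_blocks(g, gene_map, genes)
    # wholly monomorphic genes carry no association signal; skip them rather
    # than abort the replicate (they rank last in screening anyway)
    poly = [b for b in blocks if b[2].std(axis=0).max() > 0]
    if len(poly) < len(blocks):
        skipped = [b[0] for b in blocks if b[2].std(axis=0).max() == 0]
        warnings.warn(
            f"{len(skipped)} monomorphic gene(s) skipped: {skipped[:5]}",
            stacklevel=2,
        )
    if q > len(poly):
        raise ConfigError(
            f"q={q} exceeds the {len(poly)} polymorphic genes available"
        )
    outer = fit_plspm(poly, y)
    fit = fit_inner_ols(outer, cov, y)
    selected = select_top_q(fit, q, screening_order=screened_order)
    ranks = snp_ranks(outer, selected)
    return selected, ranks, fit, outer
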