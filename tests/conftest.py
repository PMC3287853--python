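"""Shared fixtures: small deterministic cohorts built at test time."""

import numpy as np
import pandas as pd
import pytest

from gbpls.cohort import CohortCovariates, GeneMap, GenotypeMatrix, compute_pcs
from gbpls.simulate import SimulationConfig, simulate_cohort


def make_genotypes(n: int, p: int, seed: int = 0,
                   maf_range=(0.05, 0.5)) -> GenotypeMatrix:
    """Random Hardy-Weinberg genotypes with common-ish MAFs (no rare tail)."""
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*maf_range, size=p)
    G = rng.binomial(2, mafs, size=(n, p))
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=[f"v{j}" for j in range(p)],
        G=G,
    )


def make_covariates(g: GenotypeMatrix, seed: int = 0,
                    k_pcs: int = 10) -> CohortCovariates:
    rng = np.random.default_rng(seed)
    base = pd.DataFrame(
        {
            "Age": rng.normal(50, 10, size=g.n),
            "Sex": rng.integers(0, 2, size=g.n).astype(float),
            "Smoke": (rng.random(g.n) < 0.3).astype(float),
        },
        index=g.sample_ids,
    )
    return CohortCovariates.assemble(base, compute_pcs(g, k=k_pcs))


def make_gene_map(snp_ids, sizes) -> GeneMap:
    pairs, j = [], 0
    for gi, size in enumerate(sizes):
        for _ in range(size):
            pairs.append((snp_ids[j], f"g{gi:03d}"))
            j += 1
    assert j == len(snp_ids)
    return GeneMap.from_pairs(pairs)


@pytest.fixture(scope="session")
def small_cohort():
    """120 samples, 30 genes, 2 strongly causal genes; R=4 replicates."""
    cfg = SimulationConfig(
        n=120,
        n_genes=30,
        R=4,
        seed=11,
        causal_h2=[(0.15, 1), (0.15, 2)],
        noise_sd=1.0,
    )
    g, gene_map, cov, traits, truth = simulate_cohort(cfg)
    return {
        "genotypes": g,
        "gene_map": gene_map,
        "covariates": cov,
        "traits": traits,
        "truth": truth,
        "config": cfg,
    }
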