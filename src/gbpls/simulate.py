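"""Synthetic cohort generator emulating a rare-variant exome association study.

The generator produces everything the association pipeline consumes: an
additive genotype matrix with a rare-skewed allele frequency spectrum, a
SNP-to-gene partition with variable gene sizes, Age/Sex/Smoke covariates,
and R quantitative-trait replicates simulated over *fixed* genotypes, with a
known causal structure (the truth set) for downstream ROC evaluation.

Defaults mirror the published cohort the generator stands in for: 697
unrelated samples, a site frequency spectrum with ~75% of SNPs below MAF
0.01 and ~91% below 0.1, and a mean gene size of ~7.6 SNPs.  SNPs are
sampled independently under Hardy-Weinberg equilibrium — there is no linkage
disequilibrium, which keeps the generator analytically transparent.  An
optional two-subpopulation mode perturbs subpopulation allele frequencies
(Balding-Nichols style) to let tests exercise the PC adjustment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import (
    CohortCovariates,
    GeneMap,
    GenotypeMatrix,
    TraitReplicates,
    compute_pcs,
    orient_minor_allele,
)
from .errors import ConfigError, DataError

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "DEFAULT_MAF_SPECTRUM",
    "draw_mafs",
    "draw_gene_sizes",
    "generate_genotypes",
    "simulate_covariate_table",
    "simulate_traits",
    "effects_for_heritability",
    "simulate_cohort",
]

# Mixture matching the two published SFS quantiles: P(maf<0.01)=0.75,
# P(maf<0.1)=0.91.  Components: log-uniform rare, log-uniform low-frequency,
# uniform common.
DEFAULT_MAF_SPECTRUM = (
    (0.75, "loguniform", 1e-4, 0.01),
    (0.16, "loguniform", 0.01, 0.1),
    (0.09, "uniform", 0.1, 0.5),
)


@dataclass
class TruthSet:
    """Known causal structure of a simulated cohort."""

    causal_gene_ids: set[str]
    causal_snp_ids: set[str]
    effects: dict[str, float]  # snp_id -> beta per minor allele
    gene_h2: dict[str, float] = field(default_factory=dict)  # realized
    target_h2: dict[str, float] = field(default_factory=dict)  # as configured

    def to_json(self, path) -> None:
        obj = {
            "causal_gene_ids": sorted(self.causal_gene_ids),
            "causal_snp_ids": sorted(self.causal_snp_ids),
            "effects": self.effects,
            "gene_h2": self.gene_h2,
            "target_h2": self.target_h2,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            causal_gene_ids=set(obj["causal_gene_ids"]),
            causal_snp_ids=set(obj["causal_snp_ids"]),
            effects={k: float(v) for k, v in obj["effects"].items()},
            gene_h2={k: float(v) for k, v in obj.get("gene_h2", {}).items()},
            target_h2={k: float(v) for k, v in obj.get("target_h2", {}).items()},
        )


@dataclass
class SimulationConfig:
    """Declarative description of one synthetic cohort.

    ``causal_genes`` gives explicit per-SNP effects as
    (gene_id, [(snp_index_within_gene, beta), ...]).  Alternatively
    ``causal_h2`` lists (per-gene heritability, n causal SNPs) pairs; genes
    and SNPs are then drawn at simulation time and effect sizes solved from
    the realized genotype variances.
    """

    n: int = 697
    n_genes: int = 1000
    R: int = 20
    seed: int = 0
    maf_spectrum: tuple = DEFAULT_MAF_SPECTRUM
    # negative-binomial gene sizes truncated to >=1; defaults give mean ~7.6
    gene_size_r: float = 2.0
    gene_size_p: float = 0.2148
    causal_genes: list = field(default_factory=list)
    causal_h2: list = field(default_factory=list)
    covariate_effects: dict = field(
        default_factory=lambda: {"Age": 0.0, "Sex": 0.0, "Smoke": 0.0}
    )
    noise_sd: float = 1.0
    n_pcs: int = 10
    trait_name: str = "Q1"
    population_structure: bool = False
    fst: float = 0.01

    def __post_init__(self) -> None:
        if self.n < 1 or self.n_genes < 1 or self.R < 1:
            raise ConfigError("n, n_genes and R must all be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.causal_genes and self.causal_h2:
            raise ConfigError("give causal_genes or causal_h2, not both")

    def to_dict(self) -> dict:
        return asdict(self)


def _component_draw(rng: np.random.Generator, kind: str, lo: float, hi: float,
                    size: int) -> np.ndarray:
    if kind == "loguniform":
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))
    if kind == "uniform":
        return rng.uniform(lo, hi, size=size)
    if kind == "point":
        return np.full(size, lo)
    raise ConfigError(f"unknown MAF spectrum component {kind!r}")


def draw_mafs(p: int, spectrum=DEFAULT_MAF_SPECTRUM, seed=0) -> np.ndarray:
    """Draw p minor allele frequencies from a mixture spectrum."""
    rng = np.random.default_rng(seed)
    weights = np.array([c[0] for c in spectrum], dtype=float)
    weights = weights / weights.sum()
    which = rng.choice(len(spectrum), size=p, p=weights)
    out = np.empty(p)
    for k, (_, kind, lo, hi) in enumerate(spectrum):
        idx = which == k
        out[idx] = _component_draw(rng, kind, lo, hi, int(idx.sum()))
    return np.clip(out, np.nextafter(0, 1), 0.5)


def draw_gene_sizes(n_genes: int, r: float = 2.0, p: float = 0.2148,
                    seed=0) -> np.ndarray:
    """Negative-binomial gene sizes, rejection-truncated to >= 1 SNP."""
    rng = np.random.default_rng(seed)
    sizes = rng.negative_binomial(r, p, size=n_genes)
    while (sizes == 0).any():
        zero = sizes == 0
        sizes[zero] = rng.negative_binomial(r, p, size=int(zero.sum()))
    return sizes


def generate_genotypes(n: int, mafs: np.ndarray, seed=0,
                       sample_ids=None, snp_ids=None,
                       population_structure: bool = False,
                       fst: float = 0.01) -> GenotypeMatrix:
    """Hardy-Weinberg sampling: entry (i, j) ~ Binomial(2, maf_j)."""
    mafs = np.asarray(mafs, dtype=float)
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise DataError("MAFs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    p = len(mafs)
    if population_structure:
        # Balding-Nichols: each of two subpopulations draws its own allele
        # frequency around the ancestral one.
        a = mafs * (1 - fst) / fst
        b = (1 - mafs) * (1 - fst) / fst
        f1 = rng.beta(a, b)
        f2 = rng.beta(a, b)
        half = n // 2
        G = np.vstack(
            [
                rng.binomial(2, f1, size=(half, p)),
                rng.binomial(2, f2, size=(n - half, p)),
            ]
        )
        G, _ = orient_minor_allele(G)
    else:
        G = rng.binomial(2, mafs, size=(n, p))
    if sample_ids is None:
        sample_ids = [f"s{i + 1:04d}" for i in range(n)]
    if snp_ids is None:
        snp_ids = [f"snp{j + 1:06d}" for j in range(p)]
    return GenotypeMatrix(sample_ids=list(sample_ids), snp_ids=list(snp_ids),
                          G=G.astype(np.int8))


def build_gene_map(sizes: np.ndarray) -> tuple[GeneMap, list[str]]:
    """Sequential SNP ids partitioned into genes of the given sizes."""
    pairs = []
    snp_ids = []
    j = 0
    for gi, size in enumerate(sizes):
        gid = f"gene{gi + 1:04d}"
        for _ in range(int(size)):
            sid = f"snp{j + 1:06d}"
            pairs.append((sid, gid))
            snp_ids.append(sid)
            j += 1
    return GeneMap.from_pairs(pairs), snp_ids


def simulate_covariate_table(n: int, seed=0, sample_ids=None) -> pd.DataFrame:
    """Age ~ Normal(50, 10), Sex ~ Bernoulli(0.5), Smoke ~ Bernoulli(0.3)."""
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"s{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(
        {
            "Age": rng.normal(50.0, 10.0, size=n),
            "Sex": rng.integers(0, 2, size=n).astype(float),
            "Smoke": (rng.random(n) < 0.3).astype(float),
        },
        index=list(sample_ids),
    )


def effects_for_heritability(g: GenotypeMatrix, gene_map: GeneMap,
                             h2_spec, seed=0,
                             noise_sd: float = 1.0,
                             min_carriers: int = 5) -> list:
    """Choose causal genes/SNPs and solve effect sizes from target heritability.

    ``h2_spec`` is a list of (h2, k) pairs: each entry creates one causal gene
    whose k causal SNPs jointly contribute the fraction h2 of the total trait
    variance (covariate effects excluded from the denominator).  Causal SNPs
    are drawn among those with at least ``min_carriers`` carriers so the
    target variance is attainable in-sample; effect signs are random.
    Returns the explicit (gene_id, [(snp_idx, beta), ...]) list and the
    gene_id -> target h2 mapping.
    """
    rng = np.random.default_rng(seed)
    h2_total = float(sum(h for h, _ in h2_spec))
    if not 0 <= h2_total < 1:
        raise ConfigError("total heritability must lie in [0, 1)")
    sigma2_tot = noise_sd**2 / (1.0 - h2_total)
    carriers = (g.G > 0).sum(axis=0)
    snp_col = {sid: j for j, sid in enumerate(g.snp_ids)}
    eligible = []
    for gid in gene_map.genes:
        snps = gene_map.snps_of(gid)
        ok = [i for i, sid in enumerate(snps)
              if carriers[snp_col[sid]] >= min_carriers]
        if len(ok) >= max(k for _, k in h2_spec):
            eligible.append((gid, ok))
    if len(eligible) < len(h2_spec):
        raise ConfigError(
            f"only {len(eligible)} genes have enough informative SNPs for "
            f"{len(h2_spec)} causal genes"
        )
    chosen = rng.choice(len(eligible), size=len(h2_spec), replace=False)
    causal = []
    target_h2 = {}
    for (h2, k), ci in zip(h2_spec, chosen):
        gid, ok = eligible[ci]
        target_h2[gid] = float(h2)
        idx = rng.choice(len(ok), size=k, replace=False)
        per_snp_var = h2 * sigma2_tot / k
        effects = []
        for ii in idx:
            snp_i = ok[ii]
            col = g.G[:, snp_col[gene_map.snps_of(gid)[snp_i]]].astype(float)
            beta = np.sqrt(per_snp_var / col.var())
            if rng.random() < 0.5:
                beta = -beta
            effects.append((int(snp_i), float(beta)))
        causal.append((gid, effects))
    return causal, target_h2


def simulate_traits(g: GenotypeMatrix, gene_map: GeneMap,
                    base_cov: pd.DataFrame, cfg: SimulationConfig,
                    seed=None) -> tuple[TraitReplicates, TruthSet]:
    """Trait replicates Q[:, r] = G beta + C gamma + eps_r over fixed genotypes.

    Only the noise eps_r ~ Normal(0, noise_sd^2) is redrawn per replicate.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    snp_col = {sid: j for j, sid in enumerate(g.snp_ids)}
    genetic = np.zeros(g.n)
    effects: dict[str, float] = {}
    causal_genes: set[str] = set()
    gene_h2: dict[str, float] = {}
    for gid, snp_effects in cfg.causal_genes:
        snps = gene_map.snps_of(gid)
        contrib = np.zeros(g.n)
        for snp_idx, beta in snp_effects:
            if not 0 <= snp_idx < len(snps):
                raise ConfigError(
                    f"causal SNP index {snp_idx} out of range for gene {gid} "
                    f"of size {len(snps)}"
                )
            sid = snps[snp_idx]
            col = g.G[:, snp_col[sid]].astype(float)
            contrib += beta * col
            effects[sid] = effects.get(sid, 0.0) + float(beta)
        genetic += contrib
        causal_genes.add(gid)
        gene_h2[gid] = float(contrib.var())
    cov_part = np.zeros(g.n)
    for name, gamma in cfg.covariate_effects.items():
        if gamma:
            cov_part += gamma * base_cov[name].to_numpy(float)
    mean = genetic + cov_part
    Q = mean[:, None] + rng.normal(0.0, cfg.noise_sd, size=(g.n, cfg.R))
    tot_var = Q.var()
    if tot_var > 0:
        gene_h2 = {k: v / tot_var for k, v in gene_h2.items()}
    traits = TraitReplicates(Q=Q, trait_name=cfg.trait_name,
                             sample_ids=list(g.sample_ids))
    truth = TruthSet(
        causal_gene_ids=causal_genes,
        causal_snp_ids=set(effects),
        effects=effects,
        gene_h2=gene_h2,
    )
    return traits, truth


def simulate_cohort(cfg: SimulationConfig):
    """Generate a full cohort: genotypes, gene map, covariates (+PCs), traits.

    Returns (GenotypeMatrix, GeneMap, CohortCovariates, TraitReplicates,
    TruthSet).  Deterministic given cfg.seed; every stage draws from its own
    derived stream so adding replicates does not perturb the genotypes.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_sizes, s_maf, s_geno, s_cov, s_fx, s_trait = ss.spawn(6)
    sizes = draw_gene_sizes(cfg.n_genes, cfg.gene_size_r, cfg.gene_size_p,
                            seed=s_sizes)
    gene_map, snp_ids = build_gene_map(sizes)
    mafs = draw_mafs(len(snp_ids), cfg.maf_spectrum, seed=s_maf)
    g = generate_genotypes(cfg.n, mafs, seed=s_geno, snp_ids=snp_ids,
                           population_structure=cfg.population_structure,
                           fst=cfg.fst)
    base_cov = simulate_covariate_table(cfg.n, seed=s_cov,
                                        sample_ids=g.sample_ids)
    target_h2: dict[str, float] = {}
    if cfg.causal_h2 and not cfg.causal_genes:
        causal, target_h2 = effects_for_heritability(
            g, gene_map, cfg.causal_h2, seed=s_fx, noise_sd=cfg.noise_sd
        )
        cfg = SimulationConfig(**{**cfg.to_dict(), "causal_h2": [],
                                  "causal_genes": causal})
    traits, truth = simulate_traits(g, gene_map, base_cov, cfg, seed=s_trait)
    truth.target_h2 = target_h2
    pcs = compute_pcs(g, k=cfg.n_pcs)
    cov = CohortCovariates.assemble(base_cov, pcs)
    return g, gene_map, cov, traits, truth
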