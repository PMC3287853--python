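"""Cohort containers and I/O: genotypes, gene map, covariates, trait replicates.

Genotypes are additive minor-allele counts (0/1/2) for n unrelated samples by
p biallelic SNPs.  Loading orients every column to the minor allele, so the
per-SNP minor allele frequency (MAF = column mean / 2) never exceeds 0.5.
Covariates are the non-SNP variables (Age in years, Sex and Smoke as 0/1
indicators) plus the leading principal components of the genotype matrix,
which adjust the association models for population structure.

All tabular files are tab-separated UTF-8 with a header row and samples as
rows; missing genotypes are rejected (the methods assume complete data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, NumericalError

__all__ = [
    "GenotypeMatrix",
    "GeneMap",
    "CohortCovariates",
    "TraitReplicates",
    "read_genotypes",
    "write_genotypes",
    "compute_maf",
    "compute_pcs",
    "read_gene_map",
    "write_gene_map",
    "read_covariates",
    "write_covariates",
    "read_traits",
    "write_traits",
]


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise DataError(f"duplicate {what}: {sorted(set(dups))[:10]}")


@dataclass
class GenotypeMatrix:
    """n samples x p SNPs of additive minor-allele counts in {0, 1, 2}."""

    sample_ids: list[str]
    snp_ids: list[str]
    G: np.ndarray
    flipped: np.ndarray | None = None  # which columns were re-oriented at load

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G)
        if self.G.ndim != 2:
            raise DataError("genotype matrix must be 2-dimensional")
        n, p = self.G.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != p:
            raise DataError(
                f"id/matrix shape mismatch: {len(self.sample_ids)} samples vs "
                f"{n} rows, {len(self.snp_ids)} SNPs vs {p} columns"
            )
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.snp_ids, "SNP ids")
        if not np.isin(self.G, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(self.G, (0, 1, 2)))[0]
            raise DataError(
                f"genotype entry outside {{0,1,2}} at sample "
                f"{self.sample_ids[bad[0]]!r}, SNP {self.snp_ids[bad[1]]!r}"
            )
        self.G = self.G.astype(np.int8, copy=False)

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def p(self) -> int:
        return self.G.shape[1]

    def maf(self) -> np.ndarray:
        return compute_maf(self)


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency: column mean over 2, in [0, 0.5]."""
    return g.G.mean(axis=0) / 2.0


def orient_minor_allele(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip 0<->2 coding for columns whose allele frequency exceeds 0.5.

    Returns the oriented matrix and a boolean vector of flipped columns.
    """
    G = np.asarray(G)
    flip = G.mean(axis=0) / 2.0 > 0.5
    out = G.copy()
    out[:, flip] = 2 - out[:, flip]
    return out, flip


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Load genotypes from an additive TSV or a biallelic VCF.

    The format is inferred from the extension when not given.  Columns are
    oriented to the minor allele on load.
    """
    path = str(path)
    if format is None:
        format = "vcf" if path.endswith(".vcf") or path.endswith(".vcf.gz") else "tsv"
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise DataError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    _check_unique(header, "SNP ids in header")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pandas raises many flavours; unify
        raise DataError(f"cannot parse genotype TSV {path}: {exc}") from exc
    try:
        G = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataError(f"non-numeric genotype entry in {path}: {exc}") from exc
    if np.isnan(G).any():
        r, c = np.argwhere(np.isnan(G))[0]
        raise DataError(
            f"missing genotype at sample {df.index[r]!r}, SNP {df.columns[c]!r}; "
            "missing data are not supported"
        )
    if not np.isin(G, (0.0, 1.0, 2.0)).all():
        r, c = np.argwhere(~np.isin(G, (0.0, 1.0, 2.0)))[0]
        raise DataError(
            f"genotype entry outside {{0,1,2}} at sample {df.index[r]!r}, "
            f"SNP {df.columns[c]!r} (line {r + 2} of {path})"
        )
    Gi, flip = orient_minor_allele(G.astype(np.int8))
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        snp_ids=[str(s) for s in df.columns],
        G=Gi,
        flipped=flip,
    )


def _read_genotypes_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    cols: list[np.ndarray] = []
    for i, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            raise DataError(
                f"VCF record {i + 1} ({variant.CHROM}:{variant.POS}) is not "
                "biallelic; split multiallelic sites first"
            )
        gts = np.array(variant.genotypes, dtype=int)[:, :2]
        if (gts < 0).any():
            raise DataError(
                f"missing genotype at VCF record {i + 1} "
                f"({variant.CHROM}:{variant.POS}); missing data are not supported"
            )
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        cols.append(gts.sum(axis=1).astype(np.int8))
    if not cols:
        raise DataError(f"no variant records in {path}")
    G = np.column_stack(cols)
    Gi, flip = orient_minor_allele(G)
    return GenotypeMatrix(sample_ids=samples, snp_ids=snp_ids, G=Gi, flipped=flip)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.G, index=g.sample_ids, columns=g.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def compute_pcs(g: GenotypeMatrix, k: int = 10) -> np.ndarray:
    """First k principal-component score vectors of the genotype matrix.

    Each SNP column is centered and scaled to unit variance (zero-variance
    SNPs dropped); scores are U*S columns of the thin SVD, ordered by
    decreasing singular value, with each score's largest-magnitude entry
    forced positive.
    """
    X = g.G.astype(float)
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    if X.shape[1] == 0:
        raise NumericalError("no polymorphic SNPs: attainable rank is 0")
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if k > rank:
        raise NumericalError(f"requested {k} PCs but attainable rank is {rank}")
    scores = U[:, :k] * s[:k]
    for j in range(k):
        if scores[np.abs(scores[:, j]).argmax(), j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


@dataclass
class GeneMap:
    """Partition of SNP ids into genes."""

    gene_of: dict[str, str]
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            seen: dict[str, None] = {}
            for gid in self.gene_of.values():
                seen.setdefault(gid, None)
            self.genes = list(seen)
        self._snps_of: dict[str, list[str]] = {gid: [] for gid in self.genes}
        for sid, gid in self.gene_of.items():
            if gid not in self._snps_of:
                raise DataError(f"gene {gid!r} missing from gene list")
            self._snps_of[gid].append(sid)
        for gid, snps in self._snps_of.items():
            if not snps:
                raise DataError(f"gene {gid!r} has no SNPs")

    @property
    def gene_sizes(self) -> dict[str, int]:
        return {gid: len(snps) for gid, snps in self._snps_of.items()}

    def snps_of(self, gene_id: str) -> list[str]:
        return list(self._snps_of[gene_id])

    @classmethod
    def from_pairs(cls, pairs) -> "GeneMap":
        gene_of: dict[str, str] = {}
        for sid, gid in pairs:
            if sid in gene_of:
                raise DataError(f"SNP {sid!r} mapped to more than one gene")
            gene_of[str(sid)] = str(gid)
        return cls(gene_of=gene_of)

    def check_covers(self, g: GenotypeMatrix) -> None:
        missing = [s for s in g.snp_ids if s not in self.gene_of]
        if missing:
            raise DataError(
                f"{len(missing)} genotyped SNPs absent from gene map, e.g. "
                f"{missing[:10]}"
            )


def read_gene_map(path, genotypes: GenotypeMatrix | None = None) -> GeneMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"gene map {path} needs columns (snp_id, gene_id)")
    gm = GeneMap.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if genotypes is not None:
        gm.check_covers(genotypes)
    return gm


def write_gene_map(gm: GeneMap, path) -> None:
    rows = [(sid, gid) for sid, gid in gm.gene_of.items()]
    pd.DataFrame(rows, columns=["snp_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class CohortCovariates:
    """Per-sample Age/Sex/Smoke plus genotype PC scores P_1..P_k."""

    table: pd.DataFrame

    BASE = ("Age", "Sex", "Smoke")

    def __post_init__(self) -> None:
        missing = [c for c in self.BASE if c not in self.table.columns]
        if missing:
            raise DataError(f"covariate table missing columns {missing}")
        if self.table.isna().any().any():
            raise DataError("covariate table contains missing values")
        pcs = self.pc_columns
        if pcs:
            P = self.table[pcs].to_numpy(float)
            scale = max(1.0, float(np.abs(P).max()) ** 2 * len(P))
            if np.abs(P.mean(axis=0)).max() > 1e-8 * max(1.0, np.abs(P).max()):
                raise DataError("PC score columns must be centered")
            cross = P.T @ P
            off = cross - np.diag(np.diag(cross))
            if np.abs(off).max() > 1e-8 * scale:
                raise DataError("PC score columns must be mutually orthogonal")

    @property
    def pc_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("P_")]

    @property
    def names(self) -> list[str]:
        return list(self.BASE) + self.pc_columns

    def design(self) -> np.ndarray:
        """Covariate block of the inner-model design matrix (no intercept)."""
        return self.table[self.names].to_numpy(float)

    @classmethod
    def assemble(cls, base: pd.DataFrame, pcs: np.ndarray) -> "CohortCovariates":
        tab = base.copy()
        for j in range(pcs.shape[1]):
            tab[f"P_{j + 1}"] = pcs[:, j]
        return cls(tab)


def read_covariates(path, genotypes: GenotypeMatrix | None = None) -> CohortCovariates:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if genotypes is not None:
        want = genotypes.sample_ids
        missing = [s for s in want if s not in df.index]
        extra = [s for s in df.index if s not in set(want)]
        if missing or extra:
            raise DataError(
                f"covariate/sample mismatch: missing {missing[:5]}, extra {extra[:5]}"
            )
        df = df.loc[want]
    return CohortCovariates(df)


def write_covariates(cov: CohortCovariates, path) -> None:
    out = cov.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


@dataclass
class TraitReplicates:
    """Quantitative trait values, n samples x R replicates, fixed genotypes."""

    Q: np.ndarray
    trait_name: str = "Q1"
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        if self.Q.ndim != 2 or self.Q.shape[1] < 1:
            raise DataError("trait matrix must be n x R with R >= 1")

    def validate(self) -> None:
        """Strict check applied to loaded data: every replicate must vary."""
        if (self.Q.std(axis=0) == 0).any():
            j = int(np.argwhere(self.Q.std(axis=0) == 0)[0][0])
            raise DataError(f"trait replicate column {j} has zero variance")

    @property
    def R(self) -> int:
        return self.Q.shape[1]


def read_traits(path, genotypes: GenotypeMatrix | None = None,
                trait_name: str = "Q1") -> TraitReplicates:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if genotypes is not None:
        want = genotypes.sample_ids
        missing = [s for s in want if s not in df.index]
        extra = [s for s in df.index if s not in set(want)]
        if missing or extra:
            raise DataError(
                f"trait/sample mismatch: missing {missing[:5]}, extra {extra[:5]}"
            )
        df = df.loc[want]
    tr = TraitReplicates(
        Q=df.to_numpy(float),
        trait_name=trait_name,
        sample_ids=[str(s) for s in df.index],
    )
    tr.validate()
    return tr


def write_traits(tr: TraitReplicates, path, sample_ids=None) -> None:
    ids = tr.sample_ids if tr.sample_ids is not None else sample_ids
    if ids is None:
        ids = [f"s{i}" for i in range(tr.Q.shape[0])]
    df = pd.DataFrame(
        tr.Q, index=ids, columns=[f"rep{r + 1}" for r in range(tr.R)]
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
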