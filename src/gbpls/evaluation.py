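"""Replicate aggregation: gene calls, ROC curves, associated SNPs, t-test.

Each trait replicate yields a set of selected genes and, for those genes,
per-SNP ranks by outer-weight magnitude.  Aggregation follows the
cutoff-c rule: a gene is called associated when it is selected in at least
c of the R replicates; sweeping c traces a ROC curve against the known
causal genes.  Within a called gene, the median SNP rank over the selecting
replicates orders the SNPs, and the top half are called associated SNPs.

A single-SNP baseline is included for contrast: because rare variants have
essentially no minor-allele homozygotes, each SNP is dichotomized into
carriers versus non-carriers and a two-sample t-test is run per replicate;
the per-SNP median p-value over replicates is compared with a Bonferroni
genome-wide threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GenotypeMatrix, TraitReplicates
from .errors import ConfigError, DataError
from .simulate import TruthSet

__all__ = [
    "ReplicateSelections",
    "RocResult",
    "call_genes",
    "tpr_fpr",
    "roc_curve",
    "associated_snps",
    "median_snp_ranks",
    "snp_t_test",
    "BONFERRONI_ALPHA",
]

BONFERRONI_ALPHA = 2e-6
DEFAULT_C_MAX = 25


@dataclass
class ReplicateSelections:
    """Gene-by-replicate selection indicators plus per-selection SNP ranks."""

    genes: list[str]  # the gene universe
    selected: pd.DataFrame  # bool, index genes, columns replicate ints
    snp_ranks: dict[tuple[str, int], dict[str, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self.selected = self.selected.astype(bool)
        if list(self.selected.index) != list(self.genes):
            self.selected = self.selected.reindex(self.genes, fill_value=False)
        for (gid, rep), _ in self.snp_ranks.items():
            if not bool(self.selected.loc[gid].iloc[rep]):
                raise DataError(
                    f"SNP ranks present for gene {gid}, replicate {rep}, "
                    "which was not selected"
                )

    @property
    def R(self) -> int:
        return self.selected.shape[1]

    def selection_counts(self) -> pd.Series:
        return self.selected.sum(axis=1)

    def selection_frequency(self) -> pd.Series:
        return self.selection_counts() / self.R


def call_genes(sel: ReplicateSelections, c: int) -> set[str]:
    """Genes selected in at least c of the R replicates."""
    if not 1 <= c <= sel.R:
        raise ConfigError(f"cutoff c={c} outside 1..{sel.R}")
    counts = sel.selection_counts()
    return set(counts.index[counts >= c])


def tpr_fpr(called: set[str], truth: TruthSet,
            universe: set[str]) -> tuple[float, float]:
    """True/false positive rates of a gene call set against the truth."""
    causal = truth.causal_gene_ids & universe
    if not causal:
        raise ConfigError("truth set has no causal genes in the universe")
    noncausal = universe - causal
    tp = len(called & causal)
    fp = len(called & noncausal)
    fpr = fp / len(noncausal) if noncausal else 0.0
    return tp / len(causal), fpr


@dataclass
class RocResult:
    table: pd.DataFrame  # columns c, tpr, fpr
    method: str = ""

    def auc(self) -> float:
        """Area under the (FPR, TPR) curve, anchored at (0,0) and (1,1)."""
        pts = sorted(zip(self.table["fpr"], self.table["tpr"]))
        fpr = np.concatenate([[0.0], [p[0] for p in pts], [1.0]])
        tpr = np.concatenate([[0.0], [p[1] for p in pts], [1.0]])
        return float(np.trapezoid(tpr, fpr))


def roc_curve(sel: ReplicateSelections, truth: TruthSet,
              universe: set[str] | None = None,
              c_max: int = DEFAULT_C_MAX, method: str = "") -> RocResult:
    """(c, TPR, FPR) for c = 1..c_max; both rates non-increasing in c."""
    if universe is None:
        universe = set(sel.genes)
    c_max = min(c_max, sel.R)
    rows = []
    for c in range(1, c_max + 1):
        t, f = tpr_fpr(call_genes(sel, c), truth, universe)
        rows.append((c, t, f))
    return RocResult(
        table=pd.DataFrame(rows, columns=["c", "tpr", "fpr"]), method=method
    )


def median_snp_ranks(sel: ReplicateSelections, gene: str) -> pd.Series:
    """Per-SNP median rank over the replicates that selected the gene."""
    reps = [r for r in range(sel.R) if bool(sel.selected.loc[gene].iloc[r])]
    if not reps:
        warnings.warn(f"gene {gene} was never selected", stacklevel=2)
        return pd.Series(dtype=float)
    ranks: dict[str, list[float]] = {}
    for r in reps:
        for sid, rk in sel.snp_ranks[(gene, r)].items():
            ranks.setdefault(sid, []).append(rk)
    med = {sid: float(np.median(v)) for sid, v in ranks.items()}
    return pd.Series(med).sort_values(kind="mergesort")


def associated_snps(sel: ReplicateSelections, gene: str) -> set[str]:
    """SNPs in the top half of a called gene by median rank.

    SNPs are ordered by (median rank, snp_id) and the first ceil(m/2) of the
    gene's m SNPs are returned; an empty set if the gene was never selected.
    """
    med = median_snp_ranks(sel, gene)
    if med.empty:
        return set()
    order = sorted(med.index, key=lambda sid: (med[sid], sid))
    keep = math.ceil(len(order) / 2)
    return set(order[:keep])


def snp_t_test(g: GenotypeMatrix, traits: TraitReplicates,
               alpha: float = BONFERRONI_ALPHA,
               welch: bool = False) -> pd.DataFrame:
    """Carrier vs non-carrier t-test per SNP and replicate; median p-value.

    Each SNP is dichotomized as minor-allele carrier (count >= 1) versus
    non-carrier.  Per replicate a two-sample t-test (pooled variance by
    default, Welch by flag) compares trait means; the per-SNP median p over
    replicates is flagged significant below the Bonferroni threshold.
    SNPs with an empty group in a replicate get a missing p there; SNPs
    monomorphic in the whole cohort are excluded with a warning.
    """
    C = g.G > 0
    n1 = C.sum(axis=0)
    n0 = g.n - n1
    informative = (n1 > 0) & (n0 > 0)
    if not informative.all():
        warnings.warn(
            f"{int((~informative).sum())} monomorphic SNP(s) excluded from "
            "the t-test",
            stacklevel=2,
        )
    # one carrier is enough for the pooled test (dof = n - 2); Welch needs
    # a variance estimate in both groups
    testable = informative & ((n1 >= 2) & (n0 >= 2) if welch else g.n >= 3)
    pvals = np.full((g.p, traits.R), np.nan)
    Cf = C.astype(float)
    Nf = (~C).astype(float)
    for r in range(traits.R):
        y = traits.Q[:, r]
        s1 = y @ Cf
        s0 = y @ Nf
        ss1 = (y**2) @ Cf
        ss0 = (y**2) @ Nf
        with np.errstate(invalid="ignore", divide="ignore"):
            m1 = s1 / n1
            m0 = s0 / n0
            v1 = ss1 - n1 * m1**2
            v0 = ss0 - n0 * m0**2
            if welch:
                se2 = v1 / np.maximum(n1 - 1, 1) / n1 + v0 / np.maximum(n0 - 1, 1) / n0
                num = (v1 / np.maximum(n1 - 1, 1) / n1) ** 2 / np.maximum(n1 - 1, 1)
                den = (v0 / np.maximum(n0 - 1, 1) / n0) ** 2 / np.maximum(n0 - 1, 1)
                dof = se2**2 / (num + den)
            else:
                dof = n1 + n0 - 2.0
                sp2 = (v1 + v0) / dof
                se2 = sp2 * (1.0 / n1 + 1.0 / n0)
            tstat = (m1 - m0) / np.sqrt(se2)
            p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        p[~testable] = np.nan
        pvals[:, r] = p
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        med = np.nanmedian(pvals, axis=1)
    df = pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "median_p": med,
            "n_carriers": n1,
            "significant": med < alpha,
        }
    )
    return df[testable].reset_index(drop=True)
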