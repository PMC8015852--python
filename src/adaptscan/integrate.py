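"""Cross-stage synthesis: sweep x association overlap and the Mantel test.

Gene-level overlap uses interval containment only (strand and feature
hierarchy ignored); genetic distance defaults to 1 - IBS kinship and
environmental distance to Euclidean distance on standardized EVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import kinship_matrix
from .genio import GeneSet, GenotypeMatrix


# ---------------------------------------------------------------------------
# gene overlap
# ---------------------------------------------------------------------------

def genes_in_regions(regions: pd.DataFrame, genes: GeneSet) -> set:
    """Gene ids whose interval overlaps any region by >= 1 bp.

    ``regions`` has columns chrom, start, end (0-based half-open), matching
    the internal gene coordinates.
    """
    hit: set = set()
    gt = genes.table
    for chrom, sub in gt.groupby("chrom", sort=False):
        regs = regions[regions["chrom"] == chrom]
        if regs.empty:
            continue
        gs = sub["start"].to_numpy()
        ge = sub["end"].to_numpy()
        ids = sub["gene_id"].to_numpy()
        for rs, re_ in zip(regs["start"].to_numpy(), regs["end"].to_numpy()):
            sel = (gs < re_) & (ge > rs)
            hit.update(ids[sel])
    return hit


@dataclass
class OverlapReport:
    sweep_genes: set
    assoc_genes: set
    shared: set = field(init=False)
    fraction_of_assoc: float = field(init=False)
    fraction_of_sweep: float = field(init=False)
    by_group: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shared = set(self.sweep_genes) & set(self.assoc_genes)
        self.fraction_of_assoc = (len(self.shared) / len(self.assoc_genes)
                                  if self.assoc_genes else 0.0)
        self.fraction_of_sweep = (len(self.shared) / len(self.sweep_genes)
                                  if self.sweep_genes else 0.0)


def overlap_sweeps_associations(csr_genes, assoc_genes,
                                csr_by_group: dict | None = None) -> OverlapReport:
    """Intersection of sweep-region genes with association genes.

    ``csr_by_group`` optionally maps a group label to its own gene set for a
    per-group breakdown of the shared fraction.
    """
    rep = OverlapReport(set(csr_genes), set(assoc_genes))
    if csr_by_group:
        for grp, gset in csr_by_group.items():
            inter = set(gset) & set(assoc_genes)
            rep.by_group[grp] = dict(
                n_sweep=len(set(gset)), n_shared=len(inter),
                fraction=(len(inter) / len(set(gset)) if gset else 0.0),
            )
    return rep


# ---------------------------------------------------------------------------
# distance matrices + Mantel
# ---------------------------------------------------------------------------

def genetic_distance(geno: GenotypeMatrix) -> np.ndarray:
    """1 - IBS similarity (zero diagonal, symmetric, non-negative)."""
    K = kinship_matrix(geno).values
    D = 1.0 - K
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def environmental_distance(env: pd.DataFrame) -> np.ndarray:
    """Euclidean distance on standardized EV columns."""
    cols = [c for c in env.columns if c != "sample"]
    X = env[cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    sq = (Z**2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    D = np.sqrt(np.maximum(D2, 0.0))
    np.fill_diagonal(D, 0.0)
    return D


def mantel_test(d1: np.ndarray, d2: np.ndarray, n_perm: int = 9_999,
                seed: int | None = None) -> tuple[float, float]:
    """One-sided Mantel test of matrix correlation.

    r is the Pearson correlation of the upper-triangle entries; the p-value
    is (1 + #{permuted r >= observed}) / (1 + n_perm), permuting rows and
    columns of ``d2`` jointly.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.shape[0] != d1.shape[1]:
        raise ValueError("distance matrices must be square and congruent")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = d1[iu]
    if x.std() == 0 or d2[iu].std() == 0:
        raise ValueError("zero variance in a distance matrix")
    xc = (x - x.mean()) / x.std()

    def corr_with(mat):
        yv = mat[iu]
        return float(np.mean(xc * (yv - yv.mean()) / yv.std()))

    r_obs = corr_with(d2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(d2[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return r_obs, float(p)


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------

def summary_report(overlap: OverlapReport | None = None,
                   mantel: tuple | None = None,
                   regions: pd.DataFrame | None = None) -> dict:
    """Assemble the cross-stage results into a JSON-serializable dict."""
    out: dict = {}
    if regions is not None:
        out["n_regions"] = int(len(regions))
        out["total_span_bp"] = int((regions["end"] - regions["start"]).sum())
    if overlap is not None:
        out["n_sweep_genes"] = len(overlap.sweep_genes)
        out["n_assoc_genes"] = len(overlap.assoc_genes)
        out["n_shared_genes"] = len(overlap.shared)
        out["fraction_of_assoc_genes_shared"] = overlap.fraction_of_assoc
        if overlap.by_group:
            out["by_group"] = overlap.by_group
    if mantel is not None:
        out["mantel_r"], out["mantel_p"] = mantel
    return out
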