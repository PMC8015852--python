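"""Windowed diversity and differentiation statistics.

Sliding-window nucleotide diversity (pi), Tajima's D and Weir-Cockerham
F_ST, plus the reduction-of-diversity ratio (ROD) between a focal group and
a pooled reference, all on a shared 10-kb / 1-kb window grid by default.
Per-bp pi uses the full window span as denominator (no callability mask is
modelled).  Windows with fewer SNPs than the per-metric minimum carry NaN
and never enter empirical-quantile ranking downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genio import GenotypeMatrix


@dataclass
class WindowSpec:
    size: int = 10_000
    step: int = 1_000
    min_snps_pi: int = 1
    min_snps_d: int = 3

    def __post_init__(self) -> None:
        if self.size <= 0 or self.step <= 0 or self.step > self.size:
            raise ValueError("require 0 < step <= size")


@dataclass
class WindowStatTrack:
    """Per-window values of one scan metric over one chromosome."""

    chrom: str
    starts: np.ndarray  # 0-based
    ends: np.ndarray  # half-open
    n_snps: np.ndarray
    values: np.ndarray
    metric: str

    def same_grid(self, other: "WindowStatTrack") -> bool:
        return (self.chrom == other.chrom
                and np.array_equal(self.starts, other.starts)
                and np.array_equal(self.ends, other.ends))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "chrom": self.chrom, "start": self.starts, "end": self.ends,
            "n_snps": self.n_snps, "value": self.values, "metric": self.metric,
        })


def make_windows(seq_length: int, spec: WindowSpec) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, max(seq_length - spec.size, 0) + 1, spec.step, dtype=np.int64)
    if starts.size == 0:
        starts = np.array([0], dtype=np.int64)
    ends = np.minimum(starts + spec.size, seq_length)
    return starts, ends


def _window_slices(pos0: np.ndarray, starts: np.ndarray, ends: np.ndarray):
    """searchsorted index pairs of sites (0-based pos) per window."""
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, ends, side="left")
    return lo, hi


def _window_sum(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(x)])
    return c[hi] - c[lo]


def _subset(geno: GenotypeMatrix, samples) -> GenotypeMatrix:
    if samples is None:
        return geno
    return geno.take_samples(list(samples))


def _per_site_pi(sub: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-site pairwise diversity 2c(n-c)/(n(n-1)) and called allele numbers."""
    c = sub.alt_counts().astype(float)
    n = sub.called_allele_numbers().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * c * (n - c) / (n * (n - 1.0))
    pi[n < 2] = 0.0
    return pi, n


def windowed_pi(geno: GenotypeMatrix, samples=None,
                spec: WindowSpec | None = None,
                seq_length: int | None = None) -> WindowStatTrack:
    """Nucleotide diversity per bp of window span."""
    spec = spec or WindowSpec()
    sub = _subset(geno, samples)
    if sub.n_samples < 2:
        raise ValueError("windowed_pi needs >= 2 samples")
    L = seq_length or int(geno.variants["pos"].max() if geno.n_variants else spec.size)
    chrom = geno.variants["chrom"].iloc[0] if geno.n_variants else "chr"
    starts, ends = make_windows(L, spec)
    pos0 = sub.variants["pos"].to_numpy() - 1
    pi_site, _ = _per_site_pi(sub)
    lo, hi = _window_slices(pos0, starts, ends)
    n_snps = (hi - lo).astype(np.int64)
    vals = _window_sum(pi_site, lo, hi) / (ends - starts)
    vals = np.where(n_snps >= spec.min_snps_pi, vals,
                    np.where(n_snps == 0, 0.0, vals))
    return WindowStatTrack(chrom, starts, ends, n_snps, vals, "pi")


def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalizing constants for sample size n (alleles)."""
    if n < 2:
        raise ValueError("need n >= 2 alleles")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(geno: GenotypeMatrix, samples=None,
              spec: WindowSpec | None = None,
              seq_length: int | None = None) -> WindowStatTrack:
    """Windowed Tajima's D.

    D = (pi_sum - S/a1) / sqrt(e1*S + e2*S*(S-1)) with constants evaluated
    at the modal called-allele number among the window's sites (single-n
    constants; with no missing data this is just 2 x subset size).  Windows
    with fewer than ``min_snps_d`` segregating sites are NaN.
    """
    spec = spec or WindowSpec()
    sub = _subset(geno, samples)
    L = seq_length or int(geno.variants["pos"].max() if geno.n_variants else spec.size)
    chrom = geno.variants["chrom"].iloc[0] if geno.n_variants else "chr"
    starts, ends = make_windows(L, spec)
    pos0 = sub.variants["pos"].to_numpy() - 1
    pi_site, n_site = _per_site_pi(sub)
    c = sub.alt_counts().astype(float)
    seg = (c > 0) & (c < n_site) & (n_site >= 4)
    lo, hi = _window_slices(pos0, starts, ends)
    n_snps = (hi - lo).astype(np.int64)
    S_w = _window_sum(seg.astype(float), lo, hi)
    pi_w = _window_sum(np.where(seg, pi_site, 0.0), lo, hi)

    vals = np.full(starts.size, np.nan)
    const_cache: dict[int, dict] = {}
    for w in range(starts.size):
        S = S_w[w]
        if S < max(spec.min_snps_d, 1):
            continue
        ns = n_site[lo[w]:hi[w]][seg[lo[w]:hi[w]]].astype(int)
        if ns.size == 0:
            continue
        counts = np.bincount(ns)
        n_mode = int(np.flatnonzero(counts == counts.max())[0])  # smallest mode on ties
        if n_mode < 4:
            continue
        k = const_cache.setdefault(n_mode, tajima_constants(n_mode))
        var = k["e1"] * S + k["e2"] * S * (S - 1.0)
        if var <= 0:
            continue
        vals[w] = (pi_w[w] - S / k["a1"]) / np.sqrt(var)
    return WindowStatTrack(chrom, starts, ends, n_snps, vals, "tajd")


def wc_fst_components(geno: GenotypeMatrix, group_a, group_b):
    """Weir & Cockerham (1984) per-site variance components for two groups.

    Returns ``(a, b, c)`` arrays over variants, from genotype counts: sample
    sizes, allele frequencies and observed heterozygosities per group.
    Monomorphic-across-both sites yield a = b = c = 0 (NaN estimate).
    """
    subs = [geno.take_samples(list(g)) for g in (group_a, group_b)]
    for g, sub in zip((group_a, group_b), subs):
        if sub.n_samples < 2:
            raise ValueError("each group needs >= 2 samples")
    r = 2
    n_i = np.stack([(s.dosage >= 0).sum(axis=0).astype(float) for s in subs])
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([
            np.where(s.dosage >= 0, s.dosage, 0).sum(axis=0) / (2.0 * ni)
            for s, ni in zip(subs, n_i)
        ])
        h_i = np.stack([(s.dosage == 1).sum(axis=0) / ni for s, ni in zip(subs, n_i)])
    n_bar = n_i.sum(axis=0) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1.0)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0
        a = n_bar / n_c * (s2 - (inner) / (n_bar - 1.0))
        b = n_bar / (n_bar - 1.0) * (
            p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    mono = (p_bar <= 0) | (p_bar >= 1)
    for arr in (a, b, c):
        arr[mono] = 0.0
    return a, b, c


def weir_cockerham_fst(geno: GenotypeMatrix, group_a, group_b,
                       spec: WindowSpec | None = None,
                       seq_length: int | None = None):
    """Per-SNP and windowed Weir-Cockerham F_ST between two groups.

    The per-SNP estimate is a/(a+b+c) (raw, possibly negative; NaN where
    monomorphic).  The windowed estimate is the ratio-of-sums
    sum(a)/sum(a+b+c) over the window's informative SNPs, clamped to [0, 1]
    on report.
    """
    spec = spec or WindowSpec()
    a, b, c = wc_fst_components(geno, group_a, group_b)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = np.where(denom != 0, a / denom, np.nan)

    L = seq_length or int(geno.variants["pos"].max() if geno.n_variants else spec.size)
    chrom = geno.variants["chrom"].iloc[0] if geno.n_variants else "chr"
    starts, ends = make_windows(L, spec)
    pos0 = geno.variants["pos"].to_numpy() - 1
    lo, hi = _window_slices(pos0, starts, ends)
    inf = denom != 0
    num_w = _window_sum(np.where(inf, a, 0.0), lo, hi)
    den_w = _window_sum(np.where(inf, denom, 0.0), lo, hi)
    n_inf = _window_sum(inf.astype(float), lo, hi).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den_w != 0, num_w / den_w, np.nan)
    vals = np.clip(vals, 0.0, 1.0)
    vals[n_inf < spec.min_snps_pi] = np.nan
    snp_track = WindowStatTrack(chrom, pos0, pos0 + 1, np.ones_like(pos0), per_snp, "fst_snp")
    win_track = WindowStatTrack(chrom, starts, ends, n_inf, vals, "fst")
    return snp_track, win_track


def rod(pi_target: WindowStatTrack, pi_rest: WindowStatTrack) -> WindowStatTrack:
    """Reduction of diversity: 1 - pi_target / pi_rest per window."""
    if not pi_target.same_grid(pi_rest):
        raise ValueError("ROD requires tracks on identical windows")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = 1.0 - pi_target.values / pi_rest.values
    vals = np.where(pi_rest.values == 0, np.nan, vals)
    return WindowStatTrack(pi_target.chrom, pi_target.starts, pi_target.ends,
                           pi_target.n_snps, vals, "rod")


def windowed_theta_w(geno: GenotypeMatrix, samples=None,
                     spec: WindowSpec | None = None,
                     seq_length: int | None = None) -> WindowStatTrack:
    """Watterson's theta per bp of window span (S / a1 / span)."""
    spec = spec or WindowSpec()
    sub = _subset(geno, samples)
    L = seq_length or int(geno.variants["pos"].max() if geno.n_variants else spec.size)
    chrom = geno.variants["chrom"].iloc[0] if geno.n_variants else "chr"
    starts, ends = make_windows(L, spec)
    pos0 = sub.variants["pos"].to_numpy() - 1
    c = sub.alt_counts().astype(float)
    n = sub.called_allele_numbers().astype(float)
    seg = (c > 0) & (c < n) & (n >= 2)
    a1 = np.zeros_like(c)
    uniq = np.unique(n[seg].astype(int)) if seg.any() else []
    for nv in uniq:
        a1[(n == nv) & seg] = np.sum(1.0 / np.arange(1, nv))
    contrib = np.where(seg & (a1 > 0), 1.0 / np.where(a1 > 0, a1, 1.0), 0.0)
    lo, hi = _window_slices(pos0, starts, ends)
    n_snps = (hi - lo).astype(np.int64)
    vals = _window_sum(contrib, lo, hi) / (ends - starts)
    return WindowStatTrack(chrom, starts, ends, n_snps, vals, "theta_w")
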