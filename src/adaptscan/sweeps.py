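"""Sweep-model scans (CLR, mu, iHS) and the consensus candidate-region caller.

* ``clr_scan`` contrasts a hard-sweep-distorted site-frequency spectrum
  against the genome-wide background spectrum, composite over sites, in the
  style of Nielsen et al. (2005): at distance d from the sweep a lineage
  escapes the sweep with probability ``p_e = 1 - exp(-alpha*d)``; escapees
  plus one hitchhiking lineage are a hypergeometric subsample of the
  background spectrum, and non-escaped lineages copy the hitchhiking
  lineage's allele.  The sweep-strength parameter alpha is maximized per
  grid point (log-grid then golden-section refinement).
* ``mu_scan`` multiplies three sweep signals over SNP-count windows: local
  SNP density (mu_var), SFS shape via the low/high-frequency classes
  (mu_sfs), and the LD contrast between window halves (mu_ld).
* ``ihs_scan`` integrates extended haplotype homozygosity outward from each
  core SNP per allele and standardizes the log-ratio within
  derived-frequency bins.
* ``consensus_regions`` marks the empirical top tail of each metric's
  windows, merges adjacent outliers per metric, and keeps merged spans
  supported by at least ``min_metrics`` metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import binom, hypergeom

from .genio import GenotypeMatrix
from .winstats import WindowSpec, WindowStatTrack, make_windows


# ---------------------------------------------------------------------------
# site-frequency spectrum
# ---------------------------------------------------------------------------

@dataclass
class SFS:
    """Genome-wide allele-frequency spectrum at fixed sample size n."""

    n: int
    counts: np.ndarray  # xi_1..xi_{n-1} (unfolded) or eta_1..eta_{n//2} (folded)
    folded: bool = False

    def probs(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            raise ValueError("empty spectrum")
        return self.counts / tot


def background_sfs(geno: GenotypeMatrix, samples=None, folded: bool = False) -> SFS:
    """Count derived (alt) allele frequencies over all polymorphic sites.

    Sites with missing calls (called alleles != n) are excluded so the
    spectrum has a single sample size.
    """
    sub = geno if samples is None else geno.take_samples(list(samples))
    n = 2 * sub.n_samples
    if n < 4:
        raise ValueError("need >= 4 allele copies")
    c = sub.alt_counts()
    an = sub.called_allele_numbers()
    ok = (an == n) & (c > 0) & (c < n)
    if not ok.any():
        raise ValueError("zero polymorphic sites")
    xi = np.bincount(c[ok], minlength=n)[1:n].astype(float)
    if folded:
        eta = np.zeros(n // 2)
        for i in range(1, n // 2 + 1):
            eta[i - 1] = xi[i - 1] + (xi[n - i - 1] if i != n - i else 0.0)
        return SFS(n, eta, folded=True)
    return SFS(n, xi, folded=False)


# ---------------------------------------------------------------------------
# CLR scan
# ---------------------------------------------------------------------------

@dataclass
class SweepModelFit:
    pos: int
    alpha: float
    loglik_sweep: float
    loglik_background: float
    clr: float


def _sweep_spectrum_table(sfs: SFS, pe_grid: np.ndarray) -> np.ndarray:
    """P(derived count k | p_e) for k = 1..n-1, for each escape probability.

    For each number of escapees e ~ Binom(n, p_e): the e escapees plus one
    hitchhiking ancestor are a subsample of size e+1 (without replacement)
    from the background sample of size n; the hitchhiking lineage's allele is
    copied onto the n - e non-escaped lineages.  Outcomes monomorphic in the
    sample are dropped and the distribution renormalized over 1..n-1.
    """
    n = sfs.n
    if sfs.folded:
        raise ValueError("CLR needs the unfolded spectrum")
    p_j = sfs.probs()  # index j-1 -> background derived count j
    j = np.arange(1, n)

    # q[e'][h]: P(h derived among a subsample of size e') under the background
    q = []
    for ep in range(0, n + 1):
        h = np.arange(0, ep + 1)
        # hypergeom.pmf(h; M=n, n_success=j, N=ep) for each background count j
        pm = hypergeom.pmf(h[None, :], n, j[:, None], ep)
        q.append(p_j @ pm)

    table = np.zeros((pe_grid.size, n - 1))
    ppoly = np.zeros(pe_grid.size)
    for gi, pe in enumerate(pe_grid):
        pk = np.zeros(n + 1)
        w_e = binom.pmf(np.arange(0, n + 1), n, pe)
        for e in range(0, n + 1):
            if w_e[e] < 1e-14:
                continue
            if e == n:  # everyone escaped: plain background subsample of size n
                pk[1:n] += w_e[e] * q[n][1:n]
                continue
            ep = e + 1
            qe = q[ep]
            h = np.arange(0, ep + 1)
            p_swept_derived = h / ep
            # swept lineage derived: k = (h-1) + (n-e); ancestral: k = h
            for hi, ph in enumerate(qe):
                if ph == 0:
                    continue
                k_d = hi - 1 + n - e
                if 0 <= k_d <= n:
                    pk[k_d] += w_e[e] * ph * p_swept_derived[hi]
                pk[hi] += w_e[e] * ph * (1.0 - p_swept_derived[hi])
        poly = pk[1:n]
        s = poly.sum()
        table[gi] = poly / s if s > 0 else p_j
        ppoly[gi] = s
    return table, ppoly


class ClrModel:
    """Precomputed escape-probability table for one background spectrum.

    ``mix`` weights a recurrent-mutation component: mutations arising during
    or just after the sweep are young, low-frequency alleles (spectrum taken
    proportional to 1/i^2) that the pure escape model cannot produce — at
    p_e -> 0 it assigns polymorphic sites probability zero, so one
    post-sweep singleton would veto an otherwise obvious sweep.  The
    component's weight scales with how much variation the sweep removed
    (full replacement in the swept limit, matching mutation-dense data where
    site density recovers long before the frequency spectrum), so the
    background limit p_e -> 1 is untouched.
    """

    def __init__(self, sfs: SFS, n_pe: int = 64, mix: float = 1.0):
        self.sfs = sfs
        self.n = sfs.n
        # p_e grid log-dense near BOTH ends: the sweep signal lives at small
        # p_e (near the sweep) and the background limit at p_e -> 1
        half = n_pe // 2
        lo = np.logspace(-4, np.log10(0.5), half)
        hi = 1.0 - np.logspace(np.log10(0.5), -6, half)
        self.pe_grid = np.unique(np.concatenate([[0.0], lo, hi, [1.0]]))
        table, ppoly = _sweep_spectrum_table(sfs, self.pe_grid)
        bg = sfs.probs()
        young = 1.0 / np.arange(1, self.n) ** 2  # recent-mutation spectrum
        young /= young.sum()
        m_eff = mix * (1.0 - ppoly)  # vanishes where the sweep removed nothing
        joint = ((1.0 - m_eff)[:, None] * ppoly[:, None] * table
                 + m_eff[:, None] * young[None, :])
        ppoly_mixed = (1.0 - m_eff) * ppoly + m_eff
        table_mixed = joint / np.maximum(ppoly_mixed[:, None], 1e-300)
        self.log_table = np.log(np.maximum(table_mixed, 1e-300))
        self.ppoly = ppoly_mixed  # P(site still polymorphic | p_e), vs background
        self.log_bg = np.log(np.maximum(bg, 1e-300))

    def _interp_idx(self, pe: np.ndarray):
        idx = np.clip(np.searchsorted(self.pe_grid, pe) - 1, 0, self.pe_grid.size - 2)
        f = (pe - self.pe_grid[idx]) / (self.pe_grid[idx + 1] - self.pe_grid[idx])
        return idx, np.clip(f, 0.0, 1.0)

    def site_loglik(self, pe: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Interpolate log P(k | p_e, polymorphic) from the table."""
        idx, f = self._interp_idx(pe)
        lo = self.log_table[idx, k - 1]
        hi = self.log_table[idx + 1, k - 1]
        return lo + f * (hi - lo)

    def poly_prob(self, pe: np.ndarray) -> np.ndarray:
        """Interpolated probability that a site stays polymorphic under the sweep."""
        idx, f = self._interp_idx(pe)
        return self.ppoly[idx] + f * (self.ppoly[idx + 1] - self.ppoly[idx])


def clr_scan(geno: GenotypeMatrix, samples=None, sfs: SFS | None = None,
             grid_step: int = 2_000, seq_length: int | None = None,
             spec: WindowSpec | None = None,
             alpha_bounds: tuple = (1e-7, 1e-2), n_alpha: int = 16):
    """Composite-likelihood-ratio sweep scan on a positional grid.

    Returns ``(WindowStatTrack, list[SweepModelFit])``; the window value is
    the maximum CLR over grid points in the window.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    sub = geno if samples is None else geno.take_samples(list(samples))
    if sfs is None:
        sfs = background_sfs(sub)
    model = ClrModel(sfs)
    n = sfs.n
    c = sub.alt_counts()
    an = sub.called_allele_numbers()
    ok = (an == n) & (c > 0) & (c < n)
    pos = sub.variants["pos"].to_numpy()[ok].astype(float)
    k = c[ok].astype(int)
    L = seq_length or int(geno.variants["pos"].max() if geno.n_variants else grid_step)
    spec = spec or WindowSpec()

    bg_site = model.log_bg[k - 1]
    grid = np.arange(grid_step // 2, L, grid_step, dtype=float)
    alphas = np.geomspace(alpha_bounds[0], alpha_bounds[1], n_alpha)
    fits: list[SweepModelFit] = []
    lam = pos.size / float(L)  # genome-wide density of used polymorphic sites

    def delta_ll(a: float, x: float) -> float:
        d = np.abs(pos - x)
        pe = 1.0 - np.exp(-a * d)
        shape = float((model.site_loglik(pe, k) - bg_site).sum())
        s_here = model.poly_prob(pe)
        thin = float(np.log(np.maximum(s_here, 1e-300)).sum())
        # Poisson compensation for sites swept away: the polymorphic-site
        # field is thinned to lam * s(p_e(b)) near the sweep
        d_max = 7.0 / a
        blo, bhi = max(0.0, x - d_max), min(float(L), x + d_max)
        bgrid = np.linspace(blo, bhi, 128)
        s_field = model.poly_prob(1.0 - np.exp(-a * np.abs(bgrid - x)))
        missing = lam * float(np.trapezoid(1.0 - s_field, bgrid))
        return shape + thin + missing

    def neg_delta(log_a: float, x: float):
        return -delta_ll(float(np.exp(log_a)), x)

    for x in grid:
        deltas = np.array([delta_ll(a, x) for a in alphas])
        ai = int(np.argmax(deltas))
        lo = np.log(alphas[max(ai - 1, 0)])
        hi = np.log(alphas[min(ai + 1, alphas.size - 1)])
        if hi > lo:
            res = minimize_scalar(neg_delta, bounds=(lo, hi), args=(x,),
                                  method="bounded", options={"xatol": 0.05})
            best = (max(-res.fun, deltas[ai]), float(np.exp(res.x)))
        else:
            best = (deltas[ai], float(alphas[ai]))
        gain = max(best[0], 0.0)  # sup over alpha includes the background limit
        fits.append(SweepModelFit(
            pos=int(x), alpha=best[1],
            loglik_sweep=float(bg_site.sum() + gain),
            loglik_background=float(bg_site.sum()),
            clr=float(2.0 * gain),
        ))

    starts, ends = make_windows(L, spec)
    clr_vals = np.array([f.clr for f in fits])
    gp = np.array([f.pos for f in fits], dtype=float)
    vals = np.full(starts.size, np.nan)
    n_gp = np.zeros(starts.size, dtype=np.int64)
    lo_i = np.searchsorted(gp, starts, side="left")
    hi_i = np.searchsorted(gp, ends, side="left")
    for w in range(starts.size):
        if hi_i[w] > lo_i[w]:
            vals[w] = clr_vals[lo_i[w]:hi_i[w]].max()
            n_gp[w] = hi_i[w] - lo_i[w]
    chrom = geno.variants["chrom"].iloc[0] if geno.n_variants else "chr"
    track = WindowStatTrack(chrom, starts, ends, n_gp, vals, "clr")
    return track, fits


# ---------------------------------------------------------------------------
# mu scan
# ---------------------------------------------------------------------------

@dataclass
class MuComponents:
    index: int
    start: int  # 1-based bp of first SNP
    end: int  # 1-based bp of last SNP
    mu_var: float
    mu_sfs: float
    mu_ld: float
    mu: float = field(init=False)

    def __post_init__(self) -> None:
        self.mu = self.mu_var * self.mu_sfs * self.mu_ld


def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    """r^2 between columns of X (haplotype 0/1 or dosage matrix)."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    keep = sd > 0
    r2 = np.zeros((X.shape[1], X.shape[1]))
    if keep.sum() >= 2:
        corr = np.corrcoef(Xc[:, keep], rowvar=False)
        r2_sub = corr**2
        idx = np.flatnonzero(keep)
        r2[np.ix_(idx, idx)] = r2_sub
    return r2


def mu_scan(geno: GenotypeMatrix, samples=None, snps_per_window: int = 20,
            seq_length: int | None = None, eps: float = 0.01) -> list[MuComponents]:
    """RAiSD-style mu statistic over sliding windows of W consecutive SNPs.

    mu_var = (span/L) * (S/W); mu_sfs = (xi_1 + xi_{n-1} + 1)/(W + 2)
    normalized by its genome-wide mean; mu_ld = (mean within-half r^2 + eps)
    / (2 * mean cross-half r^2 + eps).
    """
    W = snps_per_window
    if W < 4 or W % 2:
        raise ValueError("snps_per_window must be >= 4 and even")
    sub = geno if samples is None else geno.take_samples(list(samples))
    c = sub.alt_counts()
    an = sub.called_allele_numbers()
    n = 2 * sub.n_samples
    ok = (an > 0) & (c > 0) & (c < an)
    pos = sub.variants["pos"].to_numpy()[ok]
    c = c[ok]
    an = an[ok]
    S = pos.size
    if S < W:
        return []
    L = seq_length or int(geno.variants["pos"].max())
    X = (sub.haplotypes[:, ok] if sub.haplotypes is not None
         else sub.dosage[:, ok]).astype(float)
    X[X < 0] = np.nan
    col_means = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_means, inds[1])

    half = W // 2
    raw_sfs = np.empty(S - W + 1)
    comps = []
    for i in range(S - W + 1):
        sl = slice(i, i + W)
        singles = int(((c[sl] == 1) | (c[sl] == an[sl] - 1)).sum())
        raw_sfs[i] = (singles + 1.0) / (W + 2.0)
    sfs_norm = raw_sfs / raw_sfs.mean()
    for i in range(S - W + 1):
        sl = slice(i, i + W)
        span = float(pos[i + W - 1] - pos[i])
        mu_var = (span / L) * (S / W)
        r2 = _pairwise_r2(X[:, sl])
        iu = np.triu_indices(half, k=1)
        left = r2[:half, :half][iu].mean() if half > 1 else 0.0
        right = r2[half:, half:][iu].mean() if half > 1 else 0.0
        cross = r2[:half, half:].mean()
        mu_ld = (left + right + eps) / (2.0 * cross + eps)
        comps.append(MuComponents(index=i, start=int(pos[i]), end=int(pos[i + W - 1]),
                                  mu_var=mu_var, mu_sfs=float(sfs_norm[i]),
                                  mu_ld=float(mu_ld)))
    return comps


def mu_to_track(comps: list[MuComponents], seq_length: int,
                spec: WindowSpec | None = None, chrom: str = "chr") -> WindowStatTrack:
    """Project SNP-window mu values onto the positional window grid (max per window)."""
    spec = spec or WindowSpec()
    starts, ends = make_windows(seq_length, spec)
    centers = np.array([(c.start + c.end) / 2.0 - 1 for c in comps])
    mu = np.array([c.mu for c in comps])
    vals = np.full(starts.size, np.nan)
    n_w = np.zeros(starts.size, dtype=np.int64)
    if centers.size:
        order = np.argsort(centers)
        centers, mu = centers[order], mu[order]
        lo = np.searchsorted(centers, starts, side="left")
        hi = np.searchsorted(centers, ends, side="left")
        for w in range(starts.size):
            if hi[w] > lo[w]:
                vals[w] = mu[lo[w]:hi[w]].max()
                n_w[w] = hi[w] - lo[w]
    return WindowStatTrack(chrom, starts, ends, n_w, vals, "mu")


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------

@dataclass
class IhsResult:
    variant_idx: int
    pos: int
    daf: float
    ihh_a: float
    ihh_d: float
    unstandardized: float
    ihs: float = np.nan


def _ehh_integral(hap: np.ndarray, pos: np.ndarray, core: int, carriers: np.ndarray,
                  cutoff: float) -> float:
    """Integrated EHH (trapezoid over bp) away from the core on both sides.

    EHH(x) is the probability that two random carrier haplotypes are
    identical over every site between the core and x inclusive; EHH at the
    core itself is 1.  Integration stops once EHH < cutoff (the final
    segment down to the crossing is included) or at the last SNP.
    """
    n = carriers.sum()
    if n < 2:
        return np.nan
    denom = n * (n - 1) / 2.0
    total = 0.0
    for direction in (1, -1):
        labels = np.zeros(int(n), dtype=np.int64)
        ehh_prev = 1.0
        x_prev = float(pos[core])
        j = core + direction
        while 0 <= j < pos.size:
            keys = labels * 2 + hap[carriers, j]
            _, labels = np.unique(keys, return_inverse=True)
            sizes = np.bincount(labels)
            ehh = (sizes * (sizes - 1) / 2.0).sum() / denom
            x = float(pos[j])
            total += 0.5 * (ehh_prev + ehh) * abs(x - x_prev)
            ehh_prev, x_prev = ehh, x
            if ehh < cutoff:
                break
            j += direction
    return total


def ihs_scan(geno: GenotypeMatrix, samples=None, freq_bin_width: float = 0.05,
             ehh_cutoff: float = 0.05, min_bin: int = 10,
             daf_range: tuple = (0.05, 0.95)) -> list[IhsResult]:
    """Integrated haplotype score per core SNP, standardized within DAF bins.

    Requires phased haplotypes; the alternate allele is treated as derived
    (the simulator emits ancestral = REF).  Scores in bins with fewer than
    ``min_bin`` values are set NaN with a warning.
    """
    sub = geno if samples is None else geno.take_samples(list(samples))
    if sub.haplotypes is None:
        raise ValueError("phased haplotypes required for iHS")
    hap = sub.haplotypes
    if (hap < 0).any():
        raise ValueError("iHS requires complete haplotype data")
    pos = sub.variants["pos"].to_numpy()
    n_hap = hap.shape[0]
    daf = hap.sum(axis=0) / n_hap

    results: list[IhsResult] = []
    for core in range(pos.size):
        f = daf[core]
        if not (daf_range[0] <= f <= daf_range[1]):
            continue
        derived = hap[:, core] == 1
        ihh_d = _ehh_integral(hap, pos, core, derived, ehh_cutoff)
        ihh_a = _ehh_integral(hap, pos, core, ~derived, ehh_cutoff)
        if not np.isfinite(ihh_a) or not np.isfinite(ihh_d) or ihh_a <= 0 or ihh_d <= 0:
            continue
        results.append(IhsResult(
            variant_idx=core, pos=int(pos[core]), daf=float(f),
            ihh_a=float(ihh_a), ihh_d=float(ihh_d),
            unstandardized=float(np.log(ihh_a / ihh_d)),
        ))

    # standardize within derived-frequency bins
    if results:
        bins = np.floor(np.array([r.daf for r in results]) / freq_bin_width).astype(int)
        raw = np.array([r.unstandardized for r in results])
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() < min_bin:
                warnings.warn(f"iHS frequency bin {b} has {int(sel.sum())} < {min_bin} "
                              "scores; set to NaN")
                continue
            mu, sd = raw[sel].mean(), raw[sel].std(ddof=0)
            if sd == 0:
                continue
            for i in np.flatnonzero(sel):
                results[i].ihs = float((raw[i] - mu) / sd)
    return results


# ---------------------------------------------------------------------------
# consensus regions
# ---------------------------------------------------------------------------

@dataclass
class SweepRegion:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    supports: list  # metric names contributing >=1 bp
    member_windows: list  # window indices of the union span
    genes: list = field(default_factory=list)


def _merge_marked(starts, ends, marked) -> list[tuple[int, int, list]]:
    """Merge overlapping/touching marked windows into (start, end, idx) runs."""
    out = []
    cur = None
    for w in np.flatnonzero(marked):
        s, e = int(starts[w]), int(ends[w])
        if cur is not None and s <= cur[1]:
            cur[1] = max(cur[1], e)
            cur[2].append(w)
        else:
            if cur is not None:
                out.append(tuple(cur))
            cur = [s, e, [w]]
    if cur is not None:
        out.append(tuple(cur))
    return out


def metric_outliers(track: WindowStatTrack, tail_fraction: float = 0.05,
                    tail: str = "upper"):
    """Windows at or beyond the empirical tail quantile (ties included)."""
    vals = track.values
    finite = np.isfinite(vals)
    if not finite.any():
        return np.zeros(vals.size, dtype=bool), np.nan
    if tail == "upper":
        thr = np.quantile(vals[finite], 1.0 - tail_fraction)
        marked = finite & (vals >= thr)
    elif tail == "lower":
        thr = np.quantile(vals[finite], tail_fraction)
        marked = finite & (vals <= thr)
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return marked, float(thr)


def consensus_regions(tracks: list[WindowStatTrack], tail_fraction: float = 0.05,
                      tail_side: dict | None = None, min_metrics: int = 2
                      ) -> list[SweepRegion]:
    """Call candidate selection regions supported by >= min_metrics metrics.

    Per metric: mark the empirical top tail of windows and merge adjacent
    marked windows into per-metric outlier regions.  Merged spans of the
    union of all marked windows become :class:`SweepRegion` s when at least
    ``min_metrics`` metrics overlap the span by >= 1 bp.
    """
    if len(tracks) < 2:
        raise ValueError("need >= 2 tracks")
    t0 = tracks[0]
    for t in tracks[1:]:
        if not t.same_grid(t0):
            raise ValueError("tracks must share an identical window grid")
    tail_side = tail_side or {}
    default_tail = {"rod": "upper", "fst": "upper", "clr": "upper",
                    "mu": "upper", "tajd": "upper", "pi": "lower"}

    marked_by_metric = {}
    for t in tracks:
        tail = tail_side.get(t.metric, default_tail.get(t.metric, "upper"))
        marked, _thr = metric_outliers(t, tail_fraction, tail)
        marked_by_metric[t.metric] = marked

    union = np.zeros(t0.starts.size, dtype=bool)
    for m in marked_by_metric.values():
        union |= m
    regions = []
    for s, e, widx in _merge_marked(t0.starts, t0.ends, union):
        supports = []
        for name, marked in marked_by_metric.items():
            runs = _merge_marked(t0.starts, t0.ends, marked)
            if any(rs < e and re_ > s for rs, re_, _ in runs):
                supports.append(name)
        if len(supports) >= min_metrics:
            regions.append(SweepRegion(chrom=t0.chrom, start=s, end=e,
                                       supports=sorted(supports),
                                       member_windows=widx))
    return regions


def regions_to_frame(regions: list[SweepRegion]):
    import pandas as pd

    return pd.DataFrame(
        [(r.chrom, r.start, r.end, ",".join(r.supports)) for r in regions],
        columns=["chrom", "start", "end", "supports"],
    )
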