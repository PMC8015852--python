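"""Genotype-environment and genotype-trait association.

The mixed-model scan follows the EMMAX strategy: variance components are
estimated once on the null model by REML (P3D - population parameters
previously determined), then every variant is tested by generalized least
squares in the eigenspace of the kinship matrix.  The latent-factor scan is
a ridge / alternating-least-squares latent factor mixed model (lfmm2-style):
deterministic, desk-scale, same estimand as the MCMC original, with
genomic-control calibration of the per-locus z-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .genio import GenotypeMatrix


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    samples: list
    values: np.ndarray  # (n, n), symmetric, unit diagonal, PSD after bending


def kinship_matrix(geno: GenotypeMatrix, bend_floor: float = 1e-6) -> KinshipMatrix:
    """Pairwise identity-by-state similarity, bent to positive semidefinite.

    IBS(i, j) = mean over jointly-called sites of (2 - |d_i - d_j|)/2.
    Negative eigenvalues are floored at ``bend_floor`` and the diagonal is
    rescaled back to 1.
    """
    if geno.n_samples < 2 or geno.n_variants < 1:
        raise ValueError("kinship needs >= 2 samples and >= 1 variant")
    D = geno.dosage.astype(float)
    called = D >= 0
    D[~called] = 0.0
    n = geno.n_samples
    K = np.empty((n, n))
    for i in range(n):
        both = called[i][None, :] & called
        diff = np.abs(D[i][None, :] - D)
        diff[~both] = 0.0
        cnt = both.sum(axis=1)
        if (cnt == 0).any():
            j = int(np.flatnonzero(cnt == 0)[0])
            raise ValueError(f"samples {geno.samples[i]!r} and {geno.samples[j]!r} "
                             "share zero jointly-called sites")
        K[i] = 1.0 - diff.sum(axis=1) / (2.0 * cnt)
    K = (K + K.T) / 2.0
    w, V = np.linalg.eigh(K)
    if w.min() < bend_floor:
        w = np.maximum(w, bend_floor)
        K = (V * w) @ V.T
        d = np.sqrt(np.diag(K))
        K = K / d[:, None] / d[None, :]
    return KinshipMatrix(list(geno.samples), K)


# ---------------------------------------------------------------------------
# EMMAX-style mixed model
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    delta: float  # sigma2_e / sigma2_g
    reml_loglik: float
    eigenvalues: np.ndarray
    rotation: np.ndarray
    covariates: np.ndarray  # fixed-effect design (incl. intercept + genotype PCs)
    beta_null: np.ndarray


def _reml_loglik(log_delta: float, lam: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    delta = np.exp(log_delta)
    d = lam + delta
    Xd = Xt / d[:, None]
    XtX = Xt.T @ Xd
    beta = np.linalg.solve(XtX, Xd.T @ yt)
    r = yt - Xt @ beta
    n, p = Xt.shape
    rss = float(r @ (r / d))
    sigma2 = rss / (n - p)
    _, logdet_xtx = np.linalg.slogdet(XtX)
    return -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                   + np.log(d).sum() + logdet_xtx)


def fit_null_mixed_model(y: np.ndarray, K: KinshipMatrix, X: np.ndarray,
                         grid: tuple = (-10.0, 10.0), n_grid: int = 100) -> MixedModelFit:
    """REML fit of y = X beta + u + e with cov(u) = sigma2_g K.

    delta = sigma2_e / sigma2_g is profiled over a log grid then refined by
    bounded scalar minimization.
    """
    lam, U = np.linalg.eigh(K.values)
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    Xt = U.T @ X
    lds = np.linspace(grid[0], grid[1], n_grid)
    lls = np.array([_reml_loglik(ld, lam, yt, Xt) for ld in lds])
    i = int(np.argmax(lls))
    lo, hi = lds[max(i - 1, 0)], lds[min(i + 1, n_grid - 1)]
    res = minimize_scalar(lambda ld: -_reml_loglik(ld, lam, yt, Xt),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    delta = float(np.exp(res.x))
    ll = float(-res.fun)
    d = lam + delta
    Xd = Xt / d[:, None]
    beta = np.linalg.solve(Xt.T @ Xd, Xd.T @ yt)
    return MixedModelFit(delta=delta, reml_loglik=ll, eigenvalues=lam, rotation=U,
                         covariates=X, beta_null=beta)


def genotype_pcs(geno: GenotypeMatrix, n_pcs: int) -> np.ndarray:
    """Top principal-component scores of the (mean-imputed) dosage matrix."""
    if n_pcs == 0:
        return np.zeros((geno.n_samples, 0))
    X = _imputed_dosage(geno)
    X = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :n_pcs] * s[:n_pcs]


def _imputed_dosage(geno: GenotypeMatrix) -> np.ndarray:
    X = geno.dosage.astype(float)
    X[X < 0] = np.nan
    mean = np.nanmean(X, axis=0)
    mean[np.isnan(mean)] = 0.0
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mean, idx[1])
    return X


def emmax_scan(geno: GenotypeMatrix, y: np.ndarray, K: KinshipMatrix | None = None,
               n_pcs: int = 3, name: str = "trait", exact: bool = False) -> pd.DataFrame:
    """Per-variant mixed-model association scan.

    The null-model variance ratio is reused for every variant (P3D); with
    ``exact=True`` the REML fit is repeated per marker.  Returns a DataFrame
    with variant id, effect, standard error, t statistic and two-sided
    p-value.
    """
    y = np.asarray(y, dtype=float)
    if y.size != geno.n_samples:
        raise ValueError("phenotype length must equal sample count")
    if np.std(y) == 0:
        raise ValueError("constant phenotype")
    if K is None:
        K = kinship_matrix(geno)
    pcs = genotype_pcs(geno, n_pcs)
    X = np.column_stack([np.ones(geno.n_samples), pcs])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("singular covariate matrix (collinear genotype PCs)")

    null = fit_null_mixed_model(y, K, X)
    G = _imputed_dosage(geno)

    def _stats_for(delta: float):
        d = np.sqrt(null.eigenvalues + delta)
        U = null.rotation
        ys = (U.T @ y) / d
        Xs = (U.T @ X) / d[:, None]
        Gs = (U.T @ G) / d[:, None]
        # residualize on covariates in the whitened space
        Q, _ = np.linalg.qr(Xs)
        yr = ys - Q @ (Q.T @ ys)
        Gr = Gs - Q @ (Q.T @ Gs)
        gg = (Gr**2).sum(axis=0)
        gy = Gr.T @ yr
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = gy / gg
        dof = geno.n_samples - X.shape[1] - 1
        rss = (yr**2).sum() - beta * gy
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(np.maximum(rss, 0.0) / dof / gg)
            tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        return beta, se, tstat, p

    if exact:
        betas, ses, ts, ps = [], [], [], []
        for j in range(geno.n_variants):
            Xj = np.column_stack([X, G[:, j]])
            if np.linalg.matrix_rank(Xj) < Xj.shape[1]:
                betas.append(np.nan); ses.append(np.nan); ts.append(np.nan); ps.append(np.nan)
                continue
            fitj = fit_null_mixed_model(y, K, Xj)
            b, s, t, p = _stats_for(fitj.delta)
            betas.append(b[j]); ses.append(s[j]); ts.append(t[j]); ps.append(p[j])
        beta, se, tstat, p = map(np.asarray, (betas, ses, ts, ps))
    else:
        beta, se, tstat, p = _stats_for(null.delta)

    out = geno.variants[["chrom", "pos"]].copy()
    out["variant"] = out["chrom"].astype(str) + ":" + out["pos"].astype(str)
    out["beta"] = beta
    out["se"] = se
    out["stat"] = tstat
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["phenotype"] = name
    return out


# ---------------------------------------------------------------------------
# environmental PCA
# ---------------------------------------------------------------------------

@dataclass
class EnvPCA:
    ev_names: list
    loadings: np.ndarray  # (n_evs_kept, n_comp), orthonormal columns
    scores: np.ndarray  # (n_samples, n_comp)
    variance_fraction: np.ndarray


def env_pca(env: pd.DataFrame) -> EnvPCA:
    """PCA of the standardized EV table (zero-variance columns dropped)."""
    ev_cols = [c for c in env.columns if c != "sample"]
    if len(ev_cols) < 2:
        raise ValueError("need >= 2 EV columns")
    X = env[ev_cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    drop = sd == 0
    if drop.any():
        warnings.warn(f"dropping zero-variance EVs: {[c for c, d in zip(ev_cols, drop) if d]}")
        ev_cols = [c for c, d in zip(ev_cols, drop) if not d]
        X, sd = X[:, ~drop], sd[~drop]
    Z = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    return EnvPCA(ev_names=ev_cols, loadings=Vt.T, scores=U * s,
                  variance_fraction=var / var.sum())


# ---------------------------------------------------------------------------
# latent factor mixed model (ridge / ALS)
# ---------------------------------------------------------------------------

@dataclass
class LfmmFit:
    k: int
    U: np.ndarray  # (n, k) factor scores
    V: np.ndarray  # (m, k) loadings
    b: np.ndarray  # (m,) per-locus effects of x
    lambda_gc: float
    converged: bool
    n_iter: int


def lfmm_scan(geno: GenotypeMatrix, x: np.ndarray, k_factors: int = 3,
              max_iter: int = 100, tol: float = 1e-6, ridge: float = 1e-4,
              name: str = "env") -> tuple[LfmmFit, pd.DataFrame]:
    """Latent factor mixed model scan of all loci against one covariate.

    The latent factors are fit by alternating ridge least squares on the
    genotype matrix itself (initialized from its top-k singular vectors);
    per-locus effects then come from the partial regression of Y on x given
    U, with genomic-control calibration (z^2 * 0.456 / median(z^2)) and
    p-values from chi2(1).

    Fitting the factors jointly with free per-locus effects of x looks
    attractive but is ill-posed here: the joint optimum splits any
    structure-confounded signal back into the per-locus effects (the
    factors end up orthogonal to x), which provably inflates null z-scores.
    Decoupling factor estimation from the effect estimate is what keeps the
    null calibrated, at the usual cost of absorbing genuinely environmental
    variance that parallels structure.
    """
    n = geno.n_samples
    if k_factors >= n - 2:
        raise ValueError("k_factors must be < samples - 2")
    x = np.asarray(x, dtype=float)
    xc = (x - x.mean())
    sx = xc.std()
    if sx == 0:
        raise ValueError("constant covariate")
    xc = xc / sx
    Y = _imputed_dosage(geno)
    Y = Y - Y.mean(axis=0)

    xtx = float(xc @ xc)
    if k_factors == 0:
        U = np.zeros((n, 0))
        V = np.zeros((Y.shape[1], 0))
        b = (xc @ Y) / xtx
        converged, it = True, 0
    else:
        Uf, sf, _ = np.linalg.svd(Y, full_matrices=False)
        U = Uf[:, :k_factors] * sf[:k_factors]
        V = np.zeros((Y.shape[1], k_factors))
        prev = np.inf
        converged = False
        for it in range(1, max_iter + 1):
            V = np.linalg.solve(U.T @ U + ridge * np.eye(k_factors), U.T @ Y).T
            U = np.linalg.solve(V.T @ V + ridge * np.eye(k_factors), V.T @ Y.T).T
            obj = float(((Y - U @ V.T) ** 2).sum()
                        + ridge * ((U**2).sum() + (V**2).sum()))
            if prev < np.inf and abs(prev - obj) <= tol * max(prev, 1.0):
                converged = True
                break
            prev = obj
        if not converged:
            warnings.warn(f"LFMM did not converge in {max_iter} iterations")
        b = (xc @ (Y - U @ V.T)) / xtx

    # final per-locus z: regression of Y on x CONDITIONING on the latent
    # factors (partial regression), so any structure-aligned component of x
    # is absorbed by U rather than credited to the environmental effect
    if k_factors:
        Q, _ = np.linalg.qr(U)
        x_perp = xc - Q @ (Q.T @ xc)
        Y_perp = Y - Q @ (Q.T @ Y)
    else:
        x_perp, Y_perp = xc, Y
    xpx = float(x_perp @ x_perp)
    if xpx < 1e-12 * xtx:
        raise ValueError("covariate is collinear with the latent factors")
    b_final = (x_perp @ Y_perp) / xpx
    resid = Y_perp - np.outer(x_perp, b_final)
    dof = max(n - 2 - k_factors, 1)
    s2 = (resid**2).sum(axis=0) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s2 / xpx)
        z = b_final / se
    z = np.where(np.isfinite(z), z, 0.0)
    z2 = z**2
    med = np.median(z2[z2 > 0]) if (z2 > 0).any() else 1.0
    lam = med / stats.chi2.ppf(0.5, 1)  # 0.456...
    z2_cal = z2 / lam
    p = stats.chi2.sf(z2_cal, 1)

    fit = LfmmFit(k=k_factors, U=U, V=V, b=b_final, lambda_gc=float(lam),
                  converged=converged, n_iter=it if k_factors else 0)
    out = geno.variants[["chrom", "pos"]].copy()
    out["variant"] = out["chrom"].astype(str) + ":" + out["pos"].astype(str)
    out["beta"] = b_final
    out["se"] = se
    out["stat"] = np.sign(z) * np.sqrt(z2_cal)
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["phenotype"] = name
    return fit, out


# ---------------------------------------------------------------------------
# thresholds and hotspots
# ---------------------------------------------------------------------------

def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """Family-wise threshold alpha/n and its -log10."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    thr = alpha / n_tests
    return thr, float(-np.log10(thr))


def hotspot_loci(results_by_ev: dict, cluster_bp: int = 10_000,
                 min_evs: int = 5) -> pd.DataFrame:
    """Cluster already-thresholded association SNPs into multi-EV hotspots.

    Significant SNPs within ``cluster_bp`` of each other (same chromosome)
    merge into one locus; a locus is a hotspot iff it is associated with
    strictly more than ``min_evs`` distinct EVs.
    """
    rows = []
    for ev, df in results_by_ev.items():
        for r in df.itertuples():
            rows.append((r.chrom, int(r.pos), ev))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start_pos", "end_pos", "n_evs", "evs"])
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ev"]).sort_values(
        ["chrom", "pos"]).reset_index(drop=True)
    loci = []
    for chrom, sub in snps.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > cluster_bp)
        bounds = np.concatenate([[0], breaks + 1, [pos.size]])
        for i in range(bounds.size - 1):
            chunk = sub.iloc[bounds[i]:bounds[i + 1]]
            evs = sorted(set(chunk["ev"]))
            loci.append((chrom, int(chunk["pos"].min()), int(chunk["pos"].max()),
                         len(evs), ",".join(evs)))
    out = pd.DataFrame(loci, columns=["chrom", "start_pos", "end_pos", "n_evs", "evs"])
    return out[out["n_evs"] > min_evs].reset_index(drop=True)
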