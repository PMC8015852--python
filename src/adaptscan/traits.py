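"""Adaptive-trait analytics.

AMMI genotype-by-year decomposition of multiyear bloom dates, per-accession
advance-in-bloom-date regression, logistic LT50 fitting from relative
electrolyte conductance, the 0-7.2 degC chilling-hour model, and multiyear
association-stability classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit


# ---------------------------------------------------------------------------
# AMMI
# ---------------------------------------------------------------------------

@dataclass
class AmmiDecomposition:
    """Additive main effects + multiplicative interaction decomposition.

    Cell means Y[i, j] (accession x year) decompose as
    mu + g_i + e_j + sum_k lambda_k u_ik v_jk; main effects sum to zero,
    u/v columns are orthonormal, and sum(lambda_k^2) equals the interaction
    sum of squares.
    """

    accessions: list
    years: list
    grand_mean: float
    genotype_effects: np.ndarray
    year_effects: np.ndarray
    singular_values: np.ndarray
    u: np.ndarray  # (g, K) accession interaction scores
    v: np.ndarray  # (e, K) year interaction scores
    anova: pd.DataFrame
    imputed_cells: int = 0
    covariate_r2: float | None = None

    def reconstruct(self) -> np.ndarray:
        inter = (self.u * self.singular_values) @ self.v.T
        return (self.grand_mean + self.genotype_effects[:, None]
                + self.year_effects[None, :] + inter)


def _cell_means(panel: pd.DataFrame) -> pd.DataFrame:
    if "replicate" in panel.columns:
        panel = panel.groupby(["sample", "year"], as_index=False)["bloom_doy"].mean()
    return panel.pivot_table(index="sample", columns="year", values="bloom_doy")


def ammi_decompose(panel: pd.DataFrame, covariate: pd.Series | np.ndarray | None = None,
                   covariate_on: str = "year_effects") -> AmmiDecomposition:
    """Two-way ANOVA + SVD of the doubly-centered interaction matrix.

    ``panel`` needs columns sample, year, bloom_doy (replicates averaged to
    cell means first).  Missing cells are imputed by row+column means and
    flagged.  IPCA terms carry Gollob degrees of freedom
    (g - 1) + (e - 1) - 2k + 1 and are F-tested against the pooled residual
    of the remaining interaction terms.  ``covariate`` (one value per year,
    e.g. a spring-temperature anomaly series) yields the squared correlation
    with the year main effects (or with IPCA-1 year scores when
    ``covariate_on='ipca1'``).
    """
    cells = _cell_means(panel)
    g, e = cells.shape
    if g < 3 or e < 3:
        raise ValueError("AMMI needs >= 3 accessions and >= 3 years")
    Y = cells.to_numpy(dtype=float)
    n_missing = int(np.isnan(Y).sum())
    if n_missing:
        warnings.warn(f"imputing {n_missing} missing accession x year cells")
        row = np.nanmean(Y, axis=1, keepdims=True)
        col = np.nanmean(Y, axis=0, keepdims=True)
        grand = np.nanmean(Y)
        fill = row + col - grand
        Y = np.where(np.isnan(Y), fill, Y)

    mu = Y.mean()
    gi = Y.mean(axis=1) - mu
    ej = Y.mean(axis=0) - mu
    Z = Y - mu - gi[:, None] - ej[None, :]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    K = min(g, e) - 1
    U, s, Vt = U[:, :K], s[:K], Vt[:K]

    ss_g = e * float(np.sum(gi**2))
    ss_e = g * float(np.sum(ej**2))
    ss_int = float(np.sum(Z**2))
    ss_k = s**2

    rows = [
        ("G", ss_g, g - 1),
        ("E", ss_e, e - 1),
    ]
    for k in range(K):
        df_k = (g - 1) + (e - 1) - 2 * (k + 1) + 1  # Gollob
        rows.append((f"IPCA{k + 1}", float(ss_k[k]), max(df_k, 1)))
    anova = pd.DataFrame(rows, columns=["source", "ss", "df"])
    # F for each IPCA against the pooled residual of later interaction terms
    fvals, pvals = [], []
    for idx, r in anova.iterrows():
        if not r["source"].startswith("IPCA"):
            fvals.append(np.nan)
            pvals.append(np.nan)
            continue
        k = int(r["source"][4:])
        ss_rest = float(ss_k[k:].sum())
        df_rest = int(anova["df"].iloc[2 + k:].sum())
        if ss_rest <= 0 or df_rest <= 0:
            fvals.append(np.nan)
            pvals.append(np.nan)
            continue
        F = (r["ss"] / r["df"]) / (ss_rest / df_rest)
        fvals.append(float(F))
        pvals.append(float(stats.f.sf(F, r["df"], df_rest)))
    anova["F"] = fvals
    anova["p"] = pvals
    anova.loc[len(anova)] = ("interaction_total", ss_int,
                             (g - 1) * (e - 1), np.nan, np.nan)

    cov_r2 = None
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if cov.size != e:
            raise ValueError("covariate must have one value per year")
        target = ej if covariate_on == "year_effects" else Vt[0] * s[0]
        if np.std(cov) > 0 and np.std(target) > 0:
            cov_r2 = float(np.corrcoef(cov, target)[0, 1] ** 2)

    return AmmiDecomposition(
        accessions=list(cells.index), years=[int(y) for y in cells.columns],
        grand_mean=float(mu), genotype_effects=gi, year_effects=ej,
        singular_values=s, u=U, v=Vt.T, anova=anova,
        imputed_cells=n_missing, covariate_r2=cov_r2,
    )


# ---------------------------------------------------------------------------
# advance in bloom date
# ---------------------------------------------------------------------------

@dataclass
class AbdEstimate:
    accession: str
    slope: float  # days per year (negative = earlier over time)
    slope_se: float
    abd_days: float  # -slope * span; positive = earlier bloom at the end


def abd_slopes(panel: pd.DataFrame, min_years: int = 5
               ) -> tuple[list[AbdEstimate], float]:
    """Per-accession OLS of bloom day-of-year on calendar year.

    ABD = -slope x (max_year - min_year); positive ABD means bloom advanced
    (got earlier).  Accessions observed in fewer than ``min_years`` distinct
    years are skipped with a warning.  Returns the estimates and the
    population mean ABD.
    """
    if "replicate" in panel.columns:
        panel = panel.groupby(["sample", "year"], as_index=False)["bloom_doy"].mean()
    span = float(panel["year"].max() - panel["year"].min())
    out: list[AbdEstimate] = []
    skipped = []
    for acc, sub in panel.groupby("sample", sort=False):
        if sub["year"].nunique() < min_years:
            skipped.append(acc)
            continue
        res = stats.linregress(sub["year"], sub["bloom_doy"])
        out.append(AbdEstimate(accession=acc, slope=float(res.slope),
                               slope_se=float(res.stderr),
                               abd_days=float(-res.slope * span)))
    if skipped:
        warnings.warn(f"skipped {len(skipped)} accessions with < {min_years} years")
    if not out:
        raise ValueError("no accession satisfies the year minimum")
    mean_abd = float(np.mean([a.abd_days for a in out]))
    return out, mean_abd


# ---------------------------------------------------------------------------
# LT50 logistic
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    lt50: float  # degC at 50% relative conductance
    k: float  # slope; > 0 means conductance rises as temperature falls
    residual_ss: float
    converged: bool


def _rc_model(T, lt50, k):
    return 1.0 / (1.0 + np.exp(k * (T - lt50)))


def fit_lt50(curve: pd.DataFrame, k_starts=(0.1, 0.3, 1.0)) -> LogisticFit:
    """Fit RC(T) = 1/(1 + exp(k (T - LT50))) by nonlinear least squares.

    ``curve`` has columns temperature_C and relative_conductance in [0, 1].
    Multi-start over ``k_starts`` with LT50 initialized at the measured
    temperature whose conductance is nearest 0.5; LT50 is bounded to the
    tested range +- 10 degC to prevent divergence on flat curves.
    """
    T = curve["temperature_C"].to_numpy(dtype=float)
    rc = curve["relative_conductance"].to_numpy(dtype=float)
    if np.unique(T).size < 4:
        raise ValueError("need >= 4 distinct temperatures")
    if rc.min() < -1e-9 or rc.max() > 1 + 1e-9:
        raise ValueError("relative conductance must lie in [0, 1]")
    if np.allclose(rc, rc[0]):
        raise ValueError("no transition observed")
    lt50_0 = float(T[np.argmin(np.abs(rc - 0.5))])
    lo, hi = T.min() - 10.0, T.max() + 10.0
    best = None
    for k0 in k_starts:
        try:
            popt, _ = curve_fit(_rc_model, T, rc, p0=[lt50_0, k0],
                                bounds=([lo, 1e-6], [hi, 10.0]), maxfev=10_000)
        except RuntimeError:
            continue
        rss = float(np.sum((rc - _rc_model(T, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return LogisticFit(lt50=np.nan, k=np.nan, residual_ss=np.nan, converged=False)
    (lt50, k), rss = best
    return LogisticFit(lt50=float(lt50), k=float(k), residual_ss=rss, converged=True)


# ---------------------------------------------------------------------------
# chilling hours
# ---------------------------------------------------------------------------

def chilling_hours(hourly: pd.DataFrame | np.ndarray, lo: float = 0.0,
                   hi: float = 7.2) -> int:
    """Count hours with temperature in (lo, hi]: 0 degC excluded, 7.2 included."""
    if isinstance(hourly, pd.DataFrame):
        temps = hourly["temperature_C"].to_numpy(dtype=float)
    else:
        temps = np.asarray(hourly, dtype=float)
    if temps.size == 0:
        raise ValueError("empty temperature series")
    return int(((temps > lo) & (temps <= hi)).sum())


# ---------------------------------------------------------------------------
# multiyear association stability
# ---------------------------------------------------------------------------

def classify_yearly_associations(per_year: dict, threshold: float | None = None
                                 ) -> dict:
    """Partition SNPs by the number of years they reach significance.

    ``per_year`` maps year -> either an iterable of significant SNP ids, or
    an association DataFrame (then ``threshold`` is applied to its ``p``
    column).  Classes: temporary (exactly 1 year), recurrent (2-5 years),
    stable (strictly more than 5 years); the three sets partition the union
    of significant SNPs.
    """
    if len(per_year) < 2:
        raise ValueError("need >= 2 years of results")
    years_sig: dict[str, int] = {}
    for year, res in per_year.items():
        if isinstance(res, pd.DataFrame):
            if threshold is None:
                raise ValueError("threshold required with DataFrame input")
            ids = res.loc[res["p"] <= threshold, "variant"]
        else:
            ids = res
        for snp in set(ids):
            years_sig[snp] = years_sig.get(snp, 0) + 1
    temporary = {s for s, y in years_sig.items() if y == 1}
    stable = {s for s, y in years_sig.items() if y > 5}
    recurrent = {s for s, y in years_sig.items() if 2 <= y <= 5}
    return {"temporary": temporary, "recurrent": recurrent, "stable": stable}
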