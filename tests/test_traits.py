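import numpy as np
import pandas as pd
import pytest

from adaptscan.traits import (abd_slopes, ammi_decompose, chilling_hours,
                              classify_yearly_associations, fit_lt50)


def panel_from_matrix(Y, accessions=None, years=None):
    g, e = Y.shape
    accessions = accessions or [f"acc{i}" for i in range(g)]
    years = years or list(range(2000, 2000 + e))
    rows = [(accessions[i], years[j], Y[i, j]) for i in range(g) for j in range(e)]
    return pd.DataFrame(rows, columns=["sample", "year", "bloom_doy"])


# ---------------------------------------------------------------------------
# AMMI
# ---------------------------------------------------------------------------

def test_purely_additive_data_has_zero_interaction():
    g_eff = np.array([0.0, 2.0, -2.0, 1.0, -1.0])
    e_eff = np.array([-1.0, 0.0, 1.0, 3.0])
    Y = 100.0 + g_eff[:, None] + e_eff[None, :]
    dec = ammi_decompose(panel_from_matrix(Y), covariate=np.arange(4.0))
    assert np.allclose(dec.singular_values, 0.0, atol=1e-10)
    np.testing.assert_allclose(dec.genotype_effects, g_eff, atol=1e-10)
    np.testing.assert_allclose(dec.year_effects, e_eff - e_eff.mean(), atol=1e-10)
    assert dec.covariate_r2 is not None  # defined on year effects alone


def test_full_reconstruction_and_ss_additivity():
    rng = np.random.default_rng(0)
    Y = 90 + rng.normal(size=(8, 6)) * 4
    dec = ammi_decompose(panel_from_matrix(Y))
    np.testing.assert_allclose(dec.reconstruct(), Y, atol=1e-8)
    total_ss = ((Y - Y.mean()) ** 2).sum()
    parts = (dec.anova.set_index("source")["ss"]["G"]
             + dec.anova.set_index("source")["ss"]["E"]
             + (dec.singular_values ** 2).sum())
    assert parts == pytest.approx(total_ss, abs=1e-8)
    # interaction SS equals the sum of squared singular values
    sv_ss = (dec.singular_values ** 2).sum()
    assert dec.anova.set_index("source")["ss"]["interaction_total"] == \
        pytest.approx(sv_ss, abs=1e-8)
    # main effects centered; interaction scores orthonormal
    assert dec.genotype_effects.sum() == pytest.approx(0.0, abs=1e-10)
    assert dec.year_effects.sum() == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(dec.u.T @ dec.u, np.eye(dec.u.shape[1]), atol=1e-8)


def test_gollob_degrees_of_freedom():
    Y = np.random.default_rng(1).normal(size=(7, 5))
    dec = ammi_decompose(panel_from_matrix(Y))
    an = dec.anova.set_index("source")
    g, e = 7, 5
    for k in range(1, min(g, e) - 1 + 1):
        assert an.loc[f"IPCA{k}", "df"] == max((g - 1) + (e - 1) - 2 * k + 1, 1)


def test_warming_covariate_explains_year_effects(study_bundle):
    """Generated panel: year effects track the linear warming series."""
    pheno = study_bundle["pheno"]
    years = np.sort(pheno["year"].unique())
    dT = (years - years[0]) / (years[-1] - years[0])  # scenario warming ramp
    dec = ammi_decompose(pheno, covariate=dT)
    assert dec.covariate_r2 > 0.9


def test_missing_cells_imputed_with_flag():
    Y = 90 + np.random.default_rng(2).normal(size=(5, 4))
    panel = panel_from_matrix(Y).drop(index=[3, 11])
    with pytest.warns(UserWarning, match="imputing"):
        dec = ammi_decompose(panel)
    assert dec.imputed_cells == 2


def test_too_small_panel_errors():
    Y = np.zeros((2, 5))
    with pytest.raises(ValueError, match=">= 3"):
        ammi_decompose(panel_from_matrix(Y))


# ---------------------------------------------------------------------------
# ABD
# ---------------------------------------------------------------------------

def test_constant_bloom_dates_give_zero_abd():
    Y = np.full((3, 6), 95.0)
    ests, mean_abd = abd_slopes(panel_from_matrix(Y))
    assert all(e.slope == pytest.approx(0.0) for e in ests)
    assert mean_abd == pytest.approx(0.0)


def test_linear_advance_matches_construction():
    """BD = 100 - 0.357 (year - 1983) over 1983-2011: ABD = 0.357 * 28."""
    years = list(range(1983, 2012))
    Y = np.array([[100 - 0.357 * (y - 1983) for y in years]] * 3)
    ests, mean_abd = abd_slopes(panel_from_matrix(Y, years=years))
    assert mean_abd == pytest.approx(0.357 * 28, abs=1e-10)
    assert ests[0].abd_days == pytest.approx(-ests[0].slope * 28)


def test_noisy_panel_recovers_true_advance():
    rng = np.random.default_rng(3)
    years = np.arange(1983, 2012)
    abds = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        Y = 100 - 0.357 * (years - 1983) + r.normal(scale=3.0, size=(10, 29))
        _, mean_abd = abd_slopes(panel_from_matrix(Y, years=list(years)))
        abds.append(mean_abd)
    assert abs(np.mean(abds) - 10.0) < 1.5


def test_abd_shift_equivariance():
    rng = np.random.default_rng(4)
    Y = 90 + rng.normal(size=(4, 8))
    e1, _ = abd_slopes(panel_from_matrix(Y))
    e2, _ = abd_slopes(panel_from_matrix(Y + 17.0))
    for a, b in zip(e1, e2):
        assert a.slope == pytest.approx(b.slope, abs=1e-10)


def test_short_series_skipped_with_warning():
    Y = np.zeros((2, 8))
    panel = panel_from_matrix(Y)
    panel = panel[(panel["sample"] == "acc0") | (panel["year"] < 2003)]
    with pytest.warns(UserWarning, match="skipped"):
        ests, _ = abd_slopes(panel, min_years=5)
    assert [e.accession for e in ests] == ["acc0"]


# ---------------------------------------------------------------------------
# LT50
# ---------------------------------------------------------------------------

def conductance_frame(lt50, k, temps=(-10, -15, -20, -25, -30, -35), noise=0.0,
                      seed=0):
    temps = np.array(temps, dtype=float)
    rc = 1.0 / (1.0 + np.exp(k * (temps - lt50)))
    if noise:
        rc = np.clip(rc + np.random.default_rng(seed).normal(0, noise, temps.size),
                     0, 1)
    return pd.DataFrame({"temperature_C": temps, "relative_conductance": rc})


def test_noise_free_recovery_exact():
    fit = fit_lt50(conductance_frame(-22.5, 0.4))
    assert fit.lt50 == pytest.approx(-22.5, abs=1e-6)
    assert fit.k == pytest.approx(0.4, abs=1e-6)
    assert fit.converged


def test_half_conductance_at_measured_temperature():
    """Symmetric design with RC exactly 0.5 at -20: LT50 = -20."""
    temps = np.array([-10.0, -15.0, -20.0, -25.0, -30.0])
    rc = 1.0 / (1.0 + np.exp(0.5 * (temps - (-20.0))))
    assert rc[2] == pytest.approx(0.5)
    fit = fit_lt50(pd.DataFrame({"temperature_C": temps,
                                 "relative_conductance": rc}))
    assert fit.lt50 == pytest.approx(-20.0, abs=1e-6)


def test_fitted_curve_monotone_decreasing_in_temperature():
    fit = fit_lt50(conductance_frame(-18, 0.3, noise=0.03, seed=1))
    T = np.linspace(-40, 0, 50)
    rc = 1.0 / (1.0 + np.exp(fit.k * (T - fit.lt50)))
    assert np.all(np.diff(rc) < 0)


def test_noisy_recovery_within_half_degree():
    errs = []
    for seed in range(20):
        fit = fit_lt50(conductance_frame(-22.5, 0.4, noise=0.05, seed=seed))
        errs.append(abs(fit.lt50 - (-22.5)))
    assert np.mean(errs) < 0.5


@pytest.mark.parametrize("frame,msg", [
    (pd.DataFrame({"temperature_C": [-10, -20, -20, -10],
                   "relative_conductance": [0.1, 0.9, 0.9, 0.1]}), "distinct"),
    (pd.DataFrame({"temperature_C": [-10, -15, -20, -25],
                   "relative_conductance": [0.4, 0.4, 0.4, 0.4]}), "transition"),
])
def test_lt50_error_cases(frame, msg):
    with pytest.raises(ValueError, match=msg):
        fit_lt50(frame)


# ---------------------------------------------------------------------------
# chilling hours
# ---------------------------------------------------------------------------

def test_chilling_hours_count_and_boundaries():
    temps = np.concatenate([np.full(300, 5.0), np.full(100, -4.0),
                            np.full(50, 12.0)])
    assert chilling_hours(temps) == 300
    # 0 excluded, 7.2 included
    assert chilling_hours(np.array([0.0])) == 0
    assert chilling_hours(np.array([7.2])) == 1
    assert chilling_hours(np.array([7.2000001])) == 0


def test_constructed_900_hour_series():
    """A series built to contain 900 qualifying hours counts exactly 900."""
    rng = np.random.default_rng(5)
    qualifying = rng.uniform(0.01, 7.2, 900)
    cold = rng.uniform(-15, -0.01, 500)
    warm = rng.uniform(7.3, 20, 600)
    series = rng.permutation(np.concatenate([qualifying, cold, warm]))
    assert chilling_hours(pd.DataFrame({"temperature_C": series})) == 900


def test_empty_series_errors():
    with pytest.raises(ValueError, match="empty"):
        chilling_hours(np.array([]))


# ---------------------------------------------------------------------------
# multiyear stability classes
# ---------------------------------------------------------------------------

def test_stability_classes_hand_enumeration():
    """Year-counts {1,1,1,2,3,5,6,6,8,1} partition into (4, 3, 3)."""
    year_counts = [1, 1, 1, 2, 3, 5, 6, 6, 8, 1]
    per_year = {y: set() for y in range(1, 9)}
    for i, c in enumerate(year_counts):
        for y in range(1, c + 1):
            per_year[y].add(f"snp{i}")
    out = classify_yearly_associations(per_year)
    assert len(out["temporary"]) == 4
    assert len(out["recurrent"]) == 3
    assert len(out["stable"]) == 3


def test_boundary_years():
    per_year = {y: {"one"} if y == 1 else set() for y in range(1, 9)}
    for y in range(1, 7):
        per_year[y].add("six")
    out = classify_yearly_associations(per_year)
    assert "one" in out["temporary"]
    assert "six" in out["stable"]  # 6 years: strictly more than 5


def test_classes_partition_significant_snps():
    rng = np.random.default_rng(6)
    per_year = {y: {f"s{i}" for i in rng.choice(30, size=10, replace=False)}
                for y in range(2000, 2010)}
    out = classify_yearly_associations(per_year)
    union = out["temporary"] | out["recurrent"] | out["stable"]
    assert union == set.union(*per_year.values())
    assert not (out["temporary"] & out["recurrent"])
    assert not (out["temporary"] & out["stable"])
    assert not (out["recurrent"] & out["stable"])


def test_dataframe_input_with_threshold():
    res = {
        2000: pd.DataFrame({"variant": ["a", "b"], "p": [1e-9, 0.5]}),
        2001: pd.DataFrame({"variant": ["a", "b"], "p": [1e-9, 1e-9]}),
    }
    out = classify_yearly_associations(res, threshold=1e-8)
    assert out["recurrent"] == {"a"}
    assert out["temporary"] == {"b"}
    with pytest.raises(ValueError, match="threshold"):
        classify_yearly_associations(res)
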