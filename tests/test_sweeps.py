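import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

import adaptscan as ad
from adaptscan.sweeps import (SFS, ClrModel, IhsResult, background_sfs, clr_scan,
                              consensus_regions, ihs_scan, metric_outliers,
                              mu_scan, mu_to_track, _ehh_integral)
from adaptscan.winstats import WindowSpec, WindowStatTrack

from conftest import hap_geno, make_geno


def track_of(values, metric, size=10, chrom="c"):
    values = np.asarray(values, dtype=float)
    starts = np.arange(values.size) * size
    return WindowStatTrack(chrom, starts, starts + size,
                           np.ones(values.size, dtype=int), values, metric)


# ---------------------------------------------------------------------------
# background SFS
# ---------------------------------------------------------------------------

def test_sfs_counting_example():
    """3 sites with derived counts {1, 1, 2} at n = 4 -> xi = (2, 1, 0)."""
    g = make_geno([[1, 0, 1], [0, 1, 1]], pos=[10, 20, 30])
    sfs = background_sfs(g)
    assert sfs.n == 4
    assert list(sfs.counts) == [2, 1, 0]


def test_folded_sfs_collapses_mirror_classes():
    g = make_geno([[1, 0, 1], [0, 1, 1]], pos=[10, 20, 30])
    folded = background_sfs(g, folded=True)
    assert folded.folded
    assert list(folded.counts) == [2, 1]  # eta_2 = xi_2 (self-conjugate class)


def test_sfs_errors_without_polymorphism():
    with pytest.raises(ValueError, match="polymorphic"):
        background_sfs(make_geno([[0, 2], [0, 2]], pos=[10, 20]))


def test_neutral_sfs_follows_one_over_i(neutral_sim):
    """Neutral spectrum shape consistent with xi_i proportional to 1/i.

    Sites on one chromosome share genealogies, so exact per-class counts are
    heavily overdispersed relative to multinomial sampling; the unit-level
    check compares broad frequency classes of a subsampled panel within a
    linkage-generous tolerance (the replicate-calibrated goodness-of-fit
    lives in the acceptance suite).
    """
    _, geno, _ = neutral_sim
    rng = np.random.default_rng(42)
    panel = list(rng.choice(geno.samples, size=10, replace=False))
    sfs = background_sfs(geno, samples=panel)
    w = 1.0 / np.arange(1, sfs.n)
    expected = w / w.sum()
    obs = sfs.counts / sfs.counts.sum()
    # broad classes: singletons, 2-4, 5-9, rest
    bins = [(0, 1), (1, 4), (4, 9), (9, sfs.n - 1)]
    for lo, hi in bins:
        o, e = obs[lo:hi].sum(), expected[lo:hi].sum()
        assert abs(o - e) / e < 0.35
    # monotone decay over the broad classes
    means = [obs[lo:hi].sum() / (hi - lo) for lo, hi in bins]
    assert all(a > b for a, b in zip(means, means[1:]))


# ---------------------------------------------------------------------------
# CLR
# ---------------------------------------------------------------------------

def test_full_escape_reduces_to_background_probability():
    """p_e = 1: site likelihood equals the background probability (1/3 for
    derived count 2 under xi = (2, 1, 0))."""
    sfs = SFS(n=4, counts=np.array([2.0, 1.0, 0.0]))
    model = ClrModel(sfs)
    ll = model.site_loglik(np.array([1.0]), np.array([2]))
    assert ll[0] == pytest.approx(np.log(1.0 / 3.0), abs=1e-12)
    assert model.poly_prob(np.array([1.0]))[0] == pytest.approx(1.0, abs=1e-12)


def test_sweep_model_spectrum_is_normalized_everywhere():
    sfs = SFS(n=10, counts=1.0 / np.arange(1, 10))
    model = ClrModel(sfs)
    sums = np.exp(model.log_table).sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-10)


def test_weak_sweep_limit_recovers_background():
    """As alpha grows every site escapes and the likelihood gain vanishes."""
    rng = np.random.default_rng(0)
    g = make_geno(rng.integers(0, 3, size=(10, 40)).astype(np.int8),
                  pos=np.sort(rng.choice(np.arange(1, 10_000), 40, replace=False)))
    sfs = background_sfs(g)
    model = ClrModel(sfs)
    c = g.alt_counts()
    pos = g.variants["pos"].to_numpy().astype(float)
    keep = (c > 0) & (c < 2 * g.n_samples)
    k, pos = c[keep], pos[keep]
    bg = model.log_bg[k - 1]
    gains = []
    for alpha in (1e-4, 1e-2, 1e0):
        pe = 1.0 - np.exp(-alpha * np.abs(pos - 5000))
        gains.append((model.site_loglik(pe, k) - bg).sum())
    assert abs(gains[-1]) < 1e-6  # alpha -> infinity: identical to background
    # on non-swept data the sweep model can only lose likelihood, and the
    # loss vanishes monotonically as the modeled footprint shrinks
    assert gains[0] <= gains[1] <= gains[2] + 1e-9
    assert all(g <= 1e-9 for g in gains)


def test_clr_grid_step_must_be_positive(neutral_sim):
    _, geno, _ = neutral_sim
    with pytest.raises(ValueError, match="grid_step"):
        clr_scan(geno, grid_step=0)


def test_sweep_clr_exceeds_neutral_maximum():
    """Paired replicates: the sweep-locus CLR beats the genome-wide maximum
    of a matched neutral simulation in most pairs (s = 0.1 hard sweep)."""
    wins = 0
    L = 1_000_000  # sweep footprint must stay a small fraction of the
    # scanned region or the background spectrum is itself sweep-distorted
    for seed in range(3):
        sweep_sc = ad.datagen.group_scan_scenario(seed=seed, s=0.1)
        neut_sc = ad.SimScenario(
            n_demes=1, deme_sizes=(250,), deme_labels=("TB",),
            n_generations=900, migration_rate=0.0, seq_length=L,
            mut_rate=1e-6, rec_rate=2e-7, seed=100 + seed)
        gs, _ = ad.simulate_population(sweep_sc, retry_cap=200)
        gn, _ = ad.simulate_population(neut_sc)
        rng = np.random.default_rng(seed)
        panel_s = list(rng.choice(gs.samples, size=50, replace=False))
        panel_n = list(rng.choice(gn.samples, size=50, replace=False))
        _, fits_s = clr_scan(gs, panel_s, grid_step=10_000, seq_length=L,
                             alpha_bounds=(2e-6, 2e-4))
        _, fits_n = clr_scan(gn, panel_n, grid_step=10_000, seq_length=L,
                             alpha_bounds=(2e-6, 2e-4))
        near = [f.clr for f in fits_s if abs(f.pos - 500_000) <= 50_000]
        if max(near) > max(f.clr for f in fits_n):
            wins += 1
    assert wins >= 2


# ---------------------------------------------------------------------------
# mu
# ---------------------------------------------------------------------------

def test_mu_var_near_one_on_uniform_neutral_data(neutral_sim):
    sc, geno, _ = neutral_sim
    comps = mu_scan(geno, snps_per_window=20, seq_length=sc.seq_length)
    mean_var = np.mean([c.mu_var for c in comps])
    assert 0.8 < mean_var < 1.2


def test_mu_sfs_rewards_singleton_windows():
    """All-singleton window scores higher on the SFS factor than an
    intermediate-frequency window of the same size."""
    n_hap = 20
    hap = np.zeros((n_hap, 8), dtype=np.int8)
    for j in range(4):  # singletons
        hap[j % n_hap, j] = 1
    hap[: n_hap // 2, 4:] = 1  # intermediates
    g = hap_geno(hap, pos=np.array([10, 20, 30, 40, 1010, 1020, 1030, 1040]))
    comps = mu_scan(g, snps_per_window=4, seq_length=2000)
    by_start = {c.start: c for c in comps}
    assert by_start[10].mu_sfs > by_start[1010].mu_sfs


def test_mu_requires_even_window_and_enough_snps():
    g = make_geno(np.eye(4, dtype=np.int8), pos=[10, 20, 30, 40])
    with pytest.raises(ValueError):
        mu_scan(g, snps_per_window=5)
    assert mu_scan(g, snps_per_window=6, seq_length=100) == []


def test_mu_track_projection(neutral_sim):
    sc, geno, _ = neutral_sim
    comps = mu_scan(geno, snps_per_window=20, seq_length=sc.seq_length)
    track = mu_to_track(comps, sc.seq_length, WindowSpec(), chrom="Pp01")
    finite = np.isfinite(track.values)
    assert finite.any()
    assert np.nanmax(track.values) == pytest.approx(max(c.mu for c in comps))


# ---------------------------------------------------------------------------
# iHS / EHH
# ---------------------------------------------------------------------------

def brute_force_ihh(hap, pos, core, carriers, cutoff):
    """Trapezoid-integrated pairwise haplotype homozygosity, enumerated."""
    idx = np.flatnonzero(carriers)
    n = idx.size
    denom = n * (n - 1) / 2
    total = 0.0
    for direction in (1, -1):
        prev_ehh, prev_x = 1.0, pos[core]
        j = core + direction
        while 0 <= j < len(pos):
            lo, hi = (core, j) if direction == 1 else (j, core)
            same = sum(
                np.array_equal(hap[a, lo:hi + 1], hap[b, lo:hi + 1])
                for a, b in itertools.combinations(idx, 2))
            ehh = same / denom
            total += 0.5 * (prev_ehh + ehh) * abs(pos[j] - prev_x)
            prev_ehh, prev_x = ehh, pos[j]
            if ehh < cutoff:
                break
            j += direction
    return total


def test_ihh_matches_pair_enumeration_oracle():
    rng = np.random.default_rng(7)
    hap = rng.integers(0, 2, size=(8, 7)).astype(np.int8)
    hap[:4, 3] = 1  # core at index 3, derived on first four haplotypes
    hap[4:, 3] = 0
    pos = np.array([100, 300, 450, 500, 620, 800, 1000])
    carriers = hap[:, 3] == 1
    got = _ehh_integral(hap, pos, 3, carriers, cutoff=0.05)
    want = brute_force_ihh(hap, pos, 3, carriers, cutoff=0.05)
    assert got == pytest.approx(want, abs=1e-12)
    got_a = _ehh_integral(hap, pos, 3, ~carriers, cutoff=0.05)
    want_a = brute_force_ihh(hap, pos, 3, ~carriers, cutoff=0.05)
    assert got_a == pytest.approx(want_a, abs=1e-12)


def test_identical_flanks_give_zero_unstandardized_score():
    """Derived and ancestral carriers share identical flanking haplotypes,
    so ln(iHH_A / iHH_D) = 0; EHH at the core itself is 1 by definition."""
    flank = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0], [1, 0, 1]], dtype=np.int8)
    hap = np.concatenate([flank[:, :1], np.array([[1], [1], [0], [0]], dtype=np.int8),
                          flank[:, 1:]], axis=1)
    pos = np.array([50, 100, 150, 200])
    g = hap_geno(hap, pos=pos)
    res = ihs_scan(g, min_bin=1, daf_range=(0.25, 0.75))
    core_res = [r for r in res if r.pos == 100]
    assert core_res and core_res[0].unstandardized == pytest.approx(0.0, abs=1e-12)
    # EHH at distance zero: integrating over an empty interval contributes 0,
    # and both iHH values start from EHH = 1 at the core
    assert core_res[0].ihh_a > 0 and core_res[0].ihh_d > 0


def test_ihs_requires_phased_haplotypes():
    g = make_geno([[1, 0], [1, 2]], pos=[10, 20])
    with pytest.raises(ValueError, match="phased"):
        ihs_scan(g)


def test_small_bins_get_nan_with_warning():
    rng = np.random.default_rng(3)
    hap = rng.integers(0, 2, size=(10, 30)).astype(np.int8)
    g = hap_geno(hap, pos=np.arange(1, 31) * 100)
    with pytest.warns(UserWarning, match="bin"):
        res = ihs_scan(g, min_bin=1000)
    assert all(np.isnan(r.ihs) for r in res)


# ---------------------------------------------------------------------------
# consensus regions
# ---------------------------------------------------------------------------

def test_consensus_worked_example():
    """Metric A outliers w10-w12, metric B {w11, w90}: one region spanning
    w10-w12 supported by both; w90 alone is dropped."""
    rng = np.random.default_rng(0)
    a = rng.uniform(0.0, 1.0, 100)  # distinct background values, outliers on top
    a[[10, 11, 12]] = 10.0
    b = rng.uniform(0.0, 1.0, 100)
    b[[11, 90]] = 10.0
    regions = consensus_regions([track_of(a, "rod"), track_of(b, "fst")],
                                tail_fraction=0.02, min_metrics=2)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end) == (100, 130)
    assert r.supports == ["fst", "rod"]
    assert r.member_windows == [10, 11, 12]


def test_single_metric_yields_no_region():
    rng = np.random.default_rng(1)
    a = rng.uniform(0.0, 1.0, 100)
    a[50] = 10.0
    b = rng.uniform(0.0, 1.0, 100)
    b[80] = 10.0
    regions = consensus_regions([track_of(a, "rod"), track_of(b, "fst")],
                                tail_fraction=0.01, min_metrics=2)
    assert regions == []


def test_three_metrics_one_window():
    tracks = []
    rng = np.random.default_rng(2)
    for m in ("rod", "fst", "tajd"):
        v = rng.uniform(0.0, 1.0, 50)
        v[25] = 5.0
        tracks.append(track_of(v, m))
    regions = consensus_regions(tracks, tail_fraction=0.02, min_metrics=2)
    assert len(regions) == 1
    assert len(regions[0].supports) == 3


def test_differing_grids_error():
    with pytest.raises(ValueError, match="grid"):
        consensus_regions([track_of(np.zeros(10), "rod"),
                           track_of(np.zeros(11), "fst")])


def test_lower_tail_and_tie_inclusion():
    vals = np.concatenate([np.full(95, 1.0), np.full(5, -3.0)])
    marked, thr = metric_outliers(track_of(vals, "tajd"), 0.05, tail="lower")
    assert marked.sum() == 5
    assert set(np.flatnonzero(marked)) == set(range(95, 100))
    # ties at the threshold are all included
    vals2 = np.concatenate([np.zeros(90), np.full(10, 7.0)])
    marked2, thr2 = metric_outliers(track_of(vals2, "rod"), 0.05, tail="upper")
    assert thr2 == 7.0 and marked2.sum() == 10


def test_consensus_regions_subset_of_marked_union(neutral_sim):
    sc, geno, _ = neutral_sim
    rng = np.random.default_rng(0)
    half = list(rng.permutation(geno.samples))
    spec = WindowSpec()
    pi_a = ad.windowed_pi(geno, half[:50], spec, sc.seq_length)
    pi_b = ad.windowed_pi(geno, half[50:], spec, sc.seq_length)
    t_rod = ad.rod(pi_a, pi_b)
    t_d = ad.tajimas_d(geno, half[:50], spec, sc.seq_length)
    regions = consensus_regions([t_rod, t_d], 0.05,
                                tail_side={"tajd": "lower"}, min_metrics=2)
    m1, _ = metric_outliers(t_rod, 0.05, "upper")
    m2, _ = metric_outliers(t_d, 0.05, "lower")
    union_windows = np.flatnonzero(m1 | m2)
    for r in regions:
        assert len(r.supports) >= 2
        assert set(r.member_windows) <= set(union_windows)


def test_nan_windows_never_ranked():
    vals = np.full(100, np.nan)
    vals[:10] = np.arange(10)
    marked, _ = metric_outliers(track_of(vals, "rod"), 0.2, "upper")
    assert not marked[10:].any()
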