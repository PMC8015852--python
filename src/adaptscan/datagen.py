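"""Forward-time Wright-Fisher simulator and phenotype/environment generators.

The simulator produces every input the pipeline consumes, with known ground
truth for recovery tests: a structured diploid population under an island
migration model, infinite-sites mutation on integer base pairs,
single-crossover recombination, and optional hard selective sweeps
conditioned on establishment by rejection sampling.  Default scenario
parameters emulate the study system: a 263-accession panel split into seven
ecotype groups with deme-correlated climate gradients, 51 environmental
variables, 29 years of bloom dates under a warming trend, freezing-test
conductance curves, and hourly winter temperatures.

Forward (rather than coalescent) simulation keeps sweeps, migration and
phasing explicit at small population sizes; mutation and recombination rates
are rescaled upward accordingly, the usual small-N forward-simulation
convention.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, write_vcf

# Ecotype groups of the emulated panel with rough geographic anchors
# (latitude deg N, longitude deg E, altitude m) and default deme sizes.
DEFAULT_DEMES = {
    "YG": dict(size=30, lat=25.0, lon=103.0, alt=2000.0),
    "NW": dict(size=45, lat=43.0, lon=87.0, alt=800.0),
    "NP": dict(size=50, lat=36.0, lon=114.0, alt=60.0),
    "YT": dict(size=60, lat=30.0, lon=112.0, alt=50.0),
    "NE": dict(size=19, lat=45.0, lon=126.0, alt=200.0),
    "TB": dict(size=45, lat=29.0, lon=91.0, alt=3500.0),
    "ST": dict(size=14, lat=23.0, lon=113.0, alt=100.0),
}

# Deme-mean semilethal temperatures (degC) reflecting winter climate.
DEME_LT50 = {"YG": -16.0, "NW": -26.0, "NP": -22.0, "YT": -18.0,
             "NE": -30.0, "TB": -28.0, "ST": -12.0}


@dataclass
class SweepSpec:
    """A hard sweep: beneficial allele in one deme."""

    deme: int
    pos: int  # 1-based bp
    s: float  # selection coefficient per allele copy (genic selection)
    start_gen: int
    fix_freq: float = 1.0  # focal-deme frequency required at the final generation
    stop_at_fixation: bool = False  # end the simulation the generation fix_freq is reached

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")


@dataclass
class EnvSpec:
    """Deme-correlated environmental gradients.

    ``n_shared`` of the ``n_evs`` variables load on one latent climate axis
    (emulating the strong inter-EV correlations of real climate layers); the
    rest get independent deme means.  ``noise_sd`` is the within-deme
    standard deviation on the standardized axis scale.
    """

    n_evs: int = 51
    n_shared: int = 35
    noise_sd: float = 0.3


@dataclass
class PhenoSpec:
    """Polygenic bloom dates with a linear warming trend.

    BD_{i,y} = mu + sum_k beta_k g_{ik} - warming_slope * dT_y + eps, where
    dT_y rises linearly from 0 to ``warming_total`` degC over the year range
    and ``warming_slope`` is days ADVANCED per degC (positive slope + warming
    means earlier bloom).  The constructed default advance is
    warming_slope * warming_total = 10 days over the span.
    """

    n_causal: int = 5
    beta_scale: float = 2.0  # days per alt allele; effects drawn +-U(1,1)*scale
    mu: float = 85.0  # grand-mean bloom day-of-year
    year_start: int = 1983
    year_end: int = 2011
    warming_total: float = 1.0  # degC rise over the span
    warming_slope: float = 10.0  # days advanced per degC
    residual_sd: float = 3.0
    n_replicates: int = 2
    lt50_k: float = 0.4
    lt50_sd: float = 1.5  # accession spread around the deme-mean LT50
    rc_noise_sd: float = 0.02


@dataclass
class SimScenario:
    """Complete description of one synthetic study."""

    n_demes: int = 7
    deme_sizes: tuple = tuple(v["size"] for v in DEFAULT_DEMES.values())
    deme_labels: tuple = tuple(DEFAULT_DEMES)
    n_generations: int = 1000
    migration_rate: float = 0.05
    seq_length: int = 1_000_000
    mut_rate: float = 1e-6
    rec_rate: float = 5e-7
    chrom: str = "Pp01"
    sweep_specs: list = field(default_factory=list)
    env_spec: EnvSpec = field(default_factory=EnvSpec)
    pheno_spec: PhenoSpec = field(default_factory=PhenoSpec)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.migration_rate < 0.5):
            raise ValueError("migration_rate must be in [0, 0.5)")
        if len(self.deme_sizes) != self.n_demes:
            raise ValueError("deme_sizes length must equal n_demes")
        if len(self.deme_labels) != self.n_demes:
            raise ValueError("deme_labels length must equal n_demes")
        if any(n < 10 for n in self.deme_sizes):
            raise ValueError("deme_size must be >= 10")
        self.sweep_specs = [
            s if isinstance(s, SweepSpec) else SweepSpec(*s) for s in self.sweep_specs
        ]
        for sw in self.sweep_specs:
            if not (1 <= sw.pos <= self.seq_length):
                raise ValueError("sweep position outside sequence")
            if not (0 <= sw.deme < self.n_demes):
                raise ValueError("sweep deme index out of range")


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    sample_frame: pd.DataFrame  # sample, deme, lat, lon, altitude
    sweeps: list = field(default_factory=list)  # dicts: deme, pos, s, interval, ...
    causal: pd.DataFrame | None = None  # variant_idx, chrom, pos, beta
    true_abd: pd.DataFrame | None = None  # sample, abd_days, slope
    true_lt50: pd.DataFrame | None = None  # sample, lt50, k
    env_structure: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "sweeps": self.sweeps,
            "causal": None if self.causal is None else self.causal.to_dict("records"),
            "true_abd": None if self.true_abd is None else self.true_abd.to_dict("records"),
            "true_lt50": None if self.true_lt50 is None else self.true_lt50.to_dict("records"),
            "env_structure": self.env_structure,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


class SweepNotEstablishable(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Wright-Fisher core
# ---------------------------------------------------------------------------

def _reproduce(rng, H, pos, deme_of_ind, deme_slices, mig, rec_rate, L, fitness):
    """One generation of migration, selection, recombination and reproduction.

    ``H`` is (2N, S) uint8; haplotypes 2i, 2i+1 belong to individual i.
    Returns the offspring haplotype matrix (same shape).  Migration follows
    the backward island convention: each offspring stays in its deme but
    draws each parent, with probability ``mig``, from a uniformly chosen
    other deme.  Parents within a source deme are drawn with probability
    proportional to fitness.  Each gamete undergoes at most one crossover
    (probability ``rec_rate * L``, breakpoint uniform on the sequence).
    """
    n_ind = len(deme_of_ind)
    n_demes = len(deme_slices)
    parent = np.empty((n_ind, 2), dtype=np.int64)
    for g in (0, 1):  # two independent parents per offspring
        src = deme_of_ind.copy()
        if mig > 0 and n_demes > 1:
            moves = rng.random(n_ind) < mig
            shift = rng.integers(1, n_demes, size=n_ind)
            src[moves] = (src[moves] + shift[moves]) % n_demes
        for d in range(n_demes):
            lo, hi = deme_slices[d]
            members = np.arange(lo, hi)
            w = fitness[lo:hi]
            pick = rng.choice(members, size=int((src == d).sum()), p=w / w.sum())
            parent[src == d, g] = pick
    # gametes
    swap = rng.integers(0, 2, size=(n_ind, 2))
    first = 2 * parent + swap
    second = 2 * parent + 1 - swap
    co = rng.random((n_ind, 2)) < min(rec_rate * L, 1.0)
    xpos = rng.integers(1, L + 1, size=(n_ind, 2))
    child = np.empty((2 * n_ind, H.shape[1]), dtype=np.uint8)
    for g in (0, 1):
        a = H[first[:, g]]
        b = H[second[:, g]]
        take_b = co[:, g][:, None] & (pos[None, :] >= xpos[:, g][:, None])
        child[g::2] = np.where(take_b, b, a)
    return child


def _mutate(rng, H, pos, mu, L):
    """Add Poisson(2N*mu*L) new mutations at unoccupied integer positions."""
    n_hap = H.shape[0]
    k = rng.poisson(n_hap * mu * L)
    if k == 0:
        return H, pos, np.zeros(0, dtype=bool)
    newpos = rng.integers(1, L + 1, size=k)
    fresh = ~np.isin(newpos, pos)
    newpos = np.unique(newpos[fresh])  # drop duplicates within the batch too
    if newpos.size == 0:
        return H, pos, np.zeros(0, dtype=bool)
    cols = np.zeros((n_hap, newpos.size), dtype=np.uint8)
    cols[rng.integers(0, n_hap, size=newpos.size), np.arange(newpos.size)] = 1
    H = np.concatenate([H, cols], axis=1)
    pos = np.concatenate([pos, newpos])
    order = np.argsort(pos, kind="stable")
    return H[:, order], pos[order], None


def simulate_population(scenario: SimScenario, retry_cap: int = 100):
    """Run the forward simulation; returns ``(GenotypeMatrix, GroundTruth)``.

    Sweeps are conditioned on establishment: if a sweep allele is lost, or
    has not reached its ``fix_freq`` in the focal deme by the final
    generation, the trajectory is re-drawn from the injection generation, up
    to ``retry_cap`` attempts.
    """
    rng = np.random.default_rng(scenario.seed)
    sizes = np.asarray(scenario.deme_sizes)
    n_ind = int(sizes.sum())
    L = scenario.seq_length
    deme_of_ind = np.repeat(np.arange(scenario.n_demes), sizes)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    deme_slices = [(int(bounds[d]), int(bounds[d + 1])) for d in range(scenario.n_demes)]
    hap_deme = np.repeat(deme_of_ind, 2)

    H = np.zeros((2 * n_ind, 0), dtype=np.uint8)
    pos = np.zeros(0, dtype=np.int64)
    sweep_state: dict[int, dict] = {}  # sweep index -> {pos, trajectory}
    attempts_count: dict[int, int] = {}  # persists across trajectory restarts
    by_start: dict[int, list[int]] = {}
    for i, sw in enumerate(scenario.sweep_specs):
        by_start.setdefault(sw.start_gen, []).append(i)

    def inject(idx: int):
        nonlocal H, pos
        sw = scenario.sweep_specs[idx]
        p = sw.pos
        while p in pos:
            p += 1  # infinite-sites: bump to the next free integer bp
        lo, hi = deme_slices[sw.deme]
        carrier = rng.integers(2 * lo, 2 * hi)
        col = np.zeros((H.shape[0], 1), dtype=np.uint8)
        col[carrier, 0] = 1
        j = np.searchsorted(pos, p)
        H = np.concatenate([H[:, :j], col, H[:, j:]], axis=1)
        pos = np.insert(pos, j, p)
        attempts_count[idx] = attempts_count.get(idx, 0) + 1
        sweep_state[idx] = dict(pos=p, traj=[])

    gen = 0
    snapshots: dict[int, tuple] = {}  # start_gen -> (H, pos) just before injection
    while gen < scenario.n_generations:
        if gen in by_start:
            if gen not in snapshots:
                snapshots[gen] = (H.copy(), pos.copy())
            for idx in by_start[gen]:
                if idx not in sweep_state:
                    inject(idx)

        # fitness: product over active sweeps of (1 + s * dosage) in the sweep deme
        fitness = np.ones(n_ind)
        for idx, st in sweep_state.items():
            sw = scenario.sweep_specs[idx]
            j = np.searchsorted(pos, st["pos"])
            if j < pos.size and pos[j] == st["pos"]:
                dos = H[0::2, j].astype(np.int64) + H[1::2, j]
                lo, hi = deme_slices[sw.deme]
                fitness[lo:hi] *= 1.0 + sw.s * dos[lo:hi]

        H = _reproduce(rng, H, pos, deme_of_ind, deme_slices,
                       scenario.migration_rate, scenario.rec_rate, L, fitness)
        H, pos, _ = _mutate(rng, H, pos, scenario.mut_rate, L)
        gen += 1

        # prune fixed / lost columns, protecting live sweep loci
        freq = H.sum(axis=0)
        keep = (freq > 0) & (freq < H.shape[0])
        restart_from = None
        for idx, st in list(sweep_state.items()):
            sw = scenario.sweep_specs[idx]
            j = np.searchsorted(pos, st["pos"])
            present = j < pos.size and pos[j] == st["pos"]
            f_global = int(freq[j]) if present else 0
            lo, hi = deme_slices[sw.deme]
            f_focal = (H[2 * lo:2 * hi, j].sum() / (2 * (hi - lo))) if present else 0.0
            st["traj"].append(float(f_focal))
            if f_global == 0:
                restart_from = sw.start_gen if restart_from is None else min(restart_from, sw.start_gen)
            elif present:
                keep[j] = True  # protect even if locally/globally fixed
        if restart_from is None:
            for idx, st in sweep_state.items():
                sw = scenario.sweep_specs[idx]
                if sw.stop_at_fixation and st["traj"] and st["traj"][-1] >= sw.fix_freq - 1e-12:
                    gen = scenario.n_generations  # sample at the moment of fixation
                    break
        failed_end = []
        if restart_from is None and gen == scenario.n_generations:
            for idx, st in sweep_state.items():
                sw = scenario.sweep_specs[idx]
                if st["traj"] and st["traj"][-1] < sw.fix_freq - 1e-12:
                    failed_end.append(idx)
            if failed_end:
                restart_from = min(scenario.sweep_specs[i].start_gen for i in failed_end)

        if restart_from is not None:
            for idx in [i for i, sw in enumerate(scenario.sweep_specs)
                        if sw.start_gen >= restart_from and i in sweep_state]:
                if attempts_count.get(idx, 0) >= retry_cap:
                    raise SweepNotEstablishable(
                        f"sweep not establishable at pos {scenario.sweep_specs[idx].pos} "
                        f"after {retry_cap} attempts"
                    )
                del sweep_state[idx]
            H, pos = snapshots[restart_from]
            H, pos = H.copy(), pos.copy()
            gen = restart_from
            continue

        H, pos = H[:, keep], pos[keep]

    # drop monomorphic columns (globally fixed sweep alleles are substitutions)
    freq = H.sum(axis=0)
    poly = (freq > 0) & (freq < H.shape[0])
    H, pos = H[:, poly], pos[poly]

    labels = scenario.deme_labels
    samples = [f"{labels[deme_of_ind[i]]}_{i:03d}" for i in range(n_ind)]
    nts = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=pos.size)
    alt_i = (ref_i + rng.integers(1, 4, size=pos.size)) % 4
    variants = pd.DataFrame({
        "chrom": scenario.chrom,
        "pos": pos.astype(np.int64),
        "ref": nts[ref_i],
        "alt": nts[alt_i],
    })
    dosage = (H[0::2].astype(np.int8) + H[1::2].astype(np.int8))
    hap = H.astype(np.int8)
    if scenario.missing_rate > 0:
        miss = rng.random(dosage.shape) < scenario.missing_rate
        dosage = np.where(miss, -1, dosage).astype(np.int8)
        hap = hap.copy()
        hap[np.repeat(miss, 2, axis=0)] = -1
    geno = GenotypeMatrix(samples, variants, dosage, hap)

    sf = pd.DataFrame({
        "sample": samples,
        "deme": [labels[d] for d in deme_of_ind],
    })
    geo = {lab: DEFAULT_DEMES.get(lab, dict(lat=30.0, lon=100.0, alt=500.0))
           for lab in labels}
    sf["lat"] = [geo[d]["lat"] + rng.normal(0, 0.5) for d in sf["deme"]]
    sf["lon"] = [geo[d]["lon"] + rng.normal(0, 0.5) for d in sf["deme"]]
    sf["altitude"] = [geo[d]["alt"] * (1 + rng.normal(0, 0.05)) for d in sf["deme"]]

    truth = GroundTruth(sample_frame=sf)
    half = 25_000  # nominal footprint half-width recorded for recovery tests
    for idx, sw in enumerate(scenario.sweep_specs):
        st = sweep_state.get(idx, {})
        truth.sweeps.append(dict(
            deme=int(sw.deme), deme_label=labels[sw.deme], pos=int(st.get("pos", sw.pos)),
            s=float(sw.s), start_gen=int(sw.start_gen),
            final_focal_freq=float(st["traj"][-1]) if st.get("traj") else 0.0,
            interval=[max(1, int(st.get("pos", sw.pos)) - half),
                      min(L, int(st.get("pos", sw.pos)) + half)],
            attempts=int(attempts_count.get(idx, 0)),
            trajectory=[float(f) for f in st.get("traj", [])],
        ))
    return geno, truth


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def simulate_environment(scenario: SimScenario, sample_frame: pd.DataFrame,
                         seed: int | None = None) -> pd.DataFrame:
    """Per-sample EV table: deme mean + Gaussian noise.

    A configurable subset of EVs (``env_spec.n_shared``) shares one latent
    per-deme climate axis, which makes them strongly collinear, emulating
    the correlation structure of real temperature/precipitation layers; the
    remainder get independent deme means.
    """
    spec = scenario.env_spec
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    labels = list(scenario.deme_labels)
    unknown = set(sample_frame["deme"]) - set(labels)
    if unknown:
        raise ValueError(f"samples with unknown deme labels: {sorted(unknown)}")

    axis = rng.normal(0.0, 1.0, size=len(labels))  # latent climate score per deme
    axis = (axis - axis.mean()) / (axis.std() or 1.0)
    deme_idx = np.array([labels.index(d) for d in sample_frame["deme"]])
    n = len(sample_frame)
    cols = {}
    shared_loadings = {}
    for k in range(spec.n_evs):
        name = f"EV{k + 1:02d}"
        if k < spec.n_shared:
            a = rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 1.2)
            means = a * axis
            shared_loadings[name] = float(a)
        else:
            means = rng.normal(0.0, 1.0, size=len(labels))
        vals = means[deme_idx] + rng.normal(0.0, spec.noise_sd, size=n)
        cols[name] = vals
    env = pd.DataFrame({"sample": sample_frame["sample"].to_numpy(), **cols})
    return env


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(geno: GenotypeMatrix, truth: GroundTruth,
                        spec: PhenoSpec | None = None, seed: int | None = None,
                        scenario: SimScenario | None = None):
    """Bloom dates, conductance curves and hourly winter temperatures.

    Returns ``(pheno_panel, conductance_panel, hourly_temps)`` and records
    causal effects, true ABD and true LT50 in ``truth``.
    """
    if spec is None:
        spec = scenario.pheno_spec if scenario is not None else PhenoSpec()
    rng = np.random.default_rng((scenario.seed + 2 if scenario is not None else 0)
                                if seed is None else seed)
    years = np.arange(spec.year_start, spec.year_end + 1)
    if years.size == 0:
        raise ValueError("year range is empty")
    n = geno.n_samples

    # causal loci: common variants, effects in days per alt allele
    if geno.n_variants and spec.n_causal:
        common = np.flatnonzero(geno.maf() >= 0.2)
        pool = common if common.size >= spec.n_causal else np.arange(geno.n_variants)
        k = min(spec.n_causal, pool.size)
        causal_idx = np.sort(rng.choice(pool, size=k, replace=False))
        betas = rng.choice([-1.0, 1.0], size=k) * rng.uniform(1.0, 2.0, size=k) \
            * spec.beta_scale / 2.0
    else:
        causal_idx = np.zeros(0, dtype=int)
        betas = np.zeros(0)
    dos = np.where(geno.dosage[:, causal_idx] >= 0,
                   geno.dosage[:, causal_idx], 0).astype(float)
    genetic = dos @ betas if causal_idx.size else np.zeros(n)

    span = max(years[-1] - years[0], 1)
    dT = spec.warming_total * (years - years[0]) / span  # degC anomaly per year
    rows = []
    for yi, y in enumerate(years):
        base = spec.mu + genetic - spec.warming_slope * dT[yi]
        for rep in range(max(spec.n_replicates, 1)):
            eps = rng.normal(0.0, spec.residual_sd, size=n) if spec.residual_sd > 0 else 0.0
            rows.append(pd.DataFrame({
                "sample": geno.samples, "year": y, "replicate": rep + 1,
                "bloom_doy": base + eps,
            }))
    pheno = pd.concat(rows, ignore_index=True)

    truth.causal = pd.DataFrame({
        "variant_idx": causal_idx,
        "chrom": geno.variants["chrom"].iloc[causal_idx].to_numpy() if causal_idx.size else [],
        "pos": geno.variants["pos"].iloc[causal_idx].to_numpy() if causal_idx.size else [],
        "beta": betas,
    })
    true_abd = spec.warming_slope * spec.warming_total  # days earlier over the span
    truth.true_abd = pd.DataFrame({
        "sample": geno.samples,
        "abd_days": true_abd,
        "slope_days_per_year": -spec.warming_slope * spec.warming_total / span,
    })

    # conductance curves from the logistic freezing-damage model
    deme_of = truth.sample_frame.set_index("sample")["deme"]
    temps = np.array([-10.0, -15.0, -20.0, -25.0, -30.0, -35.0])
    lt50s, crows = [], []
    for s in geno.samples:
        base_lt = DEME_LT50.get(deme_of.get(s, ""), -20.0)
        lt50 = base_lt + rng.normal(0.0, spec.lt50_sd)
        lt50s.append(lt50)
        rc = 1.0 / (1.0 + np.exp(spec.lt50_k * (temps - lt50)))
        if spec.rc_noise_sd > 0:
            rc = np.clip(rc + rng.normal(0.0, spec.rc_noise_sd, size=temps.size), 0.0, 1.0)
        crows.append(pd.DataFrame({
            "sample": s, "temperature_C": temps, "relative_conductance": rc,
        }))
    conductance = pd.concat(crows, ignore_index=True)
    truth.true_lt50 = pd.DataFrame({
        "sample": geno.samples, "lt50": lt50s, "k": spec.lt50_k,
    })

    hourly = simulate_hourly_temps(rng)
    return pheno, conductance, hourly


def simulate_hourly_temps(rng=None, n_days: int = 120, mean_start: float = 8.0,
                          mean_mid: float = -2.0, diurnal_amp: float = 5.0,
                          noise_sd: float = 1.0, seed: int | None = None) -> pd.DataFrame:
    """Hourly winter temperature series (Nov 1 through the dormancy window).

    Seasonal mean slides from ``mean_start`` down to ``mean_mid`` and back,
    with a sinusoidal diurnal cycle, so a realistic fraction of hours falls
    in the effective chilling band (0, 7.2] degC.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    hours = np.arange(n_days * 24)
    day = hours / 24.0
    seasonal = mean_mid + (mean_start - mean_mid) * np.abs(1 - 2 * day / n_days)
    diurnal = diurnal_amp * np.sin(2 * np.pi * (hours % 24) / 24.0 - np.pi / 2)
    temp = seasonal + diurnal + rng.normal(0.0, noise_sd, size=hours.size)
    return pd.DataFrame({"hour": hours, "temperature_C": temp})


# ---------------------------------------------------------------------------
# output bundle
# ---------------------------------------------------------------------------

def simulate_all(scenario: SimScenario, outdir: str | None = None):
    """Run the whole generator; optionally write the file bundle.

    Emits VCFv4.2 (phased), sample metadata TSV, EV TSV, phenotype TSV,
    conductance TSV, hourly temperature TSV, and ground-truth JSON.
    """
    geno, truth = simulate_population(scenario)
    env = simulate_environment(scenario, truth.sample_frame)
    pheno, conductance, hourly = simulate_phenotypes(geno, truth, scenario=scenario)

    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_vcf(geno, os.path.join(outdir, "genotypes.vcf"),
                  {scenario.chrom: scenario.seq_length})
        truth.sample_frame.to_csv(os.path.join(outdir, "samples.tsv"),
                                  sep="\t", index=False)
        env.to_csv(os.path.join(outdir, "env.tsv"), sep="\t", index=False)
        pheno.to_csv(os.path.join(outdir, "pheno.tsv"), sep="\t", index=False)
        conductance.to_csv(os.path.join(outdir, "conductance.tsv"), sep="\t", index=False)
        hourly.to_csv(os.path.join(outdir, "hourly_temps.tsv"), sep="\t", index=False)
        truth.to_json(os.path.join(outdir, "truth.json"))
    return geno, truth, env, pheno, conductance, hourly


# ---------------------------------------------------------------------------
# canonical study scenarios
# ---------------------------------------------------------------------------

def neutral_scenario(seed: int = 0, deme_size: int = 100,
                     seq_length: int = 2_000_000) -> SimScenario:
    """Single-deme neutral equilibrium population (calibration substrate)."""
    return SimScenario(
        n_demes=1, deme_sizes=(deme_size,), deme_labels=("A",),
        n_generations=1000, migration_rate=0.0, seq_length=seq_length,
        mut_rate=1e-6, rec_rate=5e-7, seed=seed,
    )


def sweep_consensus_scenario(seed: int = 0, s: float = 0.05,
                             sweep_pos: int = 500_000) -> SimScenario:
    """Two demes, low gene flow, one local hard sweep in the focal deme.

    The sweep starts after a long shared history, is conditioned to reach
    focal frequency 0.95 (migration-selection balance precludes literal
    fixation), and sampling happens the generation the threshold is reached
    so the footprint is fresh.  Substrate for the ROD + Tajima's D + F_ST
    consensus recovery check.
    """
    return SimScenario(
        n_demes=2, deme_sizes=(100, 100), deme_labels=("T", "R"),
        n_generations=900, migration_rate=0.002, seq_length=1_000_000,
        mut_rate=1e-6, rec_rate=5e-7,
        sweep_specs=[SweepSpec(deme=0, pos=sweep_pos, s=s, start_gen=650,
                               fix_freq=0.95, stop_at_fixation=True)],
        seed=seed,
    )


def group_scan_scenario(seed: int = 0, s: float = 0.05,
                        sweep_pos: int = 500_000) -> SimScenario:
    """One larger deme with a hard sweep sampled exactly at fixation.

    Substrate for the within-group scans (CLR, mu, Tajima's D) that do not
    use a reference population; the bigger deme gives the sweep a footprint
    wide enough to dominate drift at the 10-kb scale.
    """
    return SimScenario(
        n_demes=1, deme_sizes=(250,), deme_labels=("TB",),
        n_generations=900, migration_rate=0.0, seq_length=1_000_000,
        mut_rate=1e-6, rec_rate=2e-7,
        sweep_specs=[SweepSpec(deme=0, pos=sweep_pos, s=s, start_gen=700,
                               fix_freq=1.0, stop_at_fixation=True)],
        seed=seed,
    )


def association_scenario(seed: int = 0) -> SimScenario:
    """Four moderately connected demes, 200 samples, association substrate.

    The higher recombination rate keeps locus-specific signals close to
    exchangeable, which the genomic-control calibration of the scans
    presumes.
    """
    return SimScenario(
        n_demes=4, deme_sizes=(50, 50, 50, 50), deme_labels=("A", "B", "C", "D"),
        n_generations=800, migration_rate=0.02, seq_length=1_000_000,
        mut_rate=1e-6, rec_rate=1e-6, seed=seed,
    )


def scenario_from_yaml(path: str) -> SimScenario:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for key, cls in (("env_spec", EnvSpec), ("pheno_spec", PhenoSpec)):
        if key in cfg and isinstance(cfg[key], dict):
            cfg[key] = cls(**cfg[key])
    if "sweep_specs" in cfg:
        cfg["sweep_specs"] = [SweepSpec(**s) if isinstance(s, dict) else SweepSpec(*s)
                              for s in cfg["sweep_specs"]]
    for tup in ("deme_sizes", "deme_labels"):
        if tup in cfg:
            cfg[tup] = tuple(cfg[tup])
    known = {f.name for f in dataclasses.fields(SimScenario)}
    bad = set(cfg) - known
    if bad:
        raise ValueError(f"unknown scenario keys: {sorted(bad)}")
    return SimScenario(**cfg)
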