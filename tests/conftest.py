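import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import adaptscan as ad
from adaptscan.genio import GenotypeMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_geno(dosage, pos=None, chrom="Pp01", haplotypes=None, samples=None):
    """Small GenotypeMatrix from a dosage array (rows = samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 10
    variants = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(pos, dtype=np.int64),
        "ref": "A", "alt": "T",
    })
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(samples, variants, dosage, haplotypes)


def hap_geno(hap, pos=None, chrom="Pp01"):
    """GenotypeMatrix from a phased haplotype array (rows = haplotypes)."""
    hap = np.asarray(hap, dtype=np.int8)
    dosage = hap[0::2] + hap[1::2]
    g = make_geno(dosage, pos=pos, chrom=chrom)
    g.haplotypes = hap
    return g


@pytest.fixture(scope="session")
def neutral_sim():
    """One-deme neutral equilibrium population, 500 kb (shared, read-only)."""
    scenario = ad.datagen.neutral_scenario(seed=1, seq_length=500_000)
    geno, truth = ad.simulate_population(scenario)
    return scenario, geno, truth


@pytest.fixture(scope="session")
def assoc_sim():
    """Four-deme structured population for association tests (read-only)."""
    scenario = ad.datagen.association_scenario(seed=11)
    geno, truth = ad.simulate_population(scenario)
    geno = geno.take_variants(geno.maf() >= 0.05)
    return scenario, geno, truth


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """Small end-to-end synthetic study written to disk (read-only)."""
    scenario = ad.SimScenario(
        n_demes=2, deme_sizes=(15, 12), deme_labels=("NE", "ST"),
        n_generations=300, migration_rate=0.05, seq_length=100_000,
        mut_rate=1e-6, rec_rate=5e-7, seed=7,
    )
    outdir = tmp_path_factory.mktemp("bundle")
    geno, truth, env, pheno, conductance, hourly = ad.simulate_all(scenario, str(outdir))
    return dict(scenario=scenario, geno=geno, truth=truth, env=env,
                pheno=pheno, conductance=conductance, hourly=hourly,
                outdir=outdir)
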