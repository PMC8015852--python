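"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions: everything in memory is 0-based half-open; VCF and
GFF3 are 1-based fully-closed on disk; BED is 0-based half-open.  The
``pos`` column of :class:`GenotypeMatrix.variants` keeps the 1-based VCF
position because that is how variants are named throughout (``Pp06:9187362``
style); interval arithmetic on genes and regions is 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # dosage / haplotype code for uncalled genotypes


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid dosages plus optional phased haplotypes.

    Parameters
    ----------
    samples
        Sample identifiers, unique, length ``n``.
    variants
        DataFrame with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``;
        one row per biallelic SNP, positions strictly increasing within each
        chromosome.
    dosage
        ``(n, m)`` int8 array of alternate-allele dosages 0/1/2, ``-1`` for
        missing.
    haplotypes
        Optional ``(2n, m)`` int8 array of phased alleles 0/1 (``-1``
        missing); rows ``2i`` and ``2i+1`` are the two haplotypes of sample
        ``i`` and their column sums must equal the dosage wherever both are
        called.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * len(self.samples), len(self.variants)):
                raise ValueError("haplotype matrix must be (2*samples, variants)")
            both = (self.haplotypes[0::2] >= 0) & (self.haplotypes[1::2] >= 0)
            hsum = self.haplotypes[0::2] + self.haplotypes[1::2]
            if not np.array_equal(hsum[both], self.dosage[both]):
                raise ValueError("dosage must equal haplotype column-pair sum")
        for _, sub in self.variants.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError("positions must be strictly increasing within chrom")

    # -- derived quantities -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def alt_counts(self) -> np.ndarray:
        """Alternate-allele count per variant, over called alleles."""
        d = self.dosage
        return np.where(d >= 0, d, 0).sum(axis=0)

    def called_allele_numbers(self) -> np.ndarray:
        """Number of called alleles (2 x called genotypes) per variant."""
        return 2 * (self.dosage >= 0).sum(axis=0)

    def maf(self) -> np.ndarray:
        an = self.called_allele_numbers().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.alt_counts() / an
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return (self.dosage < 0).mean(axis=0)

    # -- subsetting ---------------------------------------------------------

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in ids]
        hap = None
        if self.haplotypes is not None:
            hidx = np.repeat(np.asarray(idx) * 2, 2)
            hidx[1::2] += 1
            hap = self.haplotypes[hidx]
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.variants.reset_index(drop=True),
            self.dosage[idx],
            hap,
        )

    def take_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.samples,
            self.variants.loc[mask].reset_index(drop=True),
            self.dosage[:, mask],
            None if self.haplotypes is None else self.haplotypes[:, mask],
        )


@dataclass
class GeneSet:
    """Gene intervals, internally 0-based half-open."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand"]
        )
    )

    def __post_init__(self) -> None:
        if len(self.table) and (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene start must be <= end")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str,
    maf_min: float = 0.0,
    max_missing: float = 1.0,
    require_phase: bool = False,
) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Non-SNP and multiallelic records are skipped (counted in the log, never
    split).  MAF is computed on called alleles only.  ``max_missing`` is the
    largest tolerated fraction of missing genotypes per site.  Haplotypes are
    populated only when every genotype of every retained record is phased;
    with ``require_phase=True`` an unphased genotype is an error instead.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")

    chroms, poss, refs, alts = [], [], [], []
    hap_rows: list[np.ndarray] = []
    n_skipped = 0
    all_phased = True
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = np.array(v.genotypes, dtype=np.int64)  # (n, 3): a0, a1, phased
        if not np.all(gts[:, 2] | (gts[:, 0] < 0)):
            if require_phase:
                raise ValueError("phased haplotypes required for iHS")
            all_phased = False
        hap = gts[:, :2].reshape(-1).astype(np.int8)
        hap[hap < 0] = MISSING
        hap_rows.append(hap)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)

    variants = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    if hap_rows:
        hap = np.stack(hap_rows, axis=1)  # (2n, m)
    else:
        hap = np.zeros((2 * len(samples), 0), dtype=np.int8)
    a, b = hap[0::2], hap[1::2]
    dosage = np.where((a >= 0) & (b >= 0), a + b, MISSING).astype(np.int8)

    geno = GenotypeMatrix(samples, variants, dosage, hap if all_phased else None)
    return filter_variants(geno, maf_min=maf_min, max_missing=max_missing)


def filter_variants(
    geno: GenotypeMatrix, maf_min: float = 0.0, max_missing: float = 1.0
) -> GenotypeMatrix:
    """Drop variants failing MAF / missingness filters (order-independent)."""
    an = geno.called_allele_numbers()
    keep = (an > 0) & (geno.maf() >= maf_min) & (geno.missing_rate() <= max_missing)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "filter_variants: removed %d of %d variants (maf_min=%g, max_missing=%g)",
            n_drop, geno.n_variants, maf_min, max_missing,
        )
    return geno.take_variants(keep)


def write_vcf(geno: GenotypeMatrix, path: str, contig_lengths: dict | None = None) -> None:
    """Write a GenotypeMatrix as VCFv4.2 text (phased GT if haplotypes exist)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=adaptscan\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={int(ln)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples) + "\n"
        )
        phased = geno.haplotypes is not None
        sep = "|" if phased else "/"
        for j in range(geno.n_variants):
            row = geno.variants.iloc[j]
            gts = []
            for i in range(geno.n_samples):
                if phased:
                    a, b = geno.haplotypes[2 * i, j], geno.haplotypes[2 * i + 1, j]
                else:
                    d = geno.dosage[i, j]
                    a, b = (MISSING, MISSING) if d < 0 else (min(d, 1), max(d - 1, 0))
                gts.append("./." if a < 0 or b < 0 else f"{a}{sep}{b}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# tabular metadata
# ---------------------------------------------------------------------------

def read_sample_frame(path: str, groups: set[str] | None = None) -> pd.DataFrame:
    """Sample metadata TSV: sample, deme, lat, lon, altitude."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "deme": str})
    required = {"sample", "deme", "lat", "lon", "altitude"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    if groups is not None and (bad := set(df["deme"]) - groups):
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}")
    return df


def read_env_table(path: str) -> pd.DataFrame:
    """Environmental-variable TSV: sample column + >=1 numeric EV column."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    ev_cols = [c for c in df.columns if c != "sample"]
    if not ev_cols:
        raise ValueError(f"{path}: no EV columns")
    if len(set(ev_cols)) != len(ev_cols):
        raise ValueError(f"{path}: duplicate EV names")
    for c in ev_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        if coerced.isna().sum() > df[c].isna().sum():
            bad = df.loc[coerced.isna() & df[c].notna(), "sample"].iloc[0]
            raise ValueError(f"{path}: non-numeric EV value in column {c!r}, sample {bad!r}")
        df[c] = coerced
    return df


def read_pheno_panel(path: str) -> pd.DataFrame:
    """Phenotype TSV: sample, year, bloom_doy (+ optional replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "year", "bloom_doy"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_tables(
    sample_path: str,
    env_path: str,
    pheno_path: str | None = None,
    geno: GenotypeMatrix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Read and cross-validate the metadata tables against the genotypes.

    Samples present in the VCF but absent from the sample frame raise; extra
    table rows are dropped with a warning.  Row order of the sample frame and
    EV table is harmonized to VCF sample order when ``geno`` is given.
    """
    sf = read_sample_frame(sample_path)
    env = read_env_table(env_path)
    pheno = read_pheno_panel(pheno_path) if pheno_path else None

    if geno is not None:
        want = list(geno.samples)
        for name, df in (("sample frame", sf), ("EV table", env)):
            absent = sorted(set(want) - set(df["sample"]))
            if absent:
                raise ValueError(f"samples in VCF missing from {name}: {absent}")
        extra = sorted(set(sf["sample"]) - set(want))
        if extra:
            logger.warning("dropping %d metadata rows not in VCF", len(extra))
        sf = sf.set_index("sample").loc[want].reset_index()
        env = env.set_index("sample").loc[want].reset_index()
        if pheno is not None:
            pheno = pheno[pheno["sample"].isin(want)].reset_index(drop=True)
    return sf, env, pheno


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

def read_gff_genes(path: str) -> GeneSet:
    """Extract ``gene`` features from a GFF3 file (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF line ({len(parts)} fields)")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if gene_id is None:
                gene_id = f"gene_{lineno}"
            rows.append((gene_id, chrom, start_i - 1, end_i, strand))
    return GeneSet(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )


def write_gff_genes(genes: GeneSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.table.itertuples():
            fh.write(
                f"{r.chrom}\tadaptscan\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t"
                f"ID={r.gene_id}\n"
            )


def write_bed(regions: pd.DataFrame, path: str) -> None:
    """Write regions (chrom, start, end 0-based half-open [+extras]) as BED."""
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend" + "\n")
        for r in regions.itertuples(index=False):
            extras = [str(x) for x in r[3:]]
            fh.write("\t".join([str(r[0]), str(int(r[1])), str(int(r[2]))] + extras) + "\n")


def read_bed(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
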