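# adaptscan

Genomic local-adaptation analysis for structured plant populations:
multi-metric selective-sweep scanning with consensus region calling,
genome-wide environmental association (mixed model and latent-factor model),
and adaptive-trait analytics for phenology — bloom-date genotype-by-year
decomposition, bloom-date advance under warming, cold-hardiness LT50 and
chilling requirement.  The package is aimed at population-genomics analyses
of landrace/wild panels (the defaults emulate a 263-accession peach panel
split into seven ecotype groups), and ships a forward-time Wright–Fisher
simulator that generates every input the pipeline consumes with known ground
truth, so every stage is testable end to end.

## What it computes

**Selection scans** (per landrace group, 10-kb windows sliding by 1 kb):

- nucleotide diversity π (per site `2c(n−c)/n(n−1)`, summed per bp of window);
- reduction of diversity `ROD = 1 − π_group / π_rest` against the pooled
  other groups;
- Tajima's *D* with the 1989 standardization constants;
- Weir–Cockerham (1984) *F*<sub>ST</sub> from the a/b/c variance components,
  per SNP and as windowed ratio-of-sums;
- a composite-likelihood-ratio (CLR) sweep scan contrasting a hard-sweep
  escape model (`p_e = 1 − e^{−αd}`) against the genome-wide site-frequency
  spectrum, with an invariant-site density term and a recurrent-mutation
  component;
- the RAiSD-style μ statistic (SNP-density × SFS-shape × LD-contrast over
  windows of W consecutive SNPs);
- iHS from extended haplotype homozygosity, standardized within
  derived-allele-frequency bins.

Windows in the empirical top 5% of at least two metrics, merged, become
candidate selection regions (CSRs).

**Associations**: IBS kinship, EMMAX-style mixed-model scans (P3D: REML
variance components fitted once on the null, then per-marker GLS) for
environmental variables and traits, PCA of the environmental table, a
latent-factor model for structure-corrected environmental association with
genomic-control calibration, Bonferroni thresholds, and the
more-than-five-EV hotspot rule.

**Traits**: AMMI (additive main effects + multiplicative interaction)
decomposition of accession × year bloom dates with a warming covariate,
per-accession advance-in-bloom-date (ABD) regressions, logistic LT50 fits
from relative electrolyte conductance, chilling hours in (0, 7.2] °C, and
temporary/recurrent/stable multiyear association classes.

**Integration**: genes overlapping CSRs, sweep × association gene overlap,
and a seeded permutation Mantel test of environment–genotype distance
correlation.

## Worked example

```python
import numpy as np
import adaptscan as ad
from adaptscan.winstats import WindowSpec

# simulate a two-deme panel with one local hard sweep at 500 kb
scenario = ad.datagen.sweep_consensus_scenario(seed=0)
geno, truth = ad.simulate_population(scenario, retry_cap=200)

focal = [s for s in geno.samples if s.startswith("T")]
rest = [s for s in geno.samples if s.startswith("R")]
spec, L = WindowSpec(), scenario.seq_length

pi_t = ad.windowed_pi(geno, focal, spec, L)
pi_r = ad.windowed_pi(geno, rest, spec, L)
rod = ad.rod(pi_t, pi_r)
tajd = ad.tajimas_d(geno, focal, spec, L)
_, fst = ad.weir_cockerham_fst(geno, focal, rest, spec, L)

regions = ad.consensus_regions([rod, tajd, fst], tail_fraction=0.05,
                               tail_side={"tajd": "lower"}, min_metrics=2)
for r in regions:
    print(f"{r.chrom}:{r.start}-{r.end}  supports={','.join(r.supports)}")
```

prints (seed 0; the designated sweep sits at position 500,000):

```
Pp01:453000-480000  supports=fst,tajd
Pp01:503000-519000  supports=fst,tajd
Pp01:537000-564000  supports=fst,rod,tajd
Pp01:584000-634000  supports=fst,rod,tajd
Pp01:766000-793000  supports=rod,tajd
Pp01:814000-851000  supports=rod,tajd
Pp01:861000-881000  supports=rod,tajd
```

Four of the seven called regions cluster on the sweep: two flank the site
directly (453–480 kb and 503–519 kb) and two sit on its right shoulder with
all three metrics agreeing — hitchhiking distorts a neighbourhood much wider
than the selected base itself.  The remaining regions are the expected
scatter of top-5% windows under drift; with `min_metrics=2` over three
metrics, roughly 5–10% of windows pass somewhere in a 1-Mb background.  The
same machinery is available from the shell via the `adaptscan` CLI
(`adaptscan simulate | scan | sweep | gweas | traits | report`).

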