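# Methods

This note documents the models behind `adaptscan`: what each component
assumes, the parameters that matter, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer would otherwise
have to reverse-engineer from the code.

## Forward Wright–Fisher simulator (`datagen`)

The generator is a discrete-generation, diploid Wright–Fisher simulation
with an island migration model. Per generation, for each offspring: each of
its two parents is drawn from the home deme, or with probability `m` from a
uniformly chosen other deme (backward migration convention); parents within
the source deme are sampled with probability proportional to fitness; each
gamete is a parental haplotype with at most one crossover (probability
`r·L`, breakpoint uniform); new mutations are Poisson(`2N·µ·L`) per
generation on an infinite-sites lattice of integer base pairs (occupied
positions are skipped). Fitness is multiplicative over active sweep loci,
`w = Π (1 + s·dosage)`, applied within the sweep's deme only (local
adaptation).

Hard sweeps are conditioned on establishment by rejection: if the beneficial
allele is lost, or has not reached its target focal-deme frequency
(`fix_freq`) by the final generation, the trajectory is re-drawn from the
injection generation (default cap 100 attempts, then a
`SweepNotEstablishable` error). `stop_at_fixation=True` ends the simulation
the generation the target frequency is reached — the textbook sampling
point for a *just-completed* hard sweep. This matters more here than in
coalescent-scaled simulators: at the rescaled mutation rates below, the
count of segregating sites inside a swept footprint recovers within tens of
generations (as a blizzard of young, low-frequency alleles), so sampling
even 100 generations after fixation visibly erodes every scan signal.

### Rescaled parameter regime

Desk-scale simulations use small populations with mutation and recombination
rates scaled up so that the population-scaled compound parameters stay in a
realistic range:

| parameter | default | rationale |
|---|---|---|
| deme sizes | (30, 45, 50, 60, 19, 45, 14) | seven-group panel totalling 263 diploids; the NE (19), TB (45) and ST (14) group sizes follow the emulated panel, the rest are free choices |
| `mut_rate` | 1e-6 /bp/gen | θ = 4Nµ ≈ 4e-4 /bp at N = 100 — typical for a perennial outcrosser |
| `rec_rate` | 5e-7 /bp/gen | ~0.5 crossovers per gamete per Mb |
| `migration_rate` | 0.05 | equilibrium island-model F_ST ≈ 0.1, the upper end of the emulated panel's group differentiation |
| `n_generations` | 1000 | ≥ 2.5 × TMRCA at N = 100; segregating-site counts reach Watterson's expectation |

Named scenario builders freeze the study conditions used by the acceptance
suite: `neutral_scenario` (one deme, N = 100), `sweep_consensus_scenario`
(two demes of 100, m = 0.002, one local sweep with s = 0.05 conditioned to
reach focal frequency 0.95 — migration–selection balance precludes literal
fixation in a connected deme), `group_scan_scenario` (one deme of 250,
r = 2e-7, a sweep sampled exactly at fixation; the larger deme and tighter
linkage give 2Ns = 25 and a footprint that dominates drift at the 10-kb
scale), and `association_scenario` (four demes of 50, r = 1e-6 over 1 Mb so
locus-specific signals are approximately exchangeable, which genomic-control
calibration presumes).

### Environment, phenotypes, ground truth

Environmental variables are deme means plus Gaussian noise; 35 of the 51
default EVs load on one latent per-deme climate axis (loadings ±U(0.8,
1.2)), producing the strong inter-EV correlation structure of real climate
layers — the first EV principal component then carries >60% of the variance.
The rest get independent deme means. Sample latitude/longitude/altitude
come from fixed per-group geographic anchors.

Bloom dates follow `BD_iy = µ + Σ_k β_k g_ik − γ·ΔT_y + ε` with five causal
variants (effects ±1–2 d per allele, drawn among variants with MAF ≥ 0.2), a
linear warming ramp ΔT rising 1 °C over 1983–2011, warming sensitivity γ =
10 d advanced per °C (so the constructed population-mean advance is 10 days
over the span), residual SD 3 d, and two replicates per accession × year.
Conductance curves are generated from the logistic freezing-damage model
with per-deme LT50 means (−12 °C for the subtropical group down to −30 °C
for the northeastern group, accession SD 1.5 °C), slope k = 0.4, and RC
noise SD 0.02. Hourly winter temperatures combine a seasonal ramp and a
sinusoidal diurnal cycle.

`GroundTruth` records sweep positions, trajectories and attempt counts,
causal variants and effects, the true per-accession advance and LT50, so
recovery tests need no external reference.

What the generator does **not** emulate: soft sweeps and standing-variation
adaptation, realistic recombination maps or gene conversion, demographic
history (bottlenecks, expansions), genotyping error and allelic dropout,
reference bias, and linked background selection. Passing recovery tests
therefore demonstrate that the estimators implement their models correctly
and can find textbook hard sweeps at desk scale — not that the pipeline's
power transfers to any particular empirical data set.

## Windowed statistics (`winstats`)

Windows are 10 kb sliding by 1 kb by default. Per-bp π divides by the full
window span (no callability mask is modelled). Tajima's D uses single-n
1989 constants with n the modal called-allele count among the window's sites
(equal to 2 × subset size when missingness is zero, the generator default);
windows with fewer than 3 segregating sites are NaN and excluded from
outlier ranking. F_ST follows Weir & Cockerham (1984) exactly: per-SNP
a/(a+b+c) is reported raw (negative estimates retained), windowed values are
ratio-of-sums Σa/Σ(a+b+c), clamped to [0, 1] on report. ROD compares a
focal group against the *pooled* samples of the other groups, not the mean
of per-group values.

## Sweep-model scans (`sweeps`)

**CLR.** At each grid point (default every 2 kb; the acceptance runs use
5 kb) a hard-sweep model is contrasted against the genome-wide SFS of the
scanned panel. A lineage at distance d escapes the sweep with probability
`p_e = 1 − exp(−α·d)`; the escapees plus one hitchhiking ancestor are a
hypergeometric subsample of the background spectrum and non-escaped lineages
copy the hitchhiking lineage's allele. Three additions make the model work
on data rather than only on blackboards:

1. *Invariant-site density term.* Conditioning on polymorphism discards the
   loss-of-diversity signal, so the composite likelihood treats polymorphic
   sites as a Poisson field thinned by the model's polymorphism-survival
   probability (the SweepFinder2 idea): observed sites contribute
   `log s(p_e)` and the thinned expectation contributes `λ ∫ (1 − s) db`.
2. *Recurrent-mutation component.* Mutations arising during/after the sweep
   are young alleles the escape model cannot produce; they are mixed in with
   a 1/i² spectrum and a weight proportional to the variation the sweep
   removed (`mix·(1 − s(p_e))`, default mix = 1, i.e. full density recovery
   in the swept limit — the right limit for the simulator's rescaled
   mutation rates). The background limit p_e → 1 is exactly untouched.
3. *α search.* Log-grid (16 points, default bounds 1e-7–1e-2 /bp; the
   acceptance scans restrict to 2e-6–2e-4, footprints of 5–500 kb) plus
   bounded golden-section refinement; CLR = 2·max(Δ log L, 0), so the
   background is always an admissible fit and CLR ≥ 0.

Site-frequency probabilities are precomputed on a p_e grid that is log-dense
near *both* 0 and 1 and linearly interpolated.

**μ.** Sliding windows of W consecutive SNPs (default 20; the sweep-recovery
runs use 50): `μ_var = (span/L)(S/W)`;
`μ_sfs = (ξ₁ + ξ_{n−1} + 1)/(W + 2)` normalized by its genome-wide mean;
`μ_ld = (mean within-half r² + ε)/(2·mean cross-half r² + ε)` with ε = 0.01,
r² on haplotypes when present; μ is the product. The three normalizations
are this package's own — the statistic's three-signal design follows the
RAiSD idea, not its exact constants.

**iHS.** EHH is the probability two random carrier haplotypes are identical
over every site between the core and x; iHH integrates EHH by trapezoid in
physical bp outward until EHH < 0.05 (the crossing segment is included) or
the last SNP. Scores ln(iHH_A/iHH_D) are standardized within
derived-frequency bins of width 0.05; bins with fewer than 10 scores get NaN
with a warning.

**Consensus regions.** Per metric, windows at or beyond the empirical
1 − tail quantile (ties included; "lower" tails declared per metric — e.g.
Tajima's D for within-group sweep scans) are merged when overlapping or
touching; merged spans of the union are reported when ≥ `min_metrics`
metrics overlap them by ≥ 1 bp.

## Association (`assoc`)

Kinship is mean IBS over jointly-called sites, bent to positive-semidefinite
by flooring eigenvalues at 1e-6 and rescaling the diagonal to 1. The mixed
model `y = Xβ + u + ε`, cov(u) = σ²_g K, is fitted once by REML — profile
over ln δ (δ = σ²_e/σ²_g) on a 100-point grid over [−10, 10] plus bounded
refinement in the kinship eigenbasis — and every variant is then tested by
GLS with δ̂ fixed (the EMMAX/P3D approximation; `exact=True` refits per
marker). Fixed covariates are an intercept plus 3 genotype PCs by default.
Missing dosages are mean-imputed for association only, never for the
diversity statistics.

The latent-factor scan fits K factors (default 3) to the centered genotype
matrix by alternating ridge least squares (initialized from the top-K SVD),
then estimates each locus's environmental effect by partial regression of
the genotype on the covariate given the factors, with genomic-control
calibration `z² · 0.456 / median(z²)` and χ²₁ p-values. Fitting the factors
jointly with free per-locus effects is deliberately avoided: the joint
least-squares optimum re-splits structure-confounded signal into the
per-locus effects (the fitted factors end up orthogonal to the covariate),
which demonstrably inflates the null — λ values near 3 in structured null
simulations — whereas the decoupled estimand centers λ on 1. The price is
the usual one: genuinely environmental variance that parallels structure is
absorbed by the factors.

λ is itself a noisy statistic (a median over correlated loci); calibration
checks therefore report the median λ over five independent null covariates.

Bonferroni thresholds are always computed as α divided by the number of
variants actually tested, never hard-coded. Hotspots merge significant SNPs
within 10 kb and require strictly more than five distinct EVs.

## Traits (`traits`)

AMMI averages replicates to accession × year cell means (missing cells
imputed by row+column means and flagged), removes the additive main effects,
and SVDs the doubly-centered interaction. IPCA k carries Gollob degrees of
freedom `(g−1)+(e−1)−2k+1` and is F-tested against the pooled residual of
the remaining interaction terms. The warming covariate's share of the
bloom-date trend is the squared correlation between the year main effects
and the temperature series (a flag switches to IPCA-1 year scores) —
attribution to the year *main* effect, because the driver of interest acts
on bloom date overall, not only on its genotype-specific component.

ABD is −slope × span from per-accession OLS of bloom day-of-year on calendar
year (positive = earlier bloom; accessions with fewer than 5 years are
skipped with a warning). LT50 is the midpoint of
`RC(T) = 1/(1 + exp(k(T − LT50)))` by bounded nonlinear least squares,
multi-start over k ∈ {0.1, 0.3, 1.0}, LT50 initialized at the temperature
nearest RC = 0.5 and clipped to the tested range ± 10 °C. Chilling hours
count `0 < T ≤ 7.2` °C — zero excluded, the 7.2 boundary included.
Stability classes partition significant SNPs by years significant:
temporary = 1, recurrent = 2–5, stable = strictly more than 5.

## Integration (`integrate`)

Gene overlap is ≥ 1 bp interval intersection on 0-based half-open
coordinates, strand ignored. Genetic distance defaults to 1 − IBS,
environmental distance to Euclidean on standardized EVs. The Mantel test
permutes rows and columns of the second matrix jointly with a seeded
generator; the p-value is one-sided,
`(1 + #{permuted r ≥ observed}) / (1 + n_perm)`.

## Validation design and problem sizes

The acceptance suite runs entirely on simulator output: the fixed-difference
F_ST worked example (exact 1); brute-force oracle equivalence at 1e-10 for
π, D, the F_ST components, iHH, kinship and Mantel r on random 5–10-sample
instances; neutral calibration on a 1-Mb, N = 100 simulation (mean D, random
split F_ST) with the SFS-vs-1/i check done across ten independent 500-kb
replicates — sites on one chromosome share genealogies, so a naive
multinomial χ² is overdispersed roughly tenfold and the goodness-of-fit uses
per-class z-scores across replicates (t-moment corrected) on a 10-sample
subpanel instead; sweep recovery over 20 seeds each for the two-deme
consensus caller and the within-group CLR/μ scans (localization = distance
from the reported maximum window to the sweep site, ≤ 50 kb); association
calibration and power on 200 samples × ~2300 variants; iHS standardization
on 2500 scores from a 2-Mb neutral simulation; and exact rule fidelity on
hand-enumerated toys. On one CPU the full suite takes roughly a quarter of
an hour, dominated by the 40 sweep-recovery simulations.

## Known limitations

- The CLR recurrent-mutation weight (mix = 1) is tuned to the simulator's
  rescaled-mutation regime; empirical data with slower density recovery may
  warrant a smaller value (it is a constructor argument).
- Tajima's D with heavy, variant-specific missingness uses one modal n per
  window; spectra with bimodal call rates would be better served by
  per-site projection.
- The latent-factor scan absorbs environment that parallels structure —
  clinal selection perfectly confounded with demography is invisible to it,
  a property of the estimand rather than the implementation.
- iHH integration is truncated at the last SNP when EHH has not yet decayed
  below the cutoff, which slightly biases scores near chromosome edges;
  selscan instead drops such cores.
- The simulator's single-crossover meiosis caps the map length at one
  Morgan per gamete; very long chromosomes would need multi-crossover
  recombination.
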