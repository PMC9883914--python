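# Methods

This note documents the models implemented in `heterokaryon`, the
assumptions behind them, the defaults that matter, and what the synthetic
data generator does and does not emulate.

## The two-nucleotype model

The organism is modelled as a population of haploid nuclei of two types,
MAT-1 and MAT-2, mixed at ratio *r* (the MAT-1 share) in one cytoplasm.
Every biallelic SNP is assumed to be fixed within one nucleotype and absent
from the other, except for a configurable minority of *low-frequency*
variants carried by only a sub-fraction of one nucleotype's nuclei. Under
uniform sampling of reads from nuclei, the expected pooled alt-allele
frequency at a nucleotype-fixed site is *r* or 1 − *r*, which is what makes
the pooled AF spectrum informative about karyotype: one ~50% peak for a
balanced dikaryon, twin peaks at 100(1 − *r*)/100·*r* percent otherwise, and
only residual low-frequency mass for a monokaryon.

Assumptions worth keeping in mind: reads sample nuclei independently and
uniformly (no amplification bias beyond the explicit dropout/contamination
model), sites are treated as independent in the likelihood (no linkage), and
MAT assignment of nuclei is taken as error-free.

## Ratio estimation

`estimate_ratio_mle` maximizes, over r ∈ [0.5, 1],

    Σ_i log[ ½·Binom(AO_i; RO_i+AO_i, r) + ½·Binom(AO_i; RO_i+AO_i, 1−r) ],

i.e. each site's alternate allele belongs to the major or minor nucleotype
with equal prior probability. Maximization is a 0.001-resolution grid scan
followed by bounded scalar refinement (xatol 1e-6); the grid makes the
bimodal-in-r likelihood safe for a local refiner. The estimate is invariant
under ref/alt relabelling because the mixture is symmetric. Karyotype is
called monokaryon at r ≥ 0.95 (configurable): residual low-frequency
variants keep real monokaryons just short of r = 1. Degenerate input where
every site is monoallelic short-circuits to r = 1. At least 50 informative
sites are required.

`detect_modes` smooths the spectrum with a fixed-bandwidth Gaussian kernel
(default bandwidth 0.02 in frequency units, evaluated on a 0.001 grid) and
reports local maxima with prominence above 10% of the peak density, in
percent. Bandwidth 0.02 resolves the 1:1 vs 2:1 contrast at depth ~100
while suppressing binomial-noise wiggles. Note the intrinsic resolution
limit: two mixture components closer than roughly twice the per-site
binomial spread (e.g. r = 0.55 at depth ~110) produce a genuinely unimodal
smoothed spectrum, and no mode detector can separate them; the property test
for mode/MLE agreement therefore runs at depth 500, where all tested ratios
resolve. The MLE has no such limit and is the preferred estimator near 0.5.

`mat_coverage_ratio` normalizes the two MAT loci's mean per-base depths to
proportions — an independent check on the genome-wide MLE. Per-base mean
depth (rather than raw read counts) is used so loci of unequal length
compare fairly.

PCA on shared-SNP allele frequencies restricts to sites covered in every
sample, drops zero-variance columns, centers and scales columns to unit
variance, and uses scikit-learn's exact PCA.

## Filters

Pooled DNA (`filter_pool_snps`): depth within [cov_lo, cov_hi] — default
85–135, i.e. mean 110 ± 25, both bounds inclusive — and RO ≥ 10 and
AO ≥ 10, outside annotated repeats. Both-allele support is what removes
fixed differences and sequencing errors, leaving genuinely segregating
sites. Missing data is explicit and excluded from denominators, never
zero-filled. The filter is idempotent and monotone in each threshold
(property-tested).

RNA (`filter_rna_snps`): a site survives iff in *every* host its
replicate-summed depth is ≥ 20 with ≥ 10 observations of both alleles.
Summing replicates before thresholding is the default because the
per-host question ("is this SNP expressed on this host?") is about the
host, not the library; a per-replicate mode (`pool_replicates=False`) is
available for stricter reproducibility demands.

Single-nucleus calls (`call_nucleus`): depth < 10 → missing; both allele
fractions strictly above 0.1 → heterozygous (impossible for a clean haploid
nucleus, so treated as an amplification/contamination artefact: the call is
suppressed and the site plus its ±500 bp neighborhood — pooled across all
nuclei, inclusive at exactly 500 bp — is removed); otherwise the majority
allele. The conjunctive reading of the het rule (both fractions above the
threshold) is the only one consistent with "both alleles present"; a
disjunctive reading would flag nearly every covered site. RO = AO without
tripping the het rule would mean ≥ 80% of reads support neither allele;
such pathological sites are recorded as missing rather than asserted away.
A per-site boolean mask can mark sites supported by non-paired reads only
(information not derivable from count data); it defaults to a no-op.

## Discordance and blocks

Within each MAT group, a site showing both ref and alt calls (missing calls
excluded) is discordant. Blocks are maximal runs of ≥ `min_run` = 5
consecutive discordant SNPs in post-filter site-index space — "consecutive"
is an ordinal statement about retained SNPs, not a bp distance — and never
span contigs. Contigs with fewer than 2 SNPs total are skipped (a single
SNP cannot form a meaningful run and is disproportionately an artefact).
Each block records the union, over its sites, of nuclei carrying the
within-group minority allele; on an exact within-group tie, carriers of
both alleles are implicated. Correctness of both the discordance test and
the block scan is checked against a brute-force enumerator over random
genotype matrices, and recovery of implanted tracts is exact (boundaries in
site-index space) on clean simulated data.

The discordance denominator counts *sites*, not site×nucleus observations.

## Spore bottleneck

`spore_bottleneck` iterates r' = Binom(n, r)/n per lineage per generation;
with mixing rate m the post-sampling ratio is (1 − m)·sampled +
m·mean(sampled across lineages). Without mixing the ratio is a bounded
martingale: variance grows, lineages fix, and the long-run fixation
probability at 1 equals the founding ratio — both checked quantitatively
(offspring variance r(1 − r)/n; fixation fraction within ±0.03 of r at
n = 50 over 500 generations × 2000 lineages). With m = 1 all lineages
coincide after one generation. Mixing across *all* lineages is an
idealization of nuclear exchange through anastomosis within one connected
culture.

## ASE statistics

`ase_shift` reports, per host, the fraction of shared expressed SNPs with
allele frequency in [0.5 − w, 0.5 + w] (w = 0.07, roughly the half-distance
between a 50% peak and a 33/67% peak pair, so the statistic separates the
two regimes cleanly), plus all pairwise two-sample KS statistics.
`replicate_consistency` gives the within-host replicate KS scale that
between-host distances should be judged against. These are expression-level
statistics only: without DNA from the same material they cannot distinguish
host-dependent nucleotype expression from a host-driven shift in the
nucleotype ratio itself.

## The synthetic generator

`make_genome` draws per-contig SNP counts Poisson(length × density),
positions uniformly without replacement, repeat annotation by marking 2 kb
windows with probability `repeat_fraction`, and assigns each
non-low-frequency site's alternate allele to MAT-1 with probability
`alt_mat1_prob` (default 0.5; lowering it reproduces the convention that
the reference assembly collapses to the MAT-1 consensus). Low-frequency
sites draw their carrier sub-fraction uniformly from 0.10–0.25 and assign
the alternate allele to that fraction of one (randomly chosen) nucleotype's
nuclei. Eight rDNA copies of 600 bp are generated with copy *i* mutated at
exactly *i* positions, so all copies are pairwise distinct by construction.

`make_nucleus_population` gives each nucleus its nucleotype's consensus,
then implants each recombination tract by swapping a run of consecutive
sites in one nucleus to the opposite consensus; tracts on a contig are kept
separated by at least one unswapped site so ground-truth boundaries remain
distinct. Depth is negative binomial with mean `mean_depth` and variance
mean + dispersion·mean² (Poisson at dispersion 0). Sequencing error sends a
read to one of the three other bases uniformly, so RO + AO ≤ DP with
equality at zero error. Single-nucleus data add per-nucleus dropout (an
exact fraction of sites at depth 0) and contamination (a read reports a
uniformly chosen other nucleus's allele). RNA simulation draws a read's
source nucleotype with probability proportional to (nuclei count) ×
(host weight) and reuses one expressed-site subset across a host's
replicates.

What the generator does *not* emulate: linkage between sites beyond shared
nucleotype identity, MDA amplification waves (only dropout + uniform
contamination), mapping and assembly artefacts, indels/multiallelic sites,
or read-level data. Passing tests therefore demonstrate correctness of the
inference given the count-level model, not robustness to alignment or
amplification pathologies in real libraries.

## Problem sizes and determinism

The analysis drivers use a 4 Mb, 40-contig genome at 0.78 SNPs/kb with 46%
repeat content, 30 nuclei at ratio 2:1, three 12-SNP tracts (long enough
that ≥ 5 consecutive SNPs typically survive repeat masking), depth 110
with dispersion 0.05 and error 0.002 — small enough to run in seconds while
keeping every spectral feature well resolved. Tests and the acceptance
script use 2000–5000-site simulations at depths 40–500 as stated in each
test. All randomness flows through `numpy.random.default_rng` seeds;
identical seeds give bit-identical outputs.

## Known limitations

* The equal-prior binomial mixture ignores site-specific mapping bias; a
  strongly reference-biased library would bias r̂ upward.
* The monokaryon threshold (0.95) is a convention; isolates with extreme
  but genuine nucleotype skew near 19:1 are indistinguishable from
  monokaryons with residual variants at moderate depth.
* Block calling in site-index space means heavy filtering shortens
  detectable tracts; tract length in the generator is specified pre-filter.
* KS distances on thousands of sites are extremely powerful; judge effect
  sizes against the replicate null, not p-values.
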