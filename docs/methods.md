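# Methods

## Data model and conventions

Genotypes are unphased diploid dosage codes (0 = hom-ref, 1 = het,
2 = hom-alt, −1 = missing) over biallelic SNPs only; indels and multiallelic
records are dropped on VCF import and phase separators are accepted but
discarded (no implemented statistic uses phase). Internal coordinates are
0-based half-open; VCF and GFF3 positions (1-based) are converted at the I/O
boundary and converted back on output. The population design is two-level:
every sample belongs to exactly one population and every population to
exactly one group.

## Site filtering

Minor-allele frequency is computed from non-missing calls only,
p̂ = (n_het + 2·n_homalt)/(2·n_called), maf = min(p̂, 1−p̂); integrity is the
fraction of samples called. The default retention rule is maf ≥ 0.05 AND
integrity ≥ 0.5 with inclusive boundaries. MAF and integrity are computed
jointly over all samples (not per population), producing a single genome-wide
filtered site set carried into every downstream analysis. Sites with zero
calls have undefined MAF and never pass. Filtering is idempotent and
order-preserving.

## Diversity statistics

At a biallelic site with alt frequency p estimated from n called diploids,
the unbiased gene diversity is (2n/(2n−1))(1 − p² − q²); it equals the mean
number of pairwise differences among the 2n sampled alleles, so per-SNP
nucleotide diversity is the mean of per-site values and per-bp π divides the
per-site sum by a surveyed length. Both conventions are exposed because
per-SNP averages and per-bp densities differ by orders of magnitude and
published tables do not always state their denominator; per-SNP is the
default. PIC follows Botstein et al. (1980). Per population, allele
frequencies use only that population's non-missing calls; frequency-based
statistics (π, H_e, PIC) average over sites with ≥ 2 called diploids in that
population (the unbiased estimator is undefined at n = 1), while H_o pools
every non-missing call. The summary's mean row is the unweighted mean across
populations. An uncorrected H_e option exists for cross-tool comparison.

## Weir–Cockerham F_ST

Per-site variance components a (among populations), b (among individuals
within populations), and c (within individuals) follow Weir & Cockerham
(1984) for diploids, using observed heterozygote counts, sample-size-weighted
means, and n_c. Multi-locus θ is the ratio of sums Σa/Σ(a+b+c) over
informative sites (every population called, mean sample size > 1, nonzero
denominator), which makes θ invariant to duplicating sites. Small negative
estimates are reported as estimated; flooring at 0 is optional and off by
default. The estimator is pinned to this form because it is the default
behind the standard VCF-based and classical AMOVA-program pipelines; an AMOVA-based
pairwise Φ_ST is available as an alternative reading via the amova module.

## AMOVA

The hierarchical decomposition follows the distance-based
Excoffier–Smouse–Quattro framework with the standard expected-mean-square
coefficients for unbalanced designs. Sums of squares are computed at the
**allele level**: each diploid is expanded into its two alleles, which is
phase-free per locus because per-locus sums of squares depend only on allele
counts. The within-population stratum therefore pools among- and
within-individual allelic variation, and Φ_ST sits on the same scale as
Weir–Cockerham θ. This was a deliberate design choice: decomposing squared
Euclidean distances between genotype dosage vectors instead estimates
2F/(1+F) under an island model with divergence F (≈ 0.26 at F = 0.15), which
is not comparable with F_ST and breaks the Φ_ST ≈ θ̂ agreement the package
tests. Pairs with missing data use pairwise-complete loci rescaled by
(total/complete); negative variance components are reported as estimated (a
flag notes when percentages can leave [0, 100]).

Permutation significance (p = (#{Φ* ≥ Φ} + 1)/(n_perm + 1), so p > 0; the
seed is a required, logged argument):

- Φ_ST — individuals permuted among populations across the whole sample;
- Φ_SC — individuals permuted among populations within their group;
- Φ_CT — whole populations permuted among groups (the classical scheme).

Whole individuals move in every scheme (both alleles together). The
population-level Φ_CT scheme has a combinatorial limitation: with P
populations in fixed group sizes the permutation support has at most
P!/(Π n_g!) distinct assignments, so with very few populations (e.g. 3
populations in groups of 2+1 → 3 assignments) the p-value lattice is
~{1/3, 2/3, 1} and no uniform null distribution is attainable, regardless of
n_perm. For such designs `ct_permutation="individuals"` permutes individuals
among groups instead, which restores a continuous, well-calibrated null (the
test suite demonstrates both behaviours). The default remains the
population-level scheme for fidelity to standard practice.

## PCA

Sites monomorphic across called samples are excluded; missing dosages are
imputed with the site mean; each site is centered by 2p̂ and scaled by
√(2p̂(1−p̂)) (the normalization of the EIGENSOFT family); the sample×sample
covariance is eigendecomposed and PC scores are eigenvectors scaled by the
square root of their eigenvalues. No Tracy–Widom significance is attempted.

## Sweep scan

Chromosomes are tiled with non-overlapping windows (default 10 kb, anchored
at 0; a window offset replicates 1-anchored tools; the terminal window is
truncated). Chromosome lengths come from VCF contig headers, else the
maximum SNP position. Per window, between the two contrast gene pools A
(control, named first — direction is never implicit) and B: weighted F_ST is
the ratio of sums over in-window sites; π per pool is the in-window sum of
unbiased per-site gene diversities divided by the window length in bp (the
windowed-π convention, deliberately distinct from the per-SNP convention of
the diversity module); the ratio statistic is log₂(π_A/π_B). Windows with
fewer than `min_snps` SNPs (default 2), no informative F_ST site, or zero
diversity in either pool are excluded from quantile computation
(zero-diversity windows are excluded rather than pseudocounted; a
pseudocount option exists for sensitivity analysis).

Cutoffs are empirical quantiles with type-7 linear interpolation over
informative windows, always reported so results are auditable: F_ST at the
95th percentile and the ratio at both the 5th and 95th percentiles. Both
ratio tails are used, each assigned to selection in the pool whose diversity
is depleted: F_ST ≥ cutoff AND ratio ≥ upper tail → selected in B;
F_ST ≥ cutoff AND ratio ≤ lower tail → selected in A. Comparisons at the
cutoffs are inclusive. At least 20 informative windows are required.

Genes are candidates when their interval intersects a selected window by
≥ 1 bp under half-open semantics (adjacency is not overlap). Enrichment is a
one-sided hypergeometric tail P(X ≥ k) per term against a user-supplied
term→gene mapping restricted to the gene universe, flagged at raw p < 0.05
with no multiple-testing correction by default (a Benjamini–Hochberg column
is optional). Group compositions and population exclusions for contrasts are
configuration, not code.

## Synthetic data

The generator is the package's validation instrument and defines what the
passing tests demonstrate. Per site: an ancestral frequency p₀ from a
configurable law (default Uniform[0.05, 0.95]); a group frequency from the
Balding–Nichols Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) with F = f_ct (identity when
f_ct = 0); a population frequency likewise around the group frequency with
f_sc; genotypes Binomial(2, p_pop) per individual (Hardy–Weinberg);
missingness uniform at `missing_rate`. SNP positions are uniform without
replacement and sorted; genes are non-overlapping intervals tiling a
configurable fraction of each chromosome. Sweep windows replace the target
population's (or every member population's, for a group target) frequency by
p′ = (1−s)p + s·round(p), pulling toward the nearer fixation boundary (ties
at p = 0.5 round up); s = 1 fixes the target. This frequency-pull model was
chosen over coalescent/forward simulation because it directly parameterizes
the quantities the estimators recover (F_CT, F_SC, joint low-π/high-F_ST
windows) and none of the implemented statistics uses linkage.

What the simulator does **not** emulate: linkage disequilibrium, mutation
models, demographic history, genotyping error structure, depth-dependent
missingness, or allele-frequency spectra shaped by ascertainment. Passing
recovery tests therefore demonstrates estimator correctness under the
island-model assumptions, not robustness to those real-data features.

A single global seed drives a label-keyed stream-splitting scheme (each
(purpose, chromosome, population) tuple hashes to its own child stream), so
extending a design does not perturb existing draws, and identical
(config, seed) yields byte-identical outputs.

## Validation problem sizes

The self-validation (`scripts/acceptance.py`, mirrored in the acceptance
tests) uses: 50 random genotype-count configurations for the
component-oracle check (tolerance 1e−12); 2 populations × 20 diploids ×
20,000 sites × 3 replicates for divergence recovery at F ∈ {0.05, 0.15,
0.30} (|θ̂ − F| ≤ 0.02, |Φ_ST − θ̂| ≤ 0.05); 200 panmictic replicates of 30
individuals × 300 sites with 500 permutations each for Φ_CT null
calibration; 510 10-kb windows (10 embedded sweeps at s = 0.9 over a 5%
background divergence) for sweep recovery; and 25 random instances on ≤ 12
gene universes for enrichment enumeration.

## Known limitations

- The Φ_CT population-permutation p-value is coarse for small numbers of
  populations (see above); use the individual-level scheme or interpret the
  lattice directly.
- Window π treats unreported/invariant positions as absent: per-bp values are
  comparable across windows of one dataset but not across datasets with
  different site densities.
- AMOVA missing-data rescaling assumes loci are missing at random.
- Enrichment assumes the gene universe is the annotation supplied by the
  user; no live ontology/pathway retrieval is performed.
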