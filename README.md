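# popsweep

Population-genomic analysis of multi-sample SNP datasets with a two-level
population hierarchy (populations nested in geographic groups), aimed at
reduced-representation (RAD/GBS-style) or whole-genome genotype panels of
wild populations: site filtering, per-population diversity, pairwise and
hierarchical differentiation, PCA, and a windowed F_ST / π-ratio
selective-sweep scan with gene overlap and term enrichment. A
Balding–Nichols genotype simulator with embedded sweep windows provides
ground-truth data for validating every stage.

## What it computes

Given biallelic SNP genotypes for samples assigned to populations and groups:

- **Site filtering** — retain sites with minor-allele frequency MAF ≥ 0.05
  and call-rate integrity INT ≥ 0.5 (both thresholds configurable, inclusive).
- **Diversity** (per population): nucleotide diversity π (per-SNP mean of the
  unbiased gene diversity `(2n/(2n−1))(1−Σp_i²)`, or per-bp given a surveyed
  length), expected heterozygosity H_e, observed heterozygosity H_o, and
  polymorphism information content `PIC = 1 − Σp_i² − Σ_{i<j} 2p_i²p_j²`.
- **Pairwise F_ST** — Weir–Cockerham (1984) variance components a, b, c per
  site, combined across loci as the ratio of sums θ = Σa / Σ(a+b+c).
- **AMOVA** — hierarchical decomposition (among groups / among populations
  within groups / within populations) over allele units, with Φ_CT, Φ_SC,
  Φ_ST and level-appropriate permutation tests
  (p = (#{Φ* ≥ Φ} + 1)/(n_perm + 1)).
- **PCA** — Patterson-normalized genotype matrix (center 2p̂, scale
  √(2p̂(1−p̂)), mean imputation of missing calls), leading eigenvectors.
- **Sweep scan** — non-overlapping 10-kb windows; per-window weighted F_ST
  between two contrast gene pools and per-bp π within each pool;
  log₂(π_A/π_B); joint outliers = windows above the empirical 95% F_ST
  cutoff AND inside a 5% tail of the ratio distribution, with the tail sign
  giving the direction of selection (diversity-depleted pool). Genes
  intersecting selected windows by ≥ 1 bp are candidates; term
  over-representation is scored with one-sided hypergeometric tests at raw
  p < 0.05.

Input formats: VCF (GT field), popmap TSV (`sample  population  group`),
BED4/GFF3 gene intervals, TSV/GMT term→gene mappings. All outputs are TSV
with headers plus a manifest of parameters, versions, and input checksums.

## Worked example

Simulate a six-population design split into three gene pools, with two
sweep windows of intensity 0.85 embedded in the `highland` pool (the config
is `docs/example_sim.yaml`, annotated), then run the stages:

```sh
popsweep simulate --config docs/example_sim.yaml --out sim/demo
popsweep diversity --vcf sim/demo.vcf --popmap sim/demo.popmap.tsv --out diversity.tsv
popsweep fst       --vcf sim/demo.vcf --popmap sim/demo.popmap.tsv --out fst.tsv
popsweep amova     --vcf sim/demo.vcf --popmap sim/demo.popmap.tsv \
                   --grouping "[N1; N2; N3] [H1] [S1; S2]" --n-perm 1000 --seed 4 --out amova.tsv
popsweep sweep     --vcf sim/demo.vcf --popmap sim/demo.popmap.tsv \
                   --group-a north --group-b highland --genes sim/demo.genes.bed --out sweep_n_vs_h
```

`amova.tsv` (this run):

```text
source                           df   ss       sigma2   percent_variation  phi_statistic  phi        p_value
among_groups                     2    3530.76  25.7932  5.82857            Phi_CT         0.0582857  0.018981
among_populations_within_groups  3    1838.91  12.4975  2.8241             Phi_SC         0.0299889  0.000999001
within_populations               126  50934.3  404.24   91.3473            Phi_ST         0.0865267  0.000999001
```

Most variation (91.3%) lies within populations; the group level is modest but
significant (Φ_CT = 0.058, p ≈ 0.019 over 1,000 permutations), matching the
simulated divergence (f_ct = 0.06, f_sc = 0.03). The sweep scan prints its
realized cutoffs and calls:

```text
fst cutoff 0.143208; ratio tails (-0.257047, 0.359196); 2 selected windows
2 candidate genes
```

Both selected windows are exactly the two embedded sweep intervals
(chr1:200000–210000, chr2:50000–60000, direction `highland`: F_ST 0.16 and
0.38 against a 95% cutoff of 0.143, log₂ ratios 1.95 and 2.74 — the highland
pool lost ~4- to 7-fold diversity there), and the two candidate genes are the
genes overlapping those windows.

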