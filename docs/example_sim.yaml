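# Annotated simulation config for `popsweep simulate`.
# Groups of populations with diploid sample sizes: [group, [[population, n], ...]]
groups:
  - ["north", [["N1", 10], ["N2", 5], ["N3", 20]]]
  - ["southwest", [["S1", 16], ["S2", 3]]]
  - ["highland", [["H1", 12]]]
n_chromosomes: 3          # chromosomes chr1..chrN
chrom_length: 500000      # bp per chromosome
n_snps_per_chrom: 800     # SNP positions drawn uniformly without replacement
freq_law: ["uniform", 0.05, 0.95]   # ancestral frequency law; or ["beta", a, b]
f_ct: 0.06                # Balding-Nichols divergence of groups from the ancestor
f_sc: 0.03                # divergence of populations from their group
missing_rate: 0.05        # uniform random missing-call rate
gene_fraction: 0.2        # fraction of each chromosome tiled by genes
gene_length: 2000         # bp per gene interval
sweeps:                   # frequency-pull sweeps; target is a population or group
  - {chrom: chr1, start: 200000, end: 210000, target: highland, intensity: 0.85}
  - {chrom: chr2, start: 50000, end: 60000, target: highland, intensity: 0.85}
seed: 4                   # drives every random stream (label-keyed splitting)
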