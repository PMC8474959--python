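"""Structured-population genotype simulator with embedded selective sweeps.

The generator follows the Balding-Nichols model at two hierarchy levels.  For
each site an ancestral frequency p0 is drawn from a configurable law; each
group's frequency is Beta-distributed around p0 with divergence parameter
f_ct; each population's frequency is Beta-distributed around its group's
frequency with f_sc (f = 0 is handled as an exact identity).  Genotypes are
Binomial(2, p_pop) per individual (Hardy-Weinberg), with uniform random
missingness.

Sweep windows act directly on allele frequencies: inside a window targeting
population or group T with intensity s, T's frequency becomes
p' = (1 - s) * p + s * round(p) (round half up), pulling the frequency toward
the nearer fixation boundary.  This produces the joint low-diversity /
high-differentiation signal a windowed F_ST-pi-ratio scan detects, without
simulating selection trajectories or linkage.

Randomness is driven by a single global seed through a label-keyed
stream-splitting scheme: each (purpose, chromosome, population/group) tuple
hashes to its own child seed, so adding populations or chromosomes does not
perturb draws made for existing ones.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GeneSet, GenotypeDataset, PopulationMap, write_bed, write_popmap, write_vcf

logger = logging.getLogger(__name__)

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


def _rng(seed: int, *labels) -> np.random.Generator:
    """Child generator for a (seed, labels...) stream, stable across runs."""
    key = [
        int.from_bytes(hashlib.blake2s(str(l).encode(), digest_size=4).digest(), "little")
        for l in labels
    ]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


@dataclass(frozen=True)
class SweepSpec:
    """A frequency-pull sweep over [start, end) on ``chrom`` in target T."""

    chrom: str
    start: int
    end: int
    target: str  # population or group name
    intensity: float  # s in (0, 1]


@dataclass
class SimConfig:
    """Study design and generative parameters for :func:`simulate_dataset`.

    ``groups`` lists (group name, [(population name, n_diploids), ...]).
    ``freq_law`` is ("uniform", lo, hi) or ("beta", a, b) for the ancestral
    allele frequency.  ``f_ct``/``f_sc`` are the Balding-Nichols divergence
    parameters at the group and population-within-group levels.
    """

    groups: list[tuple[str, list[tuple[str, int]]]]
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_snps_per_chrom: int = 1_000
    freq_law: tuple = ("uniform", 0.05, 0.95)
    f_ct: float = 0.0
    f_sc: float = 0.05
    missing_rate: float = 0.02
    sweeps: list[SweepSpec] = field(default_factory=list)
    gene_fraction: float = 0.2
    gene_length: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.sweeps = [s if isinstance(s, SweepSpec) else SweepSpec(**s) for s in self.sweeps]
        pops = [p for _, members in self.groups for p, _ in members]
        if len(set(pops)) != len(pops):
            raise ValueError("population names must be unique")
        for rate, name in ((self.f_ct, "f_ct"), (self.f_sc, "f_sc"),
                           (self.missing_rate, "missing_rate")):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        group_names = {g for g, _ in self.groups}
        chroms = set(self.chrom_names)
        for sw in self.sweeps:
            if sw.target not in set(pops) | group_names:
                raise ValueError(f"sweep target {sw.target!r} is not a population or group")
            if sw.chrom not in chroms:
                raise ValueError(f"sweep chromosome {sw.chrom!r} not simulated")
            if not (0 <= sw.start < sw.end <= self.chrom_length):
                raise ValueError(f"sweep interval {sw.start}-{sw.end} out of bounds")
            if not 0.0 < sw.intensity <= 1.0:
                raise ValueError("sweep intensity must lie in (0, 1]")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def populations(self) -> list[tuple[str, str, int]]:
        """(population, group, n) triples in declaration order."""
        return [(p, g, n) for g, members in self.groups for p, n in members]

    def to_dict(self) -> dict:
        # JSON-native form (tuples -> lists) so truth files round-trip exactly
        return json.loads(json.dumps(asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["groups"] = [(g, [(p, int(n)) for p, n in members]) for g, members in d["groups"]]
        if "freq_law" in d:
            d["freq_law"] = tuple(d["freq_law"])
        d["sweeps"] = [SweepSpec(**s) if isinstance(s, dict) else s for s in d.get("sweeps", [])]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimTruth:
    """Generative ground truth for parameter- and sweep-recovery testing."""

    config: dict
    seed: int
    positions: dict[str, list[int]]            # 0-based site coordinates per chrom
    ancestral_freq: dict[str, list[float]]
    group_freq: dict[str, dict[str, list[float]]]       # chrom -> group -> freqs
    population_freq: dict[str, dict[str, list[float]]]  # chrom -> pop -> freqs (post-sweep)
    sweeps: list[dict]

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _ancestral_frequencies(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=size)
    if kind == "beta":
        return rng.beta(law[1], law[2], size=size)
    raise ValueError(f"unknown frequency law {kind!r}")


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Beta(p(1-f)/f, (1-p)(1-f)/f) draw; exact identity when f == 0."""
    if f == 0.0:
        return p.copy()
    scale = (1.0 - f) / f
    return rng.beta(np.maximum(p * scale, 1e-300), np.maximum((1.0 - p) * scale, 1e-300))


def _apply_sweep(p: np.ndarray, mask: np.ndarray, s: float) -> np.ndarray:
    pulled = (1.0 - s) * p + s * (p >= 0.5).astype(float)
    return np.where(mask, pulled, p)


def simulate_dataset(
    config: SimConfig,
) -> tuple[GenotypeDataset, PopulationMap, GeneSet, SimTruth]:
    """Simulate genotypes, population map, gene intervals, and ground truth."""
    seed = config.seed
    pops = config.populations
    group_names = [g for g, _ in config.groups]
    sample_names: list[str] = []
    sample_population: dict[str, str] = {}
    population_group: dict[str, str] = {}
    for pop, group, n in pops:
        population_group[pop] = group
        for i in range(n):
            name = f"{pop}_{i + 1:02d}"
            sample_names.append(name)
            sample_population[name] = pop

    chrom_frames = []
    call_blocks = []
    positions_t: dict[str, list[int]] = {}
    anc_t: dict[str, list[float]] = {}
    group_t: dict[str, dict[str, list[float]]] = {}
    pop_t: dict[str, dict[str, list[float]]] = {}
    for chrom in config.chrom_names:
        pos0 = np.sort(
            _rng(seed, "positions", chrom).choice(
                config.chrom_length, size=config.n_snps_per_chrom, replace=False
            )
        )
        p0 = _ancestral_frequencies(
            _rng(seed, "ancestral", chrom), config.freq_law, config.n_snps_per_chrom
        )
        group_freq = {
            g: _balding_nichols(_rng(seed, "group", g, chrom), p0, config.f_ct)
            for g in group_names
        }
        pop_freq: dict[str, np.ndarray] = {}
        for pop, group, _ in pops:
            pf = _balding_nichols(_rng(seed, "population", pop, chrom), group_freq[group], config.f_sc)
            for sw in config.sweeps:
                if sw.chrom != chrom or sw.target not in (pop, group):
                    continue
                mask = (pos0 >= sw.start) & (pos0 < sw.end)
                pf = _apply_sweep(pf, mask, sw.intensity)
            pop_freq[pop] = pf
        blocks = []
        for pop, _, n in pops:
            g = _rng(seed, "genotypes", pop, chrom).binomial(
                2, pop_freq[pop], size=(n, config.n_snps_per_chrom)
            )
            blocks.append(g.astype(np.int8))
        call_blocks.append(np.vstack(blocks))
        ref_alt = _rng(seed, "alleles", chrom).integers(0, len(_ALLELE_PAIRS),
                                                        size=config.n_snps_per_chrom)
        chrom_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos0 + 1,  # VCF 1-based
                    "id": [f"{chrom}_{p}" for p in pos0],
                    "ref": [_ALLELE_PAIRS[i][0] for i in ref_alt],
                    "alt": [_ALLELE_PAIRS[i][1] for i in ref_alt],
                }
            )
        )
        positions_t[chrom] = [int(x) for x in pos0]
        anc_t[chrom] = [float(x) for x in p0]
        group_t[chrom] = {g: [float(x) for x in f] for g, f in group_freq.items()}
        pop_t[chrom] = {p: [float(x) for x in f] for p, f in pop_freq.items()}

    calls = np.hstack(call_blocks)
    if config.missing_rate > 0:
        miss = _rng(seed, "missing").random(calls.shape) < config.missing_rate
        calls = np.where(miss, np.int8(-1), calls)
    variants = pd.concat(chrom_frames, ignore_index=True)
    dataset = GenotypeDataset(
        variants, sample_names, calls,
        chrom_lengths={c: config.chrom_length for c in config.chrom_names},
    )
    popmap = PopulationMap(sample_population, population_group)
    genes = _tile_genes(config)
    truth = SimTruth(
        config=config.to_dict(),
        seed=seed,
        positions=positions_t,
        ancestral_freq=anc_t,
        group_freq=group_t,
        population_freq=pop_t,
        sweeps=[asdict(s) for s in config.sweeps],
    )
    logger.info(
        "simulated %d samples x %d SNPs over %d chromosome(s)",
        dataset.n_samples, dataset.n_variants, config.n_chromosomes,
    )
    return dataset, popmap, genes, truth


def _tile_genes(config: SimConfig) -> GeneSet:
    """Non-overlapping gene intervals covering ~gene_fraction of each chromosome."""
    rows = []
    n_genes = int(config.chrom_length * config.gene_fraction // config.gene_length)
    for chrom in config.chrom_names:
        if n_genes == 0:
            continue
        step = config.chrom_length // n_genes
        for i in range(n_genes):
            start = i * step
            end = min(start + config.gene_length, config.chrom_length)
            rows.append((f"{chrom}_g{i + 1:04d}", chrom, start, end))
    return GeneSet(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]))


def write_outputs(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    genes: GeneSet,
    truth: SimTruth,
    out_prefix: str | os.PathLike,
) -> dict[str, str]:
    """Write VCF, popmap TSV, genes BED, and truth JSON under ``out_prefix``."""
    prefix = os.fspath(out_prefix)
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    paths = {
        "vcf": prefix + ".vcf",
        "popmap": prefix + ".popmap.tsv",
        "genes": prefix + ".genes.bed",
        "truth": prefix + ".truth.json",
    }
    write_vcf(dataset, paths["vcf"])
    write_popmap(popmap, paths["popmap"])
    write_bed(genes, paths["genes"])
    truth.to_json(paths["truth"])
    return paths
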