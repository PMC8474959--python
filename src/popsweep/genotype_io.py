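"""Genotype data model, VCF and annotation I/O, and site filtering.

The central container is :class:`GenotypeDataset`: a samples x variants matrix of
unphased diploid dosage codes (0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing)
over biallelic SNPs only.  All downstream statistics (diversity, F_ST, AMOVA,
PCA, windowed sweep scans) consume this container.

Coordinate conventions: VCF and GFF3 positions (1-based) are converted to the
internal 0-based half-open convention at the boundary and converted back on
output.  BED input is already 0-based half-open.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage code for a missing diploid call.
MISSING: int = -1

_VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP locus. ``pos`` is 1-based, as printed in a VCF."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("only single-nucleotide alleles are supported")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


class GenotypeDataset:
    """Samples x biallelic-SNP matrix of diploid dosage calls.

    Parameters
    ----------
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt`` (``pos`` 1-based).
    samples
        Unique sample identifiers, one per matrix row.
    calls
        ``(n_samples, n_variants)`` integer matrix with entries in
        {0, 1, 2, MISSING}.
    chrom_lengths
        Optional chromosome lengths in bp (e.g. from VCF contig headers).
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        samples: Sequence[str],
        calls: np.ndarray,
        chrom_lengths: Mapping[str, int] | None = None,
    ) -> None:
        variants = variants.reset_index(drop=True)
        missing_cols = [c for c in _VARIANT_COLUMNS if c not in variants.columns]
        if missing_cols:
            raise ValueError(f"variant table missing columns: {missing_cols}")
        samples = list(samples)
        if len(set(samples)) != len(samples):
            raise ValueError("sample identifiers must be unique")
        calls = np.asarray(calls)
        if calls.shape != (len(samples), len(variants)):
            raise ValueError(
                f"calls shape {calls.shape} != (n_samples={len(samples)}, "
                f"n_variants={len(variants)})"
            )
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be coded 0/1/2 or MISSING (-1)")
        order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(variants))):
            variants = variants.iloc[order].reset_index(drop=True)
            calls = calls[:, order]
        self.variants = variants
        self.samples = samples
        self.calls = np.ascontiguousarray(calls, dtype=np.int8)
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_indices(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in dataset") from None

    def genotype_counts(
        self, sample_idx: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-site (n_called, n_het, n_hom_alt) over the given sample rows."""
        g = self.calls if sample_idx is None else self.calls[sample_idx]
        n_called = (g >= 0).sum(axis=0)
        n_het = (g == 1).sum(axis=0)
        n_hom_alt = (g == 2).sum(axis=0)
        return n_called, n_het, n_hom_alt

    def alt_allele_frequency(
        self, sample_idx: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-site alt-allele frequency and called-diploid count.

        Frequencies use non-missing calls only; sites with no calls are NaN.
        """
        n_called, n_het, n_hom_alt = self.genotype_counts(sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, (n_het + 2.0 * n_hom_alt) / (2.0 * n_called), np.nan)
        return p, n_called

    def subset_sites(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            self.variants.loc[mask].reset_index(drop=True),
            self.samples,
            self.calls[:, mask],
            self.chrom_lengths,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variants.equals(other.variants)
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# Site statistics and filtering
# ---------------------------------------------------------------------------

def compute_site_stats(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-site minor-allele frequency, call-rate integrity, and call count.

    ``maf`` is computed from non-missing calls only and is NaN (undefined,
    never passing any filter) at sites with zero calls.  ``integrity`` is the
    fraction of samples with a non-missing call.
    """
    if dataset.n_samples < 1:
        raise ValueError("dataset has no samples")
    p, n_called = dataset.alt_allele_frequency()
    maf = np.minimum(p, 1.0 - p)
    integrity = n_called / dataset.n_samples
    return pd.DataFrame(
        {"maf": maf, "integrity": integrity, "n_called": n_called},
        index=dataset.variants.index,
    )


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_retained: int
    n_removed_maf: int
    n_removed_integrity: int
    n_undefined: int


def filter_sites(
    dataset: GenotypeDataset, maf_min: float = 0.05, int_min: float = 0.5
) -> tuple[GenotypeDataset, FilterReport]:
    """Retain sites with MAF >= ``maf_min`` AND integrity >= ``int_min``.

    Both thresholds are inclusive. Site order is preserved; sites with
    undefined MAF (zero calls) never pass. Raises if no site survives.
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= int_min <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    stats = compute_site_stats(dataset)
    maf_ok = stats["maf"].to_numpy() >= maf_min  # NaN compares False
    int_ok = stats["integrity"].to_numpy() >= int_min
    keep = maf_ok & int_ok
    report = FilterReport(
        n_input=dataset.n_variants,
        n_retained=int(keep.sum()),
        n_removed_maf=int((~maf_ok).sum()),
        n_removed_integrity=int((~int_ok).sum()),
        n_undefined=int(stats["maf"].isna().sum()),
    )
    logger.info(
        "filter_sites: %d/%d sites retained (maf<%g removed %d, integrity<%g removed %d)",
        report.n_retained, report.n_input, maf_min, report.n_removed_maf,
        int_min, report.n_removed_integrity,
    )
    if report.n_retained == 0:
        raise ValueError(
            f"no sites pass maf >= {maf_min} and integrity >= {int_min} "
            f"({report.n_input} input sites)"
        )
    return dataset.subset_sites(keep), report


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> GenotypeDataset:
    """Read biallelic SNP genotypes from a VCF into a :class:`GenotypeDataset`.

    Multiallelic and non-SNP records are skipped (logged count).  Phased and
    unphased GT separators are both accepted; phase is discarded.
    """
    from cyvcf2 import VCF

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    ids: list[str | None] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        ids.append(rec.ID)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gt = rec.gt_types.copy()  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = MISSING
        rows.append(gt.astype(np.int8))
    chrom_lengths = None
    try:
        if vcf.seqnames and vcf.seqlens:
            chrom_lengths = {c: int(l) for c, l in zip(vcf.seqnames, vcf.seqlens) if l > 0}
    except AttributeError:  # header without contig lengths
        pass
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"{path}: no biallelic SNP records retained")
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "id": ids, "ref": refs, "alt": alts}
    )
    calls = np.column_stack(rows)
    return GenotypeDataset(variants, samples, calls, chrom_lengths)


def write_vcf(dataset: GenotypeDataset, path: str | os.PathLike) -> None:
    """Write the dataset as a minimal GT-only VCF v4.2 (with contig headers)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popsweep\n")
        if dataset.chrom_lengths:
            for chrom, length in dataset.chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(dataset.samples) + "\n")
        var = dataset.variants
        calls = dataset.calls
        for j in range(dataset.n_variants):
            row = var.iloc[j]
            vid = row["id"] if isinstance(row["id"], str) and row["id"] else "."
            gts = "\t".join(_GT_STRINGS[int(calls[i, j])] for i in range(dataset.n_samples))
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

@dataclass
class PopulationMap:
    """Two-level design: samples belong to populations, populations to groups."""

    sample_population: dict[str, str]
    population_group: dict[str, str]

    def __post_init__(self) -> None:
        if not self.population_group:
            raise ValueError("population map must define at least one group")
        for pop in set(self.sample_population.values()):
            if pop not in self.population_group:
                raise ValueError(f"population {pop!r} has no group assignment")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.sample_population.values():
            seen.setdefault(pop, None)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for grp in self.population_group.values():
            seen.setdefault(grp, None)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.sample_population.items() if p == population]

    def populations_of(self, group: str) -> list[str]:
        return [p for p, g in self.population_group.items() if g == group]

    def samples_of_group(self, group: str) -> list[str]:
        pops = set(self.populations_of(group))
        return [s for s, p in self.sample_population.items() if p in pops]

    def validate_dataset(self, dataset: GenotypeDataset) -> None:
        """Every dataset sample must be mapped exactly once (dict keys are unique)."""
        unmapped = [s for s in dataset.samples if s not in self.sample_population]
        if unmapped:
            raise ValueError(f"samples missing from population map: {unmapped[:5]}")


def read_popmap(path: str | os.PathLike) -> PopulationMap:
    """Read a TSV with header ``sample<TAB>population<TAB>group``."""
    sample_population: dict[str, str] = {}
    population_group: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:3]] != ["sample", "population", "group"]:
            raise ValueError(f"{path}: expected header 'sample\\tpopulation\\tgroup'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            sample, pop, group = (p.strip() for p in parts[:3])
            if sample in sample_population:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            if pop in population_group and population_group[pop] != group:
                raise ValueError(
                    f"{path}:{lineno}: population {pop!r} assigned to multiple groups"
                )
            sample_population[sample] = pop
            population_group[pop] = group
    return PopulationMap(sample_population, population_group)


def write_popmap(popmap: PopulationMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tgroup\n")
        for sample, pop in popmap.sample_population.items():
            fh.write(f"{sample}\t{pop}\t{popmap.population_group[pop]}\n")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    """Gene intervals in the internal 0-based half-open convention."""

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "start", "end"]
        missing = [c for c in required if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        if (self.genes["start"] >= self.genes["end"]).any():
            raise ValueError("gene intervals must satisfy start < end")
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene id {dup!r}")

    def __len__(self) -> int:
        return len(self.genes)


def read_annotation(
    path: str | os.PathLike,
    fmt: str | None = None,
    feature_type: str = "gene",
) -> GeneSet:
    """Read gene intervals from BED4 (0-based half-open) or GFF3 (1-based inclusive).

    Format is auto-detected from the extension unless ``fmt`` ("bed"/"gff3") is
    given.  GFF3 records are restricted to ``feature_type`` rows.  Malformed
    lines are fatal with their line number.
    """
    path = os.fspath(path)
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = "gff3" if ext in (".gff", ".gff3") else "bed"
    records: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: BED4 needs 4 fields")
                chrom, start_s, end_s, gene_id = fields[:4]
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            else:
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: GFF3 needs 9 fields")
                chrom, _, ftype, start_s, end_s = fields[0], fields[1], fields[2], fields[3], fields[4]
                if ftype != feature_type:
                    continue
                try:
                    start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
                gene_id = _gff3_feature_id(fields[8]) or f"{feature_type}_{lineno}"
            if start >= end:
                raise ValueError(f"{path}:{lineno}: interval start >= end")
            records.append((gene_id, chrom, start, end))
    genes = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end"])
    return GeneSet(genes)


def _gff3_feature_id(attributes: str) -> str | None:
    for item in attributes.split(";"):
        item = item.strip()
        for key in ("ID=", "gene_id=", "Name="):
            if item.startswith(key):
                return item[len(key):]
    return None


def write_bed(genes: GeneSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for row in genes.genes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{row.gene_id}\n")
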