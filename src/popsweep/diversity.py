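"""Per-population genetic diversity summaries: pi, He, Ho, and PIC.

At a biallelic SNP the unbiased gene diversity (Nei's He with the small-sample
2n/(2n-1) correction) equals the average number of pairwise differences per
site among the 2n sampled alleles, so per-SNP nucleotide diversity is the mean
of per-site gene diversities.  PIC follows Botstein et al.'s definition.

Frequency-based statistics (pi, He, PIC) for a population are averaged over
sites with at least two called diploids in that population (the unbiased
estimator is undefined at n = 1); observed heterozygosity pools every
non-missing call.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset, PopulationMap

logger = logging.getLogger(__name__)


def site_gene_diversity(p: Sequence[float], n: int) -> float:
    """Nei's unbiased gene diversity (2n/(2n-1)) * (1 - sum p_i^2).

    Parameters
    ----------
    p : allele-frequency vector summing to 1
    n : number of diploid individuals sampled (>= 2)
    """
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("allele frequencies must sum to 1")
    if n < 2:
        raise ValueError("unbiased gene diversity requires n >= 2 diploids")
    return float(2 * n / (2 * n - 1) * (1.0 - np.sum(p**2)))


def pic(p: Sequence[float]) -> float:
    """Polymorphism information content: 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("allele frequencies must sum to 1")
    sq = p**2
    cross = (np.sum(sq) ** 2 - np.sum(sq**2)) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - np.sum(sq) - 2.0 * cross)


def _site_values(
    dataset: GenotypeDataset, sample_idx: np.ndarray, unbiased: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (gene diversity, PIC, usable mask) for the given samples."""
    p, n_called = dataset.alt_allele_frequency(sample_idx)
    usable = n_called >= 2
    q = 1.0 - p
    h = 2.0 * p * q
    if unbiased:
        with np.errstate(invalid="ignore", divide="ignore"):
            h = h * (2.0 * n_called) / (2.0 * n_called - 1.0)
    pic_site = 2.0 * p * q - 2.0 * (p * q) ** 2  # biallelic Botstein form
    return h, pic_site, usable


def nucleotide_diversity(
    dataset: GenotypeDataset,
    samples: Iterable[str] | None = None,
    surveyed_length: float | None = None,
    unbiased: bool = True,
) -> tuple[float, float | None]:
    """Nucleotide diversity for a sample subset.

    Returns ``(pi_snp, pi_bp)`` where ``pi_snp`` is the mean per-site gene
    diversity over usable sites and ``pi_bp`` divides the summed site values by
    ``surveyed_length`` (None when no length is supplied).
    """
    idx = None if samples is None else dataset.sample_indices(samples)
    if idx is not None and len(idx) == 0:
        raise ValueError("sample subset is empty")
    h, _, usable = _site_values(dataset, idx if idx is not None else np.arange(dataset.n_samples), unbiased)
    if not usable.any():
        raise ValueError("no usable sites (>= 2 called diploids) in subset")
    pi_snp = float(h[usable].mean())
    pi_bp = None
    if surveyed_length is not None:
        if surveyed_length <= 0:
            raise ValueError("surveyed_length must be positive")
        pi_bp = float(h[usable].sum() / surveyed_length)
    return pi_snp, pi_bp


def observed_heterozygosity(
    dataset: GenotypeDataset, samples: Iterable[str] | None = None
) -> float:
    """Fraction of het calls among all non-missing calls, pooled over sites."""
    idx = None if samples is None else dataset.sample_indices(samples)
    g = dataset.calls if idx is None else dataset.calls[idx]
    if g.size == 0:
        raise ValueError("sample subset is empty")
    n_called = int((g >= 0).sum())
    if n_called == 0:
        raise ValueError("no non-missing calls in subset")
    return float((g == 1).sum() / n_called)


def population_summary(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    surveyed_length: float | None = None,
    unbiased: bool = True,
) -> pd.DataFrame:
    """One diversity row per population plus an unweighted ``Mean`` row.

    Columns: population, group, n_samples, n_sites, pi_snp, (pi_bp,) he, ho,
    pic.  The mean row averages population rows without weighting by sample
    size.  Populations with fewer than two samples are reported with a warning.
    """
    popmap.validate_dataset(dataset)
    rows = []
    for pop in popmap.populations:
        samples = [s for s in popmap.samples_of(pop) if s in set(dataset.samples)]
        if not samples:
            raise ValueError(f"population {pop!r} has no samples in the dataset")
        if len(samples) < 2:
            logger.warning("population %s has only %d sample(s)", pop, len(samples))
        idx = dataset.sample_indices(samples)
        h, pic_site, usable = _site_values(dataset, idx, unbiased)
        if not usable.any():
            raise ValueError(f"population {pop!r} has no usable sites")
        row = {
            "population": pop,
            "group": popmap.population_group[pop],
            "n_samples": len(samples),
            "n_sites": int(usable.sum()),
            "pi_snp": float(h[usable].mean()),
        }
        if surveyed_length is not None:
            row["pi_bp"] = float(h[usable].sum() / surveyed_length)
        row["he"] = float(h[usable].mean())
        row["ho"] = observed_heterozygosity(dataset, samples)
        row["pic"] = float(pic_site[usable].mean())
        rows.append(row)
    table = pd.DataFrame(rows)
    numeric = table.columns.drop(["population", "group"])
    mean_row = {c: table[c].mean() for c in numeric}
    mean_row["population"] = "Mean"
    mean_row["group"] = ""
    table = pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
    return table
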