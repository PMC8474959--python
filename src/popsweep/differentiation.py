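"""Pairwise Weir-Cockerham F_ST, hierarchical AMOVA, and genotype-matrix PCA.

F_ST follows the Weir & Cockerham (1984) moment estimator theta for diploids:
per-site variance components a (among populations), b (among individuals
within populations), and c (within individuals) are combined across loci as a
ratio of sums, theta = sum(a) / sum(a + b + c).

AMOVA is the distance-based Excoffier-Smouse-Quattro decomposition with the
standard unbalanced-design expected-mean-square coefficients and
level-appropriate permutation tests.  Sums of squares are computed at the
allele level: each diploid is expanded into its two alleles (phase-free per
locus, since per-locus sums of squares depend only on allele counts), so the
within-population stratum pools among- and within-individual allelic
variation and Phi_ST is on the same scale as Weir-Cockerham theta.  A
genotype-dosage decomposition would instead estimate 2F/(1+F) under an
island model with divergence F, which is not comparable with F_ST.

PCA uses Patterson-style normalization (center by 2*p_hat, scale by
sqrt(2*p_hat*(1-p_hat))) with mean imputation of missing dosages.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset, PopulationMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WCSiteComponents:
    """Per-site Weir-Cockerham variance components (variance units)."""

    a: float  # among populations
    b: float  # among individuals within populations
    c: float  # within individuals
    informative: bool


def _wc_components_arrays(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized W&C (1984) components for r populations at many sites.

    Parameters are (r, n_sites) arrays: diploid counts ``n``, alt-allele
    frequencies ``p``, observed heterozygote proportions ``h``.  Returns
    (a, b, c, valid) where ``valid`` marks sites where the estimator is
    defined (every population sampled, mean sample size > 1, n_c > 0).
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[0]
    n_total = n.sum(axis=0)
    nbar = n_total / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_total - (n**2).sum(axis=0) / n_total) / (r - 1)
        pbar = (n * p).sum(axis=0) / n_total
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / n_total
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    valid = (n >= 1).all(axis=0) & (nbar > 1.0) & (nc > 0)
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, 0.0)
    return a, b, c, valid


def wc_site_components(
    genotype_counts: Sequence[Sequence[int]],
) -> WCSiteComponents:
    """W&C components at one biallelic site.

    ``genotype_counts`` holds one ``(n_hom_ref, n_het, n_hom_alt)`` triple per
    population; every population needs at least one called diploid.  A site
    that is monomorphic across the pooled populations returns (0, 0, 0) and is
    flagged uninformative.
    """
    counts = np.asarray(genotype_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 3:
        raise ValueError("expected one (hom_ref, het, hom_alt) triple per population")
    if counts.shape[0] < 2:
        raise ValueError("need >= 2 populations")
    n = counts.sum(axis=1)
    if (n < 1).any():
        raise ValueError("every population needs >= 1 called diploid")
    p = (counts[:, 1] + 2 * counts[:, 2]) / (2 * n)
    h = counts[:, 1] / n
    a, b, c, valid = _wc_components_arrays(
        n[:, None], p[:, None], h[:, None]
    )
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    pooled_p = float((n * p).sum() / n.sum())
    if pooled_p in (0.0, 1.0):
        return WCSiteComponents(0.0, 0.0, 0.0, informative=False)
    informative = bool(valid[0]) and (a + b + c) != 0.0
    return WCSiteComponents(a, b, c, informative)


@dataclass
class FstMatrix:
    """Symmetric pairwise multi-locus theta estimates (diagonal NaN)."""

    populations: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)


def _population_site_arrays(
    dataset: GenotypeDataset, sample_groups: dict[str, list[str]]
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Per-unit (n_called, p, het_rate) arrays, one row per sample group."""
    names = list(sample_groups)
    n = np.zeros((len(names), dataset.n_variants))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for i, name in enumerate(names):
        idx = dataset.sample_indices(sample_groups[name])
        n_called, n_het, n_hom_alt = dataset.genotype_counts(idx)
        n[i] = n_called
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = np.where(n_called > 0, (n_het + 2.0 * n_hom_alt) / (2.0 * n_called), np.nan)
            h[i] = np.where(n_called > 0, n_het / n_called, np.nan)
    return names, n, p, h


def multilocus_theta(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[float, int]:
    """Ratio-of-sums theta over informative sites; returns (theta, n_sites)."""
    a, b, c, valid = _wc_components_arrays(n, p, h)
    denom = a + b + c
    informative = valid & (denom > 0)
    if not informative.any():
        return float("nan"), 0
    theta = float(a[informative].sum() / denom[informative].sum())
    return theta, int(informative.sum())


def pairwise_fst(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    floor_negative: bool = False,
) -> FstMatrix:
    """Pairwise multi-locus Weir-Cockerham theta for every population pair.

    Small negative estimates are reported as estimated unless
    ``floor_negative`` truncates them at 0.  Pairs with no informative site
    are NaN with a warning.
    """
    popmap.validate_dataset(dataset)
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("pairwise F_ST requires >= 2 populations")
    names, n, p, h = _population_site_arrays(
        dataset, {pop: popmap.samples_of(pop) for pop in pops}
    )
    k = len(names)
    values = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            pair = [i, j]
            theta, n_sites = multilocus_theta(n[pair], p[pair], h[pair])
            if n_sites == 0:
                logger.warning("no informative sites for pair (%s, %s)", names[i], names[j])
            if floor_negative and np.isfinite(theta):
                theta = max(theta, 0.0)
            values[i, j] = values[j, i] = theta
    return FstMatrix(names, values)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Hierarchical variance decomposition with permutation significance."""

    grouping: list[list[str]]
    df: dict[str, int]
    ss: dict[str, float]
    sigma: dict[str, float]  # variance components a (among groups), b, c
    percent: dict[str, float]
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_ct: float
    p_sc: float
    p_st: float
    n_permutations: int
    seed: int | None
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("among_groups", self.df["among_groups"], self.ss["among_groups"],
             self.sigma["a"], self.percent["among_groups"], "Phi_CT", self.phi_ct, self.p_ct),
            ("among_populations_within_groups", self.df["among_populations"],
             self.ss["among_populations"], self.sigma["b"],
             self.percent["among_populations"], "Phi_SC", self.phi_sc, self.p_sc),
            ("within_populations", self.df["within_populations"],
             self.ss["within_populations"], self.sigma["c"],
             self.percent["within_populations"], "Phi_ST", self.phi_st, self.p_st),
        ]
        return pd.DataFrame(
            rows,
            columns=["source", "df", "ss", "sigma2", "percent_variation",
                     "phi_statistic", "phi", "p_value"],
        )


def expand_alleles(calls: np.ndarray) -> np.ndarray:
    """Expand an (N, S) dosage matrix into a (2N, S) allele matrix.

    Rows 2i and 2i+1 hold sample i's two alleles (0/1); a missing genotype
    yields two missing alleles.  Heterozygote allele order is arbitrary and
    irrelevant: every statistic derived from this matrix depends only on
    per-locus allele counts.
    """
    low = calls // 2          # 0,0,1 for dosages 0,1,2
    high = (calls + 1) // 2   # 0,1,1
    out = np.empty((2 * calls.shape[0], calls.shape[1]), dtype=np.int8)
    out[0::2] = low
    out[1::2] = high
    miss = calls < 0
    out[0::2][miss] = MISSING_ALLELE
    out[1::2][miss] = MISSING_ALLELE
    return out


MISSING_ALLELE = -1


def _allele_rows(ind_idx: np.ndarray) -> np.ndarray:
    """Allele-matrix row indices for the given individual indices."""
    return np.ravel(np.column_stack((2 * ind_idx, 2 * ind_idx + 1)))


def squared_distance_matrix(calls: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between the rows of a coded matrix.

    Negative entries are missing; pairs with missing data use
    pairwise-complete loci rescaled by (total loci / complete loci).
    """
    X = calls.astype(float)
    miss = calls < 0
    X[miss] = 0.0
    B = (~miss).astype(float)
    G = X @ X.T
    S = (X * X) @ B.T
    D2 = S + S.T - 2.0 * G
    L = calls.shape[1]
    Lij = B @ B.T
    if (Lij == 0).any():
        raise ValueError("a sample pair shares no called locus")
    D2 *= L / Lij
    np.fill_diagonal(D2, 0.0)
    return np.clip(D2, 0.0, None)


def _ss_within(D2: np.ndarray, index_sets: list[np.ndarray]) -> float:
    ss = 0.0
    for idx in index_sets:
        ss += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def _amova_components(
    D2: np.ndarray,
    pop_indices: list[np.ndarray],
    group_of_pop: np.ndarray,
    n_groups: int,
) -> tuple[dict, dict, dict]:
    """SS decomposition and variance components for one population/group layout."""
    N = D2.shape[0]
    P = len(pop_indices)
    G = n_groups
    sizes = np.array([len(idx) for idx in pop_indices], dtype=float)
    group_sets = [
        np.concatenate([pop_indices[p] for p in range(P) if group_of_pop[p] == g])
        for g in range(G)
    ]
    group_sizes = np.array([len(s) for s in group_sets], dtype=float)
    ss_total = D2.sum() / (2.0 * N)
    ss_wp = _ss_within(D2, pop_indices)
    ss_wg = _ss_within(D2, group_sets)
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp
    df = {
        "among_groups": G - 1,
        "among_populations": P - G,
        "within_populations": N - P,
    }
    ss = {
        "among_groups": ss_ag,
        "among_populations": ss_ap,
        "within_populations": ss_wp,
        "total": ss_total,
    }
    sum_np2_by_group = np.array(
        [sum(sizes[p] ** 2 for p in range(P) if group_of_pop[p] == g) for g in range(G)]
    )
    sigma_c = ss_wp / df["within_populations"] if df["within_populations"] > 0 else np.nan
    if G > 1:
        if df["among_populations"] > 0:
            n1 = (N - (sum_np2_by_group / group_sizes).sum()) / df["among_populations"]
            sigma_b = (ss_ap / df["among_populations"] - sigma_c) / n1
        else:
            sigma_b = 0.0  # each group holds one population: level collapses
        n2 = ((sum_np2_by_group / group_sizes).sum() - (sizes**2).sum() / N) / (G - 1)
        n3 = (N - (group_sizes**2).sum() / N) / (G - 1)
        sigma_a = (ss_ag / (G - 1) - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = 0.0
        if df["among_populations"] > 0:
            n1 = (N - (sizes**2).sum() / N) / df["among_populations"]
            sigma_b = (ss_ap / df["among_populations"] - sigma_c) / n1
        else:
            sigma_b = 0.0
    sigma = {"a": float(sigma_a), "b": float(sigma_b), "c": float(sigma_c)}
    return df, ss, sigma


def _phi_from_sigma(sigma: dict, n_groups: int) -> tuple[float, float, float]:
    a, b, c = sigma["a"], sigma["b"], sigma["c"]
    total = a + b + c
    phi_st = (a + b) / total if total != 0 else np.nan
    phi_sc = b / (b + c) if (b + c) != 0 else np.nan
    phi_ct = a / total if (n_groups > 1 and total != 0) else np.nan
    return phi_ct, phi_sc, phi_st


def amova(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    grouping: Sequence[Sequence[str]],
    n_perm: int = 10_000,
    seed: int | None = None,
    ct_permutation: str = "populations",
) -> AmovaResult:
    """Hierarchical AMOVA on squared Euclidean dosage distances.

    ``grouping`` partitions the population labels into groups.  Sums of
    squares are decomposed over allele units (2 per called genotype), so the
    within-population component pools among- and within-individual variation.
    Permutation p-values use (#{permuted >= observed} + 1) / (n_perm + 1)
    with level-appropriate schemes, always moving whole individuals (both
    alleles together): Phi_ST permutes individuals among populations across
    the whole sample; Phi_SC permutes individuals among populations within
    their group; Phi_CT permutes whole populations among groups
    (``ct_permutation="individuals"`` instead permutes individuals among
    groups, a continuous alternative useful when few populations exist).

    ``seed`` is required whenever ``n_perm >= 1``; it is logged and stored in
    the result for reproducibility.
    """
    popmap.validate_dataset(dataset)
    if ct_permutation not in ("populations", "individuals"):
        raise ValueError("ct_permutation must be 'populations' or 'individuals'")
    grouping = [list(g) for g in grouping]
    all_pops = [p for g in grouping for p in g]
    if sorted(all_pops) != sorted(popmap.populations):
        raise ValueError("grouping must partition the populations exactly")
    if n_perm >= 1 and seed is None:
        raise ValueError("a seed is required for permutation testing")
    flags: list[str] = []
    pops = all_pops
    G = len(grouping)
    group_of_pop = np.concatenate(
        [np.full(len(g), gi, dtype=int) for gi, g in enumerate(grouping)]
    )
    ind_pop_indices = [dataset.sample_indices(popmap.samples_of(p)) for p in pops]
    sizes = np.array([len(idx) for idx in ind_pop_indices])
    if (sizes == 0).any():
        empty = pops[int(np.argmin(sizes))]
        raise ValueError(f"population {empty!r} has no samples in the dataset")
    for gi, g in enumerate(grouping):
        if G > 1 and len(g) == 1:
            flags.append(f"group {gi} has a single population: Phi_SC degenerate there")
    D2 = squared_distance_matrix(expand_alleles(dataset.calls))
    pop_indices = [_allele_rows(idx) for idx in ind_pop_indices]
    df, ss, sigma = _amova_components(D2, pop_indices, group_of_pop, G)
    if ss["total"] == 0:
        flags.append("zero total sum of squares: Phi statistics undefined")
        nan = float("nan")
        return AmovaResult(grouping, df, ss, sigma,
                           {"among_groups": nan, "among_populations": nan,
                            "within_populations": nan},
                           nan, nan, nan, nan, nan, nan, n_perm, seed, flags)
    total = sigma["a"] + sigma["b"] + sigma["c"]
    percent = {
        "among_groups": 100.0 * sigma["a"] / total,
        "among_populations": 100.0 * sigma["b"] / total,
        "within_populations": 100.0 * sigma["c"] / total,
    }
    if min(sigma.values()) < 0:
        flags.append("negative variance component: percentages may fall outside [0, 100]")
    phi_ct, phi_sc, phi_st = _phi_from_sigma(sigma, G)

    p_ct = p_sc = p_st = float("nan")
    if n_perm >= 1:
        rng = np.random.default_rng(seed)
        logger.info("amova: %d permutations with seed %s", n_perm, seed)
        p_st = _permute_phi(D2, ind_pop_indices, group_of_pop, G, phi_st, n_perm, rng, "st")
        p_sc = _permute_phi(D2, ind_pop_indices, group_of_pop, G, phi_sc, n_perm, rng, "sc")
        if G > 1:
            if ct_permutation == "populations":
                p_ct = _permute_phi_ct_pops(D2, pop_indices, group_of_pop, G, phi_ct, n_perm, rng)
            else:
                p_ct = _permute_phi(D2, ind_pop_indices, group_of_pop, G, phi_ct, n_perm, rng, "ct_ind")
    return AmovaResult(grouping, df, ss, sigma, percent, phi_ct, phi_sc, phi_st,
                       p_ct, p_sc, p_st, n_perm, seed, flags)


def _split_sizes(order: np.ndarray, sizes: np.ndarray) -> list[np.ndarray]:
    bounds = np.cumsum(sizes)[:-1]
    return np.split(order, bounds)


def _permute_phi(
    D2: np.ndarray,
    pop_indices: list[np.ndarray],
    group_of_pop: np.ndarray,
    n_groups: int,
    observed: float,
    n_perm: int,
    rng: np.random.Generator,
    scheme: str,
) -> float:
    """Individual-level permutation schemes (phi_st, phi_sc, phi_ct-by-individuals).

    ``pop_indices`` are individual-level; whole individuals move and each
    assignment is mapped to allele rows before recomputing components.
    ``st``/``ct_ind`` reassign individuals to populations across the whole
    sample; ``sc`` reassigns individuals only among the populations of their
    own group.  Population sizes are preserved in every scheme.
    """
    if not np.isfinite(observed):
        return float("nan")
    sizes = np.array([len(idx) for idx in pop_indices])
    stat_index = {"st": 2, "sc": 1, "ct_ind": 0}[scheme]
    all_idx = np.concatenate(pop_indices)
    group_members: list[np.ndarray] = []
    if scheme == "sc":
        group_members = [np.where(group_of_pop == g)[0] for g in range(n_groups)]
    count = 0
    for _ in range(n_perm):
        perm_pop_indices: list[np.ndarray]
        if scheme == "sc":
            perm_pop_indices = [np.empty(0, dtype=int)] * len(pop_indices)
            for members in group_members:
                pool = np.concatenate([pop_indices[p] for p in members])
                pool = pool[rng.permutation(len(pool))]
                for p, chunk in zip(members, _split_sizes(pool, sizes[members])):
                    perm_pop_indices[p] = chunk
        else:
            order = all_idx[rng.permutation(len(all_idx))]
            perm_pop_indices = _split_sizes(order, sizes)
        perm_allele_indices = [_allele_rows(idx) for idx in perm_pop_indices]
        _, _, sigma = _amova_components(D2, perm_allele_indices, group_of_pop, n_groups)
        phi = _phi_from_sigma(sigma, n_groups)[stat_index]
        if np.isfinite(phi) and phi >= observed:
            count += 1
    return (count + 1) / (n_perm + 1)


def _permute_phi_ct_pops(
    D2: np.ndarray,
    pop_indices: list[np.ndarray],
    group_of_pop: np.ndarray,
    n_groups: int,
    observed: float,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permute whole populations among groups (group sizes in populations fixed)."""
    if not np.isfinite(observed):
        return float("nan")
    P = len(pop_indices)
    count = 0
    for _ in range(n_perm):
        perm_groups = group_of_pop[rng.permutation(P)]
        _, _, sigma = _amova_components(D2, pop_indices, perm_groups, n_groups)
        phi = _phi_from_sigma(sigma, n_groups)[0]
        if np.isfinite(phi) and phi >= observed:
            count += 1
    return (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    eigenvalues: np.ndarray          # descending
    coords: np.ndarray               # (n_samples, n_components) PC scores
    explained: np.ndarray            # proportion of total variance per axis
    n_sites_used: int


def pca(dataset: GenotypeDataset, n_components: int = 10) -> PcaResult:
    """PCA of the genotype matrix with Patterson-style normalization.

    Sites fixed across all called samples are excluded (warning); missing
    entries are imputed with the site mean dosage before centering.
    """
    if dataset.n_samples < 2 or dataset.n_variants < 2:
        raise ValueError("PCA requires >= 2 samples and >= 2 sites")
    p, n_called = dataset.alt_allele_frequency()
    keep = (n_called > 0) & (p > 0.0) & (p < 1.0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("pca: excluding %d monomorphic/uncalled sites", n_dropped)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 polymorphic sites available for PCA")
    X = dataset.calls[:, keep].astype(float)
    p = p[keep]
    miss = X < 0
    X[miss] = np.broadcast_to(2.0 * p, X.shape)[miss]
    X = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    C = X @ X.T / X.shape[1]
    w, v = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    k = min(n_components, len(w))
    explained = w / w.sum()
    coords = v[:, :k] * np.sqrt(np.clip(w[:k], 0.0, None))
    return PcaResult(w, coords, explained, int(keep.sum()))
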