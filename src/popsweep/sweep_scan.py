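"""Windowed F_ST / pi-ratio selective-sweep scan with gene overlap and enrichment.

The scan tiles each chromosome with non-overlapping windows (10 kb default),
computes per-window weighted F_ST between two contrast groups and per-bp
nucleotide diversity within each group, forms log2(pi_A / pi_B) (A is the
control/contrast group named first), and calls joint outliers: windows in the
upper empirical tail of F_ST that also fall in a tail of the ratio
distribution.  The upper ratio tail (diversity depleted in B) flags selection
in group B; the lower tail flags selection in group A.  Genes intersecting a
selected window by >= 1 bp are candidates; over-representation of terms among
candidates is scored with a one-sided hypergeometric test.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differentiation import _wc_components_arrays
from .genotype_io import GeneSet, GenotypeDataset, PopulationMap

logger = logging.getLogger(__name__)


def make_windows(
    chrom_lengths: Mapping[str, int], size: int = 10_000, offset: int = 0
) -> pd.DataFrame:
    """Tile each chromosome [0, L) with non-overlapping windows of ``size`` bp.

    The final window per chromosome is truncated at L.  A nonzero ``offset``
    anchors the tiling at that coordinate (with a leading partial window),
    which replicates 1-anchored windowing tools.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if not 0 <= offset < size:
        raise ValueError("offset must lie in [0, size)")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            logger.warning("chromosome %s has unknown length: skipped", chrom)
            continue
        if offset > 0 and offset < length:
            rows.append((chrom, 0, offset))
        start = offset if offset < length else 0
        for s in range(start, length, size):
            rows.append((chrom, s, min(s + size, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _infer_chrom_lengths(dataset: GenotypeDataset) -> dict[str, int]:
    if dataset.chrom_lengths:
        return dict(dataset.chrom_lengths)
    lengths = dataset.variants.groupby("chrom", sort=False)["pos"].max()
    return {c: int(l) for c, l in lengths.items()}  # 1-based max pos == length bound


def window_stats(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    group_a: str,
    group_b: str,
    window_size: int = 10_000,
    min_snps: int = 2,
    windows: pd.DataFrame | None = None,
    pseudocount: float = 0.0,
    offset: int = 0,
) -> pd.DataFrame:
    """Per-window F_ST and per-group per-bp pi for a two-group contrast.

    Returns a table with columns chrom, start, end, n_snps, fst, pi_a, pi_b,
    log2_ratio, informative, reason.  Windows with fewer than ``min_snps``
    SNPs, an undefined F_ST, or zero diversity in either group (unless a
    ``pseudocount`` is added to the window diversity sums) are marked
    uninformative.  Group A is the control/contrast group: the ratio is
    pi_A / pi_B.
    """
    if group_a == group_b:
        raise ValueError("contrast groups must be disjoint")
    for g in (group_a, group_b):
        if g not in popmap.groups:
            raise ValueError(f"group {g!r} not defined in population map")
        if len(popmap.samples_of_group(g)) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    idx_a = dataset.sample_indices(popmap.samples_of_group(group_a))
    idx_b = dataset.sample_indices(popmap.samples_of_group(group_b))
    if set(idx_a) & set(idx_b):
        raise ValueError("contrast groups share samples")

    if windows is None:
        windows = make_windows(_infer_chrom_lengths(dataset), window_size, offset)
    windows = windows.reset_index(drop=True)

    # per-site quantities for the pooled gene pools
    stats = {}
    for label, idx in (("a", idx_a), ("b", idx_b)):
        p, n_called = dataset.alt_allele_frequency(idx)
        n_het = (dataset.calls[idx] == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            h_obs = np.where(n_called > 0, n_het / n_called, np.nan)
            div = np.where(
                n_called >= 2,
                2.0 * p * (1.0 - p) * (2.0 * n_called) / (2.0 * n_called - 1.0),
                0.0,
            )
        stats[label] = {"p": p, "n": n_called, "h": h_obs, "div": np.nan_to_num(div)}
    n2 = np.vstack([stats["a"]["n"], stats["b"]["n"]])
    p2 = np.vstack([stats["a"]["p"], stats["b"]["p"]])
    h2 = np.vstack([stats["a"]["h"], stats["b"]["h"]])
    a, b, c, valid = _wc_components_arrays(n2, p2, h2)
    denom = a + b + c
    fst_ok = valid & (denom > 0)

    pos0 = dataset.variants["pos"].to_numpy() - 1  # 0-based site coordinates
    chrom = dataset.variants["chrom"].to_numpy()
    out = []
    for w in windows.itertuples(index=False):
        in_w = (chrom == w.chrom) & (pos0 >= w.start) & (pos0 < w.end)
        n_snps = int(in_w.sum())
        length = w.end - w.start
        pi_a = (stats["a"]["div"][in_w].sum() + pseudocount) / length
        pi_b = (stats["b"]["div"][in_w].sum() + pseudocount) / length
        sel = in_w & fst_ok
        fst = float(a[sel].sum() / denom[sel].sum()) if sel.any() else np.nan
        reason = ""
        if n_snps < min_snps:
            reason = "too few SNPs"
        elif not sel.any():
            reason = "no informative F_ST sites"
        elif pi_a <= 0 or pi_b <= 0:
            reason = "zero diversity"
        informative = reason == ""
        ratio = np.log2(pi_a / pi_b) if (pi_a > 0 and pi_b > 0) else np.nan
        out.append((w.chrom, w.start, w.end, n_snps, fst, pi_a, pi_b, ratio,
                    informative, reason))
    table = pd.DataFrame(
        out,
        columns=["chrom", "start", "end", "n_snps", "fst", "pi_a", "pi_b",
                 "log2_ratio", "informative", "reason"],
    )
    n_uninf = int((~table["informative"]).sum())
    if n_uninf:
        logger.info("window_stats: %d/%d windows uninformative", n_uninf, len(table))
    if not table["informative"].any():
        raise ValueError("no informative windows")
    table.attrs["group_a"] = group_a
    table.attrs["group_b"] = group_b
    return table


@dataclass
class SweepCall:
    """Joint-outlier windows per direction with the realized cutoffs."""

    group_a: str
    group_b: str
    fst_level: float
    tail_level: float
    fst_cutoff: float
    ratio_lower: float
    ratio_upper: float
    selected: pd.DataFrame  # window rows plus a `direction` column (group name)

    def windows_for(self, group: str) -> pd.DataFrame:
        return self.selected[self.selected["direction"] == group]


def call_selected_windows(
    stats: pd.DataFrame,
    fst_level: float = 0.95,
    tail_level: float = 0.05,
    group_a: str | None = None,
    group_b: str | None = None,
) -> SweepCall:
    """Call joint F_ST / pi-ratio outlier windows.

    Cutoffs are empirical quantiles (type-7 linear interpolation) over
    informative windows only; comparisons at the cutoffs are inclusive.
    Selected-for-B: fst >= q(fst_level) and log2_ratio >= q(1 - tail_level)
    (diversity depleted in B); selected-for-A mirrors with the lower tail.
    """
    group_a = group_a or stats.attrs.get("group_a", "A")
    group_b = group_b or stats.attrs.get("group_b", "B")
    info = stats[stats["informative"]]
    if len(info) < 20:
        raise ValueError(f"only {len(info)} informative windows: quantiles unreliable")
    fst = info["fst"].to_numpy(dtype=float)
    ratio = info["log2_ratio"].to_numpy(dtype=float)
    fst_cutoff = float(np.quantile(fst, fst_level))
    ratio_upper = float(np.quantile(ratio, 1.0 - tail_level))
    ratio_lower = float(np.quantile(ratio, tail_level))
    logger.info(
        "sweep cutoffs: fst >= %.6g; log2 ratio <= %.6g (for %s) or >= %.6g (for %s)",
        fst_cutoff, ratio_lower, group_a, ratio_upper, group_b,
    )
    pass_fst = fst >= fst_cutoff
    sel_b = info[pass_fst & (ratio >= ratio_upper)].copy()
    sel_b["direction"] = group_b
    sel_a = info[pass_fst & (ratio <= ratio_lower)].copy()
    sel_a["direction"] = group_a
    selected = pd.concat([sel_a, sel_b], ignore_index=True)
    return SweepCall(group_a, group_b, fst_level, tail_level, fst_cutoff,
                     ratio_lower, ratio_upper, selected)


def overlap_genes(call: SweepCall, genes: GeneSet) -> pd.DataFrame:
    """Candidate genes per direction: genes intersecting a selected window.

    Half-open intersection by >= 1 bp; a gene merely adjacent to a window
    boundary is not a candidate.  Each gene appears once per direction with
    the windows that recruited it.
    """
    rows = []
    for direction in (call.group_a, call.group_b):
        wins = call.windows_for(direction)
        if wins.empty:
            continue
        for g in genes.genes.itertuples(index=False):
            hits = wins[
                (wins["chrom"] == g.chrom)
                & (wins["start"] < g.end)
                & (g.start < wins["end"])
            ]
            if not hits.empty:
                labels = ";".join(
                    f"{h.chrom}:{h.start}-{h.end}" for h in hits.itertuples(index=False)
                )
                rows.append((g.gene_id, g.chrom, g.start, g.end, direction, labels))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "direction", "windows"]
    )


def enrich(
    candidates: Iterable[str],
    universe: Iterable[str],
    term2gene: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    For a term annotating K of N universe genes, with k of the m candidates in
    the term, p = P(X >= k) for X ~ Hypergeom(N, K, m).  Terms are flagged at
    raw p < ``alpha`` (no multiple-testing correction by default, matching the
    raw-p convention; ``bh_correct`` adds a Benjamini-Hochberg column).
    """
    universe_set = set(universe)
    candidate_set = set(candidates)
    stray = candidate_set - universe_set
    if stray:
        raise ValueError(f"candidate gene(s) absent from universe: {sorted(stray)[:5]}")
    N, m = len(universe_set), len(candidate_set)
    rows = []
    for term, members in term2gene.items():
        members = set(members) & universe_set
        K = len(members)
        if K == 0:
            logger.warning("term %s has no genes in the universe: skipped", term)
            continue
        k = len(members & candidate_set)
        p = float(hypergeom.sf(k - 1, N, K, m))
        rows.append((term, K, k, m, N, p))
    table = pd.DataFrame(
        rows, columns=["term", "term_size", "overlap", "candidate_size",
                       "universe_size", "p_value"],
    )
    if bh_correct and len(table):
        p = table["p_value"].to_numpy()
        order = np.argsort(p)
        adj = np.minimum.accumulate((p[order] * len(p) / (np.arange(len(p)) + 1))[::-1])[::-1]
        table["p_adjusted"] = np.clip(adj[np.argsort(order)], 0.0, 1.0)
    table["significant"] = table["p_value"] < alpha
    return table


def read_term2gene(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a term->gene mapping from a 2-column TSV or a GMT file."""
    path = os.fspath(path)
    mapping: dict[str, set[str]] = {}
    is_gmt = path.lower().endswith(".gmt")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if is_gmt:
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT needs term, description, genes")
                mapping.setdefault(fields[0], set()).update(g for g in fields[2:] if g)
            else:
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected term<TAB>gene")
                mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping
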