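"""Window tiling, joint-outlier calling, gene overlap, and enrichment."""
import math

import numpy as np
import pandas as pd
import pytest

from popsweep.genotype_io import GeneSet
from popsweep.sweep_scan import (
    call_selected_windows,
    enrich,
    make_windows,
    overlap_genes,
    window_stats,
)
from popsweep.synthetic_data import SimConfig, SweepSpec, simulate_dataset

from conftest import build_dataset, popmap_for


def _stats_frame(fst, ratio, group_a="A", group_b="B"):
    n = len(fst)
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * 10_000,
            "end": (np.arange(n) + 1) * 10_000,
            "n_snps": 5,
            "fst": fst,
            "pi_a": 1e-4,
            "pi_b": 1e-4,
            "log2_ratio": ratio,
            "informative": True,
            "reason": "",
        }
    )
    df.attrs.update(group_a=group_a, group_b=group_b)
    return df


class TestMakeWindows:
    def test_tiling_with_truncated_tail(self):
        w = make_windows({"chr1": 25_000})
        assert list(map(tuple, w[["start", "end"]].values)) == [
            (0, 10_000), (10_000, 20_000), (20_000, 25_000)
        ]

    def test_exact_single_window(self):
        w = make_windows({"chr1": 10_000})
        assert len(w) == 1 and tuple(w.iloc[0][["start", "end"]]) == (0, 10_000)

    def test_snp_at_boundary_position(self):
        # 1-based SNP position 10,000 -> 0-based 9,999 -> first window
        ds = build_dataset(
            np.array([[0, 1], [1, 0], [2, 1], [1, 1]]),
            positions=[10_000, 15_000],
            chrom_lengths={"chr1": 20_000},
        )
        pm = popmap_for(ds, {"A": 2, "B": 2}, {"A": "GA", "B": "GB"})
        stats = window_stats(ds, pm, "GA", "GB", min_snps=1)
        assert list(stats["n_snps"]) == [1, 1]

    def test_every_snp_covered_once(self, sim_two_group):
        ds, pm, *_ = sim_two_group
        stats = window_stats(ds, pm, "north", "south", min_snps=0)
        assert stats["n_snps"].sum() == ds.n_variants


class TestWindowStats:
    def test_identical_groups_null_window(self):
        # same genotype block in both groups: ratio exactly 0 and F_ST at the
        # slightly negative finite-sample null value, far from any outlier
        rng = np.random.default_rng(12)
        block = rng.integers(0, 3, size=(10, 2)).astype(np.int8)
        calls = np.vstack([block, block])
        ds = build_dataset(calls, positions=[100, 200], chrom_lengths={"chr1": 10_000})
        pm = popmap_for(ds, {"A": 10, "B": 10}, {"A": "GA", "B": "GB"})
        stats = window_stats(ds, pm, "GA", "GB", min_snps=1)
        row = stats.iloc[0]
        assert row["log2_ratio"] == pytest.approx(0.0)
        assert -0.12 < row["fst"] <= 0.0

    def test_zero_snp_window_uninformative(self):
        ds = build_dataset(
            np.array([[0, 1], [1, 1], [2, 0], [1, 2]]),
            positions=[100, 200],
            chrom_lengths={"chr1": 30_000},
        )
        pm = popmap_for(ds, {"A": 2, "B": 2}, {"A": "GA", "B": "GB"})
        stats = window_stats(ds, pm, "GA", "GB", min_snps=1)
        empty = stats[stats["start"] == 10_000].iloc[0]
        assert not empty["informative"]
        assert empty["pi_a"] == 0.0 and empty["pi_b"] == 0.0

    def test_monomorphic_group_zero_diversity_reason(self):
        calls = np.vstack([
            np.array([[0, 1], [2, 0]]),      # group A polymorphic at both sites
            np.zeros((2, 2), dtype=int),     # group B monomorphic
        ])
        ds = build_dataset(calls, positions=[100, 200], chrom_lengths={"chr1": 10_000})
        pm = popmap_for(ds, {"A": 2, "B": 2}, {"A": "GA", "B": "GB"})
        with pytest.raises(ValueError, match="no informative windows"):
            window_stats(ds, pm, "GA", "GB", min_snps=1)

    def test_sample_order_invariance(self, sim_two_group):
        ds, pm, *_ = sim_two_group
        stats1 = window_stats(ds, pm, "north", "south")
        perm = np.random.default_rng(0).permutation(ds.n_samples)
        ds2 = build_dataset(ds.calls[perm], chrom_lengths=ds.chrom_lengths)
        ds2.variants = ds.variants
        ds2.samples = [ds.samples[i] for i in perm]
        stats2 = window_stats(ds2, pm, "north", "south")
        pd.testing.assert_frame_equal(stats1, stats2)


class TestCallSelectedWindows:
    def test_distinct_values_quantile_count(self):
        rng = np.random.default_rng(4)
        fst = rng.permutation(np.linspace(0.01, 0.99, 1000))
        ratio = rng.normal(size=1000)
        call = call_selected_windows(_stats_frame(fst, ratio))
        n_pass_fst = int((fst >= call.fst_cutoff).sum())
        assert n_pass_fst == 50

    def test_joint_bound_by_marginals(self):
        rng = np.random.default_rng(9)
        fst, ratio = rng.random(500), rng.normal(size=500)
        call = call_selected_windows(_stats_frame(fst, ratio))
        n_fst = (fst >= call.fst_cutoff).sum()
        assert len(call.windows_for("B")) <= min(n_fst, (ratio >= call.ratio_upper).sum())
        assert len(call.windows_for("A")) <= min(n_fst, (ratio <= call.ratio_lower).sum())

    def test_saturation_every_window_selected(self):
        rng = np.random.default_rng(2)
        stats = _stats_frame(rng.random(100), rng.normal(size=100))
        call = call_selected_windows(stats, fst_level=0.0, tail_level=0.5)
        assert len(call.selected) >= 100  # median ties may land in both tails
        got = set(map(tuple, call.selected[["chrom", "start"]].values))
        assert got == set(map(tuple, stats[["chrom", "start"]].values))

    def test_too_few_windows_error(self):
        stats = _stats_frame(np.linspace(0, 1, 10), np.zeros(10))
        with pytest.raises(ValueError, match="informative windows"):
            call_selected_windows(stats)

    def test_embedded_sweeps_recovered(self):
        sweeps = [SweepSpec("chr1", s, s + 10_000, "B", 0.9)
                  for s in (100_000, 400_000, 700_000)]
        cfg = SimConfig(
            groups=[("A", [("A1", 15)]), ("B", [("B1", 15)])],
            n_chromosomes=1, chrom_length=1_000_000, n_snps_per_chrom=1000,
            f_ct=0.05, f_sc=0.0, missing_rate=0.02, sweeps=sweeps, seed=21,
        )
        ds, pm, genes, truth = simulate_dataset(cfg)
        stats = window_stats(ds, pm, "A", "B")
        call = call_selected_windows(stats)
        hits = set(map(tuple, call.windows_for("B")[["chrom", "start"]].values))
        assert {("chr1", s.start) for s in sweeps} <= hits


class TestOverlapGenes:
    def _call(self, windows):
        sel = pd.DataFrame(windows, columns=["chrom", "start", "end"])
        sel["direction"] = "B"
        from popsweep.sweep_scan import SweepCall

        return SweepCall("A", "B", 0.95, 0.05, 0.1, -1, 1, sel)

    def test_containment_and_partial_overlap(self):
        genes = GeneSet(pd.DataFrame(
            {"gene_id": ["inside", "partial", "adjacent"],
             "chrom": "chr1",
             "start": [100, 9_990, 10_000],
             "end": [200, 10_050, 10_050]}
        ))
        out = overlap_genes(self._call([("chr1", 0, 10_000)]), genes)
        assert set(out["gene_id"]) == {"inside", "partial"}

    def test_gene_recruited_with_window_labels(self):
        genes = GeneSet(pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "start": [9_000], "end": [21_000]}
        ))
        out = overlap_genes(self._call([("chr1", 0, 10_000), ("chr1", 20_000, 30_000)]), genes)
        assert len(out) == 1
        assert out.iloc[0]["windows"] == "chr1:0-10000;chr1:20000-30000"


def hypergeom_tail_oracle(N, K, m, k):
    """P(X >= k) by exhaustive enumeration of the hypergeometric pmf."""
    total = math.comb(N, m)
    return sum(
        math.comb(K, j) * math.comb(N - K, m - j)
        for j in range(k, min(K, m) + 1)
    ) / total


class TestEnrich:
    def test_full_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        term2gene = {"T": set(universe[:5])}
        out = enrich(universe[:5], universe, term2gene)
        assert out.iloc[0]["p_value"] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)
        assert out.iloc[0]["significant"]

    def test_zero_overlap_certain(self):
        universe = [f"g{i}" for i in range(10)]
        out = enrich(universe[5:8], universe, {"T": set(universe[:3])})
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_empty_term_skipped(self):
        universe = ["g1", "g2"]
        out = enrich(["g1"], universe, {"T": {"zz"}})
        assert out.empty

    def test_matches_enumeration_oracle_small_universes(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            N = int(rng.integers(4, 13))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            m = int(rng.integers(1, N + 1))
            term = set(rng.choice(universe, size=K, replace=False))
            cand = list(rng.choice(universe, size=m, replace=False))
            out = enrich(cand, universe, {"T": term})
            k = len(term & set(cand))
            assert out.iloc[0]["p_value"] == pytest.approx(
                hypergeom_tail_oracle(N, K, m, k), rel=1e-9
            )

    def test_candidate_outside_universe_fatal(self):
        with pytest.raises(ValueError, match="ghost"):
            enrich(["ghost"], ["g1"], {"T": {"g1"}})
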