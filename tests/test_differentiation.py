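"""F_ST, AMOVA, and PCA against independent transcriptions of the estimators."""
import numpy as np
import pytest

from popsweep.differentiation import (
    amova,
    multilocus_theta,
    pairwise_fst,
    pca,
    squared_distance_matrix,
    wc_site_components,
)
from popsweep.synthetic_data import SimConfig, simulate_dataset

from conftest import build_dataset, popmap_for


def wc_oracle(counts):
    """Straight-line transcription of the 1984 diploid variance components.

    Written independently of the vectorized implementation: scalar arithmetic
    over r populations with sample sizes n_i, alt frequencies p_i, observed
    het proportions h_i.
    """
    counts = [tuple(c) for c in counts]
    r = len(counts)
    n = [a + b + c for a, b, c in counts]
    p = [(b + 2 * c) / (2 * ni) for (a, b, c), ni in zip(counts, n)]
    h = [b / ni for (a, b, c), ni in zip(counts, n)]
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def random_count_configs(rng, n_configs, max_pops=4, max_n=30):
    configs = []
    while len(configs) < n_configs:
        r = rng.integers(2, max_pops + 1)
        counts = rng.integers(0, max_n, size=(r, 3))
        if (counts.sum(axis=1) >= 2).all():
            configs.append(counts)
    return configs


class TestWcComponents:
    def test_matches_straight_line_oracle(self):
        rng = np.random.default_rng(2024)
        for counts in random_count_configs(rng, 50):
            got = wc_site_components(counts)
            want = wc_oracle(counts)
            pooled_alt = counts[:, 1].sum() + 2 * counts[:, 2].sum()
            if pooled_alt in (0, 2 * counts.sum()):
                assert (got.a, got.b, got.c) == (0.0, 0.0, 0.0)
                continue
            assert got.a == pytest.approx(want[0], abs=1e-12)
            assert got.b == pytest.approx(want[1], abs=1e-12)
            assert got.c == pytest.approx(want[2], abs=1e-12)

    def test_fixed_difference_gives_theta_one(self):
        comp = wc_site_components([(10, 0, 0), (0, 0, 10)])
        assert comp.a / (comp.a + comp.b + comp.c) == pytest.approx(1.0)

    def test_identical_counts_nonpositive(self):
        comp = wc_site_components([(4, 4, 2), (4, 4, 2)])
        assert comp.a <= 0
        assert comp.a / (comp.a + comp.b + comp.c) <= 0

    def test_pooled_monomorphic_flagged(self):
        comp = wc_site_components([(5, 0, 0), (8, 0, 0)])
        assert (comp.a, comp.b, comp.c) == (0.0, 0.0, 0.0)
        assert not comp.informative


class TestPairwiseFst:
    def test_duplicated_population_near_zero(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.9, size=2000)
        genos = rng.binomial(2, p, size=(40, 2000)).astype(np.int8)
        ds = build_dataset(genos, positions=np.arange(1, 2001))
        pm = popmap_for(ds, {"A": 20, "B": 20})
        theta = pairwise_fst(ds, pm).to_frame().loc["A", "B"]
        assert abs(theta) < 0.02

    def test_all_fixed_differences(self):
        calls = np.vstack([np.zeros((5, 10)), np.full((5, 10), 2)])
        ds = build_dataset(calls)
        pm = popmap_for(ds, {"A": 5, "B": 5})
        assert pairwise_fst(ds, pm).to_frame().loc["A", "B"] == pytest.approx(1.0)

    def test_three_population_matrix_shape(self, sim_two_group):
        ds, pm, *_ = sim_two_group
        frame = pairwise_fst(ds, pm).to_frame()
        assert frame.shape == (3, 3)
        assert np.allclose(frame.values, frame.values.T, equal_nan=True)
        assert np.isnan(np.diag(frame.values)).all()
        off = frame.values[~np.eye(3, dtype=bool)]
        assert np.isfinite(off).all()

    def test_invariant_to_site_duplication(self, sim_two_group):
        ds, pm, *_ = sim_two_group
        t1 = pairwise_fst(ds, pm).values
        doubled = build_dataset(
            np.hstack([ds.calls, ds.calls]),
            positions=np.arange(1, 2 * ds.n_variants + 1),
        )
        doubled.samples = ds.samples  # keep identifiers aligned with the popmap
        t2 = pairwise_fst(doubled, pm).values
        assert np.allclose(t1, t2, equal_nan=True)


class TestAmova:
    def test_all_variance_between_populations(self):
        # each population internally identical, populations maximally distinct
        calls = np.vstack([np.zeros((6, 20)), np.full((6, 20), 2)])
        ds = build_dataset(calls)
        pm = popmap_for(ds, {"A": 6, "B": 6})
        res = amova(ds, pm, [["A", "B"]], n_perm=99, seed=0)
        assert res.sigma["c"] == pytest.approx(0.0, abs=1e-12)
        assert res.percent["among_populations"] == pytest.approx(100.0)
        assert res.phi_st == pytest.approx(1.0)

    def test_single_population_degenerate(self):
        ds = build_dataset(np.array([[0, 1, 2, 1], [2, 1, 0, 0]]).T)
        pm = popmap_for(ds, {"A": 4})
        res = amova(ds, pm, [["A"]], n_perm=0)
        assert res.ss["among_groups"] == pytest.approx(0.0, abs=1e-9)
        assert res.ss["among_populations"] == pytest.approx(0.0, abs=1e-9)

    def test_identical_individuals_flagged_undefined(self):
        # every individual carries the same homozygous multilocus genotype
        ds = build_dataset(np.tile([0, 2, 2, 0, 2], (8, 2)))
        pm = popmap_for(ds, {"A": 4, "B": 4})
        res = amova(ds, pm, [["A", "B"]], n_perm=0)
        assert np.isnan(res.phi_st)
        assert any("undefined" in f for f in res.flags)

    def test_ss_decomposition_exact(self, sim_two_group):
        ds, pm, *_ = sim_two_group
        res = amova(ds, pm, [["P1", "P2"], ["P3"]], n_perm=0)
        total = (
            res.ss["among_groups"]
            + res.ss["among_populations"]
            + res.ss["within_populations"]
        )
        assert total == pytest.approx(res.ss["total"], rel=1e-9)

    def test_permutation_pvalues_reproducible(self, sim_two_group):
        ds, pm, *_ = sim_two_group
        kw = dict(grouping=[["P1", "P2"], ["P3"]], n_perm=200, seed=77)
        r1 = amova(ds, pm, **kw)
        r2 = amova(ds, pm, **kw)
        assert (r1.p_ct, r1.p_sc, r1.p_st) == (r2.p_ct, r2.p_sc, r2.p_st)

    def test_seed_required_for_permutations(self, sim_two_group):
        ds, pm, *_ = sim_two_group
        with pytest.raises(ValueError, match="seed"):
            amova(ds, pm, [["P1", "P2"], ["P3"]], n_perm=10)

    def test_grouping_must_partition(self, sim_two_group):
        ds, pm, *_ = sim_two_group
        with pytest.raises(ValueError, match="partition"):
            amova(ds, pm, [["P1"], ["P3"]], n_perm=0)

    def test_phi_st_tracks_pairwise_theta(self):
        cfg = SimConfig(
            groups=[("G", [("A", 20), ("B", 20)])], n_chromosomes=1,
            chrom_length=10**6, n_snps_per_chrom=5000, f_ct=0.0, f_sc=0.15,
            missing_rate=0.0, seed=13,
        )
        ds, pm, *_ = simulate_dataset(cfg)
        theta = pairwise_fst(ds, pm).to_frame().loc["A", "B"]
        res = amova(ds, pm, [["A", "B"]], n_perm=0)
        assert np.sign(res.phi_st) == np.sign(theta)
        assert abs(res.phi_st - theta) <= 0.05

    def test_missing_data_distance_rescaling(self):
        # one masked locus: pairwise-complete distance rescaled by L/L_ij
        calls = np.array([[0, 2, 1], [2, -1, 1]], dtype=np.int8)
        D2 = squared_distance_matrix(calls)
        assert D2[0, 1] == pytest.approx((0 - 2) ** 2 * 3 / 2)


class TestPca:
    def test_two_cluster_separation(self):
        rng = np.random.default_rng(1)
        base = rng.binomial(2, 0.5, size=(1, 50))
        cluster1 = np.clip(base + rng.integers(0, 1, (10, 50)), 0, 2)
        cluster2 = 2 - cluster1
        ds = build_dataset(np.vstack([cluster1, cluster2]))
        res = pca(ds)
        pc1 = res.coords[:, 0]
        assert (np.sign(pc1[:10]) != np.sign(pc1[10:])).all()

    def test_duplicated_samples_same_coordinates(self):
        rng = np.random.default_rng(3)
        block = rng.integers(0, 3, size=(5, 30)).astype(np.int8)
        ds = build_dataset(np.vstack([block, block]))
        res = pca(ds)
        # compare axes carrying real variance (duplication halves the rank;
        # null-space eigenvectors are arbitrary)
        informative = res.eigenvalues[:4] > 1e-9
        assert informative.all()
        assert np.allclose(res.coords[:5, :4], res.coords[5:10, :4], atol=1e-8)

    def test_eigenvalues_match_dense_oracle(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
        ds = build_dataset(calls)
        res = pca(ds)
        # independent dense computation of the normalized covariance spectrum
        X = calls.astype(float)
        p = X.mean(axis=0) / 2.0
        keep = (p > 0) & (p < 1)
        X = (X[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        w = np.sort(np.linalg.eigvalsh(X @ X.T / keep.sum()))[::-1]
        assert np.allclose(res.eigenvalues, w, atol=1e-9)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_monomorphic_sites_excluded(self):
        calls = np.hstack([np.zeros((6, 3)), np.array([[0, 1, 2, 1, 0, 2]]).T,
                           np.array([[2, 1, 0, 0, 1, 2]]).T])
        res = pca(build_dataset(calls))
        assert res.n_sites_used == 2
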