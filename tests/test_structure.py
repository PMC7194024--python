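"""GRM construction, PCA, population tree, Weir-Cockerham FST."""

import numpy as np
import pytest

from conngen.io import make_dataset
from conngen.sim import PopulationConfig, SimConfig, hwe_genotypes, simulate
from conngen.structure import fst_scan, grm, pca, population_tree
from tests.conftest import random_dataset


def grm_oracle(calls, method):
    """Direct-formula GRM evaluation (independent of the implementation)."""
    x = calls.astype(float)
    p = x.mean(axis=0) / 2.0
    z = x - 2 * p
    if method == 1:
        return z @ z.T / (2 * (p * (1 - p)).sum())
    cols = [np.outer(z[:, j], z[:, j]) / (2 * p[j] * (1 - p[j])) for j in range(x.shape[1])]
    return np.mean(cols, axis=0)


class TestGRM:
    def test_single_heterozygous_individual_zero_diagonal(self):
        # two copies so observed p = 0.5 at every SNP, both individuals het
        calls = np.ones((2, 6), dtype=np.int8)
        for method in (1, 2):
            g = grm(make_dataset(calls), method=method)
            np.testing.assert_allclose(np.diag(g.values), 0.0, atol=1e-12)

    def test_small_matrix_matches_direct_formula(self, rng):
        calls = rng.integers(0, 3, size=(4, 3)).astype(np.int8)
        while (calls.mean(axis=0) % 2 == 0).any():  # avoid monomorphic columns
            calls = rng.integers(0, 3, size=(4, 3)).astype(np.int8)
        data = make_dataset(calls)
        for method in (1, 2):
            np.testing.assert_allclose(
                grm(data, method=method).values, grm_oracle(calls, method), atol=1e-12
            )

    def test_methods_agree_at_shared_maf(self, rng):
        """With one common MAF the per-SNP variance equals the mean variance."""
        p = 0.3
        calls = rng.binomial(2, p, size=(40, 200)).astype(np.int8)
        # force identical observed frequencies across SNPs
        base = np.array([0] * 4 + [1] * 12 + [2] * 24, dtype=np.int8)
        calls = np.stack([np.random.default_rng(j).permutation(base) for j in range(50)]).T
        data = make_dataset(calls)
        g1 = grm(data, method=1).values
        g2 = grm(data, method=2).values
        np.testing.assert_allclose(g1, g2, atol=1e-10)

    def test_hwe_calibration_diag_near_one(self):
        data = hwe_genotypes(400, 4000, seed=2)
        g = grm(data, method=1)
        assert np.diag(g.values).mean() == pytest.approx(1.0, abs=0.02)

    def test_monomorphic_rejected_for_method2(self):
        calls = np.array([[2, 1], [2, 1], [2, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="monomorphic"):
            grm(make_dataset(calls), method=2)

    def test_missing_calls_mean_imputed(self, rng):
        data = random_dataset(rng, n=20, m=50, missing_rate=0.1)
        g = grm(data, method=1)
        assert g.n_imputed_calls == int((data.calls == -1).sum())
        assert np.isfinite(g.values).all()


class TestPCA:
    def test_variance_fractions_sum_to_one(self, rng):
        data = random_dataset(rng, n=30, m=200)
        res = pca(grm(data, method=2), k=5)
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()

    def test_matches_sklearn_on_standardised_genotypes(self, rng):
        """PCA of the method-2 GRM equals sklearn PCA scores of the
        variance-standardised genotype matrix, up to sign and 1/sqrt(m)."""
        from sklearn.decomposition import PCA as SkPCA

        data = random_dataset(rng, n=25, m=300)
        poly = np.flatnonzero(data.calls.std(axis=0) > 0)
        data = data.subset(variant_idx=poly)
        g = grm(data, method=2)
        res = pca(g, k=4)

        x = data.calls.astype(float)
        p = x.mean(axis=0) / 2
        z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
        scores = SkPCA(n_components=4).fit_transform(z) / np.sqrt(data.n_variants)
        for c in range(4):
            ours = res.coordinates.iloc[:, c].to_numpy()
            theirs = scores[:, c]
            agree = min(
                np.abs(ours - theirs).max(), np.abs(ours + theirs).max()
            )
            assert agree < 1e-8

    def test_sample_order_invariance_up_to_sign(self, rng):
        data = random_dataset(rng, n=20, m=150)
        perm = rng.permutation(20)
        res_a = pca(grm(data, method=2), k=3)
        res_b = pca(grm(data.subset(sample_idx=perm), method=2), k=3)
        for c in range(3):
            a = res_a.coordinates.iloc[perm, c].to_numpy()
            b = res_b.coordinates.iloc[:, c].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_two_diverged_populations_separate_on_pc1(self):
        cfg = SimConfig(
            populations=[PopulationConfig("A", 100, 30), PopulationConfig("B", 100, 30)],
            topology=(100, "A", "B"),
            n_chromosomes=2,
            snps_per_chromosome=150,
            ancestral_n_e=100,
            burn_in_generations=20,
            pedigree_generations=0,
            seed=42,
        )
        out = simulate(cfg)
        data = out.genotypes
        maf = data.calls.mean(axis=0) / 2
        keep = np.flatnonzero((maf > 0.01) & (maf < 0.99))
        res = pca(grm(data.subset(variant_idx=keep), method=2), k=2)
        pc1 = res.coordinates["PC1"].to_numpy()
        pops = data.samples["population"].to_numpy()
        assert pc1[pops == "A"].max() < pc1[pops == "B"].min() or (
            pc1[pops == "B"].max() < pc1[pops == "A"].min()
        )

    def test_asymmetric_input_rejected(self):
        from conngen.structure import GRMatrix

        bad = GRMatrix(np.array([[1.0, 0.5], [0.2, 1.0]]), 2, 10, ["a", "b"], 0)
        with pytest.raises(ValueError, match="symmetric"):
            pca(bad)


class TestPopulationTree:
    def test_two_populations_single_merge_at_distance(self, rng):
        calls = rng.binomial(2, 0.4, size=(20, 100)).astype(np.int8)
        data = make_dataset(calls, populations=["A"] * 10 + ["B"] * 10)
        tree = population_tree(data)
        assert len(tree.linkage_matrix) == 1
        merged_a, merged_b, height = tree.merge_order()[0]
        assert merged_a | merged_b == {"A", "B"}
        assert height == pytest.approx(tree.distance.loc["A", "B"])
        assert tree.newick.endswith(";") and "A" in tree.newick

    def test_exchangeable_populations_equal_distances(self, rng):
        calls = rng.binomial(2, 0.4, size=(60, 400)).astype(np.int8)
        data = make_dataset(calls, populations=["A"] * 20 + ["B"] * 20 + ["C"] * 20)
        tree = population_tree(data)
        d = tree.distance
        vals = [d.loc["A", "B"], d.loc["A", "C"], d.loc["B", "C"]]
        assert max(vals) - min(vals) < 0.01

    def test_subsample_is_seeded(self, rng):
        calls = rng.binomial(2, 0.4, size=(40, 200)).astype(np.int8)
        data = make_dataset(calls, populations=["A"] * 20 + ["B"] * 20)
        t1 = population_tree(data, subsample=8, seed=5)
        t2 = population_tree(data, subsample=8, seed=5)
        np.testing.assert_allclose(t1.distance.values, t2.distance.values)


def wc_fst_oracle(n1, p1, h1, n2, p2, h2):
    """Scalar two-population Weir-Cockerham theta (independent evaluation)."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


def dataset_from_counts(hom1, het, hom2, pop):
    calls = np.array([2] * hom1 + [1] * het + [0] * hom2, dtype=np.int8)[:, None]
    calls = np.hstack([calls, calls])  # two identical SNPs for shape
    return make_dataset(calls, pos=[1000, 2000], populations=pop)


class TestFst:
    def test_single_population_sampled_twice_near_zero(self, rng):
        p = rng.uniform(0.2, 0.5, 500)
        a = make_dataset(rng.binomial(2, p, (60, 500)).astype(np.int8), populations="A")
        b = make_dataset(rng.binomial(2, p, (60, 500)).astype(np.int8), populations="B")
        res = fst_scan(a, b)
        assert abs(res.mean) < 0.01
        assert abs(res.weighted_mean) < 0.01

    def test_fixed_opposite_alleles_near_one(self):
        a = make_dataset(np.full((50, 2), 2, dtype=np.int8), populations="A")
        b = make_dataset(np.full((50, 2), 0, dtype=np.int8), populations="B")
        res = fst_scan(a, b)
        assert res.mean == pytest.approx(1.0, abs=0.02)

    def test_worked_counts_match_oracle(self):
        """hom1/het/hom2 = 30/10/10 vs 10/10/30."""
        a = dataset_from_counts(30, 10, 10, "A")
        b = dataset_from_counts(10, 10, 30, "B")
        res = fst_scan(a, b)
        expected = wc_fst_oracle(50, 0.7, 0.2, 50, 0.3, 0.2)
        assert res.table["fst"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a = random_dataset(rng, n=40, m=80)
        b_calls = rng.binomial(2, 0.35, (40, 80)).astype(np.int8)
        b = make_dataset(b_calls, pos=a.variants["pos"], variant_ids=list(a.variants["id"]))
        r1 = fst_scan(a, b)
        r2 = fst_scan(b, a)
        np.testing.assert_allclose(r1.table["fst"], r2.table["fst"], atol=1e-12)

    def test_outlier_rule_mean_plus_three_sd(self, rng):
        a = random_dataset(rng, n=60, m=300)
        b_calls = a.calls.copy()
        b_calls[:, 5] = 2 - b_calls[:, 5]  # plant one divergent SNP
        b = make_dataset(b_calls, pos=a.variants["pos"], variant_ids=list(a.variants["id"]))
        b.samples["id"] = [f"y{i}" for i in range(60)]
        res = fst_scan(a, b)
        assert (res.outliers["fst"] > res.threshold).all()
        assert res.threshold == pytest.approx(res.mean + 3 * res.sd)

    def test_frequency_ratio_estimator_flag(self, rng):
        a = random_dataset(rng, n=40, m=50)
        b_calls = rng.binomial(2, 0.3, (40, 50)).astype(np.int8)
        b = make_dataset(b_calls, pos=a.variants["pos"], variant_ids=list(a.variants["id"]))
        res = fst_scan(a, b, estimator="frequency-ratio")
        assert res.estimator == "frequency-ratio"
        assert (res.table["fst"] >= 0).all()
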