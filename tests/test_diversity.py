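"""Heterozygosity, MAF spectrum, IBS distance, ROH scan, inbreeding."""

import numpy as np
import pandas as pd
import pytest

from conngen.diversity import (
    ROHParams,
    heterozygosity,
    ibs_distance,
    inbreeding_excess_hom,
    inbreeding_grm,
    inbreeding_pedigree,
    inbreeding_roh,
    maf_spectrum,
    roh_length_categories,
    roh_min_snps,
    roh_scan,
)
from conngen.io import Pedigree, make_dataset
from conngen.sim import hwe_genotypes, plant_roh
from tests.conftest import random_dataset


class TestHeterozygosity:
    def test_observed_proportion(self):
        calls = np.full((1, 100), 0, dtype=np.int8)
        calls[0, :40] = 1
        stats = heterozygosity(make_dataset(calls))
        assert stats.ho_per_individual.iloc[0] == pytest.approx(0.4)

    def test_expected_at_half_frequency(self):
        stats = heterozygosity(make_dataset([[2], [0]]))  # p = 0.5
        assert stats.he_per_snp.iloc[0] == pytest.approx(0.5)

    def test_random_mating_ho_matches_he(self):
        data = hwe_genotypes(500, 800, seed=4)
        stats = heterozygosity(data)
        assert stats.mean_ho == pytest.approx(stats.mean_he, abs=0.01)

    def test_uncalled_individual_is_nan(self):
        stats = heterozygosity(make_dataset([[-1, -1], [1, 0]]))
        assert np.isnan(stats.ho_per_individual.iloc[0])


class TestMafSpectrum:
    def test_monomorphic_panel(self):
        poly, hist = maf_spectrum(make_dataset(np.full((4, 5), 2, dtype=np.int8)))
        assert poly == 0.0
        assert hist["n_snps"].sum() == 0

    def test_bin_placement(self):
        # MAFs 0.03, 0.07 -> hom/het mixes over 50 samples; easier to plant
        # frequencies directly via genotype columns
        n = 50
        calls = np.full((n, 3), 2, dtype=np.int8)
        calls[:3, 0] = 1  # maf 3/100 = 0.03 -> bin 1 (0.01, 0.05]
        calls[:7, 1] = 1  # maf 0.07 -> bin 2 (0.05, 0.10]
        calls[:23, 2] = 1  # maf 0.23 -> bin 5 (0.20, 0.25]
        _, hist = maf_spectrum(make_dataset(calls))
        assert hist.loc[hist["bin"] == 1, "n_snps"].iloc[0] == 1
        assert hist.loc[hist["bin"] == 2, "n_snps"].iloc[0] == 1
        assert hist.loc[hist["bin"] == 5, "n_snps"].iloc[0] == 1

    def test_uniform_founder_maf_flat_histogram(self, rng):
        p = rng.uniform(0.01, 0.5, 4000)
        calls = rng.binomial(2, p, size=(300, 4000)).astype(np.int8)
        poly, hist = maf_spectrum(make_dataset(calls, pos=np.arange(4000) * 100 + 1))
        assert poly > 0.97
        props = hist["n_snps"] / hist["n_snps"].sum()
        assert props.max() - props.min() < 0.06  # roughly flat


class TestIBSDistance:
    def test_identical_vectors_share_everything(self):
        calls = np.array([[0, 1, 2, 1], [0, 1, 2, 1]], dtype=np.int8)
        sim, dist = ibs_distance(make_dataset(calls))
        assert sim.iloc[0, 1] == pytest.approx(1.0)
        assert dist.iloc[0, 1] == pytest.approx(0.0)

    def test_opposite_homozygotes_share_nothing(self):
        calls = np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8)
        sim, dist = ibs_distance(make_dataset(calls))
        assert sim.iloc[0, 1] == pytest.approx(0.0)
        assert dist.iloc[0, 1] == pytest.approx(1.0)

    def test_worked_ibs_counts(self):
        """IBS2 x2, IBS1 x1, IBS0 x1 over 4 SNPs -> D_ST = 2.5/4."""
        calls = np.array([[2, 1, 2, 0], [2, 1, 1, 2]], dtype=np.int8)
        sim, _ = ibs_distance(make_dataset(calls))
        assert sim.iloc[0, 1] == pytest.approx(0.625)

    def test_symmetric_zero_diagonal_matches_pair_loop(self, rng):
        data = random_dataset(rng, n=12, m=30, missing_rate=0.1)
        sim, dist = ibs_distance(data)
        np.testing.assert_allclose(sim.values, sim.values.T)
        np.testing.assert_allclose(np.diag(dist.values), 0.0)
        for i, j in [(0, 5), (3, 11), (2, 7)]:
            gi, gj = data.calls[i].astype(float), data.calls[j].astype(float)
            ok = (data.calls[i] != -1) & (data.calls[j] != -1)
            manual = np.mean(1 - np.abs(gi[ok] - gj[ok]) / 2)
            assert sim.iloc[i, j] == pytest.approx(manual)


class TestRohMinSnps:
    def test_worked_formula_value(self):
        # ceil(ln(0.05 / (1000 * 10)) / ln(0.5)) = ceil(17.6) = 18
        assert roh_min_snps(1000, 10, 0.5, alpha=0.05) == 18

    def test_monotone_decreasing_in_alpha(self):
        counts = [roh_min_snps(1000, 10, 0.3, alpha=a) for a in (0.001, 0.05, 0.5, 0.99)]
        assert counts == sorted(counts, reverse=True)

    def test_monotone_in_problem_size(self):
        base = roh_min_snps(1000, 10, 0.4)
        assert roh_min_snps(1000, 20, 0.4) >= base
        assert roh_min_snps(2000, 10, 0.4) >= base

    def test_degenerate_het_rejected(self):
        with pytest.raises(ValueError):
            roh_min_snps(1000, 10, 0.0)


def het_background_dataset(n_ind=3, n_snps=2000, spacing=25_000):
    """Fully heterozygous phased individuals on a uniform 25 kb map."""
    haps = np.zeros((n_ind, 2, n_snps), dtype=np.int8)
    haps[:, 1, :] = 1
    return make_dataset(
        haps.sum(axis=1),
        pos=np.arange(n_snps) * spacing + 1,
        haplotypes=haps,
        sample_ids=[f"i{k}" for k in range(n_ind)],
    )


class TestRohScan:
    def test_fully_heterozygous_yields_nothing(self):
        data = het_background_dataset()
        assert roh_scan(data, ROHParams(min_snps=50)) == []

    def test_planted_tract_recovered_within_one_interval(self):
        data = het_background_dataset()
        pos = data.variants["pos"].to_numpy()
        a, b = 400, 520  # 120 SNPs, 3000 kb
        planted = plant_roh(data, "i0", "1", int(pos[a]), int(pos[b]))
        segs = roh_scan(planted, ROHParams(min_snps=50))
        assert len(segs) == 1
        seg = segs[0]
        assert seg.individual == "i0"
        assert abs(seg.start_bp - pos[a]) <= 25_000
        assert abs(seg.end_bp - pos[b]) <= 25_000
        assert seg.het_calls_inside == 0

    def test_two_tracts_beyond_max_gap_stay_separate(self):
        data = het_background_dataset()
        pos = data.variants["pos"].to_numpy()
        planted = plant_roh(data, "i0", "1", int(pos[200]), int(pos[300]))
        planted = plant_roh(planted, "i0", "1", int(pos[390]), int(pos[490]))
        # gap 300..390 = 2250 kb of heterozygous SNPs > max_gap
        segs = roh_scan(planted, ROHParams(min_snps=50))
        assert len(segs) == 2

    def test_invariant_to_individual_order_and_allele_relabeling(self):
        data = het_background_dataset(n_ind=4)
        pos = data.variants["pos"].to_numpy()
        planted = plant_roh(data, "i2", "1", int(pos[100]), int(pos[220]))
        segs = roh_scan(planted, ROHParams(min_snps=50))
        reordered = planted.subset(sample_idx=[3, 2, 1, 0])
        segs_r = roh_scan(reordered, ROHParams(min_snps=50))
        flipped = planted.copy()
        flipped.haplotypes = None
        flipped.calls = 2 - flipped.calls
        segs_f = roh_scan(flipped, ROHParams(min_snps=50))
        as_tuples = lambda ss: sorted((s.individual, s.start_bp, s.end_bp) for s in ss)
        assert as_tuples(segs) == as_tuples(segs_r) == as_tuples(segs_f)

    def test_summary_and_categories(self):
        data = het_background_dataset()
        pos = data.variants["pos"].to_numpy()
        planted = plant_roh(data, "i0", "1", int(pos[100]), int(pos[220]))  # 3.0 Mb
        planted = plant_roh(planted, "i1", "1", int(pos[500]), int(pos[980]))  # 12 Mb
        segs = roh_scan(planted, ROHParams(min_snps=50))
        summary = roh_summary(segs, planted)
        assert summary["n_total"].sum() == 2
        cats = roh_length_categories(segs)
        assert cats.loc[cats["category_mb"] == "2.5-5", "n_segments"].iloc[0] == 1
        assert cats.loc[cats["category_mb"] == ">10", "n_segments"].iloc[0] == 1


from conngen.diversity import roh_summary  # noqa: E402  (used above)


class TestInbreedingMarkers:
    def test_all_het_individual_forced_minus_one(self):
        # 4 SNPs at p = 0.5 with many samples -> F_E close to (0 - 2)/(4 - 2)
        rngl = np.random.default_rng(0)
        calls = rngl.binomial(2, 0.5, size=(200, 4)).astype(np.int8)
        calls[0] = 1
        f = inbreeding_excess_hom(make_dataset(calls))
        assert f.iloc[0] == pytest.approx(-1.0, abs=0.1)

    def test_zero_excess_gives_zero(self):
        data = hwe_genotypes(800, 500, seed=9)
        f = inbreeding_excess_hom(data)
        assert f.mean() == pytest.approx(0.0, abs=0.02)

    def test_grm_inbreeding_mean_zero_under_random_mating(self):
        data = hwe_genotypes(400, 2000, seed=10)
        f = inbreeding_grm(data)
        assert f.mean() == pytest.approx(0.0, abs=0.02)

    def test_fe_fg_positively_correlated(self):
        """Both marker estimators track per-individual autozygosity: with
        true F varying over individuals they agree strongly."""
        rngl = np.random.default_rng(11)
        n, m = 300, 3000
        p = rngl.uniform(0.1, 0.5, m)
        true_f = rngl.uniform(0, 0.3, n)
        ibd = rngl.random((n, m)) < true_f[:, None]
        one = rngl.binomial(1, p, size=(n, m))
        two = one + rngl.binomial(1, p, size=(n, m))
        calls = np.where(ibd, 2 * one, two).astype(np.int8)
        data = make_dataset(calls, pos=np.arange(m) * 1000 + 1)
        fe = inbreeding_excess_hom(data)
        fg = inbreeding_grm(data)
        assert np.corrcoef(fe, fg)[0, 1] > 0.8
        assert np.corrcoef(fe, true_f)[0, 1] > 0.8


class TestInbreedingRoh:
    def test_no_segments_zero(self):
        data = het_background_dataset()
        f = inbreeding_roh([], data)
        assert (f == 0).all()

    def test_tiling_segments_reach_one(self):
        data = het_background_dataset(n_ind=1)
        pos = data.variants["pos"].to_numpy()
        planted = plant_roh(data, "i0", "1", int(pos[0]), int(pos[-1]))
        segs = roh_scan(planted, ROHParams(min_snps=50))
        f = inbreeding_roh(segs, planted)
        assert f.iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_monotone_under_added_tracts(self):
        data = het_background_dataset(n_ind=1)
        pos = data.variants["pos"].to_numpy()
        one = plant_roh(data, "i0", "1", int(pos[100]), int(pos[200]))
        two = plant_roh(one, "i0", "1", int(pos[600]), int(pos[800]))
        f1 = inbreeding_roh(roh_scan(one, ROHParams(min_snps=50)), one)
        f2 = inbreeding_roh(roh_scan(two, ROHParams(min_snps=50)), two)
        assert f2.iloc[0] > f1.iloc[0]


def tabular_a_matrix(sire, dam):
    """Full numerator-relationship matrix by the tabular method (oracle)."""
    n = sire.size
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        a_sd = a[s, d] if s >= 0 and d >= 0 else 0.0
        a[i, i] = 1.0 + 0.5 * a_sd
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * a[s, :i]
        if d >= 0:
            row += 0.5 * a[d, :i]
        a[i, :i] = row
        a[:i, i] = row
    return a


def random_pedigree(rng, n=200, founder_prob=0.15):
    ids = [f"x{i}" for i in range(n)]
    rows = []
    for i in range(n):
        if i < 5 or rng.random() < founder_prob:
            rows.append((ids[i], "0", "0"))
        else:
            s, d = rng.integers(0, i, size=2)
            rows.append((ids[i], ids[s], ids[d]))
    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam"]))


class TestInbreedingPedigree:
    def test_outbred_offspring_zero(self):
        ped = Pedigree(
            pd.DataFrame(
                {"id": ["a", "b", "c"], "sire": ["0", "0", "a"], "dam": ["0", "0", "b"]}
            )
        )
        assert inbreeding_pedigree(ped)["c"] == 0.0

    def test_full_sib_offspring_quarter(self):
        rows = [
            ("a", "0", "0"),
            ("b", "0", "0"),
            ("s1", "a", "b"),
            ("s2", "a", "b"),
            ("kid", "s1", "s2"),
        ]
        ped = Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam"]))
        f = inbreeding_pedigree(ped)
        assert f["kid"] == pytest.approx(0.25, abs=1e-14)

    def test_matches_tabular_method_on_random_pedigrees(self, rng):
        for rep in range(8):
            ped = random_pedigree(rng, n=150)
            f = inbreeding_pedigree(ped)
            order, sire, dam = ped.parent_arrays()
            a = tabular_a_matrix(sire, dam)
            np.testing.assert_allclose(
                f[order].to_numpy(), np.diag(a) - 1.0, atol=1e-12
            )

    def test_f_ped_tracks_true_autozygosity(self, rng):
        """Across families with F in {0, 1/8, 1/4, 3/8}, pedigree F and the
        gene-dropped autozygous fraction correlate strongly."""
        from conngen.sim import autozygous_fraction, gene_drop

        rows, focal = [], []
        for fam in range(12):
            p = f"f{fam}"
            rows += [(p + "a", "0", "0"), (p + "b", "0", "0"), (p + "c", "0", "0")]
            rows += [(p + "s1", p + "a", p + "b"), (p + "s2", p + "a", p + "b")]
            rows += [(p + "h1", p + "a", p + "c")]
            rows += [(p + "k0", p + "s1", p + "c")]  # outbred, F = 0
            rows += [(p + "k1", p + "s1", p + "h1")]  # half-sib parents, F = 1/8
            rows += [(p + "k2", p + "s1", p + "s2")]  # full-sib parents, F = 1/4
            rows += [(p + "k3", p + "k2", p + "s1")]  # parent-offspring w/ inbred
            focal += [p + k for k in ("k0", "k1", "k2", "k3")]
        ped = Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam"]))
        data, tracts = gene_drop(ped, n_chromosomes=10, snps_per_chromosome=120, seed=3)
        chrom = data.variants["chrom"].astype(str).to_numpy()
        pos = data.variants["pos"].to_numpy()
        f_ped = inbreeding_pedigree(ped)[focal].to_numpy()
        realised = np.array([autozygous_fraction(tracts[i], chrom, pos) for i in focal])
        assert np.corrcoef(f_ped, realised)[0, 1] > 0.7
        assert realised.mean() == pytest.approx(f_ped.mean(), abs=0.04)
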