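import numpy as np
import pytest

from _oracles import pearson_brute, tajima_constants
from trimark import snp_popgen
from trimark.data_io import DistanceMatrix, GenotypeMatrix
from trimark.synthetic_data import PopulationSpec, simulate_genotypes


def gm(calls, pos=None, chrom=None, depth=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        [f"s{i}" for i in range(n)],
        np.array([chrom or "1"] * m, dtype=object) if not isinstance(chrom, (list, np.ndarray))
        else np.asarray(chrom, dtype=object),
        np.asarray(pos if pos is not None else np.arange(1, m + 1) * 100),
        calls, depth=depth)


class TestFilterVariants:
    def test_low_maf_site_removed(self):
        # site 0: alt freq 0.03 (3/100); site 1: 0.3
        calls = np.zeros((50, 2), dtype=np.int8)
        calls[:3, 0] = 1
        calls[:30, 1] = 1
        g = gm(calls)
        out = snp_popgen.filter_variants(g, min_maf=0.05)
        assert out.n_sites == 1
        assert out.pos.tolist() == [200]

    def test_identity_when_nothing_filters(self, small_cohort):
        g, _, _ = small_cohort
        out = snp_popgen.filter_variants(g, min_depth=0, max_missing=1.0,
                                         min_maf=0.0)
        np.testing.assert_array_equal(out.calls, g.calls)

    def test_depth_filter_masks_before_site_filters(self):
        calls = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8)
        depth = np.array([[1, 5], [1, 5], [5, 5], [5, 5]])
        g = gm(calls, depth=depth)
        out = snp_popgen.filter_variants(g, min_depth=2, max_missing=0.3,
                                         min_maf=0.0)
        # site 0 lost half its calls -> missing 0.5 > 0.3 -> dropped
        assert out.n_sites == 1

    def test_survivors_match_direct_bookkeeping(self):
        g, _, _ = simulate_genotypes(
            PopulationSpec(n_samples=80, n_sites=1000, missing_rate=0.1,
                           seed=9))
        out = snp_popgen.filter_variants(g, max_missing=0.3, min_maf=0.05)
        ok = g.calls != -1
        n_ok = ok.sum(axis=0)
        alt = np.where(ok, g.calls, 0).sum(axis=0) / (2 * n_ok)
        maf = np.minimum(alt, 1 - alt)
        expected = ((1 - n_ok / 80 <= 0.3) & (maf >= 0.05)).sum()
        assert out.n_sites == expected

    def test_everything_removed_warns_not_raises(self):
        g = gm(np.zeros((4, 3)))
        with pytest.warns(UserWarning, match="all sites removed"):
            out = snp_popgen.filter_variants(g, min_maf=0.05)
        assert out.n_sites == 0


class TestMafSpectrum:
    def test_monomorphic_site(self):
        assert snp_popgen.maf_spectrum(gm([[0], [0], [0]])).maf[0] == 0.0

    def test_half_half(self):
        s = snp_popgen.maf_spectrum(gm([[0], [1], [2]]))
        assert s.maf[0] == pytest.approx(0.5)

    def test_folding(self):
        s = snp_popgen.maf_spectrum(gm([[2], [2], [2], [1]]))
        assert s.maf[0] == pytest.approx(0.125)

    def test_all_missing_site_rejected(self):
        with pytest.raises(ValueError, match="non-missing"):
            snp_popgen.maf_spectrum(gm([[-1], [-1]]))


class TestHetRate:
    def test_all_heterozygous(self):
        assert snp_popgen.het_rate(gm(np.ones((4, 5)))) == 1.0

    def test_matches_direct_count(self, small_cohort):
        g, _, _ = small_cohort
        het = (g.calls == 1).sum()
        ok = (g.calls != -1).sum()
        assert snp_popgen.het_rate(g) == pytest.approx(het / ok)


class TestIbsDistance:
    def test_identical_rows(self):
        d = snp_popgen.ibs_distance(gm([[0, 1, 2], [0, 1, 2]]))
        assert d.values[0, 1] == 0.0

    def test_opposite_homozygotes(self):
        d = snp_popgen.ibs_distance(gm([[0, 0], [2, 2]]))
        assert d.values[0, 1] == 1.0

    def test_half_shared_single_site(self):
        d = snp_popgen.ibs_distance(gm([[0], [1]]))
        assert d.values[0, 1] == 0.5

    def test_invariant_to_allele_relabeling(self, small_cohort):
        g, _, _ = small_cohort
        d1 = snp_popgen.ibs_distance(g)
        flipped = g.calls.copy()
        sel = np.arange(0, g.n_sites, 3)
        mask = flipped[:, sel] != -1
        flipped[:, sel] = np.where(mask, 2 - flipped[:, sel], -1)
        g2 = GenotypeMatrix(g.sample_ids, g.chrom, g.pos, flipped)
        d2 = snp_popgen.ibs_distance(g2)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)

    def test_pair_without_comparable_sites_rejected(self):
        g = gm([[0, -1], [-1, 2]])
        with pytest.raises(ValueError, match="no comparable"):
            snp_popgen.ibs_distance(g)


class TestLdScan:
    def test_duplicated_site_in_perfect_ld(self):
        col = np.array([0, 0, 1, 2, 2, 1, 0, 2], dtype=np.int8)
        g = gm(np.column_stack([col, col]))
        ld = snp_popgen.ld_scan(g)
        assert ld["r2"].item() == pytest.approx(1.0)

    def test_r2_matches_brute_force_pearson(self, small_cohort):
        g, _, _ = small_cohort
        sub = g.take_sites(np.arange(12))
        ld = snp_popgen.ld_scan(sub, window_bp=10 ** 9)
        for row in ld.itertuples():
            a = sub.calls[:, row.i].astype(float)
            b = sub.calls[:, row.j].astype(float)
            ok = (a >= 0) & (b >= 0)
            r = pearson_brute(a[ok].tolist(), b[ok].tolist())
            assert row.r2 == pytest.approx(r * r, abs=1e-12)

    def test_independent_sites_have_negligible_r2(self, rng):
        mean = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            calls = r.binomial(2, 0.4, size=(500, 10)).astype(np.int8)
            ld = snp_popgen.ld_scan(gm(calls), window_bp=10 ** 9)
            mean.append(ld["r2"].mean())
        assert np.mean(mean) < 0.01

    def test_phased_toy_haplotype_counts(self):
        # haplotype counts AB:40 ab:40 Ab:10 aB:10 carried by homozygotes
        ga = np.array([2] * 40 + [0] * 40 + [2] * 10 + [0] * 10, dtype=np.int8)
        gb = np.array([2] * 40 + [0] * 40 + [0] * 10 + [2] * 10, dtype=np.int8)
        g = gm(np.column_stack([ga, gb]))
        ld = snp_popgen.ld_scan(g)
        assert ld["r2"].item() == pytest.approx(0.36, abs=1e-10)
        assert ld["dprime"].item() == pytest.approx(0.6, abs=1e-6)

    def test_em_dprime_matches_closed_form_without_double_hets(self, rng):
        # no double heterozygotes -> phase is unambiguous and EM equals
        # direct haplotype counting
        ga = rng.choice([0, 2], size=200).astype(np.int8)
        gb = np.where(ga == 2, rng.choice([0, 2], size=200, p=[0.2, 0.8]),
                      rng.choice([0, 2], size=200, p=[0.7, 0.3])).astype(np.int8)
        h = snp_popgen.em_haplotype_freqs(ga, gb)
        # direct counts
        direct = np.zeros(4)
        for a, b in zip(ga // 2, gb // 2):
            direct[2 * a + b] += 2
        direct /= direct.sum()
        np.testing.assert_allclose(h, direct, atol=1e-8)

    def test_monomorphic_pairs_skipped(self):
        g = gm([[0, 0], [0, 1], [0, 2]])
        ld = snp_popgen.ld_scan(g)
        assert len(ld) == 0

    def test_window_limits_pairs(self):
        calls = np.array([[0, 0, 0, 0], [1, 1, 1, 1], [2, 2, 2, 2],
                          [0, 1, 2, 0]], dtype=np.int8)
        g = gm(calls, pos=[100, 200, 100000, 100100])
        ld = snp_popgen.ld_scan(g, window_bp=500)
        pairs = set(zip(ld["i"], ld["j"]))
        assert pairs <= {(0, 1), (2, 3)}


class TestHaplotypeBlocks:
    def test_perfectly_linked_sites_form_one_block(self, rng):
        col = rng.binomial(2, 0.4, size=300).astype(np.int8)
        g = gm(np.column_stack([col] * 5), pos=[1000, 2000, 3000, 4000, 5000])
        blocks = snp_popgen.haplotype_blocks(g)
        assert len(blocks) == 1
        assert blocks[0].n_snps == 5
        assert blocks[0].length == 4000

    def test_independent_sites_give_no_blocks(self, rng):
        calls = rng.binomial(2, 0.4, size=(400, 8)).astype(np.int8)
        blocks = snp_popgen.haplotype_blocks(gm(calls))
        assert blocks == []

    def test_generator_defined_blocks_recovered(self):
        """A clean two-block chromosome separated by a recombination
        break is recovered exactly in at least 9 of 10 replicates."""
        hits = 0
        for seed in range(10):
            spec = PopulationSpec(n_samples=200, n_sites=7, K=1, F=0.1,
                                  maf_bounds=(0.2, 0.5), missing_rate=0,
                                  n_chromosomes=1, site_spacing_bp=5000,
                                  block_length_bp=20000, block_r=0.95,
                                  seed=seed)
            g, _, _ = simulate_genotypes(spec)
            blocks = snp_popgen.haplotype_blocks(g, window_bp=200_000)
            sig = sorted(tuple(b.sites.tolist()) for b in blocks)
            hits += sig == [(0, 1, 2), (3, 4, 5, 6)]
        assert hits >= 9

    def test_summary_of_empty_block_list(self):
        assert snp_popgen.block_summary([])["count"] == 0


class TestTajimasD:
    def test_constants_against_independent_formulas(self):
        for n in (4, 10, 100):
            calls = np.zeros((n // 2, 3), dtype=np.int8)
            calls[0] = [1, 0, 1]
            calls[1] = [0, 1, 1]
            d = snp_popgen.tajimas_d(gm(calls))
            ref = tajima_constants(n)
            for key, val in ref.items():
                assert getattr(d, key) == pytest.approx(val, abs=1e-12), (n, key)

    def test_toy_frequency_spectrum(self):
        # 4 sequences (2 diploids), 3 segregating sites at 1/4, 1/4, 2/4
        h = np.array([[1, 0, 0], [0, 1, 1], [0, 0, 1], [0, 0, 0]])
        calls = (h[0::2] + h[1::2]).astype(np.int8)
        d = snp_popgen.tajimas_d(gm(calls))
        n, S = 4, 3
        c = tajima_constants(n)
        pi = sum(2 * p * (1 - p) * n / (n - 1) for p in (0.25, 0.25, 0.5))
        expect = (pi - S / c["a1"]) / np.sqrt(c["e1"] * S
                                             + c["e2"] * S * (S - 1))
        assert d.D == pytest.approx(expect, abs=1e-12)
        assert d.S == 3

    def test_zero_numerator_gives_zero_d(self):
        # one singleton site among 4 sequences: pi = 2*(1/4)(3/4)*4/3 = 0.5
        # and S/a1 = 1/(1+1/2+1/3); engineer equality via S=1? use direct
        # check that D sign follows pi - theta_w
        calls = np.array([[1, 0], [0, 0]], dtype=np.int8)
        d = snp_popgen.tajimas_d(gm(calls))
        assert np.sign(d.D) == np.sign(d.pi - d.theta_w)

    def test_no_segregating_sites_rejected(self):
        with pytest.raises(ValueError, match="segregating"):
            snp_popgen.tajimas_d(gm([[0, 0], [0, 0]]))


class TestAmova:
    def test_maximal_structure(self):
        # groups large enough that no sampled permutation recreates the
        # partition, so the permutation p hits its floor
        n, h = 16, 8
        labels = ["a"] * h + ["b"] * h
        d = np.ones((n, n))
        for i in range(h):
            for j in range(h):
                d[i, j] = 0.0
                d[i + h, j + h] = 0.0
        dist = DistanceMatrix([f"s{i}" for i in range(n)], d)
        res = snp_popgen.amova(dist, labels, n_perm=99, seed=0)
        assert res.pct_among == pytest.approx(100.0, abs=1e-9)
        assert res.p_value == pytest.approx(1 / 100)

    def test_percentages_sum_to_hundred(self, recovery_sims):
        g, _, labels = recovery_sims[0]
        dist = snp_popgen.ibs_distance(g)
        res = snp_popgen.amova(dist, labels, n_perm=49, seed=1,
                               already_squared=True)
        assert res.pct_among + res.pct_within == pytest.approx(100.0,
                                                               abs=1e-9)

    def test_random_labels_give_null_phi(self, rng):
        g, _, _ = simulate_genotypes(
            PopulationSpec(n_samples=60, n_sites=500, K=1, seed=2))
        dist = snp_popgen.ibs_distance(g)
        phis, ps = [], []
        for seed in range(8):
            r = np.random.default_rng(seed)
            labels = r.permutation(np.repeat([0, 1], 30))
            res = snp_popgen.amova(dist, labels, n_perm=199, seed=seed,
                                   already_squared=True)
            phis.append(res.phi_st)
            ps.append(res.p_value)
        assert abs(np.mean(phis)) < 0.02
        assert 0.15 < np.mean(ps) < 0.85  # roughly uniform p under the null

    def test_group_of_one_rejected(self):
        dist = DistanceMatrix(list("abc"), np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValueError, match="fewer than 2"):
            snp_popgen.amova(dist, ["x", "x", "y"], n_perm=9)

    def test_equal_group_size_sums_of_squares_identity(self, rng):
        """With equal group sizes, Phi from variance components equals
        the direct sums-of-squares expression."""
        n = 20
        d2 = rng.random((n, n))
        d2 = d2 + d2.T
        np.fill_diagonal(d2, 0.0)
        dist = DistanceMatrix([f"s{i}" for i in range(n)], d2)
        labels = np.repeat([0, 1], 10)
        res = snp_popgen.amova(dist, labels, n_perm=9, seed=0,
                               already_squared=True)
        n0 = 10.0
        msa = res.ss_among / res.df_among
        msw = res.ss_within / res.df_within
        phi = ((msa - msw) / n0) / (((msa - msw) / n0) + msw)
        assert res.phi_st == pytest.approx(phi, abs=1e-12)


class TestGeneFlow:
    @pytest.mark.parametrize("fst, nm", [(0.2, 1.0), (0.5, 0.25),
                                         (0.61, 0.16)])
    def test_closed_forms(self, fst, nm):
        value, _ = snp_popgen.nm_from_fst(fst)
        assert round(value, 2) == nm

    def test_interpretation_bands(self):
        assert snp_popgen.nm_from_fst(0.05)[1] == "ample"
        assert snp_popgen.nm_from_fst(0.1)[1] == "high"
        assert snp_popgen.nm_from_fst(0.61)[1] == "drift-dominated"

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 2.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            snp_popgen.nm_from_fst(bad)

    def test_round_trip_identity(self):
        for fst in (0.1, 0.3, 0.61, 0.9):
            nm, _ = snp_popgen.nm_from_fst(fst)
            back = 1.0 / (4.0 * nm + 1.0)
            assert back == pytest.approx(fst, abs=1e-12)


class TestMerge:
    def test_keep_first_on_duplicate_positions(self):
        a = gm([[0, 1], [2, 1]], pos=[100, 200])
        b = gm([[1, 0], [1, 2]], pos=[200, 300])
        merged = snp_popgen.merge_genotypes(a, b)
        assert merged.pos.tolist() == [100, 200, 300]
        # position 200 keeps the calls from the first set
        np.testing.assert_array_equal(merged.calls[:, 1], a.calls[:, 1])
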