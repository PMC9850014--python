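"""VCF parsing and the filtering cascade against brute-force oracles."""

import numpy as np
import pytest

import invadepop as ip
from invadepop.genotype_io import FilterLog, InvadepopError, qc_report

TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=loc1>
##contig=<ID=loc2>
##contig=<ID=loc3>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
loc1\t5\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
loc2\t9\t.\tC\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0
loc3\t2\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/0\t0/1\t2/2
"""


class TestReadVcf:
    def test_gt_parsing_and_missing(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(TOY_VCF)
        g = ip.read_vcf(str(p))
        # triallelic loc3 excluded
        assert g.locus_ids == ["loc1:5", "loc2:9"]
        assert list(g.codes[:, 0]) == [0, 1, 2]
        assert g.codes[0, 1] == -1 and g.missing[0, 1]

    def test_malformed_vcf_raises(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("this is not a vcf\n")
        with pytest.raises(InvadepopError):
            ip.read_vcf(str(p))


def brute_force_missingness(codes, schedule, final):
    """Independent re-implementation of the alternating filter."""
    m = codes.copy()
    keep_l = np.arange(m.shape[1])
    keep_s = np.arange(m.shape[0])
    steps = [t for t in schedule if t >= final] + [final]
    for step in steps:
        sub = m[np.ix_(keep_s, keep_l)]
        frac_l = (sub == -1).mean(axis=0)
        keep_l = keep_l[frac_l <= step]
        sub = m[np.ix_(keep_s, keep_l)]
        frac_s = (sub == -1).mean(axis=1)
        keep_s = keep_s[frac_s <= step]
    while True:
        sub = m[np.ix_(keep_s, keep_l)]
        frac_l = (sub == -1).mean(axis=0)
        if (frac_l > final).any():
            keep_l = keep_l[frac_l <= final]
            continue
        frac_s = (sub == -1).mean(axis=1)
        if (frac_s > final).any():
            keep_s = keep_s[frac_s <= final]
            continue
        break
    return len(keep_s), len(keep_l)


class TestMissingnessFilter:
    def test_clean_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, (20, 30)).astype(np.int16)
        g = ip.GenotypeMatrix(codes, [f"s{i}" for i in range(20)],
                              [f"l{j}:1" for j in range(30)])
        out = ip.iterative_missingness_filter(g)
        assert out.codes.shape == (20, 30)

    def test_fully_missing_individual_removed(self):
        codes = np.ones((4, 10), dtype=np.int16)
        codes[2, :] = -1
        g = ip.GenotypeMatrix(codes, list("abcd"), [f"l{j}:1" for j in range(10)])
        log = FilterLog()
        out = ip.iterative_missingness_filter(g, log=log)
        assert "c" not in out.sample_ids
        assert ("c" in [s for s, _ in log.removed_samples])

    def test_missingness_gradient_matches_brute_force(self):
        """Planted gradient: surviving counts equal the independent
        oracle applying the same schedule."""
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, (40, 80)).astype(np.int16)
        p_locus = np.linspace(0, 0.8, 80)
        p_ind = np.linspace(0, 0.6, 40)
        miss = rng.random((40, 80)) < np.sqrt(np.outer(p_ind, p_locus))
        codes[miss] = -1
        g = ip.GenotypeMatrix(codes, [f"s{i}" for i in range(40)],
                              [f"l{j}:1" for j in range(80)])
        out = ip.iterative_missingness_filter(g)
        ns, nl = brute_force_missingness(codes, (0.9, 0.7, 0.5, 0.3), 0.3)
        assert (out.n_samples, out.n_loci) == (ns, nl)

    def test_purity(self):
        codes = np.full((3, 4), -1, dtype=np.int16)
        codes[:, 0] = 1
        g = ip.GenotypeMatrix(codes, list("abc"), [f"l{j}:1" for j in range(4)])
        before = g.codes.copy()
        ip.iterative_missingness_filter(g)
        assert np.array_equal(g.codes, before)


class TestMacFilter:
    def test_singleton_het_removed_at_mac2(self):
        codes = np.array([[1], [0], [0]], dtype=np.int16)
        g = ip.GenotypeMatrix(codes, list("abc"), ["l:1"])
        assert ip.mac_filter(g, 2).n_loci == 0

    def test_mac2_retained(self):
        codes = np.array([[0], [1], [1]], dtype=np.int16)
        g = ip.GenotypeMatrix(codes, list("abc"), ["l:1"])
        assert ip.mac_filter(g, 2).n_loci == 1

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(-1, 3, (30, 100)).astype(np.int16)
        g = ip.GenotypeMatrix(codes, [f"s{i}" for i in range(30)],
                              [f"l{j}:1" for j in range(100)])
        out = ip.mac_filter(g, 2)
        expected = 0
        for j in range(100):
            col = codes[:, j]
            col = col[col >= 0]
            alt = col.sum()
            mac = min(alt, 2 * len(col) - alt)
            expected += mac >= 2
        assert out.n_loci == expected


class TestHdplot:
    def _with_depths(self, codes, ref, alt):
        n, m = codes.shape
        return ip.GenotypeMatrix(
            codes.astype(np.int16), [f"s{i}" for i in range(n)],
            [f"l{j}:1" for j in range(m)],
            np.asarray(ref, dtype=np.int32), np.asarray(alt, dtype=np.int32),
        )

    def test_balanced_depths_give_d_zero(self):
        codes = np.ones((4, 1))
        g = self._with_depths(codes, np.full((4, 1), 10), np.full((4, 1), 10))
        qc = ip.hdplot(g)
        assert qc[0].read_ratio_deviation == 0.0

    def test_d_arithmetic(self):
        """A=49 ref, B=15 alt over hets -> D = 34/sqrt(64) = 4.25."""
        codes = np.ones((4, 1))
        ref = np.array([[12], [12], [12], [13]])
        alt = np.array([[4], [4], [4], [3]])
        g = self._with_depths(codes, ref, alt)
        qc = ip.hdplot(g)
        assert qc[0].read_ratio_deviation == pytest.approx(4.25)
        # retained by the D rule (h_max raised to isolate it)
        assert ip.filter_hdplot(g, h_max=1.0, d_max=7.0).n_loci == 1

    def test_missing_depths_rejected(self):
        g = ip.GenotypeMatrix(np.ones((3, 2), dtype=np.int16), list("abc"),
                              ["l1:1", "l2:1"])
        with pytest.raises(InvadepopError):
            ip.hdplot(g)

    def test_paralog_separability(self, bottleneck_dataset):
        """Injected paralogs: >= 90% removed, <= 10% of true SNPs lost."""
        ds = ip.inject_paralogs(bottleneck_dataset, 60, seed=3)
        g = ds.genotypes
        from invadepop.simulate import synthesize_depths

        g = synthesize_depths(g, seed=4, mean_depth=100,
                              paralog_mask=ds.paralog_mask)
        kept = set(ip.filter_hdplot(g).locus_ids)
        paralogs = {lid for lid, is_par in zip(g.locus_ids, ds.paralog_mask) if is_par}
        true = set(g.locus_ids) - paralogs
        frac_par_removed = len(paralogs - kept) / len(paralogs)
        frac_true_removed = len(true - kept) / len(true)
        assert frac_par_removed >= 0.9
        assert frac_true_removed <= 0.1


class TestOneSnpPerLocus:
    def _mk(self, cols, ids):
        codes = np.array(cols, dtype=np.int16).T
        return ip.GenotypeMatrix(codes, [f"s{i}" for i in range(codes.shape[0])], ids)

    def test_highest_maf_kept(self):
        g = self._mk(
            [[0, 0, 0, 1], [0, 1, 1, 2]], ["locA:3", "locA:7"]
        )  # MAF 0.125 vs 0.5
        out = ip.select_one_snp_per_locus(g)
        assert out.locus_ids == ["locA:7"]

    def test_single_snp_locus_unchanged(self):
        g = self._mk([[0, 1, 1]], ["locB:4"])
        assert ip.select_one_snp_per_locus(g).locus_ids == ["locB:4"]

    def test_tie_broken_by_position(self):
        g = self._mk([[0, 1, 1, 0], [1, 1, 0, 0]], ["locC:9", "locC:2"])
        out = ip.select_one_snp_per_locus(g)
        assert out.locus_ids == ["locC:2"]


class TestRelatedness:
    def test_identical_rows_near_one(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.2, 0.8, 800)
        base = rng.binomial(2, p)
        others = rng.binomial(2, p, (30, 800))
        codes = np.vstack([base, base, others]).astype(np.int16)
        g = ip.GenotypeMatrix(codes, [f"s{i}" for i in range(32)],
                              [f"l{j}:1" for j in range(800)])
        r = ip.pairwise_relatedness(g)
        assert r[0, 1] > 0.85

    def test_parent_offspring_near_half_and_unrelated_near_zero(self):
        rng = np.random.default_rng(6)
        L = 1000
        p = rng.uniform(0.1, 0.9, L)
        po, un = [], []
        for _ in range(100):
            mother = rng.binomial(2, p)
            father = rng.binomial(2, p)
            child = (rng.random(L) * 2 < mother).astype(int) + (
                rng.random(L) * 2 < father
            ).astype(int)
            others = rng.binomial(2, p, (80, L))
            codes = np.vstack([mother, child, others]).astype(np.int16)
            g = ip.GenotypeMatrix(codes, [f"s{i}" for i in range(82)],
                                  [f"l{j}:1" for j in range(L)])
            r = ip.pairwise_relatedness(g)
            po.append(r[0, 1])
            un.append(r[2, 3])
        assert abs(np.mean(po) - 0.5) < 0.05
        assert abs(np.mean(un)) < 0.05


class TestCascade:
    def test_cascade_counts_match_independent_pass(self, bottleneck_dataset):
        """Full cascade on a noisy fixture equals step-by-step brute force."""
        rng = np.random.default_rng(8)
        ds = ip.inject_paralogs(bottleneck_dataset, 30, seed=9)
        from invadepop.simulate import synthesize_depths

        g = synthesize_depths(ds.genotypes, seed=10, paralog_mask=ds.paralog_mask)
        mask = rng.random(g.codes.shape) < 0.1
        g.codes[mask] = -1
        g.ref_depth[mask] = 0
        g.alt_depth[mask] = 0
        out = ip.filter_cascade(g)
        step = ip.iterative_missingness_filter(g)
        step = ip.mac_filter(step, 2)
        step = ip.filter_hdplot(step)
        step = ip.select_one_snp_per_locus(step)
        assert out.locus_ids == step.locus_ids
        assert out.sample_ids == step.sample_ids

    def test_qc_report_columns(self, bottleneck_dataset):
        from invadepop.simulate import synthesize_depths

        g = synthesize_depths(bottleneck_dataset.genotypes, seed=11)
        per_locus, per_ind = qc_report(g)
        assert {"H", "D", "maf", "missing_fraction"} <= set(per_locus.columns)
        assert {"missing_fraction", "mean_depth"} <= set(per_ind.columns)
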