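import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from islescan import genotype_io as gio
from tests.conftest import make_gm

TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=Super-Scaffold_1,length=1000>
##contig=<ID=Super-Scaffold_13,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
Super-Scaffold_1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t1|1\t./.
Super-Scaffold_1\t200\t.\tG\tC,T\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0
Super-Scaffold_1\t300\t.\tC\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t1/1
Super-Scaffold_13\t150\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/1\t0/1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


class TestReadVcf:
    def test_multiallelic_excluded(self, toy_vcf):
        gm = gio.read_vcf(toy_vcf)
        assert 200 not in gm.sites["pos"].tolist()

    def test_sex_scaffold_excluded(self, toy_vcf):
        gm = gio.read_vcf(toy_vcf, exclude_scaffolds={"Super-Scaffold_13"})
        assert set(gm.sites["scaffold"]) == {"Super-Scaffold_1"}
        assert gm.n_sites == 2

    def test_dosage_codes(self, toy_vcf):
        gm = gio.read_vcf(toy_vcf)
        row = gm.dosage[gm.sites["pos"].tolist().index(100)]
        # 0/1 -> 1, 1|1 -> 2 (phase ignored), ./. -> missing
        assert row.tolist() == [1, 2, gio.MISSING]

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        dosage = rng.integers(-1, 3, size=(30, 4))
        gm = make_gm(dosage, contig_len=1000)
        out = tmp_path / "rt.vcf"
        gio.write_vcf(gm, out)
        back = gio.read_vcf(out)
        assert back.samples == gm.samples
        assert np.array_equal(back.dosage, gm.dosage)
        pd.testing.assert_frame_equal(back.sites, gm.sites)
        assert back.contig_lengths == gm.contig_lengths


class TestHweExact:
    @pytest.mark.parametrize("counts, expected", [
        ((5, 0, 0), 1.0),            # monomorphic
        ((1, 0, 1), 1.0 / 3.0),      # only h=0 (p=1/3) no more probable than itself
    ])
    def test_known_values(self, counts, expected):
        assert gio.hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)

    def test_matches_combinatorial_oracle(self):
        # independent oracle: exact rational Levene probabilities via math.comb
        def levene_p(n_AA, n_Aa, n_aa):
            n = n_AA + n_Aa + n_aa
            nA = 2 * n_AA + n_Aa
            na = 2 * n - nA
            def prob(h):
                return (math.comb(n, h) * math.comb(n - h, (nA - h) // 2)
                        * 2 ** h * math.comb(2 * n, nA) ** -1
                        * math.comb(n - h - (nA - h) // 2, (na - h) // 2))
            hs = [h for h in range(nA % 2, min(nA, na) + 1, 2)]
            ps = {h: prob(h) for h in hs}
            p_obs = ps[n_Aa]
            return sum(p for p in ps.values() if p <= p_obs * (1 + 1e-12))
        for counts in [(3, 2, 1), (4, 4, 4), (0, 5, 0), (2, 1, 7), (10, 3, 2)]:
            assert gio.hwe_exact_test(*counts) == pytest.approx(
                levene_p(*counts), abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    def test_distribution_sums_to_one(self, a, h, b):
        if a + h + b == 0:
            return
        _, probs = gio.hwe_distribution(a, h, b)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestFilterSites:
    def test_ten_percent_missing_dropped(self):
        dosage = np.ones((1, 10), dtype=np.int8)
        dosage[0, 0] = gio.MISSING  # 10% missing >= 5% threshold
        gm = make_gm(dosage)
        out, report = gio.filter_sites(gm, max_missing=0.05)
        assert out.n_sites == 0 and report.n_dropped_missing == 1

    def test_hwe_keeps_nonsignificant_site(self):
        # (1, 0, 1): exact p = 1/3 > 0.05 -> kept despite het deficit
        gm = make_gm([[0, 2]])
        out, report = gio.filter_sites(gm, apply_hwe=True, hwe_alpha=0.05)
        assert out.n_sites == 1 and report.n_dropped_hwe == 0

    def test_identity_and_idempotence(self):
        rng = np.random.default_rng(1)
        gm = make_gm(rng.integers(0, 3, size=(20, 8)))
        once, _ = gio.filter_sites(gm, apply_hwe=True)
        twice, _ = gio.filter_sites(once, apply_hwe=True)
        assert np.array_equal(once.dosage, twice.dosage)

    def test_bad_threshold(self):
        gm = make_gm([[0, 1]])
        with pytest.raises(ValueError):
            gio.filter_sites(gm, max_missing=1.5)


class TestLdPrune:
    def test_duplicated_locus_removed(self):
        x = [0, 1, 2, 1, 0, 2, 1, 1]
        gm = make_gm([x, x, [0, 0, 1, 2, 1, 0, 2, 1]])
        out = gio.ld_prune(gm)
        assert out.n_sites == 2
        assert out.sites["pos"].tolist()[0] == 10  # earlier duplicate kept

    def test_independent_loci_untouched(self):
        # orthogonal dosage patterns, all pairwise r2 = 0
        gm = make_gm([[0, 0, 2, 2], [0, 2, 0, 2], [2, 0, 0, 2]])
        assert gio.ld_prune(gm).n_sites == 3

    def test_hand_computed_pair(self):
        l1 = [0, 0, 1, 1, 2, 2, 0, 2]
        l2 = [0, 1, 1, 1, 2, 2, 0, 0]  # r2 with l1 ~ 0.31 > 0.1
        l3 = [0, 2, 1, 2, 1, 1, 2, 2]  # near-zero r2 with both
        assert gio.pairwise_r2(np.array(l1), np.array(l2)) > 0.1
        assert gio.pairwise_r2(np.array(l1), np.array(l3)) < 0.1
        assert gio.pairwise_r2(np.array(l2), np.array(l3)) < 0.1
        out = gio.ld_prune(make_gm([l1, l2, l3]))
        assert out.sites["pos"].tolist() == [10, 30]  # locus 2 removed

    def test_no_high_r2_pair_survives(self):
        rng = np.random.default_rng(2)
        gm = make_gm(rng.integers(0, 3, size=(40, 12)))
        out = gio.ld_prune(gm, window_snps=40, step_snps=10, r2_max=0.3)
        for i in range(out.n_sites):
            for j in range(i + 1, out.n_sites):
                r2 = gio.pairwise_r2(out.dosage[i], out.dosage[j])
                assert not (np.isfinite(r2) and r2 > 0.3)

    def test_window_too_small(self):
        with pytest.raises(ValueError):
            gio.ld_prune(make_gm([[0, 1]]), window_snps=1)


TOY_GFF = """\
##gff-version 3
##sequence-region s1 1 5000
s1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1;Name=geneA
s1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=m1;Parent=g1
s2\tsrc\tgene\t501\t900\t.\t-\t.\tID=g2
"""


class TestReadGff:
    def test_coordinates_and_names(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(TOY_GFF)
        ann = gio.read_gff(p)
        assert len(ann.genes) == 2
        g1 = ann.genes.iloc[0]
        assert (g1["start"], g1["end"]) == (100, 200)  # 1-based -> half-open
        assert g1["name"] == "geneA"
        assert ann.genes.iloc[1]["name"] == "g2"  # fallback to ID
        assert set(ann.genes["scaffold"]) == {"s1", "s2"}

    def test_mrna_only_file_warns_empty(self, tmp_path):
        p = tmp_path / "empty.gff3"
        p.write_text("##gff-version 3\n"
                     "s1\tsrc\tmRNA\t1\t10\t.\t+\t.\tID=m1\n")
        with pytest.warns(UserWarning):
            ann = gio.read_gff(p)
        assert len(ann.genes) == 0
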