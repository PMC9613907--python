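import numpy as np
import pytest

from islescan import diversity as dv
from islescan.genotype_io import SampleSheet
from tests.conftest import make_gm


class TestObservedHeterozygosity:
    def test_examples(self):
        # ind1 all-homozygous; ind2 dosages [1,1,0,2]; ind3 has a missing site
        dosage = np.array([[0, 1, 1], [2, 1, -1], [0, 0, 0], [2, 2, 1]],
                          dtype=np.int8).T
        # rows above are individuals; transpose back to sites x samples
        dosage = dosage.T
        gm = make_gm(dosage, samples=["i1", "i2", "i3"])
        sheet = SampleSheet({"i1": "P", "i2": "P", "i3": "Q"})
        per_ind, per_pop = dv.observed_heterozygosity(gm, sheet)
        assert per_ind["i1"] == 0.0
        assert per_ind["i2"] == pytest.approx(0.5)
        assert per_ind["i3"] == pytest.approx(2.0 / 3.0)  # missing excluded

    def test_hardy_weinberg_concentration(self):
        rng = np.random.default_rng(20)
        p = 0.3
        dosage = rng.binomial(2, p, size=(20_000, 6)).astype(np.int8)
        gm = make_gm(dosage, positions=np.arange(20_000) + 1)
        sheet = SampleSheet({s: "P" for s in gm.samples})
        per_ind, _ = dv.observed_heterozygosity(gm, sheet)
        expected = 2 * p * (1 - p)
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert per_ind.mean() == pytest.approx(expected, abs=3 * se)


def three_pop_toy():
    # sites x samples, pops: P = {s1,s2}, Q = {s3,s4}, R = {s5,s6}
    dosage = np.array([
        [1, 0, 0, 0, 0, 0],   # alt only in P -> private to P
        [1, 0, 2, 0, 0, 0],   # alt in P and Q -> private to neither
        [2, 2, 2, 2, 1, 2],   # ref only in R -> private to R
        [0, 0, 0, 0, 0, 0],   # alt absent everywhere -> nothing private
    ], dtype=np.int8)
    gm = make_gm(dosage, samples=[f"s{i+1}" for i in range(6)])
    sheet = SampleSheet({"s1": "P", "s2": "P", "s3": "Q", "s4": "Q",
                         "s5": "R", "s6": "R"})
    return gm, sheet


class TestPrivateAlleles:
    def test_toy_counts(self):
        gm, sheet = three_pop_toy()
        counts = dv.private_alleles(gm, sheet)
        assert counts["P"] == 1
        assert counts["Q"] == 0
        assert counts["R"] == 1

    def test_order_invariance(self):
        gm, sheet = three_pop_toy()
        base = dv.private_alleles(gm, sheet)
        flipped = gm.subset_samples(gm.samples[::-1])
        assert dv.private_alleles(flipped, sheet).equals(base[base.index])

    def test_missing_carries_no_evidence(self):
        dosage = np.array([[1, -1, 0, 0]], dtype=np.int8)
        gm = make_gm(dosage, samples=list("abcd"))
        sheet = SampleSheet({"a": "P", "b": "P", "c": "Q", "d": "Q"})
        assert dv.private_alleles(gm, sheet)["P"] == 1


class TestRarefiedPrivateAlleles:
    def test_full_sample_equals_raw(self):
        gm, sheet = three_pop_toy()
        out = dv.rarefied_private_alleles(gm, sheet, g=2, reps=10, seed=0)
        raw = dv.private_alleles(gm, sheet)
        out = out.set_index("population")
        for pop in raw.index:
            assert out.loc[pop, "rarefied_mean"] == raw[pop]
            assert out.loc[pop, "rarefied_sd"] == 0.0

    def test_exhaustive_two_individual_case(self):
        # 2-individual pop, one carries the only private allele; g=1 -> 0.5
        dosage = np.array([[1, 0, 0, 0]], dtype=np.int8)
        gm = make_gm(dosage, samples=list("abcd"))
        sheet = SampleSheet({"a": "P", "b": "P", "c": "Q", "d": "Q"})
        out = dv.rarefied_private_alleles(gm, sheet, g=1, exhaustive=True)
        out = out.set_index("population")
        assert out.loc["P", "rarefied_mean"] == pytest.approx(0.5)

    def test_monte_carlo_matches_exhaustive_within_3se(self):
        rng = np.random.default_rng(21)
        gm = make_gm(rng.integers(0, 3, size=(200, 6)),
                     samples=[f"s{i}" for i in range(6)])
        sheet = SampleSheet({f"s{i}": ("P" if i < 3 else "Q")
                             for i in range(6)})
        ex = dv.rarefied_private_alleles(gm, sheet, g=2, exhaustive=True
                                         ).set_index("population")
        reps = 400
        mc = dv.rarefied_private_alleles(gm, sheet, g=2, reps=reps, seed=3
                                         ).set_index("population")
        for pop in ["P", "Q"]:
            se = mc.loc[pop, "rarefied_sd"] / np.sqrt(reps)
            assert mc.loc[pop, "rarefied_mean"] == pytest.approx(
                ex.loc[pop, "rarefied_mean"], abs=3 * se + 1e-9)

    def test_seed_determinism(self):
        gm, sheet = three_pop_toy()
        merge = None
        a = dv.rarefied_private_alleles(gm, sheet, g=2, reps=50, seed=7)
        b = dv.rarefied_private_alleles(gm, sheet, g=2, reps=50, seed=7)
        assert a.equals(b)

    def test_population_smaller_than_g(self):
        gm, sheet = three_pop_toy()
        with pytest.raises(ValueError, match="P"):
            dv.rarefied_private_alleles(gm, sheet, g=5)

    def test_merge_pools_small_populations(self):
        gm, sheet = three_pop_toy()
        out = dv.rarefied_private_alleles(
            gm, sheet, g=2, reps=5, seed=0,
            merge={"P": "PQ", "Q": "PQ"})
        assert set(out["population"]) == {"PQ", "R"}


class TestInbreedingCoefficients:
    def test_fully_homozygous_individual(self):
        rng = np.random.default_rng(22)
        dosage = rng.integers(0, 3, size=(100, 4)).astype(np.int8)
        dosage[:, 0] = np.where(dosage[:, 0] == 1, 0, dosage[:, 0])
        gm = make_gm(dosage)
        sheet = SampleSheet({s: ("P" if i < 2 else "Q")
                             for i, s in enumerate(gm.samples)})
        res = dv.inbreeding_coefficients(gm, sheet)
        assert res.f_it[gm.samples[0]] == pytest.approx(1.0)

    def test_fully_heterozygous_with_half_baseline(self):
        # pop P: ind1 fully het, ind2/ind3 chosen so their pair baseline is 0.5
        dosage = np.array([
            [1, 0, 0, 0, 2],
            [1, 0, 2, 0, 0],
            [1, 2, 0, 2, 0],
            [1, 2, 2, 2, 2],
        ], dtype=np.int8)
        gm = make_gm(dosage, samples=["het", "p2", "p3", "q1", "q2"])
        sheet = SampleSheet({"het": "P", "p2": "P", "p3": "P",
                             "q1": "Q", "q2": "Q"})
        res = dv.inbreeding_coefficients(gm, sheet)
        # within-P pair matchings: (het,p2)=0.5, (het,p3)=0.5, (p2,p3)=0.5
        assert res.f_is["het"] == pytest.approx(-1.0)

    def test_overall_fst_recovery(self):
        from islescan.synthetic_data import SimConfig, simulate_neutral
        cfg = SimConfig(pop_sizes={"A": 10, "B": 10},
                        pop_F={"A": 0.08, "B": 0.08},
                        group_of_pop={"A": "island", "B": "mainland"},
                        n_snps=20_000, contigs={"c1": 10_000_000}, seed=23)
        gm, sheet, _ = simulate_neutral(cfg)
        res = dv.inbreeding_coefficients(gm, sheet)
        assert res.overall_fst == pytest.approx(0.08, abs=0.02)

    def test_panmictic_fis_near_zero(self):
        rng = np.random.default_rng(24)
        p = rng.uniform(0.1, 0.9, size=20_000)
        dosage = rng.binomial(2, p[:, None], size=(20_000, 10)).astype(np.int8)
        gm = make_gm(dosage, positions=np.arange(20_000) + 1)
        sheet = SampleSheet({s: "P" for s in gm.samples})
        res = dv.inbreeding_coefficients(gm, sheet)
        # centred near 0, slightly negative for small n
        assert abs(res.f_is_pop["F_IS_mean"].iloc[0]) < 0.05
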