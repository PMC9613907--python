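import itertools

import numpy as np
import pytest

from islescan import allele_sharing as ash
from islescan import synthetic_data as sd
from tests.conftest import make_gm, matching_oracle


class TestMatchingMatrix:
    @pytest.mark.parametrize("xi, xj, expected", [
        ([0, 2], [0, 2], 1.0),        # identical homozygotes
        ([1], [1], 0.5),              # het x het
        ([2, 1, 0], [2, 2, 1], 2.0 / 3.0),
    ])
    def test_known_pairs(self, xi, xj, expected):
        gm = make_gm(np.column_stack([xi, xj]))
        M = ash.matching_matrix(gm)
        assert M.M[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_all_dosage_combinations_match_allele_draw_oracle(self):
        """Per-site matching equals brute-force enumeration of the four
        allele pairings, for all 9 dosage combinations."""
        for a, b in itertools.product([0, 1, 2], repeat=2):
            gm = make_gm([[a, b]])
            M = ash.matching_matrix(gm)
            assert M.M[0, 1] == pytest.approx(matching_oracle(a, b), abs=1e-12)

    def test_missing_sites_excluded_per_pair(self):
        gm = make_gm([[0, 0, 0], [-1, 2, 2], [2, 2, 0]])
        M = ash.matching_matrix(gm)
        # ind1 is missing at site 2, so pair (1,2) uses sites 1 and 3 only
        assert M.n_sites_used[0, 1] == 2
        assert M.M[0, 1] == pytest.approx(1.0)   # (0,0) and (2,2) both match
        assert M.n_sites_used[1, 2] == 3
        assert M.M[1, 2] == pytest.approx(2.0 / 3.0)

    def test_pair_with_no_usable_sites_is_missing(self):
        gm = make_gm([[-1, 0, 1], [0, -1, 1]])
        M = ash.matching_matrix(gm)
        assert np.isnan(M.M[0, 1])

    def test_self_matching(self):
        gm = make_gm([[0, 1], [2, 1], [1, 0], [-1, 2]])
        M = ash.matching_matrix(gm)
        assert M.self_matching[0] == pytest.approx(2.0 / 3.0)  # hom,hom,het
        assert M.self_matching[1] == pytest.approx(0.5)


class TestGroupSpecificFst:
    def test_fixed_difference_is_one(self):
        gm = make_gm([[2, 2, 0]], samples=["a", "b", "c"])
        M = ash.matching_matrix(gm)
        c = ash.group_specific_fst(M, ["a", "b"], ["c"])
        assert c.fst_specific == pytest.approx(1.0)

    def test_all_heterozygous_is_zero(self):
        gm = make_gm([[1, 1, 1, 1]], samples=list("abcd"))
        M = ash.matching_matrix(gm)
        c = ash.group_specific_fst(M, ["a", "b"], ["c", "d"])
        assert c.M_within == pytest.approx(0.5)
        assert c.M_between == pytest.approx(0.5)
        assert c.fst_specific == pytest.approx(0.0)

    def test_hand_computed_contrast(self):
        # target a=[2,1] b=[2,0]; reference c=[0,1] d=[0,1]
        gm = make_gm(np.array([[2, 2, 0, 0], [1, 0, 1, 1]]),
                     samples=list("abcd"))
        M = ash.matching_matrix(gm)
        c = ash.group_specific_fst(M, ["a", "b"], ["c", "d"])
        assert c.M_within == pytest.approx(0.75)
        assert c.M_between == pytest.approx(0.25)
        assert c.fst_specific == pytest.approx(2.0 / 3.0, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        gm = make_gm(rng.integers(0, 3, size=(50, 6)), samples=list("abcdef"))
        M = ash.matching_matrix(gm)
        f1 = ash.group_specific_fst(M, ["a", "b", "c"], ["d", "e", "f"])
        f2 = ash.group_specific_fst(M, ["c", "a", "b"], ["f", "d", "e"])
        assert f1.fst_specific == pytest.approx(f2.fst_specific, abs=1e-15)

    def test_overlapping_sets_rejected(self):
        gm = make_gm([[0, 1, 2]], samples=list("abc"))
        M = ash.matching_matrix(gm)
        with pytest.raises(ValueError):
            ash.group_specific_fst(M, ["a", "b"], ["b", "c"])

    def test_panmictic_expectation_zero(self):
        """Arbitrary target/reference split of one panmictic pool: mean
        windowed specific FST within 3 SE of 0 over 1000 replicate chunks."""
        rng = np.random.default_rng(11)
        p = rng.uniform(0.1, 0.9, size=20_000)
        dosage = rng.binomial(2, p[:, None], size=(20_000, 12)).astype(np.int8)
        vals = []
        for chunk in np.array_split(np.arange(20_000), 1000):
            gm = make_gm(dosage[chunk], positions=np.arange(len(chunk)) + 1)
            M = ash.matching_matrix(gm)
            vals.append(ash.group_specific_fst(
                M, gm.samples[:6], gm.samples[6:]).fst_specific)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se


class TestPairwiseFst:
    def test_fixed_difference(self):
        gm = make_gm([[2, 2, 0, 0]], samples=list("abcd"))
        M = ash.matching_matrix(gm)
        assert ash.pairwise_fst(M, ["a", "b"], ["c", "d"]) == pytest.approx(1.0)

    def test_hand_computed(self):
        # A: a1=[2,2] a2=[2,0]; B: b1=[0,0] b2=[0,2]
        gm = make_gm(np.array([[2, 2, 0, 0], [2, 0, 0, 2]]),
                     samples=["a1", "a2", "b1", "b2"])
        M = ash.matching_matrix(gm)
        fst = ash.pairwise_fst(M, ["a1", "a2"], ["b1", "b2"])
        assert fst == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_no_differentiation_near_zero(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, size=5000)
        dosage = rng.binomial(2, p[:, None], size=(5000, 20)).astype(np.int8)
        gm = make_gm(dosage, positions=np.arange(5000) + 1)
        M = ash.matching_matrix(gm)
        fst = ash.pairwise_fst(M, gm.samples[:10], gm.samples[10:])
        assert abs(fst) < 0.01

    def test_balding_nichols_recovery(self):
        cfg = sd.SimConfig(pop_sizes={"A": 10, "B": 10},
                           pop_F={"A": 0.1, "B": 0.1},
                           group_of_pop={"A": "island", "B": "mainland"},
                           n_snps=10_000, contigs={"c1": 5_000_000}, seed=5)
        gm, sheet, _ = sd.simulate_neutral(cfg)
        M = ash.matching_matrix(gm)
        fst = ash.pairwise_fst(M, sheet.samples_of("A"), sheet.samples_of("B"))
        assert fst == pytest.approx(0.1, abs=0.02)


class TestBetaRelatedness:
    def test_two_individuals_zero(self):
        gm = make_gm([[0, 2], [1, 1], [2, 0]])
        rel = ash.beta_relatedness(ash.matching_matrix(gm))
        assert rel.beta[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_clone_pair_exceeds_outbred(self):
        rng = np.random.default_rng(6)
        panel = rng.integers(0, 3, size=(200, 5)).astype(np.int8)
        dosage = np.column_stack([panel, panel[:, 0]])  # ind6 clones ind1
        rel = ash.beta_relatedness(ash.matching_matrix(make_gm(dosage)))
        clone = rel.beta[0, 5]
        others = [rel.beta[i, j] for i in range(6) for j in range(i + 1, 6)
                  if (i, j) != (0, 5)]
        assert clone > max(others)

    def test_four_individual_direct_evaluation(self):
        rng = np.random.default_rng(7)
        gm = make_gm(rng.integers(0, 3, size=(30, 4)))
        M = ash.matching_matrix(gm)
        rel = ash.beta_relatedness(M)
        iu = np.triu_indices(4, k=1)
        mb = M.M[iu].mean()
        for i, j in zip(*iu):
            assert rel.beta[i, j] == pytest.approx(
                (M.M[i, j] - mb) / (1 - mb), abs=1e-12)
        assert rel.beta[iu].mean() == pytest.approx(0.0, abs=1e-12)
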