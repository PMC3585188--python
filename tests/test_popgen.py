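import math

import numpy as np
import pytest

from sawyerflow import (
    gene_flow,
    haplotype_diversity,
    k2p_pairwise,
    k2p_population,
    nei_between,
    nei_within,
    nucleotide_diversity,
    pairwise_fst,
    rshr,
)
from sawyerflow.errors import (
    InsufficientSampleError,
    SaturationError,
    UndefinedStatisticError,
)

from _oracles import phi_st_bruteforce
from conftest import make_alignment


class TestK2P:
    def test_identical(self):
        assert k2p_pairwise("ACGTACGTAC", "ACGTACGTAC") == 0.0

    def test_single_transition_closed_form(self):
        # P = 0.1, Q = 0 -> -0.5 ln(0.8) = 0.111571...
        assert k2p_pairwise("ACGTACGTAC", "ACGTACGTAT") == pytest.approx(0.1115717757, abs=1e-9)

    def test_saturation(self):
        with pytest.raises(SaturationError):
            k2p_pairwise("AG", "GA")  # P = 1

    def test_transversion_only(self):
        # Q = 0.5 exactly at the K2P singularity for the transversion term
        with pytest.raises(SaturationError):
            k2p_pairwise("AA", "TA")  # P=0, Q=0.5 -> sqrt term vanishes
        d = k2p_pairwise("AAAAAAAAAA", "TAAAAAAAAA")  # P = 0, Q = 0.1
        assert d == pytest.approx(-0.5 * math.log(0.9 * math.sqrt(0.8)), abs=1e-12)

    def test_dominates_p_distance(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            L = 60
            a = rng.choice(list("ACGT"), size=L)
            b = a.copy()
            k = rng.integers(1, 8)
            for j in rng.choice(L, size=k, replace=False):
                b[j] = rng.choice([c for c in "ACGT" if c != b[j]])
            p_dist = (a != b).mean()
            assert k2p_pairwise("".join(a), "".join(b)) >= p_dist - 1e-12

    def test_gaps_excluded(self):
        # gap column ignored; remaining 9 sites, one transition
        assert k2p_pairwise("-CGTACGTAC", "ACGTACGTAT") == pytest.approx(
            -0.5 * math.log(1 - 2 / 9), abs=1e-12
        )


class TestK2PPopulation:
    def test_fixed_identical(self):
        seqs = make_alignment({"X": ["ACGT" * 25] * 3, "Y": ["ACGT" * 25] * 3})
        assert k2p_population(seqs, "X", "Y", n_boot=50, seed=0) == (0.0, 0.0)

    def test_one_transition_mean_and_se(self):
        a = "A" * 100
        b = "G" + "A" * 99
        seqs = make_alignment({"X": [a] * 3, "Y": [b] * 3})
        mean, se = k2p_population(seqs, "X", "Y", n_boot=200, seed=1)
        assert mean == pytest.approx(k2p_pairwise(a, b), abs=1e-12)
        assert se > 0

    def test_symmetric_in_population_order(self):
        seqs = make_alignment({"X": ["ACGTAAGG" * 10, "ACGTAAGC" * 10],
                               "Y": ["ACGTATGG" * 10, "TCGTAAGG" * 10]})
        assert k2p_population(seqs, "X", "Y", n_boot=100, seed=7) == \
               k2p_population(seqs, "Y", "X", n_boot=100, seed=7)


class TestNei:
    def test_within_identical(self):
        seqs = make_alignment({"X": ["ACGT"] * 4})
        assert nei_within(seqs, "X") == 0.0

    def test_within_hand_enumeration(self):
        # pairs differ by 1, 1, 0 -> K = 2/3
        seqs = make_alignment({"X": ["ACGT", "ACGA", "ACGA"]})
        assert nei_within(seqs, "X") == pytest.approx(2 / 3)

    def test_within_needs_two(self):
        seqs = make_alignment({"X": ["ACGT"], "Y": ["ACGT", "ACGA"]})
        with pytest.raises(InsufficientSampleError):
            nei_within(seqs, "X")

    def test_between_identical_fixed(self):
        seqs = make_alignment({"X": ["ACGT"] * 3, "Y": ["ACGT"] * 3})
        mean, p = nei_between(seqs, "X", "Y", n_perm=99, seed=0)
        assert mean == 0.0
        assert p == 1.0

    def test_between_fixed_five_apart(self):
        seqs = make_alignment({"X": ["AAAAACCCCC"] * 3, "Y": ["AAAAAGGGGG"] * 3})
        mean, _ = nei_between(seqs, "X", "Y", n_perm=49, seed=0)
        assert mean == 5.0

    def test_between_close_to_within_for_random_split(self):
        rng = np.random.default_rng(11)
        pool = []
        base = "ACGT" * 50
        for _ in range(16):
            s = list(base)
            for j in rng.choice(len(base), size=rng.integers(0, 6), replace=False):
                s[j] = rng.choice([c for c in "ACGT" if c != s[j]])
            pool.append("".join(s))
        seqs = make_alignment({"X": pool[:8], "Y": pool[8:]})
        whole = make_alignment({"Z": pool})
        between, _ = nei_between(seqs, "X", "Y", n_perm=1, seed=0)
        assert between == pytest.approx(nei_within(whole, "Z"), rel=0.25)


class TestDiversity:
    def test_pi_monomorphic(self):
        seqs = make_alignment({"X": ["ACGT" * 25] * 5})
        assert nucleotide_diversity(seqs, "X") == 0.0

    def test_pi_division(self):
        seqs = make_alignment({"X": ["A" * 100, "G" + "A" * 99, "G" + "A" * 99]})
        assert nucleotide_diversity(seqs, "X") == pytest.approx(2 / 3 / 100)

    def test_pi_bounded_by_polymorphic_fraction(self, small_sim):
        from sawyerflow import variability_summary

        seqs, _, _ = small_sim
        frac = variability_summary(seqs).n_polymorphic / seqs.length
        for p in seqs.populations:
            assert 0.0 <= nucleotide_diversity(seqs, p) <= frac + 1e-12

    def test_dhap_extremes(self):
        assert haplotype_diversity([1] * 10) == pytest.approx(1.0)
        assert haplotype_diversity([10]) == 0.0

    def test_dhap_hand_value(self):
        assert haplotype_diversity([4, 3, 3]) == pytest.approx((10 / 9) * (1 - 0.34))

    def test_dhap_needs_two(self):
        with pytest.raises(InsufficientSampleError):
            haplotype_diversity([1])


class TestRshr:
    def test_published_values(self, published_tables):
        table, _ = published_tables
        assert rshr(table, "HA") == 1.0
        assert rshr(table, "GX") == 0.0
        assert rshr(table, "JS") == pytest.approx(1 / 3)

    def test_bounds(self, published_tables):
        table, _ = published_tables
        for p in table.populations:
            assert 0.0 <= rshr(table, p) <= 1.0


class TestFst:
    def test_fixed_divergent_pops(self):
        seqs = make_alignment({"X": ["AAAA"] * 4, "Y": ["AAAT"] * 4})
        f, p = pairwise_fst(seqs, "X", "Y", n_perm=999, seed=3)
        assert f == pytest.approx(1.0)
        # only a perfectly sorting permutation ties the observed Fst: p ~ 2/C(8,4)
        assert p < 0.05

    def test_random_split_near_zero_and_negatives_occur(self):
        rng = np.random.default_rng(21)
        fsts = []
        for _ in range(40):
            a, b = [], []
            base = "ACGT" * 10
            for k in range(12):
                s = list(base)
                for j in rng.choice(40, size=rng.integers(1, 4), replace=False):
                    s[j] = rng.choice([c for c in "ACGT" if c != s[j]])
                (a if k < 6 else b).append("".join(s))
            seqs = make_alignment({"X": a, "Y": b})
            try:
                f, _ = pairwise_fst(seqs, "X", "Y", n_perm=0, seed=0)
            except UndefinedStatisticError:
                continue
            fsts.append(f)
        assert abs(np.mean(fsts)) < 0.05
        assert min(fsts) < 0  # negative estimates are reported, not clamped

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(33)
        from conftest import random_toy_pops

        for _ in range(20):
            a, b = random_toy_pops(rng)
            seqs = make_alignment({"X": a, "Y": b})
            f, _ = pairwise_fst(seqs, "X", "Y", n_perm=0, seed=0)
            assert f == pytest.approx(phi_st_bruteforce(a, b), abs=1e-12)

    def test_degenerate(self):
        seqs = make_alignment({"X": ["AAAA"] * 3, "Y": ["AAAA"] * 3})
        with pytest.raises(UndefinedStatisticError):
            pairwise_fst(seqs, "X", "Y", n_perm=0)

    def test_binary_mode_is_frequency_fst(self):
        seqs = make_alignment({"X": ["AAAA"] * 4, "Y": ["AATT"] * 2 + ["AAAA"] * 2})
        f, _ = pairwise_fst(seqs, "X", "Y", mode="binary", n_perm=0)
        assert 0.0 < f <= 1.0

    def test_seed_reproducible(self):
        seqs = make_alignment({"X": ["AAAA", "AAAT", "AATA", "AAAA"],
                               "Y": ["TTAA", "TTAT", "TTAA", "ATAA"]})
        r1 = pairwise_fst(seqs, "X", "Y", n_perm=199, seed=42)
        r2 = pairwise_fst(seqs, "X", "Y", n_perm=199, seed=42)
        assert r1 == r2


class TestGeneFlow:
    def test_half(self):
        assert gene_flow(0.5) == pytest.approx(0.5)

    def test_negative_is_infinite(self):
        assert gene_flow(-0.0026) == math.inf
        assert gene_flow(0.0) == math.inf

    def test_complete_fixation(self):
        assert gene_flow(1.0) == 0.0
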