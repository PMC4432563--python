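import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snptag import GenotypeMatrix, MISSING, SimSpec, simulate_hwe
from snptag.entropy import (
    LOG2_3,
    MiMatrix,
    UndefinedEntropyError,
    exact_joint_entropy,
    joint_entropy_bounds,
    mi_matrix,
    mutual_information,
    pair_joint_counts,
    snp_entropy,
)


class TestSnpEntropy:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((1, 1, 1), LOG2_3),          # equiprobable genotypes: 1.585 bits
            ((25, 50, 25), 1.5),           # HWE at MAF 0.5: 1.5 bits
            ((10, 0, 0), 0.0),             # monomorphic
            ((0, 7, 0), 0.0),
            ((1, 1, 0), 1.0),
        ],
    )
    def test_known_values(self, counts, expected):
        assert snp_entropy(counts) == pytest.approx(expected, abs=1e-9)

    def test_max_is_1585_to_3dp(self):
        assert round(snp_entropy((1, 1, 1)), 3) == 1.585

    def test_zero_total_raises(self):
        with pytest.raises(UndefinedEntropyError):
            snp_entropy((0, 0, 0))

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*(st.integers(0, 50),) * 3).filter(lambda c: sum(c) > 0))
    def test_bounded_and_uniform_maximal(self, counts):
        h = snp_entropy(counts)
        assert -1e-12 <= h <= LOG2_3 + 1e-12
        if counts[0] == counts[1] == counts[2]:
            assert h == pytest.approx(LOG2_3)
        else:
            assert h < LOG2_3


class TestMutualInformation:
    def test_self_information_equals_entropy(self):
        table = np.diag([3, 4, 5])
        assert mutual_information(table) == pytest.approx(snp_entropy((3, 4, 5)))

    def test_independent_product_table_is_zero(self):
        px = np.array([2, 3, 5], dtype=float)
        table = np.outer(px, px)
        assert mutual_information(table) == pytest.approx(0.0, abs=1e-12)

    def test_two_state_diagonal_is_one_bit(self):
        # [[2,0],[0,2]] padded: hand evaluation of the double sum gives 1 bit
        table = np.zeros((3, 3))
        table[0, 0] = table[1, 1] = 2
        assert mutual_information(table) == pytest.approx(1.0)

    def test_empty_table_raises(self):
        with pytest.raises(UndefinedEntropyError):
            mutual_information(np.zeros((3, 3)))

    def test_agrees_with_sklearn(self):
        # independent oracle for the double sum on an arbitrary table
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        table = np.array([[30, 5, 1], [4, 40, 6], [2, 7, 25]], dtype=float)
        ref = sklearn_metrics.mutual_info_score(None, None, contingency=table) / np.log(2)
        assert mutual_information(table) == pytest.approx(ref, rel=1e-10)


class TestMiMatrix:
    def test_shape_symmetry_and_diagonal(self, hwe_population):
        mi = mi_matrix(hwe_population)
        n = hwe_population.n_snps
        assert mi.values.shape == (n, n)
        assert np.allclose(mi.values, mi.values.T)
        for s in mi.snp_ids:
            assert 0 <= mi.entropy(s) <= LOG2_3

    def test_independent_snps_near_zero_mi(self):
        M = simulate_hwe(SimSpec((0.4, 0.5), 10_000, seed=3))
        mi = mi_matrix(M)
        # sampling-noise scale ~ log2(e) * df / (2n) with df=4
        assert mi.values[0, 1] < 0.01

    def test_duplicated_snp_mi_equals_entropy(self, hwe_population):
        calls = np.column_stack([hwe_population.calls[:, 0]] * 2)
        M = GenotypeMatrix(hwe_population.sample_ids, ["a", "b"], calls)
        mi = mi_matrix(M)
        assert mi.mi("a", "b") == pytest.approx(mi.entropy("a"))

    def test_invariant_under_sample_permutation(self, hwe_population):
        rng = np.random.default_rng(0)
        perm = rng.permutation(hwe_population.n_samples)
        M2 = GenotypeMatrix(
            [hwe_population.sample_ids[i] for i in perm],
            hwe_population.snp_ids,
            hwe_population.calls[perm],
        )
        assert np.allclose(mi_matrix(hwe_population).values, mi_matrix(M2).values)

    def test_pairwise_complete_case(self):
        a = np.array([0, 1, 2, MISSING, 1], dtype=np.int8)
        b = np.array([0, MISSING, 2, 1, 1], dtype=np.int8)
        joint = pair_joint_counts(a, b)
        assert joint.sum() == 3  # only co-observed samples
        assert joint[0, 0] == joint[2, 2] == joint[1, 1] == 1

    def test_zero_co_observed_pair_raises(self):
        calls = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
        M = GenotypeMatrix(["s1", "s2"], ["a", "b"], calls)
        with pytest.raises(ValueError, match="co-observed"):
            mi_matrix(M)

    def test_tsv_round_trip(self, hwe_population, tmp_path):
        mi = mi_matrix(hwe_population)
        p = tmp_path / "mi.tsv"
        mi.to_tsv(p)
        back = MiMatrix.from_tsv(p)
        assert back.snp_ids == mi.snp_ids
        # format carries 12 significant digits -> half-ulp relative error
        assert np.allclose(back.values, mi.values, rtol=5e-12, atol=1e-14)


class TestExactJointEntropy:
    def test_single_snp_reduces_to_entropy(self, hwe_population):
        from snptag.entropy import genotype_counts

        s = hwe_population.snp_ids[0]
        h1 = exact_joint_entropy(hwe_population, [s])
        assert h1 == pytest.approx(snp_entropy(genotype_counts(hwe_population.snp_column(s))))

    def test_exact_copy_adds_nothing(self, hwe_population):
        calls = np.column_stack([hwe_population.calls[:, 0]] * 2)
        M = GenotypeMatrix(hwe_population.sample_ids, ["a", "b"], calls)
        assert exact_joint_entropy(M, ["a", "b"]) == pytest.approx(
            exact_joint_entropy(M, ["a"])
        )

    def test_uniform_product_population(self):
        # all 9 two-SNP combinations equally often -> log2 9
        combos = np.array([(x, y) for x in range(3) for y in range(3)], dtype=np.int8)
        M = GenotypeMatrix([f"s{i}" for i in range(9)], ["a", "b"], combos)
        assert exact_joint_entropy(M, ["a", "b"]) == pytest.approx(np.log2(9))

    def test_cap_refusal(self, hwe_population):
        with pytest.raises(ValueError, match="cap"):
            exact_joint_entropy(hwe_population, hwe_population.snp_ids[:5], cap=4)


class TestJointEntropyBounds:
    def _mi(self, h, pairs):
        n = len(h)
        v = np.diag(np.asarray(h, dtype=float)).copy()
        for (i, j), val in pairs.items():
            v[i, j] = v[j, i] = val
        return MiMatrix([f"x{i}" for i in range(n)], v)

    def test_single_snp_bounds_collapse(self):
        mi = self._mi([1.5], {})
        b = joint_entropy_bounds(mi, ["x0"])
        assert (b.h_sum, b.h_lower, b.h_upper) == (1.5, 1.5, 1.5)

    def test_snp_plus_exact_copy(self):
        mi = self._mi([1.5, 1.5], {(0, 1): 1.5})
        b = joint_entropy_bounds(mi, ["x0", "x1"])
        assert b.h_lower == pytest.approx(1.5)
        assert b.h_upper == pytest.approx(1.5)

    def test_22_independent_snps_give_33_bits(self):
        mi = self._mi([1.5] * 22, {})
        b = joint_entropy_bounds(mi, mi.snp_ids)
        assert b.h_lower == pytest.approx(33.0)
        assert b.h_upper == pytest.approx(33.0)

    def test_lower_clamped_at_max_marginal(self):
        # three mutual copies over-subtract pairwise MI; clamp keeps H_L >= max H
        mi = self._mi([1.5] * 3, {(0, 1): 1.5, (0, 2): 1.5, (1, 2): 1.5})
        b = joint_entropy_bounds(mi, mi.snp_ids)
        assert b.h_lower == pytest.approx(1.5)
        assert b.h_lower <= b.h_upper <= b.h_sum

    def test_upper_rule_variants(self):
        mi = self._mi([1.5, 1.4, 1.3], {(0, 1): 0.2, (0, 2): 0.05, (1, 2): 0.3})
        b_max = joint_entropy_bounds(mi, mi.snp_ids, upper_rule="max")
        b_first = joint_entropy_bounds(mi, mi.snp_ids, upper_rule="first")
        # max rule subtracts 0.2 + 0.3; first-anchor rule 0.2 + 0.05
        assert b_max.h_upper == pytest.approx(4.2 - 0.5)
        assert b_first.h_upper == pytest.approx(4.2 - 0.25)
        assert b_max.h_upper <= b_first.h_upper

    def test_unknown_snp_raises(self):
        mi = self._mi([1.0], {})
        with pytest.raises(KeyError):
            joint_entropy_bounds(mi, ["nope"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bounds_bracket_exact_joint_entropy(self, seed):
        # HWE independence plus one injected-LD pair, N=5, n=3000
        from snptag import LdSpec, inject_ld

        rng = np.random.default_rng(seed)
        freqs = tuple(rng.uniform(0.2, 0.5, 5))
        M = simulate_hwe(SimSpec(freqs, 3000, seed=seed))
        M = inject_ld(M, LdSpec(((M.snp_ids[0], M.snp_ids[1], 0.7),)), seed=seed)
        mi = mi_matrix(M)
        b = joint_entropy_bounds(mi, M.snp_ids)
        h_exact = exact_joint_entropy(M, M.snp_ids)
        eps = 0.05  # sampling/plug-in tolerance at n=3000
        assert b.h_lower - eps <= h_exact <= b.h_upper + eps
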