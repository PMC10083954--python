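"""Diversity / LD / differentiation statistics against brute-force oracles."""

from itertools import combinations
from math import comb, log, sqrt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parshift import popgen


def brute_pairwise_pi(A: np.ndarray, L: int) -> float:
    """Mean pairwise difference per site over all haplotype pairs."""
    n = A.shape[0]
    total = 0
    for i, j in combinations(range(n), 2):
        total += np.sum(A[i] != A[j])
    return total / comb(n, 2) / L


def brute_tajimas_d(A: np.ndarray) -> float:
    """Independent textbook implementation with explicit loops."""
    n, S_cols = A.shape[0], []
    for j in range(A.shape[1]):
        if len(set(A[:, j])) > 1:
            S_cols.append(j)
    S = len(S_cols)
    k_hat = 0.0
    for i, j in combinations(range(n), 2):
        k_hat += np.sum(A[i] != A[j])
    k_hat /= comb(n, 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (k_hat - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))


def brute_kst(A: np.ndarray, labels: list[str]) -> float:
    def mean_logd(pairs):
        vals = [log(1 + np.sum(A[i] != A[j])) for i, j in pairs]
        return sum(vals) / len(vals)

    n = A.shape[0]
    within = []
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        within += list(combinations(idx, 2))
    k_s = mean_logd(within)
    k_t = mean_logd(list(combinations(range(n), 2)))
    return 1 - k_s / k_t


def random_matrix(rng, n=6, sites=20, alleles=2):
    return rng.integers(0, alleles, size=(n, sites)).astype(np.int8)


class TestPi:
    def test_identical_haplotypes_zero(self):
        A = np.zeros((4, 10), dtype=np.int8)
        assert popgen.pi(A, 100) == 0.0

    def test_two_haplotypes_one_difference(self):
        A = np.array([[0], [1]], dtype=np.int8)
        assert popgen.pi(A, 100, min_called=2) == pytest.approx(0.01)

    def test_matches_brute_force_pairwise(self, rng):
        A = random_matrix(rng, n=6, sites=30, alleles=4)
        assert popgen.pi(A, 30) == pytest.approx(brute_pairwise_pi(A, 30), abs=1e-12)

    def test_zero_sites_is_null(self):
        assert popgen.pi(np.zeros((4, 0), dtype=np.int8), 0) is None

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_frequency_and_pairwise_forms_agree(self, seed):
        A = random_matrix(np.random.default_rng(seed), n=8, sites=25, alleles=3)
        assert popgen.pi(A, 25) == pytest.approx(brute_pairwise_pi(A, 25), abs=1e-12)


class TestTajimasD:
    def test_all_singletons_negative(self):
        A = np.zeros((10, 5), dtype=np.int8)
        for j in range(5):
            A[j, j] = 1
        assert popgen.tajimas_d(A) < 0

    def test_balanced_haplotype_structure_positive(self):
        A = np.zeros((10, 4), dtype=np.int8)
        A[5:, :] = 1  # two haplotype classes, 4 fixed-different sites
        assert popgen.tajimas_d(A) > 0

    def test_no_segregating_sites_null(self):
        assert popgen.tajimas_d(np.zeros((5, 3), dtype=np.int8)) is None

    def test_matches_independent_implementation(self, rng):
        for _ in range(5):
            A = random_matrix(rng, n=8, sites=40)
            if popgen.segregating_sites(A) == 0:
                continue
            assert popgen.tajimas_d(A) == pytest.approx(brute_tajimas_d(A), abs=1e-10)


class TestZns:
    def test_perfect_association_is_one(self):
        A = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.int8)
        assert popgen.kellys_zns(A) == pytest.approx(1.0)

    def test_exact_linkage_equilibrium_is_zero(self):
        # haplotype counts factorise exactly: 00,01,10,11 equally frequent
        A = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        assert popgen.kellys_zns(A) == pytest.approx(0.0, abs=1e-12)

    def test_single_site_is_null(self):
        A = np.array([[0], [1], [0], [1]], dtype=np.int8)
        assert popgen.kellys_zns(A) is None

    def test_four_site_toy_matches_pair_enumeration(self, rng):
        A = random_matrix(rng, n=8, sites=4)
        expected_terms = []
        for a, b in combinations(range(4), 2):
            pa, pb = A[:, a].mean(), A[:, b].mean()
            if pa in (0, 1) or pb in (0, 1):
                continue
            pab = (A[:, a] * A[:, b]).mean()
            expected_terms.append((pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb)))
        assert popgen.kellys_zns(A) == pytest.approx(np.mean(expected_terms), abs=1e-12)


class TestKst:
    def test_zero_within_positive_between_is_one(self):
        A = np.array([[0] * 5, [0] * 5, [1] * 5, [1] * 5], dtype=np.int8)
        assert popgen.kst_star(A, ["a", "a", "b", "b"]) == pytest.approx(1.0)

    def test_three_vs_three_matches_direct_arithmetic(self, rng):
        A = random_matrix(rng, n=6, sites=30)
        labels = ["a", "a", "a", "b", "b", "b"]
        assert popgen.kst_star(A, labels) == pytest.approx(brute_kst(A, labels), abs=1e-12)

    def test_invariant_to_group_relabelling_and_within_group_shuffles(self, rng):
        A = random_matrix(rng, n=8, sites=25)
        labels = ["a"] * 4 + ["b"] * 4
        base = popgen.kst_star(A, labels)
        assert popgen.kst_star(A, ["b"] * 4 + ["a"] * 4) == pytest.approx(base)
        perm = [1, 3, 0, 2, 6, 4, 7, 5]  # shuffles within each group
        assert popgen.kst_star(A[perm], labels) == pytest.approx(base)

    def test_identical_sequences_null(self):
        A = np.zeros((4, 5), dtype=np.int8)
        assert popgen.kst_star(A, ["a", "a", "b", "b"]) is None


class TestKstPermutation:
    def test_exact_enumeration_small_design(self, rng):
        # 3v3 individuals: only C(6,3)=20 label arrangements -> exact p
        A = random_matrix(rng, n=12, sites=40)
        inds = [f"i{k // 2}" for k in range(12)]
        labels = {f"i{k}": ("M" if k < 3 else "F") for k in range(6)}
        obs, p = popgen.kst_permutation_p(A, inds, labels, n_perm=1000, seed=1)
        # independent enumeration over all 20 splits
        from itertools import combinations as icombs

        hits = 0
        for subset in icombs(range(6), 3):
            lab = {f"i{k}": ("M" if k in subset else "F") for k in range(6)}
            hap_labels = [lab[i] for i in inds]
            k = popgen.kst_star(A, hap_labels)
            if k >= obs - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / 20)
        assert 0 < p <= 1

    def test_sex_linked_gene_gives_small_p(self, default_dataset):
        """A gene with a distinct Y haplotype pool separates males from
        females; the permutation test should detect it."""
        from parshift.degeneracy import classify_degeneracy, fourfold_sites
        from parshift.types import Role, Sex, Species

        ds = default_dataset
        gene = "g050"  # right region, anciently sex-linked
        haps = ds.haplotypes[gene]
        by_id = {s.id: s for s in ds.samples}
        rows = [i for i, sid in enumerate(haps.sample_ids)
                if by_id[sid].species is Species.A and by_id[sid].role is Role.WILD]
        sub = haps.select(rows)
        mask = classify_degeneracy(ds.annotations[gene])
        sites, L4 = fourfold_sites(mask, sub)
        codes = sub.allele_codes(sites)
        labels = {sid: by_id[sid].sex.value for sid in set(sub.sample_ids)}
        obs, p = popgen.kst_permutation_p(codes, sub.sample_ids, labels, n_perm=1000, seed=3)
        assert obs > 0
        assert p <= 0.01


class TestHudsonFst:
    def test_panmictic_pools_average_zero(self, rng):
        # labels carry no information -> estimator centred on 0
        labels = ["a"] * 4 + ["b"] * 4
        values = [popgen.hudson_fst(random_matrix(rng, n=8, sites=50), labels) for _ in range(200)]
        assert abs(np.mean(values)) < 0.03

    def test_reciprocally_monomorphic_fixed_difference_is_one(self):
        A = np.array([[0] * 3, [0] * 3, [1] * 3, [1] * 3], dtype=np.int8)
        assert popgen.hudson_fst(A, ["a", "a", "b", "b"]) == pytest.approx(1.0)

    def test_four_vs_four_matches_brute_force(self, rng):
        A = random_matrix(rng, n=8, sites=40)
        labels = ["a"] * 4 + ["b"] * 4
        idx_a, idx_b = range(4), range(4, 8)
        pw = lambda pairs: np.mean([np.sum(A[i] != A[j]) for i, j in pairs])
        pw_a = pw(list(combinations(idx_a, 2)))
        pw_b = pw(list(combinations(idx_b, 2)))
        pw_ab = pw([(i, j) for i in idx_a for j in idx_b])
        expected = 1 - 0.5 * (pw_a + pw_b) / pw_ab
        assert popgen.hudson_fst(A, labels) == pytest.approx(expected, abs=1e-12)
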