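"""HKA and ML-HKA: analytic points, grid-search oracles and invariants."""

import numpy as np
import pytest

from parshift.hka import (
    HkaLocus,
    chisq_upper_tail,
    concatenate_loci,
    harmonic,
    hka_test,
    mlhka_fit,
)


def independent_x2(loci, thetas, tau):
    """X^2 recomputed with explicit loops, independent of the implementation."""
    total = 0.0
    for loc, theta in zip(loci, thetas):
        a = sum(1.0 / i for i in range(1, loc.n))
        b = sum(1.0 / i**2 for i in range(1, loc.n))
        es = loc.x * theta * a
        vs = es + (loc.x * theta) ** 2 * b
        ed = theta * (tau + loc.x)
        vd = ed + theta**2
        total += (loc.S - es) ** 2 / vs + (loc.D - ed) ** 2 / vd
    return total


def poisson_loglik(loci, thetas, tau, ks):
    """Direct Poisson log-likelihood, written independently of the
    implementation's profile shortcut."""
    lnl = 0.0
    for loc, theta, k in zip(loci, thetas, ks):
        a = sum(1.0 / i for i in range(1, loc.n))
        lam = k * loc.x * theta * a
        mu = theta * (tau + k * loc.x)
        lnl += loc.S * np.log(lam) - lam + loc.D * np.log(mu) - mu
    return lnl


def saturated_term(S, D):
    """Poisson log-likelihood of a locus whose rates hit the data exactly."""
    term = lambda x: x * np.log(x) - x if x > 0 else 0.0
    return term(S) + term(D)


def grid_maximise_reference_part(ref_loci, rounds=10, points=9):
    """Independent zooming grid over (theta_1..theta_R, tau) for the k=1
    reference loci (the selected locus's free (theta, k) pair can match
    its own counts exactly at any tau, contributing the saturated term)."""
    R = len(ref_loci)
    centres = np.array([15.0] * R + [4.0])
    widths = np.array([14.5] * R + [3.8])
    best = (-np.inf, None)
    for _ in range(rounds):
        axes = [np.linspace(max(c - w, 1e-3), c + w, points) for c, w in zip(centres, widths)]
        grids = np.meshgrid(*axes, indexing="ij")
        flat = np.stack([g.ravel() for g in grids], axis=1)
        for params in flat:
            val = poisson_loglik(ref_loci, params[:R], params[R], [1.0] * R)
            if val > best[0]:
                best = (val, params)
        centres = best[1]
        widths = widths / 2.5
    return best


class TestChisq:
    def test_zero_statistic_gives_one(self):
        assert chisq_upper_tail(0.0, 1) == 1.0
        assert chisq_upper_tail(0.0, 5) == 1.0

    @pytest.mark.parametrize(
        "x2,p",
        [(4.962, 0.0259), (5.104, 0.0239), (2.383, 0.1226), (4.368, 0.0366)],
    )
    def test_reported_chi_square_p_pairs(self, x2, p):
        # printed to 4 decimal places
        assert chisq_upper_tail(x2, 1) == pytest.approx(p, abs=1e-4)

    def test_invalid_input_raises(self):
        with pytest.raises(ValueError):
            chisq_upper_tail(-1.0, 1)


class TestHkaTest:
    def test_model_manifold_point_fits_exactly(self):
        # S = theta * a_2 = theta, D = theta (tau + 1): theta=10, tau=2
        loci = [HkaLocus("a", S=10, n=2, L=500, D=30), HkaLocus("b", S=10, n=2, L=500, D=30)]
        res = hka_test(loci)
        assert res.x2 == pytest.approx(0.0, abs=1e-6)
        assert res.theta == pytest.approx([10, 10], rel=1e-3)
        assert res.tau == pytest.approx(2.0, rel=1e-3)
        assert res.p == pytest.approx(1.0, abs=1e-4)

    def test_perturbed_counts_satisfy_moment_equations(self):
        """The classical estimators solve: total S and total D match their
        expectations, and the per-locus totals S_i + D_i match for all but
        the last locus. For n = 2, a = 1, the 2-locus system has the
        closed-form solution tau = 1, theta = (50/3, 40/3)."""
        loci = [HkaLocus("a", S=20, n=2, L=500, D=30), HkaLocus("b", S=10, n=2, L=500, D=30)]
        res = hka_test(loci)
        assert res.tau == pytest.approx(1.0, abs=1e-8)
        assert res.theta == pytest.approx([50 / 3, 40 / 3], abs=1e-8)
        # moment identities, written out independently
        assert res.theta.sum() * 1.0 == pytest.approx(30.0, abs=1e-8)  # sum x theta a = sum S
        assert np.sum(res.theta * (res.tau + 1.0)) == pytest.approx(60.0, abs=1e-8)
        assert res.theta[0] * (1.0 + res.tau + 1.0) == pytest.approx(50.0, abs=1e-8)
        assert res.x2 > 0
        assert res.x2 == pytest.approx(independent_x2(loci, res.theta, res.tau), abs=1e-10)

    def test_ploidy_factor_enters_expectations(self):
        auto = [HkaLocus("a", S=10, n=10, L=500, D=30, x=1.0),
                HkaLocus("b", S=10, n=10, L=500, D=30, x=1.0)]
        xlink = [HkaLocus("a", S=10, n=10, L=500, D=30, x=0.75),
                 HkaLocus("b", S=10, n=10, L=500, D=30, x=0.75)]
        # both are exactly fittable (symmetric loci), but thetas differ by 1/x
        r_auto, r_x = hka_test(auto), hka_test(xlink)
        assert r_x.theta[0] == pytest.approx(r_auto.theta[0] / 0.75, rel=1e-2)

    def test_requires_two_loci(self):
        with pytest.raises(ValueError):
            hka_test([HkaLocus("a", S=5, n=4, L=100, D=10)])


class TestMlhka:
    def test_neutral_counts_give_unit_k_and_zero_lrt(self):
        # counts sitting exactly on the k=1 manifold
        n, theta, tau = 10, 12.0, 3.0
        a = harmonic(n)
        loci = [
            HkaLocus(f"r{i}", S=round(theta * a), n=n, L=800, D=round(theta * (tau + 1)))
            for i in range(4)
        ] + [HkaLocus("test", S=round(theta * a), n=n, L=800, D=round(theta * (tau + 1)))]
        res = mlhka_fit(loci, ["test"])
        assert res.k["test"] == pytest.approx(1.0, abs=0.02)
        assert res.lrt == pytest.approx(0.0, abs=1e-4)
        assert res.p == pytest.approx(1.0, abs=1e-3)

    def test_optimum_matches_independent_oracle(self):
        """With one selected locus, its free (theta, k) pair saturates its
        own counts at the tau the reference loci determine, so the exact
        maximum is grid-max(reference part over theta_ref, tau) + the
        closed-form saturated term of the selected locus (valid whenever
        D_sel > S_sel / a_n, as here)."""
        ref = [HkaLocus("r1", S=28, n=10, L=800, D=45),
               HkaLocus("r2", S=24, n=10, L=800, D=38)]
        sel = HkaLocus("sel", S=80, n=10, L=800, D=40)
        res = mlhka_fit(ref + [sel], ["sel"])
        grid_val, _ = grid_maximise_reference_part(ref)
        expected = grid_val + saturated_term(sel.S, sel.D)
        assert res.lnl_alt == pytest.approx(expected, abs=1e-3)

    def test_alternative_never_below_null(self):
        loci = [HkaLocus("ref", S=30, n=10, L=800, D=50),
                HkaLocus("sel", S=31, n=10, L=800, D=49)]
        res = mlhka_fit(loci, ["sel"])
        assert res.lnl_alt >= res.lnl_null
        assert res.lrt >= 0

    def test_needs_a_neutral_reference(self):
        loci = [HkaLocus("a", S=5, n=4, L=100, D=10)]
        with pytest.raises(ValueError, match="reference"):
            mlhka_fit(loci, ["a"])

    def test_lrt_invariant_to_common_length_rescaling(self):
        loci = [HkaLocus("ref", S=28, n=10, L=800, D=45),
                HkaLocus("sel", S=80, n=10, L=800, D=40)]
        scaled = [HkaLocus(l.locus_id, S=l.S, n=l.n, L=l.L * 3, D=l.D, x=l.x) for l in loci]
        assert mlhka_fit(loci, ["sel"]).lrt == pytest.approx(mlhka_fit(scaled, ["sel"]).lrt, abs=1e-6)

    def test_sign_agreement_with_classical_hka(self):
        """Both formulations should agree on which locus has the
        polymorphism excess."""
        loci = [HkaLocus("a", S=60, n=10, L=800, D=40),
                HkaLocus("b", S=20, n=10, L=800, D=40)]
        res_cls = hka_test(loci)
        a = harmonic(10)
        excess_cls = [l.S - x * th * a for l, th, x in zip(loci, res_cls.theta, [1, 1])]
        res_ml = mlhka_fit(loci, ["a"])
        assert excess_cls[0] > 0 and excess_cls[1] < 0
        assert res_ml.k["a"] > 1


class TestPlantedDiversityExcess:
    def test_concatenated_x2_grows_with_par_diversity_multiplier(self):
        """Doubling pseudoautosomal diversity (balancing-selection proxy
        k = 2) without touching divergence must inflate the concatenated
        left-vs-right X2 relative to the k = 1 datasets (paired seeds)."""
        from parshift.degeneracy import classify_degeneracy
        from parshift.pipeline import hka_locus_from_haplotypes
        from parshift.simulate import SimulationConfig, simulate_dataset
        from parshift.types import Sex, Species

        def concat_x2(par_k, seed):
            ds = simulate_dataset(SimulationConfig(par_k=par_k), seed=seed,
                                  with_fragments=False, with_counts=False)
            left, right = [], []
            for g, regime in ds.truth.regimes.items():
                if regime == "mid":
                    continue
                x = 0.75 if regime == "right" else 1.0
                mask = classify_degeneracy(ds.annotations[g])
                loc = hka_locus_from_haplotypes(g, ds.haplotypes[g], mask, ds.samples,
                                                Species.A, Sex.F, x)
                if loc is not None:
                    (left if regime == "left" else right).append(loc)
            pair = [concatenate_loci(left, "L"), concatenate_loci(right, "R")]
            return hka_test(pair).x2

        wins = sum(concat_x2(2.0, 60_000 + rep) > concat_x2(1.0, 60_000 + rep) for rep in range(8))
        assert wins >= 7


class TestConcatenate:
    def test_single_locus_identity(self):
        l = HkaLocus("a", S=3, n=8, L=100, D=7)
        c = concatenate_loci([l])
        assert (c.S, c.n, c.L, c.D) == (3, 8, 100, 7)

    def test_additivity(self):
        a = HkaLocus("a", S=3, n=8, L=100, D=7)
        b = HkaLocus("b", S=7, n=6, L=200, D=11)
        c = concatenate_loci([a, b])
        assert (c.S, c.L, c.D) == (10, 300, 18)
        assert c.n == 6

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            concatenate_loci([])

    def test_mixed_ploidy_rejected(self):
        a = HkaLocus("a", S=3, n=8, L=100, D=7, x=1.0)
        b = HkaLocus("b", S=7, n=6, L=200, D=11, x=0.75)
        with pytest.raises(ValueError):
            concatenate_loci([a, b])
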