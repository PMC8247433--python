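"""Unit tests for the closed-form inclusive-fitness machinery."""

import math
from fractions import Fraction

import pytest

from foundress import (
    DegenerateGroupError,
    GroupContext,
    Kinship,
    Ploidy,
    SexAllocationStrategy,
    consanguinities,
    equilibrium_inbredness,
    frank_decomposition,
    harmonic_mean_foundress_number,
    inclusive_fitness,
    marginal_effect,
    reproductive_values,
    unbeatable_z_closed,
    unbeatable_z_equal_groups,
    unbeatable_z_general,
    unbeatable_z_variable_groups,
)


class TestEquilibriumInbredness:
    def test_values(self):
        assert equilibrium_inbredness(1) == 1
        assert equilibrium_inbredness(2) == Fraction(1, 5)
        assert equilibrium_inbredness(10**6) < 1e-6

    def test_decreasing(self):
        xs = [1, 1.5, 2, 5, 50]
        fs = [float(equilibrium_inbredness(x)) for x in xs]
        assert all(a > b for a, b in zip(fs, fs[1:]))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            equilibrium_inbredness(0.5)


class TestHarmonicMeanFoundressNumber:
    def test_degenerate(self):
        assert harmonic_mean_foundress_number({4: 1.0}) == 4

    def test_two_point_against_enumeration(self):
        # brute force: one size-1 group and one size-3 group produce equal
        # per-foundress daughter cohorts; list every daughter's maternal
        # group size and take the harmonic mean over daughters
        daughters = [1] * 1 + [3] * 3
        oracle = len(daughters) / sum(Fraction(1, n) for n in daughters)
        assert oracle == 2
        assert harmonic_mean_foundress_number({1: 0.5, 3: 0.5}) == oracle

    def test_duplicate_sizes_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean_foundress_number([(2, 0.25), (2, 0.75)])

    def test_empty_and_zero(self):
        with pytest.raises(ValueError):
            harmonic_mean_foundress_number({})
        with pytest.raises(ValueError):
            harmonic_mean_foundress_number({2: 0.0, 3: 0.0})


class TestConsanguinities:
    def test_diplodiploid_outbred_unrelated(self):
        kin = consanguinities("D", "U", 0)
        assert kin.p_d == kin.p_s == Fraction(1, 4)
        assert kin.p_m == 0 and kin.p_f == 0

    def test_haplodiploid_outbred_sisters(self):
        kin = consanguinities("H", "S", 0)
        assert kin.p_d == Fraction(1, 4)
        assert kin.p_s == Fraction(1, 2)
        assert kin.p_m == Fraction(3, 8)

    def test_complete_inbredness_collapses(self):
        kin = consanguinities("H", "S", 1)
        assert kin.p_d == kin.p_s == kin.p_m == 1

    def test_diplodiploid_sisters(self):
        kin = consanguinities("D", "S", Fraction(1, 5))
        assert kin.p_m == Fraction(1 + 7 * Fraction(1, 5), 8) == kin.p_f

    def test_domain_error(self):
        with pytest.raises(ValueError):
            consanguinities("D", "U", 1.5)


class TestReproductiveValues:
    def test_ratios(self):
        assert reproductive_values("D").v_f / reproductive_values("D").v_m == 1
        assert reproductive_values("H").v_f / reproductive_values("H").v_m == 2

    def test_scale_invariance_of_z_star(self):
        from foundress.kin import ReproductiveValues

        kin = consanguinities("H", "S", Fraction(1, 10))
        rv = reproductive_values("H")
        rv3 = ReproductiveValues(v_f=3 * rv.v_f, v_m=3 * rv.v_m)
        assert (
            unbeatable_z_general(4, kin, rv).z_star
            == unbeatable_z_general(4, kin, rv3).z_star
        )


class TestInclusiveFitness:
    def test_sole_foundress_closed_form(self):
        # n = 1: her own sons sire all her daughters, so
        # H = N (1 - z) (p_d v_f + p_s v_m)
        kin = consanguinities("H", "U", 0.2)
        rv = reproductive_values("H")
        ctx = GroupContext(n=1, f=0.2, N=1000)
        z = 0.3
        H = inclusive_fitness(SexAllocationStrategy(z=z), ctx, kin, rv, z_others=z)
        expected = 1000 * (1 - z) * (kin.p_d * rv.v_f + kin.p_s * rv.v_m)
        assert math.isclose(float(H), float(expected), rel_tol=1e-12)

    def test_term_by_term_oracle(self):
        # independent direct summation of the four terms of H
        kin = consanguinities("H", "U", 0.2)
        rv = reproductive_values("H")
        n, N, z = 2, 10**6, 0.2
        ctx = GroupContext(n=n, f=0.2, N=N)
        H = inclusive_fitness(SexAllocationStrategy(z=z), ctx, kin, rv, z_others=z)
        N_d, N_s = N * (1 - z), N * z
        N_f, N_m = (n - 1) * N * (1 - z), (n - 1) * N * z
        share_own = N_s / (N_s + N_m)
        oracle = (
            N_d * float(kin.p_d) * float(rv.v_f)
            + N_f * float(kin.p_f) * float(rv.v_f)
            + (N_d + N_f) * share_own * float(kin.p_s) * float(rv.v_m)
            + (N_d + N_f) * (1 - share_own) * float(kin.p_m) * float(rv.v_m)
        )
        assert math.isclose(float(H), oracle, rel_tol=1e-12)

    def test_no_relatedness_asymmetry_means_no_male_bias(self):
        # p_m = p_s and p_f = p_d: kin-value of local males and females is
        # symmetric between foundresses, so z* collapses to 0
        from foundress.kin import KinCoefficients

        kin = KinCoefficients(p_d=0.3, p_s=0.4, p_f=0.3, p_m=0.4)
        rv = reproductive_values("D")
        assert unbeatable_z_general(5, kin, rv).z_star == 0

    def test_degenerate_group_error(self):
        kin = consanguinities("D", "U", 0)
        rv = reproductive_values("D")
        ctx = GroupContext(n=1, f=0, N=100)
        with pytest.raises(DegenerateGroupError):
            inclusive_fitness(SexAllocationStrategy(z=0), ctx, kin, rv, z_others=0)


class TestMarginalEffect:
    @pytest.mark.parametrize("mode,kinship", [("D", "U"), ("D", "S"), ("H", "U"), ("H", "S")])
    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_zero_at_optimum_positive_below_negative_above(self, mode, kinship, n):
        f = 0.1
        z_star = float(unbeatable_z_closed(mode, kinship, n, f).z_star)
        kin = consanguinities(mode, kinship, f)
        rv = reproductive_values(mode)
        ctx = GroupContext(n=n, f=f, N=1)
        d0 = marginal_effect(z_star, ctx, kin, rv)
        assert abs(d0) < 1e-6
        assert marginal_effect(z_star / 2, ctx, kin, rv) > 0
        assert marginal_effect(min(1.0, z_star * 1.5), ctx, kin, rv) < 0

    def test_sole_foundress_always_negative(self):
        kin = consanguinities("H", "U", 0)
        rv = reproductive_values("H")
        ctx = GroupContext(n=1, f=0, N=1)
        assert marginal_effect(0.1, ctx, kin, rv) < 0

    def test_invariant_to_haplodiploid_sister_pf(self):
        # p_f is not given by the theory for haplodiploid sister groups; it
        # cancels from dH/ddelta
        rv = reproductive_values("H")
        ctx = GroupContext(n=3, f=0.2, N=1)
        vals = [
            marginal_effect(0.1, ctx, consanguinities("H", "S", 0.2, p_f_sisters_haplodiploid=pf), rv)
            for pf in (0.0, 0.3, 1.0)
        ]
        assert max(vals) - min(vals) < 1e-12


class TestUnbeatableStrategies:
    def test_general_reduces_to_hamilton(self):
        kin = consanguinities("D", "U", 0)
        rv = reproductive_values("D")
        assert unbeatable_z_general(4, kin, rv).z_star == Fraction(3, 8)

    def test_general_zero_for_sole_foundress(self):
        kin = consanguinities("H", "S", 0.3)
        rv = reproductive_values("H")
        assert unbeatable_z_general(1, kin, rv).z_star == 0

    def test_general_matches_sister_closed_form(self):
        kin = consanguinities("H", "S", 0)
        rv = reproductive_values("H")
        assert unbeatable_z_general(2, kin, rv).z_star == Fraction(1, 16)

    def test_general_rejects_pm_above_ps(self):
        from foundress.kin import KinCoefficients

        kin = KinCoefficients(p_d=0.25, p_s=0.25, p_f=0.5, p_m=0.5)
        with pytest.raises(ValueError):
            unbeatable_z_general(2, kin, reproductive_values("D"))

    @pytest.mark.parametrize(
        "mode,kinship,n,f,expected",
        [
            ("D", "U", 2, Fraction(7, 10), Fraction(1, 4)),  # f-independent
            ("H", "U", 2, Fraction(1, 5), Fraction(3, 14)),
            ("H", "S", 2, 0, Fraction(1, 16)),
            ("D", "S", 3, Fraction(1, 2), Fraction(1, 30)),
        ],
    )
    def test_closed_forms(self, mode, kinship, n, f, expected):
        assert unbeatable_z_closed(mode, kinship, n, f).z_star == expected

    @pytest.mark.parametrize(
        "mode,kinship,n,expected",
        [
            ("D", "S", 2, Fraction(1, 16)),  # (n-1)^2 / (4 n^2)
            ("H", "U", 2, Fraction(3, 14)),  # (n-1)(2n-1) / (n(4n-1))
            ("H", "S", 3, Fraction(4, 66)),  # (n-1)^2 / (2n(4n-1))
        ],
    )
    def test_equal_groups_printed_reductions(self, mode, kinship, n, expected):
        assert unbeatable_z_equal_groups(mode, kinship, n).z_star == expected

    @pytest.mark.parametrize(
        "mode,kinship,n,nu,expected",
        [
            ("D", "S", 2, 2, Fraction(1, 16)),  # consistency with equal groups
            ("H", "U", 3, 2, Fraction(6, 21)),  # (n-1)(2nu-1) / (n(4nu-1))
            ("H", "S", 2, 4, Fraction(3, 60)),  # (n-1)(nu-1) / (2n(4nu-1))
        ],
    )
    def test_variable_groups_printed_forms(self, mode, kinship, n, nu, expected):
        assert unbeatable_z_variable_groups(mode, kinship, n, nu).z_star == expected

    def test_variable_reduces_to_equal_at_nu_equals_n(self):
        for mode in Ploidy:
            for kinship in Kinship:
                for n in (1, 2, 5):
                    assert (
                        unbeatable_z_variable_groups(mode, kinship, n, n).z_star
                        == unbeatable_z_equal_groups(mode, kinship, n).z_star
                    )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            unbeatable_z_closed("D", "S", 2, 1.2)
        with pytest.raises(ValueError):
            unbeatable_z_variable_groups("H", "U", 2, 0.5)


class TestFrankDecomposition:
    def test_hamilton_case(self):
        kin = consanguinities("D", "U", 0)
        rv = reproductive_values("D")
        for n in (1, 2, 7):
            dec = frank_decomposition(n, kin, rv)
            assert dec.R == 1
            assert dec.P == Fraction(n - 1, n)

    def test_no_local_competition_for_sole_foundress(self):
        kin = consanguinities("H", "S", 0.4)
        rv = reproductive_values("H")
        assert frank_decomposition(1, kin, rv).P == 0

    def test_product_matches_haplodiploid_unrelated(self):
        kin = consanguinities("H", "U", 0)
        rv = reproductive_values("H")
        assert frank_decomposition(2, kin, rv).product == Fraction(1, 4)

    def test_product_equals_general_solver_exactly(self):
        for mode in Ploidy:
            for kinship in Kinship:
                for n in (1, 2, 3, 8):
                    for f in (0, Fraction(1, 4), Fraction(9, 10)):
                        kin = consanguinities(mode, kinship, f)
                        rv = reproductive_values(mode)
                        dec = frank_decomposition(n, kin, rv)
                        assert dec.product == unbeatable_z_general(n, kin, rv).z_star

    def test_ps_zero_rejected(self):
        from foundress.kin import KinCoefficients

        kin = KinCoefficients(p_d=0.25, p_s=0.0, p_f=0.0, p_m=0.0)
        with pytest.raises(ValueError):
            frank_decomposition(2, kin, reproductive_values("D"))
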