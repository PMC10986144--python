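"""Unit tests for the strategy space and the elementary game operations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cueqs.core import (
    ALL_GENOTYPES,
    Genotype,
    GroupConfig,
    ModelParams,
    imitation_probability,
    mutate,
    realized_cost,
    resolve_activation,
    signal_doses,
)

LA, VO, LI, CL = Genotype.LA, Genotype.VO, Genotype.LI, Genotype.CL
TR, SM, BO, NE = Genotype.TR, Genotype.SM, Genotype.BO, Genotype.NE


class TestGenotype:
    def test_eight_distinct_strategies_with_total_bijection(self):
        assert len(ALL_GENOTYPES) == 8
        alleles = {g.allele_string for g in ALL_GENOTYPES}
        names = {g.strategy_name for g in ALL_GENOTYPES}
        assert len(alleles) == len(names) == 8
        for g in ALL_GENOTYPES:
            assert Genotype.from_string(g.allele_string) is g
            assert Genotype.from_string(g.strategy_name) is g
            assert Genotype.from_string(g.name.lower()) is g

    @pytest.mark.parametrize(
        "name, alleles", [("La", "csr"), ("Tr", "Csr"), ("Bo", "CSr"),
                          ("Sm", "CsR"), ("Ne", "CSR"), ("Li", "cSr"),
                          ("Cl", "cSR"), ("Vo", "csR")]
    )
    def test_canonical_allele_strings(self, name, alleles):
        assert Genotype.from_string(name).allele_string == alleles

    def test_cooperator_classification(self):
        assert {g for g in ALL_GENOTYPES if g.is_conditional_cooperator} == {SM, NE}
        assert {g for g in ALL_GENOTYPES if g.is_unconditional_cooperator} == {TR, BO}

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            Genotype.from_string("Sneaky")


class TestSignalDoses:
    @pytest.mark.parametrize(
        "members, expected",
        [
            ([TR] * 3 + [LA] * 6, 3),       # each Trusty carries the cue only
            ([BO] + [LA] * 8, 2),           # a Bouncer counts as two signalers
            ([LI] * 2 + [SM] + [VO] * 6, 3),  # Li: extra signal; Sm: cue; Vo: none
        ],
    )
    def test_dose_accounting(self, members, expected):
        assert signal_doses(GroupConfig.from_genotypes(members)) == expected

    def test_wrong_group_size_rejected(self):
        with pytest.raises(ValueError, match="exactly N"):
            signal_doses(GroupConfig.from_genotypes([LA] * 5))

    @given(st.lists(st.sampled_from(list(ALL_GENOTYPES)), min_size=9, max_size=9))
    def test_additive_and_permutation_invariant(self, members):
        total = signal_doses(GroupConfig.from_genotypes(members))
        assert total == sum(g.doses for g in members)
        assert total == signal_doses(GroupConfig.from_genotypes(members[::-1]))


class TestResolveActivation:
    def test_quorate_group_activates_conditional(self, params):
        group = GroupConfig.from_genotypes([TR] * 2 + [SM] + [LA] * 6)
        out = resolve_activation(group, params)
        assert out.doses == 3
        assert out.gamma(SM) == 1
        assert out.n_active_cooperators == 3
        assert out.theta == 1

    def test_all_lazy_group_is_silent(self, params):
        out = resolve_activation(GroupConfig.from_genotypes([LA] * 9), params)
        assert (out.doses, out.n_active_cooperators, out.theta) == (0, 0, 0)

    def test_subquorate_conditional_stays_silent(self, params):
        group = GroupConfig.from_genotypes([TR, SM] + [LA] * 7)
        out = resolve_activation(group, params)
        assert out.doses == 2 < params.Q
        assert out.gamma(SM) == 0
        assert out.n_active_cooperators == 1
        assert out.theta == 0

    def test_unconditional_cooperators_always_active(self, params):
        out = resolve_activation(GroupConfig.from_genotypes([BO] + [LA] * 8), params)
        assert out.gamma(BO) == 1 and out.gamma(TR) == 1


# Per-strategy cost annotations, written out independently of the
# implementation's general formula.
_COST_TABLE = {
    LA: lambda p, g, t: (1 - t * p.b) * p.c0,
    VO: lambda p, g, t: (1 - t * p.b) * (p.c0 + p.r),
    LI: lambda p, g, t: (1 - t * p.b) * (p.c0 + p.s),
    CL: lambda p, g, t: (1 - t * p.b) * (p.c0 + p.s + p.r),
    TR: lambda p, g, t: (1 - t * p.b) * (p.c0 + g * p.c),
    SM: lambda p, g, t: (1 - t * p.b) * (p.c0 + g * p.c + p.r),
    BO: lambda p, g, t: (1 - t * p.b) * (p.c0 + g * p.c + p.s),
    NE: lambda p, g, t: (1 - t * p.b) * (p.c0 + g * p.c + p.s + p.r),
}


class TestRealizedCost:
    @pytest.mark.parametrize("genotype", list(ALL_GENOTYPES))
    @pytest.mark.parametrize("gamma", [0, 1])
    @pytest.mark.parametrize("theta", [0, 1])
    def test_matches_strategy_cost_annotations(self, params, genotype, gamma, theta):
        if gamma and not genotype.has_C:
            return
        expected = _COST_TABLE[genotype](params, gamma, theta)
        assert realized_cost(genotype, gamma, theta, params) == pytest.approx(expected)

    def test_examples(self, params):
        assert realized_cost(LA, 0, 0, params) == 1.0
        assert realized_cost(SM, 1, 1, params) == pytest.approx(0.655)
        assert realized_cost(LI, 0, 1, params) == pytest.approx(0.505)

    def test_benefit_scales_whole_bracket(self, params):
        for g in ALL_GENOTYPES:
            gamma = 1 if g.has_C else 0
            assert realized_cost(g, gamma, 1, params) == pytest.approx(
                (1 - params.b) * realized_cost(g, gamma, 0, params)
            )
            assert realized_cost(g, gamma, 1, params) < realized_cost(g, gamma, 0, params)

    def test_activated_noncooperator_rejected(self, params):
        with pytest.raises(ValueError):
            realized_cost(LA, 1, 0, params)


class TestImitationProbability:
    def test_equal_costs_give_coin_flip(self, params):
        assert imitation_probability(0.7, 0.7, params) == 0.5

    def test_maximal_advantage(self, params):
        assert imitation_probability(0.0, params.delta_C_max, params) == 1.0

    def test_worked_example(self):
        p = ModelParams(c=0.3, s=0.01, r=0.01, b=0.5)
        assert p.delta_C_max == pytest.approx(0.82)
        assert imitation_probability(1.0, 1.31, p) == pytest.approx(
            0.5 * (1 + 0.31 / 0.82)
        )

    @given(
        st.floats(0.0, 0.82),
        st.floats(0.0, 0.82),
        st.floats(0.1, 1.0),
    )
    def test_antisymmetry(self, ci, cj, sigma):
        p = ModelParams(sigma=sigma)
        assert imitation_probability(ci, cj, p) + imitation_probability(
            cj, ci, p
        ) == pytest.approx(1.0)

    def test_inconsistent_costs_rejected(self, params):
        with pytest.raises(ValueError, match="delta_C_max"):
            imitation_probability(0.0, 2 * params.delta_C_max, params)


class TestMutate:
    def test_zero_rates_are_identity(self, rng):
        mu = np.zeros((3, 2))
        for g in ALL_GENOTYPES:
            assert mutate(g, mu, rng) is g

    def test_forced_flip(self, rng):
        mu = np.zeros((3, 2))
        mu[0, 0] = 1.0  # C -> c guaranteed
        assert mutate(TR, mu, rng) is LA
        mu = np.zeros((3, 2))
        mu[2, 1] = 1.0  # r -> R guaranteed
        assert mutate(LA, mu, rng) is VO

    def test_mutant_fraction_matches_binomial(self, rng):
        rate = 1e-4
        mu = np.full((3, 2), rate)
        n = 100_000
        mutants = sum(mutate(LA, mu, rng) is not LA for _ in range(n))
        p_any = 1 - (1 - rate) ** 3
        se = np.sqrt(p_any * (1 - p_any) / n)
        assert abs(mutants / n - p_any) < 3 * se + 1e-12


class TestModelParams:
    def test_quorum_defaults_to_cooperation_threshold(self):
        assert ModelParams(kappa=4).Q == 4
        assert ModelParams(kappa=4, Q=5).Q == 5

    def test_with_rederives_quorum_and_mutation(self):
        p = ModelParams(kappa=3).with_(kappa=5)
        assert p.Q == 5
        p2 = p.with_(rho=1e-4)
        assert np.all(p2.mu == 1e-4)

    @pytest.mark.parametrize(
        "bad", [{"b": 0.0}, {"b": 1.0}, {"sigma": 0.0}, {"kappa": 1},
                {"kappa": 10}, {"c": -0.1}]
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)
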