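import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igevar.scenarios import GeneticParams, derive_variances
from igevar.simulate import (
    OffspringCohort,
    ParentPopulation,
    interaction_coefficient,
    pair_individuals,
    sample_base_population,
    sample_offspring,
    simulate_growth,
    simulate_scenario,
)

from conftest import make_spec


def _noise_free_params(**over):
    base = dict(
        b_bar=0.0, sigma_a_gr=0.0, sigma_ad=0.0, sigma_ai=0.0,
        sigma_ed=0.0, sigma_ei=0.0, h2=1.0, repeatability=1.0,
    )
    base.update(over)
    return GeneticParams(**base)


def _manual_cohort(a_gr):
    """Two mutually paired individuals with explicit A_GR values and no
    other variation."""
    n = len(a_gr)
    zeros = np.zeros(n)
    return OffspringCohort(
        sire_id=np.zeros(n, dtype=int),
        dam_id=np.zeros(n, dtype=int),
        a_gr=np.asarray(a_gr, dtype=float),
        a_d=zeros.copy(),
        a_i=zeros.copy(),
        ep=zeros.copy(),
        e_d=zeros.copy(),
        e_i=zeros.copy(),
        partner=np.array([1, 0]),
    )


class TestBasePopulation:
    def test_zero_variance_gives_point_mass(self, rng):
        spec = make_spec(sigma_a_gr=0, sigma_ad=0, sigma_ai=0)
        pop = sample_base_population(spec, rng)
        assert np.all(pop.sire_bv == 0) and np.all(pop.dam_bv == 0)

    def test_breeding_value_sd_recovered(self, rng):
        spec = make_spec(n_sires=100, n_dams_per_sire=100)  # 10,000 dams
        pop = sample_base_population(spec, rng)
        sd = pop.dam_bv[:, 1].std(ddof=1)
        se = 0.015 / np.sqrt(2 * spec.n_dams)  # SE of a normal SD estimate
        assert abs(sd - 0.015) < 3 * se

    def test_genetic_correlation_recovered(self, rng):
        corr = np.array([[1, 0, 0], [0, 1, 0.5], [0, 0.5, 1.0]])
        spec = make_spec(n_sires=100, n_dams_per_sire=100, genetic_corr=corr)
        pop = sample_base_population(spec, rng)
        r = np.corrcoef(pop.dam_bv[:, 1], pop.dam_bv[:, 2])[0, 1]
        se = (1 - 0.5**2) / np.sqrt(spec.n_dams)
        assert abs(r - 0.5) < 3 * se


class TestOffspring:
    def test_midparent_with_no_mendelian_variance(self, rng):
        spec = make_spec(n_sires=1, n_dams_per_sire=1, n_offspring_per_dam=4,
                         sigma_a_gr=0, sigma_ad=0, sigma_ai=0,
                         sigma_ed=0, sigma_ei=0, h2=1.0, repeatability=1.0)
        pop = ParentPopulation(
            sire_bv=np.array([[1.0, 0.0, 0.0]]), dam_bv=np.array([[0.0, 0.0, 0.0]])
        )
        cohort = sample_offspring(pop, spec, rng)
        assert np.allclose(cohort.a_gr, 0.5)
        assert np.allclose(cohort.a_d, 0.0)

    def test_offspring_variance_equals_additive_variance(self, rng):
        # 1/4 sire + 1/4 dam + 1/2 Mendelian = full additive variance
        spec = make_spec(n_sires=50, n_dams_per_sire=20, n_offspring_per_dam=20)
        pop = sample_base_population(spec, rng)
        cohort = sample_offspring(pop, spec, rng)
        v = cohort.a_gr.var(ddof=1)
        se = 1.0 * np.sqrt(2 / cohort.n)  # iid approximation; inflated below
        assert abs(v - 1.0) < 6 * se

    def test_unmated_dams_rejected(self, rng):
        spec = make_spec(n_sires=2, n_dams_per_sire=3)
        pop = ParentPopulation(sire_bv=np.zeros((2, 3)), dam_bv=np.zeros((5, 3)))
        with pytest.raises(ValueError, match="mated"):
            sample_offspring(pop, spec, rng)


class TestPairing:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(half=st.integers(1, 100), seed=st.integers(0, 2**31 - 1))
    def test_partner_map_is_fixed_point_free_involution(self, half, seed):
        n = 2 * half
        partner = pair_individuals(n, np.random.default_rng(seed))
        assert np.all(partner[partner] == np.arange(n))
        assert np.all(partner != np.arange(n))

    def test_odd_cohort_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            pair_individuals(5, rng)

    def test_cohort_of_two_forms_the_single_pair(self, rng):
        assert pair_individuals(2, rng).tolist() == [1, 0]

    def test_matchings_of_four_are_uniform(self):
        # 3 perfect matchings on 4 items, each with probability 1/3
        counts = {}
        for seed in range(3000):
            p = tuple(pair_individuals(4, np.random.default_rng(seed)))
            counts[p] = counts.get(p, 0) + 1
        assert len(counts) == 3
        for c in counts.values():
            assert abs(c / 3000 - 1 / 3) < 0.03


class TestInteractionCoefficient:
    def test_mean_only(self):
        assert interaction_coefficient(-0.05, 0, 0, 0, 0) == -0.05

    def test_direct_and_indirect_cancel(self):
        assert interaction_coefficient(-0.05, 0.015, 0, -0.015, 0) == pytest.approx(-0.05)

    def test_asymmetry_between_ordered_pairs(self):
        b_ij = interaction_coefficient(0.0, 0.01, 0.0, 0.02, 0.0)
        b_ji = interaction_coefficient(0.0, 0.005, 0.0, 0.001, 0.0)
        assert b_ij == pytest.approx(0.03)
        assert b_ij != b_ji


class TestGrowth:
    def test_deterministic_recursion_reaches_110_g(self, rng):
        spec = make_spec(n_sires=2, n_dams_per_sire=1, n_offspring_per_dam=1)
        params = _noise_free_params()
        cohort = _manual_cohort([0.0, 0.0])
        res = simulate_growth(cohort, params, derive_variances(params), rng)
        assert np.allclose(res.final_weight, 110.0)
        assert np.allclose(res.weights[:, 0], 10.0)
        assert res.weights.shape == (2, 11)

    def test_growth_matches_scalar_oracle(self, rng):
        # one individual with A_GR = 1 paired with an average one, under
        # competition and no noise; iterate the recursion by hand
        params = _noise_free_params(b_bar=-0.05)
        cohort = _manual_cohort([1.0, 0.0])
        res = simulate_growth(cohort, params, derive_variances(params), rng)

        wi = wj = 10.0
        expected = [(wi, wj)]
        for _ in range(10):
            wi, wj = (
                wi + 10.0 + 1.0 - 0.05 * (wj - wi),
                wj + 10.0 - 0.05 * (wi - wj),
            )
            expected.append((wi, wj))
        assert expected[1] == (21.0, 20.0)
        assert expected[2] == (32.05, 29.95)
        assert np.allclose(res.weights.T, expected)

    def test_identical_pair_members_never_diverge(self, rng):
        params = _noise_free_params(b_bar=-0.05)
        cohort = _manual_cohort([0.7, 0.7])
        cohort.a_d += 0.01
        cohort.a_i -= 0.02
        res = simulate_growth(cohort, params, derive_variances(params), rng)
        assert np.allclose(res.weights[0], res.weights[1])

    def test_final_weight_variance_closed_form(self):
        # With b = 0 and no genetic/environmental variation in b,
        # Var(final) = n^2 (sigma2_A + sigma2_Ep) + n sigma2_Et = 146 g^2.
        spec = make_spec(n_sires=50, n_dams_per_sire=20, n_offspring_per_dam=20,
                         b_bar=0.0, sigma_ad=0, sigma_ai=0, sigma_ed=0, sigma_ei=0)
        _, _, growth = simulate_scenario(spec, 11)
        v = growth.final_weight.var(ddof=1)
        # 3 SE for an iid sample of 20,000, doubled for family clustering
        se = 146 * np.sqrt(2 / 20_000)
        assert abs(v - 146.0) < 6 * se

    def test_competition_amplifies_within_pair_divergence(self):
        spec_comp = make_spec(n_sires=40, n_dams_per_sire=5, n_offspring_per_dam=20,
                              b_bar=-0.05)
        spec_neut = dataclasses.replace(
            spec_comp, params=dataclasses.replace(spec_comp.params, b_bar=0.0)
        )
        diffs = {}
        for key, spec in [("comp", spec_comp), ("neut", spec_neut)]:
            _, cohort, growth = simulate_scenario(spec, 5)
            w = growth.final_weight
            diffs[key] = np.abs(w - w[cohort.partner]).mean()
        assert diffs["comp"] > diffs["neut"]

    def test_unpaired_cohort_rejected(self, rng):
        params = _noise_free_params()
        cohort = _manual_cohort([0.0, 0.0])
        cohort.partner = None
        with pytest.raises(ValueError, match="partner"):
            simulate_growth(cohort, params, derive_variances(params), rng)


class TestDeterminism:
    def test_identical_seeds_give_identical_replicates(self, tiny_var_spec):
        runs = [simulate_scenario(tiny_var_spec, 77, store_trajectory=True)
                for _ in range(2)]
        (p1, c1, g1), (p2, c2, g2) = runs
        assert np.array_equal(p1.sire_bv, p2.sire_bv)
        assert np.array_equal(c1.a_gr, c2.a_gr)
        assert np.array_equal(c1.partner, c2.partner)
        assert np.array_equal(g1.weights, g2.weights)

    def test_different_seeds_differ(self, tiny_var_spec):
        _, _, g1 = simulate_scenario(tiny_var_spec, 77)
        _, _, g2 = simulate_scenario(tiny_var_spec, 78)
        assert not np.array_equal(g1.final_weight, g2.final_weight)
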