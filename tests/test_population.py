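"""Founder generation, infection model and reproduction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capturebias import (
    ConfigError,
    ScenarioConfig,
    apply_infection,
    genotype_risk,
    infection_probability,
    make_founders,
    offspring_lambda,
    pair_parents,
    reproduce,
)
from capturebias.population import allele_frequency

from conftest import make_population


class TestFounders:
    def test_genotypes_follow_binomial_proportions(self, rng):
        cfg = ScenarioConfig(population_size=10_000)
        pop = make_founders(cfg, rng)
        assert len(pop) == 10_000
        assert not pop["infected"].any()
        assert (pop["generation"] == "parent").all()
        counts = pop["geno"].value_counts()
        # Hardy-Weinberg at q=0.5: 0.25 / 0.50 / 0.25, 3 binomial SE slack
        for geno, expect in ((0, 0.25), (1, 0.5), (2, 0.25)):
            se = np.sqrt(expect * (1 - expect) / 10_000)
            assert abs(counts[geno] / 10_000 - expect) < 3 * se

    def test_focal_allele_frequency_near_half(self, rng):
        cfg = ScenarioConfig(population_size=10_000)
        pop = make_founders(cfg, rng)
        se = np.sqrt(0.25 / (2 * 10_000))
        assert abs(allele_frequency(pop) - 0.5) < 3 * se

    def test_minimal_population(self, rng):
        pop = make_founders(ScenarioConfig(population_size=2, sample_size=2), rng)
        assert len(pop) == 2
        assert pop["geno"].isin([0, 1, 2]).all()

    def test_odd_population_rejected(self):
        with pytest.raises(ConfigError):
            ScenarioConfig(population_size=5001)


class TestInfectionRisk:
    @pytest.mark.parametrize(
        "geno,scheme,expected",
        [
            (1, "heterozygote_advantage", 0.2),
            (0, "heterozygote_advantage", 0.8),
            (2, "heterozygote_advantage", 0.8),
            (0, "resistance_allele", 0.8),
            (1, "resistance_allele", 0.2),
            (2, "resistance_allele", 0.2),
        ],
    )
    def test_risk_class_assignment(self, geno, scheme, expected):
        assert genotype_risk(geno, scheme, 0.8, 0.2) == expected

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError):
            genotype_risk(3, "heterozygote_advantage", 0.8, 0.2)

    @pytest.mark.parametrize(
        "g_risk,w,r_i,expected",
        [
            (0.8, 1.0, 123.0, 0.8),   # w=1 removes the noise term
            (0.2, 0.0, 0.5, 0.5),     # w=0 removes the genotype term
            (0.2, 0.5, 1.4, 0.8),     # plain mixing, no clamping
            (0.8, 0.5, 1.4, 1.0),     # clamped above
            (0.2, 0.5, -1.0, 0.0),    # clamped below
        ],
    )
    def test_infection_probability_formula(self, g_risk, w, r_i, expected):
        assert infection_probability(g_risk, w, r_i) == pytest.approx(expected)

    def test_weight_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            infection_probability(0.5, 1.2, 0.5)

    @given(
        g=st.floats(0, 1), w=st.floats(0, 1),
        r=st.floats(-3, 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_probability_always_in_unit_interval(self, g, w, r):
        p = infection_probability(g, w, r)
        assert 0.0 <= p <= 1.0

    @given(
        g1=st.floats(0, 1), g2=st.floats(0, 1),
        w=st.floats(0, 1), r=st.floats(-3, 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_genotype_risk(self, g1, g2, w, r):
        lo, hi = sorted((g1, g2))
        assert infection_probability(lo, w, r) <= infection_probability(hi, w, r)


class TestApplyInfection:
    def test_pure_genotype_risk_recovers_rate(self, rng):
        # all-AA population, resistance scheme, w=1: everyone at risk 0.8
        cfg = ScenarioConfig(
            population_size=10_000, scheme="resistance_allele",
            genotype_prediction_value=1.0,
        )
        pop = make_population([0] * 10_000)
        out = apply_infection(pop, cfg, rng)
        se = np.sqrt(0.8 * 0.2 / 10_000)
        assert abs(out["infected"].mean() - 0.8) < 3 * se

    def test_zero_risk_infects_nobody(self, rng):
        cfg = ScenarioConfig(
            population_size=1000, genotype_prediction_value=0.0,
            noise_mean=0.0, noise_sd=0.0,
        )
        pop = make_population([1] * 1000)
        assert not apply_infection(pop, cfg, rng)["infected"].any()

    def test_genotype_decoupled_at_zero_weight(self, rng):
        cfg = ScenarioConfig(
            population_size=10_000, genotype_prediction_value=0.0,
            noise_mean=0.5, noise_sd=0.0,
        )
        pop = make_population([0] * 5000 + [1] * 5000)
        out = apply_infection(pop, cfg, rng)
        by_geno = out.groupby("geno")["infected"].mean()
        se = np.sqrt(0.25 / 5000)
        assert abs(by_geno[0] - 0.5) < 3 * se
        assert abs(by_geno[1] - 0.5) < 3 * se


class TestPairing:
    def test_perfect_matching(self, rng):
        pop = make_population([1] * 5000)
        pairs = pair_parents(pop, rng)
        assert pairs.shape == (2500, 2)
        assert sorted(pairs.ravel().tolist()) == sorted(pop["id"].tolist())

    def test_two_parents_one_pair(self, rng):
        pairs = pair_parents(make_population([0, 2]), rng)
        assert pairs.shape == (1, 2)

    def test_odd_count_rejected(self, rng):
        with pytest.raises(ValueError):
            pair_parents(make_population([1, 1, 1]), rng)


class TestOffspringLambda:
    @pytest.mark.parametrize(
        "inf_a,inf_b,penalty,expected",
        [
            (False, False, 0.3, 10.0),
            (True, False, 0.6, 8.0),   # 5 + round(3.0)
            (True, True, 0.0, 0.0),
            (True, True, 0.7, 7.0),    # unrounded product
        ],
    )
    def test_lambda_by_infection_configuration(self, inf_a, inf_b, penalty, expected):
        assert offspring_lambda(inf_a, inf_b, 10.0, penalty) == pytest.approx(expected)

    def test_rounding_convention_at_halves(self):
        # penalty*half = 2.5: half-up gives 3, banker's gives 2
        assert offspring_lambda(True, False, 10.0, 0.5, rounding="half_up") == 8.0
        assert offspring_lambda(True, False, 10.0, 0.5, rounding="half_even") == 7.0

    def test_penalty_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            offspring_lambda(True, False, 10.0, 1.5)


class TestReproduce:
    def test_cross_of_opposite_homozygotes_yields_heterozygotes(self, rng):
        cfg = ScenarioConfig(population_size=2, sample_size=1, infection_penalty=1.0)
        pop = make_population([0, 2])
        off = reproduce(pop, np.array([[0, 1]]), cfg, rng)
        assert len(off) > 0
        assert (off["geno"] == 1).all()
        assert (off["mother_id"] == 0).all() and (off["father_id"] == 1).all()

    def test_heterozygote_cross_segregates_mendelian(self, rng):
        cfg = ScenarioConfig(population_size=600, sample_size=10,
                             infection_penalty=1.0, base_lambda=30.0)
        pop = make_population([1] * 600)
        pairs = pair_parents(pop, rng)
        off = reproduce(pop, pairs, cfg, rng)
        n = len(off)
        props = off["geno"].value_counts(normalize=True)
        for geno, expect in ((0, 0.25), (1, 0.5), (2, 0.25)):
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(props[geno] - expect) < 4 * se

    def test_no_penalty_mean_offspring_matches_lambda(self, rng):
        cfg = ScenarioConfig(population_size=5000, infection_penalty=1.0)
        pop = make_population([1] * 5000, infected=[True, False] * 2500)
        pairs = pair_parents(pop, rng)
        off = reproduce(pop, pairs, cfg, rng)
        mean = len(off) / 2500
        se = np.sqrt(10.0 / 2500)
        assert abs(mean - 10.0) < 3 * se

    def test_allele_conservation_without_selection(self, rng):
        # penalty=1 and no infection: offspring frequency tracks parents
        cfg = ScenarioConfig(population_size=4000, infection_penalty=1.0)
        pop = make_founders(cfg, rng)
        off = reproduce(pop, pair_parents(pop, rng), cfg, rng)
        se = np.sqrt(0.25 / (2 * len(off)))
        assert abs(allele_frequency(off) - allele_frequency(pop)) < 4 * se

    def test_selection_raises_resistance_allele_frequency(self):
        # full fecundity loss for infected parents, genotype fully
        # predictive: the resistance allele must gain ground in most runs
        cfg = ScenarioConfig(
            population_size=500, sample_size=50, scheme="resistance_allele",
            genotype_prediction_value=1.0, infection_penalty=0.0,
        )
        wins = 0
        n_trials = 50
        for i in range(n_trials):
            r = np.random.default_rng(1000 + i)
            pop = make_founders(cfg, r)
            pop = apply_infection(pop, cfg, r)
            off = reproduce(pop, pair_parents(pop, r), cfg, r)
            wins += allele_frequency(off) > allele_frequency(pop)
        # sign test: one-sided binomial(50, 0.5) critical value
        assert wins >= 32
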