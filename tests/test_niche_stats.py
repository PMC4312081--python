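"""Overlap, niche width, individual specialization and rank ANOVAs."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tundradiet.diet_composition import DietProfile, population_mean_diet
from tundradiet.niche_stats import (aligned_rank_anova,
                                    exclude_and_renormalize,
                                    individual_specialization, rank_anova,
                                    resampled_is, schoener_overlap,
                                    trophic_niche_width)

FAMS = ["Salicaceae", "Poaceae", "Juncaceae", "Polytrichaceae", "Rosaceae"]


def random_profiles(rng, n, k=5, alpha=1.0):
    return [DietProfile(f"s{i}", dict(zip(FAMS[:k],
                                          rng.dirichlet(np.full(k, alpha)))))
            for i in range(n)]


proportions = st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6).map(
    lambda xs: {f"t{i}": x / sum(xs) for i, x in enumerate(xs)})


class TestSchoenerOverlap:
    def test_identical_profiles(self):
        p = {"Salicaceae": 0.7, "Poaceae": 0.3}
        assert schoener_overlap(p, p).value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert schoener_overlap({"Salicaceae": 1.0},
                                {"Poaceae": 1.0}).value == 0.0

    def test_printed_broad_group_means_give_075(self):
        o = schoener_overlap({"dicot": 0.86, "monocot": 0.14, "moss": 0.01},
                             {"dicot": 0.65, "monocot": 0.09, "moss": 0.26},
                             normalize=True)
        from tundradiet._util import round_half_up
        assert round_half_up(o.value, 2) == 0.75

    def test_unnormalized_profile_rejected(self):
        with pytest.raises(ValueError):
            schoener_overlap({"a": 0.6, "b": 0.5}, {"a": 1.0})

    @given(proportions, proportions)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetry_bounds_and_min_identity(self, p, q):
        o1 = schoener_overlap(p, q).value
        o2 = schoener_overlap(q, p).value
        assert o1 == pytest.approx(o2)
        assert 0.0 <= o1 <= 1.0
        taxa = set(p) | set(q)
        min_sum = sum(min(p.get(t, 0.0), q.get(t, 0.0)) for t in taxa)
        assert o1 == pytest.approx(min_sum, abs=1e-9)


class TestExcludeAndRenormalize:
    def test_zero_share_exclusion_is_noop(self):
        p = {"Salicaceae": 0.5, "Poaceae": 0.5, "Rosaceae": 0.0}
        out = exclude_and_renormalize(p, {"Rosaceae"})
        assert out == pytest.approx({"Salicaceae": 0.5, "Poaceae": 0.5})

    def test_simple_renormalization(self):
        out = exclude_and_renormalize({"A": 0.5, "B": 0.25, "C": 0.25},
                                      {"A"})
        assert out == pytest.approx({"B": 0.5, "C": 0.5})

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            p = dict(zip(FAMS, rng.dirichlet(np.ones(5))))
            out = exclude_and_renormalize(p, {"Salicaceae"})
            rest = {f: v for f, v in p.items() if f != "Salicaceae"}
            z = sum(rest.values())
            assert out == pytest.approx({f: v / z for f, v in rest.items()})

    def test_total_exclusion_is_error(self):
        with pytest.raises(ValueError):
            exclude_and_renormalize({"A": 1.0}, {"A"})


class TestTrophicNicheWidth:
    def test_single_taxon_zero(self):
        assert trophic_niche_width({"Salicaceae": 1.0}) == 0.0

    def test_uniform_is_log_k(self):
        q = {f: 0.25 for f in FAMS[:4]}
        assert trophic_niche_width(q) == pytest.approx(math.log(4))

    def test_invariant_to_zero_padding(self):
        q = {"Salicaceae": 0.6, "Poaceae": 0.4}
        padded = dict(q, Rosaceae=0.0, Juncaceae=0.0)
        assert trophic_niche_width(padded) == pytest.approx(
            trophic_niche_width(q))

    def test_matches_brute_force_entropy(self):
        rng = np.random.default_rng(6)
        q = dict(zip(FAMS, rng.dirichlet(np.ones(5))))
        brute = -sum(v * math.log(v) for v in q.values() if v > 0)
        assert trophic_niche_width(q) == pytest.approx(brute)

    def test_base_configurable(self):
        q = {f: 0.25 for f in FAMS[:4]}
        assert trophic_niche_width(q, base=2) == pytest.approx(2.0)

    def test_negative_proportion_is_error(self):
        with pytest.raises(ValueError):
            trophic_niche_width({"a": 1.2, "b": -0.2})


class TestIndividualSpecialization:
    def test_identical_individuals_give_one(self):
        p = {"Salicaceae": 0.7, "Poaceae": 0.3}
        cm = population_mean_diet(
            [DietProfile(f"s{i}", dict(p)) for i in range(5)])
        assert individual_specialization(cm) == pytest.approx(1.0)

    def test_two_disjoint_individuals_give_half(self):
        cm = population_mean_diet([DietProfile("a", {"Salicaceae": 1.0}),
                                   DietProfile("b", {"Poaceae": 1.0})])
        assert individual_specialization(cm) == pytest.approx(0.5)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(8)
        profiles = random_profiles(rng, 54)
        cm = population_mean_diet(profiles)
        q = {f: sum(p.proportions[f] for p in profiles) / 54 for f in FAMS}
        brute = sum(1 - 0.5 * sum(abs(p.proportions[f] - q[f]) for f in FAMS)
                    for p in profiles) / 54
        assert individual_specialization(cm) == pytest.approx(brute)

    def test_more_extreme_profile_lowers_is(self):
        base = [DietProfile("a", {"Salicaceae": 0.6, "Poaceae": 0.4}),
                DietProfile("b", {"Salicaceae": 0.5, "Poaceae": 0.5}),
                DietProfile("c", {"Salicaceae": 0.55, "Poaceae": 0.45})]
        extreme = [base[0], base[1],
                   DietProfile("c", {"Salicaceae": 0.95, "Poaceae": 0.05})]
        assert (individual_specialization(population_mean_diet(extreme))
                < individual_specialization(population_mean_diet(base)))

    def test_fewer_than_two_profiles_is_error(self):
        cm = population_mean_diet([DietProfile("a", {"Salicaceae": 1.0})])
        with pytest.raises(ValueError):
            individual_specialization(cm)


class TestResampledIS:
    def test_full_subsample_equals_full_is_for_any_seed(self):
        rng = np.random.default_rng(10)
        cm = population_mean_diet(random_profiles(rng, 12))
        full = individual_specialization(cm)
        for seed in range(10):
            mean, sd = resampled_is(cm, n_sub=12, n_rep=5, seed=seed)
            assert mean == pytest.approx(full)
            assert sd == pytest.approx(0.0)

    def test_single_replicate_reproducible(self):
        rng = np.random.default_rng(11)
        cm = population_mean_diet(random_profiles(rng, 30))
        a = resampled_is(cm, n_sub=10, n_rep=1, seed=7)
        b = resampled_is(cm, n_sub=10, n_rep=1, seed=7)
        assert a == b

    def test_homogeneous_population_mean_close_to_full(self):
        """Matched-size resampling reproduces the full-sample IS."""
        rng = np.random.default_rng(12)
        cm = population_mean_diet(random_profiles(rng, 54, alpha=15.0))
        full = individual_specialization(cm)
        mean, sd = resampled_is(cm, n_sub=22, n_rep=100, seed=3)
        assert abs(mean - full) < max(2 * sd / math.sqrt(100), 0.01)

    def test_oversized_subsample_is_error(self):
        rng = np.random.default_rng(13)
        cm = population_mean_diet(random_profiles(rng, 5))
        with pytest.raises(ValueError):
            resampled_is(cm, n_sub=6, n_rep=1, seed=0)


class TestRankAnova:
    def test_separated_groups_detected(self):
        values = [1, 2, 3, 4, 5, 6, 7, 8, 21, 22, 23, 24, 25, 26, 27, 28]
        groups = ["a"] * 8 + ["b"] * 8
        res = rank_anova(values, groups)
        assert res.F > 10
        assert res.p < 0.01
        assert res.df == (1, 14)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(14)
        values = rng.normal(size=24)
        groups = ["a", "b", "c"] * 8
        r1 = rank_anova(values, groups)
        r2 = rank_anova(np.exp(3 * values), groups)
        assert r1.F == pytest.approx(r2.F)
        assert r1.p == pytest.approx(r2.p)

    def test_ties_get_midranks_and_f_stays_finite(self):
        values = [1.0, 1.0, 2.0, 2.0, 5.0, 5.0, 6.0, 6.0]
        res = rank_anova(values, ["a"] * 4 + ["b"] * 4)
        assert math.isfinite(res.F)
        assert res.p < 0.05

    def test_constant_data_gives_f_zero(self):
        res = rank_anova([3.0] * 10, ["a"] * 5 + ["b"] * 5)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_small_group_is_error(self):
        with pytest.raises(ValueError):
            rank_anova([1, 2, 3], ["a", "a", "b"])

    def test_null_rejection_rate_near_nominal(self):
        """Type-I error close to 5% under permuted labels (small pilot;
        the full 2,000-replicate calibration runs with the acceptance
        checks)."""
        rng = np.random.default_rng(15)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            values = rng.normal(size=40)
            groups = ["a"] * 20 + ["b"] * 20
            if rank_anova(values, groups).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07


class TestAlignedRankAnova:
    @staticmethod
    def layout(n_per_cell):
        a = ["x"] * (2 * n_per_cell) + ["y"] * (2 * n_per_cell)
        b = (["u"] * n_per_cell + ["v"] * n_per_cell) * 2
        return np.array(a), np.array(b)

    def test_pure_main_effects_rarely_rejected(self):
        rng = np.random.default_rng(16)
        a, b = self.layout(10)
        main_a = np.where(a == "x", 0.0, 2.0)
        main_b = np.where(b == "u", 0.0, -1.0)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            y = main_a + main_b + rng.normal(size=40)
            if aligned_rank_anova(y, a, b).p < 0.05:
                rejections += 1
        # null interaction: rate near nominal despite strong main effects
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_crossover_interaction_detected_with_power(self):
        rng = np.random.default_rng(17)
        a, b = self.layout(20)
        # planted crossover: effect size ~1.2 sd (pilot-calibrated for
        # power > 0.8 at 20 replicates per cell)
        inter = np.where((a == "x") == (b == "u"), 0.6, -0.6)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            y = inter + rng.normal(size=80)
            if aligned_rank_anova(y, a, b).p < 0.05:
                hits += 1
        assert hits / n_sim > 0.8

    def test_constant_data_degenerate(self):
        a, b = self.layout(3)
        res = aligned_rank_anova(np.zeros(12), a, b)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_empty_cell_is_error(self):
        a = np.array(["x"] * 4 + ["y"] * 4)
        b = np.array(["u"] * 4 + ["u"] * 4)
        b2 = np.array(["u", "u", "v", "v", "u", "u", "u", "u"])
        with pytest.raises(ValueError):
            aligned_rank_anova(np.arange(8.0), a, b2)
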