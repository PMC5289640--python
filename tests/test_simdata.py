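"""Synthetic population generator and sequencing simulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from tcrpair import simdata
from tcrpair.simdata import (
    DEFAULT_ALPHA_SHARING,
    DEFAULT_BETA_SHARING,
    SamplingPlan,
    SharingSpec,
    build_clone_size_distribution,
    build_sampling_plan,
    generate_population,
    sample_wells,
    simulate_single_cells,
)

from conftest import make_population


class TestCloneSizeDistribution:
    def test_reference_solution(self):
        # solved the 2x2 linear system by hand for N=2100, n_s=25, p_s=0.5
        f = build_clone_size_distribution(2100, 25, 0.5)
        assert f[0] == pytest.approx(0.0397349397590361, rel=1e-10)
        assert f[1] - f[0] == pytest.approx(-1.6445783132530e-3, rel=1e-9)
        assert f[-1] == pytest.approx(0.5 / 2075, rel=1e-12)
        assert f[24] == pytest.approx(1.1 * 0.5 / 2075, rel=1e-12)

    def test_two_clone_edge_case(self):
        assert build_clone_size_distribution(2, 1, 0.5) == pytest.approx([0.5, 0.5])

    def test_highly_skewed(self):
        f = build_clone_size_distribution(2100, 5, 0.5)
        assert f[4] == pytest.approx(1.1 * 0.5 / 2095, rel=1e-12)
        assert f[:5].sum() == pytest.approx(0.5, abs=1e-12)

    @given(
        N=st.integers(200, 5000),
        n_s=st.integers(2, 40),
        p_s=st.floats(0.48, 0.9),
    )
    def test_mass_constraints(self, N, n_s, p_s):
        f = build_clone_size_distribution(N, n_s, p_s)
        assert abs(f.sum() - 1.0) < 1e-9
        assert abs(f[:n_s].sum() - p_s) < 1e-9
        assert np.all(np.diff(f) <= 1e-15)

    def test_rejects_flat_or_negative(self):
        with pytest.raises(ValueError):
            build_clone_size_distribution(10, 5, 1.5)
        with pytest.raises(ValueError):
            # p_s so small the ramp would have to increase
            build_clone_size_distribution(100, 50, 0.05)


class TestSamplingPlan:
    @pytest.mark.parametrize(
        "strategy,plates,blocks,total",
        [
            ("high-mixed", 1, ((26, 20), (13, 50), (19, 100), (19, 200), (19, 300)), 96),
            ("high-mixed", 5, ((128, 20), (64, 50), (96, 100), (96, 200), (96, 300)), 480),
            ("low-mixed", 5, ((96, 15), (32, 20), (64, 30), (96, 50), (96, 100), (96, 150)), 480),
            ("uniform-10", 1, ((96, 10),), 96),
        ],
    )
    def test_published_layouts(self, strategy, plates, blocks, total):
        plan = build_sampling_plan(strategy, plates)
        assert plan.blocks == blocks
        assert plan.total_wells == total

    def test_unknown_strategy(self):
        with pytest.raises(ValueError):
            build_sampling_plan("nonsense", 1)

    def test_size_summary(self):
        n_l, w_l = build_sampling_plan("high-mixed", 1).size_summary()
        assert list(n_l) == [20, 50, 100, 200, 300]
        assert list(w_l) == [26, 13, 19, 19, 19]


class TestGeneratePopulation:
    def test_drop_rates_capped(self):
        pop = generate_population(N=300, n_s=10, drop_mean=0.8, drop_sd=0.3, seed=0)
        assert all(c.drop_rate <= 0.9 for c in pop.clones)

    def test_no_sharing_no_duals(self):
        spec = SharingSpec({1: 1.0})
        pop = generate_population(
            N=100, n_s=5, alpha_sharing=spec, beta_sharing=spec,
            dual_alpha_prev=0.0, dual_beta_prev=0.0, seed=1,
        )
        assert len(pop.alpha_error_rate) == 100
        assert len(pop.beta_error_rate) == 100
        assert all(v == 1 for v in pop.chain_multiplicities("alpha").values())
        assert all(v == 1 for v in pop.chain_multiplicities("beta").values())

    def test_dual_prevalences(self):
        pop = generate_population(N=1000, n_s=10, seed=2)
        n_dual_a = sum(c.is_dual_alpha for c in pop.clones)
        n_dual_b = sum(c.is_dual_beta for c in pop.clones)
        assert n_dual_a == 300
        assert n_dual_b == 60

    def test_sharing_spectrum_matches_spec(self):
        # empirical multiplicity histograms within 3 binomial s.e. per bin
        pop = generate_population(N=50_000, n_s=50, seed=3)
        for locus, spec in (
            ("alpha", DEFAULT_ALPHA_SHARING),
            ("beta", DEFAULT_BETA_SHARING),
        ):
            mult = np.array(list(pop.chain_multiplicities(locus).values()))
            n = len(mult)
            for k, p in spec.multiplicity_probs.items():
                obs = np.mean(mult == k)
                se = np.sqrt(p * (1 - p) / n)
                assert abs(obs - p) < 3 * se + 1.0 / n, (locus, k, obs, p)

    def test_daughter_registry_is_collision_free(self):
        pop = generate_population(N=200, n_s=5, seed=4)
        true_ids = set(pop.alpha_error_rate) | set(pop.beta_error_rate)
        daughters = [d for trio in pop.daughters.values() for d in trio]
        assert len(daughters) == 3 * len(true_ids)
        assert len(set(daughters)) == len(daughters)
        assert not set(daughters) & true_ids

    def test_impossible_sharing_rejected(self):
        with pytest.raises(ValueError):
            generate_population(
                N=3, n_s=1, alpha_sharing=SharingSpec({7: 1.0}), seed=0
            )


class TestSampleWells:
    def test_deterministic_limit_single_clone(self):
        pop = make_population([(("a0",), ("b0",), 1.0)])
        plan = SamplingPlan(((3, 5),))
        wells, truth = sample_wells(pop, plan, seed=0)
        for w, t in zip(wells, truth):
            assert w.alpha_set == {"a0"} and w.beta_set == {"b0"}
            assert t == {0: 5}

    def test_drop_rate_definition(self):
        # drop 0.9: a chain of a 1-cell well is absent with probability 0.9
        pop = make_population([(("a0",), ("b0",), 1.0)], drop=0.9)
        plan = SamplingPlan(((4000, 1),))
        wells, _ = sample_wells(pop, plan, seed=1)
        absent = np.mean(["a0" not in w.alpha_set for w in wells])
        assert absent == pytest.approx(0.9, abs=3 * np.sqrt(0.9 * 0.1 / 4000))

    def test_error_rate_definition(self):
        # err 0.02: ~2% of chain instances come out mutated
        pop = make_population([(("a0",), ("b0",), 1.0)], err=0.02)
        plan = SamplingPlan(((3000, 1),))
        wells, _ = sample_wells(pop, plan, seed=2)
        mutated = np.mean(["a0" not in w.alpha_set for w in wells])
        assert mutated == pytest.approx(0.02, abs=3 * np.sqrt(0.02 * 0.98 / 3000))

    def test_multinomial_well_occupancy(self):
        # per-well clone counts follow the multinomial law (chi-square, 3 clones)
        pop = make_population(
            [(("a0",), ("b0",), 0.5), (("a1",), ("b1",), 0.3), (("a2",), ("b2",), 0.2)]
        )
        plan = SamplingPlan(((500, 4),))
        _, truth = sample_wells(pop, plan, seed=3)
        counts = np.zeros((500, 3), int)
        for i, t in enumerate(truth):
            for c, m in t.items():
                counts[i, c] = m
        # marginal count of clone 0 across wells ~ Binomial(4, 0.5)
        obs = np.bincount(counts[:, 0], minlength=5)
        exp = 500 * stats.binom.pmf(np.arange(5), 4, 0.5)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=4)

    def test_union_converges_to_true_chain_set(self):
        pop = make_population(
            [(("a0",), ("b0",), 0.5), (("a1",), ("b1",), 0.5)]
        )
        wells, _ = sample_wells(pop, SamplingPlan(((50, 10),)), seed=4)
        seen_a = set().union(*(w.alpha_set for w in wells))
        seen_b = set().union(*(w.beta_set for w in wells))
        assert seen_a == {"a0", "a1"} and seen_b == {"b0", "b1"}


class TestSingleCells:
    def test_error_free_cells_reproduce_clone(self):
        pop = make_population([(("a0", "a1"), ("b0",), 1.0)])
        cells = simulate_single_cells(pop, 10, seed=0)
        for a, b in cells:
            assert a == {"a0", "a1"} and b == {"b0"}

    def test_mismatch_rate_about_twice_error_rate(self):
        pop = make_population([(("a0",), ("b0",), 1.0)], err=0.02)
        cells = simulate_single_cells(pop, 20000, seed=1)
        bad = sum(
            1 for a, b in cells if (a, b) != (frozenset({"a0"}), frozenset({"b0"}))
        )
        # P(any of the two chains mutated) = 1 - 0.98^2 = 0.0396
        assert bad / len(cells) == pytest.approx(0.0396, abs=0.005)
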