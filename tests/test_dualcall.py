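"""Dual-TCRα vs β-sharing discrimination: ratios, clustering, likelihoods."""

import numpy as np
import pytest

from tcrpair import dualcall
from tcrpair.dualcall import (
    call_duals,
    cluster_ratios,
    coincidence_ratio,
    expected_coincident_wells,
    find_sharing_candidates,
    pattern_counts,
    pattern_distribution,
    pattern_loglik,
)
from tcrpair.freq import estimate_frequency, occupancy_counts
from tcrpair.pairing import PairingConfig, consensus_pairs
from tcrpair.simdata import SamplingPlan, sample_wells

from conftest import make_population

_ALL_PRESENT = dualcall._PATTERNS.index((1, 1, 1))


class TestExpectedCoincidence:
    def test_one_cell_wells_cannot_cooccupy(self):
        plan = SamplingPlan(((10, 1),))
        assert expected_coincident_wells(0.5, 0.5, plan) == pytest.approx(0.0)

    def test_two_cell_well_hand_value(self):
        # 1 - 0.25 - 0.25 + 0 = 0.5
        plan = SamplingPlan(((1, 2),))
        assert expected_coincident_wells(0.5, 0.5, plan) == pytest.approx(0.5)

    def test_absent_clone_never_coincides(self):
        plan = SamplingPlan(((5, 10), (3, 50)))
        assert expected_coincident_wells(0.2, 0.0, plan) == pytest.approx(0.0)

    def test_overlapping_frequencies_rejected(self):
        with pytest.raises(ValueError):
            expected_coincident_wells(0.7, 0.6, SamplingPlan(((1, 2),)))

    def test_matches_monte_carlo_for_independent_clones(self):
        # Monte-Carlo oracle of triple-co-occurrence well counts
        rng = np.random.default_rng(3)
        f1, f2 = 0.08, 0.15
        plan = SamplingPlan(((40, 5), (20, 30)))
        n_l, w_l = plan.size_summary()
        e = expected_coincident_wells(f1, f2, plan)
        sims = 4000
        counts = np.zeros(sims)
        for n, w in zip(n_l, w_l):
            draws = rng.multinomial(n, [f1, f2, 1 - f1 - f2], size=(sims, w))
            both = (draws[..., 0] > 0) & (draws[..., 1] > 0)
            counts += both.sum(axis=1)
        se = counts.std() / np.sqrt(sims)
        assert abs(counts.mean() - e) < 3 * se + 1e-3


class TestCoincidenceRatio:
    @pytest.mark.parametrize(
        "a,e,expected", [(4, 2.0, 2.0), (0, 5.0, 0.0), (0, 0.0, 1.0)]
    )
    def test_basic_values(self, a, e, expected):
        assert coincidence_ratio(a, e) == expected

    def test_impossible_coincidence_is_infinite(self):
        assert coincidence_ratio(3, 0.0) == float("inf")


class TestClusterRatios:
    def test_two_means_split_matches_exhaustive_search(self):
        # optimal 1-D 2-means split found by scanning all split points
        verdicts = cluster_ratios([0.9, 1.0, 1.1, 2.8, 3.1], seed=0)
        assert list(verdicts) == [False, False, False, True, True]

    def test_two_point_split(self):
        assert list(cluster_ratios([1.0, 10.0], seed=0)) == [False, True]

    def test_identical_ratios_yield_no_duals(self):
        assert not cluster_ratios([2.0, 2.0, 2.0], seed=0).any()

    def test_infinite_ratios_preassigned_dual(self):
        v = cluster_ratios([float("inf"), 0.9, 1.0, 1.1, 3.0], seed=0)
        assert v[0]
        assert list(v[1:]) == [False, False, False, True]

    def test_single_finite_ratio_uses_threshold(self):
        assert list(cluster_ratios([3.5], seed=0)) == [True]
        assert list(cluster_ratios([1.5], seed=0)) == [False]


class TestPatternLikelihood:
    def test_dual_certain_clone_always_fully_seen(self):
        probs = pattern_distribution(1, ("dual", 1.0), eps=0.0)
        assert probs[_ALL_PRESENT] == pytest.approx(1.0)

    def test_two_clones_cannot_share_a_single_cell(self):
        probs = pattern_distribution(1, ("two_clones", 0.5, 0.5), eps=0.0)
        assert probs[_ALL_PRESENT] == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "hypothesis", [("dual", 0.3), ("two_clones", 0.25, 0.4)]
    )
    @pytest.mark.parametrize("n", [1, 3, 6, 20])
    @pytest.mark.parametrize("eps", [0.0, 0.15])
    def test_distribution_normalises(self, hypothesis, n, eps):
        probs = pattern_distribution(n, hypothesis, eps)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(probs >= -1e-15)

    @pytest.mark.parametrize(
        "hypothesis", [("dual", 0.35), ("two_clones", 0.2, 0.3)]
    )
    def test_distribution_matches_monte_carlo(self, hypothesis):
        # instance-level Monte-Carlo oracle of the 8-pattern distribution,
        # with an 8x-draws confirmation stage for 3-sigma false alarms
        eps, n = 0.2, 6
        probs = pattern_distribution(n, hypothesis, eps)

        def simulate(draws, rng):
            if hypothesis[0] == "dual":
                m = rng.binomial(n, hypothesis[1], size=draws)
                carried = np.stack([m, m, m], axis=1)
            else:
                f1, f2 = hypothesis[1], hypothesis[2]
                mm = rng.multinomial(n, [f1, f2, 1 - f1 - f2], size=draws)
                carried = np.stack([mm[:, 0], mm[:, 1], mm[:, 0] + mm[:, 1]], axis=1)
            present = rng.binomial(carried, 1 - eps) > 0
            idx = present[:, 0] * 4 + present[:, 1] * 2 + present[:, 2]
            return np.bincount(idx, minlength=8) / draws

        rng = np.random.default_rng(17)
        for draws in (200_000, 1_600_000):
            emp = simulate(draws, rng)
            se = np.sqrt(np.maximum(probs * (1 - probs), 1e-12) / draws)
            if np.all(np.abs(emp - probs) < 3 * se + 1e-5):
                break
        else:
            raise AssertionError(f"pattern MC disagrees: {emp} vs {probs}")

    def test_loglik_requires_wells_below_cap(self):
        with pytest.raises(ValueError):
            pattern_loglik({}, ("dual", 0.1), eps=0.1)


class TestLikelihoodConsistency:
    def _simulate_delta(self, dual: bool, seed: int) -> float:
        f = 0.10
        if dual:
            specs = [(("a1", "a2"), ("b1",), f), (("a9",), ("b9",), 1 - f)]
        else:
            specs = [
                (("a1",), ("b1",), f / 2),
                (("a2",), ("b1",), f / 2),
                (("a9",), ("b9",), 1 - f),
            ]
        pop = make_population(specs, drop=0.15)
        wells, _ = sample_wells(pop, SamplingPlan(((60, 20),)), seed=seed)
        pat = pattern_counts(wells, ("a1", "a2", "b1"), size_cap=50)
        triple = occupancy_counts(wells, ("a1", "a2", "b1"))
        if triple.total_hits == 0:
            return 0.0
        f_dual = estimate_frequency(triple, eps=0.15, mode="dual").f_hat
        e1 = estimate_frequency(occupancy_counts(wells, ("a1", "b1")), eps=0.15).f_hat
        e2 = estimate_frequency(occupancy_counts(wells, ("a2", "b1")), eps=0.15).f_hat
        ll_dual = pattern_loglik(pat, ("dual", f_dual), eps=0.15)
        ll_two = pattern_loglik(pat, ("two_clones", e1, e2), eps=0.15)
        return ll_dual - ll_two

    def test_simulation_under_each_hypothesis_favours_it(self):
        deltas_dual = [self._simulate_delta(True, 100 + s) for s in range(30)]
        deltas_two = [self._simulate_delta(False, 200 + s) for s in range(30)]
        assert np.median(deltas_dual) > 0
        assert np.median(deltas_two) < 0


class TestCallDuals:
    def test_candidates_share_beta_never_alpha(self):
        pairs = [("a1", "b1"), ("a2", "b1"), ("a1", "b2"), ("a3", "b3")]
        triples = find_sharing_candidates(pairs)
        assert triples == [("a1", "a2", "b1")]

    def test_simulated_dual_clone_called_dual(self):
        # a true dual clone at f=0.05 under the five-plate high-mixed plan,
        # eps=0.15: recovered as dual in >= 90% of simulated datasets.  At
        # this abundance the coincidence ratio saturates toward 1, so the
        # call must come from the full-likelihood route over the small wells.
        plan = SamplingPlan(((128, 20), (64, 50), (96, 100), (96, 200), (96, 300)))
        tail_n = 40
        called = 0
        total = 60
        for s in range(total):
            specs = [(("a1", "a2"), ("b1",), 0.05)] + [
                ((f"x{i}",), (f"y{i}",), 0.95 / tail_n) for i in range(tail_n)
            ]
            pop = make_population(specs, drop=0.15)
            wells, _ = sample_wells(pop, plan, seed=1000 + s)
            pairs = [("a1", "b1"), ("a2", "b1")] + [
                (f"x{i}", f"y{i}") for i in range(tail_n)
            ]
            estimates = {}
            ok = True
            for a, b in pairs:
                counts = occupancy_counts(wells, (a, b))
                if counts.total_hits == 0:
                    ok = False
                    break
                estimates[(a, b)] = estimate_frequency(counts, eps=0.15)
            if not ok:
                total -= 1
                continue
            calls, _ = call_duals(pairs, wells, estimates, eps=0.15, seed=s)
            assert len(calls) == 1
            called += calls[0].verdict == "dual"
        assert called / total >= 0.90

    def test_delta_loglik_overrides_clustering(self, monkeypatch):
        # ΔlogL >= 10 forces dual, <= -10 forces two_clones, regardless of
        # which k-means cluster the ratio fell into
        recorded = {}

        def fake_cluster(ratios, seed=0, n_init=20):
            return np.zeros(len(ratios), dtype=bool)  # cluster says two_clones

        monkeypatch.setattr(dualcall, "cluster_ratios", fake_cluster)
        # 1-cell wells: a two-clone pair can never show all three chains in
        # one cell, so any observed triple makes the likelihood gap decisive
        specs = [(("a1", "a2"), ("b1",), 0.3), (("a9",), ("b9",), 0.7)]
        pop = make_population(specs, drop=0.1)
        wells, _ = sample_wells(pop, SamplingPlan(((60, 1),)), seed=7)
        pairs = [("a1", "b1"), ("a2", "b1")]
        estimates = {
            p: estimate_frequency(occupancy_counts(wells, p), eps=0.1)
            for p in pairs
        }
        calls, cands = call_duals(pairs, wells, estimates, eps=0.1, seed=0)
        assert calls[0].method == "full_likelihood"
        assert cands[0].delta_loglik >= 10
        assert calls[0].verdict == "dual"
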