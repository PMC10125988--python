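"""Random bipartite model, score-function rewiring, proximity index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from glomnet.network import (
    BipartiteNetwork,
    ImpossiblePlacementError,
    InvalidPairError,
    ScoreUndefinedError,
    build_random_network,
    evaluate_swap,
    label_coverage_fraction,
    mean_proximity_index,
    proximity_index,
    rewire,
)


def _net_from_gloms(member_lists, n_gc=3000):
    """Hand-built network from explicit per-glomerulus dendrite-ID lists."""
    gc, gl = [], []
    for g, ids in enumerate(member_lists, start=1):
        for x in ids:
            gc.append(x)
            gl.append(g)
    return BipartiteNetwork(
        n_gc=n_gc,
        n_glom=len(member_lists),
        dendrites_per_gc=1,
        gc_ids=np.array(gc, dtype=np.int64),
        glom_ids=np.array(gl, dtype=np.int64),
    )


class TestBuildRandom:
    def test_default_scale_degrees(self, default_network):
        net = default_network
        net.validate()
        assert net.n_edges == 12000
        deg = net.glomerulus_degrees()
        assert deg.mean() == pytest.approx(12.0)

    def test_forced_full_usage(self):
        # each GC must use all 4 glomeruli, so every glomerulus degree == n_gc
        for n_gc in (1, 2):
            net = build_random_network(n_gc, 4, 4, seed=0)
            assert (net.glomerulus_degrees() == n_gc).all()

    def test_impossible_placement(self):
        with pytest.raises(ImpossiblePlacementError):
            build_random_network(10, 3, 4, seed=0)

    def test_seed_reproducibility(self):
        a = build_random_network(100, 40, 4, seed=5)
        b = build_random_network(100, 40, 4, seed=5)
        assert (a.gc_ids == b.gc_ids).all() and (a.glom_ids == b.glom_ids).all()

    def test_degree_distribution_binomial(self):
        """Pooled glomerulus degrees are consistent with Binomial(n_gc*4, 1/n_glom)."""
        degs = np.concatenate(
            [
                build_random_network(3000, 1000, 4, seed=s).glomerulus_degrees()
                for s in range(50)
            ]
        )
        n_trials, p = 3000 * 4, 1 / 1000
        lo, hi = 4, 21  # bins with decent expected counts; tails pooled
        edges = np.arange(lo, hi + 1)
        expected = stats.binom.pmf(edges, n_trials, p)
        probs = np.concatenate(
            [[stats.binom.cdf(lo - 1, n_trials, p)], expected,
             [stats.binom.sf(hi, n_trials, p)]]
        )
        observed = np.concatenate(
            [[np.sum(degs < lo)], [np.sum(degs == k) for k in edges], [np.sum(degs > hi)]]
        )
        chi2 = ((observed - probs * degs.size) ** 2 / (probs * degs.size)).sum()
        p_value = stats.chi2.sf(chi2, df=len(observed) - 1)
        assert p_value > 0.01


class TestEvaluateSwap:
    def test_hand_worked_rejected_swap(self):
        net = _net_from_gloms([[10, 20, 30], [100, 110, 120]])
        ev = evaluate_swap(net, (10, 1), (100, 2), "preferential")
        assert ev.D_x == 15 and ev.D_y == 15 and ev.S0 == 30
        assert ev.d_x == 75 and ev.d_y == 105 and ev.S == 180
        assert not ev.executed
        # the same pair under avoidance is an improvement
        assert evaluate_swap(net, (10, 1), (100, 2), "avoidance").executed

    def test_hand_worked_executed_swap(self):
        net = _net_from_gloms([[100, 900], [850, 950]])
        ev = evaluate_swap(net, (900, 1), (850, 2), "preferential")
        assert ev.S0 == 900 and ev.S == 800
        assert ev.executed

    def test_tie_never_executes(self):
        # symmetric configuration: swapping equidistant IDs leaves the score fixed
        net = _net_from_gloms([[10, 20], [20, 30]], n_gc=100)
        ev_p = evaluate_swap(net, (10, 1), (30, 2), "preferential")
        ev_a = evaluate_swap(net, (10, 1), (30, 2), "avoidance")
        assert ev_p.S == ev_p.S0
        assert not ev_p.executed and not ev_a.executed

    def test_invalid_pairs(self):
        net = _net_from_gloms([[10, 20, 30], [100, 110, 120], [500]])
        with pytest.raises(InvalidPairError):
            evaluate_swap(net, (10, 1), (20, 1), "preferential")
        with pytest.raises(InvalidPairError):
            evaluate_swap(net, (10, 1), (10, 2), "preferential")
        with pytest.raises(ScoreUndefinedError):
            evaluate_swap(net, (10, 1), (500, 3), "preferential")

    def test_matches_bruteforce_on_toy_network(self, toy_network):
        """Score agrees with an independent brute-force recomputation."""
        members = toy_network.glomerulus_members()
        for ga in range(1, toy_network.n_glom + 1):
            for gb in range(1, toy_network.n_glom + 1):
                if ga == gb or len(members[ga - 1]) < 2 or len(members[gb - 1]) < 2:
                    continue
                for x_p in members[ga - 1]:
                    for y_q in members[gb - 1]:
                        if x_p == y_q:
                            continue
                        ev = evaluate_swap(toy_network, (x_p, ga), (y_q, gb), "preferential")
                        xs = members[ga - 1]
                        ys = members[gb - 1]
                        D_x = np.mean([abs(x_p - x) for x in xs if x != x_p])
                        D_y = np.mean([abs(y_q - y) for y in ys if y != y_q])
                        d_x = np.mean([abs(y_q - x) for x in xs if x != x_p])
                        d_y = np.mean([abs(x_p - y) for y in ys if y != y_q])
                        assert ev.S0 == pytest.approx(D_x + D_y)
                        assert ev.S == pytest.approx(d_x + d_y)
                        assert ev.executed == (ev.S < ev.S0)


class TestRewire:
    def test_zero_trials_identity(self, default_network):
        out = rewire(default_network, "preferential", 0, seed=1)
        assert (out.gc_ids == default_network.gc_ids).all()
        assert (out.glom_ids == default_network.glom_ids).all()

    def test_degree_conservation_and_validity(self, default_network):
        for mode, trials in (("preferential", 2500), ("avoidance", 1000)):
            out = rewire(default_network, mode, trials, seed=3)
            out.validate()
            assert (
                out.glomerulus_degrees() == default_network.glomerulus_degrees()
            ).all()

    def test_pi_moves_in_the_right_direction(self, default_network):
        base = mean_proximity_index(default_network)
        pref = mean_proximity_index(rewire(default_network, "preferential", 2500, 1))
        avoid = mean_proximity_index(rewire(default_network, "avoidance", 1000, 1))
        assert pref > base > avoid

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=15)
    def test_small_network_invariants_preserved(self, seed):
        net = build_random_network(30, 10, 3, seed=seed)
        out = rewire(net, "preferential", 200, seed=seed + 1)
        out.validate()
        assert (out.glomerulus_degrees() == net.glomerulus_degrees()).all()


class TestProximityIndex:
    @pytest.mark.parametrize(
        "ids, expected",
        [({1, 2}, 1.0), ({1, 3, 5}, 3 / 8), ({1, 2, 3, 4}, 0.6)],
    )
    def test_hand_values(self, ids, expected):
        assert proximity_index(ids) == pytest.approx(expected)

    def test_mean_pi_matches_per_glomerulus_oracle(self, toy_network):
        members = [m for m in toy_network.glomerulus_members() if len(m) >= 2]
        oracle = np.mean([proximity_index(m) for m in members])
        assert mean_proximity_index(toy_network) == pytest.approx(oracle)

    def test_undefined_for_singletons(self):
        with pytest.raises(ScoreUndefinedError):
            proximity_index([5])


class TestLabelCoverage:
    def test_full_and_empty_windows(self, default_network):
        assert label_coverage_fraction(default_network, (1, 3000)) == 1.0
        assert label_coverage_fraction(default_network, None) == 0.0
        assert label_coverage_fraction(default_network, (10, 5)) == 0.0

    def test_thirty_percent_window_near_binomial_expectation(self, default_network):
        # P(no dendrite of 900 GCs among ~12) ~ 0.7^12; coverage ~ 0.986
        cov = label_coverage_fraction(default_network, (1, 900))
        assert cov > 0.8
        assert cov == pytest.approx(1 - 0.7**12, abs=0.02)


def test_tsv_roundtrip(tmp_path, toy_network):
    path = tmp_path / "edges.tsv"
    toy_network.to_tsv(path)
    back = BipartiteNetwork.from_tsv(path)
    assert (back.gc_ids == toy_network.gc_ids).all()
    assert (back.glom_ids == toy_network.glom_ids).all()
    assert back.n_glom == toy_network.n_glom
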