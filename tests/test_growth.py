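"""Growth process: candidate sampling, selection law, walk distances."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from netevo.growth import (GrowthState, NetworkComplete, SamplingConfig,
                           generate_network, heuristic_distances,
                           sample_candidates, selection_probabilities)
from netevo.programs import parse


def _full_cfg():
    return SamplingConfig(s_r=1.0, min_sample=1)


class TestSelectionProbabilities:
    @pytest.mark.parametrize("weights, expected", [
        ([2, 3, 5], [0.2, 0.3, 0.5]),
        ([0, 0, 0], [1 / 3, 1 / 3, 1 / 3]),        # all-zero fallback
        ([-1, 2, 2], [0.0, 0.5, 0.5]),             # negative gated to zero
        ([-3, -1, 0], [1 / 3, 1 / 3, 1 / 3]),      # no positive weight
        ([7.0], [1.0]),
    ])
    def test_law(self, weights, expected):
        assert np.allclose(selection_probabilities(weights), expected)

    def test_huge_weights_stay_normalized(self):
        p = selection_probabilities([1e300, 1e300, 1e300])
        assert np.allclose(p, [1 / 3, 1 / 3, 1 / 3])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            selection_probabilities([])


class TestSampleCandidates:
    def test_exhaustive_on_empty_directed_triangle(self, rng):
        state = GrowthState(3, directed=True)
        us, vs = sample_candidates(state, _full_cfg(), rng)
        assert sorted(zip(us.tolist(), vs.tolist())) == sorted(
            (u, v) for u in (1, 2, 3) for v in (1, 2, 3) if u != v)

    def test_existing_arc_excluded(self, rng):
        state = GrowthState(3, directed=True)
        state.add_arc(1, 2)
        us, vs = sample_candidates(state, _full_cfg(), rng)
        pairs = set(zip(us.tolist(), vs.tolist()))
        assert len(pairs) == 5 and (1, 2) not in pairs

    def test_no_duplicates_or_self_links(self, rng):
        state = GrowthState(30, directed=True)
        for v in range(2, 12):
            state.add_arc(1, v)
        cfg = SamplingConfig(s_r=0.05, min_sample=40)
        for _ in range(300):
            us, vs = sample_candidates(state, cfg, rng)
            pairs = list(zip(us.tolist(), vs.tolist()))
            assert len(set(pairs)) == len(pairs)
            assert all(u != v for u, v in pairs)
            assert all(not state.has_arc(u, v) for u, v in pairs)

    def test_undirected_pairs_unordered(self, rng):
        state = GrowthState(4, directed=False)
        state.add_arc(1, 2)
        us, vs = sample_candidates(state, _full_cfg(), rng)
        keys = {tuple(sorted(p)) for p in zip(us.tolist(), vs.tolist())}
        assert keys == {(1, 3), (1, 4), (2, 3), (2, 4), (3, 4)}

    def test_complete_network_raises(self, rng):
        state = GrowthState(3, directed=False)
        for u, v in [(1, 2), (1, 3), (2, 3)]:
            state.add_arc(u, v)
        with pytest.raises(NetworkComplete):
            sample_candidates(state, _full_cfg(), rng)

    def test_degree_tallies_match_arcs(self, rng):
        state = GrowthState(20, directed=True)
        program = parse("(+ i j)")
        graph = generate_network(program, 20, 60, rng=rng)
        for v in graph.nodes():
            assert graph.in_degree(v) + graph.out_degree(v) == graph.degree(v)


class TestHeuristicDistances:
    def _path_state(self, n=10):
        state = GrowthState(n, directed=True)
        for u in range(1, n):
            state.add_arc(u, u + 1)
        return state

    def test_lower_bounded_by_bfs_on_path(self, rng):
        state = self._path_state()
        cfg = SamplingConfig(walk_count=20, walk_length=9)
        hits = 0
        for _ in range(50):
            origin, target = 1, int(rng.integers(2, 11))
            true = target - origin
            d, d_d, d_r = heuristic_distances(state, origin, target, cfg, rng)
            assert d_d >= true and d >= min(true, cfg.distance_cap)
            hits += d_d == true
        assert hits > 0  # walks do find the true distance on a path

    def test_budget_improves_accuracy(self, rng):
        # star with one extended branch: a single walk usually picks the
        # wrong spoke, so more walks find the true 2-hop route more often
        state = GrowthState(8, directed=True)
        for v in range(2, 7):
            state.add_arc(1, v)
        state.add_arc(2, 7)
        small = SamplingConfig(walk_count=1, walk_length=4)
        large = SamplingConfig(walk_count=60, walk_length=4)
        exact_small = sum(
            heuristic_distances(state, 1, 7, small, rng)[1] == 2
            for _ in range(200))
        exact_large = sum(
            heuristic_distances(state, 1, 7, large, rng)[1] == 2
            for _ in range(200))
        assert exact_large > exact_small

    def test_direct_arc_found_with_ample_budget(self, rng):
        state = GrowthState(5, directed=True)
        state.add_arc(1, 2)
        cfg = SamplingConfig(walk_count=50, walk_length=3)
        assert heuristic_distances(state, 1, 2, cfg, rng)[1] == 1

    def test_disconnected_reports_cap(self, rng):
        state = GrowthState(6, directed=True)
        state.add_arc(1, 2)
        state.add_arc(4, 5)
        cfg = SamplingConfig(walk_count=10, walk_length=4)
        assert heuristic_distances(state, 1, 5, cfg, rng) == (5, 5, 5)

    def test_reverse_view(self, rng):
        state = GrowthState(4, directed=True)
        state.add_arc(2, 1)  # reachable from 1 only against arc direction
        cfg = SamplingConfig(walk_count=50, walk_length=3)
        d, d_d, d_r = heuristic_distances(state, 1, 2, cfg, rng)
        assert d_r == 1 and d == 1 and d_d == cfg.distance_cap


class TestGenerateNetwork:
    def test_counts_and_constraints(self, rng):
        graph = generate_network(parse("1.0"), 10, 20, rng=rng)
        assert graph.number_of_nodes() == 10
        assert graph.number_of_edges() == 20
        assert not any(u == v for u, v in graph.edges())
        assert sorted(graph.nodes()) == list(range(1, 11))

    def test_seeded_reproducibility(self):
        a = generate_network(parse("(/ 1 i)"), 30, 100, rng=5)
        b = generate_network(parse("(/ 1 i)"), 30, 100, rng=5)
        assert set(a.edges()) == set(b.edges())

    def test_m_too_large_refused(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_network(parse("1.0"), 5, 21, rng=0)
        with pytest.raises(ValueError, match="exceeds"):
            # undirected mode halves the legal arc count
            generate_network(parse("1.0", directed=False), 5, 11, rng=0)

    def test_zero_weight_fallback_bootstraps_pa(self, rng):
        # all in-degrees are 0 at step 1, so "k'" relies on the uniform fallback
        graph = generate_network(parse("k'"), 30, 60, rng=rng)
        assert graph.number_of_edges() == 60

    def test_pa_has_heavier_in_degree_tail_than_er(self):
        pa_max, er_max = [], []
        for seed in range(8):
            g_pa = generate_network(parse("k'"), 200, 2000, rng=1000 + seed)
            g_er = generate_network(parse("1.0"), 200, 2000, rng=2000 + seed)
            pa_max.append(max(d for _, d in g_pa.in_degree()))
            er_max.append(max(d for _, d in g_er.in_degree()))
        assert np.mean(pa_max) > 1.5 * np.mean(er_max)

    def test_er_program_matches_gnm_degrees(self):
        """Uniform growth is exactly G(n, m); degree samples agree (KS)."""
        grown, gnm = [], []
        for seed in range(20):
            g = generate_network(parse("2.5"), 80, 240, rng=seed)
            grown.extend(d for _, d in g.in_degree())
            h = nx.gnm_random_graph(80, 240, seed=seed, directed=True)
            gnm.extend(d for _, d in h.in_degree())
        assert stats.ks_2samp(grown, gnm).pvalue > 0.01

    def test_exhaustive_sampling_is_uniform_over_outcomes(self):
        """With s_r=1 and a constant program every arc sequence is equally
        likely, so the C(6,2)=15 possible two-arc networks on n=3 are
        uniform: chi-square against the enumeration oracle."""
        program = parse("1.0")
        cfg = _full_cfg()
        counts = {}
        runs = 5000
        for seed in range(runs):
            g = generate_network(program, 3, 2, cfg=cfg, rng=seed)
            key = tuple(sorted(g.edges()))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 15
        observed = np.array(list(counts.values()))
        assert stats.chisquare(observed).pvalue > 0.001
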