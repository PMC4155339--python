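"""Feature distributions, dissimilarities and the minimax fitness."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.optimize import linprog

from netevo.growth import generate_network
from netevo.metrics import (TRIAD_CLASSES, distance_distribution,
                            dissimilarities, emd_1d, er_baseline,
                            extract_features, fitness, pagerank_values,
                            ratio_dissimilarity, triadic_profile)
from netevo.programs import parse


def emd_lp(p, q):
    """Independent transport-LP oracle for the 1-D EMD (unit bin distance)."""
    bins = len(p)
    cost = np.abs(np.subtract.outer(np.arange(bins), np.arange(bins))).ravel()
    a_eq = []
    for i in range(bins):  # row sums = p
        row = np.zeros((bins, bins))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(bins):  # column sums = q
        col = np.zeros((bins, bins))
        col[:, j] = 1
        a_eq.append(col.ravel())
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.concatenate([p, q]),
                  bounds=(0, None), method="highs")
    assert res.success
    return res.fun


class TestEmd:
    def test_identity(self):
        p = np.array([0.2, 0.3, 0.5])
        assert emd_1d(p, p) == 0.0

    def test_two_bin_example(self):
        assert emd_1d([0.75, 0.25], [0.25, 0.75]) == pytest.approx(0.5)

    def test_symmetry_and_positivity(self, rng):
        for _ in range(50):
            size = int(rng.integers(2, 12))
            p = rng.dirichlet(np.ones(size))
            q = rng.dirichlet(np.ones(size))
            assert emd_1d(p, q) == pytest.approx(emd_1d(q, p))
            assert emd_1d(p, q) >= 0

    def test_against_transport_lp(self, rng):
        for _ in range(30):
            size = int(rng.integers(2, 15))
            p = rng.dirichlet(np.ones(size))
            q = rng.dirichlet(np.ones(size))
            assert emd_1d(p, q) == pytest.approx(emd_lp(p, q), abs=1e-9)

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError):
            emd_1d([], [])


class TestRatioDissimilarity:
    def test_zero_iff_equal(self, rng):
        x = rng.integers(0, 50, size=8)
        assert ratio_dissimilarity(x, x) == 0.0
        y = x.copy()
        y[3] += 5
        assert ratio_dissimilarity(x, y) > 0

    def test_symmetric(self, rng):
        for _ in range(100):
            x = rng.integers(0, 100, size=6)
            y = rng.integers(0, 100, size=6)
            assert ratio_dissimilarity(x, y) == pytest.approx(
                ratio_dissimilarity(y, x))

    def test_extremal_two_bin_unit_mass(self):
        crossed = ratio_dissimilarity([1, 0], [0, 1])
        for x, y in itertools.product([[1, 0], [0, 1]], repeat=2):
            assert ratio_dissimilarity(x, y) <= crossed + 1e-12

    def test_monotone_in_divergence(self):
        base = np.array([40, 40, 20])
        near = np.array([45, 38, 17])
        far = np.array([80, 15, 5])
        assert ratio_dissimilarity(base, near) < ratio_dissimilarity(base, far)


def classify_triad_bruteforce(graph):
    """Exhaustive triple enumeration with isomorphism matching — the
    independent oracle for the directed triad census."""
    references = {name: nx.triad_graph(name) for name in TRIAD_CLASSES}
    counts = dict.fromkeys(TRIAD_CLASSES, 0)
    for triple in itertools.combinations(sorted(graph.nodes()), 3):
        sub = graph.subgraph(triple)
        if not nx.is_weakly_connected(sub):
            continue
        for name, ref in references.items():
            if nx.is_isomorphic(sub, ref):
                counts[name] += 1
                break
        else:  # pragma: no cover
            raise AssertionError("connected triad matched no class")
    return np.array([counts[name] for name in TRIAD_CLASSES])


class TestTriadicProfile:
    def test_directed_three_cycle(self):
        g = nx.DiGraph([(1, 2), (2, 3), (3, 1)])
        profile = triadic_profile(g)
        assert profile.sum() == 1
        assert profile[TRIAD_CLASSES.index("030C")] == 1

    def test_undirected_triangle_and_path(self):
        assert triadic_profile(nx.Graph([(1, 2), (2, 3), (3, 1)])).tolist() == [0, 1]
        assert triadic_profile(nx.Graph([(1, 2), (2, 3)])).tolist() == [1, 0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_census_matches_bruteforce(self, seed):
        g = nx.gnm_random_graph(18, 60, seed=seed, directed=True)
        assert np.array_equal(triadic_profile(g), classify_triad_bruteforce(g))

    def test_undirected_counts_match_enumeration(self, rng):
        g = nx.gnm_random_graph(15, 30, seed=7)
        open_triples = triangles = 0
        for triple in itertools.combinations(g.nodes(), 3):
            edges = g.subgraph(triple).number_of_edges()
            if edges == 3:
                triangles += 1
            elif edges == 2:
                open_triples += 1
        assert triadic_profile(g).tolist() == [open_triples, triangles]


class TestDistanceDistribution:
    def test_five_node_path(self):
        g = nx.path_graph(range(1, 6))
        dist = distance_distribution(g, directed=False)
        assert dist.counts.tolist() == [4, 3, 2, 1]
        assert dist.unreachable == 0
        assert dist.pairs == 10

    def test_disconnected_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        dist = distance_distribution(g, directed=False)
        assert dist.unreachable == 16  # the 4*4 cross pairs
        assert dist.counts.tolist() == [12]

    def test_directed_counts_ordered_pairs(self):
        g = nx.DiGraph([(1, 2), (2, 3)])
        dist = distance_distribution(g, directed=True)
        assert dist.counts.tolist() == [2, 1]       # 1->2, 2->3; 1->3
        assert dist.unreachable == 3
        assert dist.pairs == 6

    def test_sampled_agrees_with_exhaustive(self, rng, monkeypatch):
        g = nx.gnm_random_graph(300, 900, seed=3, directed=True)
        exhaustive = distance_distribution(g, directed=True)
        import netevo.metrics as metrics_mod
        monkeypatch.setattr(metrics_mod, "DISTANCE_EXHAUSTIVE_LIMIT", 10)
        monkeypatch.setattr(metrics_mod, "DISTANCE_SAMPLE_SOURCES", 150)
        sampled = metrics_mod.distance_distribution(g, directed=True, rng=rng)
        hops = max(exhaustive.counts.size, sampled.counts.size)
        f_ex = exhaustive.aligned(hops) / exhaustive.pairs
        f_sa = sampled.aligned(hops) / sampled.pairs
        assert np.abs(f_ex - f_sa).max() < 0.05


class TestPagerank:
    def test_regular_cycle_uniform(self):
        g = nx.cycle_graph(8, create_using=nx.DiGraph)
        assert np.allclose(pagerank_values(g), 1 / 8)

    def test_reverse_equals_reversed_copy(self):
        g = nx.gnm_random_graph(40, 160, seed=5, directed=True)
        assert np.allclose(pagerank_values(g, reverse=True),
                           pagerank_values(g.reverse()))

    def test_sums_to_one(self, rng):
        for seed in range(20):
            g = nx.gnm_random_graph(30, 90, seed=seed, directed=True)
            assert pagerank_values(g).sum() == pytest.approx(1.0, abs=1e-10)


@pytest.fixture(scope="module")
def target():
    return generate_network(parse("k'"), 60, 360, rng=17)


@pytest.fixture(scope="module")
def baselines(target):
    return er_baseline(target, rng=18, replicates=10)


class TestFitness:
    def test_baselines_positive_and_deterministic(self, target):
        a = er_baseline(target, rng=7, replicates=5)
        b = er_baseline(target, rng=7, replicates=5)
        assert a == b
        assert all(v > 0 for v in a.values())

    def test_exact_copy_scores_zero(self, target, baselines):
        vector = fitness(target, target.copy(), baselines)
        assert vector.fitness == 0.0
        assert all(v == 0.0 for v in vector.raw.values())

    def test_fitness_is_max_ratio(self, target, baselines, rng):
        candidate = generate_network(parse("1.0"), 60, 360, rng=rng)
        vector = fitness(target, candidate, baselines)
        assert vector.fitness == max(vector.ratios.values())
        assert all(vector.fitness >= r for r in vector.ratios.values())

    def test_invariant_under_candidate_relabeling(self, target, baselines, rng):
        candidate = generate_network(parse("(/ 1 i)"), 60, 360, rng=4)
        perm = dict(zip(sorted(candidate.nodes()),
                        rng.permutation(sorted(candidate.nodes())).tolist()))
        relabeled = nx.relabel_nodes(candidate, perm)
        a = fitness(target, candidate, baselines)
        b = fitness(target, relabeled, baselines)
        assert a.fitness == pytest.approx(b.fitness)
        for name in a.ratios:
            assert a.ratios[name] == pytest.approx(b.ratios[name])

    def test_dissimilarities_symmetric_nonnegative(self, rng):
        f1 = extract_features(generate_network(parse("k'"), 40, 160, rng=1))
        f2 = extract_features(generate_network(parse("1.0"), 40, 160, rng=2))
        d12 = dissimilarities(f1, f2)
        d21 = dissimilarities(f2, f1)
        for name in d12:
            assert d12[name] >= 0
            assert d12[name] == pytest.approx(d21[name])

    def test_zero_baseline_flagged(self, target):
        feats = extract_features(target)
        zero_base = {name: 0.0 for name in feats.metric_names}
        vector = fitness(feats, feats, zero_base)
        assert vector.fitness == 0.0  # zero raw with zero baseline
        other = extract_features(generate_network(parse("1.0"), 60, 360, rng=9))
        vector = fitness(feats, other, zero_base)
        assert np.isinf(vector.fitness) and vector.degenerate
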