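"""Network feature distributions and the ER-normalized minimax fitness.

Synthetic-vs-target similarity is scored on a panel of structural feature
distributions: degree (in/out when directed), PageRank computed on the
actual and on the arc-reversed network, shortest-path distance
distributions (directed and undirected views) and the triadic profile
(frequencies of the 13 connected 3-node digraph classes, or open
triple/triangle for undirected networks).

Degree and PageRank distributions are compared with the 1-D Earth mover's
distance; distance distributions and triadic profiles with a smoothed
ratio dissimilarity on raw counts.  Each raw dissimilarity is divided by
the mean dissimilarity between the target and 30 size-matched Erdős–Rényi
networks, putting all metrics on one "improvement over random" scale: a
ratio of 1 means no better than random, 0 means a perfect match.  The
fitness of a candidate is the *largest* of these ratios, so the search
must improve its worst feature to improve at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse import csgraph

__all__ = [
    "FeatureBundle",
    "DissimilarityVector",
    "METRICS_DIRECTED",
    "METRICS_UNDIRECTED",
    "emd_1d",
    "ratio_dissimilarity",
    "triadic_profile",
    "distance_distribution",
    "pagerank_values",
    "extract_features",
    "dissimilarities",
    "er_baseline",
    "fitness",
]

METRICS_DIRECTED = ("k_in", "k_out", "pr_d", "pr_r", "dist_d", "dist_u", "triads")
METRICS_UNDIRECTED = ("k", "pr", "dist_u", "triads")

#: PageRank settings (damping and convergence tolerance)
PAGERANK_ALPHA = 0.85
PAGERANK_TOL = 1e-10
#: number of equal-width bins for PageRank EMD support
PAGERANK_BINS = 50
#: exhaustive all-pairs distances up to this many nodes, sampled beyond
DISTANCE_EXHAUSTIVE_LIMIT = 1000
DISTANCE_SAMPLE_SOURCES = 1000

# the 13 connected classes of the 16-entry triad census, in census order
TRIAD_CLASSES = ("021D", "021U", "021C", "111D", "111U", "030T", "030C",
                 "201", "120D", "120U", "120C", "210", "300")
_CONNECTED_TRIADS = slice(3, 16)


# ---------------------------------------------------------------------------
# elementary dissimilarities
# ---------------------------------------------------------------------------

def emd_1d(p: np.ndarray, q: np.ndarray) -> float:
    """Earth mover's distance between two histograms on a shared support.

    Both inputs must be normalized to total mass 1 on the same binning;
    the ground distance between adjacent bins is 1, so the EMD reduces to
    the summed absolute difference of the CDFs.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.size == 0 or q.size == 0:
        raise ValueError("empty support")
    if p.shape != q.shape:
        raise ValueError("supports differ")
    return float(np.abs(np.cumsum(p - q)).sum())


def ratio_dissimilarity(x: np.ndarray, y: np.ndarray) -> float:
    """Smoothed per-bin ratio dissimilarity between two raw count vectors.

    Each bin contributes its excess ratio ``max(x̃_i, ỹ_i) / min(x̃_i, ỹ_i) - 1``,
    averaged with weights proportional to the bin's combined smoothed
    mass.  The pseudo-count is the mean bin occupancy (at least 1), so
    smoothing scales with the population being compared.  The value is
    zero iff the counts agree, symmetric, and grows with per-bin
    divergence; weighting and occupancy-scaled smoothing keep near-empty
    tail bins — whose count ratios are pure sampling noise — from
    swamping the signal carried by the populated bins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("supports differ")
    s = max(1.0, (x.sum() + y.sum()) / (2.0 * x.size))
    x = x + s
    y = y + s
    hi = np.maximum(x, y)
    lo = np.minimum(x, y)
    weights = x + y
    return float(np.sum(weights * (hi / lo - 1.0)) / weights.sum())


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceDistribution:
    """Counts of pair shortest-path lengths plus an unreachable bucket.

    ``counts[h - 1]`` is the number of pairs at hop distance ``h``;
    ``unreachable`` counts pairs with no path; ``pairs`` is the population.
    """

    counts: np.ndarray
    unreachable: int
    pairs: int

    def aligned(self, max_hops: int) -> np.ndarray:
        """Raw count vector padded to ``max_hops`` with the unreachable
        bucket appended last."""
        padded = np.zeros(max_hops + 1, dtype=float)
        padded[: self.counts.size] = self.counts
        padded[-1] = self.unreachable
        return padded


def _hop_counts(dmat: np.ndarray) -> tuple[np.ndarray, int]:
    finite = dmat[np.isfinite(dmat)]
    finite = finite[finite > 0].astype(np.int64)
    unreachable = int(np.isinf(dmat).sum())
    if finite.size:
        counts = np.bincount(finite)[1:]
    else:
        counts = np.zeros(0, dtype=np.int64)
    return counts.astype(np.int64), unreachable


def _to_csr(graph: nx.Graph) -> sp.csr_array:
    return nx.to_scipy_sparse_array(graph, nodelist=sorted(graph.nodes()),
                                    format="csr")


def distance_distribution(graph: nx.Graph, directed: bool,
                          rng: np.random.Generator | None = None) -> DistanceDistribution:
    """Distribution of shortest-path hop counts between node pairs.

    Exhaustive BFS for networks up to 1000 nodes; beyond that, 1000 source
    nodes are sampled.  Directed networks count ordered pairs; undirected
    exhaustive counts unordered pairs.  Unreachable pairs land in a
    dedicated bucket instead of being dropped.
    """
    return _distance_from_csr(_to_csr(graph), directed, rng)


def _distance_from_csr(adj: sp.csr_array, directed: bool,
                       rng: np.random.Generator | None = None) -> DistanceDistribution:
    n = adj.shape[0]
    if n <= DISTANCE_EXHAUSTIVE_LIMIT:
        dmat = csgraph.shortest_path(adj, method="D", unweighted=True,
                                     directed=directed)
        np.fill_diagonal(dmat, 0.0)
        if not directed:
            dmat = dmat[np.triu_indices(n, k=1)]
            pairs = n * (n - 1) // 2
        else:
            pairs = n * (n - 1)
        counts, unreachable = _hop_counts(np.asarray(dmat))
    else:
        rng = rng or np.random.default_rng(0)
        sources = rng.choice(n, size=min(DISTANCE_SAMPLE_SOURCES, n), replace=False)
        dmat = csgraph.dijkstra(adj, unweighted=True, directed=directed,
                                indices=sources)
        dmat[np.arange(sources.size), sources] = 0.0
        pairs = sources.size * (n - 1)
        counts, unreachable = _hop_counts(np.asarray(dmat))
    return DistanceDistribution(counts=counts, unreachable=unreachable, pairs=pairs)


def triadic_profile(graph: nx.Graph) -> np.ndarray:
    """Raw counts of connected 3-node subgraph classes.

    Directed: the 13 connected triad-census classes (021D, 021U, 021C,
    111D, 111U, 030T, 030C, 201, 120D, 120U, 120C, 210, 300), counted with
    igraph's triad census.  Undirected: ``[open triples, triangles]``.
    Normalize externally when a frequency profile is wanted.
    """
    if graph.is_directed():
        nodes = sorted(graph.nodes())
        index = {v: t for t, v in enumerate(nodes)}
        g = ig.Graph(n=len(nodes),
                     edges=[(index[u], index[v]) for u, v in graph.edges()],
                     directed=True)
        census = np.asarray(g.triad_census(), dtype=np.int64)
        return census[_CONNECTED_TRIADS].copy()
    return _undirected_triads(_to_csr(graph))


def _undirected_triads(adj: sp.csr_array) -> np.ndarray:
    adj = adj.astype(np.int64)
    triangles = int((adj @ adj).multiply(adj).sum()) // 6
    degrees = np.asarray(adj.sum(axis=1)).ravel()
    triples = int((degrees * (degrees - 1) // 2).sum()) - 3 * triangles
    return np.array([triples, triangles], dtype=np.int64)


def _pagerank_csr(adj: sp.csr_array, alpha: float = PAGERANK_ALPHA,
                  tol: float = PAGERANK_TOL, max_iter: int = 1000) -> np.ndarray:
    """Power-iteration PageRank on a 0/1 adjacency (rows = out-arcs).

    Dangling nodes spread their mass uniformly; iteration stops when the
    L1 change drops below ``n * tol``.
    """
    n = adj.shape[0]
    out_deg = np.asarray(adj.sum(axis=1)).ravel().astype(float)
    dangling = out_deg == 0.0
    inv_out = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, out_deg))
    transition = (sp.diags_array(inv_out) @ adj).T.tocsr()
    x = np.full(n, 1.0 / n)
    teleport = (1.0 - alpha) / n
    for _ in range(max_iter):
        x_new = alpha * (transition @ x + x[dangling].sum() / n) + teleport
        if np.abs(x_new - x).sum() < n * tol:
            return x_new
        x = x_new
    return x  # pragma: no cover - converges long before max_iter


def pagerank_values(graph: nx.Graph, reverse: bool = False) -> np.ndarray:
    """PageRank vector (damping 0.85, tolerance 1e-10), optionally on the
    arc-reversed network.  Values sum to 1."""
    adj = _to_csr(graph)
    if reverse and graph.is_directed():
        adj = adj.T.tocsr()
    return _pagerank_csr(adj)


@dataclass(frozen=True)
class FeatureBundle:
    """All feature distributions of one network, extracted once.

    Directed networks carry in/out degree histograms, direct and reverse
    PageRank values, directed and undirected distance distributions and
    the 13-class triad counts; undirected networks carry the collapsed
    equivalents (``out_degrees``, ``pagerank_reverse`` and
    ``distances_directed`` are ``None``).
    """

    n: int
    m: int
    directed: bool
    degrees: np.ndarray               # in-degree histogram (degree histogram)
    out_degrees: np.ndarray | None
    pagerank: np.ndarray
    pagerank_reverse: np.ndarray | None
    distances_directed: DistanceDistribution | None
    distances_undirected: DistanceDistribution
    triads: np.ndarray

    @property
    def metric_names(self) -> tuple[str, ...]:
        return METRICS_DIRECTED if self.directed else METRICS_UNDIRECTED


def _degree_histogram(degrees: np.ndarray) -> np.ndarray:
    return np.bincount(degrees.astype(np.int64))


def extract_features(graph: nx.Graph,
                     rng: np.random.Generator | None = None) -> FeatureBundle:
    """Compute the full feature bundle of a network.

    The sparse adjacency is built once and shared by the PageRank,
    distance and triangle computations.
    """
    directed = graph.is_directed()
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    adj = _to_csr(graph)
    if directed:
        in_deg = np.asarray(adj.sum(axis=0)).ravel().astype(np.int64)
        out_deg = np.asarray(adj.sum(axis=1)).ravel().astype(np.int64)
        und = adj + adj.T  # weights irrelevant: BFS is unweighted
        return FeatureBundle(
            n=n, m=m, directed=True,
            degrees=_degree_histogram(in_deg),
            out_degrees=_degree_histogram(out_deg),
            pagerank=_pagerank_csr(adj),
            pagerank_reverse=_pagerank_csr(adj.T.tocsr()),
            distances_directed=_distance_from_csr(adj, directed=True, rng=rng),
            distances_undirected=_distance_from_csr(und.tocsr(), directed=False,
                                                    rng=rng),
            triads=triadic_profile(graph),
        )
    deg = np.asarray(adj.sum(axis=1)).ravel().astype(np.int64)
    return FeatureBundle(
        n=n, m=m, directed=False,
        degrees=_degree_histogram(deg),
        out_degrees=None,
        pagerank=_pagerank_csr(adj),
        pagerank_reverse=None,
        distances_directed=None,
        distances_undirected=_distance_from_csr(adj, directed=False, rng=rng),
        triads=_undirected_triads(adj),
    )


# ---------------------------------------------------------------------------
# pairwise dissimilarities
# ---------------------------------------------------------------------------

def _degree_emd(hist_a: np.ndarray, hist_b: np.ndarray) -> float:
    support = max(hist_a.size, hist_b.size)
    a = np.zeros(support)
    b = np.zeros(support)
    a[: hist_a.size] = hist_a
    b[: hist_b.size] = hist_b
    return emd_1d(a / a.sum(), b / b.sum())


def _pagerank_emd(vals_a: np.ndarray, vals_b: np.ndarray) -> float:
    lo = min(vals_a.min(), vals_b.min())
    hi = max(vals_a.max(), vals_b.max())
    if hi <= lo:
        return 0.0
    ha, _ = np.histogram(vals_a, bins=PAGERANK_BINS, range=(lo, hi))
    hb, _ = np.histogram(vals_b, bins=PAGERANK_BINS, range=(lo, hi))
    return emd_1d(ha / ha.sum(), hb / hb.sum())


def _distance_ratio(da: DistanceDistribution, db: DistanceDistribution) -> float:
    max_hops = max(da.counts.size, db.counts.size, 1)
    return ratio_dissimilarity(da.aligned(max_hops), db.aligned(max_hops))


def dissimilarities(a: FeatureBundle, b: FeatureBundle) -> dict[str, float]:
    """Per-metric raw dissimilarities between two feature bundles."""
    if a.directed != b.directed:
        raise ValueError("cannot compare directed with undirected features")
    if a.directed:
        return {
            "k_in": _degree_emd(a.degrees, b.degrees),
            "k_out": _degree_emd(a.out_degrees, b.out_degrees),
            "pr_d": _pagerank_emd(a.pagerank, b.pagerank),
            "pr_r": _pagerank_emd(a.pagerank_reverse, b.pagerank_reverse),
            "dist_d": _distance_ratio(a.distances_directed, b.distances_directed),
            "dist_u": _distance_ratio(a.distances_undirected, b.distances_undirected),
            "triads": ratio_dissimilarity(a.triads, b.triads),
        }
    return {
        "k": _degree_emd(a.degrees, b.degrees),
        "pr": _pagerank_emd(a.pagerank, b.pagerank),
        "dist_u": _distance_ratio(a.distances_undirected, b.distances_undirected),
        "triads": ratio_dissimilarity(a.triads, b.triads),
    }


# ---------------------------------------------------------------------------
# ER baseline and fitness
# ---------------------------------------------------------------------------

def er_baseline(target: FeatureBundle | nx.Graph,
                rng: np.random.Generator | int | None = None,
                replicates: int = 30) -> dict[str, float]:
    """Mean dissimilarity from the target to size-matched ER networks.

    Each replicate is a G(n, m) draw with the target's node and arc counts
    (no self-loops or duplicates, matching the growth constraints).  The
    per-metric means are the normalization baselines b_m.
    """
    feats = target if isinstance(target, FeatureBundle) else extract_features(target)
    rng = np.random.default_rng(rng)
    totals: dict[str, float] = {name: 0.0 for name in feats.metric_names}
    for _ in range(replicates):
        seed = int(rng.integers(2**31))
        er = nx.gnm_random_graph(feats.n, feats.m, seed=seed, directed=feats.directed)
        dvals = dissimilarities(feats, extract_features(er))
        for name, val in dvals.items():
            totals[name] += val
    return {name: tot / replicates for name, tot in totals.items()}


@dataclass(frozen=True)
class DissimilarityVector:
    """Raw dissimilarities, baselines, ratios and the minimax fitness.

    ``ratios[m] = raw[m] / baseline[m]``; a zero baseline yields ratio 0
    when the raw value is also 0, else infinity (``degenerate`` flags any
    such metric).  ``fitness`` is the maximum ratio.
    """

    raw: dict[str, float]
    baseline: dict[str, float]
    ratios: dict[str, float]
    fitness: float
    degenerate: tuple[str, ...] = ()

    def __repr__(self):
        parts = ", ".join(f"{k}={v:.3g}" for k, v in self.ratios.items())
        return f"DissimilarityVector(fitness={self.fitness:.4g}, {parts})"


def fitness(target: FeatureBundle | nx.Graph,
            candidate: FeatureBundle | nx.Graph,
            baselines: dict[str, float]) -> DissimilarityVector:
    """Score a candidate network against the target.

    Every applicable metric's raw dissimilarity is divided by its ER
    baseline; the fitness (to be minimized) is the largest ratio.
    """
    ft = target if isinstance(target, FeatureBundle) else extract_features(target)
    fc = candidate if isinstance(candidate, FeatureBundle) else extract_features(candidate)
    raw = dissimilarities(ft, fc)
    ratios: dict[str, float] = {}
    degenerate: list[str] = []
    for name, val in raw.items():
        base = baselines[name]
        if base == 0.0:
            ratios[name] = 0.0 if val == 0.0 else float("inf")
            if val != 0.0:
                degenerate.append(name)
        else:
            ratios[name] = val / base
    return DissimilarityVector(
        raw=raw,
        baseline=dict(baselines),
        ratios=ratios,
        fitness=max(ratios.values()),
        degenerate=tuple(degenerate),
    )
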