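"""Arc-by-arc network growth driven by a generator program.

A network of ``n`` nodes (identifiers ``1..n``) starts empty and gains one
arc per step.  At each step a random sample of currently non-existing,
non-self arcs is drawn, the generator assigns each candidate a weight, and
one arc is selected with probability proportional to its (positive) weight.
Self-links and duplicate arcs are never created.

Distances between candidate endpoints are estimated with bounded random
walks rather than exact shortest paths: linking is modelled as hop-by-hop
navigation, and walks keep the per-candidate cost constant.  All
randomness — candidate sampling, arc selection and the walks — flows from
one seedable generator per run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
from numba import njit

from .programs import GeneratorProgram, compile_program

__all__ = [
    "SamplingConfig",
    "GrowthState",
    "NetworkComplete",
    "sample_candidates",
    "selection_probabilities",
    "heuristic_distances",
    "generate_network",
    "grow",
]


class NetworkComplete(RuntimeError):
    """Raised when no legal (non-self, non-duplicate) arc remains."""


@dataclass(frozen=True)
class SamplingConfig:
    """Knobs of the growth process.

    s_r
        Candidate sampling ratio: each step scores ``|S| = s_r * n**2``
        candidate arcs (subject to ``min_sample`` and to the number of arcs
        still absent).  Small ratios keep growth cheap but add selection
        noise on small networks.
    min_sample
        Floor on the candidate sample size, protecting small networks.
    walk_count, walk_length
        Budget of the random-walk distance heuristic: per query, up to
        ``walk_count`` independent walks of at most ``walk_length`` hops.
        Unreached targets report the cap ``walk_length + 1``.
    """

    s_r: float = 0.001
    min_sample: int = 100
    walk_count: int = 5
    walk_length: int = 7

    def __post_init__(self):
        if not (0 < self.s_r <= 1):
            raise ValueError("s_r must be in (0, 1]")
        if self.min_sample < 1 or self.walk_count < 1 or self.walk_length < 1:
            raise ValueError("min_sample, walk_count, walk_length must be >= 1")

    def sample_size(self, n: int) -> int:
        return max(self.min_sample, int(round(self.s_r * n * n)))

    @property
    def distance_cap(self) -> int:
        """Sentinel hop count reported when walks never reach the target."""
        return self.walk_length + 1


class _AdjacencyStore:
    """Append-only ragged adjacency with O(1) vectorized neighbor lookup."""

    __slots__ = ("table", "counts")

    def __init__(self, n: int, cap: int = 8):
        self.table = np.zeros((n + 1, cap), dtype=np.int64)
        self.counts = np.zeros(n + 1, dtype=np.int64)

    def append(self, u: int, v: int) -> None:
        c = int(self.counts[u])
        if c == self.table.shape[1]:
            self.table = np.concatenate(
                [self.table, np.zeros_like(self.table)], axis=1)
        self.table[u, c] = v
        self.counts[u] = c + 1

    def neighbors(self, u: int) -> np.ndarray:
        return self.table[u, : self.counts[u]]


@dataclass
class GrowthState:
    """The partially built network (1-based node identifiers).

    Degree tallies and adjacency are maintained incrementally and always
    agree with the arc set.  For directed growth three adjacency views are
    kept — out-arcs, in-arcs (the arc-reversed view) and the undirected
    union — each feeding one of the walk distances.
    """

    n: int
    directed: bool = True

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 nodes")
        self.arcs: set[tuple[int, int]] = set()
        self.in_deg = np.zeros(self.n + 1, dtype=np.int64)  # total deg if undirected
        self.out_deg = np.zeros(self.n + 1, dtype=np.int64)
        self.out_adj = _AdjacencyStore(self.n)
        self.in_adj = _AdjacencyStore(self.n)
        self.und_adj = _AdjacencyStore(self.n)
        # dense existence mask for vectorized candidate filtering (small n)
        self._exists = (np.zeros((self.n + 1, self.n + 1), dtype=bool)
                        if self.n <= 2048 else None)

    # ------------------------------------------------------------------
    @property
    def max_arcs(self) -> int:
        return self.n * (self.n - 1) if self.directed else self.n * (self.n - 1) // 2

    @property
    def arc_count(self) -> int:
        return len(self.arcs)

    def _key(self, u: int, v: int) -> tuple[int, int]:
        if self.directed or u < v:
            return (u, v)
        return (v, u)

    def has_arc(self, u: int, v: int) -> bool:
        return self._key(u, v) in self.arcs

    def add_arc(self, u: int, v: int) -> None:
        if u == v:
            raise ValueError("self-links are not allowed")
        key = self._key(u, v)
        if key in self.arcs:
            raise ValueError(f"duplicate arc {key}")
        self.arcs.add(key)
        if self._exists is not None:
            self._exists[u, v] = True
            if not self.directed:
                self._exists[v, u] = True
        if self.directed:
            self.out_deg[u] += 1
            self.in_deg[v] += 1
            self.out_adj.append(u, v)
            self.in_adj.append(v, u)
        else:
            self.in_deg[u] += 1
            self.in_deg[v] += 1
        self.und_adj.append(u, v)
        self.und_adj.append(v, u)

    def to_graph(self) -> nx.DiGraph | nx.Graph:
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(range(1, self.n + 1))
        g.add_edges_from(self.arcs)
        return g


def selection_probabilities(weights: Iterable[float]) -> np.ndarray:
    """Turn candidate weights into arc-selection probabilities.

    Probabilities are proportional to the weight for strictly positive
    weights; non-positive weights get probability zero.  When no weight is
    positive all weights are treated as 1, i.e. the choice is uniform.
    """
    w = np.asarray(weights if isinstance(weights, np.ndarray) else list(weights),
                   dtype=float)
    if w.size == 0:
        raise ValueError("empty weight list")
    positive = w > 0
    if not positive.any():
        return np.full(w.size, 1.0 / w.size)
    p = w * positive
    total = p.sum()
    if not np.isfinite(total):  # rescale first for huge weights
        p = p / p.max()
        total = p.sum()
    return p / total


def sample_candidates(state: GrowthState, cfg: SamplingConfig,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw distinct candidate arcs absent from the network (no self-links).

    Returns parallel arrays of origins and targets.  The sample size is
    ``cfg.sample_size(n)`` capped at the number of remaining legal arcs;
    a complete network raises :class:`NetworkComplete`.
    """
    n = state.n
    remaining = state.max_arcs - state.arc_count
    if remaining <= 0:
        raise NetworkComplete(f"all {state.max_arcs} legal arcs exist")
    size = min(cfg.sample_size(n), remaining)

    if remaining <= 2 * size or remaining <= 64:
        pairs = _remaining_arcs(state)
        if len(pairs) > size:
            idx = rng.choice(len(pairs), size=size, replace=False)
            pairs = [pairs[int(t)] for t in idx]
        us = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
        vs = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
        return us, vs

    if state._exists is not None:
        return _sample_rejection_dense(state, size, rng)

    chosen: set[tuple[int, int]] = set()
    us_list: list[int] = []
    vs_list: list[int] = []
    while len(us_list) < size:
        batch = max(16, 2 * (size - len(us_list)))
        bu = rng.integers(1, n + 1, size=batch)
        bv = rng.integers(1, n + 1, size=batch)
        for u, v in zip(bu.tolist(), bv.tolist()):
            if u == v:
                continue
            key = (u, v) if (state.directed or u < v) else (v, u)
            if key in chosen or key in state.arcs:
                continue
            chosen.add(key)
            us_list.append(u)
            vs_list.append(v)
            if len(us_list) == size:
                break
    return np.array(us_list, dtype=np.int64), np.array(vs_list, dtype=np.int64)


@njit(cache=True)
def _sample_kernel(exists, n, size, directed, rand):  # pragma: no cover
    out_u = np.empty(size, np.int64)
    out_v = np.empty(size, np.int64)
    found = 0
    r = 0
    limit = rand.size - 1
    while found < size and r < limit:
        u = 1 + int(rand[r] * n)
        v = 1 + int(rand[r + 1] * n)
        r += 2
        if u == v:
            continue
        if not directed and u > v:
            u, v = v, u
        if exists[u, v]:
            continue
        duplicate = False
        for t in range(found):
            if out_u[t] == u and out_v[t] == v:
                duplicate = True
                break
        if duplicate:
            continue
        out_u[found] = u
        out_v[found] = v
        found += 1
    return out_u, out_v, found


def _sample_rejection_dense(state: GrowthState, size: int,
                            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rejection sampling against the dense existence mask."""
    n = state.n
    us, vs, found = _sample_kernel(state._exists, n, size, state.directed,
                                   rng.random(6 * size + 32))
    while found < size:  # randomness budget exhausted (rare, dense endgame)
        more_u, more_v, extra = _sample_kernel(
            state._exists, n, size - found, state.directed,
            rng.random(12 * (size - found) + 64))
        for t in range(extra):
            u, v = int(more_u[t]), int(more_v[t])
            if not ((us[:found] == u) & (vs[:found] == v)).any():
                us[found] = u
                vs[found] = v
                found += 1
    if not state.directed:
        flip = rng.random(size) < 0.5  # random orientation of unordered pairs
        us, vs = np.where(flip, vs, us).astype(np.int64), \
            np.where(flip, us, vs).astype(np.int64)
    return us, vs


def _remaining_arcs(state: GrowthState) -> list[tuple[int, int]]:
    n = state.n
    out = []
    if state.directed:
        for u in range(1, n + 1):
            for v in range(1, n + 1):
                if u != v and (u, v) not in state.arcs:
                    out.append((u, v))
    else:
        for u in range(1, n + 1):
            for v in range(u + 1, n + 1):
                if (u, v) not in state.arcs:
                    out.append((u, v))
    return out


@njit(cache=True)
def _walk_kernel(table, counts, us, vs, walks, length, rand):  # pragma: no cover
    pairs = us.size
    out = np.empty(pairs, np.int64)
    r = 0
    for p in range(pairs):
        best = length + 1
        for _ in range(walks):
            cur = us[p]
            for hop in range(1, best):
                c = counts[cur]
                if c == 0:
                    break
                cur = table[cur, int(rand[r] * c)]
                r += 1
                if cur == vs[p]:
                    best = hop
                    break
            if best == 1:
                break
        out[p] = best
    return out


def _batch_walk_distances(adj: _AdjacencyStore, us: np.ndarray, vs: np.ndarray,
                          walks: int, length: int,
                          rng: np.random.Generator) -> np.ndarray:
    """First-hit hop counts for all candidate pairs on one adjacency view.

    Runs ``walks`` independent bounded walks per pair; a pair's estimate
    is the minimum hop at which any of its walks first reached the
    target, or ``length + 1`` if none did.  Walks that cannot improve on
    a pair's current best hit are cut short, which changes only how much
    of the pre-drawn randomness is consumed, never the estimate.
    """
    rand = rng.random(us.size * walks * length)
    return _walk_kernel(adj.table, adj.counts, us, vs, walks, length, rand)


def heuristic_distances(state: GrowthState, origin: int, target: int,
                        cfg: SamplingConfig,
                        rng: np.random.Generator) -> tuple[int, ...]:
    """Random-walk estimates of the distance(s) from ``origin`` to ``target``.

    Directed state: returns ``(d, d_D, d_R)`` — over the undirected view,
    following arc direction, and on the arc-reversed view.  Undirected
    state: returns ``(d,)``.  Estimates never undershoot the true shortest
    path; failures to reach report the cap ``walk_length + 1``.
    """
    if origin == target:
        raise ValueError("origin and target must differ")
    us = np.array([origin], dtype=np.int64)
    vs = np.array([target], dtype=np.int64)
    W, L = cfg.walk_count, cfg.walk_length
    d = int(_batch_walk_distances(state.und_adj, us, vs, W, L, rng)[0])
    if not state.directed:
        return (d,)
    d_d = int(_batch_walk_distances(state.out_adj, us, vs, W, L, rng)[0])
    d_r = int(_batch_walk_distances(state.in_adj, us, vs, W, L, rng)[0])
    return (d, d_d, d_r)


def _build_context(state: GrowthState, us: np.ndarray, vs: np.ndarray,
                   distance_vars: frozenset[str], cfg: SamplingConfig,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Variable bundle for a candidate batch, reflecting the pre-step state."""
    ctx = {
        "i": us.astype(float),
        "j": vs.astype(float),
        "k": state.in_deg[us].astype(float),
        "k'": state.in_deg[vs].astype(float),
    }
    if distance_vars:
        W, L = cfg.walk_count, cfg.walk_length
        views = (("d", state.und_adj), ("d_D", state.out_adj),
                 ("d_R", state.in_adj))
        for name, adj in views:
            if name in distance_vars:
                ctx[name] = _batch_walk_distances(adj, us, vs, W, L,
                                                  rng).astype(float)
    return ctx


def _evaluate_batch(program: GeneratorProgram, ctx: dict[str, np.ndarray],
                    size: int) -> np.ndarray:
    """Evaluate a program over a candidate batch; constant-only programs
    broadcast to the batch size."""
    w = np.atleast_1d(np.asarray(program.evaluate(ctx), dtype=float))
    if w.size != size:
        w = np.broadcast_to(w, (size,))
    return w


def _pick(rng: np.random.Generator, p: np.ndarray) -> int:
    cdf = np.cumsum(p)
    idx = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
    return min(idx, p.size - 1)


# ---------------------------------------------------------------------------
# compiled growth engine
# ---------------------------------------------------------------------------
# The whole growth loop — candidate sampling, walk distances, program
# evaluation, selection — runs inside one numba kernel for networks up to
# _KERNEL_MAX_N nodes.  The pure-python loop below it implements the same
# process and serves both as the fallback for larger networks and as the
# reference implementation the equivalence test compares against.

_KERNEL_MAX_N = 1024


@njit(cache=True)
def _eval_stack(codes, consts, ctx, stack, size):  # pragma: no cover
    """Postorder stack evaluation with protected semantics (see programs)."""
    sp = 0
    cp = 0
    for t in range(codes.size):
        op = codes[t]
        if op < 7:  # variable push
            for s in range(size):
                stack[sp, s] = ctx[op, s]
            sp += 1
        elif op == 10:  # constant push
            value = consts[cp]
            cp += 1
            for s in range(size):
                stack[sp, s] = value
            sp += 1
        elif op == 20:  # +
            sp -= 1
            for s in range(size):
                x = stack[sp - 1, s] + stack[sp, s]
                stack[sp - 1, s] = min(max(x, -1e300), 1e300)
        elif op == 21:  # -
            sp -= 1
            for s in range(size):
                x = stack[sp - 1, s] - stack[sp, s]
                stack[sp - 1, s] = min(max(x, -1e300), 1e300)
        elif op == 22:  # *
            sp -= 1
            for s in range(size):
                x = stack[sp - 1, s] * stack[sp, s]
                stack[sp - 1, s] = min(max(x, -1e300), 1e300)
        elif op == 23:  # protected /
            sp -= 1
            for s in range(size):
                b = stack[sp, s]
                if b == 0.0:
                    stack[sp - 1, s] = 0.0
                else:
                    x = stack[sp - 1, s] / b
                    stack[sp - 1, s] = min(max(x, -1e300), 1e300)
        elif op == 24:  # protected pow: |base| ** exponent
            sp -= 1
            for s in range(size):
                x = abs(stack[sp - 1, s]) ** stack[sp, s]
                stack[sp - 1, s] = min(max(x, -1e300), 1e300)
        elif op == 25:  # min
            sp -= 1
            for s in range(size):
                stack[sp - 1, s] = min(stack[sp - 1, s], stack[sp, s])
        elif op == 26:  # max
            sp -= 1
            for s in range(size):
                stack[sp - 1, s] = max(stack[sp - 1, s], stack[sp, s])
        elif op == 27:  # exp (argument capped)
            for s in range(size):
                a = stack[sp - 1, s]
                if a > 690.0:
                    a = 690.0
                stack[sp - 1, s] = np.exp(a)
        elif op == 28:  # protected log
            for s in range(size):
                a = stack[sp - 1, s]
                stack[sp - 1, s] = np.log(a) if a > 0.0 else 0.0
        elif op == 29:  # abs
            for s in range(size):
                stack[sp - 1, s] = abs(stack[sp - 1, s])
        elif op == 30 or op == 31 or op == 32:  # gt / lt / eq branches
            sp -= 3
            for s in range(size):
                a = stack[sp - 1, s]
                b = stack[sp, s]
                if op == 30:
                    hold = a > b
                elif op == 31:
                    hold = a < b
                else:
                    hold = a == b
                stack[sp - 1, s] = stack[sp + 1, s] if hold else stack[sp + 2, s]
        elif op == 33:  # eq0
            sp -= 2
            for s in range(size):
                x = stack[sp - 1, s]
                stack[sp - 1, s] = stack[sp, s] if x == 0.0 else stack[sp + 1, s]
        else:  # psi (op == 34)
            sp -= 2
            for s in range(size):
                g = np.trunc(stack[sp - 1, s])
                if g < 1.0:
                    g = 1.0
                same = (ctx[0, s] % g) == (ctx[1, s] % g)
                stack[sp - 1, s] = stack[sp, s] if same else stack[sp + 1, s]
    return sp


@njit(cache=True)
def _kernel_walks(table, counts, reach, su, sv, size, walks, length,
                  ctx, row):  # pragma: no cover
    for s in range(size):
        best = length + 1
        if reach[sv[s]] == 0:  # no arc enters the target on this view
            ctx[row, s] = best
            continue
        for _ in range(walks):
            cur = su[s]
            for hop in range(1, best):
                c = counts[cur]
                if c == 0:
                    break
                cur = table[cur, int(np.random.random() * c)]
                if cur == sv[s]:
                    best = hop
                    break
            if best == 1:
                break
        ctx[row, s] = best


@njit(cache=True)
def _kernel_probs(w, p, size):  # pragma: no cover
    """Selection law: P proportional to positive weights, uniform fallback."""
    mx = 0.0
    for s in range(size):
        if w[s] > mx:
            mx = w[s]
    if mx <= 0.0:
        for s in range(size):
            p[s] = 1.0 / size
        return
    total = 0.0
    for s in range(size):
        x = w[s] / mx if w[s] > 0.0 else 0.0
        p[s] = x
        total += x
    for s in range(size):
        p[s] /= total


@njit(cache=True)
def _grow_kernel(n, m, directed, codes_a, consts_a, codes_b, consts_b,
                 has_shadow, need_d, need_dd, need_dr, cfg_size,
                 walks, length, seed):  # pragma: no cover
    np.random.seed(seed)
    max_arcs = n * (n - 1) if directed else n * (n - 1) // 2
    exists = np.zeros((n + 1, n + 1), np.bool_)
    in_deg = np.zeros(n + 1, np.int64)
    out_deg = np.zeros(n + 1, np.int64)
    out_tab = np.zeros((n + 1, n), np.int64)
    out_cnt = np.zeros(n + 1, np.int64)
    in_tab = np.zeros((n + 1, n), np.int64)
    in_cnt = np.zeros(n + 1, np.int64)
    und_tab = np.zeros((n + 1, 2 * n), np.int64)
    und_cnt = np.zeros(n + 1, np.int64)
    arcs = np.empty((m, 2), np.int64)
    su = np.empty(cfg_size, np.int64)
    sv = np.empty(cfg_size, np.int64)
    ctx = np.zeros((7, cfg_size), np.float64)
    stack_a = np.empty((codes_a.size + 1, cfg_size), np.float64)
    stack_b = np.empty((codes_b.size + 1, cfg_size), np.float64)
    pa = np.empty(cfg_size, np.float64)
    pb = np.empty(cfg_size, np.float64)
    diff_sum = 0.0
    diff_cnt = 0

    for step in range(m):
        remaining = max_arcs - step
        size = cfg_size if cfg_size < remaining else remaining

        # ---- candidate sample: distinct absent non-self arcs -------------
        if remaining <= 2 * size or remaining <= 64:
            pool_u = np.empty(remaining, np.int64)
            pool_v = np.empty(remaining, np.int64)
            cnt = 0
            for u in range(1, n + 1):
                lo = 1 if directed else u + 1
                for v in range(lo, n + 1):
                    if u != v and not exists[u, v]:
                        pool_u[cnt] = u
                        pool_v[cnt] = v
                        cnt += 1
            for t in range(size):  # partial Fisher-Yates draw
                r = t + int(np.random.random() * (cnt - t))
                pool_u[t], pool_u[r] = pool_u[r], pool_u[t]
                pool_v[t], pool_v[r] = pool_v[r], pool_v[t]
                su[t] = pool_u[t]
                sv[t] = pool_v[t]
            if not directed:  # randomize orientation of unordered pairs
                for t in range(size):
                    if np.random.random() < 0.5:
                        su[t], sv[t] = sv[t], su[t]
        else:
            found = 0
            while found < size:
                u = 1 + int(np.random.random() * n)
                v = 1 + int(np.random.random() * n)
                if u == v:
                    continue
                if directed or u < v:
                    a, b = u, v
                else:
                    a, b = v, u
                if exists[a, b]:
                    continue
                duplicate = False
                for t in range(found):
                    x, y = su[t], sv[t]
                    if not directed and x > y:
                        x, y = y, x
                    if x == a and y == b:
                        duplicate = True
                        break
                if duplicate:
                    continue
                su[found] = u
                sv[found] = v
                found += 1

        # ---- per-candidate context (pre-step state) ----------------------
        for s in range(size):
            ctx[0, s] = su[s]
            ctx[1, s] = sv[s]
            ctx[2, s] = in_deg[su[s]]
            ctx[3, s] = in_deg[sv[s]]
        if need_d:
            _kernel_walks(und_tab, und_cnt, und_cnt, su, sv, size, walks,
                          length, ctx, 4)
        if need_dd:
            _kernel_walks(out_tab, out_cnt, in_cnt, su, sv, size, walks,
                          length, ctx, 5)
        if need_dr:
            _kernel_walks(in_tab, in_cnt, out_cnt, su, sv, size, walks,
                          length, ctx, 6)

        # ---- weights, probabilities, selection ---------------------------
        _eval_stack(codes_a, consts_a, ctx, stack_a, size)
        _kernel_probs(stack_a[0], pa, size)
        if has_shadow:
            _eval_stack(codes_b, consts_b, ctx, stack_b, size)
            _kernel_probs(stack_b[0], pb, size)
            for s in range(size):
                diff_sum += abs(pa[s] - pb[s])
            diff_cnt += size
        r = np.random.random()
        acc = 0.0
        idx = size - 1
        for s in range(size):
            acc += pa[s]
            if r < acc:
                idx = s
                break
        u = su[idx]
        v = sv[idx]

        # ---- commit the arc ---------------------------------------------
        arcs[step, 0] = u
        arcs[step, 1] = v
        exists[u, v] = True
        if directed:
            out_deg[u] += 1
            in_deg[v] += 1
            out_tab[u, out_cnt[u]] = v
            out_cnt[u] += 1
            in_tab[v, in_cnt[v]] = u
            in_cnt[v] += 1
        else:
            exists[v, u] = True
            in_deg[u] += 1
            in_deg[v] += 1
        und_tab[u, und_cnt[u]] = v
        und_cnt[u] += 1
        und_tab[v, und_cnt[v]] = u
        und_cnt[v] += 1
    return arcs, diff_sum, diff_cnt


def _grow_python(program: GeneratorProgram, n: int, m: int,
                 cfg: SamplingConfig, rng: np.random.Generator,
                 shadow: GeneratorProgram | None) -> tuple[GrowthState, float]:
    """Reference step-by-step growth loop (also used for n > _KERNEL_MAX_N)."""
    state = GrowthState(n, directed=program.directed)
    needed = program.distance_variables
    if shadow is not None:
        needed = needed | shadow.distance_variables
    diff_sum = 0.0
    diff_count = 0
    for _ in range(m):
        us, vs = sample_candidates(state, cfg, rng)
        ctx = _build_context(state, us, vs, needed, cfg, rng)
        w = _evaluate_batch(program, ctx, us.size)
        p = selection_probabilities(w)
        if shadow is not None:
            p2 = selection_probabilities(_evaluate_batch(shadow, ctx, us.size))
            diff_sum += float(np.abs(p - p2).sum())
            diff_count += p.size
        idx = _pick(rng, p)
        state.add_arc(int(us[idx]), int(vs[idx]))
    mean_diff = diff_sum / diff_count if diff_count else 0.0
    return state, mean_diff


def grow(program: GeneratorProgram, n: int, m: int,
         cfg: SamplingConfig | None = None,
         rng: np.random.Generator | int | None = None,
         shadow: GeneratorProgram | None = None,
         compiled: bool | None = None) -> tuple[GrowthState, float]:
    """Run the growth process; optionally shadow it with a second program.

    The shadow program scores every candidate sample alongside the driver;
    the returned float is the mean absolute difference between the two
    probability assignments over all candidates of all steps (0.0 when no
    shadow is given) — the one-directional generator dissimilarity.

    Networks up to 1024 nodes run in the compiled kernel; pass
    ``compiled=False`` to force the reference python loop (the two
    implement the same process with different random streams).
    """
    cfg = cfg or SamplingConfig()
    rng = np.random.default_rng(rng)
    directed = program.directed
    max_arcs = n * (n - 1) if directed else n * (n - 1) // 2
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if m > max_arcs:
        raise ValueError(f"m={m} exceeds the {max_arcs} legal arcs for n={n}")
    if shadow is not None and shadow.directed != directed:
        raise ValueError("shadow program must share the driver's mode")
    if compiled is None:
        compiled = n <= _KERNEL_MAX_N
    if not compiled:
        return _grow_python(program, n, m, cfg, rng, shadow)

    codes_a, consts_a = compile_program(program)
    if shadow is not None:
        codes_b, consts_b = compile_program(shadow)
    else:
        codes_b, consts_b = codes_a[:1], consts_a[:1]
    needed = program.distance_variables
    if shadow is not None:
        needed = needed | shadow.distance_variables
    size = min(cfg.sample_size(n), max_arcs)
    arcs, diff_sum, diff_cnt = _grow_kernel(
        n, m, directed, codes_a, consts_a, codes_b, consts_b,
        shadow is not None, "d" in needed, "d_D" in needed, "d_R" in needed,
        size, cfg.walk_count, cfg.walk_length,
        int(rng.integers(2**31)),
    )
    state = GrowthState(n, directed=directed)
    for t in range(arcs.shape[0]):
        state.add_arc(int(arcs[t, 0]), int(arcs[t, 1]))
    mean_diff = diff_sum / diff_cnt if diff_cnt else 0.0
    return state, mean_diff


def generate_network(program: GeneratorProgram, n: int, m: int,
                     cfg: SamplingConfig | None = None,
                     rng: np.random.Generator | int | None = None) -> nx.Graph:
    """Grow a network of ``n`` nodes and exactly ``m`` arcs with ``program``.

    Returns a :class:`networkx.DiGraph` (directed mode) or ``Graph`` with
    nodes ``1..n``; a seeded ``rng`` makes the result reproducible.
    """
    state, _ = grow(program, n, m, cfg=cfg, rng=rng)
    return state.to_graph()
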