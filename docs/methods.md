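# Methods

## The model: network growth rules as programs

`netevo` treats a network-growth rule ("generator") as a small program —
an expression tree over arithmetic operators (`+ - * / pow exp log abs
min max`), branch-selecting comparisons (`gt lt eq eq0`) and a group
affinity function `ψ` — that assigns a weight `w(i, j)` to a candidate
arc from node *i* to node *j*.  Growth is a sequence of discrete steps on
a fixed node set `1..n`: at each step a random sample *S* of
currently-absent, non-self arcs is scored by the program and one arc is
selected with probability

    P_ij = π(w_ij) · w_ij / Σ_S π(w) · w,     π(w) = 1 if w > 0 else 0,

falling back to the uniform distribution when no weight is positive
(this fallback is what bootstraps degree-based rules on an empty
network).  Duplicate arcs and self-links are never created.

Programs read per-candidate variables: the endpoint identifiers *i*, *j*
(1-based, usable to encode a-priori node heterogeneity), degree
descriptors *k*, *k′* (in directed mode the in-degrees of origin and
target, so the program `k'` is in-degree preferential attachment; in
undirected mode the endpoint total degrees), and random-walk distance
estimates *d*, *d_D*, *d_R* (undirected, arc-following, arc-reversed).
Undirected programs may not reference *d_D*/*d_R*.

Evaluation is *protected*: division by zero and logs of non-positive
values return 0, `pow` uses the absolute base, `exp` is capped, and
every intermediate magnitude is clamped to 1e300 — arbitrary mutated
programs therefore always return finite weights, and evaluation is pure.

### Why walks, not shortest paths

Distances are estimated by up to *W* = 5 independent random walks of at
most *L* = 7 hops on the relevant adjacency view; the estimate is the
first hop at which any walk reaches the target, else the cap *L* + 1.
Estimates therefore never undershoot the true shortest path and improve
with budget.  Besides being O(1) per query, this matches the modelling
stance that link formation is hop-by-hop navigation rather than
computation of an omniscient distance.  (*W*, *L* are configurable; the
defaults are conventional and were fixed before any experiments.)

## Dissimilarity and fitness

A candidate network is compared with the target on a feature panel:
in-/out-degree histograms, PageRank on the actual and arc-reversed
network (damping 0.85, tolerance 1e-10), directed and undirected
shortest-path distance distributions with an explicit unreachable
bucket (exhaustive BFS up to 1000 nodes, 1000 sampled sources beyond),
and the triadic profile (counts of the 13 connected directed triad
classes; open triples vs triangles when undirected).  Undirected
networks use the collapsed panel (degree, PageRank, distances, triads).

Degree and PageRank distributions are compared with the 1-D Earth
mover's distance (adjacent bins at unit ground distance, i.e. the summed
absolute CDF difference); degree histograms share an integer support up
to the larger maximum degree, PageRank values are binned into 50
equal-width bins spanning both value ranges.  Distance distributions and
triadic profiles use a ratio dissimilarity on raw counts: per-bin excess
ratios `max/min − 1` averaged with weights proportional to the bin's
combined mass, after adding a pseudo-count equal to the mean bin
occupancy (at least 1).  The occupancy-scaled smoothing and mass
weighting were chosen because an unweighted per-bin mean is dominated by
near-empty frontier and unreachable bins, whose count ratios are pure
sampling noise; measured on same-law network pairs the unweighted form
produced occasional thousand-fold spikes, the weighted form does not.

Each raw dissimilarity `D_m` is divided by the mean dissimilarity `b_m`
between the target and 30 size-matched Erdős–Rényi G(n, m) networks.
The fitness of a candidate is `max_m D_m / b_m`: 0 is a perfect match, 1
means no better than a random network, and the max forces the search to
improve its worst feature.  A known property of this minimax statistic:
for a same-law candidate every individual ratio averages ≈ 1, but the
maximum of several noisy ratios averages above 1 (≈ 1.5–1.7 at the
study sizes with this panel — the acceptance script's
`er_candidate_mean_fitness` measures it); fitness values are therefore
comparable between candidates, not calibrated so that "same law" sits
exactly at 1.

## The search

The evolutionary state is two programs: `w_o`, the best fitness seen,
and `w_s`, the shortest program whose fitness is within the anti-bloat
tolerance (10 %) of `w_o`'s.  Initially a random program (grow-style,
depth ≤ 5, terminal probability 0.4, terminals 60 % variables) fills
both roles.  Each generation picks a parent uniformly from
`{w_o, w_s}`, mutates it by replacing a uniformly chosen subtree with a
subtree extracted from a fresh random tree (children above 200 nodes are
re-drawn), grows **one** synthetic network at the target's n and m,
scores it, and updates the incumbents; ties keep the incumbent.  All
evaluated programs are archived so `w_s` can be re-derived whenever
`w_o` improves and the tolerance bound tightens.  The search stops after
1000 generations (configurable) without any change to either incumbent,
and returns `w_s`.  A single seed drives the entire trajectory —
baselines, initial program, mutations, growth — so runs replay exactly.

### Candidate sample size

`|S| = max(min_sample, s_r · n²)` with defaults `s_r = 0.001`,
`min_sample = 100`.  The sample size controls how sharply a program's
preference is expressed: with |S| ≈ 25 at n = 100 the selection is so
noisy that the true generator of a preferential-attachment target scored
the same fitness (≈ 0.38) as degenerate identifier-hub programs, and
searches converged on overfit expressions; at |S| = 100 the true
generator separates cleanly (≈ 0.14 vs ≈ 0.22).  The floor of 100 was
fixed from that landscape measurement before the recovery experiments
were run, and matches the qualitative requirement that the sample be
large enough for the smallest study networks.

## Generator similarity and recovery classification

Two programs are compared behaviorally: grow a network with *w* while
*w′* shadows it, scoring the identical candidate samples at every step;
average the absolute difference between the two probability vectors over
all candidates and steps (`d_ww′`), repeat with roles swapped, and
average the two directions.  Identical or positively rescaled programs
score exactly 0 because the probabilities coincide; the per-candidate
absolute difference and the 3-replicate default are package choices.

A found program "recovers" a canonical generator when its behavioral
distance to it is at most one quarter of the measured distance between
the two canonical laws (uniform vs preferential attachment) at the
experiment's n and m.  This calibration replaces a self-noise percentile
because the shadowed-sample estimator gives *exactly* zero for
equivalent programs — there is no self-noise floor to calibrate against
(a sorted-probability independent-realization floor is available as the
`self_noise` diagnostic).  "Exact, no bloat" means the found tree is the
canonical tree; any single positive constant counts as the uniform law.

## Synthetic study conditions

Targets are grown by the package itself from four canonical generators:
`1.0` (uniform/ER), `k'` (preferential attachment), `(/ 1 i)`
(hyperbolic identifier propensities) and `(psi 4 10 1)` (four affinity
groups), at the standard sizes n = 100..500 with m = 10 n.  These
targets share the growth machinery's constraints (fixed node set, no
self/duplicate arcs), so recovery experiments test the search, not
format conversions.  What passing does **not** show: real networks are
not stationary-rule growth processes with 1-based identifier
heterogeneity, and features beyond the panel (assortativity, community
structure, clustering spectra) are not scored, so a recovered program
reproduces the panel, not every property of a real system.

The replication experiments run 10 searches per canonical law at
n = 100, m = 1000 with the stall limit reduced to 200; one search takes
under a minute on one CPU (lineages that adopt walk-distance variables
are the slow ones), so the batch finishes in under a quarter of an
hour.  The full-scale protocol (30 networks × 5 sizes per law, stall
limit 1000) uses the same code path via
`netevo.experiments.recovery_experiment(kind, runs, n, m, stall_limit)`.

## Numerical choices and degenerate inputs

* Weight vectors with non-finite sums are rescaled by their maximum
  before normalization; all-non-positive vectors become uniform.
* A metric with a zero ER baseline gets ratio 0 if the raw dissimilarity
  is also 0, else infinity, and is flagged (`DissimilarityVector.degenerate`).
* `w_s` ties break toward shorter length, then better fitness, then
  earlier discovery; fitness ties never replace `w_o` (stalls stay honest).
* `ψ(g, a, b)` truncates g to an integer and treats g ≤ 1 as a single
  group; its group-membership relation is an equivalence relation.
* Network files reject self-links, duplicate arcs and malformed lines
  with line numbers; arbitrary node labels map to sequential identifiers
  in order of first appearance (integer labels already forming 1..n are
  kept, and a `# nodes N` header preserves isolated nodes).

## Known limitations

* No crossover/recombination and no population: the two-incumbent
  mutation-only loop is cheap but can linger in local minima; reseeding
  is the intended remedy.
* The fitness is evaluated on a single synthetic network per candidate
  (configurable), so incumbents ratchet on evaluation luck; the
  behavioral classifier, not the fitness value, decides recovery.
* Distance variables make growth several times more expensive than
  degree/identifier variables because of the per-candidate walks.
* The minimax fitness scale inflation (above) means "fitness ≈ 1" is a
  per-metric, not a whole-fitness, statement for same-law candidates.
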