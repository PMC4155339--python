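"""Canned study-scale experiments: canonical-generator recovery and
fitness-normalization checks.

These drive the whole pipeline end to end — grow seeded targets from a
canonical generator, run the evolutionary search against each, and judge
every found program with the behavioral recovery classifier — and are
what the acceptance script and the replication tests execute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixtures import canonical_program
from .growth import SamplingConfig, generate_network
from .metrics import er_baseline, extract_features, fitness
from .search import (GeneratorSearch, SearchConfig, calibrate_threshold,
                     classify_recovery)

__all__ = ["RecoveryRun", "RecoveryExperiment", "recovery_experiment",
           "normalization_experiment"]

_CONTRAST = {"PA": "ER", "ER": "PA", "hyperbolic": "ER", "affinity": "ER"}


@dataclass(frozen=True)
class RecoveryRun:
    """One search against one seeded target."""

    target_seed: int
    search_seed: int
    program: str
    length: int
    fitness: float
    distance: float
    correct: bool
    exact: bool
    generations: int


@dataclass(frozen=True)
class RecoveryExperiment:
    """Outcome of a batch of recovery searches for one canonical law."""

    kind: str
    n: int
    m: int
    stall_limit: int
    threshold: float
    runs: tuple[RecoveryRun, ...] = field(default_factory=tuple)
    #: full GeneratorSearchResults objects (only when keep_results=True)
    results: tuple = field(default_factory=tuple, compare=False, repr=False)

    @property
    def correct_rate(self) -> float:
        """Percentage of runs whose program is behaviorally the canonical law."""
        return 100.0 * sum(r.correct for r in self.runs) / len(self.runs)

    @property
    def exact_rate(self) -> float:
        """Percentage of runs that found the canonical program with no bloat."""
        return 100.0 * sum(r.exact for r in self.runs) / len(self.runs)


def recovery_experiment(kind: str, runs: int = 10, n: int = 100, m: int = 1000,
                        stall_limit: int = 200,
                        seed: int | np.random.Generator | None = None,
                        cfg: SamplingConfig | None = None,
                        log: bool = False,
                        keep_results: bool = False) -> RecoveryExperiment:
    """Rediscover a canonical generator from networks it grew.

    For each run a fresh target is grown from the canonical ``kind``
    generator, an evolutionary search (with the given ``stall_limit``) is
    fitted to it, and the found program is classified against the
    canonical one with the behaviorally calibrated threshold.
    """
    rng = np.random.default_rng(seed)
    cfg = cfg or SamplingConfig()
    canonical = canonical_program(kind)
    contrast = canonical_program(_CONTRAST[kind])
    threshold = calibrate_threshold(canonical, contrast, n, m, cfg=cfg, rng=rng)
    search_cfg = SearchConfig(stall_limit=stall_limit, sampling=cfg)
    records = []
    kept = []
    for _ in range(runs):
        target_seed = int(rng.integers(2**31))
        search_seed = int(rng.integers(2**31))
        target = generate_network(canonical, n, m, cfg=cfg, rng=target_seed)
        result = GeneratorSearch(target, config=search_cfg).fit(seed=search_seed)
        verdict = classify_recovery(result.program, canonical, threshold,
                                    n, m, cfg=cfg, rng=rng)
        records.append(RecoveryRun(
            target_seed=target_seed, search_seed=search_seed,
            program=result.program.format(), length=len(result.program),
            fitness=result.fitness, distance=verdict.distance,
            correct=verdict.correct, exact=verdict.exact,
            generations=result.generations,
        ))
        if keep_results:
            kept.append(result)
        if log:
            r = records[-1]
            print(f"  [{kind}] seed {search_seed}: {r.program!r} "
                  f"fit={r.fitness:.3f} d={r.distance:.4f} "
                  f"correct={r.correct} exact={r.exact} gens={r.generations}",
                  flush=True)
    return RecoveryExperiment(kind=kind, n=n, m=m, stall_limit=stall_limit,
                              threshold=threshold, runs=tuple(records),
                              results=tuple(kept))


def normalization_experiment(n: int = 100, m: int = 1000, candidates: int = 30,
                             seed: int | np.random.Generator | None = None,
                             cfg: SamplingConfig | None = None) -> dict:
    """Fitness scale checks on an ER target.

    Grows an ER target, then scores (a) an exact copy of the target —
    which must reach fitness 0 — and (b) ``candidates`` fresh ER
    networks, whose mean fitness measures where same-law candidates sit
    on the ER-normalized minimax scale.
    """
    rng = np.random.default_rng(seed)
    cfg = cfg or SamplingConfig()
    program = canonical_program("ER")
    target = generate_network(program, n, m, cfg=cfg, rng=rng)
    feats = extract_features(target)
    baselines = er_baseline(feats, rng=rng)
    copy_fitness = fitness(feats, feats, baselines).fitness
    values = [fitness(feats, generate_network(program, n, m, cfg=cfg, rng=rng),
                      baselines).fitness
              for _ in range(candidates)]
    return {
        "copy_fitness": copy_fitness,
        "er_candidate_mean_fitness": float(np.mean(values)),
        "er_candidate_fitness_values": values,
    }
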