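"""Seeded synthetic study networks grown from canonical generators.

Four generator families cover the structural regimes the search is tested
on: uniform random attachment (ER), in-degree preferential attachment
(PA), hyperbolically distributed node propensities keyed on the
sequential identifier, and modular affinity groups.  The standard study
sizes pair ``n`` vertices with ``10 n`` arcs, from 100/1000 up to
500/5000.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .growth import SamplingConfig, generate_network
from .io import write_network, write_program
from .programs import GeneratorProgram, parse

__all__ = ["CANONICAL_PROGRAMS", "STANDARD_SIZES", "canonical_program", "make_fixture"]

#: canonical generator expressions by fixture kind
CANONICAL_PROGRAMS: dict[str, str] = {
    "ER": "1.0",            # uniform attachment: any positive constant
    "PA": "k'",             # preferential attachment to the target's degree
    "hyperbolic": "(/ 1 i)",  # propensity decays hyperbolically with the identifier
    "affinity": "(psi 4 10 1)",  # 4 groups, 10x weight within a group
}

#: the five standard study sizes (vertices, arcs)
STANDARD_SIZES: tuple[tuple[int, int], ...] = (
    (100, 1000), (200, 2000), (300, 3000), (400, 4000), (500, 5000),
)


def canonical_program(kind: str, directed: bool = True) -> GeneratorProgram:
    """The canonical generator for a fixture kind (``ER``, ``PA``,
    ``hyperbolic`` or ``affinity``)."""
    try:
        text = CANONICAL_PROGRAMS[kind]
    except KeyError:
        raise ValueError(
            f"unknown fixture kind {kind!r}; choose from {sorted(CANONICAL_PROGRAMS)}"
        ) from None
    return parse(text, directed=directed)


def make_fixture(kind: str, n: int, m: int, seed: int,
                 outdir: str | Path | None = None,
                 directed: bool = True,
                 cfg: SamplingConfig | None = None,
                 ) -> tuple[nx.Graph, GeneratorProgram]:
    """Grow a seeded study network from a canonical generator.

    Returns ``(network, program)``; when ``outdir`` is given, writes
    ``<kind>_n<n>_m<m>_s<seed>.edges`` and the generating program next to
    it, so the ground truth always travels with the network.
    """
    program = canonical_program(kind, directed=directed)
    rng = np.random.default_rng(seed)
    graph = generate_network(program, n, m, cfg=cfg, rng=rng)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = f"{kind.lower()}_n{n}_m{m}_s{seed}"
        write_network(graph, outdir / f"{stem}.edges")
        write_program(program, outdir / f"{stem}.gen")
    return graph, program
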