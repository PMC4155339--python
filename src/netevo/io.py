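"""File formats and run configuration.

Networks travel as plain edge lists (two whitespace-separated labels per
line, ``#`` comments, directedness recorded in a header comment) or GML.
Node labels may be arbitrary strings; they are mapped to the 1-based
sequential identifiers the generator language exposes, in order of first
appearance, and the mapping is returned/saved because identifiers are
semantically meaningful (programs can condition on them).

Generator programs travel as one prefix s-expression per file, with
``#`` comment lines.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import yaml

from .growth import SamplingConfig
from .programs import GeneratorProgram, parse
from .search import SearchConfig

__all__ = [
    "NetworkFormatError",
    "read_network",
    "write_network",
    "read_program",
    "write_program",
    "write_label_map",
    "RunConfig",
]


class NetworkFormatError(ValueError):
    """Malformed network file (message carries the offending line)."""


def _finalize(edges: list[tuple[str, str]], directed: bool,
              lines: list[int] | None = None,
              declared_nodes: int | None = None) -> tuple[nx.Graph, dict]:
    labels: dict[str, int] = {}
    if declared_nodes is not None:
        # a "# nodes N" header fixes identifiers 1..N (keeps isolated nodes)
        labels = {str(v): v for v in range(1, declared_nodes + 1)}
    for u, v in edges:
        for lab in (u, v):
            if lab not in labels:
                labels[lab] = len(labels) + 1
    if declared_nodes is None and all(lab.lstrip("-").isdigit() for lab in labels):
        # integer labels forming exactly 1..n keep their own identifiers
        values = sorted(int(lab) for lab in labels)
        if values == list(range(1, len(labels) + 1)):
            labels = {lab: int(lab) for lab in labels}
    graph = nx.DiGraph() if directed else nx.Graph()
    graph.add_nodes_from(range(1, len(labels) + 1))
    seen = set()
    for pos, (u, v) in enumerate(edges):
        a, b = labels[u], labels[v]
        where = f" (line {lines[pos]})" if lines else ""
        if a == b:
            raise NetworkFormatError(
                f"self-link {u!r} -> {v!r}{where}: the growth model forbids self-links")
        key = (a, b) if (directed or a < b) else (b, a)
        if key in seen:
            raise NetworkFormatError(
                f"duplicate arc {u!r} -> {v!r}{where}: the growth model forbids duplicates")
        seen.add(key)
        graph.add_edge(a, b)
    return graph, labels


def read_network(path, directed: bool | None = None) -> tuple[nx.Graph, dict]:
    """Read an edge-list or GML network file.

    Returns ``(graph, label_map)`` where the graph has nodes ``1..n`` and
    ``label_map`` maps each original label to its sequential identifier.
    A ``# directed`` / ``# undirected`` header comment in an edge list
    sets the mode; the ``directed`` argument overrides it (edge lists
    default to directed when neither is present).  Self-links and
    duplicate arcs are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".gml":
        raw = nx.read_gml(path, label="label")
        if directed is not None and raw.is_directed() != directed:
            raw = raw.to_directed() if directed else raw.to_undirected()
        edges = [(str(u), str(v)) for u, v in raw.edges()]
        return _finalize(edges, raw.is_directed() if directed is None else directed)

    header_directed: bool | None = None
    declared_nodes: int | None = None
    edges: list[tuple[str, str]] = []
    lines: list[int] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            tag = stripped.lstrip("#").strip().lower()
            if tag in {"directed", "undirected"}:
                header_directed = tag == "directed"
            elif tag.startswith("nodes"):
                declared_nodes = int(tag.split()[1])
            continue
        fields = stripped.split()
        if len(fields) != 2:
            raise NetworkFormatError(
                f"line {lineno}: expected two whitespace-separated labels, "
                f"got {len(fields)}: {stripped!r}")
        edges.append((fields[0], fields[1]))
        lines.append(lineno)
    if not edges:
        raise NetworkFormatError(f"{path}: no arcs found")
    if directed is None:
        directed = header_directed if header_directed is not None else True
    return _finalize(edges, directed, lines, declared_nodes=declared_nodes)


def write_network(graph: nx.Graph, path, label_map: dict | None = None) -> None:
    """Write a network as an edge list (or GML if the path ends in .gml).

    ``label_map`` (original label -> identifier) restores the original
    labels in the output; without it the sequential identifiers are
    written.
    """
    path = Path(path)
    if path.suffix.lower() == ".gml":
        nx.write_gml(graph, path, stringizer=str)
        return
    inverse = {v: k for k, v in (label_map or {}).items()}
    mode = "directed" if graph.is_directed() else "undirected"
    nodes = sorted(graph.nodes())
    sequential = nodes == list(range(1, len(nodes) + 1))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {mode}\n")
        if sequential and not label_map:
            fh.write(f"# nodes {len(nodes)}\n")
        for u, v in graph.edges():
            fh.write(f"{inverse.get(u, u)} {inverse.get(v, v)}\n")


def write_label_map(label_map: dict, path) -> None:
    Path(path).write_text(json.dumps(label_map, indent=2), encoding="utf-8")


def read_program(path, directed: bool = True) -> GeneratorProgram:
    """Read a one-expression program file (``#`` comment lines ignored)."""
    text = Path(path).read_text(encoding="utf-8")
    body = "\n".join(line for line in text.splitlines()
                     if not line.strip().startswith("#"))
    return parse(body, directed=directed)


def write_program(program: GeneratorProgram, path) -> None:
    Path(path).write_text(program.format() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full configuration of a run, YAML-serializable.

    Mirrors every CLI flag; CLI flags override file values.
    """

    mode: str = "directed"
    s_r: float = 0.001
    min_sample: int = 100
    walk_count: int = 5
    walk_length: int = 7
    anti_bloat_tolerance: float = 0.10
    stall_limit: int = 1000
    init_max_depth: int = 5
    fitness_replicates: int = 1
    baseline_replicates: int = 30
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in {"directed", "undirected"}:
            raise ValueError("mode must be 'directed' or 'undirected'")
        # delegate numeric range checks to the component configs
        self.sampling_config()
        SearchConfig(anti_bloat_tolerance=self.anti_bloat_tolerance,
                     stall_limit=self.stall_limit,
                     init_max_depth=self.init_max_depth,
                     fitness_replicates=self.fitness_replicates,
                     baseline_replicates=self.baseline_replicates)

    @property
    def directed(self) -> bool:
        return self.mode == "directed"

    def sampling_config(self) -> SamplingConfig:
        return SamplingConfig(s_r=self.s_r, min_sample=self.min_sample,
                              walk_count=self.walk_count,
                              walk_length=self.walk_length)

    def search_config(self) -> SearchConfig:
        return SearchConfig(anti_bloat_tolerance=self.anti_bloat_tolerance,
                            stall_limit=self.stall_limit,
                            sampling=self.sampling_config(),
                            init_max_depth=self.init_max_depth,
                            fitness_replicates=self.fitness_replicates,
                            baseline_replicates=self.baseline_replicates)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
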