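"""Edge-partitioned directed pathway graphs for kinetic flux profiling.

A metabolic pathway is represented as a directed weighted graph whose nodes
are metabolites and whose edges are reactions, partitioned into four classes:

* **labeled inputs** — external influxes carrying isotopically labeled
  nutrient (at least one is required, or no label ever enters the system);
* **unlabeled inputs** — external influxes of unlabeled material;
* **exits** — effluxes leaving the scope of the diagram;
* **internal edges** — reactions converting one metabolite into another.

Edge weights (fluxes) are attached separately through :class:`FluxAssignment`
so that the same topology can be reused across flux scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "PathwayGraph",
    "FluxAssignment",
    "ValidationReport",
    "validate_graph",
    "partition_counts",
    "is_arborescence",
]


@dataclass(frozen=True)
class PathwayGraph:
    """Directed pathway graph with the four-way edge partition.

    Parameters
    ----------
    nodes
        Ordered metabolite identifiers. The declaration order fixes the
        matrix index order used throughout the package (0-based internally,
        reported 1-based in human-readable output).
    internal_edges
        ``(source, target, edge_id)`` triples for metabolite-to-metabolite
        reactions.
    labeled_inputs
        ``(target, edge_id)`` pairs for labeled external influxes.
    unlabeled_inputs
        ``(target, edge_id)`` pairs for unlabeled external influxes.
    exits
        ``(source, edge_id)`` pairs for effluxes leaving the diagram.
    """

    nodes: tuple[str, ...]
    internal_edges: tuple[tuple[str, str, str], ...] = ()
    labeled_inputs: tuple[tuple[str, str], ...] = ()
    unlabeled_inputs: tuple[tuple[str, str], ...] = ()
    exits: tuple[tuple[str, str], ...] = ()

    def __init__(self, nodes, internal_edges=(), labeled_inputs=(),
                 unlabeled_inputs=(), exits=()):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "internal_edges",
                           tuple((str(a), str(b), str(e)) for a, b, e in internal_edges))
        object.__setattr__(self, "labeled_inputs",
                           tuple((str(a), str(e)) for a, e in labeled_inputs))
        object.__setattr__(self, "unlabeled_inputs",
                           tuple((str(a), str(e)) for a, e in unlabeled_inputs))
        object.__setattr__(self, "exits",
                           tuple((str(a), str(e)) for a, e in exits))

    # -- indexing helpers -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self, node: str) -> int:
        return self.nodes.index(node)

    @property
    def edge_ids(self) -> tuple[str, ...]:
        """All edge ids in canonical order: labeled, unlabeled, exits, internal."""
        return tuple(
            [e for _, e in self.labeled_inputs]
            + [e for _, e in self.unlabeled_inputs]
            + [e for _, e in self.exits]
            + [e for _, _, e in self.internal_edges]
        )

    @property
    def n_edges(self) -> int:
        return len(self.edge_ids)

    def labeled_nodes(self) -> set[str]:
        return {t for t, _ in self.labeled_inputs}

    def internal_digraph(self) -> nx.DiGraph:
        """networkx view of the internal-edge subgraph (all nodes included)."""
        dg = nx.DiGraph()
        dg.add_nodes_from(self.nodes)
        for src, tgt, eid in self.internal_edges:
            dg.add_edge(src, tgt, edge_id=eid)
        return dg


@dataclass(frozen=True)
class FluxAssignment:
    """Nonnegative flux values per edge id, with optional pool sizes.

    ``concentrations`` maps node -> total concentration; it is only needed
    when turnover rates (flux / pool size) are wanted, since the enrichment
    scaling is otherwise concentration-free.
    """

    values: Mapping[str, float]
    concentrations: Mapping[str, float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))
        if self.concentrations is not None:
            object.__setattr__(self, "concentrations", dict(self.concentrations))
        for eid, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative flux for edge {eid!r}: {v}")
        if self.concentrations is not None:
            for node, c in self.concentrations.items():
                if c <= 0:
                    raise ValueError(f"non-positive concentration for node {node!r}: {c}")

    def __getitem__(self, eid: str) -> float:
        try:
            return float(self.values[eid])
        except KeyError:
            raise KeyError(f"no flux value for edge {eid!r}") from None


@dataclass
class ValidationReport:
    """Outcome of structural validation; ``ok`` iff ``failures`` is empty."""

    failures: list[tuple[str, str, object]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def add(self, rule: str, message: str, element: object = None) -> None:
        self.failures.append((rule, message, element))

    def rules(self) -> set[str]:
        return {r for r, _, _ in self.failures}

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "graph OK"
        return "\n".join(f"[{r}] {m}" for r, m, _ in self.failures)


def _check_duplicate_ids(g: PathwayGraph, report: ValidationReport) -> None:
    seen: set[str] = set()
    for eid in g.edge_ids:
        if eid in seen:
            report.add("duplicate_edge_id", f"edge id {eid!r} used more than once", eid)
        seen.add(eid)


def validate_graph(g: PathwayGraph) -> ValidationReport:
    """Check every structural invariant of the pathway-graph class.

    All violations are collected into the report rather than raised, so a
    single pass surfaces every problem:

    * at least one labeled input and at least one exit;
    * at most one labeled input, one unlabeled input and one exit per node
      (the external-edge matrices are diagonal);
    * endpoints of every edge are declared nodes; edge ids unique;
    * no self-loops and at most one internal edge per ordered node pair;
    * every node reachable from the target of some labeled input through
      internal edges (unreachable nodes can never acquire label).
    """
    report = ValidationReport()
    node_set = set(g.nodes)
    if len(node_set) != len(g.nodes):
        report.add("duplicate_node", "node identifiers are not unique", g.nodes)
    if not g.labeled_inputs:
        report.add("no_labeled_input", "graph has no labeled input; no label can enter")
    if not g.exits:
        report.add("no_exit", "graph has no exit edge")
    _check_duplicate_ids(g, report)

    for name, pairs in (("labeled_input", g.labeled_inputs),
                        ("unlabeled_input", g.unlabeled_inputs),
                        ("exit", g.exits)):
        seen_nodes: set[str] = set()
        for node, eid in pairs:
            if node not in node_set:
                report.add("unknown_node", f"{name} edge {eid!r} references unknown node {node!r}", eid)
            if node in seen_nodes:
                report.add(f"multiple_{name}", f"node {node!r} has more than one {name}", node)
            seen_nodes.add(node)

    seen_pairs: set[tuple[str, str]] = set()
    for src, tgt, eid in g.internal_edges:
        for endpoint in (src, tgt):
            if endpoint not in node_set:
                report.add("unknown_node", f"internal edge {eid!r} references unknown node {endpoint!r}", eid)
        if src == tgt:
            report.add("self_loop", f"internal edge {eid!r} is a self-loop on {src!r}", eid)
        if (src, tgt) in seen_pairs:
            report.add("parallel_edge", f"more than one internal edge {src!r}->{tgt!r}", (src, tgt))
        seen_pairs.add((src, tgt))

    # Reachability from all labeled-input targets jointly.
    if g.labeled_inputs and not report.rules() & {"unknown_node", "duplicate_node"}:
        dg = g.internal_digraph()
        reachable: set[str] = set()
        for root in g.labeled_nodes():
            reachable |= {root} | nx.descendants(dg, root)
        for node in g.nodes:
            if node not in reachable:
                report.add("unreachable", f"node {node!r} unreachable from labeled input", node)
    return report


def partition_counts(g: PathwayGraph) -> dict[str, int]:
    """Sizes of the node set and the four edge classes.

    Returns a dict with keys ``N``, ``R``, ``L``, ``U``, ``V``, ``W`` where
    ``R = L + U + V + W`` is the total reaction count.
    """
    counts = {
        "N": g.n_nodes,
        "L": len(g.labeled_inputs),
        "U": len(g.unlabeled_inputs),
        "V": len(g.exits),
        "W": len(g.internal_edges),
    }
    counts["R"] = counts["L"] + counts["U"] + counts["V"] + counts["W"]
    return counts


def is_arborescence(g: PathwayGraph) -> bool:
    """True iff the graph is a directed tree rooted at the labeled input.

    An arborescence here has exactly one labeled input, ``N - 1`` internal
    edges, and exactly one directed path from the root to every node. Such
    graphs retain no free metabolite-to-metabolite flux-proportion
    parameters after reduction.
    """
    if len(g.labeled_inputs) != 1:
        return False
    if len(g.internal_edges) != g.n_nodes - 1:
        return False
    root = g.labeled_inputs[0][0]
    dg = g.internal_digraph()
    if g.n_nodes == 1:
        return True
    if not nx.is_arborescence(dg):
        return False
    # the arborescence must be rooted at the labeled-input target
    return all(deg == (0 if n == root else 1) for n, deg in dg.in_degree())
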