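"""Reading and writing pathway specs, parameter sets and run configs.

The graph spec is a small YAML (or JSON — YAML is a superset) document:

.. code-block:: yaml

    nodes: [X1, X2]
    labeled_in:   [{to: X1, id: f1}]
    unlabeled_in: [{to: X1, id: f2}, {to: X2, id: f5}]
    exits:        [{from: X1, id: f3}, {from: X2, id: f6}]
    internal:     [{from: X1, to: X2, id: f4}]
    fluxes:          {f1: 0.15, f2: 0.05, ...}   # optional
    concentrations:  {X1: 0.571, X2: 0.667}      # optional

Parameter sets (truths, priors) are flat ``name: value`` maps.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .enrichment import ParameterSet
from .graph import FluxAssignment, PathwayGraph, ValidationReport, validate_graph

__all__ = [
    "GraphSpecError",
    "GraphValidationError",
    "read_graph_spec",
    "read_flux_assignment",
    "write_graph_spec",
    "read_parameter_set",
    "write_parameter_set",
]

_GRAPH_KEYS = {"nodes", "internal", "labeled_in", "unlabeled_in", "exits",
               "fluxes", "concentrations"}


class GraphSpecError(ValueError):
    """The file could not be parsed into a pathway graph."""


class GraphValidationError(ValueError):
    """The parsed graph violates a structural invariant."""

    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(f"graph failed validation:\n{report}")


def _load(path) -> dict:
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise GraphSpecError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise GraphSpecError(f"{path}: expected a mapping at top level")
    return doc


def _edge_list(doc: dict, key: str, fields: tuple[str, ...]) -> list[tuple]:
    out = []
    for entry in doc.get(key) or []:
        if not isinstance(entry, dict) or set(entry) != set(fields):
            raise GraphSpecError(
                f"entry {entry!r} under {key!r} must have keys {fields}"
            )
        out.append(tuple(str(entry[f]) for f in fields))
    return out


def read_graph_spec(path, validate: bool = True) -> PathwayGraph:
    """Parse a graph spec file; optionally enforce structural validity.

    Unknown top-level keys are a parse error (they usually indicate a
    misspelled edge class). Validation failures raise
    :class:`GraphValidationError` carrying the full report.
    """
    doc = _load(path)
    unknown = set(doc) - _GRAPH_KEYS
    if unknown:
        raise GraphSpecError(
            f"{path}: unknown key(s) {sorted(unknown)}; expected {sorted(_GRAPH_KEYS)}"
        )
    if "nodes" not in doc:
        raise GraphSpecError(f"{path}: missing required key 'nodes'")
    g = PathwayGraph(
        nodes=[str(n) for n in doc["nodes"]],
        internal_edges=_edge_list(doc, "internal", ("from", "to", "id")),
        labeled_inputs=_edge_list(doc, "labeled_in", ("to", "id")),
        unlabeled_inputs=_edge_list(doc, "unlabeled_in", ("to", "id")),
        exits=_edge_list(doc, "exits", ("from", "id")),
    )
    if validate:
        report = validate_graph(g)
        if not report.ok:
            raise GraphValidationError(report)
    return g


def read_flux_assignment(path) -> FluxAssignment | None:
    """Fluxes/concentrations from a graph spec file, or None if absent."""
    doc = _load(path)
    if "fluxes" not in doc:
        return None
    conc = doc.get("concentrations")
    return FluxAssignment(
        values={str(k): float(v) for k, v in doc["fluxes"].items()},
        concentrations={str(k): float(v) for k, v in conc.items()} if conc else None,
    )


def write_graph_spec(path, g: PathwayGraph, f: FluxAssignment | None = None) -> None:
    doc: dict = {
        "nodes": list(g.nodes),
        "labeled_in": [{"to": t, "id": e} for t, e in g.labeled_inputs],
        "unlabeled_in": [{"to": t, "id": e} for t, e in g.unlabeled_inputs],
        "exits": [{"from": s, "id": e} for s, e in g.exits],
        "internal": [{"from": s, "to": t, "id": e} for s, t, e in g.internal_edges],
    }
    if f is not None:
        doc["fluxes"] = {k: float(v) for k, v in f.values.items()}
        if f.concentrations is not None:
            doc["concentrations"] = {k: float(v) for k, v in f.concentrations.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_parameter_set(path) -> ParameterSet:
    doc = _load(path)
    return ParameterSet({str(k): float(v) for k, v in doc.items()})


def write_parameter_set(path, params: ParameterSet) -> None:
    path = Path(path)
    data = {k: float(v) for k, v in params.values.items()}
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
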