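"""Ready-made pathway fixtures used throughout the docs, examples and tests.

Three small networks cover the qualitatively distinct regimes:

* a three-metabolite **cycle** (labeled input into X1, an unlabeled input
  and an exit at every node, internal edges X1->X2->X3->X1) — the smallest
  graph with a surviving free beta after reduction;
* the **irreversible two-pool chain** X1 -> X2 — an arborescence, whose
  flux proportions are recoverable from steady-state data alone;
* the **reversible two-pool chain** X1 <-> X2 — one extra proportional
  parameter, which breaks steady-state identifiability and produces the
  characteristic posterior ridge between alpha_1 and beta_{1,2}.
"""

from __future__ import annotations

from .enrichment import ParameterSet
from .graph import FluxAssignment, PathwayGraph

__all__ = [
    "three_node_cycle",
    "cycle_fluxes",
    "two_pool_chain",
    "chain_fluxes",
    "irreversible_truth",
    "reversible_truth",
    "fast_slow_truth",
]


def three_node_cycle() -> PathwayGraph:
    """Three metabolites in a cycle; 10 reactions, one labeled input."""
    return PathwayGraph(
        nodes=["X1", "X2", "X3"],
        labeled_inputs=[("X1", "f1")],
        unlabeled_inputs=[("X1", "f2"), ("X2", "f5"), ("X3", "f8")],
        exits=[("X1", "f3"), ("X2", "f6"), ("X3", "f9")],
        internal_edges=[("X1", "X2", "f4"), ("X2", "X3", "f7"),
                        ("X3", "X1", "f10")],
    )


def cycle_fluxes() -> FluxAssignment:
    """A balanced flux assignment for the cycle (unit pool sizes)."""
    return FluxAssignment(
        values={"f1": 1.0, "f2": 2.0, "f3": 2.0, "f4": 4.0, "f5": 3.0,
                "f6": 2.0, "f7": 5.0, "f8": 1.0, "f9": 3.0, "f10": 3.0},
        concentrations={"X1": 1.0, "X2": 1.0, "X3": 1.0},
    )


def two_pool_chain(reversible: bool = False) -> PathwayGraph:
    """Two-metabolite chain; set ``reversible`` for the X2 -> X1 back edge."""
    internal = [("X1", "X2", "f4")]
    if reversible:
        internal.append(("X2", "X1", "f-4"))
    return PathwayGraph(
        nodes=["X1", "X2"],
        labeled_inputs=[("X1", "f1")],
        unlabeled_inputs=[("X1", "f2"), ("X2", "f5")],
        exits=[("X1", "f3"), ("X2", "f6")],
        internal_edges=internal,
    )


def chain_fluxes(reversible: bool = False) -> FluxAssignment:
    """Balanced fluxes reproducing the reference truth parameter values.

    Irreversible: k1 = 7/20, alpha1 = 1/4, k2 = 3/10, alpha2 = 2/5 (pool
    sizes 4/7 and 2/3 give flux F = 0.2 through both pools). Reversible:
    k1 = 7/20, alpha1 = 1/4, beta_{1,2} = 3/20, k2 = 3/10, alpha2 = 3/10
    at unit pool sizes.
    """
    if not reversible:
        return FluxAssignment(
            values={"f1": 0.15, "f2": 0.05, "f3": 0.08, "f4": 0.12,
                    "f5": 0.08, "f6": 0.2},
            concentrations={"X1": 4.0 / 7.0, "X2": 2.0 / 3.0},
        )
    return FluxAssignment(
        values={"f1": 0.21, "f2": 0.0875, "f3": 0.14, "f4": 0.21,
                "f-4": 0.0525, "f5": 0.09, "f6": 0.2475},
        concentrations={"X1": 1.0, "X2": 1.0},
    )


def irreversible_truth() -> ParameterSet:
    """Reference truth for the irreversible chain."""
    return ParameterSet({"k_X1": 7 / 20, "alpha_X1": 1 / 4,
                         "k_X2": 3 / 10, "alpha_X2": 2 / 5})


def reversible_truth() -> ParameterSet:
    """Reference truth for the reversible chain (similar turnover rates)."""
    return ParameterSet({"k_X1": 7 / 20, "alpha_X1": 1 / 4,
                         "beta_X1_X2": 3 / 20,
                         "k_X2": 3 / 10, "alpha_X2": 3 / 10})


def fast_slow_truth(fast_node: str = "X1") -> ParameterSet:
    """Reversible-chain truth with a 25-fold time-scale separation.

    ``fast_node="X1"`` puts the fast turnover on the labeled-input node
    (fast transient observable); ``"X2"`` puts it downstream (initial
    condition on the slow manifold, fast rate unidentifiable).
    """
    if fast_node == "X1":
        k1, k2 = 1.0, 1.0 / 25.0
    elif fast_node == "X2":
        k1, k2 = 1.0 / 25.0, 1.0
    else:
        raise ValueError("fast_node must be 'X1' or 'X2'")
    return ParameterSet({"k_X1": k1, "alpha_X1": 1 / 4, "beta_X1_X2": 3 / 20,
                         "k_X2": k2, "alpha_X2": 3 / 10})
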