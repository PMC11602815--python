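"""Isotopic steady state: solution, invertibility, identifiability.

At the isotopic steady state the unlabeled fractions satisfy the linear
system ``(I - B) xbar_ss = alpha``. Two structural facts drive everything
here:

* ``(I - B)`` is *weakly chained diagonally dominant* (every row weakly
  dominant, and every non-strict row connected through the influence graph
  to a strictly dominant row — the rows of nodes with a labeled input), so
  the steady state exists and is unique;
* the turnover rates ``K`` cancel out of the steady-state equation, so
  steady-state-only data can never inform them.

Counting equations against unknowns gives a *necessary* (not sufficient)
condition for recovering the flux proportions from steady-state data alone:
the number of proportional parameters after reduction,
``|labeled| + |unlabeled| + |internal| - N``, must not exceed the N
observed steady states.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .enrichment import EnrichmentModel, ParameterSet, alpha_name
from .graph import PathwayGraph, is_arborescence, partition_counts

__all__ = [
    "SteadyStateResult",
    "SSIdentifiabilityReport",
    "solve_steady_state",
    "wcdd_check",
    "ss_identifiability",
    "recover_arborescence_alphas",
]


@dataclass(frozen=True)
class SteadyStateResult:
    xbar_ss: np.ndarray
    wcdd_ok: bool
    strict_rows: frozenset[int]
    chain_witness: dict[int, tuple[int, ...]]


@dataclass(frozen=True)
class SSIdentifiabilityReport:
    """Necessary-condition check for steady-state-only parameter recovery."""

    condition_holds: bool
    n_proportional_params: int
    n_steady_states: int
    arborescence_closed_form: bool
    degenerate_all_labeled: bool = False
    degenerate_single_parent: tuple[str, ...] = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        verdict = "satisfied" if self.condition_holds else "NOT satisfied"
        lines = [
            f"steady-state counting condition {verdict}: "
            f"{self.n_proportional_params} proportional parameters vs "
            f"{self.n_steady_states} steady-state values",
        ]
        if self.arborescence_closed_form:
            lines.append("graph is an arborescence: alphas recoverable in closed form")
        if self.degenerate_all_labeled:
            lines.append("degenerate: no unlabeled input anywhere, steady state is 0")
        if self.degenerate_single_parent:
            lines.append(
                "degenerate: nodes fed by a single parent with no external input: "
                + ", ".join(self.degenerate_single_parent)
            )
        return "\n".join(lines)


def _wcdd(B: np.ndarray, tol: float = 1e-12) -> tuple[bool, frozenset[int], dict[int, tuple[int, ...]]]:
    """Weak chained diagonal dominance of (I - B) for a nonnegative B.

    Row i of (I - B) is weakly dominant iff the row sum of B is <= 1 and
    strictly dominant iff it is < 1. For every non-strict row a directed
    path through nonzero off-diagonals to a strict row is searched
    breadth-first and returned as witness.
    """
    n = B.shape[0]
    row_sums = B.sum(axis=1)
    if np.any(row_sums > 1.0 + tol):
        bad = frozenset(int(i) for i in np.flatnonzero(row_sums > 1.0 + tol))
        return False, frozenset(), {int(i): () for i in bad}
    strict = frozenset(int(i) for i in np.flatnonzero(row_sums < 1.0 - tol))
    witness: dict[int, tuple[int, ...]] = {}
    ok = True
    for i in range(n):
        if i in strict:
            continue
        # BFS over the graph of (I - B): edge i -> j where B[i, j] != 0
        queue: deque[tuple[int, tuple[int, ...]]] = deque([(i, (i,))])
        seen = {i}
        path = None
        while queue:
            node, p = queue.popleft()
            if node in strict:
                path = p
                break
            for j in np.flatnonzero(np.abs(B[node]) > tol):
                if int(j) not in seen:
                    seen.add(int(j))
                    queue.append((int(j), p + (int(j),)))
        if path is None:
            ok = False
            witness[i] = ()
        else:
            witness[i] = path
    return ok, strict, witness


def wcdd_check(model: EnrichmentModel, params: ParameterSet
               ) -> tuple[bool, frozenset[int], dict[int, tuple[int, ...]]]:
    """Verify weak chained diagonal dominance of ``(I - B)``.

    Returns ``(ok, strict_rows, chain_witness)``; a failure (some row of B
    summing above one, or a non-strict row with no path to a strict one)
    indicates inadmissible parameters rather than a broken theorem.
    """
    _, B, _ = model.numeric(params)
    return _wcdd(B)


def solve_steady_state(model: EnrichmentModel, params: ParameterSet) -> SteadyStateResult:
    """Solve ``(I - B) x = alpha`` by a dense direct method.

    The result depends only on the flux proportions; the turnover rates are
    never touched. A numerically singular ``(I - B)`` signals an internal
    inconsistency (it cannot occur for admissible parameters on a valid
    graph) and is raised.
    """
    model.require_admissible(params)
    _, B, alpha = model.numeric(params)
    ok, strict, witness = _wcdd(B)
    A = np.eye(model.n_nodes) - B
    try:
        x = np.linalg.solve(A, alpha)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            "(I - B) is singular despite admissible parameters; "
            "internal consistency failure"
        ) from exc
    return SteadyStateResult(xbar_ss=x, wcdd_ok=ok, strict_rows=strict,
                             chain_witness=witness)


def ss_identifiability(g: PathwayGraph,
                       model: EnrichmentModel | None = None,
                       params: ParameterSet | None = None) -> SSIdentifiabilityReport:
    """Evaluate the steady-state counting condition and its known failure modes.

    The condition ``|labeled| + |unlabeled| + |internal| <= 2N`` is necessary
    only. Two documented degeneracies defeat it even when it holds and are
    flagged when parameter values are available: all-labeled input
    (``alpha = 0`` everywhere, steady state identically zero) and a node fed
    by exactly one other node with no external input (its steady state
    duplicates the parent's information).
    """
    counts = partition_counts(g)
    n = counts["N"]
    lhs = counts["L"] + counts["U"] + counts["W"]
    n_prop = lhs - n

    all_labeled = False
    single_parent: list[str] = []
    if model is not None and params is not None:
        _, B, alpha = model.numeric(params)
        all_labeled = bool(np.all(alpha == 0.0))
        # a node with alpha == 0, no labeled input, and exactly one parent
        labeled = g.labeled_nodes()
        for i, node in enumerate(g.nodes):
            if node in labeled or alpha[i] != 0.0:
                continue
            parents = np.flatnonzero(B[i])
            if parents.size == 1:
                single_parent.append(node)
    else:
        # structural reading: no unlabeled inputs at all means alpha == 0
        all_labeled = counts["U"] == 0
        labeled = g.labeled_nodes()
        unlabeled = {t for t, _ in g.unlabeled_inputs}
        indeg: dict[str, int] = {node: 0 for node in g.nodes}
        for _, tgt, _ in g.internal_edges:
            indeg[tgt] += 1
        for node in g.nodes:
            if node not in labeled and node not in unlabeled and indeg[node] == 1:
                single_parent.append(node)

    return SSIdentifiabilityReport(
        condition_holds=lhs <= 2 * n,
        n_proportional_params=n_prop,
        n_steady_states=n,
        arborescence_closed_form=is_arborescence(g),
        degenerate_all_labeled=all_labeled,
        degenerate_single_parent=tuple(single_parent),
    )


def recover_arborescence_alphas(g: PathwayGraph, xbar_ss: np.ndarray) -> np.ndarray:
    """Closed-form recovery of the unlabeled-input proportions on a tree.

    On an arborescence the root's steady state equals its own unlabeled
    share, and each other node's alpha follows from its unique parent j via
    ``alpha_i = (x_i - x_j) / (1 - x_j)``. Raises when the graph is not an
    arborescence or a parent sits exactly at 1 (no label reaches the
    subtree, leaving alpha undetermined).
    """
    if not is_arborescence(g):
        raise ValueError("alpha recovery in closed form requires an arborescence")
    x = np.asarray(xbar_ss, dtype=float)
    idx = {node: i for i, node in enumerate(g.nodes)}
    parent = {tgt: src for src, tgt, _ in g.internal_edges}
    root = g.labeled_inputs[0][0]
    alpha = np.zeros(g.n_nodes)
    alpha[idx[root]] = x[idx[root]]
    for node in g.nodes:
        if node == root:
            continue
        j = parent[node]
        denom = 1.0 - x[idx[j]]
        if denom == 0.0:
            raise ZeroDivisionError(
                f"parent {j!r} of node {node!r} is fully unlabeled at steady "
                f"state; alpha_{node} is undetermined"
            )
        alpha[idx[node]] = (x[idx[node]] - x[idx[j]]) / denom
    return alpha
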