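"""Structural matrices, incidence matrix and flux-balance machinery.

Given a pathway graph and a flux assignment, this module assembles the
matrices that define the linear ODE for unlabeled metabolite concentrations

    dX_u/dt = A_hat X_u + b_hat

where ``A_hat = (W^T - F_out) X_T^{-1}`` couples metabolite pools through
the weighted adjacency matrix ``W`` and the total-outflux diagonal
``F_out``, and ``b_hat`` carries the unlabeled external influxes. The
incidence (stoichiometry) matrix encodes the metabolic steady-state
constraint ``M f = 0`` — total influx equals total efflux at every node —
which removes N of the R flux parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import FluxAssignment, PathwayGraph, validate_graph

__all__ = [
    "StructuralMatrices",
    "IncidenceMatrix",
    "build_structural_matrices",
    "incidence_matrix",
    "flux_balance_residual",
    "independent_parameter_count",
    "FLUX_BALANCE_RTOL",
]

#: default relative tolerance (times the largest flux) for declaring balance
FLUX_BALANCE_RTOL = 1e-9


@dataclass(frozen=True)
class StructuralMatrices:
    """The matrix decomposition of a flux-weighted pathway graph.

    ``W[i, j]`` is the flux from node ``i`` to node ``j``; ``D_out``/``D_in``
    are the weighted out-/in-degree diagonals of the internal subgraph;
    ``D_L``, ``D_U``, ``D_V`` hold the labeled-input, unlabeled-input and
    exit fluxes per node; ``F_out = D_out + D_V`` and
    ``F_in = D_in + D_L + D_U`` are the total flux out of / into each node.
    ``A_hat`` and ``X_T`` are present only when concentrations were supplied.
    """

    nodes: tuple[str, ...]
    W: np.ndarray
    D_out: np.ndarray
    D_in: np.ndarray
    D_L: np.ndarray
    D_U: np.ndarray
    D_V: np.ndarray
    X_T: np.ndarray | None

    @property
    def F_out(self) -> np.ndarray:
        return self.D_out + self.D_V

    @property
    def F_in(self) -> np.ndarray:
        return self.D_in + self.D_L + self.D_U

    @property
    def b_hat(self) -> np.ndarray:
        """Constant unlabeled-influx vector of the concentration ODE."""
        return np.diag(self.D_U).copy()

    @property
    def A_raw(self) -> np.ndarray:
        """``W^T - F_out``: the system matrix before dividing by pool sizes."""
        return self.W.T - self.F_out

    @property
    def A_hat(self) -> np.ndarray:
        if self.X_T is None:
            raise ValueError(
                "A_hat requires total concentrations; use A_raw for the "
                "concentration-free decomposition"
            )
        return self.A_raw @ np.linalg.inv(self.X_T)


@dataclass(frozen=True)
class IncidenceMatrix:
    """N x R incidence matrix with column order given by ``edge_ids``.

    Entry ``+1`` marks flux j entering metabolite i, ``-1`` flux j leaving
    it. For chemical networks with unit stoichiometry this is the
    stoichiometry matrix, and ``M f = 0`` is the flux-balance constraint.
    """

    nodes: tuple[str, ...]
    edge_ids: tuple[str, ...]
    M: np.ndarray

    def flux_vector(self, f: FluxAssignment) -> np.ndarray:
        return np.array([f[eid] for eid in self.edge_ids], dtype=float)

    def rank(self, rtol: float = 1e-10) -> int:
        s = np.linalg.svd(self.M, compute_uv=False)
        if s.size == 0:
            return 0
        return int(np.sum(s > rtol * s[0]))


def _require_valid(g: PathwayGraph) -> None:
    report = validate_graph(g)
    if not report.ok:
        raise ValueError(f"invalid pathway graph:\n{report}")


def build_structural_matrices(g: PathwayGraph, f: FluxAssignment) -> StructuralMatrices:
    """Assemble W, the degree and external-edge diagonals, and pool sizes.

    Raises ``KeyError`` if any edge lacks a flux value and ``ValueError``
    for an invalid graph or a missing concentration when some (but not all)
    are supplied.
    """
    _require_valid(g)
    n = g.n_nodes
    idx = {node: i for i, node in enumerate(g.nodes)}

    W = np.zeros((n, n))
    for src, tgt, eid in g.internal_edges:
        W[idx[src], idx[tgt]] = f[eid]
    D_L = np.zeros((n, n))
    for tgt, eid in g.labeled_inputs:
        D_L[idx[tgt], idx[tgt]] = f[eid]
    D_U = np.zeros((n, n))
    for tgt, eid in g.unlabeled_inputs:
        D_U[idx[tgt], idx[tgt]] = f[eid]
    D_V = np.zeros((n, n))
    for src, eid in g.exits:
        D_V[idx[src], idx[src]] = f[eid]

    D_out = np.diag(W.sum(axis=1))
    D_in = np.diag(W.sum(axis=0))

    X_T = None
    if f.concentrations is not None:
        missing = [node for node in g.nodes if node not in f.concentrations]
        if missing:
            raise ValueError(f"missing concentrations for nodes {missing}")
        X_T = np.diag([f.concentrations[node] for node in g.nodes])

    return StructuralMatrices(nodes=g.nodes, W=W, D_out=D_out, D_in=D_in,
                              D_L=D_L, D_U=D_U, D_V=D_V, X_T=X_T)


def incidence_matrix(g: PathwayGraph) -> IncidenceMatrix:
    """Build the N x R incidence/stoichiometry matrix of the full graph.

    Columns follow ``g.edge_ids`` (labeled inputs, unlabeled inputs, exits,
    internal edges). Input columns carry a single ``+1``, exit columns a
    single ``-1``, internal columns one of each. The matrix has full row
    rank N for every valid (label-connected) graph.
    """
    _require_valid(g)
    idx = {node: i for i, node in enumerate(g.nodes)}
    edge_ids = g.edge_ids
    col = {eid: j for j, eid in enumerate(edge_ids)}
    M = np.zeros((g.n_nodes, len(edge_ids)))
    for tgt, eid in g.labeled_inputs:
        M[idx[tgt], col[eid]] = 1.0
    for tgt, eid in g.unlabeled_inputs:
        M[idx[tgt], col[eid]] = 1.0
    for src, eid in g.exits:
        M[idx[src], col[eid]] = -1.0
    for src, tgt, eid in g.internal_edges:
        M[idx[src], col[eid]] -= 1.0
        M[idx[tgt], col[eid]] += 1.0
    return IncidenceMatrix(nodes=g.nodes, edge_ids=edge_ids, M=M)


def flux_balance_residual(M: IncidenceMatrix, f: FluxAssignment) -> np.ndarray:
    """Per-node net flux ``M f`` (influx minus efflux).

    Zero (within tolerance) at metabolic steady state.
    """
    return M.M @ M.flux_vector(f)


def is_balanced(g: PathwayGraph, f: FluxAssignment,
                rtol: float = FLUX_BALANCE_RTOL) -> bool:
    """Whether the assignment satisfies flux balance within ``rtol * max flux``."""
    M = incidence_matrix(g)
    fv = M.flux_vector(f)
    scale = max(fv.max(initial=0.0), 1.0)
    return bool(np.all(np.abs(M.M @ fv) <= rtol * scale))


def independent_parameter_count(g: PathwayGraph) -> int:
    """Minimal number of independent flux parameters, ``R - N``.

    The N flux-balance constraints are independent (the incidence matrix
    has full row rank), so N of the R reaction fluxes can be eliminated.
    """
    counts = g.n_edges, g.n_nodes
    return counts[0] - counts[1]
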