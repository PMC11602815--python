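"""Concentration-free enrichment model: scaling, reduction, constraints.

Dividing the unlabeled-concentration ODE by the (constant) pool sizes turns
it into a system for the unlabeled *fractions* ``xbar_i`` — the quantity a
mass spectrometer actually reports (one minus fractional enrichment):

    d(xbar)/dt = K (B - I) xbar + K alpha,      xbar(0) = 1

with three kinds of parameters:

* ``k_i`` (diagonal of ``K``): turnover rate of metabolite i, total flux
  through the pool divided by pool size, in 1/time;
* ``alpha_i``: proportion of metabolite i's influx arriving from an
  external unlabeled source (dimensionless, in [0, 1]);
* ``beta_{i,j}`` (entries of ``B``): proportion of metabolite i's influx
  arriving from metabolite j (dimensionless, in [0, 1]).

Because the proportions into any node without a labeled input must sum to
one, one beta per such node is redundant and is substituted away; the model
is left with ``R - |exits|`` free parameters (``R - N`` when every node has
an exit). Nodes *without* an exit induce an extra algebraic constraint that
ties turnover rates to concentration ratios; those are returned symbolically
rather than applied, since using them requires measured pool sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

from .graph import FluxAssignment, PathwayGraph, validate_graph
from .matrices import FLUX_BALANCE_RTOL, build_structural_matrices, incidence_matrix

__all__ = [
    "EnrichmentModel",
    "ParameterSet",
    "Substitution",
    "ConstraintExpression",
    "enrichment_model",
    "scale_to_enrichment",
    "reduce_parameters",
    "missing_outflux_constraints",
    "rhs",
    "fluxes_from_model",
]


def k_name(node: str) -> str:
    return f"k_{node}"


def alpha_name(node: str) -> str:
    return f"alpha_{node}"


def beta_name(target: str, source: str) -> str:
    """beta_<i>_<j> is the proportion of influx into i coming from j."""
    return f"beta_{target}_{source}"


@dataclass(frozen=True)
class Substitution:
    """Record that ``beta_{node, source}`` equals ``1 - alpha - sum(later)``.

    ``alpha`` is the alpha parameter name of the node (or None when the node
    has no unlabeled input, i.e. alpha is structurally zero) and ``later``
    are the beta names of the remaining free entries in the same row.
    """

    beta: str
    node: str
    alpha: str | None
    later: tuple[str, ...]

    def value(self, values: Mapping[str, float]) -> float:
        out = 1.0
        if self.alpha is not None:
            out -= values[self.alpha]
        for name in self.later:
            out -= values[name]
        return out

    def __str__(self) -> str:
        terms = ["1"]
        if self.alpha is not None:
            terms.append(f"- {self.alpha}")
        terms.extend(f"- {b}" for b in self.later)
        return f"{self.beta} = {' '.join(terms)}"


@dataclass(frozen=True)
class ParameterSet:
    """Flat map of free-parameter name -> value."""

    values: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    def updated(self, **kwargs: float) -> "ParameterSet":
        return ParameterSet({**self.values, **kwargs})


@dataclass(frozen=True)
class EnrichmentModel:
    """Structure (and optionally values) of the scaled enrichment system.

    ``beta_support[i]`` lists, per target node index, the source node
    indices with an internal edge into it, in node order. ``free_params``
    and ``substitutions`` come from the parameter reduction. When built
    from a flux assignment, ``K``/``B``/``alpha`` hold the implied numeric
    values (``K`` only if concentrations were supplied).
    """

    graph: PathwayGraph
    free_params: tuple[str, ...]
    substitutions: tuple[Substitution, ...]
    K: np.ndarray | None = None
    B: np.ndarray | None = None
    alpha: np.ndarray | None = None

    # -- structure --------------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return self.graph.nodes

    @property
    def n_nodes(self) -> int:
        return self.graph.n_nodes

    def labeled_nodes(self) -> set[str]:
        return self.graph.labeled_nodes()

    def param_kind(self, name: str) -> str:
        return name.split("_", 1)[0]

    # -- numeric assembly -------------------------------------------------
    def numeric(self, params: ParameterSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Assemble (K, B, alpha) from a free-parameter set.

        Substituted betas are filled in from their defining identities.
        """
        values = self._full_values(params)
        n = self.n_nodes
        idx = {node: i for i, node in enumerate(self.nodes)}
        K = np.zeros((n, n))
        for node in self.nodes:
            K[idx[node], idx[node]] = values[k_name(node)]
        alpha = np.zeros(n)
        for tgt, _ in self.graph.unlabeled_inputs:
            alpha[idx[tgt]] = values[alpha_name(tgt)]
        B = np.zeros((n, n))
        for src, tgt, _ in self.graph.internal_edges:
            B[idx[tgt], idx[src]] = values[beta_name(tgt, src)]
        return K, B, alpha

    def _full_values(self, params: ParameterSet) -> dict[str, float]:
        values = {name: params[name] for name in self.free_params}
        for sub in self.substitutions:
            values[sub.beta] = sub.value(values)
        return values

    def admissible(self, params: ParameterSet) -> bool:
        """All proportions (including substituted betas) in [0,1], k > 0,
        and labeled nodes retain a strictly positive labeled influx share."""
        try:
            values = self._full_values(params)
        except KeyError:
            return False
        for name, v in values.items():
            kind = name.split("_", 1)[0]
            if kind == "k":
                if not v > 0:
                    return False
            else:
                if not (0.0 <= v <= 1.0):
                    return False
        # labeled share 1 - alpha_i - sum_j beta_{i,j} must stay positive
        for node in self.labeled_nodes():
            if not self.labeled_share(params, node) > 0:
                return False
        return True

    def labeled_share(self, params: ParameterSet, node: str) -> float:
        """Proportion of influx into ``node`` arriving from its labeled input."""
        values = self._full_values(params)
        share = 1.0
        if any(t == node for t, _ in self.graph.unlabeled_inputs):
            share -= values[alpha_name(node)]
        for src, tgt, _ in self.graph.internal_edges:
            if tgt == node:
                share -= values[beta_name(node, src)]
        return share

    def require_admissible(self, params: ParameterSet) -> None:
        if not self.admissible(params):
            raise ValueError("parameter set is not admissible for this model")


@dataclass(frozen=True)
class ConstraintExpression:
    """A missing-outflux constraint solved for one parameter.

    ``lhs`` is a parameter name (a beta or a k); ``rhs`` is a sympy
    expression in the turnover rates ``k_<node>``, the proportions
    ``alpha_*``/``beta_*`` and the total concentrations ``xT_<node>``.
    """

    node: str
    lhs: str
    rhs: sp.Expr

    def __str__(self) -> str:
        return f"{self.lhs} = {self.rhs}"


def reduce_parameters(g: PathwayGraph) -> tuple[tuple[str, ...], tuple[Substitution, ...]]:
    """Eliminate one beta per node without a labeled input.

    For each such node the influx proportions sum to one, so the entry of
    lowest column (source-node) index in that row of ``B`` is replaced by
    ``1 - alpha_i - sum(remaining betas in the row)``. Returns the ordered
    free-parameter names (all k's, then alphas, then surviving betas) and
    the substitution records.
    """
    report = validate_graph(g)
    if not report.ok:
        raise ValueError(f"invalid pathway graph:\n{report}")
    idx = {node: i for i, node in enumerate(g.nodes)}
    labeled = g.labeled_nodes()
    unlabeled = {t for t, _ in g.unlabeled_inputs}

    # incoming internal sources per target, in column (node-index) order
    incoming: dict[str, list[str]] = {node: [] for node in g.nodes}
    for src, tgt, _ in g.internal_edges:
        incoming[tgt].append(src)
    for tgt in incoming:
        incoming[tgt].sort(key=idx.__getitem__)

    substitutions: list[Substitution] = []
    substituted: set[str] = set()
    for node in g.nodes:
        if node in labeled:
            continue
        sources = incoming[node]
        if not sources:
            # unreachable nodes are rejected by validation, so a non-labeled
            # node always has at least one incoming internal edge
            raise AssertionError(f"node {node!r} has no influx")
        first, later = sources[0], sources[1:]
        sub = Substitution(
            beta=beta_name(node, first),
            node=node,
            alpha=alpha_name(node) if node in unlabeled else None,
            later=tuple(beta_name(node, s) for s in later),
        )
        substitutions.append(sub)
        substituted.add(sub.beta)

    free: list[str] = [k_name(node) for node in g.nodes]
    free += [alpha_name(t) for t, _ in g.unlabeled_inputs]
    betas = sorted(
        (beta_name(tgt, src) for src, tgt, _ in g.internal_edges),
        key=lambda name: tuple(idx[p] for p in name.split("_")[1:]),
    )
    free += [b for b in betas if b not in substituted]
    return tuple(free), tuple(substitutions)


def enrichment_model(g: PathwayGraph) -> EnrichmentModel:
    """Structural enrichment model (no numeric values) for a graph."""
    free, subs = reduce_parameters(g)
    return EnrichmentModel(graph=g, free_params=free, substitutions=subs)


def scale_to_enrichment(g: PathwayGraph, f: FluxAssignment,
                        rtol: float = FLUX_BALANCE_RTOL) -> EnrichmentModel:
    """Scale a balanced flux assignment into (K, B, alpha).

    ``alpha_i = b_i / F_i`` and ``beta_{i,j} = w_{j,i} / F_i`` need only the
    fluxes; ``k_i = F_i / x_i^T`` additionally needs the pool sizes and is
    left unset when concentrations are absent. Raises if the fluxes are
    unbalanced beyond tolerance or if some node carries no flux.
    """
    sm = build_structural_matrices(g, f)
    M = incidence_matrix(g)
    fv = M.flux_vector(f)
    scale = max(fv.max(initial=0.0), 1.0)
    residual = M.M @ fv
    if np.any(np.abs(residual) > rtol * scale):
        raise ValueError(f"fluxes are not balanced: residual {residual}")
    F = np.diag(sm.F_in).copy()
    if np.any(F <= 0):
        dead = [g.nodes[i] for i in np.flatnonzero(F <= 0)]
        raise ValueError(f"zero flux through nodes {dead}; every pool needs throughput")
    alpha = sm.b_hat / F
    B = (sm.W.T) / F[:, None]
    K = None
    if sm.X_T is not None:
        K = np.diag(F / np.diag(sm.X_T))
    free, subs = reduce_parameters(g)
    return EnrichmentModel(graph=g, free_params=free, substitutions=subs,
                           K=K, B=B, alpha=alpha)


def true_parameters(model: EnrichmentModel) -> ParameterSet:
    """Free-parameter values implied by a flux-built model's K, B, alpha."""
    if model.B is None or model.alpha is None:
        raise ValueError("model carries no numeric values")
    idx = {node: i for i, node in enumerate(model.nodes)}
    values: dict[str, float] = {}
    for name in model.free_params:
        kind, rest = name.split("_", 1)
        if kind == "k":
            if model.K is None:
                raise ValueError("turnover rates need concentrations")
            values[name] = float(model.K[idx[rest], idx[rest]])
        elif kind == "alpha":
            values[name] = float(model.alpha[idx[rest]])
        else:
            tgt, src = rest.split("_")
            values[name] = float(model.B[idx[tgt], idx[src]])
    return ParameterSet(values)


def rhs(model: EnrichmentModel, params: ParameterSet, xbar: Sequence[float]) -> np.ndarray:
    """Right-hand side ``K (B - I) xbar + K alpha`` of the scaled ODE."""
    model.require_admissible(params)
    K, B, alpha = model.numeric(params)
    x = np.asarray(xbar, dtype=float)
    return K @ ((B - np.eye(model.n_nodes)) @ x + alpha)


def missing_outflux_constraints(g: PathwayGraph) -> tuple[ConstraintExpression, ...]:
    """One symbolic constraint per node without an exit edge.

    Flux balance at such a node i forces its entire throughput to leave via
    internal edges: ``F_i = sum_j beta_{j,i} F_j`` with ``F_i = k_i xT_i``.
    The constraint is solved for one of the node's free outgoing betas if
    any survive reduction, else for ``k_i``. The result reintroduces the
    total concentrations ``xT_<node>``, which is exactly why a missing
    outflux complicates the concentration-free workflow. Constraints are
    returned, never auto-applied.
    """
    free, subs = reduce_parameters(g)
    sub_by_beta = {s.beta: s for s in subs}
    unlabeled = {t for t, _ in g.unlabeled_inputs}
    exits = {src for src, _ in g.exits}

    def beta_expr(tgt: str, src: str) -> sp.Expr:
        name = beta_name(tgt, src)
        if name not in sub_by_beta:
            return sp.Symbol(name)
        s = sub_by_beta[name]
        expr: sp.Expr = sp.Integer(1)
        if s.alpha is not None:
            expr -= sp.Symbol(s.alpha)
        for b in s.later:
            expr -= sp.Symbol(b)
        return expr

    constraints: list[ConstraintExpression] = []
    for node in g.nodes:
        if node in exits:
            continue
        outgoing = [(src, tgt) for src, tgt, _ in g.internal_edges if src == node]
        if not outgoing:
            raise ValueError(
                f"node {node!r} has neither an exit nor an outgoing internal "
                f"edge: flux balance forces zero throughput, so no metabolic "
                f"steady state with positive fluxes exists"
            )
        ki = sp.Symbol(k_name(node))
        ci = sp.Symbol(f"xT_{node}")
        expr = ki * ci
        candidate_betas: list[str] = []
        for src, tgt, _ in g.internal_edges:
            if src != node:
                continue
            name = beta_name(tgt, src)
            if name in free:
                candidate_betas.append(name)
            expr -= beta_expr(tgt, src) * sp.Symbol(k_name(tgt)) * sp.Symbol(f"xT_{tgt}")
        target = candidate_betas[0] if candidate_betas else k_name(node)
        solutions = sp.solve(sp.Eq(expr, 0), sp.Symbol(target))
        if len(solutions) != 1:
            raise ValueError(
                f"node {node!r} lacks an exit and its balance constraint cannot "
                f"be solved for a single parameter; the model is over-constrained"
            )
        constraints.append(ConstraintExpression(node=node, lhs=target,
                                                rhs=sp.simplify(solutions[0])))
    return tuple(constraints)


def fluxes_from_model(model: EnrichmentModel, params: ParameterSet,
                      concentrations: Mapping[str, float]) -> FluxAssignment:
    """Reconstruct absolute fluxes from (K, B, alpha) values and pool sizes.

    Inverse of :func:`scale_to_enrichment`: ``F_i = k_i xT_i``, internal
    edge j->i carries ``beta_{i,j} F_i``, the unlabeled input into i carries
    ``alpha_i F_i``, the labeled input the remaining influx share, and exits
    absorb whatever balance requires.
    """
    g = model.graph
    model.require_admissible(params)
    K, B, alpha = model.numeric(params)
    idx = {node: i for i, node in enumerate(g.nodes)}
    F = np.array([K[idx[n], idx[n]] * concentrations[n] for n in g.nodes])
    values: dict[str, float] = {}
    for src, tgt, eid in g.internal_edges:
        values[eid] = float(B[idx[tgt], idx[src]] * F[idx[tgt]])
    for tgt, eid in g.unlabeled_inputs:
        values[eid] = float(alpha[idx[tgt]] * F[idx[tgt]])
    for tgt, eid in g.labeled_inputs:
        share = 1.0 - alpha[idx[tgt]] - float(B[idx[tgt]].sum())
        values[eid] = float(share * F[idx[tgt]])
    for src, eid in g.exits:
        internal_out = sum(values[e] for s, _, e in g.internal_edges if s == src)
        values[eid] = float(F[idx[src]] - internal_out)
    return FluxAssignment(values=values, concentrations=dict(concentrations))
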