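"""Build a three-metabolite cycle, validate it, and inspect its matrices.

The pathway has one labeled nutrient input (into X1), an unlabeled input
and an exit at every node, and internal reactions X1->X2->X3->X1.
"""

import numpy as np

import kfp
from kfp import pathways

g = pathways.three_node_cycle()
report = kfp.validate_graph(g)
print("valid:", report.ok)

counts = kfp.partition_counts(g)
print(f"N = {counts['N']} metabolites, R = {counts['R']} reactions "
      f"(labeled {counts['L']}, unlabeled {counts['U']}, "
      f"exits {counts['V']}, internal {counts['W']})")
print("minimum independent parameters R - N =",
      kfp.independent_parameter_count(g))

fluxes = pathways.cycle_fluxes()
M = kfp.incidence_matrix(g)
print("incidence matrix rank:", M.rank(), "(= N: balance constraints independent)")
print("flux-balance residual:", kfp.flux_balance_residual(M, fluxes),
      "<- zero means metabolic steady state")

sm = kfp.build_structural_matrices(g, fluxes)
print("W^T (flux j->i):")
print(sm.W.T)
print("total flux through each pool:", np.diag(sm.F_in))
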