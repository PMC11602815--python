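"""Parameter reduction and steady-state identifiability, side by side.

The irreversible two-pool chain satisfies the steady-state counting
condition (its flux proportions are recoverable from steady-state data);
adding the reverse reaction introduces one extra proportional parameter
and breaks it. A node without an exit induces a constraint that drags the
(unmeasured) pool sizes back into the problem.
"""

import kfp
from kfp import pathways

for reversible in (False, True):
    g = pathways.two_pool_chain(reversible=reversible)
    free, subs = kfp.reduce_parameters(g)
    rep = kfp.ss_identifiability(g)
    label = "reversible" if reversible else "irreversible"
    print(f"{label} chain: {len(free)} free parameters: {', '.join(free)}")
    for s in subs:
        print("  substitution:", s)
    verdict = "holds" if rep.condition_holds else "FAILS"
    print(f"  steady-state condition {verdict}: "
          f"{rep.n_proportional_params} proportional parameters vs "
          f"{rep.n_steady_states} steady-state values")

# remove the exit from X3 of the cycle: its balance can only be absorbed
# by reintroducing total concentrations
g = kfp.PathwayGraph(
    nodes=["X1", "X2", "X3"],
    labeled_inputs=[("X1", "f1")],
    unlabeled_inputs=[("X1", "f2"), ("X2", "f5"), ("X3", "f8")],
    exits=[("X1", "f3"), ("X2", "f6")],
    internal_edges=[("X1", "X2", "f4"), ("X2", "X3", "f7"), ("X3", "X1", "f10")],
)
print("\ncycle with no exit at X3:")
for c in kfp.missing_outflux_constraints(g):
    print("  constraint:", c, " <- needs the pool-size ratio xT_X3/xT_X1")
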