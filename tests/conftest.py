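import numpy as np
import pytest

import kfp
from kfp import pathways


@pytest.fixture
def cycle3():
    return pathways.three_node_cycle()


@pytest.fixture
def cycle3_fluxes():
    return pathways.cycle_fluxes()


@pytest.fixture
def chain_irrev():
    return pathways.two_pool_chain(reversible=False)


@pytest.fixture
def chain_rev():
    return pathways.two_pool_chain(reversible=True)


@pytest.fixture
def model_irrev(chain_irrev):
    return kfp.enrichment_model(chain_irrev)


@pytest.fixture
def model_rev(chain_rev):
    return kfp.enrichment_model(chain_rev)


@pytest.fixture
def truth_irrev():
    return pathways.irreversible_truth()


@pytest.fixture
def truth_rev():
    return pathways.reversible_truth()


def random_admissible_model(rng: np.random.Generator):
    """A random small pathway (every node with an exit) plus admissible params.

    Topology: a chain rooted at the labeled-input node X1 with optional
    extra internal edges; proportions per node drawn from a Dirichlet so
    the influx shares sum exactly to one (strictly less at the root, which
    keeps a positive labeled share).
    """
    n = int(rng.integers(2, 5))
    nodes = [f"X{i+1}" for i in range(n)]
    internal = [(nodes[i], nodes[i + 1], f"w{i}") for i in range(n - 1)]
    existing = {(s, t) for s, t, _ in internal}
    eid = n
    for s in nodes:
        for t in nodes:
            if s == t or (s, t) in existing:
                continue
            if rng.random() < 0.25:
                internal.append((s, t, f"w{eid}"))
                existing.add((s, t))
                eid += 1
    g = kfp.PathwayGraph(
        nodes=nodes,
        labeled_inputs=[(nodes[0], "lab")],
        unlabeled_inputs=[(v, f"u_{v}") for v in nodes],
        exits=[(v, f"e_{v}") for v in nodes],
        internal_edges=internal,
    )
    model = kfp.enrichment_model(g)

    incoming = {v: [s for s, t, _ in internal if t == v] for v in nodes}
    values = {f"k_{v}": float(rng.uniform(0.1, 2.0)) for v in nodes}
    for v in nodes:
        srcs = incoming[v]
        if v == nodes[0]:
            # labeled node: shares for (labeled, unlabeled, *betas), all > 0
            shares = rng.dirichlet(np.ones(2 + len(srcs)))
            values[f"alpha_{v}"] = float(shares[1])
            for s, share in zip(srcs, shares[2:]):
                values[f"beta_{v}_{s}"] = float(share)
        else:
            shares = rng.dirichlet(np.ones(1 + len(srcs)))
            values[f"alpha_{v}"] = float(shares[0])
            for s, share in zip(srcs, shares[1:]):
                values[f"beta_{v}_{s}"] = float(share)
    params = kfp.ParameterSet({k: v for k, v in values.items()
                               if k in model.free_params})
    assert model.admissible(params)
    return model, params
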