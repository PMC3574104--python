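"""Benchmark and synthetic network fixtures.

The 8-node chest-clinic network ships as a versioned YAML fixture; the
37-node ALARM fixture carries the canonical monitoring-network structure
(46 directed edges) with seeded surrogate parameters. Random networks
are sampled under a random topological order with symmetric-Dirichlet
CPT rows.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from ..errors import ContractError
from ..model_core import CPT, DAG, BayesianNetwork, Variable
from . import formats

__all__ = ["fixture_chest_clinic", "fixture_alarm", "fixture_random_bn"]


def _data_path(name: str):
    return resources.files("consensusbn.io_cli") / "data" / name


def fixture_chest_clinic() -> BayesianNetwork:
    """The canonical 8-node chest-clinic (Asia) network."""
    with resources.as_file(_data_path("chest_clinic.yaml")) as p:
        return formats.read_network(p)


def fixture_alarm() -> BayesianNetwork:
    """The 37-node ALARM network: canonical structure, surrogate CPTs."""
    with resources.as_file(_data_path("alarm.bif")) as p:
        return formats.read_bif(p)


def fixture_random_bn(
    n_nodes: int,
    max_parents: int = 2,
    cardinality: int = 2,
    seed: int = 0,
    concentration: float = 1.0,
) -> BayesianNetwork:
    """A random Bayesian network.

    The DAG is sampled under a random topological order (each node draws
    up to ``max_parents`` parents uniformly from its predecessors); CPT
    rows are symmetric Dirichlet draws with the given concentration —
    smaller values give sharper conditionals, hence stronger
    dependences.
    """
    if n_nodes < 1 or max_parents < 0 or cardinality < 2:
        raise ContractError("invalid random-network bounds")
    rng = np.random.default_rng(seed)
    width = len(str(n_nodes - 1))
    names = [f"V{i:0{width}d}" for i in range(n_nodes)]
    order = [names[i] for i in rng.permutation(n_nodes)]
    states = tuple(f"s{i}" for i in range(cardinality))

    dag = DAG(nodes=names)
    cpts: dict[str, CPT] = {}
    for i, name in enumerate(order):
        k = int(rng.integers(0, min(i, max_parents) + 1))
        parent_names = (sorted(rng.choice(order[:i], size=k, replace=False))
                        if k else [])
        for p in parent_names:
            dag.add_edge(p, name)
        child = Variable(name, states)
        parents = tuple(Variable(p, states) for p in parent_names)
        shape = tuple(cardinality for _ in parent_names)
        n_rows = int(np.prod(shape)) if shape else 1
        rows = rng.dirichlet(np.full(cardinality, concentration), size=n_rows)
        cpts[name] = CPT(child, parents, rows.reshape(shape + (cardinality,)))
    bn = BayesianNetwork(dag=dag, cpts=cpts, weight=1)
    bn.validate()
    return bn
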