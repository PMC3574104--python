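"""Three-phase information-theoretic structure learning plus parameter
estimation.

The learner follows the draft / thicken / thin scheme driven by mutual
information and conditional mutual information tests, orients edges by
collider detection, acyclicity propagation and a local MDL score, and
estimates CPTs by maximum-likelihood counting.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ContractError
from .info_metrics import (
    Thresholds,
    conditional_mutual_information,
    mutual_information,
)
from .model_core import (
    CPT,
    DAG,
    BayesianNetwork,
    DiscreteDataset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateEdgeList",
    "draft_mwst",
    "thicken",
    "thin",
    "orient_edges",
    "learn_parameters",
    "learn_bn",
]


@dataclass
class CandidateEdgeList:
    """Unordered variable pairs with MI values, sorted MI-descending."""

    pairs: list[tuple[tuple[str, str], float]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for pair, _ in self.pairs:
            key = frozenset(pair)
            if key in seen:
                raise ContractError(f"pair {pair} listed twice")
            seen.add(key)
        self.pairs.sort(key=lambda item: (-item[1], item[0]))

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)


def _chi2_bias(data: DiscreteDataset, x: str, y: str,
               cond: set[str] = frozenset()) -> float:
    """Expected value of the plug-in (C)MI estimator under independence.

    2N * I_hat is asymptotically chi-square with
    (r_x - 1)(r_y - 1) * prod(r_c) degrees of freedom, so the estimator's
    null mean is df / (2N). Dependence decisions compare the
    bias-corrected estimate against delta_mi; the raw estimators
    themselves stay uncorrected.
    """
    df = (data.variable(x).cardinality - 1) * (data.variable(y).cardinality - 1)
    for c in cond:
        df *= data.variable(c).cardinality
    return df / (2.0 * data.n_samples)


def _all_pairs_mi(data: DiscreteDataset) -> CandidateEdgeList:
    names = sorted(data.names)
    pairs = [
        ((x, y), mutual_information(data, x, y))
        for x, y in itertools.combinations(names, 2)
    ]
    return CandidateEdgeList(pairs)


def draft_mwst(
    data: DiscreteDataset, thresholds: Thresholds | None = None
) -> tuple[nx.Graph, CandidateEdgeList]:
    """Draft phase: greedy maximum-weight spanning construction.

    Pairs are scanned in MI-descending order (lexicographic ties); an
    edge is added when it closes no cycle, until n-1 edges are placed.
    Pairs with MI <= delta_mi are dropped outright; pairs skipped for
    forming a cycle are returned as the remaining candidate list.
    """
    thresholds = thresholds or Thresholds()
    if len(data.variables) < 2:
        raise ContractError("draft phase needs at least two variables")
    graph = nx.Graph()
    graph.add_nodes_from(data.names)
    remaining: list[tuple[tuple[str, str], float]] = []
    target = len(data.variables) - 1
    for (x, y), mi in _all_pairs_mi(data):
        if mi - _chi2_bias(data, x, y) <= thresholds.delta_mi:
            continue
        if graph.number_of_edges() >= target:
            remaining.append(((x, y), mi))
            continue
        if nx.has_path(graph, x, y):
            remaining.append(((x, y), mi))
        else:
            graph.add_edge(x, y, mi=mi)
    return graph, CandidateEdgeList(remaining)


def _cut_set(graph: nx.Graph, x: str, y: str) -> set[str]:
    """Neighbours of x lying on some x..y path (y excluded, x removed)."""
    sub = graph.subgraph(n for n in graph.nodes if n != x)
    if y not in sub:
        return set()
    reach = nx.node_connected_component(sub, y)
    return (set(graph.neighbors(x)) - {y}) & reach


def _condition_set(graph: nx.Graph, x: str, y: str) -> set[str]:
    cx = _cut_set(graph, x, y)
    cy = _cut_set(graph, y, x)
    if len(cy) < len(cx):
        return cy
    return cx  # ties resolved toward the lexicographically first endpoint


def _dependent(
    data: DiscreteDataset,
    x: str,
    y: str,
    cond: set[str],
    thresholds: Thresholds,
) -> bool:
    """CI decision with the small-stratum fallback to the marginal test."""
    cond = set(cond)
    if cond:
        n_configs = int(
            np.prod([data.variable(c).cardinality for c in sorted(cond)])
        )
        if data.n_samples / max(1, n_configs) < thresholds.min_stratum:
            logger.debug(
                "condition set %s too fine for %s-%s (%d samples, %d strata); "
                "falling back to the marginal test",
                sorted(cond), x, y, data.n_samples, n_configs,
            )
            cond = set()
    if cond:
        value = conditional_mutual_information(data, x, y, cond)
    else:
        value = mutual_information(data, x, y)
    return value - _chi2_bias(data, x, y, cond) > thresholds.delta_mi


def thicken(
    graph: nx.Graph,
    remaining: CandidateEdgeList,
    data: DiscreteDataset,
    thresholds: Thresholds | None = None,
) -> nx.Graph:
    """Thickening phase: add back pairs that no cut-set screens off."""
    thresholds = thresholds or Thresholds()
    graph = graph.copy()
    for (x, y), _mi in remaining:
        if graph.has_edge(x, y):
            continue
        cond = _condition_set(graph, x, y)
        if _dependent(data, x, y, cond, thresholds):
            graph.add_edge(x, y)
    return graph


def thin(
    graph: nx.Graph,
    data: DiscreteDataset,
    thresholds: Thresholds | None = None,
) -> nx.Graph:
    """Thinning phase: remove edges whose endpoints a cut-set screens off.

    Edges are visited in lexicographic order; each is removed
    temporarily, tested against the condition set in the reduced graph,
    and deleted permanently when conditional MI falls at or below
    delta_mi.
    """
    thresholds = thresholds or Thresholds()
    graph = graph.copy()
    for x, y in sorted(tuple(sorted(e)) for e in graph.edges):
        graph.remove_edge(x, y)
        if nx.has_path(graph, x, y):
            cond = _condition_set(graph, x, y)
            if cond and not _dependent(data, x, y, cond, thresholds):
                continue  # redundant edge: stays removed
        graph.add_edge(x, y)
    return graph


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def _mdl_local(data: DiscreteDataset, child: str, parents: tuple[str, ...]) -> float:
    """Local MDL score: negative log-likelihood + (ln N / 2) * #parameters."""
    n = data.n_samples
    child_var = data.variable(child)
    card = child_var.cardinality
    xi = data.column(child)
    if parents:
        dims = tuple(data.variable(p).cardinality for p in parents)
        cfg = np.ravel_multi_index(tuple(data.columns(parents).T), dims)
        n_cfg = int(np.prod(dims))
    else:
        cfg = np.zeros(n, dtype=np.int64)
        n_cfg = 1
    counts = np.bincount(cfg * card + xi, minlength=n_cfg * card).reshape(
        n_cfg, card
    ).astype(float)
    row_tot = counts.sum(axis=1, keepdims=True)
    mask = counts > 0
    ll = float(np.sum(counts[mask] * np.log(counts[mask] /
                                            np.broadcast_to(row_tot, counts.shape)[mask])))
    penalty = 0.5 * math.log(max(n, 2)) * (card - 1) * n_cfg
    return -ll + penalty


class _Orientation:
    """Mutable partial orientation of a skeleton."""

    def __init__(self, skeleton: nx.Graph):
        self.skeleton = skeleton
        self.directed: set[tuple[str, str]] = set()
        self.undirected: set[frozenset] = {frozenset(e) for e in skeleton.edges}

    def orient(self, u: str, v: str) -> None:
        key = frozenset((u, v))
        if key in self.undirected:
            self.undirected.discard(key)
            self.directed.add((u, v))

    def is_directed(self, u: str, v: str) -> bool:
        return (u, v) in self.directed

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(sorted(u for (u, w) in self.directed if w == v))

    def creates_cycle(self, u: str, v: str) -> bool:
        """Would directing u -> v close a directed cycle?"""
        stack, seen = [v], set()
        while stack:
            cur = stack.pop()
            if cur == u:
                return True
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(w for (s, w) in self.directed if s == cur)
        return False


def orient_edges(
    skeleton: nx.Graph,
    data: DiscreteDataset,
    thresholds: Thresholds | None = None,
) -> DAG:
    """Orient a learned skeleton into a DAG.

    Three stages: (1) collider detection — an unshielded triple X-Z-Y is
    a collider when conditioning on Z *increases* the X,Y dependence by
    more than the ``delta_orient`` factor; (2) constraint propagation
    using acyclicity (Meek-style rules); (3) local MDL for whatever is
    left, lexicographic parent on ties. The output is always acyclic.
    """
    thresholds = thresholds or Thresholds()
    state = _Orientation(skeleton)
    nodes = sorted(skeleton.nodes)

    # stage 1: collider detection on unshielded triples x - z - y:
    # a collider turns marginally unrelated endpoints (MI <= delta_mi)
    # into conditionally related ones (CMI above the scaled threshold)
    votes: set[tuple[str, str]] = set()
    for z in nodes:
        nbrs = sorted(skeleton.neighbors(z))
        for x, y in itertools.combinations(nbrs, 2):
            if skeleton.has_edge(x, y):
                continue
            mi = mutual_information(data, x, y) - _chi2_bias(data, x, y)
            if mi > thresholds.delta_mi:
                continue
            cmi = (conditional_mutual_information(data, x, y, {z})
                   - _chi2_bias(data, x, y, {z}))
            if cmi > thresholds.delta_orient * thresholds.delta_mi:
                votes.add((x, z))
                votes.add((y, z))
    for u, v in sorted(votes):
        if (v, u) in votes:
            # contradictory collider demands: resolve by local MDL
            s_uv = _mdl_local(data, v, state.parents(v) + (u,))
            s_vu = _mdl_local(data, u, state.parents(u) + (v,))
            winner = (u, v) if s_uv <= s_vu else (v, u)
            logger.debug("collider conflict on %s-%s resolved toward %s by MDL",
                         u, v, winner)
            if winner != (u, v):
                continue
        if state.creates_cycle(u, v):
            logger.debug("collider orientation %s->%s would close a cycle; skipped",
                         u, v)
            continue
        state.orient(u, v)

    # stage 2: propagation (Meek rules 1-2 + acyclicity forcing)
    changed = True
    while changed:
        changed = False
        for key in sorted(state.undirected, key=sorted):
            a, b = sorted(key)
            for u, v in ((a, b), (b, a)):
                # rule 1: x -> u, u - v, x and v non-adjacent  =>  u -> v
                r1 = any(
                    state.is_directed(x, u) and not skeleton.has_edge(x, v)
                    for x in skeleton.neighbors(u) if x != v
                )
                # rule 2 / acyclicity: directed path u ->* v exists => u -> v
                r2 = state.creates_cycle(v, u)
                # rule 3: u - x -> v and u - y -> v with x, y non-adjacent
                # => u -> v (avoids a new collider either way)
                into_v = [x for x in skeleton.neighbors(u)
                          if x != v and state.is_directed(x, v)
                          and frozenset((u, x)) in state.undirected]
                r3 = any(
                    not skeleton.has_edge(x, y)
                    for i, x in enumerate(into_v) for y in into_v[i + 1:]
                )
                if r1 or r2 or r3:
                    if state.creates_cycle(u, v):
                        continue
                    state.orient(u, v)
                    changed = True
                    break

    # stage 3: local MDL for the rest
    for key in sorted(state.undirected, key=sorted):
        u, v = sorted(key)
        s_uv = (_mdl_local(data, v, state.parents(v) + (u,))
                + _mdl_local(data, u, state.parents(u)))
        s_vu = (_mdl_local(data, u, state.parents(u) + (v,))
                + _mdl_local(data, v, state.parents(v)))
        if abs(s_uv - s_vu) <= 1e-9:
            choice = (u, v)  # tie-break: lexicographically smaller parent
        else:
            choice = (u, v) if s_uv < s_vu else (v, u)
        if state.creates_cycle(*choice):
            choice = (choice[1], choice[0])
        state.orient(*choice)

    dag = DAG(nodes=nodes)
    for u, v in sorted(state.directed):
        dag.add_edge(u, v)
    dag.check_acyclic()
    return dag


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def learn_parameters(data: DiscreteDataset, dag: DAG) -> BayesianNetwork:
    """Maximum-likelihood CPT estimation on a fixed structure.

    P(x | pa) = count(x, pa) / count(pa); parent configurations never
    observed receive the uniform distribution (logged). The network
    weight is the sample count, and each CPT records its per-
    configuration counts for count-weighted aggregation.
    """
    if not dag.nodes <= set(data.names):
        raise ContractError(
            f"DAG nodes not in dataset: {sorted(dag.nodes - set(data.names))}"
        )
    if data.n_samples == 0:
        raise ContractError("cannot estimate parameters from an empty dataset")
    cpts: dict[str, CPT] = {}
    for node in sorted(dag.nodes):
        child = data.variable(node)
        parents = tuple(data.variable(p) for p in dag.parents(node))
        card = child.cardinality
        xi = data.column(node)
        if parents:
            dims = tuple(p.cardinality for p in parents)
            cfg = np.ravel_multi_index(
                tuple(data.columns([p.name for p in parents]).T), dims
            )
            n_cfg = int(np.prod(dims))
        else:
            dims = ()
            cfg = np.zeros(data.n_samples, dtype=np.int64)
            n_cfg = 1
        counts = np.bincount(cfg * card + xi, minlength=n_cfg * card)
        counts = counts.reshape(n_cfg, card).astype(float)
        row_tot = counts.sum(axis=1)
        empty = row_tot == 0
        if empty.any():
            logger.debug(
                "node %s: %d unobserved parent configurations set to uniform",
                node, int(empty.sum()),
            )
        table = np.empty_like(counts)
        table[~empty] = counts[~empty] / row_tot[~empty, None]
        table[empty] = 1.0 / card
        cpts[node] = CPT(
            child=child,
            parents=parents,
            table=table.reshape(dims + (card,)),
            config_counts=row_tot.reshape(dims) if dims else row_tot.reshape(()),
        )
    bn = BayesianNetwork(dag=dag.copy(), cpts=cpts, weight=data.n_samples)
    bn.validate()
    return bn


def learn_bn(
    data: DiscreteDataset, thresholds: Thresholds | None = None
) -> BayesianNetwork:
    """Full pipeline: draft, thicken, thin, orient, estimate parameters."""
    thresholds = thresholds or Thresholds()
    if len(data.variables) == 1:
        dag = DAG(nodes=data.names)
        return learn_parameters(data, dag)
    graph, remaining = draft_mwst(data, thresholds)
    graph = thicken(graph, remaining, data, thresholds)
    graph = thin(graph, data, thresholds)
    dag = orient_edges(graph, data, thresholds)
    return learn_parameters(data, dag)
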