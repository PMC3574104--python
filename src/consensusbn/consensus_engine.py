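"""Whole-network combination, prior-order alignment, and extension of a
network onto a larger variable set.

Combination of two networks over the same variables proceeds node by
node: extend both CPTs to a common form, aggregate them with the
networks' weights, then remove bogus parents by the variance test and
rebuild the DAG from the surviving parent sets. Networks whose prior
orders conflict are first aligned by joint-preserving edge reversal.
A network over a subset of another's variables is extended onto the
full variable set before combination, borrowing conditionals from the
reference network via exact inference.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

from .cpt_algebra import (
    AggregationSpec,
    aggregate_cpts,
    canonical_parent_order,
    common_form,
    simplify_cpt,
)
from .errors import AlignmentError, ContractError, ZeroEvidenceError
from .model_core import (
    CPT,
    DAG,
    TAG_EXTENDED,
    BayesianNetwork,
    Variable,
    infer_distribution,
    orders_consistent,
    topological_order,
    union_dag,
)

logger = logging.getLogger(__name__)

__all__ = [
    "reverse_edge",
    "align_prior_orders",
    "combine_same_variables",
    "extend_bn",
    "combine",
]


def reverse_edge(bn: BayesianNetwork, u: str, v: str) -> BayesianNetwork:
    """Reverse edge u -> v while preserving the joint distribution.

    Arc reversal: both endpoints inherit the union of the two parent
    sets (u additionally gains v). For a covered edge
    (Pa(v) = Pa(u) + {u}) no parent is added and this reduces to Bayes'
    rule. Reversal is refused when another directed path u ->* v exists,
    since the result would be cyclic.
    """
    if (u, v) not in bn.dag.edges:
        raise ContractError(f"edge {u!r}->{v!r} not in the network")
    probe = bn.dag.copy()
    probe.remove_edge(u, v)
    if probe.has_path(u, v):
        raise AlignmentError(
            f"cannot reverse {u!r}->{v!r}: another directed path exists",
            conflicting_edges=[(u, v)],
        )

    cpt_u, cpt_v = bn.cpts[u], bn.cpts[v]
    a_names = tuple(cpt_u.parent_names)                       # Pa(u)
    b_names = tuple(n for n in cpt_v.parent_names if n != u)  # Pa(v) - {u}
    s_names = tuple(sorted(set(a_names) | set(b_names)))
    by_name = {p.name: p for p in cpt_u.parents + cpt_v.parents}
    s_vars = tuple(by_name[n] for n in s_names)
    var_u, var_v = cpt_u.child, cpt_v.child
    cu, cv = var_u.cardinality, var_v.cardinality

    s_dims = tuple(p.cardinality for p in s_vars)
    new_v_table = np.empty(s_dims + (cv,))
    new_u_table = np.empty(s_dims + (cv, cu))  # parents of u: S + (v,)

    pos = {n: i for i, n in enumerate(s_names)}
    for cfg in itertools.product(*(range(d) for d in s_dims)):
        a_cfg = tuple(cfg[pos[n]] for n in a_names)
        p_u = cpt_u.table[a_cfg]                                   # (cu,)
        rows_v = np.empty((cu, cv))
        for iu in range(cu):
            v_cfg = tuple(
                iu if n == u else cfg[pos[n]] for n in cpt_v.parent_names
            )
            rows_v[iu] = cpt_v.table[v_cfg]
        joint = p_u[:, None] * rows_v                              # (cu, cv)
        marg_v = joint.sum(axis=0)
        new_v_table[cfg] = marg_v
        with np.errstate(invalid="ignore", divide="ignore"):
            cond_u = np.where(marg_v[None, :] > 0,
                              joint / marg_v[None, :], 1.0 / cu)
        new_u_table[cfg] = cond_u.T  # axes: (v, u)

    dag = bn.dag.copy()
    dag.remove_edge(u, v)
    dag.add_edge(v, u)
    for s in s_names:
        if (s, v) not in dag.edges:
            dag.add_edge(s, v)
        if (s, u) not in dag.edges:
            dag.add_edge(s, u)

    cpts = dict(bn.cpts)
    cpts[v] = CPT(var_v, s_vars, new_v_table)
    cpts[u] = CPT(var_u, s_vars + (var_v,), new_u_table)
    out = BayesianNetwork(dag=dag, cpts=cpts, weight=bn.weight)
    out.validate()
    return out


def _shortest_alternate_path(dag: DAG, u: str, v: str) -> list[str] | None:
    """Shortest directed u ->* v path ignoring the direct edge (u, v)."""
    from collections import deque

    succ: dict[str, list[str]] = {n: [] for n in dag.nodes}
    for a, b in dag.edges:
        if (a, b) != (u, v):
            succ[a].append(b)
    prev: dict[str, str] = {}
    queue = deque([u])
    seen = {u}
    while queue:
        cur = queue.popleft()
        for nxt in sorted(succ[cur]):
            if nxt in seen:
                continue
            prev[nxt] = cur
            if nxt == v:
                path = [v]
                while path[-1] != u:
                    path.append(prev[path[-1]])
                return path[::-1]
            seen.add(nxt)
            queue.append(nxt)
    return None


def _reverse_unblocking(
    bn: BayesianNetwork, u: str, v: str, budget: list[int]
) -> BayesianNetwork:
    """Reverse u -> v, first clearing alternate u ->* v paths by
    recursively reversing the blocking in-edges of v. Every step is a
    joint-preserving arc reversal; ``budget`` caps the total count."""
    while True:
        if budget[0] <= 0:
            raise AlignmentError(
                f"reversal budget exhausted while clearing paths for "
                f"{u!r}->{v!r}", conflicting_edges=[(u, v)],
            )
        path = _shortest_alternate_path(bn.dag, u, v)
        if path is None:
            budget[0] -= 1
            return reverse_edge(bn, u, v)
        bn = _reverse_unblocking(bn, path[-2], v, budget)


def align_prior_orders(
    bn_fixed: BayesianNetwork, bn_adjust: BayesianNetwork
) -> BayesianNetwork:
    """Reverse edges of ``bn_adjust`` until its prior order is consistent
    with ``bn_fixed``'s, preserving the represented joint distribution.

    Conflicting edges are removed one union-cycle at a time by arc
    reversal (with recursive unblocking of alternate paths). Returns
    ``bn_adjust`` unchanged when already consistent; raises
    :class:`AlignmentError` when no joint-preserving reversal sequence
    resolves the conflicts within the reversal budget.

    ``bn_adjust`` may be defined over a subset of ``bn_fixed``'s
    variables (alignment before extension).
    """
    if not bn_adjust.nodes <= bn_fixed.nodes:
        raise ContractError(
            "alignment requires the adjusted network's variables to be "
            "contained in the fixed network's"
        )
    current = bn_adjust
    budget = [4 * len(bn_adjust.nodes) ** 2 + 16]
    while True:
        union = DAG.__new__(DAG)
        union._nodes = bn_fixed.dag.nodes | current.dag.nodes
        union._edges = bn_fixed.dag.edges | current.dag.edges
        union.edge_tags = {}
        cycle = union.find_cycle()
        if cycle is None:
            return current
        cycle_edges = list(zip(cycle, cycle[1:] + cycle[:1]))
        adjust_edges = sorted(
            e for e in cycle_edges
            if e in current.dag.edges and e not in bn_fixed.dag.edges
        )
        if not adjust_edges:
            raise AlignmentError(
                "prior-order conflict lies entirely in the fixed network: "
                f"cycle {cycle}",
                conflicting_edges=cycle_edges,
            )
        last_error: AlignmentError | None = None
        for edge in adjust_edges:
            try:
                current = _reverse_unblocking(current, *edge, budget=budget)
            except AlignmentError as exc:
                last_error = exc
                continue
            logger.debug("reversed %s->%s to restore prior-order consistency",
                         *edge)
            break
        else:
            raise AlignmentError(
                f"no reversible edge in conflict cycle {cycle}",
                conflicting_edges=adjust_edges,
            ) from last_error


def combine_same_variables(
    bn1: BayesianNetwork, bn2: BayesianNetwork, spec: AggregationSpec
) -> BayesianNetwork:
    """Combine two networks defined over the same variable set.

    Per node: common form, weighted aggregation, variance-test
    simplification. The consensus DAG is rebuilt from the surviving
    parent sets; it is acyclic because every parent respects the shared
    prior order.
    """
    if bn1.nodes != bn2.nodes:
        raise ContractError("networks are defined over different variable sets")
    for name in sorted(bn1.nodes):
        if bn1.var(name).states != bn2.var(name).states:
            raise ContractError(f"variable {name!r} has conflicting state spaces")
    if len(spec.weights) != 2:
        raise ContractError("combine_same_variables expects exactly two weights")
    if not orders_consistent(bn1.dag, bn2.dag):
        raise ContractError(
            "prior orders are inconsistent; call align_prior_orders first"
        )

    prior = topological_order(union_dag(bn1.dag, bn2.dag))
    dag = DAG(nodes=bn1.nodes)
    cpts: dict[str, CPT] = {}
    for name in sorted(bn1.nodes):
        cA, cB = common_form(bn1.cpts[name], bn2.cpts[name], order=prior)
        agg = aggregate_cpts([cA, cB], spec)
        # only extension-introduced parents are bogus candidates; a parent
        # learned independently in both networks is never pruned
        simplified, removed = simplify_cpt(agg, spec.epsilon_var,
                                           candidates=agg.bogus)
        if removed:
            logger.debug("node %s: bogus parents removed: %s",
                         name, sorted(removed))
        cpts[name] = simplified
        for parent in simplified.parent_names:
            dag.add_edge(parent, name)
    dag.check_acyclic()
    out = BayesianNetwork(dag=dag, cpts=cpts,
                          weight=int(sum(spec.weights)))
    out.validate()
    return out


def _conditional_from_ref(
    ref: BayesianNetwork,
    query: str,
    evidence: dict[str, int],
) -> np.ndarray | None:
    try:
        return infer_distribution(ref, query, evidence)
    except ZeroEvidenceError:
        return None


def extend_bn(
    bn_small: BayesianNetwork, bn_ref: BayesianNetwork
) -> BayesianNetwork:
    """Extend a network onto the (super)set of variables of a reference.

    Step 1 adds the missing variables plus every reference edge incident
    to them (tagged ``extended``). Step 2 fills in CPTs: unchanged nodes
    keep their CPT, new nodes copy the reference CPT, and old nodes that
    gained parents get rows built from the small network's conditional
    updated by the reference network's likelihood ratio for the new
    parents (computed by exact inference), with the reference conditional
    as fallback on zero-probability contexts.
    """
    small_vars = set(bn_small.nodes)
    ref_vars = set(bn_ref.nodes)
    if small_vars == ref_vars:
        return bn_small
    if not small_vars < ref_vars:
        raise ContractError(
            "extension requires the small network's variables to be a "
            f"subset of the reference's (extra: {sorted(small_vars - ref_vars)})"
        )
    for name in sorted(small_vars):
        if bn_small.var(name).states != bn_ref.var(name).states:
            raise ContractError(f"variable {name!r} has conflicting state spaces")
    if not orders_consistent(bn_small.dag, bn_ref.dag):
        raise AlignmentError(
            "prior orders of the two networks are inconsistent",
            conflicting_edges=sorted(bn_small.dag.edges ^ bn_ref.dag.edges),
        )

    new_vars = ref_vars - small_vars

    # Step 1: structure
    dag = bn_small.dag.copy()
    for name in sorted(new_vars):
        dag.add_node(name)
    for u, v in sorted(bn_ref.dag.edges):
        if (u in new_vars or v in new_vars) and (u, v) not in dag.edges:
            dag.add_edge(u, v, tag=TAG_EXTENDED)
    dag.check_acyclic()
    prior = topological_order(union_dag(bn_small.dag, bn_ref.dag))

    # Step 2: CPTs
    cpts: dict[str, CPT] = {}
    for name in sorted(dag.nodes):
        parents_here = dag.parents(name)
        if name in new_vars:
            cpts[name] = bn_ref.cpts[name]  # parents equal Pa_ref(name)
            continue
        old_parents = set(bn_small.cpts[name].parent_names)
        new_parents = set(parents_here) - old_parents
        if not new_parents:
            cpts[name] = bn_small.cpts[name]
            continue
        cpts[name] = _extended_cpt_rows(
            bn_small, bn_ref, name, sorted(old_parents), sorted(new_parents),
            prior,
        )

    out = BayesianNetwork(dag=dag, cpts=cpts, weight=bn_small.weight)
    out.validate()
    return out


def _block_case(ref: BayesianNetwork, block_a: set[str], block_b: set[str]) -> str:
    """Connectivity of the old-parent and new-parent blocks in the
    reference DAG: 'a' (edge A->B), 'b' (edge B->A) or 'c' (disconnected)."""
    edges = ref.dag.edges
    a_to_b = any((a, b) in edges for a in block_a for b in block_b)
    b_to_a = any((b, a) in edges for a in block_a for b in block_b)
    if a_to_b:
        return "a"
    if b_to_a:
        return "b"
    return "c"


def _extended_cpt_rows(
    bn_small: BayesianNetwork,
    bn_ref: BayesianNetwork,
    node: str,
    old_parents: list[str],
    new_parents: list[str],
    prior: list[str],
) -> CPT:
    """Conditional rows for an old node that gained extended in-edges.

    For each configuration (a of the old parents, b of the new):

        P(x | a, b)  ∝  P_small(x | a) * P_ref(x | a, b) / P_ref(x | a)

    i.e. the small network's conditional, updated by the reference
    network's likelihood ratio for the new evidence b. The three
    block-connectivity situations (edge from old block to new, the
    reverse, or disconnected blocks) share this update; for disconnected
    blocks it reduces to the independence form. Rows are renormalised;
    deviations beyond 1e-3 and zero-probability fallbacks are logged.
    """
    case = _block_case(bn_ref, set(old_parents), set(new_parents))
    logger.debug("extending CPT of %s: old=%s new=%s (situation %s)",
                 node, old_parents, new_parents, case)

    small_cpt = bn_small.cpts[node]
    child = small_cpt.child
    all_names = canonical_parent_order(old_parents + new_parents, prior)
    by_name = {p.name: p for p in small_cpt.parents}
    for n in new_parents:
        by_name[n] = bn_ref.var(n)
    parents = tuple(by_name[n] for n in all_names)
    dims = tuple(p.cardinality for p in parents)
    table = np.empty(dims + (child.cardinality,))
    pos = {n: i for i, n in enumerate(all_names)}

    for cfg in itertools.product(*(range(d) for d in dims)):
        a_ev = {n: cfg[pos[n]] for n in old_parents}
        b_ev = {n: cfg[pos[n]] for n in new_parents}
        small_cfg = tuple(cfg[pos[n]] for n in small_cpt.parent_names)
        p_small = small_cpt.table[small_cfg]

        q_ab = _conditional_from_ref(bn_ref, node, {**a_ev, **b_ev})
        if q_ab is None:
            q_b = _conditional_from_ref(bn_ref, node, b_ev)
            row = q_b if q_b is not None else p_small
            logger.debug(
                "node %s, config %s: zero-probability context in the "
                "reference; using fallback conditional", node, cfg,
            )
            table[cfg] = row / row.sum()
            continue
        # in situation 'c' (disconnected blocks) P_ref(b | a) = P_ref(b)
        # and the update reduces to the independence form; the ratio
        # computation below covers all three situations
        q_a = _conditional_from_ref(bn_ref, node, a_ev)
        if q_a is None:
            table[cfg] = q_ab
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(q_a > 0, p_small * q_ab / np.maximum(q_a, 1e-300), 0.0)
        total = float(row.sum())
        if total <= 0:
            logger.debug("node %s, config %s: degenerate ratio row; "
                         "falling back to the reference conditional", node, cfg)
            table[cfg] = q_ab
            continue
        if abs(total - 1.0) > 1e-3:
            logger.debug("node %s, config %s: row sum %.4f before "
                         "renormalisation", node, cfg, total)
        table[cfg] = row / total

    return CPT(child, parents, table)


def combine(
    bn1: BayesianNetwork, bn2: BayesianNetwork, spec: AggregationSpec
) -> BayesianNetwork:
    """Combine two networks whose variable sets are equal or nested.

    Nested sets: the smaller network is first extended against the
    larger, then the same-variable combination applies. Conflicting
    prior orders are aligned automatically (the first network is held
    fixed; if that fails, the roles are swapped).
    """
    v1, v2 = set(bn1.nodes), set(bn2.nodes)
    if v1 != v2 and not (v1 < v2 or v2 < v1):
        raise ContractError(
            "unsupported combination: variable sets are neither equal nor "
            f"nested (only in first: {sorted(v1 - v2)}, "
            f"only in second: {sorted(v2 - v1)})"
        )
    if v1 < v2:
        if not orders_consistent(bn1.dag, bn2.dag):
            bn1 = align_prior_orders(bn2, bn1)
        bn1 = extend_bn(bn1, bn2)
    elif v2 < v1:
        if not orders_consistent(bn1.dag, bn2.dag):
            bn2 = align_prior_orders(bn1, bn2)
        bn2 = extend_bn(bn2, bn1)

    if not orders_consistent(bn1.dag, bn2.dag):
        # adjust the less reliable (lower-weight) network first; reversal
        # preserves its joint, so the weight mapping is unaffected
        if spec.weights[0] >= spec.weights[1]:
            try:
                bn2 = align_prior_orders(bn1, bn2)
            except AlignmentError:
                bn1 = align_prior_orders(bn2, bn1)
        else:
            try:
                bn1 = align_prior_orders(bn2, bn1)
            except AlignmentError:
                bn2 = align_prior_orders(bn1, bn2)
    return combine_same_variables(bn1, bn2, spec)
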