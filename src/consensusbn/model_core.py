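"""Core representations of discrete Bayesian networks.

Provides the in-memory model types (:class:`Variable`, :class:`DAG`,
:class:`CPT`, :class:`BayesianNetwork`, :class:`DiscreteDataset`),
seeded forward sampling, exact inference by variable elimination, and
the chain-rule joint probability used by the test oracles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ContractError,
    ModelError,
    StructuralError,
    ZeroEvidenceError,
)

__all__ = [
    "Variable",
    "DAG",
    "CPT",
    "BayesianNetwork",
    "DiscreteDataset",
    "topological_order",
    "orders_consistent",
    "forward_sample",
    "infer_distribution",
    "joint_probability",
]

_ROW_TOL = 1e-9

# edge tag values used throughout the package
TAG_NORMAL = "normal"
TAG_BOGUS = "bogus"
TAG_EXTENDED = "extended"


@dataclass(frozen=True)
class Variable:
    """A named categorical variable with an ordered state space."""

    name: str
    states: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        if len(set(self.states)) != len(self.states):
            raise ModelError(f"variable {self.name!r} has duplicate state labels")
        if not self.states:
            raise ModelError(f"variable {self.name!r} has an empty state space")

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def index_of(self, state) -> int:
        """Map a state label (or an already-valid index) to its index."""
        if isinstance(state, (int, np.integer)):
            idx = int(state)
            if not 0 <= idx < self.cardinality:
                raise ContractError(
                    f"state index {idx} out of range for variable {self.name!r}"
                )
            return idx
        try:
            return self.states.index(str(state))
        except ValueError:
            raise ContractError(
                f"unknown state {state!r} for variable {self.name!r} "
                f"(states: {list(self.states)})"
            ) from None


class DAG:
    """A directed acyclic graph over named nodes with optional edge tags."""

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
        edge_tags: Mapping[tuple[str, str], str] | None = None,
    ):
        self._nodes: set[str] = set(nodes)
        self._edges: set[tuple[str, str]] = set()
        self.edge_tags: dict[tuple[str, str], str] = {}
        for u, v in edges:
            self.add_edge(u, v)
        if edge_tags:
            for e, tag in edge_tags.items():
                self.tag_edge(e[0], e[1], tag)
        self.check_acyclic()

    # -- construction ------------------------------------------------------
    def add_node(self, name: str) -> None:
        self._nodes.add(name)

    def add_edge(self, u: str, v: str, tag: str = TAG_NORMAL) -> None:
        if u == v:
            raise StructuralError(f"self-loop on {u!r}")
        if (u, v) in self._edges:
            raise StructuralError(f"duplicate edge {u!r}->{v!r}")
        self._nodes.update((u, v))
        self._edges.add((u, v))
        if tag != TAG_NORMAL:
            self.edge_tags[(u, v)] = tag

    def remove_edge(self, u: str, v: str) -> None:
        self._edges.discard((u, v))
        self.edge_tags.pop((u, v), None)

    def copy(self) -> "DAG":
        new = DAG.__new__(DAG)
        new._nodes = set(self._nodes)
        new._edges = set(self._edges)
        new.edge_tags = dict(self.edge_tags)
        return new

    # -- queries -----------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self._nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._edges)

    def tag(self, u: str, v: str) -> str:
        return self.edge_tags.get((u, v), TAG_NORMAL)

    def tag_edge(self, u: str, v: str, tag: str) -> None:
        if (u, v) not in self._edges:
            raise StructuralError(f"edge {u!r}->{v!r} not present")
        if tag == TAG_NORMAL:
            self.edge_tags.pop((u, v), None)
        else:
            self.edge_tags[(u, v)] = tag

    def parents(self, node: str) -> list[str]:
        return sorted(u for (u, v) in self._edges if v == node)

    def children(self, node: str) -> list[str]:
        return sorted(v for (u, v) in self._edges if u == node)

    def has_path(self, u: str, v: str) -> bool:
        """True if a directed path u ->* v exists."""
        stack, seen = [u], set()
        while stack:
            cur = stack.pop()
            if cur == v:
                return True
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(w for (s, w) in self._edges if s == cur)
        return False

    def find_cycle(self) -> list[str] | None:
        """Return one directed cycle as a node list, or None."""
        color = {n: 0 for n in self._nodes}  # 0 white, 1 grey, 2 black
        parent: dict[str, str] = {}
        succ = {n: sorted(v for (u, v) in self._edges if u == n) for n in self._nodes}

        for root in sorted(self._nodes):
            if color[root]:
                continue
            stack = [(root, iter(succ[root]))]
            color[root] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if color[nxt] == 0:
                        color[nxt] = 1
                        parent[nxt] = node
                        stack.append((nxt, iter(succ[nxt])))
                        advanced = True
                        break
                    if color[nxt] == 1:  # back edge: recover the cycle
                        cycle = [nxt, node]
                        cur = node
                        while cur != nxt:
                            cur = parent[cur]
                            cycle.append(cur)
                        cycle.reverse()
                        return cycle[:-1]
                if not advanced:
                    color[node] = 2
                    stack.pop()
        return None

    def is_acyclic(self) -> bool:
        return self.find_cycle() is None

    def check_acyclic(self) -> None:
        cycle = self.find_cycle()
        if cycle is not None:
            raise StructuralError(f"cycle detected: {' -> '.join(cycle + cycle[:1])}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, DAG):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return f"DAG(nodes={sorted(self._nodes)}, edges={sorted(self._edges)})"


def topological_order(dag: DAG) -> list[str]:
    """Deterministic topological order (Kahn's algorithm, lexicographic ties).

    The returned order is the network's *prior order*: every edge (u, v)
    has u before v.
    """
    import heapq

    indeg = {n: 0 for n in dag.nodes}
    for _, v in dag.edges:
        indeg[v] += 1
    heap = [n for n, d in indeg.items() if d == 0]
    heapq.heapify(heap)
    out: list[str] = []
    succ: dict[str, list[str]] = {n: [] for n in dag.nodes}
    for u, v in dag.edges:
        succ[u].append(v)
    while heap:
        n = heapq.heappop(heap)
        out.append(n)
        for v in sorted(succ[n]):
            indeg[v] -= 1
            if indeg[v] == 0:
                heapq.heappush(heap, v)
    if len(out) != len(dag.nodes):
        dag.check_acyclic()  # raises with a named cycle
    return out


def orders_consistent(dag1: DAG, dag2: DAG) -> bool:
    """True iff the two DAGs' prior orders are mutually consistent.

    Consistency is defined on the union graph: nodes(1) ∪ nodes(2),
    edges(1) ∪ edges(2) must be acyclic.
    """
    union = DAG.__new__(DAG)
    union._nodes = dag1.nodes | dag2.nodes
    union._edges = dag1.edges | dag2.edges
    union.edge_tags = {}
    return union.is_acyclic()


def union_dag(dag1: DAG, dag2: DAG) -> DAG:
    """The union graph of two order-consistent DAGs."""
    union = DAG.__new__(DAG)
    union._nodes = dag1.nodes | dag2.nodes
    union._edges = dag1.edges | dag2.edges
    union.edge_tags = {}
    union.check_acyclic()
    return union


@dataclass(frozen=True)
class CPT:
    """Conditional probability table P(child | parents).

    ``table`` has shape ``(*parent_cardinalities, child_cardinality)``;
    axis order follows ``parents``. ``bogus`` names parents introduced by
    CPT extension. ``config_counts`` (optional, same shape as the parent
    axes) carries the number of samples observed per parent configuration
    when the table was estimated from data; it enables the exact
    merged-database aggregation identity.
    """

    child: Variable
    parents: tuple[Variable, ...]
    table: np.ndarray
    bogus: frozenset[str] = frozenset()
    config_counts: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "parents", tuple(self.parents))
        tab = np.asarray(self.table, dtype=float)
        expected = tuple(p.cardinality for p in self.parents) + (
            self.child.cardinality,
        )
        if tab.shape != expected:
            raise ModelError(
                f"CPT for {self.child.name!r}: table shape {tab.shape} != "
                f"expected {expected}"
            )
        object.__setattr__(self, "table", tab)
        object.__setattr__(self, "bogus", frozenset(self.bogus))
        if self.config_counts is not None:
            cc = np.asarray(self.config_counts, dtype=float)
            if cc.shape != expected[:-1]:
                raise ModelError(
                    f"CPT for {self.child.name!r}: config_counts shape "
                    f"{cc.shape} != parent shape {expected[:-1]}"
                )
            object.__setattr__(self, "config_counts", cc)

    @property
    def parent_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parents)

    def validate(self) -> None:
        if np.any(self.table < -_ROW_TOL) or np.any(self.table > 1 + _ROW_TOL):
            raise ModelError(f"CPT for {self.child.name!r}: probability out of [0,1]")
        sums = self.table.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=_ROW_TOL, rtol=0):
            worst = float(np.abs(sums - 1).max())
            raise ModelError(
                f"CPT for {self.child.name!r}: row sums deviate from 1 "
                f"by up to {worst:.3g}"
            )

    def row(self, config: Sequence[int]) -> np.ndarray:
        """Conditional distribution for one full parent configuration."""
        if len(config) != len(self.parents):
            raise ContractError(
                f"CPT for {self.child.name!r}: configuration length "
                f"{len(config)} != {len(self.parents)} parents"
            )
        return self.table[tuple(int(c) for c in config)]

    def configurations(self):
        """Iterate (config_tuple, row) over the parent Cartesian product."""
        ranges = [range(p.cardinality) for p in self.parents]
        for cfg in itertools.product(*ranges):
            yield cfg, self.table[cfg]

    def with_table(self, table: np.ndarray, **kw) -> "CPT":
        return replace(self, table=table, **kw)


@dataclass(frozen=True)
class BayesianNetwork:
    """A DAG, one CPT per node, and a positive integer weight (belief)."""

    dag: DAG
    cpts: Mapping[str, CPT]
    weight: int = 1

    def __post_init__(self):
        object.__setattr__(self, "cpts", dict(self.cpts))

    @property
    def variables(self) -> dict[str, Variable]:
        return {name: cpt.child for name, cpt in self.cpts.items()}

    @property
    def nodes(self) -> set[str]:
        return self.dag.nodes

    def var(self, name: str) -> Variable:
        try:
            return self.cpts[name].child
        except KeyError:
            raise ContractError(f"unknown variable {name!r}") from None

    def validate(self) -> None:
        if int(self.weight) < 1:
            raise ModelError(f"network weight must be >= 1, got {self.weight}")
        if set(self.cpts) != self.dag.nodes:
            missing = self.dag.nodes - set(self.cpts)
            extra = set(self.cpts) - self.dag.nodes
            raise ModelError(
                f"CPT/DAG node mismatch (missing CPTs: {sorted(missing)}, "
                f"CPTs without node: {sorted(extra)})"
            )
        self.dag.check_acyclic()
        for name, cpt in self.cpts.items():
            if cpt.child.name != name:
                raise ModelError(f"CPT registered under {name!r} is for "
                                 f"{cpt.child.name!r}")
            if list(cpt.parent_names) != sorted(cpt.parent_names):
                pass  # parent order is canonical, not sorted; no constraint here
            if set(cpt.parent_names) != set(self.dag.parents(name)):
                raise ModelError(
                    f"node {name!r}: CPT parents {sorted(cpt.parent_names)} != "
                    f"DAG parents {self.dag.parents(name)}"
                )
            cpt.validate()

    def prior_order(self) -> list[str]:
        return topological_order(self.dag)


@dataclass
class DiscreteDataset:
    """Named categorical variables plus rows of state indices."""

    variables: list[Variable]
    rows: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=np.int64))

    def __post_init__(self):
        self.variables = list(self.variables)
        rows = np.asarray(self.rows, dtype=np.int64)
        if rows.size == 0:
            rows = rows.reshape(0, len(self.variables))
        if rows.ndim != 2 or rows.shape[1] != len(self.variables):
            raise ModelError(
                f"rows shape {rows.shape} incompatible with "
                f"{len(self.variables)} variables"
            )
        for j, var in enumerate(self.variables):
            col = rows[:, j]
            if col.size and (col.min() < 0 or col.max() >= var.cardinality):
                raise ModelError(
                    f"column {var.name!r} contains state indices outside "
                    f"[0, {var.cardinality})"
                )
        self.rows = rows
        self._index = {v.name: j for j, v in enumerate(self.variables)}
        if len(self._index) != len(self.variables):
            raise ModelError("duplicate variable names in dataset")

    @property
    def n_samples(self) -> int:
        return int(self.rows.shape[0])

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable(self, name: str) -> Variable:
        try:
            return self.variables[self._index[name]]
        except KeyError:
            raise ContractError(f"variable {name!r} not in dataset") from None

    def column(self, name: str) -> np.ndarray:
        return self.rows[:, self._index[name]]

    def columns(self, names: Sequence[str]) -> np.ndarray:
        return self.rows[:, [self._index[n] for n in names]]

    def subset_rows(self, idx) -> "DiscreteDataset":
        return DiscreteDataset(self.variables, self.rows[idx])

    def select(self, names: Sequence[str]) -> "DiscreteDataset":
        cols = [self._index[n] for n in names]
        return DiscreteDataset([self.variables[c] for c in cols],
                               self.rows[:, cols])

    def concat(self, other: "DiscreteDataset") -> "DiscreteDataset":
        if [v.name for v in other.variables] != self.names:
            raise ContractError("datasets have different variable lists")
        for a, b in zip(self.variables, other.variables):
            if a.states != b.states:
                raise ModelError(f"state spaces differ for {a.name!r}")
        return DiscreteDataset(self.variables,
                               np.vstack([self.rows, other.rows]))

    def to_dataframe(self):
        import pandas as pd

        data = {
            v.name: [v.states[i] for i in self.rows[:, j]]
            for j, v in enumerate(self.variables)
        }
        return pd.DataFrame(data, columns=self.names)

    @classmethod
    def from_dataframe(cls, df, state_spaces: Mapping[str, Sequence[str]] | None = None):
        """Build a dataset from a label-valued DataFrame.

        State spaces default to the sorted distinct labels per column.
        """
        variables, cols = [], []
        for name in df.columns:
            labels = df[name].astype(str)
            states = (tuple(state_spaces[name]) if state_spaces and name in state_spaces
                      else tuple(sorted(labels.unique())))
            var = Variable(str(name), states)
            lut = {s: i for i, s in enumerate(states)}
            try:
                cols.append(labels.map(lut).to_numpy(dtype=np.int64))
            except (TypeError, ValueError):
                raise ModelError(f"column {name!r} contains states outside "
                                 f"its declared space") from None
            if np.isnan(labels.map(lut).to_numpy(dtype=float)).any():
                raise ModelError(f"column {name!r} contains states outside "
                                 f"its declared space")
            variables.append(var)
        rows = (np.column_stack(cols) if cols else
                np.empty((len(df), 0), dtype=np.int64))
        return cls(variables, rows)


# ---------------------------------------------------------------------------
# forward sampling
# ---------------------------------------------------------------------------

def forward_sample(bn: BayesianNetwork, n: int, seed: int) -> DiscreteDataset:
    """Draw ``n`` i.i.d. samples by ancestral (topological-order) sampling."""
    if n < 0:
        raise ContractError(f"sample count must be >= 0, got {n}")
    bn.validate()
    order = topological_order(bn.dag)
    variables = [bn.var(name) for name in order]
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for name in order:
        cpt = bn.cpts[name]
        card = cpt.child.cardinality
        flat = cpt.table.reshape(-1, card)
        if cpt.parents:
            pa_cols = np.column_stack([cols[p] for p in cpt.parent_names])
            dims = tuple(p.cardinality for p in cpt.parents)
            cfg = np.ravel_multi_index(tuple(pa_cols.T), dims)
        else:
            cfg = np.zeros(n, dtype=np.int64)
        cum = np.cumsum(flat, axis=1)
        u = rng.random(n)
        cols[name] = np.minimum(
            (u[:, None] > cum[cfg]).sum(axis=1), card - 1
        ).astype(np.int64)
    rows = (np.column_stack([cols[name] for name in order]) if order
            else np.empty((n, 0), dtype=np.int64))
    return DiscreteDataset(variables, rows)


# ---------------------------------------------------------------------------
# exact inference: variable elimination
# ---------------------------------------------------------------------------

class _Factor:
    __slots__ = ("vars", "values")

    def __init__(self, vars: tuple[str, ...], values: np.ndarray):
        self.vars = vars
        self.values = values

    def product(self, other: "_Factor") -> "_Factor":
        out_vars = list(self.vars)
        for v in other.vars:
            if v not in out_vars:
                out_vars.append(v)
        a = _expand(self, out_vars)
        b = _expand(other, out_vars)
        return _Factor(tuple(out_vars), a * b)

    def marginalize(self, var: str) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(self.vars[:ax] + self.vars[ax + 1:],
                       self.values.sum(axis=ax))


def _expand(factor: _Factor, out_vars: list[str]) -> np.ndarray:
    src = factor.values
    # permute existing axes into out_vars order, then add broadcast axes
    perm = [factor.vars.index(v) for v in out_vars if v in factor.vars]
    arr = np.transpose(src, perm)
    shape = []
    k = 0
    arr_shape = arr.shape
    for v in out_vars:
        if v in factor.vars:
            shape.append(arr_shape[k])
            k += 1
        else:
            shape.append(1)
    return arr.reshape(shape)


def _normalize_evidence(bn: BayesianNetwork, evidence: Mapping) -> dict[str, int]:
    ev = {}
    for name, state in (evidence or {}).items():
        ev[name] = bn.var(name).index_of(state)
    return ev


def infer_distribution(
    bn: BayesianNetwork,
    query: str,
    evidence: Mapping | None = None,
) -> np.ndarray:
    """Exact posterior P(query | evidence) by variable elimination.

    Elimination order is greedy min-degree on the factor interaction
    graph. Raises :class:`ZeroEvidenceError` when the evidence has
    probability zero.
    """
    ev = _normalize_evidence(bn, evidence)
    if query in ev:
        raise ContractError(f"query {query!r} appears in the evidence")
    qvar = bn.var(query)

    factors: list[_Factor] = []
    for name, cpt in bn.cpts.items():
        vars_ = cpt.parent_names + (name,)
        values = cpt.table
        # slice out observed axes
        keep_vars, idx = [], []
        for v in vars_:
            if v in ev:
                idx.append(ev[v])
            else:
                idx.append(slice(None))
                keep_vars.append(v)
        factors.append(_Factor(tuple(keep_vars), values[tuple(idx)]))

    hidden = sorted(bn.nodes - set(ev) - {query})

    # greedy min-degree elimination ordering
    neighbors: dict[str, set[str]] = {h: set() for h in hidden}
    for f in factors:
        for v in f.vars:
            if v in neighbors:
                neighbors[v].update(w for w in f.vars if w != v and w in neighbors)
    remaining = set(hidden)
    order = []
    while remaining:
        nxt = min(remaining, key=lambda v: (len(neighbors[v] & remaining), v))
        order.append(nxt)
        remaining.discard(nxt)
        nb = neighbors[nxt] & remaining
        for a in nb:
            neighbors[a].update(nb - {a})

    for var in order:
        involved = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.product(f)
        factors.append(prod.marginalize(var))

    result = _Factor((), np.array(1.0))
    for f in factors:
        result = result.product(f)
    values = result.values
    if result.vars != (query,):
        values = _expand(result, [query]).reshape(qvar.cardinality)
    total = float(values.sum())
    if total <= 0.0:
        raise ZeroEvidenceError(
            f"evidence {evidence!r} has probability zero; "
            f"P({query!r} | evidence) is undefined"
        )
    return values / total


def joint_probability(bn: BayesianNetwork, assignment: Mapping) -> float:
    """Chain-rule probability of one full assignment."""
    missing = bn.nodes - set(assignment)
    if missing:
        raise ContractError(f"assignment misses variables: {sorted(missing)}")
    idx = {name: bn.var(name).index_of(state)
           for name, state in assignment.items() if name in bn.nodes}
    p = 1.0
    for name, cpt in bn.cpts.items():
        cfg = tuple(idx[pa] for pa in cpt.parent_names)
        p *= float(cpt.table[cfg + (idx[name],)])
    return p


def enumerate_joint(bn: BayesianNetwork):
    """Yield (assignment dict, probability) over the full state space.

    Oracle helper for small networks; exponential in the node count.
    """
    names = sorted(bn.nodes)
    spaces = [range(bn.var(n).cardinality) for n in names]
    for combo in itertools.product(*spaces):
        assignment = dict(zip(names, combo))
        yield assignment, joint_probability(bn, assignment)
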