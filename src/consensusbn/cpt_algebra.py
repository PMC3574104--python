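"""CPT extension, weighted aggregation, and variance-test simplification.

This is the algebra that makes whole-network combination work: two CPTs
for the same child are *extended* onto the union of their parent sets
(replicating rows along the new, independence-justified axes), then
*aggregated* as a weight-normalised convex combination, and finally
*simplified* by removing parents whose axes the aggregate table does not
actually vary along (bogus parents).

When every input CPT carries per-configuration sample counts and the
weights are the networks' sample counts, aggregation reproduces exactly
the maximum-likelihood estimate on the merged database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError, ModelError
from .info_metrics import parent_variance_profile
from .model_core import CPT, Variable

logger = logging.getLogger(__name__)

__all__ = [
    "AggregationSpec",
    "canonical_parent_order",
    "extend_cpt",
    "common_form",
    "aggregate_cpts",
    "detect_bogus_parents",
    "simplify_cpt",
]


@dataclass(frozen=True)
class AggregationSpec:
    """Weights and simplification threshold for combining networks.

    ``weights`` are positive integers, one per input network — beliefs,
    or sample counts when known. With ``count_weighted`` (default) the
    aggregation uses per-configuration sample counts whenever every
    input CPT carries them, which makes the merged-database identity
    exact; otherwise the scalar weights apply uniformly to all rows.
    """

    weights: tuple[int, ...]
    epsilon_var: float = 8e-3
    count_weighted: bool = True

    def __post_init__(self):
        object.__setattr__(self, "weights", tuple(int(w) for w in self.weights))
        if any(w < 1 for w in self.weights):
            raise ContractError(f"weights must be >= 1, got {self.weights}")
        if self.epsilon_var < 0:
            raise ContractError("epsilon_var must be nonnegative")


def canonical_parent_order(
    names: Sequence[str], priority: Sequence[str] | None = None
) -> tuple[str, ...]:
    """Canonical ordering of a parent set.

    Follows ``priority`` (a prior order, e.g. the consensus topological
    order) where given; names absent from it — and all names when no
    priority is supplied — fall back to lexicographic order.
    """
    if priority is None:
        return tuple(sorted(names))
    rank = {name: i for i, name in enumerate(priority)}
    return tuple(sorted(names, key=lambda n: (rank.get(n, len(rank)), n)))


def extend_cpt(
    cpt: CPT,
    extra_parents: Sequence[Variable],
    order: Sequence[str] | None = None,
) -> CPT:
    """Extend a CPT with independent (bogus) parents.

    Each conditional vector is replicated unchanged across every
    configuration of the new parents; the resulting parent list follows
    :func:`canonical_parent_order`. Per-configuration counts cannot be
    carried through an extension and are dropped.
    """
    extra_parents = tuple(extra_parents)
    overlap = {p.name for p in extra_parents} & (
        set(cpt.parent_names) | {cpt.child.name}
    )
    if overlap:
        raise ContractError(
            f"extra parents overlap the CPT of {cpt.child.name!r}: "
            f"{sorted(overlap)}"
        )
    if len({p.name for p in extra_parents}) != len(extra_parents):
        raise ContractError("duplicate names in extra_parents")
    if not extra_parents:
        return cpt

    combined = list(cpt.parents) + list(extra_parents)
    by_name = {p.name: p for p in combined}
    new_names = canonical_parent_order([p.name for p in combined], order)
    new_parents = tuple(by_name[n] for n in new_names)

    # broadcast: prepend the new axes, then permute into canonical order
    extra_dims = tuple(p.cardinality for p in extra_parents)
    tmp = np.broadcast_to(cpt.table, extra_dims + cpt.table.shape)
    tmp_names = [p.name for p in extra_parents] + list(cpt.parent_names)
    perm = [tmp_names.index(n) for n in new_names] + [len(tmp_names)]
    table = np.ascontiguousarray(np.transpose(tmp, perm))

    return CPT(
        child=cpt.child,
        parents=new_parents,
        table=table,
        bogus=cpt.bogus | {p.name for p in extra_parents},
        config_counts=None,
    )


def _reorder_parents(cpt: CPT, new_names: tuple[str, ...]) -> CPT:
    if tuple(cpt.parent_names) == new_names:
        return cpt
    perm = [cpt.parent_names.index(n) for n in new_names]
    table = np.ascontiguousarray(np.transpose(cpt.table, perm + [len(perm)]))
    counts = (np.ascontiguousarray(np.transpose(cpt.config_counts, perm))
              if cpt.config_counts is not None and perm else cpt.config_counts)
    return CPT(cpt.child, tuple(cpt.parents[i] for i in perm), table,
               bogus=cpt.bogus, config_counts=counts)


def common_form(
    cptA: CPT, cptB: CPT, order: Sequence[str] | None = None
) -> tuple[CPT, CPT]:
    """Extend two CPTs of the same child onto their union parent set.

    Both results share the same canonically ordered parent list, table
    shape and configuration indexing, so corresponding entries represent
    the same conditional probability.
    """
    if cptA.child.name != cptB.child.name:
        raise ContractError(
            f"different children: {cptA.child.name!r} vs {cptB.child.name!r}"
        )
    if cptA.child.states != cptB.child.states:
        raise ModelError(
            f"child {cptA.child.name!r} has conflicting state spaces"
        )
    varsA = {p.name: p for p in cptA.parents}
    varsB = {p.name: p for p in cptB.parents}
    for name in set(varsA) & set(varsB):
        if varsA[name].states != varsB[name].states:
            raise ModelError(f"shared parent {name!r} has conflicting state spaces")

    extraA = [varsB[n] for n in sorted(set(varsB) - set(varsA))]
    extraB = [varsA[n] for n in sorted(set(varsA) - set(varsB))]
    union_names = canonical_parent_order(set(varsA) | set(varsB), order)
    outA = extend_cpt(cptA, extraA, order) if extraA else cptA
    outB = extend_cpt(cptB, extraB, order) if extraB else cptB
    return _reorder_parents(outA, union_names), _reorder_parents(outB, union_names)


def aggregate_cpts(cpts: Sequence[CPT], spec: AggregationSpec) -> CPT:
    """Weight-normalised convex combination of same-form CPTs.

    Scalar mode: every entry is sum(w_i * P_i) / sum(w_i). Count
    weighted mode (all inputs carry ``config_counts``): each row is
    weighted by the number of samples that produced it, which equals
    maximum-likelihood estimation on the concatenated databases; rows
    unobserved everywhere fall back to the scalar combination.
    """
    cpts = list(cpts)
    if not cpts:
        raise ContractError("no CPTs to aggregate")
    if len(cpts) != len(spec.weights):
        raise ContractError(
            f"{len(cpts)} CPTs but {len(spec.weights)} weights"
        )
    ref = cpts[0]
    for c in cpts[1:]:
        if (c.child.name != ref.child.name
                or c.child.states != ref.child.states
                or c.parent_names != ref.parent_names
                or c.table.shape != ref.table.shape):
            raise ContractError(
                f"CPTs for {ref.child.name!r} are not in a common form"
            )

    w = np.asarray(spec.weights, dtype=float)
    scalar = np.einsum("i,i...->...", w, np.stack([c.table for c in cpts]))
    scalar /= w.sum()

    use_counts = spec.count_weighted and all(
        c.config_counts is not None for c in cpts
    )
    if use_counts:
        counts = np.stack([c.config_counts for c in cpts])  # (k, *pa)
        num = (counts[..., None] * np.stack([c.table for c in cpts])).sum(axis=0)
        denom = counts.sum(axis=0)
        table = np.where(denom[..., None] > 0,
                         num / np.maximum(denom[..., None], 1e-300),
                         scalar)
        out_counts = denom
    else:
        table = scalar
        out_counts = None

    # absorb float error only
    table = table / table.sum(axis=-1, keepdims=True)

    # a parent extended into (bogus in) any input stays a bogus candidate
    bogus = frozenset.union(*[c.bogus for c in cpts])
    return CPT(ref.child, ref.parents, table, bogus=bogus,
               config_counts=out_counts)


# variances this small are float rounding, not structure: an epsilon of
# exactly 0 must still catch rows that are equal up to arithmetic noise
_VAR_FLOAT_TOL = 1e-24


def detect_bogus_parents(cpt: CPT, epsilon_var: float) -> set[str]:
    """Parents whose average variance profile is at or below epsilon."""
    threshold = max(epsilon_var, _VAR_FLOAT_TOL)
    return {
        p for p in cpt.parent_names
        if parent_variance_profile(cpt, p) <= threshold
    }


def _drop_parent(cpt: CPT, parent: str) -> CPT:
    axis = cpt.parent_names.index(parent)
    table = cpt.table.mean(axis=axis)
    table = table / table.sum(axis=-1, keepdims=True)
    counts = (cpt.config_counts.sum(axis=axis)
              if cpt.config_counts is not None else None)
    return CPT(
        cpt.child,
        cpt.parents[:axis] + cpt.parents[axis + 1:],
        table,
        bogus=cpt.bogus - {parent},
        config_counts=counts,
    )


def simplify_cpt(
    cpt: CPT,
    epsilon_var: float,
    candidates: Iterable[str] | None = None,
) -> tuple[CPT, set[str]]:
    """Iteratively remove bogus parents (smallest variance first).

    After each removal the remaining parents are re-tested; removal
    averages the table uniformly over the dropped parent's states.
    ``candidates`` restricts which parents may be removed (e.g. the
    extension-introduced ones during network combination); by default
    every parent is tested. Returns the simplified CPT and the set of
    removed parent names.
    """
    eligible = (set(cpt.parent_names) if candidates is None
                else set(candidates) & set(cpt.parent_names))
    removed: set[str] = set()
    current = cpt
    while current.parents:
        profiles = {
            p: parent_variance_profile(current, p)
            for p in current.parent_names if p in eligible
        }
        below = {p: v for p, v in profiles.items()
                 if v <= max(epsilon_var, _VAR_FLOAT_TOL)}
        if not below:
            break
        victim = min(below, key=lambda p: (below[p], p))
        logger.debug("removing bogus parent %r of %r (variance %.3g <= %.3g)",
                     victim, current.child.name, below[victim], epsilon_var)
        current = _drop_parent(current, victim)
        removed.add(victim)
    return current, removed
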