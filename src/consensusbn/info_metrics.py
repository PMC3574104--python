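"""Empirical information measures and the CPT variance statistic.

Mutual information and conditional mutual information are computed from
maximum-likelihood (frequency) estimates in natural-log units (nats).
Unobserved configurations contribute zero to the sums. The variance
statistic quantifies how much a CPT's conditional distributions change
along one parent's axis; it is the bogus-parent detector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError
from .model_core import CPT, DiscreteDataset

__all__ = [
    "Thresholds",
    "mutual_information",
    "conditional_mutual_information",
    "parent_variance_profile",
    "calibrate_delta_mi",
    "calibrate_epsilon_var",
]


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for learning and combination.

    delta_mi     -- MI relatedness threshold (nats). Pairs with
                    MI <= delta_mi are treated as independent.
    delta_orient -- collider-detection scale: an unshielded triple
                    X - Z - Y is a collider when X and Y are marginally
                    unrelated (MI <= delta_mi) yet conditionally related
                    given Z (CMI > delta_orient * delta_mi).
    epsilon_var  -- average-variance threshold below which a parent is
                    declared bogus.
    min_stratum  -- minimum average samples per conditioning
                    configuration for a conditional test to be trusted;
                    below it the decision falls back to the marginal
                    test.
    """

    delta_mi: float = 0.01
    delta_orient: float = 0.4
    epsilon_var: float = 8e-3
    min_stratum: int = 5

    def __post_init__(self):
        if self.delta_mi < 0 or self.delta_orient < 0 or self.epsilon_var < 0:
            raise ContractError("thresholds must be nonnegative")


def _check_pair(data: DiscreteDataset, x: str, y: str) -> None:
    if x == y:
        raise ContractError(f"x and y must differ, both are {x!r}")
    if data.n_samples == 0:
        raise ContractError("empty dataset")
    data.variable(x), data.variable(y)


def _mi_from_counts(counts: np.ndarray) -> float:
    """I(X;Y) in nats from a 2-D contingency table of counts."""
    n = counts.sum()
    if n == 0:
        return 0.0
    pxy = counts / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    ratio = np.ones_like(pxy)
    np.divide(pxy, px * py, out=ratio, where=mask)
    return float(np.sum(pxy[mask] * np.log(ratio[mask])))


def mutual_information(data: DiscreteDataset, x: str, y: str) -> float:
    """Empirical mutual information I(X;Y), in nats (>= 0, symmetric)."""
    _check_pair(data, x, y)
    cx = data.variable(x).cardinality
    cy = data.variable(y).cardinality
    xi, yi = data.column(x), data.column(y)
    counts = np.bincount(xi * cy + yi, minlength=cx * cy).reshape(cx, cy)
    return max(0.0, _mi_from_counts(counts.astype(float)))


def conditional_mutual_information(
    data: DiscreteDataset, x: str, y: str, cond: Iterable[str] = ()
) -> float:
    """Empirical conditional mutual information I(X;Y | cond), in nats.

    With an empty conditioning set this equals :func:`mutual_information`.
    """
    cond = sorted(set(cond))
    if x in cond or y in cond:
        raise ContractError("x and y must not appear in the conditioning set")
    if not cond:
        return mutual_information(data, x, y)
    _check_pair(data, x, y)
    for c in cond:
        data.variable(c)

    cx = data.variable(x).cardinality
    cy = data.variable(y).cardinality
    xi, yi = data.column(x), data.column(y)
    dims = tuple(data.variable(c).cardinality for c in cond)
    cfg = np.ravel_multi_index(tuple(data.columns(cond).T), dims)

    n = data.n_samples
    total = 0.0
    for code in np.unique(cfg):
        sel = cfg == code
        nc = int(sel.sum())
        counts = np.bincount(xi[sel] * cy + yi[sel], minlength=cx * cy)
        total += (nc / n) * _mi_from_counts(counts.reshape(cx, cy).astype(float))
    return max(0.0, total)


def parent_variance_profile(cpt: CPT, parent: str) -> float:
    """Average variance of the conditionals along one parent's axis.

    For every fixed child state and configuration of the remaining
    parents, take the population variance of the conditional probability
    as only ``parent`` varies; return the mean of all these variances.
    Zero iff the parent can be marginalised out without changing any
    conditional.
    """
    if parent not in cpt.parent_names:
        raise ContractError(
            f"{parent!r} is not a parent in the CPT of {cpt.child.name!r}"
        )
    axis = cpt.parent_names.index(parent)
    return float(cpt.table.var(axis=axis, ddof=0).mean())


def calibrate_delta_mi(
    data: DiscreteDataset,
    n_shuffles: int = 200,
    quantile: float = 0.99,
    seed: int = 0,
) -> float:
    """Permutation-null calibration of the MI threshold.

    Repeatedly shuffles one column of a randomly chosen pair and records
    the null MI; returns the requested percentile. Use the result as
    ``delta_mi`` to bound the pairwise false-positive rate near
    ``1 - quantile``.
    """
    if len(data.variables) < 2:
        raise ContractError("need at least two variables to calibrate")
    rng = np.random.default_rng(seed)
    names = data.names
    null = np.empty(n_shuffles)
    for b in range(n_shuffles):
        i, j = rng.choice(len(names), size=2, replace=False)
        shuffled = data.rows.copy()
        shuffled[:, j] = shuffled[rng.permutation(data.n_samples), j]
        perm = DiscreteDataset(data.variables, shuffled)
        null[b] = mutual_information(perm, names[i], names[j])
    return float(np.quantile(null, quantile))


def calibrate_epsilon_var(
    child_cardinality: int,
    parent_cardinality: int,
    n_per_config: int,
    n_replicates: int = 200,
    quantile: float = 0.99,
    seed: int = 0,
) -> float:
    """Null calibration of the bogus-parent variance threshold.

    Simulates CPT rows for a parent that is truly independent of the
    child: each row is the frequency vector of ``n_per_config``
    multinomial draws from one random base distribution. Returns the
    requested percentile of the resulting variance profile, i.e. an
    epsilon that keeps roughly ``1 - quantile`` of independent parents.
    """
    rng = np.random.default_rng(seed)
    stats = np.empty(n_replicates)
    for b in range(n_replicates):
        base = rng.dirichlet(np.ones(child_cardinality))
        rows = np.stack([
            rng.multinomial(n_per_config, base) / n_per_config
            for _ in range(parent_cardinality)
        ])
        stats[b] = float(rows.var(axis=0, ddof=0).mean())
    return float(np.quantile(stats, quantile))
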