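"""Discretization of continuous expression matrices and the policy layer
for literature-derived network structures."""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn_learning import learn_parameters
from .errors import ContractError, ModelError
from .model_core import CPT, DAG, BayesianNetwork, DiscreteDataset, Variable

logger = logging.getLogger(__name__)

__all__ = ["Q3_STATES", "q3_discretize", "attach_literature_parameters"]

Q3_STATES = ("underexpressed", "normal", "overexpressed")


def q3_discretize(matrix: pd.DataFrame) -> DiscreteDataset:
    """Tertile (q3) discretization of a genes-by-samples expression matrix.

    Per gene, values are split at the order statistics ceil(n/3) and
    ceil(2n/3) into three states (underexpressed / normal /
    overexpressed); ties go to the lower bin, so bin sizes are as equal
    as the tie structure permits. Genes with fewer than three distinct
    values are excluded with a warning; non-finite entries raise an
    error naming the offending cells.
    """
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ModelError(f"duplicate gene names: {dupes}")
    bad = []
    values = matrix.to_numpy(dtype=float)
    finite = np.isfinite(values)
    if not finite.all():
        for i, j in zip(*np.nonzero(~finite)):
            bad.append((str(matrix.index[i]), str(matrix.columns[j])))
        raise ModelError(f"non-finite expression values at (gene, sample): {bad}")

    n = matrix.shape[1]
    if n == 0:
        raise ContractError("expression matrix has no samples")
    k1, k2 = math.ceil(n / 3), math.ceil(2 * n / 3)

    variables: list[Variable] = []
    cols: list[np.ndarray] = []
    for gene, row in zip(matrix.index, values):
        if np.unique(row).size < 3:
            logger.warning(
                "gene %r excluded: fewer than 3 distinct values", gene
            )
            continue
        ordered = np.sort(row)
        t1, t2 = ordered[k1 - 1], ordered[k2 - 1]
        states = np.where(row <= t1, 0, np.where(row <= t2, 1, 2))
        variables.append(Variable(str(gene), Q3_STATES))
        cols.append(states.astype(np.int64))
    if not variables:
        raise ModelError("no gene survived discretization")
    return DiscreteDataset(variables, np.column_stack(cols))


def attach_literature_parameters(
    structure: DAG,
    *,
    data: DiscreteDataset | None = None,
    cpts: Mapping[str, CPT] | Sequence[CPT] | None = None,
    weight: int = 1,
) -> BayesianNetwork:
    """Attach parameters to a literature-derived structure.

    Two sources are supported: a discrete dataset (maximum-likelihood
    counting on the given structure, network weight = sample count) or
    expert-elicited/program-output CPTs supplied directly (caller-chosen
    weight). Missing CPTs raise an error naming the uncovered nodes.
    """
    structure.check_acyclic()
    if (data is None) == (cpts is None):
        raise ContractError("supply exactly one of `data` or `cpts`")
    if data is not None:
        return learn_parameters(data, structure)

    if not isinstance(cpts, Mapping):
        cpts = {c.child.name: c for c in cpts}
    missing = sorted(structure.nodes - set(cpts))
    if missing:
        raise ModelError(f"no CPT supplied for nodes: {missing}")
    bn = BayesianNetwork(
        dag=structure.copy(),
        cpts={n: cpts[n] for n in structure.nodes},
        weight=weight,
    )
    bn.validate()
    return bn
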