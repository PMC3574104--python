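"""Study-level programs: MI-based associated-gene prediction, edge
similarity/diff metrics, the split/merge validation harness, and the
MI-connectivity analysis."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

from .bn_learning import learn_bn
from .consensus_engine import combine
from .cpt_algebra import AggregationSpec
from .errors import AlignmentError, ContractError
from .info_metrics import Thresholds, mutual_information
from .model_core import DAG, DiscreteDataset

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "ExperimentReport",
    "predict_associated_genes",
    "edge_similarity",
    "edge_diff",
    "split_merge_experiment",
    "mi_connectivity",
]


@dataclass(frozen=True)
class AssociationResult:
    """One (known gene, candidate gene, MI) triple above threshold."""

    known_gene: str
    candidate_gene: str
    mi: float


@dataclass
class ExperimentReport:
    """Per-run and aggregate edge-similarity statistics."""

    per_run_similarity: list[float]
    runs: int
    skipped: int = 0
    mean: float = field(init=False)
    std: float = field(init=False)

    def __post_init__(self):
        arr = np.asarray(self.per_run_similarity, dtype=float)
        self.mean = float(arr.mean()) if arr.size else float("nan")
        self.std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def predict_associated_genes(
    data: DiscreteDataset,
    known: Iterable[str],
    candidates: Iterable[str],
    delta_mi: float,
) -> list[AssociationResult]:
    """Candidates whose MI with some known pathway gene exceeds delta_mi.

    Every (known, candidate) pair is tested; qualifying pairs are
    returned sorted by MI descending (lexicographic ties). A candidate
    appears once per known gene it exceeds the threshold with.
    """
    known = sorted(set(known))
    candidates = sorted(set(candidates))
    overlap = set(known) & set(candidates)
    if overlap:
        raise ContractError(
            f"known and candidate sets overlap: {sorted(overlap)}"
        )
    results = [
        AssociationResult(g, r, mutual_information(data, g, r))
        for g in known
        for r in candidates
    ]
    hits = [a for a in results if a.mi > delta_mi]
    hits.sort(key=lambda a: (-a.mi, a.known_gene, a.candidate_gene))
    return hits


def edge_similarity(dagA: DAG, dagB: DAG, mode: str = "dice") -> float:
    """Directed-edge similarity between two DAGs on the same node set.

    ``dice`` (default): 2|Ea ∩ Eb| / (|Ea| + |Eb|);
    ``jaccard``: |Ea ∩ Eb| / |Ea ∪ Eb|. Two empty edge sets count as
    identical (similarity 1).
    """
    if dagA.nodes != dagB.nodes:
        raise ContractError("DAGs are defined over different node sets")
    ea, eb = dagA.edges, dagB.edges
    if not ea and not eb:
        return 1.0
    common = len(ea & eb)
    if mode == "dice":
        return 2.0 * common / (len(ea) + len(eb))
    if mode == "jaccard":
        return common / len(ea | eb)
    raise ContractError(f"unknown similarity mode {mode!r}")


def edge_diff(true_dag: DAG, learned_dag: DAG) -> tuple[int, int, int]:
    """(edge count, missing, extra) of a learned DAG vs the truth,
    compared on directed edges."""
    if true_dag.nodes != learned_dag.nodes:
        raise ContractError("DAGs are defined over different node sets")
    et, el = true_dag.edges, learned_dag.edges
    return len(el), len(et - el), len(el - et)


def split_merge_experiment(
    data: DiscreteDataset,
    runs: int,
    split_fraction: float = 0.25,
    thresholds: Thresholds | None = None,
    seed: int = 0,
) -> ExperimentReport:
    """The split/merge validation protocol.

    Per run: partition the rows at random into a ``split_fraction`` part
    and its complement, learn a network from each, combine the two with
    sample-count weights, and score the consensus against the reference
    network learned from the whole dataset by directed-edge similarity.
    Runs whose parts are too small to learn (fewer samples than
    variables), or whose prior orders cannot be aligned, are skipped and
    logged.
    """
    if runs < 1:
        raise ContractError("runs must be >= 1")
    if not 0 < split_fraction < 1:
        raise ContractError("split_fraction must be in (0, 1)")
    thresholds = thresholds or Thresholds()
    n = data.n_samples
    n_vars = len(data.variables)
    reference = learn_bn(data, thresholds)

    rng = np.random.default_rng(seed)
    sims: list[float] = []
    skipped = 0
    for run in range(runs):
        perm = rng.permutation(n)
        n1 = int(round(split_fraction * n))
        idx1, idx2 = perm[:n1], perm[n1:]
        if len(idx1) < n_vars or len(idx2) < n_vars:
            logger.warning("run %d skipped: split parts too small to learn", run)
            skipped += 1
            continue
        d1 = data.subset_rows(np.sort(idx1))
        d2 = data.subset_rows(np.sort(idx2))
        b1 = learn_bn(d1, thresholds)
        b2 = learn_bn(d2, thresholds)
        spec = AggregationSpec(
            weights=(d1.n_samples, d2.n_samples),
            epsilon_var=thresholds.epsilon_var,
        )
        try:
            consensus = combine(b1, b2, spec)
        except AlignmentError as exc:
            logger.warning("run %d skipped: prior orders could not be "
                           "aligned (%s)", run, exc)
            skipped += 1
            continue
        sims.append(edge_similarity(consensus.dag, reference.dag))
    return ExperimentReport(per_run_similarity=sims, runs=runs,
                            skipped=skipped)


def mi_connectivity(
    data: DiscreteDataset, delta_mi: float
) -> tuple[list[int], float]:
    """Connected components of the MI-relatedness graph.

    Builds the undirected graph with an edge wherever pairwise MI
    exceeds delta_mi and returns the component sizes (descending) plus
    the fraction of variables inside the largest component.
    """
    names = data.names
    if not names:
        raise ContractError("dataset has no variables")
    graph = nx.Graph()
    graph.add_nodes_from(names)
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            if mutual_information(data, x, y) > delta_mi:
                graph.add_edge(x, y)
    sizes = sorted((len(c) for c in nx.connected_components(graph)),
                   reverse=True)
    return sizes, sizes[0] / len(names)
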