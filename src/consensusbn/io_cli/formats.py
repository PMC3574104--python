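"""File formats: expression matrices, discrete datasets, and the network
interchange documents (canonical YAML plus a reader/writer for the
common BIF dialect)."""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ..errors import ContractError, ModelError
from ..model_core import (
    CPT,
    DAG,
    TAG_NORMAL,
    BayesianNetwork,
    DiscreteDataset,
    Variable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "read_discrete_dataset",
    "write_discrete_dataset",
    "read_network",
    "write_network",
    "read_bif",
    "write_bif",
]

_FORMAT_TAG = "consensusbn-network/1"
_ROW_SUM_TOL = 1e-6


def _sniff_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if "\t" in head else ","


def read_expression_matrix(path) -> pd.DataFrame:
    """Continuous genes-by-samples matrix from delimited text.

    First column holds gene names, header row holds sample identifiers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    if df.index.has_duplicates:
        for lineno, gene in enumerate(df.index, start=2):
            if (df.index == gene).sum() > 1:
                raise ModelError(
                    f"{path}: duplicate gene name {gene!r} (line {lineno})"
                )
    if df.columns.has_duplicates:
        raise ModelError(f"{path}: duplicate sample identifiers in the header")
    logger.info("read expression matrix %s: %d genes x %d samples",
                path, *df.shape)
    return df


def read_discrete_dataset(path) -> DiscreteDataset:
    """Categorical dataset: header of variable names, one sample per row."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    if df.columns.has_duplicates:
        raise ModelError(f"{path}: duplicate variable names in the header")
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ModelError(
            f"{path}: missing value at row {i + 2}, column {df.columns[j]!r}"
        )
    data = DiscreteDataset.from_dataframe(df)
    logger.info("read discrete dataset %s: %d samples x %d variables",
                path, data.n_samples, len(data.variables))
    return data


def write_discrete_dataset(data: DiscreteDataset, path) -> None:
    data.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# canonical network interchange (YAML, label-addressed)
# ---------------------------------------------------------------------------

def write_network(bn: BayesianNetwork, path) -> None:
    """Serialize a network to the canonical YAML interchange document.

    CPT rows are keyed by parent-state *labels*, never indices, so the
    document does not depend on internal state ordering.
    """
    bn.validate()
    doc = {
        "format": _FORMAT_TAG,
        "weight": int(bn.weight),
        "variables": [
            {"name": name, "states": list(bn.var(name).states)}
            for name in sorted(bn.nodes)
        ],
        "edges": [
            {"from": u, "to": v, **({"tag": bn.dag.tag(u, v)}
                                    if bn.dag.tag(u, v) != TAG_NORMAL else {})}
            for u, v in sorted(bn.dag.edges)
        ],
        "cpts": {},
    }
    for name in sorted(bn.nodes):
        cpt = bn.cpts[name]
        rows = []
        for cfg, row in cpt.configurations():
            rows.append({
                "given": {p.name: p.states[i]
                          for p, i in zip(cpt.parents, cfg)},
                "p": [float(x) for x in row],
            })
        doc["cpts"][name] = {
            "parents": list(cpt.parent_names),
            "rows": rows,
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _network_from_doc(doc: dict, origin: str) -> BayesianNetwork:
    if doc.get("format") != _FORMAT_TAG:
        raise ModelError(f"{origin}: unknown format tag {doc.get('format')!r}")
    variables = {
        spec["name"]: Variable(spec["name"], tuple(spec["states"]))
        for spec in doc["variables"]
    }
    dag = DAG(nodes=variables)
    for e in doc.get("edges", []):
        dag.add_edge(e["from"], e["to"], tag=e.get("tag", TAG_NORMAL))
    cpts: dict[str, CPT] = {}
    for name, spec in doc["cpts"].items():
        child = variables[name]
        parents = tuple(variables[p] for p in spec["parents"])
        shape = tuple(p.cardinality for p in parents) + (child.cardinality,)
        table = np.full(shape, np.nan)
        for row in spec["rows"]:
            cfg = tuple(p.index_of(row["given"][p.name]) for p in parents)
            vec = np.asarray(row["p"], dtype=float)
            if abs(vec.sum() - 1.0) > _ROW_SUM_TOL:
                raise ModelError(
                    f"{origin}: CPT row for {name!r} given {row['given']} "
                    f"sums to {vec.sum():.6g}, not 1"
                )
            table[cfg] = vec
        if np.isnan(table).any():
            raise ModelError(f"{origin}: CPT for {name!r} does not cover the "
                             "full parent configuration space")
        cpts[name] = CPT(child, parents, table)
    bn = BayesianNetwork(dag=dag, cpts=cpts, weight=int(doc.get("weight", 1)))
    bn.validate()
    return bn


def read_network(path) -> BayesianNetwork:
    """Read a network document (canonical YAML, or BIF by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".bif":
        return read_bif(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ModelError(f"{path}: not a network document")
    return _network_from_doc(doc, str(path))


# ---------------------------------------------------------------------------
# BIF dialect
# ---------------------------------------------------------------------------

_BIF_VARIABLE = re.compile(
    r"variable\s+(\S+)\s*\{[^}]*?type\s+discrete\s*\[\s*(\d+)\s*\]\s*\{([^}]*)\}\s*;[^}]*\}",
    re.DOTALL,
)
_BIF_PROBABILITY = re.compile(
    r"probability\s*\(\s*([^)|]+?)\s*(?:\|\s*([^)]+?)\s*)?\)\s*\{(.*?)\}",
    re.DOTALL,
)


def read_bif(path) -> BayesianNetwork:
    """Reader for the common BIF (Bayesian Interchange Format) dialect."""
    text = Path(path).read_text()
    text = re.sub(r"//[^\n]*", "", text)

    variables: dict[str, Variable] = {}
    for m in _BIF_VARIABLE.finditer(text):
        name, card, states_blob = m.group(1), int(m.group(2)), m.group(3)
        states = tuple(s.strip() for s in states_blob.split(",") if s.strip())
        if len(states) != card:
            raise ModelError(
                f"{path}: variable {name!r} declares {card} states but "
                f"lists {len(states)}"
            )
        variables[name] = Variable(name, states)

    dag = DAG(nodes=variables)
    cpts: dict[str, CPT] = {}
    for m in _BIF_PROBABILITY.finditer(text):
        child_name = m.group(1).strip()
        parent_blob = m.group(2)
        body = m.group(3)
        if child_name not in variables:
            raise ModelError(f"{path}: probability block for undeclared "
                             f"variable {child_name!r}")
        child = variables[child_name]
        parent_names = ([p.strip() for p in parent_blob.split(",")]
                        if parent_blob else [])
        parents = tuple(variables[p] for p in parent_names)
        for p in parent_names:
            dag.add_edge(p, child_name)
        shape = tuple(p.cardinality for p in parents) + (child.cardinality,)
        table = np.full(shape, np.nan)
        if not parents:
            tm = re.search(r"table\s+([^;]+);", body)
            if not tm:
                raise ModelError(f"{path}: no `table` entry for root "
                                 f"{child_name!r}")
            vec = np.array([float(x) for x in tm.group(1).split(",")])
            table[...] = vec
        else:
            for rm in re.finditer(r"\(([^)]*)\)\s*([^;]+);", body):
                labels = [s.strip() for s in rm.group(1).split(",")]
                cfg = tuple(p.index_of(s) for p, s in zip(parents, labels))
                table[cfg] = np.array(
                    [float(x) for x in rm.group(2).split(",")]
                )
        if np.isnan(table).any():
            raise ModelError(f"{path}: CPT for {child_name!r} does not cover "
                             "the full parent configuration space")
        sums = table.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=_ROW_SUM_TOL, rtol=0):
            raise ModelError(f"{path}: CPT rows for {child_name!r} do not "
                             "sum to 1")
        cpts[child_name] = CPT(child, parents, table)

    bn = BayesianNetwork(dag=dag, cpts=cpts, weight=1)
    bn.validate()
    return bn


def write_bif(bn: BayesianNetwork, path) -> None:
    """Write a network in the BIF dialect accepted by :func:`read_bif`."""
    bn.validate()
    lines = ["network unnamed {", "}"]
    for name in sorted(bn.nodes):
        var = bn.var(name)
        lines.append(f"variable {name} {{")
        lines.append(
            f"  type discrete [ {var.cardinality} ] "
            f"{{ {', '.join(var.states)} }};"
        )
        lines.append("}")
    for name in sorted(bn.nodes):
        cpt = bn.cpts[name]
        if cpt.parents:
            head = f"probability ( {name} | {', '.join(cpt.parent_names)} ) {{"
            lines.append(head)
            for cfg, row in cpt.configurations():
                labels = ", ".join(p.states[i]
                                   for p, i in zip(cpt.parents, cfg))
                probs = ", ".join(f"{x:.10g}" for x in row)
                lines.append(f"  ({labels}) {probs};")
        else:
            lines.append(f"probability ( {name} ) {{")
            probs = ", ".join(f"{x:.10g}" for x in cpt.table)
            lines.append(f"  table {probs};")
        lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
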