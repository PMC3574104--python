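"""Regenerate the packaged ALARM fixture (data/alarm.bif).

The structure is the canonical 37-node / 46-edge patient-monitoring
network. The original conditional probabilities are not redistributable
as plain text here, so the fixture carries surrogate parameters:
seeded symmetric-Dirichlet rows (concentration 0.5, seed 20130215),
which keep every edge's dependence strong enough for structure-recovery
experiments. Deterministic: rerunning reproduces the identical file.
"""

from pathlib import Path

import numpy as np

from consensusbn.io_cli.formats import write_bif
from consensusbn.model_core import CPT, DAG, BayesianNetwork, Variable

B = ("TRUE", "FALSE")
LNH = ("LOW", "NORMAL", "HIGH")
ZLNH = ("ZERO", "LOW", "NORMAL", "HIGH")
NH = ("NORMAL", "HIGH")

STATES = {
    "HISTORY": B, "CVP": LNH, "PCWP": LNH, "HYPOVOLEMIA": B,
    "LVEDVOLUME": LNH, "LVFAILURE": B, "STROKEVOLUME": LNH,
    "ERRLOWOUTPUT": B, "HRBP": LNH, "HREKG": LNH, "ERRCAUTER": B,
    "HRSAT": LNH, "INSUFFANESTH": B, "ANAPHYLAXIS": B, "TPR": LNH,
    "EXPCO2": ZLNH, "KINKEDTUBE": B, "MINVOL": ZLNH, "FIO2": ("LOW", "NORMAL"),
    "PVSAT": LNH, "SAO2": LNH, "PAP": LNH, "PULMEMBOLUS": B,
    "SHUNT": NH, "INTUBATION": ("NORMAL", "ESOPHAGEAL", "ONESIDED"),
    "PRESS": ZLNH, "DISCONNECT": B, "MINVOLSET": LNH, "VENTMACH": ZLNH,
    "VENTTUBE": ZLNH, "VENTLUNG": ZLNH, "VENTALV": ZLNH, "ARTCO2": LNH,
    "CATECHOL": NH, "HR": LNH, "CO": LNH, "BP": LNH,
}

EDGES = [
    ("LVFAILURE", "HISTORY"),
    ("LVEDVOLUME", "CVP"),
    ("LVEDVOLUME", "PCWP"),
    ("HYPOVOLEMIA", "LVEDVOLUME"), ("LVFAILURE", "LVEDVOLUME"),
    ("HYPOVOLEMIA", "STROKEVOLUME"), ("LVFAILURE", "STROKEVOLUME"),
    ("ERRLOWOUTPUT", "HRBP"), ("HR", "HRBP"),
    ("ERRCAUTER", "HREKG"), ("HR", "HREKG"),
    ("ERRCAUTER", "HRSAT"), ("HR", "HRSAT"),
    ("ANAPHYLAXIS", "TPR"),
    ("ARTCO2", "EXPCO2"), ("VENTLUNG", "EXPCO2"),
    ("INTUBATION", "MINVOL"), ("VENTLUNG", "MINVOL"),
    ("FIO2", "PVSAT"), ("VENTALV", "PVSAT"),
    ("PVSAT", "SAO2"), ("SHUNT", "SAO2"),
    ("PULMEMBOLUS", "PAP"),
    ("INTUBATION", "SHUNT"), ("PULMEMBOLUS", "SHUNT"),
    ("INTUBATION", "PRESS"), ("KINKEDTUBE", "PRESS"), ("VENTTUBE", "PRESS"),
    ("MINVOLSET", "VENTMACH"),
    ("DISCONNECT", "VENTTUBE"), ("VENTMACH", "VENTTUBE"),
    ("INTUBATION", "VENTLUNG"), ("KINKEDTUBE", "VENTLUNG"),
    ("VENTTUBE", "VENTLUNG"),
    ("INTUBATION", "VENTALV"), ("VENTLUNG", "VENTALV"),
    ("VENTALV", "ARTCO2"),
    ("ARTCO2", "CATECHOL"), ("INSUFFANESTH", "CATECHOL"),
    ("SAO2", "CATECHOL"), ("TPR", "CATECHOL"),
    ("CATECHOL", "HR"),
    ("HR", "CO"), ("STROKEVOLUME", "CO"),
    ("CO", "BP"), ("TPR", "BP"),
]

SEED = 20130215
CONCENTRATION = 0.5


def build() -> BayesianNetwork:
    assert len(STATES) == 37 and len(EDGES) == 46
    rng = np.random.default_rng(SEED)
    dag = DAG(nodes=STATES)
    for u, v in EDGES:
        dag.add_edge(u, v)
    cpts = {}
    for name in sorted(STATES):
        child = Variable(name, STATES[name])
        parents = tuple(Variable(p, STATES[p]) for p in dag.parents(name))
        shape = tuple(p.cardinality for p in parents)
        n_rows = int(np.prod(shape)) if shape else 1
        rows = rng.dirichlet(
            np.full(child.cardinality, CONCENTRATION), size=n_rows
        ).round(6)
        rows /= rows.sum(axis=1, keepdims=True)
        cpts[name] = CPT(child, parents, rows.reshape(shape + (child.cardinality,)))
    bn = BayesianNetwork(dag=dag, cpts=cpts, weight=1)
    bn.validate()
    return bn


if __name__ == "__main__":
    out = Path(__file__).resolve().parents[1] / (
        "src/consensusbn/io_cli/data/alarm.bif"
    )
    write_bif(build(), out)
    print(f"wrote {out}")
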