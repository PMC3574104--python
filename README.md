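# consensusbn

Discrete Bayesian network learning and **consensus combination** for
regulatory-pathway modelling.

The package provides:

- an information-theoretic three-phase structure learner
  (draft / thicken / thin on mutual-information tests, collider
  detection + MDL edge orientation) with maximum-likelihood parameter
  estimation;
- a **combination algebra** for Bayesian networks: CPT extension to a
  common form, weighted aggregation (linear opinion pool; with
  sample-count weights it reproduces exactly the estimate on the merged
  database), and variance-based removal of bogus parents;
- whole-network combination with prior-order alignment by
  joint-preserving edge reversal, and **extension** of a network onto a
  larger variable set using exact inference in a reference network;
- study tools: the MI-based associated-gene prediction program,
  directed-edge similarity / edge-diff metrics, the split/merge
  validation protocol, and an MI-connectivity analysis;
- tertile (q3) discretization of continuous expression matrices and a
  policy layer for attaching parameters to literature-derived
  structures;
- text fixtures: the canonical 8-node chest-clinic (Asia) network and a
  37-node patient-monitoring network (canonical 46-edge structure,
  seeded surrogate parameters), plus seeded random-network generators.

## Command line

`consensusbn` exposes one subcommand per pipeline stage:

```sh
consensusbn simulate   --net net.yaml --n 1000 --seed 1 --out data.csv
consensusbn discretize --input expression.tsv --output discrete.csv
consensusbn learn      --data data.csv --delta 0.01 --out learned.yaml
consensusbn combine    --net a.yaml --net b.yaml --weight 250 --weight 750 \
                       --epsilon 0.008 --out consensus.yaml
consensusbn extend     --small small.yaml --ref big.yaml --out extended.yaml
consensusbn predict    --data discrete.csv --known genes.txt --out assoc.tsv
consensusbn evaluate   --data data.csv --net true.yaml --runs 100 \
                       --split 0.25 --seed 1
```

All flags can be pre-set from a key-value config file
(`consensusbn --config run.cfg <command> ...`). Networks are stored in a
YAML interchange format (state labels, never indices); a reader/writer
for the common BIF dialect is included (`.bif` files are detected by
extension).

## Library quick start

```python
from consensusbn import AggregationSpec, Thresholds, forward_sample
from consensusbn.bn_learning import learn_bn
from consensusbn.consensus_engine import combine
from consensusbn.io_cli import fixture_chest_clinic

bn = fixture_chest_clinic()
data = forward_sample(bn, 1000, seed=1)
d1, d2 = data.subset_rows(range(250)), data.subset_rows(range(250, 1000))
b1, b2 = learn_bn(d1), learn_bn(d2)
consensus = combine(b1, b2, AggregationSpec(weights=(250, 750)))
```

Decision thresholds live in `Thresholds` (MI relatedness `delta_mi`,
collider scale `delta_orient`, bogus-parent variance `epsilon_var`);
permutation/null calibration helpers are in `consensusbn.info_metrics`.

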