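"""Network combination, prior-order alignment, and network extension."""

import numpy as np
import pytest

from consensusbn.bn_learning import learn_bn, learn_parameters
from consensusbn.consensus_engine import (
    align_prior_orders,
    combine,
    combine_same_variables,
    extend_bn,
    reverse_edge,
)
from consensusbn.cpt_algebra import AggregationSpec, extend_cpt
from consensusbn.errors import AlignmentError, ContractError
from consensusbn.model_core import (
    CPT,
    DAG,
    TAG_EXTENDED,
    BayesianNetwork,
    Variable,
    enumerate_joint,
    forward_sample,
    infer_distribution,
    orders_consistent,
)
from consensusbn.io_cli import fixture_random_bn


def _var(name, card=2):
    return Variable(name, tuple(f"s{i}" for i in range(card)))


def _joint_table(bn):
    names = sorted(bn.nodes)
    return {
        tuple(a[n] for n in names): p for a, p in enumerate_joint(bn)
    }


def _assert_same_joint(bn1, bn2, atol=1e-9):
    j1, j2 = _joint_table(bn1), _joint_table(bn2)
    assert set(j1) == set(j2)
    for key in j1:
        assert j1[key] == pytest.approx(j2[key], abs=atol)


class TestReverseEdge:
    def test_two_node_bayes_rule(self):
        a, b = _var("a"), _var("b")
        bn = BayesianNetwork(
            dag=DAG(edges=[("a", "b")]),
            cpts={
                "a": CPT(a, (), np.array([0.3, 0.7])),
                "b": CPT(b, (a,), np.array([[0.9, 0.1], [0.2, 0.8]])),
            },
        )
        reversed_bn = reverse_edge(bn, "a", "b")
        assert reversed_bn.dag.edges == {("b", "a")}
        _assert_same_joint(bn, reversed_bn)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_network_joint_preserved(self, seed):
        bn = fixture_random_bn(5, max_parents=2, cardinality=2, seed=seed)
        edges = sorted(bn.dag.edges)
        if not edges:
            pytest.skip("empty random DAG")
        for u, v in edges:
            probe = bn.dag.copy()
            probe.remove_edge(u, v)
            if probe.has_path(u, v):
                with pytest.raises(AlignmentError):
                    reverse_edge(bn, u, v)
            else:
                _assert_same_joint(bn, reverse_edge(bn, u, v))

    def test_missing_edge_rejected(self):
        bn = fixture_random_bn(3, seed=1)
        with pytest.raises(ContractError):
            reverse_edge(bn, "zzz", "yyy")


class TestAlignPriorOrders:
    def test_consistent_pair_unchanged(self):
        b1 = fixture_random_bn(4, seed=0)
        assert align_prior_orders(b1, b1) is b1

    def test_two_node_conflict(self):
        a, b = _var("a"), _var("b")
        bn1 = BayesianNetwork(
            dag=DAG(edges=[("a", "b")]),
            cpts={
                "a": CPT(a, (), np.array([0.4, 0.6])),
                "b": CPT(b, (a,), np.array([[0.7, 0.3], [0.1, 0.9]])),
            },
        )
        bn2 = BayesianNetwork(
            dag=DAG(edges=[("b", "a")]),
            cpts={
                "b": CPT(b, (), np.array([0.5, 0.5])),
                "a": CPT(a, (b,), np.array([[0.2, 0.8], [0.6, 0.4]])),
            },
        )
        aligned = align_prior_orders(bn1, bn2)
        assert orders_consistent(bn1.dag, aligned.dag)
        _assert_same_joint(bn2, aligned)

    @pytest.mark.parametrize("seed", range(10))
    def test_learned_pair_alignment_preserves_joint(self, chest_clinic, seed):
        data = forward_sample(chest_clinic, 600, seed=seed)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(600)
        b1 = learn_bn(data.subset_rows(np.sort(perm[:300])))
        b2 = learn_bn(data.subset_rows(np.sort(perm[300:])))
        if orders_consistent(b1.dag, b2.dag):
            assert align_prior_orders(b1, b2) is b2
        else:
            aligned = align_prior_orders(b1, b2)
            assert orders_consistent(b1.dag, aligned.dag)
            _assert_same_joint(b2, aligned)

    def test_variable_set_mismatch(self):
        with pytest.raises(ContractError):
            align_prior_orders(fixture_random_bn(3, seed=0),
                               fixture_random_bn(4, seed=0))


class TestCombineSameVariables:
    def test_self_combination_fixed_point(self, chest_clinic):
        spec = AggregationSpec(weights=(5, 5))
        out = combine_same_variables(chest_clinic, chest_clinic, spec)
        assert out.dag.edges == chest_clinic.dag.edges
        for name in chest_clinic.nodes:
            ours, theirs = out.cpts[name], chest_clinic.cpts[name]
            perm = [ours.parent_names.index(p) for p in theirs.parent_names]
            table = np.transpose(ours.table, perm + [len(perm)])
            np.testing.assert_allclose(table, theirs.table, atol=1e-12)
        assert out.weight == 10

    def test_bogus_parent_deleted(self):
        # one network gives x parents {a, b}, the other {a}; the
        # aggregated table is constant along b, so the b -> x edge is
        # detected as bogus and deleted
        a, b, x = _var("a"), _var("b"), _var("x")
        pa = np.array([0.5, 0.5])
        x_given_a = np.array([[0.9, 0.1], [0.2, 0.8]])
        bn1 = BayesianNetwork(
            dag=DAG(edges=[("a", "x"), ("b", "x")]),
            cpts={
                "a": CPT(a, (), pa),
                "b": CPT(b, (), pa),
                "x": CPT(x, (a, b), np.stack([x_given_a, x_given_a], axis=1)),
            },
        )
        bn2 = BayesianNetwork(
            dag=DAG(nodes=["b"], edges=[("a", "x")]),
            cpts={
                "a": CPT(a, (), pa),
                "b": CPT(b, (), pa),
                "x": CPT(x, (a,), x_given_a),
            },
        )
        out = combine_same_variables(bn1, bn2,
                                     AggregationSpec(weights=(1, 1)))
        assert ("b", "x") not in out.dag.edges
        assert out.cpts["x"].parent_names == ("a",)
        np.testing.assert_allclose(out.cpts["x"].table, x_given_a, atol=1e-12)

    def test_inconsistent_orders_directive(self):
        a, b = _var("a"), _var("b")
        bn1 = BayesianNetwork(
            dag=DAG(edges=[("a", "b")]),
            cpts={
                "a": CPT(a, (), np.array([0.4, 0.6])),
                "b": CPT(b, (a,), np.array([[0.7, 0.3], [0.1, 0.9]])),
            },
        )
        bn2 = BayesianNetwork(
            dag=DAG(edges=[("b", "a")]),
            cpts={
                "b": CPT(b, (), np.array([0.5, 0.5])),
                "a": CPT(a, (b,), np.array([[0.2, 0.8], [0.6, 0.4]])),
            },
        )
        with pytest.raises(ContractError, match="align_prior_orders"):
            combine_same_variables(bn1, bn2, AggregationSpec(weights=(1, 1)))


class TestExtendBN:
    def test_equal_sets_unchanged(self, chest_clinic):
        assert extend_bn(chest_clinic, chest_clinic) is chest_clinic

    def test_disconnected_new_variable(self):
        a, z = _var("a"), _var("z")
        small = BayesianNetwork(
            dag=DAG(nodes=["a"]),
            cpts={"a": CPT(a, (), np.array([0.3, 0.7]))},
        )
        ref = BayesianNetwork(
            dag=DAG(nodes=["a", "z"]),
            cpts={
                "a": CPT(a, (), np.array([0.25, 0.75])),
                "z": CPT(z, (), np.array([0.6, 0.4])),
            },
        )
        out = extend_bn(small, ref)
        assert out.nodes == {"a", "z"}
        np.testing.assert_array_equal(out.cpts["z"].table, ref.cpts["z"].table)
        np.testing.assert_array_equal(out.cpts["a"].table,
                                      small.cpts["a"].table)

    def test_new_parent_disconnected_blocks_product_oracle(self):
        """New-parent block disconnected from the old block in the
        reference: the produced rows must match exact conditionals of the
        reference network (which realises the independence case)."""
        a, x, b = _var("a"), _var("x"), _var("b")
        rng = np.random.default_rng(5)
        ref = BayesianNetwork(
            dag=DAG(edges=[("a", "x"), ("b", "x")]),
            cpts={
                "a": CPT(a, (), rng.dirichlet((2, 2))),
                "b": CPT(b, (), rng.dirichlet((2, 2))),
                "x": CPT(x, (a, b), rng.dirichlet((2, 2), size=(2, 2))),
            },
        )
        small = BayesianNetwork(
            dag=DAG(edges=[("a", "x")]),
            cpts={
                "a": ref.cpts["a"],
                "x": CPT(x, (a,), np.stack([
                    infer_distribution(ref, "x", {"a": i}) for i in range(2)
                ])),
            },
        )
        out = extend_bn(small, ref)
        assert out.dag.tag("b", "x") == TAG_EXTENDED
        for ia in range(2):
            for ib in range(2):
                expected = infer_distribution(ref, "x", {"a": ia, "b": ib})
                cfg = {n: (ia if n == "a" else ib)
                       for n in out.cpts["x"].parent_names}
                got = out.cpts["x"].row(
                    [cfg[n] for n in out.cpts["x"].parent_names]
                )
                np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_extended_edges_tagged_and_acyclic(self):
        small = fixture_random_bn(4, max_parents=2, seed=3)
        ref = fixture_random_bn(7, max_parents=2, seed=3)
        # align variable names: the random fixtures use different widths,
        # so rebuild a nested pair from one reference network instead
        names = sorted(ref.nodes)[:4]
        sub_dag = DAG(nodes=names)
        for u, v in ref.dag.edges:
            if u in names and v in names:
                sub_dag.add_edge(u, v)
        data = forward_sample(ref, 500, seed=0)
        small = learn_parameters(data.select(names), sub_dag)
        out = extend_bn(small, ref)
        assert out.nodes == ref.nodes
        out.dag.check_acyclic()
        for u, v in out.dag.edges - small.dag.edges:
            assert out.dag.tag(u, v) == TAG_EXTENDED

    def test_non_subset_rejected(self):
        b1 = fixture_random_bn(4, seed=0)
        with pytest.raises(ContractError):
            extend_bn(b1, BayesianNetwork(
                dag=DAG(nodes=["Q0", "Q1"]),
                cpts={
                    "Q0": CPT(_var("Q0"), (), np.array([0.5, 0.5])),
                    "Q1": CPT(_var("Q1"), (), np.array([0.5, 0.5])),
                },
            ))


class TestCombine:
    def test_equal_sets_delegates(self, chest_clinic):
        spec = AggregationSpec(weights=(3, 3))
        direct = combine_same_variables(chest_clinic, chest_clinic, spec)
        via_combine = combine(chest_clinic, chest_clinic, spec)
        assert direct.dag.edges == via_combine.dag.edges

    def test_non_nested_rejected(self):
        x, y, z = _var("x"), _var("y"), _var("z")
        bx = BayesianNetwork(dag=DAG(nodes=["x", "y"]), cpts={
            "x": CPT(x, (), np.array([0.5, 0.5])),
            "y": CPT(y, (), np.array([0.5, 0.5]))})
        bz = BayesianNetwork(dag=DAG(nodes=["y", "z"]), cpts={
            "y": CPT(y, (), np.array([0.5, 0.5])),
            "z": CPT(z, (), np.array([0.5, 0.5]))})
        with pytest.raises(ContractError, match="nested"):
            combine(bx, bz, AggregationSpec(weights=(1, 1)))

    def test_nested_combination_runs_end_to_end(self, chest_clinic):
        """Smaller network over a subset of the chest-clinic variables,
        combined with the full network."""
        data = forward_sample(chest_clinic, 2000, seed=8)
        names = ["bronc", "dysp", "either", "smoke"]
        small = learn_bn(data.select(names))
        out = combine(small, chest_clinic,
                      AggregationSpec(weights=(2000, 1000)))
        assert out.nodes == chest_clinic.nodes
        out.validate()
        assert len(out.dag.edges) <= len(small.dag.edges) + len(
            chest_clinic.dag.edges
        )

    def test_idempotent_extension(self, chest_clinic):
        data = forward_sample(chest_clinic, 2000, seed=9)
        names = ["bronc", "dysp", "either", "smoke"]
        small = learn_bn(data.select(names))
        spec = AggregationSpec(weights=(2000, 1000))
        if not orders_consistent(small.dag, chest_clinic.dag):
            small = align_prior_orders(chest_clinic, small)
        pre_extended = extend_bn(small, chest_clinic)
        a = combine(pre_extended, chest_clinic, spec)
        b = combine(small, chest_clinic, spec)
        assert a.dag.edges == b.dag.edges

    @pytest.mark.parametrize("seed", range(4))
    def test_consensus_acyclic_and_normalized(self, chest_clinic, seed):
        data = forward_sample(chest_clinic, 1000, seed=seed)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(1000)
        b1 = learn_bn(data.subset_rows(np.sort(perm[:250])))
        b2 = learn_bn(data.subset_rows(np.sort(perm[250:])))
        out = combine(b1, b2, AggregationSpec(weights=(250, 750)))
        out.validate()  # acyclicity + row normalization
        assert out.weight == 1000
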