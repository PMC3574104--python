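"""CPT extension, aggregation and simplification — the combination algebra."""

import itertools

import numpy as np
import pytest

from consensusbn.bn_learning import learn_parameters
from consensusbn.cpt_algebra import (
    AggregationSpec,
    aggregate_cpts,
    canonical_parent_order,
    common_form,
    detect_bogus_parents,
    extend_cpt,
    simplify_cpt,
)
from consensusbn.errors import ContractError, ModelError
from consensusbn.model_core import (
    CPT,
    DAG,
    DiscreteDataset,
    Variable,
    forward_sample,
)
from consensusbn.io_cli import fixture_random_bn


def _var(name, card=2):
    return Variable(name, tuple(f"s{i}" for i in range(card)))


def _random_cpt(child, parents, seed=0, counts=False):
    rng = np.random.default_rng(seed)
    shape = tuple(p.cardinality for p in parents)
    n_rows = int(np.prod(shape)) if shape else 1
    table = rng.dirichlet(np.ones(child.cardinality), size=n_rows)
    cc = rng.integers(5, 50, size=n_rows).astype(float) if counts else None
    return CPT(
        child, tuple(parents),
        table.reshape(shape + (child.cardinality,)),
        config_counts=cc.reshape(shape) if cc is not None else None,
    )


class TestCanonicalOrder:
    def test_lexicographic_default(self):
        assert canonical_parent_order(["b", "a", "c"]) == ("a", "b", "c")

    def test_priority_order(self):
        assert canonical_parent_order(
            ["b", "a", "c"], priority=["c", "b", "a"]
        ) == ("c", "b", "a")


class TestExtendCPT:
    def test_empty_extension_is_identity(self):
        cpt = _random_cpt(_var("x"), [_var("a")], seed=1)
        assert extend_cpt(cpt, []) is cpt

    def test_three_state_parent_triples_table(self):
        cpt = _random_cpt(_var("x"), [_var("a")], seed=2)
        out = extend_cpt(cpt, [_var("b", 3)])
        assert out.parent_names == ("a", "b")
        assert out.table.shape == (2, 3, 2)
        assert out.bogus == {"b"}
        for ia in range(2):
            for ib in range(3):
                np.testing.assert_array_equal(out.table[ia, ib],
                                              cpt.table[ia])

    @pytest.mark.parametrize("seed", range(4))
    def test_extend_then_marginalize_recovers(self, seed):
        # summation oracle: under any prior over the bogus parent, the
        # weighted average over its states returns the original rows
        rng = np.random.default_rng(seed)
        cpt = _random_cpt(_var("x", 3), [_var("a")], seed=seed)
        out = extend_cpt(cpt, [_var("b", 4)])
        prior = rng.dirichlet(np.ones(4))
        axis = out.parent_names.index("b")
        recovered = np.tensordot(prior, np.moveaxis(out.table, axis, 0),
                                 axes=(0, 0))
        np.testing.assert_allclose(recovered, cpt.table, atol=1e-12)

    def test_overlap_rejected(self):
        cpt = _random_cpt(_var("x"), [_var("a")])
        with pytest.raises(ContractError):
            extend_cpt(cpt, [_var("a")])
        with pytest.raises(ContractError):
            extend_cpt(cpt, [_var("x")])

    def test_counts_dropped(self):
        cpt = _random_cpt(_var("x"), [_var("a")], counts=True)
        assert extend_cpt(cpt, [_var("b")]).config_counts is None


class TestCommonForm:
    def test_equal_parent_sets_unchanged(self):
        a = _random_cpt(_var("x"), [_var("p")], seed=1)
        b = _random_cpt(_var("x"), [_var("p")], seed=2)
        outA, outB = common_form(a, b)
        np.testing.assert_array_equal(outA.table, a.table)
        np.testing.assert_array_equal(outB.table, b.table)

    def test_disjoint_parents(self):
        a = _random_cpt(_var("x"), [_var("A")], seed=3)
        b = _random_cpt(_var("x"), [_var("B")], seed=4)
        outA, outB = common_form(a, b)
        assert outA.parent_names == outB.parent_names == ("A", "B")
        # A-rows constant in B for the first CPT, vice versa for the second
        assert np.ptp(outA.table, axis=1).max() == 0
        assert np.ptp(outB.table, axis=0).max() == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_index_alignment_audit(self, seed):
        pa = _var("A", 2)
        pb = _var("B", 3)
        pc = _var("C", 2)
        a = _random_cpt(_var("x"), [pa, pb], seed=seed)
        b = _random_cpt(_var("x"), [pb, pc], seed=seed + 50)
        outA, outB = common_form(a, b)
        assert outA.parent_names == outB.parent_names
        assert outA.table.shape == outB.table.shape
        idx = {n: i for i, n in enumerate(outA.parent_names)}
        for cfg in itertools.product(range(2), range(3), range(2)):
            by_name = dict(zip(outA.parent_names, cfg))
            np.testing.assert_array_equal(
                outA.table[cfg], a.table[(by_name["A"], by_name["B"])]
            )
            np.testing.assert_array_equal(
                outB.table[cfg], b.table[(by_name["B"], by_name["C"])]
            )
        assert idx  # audit covered every shared configuration

    def test_conflicting_shared_parent_states(self):
        a = _random_cpt(_var("x"), [_var("p", 2)])
        b = _random_cpt(_var("x"), [_var("p", 3)])
        with pytest.raises(ModelError):
            common_form(a, b)

    def test_different_children_rejected(self):
        with pytest.raises(ContractError):
            common_form(_random_cpt(_var("x"), []), _random_cpt(_var("y"), []))


class TestAggregate:
    def test_identical_inputs_fixed_point(self):
        cpt = _random_cpt(_var("x", 3), [_var("a")], seed=5)
        for weights in [(1, 1), (3, 7)]:
            out = aggregate_cpts([cpt, cpt], AggregationSpec(weights=weights))
            np.testing.assert_allclose(out.table, cpt.table, atol=1e-12)

    def test_stated_arithmetic(self):
        x = _var("x")
        a = CPT(x, (), np.array([0.3, 0.7]))
        b = CPT(x, (), np.array([0.5, 0.5]))
        out = aggregate_cpts([a, b], AggregationSpec(weights=(1, 1)))
        assert out.table[0] == pytest.approx(0.4, abs=1e-12)
        out = aggregate_cpts([a, b], AggregationSpec(weights=(1, 3)))
        assert out.table[0] == pytest.approx(0.45, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_merged_database_identity(self, seed):
        """Count-weighted aggregation equals estimation on D1 u D2."""
        bn = fixture_random_bn(4, max_parents=2, cardinality=2, seed=seed)
        d1 = forward_sample(bn, 120, seed=seed * 2 + 1)
        d2 = forward_sample(bn, 300, seed=seed * 2 + 2)
        merged = d1.concat(d2)
        b1 = learn_parameters(d1, bn.dag)
        b2 = learn_parameters(d2, bn.dag)
        oracle = learn_parameters(merged, bn.dag)
        spec = AggregationSpec(weights=(d1.n_samples, d2.n_samples))
        for name in sorted(bn.nodes):
            got = aggregate_cpts([b1.cpts[name], b2.cpts[name]], spec)
            np.testing.assert_allclose(
                got.table, oracle.cpts[name].table, atol=1e-12
            )

    def test_associativity_under_weight_accumulation(self):
        x = _var("x", 3)
        cpts = [_random_cpt(x, [_var("p")], seed=s) for s in (1, 2, 3)]
        w = (2, 3, 5)
        spec_all = AggregationSpec(weights=w, count_weighted=False)
        joint = aggregate_cpts(cpts, spec_all)
        ab = aggregate_cpts(cpts[:2], AggregationSpec(weights=w[:2],
                                                      count_weighted=False))
        folded = aggregate_cpts(
            [ab, cpts[2]],
            AggregationSpec(weights=(w[0] + w[1], w[2]), count_weighted=False),
        )
        np.testing.assert_allclose(folded.table, joint.table, atol=1e-12)

    def test_dominant_weight_limit(self):
        a = _random_cpt(_var("x"), [], seed=9)
        b = _random_cpt(_var("x"), [], seed=10)
        out = aggregate_cpts(
            [a, b], AggregationSpec(weights=(10**9, 1), count_weighted=False)
        )
        np.testing.assert_allclose(out.table, a.table, atol=1e-8)

    def test_shape_mismatch_rejected(self):
        a = _random_cpt(_var("x"), [_var("p")])
        b = _random_cpt(_var("x"), [])
        with pytest.raises(ContractError):
            aggregate_cpts([a, b], AggregationSpec(weights=(1, 1)))

    def test_weight_validation(self):
        with pytest.raises(ContractError):
            AggregationSpec(weights=(0, 1))


class TestBogusDetection:
    def test_constant_rows_flagged(self):
        cpt = extend_cpt(_random_cpt(_var("x"), [], seed=1), [_var("p", 3)])
        assert detect_bogus_parents(cpt, 0.0) == {"p"}

    def test_strong_variation_not_flagged(self):
        table = np.array([[0.9, 0.1], [0.1, 0.9]])
        cpt = CPT(_var("x"), (_var("p"),), table)
        assert detect_bogus_parents(cpt, 1e-3) == set()

    @pytest.mark.parametrize("sigma", [1e-4, 1e-2])
    def test_noisy_extension_matches_loop_oracle(self, sigma):
        rng = np.random.default_rng(0)
        cpt = extend_cpt(_random_cpt(_var("x"), [_var("a")], seed=2),
                         [_var("p", 3)])
        noisy = cpt.table + rng.normal(0, sigma, cpt.table.shape)
        noisy = np.clip(noisy, 1e-6, None)
        noisy /= noisy.sum(-1, keepdims=True)
        noisy_cpt = cpt.with_table(noisy)
        eps = 1e-3
        flagged = detect_bogus_parents(noisy_cpt, eps)
        for parent in noisy_cpt.parent_names:
            axis = noisy_cpt.parent_names.index(parent)
            oracle_var = np.var(noisy, axis=axis, ddof=0).mean()
            assert (parent in flagged) == (oracle_var <= eps)


class TestSimplify:
    @pytest.mark.parametrize("seed", range(4))
    def test_round_trip_extension(self, seed):
        cpt = _random_cpt(_var("x", 3), [_var("a")], seed=seed)
        extended = extend_cpt(cpt, [_var("p"), _var("q", 3)])
        simplified, removed = simplify_cpt(extended, 0.0)
        assert removed == {"p", "q"}
        assert simplified.parent_names == cpt.parent_names
        np.testing.assert_allclose(simplified.table, cpt.table, atol=1e-12)

    def test_no_candidate_untouched(self):
        table = np.array([[0.9, 0.1], [0.1, 0.9]])
        cpt = CPT(_var("x"), (_var("p"),), table)
        simplified, removed = simplify_cpt(cpt, 1e-4)
        assert removed == set()
        np.testing.assert_array_equal(simplified.table, table)

    def test_near_constant_parent_removed_matches_marginalization(self):
        rng = np.random.default_rng(3)
        strong = CPT(_var("x"), (_var("a"),),
                     np.array([[0.9, 0.1], [0.1, 0.9]]))
        extended = extend_cpt(strong, [_var("p", 3)])
        noise = rng.normal(0, 5e-4, extended.table.shape)
        table = np.clip(extended.table + noise, 1e-9, None)
        table /= table.sum(-1, keepdims=True)
        noisy = extended.with_table(table)
        simplified, removed = simplify_cpt(noisy, 1e-3)
        assert removed == {"p"}
        axis = noisy.parent_names.index("p")
        oracle = table.mean(axis=axis)
        oracle /= oracle.sum(-1, keepdims=True)
        np.testing.assert_allclose(simplified.table, oracle, atol=1e-12)

    def test_candidate_restriction(self):
        cpt = extend_cpt(_random_cpt(_var("x"), [], seed=4), [_var("p", 2)])
        kept, removed = simplify_cpt(cpt, 1.0, candidates=set())
        assert removed == set()
        assert kept.parent_names == ("p",)


class TestCrossInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_extend_aggregate_simplify_identity(self, seed):
        cpt = _random_cpt(_var("x", 3), [_var("a", 2)], seed=seed)
        extended = extend_cpt(cpt, [_var("b", 2), _var("c", 3)])
        agg = aggregate_cpts(
            [extended, extended], AggregationSpec(weights=(2, 5))
        )
        simplified, removed = simplify_cpt(agg, 0.0)
        assert removed == {"b", "c"}
        np.testing.assert_allclose(simplified.table, cpt.table, atol=1e-12)
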