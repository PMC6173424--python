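"""Greedy backward/forward item selection against a reference classification."""

import numpy as np
import pytest

import readix as rx
from readix.agreement import DegenerateClassificationError
from conftest import make_random_matrix, naive_subset_kappa


def _reference(matrix, dmap, q):
    scores = rx.compute_index(matrix, rx.IndexDefinition(matrix.item_ids, dmap))
    return rx.classify_quantiles(scores, q)


class TestEvaluateSubset:
    def test_full_set_reproduces_reference_exactly(self, small_matrix):
        matrix, dmap = small_matrix
        ref = _reference(matrix, dmap, 4)
        assert rx.evaluate_subset(matrix, matrix.item_ids, dmap, ref) == 1.0

    def test_matches_naive_pipeline_on_random_subsets(self, small_matrix):
        matrix, dmap = small_matrix
        q = 4
        ref = _reference(matrix, dmap, q)
        rng = np.random.default_rng(17)
        for _ in range(12):
            size = int(rng.integers(2, 9))
            items = list(rng.choice(matrix.item_ids, size, replace=False))
            got = rx.evaluate_subset(matrix, items, dmap, ref)
            want = naive_subset_kappa(
                matrix, sorted(items, key=matrix.item_ids.index),
                dmap.assignment, dmap.domains, ref.groups, q,
            )
            assert got == pytest.approx(want, abs=1e-12)

    def test_removing_uniform_zero_item(self):
        rng = np.random.default_rng(23)
        items = (rng.random((40, 6)) < 0.5).astype(np.int8)
        items[:, 5] = 0
        matrix = rx.ItemMatrix(
            facility_ids=np.array([f"f{i}" for i in range(40)]),
            country=np.array(["c"] * 40),
            facility_type=np.array(["non-hospital"] * 40),
            weight=np.ones(40),
            item_ids=("a0", "a1", "a2", "b0", "b1", "b2"),
            items=items,
        )
        # single domain: dropping a constant-zero item rescales every score
        # by the same monotone map, so the classification cannot move
        dmap1 = rx.DomainMap({i: "A" for i in matrix.item_ids}, ("A",))
        ref1 = _reference(matrix, dmap1, 4)
        subset = ("a0", "a1", "a2", "b0", "b1")
        assert rx.evaluate_subset(matrix, subset, dmap1, ref1) == pytest.approx(
            1.0
        )
        # two domains: renormalizing one domain's denominator reweights it
        # against the other, so the expected kappa comes from the oracle
        dmap2 = rx.DomainMap({"a0": "A", "a1": "A", "a2": "A",
                              "b0": "B", "b1": "B", "b2": "B"}, ("A", "B"))
        ref2 = _reference(matrix, dmap2, 4)
        want = naive_subset_kappa(matrix, list(subset), dmap2.assignment,
                                  dmap2.domains, ref2.groups, 4)
        assert rx.evaluate_subset(matrix, subset, dmap2, ref2) == pytest.approx(
            want, abs=1e-12
        )

    def test_unknown_item_rejected(self, small_matrix):
        matrix, dmap = small_matrix
        ref = _reference(matrix, dmap, 3)
        with pytest.raises(KeyError):
            rx.evaluate_subset(matrix, ("nope",), dmap, ref)
        with pytest.raises(ValueError):
            rx.evaluate_subset(matrix, (), dmap, ref)


class TestGreedyAgainstExhaustiveOracle:
    """At every step the engine's pick must be the enumeration argmax."""

    @pytest.mark.parametrize("direction", ["backward", "forward"])
    def test_per_step_argmax_matches_enumeration(self, oracle_matrix,
                                                 direction):
        matrix, dmap = oracle_matrix
        q = 3
        ref = _reference(matrix, dmap, q)
        if direction == "backward":
            trace = rx.backward_select(matrix, dmap, ref, (), 1)
            current = list(matrix.item_ids)
            for item, kappa in trace.steps:
                best = None
                for cand in current:  # column order = tie-break order
                    rest = [i for i in current if i != cand]
                    k = naive_subset_kappa(matrix, rest, dmap.assignment,
                                           dmap.domains, ref.groups, q)
                    if best is None or k > best[1] + 1e-12:
                        best = (cand, k)
                assert item == best[0]
                assert kappa == pytest.approx(best[1], abs=1e-12)
                current.remove(item)
        else:
            trace = rx.forward_select(matrix, dmap, ref, (), len(matrix.item_ids))
            current = []
            for item, kappa in trace.steps:
                best = None
                for cand in matrix.item_ids:
                    if cand in current:
                        continue
                    k = naive_subset_kappa(
                        matrix,
                        sorted(current + [cand], key=matrix.item_ids.index),
                        dmap.assignment, dmap.domains, ref.groups, q,
                    )
                    if best is None or k > best[1] + 1e-12:
                        best = (cand, k)
                assert item == best[0]
                assert kappa == pytest.approx(best[1], abs=1e-12)
                current.append(item)


class TestBackwardSelect:
    def test_constant_items_removed_first(self):
        # 5 informative + 5 constant-zero items: the constants can never
        # change any facility's ranking, so they go in the first five steps
        rng = np.random.default_rng(31)
        informative = (rng.random((60, 5)) < rng.uniform(0.2, 0.8, 5)).astype(np.int8)
        items = np.concatenate([informative, np.zeros((60, 5), np.int8)], axis=1)
        ids = tuple(f"s{i}" for i in range(5)) + tuple(f"z{i}" for i in range(5))
        matrix = rx.ItemMatrix(
            facility_ids=np.array([f"f{i}" for i in range(60)]),
            country=np.array(["c"] * 60),
            facility_type=np.array(["non-hospital"] * 60),
            weight=np.ones(60),
            item_ids=ids,
            items=items,
        )
        dmap = rx.DomainMap({i: ("A" if i.startswith("s") else "B") for i in ids},
                            ("A", "B"))
        ref = _reference(matrix, dmap, 4)
        # verify the fixture premise with the oracle: at the start, removing
        # any informative item strictly costs agreement
        for cand in [f"s{i}" for i in range(5)]:
            rest = [i for i in ids if i != cand]
            k = naive_subset_kappa(matrix, rest, dmap.assignment, dmap.domains,
                                   ref.groups, 4)
            assert k < 1.0
        trace = rx.backward_select(matrix, dmap, ref, (), 1)
        removed = [item for item, _ in trace.steps]
        assert set(removed[:5]) == {f"z{i}" for i in range(5)}
        assert all(k == pytest.approx(1.0) for _, k in trace.steps[:5])

    def test_all_items_locked_yields_empty_trace(self, small_matrix):
        matrix, dmap = small_matrix
        ref = _reference(matrix, dmap, 4)
        trace = rx.backward_select(matrix, dmap, ref, matrix.item_ids,
                                   len(matrix.item_ids))
        assert trace.steps == ()

    def test_locked_items_never_removed(self, small_matrix):
        matrix, dmap = small_matrix
        ref = _reference(matrix, dmap, 4)
        locked = ("A0", "C3")
        trace = rx.backward_select(matrix, dmap, ref, locked, 2)
        removed = {i for i, _ in trace.steps}
        assert removed == set(matrix.item_ids) - set(locked)

    def test_stop_size_bounds(self, small_matrix):
        matrix, dmap = small_matrix
        ref = _reference(matrix, dmap, 4)
        with pytest.raises(ValueError):
            rx.backward_select(matrix, dmap, ref, (), 100)
        with pytest.raises(ValueError):
            rx.backward_select(matrix, dmap, ref, ("A0", "A1"), 1)


class TestForwardSelect:
    def test_single_dominant_item_chosen_first(self):
        # one item equals a clean facility gradient; every other item is a
        # coin flip, so the gradient item gives the best 1-item index
        rng = np.random.default_rng(41)
        n = 60
        theta_rank = np.arange(n)
        dominant = (theta_rank >= n // 2).astype(np.int8)
        noise = (rng.random((n, 5)) < 0.5).astype(np.int8)
        items = np.concatenate([dominant[:, None], noise], axis=1)
        ids = ("hero", "n1", "n2", "n3", "n4", "n5")
        matrix = rx.ItemMatrix(
            facility_ids=np.array([f"f{i}" for i in range(n)]),
            country=np.array(["c"] * n),
            facility_type=np.array(["non-hospital"] * n),
            weight=np.ones(n),
            item_ids=ids,
            items=items,
        )
        dmap = rx.DomainMap({i: "A" for i in ids}, ("A",))
        ref = rx.classify_quantiles(
            rx.compute_index(matrix, rx.IndexDefinition(("hero",), dmap)), 2
        )
        trace = rx.forward_select(matrix, dmap, ref, (), 3)
        assert trace.steps[0][0] == "hero"
        assert trace.steps[0][1] == pytest.approx(1.0)

    def test_stop_at_locked_size_yields_empty_trace(self, small_matrix):
        matrix, dmap = small_matrix
        ref = _reference(matrix, dmap, 4)
        locked = ("A0", "B0")
        trace = rx.forward_select(matrix, dmap, ref, locked, len(locked))
        assert trace.steps == ()

    def test_all_constant_candidates_raise_degenerate(self):
        items = np.zeros((10, 3), np.int8)
        items[:5, 0] = 0  # all items constant zero
        matrix = rx.ItemMatrix(
            facility_ids=np.array([f"f{i}" for i in range(10)]),
            country=np.array(["c"] * 10),
            facility_type=np.array(["non-hospital"] * 10),
            weight=np.ones(10),
            item_ids=("a", "b", "c"),
            items=items,
        )
        dmap = rx.DomainMap({"a": "A", "b": "A", "c": "A"}, ("A",))
        ref = rx.QuantileClassification(matrix.facility_ids,
                                        np.tile([1, 2], 5), 2)
        with pytest.raises(DegenerateClassificationError):
            rx.forward_select(matrix, dmap, ref, (), 1)


class TestIndexAt:
    def test_full_m_returns_whole_universe(self, small_matrix):
        matrix, dmap = small_matrix
        ref = _reference(matrix, dmap, 4)
        trace = rx.backward_select(matrix, dmap, ref, (), 1)
        assert set(rx.index_at(trace, matrix.n_items).item_ids) == set(
            matrix.item_ids
        )

    @pytest.mark.parametrize("direction", ["backward", "forward"])
    def test_nested_family(self, small_matrix, direction):
        matrix, dmap = small_matrix
        ref = _reference(matrix, dmap, 4)
        locked = ("B0",)
        if direction == "backward":
            trace = rx.backward_select(matrix, dmap, ref, locked, 1)
        else:
            trace = rx.forward_select(matrix, dmap, ref, locked,
                                      matrix.n_items)
        lo = max(1, len(locked))
        prev = None
        for m in range(lo, matrix.n_items + 1):
            ids = set(rx.index_at(trace, m).item_ids)
            assert len(ids) == m
            assert set(locked) <= ids
            if prev is not None:
                assert prev < ids
            prev = ids

    def test_out_of_range_m_rejected(self, small_matrix):
        matrix, dmap = small_matrix
        ref = _reference(matrix, dmap, 4)
        trace = rx.backward_select(matrix, dmap, ref, (), 5)
        with pytest.raises(ValueError):
            rx.index_at(trace, 4)  # below the stop size
        with pytest.raises(ValueError):
            rx.index_at(trace, matrix.n_items + 1)


class TestSelectionOrderReport:
    def test_last_discarded_item_gets_order_one(self, small_matrix):
        matrix, dmap = small_matrix
        ref = _reference(matrix, dmap, 4)
        trace = rx.backward_select(matrix, dmap, ref, ("A0",), 1)
        report = rx.selection_order_report(trace)
        last_removed = trace.steps[-1][0]
        row = report[report.item_id == last_removed]
        assert row.selection_order.iloc[0] == 1
        first_removed = trace.steps[0][0]
        assert (
            report[report.item_id == first_removed].selection_order.iloc[0]
            == len(trace.steps)
        )
        assert report[report.item_id == "A0"].selection_order.isna().all()
        assert report[report.item_id == "A0"].locked.iloc[0] == 1

    def test_forward_orders_follow_addition_order(self, small_matrix):
        matrix, dmap = small_matrix
        ref = _reference(matrix, dmap, 4)
        trace = rx.forward_select(matrix, dmap, ref, (), 4)
        report = rx.selection_order_report(trace).dropna(
            subset=["selection_order"]
        )
        got = dict(zip(report.item_id, report.selection_order))
        for pos, (item, _) in enumerate(trace.steps, start=1):
            assert got[item] == pos
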