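"""Provenance graph: links, closures, trees and origin tracing."""

import networkx as nx
import pytest

from protrack import (CycleError, DuplicateError, NotFoundError, Store,
                      ValidationError, access, synth, tracking)


def _linked_store(tmp_path, edges, n_nodes, name="g"):
    """Store holding experiments 1..n plus the given provenance edges."""
    root = tmp_path / name
    root.mkdir()
    store = Store(root / "s.db")
    access.register_user(store, "u", "pw")
    store.create_project("P", "", "u")
    for i in range(1, n_nodes + 1):
        store.create_experiment(1, "PREP", f"e{i}", "u", "2011-01-01",
                                _force_id=i)
    for parent, child in edges:
        tracking.link(store, parent, child)
    return store


class TestLink:
    def test_worked_example_topology_links_cleanly(self, demo_store):
        assert tracking.children(demo_store, 1) == {100, 146, 174}
        assert tracking.parents(demo_store, 1) == set()

    def test_self_link_rejected(self, store):
        e = store.create_experiment(1, "PREP", "t", "gloria", "2011-01-01")
        with pytest.raises(ValidationError):
            tracking.link(store, e.id, e.id)

    def test_two_cycle_rejected(self, tmp_path):
        store = _linked_store(tmp_path, [(1, 2)], 2)
        with pytest.raises(CycleError):
            tracking.link(store, 2, 1)

    def test_duplicate_edge_rejected(self, tmp_path):
        store = _linked_store(tmp_path, [(1, 2)], 2)
        with pytest.raises(DuplicateError):
            tracking.link(store, 1, 2)

    def test_cross_project_link_rejected(self, store):
        a = store.create_experiment(1, "PREP", "a", "gloria", "2011-01-01")
        store.create_project("Other", "", "gloria")
        b = store.create_experiment(2, "PREP", "b", "gloria", "2011-01-02")
        with pytest.raises(ValidationError):
            tracking.link(store, a.id, b.id)

    def test_child_predating_parent_warns_but_links(self, store):
        a = store.create_experiment(1, "PREP", "a", "gloria", "2011-06-01")
        b = store.create_experiment(1, "PREP", "b", "gloria", "2011-01-01")
        with pytest.warns(UserWarning, match="predates"):
            tracking.link(store, a.id, b.id)
        assert tracking.children(store, a.id) == {b.id}

    def test_unknown_ids_rejected(self, store):
        with pytest.raises(NotFoundError):
            tracking.link(store, 1, 999)


class TestClosures:
    def test_worked_example_descendants_and_ancestors(self, demo_store):
        assert tracking.descendants(demo_store, 1) == {100, 146, 174, 101, 148}
        assert 1 in tracking.ancestors(demo_store, 148)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_networkx_transitive_closure(self, tmp_path, seed):
        edges = synth.random_dag(20, 0.15, seed)
        store = _linked_store(tmp_path, edges, 20, name=f"dag{seed}")
        graph = nx.DiGraph(edges)
        graph.add_nodes_from(range(1, 21))
        for node in range(1, 21):
            assert tracking.descendants(store, node) == \
                nx.descendants(graph, node)
            assert tracking.ancestors(store, node) == \
                nx.ancestors(graph, node)
        store.close()

    def test_descendants_and_ancestors_are_dual(self, tmp_path):
        edges = synth.random_dag(15, 0.2, 99)
        store = _linked_store(tmp_path, edges, 15)
        for x in range(1, 16):
            for y in tracking.descendants(store, x):
                assert x in tracking.ancestors(store, y)
        store.close()

    def test_cycle_rejection_matches_brute_force_detector(self, tmp_path):
        """Feed a random edge stream; accept/reject must agree with
        networkx cycle detection on the would-be graph."""
        import random
        rng = random.Random(7)
        store = _linked_store(tmp_path, [], 12)
        graph = nx.DiGraph()
        graph.add_nodes_from(range(1, 13))
        for _ in range(120):
            u, v = rng.randint(1, 12), rng.randint(1, 12)
            trial = graph.copy()
            trial.add_edge(u, v)
            should_fail = (u == v or graph.has_edge(u, v)
                           or not nx.is_directed_acyclic_graph(trial))
            if should_fail:
                with pytest.raises((ValidationError, DuplicateError)):
                    tracking.link(store, u, v)
            else:
                tracking.link(store, u, v)
                graph.add_edge(u, v)
        store.close()


class TestTree:
    def test_worked_example_tree_shape(self, demo_store):
        tree = tracking.build_tree(demo_store, 1)
        assert tree.count_at_depth(1) == 3
        assert tree.count_at_depth(2) == 2
        assert len(tree.to_text().splitlines()) == 6

    def test_children_ordered_by_internal_id(self, demo_store):
        tree = tracking.build_tree(demo_store, 1)
        assert [c.id for c in tree.children] == [100, 146, 174]

    def test_isolated_experiment_is_single_node(self, store):
        e = store.create_experiment(1, "PREP", "solo", "gloria", "2011-01-01")
        tree = tracking.build_tree(store, e.id)
        assert tree.children == []
        assert tree.node_ids() == [e.id]

    def test_tree_nodes_equal_descendants_when_subdag_is_tree(self, demo_store):
        tree = tracking.build_tree(demo_store, 1)
        assert set(tree.node_ids()) == {1} | tracking.descendants(demo_store, 1)

    def test_shared_node_repeated_per_branch(self, tmp_path):
        # diamond 1->2, 1->3, 2->4, 3->4: node 4 appears under both branches
        store = _linked_store(tmp_path, [(1, 2), (1, 3), (2, 4), (3, 4)], 4)
        tree = tracking.build_tree(store, 1)
        assert sorted(tree.node_ids()) == [1, 2, 3, 4, 4]
        store.close()

    def test_rendering_is_deterministic(self, tmp_path):
        texts = []
        for name in ("a", "b"):
            root = tmp_path / name
            root.mkdir()
            s = Store(root / "s.db")
            synth.make_demo_store(s, seed=3)
            texts.append(tracking.build_tree(s, 1).to_json())
            s.close()
        assert texts[0] == texts[1]


class TestTraceOrigin:
    def test_worked_example_traces_to_extraction_sample(self, demo_store):
        origins = tracking.trace_origin(demo_store, 148)
        assert [root for root, _ in origins] == [1]
        (_, samples), = origins
        assert [s.organism for s in samples] == ["Schistosoma mansoni"]

    def test_root_traces_to_itself(self, demo_store):
        assert [r for r, _ in tracking.trace_origin(demo_store, 1)] == [1]

    @pytest.mark.parametrize("seed", [5, 11])
    def test_origin_set_equals_parentless_ancestors(self, tmp_path, seed):
        edges = synth.random_dag(18, 0.12, seed)
        store = _linked_store(tmp_path, edges, 18, name=f"o{seed}")
        graph = nx.DiGraph(edges)
        graph.add_nodes_from(range(1, 19))
        for node in range(1, 19):
            expected = {a for a in nx.ancestors(graph, node) | {node}
                        if graph.in_degree(a) == 0}
            assert {r for r, _ in tracking.trace_origin(store, node)} == \
                expected
        store.close()
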