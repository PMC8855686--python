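import itertools

import numpy as np
import pytest

from graphd import (
    DecisionModel,
    Graph,
    bind,
    bundle,
    decision_score,
    default_decision_model,
    encode_graph,
    encode_node_memories,
    generate_codebook,
    make_value_encoder,
    query_edge,
    query_weight,
    reconstruct_graph,
    reconstruct_node_memory,
    similarity,
)
from graphd.synthetic_io import GeneratorConfig, generate_random_graph

from .conftest import random_bipolar

MODEL = DecisionModel(T=0.5, d=5, D=10000)


class TestDecisionScore:
    def test_exact_memory_scores_one(self, triangle_codebook):
        h = triangle_codebook.vector("B")
        assert decision_score(h, h) == 1.0

    def test_non_neighbor_band(self, rng):
        # exact degree-20 memory, non-neighbor probe: |R| <= 4*sqrt(d/D)
        d, D, trials = 20, 10000, 1000
        hits = 0
        for _ in range(trials):
            mem = random_bipolar(rng, d, D).sum(axis=0)
            probe = random_bipolar(rng, 1, D)[0]
            if abs(decision_score(mem, probe)) <= 4 * np.sqrt(d / D):
                hits += 1
        assert hits / trials >= 0.99

    def test_equals_signal_noise_decomposition(self):
        # brute-force decomposition oracle on a 10-node graph
        g = generate_random_graph(GeneratorConfig(V=10, E=20, seed=5))
        cb = generate_codebook(g.nodes, 2000, seed=6)
        mems = {m.label: m.vector for m in encode_node_memories(g, cb)}
        for a in g.nodes:
            for b in g.nodes:
                if a == b:
                    continue
                r = decision_score(mems[a], cb.vector(b))
                oracle = sum(
                    similarity(cb.vector(j), cb.vector(b))
                    for j in sorted(g.neighbors(a))
                )
                assert r == pytest.approx(oracle, abs=1e-9)


class TestQueryEdge:
    def test_single_edge_scores_exactly_one(self):
        cb = generate_codebook(["a", "b", "c"], 10000, seed=1)
        g = Graph.build(["a", "b", "c"], [("a", "b")])
        gm = encode_graph(g, cb)
        exists, score = query_edge(gm, "a", "b", MODEL, cb)
        assert exists and score == 1.0
        exists, score = query_edge(gm, "a", "c", MODEL, cb)
        assert not exists and abs(score) <= 4 / np.sqrt(10000)

    def test_directed_orientation(self):
        cb = generate_codebook(["a", "b"], 10000, seed=2)
        g = Graph.build(["a", "b"], [("a", "b")], directed=True)
        gm = encode_graph(g, cb)
        assert query_edge(gm, "a", "b", MODEL, cb)[0]
        assert not query_edge(gm, "b", "a", MODEL, cb)[0]

    def test_self_query_rejected(self, triangle, triangle_codebook):
        gm = encode_graph(triangle, triangle_codebook)
        with pytest.raises(ValueError, match="self-loop"):
            query_edge(gm, "A", "A", MODEL, triangle_codebook)

    def test_unknown_label_rejected(self, triangle, triangle_codebook):
        gm = encode_graph(triangle, triangle_codebook)
        with pytest.raises(KeyError):
            query_edge(gm, "A", "Z", MODEL, triangle_codebook)


class TestQueryWeight:
    def test_single_weighted_edge_exact(self):
        # D divisible by 10 => weight 0.7 recovered exactly (zero cross-noise)
        D = 5000
        cb = generate_codebook(["a", "b", "c"], D, seed=3)
        enc = make_value_encoder(D, seed=4)
        g = Graph.build(["a", "b", "c"], [("a", "b", 0.7)], weighted=True)
        gm = encode_graph(g, cb, enc)
        exists, w = query_weight(gm, "a", "b", cb, enc, MODEL)
        assert exists
        assert w == pytest.approx(0.7, abs=1e-12)

    def test_non_edge_not_found(self):
        D = 5000
        cb = generate_codebook(["a", "b", "c"], D, seed=3)
        enc = make_value_encoder(D, seed=4)
        g = Graph.build(["a", "b", "c"], [("a", "b", 0.7)], weighted=True)
        gm = encode_graph(g, cb, enc)
        exists, _ = query_weight(gm, "a", "c", cb, enc, MODEL)
        assert not exists

    def test_twenty_edge_mean_absolute_error(self):
        D = 10000
        g = generate_random_graph(GeneratorConfig(V=15, E=20, weighted=True, seed=5))
        cb = generate_codebook(g.nodes, D, seed=6)
        enc = make_value_encoder(D, seed=7)
        gm = encode_graph(g, cb, enc)
        errs = []
        for (u, v), w in g.edges.items():
            exists, what = query_weight(gm, u, v, cb, enc, MODEL)
            assert exists
            errs.append(abs(what - w))
        assert np.mean(errs) <= 0.05

    def test_unweighted_memory_rejected(self, triangle, triangle_codebook):
        gm = encode_graph(triangle, triangle_codebook)
        enc = make_value_encoder(triangle_codebook.D, seed=0)
        with pytest.raises(ValueError, match="weighted"):
            query_weight(gm, "A", "B", triangle_codebook, enc, MODEL)


class TestNodeMemoryReconstruction:
    def test_single_edge_exact(self):
        cb = generate_codebook(["a", "b", "c"], 2000, seed=1)
        g = Graph.build(["a", "b", "c"], [("a", "b")])
        gm = encode_graph(g, cb)
        sets, res = reconstruct_node_memory(gm, cb, MODEL)
        assert sets == {"a": {"b"}, "b": {"a"}, "c": set()}
        assert res.converged

    def test_within_capacity_full_recovery(self):
        # 100 edges at D=2000: all neighbor sets exactly recovered
        for seed in range(3):
            g = generate_random_graph(GeneratorConfig(V=50, E=100, seed=seed))
            cb = generate_codebook(g.nodes, 2000, seed=seed + 50)
            gm = encode_graph(g, cb)
            sets, res = reconstruct_node_memory(gm, cb)
            assert res.converged
            assert sets == {n: g.neighbors(n) for n in g.nodes}

    def test_overloaded_failure_is_reported_not_raised(self):
        g = generate_random_graph(GeneratorConfig(V=30, E=300, seed=9))
        cb = generate_codebook(g.nodes, 500, seed=10)
        gm = encode_graph(g, cb)
        sets, res = reconstruct_node_memory(gm, cb, max_iter=10)
        truth = {n: g.neighbors(n) for n in g.nodes}
        assert (not res.converged) or sets != truth

    def test_directed_recovery(self):
        g = generate_random_graph(GeneratorConfig(V=20, E=60, directed=True, seed=11))
        cb = generate_codebook(g.nodes, 4000, seed=12)
        gm = encode_graph(g, cb)
        sets, res = reconstruct_node_memory(gm, cb)
        assert res.converged
        assert sets == {n: g.neighbors(n) for n in g.nodes}


class TestGraphReconstruction:
    def test_zero_memory_empty_graph(self):
        cb = generate_codebook(["a", "b"], 500, seed=0)
        g = Graph.build(["a", "b"], [])
        gm = encode_graph(g, cb)
        res = reconstruct_graph(gm, cb, MODEL)
        assert res.converged
        assert res.iterations == 0
        assert res.graph.n_edges == 0

    def test_triangle_one_iteration(self, triangle):
        cb = generate_codebook(["A", "B", "C"], 1000, seed=1)
        gm = encode_graph(triangle, cb)
        res = reconstruct_graph(gm, cb, reference=triangle)
        assert res.mismatched_edges == 0
        assert res.iterations == 1
        # brute-force check over all 3 pairs against the decoded graph
        for u, v in itertools.combinations(["A", "B", "C"], 2):
            assert res.graph.has_edge(u, v) == triangle.has_edge(u, v)

    def test_within_capacity_recovery_30_150(self):
        # 30 nodes / 150 edges at D=3500 recovered within 15 iterations
        g = generate_random_graph(GeneratorConfig(V=30, E=150, seed=13))
        cb = generate_codebook(g.nodes, 3500, seed=14)
        gm = encode_graph(g, cb)
        res = reconstruct_graph(gm, cb, reference=g)
        assert res.mismatched_edges == 0
        assert res.iterations <= 15

    def test_true_edge_set_is_fixed_point(self):
        # if beliefs equal the truth, the noise-corrected test keeps them
        for seed in range(20):
            g = generate_random_graph(GeneratorConfig(V=12, E=20, seed=seed))
            cb = generate_codebook(g.nodes, 4000, seed=seed + 200)
            gm = encode_graph(g, cb)
            model = default_decision_model(gm, cb)
            # with correct beliefs, residual G - G_k is exactly zero, so each
            # true edge scores f=1 > T and each non-edge scores 0 < T
            g_k = sum(
                bind(cb.vector(u), cb.vector(v)) for (u, v) in g.edges
            )
            assert np.array_equal(gm.vector, g_k)
            res = reconstruct_graph(gm, cb, model, reference=g)
            if res.mismatched_edges == 0:
                # rerunning from the converged state changes nothing
                res2 = reconstruct_graph(gm, cb, model, reference=g)
                assert res2.mismatched_edges == 0

    def test_mismatch_history_shape(self):
        g = generate_random_graph(GeneratorConfig(V=30, E=150, seed=15))
        cb = generate_codebook(g.nodes, 4000, seed=16)
        gm = encode_graph(g, cb)
        res = reconstruct_graph(gm, cb, reference=g)
        assert res.mismatch_history[-1] == res.mismatched_edges
        tail = res.mismatch_history[1:]
        assert all(b <= a for a, b in zip(tail, tail[1:]))

    def test_no_edges_outside_codebook_and_no_self_loops(self):
        g = generate_random_graph(GeneratorConfig(V=10, E=30, seed=17))
        cb = generate_codebook(g.nodes, 2000, seed=18)
        gm = encode_graph(g, cb)
        res = reconstruct_graph(gm, cb)
        for (u, v) in res.graph.edges:
            assert u in cb and v in cb and u != v

    def test_directed_reconstruction(self):
        g = generate_random_graph(GeneratorConfig(V=15, E=60, directed=True, seed=19))
        cb = generate_codebook(g.nodes, 4000, seed=20)
        gm = encode_graph(g, cb)
        res = reconstruct_graph(gm, cb, reference=g)
        assert res.mismatched_edges == 0

    def test_dropped_dimensions_still_recover(self):
        from graphd import drop_dimensions

        g = generate_random_graph(GeneratorConfig(V=30, E=150, seed=21))
        cb = generate_codebook(g.nodes, 6000, seed=22)
        gm = encode_graph(g, cb)
        vec = drop_dimensions(gm.vector, 0.10, seed=23)
        gm_noisy = type(gm)(
            vector=vec, D=gm.D, kind=gm.kind, codebook_seed=gm.codebook_seed,
            node_labels=gm.node_labels, value_seed=gm.value_seed,
            permutation_spec=gm.permutation_spec,
        )
        res = reconstruct_graph(gm_noisy, cb, reference=g)
        assert res.mismatched_edges == 0


class TestDecisionModelDefaults:
    def test_threshold_in_open_interval(self):
        g = generate_random_graph(GeneratorConfig(V=30, E=150, seed=24))
        cb = generate_codebook(g.nodes, 4000, seed=25)
        gm = encode_graph(g, cb)
        model = default_decision_model(gm, cb)
        assert 0.5 <= model.T < 1.0
        assert model.d == pytest.approx(2 * 150 / 30, rel=0.25)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            DecisionModel(T=0.0, d=2, D=100)
        with pytest.raises(ValueError):
            DecisionModel(T=1.0, d=2, D=100)
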