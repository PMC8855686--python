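"""Higher-level reasoning over graph memories.

Graph matching uses a method-of-moments trick: the difference of two node
memories is a signed sum of the atoms present in exactly one neighborhood,
so the mean squared component estimates the number of differing neighbors.
The same second-moment estimator applied to a graph memory itself estimates
its edge count.  Shortest path expands breadth-first frontiers entirely in
hypervector space, bundling the current level's node memories and probing
every unvisited atom against the bundle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_hdc import Codebook, DimensionMismatchError, bundle, similarity
from .graph_memory import GraphMemory, NodeMemory, unbind_node
from .inference import DecisionModel, decision_score

__all__ = [
    "MatchResult",
    "PathResult",
    "estimate_node_difference",
    "match_graphs",
    "estimate_edge_count",
    "shortest_path",
    "reconstructed_memories",
]


@dataclass(frozen=True)
class MatchResult:
    per_node_difference: dict[str, float]
    total_difference: float
    bias_corrected: bool


@dataclass(frozen=True)
class PathResult:
    found: bool
    distance: int | None
    path: tuple[str, ...] | None
    levels: dict[str, int]


def _vec(m) -> np.ndarray:
    return m.vector if isinstance(m, NodeMemory) else np.asarray(m)


def estimate_node_difference(Ma, Mb) -> float:
    """Mean squared component of Ma - Mb; estimates the neighborhood
    difference count for exact node memories."""
    a, b = _vec(Ma), _vec(Mb)
    if a.shape != b.shape:
        raise DimensionMismatchError(f"dimension mismatch: {a.shape} vs {b.shape}")
    d = a.astype(np.float64) - b.astype(np.float64)
    return float(np.mean(d * d))


def estimate_edge_count(G: GraphMemory) -> float:
    """Second-moment edge-count estimate: mean over components of G^2.

    Unbiased for unrefined unweighted memories, where G is a sum of |E|
    independent bipolar edge hypervectors.
    """
    if G.refined:
        raise ValueError("edge-count estimation is undefined for refined memories")
    v = G.vector.astype(np.float64)
    return float(np.mean(v * v))


def _as_memory_map(side, cb: Codebook):
    """Normalize a GraphMemory or list/dict of node memories to a dict."""
    if isinstance(side, GraphMemory):
        return side, None
    if isinstance(side, dict):
        return None, {k: _vec(v) for k, v in side.items()}
    return None, {m.label: m.vector for m in side}


def match_graphs(
    Ga,
    Gb,
    cb: Codebook,
    mode: str = "exact-memories",
) -> MatchResult:
    """Estimate how many edges differ between two graphs on the same nodes.

    Inputs are either exact node-memory collections (``mode =
    "exact-memories"``) or whole graph memories (``mode =
    "unbind-with-correction"``).  Per-node estimates come from
    :func:`estimate_node_difference`; the undirected total halves the sum
    because each differing edge shows up at both endpoints.  In unbind mode
    the expected unbinding-noise power — roughly (E - d_a) cross terms per
    graph — is subtracted before summing, flooring at 0.
    """
    if mode not in ("exact-memories", "unbind-with-correction"):
        raise ValueError(f"unknown mode {mode!r}")
    gm_a, mem_a = _as_memory_map(Ga, cb)
    gm_b, mem_b = _as_memory_map(Gb, cb)

    if mode == "exact-memories":
        if mem_a is None or mem_b is None:
            raise ValueError("exact-memories mode needs node-memory collections")
        labels = sorted(mem_a)
        if set(labels) != set(mem_b):
            raise ValueError("node sets differ between the two memory collections")
        if any(mem_a[l].shape != mem_b[l].shape for l in labels):
            raise DimensionMismatchError("memory dimensions differ between graphs")
        per_node = {
            lab: estimate_node_difference(mem_a[lab], mem_b[lab]) for lab in labels
        }
        directed = False
        corrected = False
    else:
        if gm_a is None or gm_b is None:
            raise ValueError("unbind-with-correction mode needs GraphMemory inputs")
        if gm_a.D != gm_b.D or gm_a.codebook_seed != gm_b.codebook_seed:
            raise ValueError("graph memories use different codebooks or dimensions")
        if set(gm_a.node_labels) != set(gm_b.node_labels):
            raise ValueError("graph memories cover different node sets")
        directed = gm_a.directed
        labels = sorted(gm_a.node_labels)
        v = len(labels)
        scale = 1.0 if directed else 2.0
        # With a shared codebook the cross-term noise of *shared* edges is
        # identical in both unbindings and cancels in the difference, so the
        # unbinding-noise power seen at node a is the count of *differing*
        # edges not incident to a — not (E - d_a) per graph.  That count is
        # estimated by the same second-moment trick applied to the memory
        # difference itself (binding by a bipolar atom preserves component
        # magnitudes, so every per-node raw moment equals this total).
        k_hat = float(
            np.mean(
                (gm_a.vector.astype(np.float64) - gm_b.vector.astype(np.float64))
                ** 2
            )
        )
        d_diff_hat = scale * k_hat / v  # expected differing edges at one node
        per_node = {}
        for lab in labels:
            raw = estimate_node_difference(
                unbind_node(gm_a, lab, cb), unbind_node(gm_b, lab, cb)
            )
            per_node[lab] = max(raw - max(k_hat - d_diff_hat, 0.0), 0.0)
        corrected = True

    total = sum(per_node.values())
    if not directed:
        total /= 2.0
    return MatchResult(
        per_node_difference=per_node,
        total_difference=max(total, 0.0),
        bias_corrected=corrected,
    )


def reconstructed_memories(
    G: GraphMemory, cb: Codebook, model: DecisionModel | None = None,
    max_iter: int = 30,
) -> dict[str, np.ndarray]:
    """Decode neighbor sets from a graph memory and rebuild clean integer
    node memories from them."""
    from .core_hdc import DTYPE
    from .inference import reconstruct_node_memory

    neighbor_sets, _ = reconstruct_node_memory(G, cb, model, max_iter=max_iter)
    out: dict[str, np.ndarray] = {}
    for lab, nbrs in neighbor_sets.items():
        vec = np.zeros(cb.D, dtype=DTYPE)
        for other in sorted(nbrs):
            vec += cb.vector(other)
        out[lab] = vec
    return out


def shortest_path(
    memories,
    cb: Codebook,
    a: str,
    b: str,
    model: DecisionModel,
    seed: int = 0,
) -> PathResult:
    """Hypervector-native breadth-first shortest path from ``a`` to ``b``.

    ``memories`` maps node labels to node-memory vectors (exact or
    reconstructed).  Each level's memories are bundled into one frontier
    vector; unvisited labels scoring above the threshold against it form the
    next level.  Backtracking from ``b`` picks, per level, a predecessor
    whose own memory contains the current node above threshold, breaking
    ties uniformly at random (seeded).
    """
    _, mems = _as_memory_map(memories, cb)
    if mems is None:
        raise ValueError("shortest_path needs node memories, not a GraphMemory")
    for lab in (a, b):
        if lab not in cb:
            raise KeyError(f"label {lab!r} not in codebook")
        if lab not in mems:
            raise KeyError(f"no node memory for label {lab!r}")
    rng = np.random.default_rng(seed)

    levels: dict[str, int] = {a: 0}
    frontier = [a]
    depth = 0
    while frontier and b not in levels:
        frontier_mem = bundle([mems[lab] for lab in frontier])
        depth += 1
        nxt = [
            lab
            for lab in sorted(mems)
            if lab not in levels
            and decision_score(frontier_mem, cb.vector(lab)) > model.T
        ]
        for lab in nxt:
            levels[lab] = depth
        frontier = nxt

    if b not in levels:
        return PathResult(found=False, distance=None, path=None, levels=levels)

    distance = levels[b]
    path = [b]
    current = b
    for lev in range(distance - 1, -1, -1):
        candidates = [
            lab
            for lab in sorted(levels)
            if levels[lab] == lev
            and similarity(mems[lab], cb.vector(current)) > model.T
        ]
        if not candidates:
            # frontier said `current` was reachable, but no single predecessor
            # memory confirms it — report the failed backtrack honestly
            return PathResult(found=False, distance=distance, path=None, levels=levels)
        current = candidates[int(rng.integers(len(candidates)))]
        path.append(current)
    path.reverse()
    return PathResult(
        found=True, distance=distance, path=tuple(path), levels=levels
    )
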