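"""Graph encoding into node memories and a single graph hypervector.

An undirected unweighted graph is stored as the sum, over unordered edges,
of the bound pair ``H_i * H_j``.  This equals half of ``sum_i H_i * M_i``
(where ``M_i`` bundles node i's neighbor hypervectors) in exact integer
arithmetic, because each edge appears in the memories of both endpoints.
Directed graphs permute the node memory once before binding, which makes the
edge encoding non-commutative; weighted graphs bind a deterministic value
hypervector into each edge term.

Memory refinement sweeps all ordered node pairs and nudges node memories by
whole atoms (+/- H_i) until existing edges score above and non-edges below a
decision threshold, trading extra integer mass for separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_hdc import (
    DTYPE,
    Codebook,
    ValueEncoder,
    bind,
    encode_value,
    permute,
    similarity,
)

__all__ = [
    "Graph",
    "NodeMemory",
    "GraphMemory",
    "RefinementReport",
    "encode_node_memories",
    "encode_graph",
    "unbind_node",
    "refine",
]


def canonical_edge(u: str, v: str, directed: bool) -> tuple[str, str]:
    if u == v:
        raise ValueError(f"self-loop {u!r}-{v!r} is not allowed")
    if directed or u <= v:
        return (u, v)
    return (v, u)


@dataclass(frozen=True)
class Graph:
    """Edge-list graph with direction/weight flags.

    ``edges`` maps canonical (source, target) pairs to a weight in [0, 1)
    for weighted graphs, or to None for unweighted ones.  Undirected edges
    are stored once, endpoints in sorted label order.
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float | None]
    directed: bool = False
    weighted: bool = False

    @classmethod
    def build(cls, nodes, edges, directed: bool = False, weighted: bool = False) -> "Graph":
        """Canonicalize and validate an edge collection.

        ``edges`` is an iterable of (u, v) or (u, v, w) tuples; duplicates
        collapse to one, self-loops are rejected, and weights must lie in
        [0, 1) (weight 1.0 is rejected, not clamped).
        """
        nodes = tuple(str(n) for n in nodes)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate node labels")
        node_set = set(nodes)
        canon: dict[tuple[str, str], float | None] = {}
        for e in edges:
            if weighted:
                if len(e) != 3:
                    raise ValueError(f"weighted edge needs (u, v, w): {e!r}")
                u, v, w = str(e[0]), str(e[1]), float(e[2])
                if not (0.0 <= w < 1.0):
                    raise ValueError(f"edge weight must lie in [0, 1), got {w}")
            else:
                if len(e) not in (2, 3) or (len(e) == 3 and e[2] is not None):
                    raise ValueError(f"unweighted edge must be (u, v): {e!r}")
                u, v, w = str(e[0]), str(e[1]), None
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge {u!r}-{v!r} uses a label not in the node list")
            key = canonical_edge(u, v, directed)
            if key in canon and canon[key] != w:
                raise ValueError(f"conflicting weights for duplicate edge {key}")
            canon[key] = w
        return cls(nodes=nodes, edges=canon, directed=directed, weighted=weighted)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return canonical_edge(u, v, self.directed) in self.edges

    def neighbors(self, node: str) -> set[str]:
        """Out-neighbors for directed graphs, all neighbors otherwise."""
        out = set()
        for (u, v) in self.edges:
            if u == node:
                out.add(v)
            elif not self.directed and v == node:
                out.add(u)
        return out

    def degree(self, node: str) -> int:
        return len(self.neighbors(node))

    def edge_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edges)


@dataclass(frozen=True)
class NodeMemory:
    """A node label together with the integer bundle of its neighborhood."""

    label: str
    vector: np.ndarray


@dataclass(frozen=True)
class GraphMemory:
    """A whole graph superposed into one integer hypervector, plus the
    metadata needed to regenerate the codebook and decode it."""

    vector: np.ndarray
    D: int
    kind: str  # undirected | directed | weighted-undirected | weighted-directed | refined-*
    codebook_seed: int
    node_labels: tuple[str, ...]
    value_seed: int | None = None
    permutation_spec: str = "cyclic"

    @property
    def directed(self) -> bool:
        return self.kind.endswith("directed") and not self.kind.endswith("undirected")

    @property
    def weighted(self) -> bool:
        return "weighted" in self.kind

    @property
    def refined(self) -> bool:
        return self.kind.startswith("refined")


@dataclass
class RefinementReport:
    passes: int
    updates_per_pass: list[int]
    converged: bool
    final_threshold: float


def _edge_term(
    u: str, v: str, w: float | None, cb: Codebook, enc: ValueEncoder | None
) -> np.ndarray:
    hu, hv = cb.vector(u), cb.vector(v)
    if w is None:
        return bind(hu, hv)
    return bind(hu, bind(encode_value(w, enc), hv))


def _require_labels(g: Graph, cb: Codebook) -> None:
    missing = [n for n in g.nodes if n not in cb]
    if missing:
        raise KeyError(f"graph labels missing from codebook: {missing}")


def encode_node_memories(
    g: Graph, cb: Codebook, enc: ValueEncoder | None = None
) -> list[NodeMemory]:
    """Bundle each node's (weight-bound) neighbor hypervectors.

    Directed graphs bundle out-neighbors only; isolated nodes get the zero
    vector.
    """
    _require_labels(g, cb)
    if g.weighted and enc is None:
        raise ValueError("weighted graphs need a ValueEncoder")
    mems = {n: np.zeros(cb.D, dtype=DTYPE) for n in g.nodes}
    for (u, v), w in g.edges.items():
        hv = cb.vector(v) if w is None else bind(encode_value(w, enc), cb.vector(v))
        mems[u] += hv
        if not g.directed:
            hu = cb.vector(u) if w is None else bind(encode_value(w, enc), cb.vector(u))
            mems[v] += hu
    return [NodeMemory(label=n, vector=mems[n]) for n in g.nodes]


def encode_graph(
    g: Graph, cb: Codebook, enc: ValueEncoder | None = None
) -> GraphMemory:
    """Encode a whole graph into a single integer hypervector.

    Undirected: sum over unordered edges of ``H_i * (V_w *) H_j`` — each edge
    contributes exactly once, realizing the 1/2 prefactor of the
    ``sum_i H_i * M_i`` form without fractional arithmetic.  Directed:
    ``sum_i H_i * rho(M_i)`` with a one-step permutation.
    """
    _require_labels(g, cb)
    if g.weighted and enc is None:
        raise ValueError("weighted graphs need a ValueEncoder")
    G = np.zeros(cb.D, dtype=DTYPE)
    if g.directed:
        for mem in encode_node_memories(g, cb, enc):
            G += bind(cb.vector(mem.label), permute(mem.vector, 1))
    else:
        for (u, v), w in g.edges.items():
            G += _edge_term(u, v, w, cb, enc)
    kind = ("weighted-" if g.weighted else "") + (
        "directed" if g.directed else "undirected"
    )
    return GraphMemory(
        vector=G,
        D=cb.D,
        kind=kind,
        codebook_seed=cb.seed,
        node_labels=tuple(g.nodes),
        value_seed=None if enc is None else enc.seed,
        permutation_spec="cyclic",
    )


def unbind_node(G: GraphMemory, label: str, cb: Codebook) -> NodeMemory:
    """One-shot node-memory estimate: ``H_i * G`` (inverse-permuted when
    directed).  Equals the true memory plus cross-term noise; exact when no
    other edges exist."""
    if label not in cb:
        raise KeyError(f"label {label!r} not in codebook")
    est = bind(cb.vector(label), G.vector)
    if G.directed:
        est = permute(est, -1)
    return NodeMemory(label=label, vector=est)


def refine(
    g: Graph,
    mems: list[NodeMemory],
    cb: Codebook,
    T: float = 0.5,
    max_passes: int = 50,
) -> tuple[list[NodeMemory], GraphMemory, RefinementReport]:
    """Iteratively separate edge from non-edge decision scores.

    Sweeps ordered pairs (i, j) in codebook (node-list) order.  When an
    existing edge scores ``R_ij = similarity(M_j, H_i) < T`` the atom
    ``H_i`` is added to ``M_j``; when a non-edge scores above T it is
    subtracted.  Each update moves that score by exactly +/-1.  Stops when a
    full pass makes no update, or after ``max_passes``.

    Only unweighted graphs are supported: the update currency is a whole
    node atom, and no weighted analogue is defined.  The returned graph
    memory is rebuilt as ``sum_i H_i * M_i_refined`` without halving (the
    refined memories are no longer symmetric edge sums); its kind is
    prefixed ``refined-`` so decoders can apply the matching convention.
    """
    if g.weighted:
        raise ValueError("refinement is only defined for unweighted graphs")
    if not (0.0 < T < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {T}")
    _require_labels(g, cb)
    mems = {m.label: m.vector.copy() for m in mems}
    if set(mems) != set(g.nodes):
        raise ValueError("node memories do not cover the graph's node set")
    labels = list(g.nodes)
    D = cb.D

    updates_per_pass: list[int] = []
    converged = False
    for _ in range(max_passes):
        n_updates = 0
        for i in labels:
            hi = cb.vector(i)
            for j in labels:
                if i == j:
                    continue
                # H_i should be present in M_j iff edge j->i (directed)
                # or i-j (undirected) exists.
                is_edge = g.has_edge(j, i)
                r = similarity(mems[j], hi)
                # retrieval declares an edge iff R > T, so an existing edge
                # sitting exactly at T is still mispredicted: strengthen on
                # r <= T (not the literal r < T) to make convergence imply
                # full separation under the query rule
                if is_edge and r <= T:
                    mems[j] += hi
                    n_updates += 1
                elif not is_edge and r > T:
                    mems[j] -= hi
                    n_updates += 1
        updates_per_pass.append(n_updates)
        if n_updates == 0:
            converged = True
            break

    G = np.zeros(D, dtype=DTYPE)
    for lab in labels:
        mi = mems[lab]
        if g.directed:
            mi = permute(mi, 1)
        G += bind(cb.vector(lab), mi)
    kind = "refined-" + ("directed" if g.directed else "undirected")
    gm = GraphMemory(
        vector=G,
        D=D,
        kind=kind,
        codebook_seed=cb.seed,
        node_labels=tuple(labels),
        permutation_spec="cyclic",
    )
    report = RefinementReport(
        passes=len(updates_per_pass),
        updates_per_pass=updates_per_pass,
        converged=converged,
        final_threshold=T,
    )
    refined = [NodeMemory(label=lab, vector=mems[lab]) for lab in labels]
    return refined, gm, report
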