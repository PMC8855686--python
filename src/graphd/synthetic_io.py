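"""Synthetic graph generators, noise injection, and file formats.

Random graphs are sampled as a complete graph minus a uniformly chosen set
of deleted edges — equivalently, a uniform draw of exactly E edges from all
candidate pairs.  Chained graphs join otherwise-disjoint random components
at one anchor node each, so anchor k sits at graph distance k-1 from anchor
1; they exercise the shortest-path algorithm at controlled distances.

File formats are plain text: tab-separated edge lists (``src  dst
[weight]``, '#' comments, weights printed with 6 decimals) and a ``.hdv``
memory container holding a JSON header line followed by the base64-encoded
little-endian int32 vector.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_hdc import DTYPE
from .graph_memory import Graph, GraphMemory

__all__ = [
    "GeneratorConfig",
    "ChainConfig",
    "generate_random_graph",
    "generate_chained_graph",
    "drop_dimensions",
    "read_edge_list",
    "write_edge_list",
    "save_memory",
    "load_memory",
]

FORMAT_VERSION = 1


@dataclass(frozen=True)
class GeneratorConfig:
    V: int
    E: int
    directed: bool = False
    weighted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        cap = self.V * (self.V - 1) // (1 if self.directed else 2)
        if not (0 <= self.E <= cap):
            raise ValueError(
                f"E={self.E} infeasible for V={self.V} "
                f"({'directed' if self.directed else 'undirected'} cap {cap})"
            )


@dataclass(frozen=True)
class ChainConfig:
    dnum: int
    V_av: int
    E_av: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dnum < 2:
            raise ValueError(f"need at least 2 components, got {self.dnum}")
        cap = self.V_av * (self.V_av - 1) // 2
        if not (1 <= self.E_av <= cap):
            raise ValueError(
                f"E_av={self.E_av} infeasible for V_av={self.V_av} (cap {cap})"
            )


def _node_labels(V: int, prefix: str = "v") -> list[str]:
    width = max(len(str(V - 1)), 2)
    return [f"{prefix}{i:0{width}d}" for i in range(V)]


def _all_pairs(labels: list[str], directed: bool) -> list[tuple[str, str]]:
    if directed:
        return [(u, v) for u in labels for v in labels if u != v]
    return [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]


def generate_random_graph(cfg: GeneratorConfig) -> Graph:
    """Uniformly sample exactly E unique edges among V labeled nodes."""
    labels = _node_labels(cfg.V)
    pairs = _all_pairs(labels, cfg.directed)
    rng = np.random.default_rng(cfg.seed)
    chosen = rng.choice(len(pairs), size=cfg.E, replace=False)
    edges = []
    for k in sorted(int(c) for c in chosen):
        u, v = pairs[k]
        if cfg.weighted:
            edges.append((u, v, float(rng.uniform(0.0, 1.0))))
        else:
            edges.append((u, v))
    return Graph.build(labels, edges, directed=cfg.directed, weighted=cfg.weighted)


def _bfs_distance(g: Graph, a: str, b: str) -> int | None:
    """Plain BFS used to verify chained construction at generation time."""
    adj: dict[str, set[str]] = {n: set() for n in g.nodes}
    for (u, v) in g.edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {a: 0}
    frontier = [a]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in seen:
                    seen[w] = seen[u] + 1
                    nxt.append(w)
        frontier = nxt
    return seen.get(b)


def generate_chained_graph(cfg: ChainConfig) -> tuple[Graph, list[str]]:
    """Disjoint random components joined at consecutive anchor nodes.

    Returns the graph and the anchor labels; anchor k (0-based) is at graph
    distance k from anchor 0, which is asserted against a BFS oracle before
    returning.
    """
    rng = np.random.default_rng(cfg.seed)
    all_nodes: list[str] = []
    all_edges: list[tuple[str, str]] = []
    anchors: list[str] = []
    for c in range(cfg.dnum):
        comp = generate_random_graph(
            GeneratorConfig(V=cfg.V_av, E=cfg.E_av, seed=int(rng.integers(2**31)))
        )
        prefix = f"c{c:03d}_"
        nodes = [prefix + n for n in comp.nodes]
        all_nodes.extend(nodes)
        all_edges.extend((prefix + u, prefix + v) for (u, v) in comp.edges)
        anchors.append(prefix + comp.nodes[int(rng.integers(cfg.V_av))])
    for k in range(cfg.dnum - 1):
        all_edges.append((anchors[k], anchors[k + 1]))
    g = Graph.build(all_nodes, all_edges, directed=False, weighted=False)
    for k, anchor in enumerate(anchors):
        dist = _bfs_distance(g, anchors[0], anchor)
        if dist != k:
            raise RuntimeError(
                f"chained construction broken: anchor {k} at distance {dist}"
            )
    return g, anchors


def drop_dimensions(h: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Zero exactly round(fraction * D) uniformly chosen components."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    D = h.shape[0]
    k = int(np.round(fraction * D))
    out = h.copy()
    if k:
        idx = np.random.default_rng(seed).choice(D, size=k, replace=False)
        out[idx] = 0
    return out


# ---------------------------------------------------------------- edge lists


def write_edge_list(g: Graph, path) -> None:
    """Canonical TSV: pragma comments for flags, sorted edges, weights with
    6 decimals."""
    lines = ["# graphd edge list"]
    if g.directed:
        lines.append("# directed")
    if g.weighted:
        lines.append("# weighted")
    lines.append("# nodes\t" + "\t".join(g.nodes))
    for (u, v) in sorted(g.edges):
        w = g.edges[(u, v)]
        if g.weighted:
            lines.append(f"{u}\t{v}\t{w:.6f}")
        else:
            lines.append(f"{u}\t{v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path, directed: bool | None = None) -> Graph:
    """Parse a TSV edge list; '#' lines are comments (pragmas recognized)."""
    directed_flag = bool(directed) if directed is not None else False
    weighted_flag = None
    nodes_pragma: list[str] | None = None
    rows: list[tuple] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body == "directed" and directed is None:
                directed_flag = True
            elif body == "weighted":
                weighted_flag = True
            elif body.startswith("nodes\t") or body.startswith("nodes "):
                nodes_pragma = body.split("\t")[1:] or body.split()[1:]
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            parts = line.split()
        if parts[:2] == ["src", "dst"]:  # optional header row
            continue
        if len(parts) == 2:
            if weighted_flag is True:
                raise ValueError(
                    f"{path}:{lineno}: weighted file has unweighted row {line!r}"
                )
            weighted_flag = False
            u, v = parts
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u!r}")
            rows.append((u, v))
        elif len(parts) == 3:
            if weighted_flag is False:
                raise ValueError(
                    f"{path}:{lineno}: unweighted file has weighted row {line!r}"
                )
            weighted_flag = True
            u, v, ws = parts
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u!r}")
            try:
                w = float(ws)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: cannot parse weight {ws!r}"
                ) from None
            rows.append((u, v, w))
        else:
            raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
    weighted_flag = bool(weighted_flag)
    if nodes_pragma is not None:
        nodes = nodes_pragma
    else:
        seen: dict[str, None] = {}
        for r in rows:
            seen.setdefault(r[0])
            seen.setdefault(r[1])
        nodes = sorted(seen)
    try:
        return Graph.build(
            nodes, rows, directed=directed_flag, weighted=weighted_flag
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# ------------------------------------------------------------- .hdv container


def save_memory(G: GraphMemory, path) -> None:
    """Write a memory as one JSON header line plus a base64 int32 payload."""
    vec = np.asarray(G.vector)
    if np.any(np.abs(vec) > np.iinfo(np.int32).max):
        raise ValueError("vector components exceed the int32 container range")
    header = {
        "format_version": FORMAT_VERSION,
        "D": int(G.D),
        "kind": G.kind,
        "codebook_seed": int(G.codebook_seed),
        "value_seed": None if G.value_seed is None else int(G.value_seed),
        "node_labels": list(G.node_labels),
        "permutation_spec": G.permutation_spec,
    }
    payload = base64.b64encode(
        vec.astype("<i4").tobytes()
    ).decode("ascii")
    Path(path).write_text(json.dumps(header) + "\n" + payload + "\n")


def load_memory(path) -> GraphMemory:
    text = Path(path).read_text()
    try:
        header_line, payload = text.split("\n", 1)
        header = json.loads(header_line)
    except (ValueError, json.JSONDecodeError) as exc:
        raise ValueError(f"{path}: malformed memory container: {exc}") from exc
    if header.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported format version {header.get('format_version')!r}"
        )
    try:
        raw = base64.b64decode(payload.strip().encode("ascii"), validate=True)
    except Exception as exc:
        raise ValueError(f"{path}: corrupt base64 payload: {exc}") from exc
    vec = np.frombuffer(raw, dtype="<i4").astype(DTYPE)
    D = int(header["D"])
    if vec.shape[0] != D:
        raise ValueError(
            f"{path}: header D={D} disagrees with payload length {vec.shape[0]}"
        )
    return GraphMemory(
        vector=vec,
        D=D,
        kind=header["kind"],
        codebook_seed=int(header["codebook_seed"]),
        node_labels=tuple(header["node_labels"]),
        value_seed=(
            None if header.get("value_seed") is None else int(header["value_seed"])
        ),
        permutation_spec=header.get("permutation_spec", "cyclic"),
    )
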