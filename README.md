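# graphd

Holographic graph memories in hyperdimensional vector space.

`graphd` encodes whole graphs — undirected, directed, or weighted — into a
*single* high-dimensional integer vector (a graph memory), and decodes and
reasons over that vector with native hypervector operations:

- **Encoding**: each node gets a seeded random bipolar hypervector; an edge
  is the componentwise product of its endpoints (value hypervectors bound in
  for weights, a cyclic permutation for direction); the graph memory is the
  integer sum of all edge terms.
- **Retrieval**: edge existence is a similarity test against a threshold
  separating two closed-form Gaussians (signal `N(1, (d-1)/D)`, noise
  `N(0, d/D)` for degree `d` at dimension `D`).
- **Reconstruction**: whole graphs and per-node neighbor sets are decoded by
  iterative noise cancellation — subtract the encodings of currently
  believed edges, re-test every pair, repeat until the decoded edge set
  stabilizes.
- **Refinement**: node memories are iteratively nudged by whole atoms
  (+/-H) until edge and non-edge scores fully separate, extending capacity.
- **Cognition**: method-of-moments graph matching, second-moment edge-count
  estimation, and a hypervector-native breadth-first shortest path.
- **Capacity model**: theoretical ROC curves, SNR, equal-error thresholds,
  and seeded sweep harnesses that measure when decoding succeeds.

## CLI

All commands print a JSON summary to stdout; graphs travel as plain TSV
edge lists and memories as `.hdv` containers (JSON header + base64 int32
payload).

```sh
graphd gen -V 30 -E 150 --seed 1 -o g.tsv           # random graph
graphd encode g.tsv --dim 4000 --seed 2 -o g.hdv    # graph -> hypervector
graphd query-edge g.hdv v00 v07                     # edge existence + score
graphd decode-graph g.hdv -o decoded.tsv --reference g.tsv
graphd decode-node g.hdv --label v00                # neighbor sets
graphd refine g.tsv --dim 2000 --from-unbind -o r.hdv
graphd match a.hdv b.hdv                            # edge-difference estimate
graphd gen-chain --components 4 --vav 21 --eav 42 --seed 3 -o chain.tsv
graphd path chain.hdv c000_v02 c003_v11             # hypervector BFS
graphd sweep -c sweep.yaml -o sweep.csv             # capacity grid
```

A sweep config is a small YAML mapping, e.g.

```yaml
D: [2000, 4000, 6000]
E: [100, 150, 200]
V: 30
noise_fractions: [0.0, 0.1]
trials: 20
seed: 7
```

## Layout

| module | contents |
| --- | --- |
| `graphd.core_hdc` | bipolar atoms, bind/bundle/permute/similarity, scalar value codec |
| `graphd.graph_memory` | `Graph`, node/graph encoding, unbinding, memory refinement |
| `graphd.inference` | decision model, edge/weight queries, iterative reconstruction |
| `graphd.cognition` | graph matching, edge-count estimation, shortest path |
| `graphd.capacity_stats` | Gaussian signal/noise model, ROC, SNR, capacity sweeps |
| `graphd.synthetic_io` | graph generators, dimension dropping, TSV/`.hdv` I/O |
| `graphd.cli` | the `graphd` command group |
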