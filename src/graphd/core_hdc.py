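"""Hypervector algebra.

Hypervectors are plain ``numpy`` integer vectors of a fixed dimension ``D``.
*Bipolar* atoms have every component in {-1, +1}; bundles (componentwise
integer sums) are kept at full integer width and are never clipped back to
bipolar.  Similarity is the dot product divided by ``D`` — deliberately not
cosine similarity, so that similarities of bundles decompose additively over
their constituents.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DimensionMismatchError",
    "Codebook",
    "ValueEncoder",
    "generate_codebook",
    "random_bipolar",
    "bind",
    "bundle",
    "permute",
    "make_permutation",
    "similarity",
    "make_value_encoder",
    "encode_value",
    "decode_value",
]

DTYPE = np.int64


class DimensionMismatchError(ValueError):
    """Raised when two hypervectors of different dimension are combined."""


def _check_same_dim(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape or a.ndim != 1:
        raise DimensionMismatchError(
            f"hypervector dimensions differ: {a.shape} vs {b.shape}"
        )


def _label_entropy(label: str) -> int:
    """Stable 64-bit digest of a label (independent of PYTHONHASHSEED)."""
    h = hashlib.sha256(label.encode("utf-8")).digest()
    return int.from_bytes(h[:8], "little")


def random_bipolar(D: int, rng: np.random.Generator) -> np.ndarray:
    """Draw one i.i.d. uniform bipolar hypervector of dimension ``D``."""
    return rng.choice(np.array([-1, 1], dtype=DTYPE), size=D)


@dataclass(frozen=True)
class Codebook:
    """Seeded mapping from node labels to random bipolar hypervectors.

    Each label's vector is derived from ``(seed, sha256(label))``, so the
    codebook is a pure function of (label set, D, seed) and does not depend
    on the order in which labels are listed.
    """

    labels: tuple[str, ...]
    vectors: np.ndarray  # shape (len(labels), D)
    D: int
    seed: int
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"label {label!r} not in codebook") from None

    def vector(self, label: str) -> np.ndarray:
        return self.vectors[self.index(label)]


def generate_codebook(labels, D: int, seed: int) -> Codebook:
    """Assign an i.i.d. uniform bipolar hypervector to every label.

    Deterministic in ``(labels, D, seed)``; independent labels are
    near-orthogonal in expectation (similarity ~ N(0, 1/D)).
    """
    labels = tuple(str(lab) for lab in labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate labels in codebook: {dupes}")
    if D < 1:
        raise ValueError(f"dimension must be >= 1, got {D}")
    vectors = np.empty((len(labels), D), dtype=DTYPE)
    for i, lab in enumerate(labels):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0xFFFFFFFF, _label_entropy(lab)])
        )
        vectors[i] = random_bipolar(D, rng)
    return Codebook(labels=labels, vectors=vectors, D=D, seed=int(seed))


def bind(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Componentwise product.  Self-inverse on bipolar vectors."""
    _check_same_dim(a, b)
    return a * b


def bundle(vs) -> np.ndarray:
    """Exact componentwise integer sum of a non-empty list of hypervectors."""
    vs = list(vs)
    if not vs:
        raise ValueError(
            "cannot bundle an empty list; use an explicit zero vector instead"
        )
    first = vs[0]
    for v in vs[1:]:
        _check_same_dim(first, v)
    return np.sum(np.asarray(vs, dtype=DTYPE), axis=0)


def make_permutation(D: int, seed: int) -> np.ndarray:
    """A seeded random index permutation, usable in place of the cyclic shift."""
    return np.random.default_rng(seed).permutation(D)


def permute(h: np.ndarray, p: int, perm: np.ndarray | None = None) -> np.ndarray:
    """Apply an invertible permutation ``p`` times (negative ``p`` inverts).

    The default permutation is a cyclic shift by one position: metadata-free,
    composable by exponent arithmetic.  Pass ``perm`` (an index array from
    :func:`make_permutation`) for a seeded random permutation instead.
    """
    p = int(p)
    if p == 0:
        return h.copy()
    if perm is None:
        return np.roll(h, p)
    out = h
    if p > 0:
        for _ in range(p):
            out = out[perm]
    else:
        inv = np.argsort(perm)
        for _ in range(-p):
            out = out[inv]
    return out.copy() if out is h else out


def similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Dot product divided by D (no magnitude normalization)."""
    _check_same_dim(a, b)
    return float(np.dot(a.astype(np.float64), b.astype(np.float64)) / a.shape[0])


@dataclass(frozen=True)
class ValueEncoder:
    """Deterministic codec mapping scalars in [0, 1] to hypervectors.

    ``encode(a)`` keeps the first ``round(a*D)`` components of a random
    bipolar base vector and negates the rest, so nearby scalars map to
    correlated vectors and ``(similarity(v, base) + 1) / 2`` decodes the
    scalar back (up to the 1/D grid).
    """

    base: np.ndarray
    D: int
    seed: int


def make_value_encoder(D: int, seed: int) -> ValueEncoder:
    if D < 1:
        raise ValueError(f"dimension must be >= 1, got {D}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0xFFFFFFFF, 1]))
    return ValueEncoder(base=random_bipolar(D, rng), D=D, seed=int(seed))


def encode_value(a: float, enc: ValueEncoder) -> np.ndarray:
    """Encode ``a`` in [0, 1]: negate components from index round(a*D) onward.

    The split index uses round-half-to-even.
    """
    if not (0.0 <= a <= 1.0):
        raise ValueError(f"value must lie in [0, 1], got {a}")
    k = int(np.round(a * enc.D))
    v = enc.base.copy()
    v[k:] = -v[k:]
    return v


def decode_value(v: np.ndarray, enc: ValueEncoder) -> float:
    """Evaluate ``(similarity(v, base) + 1) / 2``, clamped to [0, 1]."""
    s = similarity(v, enc.base)
    return float(min(1.0, max(0.0, (s + 1.0) / 2.0)))
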