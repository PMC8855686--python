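"""Closed-form retrieval statistics and capacity sweeps.

For a node of degree d at dimension D, the decision score of a true
neighbor is Gaussian with mean 1 and variance (d-1)/D, and that of a
non-neighbor is Gaussian with mean 0 and variance d/D.  Everything here —
SNR, theoretical ROC, equal-error threshold — is derived from those two
distributions; the sweep harness checks the predictions empirically by
encoding and reconstructing seeded random graphs across a (D, E, noise)
grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CapacityModel",
    "SweepResult",
    "signal_noise_model",
    "snr_db",
    "roc_curve",
    "equal_error_threshold",
    "run_capacity_sweep",
]


@dataclass(frozen=True)
class CapacityModel:
    """Signal N(1, (d-1)/D) and noise N(0, d/D) for degree d, dimension D."""

    d: float
    D: int

    def __post_init__(self) -> None:
        if self.d < 1 or self.D < 1:
            raise ValueError(f"need d >= 1 and D >= 1, got d={self.d}, D={self.D}")

    @property
    def signal_mean(self) -> float:
        return 1.0

    @property
    def signal_var(self) -> float:
        return (self.d - 1.0) / self.D

    @property
    def noise_mean(self) -> float:
        return 0.0

    @property
    def noise_var(self) -> float:
        return self.d / self.D


def signal_noise_model(d: float, D: int) -> CapacityModel:
    return CapacityModel(d=d, D=D)


def snr_db(d: float, D: int) -> float:
    """Retrieval SNR in decibels: 10*log10(D / (d-1)).

    The unit-magnitude signal sits over interference noise of variance
    (d-1)/D.  Degenerate d < 2 (no interfering neighbors) has no noise and
    returns +inf as the infinite-SNR sentinel.
    """
    if d < 1:
        raise ValueError(f"degree must be >= 1, got {d}")
    if d < 2:
        return math.inf
    return 10.0 * math.log10(D / (d - 1.0))


def roc_curve(
    model: CapacityModel, thresholds: Sequence[float]
) -> list[tuple[float, float]]:
    """Theoretical (FPR, TPR) at each threshold from the Gaussian tails."""
    sig_sd = math.sqrt(model.signal_var)
    noi_sd = math.sqrt(model.noise_var)
    out = []
    for t in thresholds:
        if sig_sd == 0.0:
            tpr = 1.0 if t < model.signal_mean else 0.0
        else:
            tpr = float(norm.sf(t, loc=model.signal_mean, scale=sig_sd))
        fpr = float(norm.sf(t, loc=model.noise_mean, scale=noi_sd))
        out.append((fpr, tpr))
    return out


def equal_error_threshold(model: CapacityModel) -> float:
    """Threshold equalizing false-positive and false-negative z-scores:
    T = sqrt(d) / (sqrt(d) + sqrt(d-1)); in (0.5, 1], -> 0.5 as d grows."""
    if model.d < 2:
        return 0.5
    rd = math.sqrt(model.d)
    rdm1 = math.sqrt(model.d - 1.0)
    return rd / (rd + rdm1)


@dataclass
class SweepResult:
    """Per-cell reconstruction outcomes over a (D, E, V, noise) grid."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def success_rate(self, **cell) -> float:
        q = self.table
        for key, val in cell.items():
            q = q[q[key] == val]
        if q.empty:
            raise KeyError(f"no sweep cell matching {cell}")
        return float(q["success_rate"].iloc[0])


def run_capacity_sweep(
    D_values: Iterable[int],
    E_values: Iterable[int],
    V: int = 30,
    noise_fractions: Iterable[float] = (0.0,),
    trials: int = 20,
    seed: int = 0,
    max_iter: int = 30,
) -> SweepResult:
    """Encode/reconstruct seeded random graphs over a parameter grid.

    For each (D, E, noise fraction) cell and trial: generate a V-node,
    E-edge random graph, encode it, optionally zero a random fraction of the
    graph hypervector's components, reconstruct, and record exact-recovery
    success, iterations and final mismatches.  Per-trial failures are
    recorded, never raised.
    """
    from .core_hdc import generate_codebook
    from .graph_memory import encode_graph
    from .inference import reconstruct_graph
    from .synthetic_io import GeneratorConfig, drop_dimensions, generate_random_graph

    rows = []
    for D in D_values:
        for E in E_values:
            for frac in noise_fractions:
                successes = iters = mismatches = 0
                for t in range(trials):
                    trial_seed = hash((seed, D, E, round(frac, 6), t)) & 0x7FFFFFFF
                    g = generate_random_graph(
                        GeneratorConfig(V=V, E=E, seed=trial_seed)
                    )
                    cb = generate_codebook(g.nodes, D, seed=trial_seed + 1)
                    gm = encode_graph(g, cb)
                    if frac > 0:
                        vec = drop_dimensions(gm.vector, frac, seed=trial_seed + 2)
                        gm = type(gm)(
                            vector=vec,
                            D=gm.D,
                            kind=gm.kind,
                            codebook_seed=gm.codebook_seed,
                            node_labels=gm.node_labels,
                            value_seed=gm.value_seed,
                            permutation_spec=gm.permutation_spec,
                        )
                    res = reconstruct_graph(
                        gm, cb, max_iter=max_iter, reference=g
                    )
                    ok = res.mismatched_edges == 0
                    successes += int(ok)
                    iters += res.iterations
                    mismatches += res.mismatched_edges
                rows.append(
                    {
                        "D": D,
                        "E": E,
                        "V": V,
                        "noise_frac": frac,
                        "trials": trials,
                        "seed0": seed,
                        "success_rate": successes / trials,
                        "mean_iters": iters / trials,
                        "mean_mismatches": mismatches / trials,
                    }
                )
    return SweepResult(table=pd.DataFrame(rows))
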