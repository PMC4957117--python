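"""Benchmark harness for hyperbolic embeddings.

Measures how well an embedder recovers a network's latent geometry:

* ``distance_correlation`` -- Pearson correlation between inferred and
  ground-truth pairwise hyperbolic distances (the headline recovery
  metric on PS-model networks, where true coordinates are known).
* ``benchmark_sweep`` -- grow replicate PS networks over a parameter
  grid, embed each with one or more methods, and tabulate the
  correlations.
* ``radial_vs_birth`` -- Spearman correlation between node birth order
  and inferred radius: in a popularity-similarity geometry, old nodes
  sit near the disc centre, so an embedding that respects the growth
  process places early-born nodes at small r.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .embedding import EmbeddingResult, labne_embed
from .geometry import PolarCoords, distance_matrix, hyperbolic_distance
from .hypermap import HyperMapConfig, hypermap_embed
from .ps_model import PSParams, grow_ps_network

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkRecord",
    "distance_correlation",
    "benchmark_sweep",
    "summarize_benchmark",
    "radial_vs_birth",
]

#: above this many nodes, pairwise distances are subsampled
ALL_PAIRS_MAX_N = 1000
SAMPLED_PAIRS = 1_000_000

#: likelihood temperature used for HyperMap when a grid cell has T = 0
#: (the Bernoulli likelihood needs a smooth p(x))
HYPERMAP_MIN_T = 0.1


@dataclass
class BenchmarkRecord:
    """One (parameter cell, method, replicate) recovery measurement."""

    params: PSParams
    method: str
    pearson_r: float
    seed: int


def _paired_distances(a: PolarCoords, b: PolarCoords, seed: int = 0):
    """Distance vectors of both coordinate sets over the same node pairs."""
    if set(a.node_ids) != set(b.node_ids):
        raise ValueError("coordinate sets cover different node sets")
    b = b.subset(a.node_ids)
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if n <= ALL_PAIRS_MAX_N:
        return distance_matrix(a), distance_matrix(b)
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=SAMPLED_PAIRS)
    j = rng.integers(0, n, size=SAMPLED_PAIRS)
    keep = i < j
    i, j = i[keep], j[keep]
    da = hyperbolic_distance(a.r[i], a.theta[i], a.r[j], a.theta[j])
    db = hyperbolic_distance(b.r[i], b.theta[i], b.r[j], b.theta[j])
    return da, db


def distance_correlation(
    true_coords: PolarCoords, inferred_coords: PolarCoords, seed: int = 0
) -> float:
    """Pearson correlation of inferred vs true pairwise distances.

    Computed over all N(N-1)/2 pairs for N <= 1000, else over a seeded
    sample of pairs.  Symmetric in its arguments and invariant under
    rotation/reflection of either coordinate set.
    """
    dt, di = _paired_distances(true_coords, inferred_coords, seed)
    if np.std(dt) == 0 or np.std(di) == 0:
        raise ValueError("zero variance in a distance vector; correlation undefined")
    return float(np.corrcoef(dt, di)[0, 1])


def _replicate_seed(master_seed: int, cell_index: int, rep: int) -> int:
    ss = np.random.SeedSequence([master_seed, cell_index, rep])
    return int(ss.generate_state(1)[0] % (2**31))


def benchmark_sweep(
    param_grid: dict,
    reps: int,
    methods=("labne",),
    master_seed: int = 0,
) -> list[BenchmarkRecord]:
    """Grow and embed replicate PS networks over a parameter grid.

    ``param_grid`` maps each of "N", "m", "gamma", "T" to a list of
    values; the grid is their Cartesian product.  Replicate seeds are
    derived deterministically from ``master_seed``, so a sweep is
    bit-reproducible.  A failed replicate is logged and recorded with
    pearson_r = NaN rather than aborting the sweep.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    methods = [m.lower() for m in methods]
    for m in methods:
        if m not in ("labne", "hypermap"):
            raise ValueError(f"unknown method {m!r}")
    cells = list(
        itertools.product(
            param_grid["N"], param_grid["m"], param_grid["gamma"], param_grid["T"]
        )
    )
    records: list[BenchmarkRecord] = []
    for ci, (N, m, gamma, T) in enumerate(cells):
        for rep in range(reps):
            seed = _replicate_seed(master_seed, ci, rep)
            params = PSParams(N=N, m=m, gamma=gamma, T=T, seed=seed)
            graph, true_coords = grow_ps_network(params)
            for method in methods:
                try:
                    if method == "labne":
                        inferred = labne_embed(graph, gamma=gamma).coords
                    else:
                        cfg = HyperMapConfig(
                            m=m, gamma=gamma, T=max(T, HYPERMAP_MIN_T), seed=seed
                        )
                        inferred = hypermap_embed(graph, cfg)
                    r = distance_correlation(true_coords, inferred, seed=seed)
                except Exception:
                    logger.exception(
                        "replicate failed: cell=%s method=%s seed=%d",
                        (N, m, gamma, T), method, seed,
                    )
                    r = float("nan")
                records.append(BenchmarkRecord(params, method, r, seed))
    return records


def summarize_benchmark(records) -> pd.DataFrame:
    """Mean and sd of pearson_r per (T, 2m, gamma, N, method) cell."""
    rows = [
        {
            "T": rec.params.T,
            "two_m": 2 * rec.params.m,
            "gamma": rec.params.gamma,
            "N": rec.params.N,
            "method": rec.method,
            "seed": rec.seed,
            "pearson_r": rec.pearson_r,
        }
        for rec in records
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["T", "two_m", "gamma", "N", "method"])["pearson_r"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )


def radial_vs_birth(inferred, birth_order: dict, n_bins: int = 6):
    """Spearman correlation of node birth index vs inferred radius.

    A positive correlation means early-born nodes sit closer to the
    disc centre, the signature of popularity-similarity growth.  Also
    returns per-birth-bin radial five-number summaries (box-plot data).

    ``inferred`` may be an :class:`EmbeddingResult` or a
    :class:`PolarCoords`; ``birth_order`` maps node label -> birth
    index (1 = oldest), known exactly for PS networks.
    """
    coords = inferred.coords if isinstance(inferred, EmbeddingResult) else inferred
    missing = [v for v in coords.node_ids if v not in birth_order]
    if missing:
        raise ValueError(f"birth order unknown for {len(missing)} node(s)")
    birth = np.array([birth_order[v] for v in coords.node_ids], dtype=float)
    r = coords.r
    if np.std(r) == 0:
        raise ValueError("constant radii; rank correlation undefined")
    rho = float(stats.spearmanr(birth, r).statistic)

    bins = pd.qcut(birth, q=min(n_bins, len(np.unique(birth))), duplicates="drop")
    summaries = (
        pd.DataFrame({"birth_bin": bins, "r": r})
        .groupby("birth_bin", observed=True)["r"]
        .describe()[["min", "25%", "50%", "75%", "max"]]
        .reset_index()
    )
    return rho, summaries
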