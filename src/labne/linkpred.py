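"""Topological link prediction and precision-recall evaluation.

Scores non-adjacent node pairs ("seed nodes") of an observed graph with
either neighbourhood-overlap indices -- Common Neighbours (CN), Dice
Similarity (DS), Adamic-Adar (AA), Preferential Attachment (PA) -- or
with the inferred hyperbolic distance between the pair (closer = more
likely to link).  Candidate pairs are ranked and swept with a moving
score threshold against a set of true new edges (a later temporal
snapshot, or a held-out edge sample) to build a precision-recall curve.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .geometry import PolarCoords, pairwise_distances

logger = logging.getLogger(__name__)

__all__ = [
    "ScoredPairs",
    "PRCurve",
    "candidate_pairs",
    "neighbourhood_scores",
    "hyperbolic_scores",
    "snapshot_positives",
    "label_scored_pairs",
    "precision_recall",
    "holdout_split",
]

NEIGHBOURHOOD_INDICES = ("cn", "ds", "aa", "pa")


@dataclass
class ScoredPairs:
    """Candidate node pairs with predictor scores and optional labels.

    ``pairs`` are unordered and must be non-adjacent in the observed
    graph (enforced by the scoring functions); higher score = more
    likely future link; ``labels`` marks pairs present in the
    evaluation edge set.
    """

    pairs: list
    scores: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.pairs = [tuple(p) for p in self.pairs]
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.pairs) != self.scores.shape[0]:
            raise ValueError("pairs and scores length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool)
            if self.labels.shape[0] != self.scores.shape[0]:
                raise ValueError("labels and scores length mismatch")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PRCurve:
    """Precision-recall points at descending score thresholds, plus AUPR."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    aupr: float


def candidate_pairs(graph: nx.Graph, max_pairs: int | None = None, seed: int = 0):
    """All non-adjacent unordered node pairs of ``graph``.

    With ``max_pairs`` set, a seeded uniform sample of that size is
    drawn instead (for very large graphs).
    """
    nodes = list(graph.nodes)
    pairs = [
        (u, v)
        for u, v in itertools.combinations(nodes, 2)
        if not graph.has_edge(u, v)
    ]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    return pairs


def _check_non_adjacent(graph, pairs):
    for u, v in pairs:
        if graph.has_edge(u, v):
            raise ValueError(f"pair ({u!r}, {v!r}) is an edge of the observed graph")
        if u == v:
            raise ValueError(f"self-pair ({u!r}, {u!r}) is not a valid candidate")


def neighbourhood_scores(graph: nx.Graph, pairs, index: str) -> ScoredPairs:
    """Score candidate pairs with a neighbourhood-overlap index.

    CN(x, y) = |G(x) & G(y)|                (common neighbours)
    DS(x, y) = 2 CN / (|G(x)| + |G(y)|)     (Dice similarity)
    AA(x, y) = sum_{z in G(x) & G(y)} 1/ln|G(z)|   (Adamic-Adar)
    PA(x, y) = |G(x)| |G(y)|                (preferential attachment)

    where G(x) is the neighbour set of x.  A degree-1 common neighbour
    (1/ln 1 undefined) contributes 0 to AA with a warning -- impossible
    in a simple graph, present purely as a guard.
    """
    index = index.lower()
    if index not in NEIGHBOURHOOD_INDICES:
        raise ValueError(
            f"unknown index {index!r}; choose one of {NEIGHBOURHOOD_INDICES}"
        )
    pairs = [tuple(p) for p in pairs]
    _check_non_adjacent(graph, pairs)
    adj = {v: set(graph.neighbors(v)) for v in graph.nodes}

    scores = np.empty(len(pairs))
    for k, (u, v) in enumerate(pairs):
        gu, gv = adj[u], adj[v]
        if index == "pa":
            scores[k] = len(gu) * len(gv)
            continue
        common = gu & gv
        if index == "cn":
            scores[k] = len(common)
        elif index == "ds":
            denom = len(gu) + len(gv)
            scores[k] = 2.0 * len(common) / denom if denom else 0.0
        else:  # aa
            s = 0.0
            for z in common:
                dz = len(adj[z])
                if dz <= 1:
                    logger.warning(
                        "degree-1 common neighbour %r skipped in AA", z
                    )
                    continue
                s += 1.0 / np.log(dz)
            scores[k] = s
    return ScoredPairs(pairs, scores)


def hyperbolic_scores(coords: PolarCoords, pairs) -> ScoredPairs:
    """Score pairs by negative inferred hyperbolic distance.

    Short distances correlate with high connection probability, so the
    closest pair receives the highest score.
    """
    pairs = [tuple(p) for p in pairs]
    return ScoredPairs(pairs, -pairwise_distances(coords, pairs))


def snapshot_positives(g_t: nx.Graph, g_t1: nx.Graph) -> set:
    """New edges of the later snapshot among the earlier snapshot's nodes.

    Returns the edges of ``g_t1`` whose both endpoints exist in ``g_t``
    and which are absent from ``g_t``, as a set of sorted-by-str tuples.
    Nodes of ``g_t`` missing from ``g_t1`` are logged.
    """
    nodes_t = set(g_t.nodes)
    missing = nodes_t - set(g_t1.nodes)
    if missing:
        logger.warning(
            "%d node(s) of the earlier snapshot are absent from the later "
            "one; their pairs cannot be labelled positive",
            len(missing),
        )
    out = set()
    for u, v in g_t1.edges:
        if u in nodes_t and v in nodes_t and not g_t.has_edge(u, v):
            out.add(_canon(u, v))
    return out


def _canon(u, v):
    return (u, v) if str(u) <= str(v) else (v, u)


def label_scored_pairs(scored: ScoredPairs, positives: set) -> ScoredPairs:
    """Attach boolean labels: True where the pair is in ``positives``."""
    labels = np.array([_canon(u, v) in positives for u, v in scored.pairs])
    return ScoredPairs(scored.pairs, scored.scores, labels)


def precision_recall(scored: ScoredPairs) -> PRCurve:
    """Precision-recall curve over descending score thresholds.

    One point per distinct score value; tied pairs enter together
    (block threshold semantics).  Precision = TP/(TP+FP) and
    Recall = TP/(TP+FN) among the labelled candidates; AUPR by the
    trapezoid rule over recall, anchored at (recall 0, first
    precision).
    """
    if scored.labels is None:
        raise ValueError("precision_recall requires labelled pairs")
    n_pos = int(scored.labels.sum())
    if n_pos == 0:
        raise ValueError("no positive pairs; a PR curve is undefined")

    order = np.argsort(-scored.scores, kind="stable")
    s = scored.scores[order]
    y = scored.labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # keep only the last entry of each tied-score block
    last_of_block = np.r_[s[1:] != s[:-1], True]
    thresholds = s[last_of_block]
    tp_b, fp_b = tp[last_of_block], fp[last_of_block]
    precision = tp_b / (tp_b + fp_b)
    recall = tp_b / n_pos
    aupr = float(
        np.trapezoid(np.r_[precision[0], precision], np.r_[0.0, recall])
    )
    return PRCurve(thresholds, precision, recall, aupr)


def holdout_split(graph: nx.Graph, fraction: float = 0.1, seed: int = 0):
    """Remove a random edge fraction while keeping the graph connected.

    Edges of a spanning tree are protected; the removed set is a seeded
    uniform sample of the remaining edges.  Returns
    (observed graph, removed edge set) -- the removed edges are the
    positives for link-prediction evaluation.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if not nx.is_connected(graph):
        raise ValueError("holdout_split requires a connected graph")
    rng = np.random.default_rng(seed)
    tree_edges = {_canon(u, v) for u, v in nx.minimum_spanning_edges(graph, data=False)}
    removable = [e for e in (_canon(u, v) for u, v in graph.edges) if e not in tree_edges]
    n_remove = int(round(fraction * graph.number_of_edges()))
    if n_remove > len(removable):
        raise ValueError(
            f"cannot remove {n_remove} edges while preserving connectivity "
            f"(only {len(removable)} non-tree edges)"
        )
    idx = rng.choice(len(removable), size=n_remove, replace=False)
    removed = {removable[i] for i in idx}
    observed = graph.copy()
    observed.remove_edges_from(removed)
    return observed, removed
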