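"""Edge-list and coordinate-table I/O with input sanitation.

Edge lists are whitespace-separated two-column text files (``#``
comments allowed, labels are opaque strings).  Reading cleans the graph
the way network studies usually do: self-loops and duplicate (including
reciprocal) edges are discarded with logged counts, and only the
largest connected component is kept.  Coordinate tables are TSV at full
float precision so that write/read round-trips exactly.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .geometry import PolarCoords

logger = logging.getLogger(__name__)

__all__ = [
    "read_edgelist",
    "write_edgelist",
    "write_coords",
    "read_coords",
    "write_ps_coords",
]

COORD_COLUMNS = ["node_id", "r", "theta", "degree", "rank"]


def read_edgelist(path, directed_ok: bool = True) -> nx.Graph:
    """Read and sanitise an undirected simple graph from an edge list.

    Self-loops and duplicate edges (reciprocal lines collapse, per
    ``directed_ok``) are dropped with logged counts; the graph is
    restricted to its largest connected component.  Raises
    ``ValueError`` on empty files, malformed lines, or graphs that are
    empty after cleaning.
    """
    edges = []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 whitespace-"
                    f"separated columns, got {len(parts)}"
                )
            edges.append((parts[0], parts[1]))
            n_lines += 1
    if not edges:
        raise ValueError(f"{path}: no edges found")

    n_self = sum(1 for u, v in edges if u == v)
    edges = [(u, v) for u, v in edges if u != v]
    seen = set()
    n_dup = 0
    G = nx.Graph()
    for u, v in edges:
        key = (u, v) if u <= v else (v, u)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        G.add_edge(u, v)
    if n_self:
        logger.info("dropped %d self-loop(s)", n_self)
    if n_dup:
        logger.info("dropped %d duplicate/reciprocal edge(s)", n_dup)
    if G.number_of_nodes() == 0:
        raise ValueError(f"{path}: graph is empty after cleaning")

    components = list(nx.connected_components(G))
    if len(components) > 1:
        largest = max(components, key=len)
        dropped = G.number_of_nodes() - len(largest)
        logger.info(
            "kept largest connected component (%d nodes); dropped %d node(s)",
            len(largest), dropped,
        )
        G = G.subgraph(largest).copy()
    return G


def write_edgelist(graph: nx.Graph, path) -> None:
    """Write edges as two whitespace-separated label columns, no header."""
    with open(path, "w") as fh:
        for u, v in graph.edges:
            fh.write(f"{u}\t{v}\n")


def write_coords(coords: PolarCoords, degrees, ranks, path) -> None:
    """Write a coordinate table (node_id, r, theta, degree, rank) as TSV.

    Floats are written with ``repr`` precision so the table round-trips
    bit-exactly through :func:`read_coords`.
    """
    degrees = list(degrees)
    ranks = list(ranks)
    if not (len(coords) == len(degrees) == len(ranks)):
        raise ValueError("coords, degrees and ranks must have equal lengths")
    with open(path, "w") as fh:
        fh.write("\t".join(COORD_COLUMNS) + "\n")
        for v, r, th, d, rk in zip(coords.node_ids, coords.r, coords.theta,
                                   degrees, ranks):
            fh.write(f"{v}\t{float(r)!r}\t{float(th)!r}\t{int(d)}\t{int(rk)}\n")


def read_coords(path) -> pd.DataFrame:
    """Read a coordinate table written by :func:`write_coords`.

    Returns the full table; ``to_polar_coords`` on the result gives the
    :class:`PolarCoords` view.
    """
    df = pd.read_csv(path, sep="\t", dtype={"node_id": str},
                     float_precision="round_trip")
    missing = [c for c in COORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df["node_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate node_id entries")
    return df


def to_polar_coords(df: pd.DataFrame) -> PolarCoords:
    return PolarCoords(list(df["node_id"]), df["r"].to_numpy(), df["theta"].to_numpy())


def write_ps_coords(coords: PolarCoords, path) -> None:
    """Write generator ground truth as TSV (node_id, r, theta, birth_time).

    PS nodes are labelled by birth order, so birth_time is the label.
    """
    with open(path, "w") as fh:
        fh.write("node_id\tr\ttheta\tbirth_time\n")
        for v, r, th in zip(coords.node_ids, coords.r, coords.theta):
            fh.write(f"{v}\t{float(r)!r}\t{float(th)!r}\t{int(v)}\n")
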