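"""Laplacian-based hyperbolic network embedding (LaBNE).

Embeds a connected simple graph into the hyperbolic plane in three
steps:

1. Build the graph Laplacian L = D - A (D the diagonal degree matrix).
2. Solve the generalized eigenproblem L y = lambda D y for the k = 3
   algebraically smallest eigenpairs.  The zero eigenvalue (constant
   eigenvector, guaranteed unique on a connected graph) is discarded;
   the eigenvectors y1, y2 of the two smallest non-zero eigenvalues
   minimise sum_ij A_ij ||Y_i - Y_j||^2 under D-orthonormality, pulling
   linked nodes together in the plane.
3. Angular coordinates theta_i = atan2(y2_i, y1_i); radial coordinates
   from the degree rank, r_i = 2 beta ln i + 2 (1 - beta) ln N with
   beta = 1/(gamma - 1), placing hubs near the disc centre as the
   popularity-similarity growth process would.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import TWO_PI, PolarCoords
from .ps_model import fit_power_law_exponent

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingResult",
    "build_laplacian",
    "solve_generalized_eigenproblem",
    "angular_coordinates",
    "radial_coordinates",
    "labne_embed",
]

#: eigenvalues below this are treated as the zero mode of a connected graph
ZERO_EIGENVALUE_TOL = 1e-9
#: relative residual tolerance ||Lv - lambda Dv|| <= tol * ||Dv||
RESIDUAL_TOL = 1e-8
#: below this many nodes a dense generalized eigensolve is used
DENSE_CUTOFF = 500

GAMMA_AUTO_RANGE = (2.01, 3.5)


@dataclass
class EmbeddingResult:
    """Inferred hyperbolic coordinates plus the spectral by-products.

    Attributes
    ----------
    coords
        Inferred (r, theta) per node.
    eigenvalues
        The k smallest generalized eigenvalues, ascending (first ~ 0).
    Y
        The two eigenvectors used, one row per node (columns y1, y2).
    gamma_used
        Scaling exponent applied in the radial formula.
    degree_rank
        1-based degree rank per node (rank 1 = highest degree), aligned
        with ``coords.node_ids``.
    """

    coords: PolarCoords
    eigenvalues: np.ndarray
    Y: np.ndarray
    gamma_used: float
    degree_rank: np.ndarray


def build_laplacian(graph: nx.Graph, nodelist=None):
    """Sparse Laplacian L = D - A and degree matrix D of a connected graph.

    Row/column order follows ``nodelist`` (default: the graph's node
    insertion order).  Raises on graphs with fewer than 3 nodes or more
    than one connected component.
    """
    if graph.number_of_nodes() < 3:
        raise ValueError("embedding needs a graph with at least 3 nodes")
    if not nx.is_connected(graph):
        raise ValueError(
            "graph has multiple connected components; only single-component "
            "networks are considered (restrict to the largest component)"
        )
    if nodelist is None:
        nodelist = list(graph.nodes)
    L = nx.laplacian_matrix(graph, nodelist=nodelist).astype(float).tocsr()
    degrees = np.array([graph.degree(v) for v in nodelist], dtype=float)
    D = sp.diags(degrees, format="csr")
    return L, D


def solve_generalized_eigenproblem(L, D, k: int = 3):
    """k algebraically smallest eigenpairs of L v = lambda D v.

    Returns (eigenvalues ascending, eigenvectors as columns).  The
    eigenvectors are D-orthonormal.  Uses a dense generalized solver
    below ``DENSE_CUTOFF`` nodes and shift-invert ARPACK (small negative
    shift, since L itself is singular) above it.
    """
    n = L.shape[0]
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < N, got k={k}, N={n}")
    if n < DENSE_CUTOFF:
        vals, vecs = scipy.linalg.eigh(
            L.toarray(), D.toarray(), subset_by_index=[0, k - 1]
        )
    else:
        try:
            vals, vecs = spla.eigsh(
                L.tocsc(),
                k=k,
                M=D.tocsc(),
                sigma=-1e-2,
                which="LM",
                maxiter=10 * n,
                tol=1e-10,
                # a generous Krylov subspace so degenerate eigenvalues
                # (e.g. on symmetric graphs) are resolved with their
                # full multiplicity
                ncv=min(n, max(8 * k, 80)),
            )
        except spla.ArpackNoConvergence as exc:
            raise RuntimeError(
                "generalized eigensolver did not converge; increase the "
                "iteration budget or use the dense path"
            ) from exc
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    _check_residuals(L, D, vals, vecs)
    return vals, vecs


def _check_residuals(L, D, vals, vecs):
    for lam, v in zip(vals, vecs.T):
        Dv = D @ v
        res = np.linalg.norm(L @ v - lam * Dv)
        if res > RESIDUAL_TOL * max(np.linalg.norm(Dv), 1e-300):
            raise RuntimeError(
                f"eigenpair residual {res:.2e} exceeds tolerance "
                f"{RESIDUAL_TOL:g}; increase the solver iteration budget"
            )


def angular_coordinates(Y: np.ndarray) -> np.ndarray:
    """theta_i = atan2(y2_i, y1_i) mapped into [0, 2*pi).

    The two-argument arctangent keeps all four quadrants; rows that are
    exactly (0, 0) get theta = 0 with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError(f"Y must have shape (N, 2), got {Y.shape}")
    zero_rows = (Y[:, 0] == 0.0) & (Y[:, 1] == 0.0)
    if np.any(zero_rows):
        logger.warning(
            "%d node(s) have y1 = y2 = 0 exactly; their angle is set to 0",
            int(zero_rows.sum()),
        )
    theta = np.arctan2(Y[:, 1], Y[:, 0]) % TWO_PI
    theta[zero_rows] = 0.0
    return theta


def radial_coordinates(graph: nx.Graph, gamma: float, nodelist=None):
    """Degree-rank radial coordinates r_i = 2 beta ln i + 2 (1-beta) ln N.

    Nodes are ranked i = 1..N by decreasing degree (ties broken by
    ascending node label); the hub gets r = 2(1-beta) ln N, the rank-N
    node r = 2 ln N.  Returns (r, rank) aligned with ``nodelist``
    (default: graph node order).
    """
    if gamma <= 1:
        raise ValueError(f"gamma must exceed 1, got {gamma}")
    if nodelist is None:
        nodelist = list(graph.nodes)
    N = len(nodelist)
    if N < 2:
        raise ValueError("need at least 2 nodes for radial coordinates")
    beta = 1.0 / (gamma - 1.0)
    order = sorted(nodelist, key=lambda v: (-graph.degree(v), v))
    rank_of = {v: i + 1 for i, v in enumerate(order)}
    rank = np.array([rank_of[v] for v in nodelist], dtype=int)
    r = 2.0 * beta * np.log(rank) + 2.0 * (1.0 - beta) * np.log(N)
    return r, rank


def labne_embed(graph: nx.Graph, gamma="auto", k: int = 3) -> EmbeddingResult:
    """Embed a connected simple graph into the hyperbolic disc.

    Parameters
    ----------
    graph
        Connected simple undirected graph, N >= 3.
    gamma
        Scaling exponent for the radial formula, or ``"auto"`` to fit a
        power-law MLE to the degree sequence (clamped to
        ``GAMMA_AUTO_RANGE`` with a warning).
    k
        Number of smallest eigenpairs computed (>= 3; the zero mode is
        discarded and the next two become the coordinates).

    Returns
    -------
    EmbeddingResult
    """
    nodelist = list(graph.nodes)
    L, D = build_laplacian(graph, nodelist)
    if k < 3:
        raise ValueError("k must be >= 3 (zero mode plus two coordinate axes)")
    vals, vecs = solve_generalized_eigenproblem(L, D, k=k)

    zero_idx = np.flatnonzero(np.abs(vals) < ZERO_EIGENVALUE_TOL)
    if zero_idx.size != 1:
        raise RuntimeError(
            f"expected exactly one zero eigenvalue on a connected graph, "
            f"found {zero_idx.size} below {ZERO_EIGENVALUE_TOL:g}"
        )
    keep = [i for i in range(len(vals)) if i != zero_idx[0]][:2]
    Y = vecs[:, keep]
    theta = angular_coordinates(Y)

    degrees = np.array([graph.degree(v) for v in nodelist])
    if gamma == "auto":
        k_min = max(2, int(degrees.min()))
        try:
            gamma_used = fit_power_law_exponent(degrees, k_min=k_min)
        except ValueError as exc:
            raise ValueError(
                "automatic gamma estimation failed; pass an explicit gamma"
            ) from exc
        lo, hi = GAMMA_AUTO_RANGE
        if not (lo <= gamma_used <= hi):
            warnings.warn(
                f"fitted gamma {gamma_used:.3f} outside [{lo}, {hi}]; "
                "clamping (scale-free networks typically have gamma in [2, 3])",
                stacklevel=2,
            )
            gamma_used = min(max(gamma_used, lo), hi)
    else:
        gamma_used = float(gamma)
        if gamma_used <= 1:
            raise ValueError(f"gamma must exceed 1, got {gamma_used}")

    r, rank = radial_coordinates(graph, gamma_used, nodelist)
    return EmbeddingResult(
        coords=PolarCoords(nodelist, r, theta),
        eigenvalues=vals,
        Y=Y,
        gamma_used=gamma_used,
        degree_rank=rank,
    )
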