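"""Hyperbolic-plane primitives in the native disc representation.

The native representation of the hyperbolic plane H^2 (curvature K = -1)
places every node at polar coordinates (r, theta) inside a Euclidean disc,
where r is the true hyperbolic distance from the origin and angles are
conformal.  For two points (r_s, theta_s) and (r_t, theta_t) separated by
an angle dtheta, the widely used large-distance approximation of the
hyperbolic law of cosines is

    x_st = r_s + r_t + 2 ln(dtheta / 2),

accurate to well under 0.1 for radii above ~5 and angular separations
above ~0.1 rad.  Because the formula diverges to -inf as dtheta -> 0 while
the exact distance is bounded below by |r_s - r_t|, distances returned
here are clamped from below at |r_s - r_t|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = [
    "PolarCoords",
    "angular_separation",
    "hyperbolic_distance",
    "pairwise_distances",
    "all_pairs",
    "distance_matrix",
]


@dataclass
class PolarCoords:
    """Per-node hyperbolic polar coordinates.

    Parameters
    ----------
    node_ids
        Ordered node labels (opaque, hashable).
    r
        Radial coordinates (hyperbolic length from the disc origin), >= 0.
    theta
        Angular coordinates in radians; normalised to [0, 2*pi) on
        construction.
    """

    node_ids: list
    r: np.ndarray
    theta: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        self.r = np.asarray(self.r, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float) % TWO_PI
        if not (len(self.node_ids) == self.r.shape[0] == self.theta.shape[0]):
            raise ValueError(
                "node_ids, r and theta must have identical lengths "
                f"({len(self.node_ids)}, {self.r.shape[0]}, {self.theta.shape[0]})"
            )
        if np.any(self.r < 0):
            raise ValueError("radial coordinates must be non-negative")
        self._index = {v: i for i, v in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise ValueError("duplicate node labels in coordinate set")

    def __len__(self) -> int:
        return len(self.node_ids)

    def index_of(self, node) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"node {node!r} has no coordinates") from None

    def rotated(self, phi: float) -> "PolarCoords":
        """Coordinates after a rigid rotation of the disc by phi radians."""
        return PolarCoords(self.node_ids, self.r.copy(), self.theta + phi)

    def reflected(self) -> "PolarCoords":
        """Coordinates after the reflection theta -> -theta."""
        return PolarCoords(self.node_ids, self.r.copy(), -self.theta)

    def subset(self, nodes) -> "PolarCoords":
        idx = np.array([self.index_of(v) for v in nodes], dtype=int)
        return PolarCoords(list(nodes), self.r[idx], self.theta[idx])


def angular_separation(theta1, theta2):
    """Smallest angle between two directions, in [0, pi].

    Accepts scalars or arrays (broadcast); inputs need not be normalised.
    """
    d = np.abs(np.asarray(theta1, dtype=float) - np.asarray(theta2, dtype=float)) % TWO_PI
    return np.pi - np.abs(np.pi - d)


def hyperbolic_distance(r_s, theta_s, r_t, theta_t):
    """Hyperbolic distance between two points of the native disc.

    Uses x = r_s + r_t + 2 ln(dtheta/2), clamped from below at
    |r_s - r_t| (the exact distance can never fall below the radial
    difference; the log term diverges for near-collinear points).
    Accepts scalars or broadcastable arrays.
    """
    r_s = np.asarray(r_s, dtype=float)
    r_t = np.asarray(r_t, dtype=float)
    if np.any(r_s < 0) or np.any(r_t < 0):
        raise ValueError("radial coordinates must be non-negative")
    sep = angular_separation(theta_s, theta_t)
    with np.errstate(divide="ignore"):
        approx = r_s + r_t + 2.0 * np.log(sep / 2.0)
    out = np.maximum(approx, np.abs(r_s - r_t))
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def pairwise_distances(coords: PolarCoords, pairs) -> np.ndarray:
    """Hyperbolic distance for each (u, v) pair of labelled nodes.

    Element i equals ``hyperbolic_distance`` applied to pair i.  Unknown
    labels raise ``KeyError`` naming the offending node.
    """
    pairs = list(pairs)
    if not pairs:
        return np.empty(0, dtype=float)
    ia = np.array([coords.index_of(u) for u, _ in pairs], dtype=int)
    ib = np.array([coords.index_of(v) for _, v in pairs], dtype=int)
    return hyperbolic_distance(
        coords.r[ia], coords.theta[ia], coords.r[ib], coords.theta[ib]
    )


def all_pairs(n: int):
    """Index arrays (i, j) for the n(n-1)/2 unordered pairs, i < j."""
    return np.triu_indices(n, k=1)


def distance_matrix(coords: PolarCoords) -> np.ndarray:
    """Condensed vector of all n(n-1)/2 pairwise hyperbolic distances.

    Pair order matches :func:`all_pairs` on the coordinate ordering.
    """
    i, j = all_pairs(len(coords))
    return hyperbolic_distance(
        coords.r[i], coords.theta[i], coords.r[j], coords.theta[j]
    )
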