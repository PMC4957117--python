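"""Basic link-based HyperMap: maximum-likelihood hyperbolic embedding.

HyperMap embeds a network by replaying its growth under the
popularity-similarity model.  Nodes are sorted by decreasing degree and
re-born one at a time: node i arrives at radius r_i = 2 ln i (the hub at
r_1 = 0), earlier nodes drift outward, and the newcomer's angle is the
grid point (spacing 1/i over [0, 2*pi)) maximising the Bernoulli
log-likelihood that the observed links/non-links to already-placed nodes
arose from the Fermi-Dirac connection probability p(x).

Only the basic link-based likelihood is implemented; the hybrid
common-neighbours likelihood and degree-based speed-up heuristics are
refinements outside this package's scope.  Complexity is O(N^2) per node
pair evaluation, O(N^3)-ish overall at small N -- intended as an
accuracy baseline, not a production embedder.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import networkx as nx
import numpy as np
from scipy.special import expit

from .geometry import TWO_PI, PolarCoords, angular_separation
from .ps_model import disc_radius

__all__ = ["HyperMapConfig", "local_log_likelihood", "hypermap_embed"]

#: probabilities are clamped to [CLAMP, 1 - CLAMP] before taking logs
CLAMP = 1e-12


@dataclass(frozen=True)
class HyperMapConfig:
    """Likelihood parameters for the HyperMap replay.

    m, gamma and T play the same roles as in the PS generator (T must be
    positive for a smooth Bernoulli likelihood; it is typically
    calibrated externally to the network's clustering).  ``seed`` fixes
    the random angle of the first-placed node.
    """

    m: int
    gamma: float
    T: float
    seed: int

    def __post_init__(self):
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be an integer >= 1, got {self.m}")
        if self.gamma <= 1:
            raise ValueError(f"gamma must exceed 1, got {self.gamma}")
        if not (0.0 < self.T < 1.0):
            raise ValueError(
                f"temperature must lie in (0, 1) for the Bernoulli "
                f"likelihood, got {self.T}"
            )

    @property
    def beta(self) -> float:
        return 1.0 / (self.gamma - 1.0)


def local_log_likelihood(theta, i, placed_r, placed_theta, is_neighbour, config):
    """Bernoulli log-likelihood of node i's links given a candidate angle.

    sum_{j < i} [ e_ij ln p(x_ij) + (1 - e_ij) ln(1 - p(x_ij)) ], with
    x_ij the hyperbolic distance from (2 ln i, theta) to placed node j
    and p the Fermi-Dirac probability at the current disc radius R_i.
    ``theta`` may be a scalar or a vector of candidate angles (a value
    per candidate is returned); probabilities are clamped away from
    {0, 1} so the result is always finite.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    placed_r = np.asarray(placed_r, dtype=float)
    placed_theta = np.asarray(placed_theta, dtype=float)
    e = np.asarray(is_neighbour, dtype=bool)
    if placed_r.size == 0:
        out = np.zeros(theta.shape)
        return float(out[0]) if out.size == 1 else out

    r_i = 2.0 * math.log(i)
    R_i = disc_radius(i, config.m, config.beta, config.T)
    sep = angular_separation(theta[:, None], placed_theta[None, :])
    with np.errstate(divide="ignore"):
        x = r_i + placed_r[None, :] + 2.0 * np.log(sep / 2.0)
    x = np.maximum(x, np.abs(r_i - placed_r[None, :]))
    p = expit(-(x - R_i) / (2.0 * config.T))
    p = np.clip(p, CLAMP, 1.0 - CLAMP)
    ll = np.where(e[None, :], np.log(p), np.log1p(-p)).sum(axis=1)
    return float(ll[0]) if ll.size == 1 else ll


def hypermap_embed(graph: nx.Graph, config: HyperMapConfig) -> PolarCoords:
    """Replay the network's growth, placing each node at its MLE angle.

    Nodes are processed in decreasing-degree order (ties broken by
    ascending label).  Node i's candidate angles form the half-open grid
    arange(0, 2*pi, 1/i); equal-likelihood ties resolve to the smallest
    angle.  Radial drift r_j(i) = beta r_j + (1 - beta) r_i is applied
    to all earlier nodes at each birth, so radial order equals degree
    order by construction.
    """
    order = sorted(graph.nodes, key=lambda v: (-graph.degree(v), v))
    N = len(order)
    if N < 2:
        raise ValueError("need at least 2 nodes to embed")
    index_of = {v: i for i, v in enumerate(order)}
    rng = np.random.default_rng(config.seed)
    beta = config.beta

    r = np.zeros(N)
    theta = np.zeros(N)
    theta[0] = rng.uniform(0.0, TWO_PI)

    adj = {v: set(graph.neighbors(v)) for v in order}
    birth_r = 2.0 * np.log(np.arange(1, N + 1))
    for i in range(2, N + 1):
        r_i = 2.0 * math.log(i)
        # drift from the birth radius: r_j(i) = beta r_j + (1 - beta) r_i
        r[: i - 1] = beta * birth_r[: i - 1] + (1.0 - beta) * r_i
        r[i - 1] = r_i

        grid = np.arange(0.0, TWO_PI, 1.0 / i)
        neigh = adj[order[i - 1]]
        e = np.fromiter(
            (order[j] in neigh for j in range(i - 1)), dtype=bool, count=i - 1
        )
        ll = local_log_likelihood(grid, i, r[: i - 1], theta[: i - 1], e, config)
        theta[i - 1] = grid[int(np.argmax(ll))]  # first max = smallest angle

    return PolarCoords(order, r, theta)
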