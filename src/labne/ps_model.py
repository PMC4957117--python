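"""Popularity-Similarity (PS) network generator.

Grows scale-free, strongly clustered networks on the hyperbolic plane
(native disc, K = -1).  At time t a new node appears at radius
r_t = 2 ln t and a uniform angle; every existing node s drifts outward,
r_s(t) = beta * r_s + (1 - beta) * r_t with beta = 1/(gamma - 1), which
attenuates its seniority.  The newcomer then connects to m existing
nodes: at temperature T = 0 deterministically to the m hyperbolically
closest ones, at T > 0 by accepting uniformly sampled partners with the
Fermi-Dirac probability

    p(x) = 1 / (1 + exp((x - R_t) / (2 T))),

where R_t is the current radius of the disc holding the network.  The
result is a connected simple graph whose degree distribution follows
P(k) ~ k^-gamma and whose mean clustering decreases with T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit, zeta

from .geometry import TWO_PI, PolarCoords, hyperbolic_distance

__all__ = [
    "PSParams",
    "connection_probability",
    "disc_radius",
    "grow_ps_network",
    "fit_power_law_exponent",
]

# Guard against non-terminating acceptance sampling (rounds per node).
MAX_ATTEMPT_ROUNDS_PER_LINK = 10_000


@dataclass(frozen=True)
class PSParams:
    """Configuration of a PS-model growth run.

    Parameters
    ----------
    N
        Final node count (>= 2).
    m
        Links added per new node; the mean degree approaches 2m.
    gamma
        Target scaling exponent of the degree distribution; must give
        beta = 1/(gamma - 1) in (0, 1], i.e. gamma >= 2.
    T
        Network temperature in [0, 1).  T = 0 yields the deterministic
        closest-neighbour rule and maximal clustering.
    seed
        RNG seed; identical (params, seed) reproduce the same network.
    """

    N: int
    m: int
    gamma: float
    T: float
    seed: int
    beta: float = field(init=False)

    def __post_init__(self):
        if int(self.N) != self.N or self.N < 2:
            raise ValueError(f"N must be an integer >= 2, got {self.N}")
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"m must be an integer >= 1, got {self.m}")
        if self.gamma <= 1:
            raise ValueError(f"gamma must exceed 1, got {self.gamma}")
        beta = 1.0 / (self.gamma - 1.0)
        if not (0.0 < beta <= 1.0):
            raise ValueError(
                f"beta = 1/(gamma-1) = {beta:.4g} must lie in (0, 1]; "
                "use gamma >= 2"
            )
        if not (0.0 <= self.T < 1.0):
            raise ValueError(
                f"temperature must lie in [0, 1) (cold regime), got {self.T}"
            )
        object.__setattr__(self, "beta", beta)


def connection_probability(x, R_t, T):
    """Fermi-Dirac connection probability p(x) = 1/(1 + e^{(x - R_t)/(2T)}).

    Monotonically decreasing in the hyperbolic distance x, equal to 1/2
    at the disc radius R_t.  Only defined for T > 0; the T = 0 limit is
    a step function handled by the deterministic growth rule.
    """
    if T <= 0:
        raise ValueError(
            "connection_probability requires T > 0; at T = 0 the PS model "
            "connects each new node to its m hyperbolically closest "
            "neighbours (handled by grow_ps_network directly)"
        )
    x = np.asarray(x, dtype=float)
    out = expit(-(x - R_t) / (2.0 * T))
    return float(out) if out.ndim == 0 else out


def disc_radius(t: int, m: int, beta: float, T: float) -> float:
    """Current radius R_t of the hyperbolic disc containing the network.

    For beta = 1 (no radial drift) R_t = 2 ln t exactly.  Otherwise

        R_t = r_t - 2 ln[ (2T / sin(pi T)) (1 - e^{-(1-beta) ln t})
                          / (m (1 - beta)) ],

    with the T -> 0 limit 2T/sin(pi T) -> 2/pi.
    """
    r_t = 2.0 * math.log(t)
    if beta == 1.0 or t == 1:
        return r_t
    temp_factor = 2.0 / math.pi if T == 0 else 2.0 * T / math.sin(math.pi * T)
    inner = temp_factor * (1.0 - math.exp(-(1.0 - beta) * math.log(t))) / (
        m * (1.0 - beta)
    )
    return r_t - 2.0 * math.log(inner)


def grow_ps_network(params: PSParams) -> tuple[nx.Graph, PolarCoords]:
    """Grow a PS-model network; returns the graph and final coordinates.

    Nodes are labelled 1..N by birth time.  Every node t > 1 carries
    exactly min(t-1, m) links to earlier nodes, so the graph is
    connected with sum(min(t-1, m)) edges.  Returned radii are the
    final, fully drifted values.

    Per node the RNG is consumed in a fixed order -- one angular draw,
    then (for T > 0) one permutation and one uniform vector per
    attempt round -- so results are reproducible bit-for-bit.
    """
    N, m, beta, T = params.N, params.m, params.beta, params.T
    rng = np.random.default_rng(params.seed)

    r = np.zeros(N)
    theta = np.empty(N)
    G = nx.Graph()

    theta[0] = rng.uniform(0.0, TWO_PI)
    G.add_node(1)

    birth_r = 2.0 * np.log(np.arange(1, N + 1))
    for t in range(2, N + 1):
        r_t = 2.0 * math.log(t)
        # radial drift: r_s(t) = beta * r_s + (1 - beta) * r_t, where r_s
        # is the BIRTH radius 2 ln s (a closed form in t, not an iteration)
        r[: t - 1] = beta * birth_r[: t - 1] + (1.0 - beta) * r_t
        r[t - 1] = r_t
        theta[t - 1] = rng.uniform(0.0, TWO_PI)
        G.add_node(t)

        n_links = min(t - 1, m)
        if t - 1 <= m:
            chosen = np.arange(t - 1)
        elif T == 0.0:
            d = hyperbolic_distance(r[t - 1], theta[t - 1], r[: t - 1], theta[: t - 1])
            # ties in distance broken by smaller node index (lexsort is
            # stable over the secondary key)
            order = np.lexsort((np.arange(t - 1), d))
            chosen = order[:m]
        else:
            chosen = _sample_partners(t, m, r, theta, beta, T, rng)
        G.add_edges_from((t, int(s) + 1) for s in chosen)

    node_ids = list(range(1, N + 1))
    return G, PolarCoords(node_ids, r, theta)


def _sample_partners(t, m, r, theta, beta, T, rng):
    """Acceptance-sample m distinct earlier partners for node t (T > 0).

    Each attempt round draws the not-yet-connected candidates in a fresh
    uniform order (sampling without replacement) and accepts each with
    p(x); rounds repeat until m partners are found.
    """
    R_t = disc_radius(t, m, beta, T)
    d = hyperbolic_distance(r[t - 1], theta[t - 1], r[: t - 1], theta[: t - 1])
    p = expit(-(d - R_t) / (2.0 * T))
    connected: list[int] = []
    is_connected = np.zeros(t - 1, dtype=bool)
    for _ in range(MAX_ATTEMPT_ROUNDS_PER_LINK * m):
        candidates = np.flatnonzero(~is_connected)
        order = rng.permutation(candidates)
        accept = rng.random(order.size) < p[order]
        for s in order[accept]:
            connected.append(s)
            is_connected[s] = True
            if len(connected) == m:
                return np.array(connected)
        if len(connected) == m:
            return np.array(connected)
    raise RuntimeError(
        f"acceptance sampling for node {t} did not reach {m} links within "
        f"{MAX_ATTEMPT_ROUNDS_PER_LINK * m} attempt rounds"
    )


def fit_power_law_exponent(degrees, k_min: int = 2) -> float:
    """Maximum-likelihood power-law exponent of a degree sequence.

    Fits the discrete power law P(k) = k^-gamma / zeta(gamma, k_min)
    over the n tail observations k_i >= k_min by numerically maximising
    the log-likelihood

        -gamma * sum(ln k_i) - n * ln(zeta(gamma, k_min)),

    the standard estimator for integer-valued data (the continuous
    approximation gamma_hat = 1 + n / sum(ln(k_i / (k_min - 0.5))) is
    noticeably biased at small k_min).

    Raises ``ValueError`` for fewer than 50 tail observations or a
    constant tail (no information about the exponent).
    """
    degrees = np.asarray(degrees, dtype=float)
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    tail = degrees[degrees >= k_min]
    if tail.size < 50:
        raise ValueError(
            f"need >= 50 degree observations with k >= k_min={k_min}, "
            f"got {tail.size}"
        )
    if np.all(tail == tail[0]):
        raise ValueError("degenerate input: all tail degrees are equal")
    mean_log = float(np.mean(np.log(tail)))
    nll = lambda g: g * mean_log + math.log(zeta(g, k_min))
    res = minimize_scalar(nll, bounds=(1.01, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError("power-law MLE optimisation failed")
    return float(res.x)
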