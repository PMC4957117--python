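# Methods

## The popularity–similarity growth model

The generator (`labne.ps_model`) grows a network of N nodes on the native
disc of the hyperbolic plane (curvature K = −1). At time t ≥ 1 a node is
born at radius r_t = 2 ln t with an angle drawn uniformly from [0, 2π). At
every subsequent birth, each existing node s takes the drifted radius

    r_s(t) = β r_s + (1 − β) r_t,      β = 1/(γ − 1),

where r_s on the right-hand side is the **birth** radius 2 ln s — the drift
is a closed form in t, not an accumulated iteration — so the final radii are
exactly 2β ln s + 2(1 − β) ln N. β ∈ (0, 1] controls how quickly seniority
fades and sets the degree exponent γ of the resulting scale-free network.

The newcomer makes m links to earlier nodes (all of them when t − 1 ≤ m):

* **T = 0**: deterministically, to its m hyperbolically closest nodes
  (distance ties broken by smaller node index). This is the maximally
  clustered limit of the connection rule.
* **0 < T < 1**: candidate partners are drawn uniformly without replacement
  per attempt round and accepted with the Fermi–Dirac probability
  p(x) = 1/(1 + e^{(x − R_t)/(2T)}), where

      R_t = r_t − 2 ln[ (2T / sin(πT)) · (1 − e^{−(1−β) ln t}) / (m (1 − β)) ],

  with R_t = 2 ln t when β = 1 and the limit 2T/sin(πT) → 2/π as T → 0.
  Rounds repeat until m distinct partners accept; a cap of 10⁴·m rounds
  guards against pathological non-termination. Temperatures T ≥ 1 belong to
  a different ("hot") regime of the model where this R_t expression is
  invalid, so the constructor rejects them.

A single seeded generator drives all draws in a fixed order (one angle per
node, then the round permutations and acceptance uniforms), making runs
bit-reproducible. Edge count is exactly Σ_t min(t − 1, m), so the mean
degree is 2m − m(m + 1)/N → 2m.

### Degree-exponent estimation

`fit_power_law_exponent` fits the discrete power law
P(k) = k^−γ / ζ(γ, k_min) by numerically maximising the likelihood (Hurwitz
zeta via `scipy.special.zeta`). The popular closed-form continuous
approximation 1 + n/Σ ln(k_i/(k_min − 0.5)) is materially biased at the
small k_min values relevant here (k_min = m ≈ 5); on exact discrete
power-law samples (γ = 2.5, k_min = 2, n = 10⁴) the zeta MLE recovers the
exponent to ±0.03 where the shifted continuous form errs by ≈ −0.07. The
estimator requires at least 50 tail observations with variation.

## LaBNE

`labne.embedding` embeds a connected simple graph (N ≥ 3) in three steps.

1. **Laplacian.** L = D − A as a sparse matrix, rows/columns in the graph's
   node-insertion order. Disconnected input is rejected — the zero
   eigenvalue must be simple for step 2 to be well-posed.
2. **Spectral coordinates.** The k = 3 algebraically smallest eigenpairs of
   L y = λ D y. These minimise Σ_ij A_ij ‖Y_i − Y_j‖² under D-orthonormality,
   pulling linked nodes together. Solver: dense
   `scipy.linalg.eigh(L, D)` below 500 nodes; above that, shift-invert
   ARPACK (`eigsh`, σ = −0.01 — strictly negative because L itself is
   singular) with tolerance 1e−10, an iteration cap of 10 N, and a Krylov
   subspace of ≥ 80 vectors so that degenerate eigenvalues (cycles, complete
   graphs and other symmetric inputs) are resolved with full multiplicity.
   Residuals ‖Lv − λDv‖ ≤ 1e−8 ‖Dv‖ are verified after the solve. The zero
   mode is identified as the unique eigenvalue below 1e−9, not positionally.
3. **Polar coordinates.** θ = atan2(y₂, y₁) — the quadrant-aware form; the
   single-argument arctangent would fold the disc onto a half-circle.
   Radii come from the degree rank i (1 = highest degree, ties broken by
   ascending node label): r_i = 2β ln i + 2(1 − β) ln N. This is exactly the
   final radius a PS network assigns to its i-th oldest node, so degree rank
   stands in for seniority. γ is supplied by the user or fitted from the
   degree sequence ("auto", clamped to [2.01, 3.5] with a warning, since the
   radial formula presumes a scale-free regime γ ∈ (2, 3]).

The embedding is identifiable only up to rotation/reflection of the angles;
all evaluation metrics are therefore built from pairwise distances or
angular separations, never from raw angles. Under node relabelling the
angular geometry is preserved and radii are preserved as a multiset;
individual radii may swap among degree-tied nodes because rank ties break by
node label.

## HyperMap baseline

`labne.hypermap` implements the basic link-based maximum-likelihood replay:
nodes sorted by decreasing degree become birth order; node i is born at
r_i = 2 ln i (the hub at r_1 = 0) while earlier nodes drift exactly as in
the generator; its angle is the grid point in arange(0, 2π, 1/i) maximising
the Bernoulli log-likelihood Σ_{j<i} [e_ij ln p(x_ij) + (1 − e_ij) ln(1 − p(x_ij))],
with p evaluated at the current disc radius R_i and probabilities clamped to
[1e−12, 1 − 1e−12] before the logarithm. Likelihood ties resolve to the
smallest grid angle; T must be positive (it is an input, typically
calibrated externally to the observed clustering) and m, γ play the same
roles as in the generator. The hybrid common-neighbours likelihood and the
degree-threshold speed-up heuristic of the fast HyperMap variants are out of
scope here: this module exists as an accuracy baseline, and its O(N³)-ish
cost is the motivation for the spectral method.

## Geometry and its numerical guards

Distances use x = r_s + r_t + 2 ln(θ_st/2). This small-angle form deviates
from the exact hyperbolic law of cosines by 2 ln[(θ/2)/sin(θ/2)] (≈ 0.1 at
θ ≈ 1, 0.9 at θ = π) plus terms exponentially small in the radii; since
scores and correlations depend on distance *rankings* dominated by the radii
and the logarithmic angular term, this bias is immaterial for the package's
purposes and keeps the implementation consistent with the formula the
growth model itself uses. Because the formula diverges to −∞ as θ_st → 0
while the true distance is bounded below by |r_s − r_t|, all distances are
clamped from below at |r_s − r_t|. Angles are normalised to [0, 2π) at the
`PolarCoords` boundary.

## Link prediction and evaluation

Candidate pairs are all non-adjacent node pairs (optionally a seeded uniform
sample for very large graphs). Neighbourhood indices follow their standard
definitions; Adamic–Adar skips degree-1 common neighbours (1/ln 1 is
undefined; such a neighbour cannot actually occur in a simple graph, the
branch is a pure guard). Geometric scoring is the negative inferred
distance. Pairs more than two hops apart necessarily tie at zero under
CN/DS/AA; the precision–recall sweep therefore moves tied scores across the
threshold as a block. Precision = TP/(TP+FP) and Recall = TP/(TP+FN) in
their standard senses; AUPR is the trapezoid over recall with an anchor at
(recall 0, precision of the first block). For temporal evaluation the
positive set is the later snapshot's new edges restricted to the earlier
snapshot's nodes; for single-snapshot evaluation `holdout_split` removes a
random 10% of edges while protecting a spanning tree, so the observed graph
stays connected (a requirement of the embedder).

Recovery is summarised by the Pearson correlation between inferred and true
distances over all N(N−1)/2 pairs (N ≤ 1000; a seeded 10⁶-pair sample
beyond that). `benchmark_sweep` derives replicate seeds from a master seed
via `SeedSequence([master, cell, rep])` and records failures as NaN rather
than aborting. When a sweep asks HyperMap to embed a T = 0 network, the
likelihood temperature is floored at 0.1: the Bernoulli likelihood is
undefined at T = 0, and a small positive temperature is the natural smooth
surrogate for the step-function connection rule.

## Problem sizes used in the checks

The test suite and acceptance script run the full pipelines at N = 500–1000
nodes with 5–10 replicates per condition — large enough that the scale-free
exponent, clustering–temperature trend, recovery correlations (≈ 0.85–0.95
in the dense cold regime) and predictor orderings are stable, while a full
run completes in well under a minute.

## What the generator does and does not emulate

PS networks reproduce the features that matter for validating the embedder:
power-law degrees with tunable γ, tunable clustering via T, small-world
distances, and known ground-truth coordinates. They are still idealised:
degree ties are plentiful at the low end (making radial ranks partly
arbitrary there), the angular distribution is uniform (no community
structure in similarity space), every node arrives with exactly m links (no
degree-1 leaves, no multi-scale noise), and there is no edge removal or
rewiring. Passing recovery tests on PS networks therefore demonstrates
correctness of the machinery and its behaviour in the model's own geometry,
not performance guarantees on arbitrary real networks — on real data the
radial formula inherits whatever mismatch exists between degree rank and
actual node age, and γ must be estimated from a finite, noisy tail.

## Known limitations

* Only the two-dimensional hyperbolic plane at K = −1; no weighted or
  directed Laplacians.
* The generator covers the cold regime T ∈ [0, 1) with a uniform similarity
  space.
* HyperMap here is the basic link-based variant — an accuracy baseline, not
  a performance-competitive implementation.
* Candidate enumeration for link prediction is O(N²) memory in pair count;
  use `max_pairs` beyond ~10⁴ nodes.
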