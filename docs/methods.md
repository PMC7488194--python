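# Methods

This note records the models implemented by `neuroculture`, the defaults and
the reasoning behind the choices that were genuinely open. All lengths are in
mm, times in ms (dynamics) or s (analysis), unless stated.

## Substrate geometry

A substrate is a disc of diameter 2 or 4 mm (scalable by integer factors,
preserving obstacle area fractions) with three built-in obstacle families:

* **Crosses** — 130 μm high/wide, 20 μm beams, square lattice of pitch
  180 μm (50 μm gaps). Arrays are 4×4 blocks (670 μm side) placed at the
  center (1 array), side by side (2 arrays) or in a 2×2 block (4 arrays, 4 mm
  only) with 230 μm between arrays. The full-coverage layout keeps every
  cross whose center lies at least 50 μm from the rim; on the 2 mm disc that
  is exactly 89 crosses and an area fraction of 13.6 %.
* **Circles** — 120 μm diameter on a hexagonal lattice of pitch 170 μm
  (50 μm gaps), rows straddling the horizontal axis; circles are kept while
  their center is inside the disc (125 circles, 45.0 % on 2 mm).
* **Triangles** — isosceles, 50 μm high, 20 μm base, apex up, on a
  rectangular grid with 5 μm gaps in both directions (column pitch 25 μm,
  row pitch 55 μm) and a 5 μm obstacle-free rim ring (36.0 % on 2 mm).

Lattice registrations (row/column phases, boundary keep rules) are fixed
constants of the package so the area fractions are reproducible. Boundary
obstacles may overhang the rim slightly; `area_fraction` counts whole shape
areas and the raster cross-check counts all white pixels over in-disc pixels,
so the two agree to < 0.2 percentage points at 1 μm/pixel.

A note on the triangle grid: with the stated triangle size and 5 μm
clearances no packing of same-orientation triangles exceeds ~36 % coverage
(the densest staggered variants make the array nearly impenetrable to axons
long before they gain area). The open grid above is the layout consistent
with the funnelling physics this family of patterns is used for.

Geometric queries: point membership uses half-open edge rules (a point
exactly on a boundary belongs to the obstacle only on its min-x/min-y faces),
which makes rasterization unbiased; `first_hit` returns the earliest
parametric intersection of a directed segment with any obstacle edge, circle,
or the rim, together with the unit outward normal. Concave cross corners are
handled by the face owning the earliest hit; exact ties fall to the first
face in a fixed enumeration (a measure-zero event).

User-supplied monochrome masks (white = obstacle, black = substrate, JSON
sidecar with mm/pixel) are supported through `RasterSubstrate`, which locates
segment hits by quarter-pixel marching plus bisection and estimates normals
from the local indicator gradient.

## Structural growth

* Neuron count: N = round(density · π R²). The default density 625/π ≈
  198.9 /mm² makes the counts exactly 625, 2 500, 5 625, 10 000 and 22 500
  for diameters 2, 4, 6, 8 and 12 mm.
* Placement: uniform rejection sampling in the allowed region with a 7.5 μm
  pairwise exclusion radius (somas are virtual; axons do not interact with
  them).
* Dendritic tree: disc of radius drawn from N(150, 20) μm, truncated at
  ±3σ so radii are strictly positive.
* Axon: starts at the soma center with a uniform random heading; total
  length L ~ Rayleigh(σ = 0.9 mm) (mean ℓ_a ≈ 1.13 mm); segments of
  ℓ = 10 μm with N(0, 0.1 rad) heading jitter per segment. On contact with
  an obstacle or the rim the remaining segment length continues from the hit
  point with the direction mirrored about the surface normal; arc length is
  conserved exactly, and a cap of 100 reflections per segment guards
  pathological corners. ℓ and the jitter are not independently identifiable
  from the published summary statistics; the defaults were pinned by the
  empty-substrate calibration (ensemble mean k_in within 10 % of 66.3 and
  mean connection distance within 10 % of 0.533 mm) and kept fixed across
  all configurations.
* Rim behaviour is configurable (`reflect` default, `stop`, `open`).
  Reflection keeps the axon-length invariant and reproduces the calibration
  band; stopping or letting axons leave loses ~25 % of connectivity, far
  more than the border deficit seen in the reference data.
* Connections: a directed edge i→j whenever any polyline segment of axon i
  passes within the dendritic radius of neuron j (exact point-to-segment
  distances on k-d-tree candidates); repeated crossings collapse to one
  binary edge; no self-edges.
* Reproducibility: a master seed spawns one placement stream plus one
  substream per neuron, so results do not depend on iteration order.

Known deviation from the reference data this model family cannot remove:
exact (continuous) segment–obstacle collision makes obstacle lattices block
axons somewhat harder than step-discretized collision checking would, so
full-coverage configurations land at the low edge of the published degree
statistics and the empty-vs-full contrast is stronger. Specular billiards
are also time-reversal symmetric, so triangle arrays do not impose a *net*
direction on connections: the measured angle histograms are vertically
aligned (0° and 180° both enhanced, global maximum toward the tips) while
the in-degree map still shows the expected spatial gradient, increasing away
from the tips.

## Soma and synapse dynamics

Adaptive quadratic integrate-and-fire (Izhikevich form), regular-spiking
cortical parameters: τ_c = 100 ms, τ_a = 33.33 ms, k = 0.7, v_r = −60 mV,
v_t = −40 mV, v_p = 35 mV, v_c = −50 mV, b = −2, d_0 = 100. Synapses are
depressing impulses: a spike of neuron i depolarizes each target by
g_AMPA · D_i with g_AMPA = 9.5 (expressed directly in mV since the synaptic
time constant, ~1 ms, is far below every analysis bin); D recovers with
τ_D = 2 s and is multiplied by β = 0.8 at each presynaptic spike. Background
drive: per-synapse miniature events (independent Poisson, default
0.025 Hz/synapse, amplitude g_minis = 9.5, sampled event-driven) plus an
optional white-noise current (default off). A degree-independent mini mode
(`mini_basis="neuron"`) exists as a sensitivity configuration; it weakens
the burst-suppression ordering across obstacle densities and is not the
default.

Integration: v and u advance by explicit Euler at dt = 0.1 ms; D, linear and
decoupled, advances by its exact exponential propagator so the off-spike
closed form D(t) = 1 − (1 − D₀)e^(−t/τ_D) holds to machine precision. Spikes
are processed at the first step with v ≥ v_p; delivery uses the presynaptic
D before depression. The kernel is numba-compiled and bit-reproducible for a
given (network, parameters, seed).

Calibration contract (pinning the free parameters mini_rate, noise_sd): on
the default empty 2 mm network the per-neuron rate falls in 0.1–0.5 Hz and
network bursts recruit ≥ 25 % of neurons; burst counts then decrease
monotonically with cross coverage, with the fully covered substrate nearly
silent. Conduction delays are omitted (none are specified for this model
family); all neurons are excitatory.

## Burst analysis

Windows of 0.5 s slide with a 0.1 s stride (stride ≪ window avoids splitting
bursts at boundaries); a window is coordinated when it contains spikes from
≥ 25 % of the neurons. Filtering keeps exactly the spikes inside coordinated
windows (idempotent). Overlapping coordinated windows merge into one burst;
the burst start is its earliest spike, and IBIs are differences of
consecutive starts. Initiation points fit the participants' first-spike
times to t(x, y) = t₀ + |(x, y) − o| / c by nonlinear least squares with 9
starts on a 3×3 grid over the disc (the speed c is fitted jointly, bounded
positive); fits with apex outside the disc, < 4 participants, or collinear
geometry are invalid. Spatiotemporal maps average burst-relative first-spike
times on a 25×25 grid over the substrate bounding square, normalized so the
earliest populated cell is zero, smoothed by a NaN-aware Gaussian kernel of
one-cell bandwidth.

## Effective connectivity

Rasters are binned at 50 ms (half-open bins; a 30 min raster gives 36 000
samples). Transfer entropy uses Markov order k_M = 2 with instantaneous
feedback: the target sample x_{n+1} is conditioned on (x_n, x_{n−1}) and on
(y_{n+1}, y_n) — the source word is shifted to include the same bin, because
synaptic interactions are much faster than a bin. Probabilities are raw
plug-in counts (0·log 0 := 0); the estimate is a genuine conditional mutual
information of the empirical distribution and hence non-negative.
TE is computed on burst-filtered rasters; bins outside bursts stay in the
sequence as zeros. For each ordered pair, significance is a z-score against
the empirical pool of all scores sharing the source row or the target column
(self-pairs excluded, the pair's own score included once, population SD);
z ≥ 2 defines the binary effective adjacency. Pairs with zero pool variance
get no edge, with a warning.

## Network metrics

* Degrees: exact integer in/out degrees; Gaussian fits by nonlinear least
  squares on unit-width histograms (sample moments as fallback for
  degenerate histograms).
* Clustering: Fagiolo's directed coefficient,
  CC_i = ½[(A+Aᵀ)³]_ii / [k_tot(k_tot−1) − 2k_bi].
* Modularity: Louvain on the symmetrized weighted graph A + Aᵀ (reciprocal
  pairs weigh double), best of 10 seeded restarts; the reported Q is
  re-evaluated from the partition by the explicit modularity sum on the same
  weights, so optimizer and formula agree to 1e−9. Two disjoint 5-cliques
  give Q = 1/2 exactly.
* Global efficiency: BFS shortest paths on the directed graph; unreachable
  pairs contribute 0 (1/∞); E_id = 1 for the unweighted complete digraph, so
  G_eff = ⟨1/λ⟩. Isolated neurons therefore depress G_eff.
* Small-worldness: Humphries–Gurney σ = (C/C_rand)/(L/L_rand) on the
  symmetrized graph, against ≥ 10 degree-preserving edge-swap null graphs;
  path lengths on the largest connected component.
* Spatial heatmaps: cell side 31 μm on the 2 mm disc, scaled with diameter
  (≈ 0.2 neurons per cell); empty cells are NaN; interpolation is left to
  rendering.

## Problem sizes used by the test-suite and the acceptance script

Structural ensembles use the full published protocol (12 replicates of 625
neurons). Dynamics properties are checked on reduced runs — 5-minute
simulations, three seeds per configuration — and single-neuron integrations
are verified against an adaptive high-accuracy ODE oracle; these sizes give
stable orderings while keeping a complete run in the minutes range on one
CPU.

## Known limitations

* The growth model ignores axon–axon interactions, wall adhesion and
  branching; dendritic trees are discs.
* Only excitatory neurons; no plasticity beyond synaptic depression.
* The exact-collision growth engine makes dense obstacle lattices slightly
  more opaque than step-discretized models of the same geometry (see above),
  which propagates into lower full-coverage degrees, stronger modularity
  amplification, and near-silent full-coverage dynamics whose effective
  networks can be empty at the z ≥ 2 threshold.
* Transfer entropy is bivariate; no partial/multivariate conditioning, no
  correction for network-wide activity beyond burst filtering.
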