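# neuroculture

Simulation and analysis toolkit for *in-silico* neuronal cultures grown on
obstacle-patterned circular substrates.

Microfabricated obstacles (PDMS-like pillars and walls) are one of the most
effective ways to dictate how neurons wire up in culture. This package models
that situation end to end, for millimetre-sized discs decorated with
micrometre-sized obstacles — crosses, circles, or upward-pointing isosceles
triangles, in small arrays or tiling the whole disc:

1. **Substrate geometry** (`neuroculture.substrate`) — parametric obstacle
   layouts or user-supplied monochrome masks (white = obstacle), with exact
   point-membership and segment-intersection queries.
2. **Structural growth** (`neuroculture.growth`) — neurons are scattered
   uniformly (625 on a 2 mm disc at the default density), each with a
   circular dendritic tree of radius ~ N(150, 20) μm and a single axon grown
   as a biased random walk of 10 μm segments whose total length is
   Rayleigh-distributed (σ = 0.9 mm, mean ≈ 1.13 mm). Axons reflect
   specularly off obstacles and the substrate rim (v′ = v − 2(v·n)n). A
   directed edge i→j is created when the axon of i crosses the dendritic disc
   of j, giving the structural adjacency **S**.
3. **Spiking dynamics** (`neuroculture.dynamics`) — an adaptive quadratic
   integrate-and-fire soma (Izhikevich regular-spiking parameters), depressing
   impulse synapses (resource D, recovery τ_D = 2 s, depression β = 0.8,
   strength g_AMPA = 9.5) and miniature background events, integrated at
   dt = 0.1 ms in a numba kernel. The default network fires at 0.1–0.5 Hz per
   neuron with whole-network bursts.
4. **Burst analysis** (`neuroculture.bursts`) — sliding-window filtering of
   coordinated episodes (≥ 25 % of neurons in 0.5 s), inter-burst intervals,
   initiation points by space–time cone fitting, and 25×25 spatiotemporal
   propagation maps.
5. **Effective connectivity** (`neuroculture.transfer_entropy`) — generalized
   transfer entropy (Markov order 2, 50 ms bins, instantaneous feedback) with
   row∪column z-scoring; edges with z ≥ 2 form the effective adjacency **E**.
6. **Network metrics** (`neuroculture.metrics`) — degree statistics with
   Gaussian fits, Fagiolo directed clustering, Louvain modularity

   Q = 1/(2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j),

   global efficiency G_eff = ⟨1/λ(i,j)⟩ normalized by the complete graph,
   Humphries–Gurney small-worldness, and spatial heatmaps.

`neuroculture.experiments` drives replicate studies (12 structural / 4
dynamic replicates by default), and the `neuroculture` CLI exposes each stage
on files (`grow`, `simulate`, `bursts`, `infer-te`, `metrics`, `experiment`,
`make-mask`).

## Worked example

```python
import numpy as np
from neuroculture import (build_pattern, area_fraction, grow_network,
                          connection_geometry, modularity, global_efficiency)

pattern = build_pattern("crosses_full", diameter=2)     # 89 crosses, 2 mm disc
print(f"obstacle area fraction: {100 * area_fraction(pattern):.1f}%")

net = grow_network(pattern, seed=1)
geo = connection_geometry(net)
print(f"{net.n_neurons} neurons, {net.n_edges} edges, "
      f"mean k_in = {net.k_in.mean():.1f}, mean d = {geo.distances.mean():.3f} mm")
print(f"Q = {modularity(net.adjacency, seed=1).q:.2f}, "
      f"G_eff = {global_efficiency(net.adjacency).g_eff:.2f}")
```

prints

```
obstacle area fraction: 13.6%
625 neurons, 27810 edges, mean k_in = 44.5, mean d = 0.260 mm
Q = 0.58, G_eff = 0.42
```

i.e. the full cross coverage occupies 13.6 % of the disc, pulls the mean
in-degree down from ~70 (empty substrate) to ~44 by trapping and deflecting
axons, shortens connections (0.26 mm vs 0.53 mm), and makes the network
markedly more modular (empty substrates give Q ≈ 0.37, G_eff ≈ 0.54).

Simulating activity and inferring the effective network:

```python
from neuroculture import (run_simulation, SimulationConfig, filter_raster,
                          detect_bursts, effective_network)

raster = run_simulation(net, cfg=SimulationConfig(duration=300, seed=7))
events, ibis = detect_bursts(filter_raster(raster))
eff = effective_network(filter_raster(raster))
```

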