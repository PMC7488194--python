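"""Spontaneous spiking dynamics on structural networks.

Each neuron follows an adaptive quadratic integrate-and-fire model (Izhikevich
form) with membrane potential v (mV) and adaptation current u:

    tau_c dv/dt = k (v - v_r)(v - v_t) - u + I + eta
    tau_a du/dt = b (v - v_r) - u
    if v >= v_p:  v <- v_c,  u <- u + d_0

Synapses depress: each presynaptic neuron carries a resource variable D that
recovers as dD/dt = (1 - D)/tau_D and is scaled by beta < 1 at every spike of
that neuron.  A spike of neuron i instantaneously depolarizes every target j
by g_ampa * D_i (impulse synapses: the synaptic time constant, ~1 ms, is far
below every analysis bin used downstream).  Background drive comes from
miniature synaptic events ("minis"): every synapse releases independently as a
Poisson process, so neuron j receives minis at rate mini_rate * k_in(j), each
depolarizing by g_minis.  eta is an optional white-noise current.

Defaults follow the regular-spiking cortical parameterization of the
Izhikevich model; the operative calibration contract is that the default
network (empty 2 mm substrate) fires at 0.1-0.5 Hz per neuron with network
bursts recruiting >= 25% of the neurons.

Numerics: v and u advance by explicit Euler at dt = 0.1 ms; D, being linear
and decoupled from v, advances by its exact exponential propagator, so that
between spikes D(t) = 1 - (1 - D_0) exp(-t / tau_D) holds to machine
precision.  The whole update runs in a numba kernel; a given (network, params,
seed) triple reproduces its raster bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit
from scipy import sparse

from .errors import NumericalError
from .growth import StructuralNetwork

__all__ = [
    "SomaParams",
    "SynapseParams",
    "SimulationConfig",
    "SpikeRaster",
    "step",
    "run_simulation",
]


@dataclass(frozen=True)
class SomaParams:
    """Adaptive QIF soma parameters (voltages in mV, times in ms)."""

    tau_c: float = 100.0     # fast membrane time constant
    tau_a: float = 33.33     # adaptation time constant
    k: float = 0.7           # curvature coefficient
    v_r: float = -60.0       # rest
    v_t: float = -40.0       # threshold
    v_p: float = 35.0        # spike peak
    v_c: float = -50.0       # reset
    b: float = -2.0          # adaptation coupling
    d_0: float = 100.0       # adaptation increment per spike

    def __post_init__(self) -> None:
        if not (self.v_r < self.v_t < self.v_p):
            raise ValueError("require v_r < v_t < v_p")
        if self.v_c >= self.v_p:
            raise ValueError("require v_c < v_p")
        if self.tau_c <= 0 or self.tau_a <= 0:
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class SynapseParams:
    """Depressing impulse synapses plus background minis.

    ``g_ampa`` and ``g_minis`` are expressed directly as the membrane
    depolarization (mV) caused by one event at full resource (D = 1).
    ``mini_rate`` is in Hz; with ``mini_basis="synapse"`` (default) the
    per-neuron rate is mini_rate * k_in, while ``mini_basis="neuron"`` gives
    every neuron with at least one input synapse minis at the same rate
    (degree-independent drive; a sensitivity mode).
    ``noise_sd`` is the white-noise amplitude in mV/sqrt(ms) (0 disables the
    noise term).
    """

    tau_d: float = 2.0        # vesicle recovery time, s
    beta: float = 0.8         # depression factor per spike
    g_ampa: float = 9.5
    g_minis: float = 9.5
    mini_rate: float = 0.025  # Hz per synapse
    mini_basis: str = "synapse"
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.beta < 1.0):
            raise ValueError("beta must lie in (0, 1)")
        if self.tau_d <= 0:
            raise ValueError("tau_d must be positive")
        if self.mini_basis not in ("neuron", "synapse"):
            raise ValueError("mini_basis must be 'neuron' or 'synapse'")


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 0.1           # ms
    duration: float = 1800.0  # s
    seed: int = 0
    external_current: float = 0.0  # constant injected current (for single-neuron studies)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")


@dataclass
class SpikeRaster:
    """Ordered spike events (times in seconds)."""

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def per_neuron_rate(self) -> np.ndarray:
        counts = np.bincount(self.neuron_ids, minlength=self.n_neurons)
        return counts / self.duration if self.duration > 0 else counts * 0.0

    def spike_trains(self) -> list[np.ndarray]:
        order = np.argsort(self.neuron_ids, kind="stable")
        ids = self.neuron_ids[order]
        ts = self.times[order]
        bounds = np.searchsorted(ids, np.arange(self.n_neurons + 1))
        return [np.sort(ts[bounds[i]:bounds[i + 1]]) for i in range(self.n_neurons)]


def step(v, u, d, soma: SomaParams, syn: SynapseParams, dt: float,
         i_ext=0.0, eta=0.0):
    """One update of the soma/synapse state (reference implementation).

    Advances v, u by explicit Euler and D by its exact propagator, then
    applies threshold/reset.  Returns (v, u, d, fired).  Spike *delivery*
    (g_ampa * D increments to targets) is the caller's concern; this helper
    exists for single-neuron analysis and testing.
    """
    v = np.asarray(v, float)
    u = np.asarray(u, float)
    d = np.asarray(d, float)
    dv = (soma.k * (v - soma.v_r) * (v - soma.v_t) - u + i_ext + eta) / soma.tau_c
    du = (soma.b * (v - soma.v_r) - u) / soma.tau_a
    v = v + dt * dv
    u = u + dt * du
    d = 1.0 - (1.0 - d) * math.exp(-dt / (syn.tau_d * 1000.0))
    fired = v >= soma.v_p
    v = np.where(fired, soma.v_c, v)
    u = np.where(fired, u + soma.d_0, u)
    if not np.all(np.isfinite(v)):
        raise NumericalError("non-finite membrane potential")
    return v, u, d, fired


@njit(cache=True)
def _run_kernel(indptr, indices, mini_rate_ms, n_steps, dt,
                tau_c, tau_a, k, v_r, v_t, v_p, v_c, b, d_0,
                exp_dt_tau_d, beta, g_ampa, g_minis, noise_sd, i_ext,
                seed, out_ids, out_steps):
    np.random.seed(seed)
    n = len(indptr) - 1
    v = np.full(n, v_r)
    u = np.zeros(n)
    d = np.ones(n)
    next_mini = np.empty(n)
    for i in range(n):
        if mini_rate_ms[i] > 0.0:
            next_mini[i] = -math.log(np.random.random()) / mini_rate_ms[i]
        else:
            next_mini[i] = 1e300
    cap = len(out_ids)
    n_spk = 0
    noisy = noise_sd > 0.0
    sq = noise_sd * math.sqrt(dt)
    for s in range(n_steps):
        t = s * dt
        # miniature events
        for i in range(n):
            while next_mini[i] <= t:
                v[i] += g_minis
                next_mini[i] += -math.log(np.random.random()) / mini_rate_ms[i]
        # integrate
        for i in range(n):
            vi = v[i]
            if noisy:
                vi += sq * np.random.normal()
            dv = (k * (vi - v_r) * (vi - v_t) - u[i] + i_ext) / tau_c
            u[i] += dt * (b * (vi - v_r) - u[i]) / tau_a
            v[i] = vi + dt * dv
            d[i] = 1.0 - (1.0 - d[i]) * exp_dt_tau_d
        # threshold, reset, synaptic delivery
        for i in range(n):
            if v[i] >= v_p:
                if n_spk >= cap:
                    return n_spk, 2
                out_ids[n_spk] = i
                out_steps[n_spk] = s
                n_spk += 1
                v[i] = v_c
                u[i] += d_0
                gd = g_ampa * d[i]
                for jj in range(indptr[i], indptr[i + 1]):
                    v[indices[jj]] += gd
                d[i] *= beta
        if not math.isfinite(v[0]):
            return n_spk, 1
    # final sanity scan
    for i in range(n):
        if not math.isfinite(v[i]):
            return n_spk, 1
    return n_spk, 0


def run_simulation(
    net: StructuralNetwork | sparse.spmatrix | np.ndarray,
    soma: SomaParams | None = None,
    syn: SynapseParams | None = None,
    cfg: SimulationConfig | None = None,
) -> SpikeRaster:
    """Simulate spontaneous activity of a structural network.

    ``net`` may be a :class:`StructuralNetwork` or a directed adjacency with
    ``A[i, j] = 1`` meaning i -> j.  Deterministic given (network, params,
    seed).
    """
    soma = soma or SomaParams()
    syn = syn or SynapseParams()
    cfg = cfg or SimulationConfig()
    adj = net.adjacency if isinstance(net, StructuralNetwork) else net
    adj = sparse.csr_matrix(adj)
    n = adj.shape[0]
    k_in = np.asarray(adj.sum(axis=0)).ravel()
    n_steps = int(round(cfg.duration * 1000.0 / cfg.dt))
    if syn.mini_basis == "neuron":
        # any neuron with input synapses receives background minis
        mini_rate_ms = syn.mini_rate * (k_in > 0) / 1000.0
    else:
        mini_rate_ms = syn.mini_rate * k_in / 1000.0
    cap = max(1_000_000, int(n * cfg.duration * 5))
    while True:
        out_ids = np.empty(cap, np.int32)
        out_steps = np.empty(cap, np.int64)
        n_spk, status = _run_kernel(
            adj.indptr, adj.indices, mini_rate_ms, n_steps, cfg.dt,
            soma.tau_c, soma.tau_a, soma.k, soma.v_r, soma.v_t, soma.v_p,
            soma.v_c, soma.b, soma.d_0,
            math.exp(-cfg.dt / (syn.tau_d * 1000.0)), syn.beta,
            syn.g_ampa, syn.g_minis, syn.noise_sd, cfg.external_current,
            cfg.seed % (2**32), out_ids, out_steps)
        if status == 1:
            raise NumericalError(
                f"non-finite state at spike {n_spk}; params={asdict(soma)}")
        if status == 0:
            break
        cap *= 4  # spike buffer overflow: retry bigger (identical stream)
    times = out_steps[:n_spk] * (cfg.dt / 1000.0)
    return SpikeRaster(
        neuron_ids=out_ids[:n_spk].astype(np.int64), times=times,
        n_neurons=n, duration=cfg.duration, seed=cfg.seed,
        meta={"soma": asdict(soma), "synapse": asdict(syn), "dt_ms": cfg.dt},
    )
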