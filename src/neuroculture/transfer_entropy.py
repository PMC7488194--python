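"""Effective connectivity by generalized transfer entropy.

Spike rasters are binned (50 ms default) into binary occupancy sequences.
For a source Y and target X the transfer entropy (bits) is the plug-in
estimate of

    TE(Y -> X) = sum p(x_{n+1}, xw_n, yw_n)
                 log2 [ p(x_{n+1} | xw_n, yw_n) / p(x_{n+1} | xw_n) ]

with Markov order k_M = 2: xw_n = (x_n, ..., x_{n-k_M+1}).  With
*instantaneous feedback* (the generalized-TE convention for data whose
synaptic interactions are much faster than a bin) the source word is shifted
to include the same bin as the target sample: yw_n = (y_{n+1}, ..., y_{n-k_M+2}).

Significance of an ordered pair (Y -> X) is a z-score of its TE against the
empirical pool of all scores sharing the source's row or the target's column
(all outputs of Y and all inputs to X, self-pairs excluded); edges with
z >= 2 (default) form the binary effective adjacency E.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import sparse

from .dynamics import SpikeRaster
from .errors import EstimationError

__all__ = [
    "TEConfig",
    "BinnedRaster",
    "EffectiveNetwork",
    "bin_raster",
    "transfer_entropy",
    "te_matrix",
    "significance",
    "effective_network",
]


@dataclass(frozen=True)
class TEConfig:
    bin_width: float = 0.050          # s
    markov_order: int = 2
    z_threshold: float = 2.0
    instantaneous_feedback: bool = True

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if self.markov_order < 1:
            raise ValueError("markov order must be >= 1")
        if self.z_threshold <= 0:
            raise ValueError("z threshold must be positive")


@dataclass(frozen=True)
class BinnedRaster:
    """Binary occupancy sequences, one row per neuron."""

    data: np.ndarray          # (N, n_bins) uint8
    bin_width: float

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]


@dataclass
class EffectiveNetwork:
    scores: np.ndarray                 # TE matrix, scores[i, j] = TE(i -> j)
    z: np.ndarray
    adjacency: sparse.csr_matrix       # binary, e[i, j] = 1 iff z >= threshold
    config: TEConfig

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)


def bin_raster(raster: SpikeRaster, cfg: TEConfig | None = None) -> BinnedRaster:
    """Half-open bins [t, t + width); 1 = at least one spike in the bin."""
    cfg = cfg or TEConfig()
    n_bins = max(1, int(np.ceil(raster.duration / cfg.bin_width - 1e-9)))
    data = np.zeros((raster.n_neurons, n_bins), np.uint8)
    if raster.n_spikes:
        b = np.minimum((raster.times / cfg.bin_width).astype(int), n_bins - 1)
        data[raster.neuron_ids, b] = 1
    return BinnedRaster(data=data, bin_width=cfg.bin_width)


def _codes(data: np.ndarray, k: int, instantaneous: bool):
    """Per-neuron word codes for every admissible sample index.

    Sample m corresponds to target index n+1 with n = k - 1 + m.
    cx in [0, 2^(k+1)): target bit (high) + x-word; cy in [0, 2^k): y-word.
    """
    n_bins = data.shape[1]
    m = n_bins - k  # samples: n from k-1 .. n_bins-2
    if m < 1:
        raise EstimationError("sequence too short for the requested Markov order")
    x = data.astype(np.int64)
    cx = x[:, k:] << k                       # target bit x_{n+1}
    cy_shift = 1 if instantaneous else 0
    cy = np.zeros_like(cx)
    for j in range(k):                       # words, most recent bin = high bit
        cx += x[:, k - 1 - j:n_bins - 1 - j] << (k - 1 - j)
        lo = k - 1 - j + cy_shift
        cy += x[:, lo:lo + m] << (k - 1 - j)
    return cx.astype(np.uint8), cy.astype(np.uint8)


@njit(cache=True)
def _te_from_codes(cx, cy, k):
    """TE (bits) for one ordered pair from combined code sequences."""
    n_states_x = 1 << (k + 1)
    n_states_y = 1 << k
    table = np.zeros((n_states_x, n_states_y))
    m = len(cx)
    for t in range(m):
        table[cx[t], cy[t]] += 1.0
    # marginals
    te = 0.0
    for xw in range(n_states_y):            # x-word without target bit
        c_xw = 0.0
        c_x1_xw = np.zeros(2)
        for tb in range(2):
            code = (tb << k) + xw
            for yw in range(n_states_y):
                c_x1_xw[tb] += table[code, yw]
            c_xw += c_x1_xw[tb]
        if c_xw == 0.0:
            continue
        for yw in range(n_states_y):
            c_xw_yw = table[xw, yw] + table[(1 << k) + xw, yw]
            if c_xw_yw == 0.0:
                continue
            for tb in range(2):
                c = table[(tb << k) + xw, yw]
                if c == 0.0 or c_x1_xw[tb] == 0.0:
                    continue
                te += (c / m) * np.log2((c * c_xw) / (c_xw_yw * c_x1_xw[tb]))
    return te


@njit(cache=True)
def _te_matrix_kernel(cx_all, cy_all, k):
    n = cx_all.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            out[i, j] = _te_from_codes(cx_all[j], cy_all[i], k)
    return out


def transfer_entropy(x, y, cfg: TEConfig | None = None) -> float:
    """TE(Y -> X) in bits for two binary sequences (influence of y on x)."""
    cfg = cfg or TEConfig()
    x = np.ascontiguousarray(np.asarray(x, np.uint8).reshape(1, -1))
    y = np.ascontiguousarray(np.asarray(y, np.uint8).reshape(1, -1))
    if x.shape != y.shape:
        raise EstimationError("sequences must have equal length")
    if x.shape[1] <= cfg.markov_order + 1:
        raise EstimationError("sequence too short for the requested Markov order")
    data = np.vstack([x, y])
    cx, cy = _codes(data, cfg.markov_order, cfg.instantaneous_feedback)
    return float(_te_from_codes(cx[0], cy[1], cfg.markov_order))


def te_matrix(binned: BinnedRaster, cfg: TEConfig | None = None) -> np.ndarray:
    """All-pairs TE scores; scores[i, j] = TE(i -> j)."""
    cfg = cfg or TEConfig()
    cx, cy = _codes(binned.data, cfg.markov_order, cfg.instantaneous_feedback)
    return _te_matrix_kernel(np.ascontiguousarray(cx),
                             np.ascontiguousarray(cy), cfg.markov_order)


def significance(scores: np.ndarray, cfg: TEConfig | None = None):
    """z-scores against the row-union-column pool, and the binarized network.

    For pair (i -> j) the null population is every score with source i or
    target j (diagonal excluded; the pair's own score is a member of the
    pool).  The pool's *population* standard deviation is used.  Pairs whose
    pool has zero variance get z = 0 (with a warning): their edge state is
    undefined and conservatively set to absent.
    """
    cfg = cfg or TEConfig()
    s = np.asarray(scores, float)
    n = s.shape[0]
    mask = ~np.eye(n, dtype=bool)
    row_sum = (s * mask).sum(axis=1)
    col_sum = (s * mask).sum(axis=0)
    row_sq = (s**2 * mask).sum(axis=1)
    col_sq = (s**2 * mask).sum(axis=0)
    m = 2 * (n - 1) - 1  # pool size: row + column, own score counted once
    pool_sum = row_sum[:, None] + col_sum[None, :] - s
    pool_sq = row_sq[:, None] + col_sq[None, :] - s**2
    mean = pool_sum / m
    var = pool_sq / m - mean**2
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    zero = sd <= 0
    if np.any(zero & mask):
        warnings.warn("zero-variance null pool for some pairs; edges set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(zero, 0.0, (s - mean) / sd)
    np.fill_diagonal(z, 0.0)
    adj = sparse.csr_matrix((z >= cfg.z_threshold).astype(np.int8))
    return z, adj


def effective_network(raster: SpikeRaster, cfg: TEConfig | None = None) -> EffectiveNetwork:
    """Full pipeline: bin -> all-pairs TE -> z-significance -> binary E."""
    cfg = cfg or TEConfig()
    binned = bin_raster(raster, cfg)
    scores = te_matrix(binned, cfg)
    z, adj = significance(scores, cfg)
    return EffectiveNetwork(scores=scores, z=z, adjacency=adj, config=cfg)
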