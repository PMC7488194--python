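"""Network-burst detection, inter-burst intervals, initiation points and
spatiotemporal propagation maps.

A network burst is a coordinated activation recruiting at least a fraction
(default 25%) of the neurons within a short window (default 0.5 s).  Rasters
are first *filtered*: only spikes that fall inside some above-threshold
window survive, which removes sporadic activity before effective-connectivity
inference.  Windows slide with a stride much smaller than their width so that
bursts are not split at window boundaries.

The initiation point of a burst is estimated by fitting the participants'
first-spike times to a circular wave, t(x, y) = t0 + |(x, y) - origin| / c,
and taking the cone apex as the spatial origin; fits whose apex falls outside
the substrate disc are flagged invalid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dynamics import SpikeRaster

__all__ = [
    "BurstConfig",
    "BurstEvent",
    "InitiationPoint",
    "PatternGrid",
    "filter_raster",
    "detect_bursts",
    "fit_initiation",
    "spatiotemporal_map",
]


@dataclass(frozen=True)
class BurstConfig:
    window: float = 0.5                 # s
    stride: float = 0.1                 # s, window sliding step
    participation_threshold: float = 0.25
    grid_size: int = 25
    min_participants_for_fit: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.participation_threshold <= 1.0):
            raise ValueError("participation threshold must lie in (0, 1]")
        if self.window <= 0 or self.stride <= 0:
            raise ValueError("window and stride must be positive")


@dataclass(frozen=True)
class BurstEvent:
    start_time: float
    end_time: float
    participants: np.ndarray          # neuron ids
    first_spike_times: np.ndarray     # aligned with participants

    @property
    def n_participants(self) -> int:
        return len(self.participants)


@dataclass(frozen=True)
class InitiationPoint:
    origin: tuple[float, float]
    t0: float
    speed: float                      # mm/s
    fit_residual: float               # RMS residual, s
    valid: bool


@dataclass(frozen=True)
class PatternGrid:
    """grid_size x grid_size map of mean burst-relative first-spike times (s);
    NaN where no participant mapped.  Row 0 is the bottom row (+y upward)."""

    values: np.ndarray
    smoothed: np.ndarray

    @property
    def propagation_time(self) -> float:
        v = self.values[np.isfinite(self.values)]
        return float(v.max() - v.min()) if len(v) else 0.0


def _window_counts(raster: SpikeRaster, cfg: BurstConfig):
    """Distinct-neuron count per sliding window [k*stride, k*stride + window)."""
    n_win = max(1, int(np.ceil(max(raster.duration - cfg.window, 0.0) / cfg.stride)) + 1)
    starts = np.arange(n_win) * cfg.stride
    order = np.argsort(raster.times, kind="stable")
    t = raster.times[order]
    ids = raster.neuron_ids[order]
    counts = np.zeros(n_win, int)
    for k, s in enumerate(starts):
        lo, hi = np.searchsorted(t, [s, s + cfg.window])
        if hi > lo:
            counts[k] = len(np.unique(ids[lo:hi]))
    return starts, counts, t, ids


def filter_raster(raster: SpikeRaster, cfg: BurstConfig | None = None) -> SpikeRaster:
    """Keep exactly the spikes lying in some window whose distinct-neuron
    count reaches the participation threshold.  Idempotent."""
    cfg = cfg or BurstConfig()
    if raster.n_spikes == 0:
        return raster
    starts, counts, t, ids = _window_counts(raster, cfg)
    need = cfg.participation_threshold * raster.n_neurons
    keep = np.zeros(len(t), bool)
    for k in np.flatnonzero(counts >= need):
        lo, hi = np.searchsorted(t, [starts[k], starts[k] + cfg.window])
        keep[lo:hi] = True
    return SpikeRaster(neuron_ids=ids[keep], times=t[keep],
                       n_neurons=raster.n_neurons, duration=raster.duration,
                       seed=raster.seed, meta=dict(raster.meta, filtered=True))


def detect_bursts(
    raster: SpikeRaster, cfg: BurstConfig | None = None,
) -> tuple[list[BurstEvent], np.ndarray]:
    """Detect maximal coordinated episodes and the inter-burst intervals.

    Consecutive above-threshold windows whose spans overlap are merged into
    one burst; the burst start is its earliest spike, and the IBI sequence is
    the difference between consecutive burst starts.  The input may be raw or
    already filtered (filtering is idempotent).
    """
    cfg = cfg or BurstConfig()
    if raster.n_spikes == 0:
        return [], np.empty(0)
    starts, counts, t, ids = _window_counts(raster, cfg)
    need = cfg.participation_threshold * raster.n_neurons
    above = np.flatnonzero(counts >= need)
    if len(above) == 0:
        warnings.warn("fewer than two bursts: no inter-burst intervals")
        return [], np.empty(0)
    # merge windows that overlap in time
    groups: list[tuple[float, float]] = []
    lo = hi = None
    for k in above:
        s, e = starts[k], starts[k] + cfg.window
        if lo is None:
            lo, hi = s, e
        elif s <= hi:
            hi = max(hi, e)
        else:
            groups.append((lo, hi))
            lo, hi = s, e
    groups.append((lo, hi))
    events = []
    for s, e in groups:
        a, b = np.searchsorted(t, [s, e])
        seg_ids = ids[a:b]
        seg_t = t[a:b]
        part, first_idx = np.unique(seg_ids, return_index=True)
        first_t = np.empty(len(part))
        for j, p in enumerate(part):
            first_t[j] = seg_t[seg_ids == p].min()
        events.append(BurstEvent(start_time=float(seg_t.min()),
                                 end_time=float(seg_t.max()),
                                 participants=part, first_spike_times=first_t))
    if len(events) < 2:
        warnings.warn("fewer than two bursts: no inter-burst intervals")
        ibis = np.empty(0)
    else:
        st = np.array([ev.start_time for ev in events])
        ibis = np.diff(st)
    return events, ibis


def fit_initiation(
    burst: BurstEvent,
    positions: np.ndarray,
    disc_radius: float,
    cfg: BurstConfig | None = None,
) -> InitiationPoint:
    """Least-squares fit of first-spike times to a space-time cone.

    Model: t_i = t0 + |p_i - origin| / c, fitted over the burst participants
    with multi-start (3 x 3 grid of origins over the disc).  The fit is
    invalid when there are too few participants, the geometry is degenerate,
    or the apex lands outside the disc.
    """
    cfg = cfg or BurstConfig()
    p = positions[burst.participants]
    t = burst.first_spike_times - burst.first_spike_times.min()
    if len(p) < cfg.min_participants_for_fit:
        return InitiationPoint((np.nan, np.nan), np.nan, np.nan, np.nan, False)
    # collinear participants make the apex unidentifiable
    if len(p) >= 3:
        centered = p - p.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[-1] < 1e-9:
            return InitiationPoint((np.nan, np.nan), np.nan, np.nan, np.nan, False)

    span = max(t.max() - t.min(), 1e-6)
    s0 = span / max(disc_radius, 1e-9)  # initial slowness, s/mm

    def resid(theta):
        ox, oy, t0, s = theta
        return t0 + s * np.hypot(p[:, 0] - ox, p[:, 1] - oy) - t

    best = None
    g = disc_radius * 0.5
    for ox in (-g, 0.0, g):
        for oy in (-g, 0.0, g):
            sol = least_squares(resid, x0=[ox, oy, 0.0, s0],
                                bounds=([-np.inf, -np.inf, -np.inf, 0.0],
                                        np.inf), method="trf")
            if best is None or sol.cost < best.cost:
                best = sol
    ox, oy, t0, s = best.x
    rms = float(np.sqrt(2 * best.cost / len(p)))
    inside = np.hypot(ox, oy) <= disc_radius
    speed = 1.0 / s if s > 0 else np.inf
    return InitiationPoint((float(ox), float(oy)), float(t0), float(speed),
                           rms, bool(inside))


def spatiotemporal_map(
    burst: BurstEvent,
    positions: np.ndarray,
    disc_radius: float,
    cfg: BurstConfig | None = None,
) -> PatternGrid:
    """Map burst-relative first-spike times onto a grid over the substrate's
    bounding square and smooth with a Gaussian kernel of one-cell bandwidth.

    Smoothing only mixes populated cells (NaN-aware normalized convolution).
    """
    cfg = cfg or BurstConfig()
    n = cfg.grid_size
    R = disc_radius
    p = positions[burst.participants]
    rel = burst.first_spike_times - burst.first_spike_times.min()
    ix = np.clip(((p[:, 0] + R) / (2 * R) * n).astype(int), 0, n - 1)
    iy = np.clip(((p[:, 1] + R) / (2 * R) * n).astype(int), 0, n - 1)
    sums = np.zeros((n, n))
    cnts = np.zeros((n, n))
    np.add.at(sums, (iy, ix), rel)
    np.add.at(cnts, (iy, ix), 1)
    with np.errstate(invalid="ignore"):
        vals = np.where(cnts > 0, sums / cnts, np.nan)
    finite = np.isfinite(vals)
    if finite.any():
        vals = vals - np.nanmin(vals)  # burst-relative zero at the earliest cell
    # normalized Gaussian smoothing over populated cells
    ax = np.arange(-3, 4)
    kern = np.exp(-0.5 * (ax[:, None] ** 2 + ax[None, :] ** 2))
    filled = np.where(finite, vals, 0.0)
    w = finite.astype(float)
    num = _conv2(filled, kern)
    den = _conv2(w, kern)
    with np.errstate(invalid="ignore"):
        smoothed = np.where(den > 0, num / den, np.nan)
    return PatternGrid(values=vals, smoothed=smoothed)


def _conv2(a: np.ndarray, k: np.ndarray) -> np.ndarray:
    from scipy.signal import convolve2d

    return convolve2d(a, k, mode="same", boundary="fill", fillvalue=0.0)
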