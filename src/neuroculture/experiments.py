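"""Reproducible experiment drivers.

A :class:`RunConfig` fully determines an experiment: the substrate pattern,
growth/dynamics/analysis parameters, replicate counts and a master seed
(replicate r uses seed ``master_seed + r``).  The structural driver grows
replicate networks and aggregates the descriptors reported per configuration
(obstacle area fraction, degree statistics, connection distances, modularity,
global efficiency); the dynamic driver simulates activity on those networks
and aggregates burst statistics and effective-network measures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bursts as bursts_mod
from . import metrics as metrics_mod
from .dynamics import SimulationConfig, SomaParams, SpikeRaster, SynapseParams, run_simulation
from .growth import GrowthConfig, StructuralNetwork, connection_geometry, grow_network
from .io import config_hash, save_effective, save_network, save_raster
from .substrate import build_pattern
from .transfer_entropy import TEConfig, effective_network

__all__ = [
    "RunConfig",
    "ReplicateSet",
    "run_structural_experiment",
    "run_dynamic_experiment",
]

log = logging.getLogger("neuroculture")


@dataclass
class RunConfig:
    pattern: str = "empty"              # pattern kind or path to a mask PNG
    diameter: float = 2.0
    scale: int = 1
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    soma: SomaParams = field(default_factory=SomaParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    burst: bursts_mod.BurstConfig = field(default_factory=bursts_mod.BurstConfig)
    te: TEConfig = field(default_factory=TEConfig)
    n_structural_replicates: int = 12
    n_dynamic_replicates: int = 4
    master_seed: int = 0
    outdir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, sub in (("growth", GrowthConfig), ("soma", SomaParams),
                         ("synapse", SynapseParams), ("simulation", SimulationConfig),
                         ("burst", bursts_mod.BurstConfig), ("te", TEConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)


@dataclass
class ReplicateSet:
    seeds: list
    networks: list          # StructuralNetwork
    table: pd.DataFrame     # one row per replicate
    aggregate: pd.Series    # mean over replicates (sd columns suffixed _sd)


def _pattern(cfg: RunConfig):
    if cfg.pattern.endswith(".png") or cfg.pattern.endswith(".bmp"):
        from .substrate import RasterSubstrate, load_mask

        return RasterSubstrate(load_mask(cfg.pattern))
    return build_pattern(cfg.pattern, cfg.diameter, cfg.scale)


def structural_metrics_row(net: StructuralNetwork, seed: int,
                           area_frac: float, louvain_seed: int = 0) -> dict:
    geo = connection_geometry(net) if net.n_edges else None
    row = {
        "seed": seed,
        "n_neurons": net.n_neurons,
        "n_edges": net.n_edges,
        "area_fraction": area_frac,
        "k_in_mean": float(net.k_in.mean()),
        "k_in_sd": float(net.k_in.std()),
        "k_out_mean": float(net.k_out.mean()),
        "k_out_sd": float(net.k_out.std()),
        "distance_mean": float(geo.distances.mean()) if geo is not None else np.nan,
        "distance_sd": float(geo.distances.std()) if geo is not None else np.nan,
    }
    if net.n_edges:
        mod = metrics_mod.modularity(net.adjacency, seed=louvain_seed)
        row["q"] = mod.q
        row["n_communities"] = mod.n_communities
        row["g_eff"] = metrics_mod.global_efficiency(net.adjacency).g_eff
    else:
        row["q"] = np.nan
        row["n_communities"] = 0
        row["g_eff"] = 0.0
    return row


def run_structural_experiment(cfg: RunConfig) -> ReplicateSet:
    """Grow ``n_structural_replicates`` networks and tabulate their
    descriptors; deterministic given the master seed."""
    pattern = _pattern(cfg)
    area = pattern.area_fraction() if hasattr(pattern, "area_fraction") else np.nan
    seeds, nets, rows = [], [], []
    outdir = Path(cfg.outdir) if cfg.outdir else None
    for r in range(cfg.n_structural_replicates):
        seed = cfg.master_seed + r
        t0 = time.time()
        net = grow_network(pattern, cfg.growth, seed=seed)
        row = structural_metrics_row(net, seed, area, louvain_seed=seed)
        rows.append(row)
        seeds.append(seed)
        nets.append(net)
        log.info(json.dumps({"stage": "grow", "pattern": cfg.pattern, "seed": seed,
                             "n_edges": net.n_edges, "wall_s": round(time.time() - t0, 2),
                             "config_hash": config_hash(cfg.growth)}))
        if outdir:
            save_network(net, outdir / f"net_{seed}")
    table = pd.DataFrame(rows)
    num = table.drop(columns=["seed"])
    agg = num.mean()
    for c in ("k_in_mean", "k_out_mean", "distance_mean", "q", "g_eff"):
        agg[c + "_between_replicates_sd"] = num[c].std()
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "structural_table.tsv", sep="\t", index=False)
        agg.to_frame("value").to_csv(outdir / "structural_aggregate.tsv", sep="\t")
        _write_manifest(outdir, cfg, stage="structural")
    return ReplicateSet(seeds=seeds, networks=nets, table=table, aggregate=agg)


@dataclass
class DynamicResult:
    rasters: list
    burst_tables: pd.DataFrame
    ibis: dict               # seed -> np.ndarray of inter-burst intervals
    effective: list          # EffectiveNetwork per replicate
    initiation: pd.DataFrame  # cone-fit origins (cross/empty patterns by default)
    summary: pd.DataFrame    # one row per replicate: rate, n_bursts, mean IBI, eff Q, eff G


def run_dynamic_experiment(cfg: RunConfig, networks: list | None = None,
                           fit_initiation_points: bool | None = None) -> DynamicResult:
    """Simulate activity on structural replicates, detect bursts, and infer
    effective connectivity.  ``networks`` defaults to freshly grown replicates
    (``n_dynamic_replicates`` of them).

    Initiation-point cone fits assume quasi-circular wavefronts, which holds
    for the empty and cross configurations; by default they are computed only
    there (override with ``fit_initiation_points``).
    """
    if networks is None:
        pattern = _pattern(cfg)
        networks = [grow_network(pattern, cfg.growth, seed=cfg.master_seed + r)
                    for r in range(cfg.n_dynamic_replicates)]
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if fit_initiation_points is None:
        fit_initiation_points = cfg.pattern == "empty" or cfg.pattern.startswith("crosses")
    rasters, eff_nets, rows, burst_rows, init_rows = [], [], [], [], []
    ibis = {}
    for r, net in enumerate(networks[: cfg.n_dynamic_replicates]):
        seed = cfg.master_seed + r
        sim_cfg = dataclasses.replace(cfg.simulation, seed=seed)
        t0 = time.time()
        raster = run_simulation(net, cfg.soma, cfg.synapse, sim_cfg)
        filtered = bursts_mod.filter_raster(raster, cfg.burst)
        events, ibi = bursts_mod.detect_bursts(filtered, cfg.burst)
        eff = effective_network(filtered, cfg.te)
        rasters.append(raster)
        eff_nets.append(eff)
        ibis[seed] = ibi
        for b, ev in enumerate(events):
            burst_rows.append({"seed": seed, "burst_id": b, "start_s": ev.start_time,
                               "end_s": ev.end_time, "n_participants": ev.n_participants})
            if fit_initiation_points:
                ip = bursts_mod.fit_initiation(ev, net.positions, net.diameter / 2.0,
                                               cfg.burst)
                init_rows.append({"seed": seed, "burst_id": b, "x_mm": ip.origin[0],
                                  "y_mm": ip.origin[1], "residual_s": ip.fit_residual,
                                  "valid": ip.valid})
        row = {
            "seed": seed,
            "rate_hz": raster.n_spikes / raster.n_neurons / max(raster.duration, 1e-9),
            "n_bursts": len(events),
            "ibi_mean_s": float(ibi.mean()) if len(ibi) else np.nan,
            "eff_n_edges": eff.n_edges,
        }
        if eff.n_edges:
            row["eff_q"] = metrics_mod.modularity(eff.adjacency, seed=seed).q
            row["eff_g_eff"] = metrics_mod.global_efficiency(eff.adjacency).g_eff
        else:
            row["eff_q"] = np.nan
            row["eff_g_eff"] = 0.0
        rows.append(row)
        log.info(json.dumps({"stage": "dynamics", "pattern": cfg.pattern, "seed": seed,
                             "n_spikes": raster.n_spikes, "n_bursts": len(events),
                             "wall_s": round(time.time() - t0, 2)}))
        if outdir:
            save_raster(raster, outdir / f"raster_{seed}.tsv")
            save_effective(eff, outdir / f"effective_{seed}")
    summary = pd.DataFrame(rows)
    bursts_df = pd.DataFrame(burst_rows)
    init_df = pd.DataFrame(init_rows)
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "dynamic_summary.tsv", sep="\t", index=False)
        bursts_df.to_csv(outdir / "burst_table.tsv", sep="\t", index=False)
        if fit_initiation_points:
            init_df.to_csv(outdir / "initiation_points.tsv", sep="\t", index=False)
        _write_manifest(outdir, cfg, stage="dynamic")
    return DynamicResult(rasters=rasters, burst_tables=bursts_df, ibis=ibis,
                         effective=eff_nets, initiation=init_df, summary=summary)


def _write_manifest(outdir: Path, cfg: RunConfig, stage: str) -> None:
    manifest = {
        "stage": stage,
        "config": dataclasses.asdict(cfg),
        "config_hash": config_hash(cfg),
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2, default=str))
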