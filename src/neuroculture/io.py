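"""File formats: TSV/GraphML for networks, TSV event tables for rasters.

Every artifact carries a JSON sidecar (or meta file) with the originating
configuration and seed, so any stage can be re-run from stored inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .dynamics import SpikeRaster
from .growth import GrowthConfig, StructuralNetwork

__all__ = [
    "config_hash",
    "save_network",
    "load_network",
    "save_raster",
    "load_raster",
    "save_effective",
]


def config_hash(obj) -> str:
    """Stable short hash of a (dataclass or dict) configuration."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def save_network(net: StructuralNetwork, outdir: str | Path,
                 with_axons: bool = False) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "id": np.arange(net.n_neurons),
        "x_mm": net.positions[:, 0],
        "y_mm": net.positions[:, 1],
        "dendrite_radius_mm": net.dendrite_radii,
    }).to_csv(outdir / "neurons.tsv", sep="\t", index=False)
    e = net.edges()
    pd.DataFrame({"pre_id": e[:, 0], "post_id": e[:, 1]}).to_csv(
        outdir / "edges.tsv", sep="\t", index=False)
    if with_axons:
        rows = []
        for i, axon in enumerate(net.axons):
            for j, (x, y) in enumerate(axon):
                rows.append((i, j, x, y))
        pd.DataFrame(rows, columns=["neuron_id", "vertex", "x_mm", "y_mm"]).to_csv(
            outdir / "axons.tsv", sep="\t", index=False)
    g = nx.DiGraph()
    for i in range(net.n_neurons):
        g.add_node(int(i), x=float(net.positions[i, 0]), y=float(net.positions[i, 1]),
                   dendrite_radius=float(net.dendrite_radii[i]))
    g.add_edges_from((int(a), int(b)) for a, b in e)
    nx.write_graphml(g, outdir / "network.graphml")
    meta = {
        "pattern_kind": net.pattern_kind,
        "diameter_mm": net.diameter,
        "seed": net.seed,
        "n_neurons": net.n_neurons,
        "n_edges": net.n_edges,
        "growth_config": dataclasses.asdict(net.config),
        "config_hash": config_hash(net.config),
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
    return outdir


def load_network(indir: str | Path) -> StructuralNetwork:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    neurons = pd.read_csv(indir / "neurons.tsv", sep="\t")
    edges = pd.read_csv(indir / "edges.tsv", sep="\t")
    n = len(neurons)
    adj = sparse.coo_matrix(
        (np.ones(len(edges), np.int8), (edges["pre_id"], edges["post_id"])),
        shape=(n, n)).tocsr()
    axons: list[np.ndarray] = [np.empty((0, 2))] * n
    ax_path = indir / "axons.tsv"
    if ax_path.exists():
        ax = pd.read_csv(ax_path, sep="\t")
        axons = [g[["x_mm", "y_mm"]].to_numpy()
                 for _, g in ax.groupby("neuron_id", sort=True)]
    return StructuralNetwork(
        positions=neurons[["x_mm", "y_mm"]].to_numpy(),
        dendrite_radii=neurons["dendrite_radius_mm"].to_numpy(),
        axons=axons,
        axon_lengths=np.array([
            float(np.linalg.norm(np.diff(a, axis=0), axis=1).sum()) if len(a) > 1 else 0.0
            for a in axons]),
        adjacency=adj,
        config=GrowthConfig(**meta["growth_config"]),
        pattern_kind=meta["pattern_kind"],
        diameter=meta["diameter_mm"],
        seed=meta["seed"],
    )


def save_raster(raster: SpikeRaster, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"neuron_id": raster.neuron_ids, "time_s": raster.times}).to_csv(
        path, sep="\t", index=False)
    header = {
        "n_neurons": raster.n_neurons,
        "duration_s": raster.duration,
        "seed": raster.seed,
        "params_hash": config_hash(raster.meta),
        "meta": raster.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=2))
    return path


def load_raster(path: str | Path) -> SpikeRaster:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path, sep="\t")
    return SpikeRaster(
        neuron_ids=df["neuron_id"].to_numpy(np.int64),
        times=df["time_s"].to_numpy(float),
        n_neurons=int(header["n_neurons"]),
        duration=float(header["duration_s"]),
        seed=header.get("seed"),
        meta=header.get("meta", {}),
    )


def save_effective(eff, outdir: str | Path) -> Path:
    """Write an EffectiveNetwork: edge list TSV, GraphML, score/z CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coo = eff.adjacency.tocoo()
    pd.DataFrame({"pre_id": coo.row, "post_id": coo.col}).to_csv(
        outdir / "effective_edges.tsv", sep="\t", index=False)
    np.savetxt(outdir / "te_scores.csv", eff.scores, delimiter=",")
    np.savetxt(outdir / "z_scores.csv", eff.z, delimiter=",")
    g = nx.DiGraph()
    g.add_nodes_from(range(eff.adjacency.shape[0]))
    g.add_edges_from(zip(coo.row.tolist(), coo.col.tolist()))
    nx.write_graphml(g, outdir / "effective.graphml")
    (outdir / "te_meta.json").write_text(json.dumps(
        {"config": dataclasses.asdict(eff.config),
         "config_hash": config_hash(eff.config)}, indent=2))
    return outdir
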