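"""Configuration parsing, seed management, and file readers/writers.

Configs are YAML with a strict schema: unknown keys are rejected so a typo
in a sweep axis cannot silently fall back to a default.  Every output
directory receives a JSON run manifest (config echo, master and
per-replicate seeds, realized network metadata, package version) sufficient
to reproduce its contents bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import SimulationConfig, replicate_seed_sequence
from .experiments import SweepGrid
from .networks import InteractionNetwork, PointSet, network_metrics
from .stats import AggregatedSeries, StatSeries

logger = logging.getLogger(__name__)

__all__ = [
    "RunManifest",
    "load_config",
    "dump_config",
    "read_points_csv",
    "write_points_csv",
    "write_network",
    "read_edgelist_csv",
    "write_series",
    "write_aggregated",
    "write_sweep",
    "write_manifest",
]

_CONFIG_KEYS = {
    "N": int,
    "S": int,
    "m": float,
    "mu": float,
    "T": int,
    "A0": int,
    "R": int,
    "seed": int,
    "stat_interval": int,
    "network": dict,
    "axes": dict,
}
_REQUIRED_KEYS = {"N", "S", "T"}
_NETWORK_KEYS = {"builder", "k", "p_rewire", "seed", "points_csv", "n", "island"}
_AXIS_KEYS = {"k", "S", "m"}


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically."""

    config: dict
    master_seed: int
    replicate_seeds: list
    network: dict
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )


def load_config(path) -> tuple[SimulationConfig, Optional[dict]]:
    """Load and validate a YAML config; returns the resolved
    :class:`SimulationConfig` and the optional sweep ``axes`` spec.

    Unknown keys, wrong types and out-of-range values are rejected with a
    message naming the offending key.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    missing = _REQUIRED_KEYS - set(raw)
    if missing:
        raise ValueError(f"{path}: missing required key(s): {sorted(missing)}")
    for key, typ in _CONFIG_KEYS.items():
        if key in raw and raw[key] is not None:
            try:
                raw[key] = typ(raw[key])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: key {key!r} must be of type {typ.__name__}"
                ) from None
    network = raw.get("network")
    if network is not None:
        bad = set(network) - _NETWORK_KEYS
        if bad:
            raise ValueError(f"{path}: unknown network key(s): {sorted(bad)}")
    axes = raw.pop("axes", None)
    if axes is not None:
        bad = set(axes) - _AXIS_KEYS
        if bad:
            raise ValueError(f"{path}: unknown sweep axis key(s): {sorted(bad)}")
        axes = {k: [float(v) if k == "m" else int(v) for v in vs]
                for k, vs in axes.items()}
    try:
        cfg = SimulationConfig(**raw)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
    return cfg, axes


def dump_config(cfg: SimulationConfig, path, axes: Optional[dict] = None) -> None:
    """Write the fully resolved config (every default made explicit)."""
    data = asdict(cfg)
    if axes is not None:
        data["axes"] = {k: list(map(float, v)) for k, v in axes.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Points


def read_points_csv(path) -> PointSet:
    """Read a `id,x,y` CSV of planar coordinates (meters)."""
    df = pd.read_csv(path)
    missing = {"id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {sorted(missing)}; header must be id,x,y"
        )
    if df["id"].duplicated().any():
        dupes = df["id"][df["id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate point id(s): {dupes}")
    bad = df.index[~np.isfinite(df["x"]) | ~np.isfinite(df["y"])]
    if len(bad):
        # +2: header line and 1-based numbering
        raise ValueError(f"{path}: non-finite coordinate at line {bad[0] + 2}")
    return PointSet(
        ids=tuple(df["id"]),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
    )


def write_points_csv(points: PointSet, path) -> None:
    pd.DataFrame({"id": points.ids, "x": points.x, "y": points.y}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Networks


def write_network(net: InteractionNetwork, out_dir, stem: str = "network") -> dict:
    """Write edge-list CSV, GraphML, and a JSON metadata sidecar; returns
    the metadata dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges = sorted(net.edges)
    pd.DataFrame(edges, columns=["source", "target"]).to_csv(
        out_dir / f"{stem}_edges.csv", index=False
    )
    nx.write_graphml(net.to_networkx(), out_dir / f"{stem}.graphml")
    metrics = network_metrics(net)
    meta = {
        "builder": net.builder,
        "params": net.params,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "mean_degree": metrics.mean_degree,
        "degrees": metrics.realized_k_per_node.tolist(),
        "characteristic_path_length": (
            None
            if np.isnan(metrics.characteristic_path_length)
            else metrics.characteristic_path_length
        ),
        "n_components": metrics.n_components,
    }
    (out_dir / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))
    return meta


def read_edgelist_csv(path, n_nodes: Optional[int] = None) -> InteractionNetwork:
    df = pd.read_csv(path)
    if not {"source", "target"} <= set(df.columns):
        raise ValueError(f"{path}: edge list needs source,target columns")
    edges = frozenset(
        tuple(sorted((int(a), int(b))))
        for a, b in zip(df["source"], df["target"])
    )
    if n_nodes is None:
        n_nodes = 1 + max((max(e) for e in edges), default=-1)
    return InteractionNetwork(n_nodes=n_nodes, edges=edges, builder="custom")


# ---------------------------------------------------------------------------
# Series / sweeps / manifests


def write_series(series: list[StatSeries], out_dir, stem: str = "replicates") -> None:
    """Long-format CSV `replicate,timestep,statistic,value` plus a JSON
    header (config echo, seeds, network metadata)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = [s.to_frame(replicate=i) for i, s in enumerate(series)]
    pd.concat(frames, ignore_index=True).to_csv(
        out_dir / f"{stem}.csv", index=False
    )
    header = {
        "replicate_seeds": [str(s.replicate_seed) for s in series],
        "config": asdict(series[0].config) if series[0].config else None,
        "network": series[0].network_params,
    }
    (out_dir / f"{stem}_header.json").write_text(json.dumps(header, indent=2))


def write_aggregated(agg: AggregatedSeries, out_dir, stem: str = "condition") -> None:
    """Aggregated CSV: timestep,statistic,mean,ci_low,ci_high,R."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    agg.to_frame().to_csv(out_dir / f"{stem}.csv", index=False)


def write_sweep(grid: SweepGrid, out_dir, stem: str = "sweep") -> None:
    """Tidy per-cell CSV suitable for heatmap rendering."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid.table.to_csv(out_dir / f"{stem}.csv", index=False)
    meta = {
        "axes": {k: [float(v) for v in vs] for k, vs in grid.axes.items()},
        "R": grid.R,
        "T_final": grid.T_final,
    }
    (out_dir / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))


def write_manifest(
    cfg: SimulationConfig,
    net_meta: dict,
    out_dir,
) -> RunManifest:
    seeds = [
        str(replicate_seed_sequence(cfg.seed, r).spawn_key)
        for r in range(cfg.R)
    ]
    manifest = RunManifest(
        config=asdict(cfg),
        master_seed=cfg.seed,
        replicate_seeds=seeds,
        network=net_meta,
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))
    return manifest
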