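"""Replicate orchestration, parameter sweeps, and preset experiment grids.

The preset families reproduce the study designs of the neutral network-drift
experiments: time-series comparisons across network connectivity ``k`` and
subpopulation count ``S``, heatmap sweeps over ``(k, m)`` and ``(S, m)``,
and the spatial island scenario of ~150 communities on a k-nearest-neighbor
coastline graph.  Absolute statistic levels depend on the initial trait
count ``A0`` (which defaults to one label per individual slot,
``floor(N/S)``); preset outputs are therefore compared by ordering and
trend, not by absolute curve values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core import SimulationConfig, replicate_seed_sequence, run_replicate
from .networks import (
    InteractionNetwork,
    build_small_world,
    generate_connected_island_network,
)
from .stats import AggregatedSeries, StatSeries, aggregate_replicates

logger = logging.getLogger(__name__)

__all__ = [
    "SweepGrid",
    "run_condition",
    "sweep",
    "preset",
    "PRESET_NAMES",
]

STATISTICS = ("fst", "richness", "unique_trait_subpops", "heterozygosity")


@dataclass
class SweepGrid:
    """Final-time statistics over a parameter grid, one row per cell.

    ``table`` columns: the axis values, ``valid``, plus
    ``<stat>_mean/_ci_low/_ci_high`` for every tracked statistic, and the
    replicate seeds of the cell (reproducibility record).
    """

    axes: dict
    table: pd.DataFrame
    R: int
    T_final: int

    def cell(self, **axis_values) -> pd.Series:
        mask = np.ones(len(self.table), dtype=bool)
        for name, val in axis_values.items():
            mask &= self.table[name] == val
        hits = self.table[mask]
        if len(hits) != 1:
            raise KeyError(f"no unique cell for {axis_values}")
        return hits.iloc[0]


def run_condition(
    cfg: SimulationConfig,
    net: InteractionNetwork,
    level: float = 0.95,
    ci_method: str = "t",
    keep_replicates: bool = False,
):
    """Run ``cfg.R`` replicates with seeds derived from the master seed and
    aggregate them.  Returns the :class:`AggregatedSeries`, or a
    ``(aggregated, replicates)`` pair when ``keep_replicates``."""
    series: list[StatSeries] = []
    for r in range(cfg.R):
        ss = replicate_seed_sequence(cfg.seed, r)
        logger.info("condition replicate %d/%d", r + 1, cfg.R)
        series.append(run_replicate(cfg, net, ss))
    agg = aggregate_replicates(series, level=level, method=ci_method)
    return (agg, series) if keep_replicates else agg


def _build_cell_network(
    base_cfg: SimulationConfig,
    S: int,
    k: int,
    spatial: bool,
    cell_seed: int,
) -> InteractionNetwork:
    if spatial:
        net, _ = generate_connected_island_network(n=S, k=k, seed=cell_seed)
        return net
    return build_small_world(S, k, p_rewire=0.0, seed=cell_seed)


def sweep(
    base_cfg: SimulationConfig,
    axes: dict,
    spatial: bool = False,
) -> SweepGrid:
    """Grid sweep over ``k`` and/or ``S`` and/or ``m``.

    ``axes`` maps axis names (subset of ``{"k", "S", "m"}``) to value
    vectors; every combination is a cell.  The network is rebuilt per cell
    (ring lattice, or spatial kNN when ``spatial``), with a per-cell seed
    derived from the master seed.  Infeasible cells (``k >= S``) are marked
    invalid and skipped; the sweep continues.  Statistics are taken at the
    final timestep ``base_cfg.T``.
    """
    unknown = set(axes) - {"k", "S", "m"}
    if unknown:
        raise ValueError(f"unknown sweep axes: {sorted(unknown)}")
    names = list(axes)
    grids = [list(axes[n]) for n in names]
    mesh = [()]
    for g in grids:
        mesh = [prev + (v,) for prev in mesh for v in g]

    rows = []
    for cell_idx, combo in enumerate(mesh):
        params = dict(zip(names, combo))
        S = int(params.get("S", base_cfg.S))
        k = int(params.get("k", base_cfg.network.get("k", 2) if base_cfg.network else 2))
        m = float(params.get("m", base_cfg.m))
        cell_seed = int(
            np.random.SeedSequence(
                entropy=base_cfg.seed, spawn_key=(cell_idx,)
            ).generate_state(1)[0] % (2**31)
        )
        row = dict(params)
        row["cell_seed"] = cell_seed
        if k >= S or S > base_cfg.N:
            logger.warning("cell %s infeasible; marked invalid", params)
            row["valid"] = False
            for stat in STATISTICS:
                row[f"{stat}_mean"] = np.nan
                row[f"{stat}_ci_low"] = np.nan
                row[f"{stat}_ci_high"] = np.nan
            rows.append(row)
            continue
        cfg = replace(
            base_cfg,
            S=S,
            m=m,
            A0=None,  # re-derive floor(N/S) per cell
            seed=cell_seed,
            stat_interval=base_cfg.T,  # final-time statistics only
        )
        net = _build_cell_network(base_cfg, S, k, spatial, cell_seed)
        agg = run_condition(cfg, net)
        row["valid"] = True
        for stat in STATISTICS:
            mean, lo, hi = agg.final(stat)
            row[f"{stat}_mean"] = mean
            row[f"{stat}_ci_low"] = lo
            row[f"{stat}_ci_high"] = hi
        rows.append(row)
        logger.info("sweep cell %d/%d done: %s", cell_idx + 1, len(mesh), params)
    return SweepGrid(
        axes=axes,
        table=pd.DataFrame(rows),
        R=base_cfg.R,
        T_final=base_cfg.T,
    )


# ---------------------------------------------------------------------------
# Preset experiment families

PRESET_NAMES = (
    "fig3_4",
    "fig5_6",
    "fig7_8",
    "fig9_10",
    "fig11_12",
    "rapanui_14_15",
    "rapanui_16_17",
)

_DEFAULT_M_GRID = np.geomspace(0.0001, 0.005, 10)
_DEFAULT_S_GRID = (5, 10, 20, 50, 100, 150, 200)


def _scaled(values, scale: float) -> list:
    """Thin a grid axis to roughly ``scale`` of its density, keeping both
    endpoints."""
    values = list(values)
    if scale >= 1.0 or len(values) <= 2:
        return values
    n_keep = max(2, int(round(len(values) * scale)))
    idx = np.unique(np.round(np.linspace(0, len(values) - 1, n_keep)).astype(int))
    return [values[i] for i in idx]


def preset(name: str, scale: float = 1.0, seed: int = 0):
    """Run one preset experiment family.

    ``scale`` in (0, 1] shrinks replicate counts and sweep-grid density for
    desk-scale runs; it never changes the model parameters (N, S, k, m, mu,
    T) of any condition.  Returns ``{"conditions": {label: AggregatedSeries}}``
    for time-series presets or ``{"grid": SweepGrid}`` for sweep presets,
    plus a ``"design"`` echo.

    Condition menus: the three-connectivity comparison uses k in {2, 50,
    120} at S=200; the subpopulation-count comparison uses S in {20, 50,
    200} at ring k=2 over 5000 timesteps; the (k, m) and (S, m) heatmaps
    span k = 5..190 step 5 (or S = 5..200) crossed with m in [0.0001,
    0.005]; the island presets put S=150 communities on a synthetic
    coastline kNN graph with k in {5, 50, 140} at m=0.0001.  (A caption in
    the source material lists k=2 for the island time-series; the body text
    says k=5, which we follow.)
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must be in (0, 1]")
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    R = max(1, int(round(10 * scale)))

    if name == "fig3_4":
        base = SimulationConfig(N=5000, S=200, m=0.0025, mu=0.0, T=2000,
                                R=R, seed=seed, stat_interval=10)
        conditions = {}
        for k in (2, 50, 120):
            net = build_small_world(200, k, p_rewire=0.0, seed=seed)
            conditions[f"k={k}"] = run_condition(replace(base), net)
        return {"conditions": conditions,
                "design": {"N": 5000, "S": 200, "k": [2, 50, 120],
                           "m": 0.0025, "T": 2000, "R": R}}

    if name == "fig5_6":
        conditions = {}
        for S in (20, 50, 200):
            cfg = SimulationConfig(N=5000, S=S, m=0.0025, mu=0.0, T=5000,
                                   R=R, seed=seed, stat_interval=10)
            net = build_small_world(S, 2, p_rewire=0.0, seed=seed)
            conditions[f"S={S}"] = run_condition(cfg, net)
        return {"conditions": conditions,
                "design": {"N": 5000, "S": [20, 50, 200], "k": 2,
                           "m": 0.0025, "T": 5000, "R": R}}

    if name in ("fig7_8", "fig11_12"):
        base = SimulationConfig(N=5000, S=200, mu=0.0, T=2000, R=R, seed=seed,
                                stat_interval=2000)
        axes = {
            "k": _scaled(list(range(5, 191, 5)), scale),
            "m": _scaled(list(_DEFAULT_M_GRID), scale),
        }
        grid = sweep(base, axes)
        return {"grid": grid, "design": {"N": 5000, "S": 200, "axes": axes,
                                         "T": 2000, "R": R}}

    if name == "fig9_10":
        base = SimulationConfig(N=5000, S=200, mu=0.0, T=2000, R=R, seed=seed,
                                stat_interval=2000)
        axes = {
            "S": _scaled(list(_DEFAULT_S_GRID), scale),
            "m": _scaled(list(_DEFAULT_M_GRID), scale),
        }
        grid = sweep(base, axes)
        return {"grid": grid, "design": {"N": 5000, "k": 2, "axes": axes,
                                         "T": 2000, "R": R}}

    if name == "rapanui_14_15":
        base = SimulationConfig(N=5000, S=150, m=0.0001, mu=0.0, T=2000,
                                R=R, seed=seed, stat_interval=10)
        conditions = {}
        for k in (5, 50, 140):
            net, _ = generate_connected_island_network(n=150, k=k, seed=seed)
            conditions[f"k={k}"] = run_condition(replace(base), net)
        return {"conditions": conditions,
                "design": {"N": 5000, "S": 150, "k": [5, 50, 140],
                           "m": 0.0001, "T": 2000, "R": R,
                           "network": "spatial_knn"}}

    if name == "rapanui_16_17":
        base = SimulationConfig(N=5000, S=150, mu=0.0, T=2000, R=R, seed=seed,
                                stat_interval=2000)
        axes = {
            "k": _scaled([5, 25, 50, 75, 100, 120, 140], scale),
            "m": _scaled(list(_DEFAULT_M_GRID), scale),
        }
        grid = sweep(base, axes, spatial=True)
        return {"grid": grid, "design": {"N": 5000, "S": 150, "axes": axes,
                                         "T": 2000, "R": R,
                                         "network": "spatial_knn"}}

    raise AssertionError("unreachable")
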