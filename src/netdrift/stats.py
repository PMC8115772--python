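"""Differentiation and richness statistics, and replicate aggregation.

The central measure is Wright's fixation index F_ST, the share of total
trait-frequency variance that lies between subpopulations:

    F_ST = sigma_S^2 / (p * (1 - p))

where ``p`` is the size-weighted mean frequency of a trait across the whole
population and ``sigma_S^2`` the size-weighted variance of its frequency
between subpopulations.  With more than two trait labels the per-label
numerators and denominators are aggregated as a ratio of sums, which reduces
exactly to the expression above in the biallelic case.  F_ST is 0 when all
subpopulations have identical composition and 1 when they are fixed on
disjoint labels.

Also provided: richness (distinct labels in the whole population), the
rare-trait retention count (subpopulations holding a label found nowhere
else), and expected heterozygosity (probability two random individuals
differ), which ties the simulator to closed-form neutral-theory decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import SimulationConfig, TraitPopulation

__all__ = [
    "FrequencyTable",
    "StatSeries",
    "AggregatedSeries",
    "STAT_BOUNDS",
    "subpop_allele_frequencies",
    "fst",
    "richness",
    "unique_trait_subpop_count",
    "heterozygosity",
    "snapshot",
    "aggregate_replicates",
]

# valid range per statistic, used to clip confidence bands on output
STAT_BOUNDS = {
    "fst": (0.0, 1.0),
    "heterozygosity": (0.0, 1.0),
    "richness": (1.0, np.inf),
    "unique_trait_subpops": (0.0, np.inf),
}


@dataclass(frozen=True)
class FrequencyTable:
    """Per-subpopulation trait frequencies with size-share weights.

    ``per_subpop_freq[s, a]`` is the frequency of label ``labels[a]`` inside
    subpopulation ``s``; ``global_freq`` is the weight-averaged frequency
    (Wright's ``p``).
    """

    labels: np.ndarray
    per_subpop_freq: np.ndarray
    subpop_weights: np.ndarray

    @property
    def global_freq(self) -> np.ndarray:
        return self.subpop_weights @ self.per_subpop_freq


def subpop_allele_frequencies(pop: TraitPopulation) -> FrequencyTable:
    """Exact count-derived frequency table for every label present."""
    labels, inv = np.unique(pop.traits, return_inverse=True)
    L, S = len(labels), pop.S
    counts = np.bincount(
        pop.subpop_of * L + inv, minlength=S * L
    ).reshape(S, L)
    freqs = counts / pop.subpop_sizes[:, None]
    weights = pop.subpop_sizes / pop.N
    return FrequencyTable(
        labels=labels, per_subpop_freq=freqs, subpop_weights=weights
    )


def fst(ft: FrequencyTable) -> float:
    """Multi-label fixation index as a ratio of sums over labels.

    Per label ``a``: numerator ``sigma_a^2 = sum_s w_s (f_sa - p_a)^2``,
    denominator ``p_a (1 - p_a)``; globally fixed or absent labels
    contribute zero to both.  Returns 0 when every label is fixed or absent
    (all individuals identical): the subpopulations are identical in the
    only possible sense.
    """
    p = ft.global_freq
    sigma2 = ft.subpop_weights @ (ft.per_subpop_freq - p) ** 2
    denom = float(np.sum(p * (1.0 - p)))
    if denom == 0.0:
        return 0.0
    return float(np.sum(sigma2) / denom)


def richness(pop: TraitPopulation) -> int:
    """Number of distinct trait labels in the whole population."""
    return int(len(np.unique(pop.traits)))


def unique_trait_subpop_count(pop: TraitPopulation) -> int:
    """Number of subpopulations holding at least one label that occurs in
    no other subpopulation (rare-trait retention measure)."""
    labels, inv = np.unique(pop.traits, return_inverse=True)
    L = len(labels)
    present = np.zeros((pop.S, L), dtype=bool)
    present[pop.subpop_of, inv] = True
    n_holders = present.sum(axis=0)
    private = present & (n_holders == 1)
    return int(private.any(axis=1).sum())


def heterozygosity(pop: TraitPopulation) -> float:
    """1 - sum_a (global count_a / N)^2: probability two individuals drawn
    at random (regardless of subpopulation) carry different traits."""
    _, counts = np.unique(pop.traits, return_counts=True)
    freq = counts / pop.N
    return float(1.0 - np.sum(freq**2))


def snapshot(pop: TraitPopulation) -> dict:
    """All tracked statistics of the current state.

    Computes the frequency table once and derives every statistic from it;
    equivalent to calling the individual functions (property-tested).
    """
    ft = subpop_allele_frequencies(pop)
    p = ft.global_freq  # equals global count_a / N
    present = ft.per_subpop_freq > 0
    n_holders = present.sum(axis=0)
    private = present & (n_holders == 1)
    return {
        "fst": fst(ft),
        "richness": int(len(ft.labels)),
        "unique_trait_subpops": int(private.any(axis=1).sum()),
        "heterozygosity": float(1.0 - np.sum(p**2)),
    }


@dataclass
class StatSeries:
    """Per-timestep statistics of a single replicate."""

    timesteps: np.ndarray
    values: dict  # statistic name -> array aligned with timesteps
    replicate_seed: object = None
    config: Optional[SimulationConfig] = None
    network_params: dict = field(default_factory=dict)

    def to_frame(self, replicate: Optional[int] = None) -> pd.DataFrame:
        """Long format: replicate, timestep, statistic, value."""
        frames = []
        for name, vals in self.values.items():
            frames.append(
                pd.DataFrame(
                    {
                        "replicate": replicate if replicate is not None else 0,
                        "timestep": self.timesteps,
                        "statistic": name,
                        "value": vals,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class AggregatedSeries:
    """Mean and 95% (by default) confidence band per timestep/statistic."""

    timesteps: np.ndarray
    mean: dict
    ci_low: dict
    ci_high: dict
    R: int
    level: float = 0.95
    method: str = "t"
    degenerate: bool = False  # True when R == 1 (bands collapse to mean)

    def final(self, statistic: str) -> tuple[float, float, float]:
        """(mean, ci_low, ci_high) at the last snapshot."""
        return (
            float(self.mean[statistic][-1]),
            float(self.ci_low[statistic][-1]),
            float(self.ci_high[statistic][-1]),
        )

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for name in self.mean:
            frames.append(
                pd.DataFrame(
                    {
                        "timestep": self.timesteps,
                        "statistic": name,
                        "mean": self.mean[name],
                        "ci_low": self.ci_low[name],
                        "ci_high": self.ci_high[name],
                        "R": self.R,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def aggregate_replicates(
    series: list[StatSeries],
    level: float = 0.95,
    method: str = "t",
    clip: bool = True,
) -> AggregatedSeries:
    """Aggregate replicate series into mean and confidence bands.

    ``method="t"`` gives the Student-t interval
    ``mean +/- t_{R-1, (1+level)/2} * sd / sqrt(R)``; ``method="percentile"``
    takes empirical quantiles across replicates.  With a single replicate
    the bands collapse to the mean and the result is flagged degenerate.
    Bands are clipped to each statistic's valid range unless ``clip=False``.
    """
    if not series:
        raise ValueError("no series to aggregate")
    t0 = series[0].timesteps
    for s in series[1:]:
        if not np.array_equal(s.timesteps, t0):
            raise ValueError("snapshot timestep grids differ between replicates")
        if set(s.values) != set(series[0].values):
            raise ValueError("statistic sets differ between replicates")
    R = len(series)
    mean, lo, hi = {}, {}, {}
    for name in series[0].values:
        mat = np.vstack([s.values[name] for s in series]).astype(float)
        mu = mat.mean(axis=0)
        if R == 1:
            low = high = mu.copy()
        elif method == "t":
            sd = mat.std(axis=0, ddof=1)
            half = sps.t.ppf(0.5 + level / 2.0, df=R - 1) * sd / np.sqrt(R)
            low, high = mu - half, mu + half
        elif method == "percentile":
            alpha = (1.0 - level) / 2.0
            low = np.quantile(mat, alpha, axis=0)
            high = np.quantile(mat, 1.0 - alpha, axis=0)
        else:
            raise ValueError(f"unknown CI method {method!r}")
        if clip and name in STAT_BOUNDS:
            lo_b, hi_b = STAT_BOUNDS[name]
            low = np.clip(low, lo_b, hi_b)
            high = np.clip(high, lo_b, hi_b)
        mean[name], lo[name], hi[name] = mu, low, high
    return AggregatedSeries(
        timesteps=t0,
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        R=R,
        level=level,
        method=method,
        degenerate=(R == 1),
    )
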