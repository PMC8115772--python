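"""Forward-time haploid Wright-Fisher transmission kernel.

The model: a fixed-size haploid population of ``N`` individuals partitioned
into ``S`` subpopulations (communities) that sit on the nodes of an
interaction network.  Each timestep is a synchronous generation update: every
individual copies the trait of a uniformly chosen individual (with
replacement) from a source subpopulation — its own with probability ``1-m``,
otherwise a uniformly chosen network neighbor of its node.  With probability
``mu`` per copy event the copied trait is replaced by a brand-new label
(infinite-alleles innovation).  Subpopulation sizes never change; between-
group interaction moves trait information, not people.

Timesteps are rounds of social learning, not biological generations.  The
classic neutral-theory quantities apply: within one panmictic population
heterozygosity decays as ``(1 - 1/N)^t`` without innovation, and with
innovation rate ``mu`` equilibrates near ``theta/(1+theta)`` with
``theta = 2*N*mu``; the drift/innovation transition sits at
``mu_c = 1/(2N)``.

``exact_markov_distribution`` provides a brute-force transition-matrix
oracle for tiny instances, used to validate the stochastic kernel.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import multinomial

from .networks import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TraitPopulation",
    "initialize_population",
    "step",
    "run_replicate",
    "replicate_seed_sequence",
    "exact_markov_distribution",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All model parameters of one simulation condition.

    Parameters
    ----------
    N : total number of individuals (fixed).
    S : number of subpopulations.
    m : per-individual per-timestep probability of copying from a
        neighboring subpopulation instead of one's own ("migration rate").
    mu : innovation probability per copy event (infinite alleles).
    T : number of timesteps.
    A0 : initial number of distinct traits, distributed evenly within every
        subpopulation; defaults to ``floor(N / S)``.
    R : replicates.
    seed : master seed; per-replicate streams are derived from it.
    stat_interval : timesteps between statistic snapshots (t=0 and t=T are
        always included).
    network : optional builder spec (dict) recorded for provenance; the
        network object itself is passed to the run functions.
    """

    N: int
    S: int
    m: float = 0.0025
    mu: float = 0.0
    T: int = 2000
    A0: Optional[int] = None
    R: int = 10
    seed: int = 0
    stat_interval: int = 1
    network: Optional[dict] = None

    def __post_init__(self):
        if not (self.N >= self.S >= 1):
            raise ValueError("need N >= S >= 1")
        if not (0.0 <= self.m <= 1.0):
            raise ValueError("m must be in [0, 1]")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must be in [0, 1]")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.stat_interval < 1:
            raise ValueError("stat_interval must be >= 1")
        if self.A0 is None:
            object.__setattr__(self, "A0", self.N // self.S)
        if not (1 <= self.A0 <= self.N // self.S):
            raise ValueError(
                f"A0={self.A0} must be in [1, floor(N/S)={self.N // self.S}] "
                "for an even initial trait distribution"
            )

    @property
    def mu_c(self) -> float:
        """Critical innovation rate 1/(2N) separating drift- and
        innovation-dominated regimes."""
        return 1.0 / (2.0 * self.N)


def subpopulation_sizes(N: int, S: int) -> np.ndarray:
    """floor(N/S) each, remainder given one-each to the lowest indices."""
    base = N // S
    rem = N % S
    sizes = np.full(S, base, dtype=np.int64)
    sizes[:rem] += 1
    return sizes


@dataclass
class TraitPopulation:
    """Evolving state: one trait label per individual plus the partition.

    Individuals are stored grouped by subpopulation: subpopulation ``s``
    owns the contiguous index slice ``[subpop_start[s],
    subpop_start[s] + subpop_sizes[s])``.  ``next_label`` is the smallest
    trait label never yet used (innovation counter).
    """

    traits: np.ndarray
    subpop_of: np.ndarray
    subpop_sizes: np.ndarray
    subpop_start: np.ndarray
    t: int = 0
    next_label: int = 0

    @property
    def N(self) -> int:
        return len(self.traits)

    @property
    def S(self) -> int:
        return len(self.subpop_sizes)

    def subpop_traits(self, s: int) -> np.ndarray:
        a = self.subpop_start[s]
        return self.traits[a : a + self.subpop_sizes[s]]


def initialize_population(cfg: SimulationConfig) -> TraitPopulation:
    """Identical subpopulations, each with labels ``0..A0-1`` spread evenly.

    Within every subpopulation individual ``j`` receives label ``j % A0``,
    so all subpopulations start with the same composition and every trait
    sits as close to frequency ``1/A0`` as integer counts allow.
    """
    sizes = subpopulation_sizes(cfg.N, cfg.S)
    if cfg.A0 > sizes.min():
        raise ValueError("A0 exceeds the smallest subpopulation size")
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.int64)
    subpop_of = np.repeat(np.arange(cfg.S, dtype=np.int64), sizes)
    traits = np.concatenate(
        [np.arange(n, dtype=np.int64) % cfg.A0 for n in sizes]
    )
    return TraitPopulation(
        traits=traits,
        subpop_of=subpop_of,
        subpop_sizes=sizes,
        subpop_start=starts,
        t=0,
        next_label=cfg.A0,
    )


def step(
    pop: TraitPopulation,
    net: InteractionNetwork,
    m: float,
    mu: float,
    rng: np.random.Generator,
    _nbr_cache: Optional[tuple] = None,
) -> TraitPopulation:
    """One synchronous generation update (see module docstring).

    All individuals copy from the time-``t`` state.  The random stream is
    advanced by four fixed-size draws per step (source switch, neighbor
    choice, source individual, innovation) regardless of outcomes, so runs
    are reproducible draw-for-draw.  Individuals on isolated network nodes
    always copy within their own subpopulation.
    """
    if pop.S != net.n_nodes:
        raise ValueError(
            f"population has {pop.S} subpopulations but network has "
            f"{net.n_nodes} nodes"
        )
    N = pop.N
    nb_flat, nb_start, nb_count = (
        _nbr_cache if _nbr_cache is not None else net.neighbor_arrays()
    )
    u_mig = rng.random(N)
    u_nbr = rng.random(N)
    u_ind = rng.random(N)
    u_mut = rng.random(N)

    src = pop.subpop_of.copy()
    migrate = (u_mig < m) & (nb_count[pop.subpop_of] > 0)
    if migrate.any():
        s = pop.subpop_of[migrate]
        pick = (u_nbr[migrate] * nb_count[s]).astype(np.int64)
        src[migrate] = nb_flat[nb_start[s] + pick]

    pos = pop.subpop_start[src] + (u_ind * pop.subpop_sizes[src]).astype(
        np.int64
    )
    new_traits = pop.traits[pos]

    next_label = pop.next_label
    innovate = u_mut < mu
    n_new = int(innovate.sum())
    if n_new:
        new_traits = new_traits.copy() if new_traits.base is not None else new_traits
        new_traits[innovate] = next_label + np.arange(n_new, dtype=np.int64)
        next_label += n_new

    return TraitPopulation(
        traits=new_traits,
        subpop_of=pop.subpop_of,
        subpop_sizes=pop.subpop_sizes,
        subpop_start=pop.subpop_start,
        t=pop.t + 1,
        next_label=next_label,
    )


def replicate_seed_sequence(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Stable derivation of independent per-replicate streams: the master
    seed and the replicate index are the spawn key."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate,))


def run_replicate(
    cfg: SimulationConfig,
    net: InteractionNetwork,
    replicate_seed,
) -> "StatSeries":
    """Initialize, iterate ``T`` steps, snapshot statistics on the cadence
    ``stat_interval`` (always including t=0 and t=T).  Returns a
    :class:`~netdrift.stats.StatSeries`; bit-identical for identical inputs.
    """
    from . import stats as _stats  # local import to avoid a cycle

    rng = np.random.default_rng(replicate_seed)
    pop = initialize_population(cfg)
    nbr_cache = net.neighbor_arrays()
    if (nbr_cache[2] == 0).any():
        logger.info(
            "network has %d isolated node(s); they copy within-group only",
            int((nbr_cache[2] == 0).sum()),
        )
    snap_t = [0]
    snaps = [_stats.snapshot(pop)]
    for t in range(1, cfg.T + 1):
        pop = step(pop, net, cfg.m, cfg.mu, rng, _nbr_cache=nbr_cache)
        if t % cfg.stat_interval == 0 or t == cfg.T:
            snap_t.append(t)
            snaps.append(_stats.snapshot(pop))
    seed_repr = (
        replicate_seed.entropy
        if isinstance(replicate_seed, np.random.SeedSequence)
        else replicate_seed
    )
    return _stats.StatSeries(
        timesteps=np.array(snap_t, dtype=np.int64),
        values={
            name: np.array([s[name] for s in snaps])
            for name in snaps[0]
        },
        replicate_seed=seed_repr,
        config=cfg,
        network_params={"builder": net.builder, **net.params},
    )


# ---------------------------------------------------------------------------
# Exact Markov-chain oracle for tiny instances


def _compositions(n: int, parts: int):
    """All vectors of `parts` non-negative ints summing to n."""
    if parts == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, parts - 1):
            yield (first,) + rest


def exact_markov_distribution(
    cfg: SimulationConfig,
    net: InteractionNetwork,
    t: int,
    max_states: int = 10_000,
) -> dict:
    """Exact state distribution of the trait-count chain after ``t`` steps.

    The state is the tuple of per-subpopulation trait-count vectors over the
    ``A0`` initial labels (innovation must be off: ``mu=0`` keeps the label
    set finite).  Each subpopulation's next counts are multinomial with cell
    probabilities mixing its own frequencies (weight ``1-m``) and the mean
    frequencies of its network neighbors (weight ``m``), independent across
    subpopulations — exactly the one-step law implied by :func:`step`.

    Returns a dict with ``states`` (tuple of tuples each), ``probs`` and
    ``initial`` (index of the start state).
    """
    if cfg.mu != 0:
        raise ValueError("exact oracle requires mu=0 (finite label set)")
    L = cfg.A0
    sizes = subpopulation_sizes(cfg.N, cfg.S)
    per_sub_states = [list(_compositions(int(n), L)) for n in sizes]
    n_states = math.prod(len(s) for s in per_sub_states)
    if n_states > max_states:
        raise ValueError(
            f"state space has {n_states} states (> {max_states}); refuse"
        )
    states = list(itertools.product(*per_sub_states))
    index = {s: i for i, s in enumerate(states)}

    nb_flat, nb_start, nb_count = net.neighbor_arrays()
    nbrs = [
        nb_flat[nb_start[s] : nb_start[s] + nb_count[s]].tolist()
        for s in range(cfg.S)
    ]

    # per-subpop transition pmfs computed per global state (source mixture
    # couples subpops through neighbor frequencies)
    P = np.zeros((n_states, n_states))
    for i, state in enumerate(states):
        freqs = [np.asarray(c, dtype=float) / n for c, n in zip(state, sizes)]
        sub_pmfs = []
        for s in range(cfg.S):
            if nbrs[s]:
                nbr_mean = np.mean([freqs[j] for j in nbrs[s]], axis=0)
                q = (1.0 - cfg.m) * freqs[s] + cfg.m * nbr_mean
            else:
                q = freqs[s]
            pmf = {
                c: multinomial.pmf(c, n=int(sizes[s]), p=q)
                for c in per_sub_states[s]
            }
            sub_pmfs.append(pmf)
        for j, target in enumerate(states):
            p = 1.0
            for s in range(cfg.S):
                p *= sub_pmfs[s][target[s]]
                if p == 0.0:
                    break
            P[i, j] = p

    pop0 = initialize_population(cfg)
    init_state = tuple(
        tuple(np.bincount(pop0.subpop_traits(s), minlength=L))
        for s in range(cfg.S)
    )
    dist = np.zeros(n_states)
    dist[index[init_state]] = 1.0
    for _ in range(t):
        dist = dist @ P
    return {"states": states, "probs": dist, "initial": index[init_state]}


def state_of(pop: TraitPopulation, n_labels: int) -> tuple:
    """Trait-count state tuple of a population, for comparison against
    :func:`exact_markov_distribution` (labels >= n_labels would be
    innovations and are rejected)."""
    if pop.next_label > n_labels and pop.traits.max() >= n_labels:
        raise ValueError("population contains labels outside the tracked set")
    return tuple(
        tuple(np.bincount(pop.subpop_traits(s), minlength=n_labels))
        for s in range(pop.S)
    )
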