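# Methods

## Model

The simulator is a discrete-time, haploid, single-locus Wright–Fisher
process on a metapopulation. The state is one trait label (non-negative
integer) per individual plus a fixed partition of the `N` individuals into
`S` subpopulations, which occupy the nodes of an undirected interaction
network. One timestep is a synchronous update of the whole population: for
each individual independently,

1. choose a **source subpopulation** — the individual's own with
   probability `1 − m`, otherwise a uniformly chosen network neighbor of
   its node (individuals on isolated nodes always use their own);
2. copy the trait of a **uniformly chosen individual** (with replacement)
   from that source subpopulation's state at time `t`;
3. with probability `μ` replace the copied trait with a brand-new label
   (infinite-alleles innovation: labels are never reused).

Assumptions baked into this kernel:

- **Copying, not relocation.** Between-group interaction transfers trait
  information; subpopulation sizes never change. Simulation frameworks that
  implement "migration" by physically moving individuals have slightly
  different finite-size fluctuations (deme sizes vary between migration and
  mating); with the small per-step rates used here the two agree to first
  order, but we implement the copy semantics exactly and state it.
- **Synchronous generations.** All individuals copy from the time-`t`
  state. Timesteps are rounds of maximal social learning, not biological
  generations.
- **Neutrality.** No selection, no fitness differences, no group-level
  sorting; one locus; every innovation is a never-before-seen label.
- `m` is a per-individual, per-timestep source-switch probability, split
  uniformly over however many neighbors the node has (total out-group
  copying probability is `m` regardless of degree).

With `S = 1` (or on a complete graph with `m = (S−1)/S` and equal deme
sizes, where the source individual is uniform over all `N`) the kernel
reduces to the textbook single-population Wright–Fisher model, which gives
the package its strongest correctness anchors:

- heterozygosity decay `E[H_t] = H_0 (1 − 1/N)^t` without innovation;
- infinite-alleles equilibrium `E[H] ≈ θ/(1+θ)` with `θ = 2Nμ`, and the
  drift/innovation transition at `μ_c = 1/(2N)`;
- with `m = 0`, each deme is an independent WF chain that fixes on a label
  with probability equal to its initial frequency, so a population of `S`
  demes each starting with `A0` equally frequent labels keeps on average
  `A0 (1 − (1 − 1/A0)^S)` labels in the long run.

A further, sharper anchor is `exact_markov_distribution`: for tiny
instances (state count ≤ 10,000) it enumerates all per-deme trait-count
states, builds the exact one-step transition matrix implied by the kernel
(per-deme multinomials whose cell probabilities mix own and mean-neighbor
frequencies with weights `1−m` / `m`, independent across demes), and powers
it. The simulator's empirical distribution is compared to this oracle by
total-variation distance in the tests and the acceptance script.

## Statistics

- **F_ST**: per label `a`, numerator `σ_a² = Σ_s w_s (f_{s,a} − p_a)²`
  with `w_s = n_s/N` (size-weighted *population* variance, Wright's
  definition, not the `S−1` sample variance) and denominator
  `p_a(1 − p_a)`; labels are aggregated as ratio of sums,
  `F_ST = Σ_a σ_a² / Σ_a p_a(1−p_a)`, which reduces to the single-trait
  expression in the biallelic case. Globally fixed or absent labels
  contribute zero to both sums; when the denominator is zero (every
  individual identical) F_ST is defined as 0, never NaN. Other multi-allele
  estimators (e.g. Weir–Cockerham bias correction) would shift absolute
  levels but not the orderings studied here; they are out of scope.
- **Richness**: distinct labels in the whole population.
- **Unique-trait subpopulation count**: demes holding ≥ 1 label present in
  no other deme.
- **Heterozygosity**: `1 − Σ_a (n_a/N)²` from global counts.
- **Aggregation**: replicate series are combined per timestep as mean and
  Student-t 95% interval `mean ± t_{R−1,0.975}·sd/√R` (empirical-percentile
  bands are available by flag); bands are clipped to each statistic's valid
  range on output, and a single replicate yields degenerate (flagged)
  bands.

## Initialization

Subpopulation sizes are `floor(N/S)` with the remainder distributed
one-each to the lowest-index demes. Within every deme, individual `j`
receives label `j mod A0`, so all demes start identical, F_ST(0) = 0, and
global richness is exactly `A0`. `A0` defaults to `floor(N/S)` — the
largest value compatible with an even within-deme distribution — because
the source experiments do not report their initial trait count. Absolute
richness/F_ST trajectories depend strongly on `A0`; only orderings and
trends across conditions are comparison targets.

## Networks

- **Small-world (Watts–Strogatz)**: ring lattice joining each node to
  `k/2` neighbors per side, each lattice edge rewired with probability
  `p_rewire` (default 0: the depicted configurations are neighbor rings,
  and the rewiring probability used in the source experiments is
  unreported). A ring's regular degree must be even, so odd `k` is reduced
  to `k−1` with a warning; requested and realized `k` are both recorded.
- **Spatial kNN**: each node directed to its `k` nearest others by planar
  Euclidean distance (ties broken by lower index for determinism),
  symmetrized by union — every community interacts with *at least* its `k`
  nearest, so realized mean degree lies in `[k, 2k]` and is recorded.
  Disconnected graphs are permitted (simulation proceeds; component count
  reported).
- **Synthetic island points**: `n` points on a closed coastline — evenly
  spaced angles with irregularity-scaled angular offsets, radius
  `R(1 + irregularity · low-frequency harmonic noise)` plus isotropic
  Gaussian jitter. Defaults `n=150`, `mean_radius=5000` m,
  `irregularity=0.25`, `jitter=250` m emulate ~150 dispersed coastal
  ceremonial-site locations on an island ~10 km across. These are a
  plausibility stand-in, not measured coordinates: real site patterns have
  inland sites, coastal clustering, and terrain-constrained interaction
  costs that the generator does not model, so island-preset results
  demonstrate the *k*-dependence of drift on a realistic-scale spatial
  graph, not predictions for the real settlement pattern. A
  `id,x,y` CSV reader accepts real coordinates when available.
- The characteristic path length reported by `network_metrics` is the mean
  shortest-path length over connected ordered pairs (disconnected pairs
  excluded and counted). The source text's "graph degree — the number of
  vertices between any two edges" conflates node degree with path length;
  we expose both and take no position on which was computed.

## Experiment presets and scaling

Preset families fix the study conditions: three-connectivity comparison
(`N=5000`, `S=200`, `k ∈ {2,50,120}`, `m=0.0025`, `T=2000`);
subpopulation-count comparison (`S ∈ {20,50,200}`, ring `k=2`, `T=5000`);
`(k, m)` sweep (`k = 5..190` step 5 × 10 log-spaced `m ∈ [0.0001, 0.005]`,
`R=10`, statistics at `T=2000`); `(S, m)` sweep
(`S ∈ {5,10,20,50,100,150,200}`); island scenario (`S=150` spatial kNN,
`k ∈ {5,50,140}`, `m=0.0001`). The m-grid density and S-grid points are
this package's choices (the endpoints are given, the grids are not). The
island connectivity menu follows the body-text value `k=5` where a figure
caption says `k=2`. The `scale` parameter thins replicate counts and grid
density only — never a condition's model parameters — so scaled runs stay
faithful to each condition's dynamics.

Seeding: a master seed plus replicate index (and cell index, for sweeps)
feed `numpy` `SeedSequence` spawn keys, giving independent, logged,
reproducible streams; manifests record every seed, and identical inputs
reproduce outputs bit-identically.

## Numerical and degenerate-case choices

- The RNG stream advances by four fixed-size uniform draws per step
  (source switch, neighbor pick, individual pick, innovation) regardless of
  outcomes, so trajectories are reproducible draw-for-draw.
- Individuals are stored grouped by deme (contiguous slices), making the
  update fully vectorized; a 5000-individual, 200-deme, 2000-step replicate
  with statistics at every step runs in about a second on one core.
- Empty-edge networks are valid (path length reported as NaN); `k ≥ S`
  sweep cells are marked invalid and skipped without aborting the sweep.
- Test and acceptance problem sizes (500 Monte-Carlo replicates for decay
  checks, 50,000 for the oracle comparison, 300 for fixation richness,
  `R=5` / `R=3` for the ordering experiments, sweep at `T=1000`) were
  chosen to give standard errors comfortably below the effect sizes being
  checked while keeping a full run in the minutes range.

## Known limitations

- Trajectory *levels* are not comparable to the source figures because the
  initial trait count behind those figures is unreported; only orderings
  and trends are.
- Effect sizes between adjacent high-connectivity conditions are small:
  with `A0=25`, final-richness means at `T=2000` for `k=50` vs `k=120`
  differ by ~0.4 labels against a between-replicate SD of ~2, so
  small-`R` confidence bands overlap even though the means order
  correctly. Claims about that pair need `R` in the dozens.
- With identical-deme initialization, no trait starts rare: every label
  begins in all `S` demes. Unique-trait deme counts therefore start at 0
  and rise only transiently as labels approach extinction — which happens
  *sooner* in well-mixed, high-`m` conditions. At horizons `T ≲ 1/m` the
  low-`m` corner of a sweep still sits at the richness ceiling with no
  private labels, so rare-trait retention gradients emerge only at much
  longer horizons (or under initial conditions with genuinely rare traits,
  which the even initializer cannot produce).
- No selection, demographic change, multi-locus traits, overlapping
  generations, geographic projections, or terrain-aware interaction costs.
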