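# Methods

## The model

`cueqs` implements a threshold public goods game (TPGG) with cue-based
quorum sensing (QS).  The biological template is bacteriocin systems
such as nisin in *Lactococcus lactis*: the public good itself, expressed
constitutively at a low level, is the QS signal, so genuine cooperators
signal for free while non-cooperators must pay to fake the signal.

Agents carry three binary functional loci — cooperation `C`, extra
signaling `S`, signal response `R` — giving eight genotypes: Lazy
(`csr`), Voyeur (`csR`), Liar (`cSr`), Curious liar (`cSR`), Trusty
(`Csr`), Smart (`CsR`), Bouncer (`CSr`), Nerd (`CSR`).  In an
interaction group of size `N = 9` (the focal agent plus eight
co-members):

* every `C`-carrier contributes one constitutive signal dose (the cue),
  every `S`-carrier one extra dose, so a Bouncer or Nerd counts as two
  signalers;
* a conditional cooperator (`C` and `R`: Smart, Nerd) switches its
  cooperation on (`gamma = 1`) iff the dose count in its group reaches
  the quorum threshold `Q`; unconditional cooperators (Trusty, Bouncer)
  always have `gamma = 1`;
* the benefit indicator is `theta = 1` iff at least `kappa` group
  members are *active* cooperators;
* the realized metabolic cost is
  `(1 - theta*b) * (c0 + gamma*c*[C] + s*[S] + r*[R])` — the benefit
  multiplies the whole bracket, signaling and response costs included.

Reproduction is pairwise imitation: two focal players compare realized
costs and the cheaper one's offspring replaces the other with
probability `p_ij = 0.5 * (1 + sigma * (C_j - C_i) / dC_max)`, where
`dC_max = c + s + r + b*c0` is the largest possible cost difference.
Only cost differences matter, so baseline fitness never needs a value.
Mutation acts on the offspring copy at replication: each locus flips
with a direction-specific rate (all six rates default to `rho`).

We take `Q = kappa` throughout (the evolutionary optimum: switching
cooperation on earlier or later than the benefit threshold is selected
against).

## The four tiers

**Mean-field (MF).**  `N -> inf` with `kappa/N -> K`; every group
mirrors the global frequencies, so only Lazy, Trusty and Smart can
persist and the state is a point on the 2-simplex.  The dynamic is the
replicator flow on negative costs — the exact mean field of the
imitation process — and is *piecewise smooth*: the activation and
benefit indicators are hard step functions of the state (we deliberately
do not smooth them; the integrator bisects steps that cross a threshold
surface).  Within any smooth piece Lazy strictly dominates Trusty, so
La/Tr coexistence can only be *threshold-pinned* at the cooperator
fraction `x_C = K`.  A finite-group reading (the focal's own
contribution adds `1/N` to its own group's count) shows the pinned point
is attracting from within the band `(K - 1/N, K)` precisely when a
just-quorate Trusty beats a sub-quorate Lazy, i.e.
`(1-b)(c0+c) < c0  <=>  b/c > 1/(c0+c)`; it is destroyed by
fluctuations larger than `1/N`.  `mf_fixed_points` evaluates exactly
this cost comparison.  The analogous La/Sm candidate never qualifies: a
Smart focal tipped over the quorum by its own cue sits in a group whose
other conditional cooperators are still silent, so it pays `c0 + c + r`
with no benefit.  The `focal_offset` parameter (default 0) exposes the
`1/N` correction in the flow itself.

**Configuration field (CF).**  Infinite population, finite random
groups: the focal's expected cost is the multinomial-weighted average of
its realized cost over all compositions of its `N - 1` co-members
(45 compositions for 3 strategies, 6435 for 8).  The whole group shares
one signal pool — every member evaluates `Q` and `kappa` against the
same group of `N`.  The resulting replicator flow is polynomial in the
frequencies; fixed points are found by bracketing on each edge plus
0.02-resolution barycentric grid seeding with Newton polish
(tolerance 1e-10, duplicates merged within 1e-6) and classified by the
eigenvalues of the reduced Jacobian, so transversal directions at
boundary points are included.  Mutation, when enabled (8-strategy
analysis), enters as a linear mixing term with the per-replication flip
probabilities at unit rate per unit replicator time; this choice only
rescales time and leaves fixed points and their stability untouched.

**Non-spatial agent-based model (ABM).**  The finite-`P` stochastic
realization of the CF: per elementary step, two independent uniform
samples of `N` agents (without replacement within a sample; the two
samples may overlap, which is immaterial at `P >> N`) form the groups,
one random focal per group plays the imitation game, and the loser's
array slot receives the winner's (possibly mutated) offspring.  One
generation is `floor(P/2)` steps.

**Lattice.**  Agents fill a toroidal `M x M` grid; a player's group is
its 3x3 Moore neighborhood (self included).  The key difference from
the CF rules: activation is *per agent* — each conditional cooperator
in the focal's group compares its **own** Moore-group doses against
`Q`, so a site's cost depends on (at most) the 5x5 block around it.
Competition is between a uniform random site and a uniform random
Moore-adjacent site (diagonals eligible); replacement is in place at
the loser's site.  After each game step a Poisson(`D`)-distributed
number of swaps of random Moore-adjacent pairs models agent motility.
One generation is `M^2/2` game steps.  Site selection is random with
replacement: an agent participates once per generation in expectation.

## Numerical and implementation choices

* Simulation kernels are numba-compiled over 3-bit genotype codes; the
  run kernel maintains an incrementally updated field of own-group dose
  counts, verified in the test suite to agree exactly with the direct
  per-site reference computation.
* All randomness flows from integer seeds (numpy `SeedSequence`
  spawning for replicate fans); simulations are bitwise reproducible.
* MF/CF integrators are fixed-step RK4 with simplex re-projection
  (clip + renormalize) to absorb roundoff; the MF integrator
  additionally bisects steps across indicator discontinuities.
* Stability tolerances: an eigenvalue real part within 1e-7 of zero is
  "marginal"; CF Newton polish accepts residuals below 1e-8.
* Exact-count initialization uses largest-remainder rounding so even
  starts total exactly `P` or `M^2` agents.

## Study conditions and problem sizes

Defaults mirror the reference parameterization: `c0 = 1`, `c = 0.3`
(`0.2` in the benefit-rich lattice scans), `s, r ∈ {0.01, 0.05, 0.10}`,
`b ∈ {0.3 .. 0.8}`, `sigma = 1`, `N = 9`, `kappa = Q ∈ {2..7}`,
`rho ∈ {0, 1e-4}`.  The package's working scale is a 100 x 100 lattice
run for 2,000 generations with `P = 10,000` for the non-spatial ABM and
3–5 replicate seeds — sizes chosen so a full regime battery completes on
a single CPU in minutes while the phenomena of interest (regime
selection, viscosity effects, liar suppression) are already
well-resolved at that scale.  The published full scale (`M = 300`,
`G = 10,000`, `P = 90,000`) is supported everywhere via configuration
(`--paper-scale` on the CLI).

## What the simulations do and do not emulate

The generators produce idealized study populations: exact initial
frequencies, homogeneous parameters, no empty sites, no explicit
signal-molecule chemistry (doses are integers, not concentrations), no
`Q != kappa` variants, and no spatial structure beyond the lattice
adjacency.  Passing tests therefore validate the game-theoretic
mechanism — cue-based honesty enforcement, threshold coexistence,
viscosity effects — not quantitative predictions for any real microbial
system.

## Known limitations

* Strictly zero diffusion is a knife-edge: at `D = 0` clonal domains
  never mix, and at high cooperation thresholds (`kappa = 7`) the
  lattice model settles on Trusty-dominated states even in long
  full-scale runs, whereas every positive motility tested
  (`D >= 0.05`) collapses to the monomorphic Lazy state.  The
  high-threshold collapse should be read as a statement about
  populations with any nonzero motility.
* CF fixed-point search on the full 8-strategy simplex uses random
  Dirichlet seeding rather than a dense grid (the 7-dimensional grid is
  combinatorially out of reach); for the 3-strategy analyses the dense
  grid is exhaustive.
* The CF/MF time scales are defined up to the positive factor
  `sigma/dC_max`; trajectories are comparable across tiers only up to
  time reparametrization.  Fixed points and stability classes are
  invariant to this choice.
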