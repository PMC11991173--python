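# Methods

## Model

A single flexible homopolymer of `N` identical beads occupies nearest-
neighbour-bonded sites of a two-dimensional triangular lattice (coordination
number z = 6) with periodic boundaries; every remaining site holds one
solvent molecule, so the lattice is completely filled.  Axial coordinates
(u, v) with the neighbour offsets {(±1,0), (0,±1), (1,−1), (−1,1)} embed into
the plane as (x, y) = (u + v/2, v·√3/2), which makes every bond a unit
vector.  Nearest-neighbour bonds of a planar triangular lattice cannot cross,
so chain self-avoidance plus unit bonds already guarantee non-crossing; the
code asserts bond length 1 and site-disjointness instead of an explicit
crossing test.

Interactions are square-well contact energies between the two species,
polymer (P) and solvent (S): `E_PP`, `E_PS`, `E_SS`, strictly between
nearest-neighbour sites.  Two presets reproduce the standard solvent-quality
models:

* poor preset: `E_PP = E_SS = −1`, `E_PS = 0`  (χ > 0),
* good preset: `E_PS = −1`, `E_PP = E_SS = 0`  (χ < 0),

with the Flory–Huggins parameter χ = (z/kT)(E_PS − (E_PP + E_SS)/2) and
temperature kT = (z/χ)|E_PS − (E_PP + E_SS)/2| (k = 1).  Because the lattice
is completely filled the total number of contact pairs is fixed at 3L², so
for either preset the energy reduces to a single interface count
(E = −n_PS + const for the poor preset, E = −n_PS for the good one); the
code nevertheless computes the full pair sum so that free-form energy triples
work unchanged.  Bonded neighbours count as P–P contacts; this adds the
constant (N−1)·E_PP, which cancels in every energy difference and in the
heat capacity.  Contact energies of the presets are small integers and all
sums stay exact in float64.

Note on naming: the source literature for this class of models sometimes
labels the χ > 0 branch "good" and χ < 0 "poor".  This package keys
everything to the interaction preset and the sign of χ/z, never to the
adjectives.

## Sampling: the Cooperative Motion Algorithm

At full occupancy no single particle can move alone; rearrangements happen
along closed loops with zero net displacement.  A move is constructed with a
temporary vacancy (TV):

1. an origin site is drawn uniformly over the L² sites; if it holds a bead
   the attempt is a null proposal (removing a bead would sever the chain for
   the whole walk — solvent origins keep every rest state a valid
   configuration, and chain moves still happen whenever the TV meets the
   chain); otherwise the solvent molecule is held aside and the vacancy
   starts walking;
2. at each rest the TV draws one of its six neighbour directions uniformly;
3. a solvent neighbour hops into the vacancy; a chain bead k can move only
   if the chain stays connected: if both chain neighbours of k sit adjacent
   to the vacancy the bead alone flips into it (kink/end flip); if exactly
   one side stays bonded, the tail on the other side slides one position
   along its own contour toward the vacancy (reptation), and the TV exits at
   the first point where the chain is whole again — past a chain end, or at
   a tight 60° fold where the contour loops back; if neither side stays
   bonded the draw is a null step;
4. the walk closes when the TV re-enters its origin with zero winding (the
   unwrapped return), which makes the element displacements sum to exactly
   zero even on the torus; the held solvent is restored at the origin.

Walks that fail to close within 4L² element displacements (or 16L² draws)
are abandoned and count as rejected attempts.

### Acceptance rule

Temperature enters through a Metropolis–Hastings test on the net energy
change ΔE of a completed loop:

    P(accept) = min(1, exp(−ΔE/kT) · (6 − b_initial)/(6 − b_final)),

where `b` counts blocked directions at the origin vacancy in the initial and
final states.  The second factor is required for exactness: null steps make
the effective probability of each realisable outcome of a rest state
1/(6 − b), and the product of these factors along any walk telescopes down
to the two endpoint states, leaving a proposal asymmetry
q(B→A)/q(A→B) = (6 − b_A)/(6 − b_B).  Without the correction, fold-rich
(locally compact) conformations are systematically under-sampled at the
half-percent level — detectable in this package's exact-enumeration tests.
Athermal runs keep the proposal factor and drop only the Boltzmann factor.
Exactness was additionally verified by enumerating *all* TV walk paths up to
five draws on an N=4, L=6 system and checking detailed balance pairwise to
machine precision, and by replicate-based comparisons of ⟨E⟩, C_v, ⟨R_g²⟩,
⟨R_ee²⟩ against exact enumeration (both presets, several temperatures,
|z| < 2.5 at sixteen replicates of 3·10⁵ MCS).

### Monte Carlo time and the sampling clock

One Monte Carlo step (MCS) is an attempted move of each element on average:
every element displacement attempted during loop construction accumulates
until the total reaches L², whether or not the loop is accepted (a null
attempt counts its origin element).  Counting only accepted displacements
would make run cost per MCS diverge with the heavy-tailed return time of a
two-dimensional vacancy walk; counting all attempts keeps MCS proportional
to work.  Equilibrium averages are independent of this convention — it only
rescales the time unit.

Production samples are scheduled on the *attempt* clock: the requested MCS
interval is converted once to a fixed number of attempts using the mean
elements-per-attempt of the preceding phases.  Triggering samples when the
element counter crosses a mark would condition the sampled state on a
size-biased crossing loop (inspection paradox); this is not hypothetical — it
produced a reproducible ≈0.3 % bias in ⟨R_g²⟩ on tiny systems before the
scheme was changed.  At stationarity the state after any fixed number of
attempts is exactly ensemble-distributed.

### Protocol

Each run draws the initial conformation *uniformly* over self-avoiding walks
by dimerisation (non-reversal simple sampling below nine bonds; two uniform
halves concatenated and rejected on overlap above), drops it at a random
box position, relaxes it athermally (default max(1000, N²/4) MCS), switches
on the interactions, equilibrates for `n_equil_mcs` and samples every
`sample_interval_mcs` during `n_prod_mcs`.  The uniform start matters: the
athermal ensemble of the filled box *is* the uniform SAW ensemble, so
athermal production is stationary from its first sample, whereas a grown
(biased) chain would need several R_g² autocorrelation times
(τ ≈ N² MCS — prohibitive at N = 128) to forget its too-compact start.
Boxes denser than one bead per three sites fall back to biased growth with
restarts, where any valid placement is acceptable because relaxation
follows.  Replicates differ in both the initial configuration
and the RNG stream; one integer seed reproduces everything bit-exactly.
The RNG is a splitmix64 stream per run, seeded through
`numpy.random.SeedSequence`.

## Observables

* Size: R_ee² = |r_1 − r_N|², R_g² = (1/N)Σ|r_i − r_cm|², from unwrapped
  coordinates reconstructed by accumulating unit bond vectors (exact, since
  L > 2 makes each wrapped bond unambiguous).
* Shape: eigenvalues λ1 ≥ λ2 of the 2×2 gyration tensor (closed form);
  λ1 + λ2 = R_g² to machine precision.  Asphericity
  A2 = ⟨(λ1−λ2)²⟩/⟨(λ1+λ2)²⟩ uses the ratio-of-means form for headline
  numbers; the mean per-sample ratio is logged alongside because the
  averaging order is a modelling choice (they differ at a few percent for
  small chains).
* Heat capacity: C_v/k = β²(⟨E²⟩ − ⟨E⟩²), two-pass variance.  Replicate
  means, never autocorrelated within-run samples, feed the standard errors.
* Scattering: the site–site correlation γ(r) is accumulated over exact
  integer squared-distance classes r² = du² + du·dv + dv² (no histogram
  binning); S(q) = Σ_r γ(r)·sin(qr)/(qr) with the r = 0 self term equal to
  γ(0) = 1, and the Kratky form q²S(q).  The sin(qr)/qr kernel is the 3D
  orientational average conventionally reported for this observable; a 2D
  Bessel kernel J0(qr) is available behind a flag for sensitivity checks.
  Default q grid: 60 log-spaced points in [2π/L, π].
* Bridging: a solvent site with ≥ 2 polymer neighbours whose contour indices
  differ by at least `min_contour_gap` (default 3 — contour-adjacent and
  next-adjacent contacts are trivially present in any compact state) counts
  as one bridge.  This is the diagnostic for solvent-mediated
  (bridging-induced) attraction in the polymer–solvent-attraction model.

## Scaling analysis

Heat-capacity maxima and asphericity minima on χ/z grids are located by a
quadratic fit through the five points around the discrete extremum, with the
vertex variance propagated from the weighted-fit covariance; a degenerate
quadratic falls back to the discrete extremum and is flagged.  Power laws
(T_p ~ N^α, C_v,max/kN ~ N^γ, ⟨R_g²⟩, ⟨R_ee²⟩ ~ N^{2ν}) are weighted least
squares of log y on log x.

For transition *locations* at small N the package also provides a
histogram-reweighting estimator: for the unit-depth presets χ/z equals the
inverse temperature β, so energy samples taken at a few anchor solvent
qualities reweight (Ferrenberg–Swendsen single-histogram, combined across
anchors with effective-sample-size weights) into a continuous C_v(χ/z)
curve whose argmax is far better determined than a five-point grid quadratic
at equal CPU cost.  Reweighted C_v was validated against exact enumeration
(N=4, L=6: agreement to ~1–2 % across kT ∈ [0.8, 1.25] from a single anchor
at kT = 1).  Anchors straddle the expected peak (single-trajectory
reweighting far from its anchor can inflate the variance from sparse energy
tails, pushing a spurious argmax to the window edge); the peak is read off
the replicate-averaged curve, with a delete-one jackknife over replicates
for the uncertainty.

## Validation scales and what they show

Full-scale sweeps (box 256², N up to 512, 2·10⁷ MCS, 8 replicates — the
`paper` profile, shipped in `configs/`) run for about a week per state point
on one CPU and are not exercised by the test suite.  The routine validation
uses:

* exact enumeration (N ≤ 6, L ≤ 8) as ground truth for the sampler — the
  strongest check, sensitive to sub-percent bias;
* athermal self-avoiding-walk scaling over N = 16…128 in boxes with edge
  ≳ 2.5·N^{3/4} (≈ 2.8 times the coil diameter, the same box-to-coil ratio
  as the 256² box gives the longest headline chains), with run lengths set
  from measured integrated autocorrelation times of R_g²
  (τ ≈ N² MCS; production of 2·10⁴…9·10⁴ MCS × 4 replicates);
* collapsed-regime scaling (poor preset, χ/z = 1) for N = 16, 32, 64 with
  5·10⁴ MCS equilibration and production, 4 replicates — the globule's R_g²
  autocorrelation (τ ≈ 5·10³ MCS at N = 64) makes these precise at the
  percent level;
* transition phenomenology (C_v peaks against χ/z) for N = 16, 32, 64 by
  the reweighting estimator at three anchors around the expected peaks.

Small chains, reduced boxes and 10⁴–10⁵ MCS runs reproduce exponents with
finite-size and statistical tolerances of order 0.05–0.15; they certify the
machinery, not the asymptotic values.  What these scales cannot show:
asymptotic (N → ∞) exponents, the deep non-monotonic size regime of long
chains in the polymer–solvent-attraction model at χ/z < −1 (visible only for
N ≳ 128), and any quantity requiring the 256² box.

## Numerical and design choices

* Walk cap 4L² displacements / 16L² draws; capped walks are rejected
  attempts (identical forward/reverse truncation preserves balance).
* Chain observables use unwrapped coordinates; no minimal-image corrections
  are ever applied to intrachain distances (valid while 2√⟨R_g²⟩ ≪ L, which
  the parameter layer warns about rather than enforcing — exact-enumeration
  boxes legitimately violate the coil guard).
* The undirected-chain convention (a conformation and its bead-order
  reversal are one state) is applied consistently in the enumeration oracle;
  all reported observables are reversal-symmetric, so the sampler needs no
  correction.
* Extremum location falls back to the discrete grid point (flagged) when
  the local quadratic has the wrong curvature or its vertex leaves the
  window.
* Degenerate inputs fail loudly: χ = 0 has no finite temperature (run the
  athermal mode), a single-point chain has no asphericity, power-law fits
  reject non-positive data.

## Known limitations

* Loop acceptance rates drop in deeply quenched states; no cluster or
  tempering moves are provided.
* The reweighting estimator assumes unit-depth presets (|E_PS − (E_PP +
  E_SS)/2| = 1); free-form triples fall back to grid-based extremum location.
* The asphericity-minimum "semi-exponential" N-dependence reported for the
  polymer–solvent-attraction model is not fitted (its functional form is
  underdetermined); minima locations are exported so any model can be fitted
  downstream.
* Ergodicity of the move set is verified exhaustively only for tiny chains
  (every N=4 shape class on L=5 is visited); for long chains it rests on the
  combination of reptation, kink/end flips and solvent transport, as in the
  general cooperative-motion literature.
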