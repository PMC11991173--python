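"""Cooperative Motion Algorithm sampler for the fully occupied lattice.

Because every site carries a particle, single-particle moves are impossible:
rearrangements happen along closed loops with zero net displacement.  A loop
is constructed with a temporary vacancy (TV):

1. a site is drawn uniformly over the box; its (solvent) element is
   temporarily removed, creating the vacancy;
2. the TV picks one of its six neighbour directions uniformly at random;
3. a solvent molecule at the chosen site simply hops into the vacancy;
   a chain bead can only move if chain continuity survives -- the bead hops
   into the vacancy and the chain slides along its own contour behind it,
   i.e. the TV travels *along the chain*;
4. the TV leaves the chain at the first point where the chain is whole
   again: past a chain end, or at a tight (60 degree) fold where the contour
   loops back on itself; from there it resumes free directional choice;
5. the walk terminates when the TV re-enters its origin site, closing the
   loop; the held element is restored there.

Each element moved hops exactly one lattice vector, and the displacement
vectors of a closed loop sum to zero (the continuity condition).  Temperature
enters through a Metropolis-Hastings test on the *net* energy change of a
completed loop: accept with probability

    min(1, exp(-dE/kT) * (6 - b_initial)/(6 - b_final)),

where b_initial and b_final count the blocked directions at the origin
vacancy in the initial and final states.  The second factor compensates the
proposal asymmetry introduced by null steps (blocked draws): each realisable
outcome of a rest state is drawn with probability 1/(6 - b), and the product
of these factors along any walk telescopes down to the two endpoint states.
Without the correction, fold-rich (locally compact) conformations are
measurably under-sampled.  Athermal runs keep the proposal-correction factor
and drop only the Boltzmann factor.  Correctness is certified against exact
enumeration on tiny systems (see :mod:`polycma.enumeration`).

Concrete rules at a bead encounter (vacancy at V, bead k at the chosen
neighbour site):

* if both chain neighbours of k (or the single one, for an end bead) sit
  adjacent to V, bead k alone hops into V -- a kink flip or end flip;
* if exactly one side stays bonded, the tail on the other side slides one
  position along the contour toward the vacancy, stopping at the first fold
  or at the chain end (partial or full reptation);
* if neither side stays bonded the direction is blocked and the draw is a
  null step (the TV stays put).

A walk that fails to close within ``max_loop_factor * L^2`` element
displacements is abandoned and counts as a rejected attempt, as does drawing
a polymer bead as the TV origin (removing a bead would sever the chain for
the whole walk; solvent origins keep the chain intact at every rest point,
and bead moves still occur whenever the TV meets the chain).

One Monte Carlo step (MCS) is an attempted move of each element on average:
every element displacement attempted during loop construction accumulates
until the total reaches L^2, whether or not the loop is eventually accepted
(a null attempt contributes its origin element).  MCS is thus an attempt
count, proportional to computational work; equilibrium averages do not depend
on the convention, only the meaning of one unit of Monte Carlo time does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .energetics import InteractionSet, chi_parameter, total_energy
from .lattice import (
    SOLVENT,
    VACANCY,
    Configuration,
    LatticeSpec,
    init_chain,
)

_U64 = np.uint64
_GAMMA = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)

# counters layout
_ATTEMPTS, _ACCEPTED, _ELEMENTS, _NEXT_MARK, _NSAMP, _ACC_HOPS, _CLOSED = range(7)
N_COUNTERS = 8


@njit(inline="always")
def _next64(rs):
    rs[0] = rs[0] + _GAMMA
    z = rs[0]
    z = (z ^ (z >> _U64(30))) * _MIX1
    z = (z ^ (z >> _U64(27))) * _MIX2
    return z ^ (z >> _U64(31))


@njit(inline="always")
def _rand_below(rs, n):
    x = _next64(rs) >> _U64(32)
    return np.int64((x * _U64(n)) >> _U64(32))


@njit(inline="always")
def _rand_f64(rs):
    return (_next64(rs) >> _U64(11)) * 1.1102230246251565e-16  # 2**-53


@njit(inline="always")
def _unit_delta(a, b, L):
    """Axial offset of adjacent site b relative to a, in {-1, 0, 1}^2."""
    du = (b // L - a // L) % L
    if du > 1:
        du -= L
    dv = (b % L - a % L) % L
    if dv > 1:
        dv -= L
    return du, dv


@njit(inline="always")
def _adjacent(nbr, a, b):
    for t in range(6):
        if nbr[a, t] == b:
            return True
    return False


@njit(inline="always")
def _hop(occ, pos, nbr, pairE, y, v, need_e):
    """Move the element at y into the vacancy at v; return its energy change."""
    a = occ[y]
    dE = 0.0
    if need_e:
        s = 1 if a >= 0 else 0
        for t in range(6):
            n = nbr[v, t]
            if n != y:
                dE += pairE[s, 1 if occ[n] >= 0 else 0]
            m = nbr[y, t]
            if m != v:
                dE -= pairE[s, 1 if occ[m] >= 0 else 0]
    occ[v] = a
    occ[y] = VACANCY
    if a >= 0:
        pos[a] = v
    return dE


@njit
def _slide(occ, pos, nbr, pairE, k, step, v, hop_from, hop_to, nh, L, need_e):
    """Slide the chain tail starting at bead k toward the vacancy at v.

    Beads k, k+step, ... successively advance one contour position; the TV
    exits at the first site where the chain is whole again (a 60-degree fold)
    or past the chain end.  Returns (new vacancy site, hop count, dE, and the
    TV's net axial displacement along the chain).
    """
    n_beads = pos.shape[0]
    y = pos[k]
    du, dv = _unit_delta(v, y, L)
    dE = _hop(occ, pos, nbr, pairE, y, v, need_e)
    hop_from[nh] = y
    hop_to[nh] = v
    nh += 1
    prev = y
    j = k + step
    while 0 <= j < n_beads:
        if _adjacent(nbr, pos[j - step], pos[j]):
            break  # chain whole again: the TV exits at the fold
        y = pos[j]
        ddu, ddv = _unit_delta(prev, y, L)
        du += ddu
        dv += ddv
        dE += _hop(occ, pos, nbr, pairE, y, prev, need_e)
        hop_from[nh] = y
        hop_to[nh] = prev
        nh += 1
        prev = y
        j += step
    return prev, nh, dE, du, dv


@njit
def _blocked_count(occ, pos, nbr, v):
    """Directions from the vacancy v whose target bead cannot move at all.

    A draw toward a mid-chain bead with neither chain neighbour adjacent to
    the vacancy is a null step.  Null steps make the effective probability of
    each realisable outcome 1/(6 - b); over a whole walk these factors
    telescope, leaving the ratio of forward and reverse proposal
    probabilities (6 - b_initial)/(6 - b_final) evaluated at the origin
    vacancy, which the acceptance rule must compensate (Metropolis-Hastings).
    """
    n_beads = pos.shape[0]
    b = 0
    for t in range(6):
        k = occ[nbr[v, t]]
        if k >= 0:
            lo = (k == n_beads - 1) or _adjacent(nbr, pos[k + 1], v)
            hi = (k == 0) or _adjacent(nbr, pos[k - 1], v)
            if not (lo or hi):
                b += 1
    return b


@njit
def _revert(occ, pos, hop_from, hop_to, nh):
    for i in range(nh - 1, -1, -1):
        y = hop_from[i]
        v = hop_to[i]
        a = occ[v]
        occ[y] = a
        occ[v] = VACANCY
        if a >= 0:
            pos[a] = y


@njit
def _attempt(occ, pos, nbr, pairE, rs, hop_from, hop_to, max_hops, need_e):
    """One TV loop-construction attempt; mutates the configuration in place.

    Returns (closed, n_hops, dE, origin, b_initial, b_final) where the b's
    are the blocked-direction counts at the origin vacancy before the first
    draw and at closure (see :func:`_blocked_count`).  On failure (bead
    origin, unclosed walk, displacement cap) the configuration is restored
    before returning.
    """
    n_sites = occ.shape[0]
    n_beads = pos.shape[0]
    origin = _rand_below(rs, n_sites)
    if occ[origin] >= 0:
        return False, np.int64(0), 0.0, origin, 0, 0
    occ[origin] = VACANCY
    b0 = _blocked_count(occ, pos, nbr, origin)
    dE = 0.0
    if need_e:
        for t in range(6):
            n = nbr[origin, t]
            dE -= pairE[0, 1 if occ[n] >= 0 else 0]
    v = origin
    L = np.int64(np.sqrt(n_sites) + 0.5)
    twu = np.int64(0)  # TV winding relative to the origin
    twv = np.int64(0)
    nh = np.int64(0)
    closed = False
    draws = 0
    draw_cap = 4 * max_hops
    while draws < draw_cap:
        draws += 1
        d = _rand_below(rs, 6)
        y = nbr[v, d]
        a = occ[y]
        if a == SOLVENT:
            ddu, ddv = _unit_delta(v, y, L)
            twu += ddu
            twv += ddv
            dE += _hop(occ, pos, nbr, pairE, y, v, need_e)
            hop_from[nh] = y
            hop_to[nh] = v
            nh += 1
            v = y
        else:
            k = a
            lo_ok = (k == n_beads - 1) or _adjacent(nbr, pos[k + 1], v)
            hi_ok = (k == 0) or _adjacent(nbr, pos[k - 1], v)
            if lo_ok and hi_ok:
                # kink or end flip: bead k alone hops into the vacancy
                ddu, ddv = _unit_delta(v, y, L)
                twu += ddu
                twv += ddv
                dE += _hop(occ, pos, nbr, pairE, y, v, need_e)
                hop_from[nh] = y
                hop_to[nh] = v
                nh += 1
                v = y
            elif hi_ok:
                v, nh, de_s, ddu, ddv = _slide(
                    occ, pos, nbr, pairE, k, 1, v, hop_from, hop_to, nh, L, need_e
                )
                dE += de_s
                twu += ddu
                twv += ddv
            elif lo_ok:
                v, nh, de_s, ddu, ddv = _slide(
                    occ, pos, nbr, pairE, k, -1, v, hop_from, hop_to, nh, L, need_e
                )
                dE += de_s
                twu += ddu
                twv += ddv
            else:
                continue  # blocked direction: null step
        if v == origin and twu == 0 and twv == 0:
            # true closure: the TV is back with zero winding, so the
            # displacement vectors of all moved elements sum to zero exactly
            closed = True
            break
        if nh >= max_hops:
            break
    if closed:
        b1 = _blocked_count(occ, pos, nbr, origin)
        occ[origin] = SOLVENT
        if need_e:
            for t in range(6):
                n = nbr[origin, t]
                dE += pairE[0, 1 if occ[n] >= 0 else 0]
        return True, nh, dE, origin, b0, b1
    _revert(occ, pos, hop_from, hop_to, nh)
    occ[origin] = SOLVENT
    return False, nh, 0.0, origin, b0, b0


@njit
def _run(
    occ,
    pos,
    nbr,
    pairE,
    beta,
    athermal,
    quota_end,
    sample_every_attempts,
    attempts_start,
    rs,
    hop_from,
    hop_to,
    max_hops,
    counters,
    ecur,
    samples_E,
    samples_pos,
    samples_elements,
):
    # Two stopping modes: an element quota (equilibration), or a fixed number
    # of samples taken every `sample_every_attempts` attempts (production).
    # Samples are scheduled on the attempt clock: at stationarity the state
    # after any fixed number of attempts is distributed as the target
    # ensemble, whereas triggering on element-count marks oversamples states
    # reached by large loops (size-biased crossing attempt).
    n_target = samples_E.shape[0]
    while True:
        if sample_every_attempts > 0:
            if counters[_NSAMP] >= n_target:
                break
        elif counters[_ELEMENTS] >= quota_end:
            break
        closed, nh, dE, origin, b0, b1 = _attempt(
            occ, pos, nbr, pairE, rs, hop_from, hop_to, max_hops, not athermal
        )
        counters[_ATTEMPTS] += 1
        if closed:
            counters[_CLOSED] += 1
            # Metropolis-Hastings on the completed loop: the Boltzmann factor
            # times the proposal-asymmetry correction (6-b0)/(6-b1) from the
            # null-step statistics at the origin vacancy.
            accept = True
            if b1 != b0 or ((not athermal) and dE > 0.0):
                p = (6.0 - b0) / (6.0 - b1)
                if not athermal:
                    p *= np.exp(-beta * dE)
                if p < 1.0 and _rand_f64(rs) >= p:
                    accept = False
            if accept:
                counters[_ACCEPTED] += 1
                counters[_ACC_HOPS] += nh
                ecur[0] += dE
            else:
                occ[origin] = VACANCY
                _revert(occ, pos, hop_from, hop_to, nh)
                occ[origin] = SOLVENT
        # every element displacement attempted counts toward the MCS quota,
        # whether the loop was accepted, rejected or abandoned; a null
        # attempt (bead origin) counts its origin element
        counters[_ELEMENTS] += nh if nh > 0 else 1
        if (
            sample_every_attempts > 0
            and (counters[_ATTEMPTS] - attempts_start) % sample_every_attempts
            == 0
        ):
            i = counters[_NSAMP]
            if i < n_target:
                samples_E[i] = ecur[0]
                samples_elements[i] = counters[_ELEMENTS]
                for k in range(pos.shape[0]):
                    samples_pos[i, k] = pos[k]
                counters[_NSAMP] += 1


# ---------------------------------------------------------------------------
# python-level API
# ---------------------------------------------------------------------------


@dataclass
class LoopMove:
    """A completed (or failed) cooperative loop rearrangement.

    ``hops_from[i] -> hops_to[i]`` is the i-th element displacement (one
    lattice vector each); replaying them in order transforms the originating
    configuration, replaying them backwards restores it exactly.
    """

    origin: int
    hops_from: np.ndarray
    hops_to: np.ndarray
    dE: float
    closed: bool
    accepted: bool | None = None
    b_initial: int = 0  # blocked directions at the origin vacancy, before
    b_final: int = 0  # ... and at closure (proposal-asymmetry correction)

    @property
    def proposal_correction(self) -> float:
        """q(B->A)/q(A->B) = (6 - b_initial)/(6 - b_final)."""
        return (6.0 - self.b_initial) / (6.0 - self.b_final)

    @property
    def loop_length(self) -> int:
        return int(self.hops_from.shape[0])

    def displacement_sum(self, L: int) -> tuple[int, int]:
        """Net axial displacement of all moved elements (minimal image)."""
        if self.loop_length == 0:
            return (0, 0)
        fu, fv = np.divmod(self.hops_from.astype(np.int64), L)
        tu, tv = np.divmod(self.hops_to.astype(np.int64), L)
        du = (tu - fu + L // 2) % L - L // 2
        dv = (tv - fv + L // 2) % L - L // 2
        return int(du.sum()), int(dv.sum())


@dataclass
class McsCounter:
    """Monte Carlo time accounting: mcs = elements_moved / L^2."""

    n_sites: int
    attempts: int = 0
    accepted: int = 0
    closed: int = 0
    elements_moved: int = 0
    accepted_hops: int = 0

    @property
    def mcs(self) -> float:
        return self.elements_moved / self.n_sites

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.attempts if self.attempts else float("nan")

    @property
    def mean_loop_length(self) -> float:
        return (
            self.accepted_hops / self.accepted if self.accepted else float("nan")
        )


def metropolis_accept(dE: float, kT: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dE/kT)); kT = inf always accepts."""
    if dE <= 0.0 or not np.isfinite(kT):
        return True
    if kT <= 0:
        raise ValueError("kT must be positive (or inf for athermal)")
    return bool(rng.random() < np.exp(-dE / kT))


def apply_loop(config: Configuration, move: LoopMove) -> None:
    """Replay a closed loop's hops on a configuration (in place)."""
    occ, pos = config.occ, config.chain_sites
    occ[move.origin] = VACANCY
    for f, t in zip(move.hops_from, move.hops_to):
        a = occ[f]
        occ[t] = a
        occ[f] = VACANCY
        if a >= 0:
            pos[a] = t
    occ[move.origin] = SOLVENT


def revert_loop(config: Configuration, move: LoopMove) -> None:
    """Undo :func:`apply_loop` exactly."""
    occ, pos = config.occ, config.chain_sites
    occ[move.origin] = VACANCY
    for i in range(move.loop_length - 1, -1, -1):
        f, t = move.hops_from[i], move.hops_to[i]
        a = occ[t]
        occ[f] = a
        occ[t] = VACANCY
        if a >= 0:
            pos[a] = f
    occ[move.origin] = SOLVENT


def build_loop(
    config: Configuration,
    rng_state: np.ndarray | int,
    max_len: int | None = None,
    interactions: InteractionSet | None = None,
) -> LoopMove:
    """Construct one TV loop without leaving the configuration modified.

    ``rng_state`` is either a 1-element uint64 array (advanced in place) or
    an integer seed.  The returned move carries the net energy change under
    ``interactions`` (athermal if omitted).
    """
    if isinstance(rng_state, (int, np.integer)):
        rng_state = seed_state(int(rng_state))
    if interactions is None:
        interactions = InteractionSet.athermal()
    n_sites = config.L * config.L
    max_hops = 4 * n_sites if max_len is None else int(max_len)
    hop_from = np.empty(max_hops + config.n_beads + 8, dtype=np.int32)
    hop_to = np.empty_like(hop_from)
    closed, nh, dE, origin, b0, b1 = _attempt(
        config.occ,
        config.chain_sites,
        config.nbr,
        interactions.pair_matrix(),
        rng_state,
        hop_from,
        hop_to,
        max_hops,
        True,
    )
    move = LoopMove(
        origin=int(origin),
        hops_from=hop_from[:nh].copy(),
        hops_to=hop_to[:nh].copy(),
        dE=float(dE),
        closed=bool(closed),
        b_initial=int(b0),
        b_final=int(b1),
    )
    if closed:  # leave the caller's configuration untouched
        revert_loop(config, move)
    return move


def seed_state(seed: int, *keys: int) -> np.ndarray:
    """Derive a warmed-up uint64 RNG state from a small integer seed."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[int(k) for k in keys]])
    word = int(ss.generate_state(1, np.uint64)[0])
    rs = np.array([word], dtype=np.uint64)
    _next64(rs)
    return rs


class CmaSampler:
    """Stateful CMA driver bound to one configuration and interaction set."""

    def __init__(
        self,
        config: Configuration,
        interactions: InteractionSet,
        seed: int = 0,
        max_loop_factor: float = 4.0,
        rng_state: np.ndarray | None = None,
    ):
        self.config = config
        self.interactions = interactions
        n_sites = config.L * config.L
        self.n_sites = n_sites
        self.max_hops = max(int(max_loop_factor * n_sites), 64)
        self._hop_from = np.empty(
            self.max_hops + config.n_beads + 8, dtype=np.int32
        )
        self._hop_to = np.empty_like(self._hop_from)
        self.rs = rng_state if rng_state is not None else seed_state(seed)
        self.counters = np.zeros(N_COUNTERS, dtype=np.int64)
        self._quota = 0  # element-quota cursor; carries loop overshoot
        self.ecur = np.array(
            [total_energy(config, interactions)], dtype=np.float64
        )

    @property
    def energy(self) -> float:
        return float(self.ecur[0])

    @property
    def counter(self) -> McsCounter:
        c = self.counters
        return McsCounter(
            n_sites=self.n_sites,
            attempts=int(c[_ATTEMPTS]),
            accepted=int(c[_ACCEPTED]),
            closed=int(c[_CLOSED]),
            elements_moved=int(c[_ELEMENTS]),
            accepted_hops=int(c[_ACC_HOPS]),
        )

    def set_interactions(self, interactions: InteractionSet) -> None:
        self.interactions = interactions
        self.ecur[0] = total_energy(self.config, interactions)

    def run(
        self, n_mcs: int, sample_interval_mcs: int = 0
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Advance ``n_mcs`` Monte Carlo steps (one MCS = L^2 attempted
        element displacements).

        With a positive ``sample_interval_mcs``, records ``n_mcs //
        sample_interval_mcs`` samples of (E, chain sites, elapsed mcs), taken
        every fixed number of *attempts*.  The attempt interval is converted
        from the requested MCS interval using the mean elements-per-attempt
        observed so far (a short calibration burst is run if there is no
        history), because a sampling clock driven by element-count marks
        would oversample states reached by large loops.
        """
        if n_mcs <= 0:
            raise ValueError("n_mcs must be positive")
        inter = self.interactions
        if sample_interval_mcs > 0:
            if self.counters[_ATTEMPTS] == 0:
                self.run(max(1, min(20, n_mcs)))  # calibration burst
            per_attempt = max(
                float(self.counters[_ELEMENTS]) / float(self.counters[_ATTEMPTS]),
                1.0,
            )
            n_samples = n_mcs // sample_interval_mcs
            every_attempts = max(
                1, round(sample_interval_mcs * self.n_sites / per_attempt)
            )
        else:
            n_samples = 0
            every_attempts = 0
        # the element quota carries loop overshoot across calls, so that k
        # successive 1-MCS calls advance the clock by k MCS on average
        self._quota += n_mcs * self.n_sites
        quota_end = self._quota
        self.counters[_NSAMP] = 0
        samples_E = np.empty(n_samples, dtype=np.float64)
        samples_pos = np.empty(
            (n_samples, self.config.n_beads), dtype=np.int32
        )
        samples_elements = np.empty(n_samples, dtype=np.int64)
        _run(
            self.config.occ,
            self.config.chain_sites,
            self.config.nbr,
            inter.pair_matrix(),
            inter.beta,
            inter.is_athermal,
            quota_end,
            every_attempts,
            int(self.counters[_ATTEMPTS]),
            self.rs,
            self._hop_from,
            self._hop_to,
            self.max_hops,
            self.counters,
            self.ecur,
            samples_E,
            samples_pos,
            samples_elements,
        )
        got = int(self.counters[_NSAMP])
        if sample_interval_mcs > 0:
            # production ran on the attempt clock; resync the element cursor
            self._quota = int(self.counters[_ELEMENTS])
        return (
            samples_E[:got],
            samples_pos[:got],
            samples_elements[:got] / self.n_sites,
        )

    def run_mcs(self, n: int = 1) -> None:
        """Advance exactly ``n`` MCS (no sampling)."""
        self.run(n)


@dataclass
class SimulationParams:
    """One production run at a single state point."""

    n_beads: int
    box: int
    interactions: InteractionSet
    n_equil_mcs: int
    n_prod_mcs: int
    sample_interval_mcs: int
    seed: int = 0
    n_athermal_mcs: int | None = None  # default: max(1000, N^2 / 4)
    max_loop_factor: float = 4.0

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError("n_beads must be >= 2")
        if self.box < 3:
            raise ValueError("box must be >= 3")
        if self.n_beads > self.box * self.box:
            raise ValueError("more beads than lattice sites")
        for name in ("n_equil_mcs", "n_prod_mcs", "sample_interval_mcs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.sample_interval_mcs == 0 or (
            self.n_prod_mcs and self.sample_interval_mcs > self.n_prod_mcs
        ):
            raise ValueError(
                "sample_interval_mcs must be in [1, n_prod_mcs]"
            )
        if not isinstance(self.interactions, InteractionSet):
            raise TypeError("interactions must be an InteractionSet")

    @property
    def athermal_mcs(self) -> int:
        if self.n_athermal_mcs is not None:
            return self.n_athermal_mcs
        return max(1000, self.n_beads * self.n_beads // 4)


@dataclass
class SimulationResult:
    records: pd.DataFrame
    final_config: Configuration
    params: SimulationParams
    counter: McsCounter
    chi_over_z: float


def run_simulation(params: SimulationParams) -> SimulationResult:
    """Full single-run protocol: build, athermal relax, equilibrate, produce.

    The chain is grown as a self-avoiding walk, relaxed without interactions
    (excluded volume only), then the interactions are switched on, the system
    is equilibrated for ``n_equil_mcs`` and sampled every
    ``sample_interval_mcs`` during ``n_prod_mcs`` of production.  Fully
    reproducible from the seed.
    """
    from .observables import bridge_counts, chain_observables

    rs = seed_state(params.seed)
    # chain growth uses a numpy Generator derived from the same seed stream
    grow_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([params.seed & 0x7FFFFFFF, 0xC0FFEE]))
    )
    config = init_chain(params.n_beads, LatticeSpec(params.box), grow_rng)
    sampler = CmaSampler(
        config,
        InteractionSet.athermal(),
        max_loop_factor=params.max_loop_factor,
        rng_state=rs,
    )
    if params.athermal_mcs > 0:
        sampler.run(params.athermal_mcs)
    sampler.set_interactions(params.interactions)
    if params.n_equil_mcs > 0:
        sampler.run(params.n_equil_mcs)
    prod_start_mcs = sampler.counter.mcs
    energies, positions, mcs_at = sampler.run(
        params.n_prod_mcs, params.sample_interval_mcs
    )
    records = chain_observables(params.box, positions)
    records.insert(0, "E", energies)
    records.insert(0, "mcs", mcs_at - prod_start_mcs)
    records["bridges"] = bridge_counts(
        params.box, positions, nbr=config.nbr
    )
    return SimulationResult(
        records=records,
        final_config=config,
        params=params,
        counter=sampler.counter,
        chi_over_z=chi_parameter(params.interactions).chi_over_z,
    )


def replicate_seed(seed: int, replicate: int) -> int:
    """Stable per-replicate seed derivation (kept below 2^31)."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int(replicate)])
    return int(ss.generate_state(1, np.uint64)[0] & 0x7FFFFFFF)
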