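"""Exact brute-force equilibrium averages for tiny chains.

Every self-avoiding placement of an N-bead chain on the L x L torus is
enumerated (translations included; bead-order reversal counted once), the
remaining sites are filled with solvent, and Boltzmann-weighted averages of
the energy, heat capacity and chain-size observables are formed.  Energies
and observables go through exactly the same code path as the production
sampler (:func:`polycma.energetics.total_energy` and
:mod:`polycma.observables`), so these numbers are the ground truth that the
Cooperative Motion sampler must reproduce.

The fully packed lattice fixes the total number of contact pairs at 3 L^2,
so the exact energies depend only on the chain's own contact counts; this is
exploited nowhere -- the oracle deliberately pays for the full pair sum to
stay on the shared code path.

Guards keep the enumeration at N <= 6 and L <= 8, where the conformation
count stays in the tens of thousands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .energetics import InteractionSet, total_energy
from .lattice import Configuration, build_neighbor_table, unwrap_chain
from .observables import end_to_end_sq, radius_of_gyration_sq

MAX_N = 6
MAX_L = 8


def _check_guard(N: int, L: int) -> None:
    if not (1 <= N <= MAX_N):
        raise ValueError(f"enumeration limited to 1 <= N <= {MAX_N}, got {N}")
    if not (3 <= L <= MAX_L):
        raise ValueError(f"enumeration limited to 3 <= L <= {MAX_L}, got {L}")


def enumerate_conformations(N: int, L: int) -> Iterator[np.ndarray]:
    """Yield every distinct self-avoiding N-bead placement on the torus.

    Placements are ordered site tuples; the two bead orderings of the same
    undirected chain are counted once (the lexicographically smaller of the
    tuple and its reverse is yielded).  For N = 1 all L^2 single-site
    placements are yielded (test mode).
    """
    _check_guard(N, L)
    nbr = build_neighbor_table(L)
    chain = np.empty(N, dtype=np.int32)
    taken = np.zeros(L * L, dtype=bool)

    def grow(k: int):
        if k == N:
            t = tuple(chain.tolist())
            if t <= t[::-1]:
                yield chain.copy()
            return
        for t in range(6):
            s = int(nbr[chain[k - 1], t])
            if not taken[s]:
                chain[k] = s
                taken[s] = True
                yield from grow(k + 1)
                taken[s] = False

    for s0 in range(L * L):
        chain[0] = s0
        if N == 1:
            yield chain[:1].copy()
            continue
        taken[s0] = True
        yield from grow(1)
        taken[s0] = False


@dataclass
class EnumerationResult:
    """Exact canonical-ensemble averages for one tiny system."""

    N: int
    L: int
    interactions: InteractionSet
    kT: float
    n_conformations: int
    partition_sum: float  # relative to the minimum-energy conformation
    E_mean: float
    E2_mean: float
    Cv_per_k: float
    Rg2_mean: float
    Ree2_mean: float

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "L": self.L,
            "kT": self.kT,
            "e_pp": self.interactions.e_pp,
            "e_ps": self.interactions.e_ps,
            "e_ss": self.interactions.e_ss,
            "n_conformations": self.n_conformations,
            "partition_sum": self.partition_sum,
            "E_mean": self.E_mean,
            "E2_mean": self.E2_mean,
            "Cv_per_k": self.Cv_per_k,
            "Rg2_mean": self.Rg2_mean,
            "Ree2_mean": self.Ree2_mean,
        }


def exact_averages(
    N: int, L: int, interactions: InteractionSet
) -> EnumerationResult:
    """Boltzmann-weighted averages over every conformation on the torus."""
    _check_guard(N, L)
    beta = interactions.beta
    energies = []
    rg2 = []
    ree2 = []
    for chain in enumerate_conformations(N, L):
        cfg = Configuration.from_chain_sites(L, chain)
        energies.append(total_energy(cfg, interactions))
        rg2.append(radius_of_gyration_sq(cfg))
        ree2.append(end_to_end_sq(cfg) if N > 1 else 0.0)
    e = np.asarray(energies)
    rg2 = np.asarray(rg2)
    ree2 = np.asarray(ree2)
    w = np.exp(-beta * (e - e.min()))
    z = w.sum()
    p = w / z
    e_mean = float(p @ e)
    e2_mean = float(p @ (e * e))
    return EnumerationResult(
        N=N,
        L=L,
        interactions=interactions,
        kT=interactions.kT,
        n_conformations=int(e.size),
        partition_sum=float(z),
        E_mean=e_mean,
        E2_mean=e2_mean,
        Cv_per_k=beta * beta * (e2_mean - e_mean * e_mean),
        Rg2_mean=float(p @ rg2),
        Ree2_mean=float(p @ ree2),
    )


def shape_class(chain_sites, L: int) -> tuple:
    """Translation-invariant conformation key: bond vectors up to reversal."""
    w = unwrap_chain(np.asarray(chain_sites, dtype=np.int64), L)
    bonds = [tuple(b) for b in np.diff(w, axis=0).tolist()]
    rev = [(-a, -b) for a, b in reversed(bonds)]
    return tuple(min(bonds, rev))
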