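"""Square-well contact energies and Flory-Huggins solvent-quality bookkeeping.

The only interactions are nearest-neighbour contact energies between the two
species, polymer (P) and solvent (S): E_PP, E_PS and E_SS, in units of the
well depth (k = 1, temperatures are kT in the same units).  Two presets match
the standard model choices:

    poor solvent:  E_PP = E_SS = -1, E_PS = 0   (chi > 0)
    good solvent:  E_PS = -1, E_PP = E_SS = 0   (chi < 0)

Solvent quality is measured by the Flory-Huggins parameter

    chi = (z / kT) * (E_PS - (E_PP + E_SS) / 2),        z = 6,

equivalently chi / z = eps_PS - (eps_PP + eps_SS) / 2 with eps = E / kT.

Bonded consecutive beads occupy adjacent sites and *are* counted as a P-P
contact pair; this adds the constant (N-1)*E_PP to every configuration's
energy, which cancels in all energy differences and in the heat capacity, so
the convention is observationally equivalent to excluding them.  Energies of
the presets are exact small integers, and float64 arithmetic on them is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import Z, Configuration

#: directions 0, 2, 4 of AXIAL_OFFSETS ((1,0), (0,1), (1,-1)) cover every
#: unordered nearest-neighbour pair exactly once.
_HALF_DIRECTIONS = (0, 2, 4)


@dataclass(frozen=True)
class InteractionSet:
    """The three contact energies plus the temperature (k = 1)."""

    e_pp: float
    e_ps: float
    e_ss: float
    kT: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kT > 0):
            raise ValueError(f"kT must be positive, got {self.kT}")

    @classmethod
    def poor(cls, kT: float = 1.0) -> "InteractionSet":
        """Polymer-polymer and solvent-solvent attraction (chi > 0)."""
        return cls(e_pp=-1.0, e_ps=0.0, e_ss=-1.0, kT=kT)

    @classmethod
    def good(cls, kT: float = 1.0) -> "InteractionSet":
        """Polymer-solvent attraction only (chi < 0)."""
        return cls(e_pp=0.0, e_ps=-1.0, e_ss=0.0, kT=kT)

    @classmethod
    def athermal(cls) -> "InteractionSet":
        """Excluded volume only; every contact energy vanishes."""
        return cls(e_pp=0.0, e_ps=0.0, e_ss=0.0, kT=1.0)

    @classmethod
    def from_preset(cls, name: str, kT: float = 1.0) -> "InteractionSet":
        name = name.lower()
        if name == "poor":
            return cls.poor(kT)
        if name == "good":
            return cls.good(kT)
        if name == "athermal":
            return cls.athermal()
        raise ValueError(f"unknown preset {name!r} (poor, good, athermal)")

    @property
    def beta(self) -> float:
        return 1.0 / self.kT

    @property
    def is_athermal(self) -> bool:
        return self.e_pp == self.e_ps == self.e_ss == 0.0

    def energy_magnitude(self) -> float:
        """|E_PS - (E_PP + E_SS)/2|, the well-depth scale entering kT(chi)."""
        return abs(self.e_ps - 0.5 * (self.e_pp + self.e_ss))

    def pair_matrix(self) -> np.ndarray:
        """2x2 contact-energy lookup indexed by species (0 = S, 1 = P)."""
        return np.array(
            [[self.e_ss, self.e_ps], [self.e_ps, self.e_pp]], dtype=np.float64
        )

    def with_kT(self, kT: float) -> "InteractionSet":
        return InteractionSet(self.e_pp, self.e_ps, self.e_ss, kT)


@dataclass(frozen=True)
class SolventQuality:
    """chi, chi/z and the reduced-energy form eps_PS - (eps_PP + eps_SS)/2."""

    chi: float
    chi_over_z: float
    epsilon_form: float


def chi_parameter(interactions: InteractionSet) -> SolventQuality:
    """Flory-Huggins chi of an interaction set at its temperature."""
    eps = (
        interactions.e_ps - 0.5 * (interactions.e_pp + interactions.e_ss)
    ) / interactions.kT
    return SolventQuality(chi=Z * eps, chi_over_z=eps, epsilon_form=eps)


def temperature_from_chi(chi: float, interactions: InteractionSet) -> float:
    """kT at which the given interaction set produces the requested chi.

    kT = (z / chi) * |E_PS - (E_PP + E_SS)/2|.  The sign of chi must match
    the interaction set (kT > 0); chi = 0 (athermal limit) has no finite
    temperature and is run in athermal mode instead.
    """
    if chi == 0:
        raise ValueError("chi = 0 is the athermal limit; run athermal mode")
    mag = interactions.energy_magnitude()
    if mag == 0:
        raise ValueError("interaction set has zero energy scale (athermal)")
    kT = Z / chi * mag * np.sign(
        interactions.e_ps - 0.5 * (interactions.e_pp + interactions.e_ss)
    )
    if kT <= 0:
        raise ValueError(
            f"chi={chi} has the wrong sign for this interaction set"
        )
    return float(kT)


def kT_from_chi_over_z(chi_over_z: float, interactions: InteractionSet) -> float:
    return temperature_from_chi(Z * chi_over_z, interactions)


def contact_counts(config: Configuration) -> tuple[int, int, int]:
    """(n_PP, n_PS, n_SS) over all unordered nearest-neighbour site pairs."""
    occ = config.occ
    species = (occ >= 0).astype(np.int64)  # 1 = polymer, 0 = solvent
    n_pp = n_ps = n_ss = 0
    for d in _HALF_DIRECTIONS:
        other = species[config.nbr[:, d]]
        pair = species + other
        n_pp += int(np.count_nonzero(pair == 2))
        n_ps += int(np.count_nonzero(pair == 1))
        n_ss += int(np.count_nonzero(pair == 0))
    return n_pp, n_ps, n_ss


def total_energy(config: Configuration, interactions: InteractionSet) -> float:
    """Sum of contact energies over all unordered nearest-neighbour pairs."""
    n_pp, n_ps, n_ss = contact_counts(config)
    return (
        interactions.e_pp * n_pp
        + interactions.e_ps * n_ps
        + interactions.e_ss * n_ss
    )


def energy_delta(
    config: Configuration,
    move,
    interactions: InteractionSet,
) -> float:
    """total_energy(after) - total_energy(before) for a loop rearrangement.

    ``move`` is a :class:`polycma.cma.LoopMove`; the configuration is applied
    and reverted, and the difference is computed by direct pair summation.
    This is the reference (brute-force) form; the sampler accumulates the
    same quantity incrementally during loop construction.
    """
    from .cma import apply_loop, revert_loop

    e0 = total_energy(config, interactions)
    apply_loop(config, move)
    e1 = total_energy(config, interactions)
    revert_loop(config, move)
    return e1 - e0
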