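"""Triangular-lattice geometry, periodic boundaries and chain configurations.

All objects (polymer beads and solvent molecules) live on the nodes of a
two-dimensional triangular lattice with coordination number z = 6.  Sites are
addressed by axial coordinates (u, v) with u, v in [0, L); the lattice is
periodic in both axial directions (a torus on the oblique cell).  The
Cartesian embedding

    x = u + v / 2,      y = v * sqrt(3) / 2

places the six neighbours of every site at Euclidean distance exactly 1.

A site index is ``s = u * L + v``.  Occupancy uses the convention

    occ[s] == SOLVENT (-1)   solvent molecule
    occ[s] == k >= 0         polymer bead number k (0-based contour index)

so that the box is completely filled: every site carries exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

Z = 6  # coordination number of the triangular lattice

SOLVENT = -1
VACANCY = -2  # transient marker used only inside the sampler

# Axial offsets of the six nearest neighbours.  With the Cartesian embedding
# above each offset is a unit vector.
AXIAL_OFFSETS = np.array(
    [(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)], dtype=np.int64
)

SQRT3_2 = np.sqrt(3.0) / 2.0


class AxialSite(NamedTuple):
    """Axial coordinates (u, v) of one lattice site, each in [0, L)."""

    u: int
    v: int


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the periodic triangular simulation box (L x L sites)."""

    L: int
    z: int = Z

    def __post_init__(self) -> None:
        if self.L < 3:
            raise ValueError(f"box edge must be >= 3, got L={self.L}")
        if self.z != Z:
            raise ValueError("the triangular lattice has z = 6")

    @property
    def n_sites(self) -> int:
        return self.L * self.L


def neighbors(site: tuple[int, int], lattice: LatticeSpec) -> list[tuple[int, int]]:
    """The six periodic-image neighbours of an axial site ``(u, v)``."""
    u, v = site
    L = lattice.L
    if not (0 <= u < L and 0 <= v < L):
        raise ValueError(f"site {site} outside box of edge {L}")
    return [((u + du) % L, (v + dv) % L) for du, dv in AXIAL_OFFSETS]


def build_neighbor_table(L: int) -> np.ndarray:
    """Site-index table ``nbr[s, d]`` of the 6 periodic neighbours of s."""
    u, v = np.divmod(np.arange(L * L, dtype=np.int64), L)
    cols = []
    for du, dv in AXIAL_OFFSETS:
        cols.append(((u + du) % L) * L + ((v + dv) % L))
    return np.stack(cols, axis=1).astype(np.int32)


def to_cartesian(u, v):
    """Cartesian embedding of axial coordinates (vectorised)."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    return u + 0.5 * v, SQRT3_2 * v


def squared_distance_class(a, b) -> np.ndarray:
    """Exact squared Euclidean separation of two *unwrapped* axial points.

    For axial separations (du, dv) the squared Cartesian distance is the
    integer quadratic form du^2 + du*dv + dv^2.
    """
    du = np.asarray(a[0] - b[0], dtype=np.int64)
    dv = np.asarray(a[1] - b[1], dtype=np.int64)
    return du * du + du * dv + dv * dv


@dataclass
class Configuration:
    """One fully packed system state: an N-bead chain plus solvent.

    ``chain_sites[k]`` is the site index of bead k; ``occ`` is the per-site
    occupancy described in the module docstring.  Unwrapped chain coordinates
    are reconstructed on demand by accumulating unit bond vectors from bead 0,
    which is exact because every bond is one of the six axial unit offsets and
    L > 2 makes the wrapped bond vector unambiguous.
    """

    lattice: LatticeSpec
    occ: np.ndarray
    chain_sites: np.ndarray
    _nbr: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def L(self) -> int:
        return self.lattice.L

    @property
    def n_beads(self) -> int:
        return int(self.chain_sites.shape[0])

    @property
    def nbr(self) -> np.ndarray:
        if self._nbr is None:
            self._nbr = build_neighbor_table(self.L)
        return self._nbr

    def site_uv(self, sites) -> tuple[np.ndarray, np.ndarray]:
        s = np.asarray(sites, dtype=np.int64)
        return s // self.L, s % self.L

    def unwrapped(self) -> np.ndarray:
        """Unwrapped axial coordinates of the chain, shape (N, 2), ints."""
        return unwrap_chain(self.chain_sites, self.L)

    def unwrapped_cartesian(self) -> np.ndarray:
        w = self.unwrapped()
        x, y = to_cartesian(w[:, 0], w[:, 1])
        return np.stack([x, y], axis=1)

    def copy(self) -> "Configuration":
        return Configuration(
            self.lattice, self.occ.copy(), self.chain_sites.copy(), self._nbr
        )

    @classmethod
    def from_chain_sites(cls, L: int, chain_sites) -> "Configuration":
        """Build a fully packed configuration from the ordered bead sites."""
        chain_sites = np.asarray(chain_sites, dtype=np.int32)
        occ = np.full(L * L, SOLVENT, dtype=np.int32)
        occ[chain_sites] = np.arange(chain_sites.shape[0], dtype=np.int32)
        return cls(LatticeSpec(L), occ, chain_sites)


def unwrap_chain(chain_sites: np.ndarray, L: int) -> np.ndarray:
    """Accumulate unit bond vectors into unwrapped axial coordinates."""
    s = np.asarray(chain_sites, dtype=np.int64)
    u, v = s // L, s % L
    # Wrapped bond deltas mapped into {-1, 0, 1} (valid because L > 2).
    du = (np.diff(u) + L // 2) % L - L // 2
    dv = (np.diff(v) + L // 2) % L - L // 2
    w = np.empty((s.shape[0], 2), dtype=np.int64)
    w[0, 0], w[0, 1] = u[0], v[0]
    w[1:, 0] = u[0] + np.cumsum(du)
    w[1:, 1] = v[0] + np.cumsum(dv)
    return w


def validate_configuration(config: Configuration) -> tuple[bool, str]:
    """Check every structural invariant; return (ok, first violation)."""
    L, N = config.L, config.n_beads
    occ, chain = config.occ, np.asarray(config.chain_sites, dtype=np.int64)

    if occ.shape != (L * L,):
        return False, "occupancy: wrong number of sites"
    if np.any(occ < SOLVENT):
        return False, "occupancy: unassigned (vacant) site"
    beads = np.flatnonzero(occ >= 0)
    if beads.size != N:
        return False, f"occupancy: {beads.size} bead labels, expected {N}"
    if not np.array_equal(np.sort(occ[beads]), np.arange(N)):
        return False, "occupancy: bead indices not a permutation of 0..N-1"
    if np.unique(chain).size != N:
        return False, "self-avoidance: repeated site in chain_sites"
    if not np.array_equal(occ[chain], np.arange(N)):
        return False, "occupancy: chain_sites disagree with bead labels"

    w = config.unwrapped()
    d2 = squared_distance_class(
        (w[1:, 0], w[1:, 1]), (w[:-1, 0], w[:-1, 1])
    )
    if np.any(d2 != 1):
        k = int(np.argmax(d2 != 1))
        return False, f"bond length: bond {k} has squared length {int(d2[k])}"
    # Unwrapped must reproduce wrapped sites modulo box translations.
    if not np.array_equal(
        (w[:, 0] % L) * L + (w[:, 1] % L), chain
    ):
        return False, "unwrapped/wrapped inconsistency"
    return True, "ok"


def _simple_saw(n_bonds: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform self-avoiding walk by non-reversal simple sampling.

    Every non-reversal walk carries equal probability, so rejecting
    self-intersections leaves the uniform distribution over SAWs.  Only used
    for short pieces (the dimerisation base case).
    """
    while True:
        w = np.zeros((n_bonds + 1, 2), dtype=np.int64)
        prev = -1
        occupied = {(0, 0)}
        ok = True
        for k in range(1, n_bonds + 1):
            choices = [d for d in range(6) if d != (prev ^ 1)] if prev >= 0 else range(6)
            d = choices[rng.integers(len(choices))] if prev >= 0 else int(
                rng.integers(6)
            )
            w[k] = w[k - 1] + AXIAL_OFFSETS[d]
            prev = d
            site = (int(w[k, 0]), int(w[k, 1]))
            if site in occupied:
                ok = False
                break
            occupied.add(site)
        if ok:
            return w


def random_saw(N: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform N-bead self-avoiding walk on the infinite lattice (axial).

    Dimerisation: two uniform half-walks are concatenated and the result is
    rejected unless self-avoiding.  Each self-avoiding concatenation arises
    from exactly one ordered pair of halves, so the output stays uniform.
    """
    m = N - 1  # bonds
    if m <= 8:
        return _simple_saw(m, rng)
    m1 = m // 2
    while True:
        a = random_saw(m1 + 1, rng)
        b = random_saw(m - m1 + 1, rng)
        w = np.vstack([a, a[-1] + b[1:]])
        if len({(int(u), int(v)) for u, v in w}) == w.shape[0]:
            return w


def init_chain(
    N: int, lattice: LatticeSpec, rng: np.random.Generator, max_restarts: int = 2000
) -> Configuration:
    """Place one self-avoiding N-bead chain; remaining sites become solvent.

    The conformation is drawn uniformly over self-avoiding walks
    (dimerisation) and dropped at a random position in the box; it is
    redrawn if the periodic wrap makes two beads collide, which only happens
    when the walk's extent approaches the box edge.  A uniform SAW start
    means athermal runs are stationary from the first sample, and thermal
    runs begin from a genuinely relaxed athermal configuration.

    Dense systems (more than a third of the sites are beads) fall back to
    biased growth with restarts; any valid placement is acceptable there
    because a relaxation phase follows.
    """
    L = lattice.L
    if N < 2:
        raise ValueError("chain needs at least 2 beads")
    if N > L * L:
        raise ValueError(f"cannot place N={N} beads on {L}x{L} sites")
    if L < 4.0 * N**0.75:
        # Coil-size guard: below this the chain can feel its periodic images.
        # Deliberately a warning, not an error: tiny boxes are legitimate for
        # exact-enumeration cross-checks, where the reference lives on the
        # same torus.
        import warnings

        warnings.warn(
            f"box edge L={L} is below the coil-size guard 4*N^(3/4) = "
            f"{4.0 * N ** 0.75:.1f} for N={N}; chain statistics may feel "
            "the periodic boundary",
            UserWarning,
            stacklevel=2,
        )
    nbr = build_neighbor_table(L)
    if 3 * N <= L * L:
        for _ in range(max_restarts):
            w = random_saw(N, rng)
            w = w + rng.integers(L, size=2)
            chain = ((w[:, 0] % L) * L + (w[:, 1] % L)).astype(np.int32)
            if np.unique(chain).size == N:  # no collisions through the wrap
                cfg = Configuration.from_chain_sites(L, chain)
                cfg._nbr = nbr
                return cfg
        raise RuntimeError(
            f"failed to fit a self-avoiding chain of N={N} into L={L} after "
            f"{max_restarts} draws"
        )
    # dense fallback: biased growth with restart on trapping
    taken = np.zeros(L * L, dtype=bool)
    chain = np.empty(N, dtype=np.int32)
    for _ in range(max_restarts):
        taken[:] = False
        s = int(rng.integers(L * L))
        chain[0] = s
        taken[s] = True
        ok = True
        for k in range(1, N):
            options = nbr[s][~taken[nbr[s]]]
            if options.size == 0:
                ok = False
                break
            s = int(options[rng.integers(options.size)])
            chain[k] = s
            taken[s] = True
        if ok:
            cfg = Configuration.from_chain_sites(L, chain)
            cfg._nbr = nbr
            return cfg
    raise RuntimeError(
        f"failed to place a self-avoiding chain of N={N} on L={L} after "
        f"{max_restarts} restarts"
    )


def export_snapshot(config: Configuration, header: dict | None = None) -> str:
    """Plain-text snapshot: JSON-style header, then one line per bead."""
    import json

    meta = {"N": config.n_beads, "L": config.L}
    if header:
        meta.update(header)
    xy = config.unwrapped_cartesian()
    lines = ["# " + json.dumps(meta)]
    for k, (x, y) in enumerate(xy):
        lines.append(f"{k} {x:.6f} {y:.6f}")
    return "\n".join(lines) + "\n"
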