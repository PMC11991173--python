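"""Per-sample and per-ensemble chain measurements.

Size: squared end-to-end distance Ree^2 = |r_1 - r_N|^2 and squared radius of
gyration Rg^2 = (1/N) sum_i |r_i - r_cm|^2, from unwrapped Cartesian
coordinates (valid because the coil is kept well below the box size).

Shape: the 2x2 gyration tensor T_kl = (1/N) sum_i (r_ik - r_cm,k)(r_il -
r_cm,l) with eigenvalues lambda1 >= lambda2 >= 0 (lambda1 + lambda2 = Rg^2)
and the asphericity

    A2 = <(lambda1 - lambda2)^2> / <(lambda1 + lambda2)^2>,

0 for a disk-symmetric object and 1 for a rod.  The headline (ensemble) form
averages numerator and denominator separately before taking the ratio; the
per-sample ratio is also available since the averaging order is a modelling
choice.

Energy: heat capacity from the fluctuation formula Cv/k = beta^2 (<E^2> -
<E>^2), computed with a two-pass variance for numerical stability.

Scattering: the intramolecular site-site correlation function gamma(r) is
accumulated over exact integer squared-distance classes r^2 = du^2 + du dv +
dv^2 (no histogram binning), and the single-chain structure factor is

    S(q) = sum_r gamma(r) sin(qr) / (qr),

with the r = 0 self term contributing gamma(0).  The sin(qr)/qr kernel is the
three-dimensional orientational average; it is the form conventionally
reported, and a 2D Bessel kernel J0(qr) is available as an option for
sensitivity checks.

Bridging: a solvent site with at least two polymer neighbours whose contour
indices differ by at least ``min_contour_gap`` counts as a bridge; this is
the diagnostic for solvent-mediated (bridging-induced) attraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import Configuration, build_neighbor_table

# ---------------------------------------------------------------------------
# size and shape
# ---------------------------------------------------------------------------


def end_to_end_sq(config: Configuration) -> float:
    """Squared Cartesian distance between the first and last bead."""
    xy = config.unwrapped_cartesian()
    d = xy[-1] - xy[0]
    return float(d @ d)


def radius_of_gyration_sq(config: Configuration) -> float:
    xy = config.unwrapped_cartesian()
    c = xy - xy.mean(axis=0)
    return float(np.einsum("ij,ij->", c, c) / xy.shape[0])


def gyration_tensor(config: Configuration) -> tuple[float, float]:
    """Eigenvalues (lambda1 >= lambda2) of the 2x2 gyration tensor."""
    xy = config.unwrapped_cartesian()
    l1, l2 = _eigenvalues_2x2(xy[None, :, :])
    return float(l1[0]), float(l2[0])


def _eigenvalues_2x2(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched closed-form eigenvalues; coords shape (nsamp, N, 2)."""
    c = coords - coords.mean(axis=1, keepdims=True)
    n = coords.shape[1]
    txx = np.einsum("sk,sk->s", c[:, :, 0], c[:, :, 0]) / n
    tyy = np.einsum("sk,sk->s", c[:, :, 1], c[:, :, 1]) / n
    txy = np.einsum("sk,sk->s", c[:, :, 0], c[:, :, 1]) / n
    tr = txx + tyy
    disc = np.sqrt(np.maximum((txx - tyy) ** 2 + 4.0 * txy**2, 0.0))
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    return l1, np.maximum(l2, 0.0)


def asphericity(lambda1, lambda2) -> float:
    """Single-sample asphericity (lambda1 - lambda2)^2 / (lambda1 + lambda2)^2."""
    lambda1 = float(lambda1)
    lambda2 = float(lambda2)
    if lambda1 + lambda2 == 0.0:
        raise ValueError("degenerate chain: both gyration eigenvalues vanish")
    return (lambda1 - lambda2) ** 2 / (lambda1 + lambda2) ** 2


def asphericity_ensemble(lambda1: np.ndarray, lambda2: np.ndarray) -> float:
    """Ensemble form: <(l1-l2)^2> / <(l1+l2)^2> (ratio of means)."""
    l1 = np.asarray(lambda1, dtype=np.float64)
    l2 = np.asarray(lambda2, dtype=np.float64)
    denom = np.mean((l1 + l2) ** 2)
    if denom == 0.0:
        raise ValueError("degenerate ensemble: all gyration eigenvalues vanish")
    return float(np.mean((l1 - l2) ** 2) / denom)


def chain_observables(L: int, pos_samples: np.ndarray) -> pd.DataFrame:
    """Ree2, Rg2 and gyration eigenvalues for a batch of chain snapshots.

    ``pos_samples`` holds wrapped site indices, shape (nsamp, N); each row is
    unwrapped by accumulating unit bond vectors.
    """
    from .lattice import to_cartesian, unwrap_chain

    pos_samples = np.atleast_2d(pos_samples)
    nsamp, n = pos_samples.shape
    coords = np.empty((nsamp, n, 2), dtype=np.float64)
    for i in range(nsamp):
        w = unwrap_chain(pos_samples[i], L)
        x, y = to_cartesian(w[:, 0], w[:, 1])
        coords[i, :, 0] = x
        coords[i, :, 1] = y
    d = coords[:, -1, :] - coords[:, 0, :]
    ree2 = np.einsum("sj,sj->s", d, d)
    l1, l2 = _eigenvalues_2x2(coords)
    return pd.DataFrame(
        {"Ree2": ree2, "Rg2": l1 + l2, "lambda1": l1, "lambda2": l2}
    )


# ---------------------------------------------------------------------------
# energy statistics
# ---------------------------------------------------------------------------


def heat_capacity(energies, kT: float, N: int) -> tuple[float, float]:
    """(Cv/k, Cv/kN) from the energy-fluctuation formula beta^2 Var(E)."""
    e = np.asarray(energies, dtype=np.float64)
    if e.size < 2:
        raise ValueError("heat capacity needs at least 2 energy samples")
    beta = 1.0 / kT
    cv = beta * beta * float(np.var(e))
    return cv, cv / N


def reweighted_energy_moments(
    energies, beta0: float, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First two moments of E reweighted from inverse temperature beta0.

    Standard single-histogram reweighting: samples drawn at beta0 are
    reweighted with exp(-(beta' - beta0) E) to give canonical moments at
    nearby beta'.  Returns (<E>, <E^2>, effective sample size) per beta'.
    The effective sample size (sum w)^2 / sum w^2 collapses once beta' - beta0
    exceeds ~1/std(E); keep evaluations inside that window.
    """
    e = np.asarray(energies, dtype=np.float64)
    beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
    d = -(beta[:, None] - beta0) * e[None, :]
    d -= d.max(axis=1, keepdims=True)
    w = np.exp(d)
    z = w.sum(axis=1)
    e1 = (w @ e) / z
    e2 = (w @ (e * e)) / z
    ess = z * z / (w * w).sum(axis=1)
    return e1, e2, ess


def reweighted_heat_capacity(
    energies, kT0: float, kT: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cv/k on a temperature grid, reweighted from samples taken at kT0."""
    kT = np.atleast_1d(np.asarray(kT, dtype=np.float64))
    beta = 1.0 / kT
    e1, e2, ess = reweighted_energy_moments(energies, 1.0 / kT0, beta)
    return beta * beta * (e2 - e1 * e1), ess


# ---------------------------------------------------------------------------
# scattering
# ---------------------------------------------------------------------------


@dataclass
class CorrelationTable:
    """gamma(r) over exact squared-distance classes; gamma(0)=1, sum = N."""

    N: int
    r2: np.ndarray  # ascending integer squared-distance classes
    gamma: np.ndarray

    @property
    def r(self) -> np.ndarray:
        return np.sqrt(self.r2.astype(np.float64))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r2": self.r2, "r": self.r, "gamma": self.gamma})


@dataclass
class ScatterTable:
    """S(q) and the Kratky form q^2 S(q) on a wave-vector grid."""

    q: np.ndarray
    S: np.ndarray

    @property
    def q2S(self) -> np.ndarray:
        return self.q**2 * self.S

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q": self.q, "S": self.S, "q2S": self.q2S})


def correlation_function(unwrapped_chains) -> CorrelationTable:
    """gamma(r) averaged over an ensemble of same-length chains.

    ``unwrapped_chains`` is an iterable of (N, 2) integer axial coordinate
    arrays (or Configurations).  All N^2 ordered intramolecular pairs,
    including i = j, are accumulated per chain.
    """
    counts: dict[int, float] = {}
    n_conf = 0
    n_beads = None
    for item in unwrapped_chains:
        w = item.unwrapped() if isinstance(item, Configuration) else np.asarray(item)
        if n_beads is None:
            n_beads = w.shape[0]
        elif w.shape[0] != n_beads:
            raise ValueError("mixed chain lengths in correlation ensemble")
        du = w[:, 0][:, None] - w[:, 0][None, :]
        dv = w[:, 1][:, None] - w[:, 1][None, :]
        cls = (du * du + du * dv + dv * dv).ravel()
        uniq, cnt = np.unique(cls, return_counts=True)
        for k, c in zip(uniq.tolist(), cnt.tolist()):
            counts[k] = counts.get(k, 0.0) + c
        n_conf += 1
    if n_conf == 0:
        raise ValueError("empty ensemble")
    r2 = np.array(sorted(counts), dtype=np.int64)
    gamma = np.array([counts[k] for k in r2], dtype=np.float64) / (
        n_beads * n_conf
    )
    return CorrelationTable(N=n_beads, r2=r2, gamma=gamma)


def structure_factor(
    table: CorrelationTable, q_grid, kernel: str = "sinc"
) -> ScatterTable:
    """S(q) = sum_r gamma(r) sin(qr)/(qr); the r=0 self term contributes 1.

    ``kernel='bessel'`` replaces sin(qr)/(qr) by the in-plane orientational
    average J0(qr).
    """
    q = np.asarray(q_grid, dtype=np.float64)
    if q.ndim != 1 or q.size == 0:
        raise ValueError("q grid must be a non-empty 1-D array")
    if np.any(q <= 0):
        raise ValueError("wave vectors must be strictly positive")
    if np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly ascending")
    r = table.r
    nonzero = r > 0
    qr = np.outer(q, r[nonzero])
    if kernel == "sinc":
        k = np.sin(qr) / qr
    elif kernel == "bessel":
        from scipy.special import j0

        k = j0(qr)
    else:
        raise ValueError(f"unknown kernel {kernel!r} (sinc, bessel)")
    s = k @ table.gamma[nonzero]
    if not nonzero.all():  # the r = 0 class (always present in practice)
        s = s + table.gamma[~nonzero].sum()
    return ScatterTable(q=q, S=s)


def default_q_grid(L: int, n_points: int = 60) -> np.ndarray:
    """Log-spaced wave vectors from the box scale 2*pi/L up to pi."""
    return np.geomspace(2.0 * np.pi / L, np.pi, n_points)


# ---------------------------------------------------------------------------
# solvent bridging
# ---------------------------------------------------------------------------


def bridge_count(config: Configuration, min_contour_gap: int = 3) -> int:
    """Solvent sites bridging two chain segments far apart along the contour."""
    return int(
        bridge_counts(
            config.L, config.chain_sites[None, :], min_contour_gap, nbr=config.nbr
        )[0]
    )


def bridge_counts(
    L: int, pos_samples: np.ndarray, min_contour_gap: int = 3, nbr=None
) -> np.ndarray:
    """Batched bridge counts from wrapped chain-site snapshots (nsamp, N)."""
    if nbr is None:
        nbr = build_neighbor_table(L)
    pos_samples = np.atleast_2d(pos_samples)
    nsamp, n = pos_samples.shape
    mark = np.full(L * L, -1, dtype=np.int64)
    out = np.zeros(nsamp, dtype=np.int64)
    idx = np.arange(n, dtype=np.int64)
    for i in range(nsamp):
        pos = pos_samples[i]
        mark[pos] = idx
        cand = np.unique(nbr[pos].ravel())
        cand = cand[mark[cand] < 0]  # solvent sites touching the chain
        if cand.size:
            nb = mark[nbr[cand]]  # (M, 6) bead indices, -1 for solvent
            have = nb >= 0
            cnt = have.sum(axis=1)
            hi = np.where(have, nb, -1).max(axis=1)
            lo = np.where(have, nb, n + 1).min(axis=1)
            out[i] = int(np.count_nonzero((cnt >= 2) & (hi - lo >= min_contour_gap)))
        mark[pos] = -1
    return out


# ---------------------------------------------------------------------------
# ensemble summaries
# ---------------------------------------------------------------------------


@dataclass
class EnsembleSummary:
    """Replicate-aggregated means and standard errors at one state point."""

    N: int
    chi_over_z: float
    kT: float
    n_replicates: int
    n_samples: int
    E_mean: float
    E_se: float
    Ree2_mean: float
    Ree2_se: float
    Rg2_mean: float
    Rg2_se: float
    lambda1_mean: float
    lambda1_se: float
    lambda2_mean: float
    lambda2_se: float
    A2_mean: float
    A2_se: float
    A2_sample_mean: float
    bridges_mean: float
    bridges_se: float
    Cv_per_k: float
    Cv_per_k_se: float

    @property
    def Cv_per_kN(self) -> float:
        return self.Cv_per_k / self.N

    def to_row(self) -> dict:
        d = {
            "N": self.N,
            "chi_over_z": self.chi_over_z,
            "kT": self.kT,
            "n_replicates": self.n_replicates,
            "n_samples": self.n_samples,
            "E": self.E_mean,
            "E_se": self.E_se,
            "Ree2": self.Ree2_mean,
            "Ree2_se": self.Ree2_se,
            "Rg2": self.Rg2_mean,
            "Rg2_se": self.Rg2_se,
            "lambda1": self.lambda1_mean,
            "lambda1_se": self.lambda1_se,
            "lambda2": self.lambda2_mean,
            "lambda2_se": self.lambda2_se,
            "A2": self.A2_mean,
            "A2_se": self.A2_se,
            "A2_sample": self.A2_sample_mean,
            "bridges": self.bridges_mean,
            "bridges_se": self.bridges_se,
            "Cv_per_k": self.Cv_per_k,
            "Cv_per_k_se": self.Cv_per_k_se,
            "Cv_per_kN": self.Cv_per_kN,
        }
        return d


def _mean_se(values: list[float]) -> tuple[float, float]:
    v = np.asarray(values, dtype=np.float64)
    if v.size == 1:
        return float(v[0]), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def summarize_replicates(
    replicate_records: list[pd.DataFrame],
    N: int,
    kT: float,
    chi_over_z: float,
) -> EnsembleSummary:
    """Aggregate per-replicate production records into one summary row.

    Standard errors are computed across replicate means (never across the
    autocorrelated samples within one run).
    """
    per = {
        k: [float(df[k].mean()) for df in replicate_records]
        for k in ("E", "Ree2", "Rg2", "lambda1", "lambda2", "bridges")
    }
    cv = [heat_capacity(df["E"], kT, N)[0] for df in replicate_records]
    a2 = [
        asphericity_ensemble(df["lambda1"], df["lambda2"])
        for df in replicate_records
    ]
    a2_sample = float(
        np.mean(
            [
                np.mean(
                    (df["lambda1"] - df["lambda2"]) ** 2
                    / (df["lambda1"] + df["lambda2"]) ** 2
                )
                for df in replicate_records
            ]
        )
    )
    e_m, e_se = _mean_se(per["E"])
    ree_m, ree_se = _mean_se(per["Ree2"])
    rg_m, rg_se = _mean_se(per["Rg2"])
    l1_m, l1_se = _mean_se(per["lambda1"])
    l2_m, l2_se = _mean_se(per["lambda2"])
    br_m, br_se = _mean_se(per["bridges"])
    cv_m, cv_se = _mean_se(cv)
    a2_m, a2_se = _mean_se(a2)
    return EnsembleSummary(
        N=N,
        chi_over_z=chi_over_z,
        kT=kT,
        n_replicates=len(replicate_records),
        n_samples=int(sum(len(df) for df in replicate_records)),
        E_mean=e_m,
        E_se=e_se,
        Ree2_mean=ree_m,
        Ree2_se=ree_se,
        Rg2_mean=rg_m,
        Rg2_se=rg_se,
        lambda1_mean=l1_m,
        lambda1_se=l1_se,
        lambda2_mean=l2_m,
        lambda2_se=l2_se,
        A2_mean=a2_m,
        A2_se=a2_se,
        A2_sample_mean=a2_sample,
        bridges_mean=br_m,
        bridges_se=br_se,
        Cv_per_k=cv_m,
        Cv_per_k_se=cv_se,
    )
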