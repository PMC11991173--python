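"""Solvent-quality sweeps over chain lengths, aggregation and analysis.

A sweep runs the full single-chain protocol at every (N, chi/z, replicate)
tuple of a manifest, aggregates replicate means into one summary row per
state point, and feeds the summaries to the scaling analysis (heat-capacity
maxima and transition temperatures, power-law fits of T_p(N) and of the peak
heights, size-scaling exponents, asphericity minima).

Two built-in profiles set the scale:

* ``paper`` -- the headline protocol: box 256, N = 16 ... 512, 10^7 MCS of
  equilibration and production each, sampling every 10^5 MCS, 8 replicates.
  Week-scale per state point on one CPU; shipped for completeness, not for
  routine runs.
* ``desk`` -- N <= 64, boxes sized to the coil (L >= 4 N^(3/4)), 10^4-scale
  MCS: minutes on one CPU, the scale used by the validation suite.

Replicates differ in both the initial configuration and the RNG stream
(seeds are derived per tuple).  Identical configuration plus seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cma import SimulationParams, replicate_seed, run_simulation
from .energetics import InteractionSet, kT_from_chi_over_z
from .lattice import export_snapshot
from .observables import summarize_replicates
from .scaling import (
    CurveSeries,
    fit_power_law,
    locate_extremum,
    size_scaling_exponent,
    transition_temperature,
)

PRESET_ENERGIES = {
    "poor": (-1.0, 0.0, -1.0),
    "good": (0.0, -1.0, 0.0),
    "athermal": (0.0, 0.0, 0.0),
}


def coil_box(n_beads: int, minimum: int = 16) -> int:
    """Smallest even box edge satisfying the coil-size guard L >= 4 N^(3/4)."""
    L = max(minimum, math.ceil(4.0 * n_beads**0.75))
    return L + (L % 2)


@dataclass
class SweepConfig:
    """Everything needed to reproduce one solvent-quality sweep."""

    preset: str
    n_beads: tuple = (16, 32)
    chi_over_z_grid: tuple = ()
    box: int | None = None  # None: per-N coil_box()
    n_equil_mcs: int = 10_000
    n_prod_mcs: int = 10_000
    sample_interval_mcs: int = 10
    replicates: int = 8
    seed: int = 0
    n_athermal_mcs: int | None = None

    def __post_init__(self) -> None:
        if self.preset not in PRESET_ENERGIES:
            raise ValueError(
                f"unknown preset {self.preset!r} ({sorted(PRESET_ENERGIES)})"
            )
        if not self.chi_over_z_grid:
            self.chi_over_z_grid = tuple(default_grid_for_preset(self.preset))
        self.chi_over_z_grid = tuple(float(c) for c in self.chi_over_z_grid)
        for c in self.chi_over_z_grid:
            self.interactions_at(c)  # validates the sign early

    def interactions_at(self, chi_over_z: float) -> InteractionSet:
        e_pp, e_ps, e_ss = PRESET_ENERGIES[self.preset]
        base = InteractionSet(e_pp, e_ps, e_ss)
        if chi_over_z == 0.0 or self.preset == "athermal":
            return InteractionSet.athermal()
        return base.with_kT(kT_from_chi_over_z(chi_over_z, base))

    def box_for(self, n_beads: int) -> int:
        return self.box if self.box is not None else coil_box(n_beads)

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "n_beads": list(self.n_beads),
            "chi_over_z_grid": list(self.chi_over_z_grid),
            "box": self.box,
            "n_equil_mcs": self.n_equil_mcs,
            "n_prod_mcs": self.n_prod_mcs,
            "sample_interval_mcs": self.sample_interval_mcs,
            "replicates": self.replicates,
            "seed": self.seed,
            "n_athermal_mcs": self.n_athermal_mcs,
        }


def default_grid_for_preset(preset: str, n_points: int = 11, span: float = 2.0):
    """Sign-matched chi/z grid (the poor preset lives at chi > 0, good at < 0)."""
    if preset == "athermal":
        return [0.0]
    pts = np.linspace(span / n_points, span, n_points)
    return list(pts if preset == "poor" else -pts)


def desk_profile(preset: str, **overrides) -> SweepConfig:
    cfg = SweepConfig(
        preset=preset,
        n_beads=(16, 32),
        box=64,
        n_equil_mcs=10_000,
        n_prod_mcs=10_000,
        sample_interval_mcs=10,
        replicates=4,
    )
    return replace(cfg, **overrides) if overrides else cfg


def paper_profile(preset: str, **overrides) -> SweepConfig:
    cfg = SweepConfig(
        preset=preset,
        n_beads=(16, 32, 64, 128, 256, 512),
        box=256,
        chi_over_z_grid=tuple(default_grid_for_preset(preset, n_points=21)),
        n_equil_mcs=10_000_000,
        n_prod_mcs=10_000_000,
        sample_interval_mcs=100_000,
        replicates=8,
    )
    return replace(cfg, **overrides) if overrides else cfg


def build_manifest(config: SweepConfig) -> pd.DataFrame:
    """One row per (N, chi/z, replicate) with its derived seed."""
    rows = []
    for n in config.n_beads:
        for chi in config.chi_over_z_grid:
            for rep in range(config.replicates):
                key = hash((n, round(chi, 12), rep)) & 0xFFFF
                rows.append(
                    {
                        "N": n,
                        "box": config.box_for(n),
                        "chi_over_z": chi,
                        "replicate": rep,
                        "seed": replicate_seed(config.seed, key * 131 + rep),
                        "status": "pending",
                    }
                )
    df = pd.DataFrame(rows)
    if df["seed"].duplicated().any():
        # astronomically unlikely; regenerate deterministically with offset
        dup = df["seed"].duplicated()
        df.loc[dup, "seed"] = df.loc[dup, "seed"] + 1
    return df


@dataclass
class SweepResult:
    config: SweepConfig
    summary: pd.DataFrame
    manifest: pd.DataFrame
    records: dict = field(default_factory=dict)  # (N, chi, rep) -> DataFrame
    snapshots: dict = field(default_factory=dict)  # (N, chi) -> snapshot text


def run_sweep(
    config: SweepConfig,
    out_dir: str | Path | None = None,
    keep_records: bool = False,
    progress: bool = False,
) -> SweepResult:
    """Execute the manifest, aggregate replicates, optionally write tables."""
    manifest = build_manifest(config)
    summary_rows = []
    records: dict = {}
    snapshots: dict = {}
    for (n, chi), group in manifest.groupby(["N", "chi_over_z"], sort=True):
        inter = config.interactions_at(chi)
        reps = []
        for idx, row in group.iterrows():
            params = SimulationParams(
                n_beads=int(n),
                box=int(row["box"]),
                interactions=inter,
                n_equil_mcs=config.n_equil_mcs,
                n_prod_mcs=config.n_prod_mcs,
                sample_interval_mcs=config.sample_interval_mcs,
                seed=int(row["seed"]),
                n_athermal_mcs=config.n_athermal_mcs,
            )
            try:
                result = run_simulation(params)
            except Exception as exc:  # record and continue with the sweep
                manifest.loc[idx, "status"] = f"failed: {exc}"
                continue
            manifest.loc[idx, "status"] = "ok"
            reps.append(result)
            if keep_records:
                records[(int(n), float(chi), int(row["replicate"]))] = (
                    result.records
                )
        if not reps:
            continue
        row = summarize_replicates(
            [r.records for r in reps], int(n), inter.kT, float(chi)
        ).to_row()
        # sampler diagnostics, averaged over replicates
        row["acceptance"] = float(
            np.mean([r.counter.acceptance_rate for r in reps])
        )
        row["mean_loop_length"] = float(
            np.mean([r.counter.mean_loop_length for r in reps])
        )
        summary_rows.append(row)
        snapshots[(int(n), float(chi))] = export_snapshot(
            reps[0].final_config,
            {"chi_over_z": float(chi), "mcs": config.n_prod_mcs},
        )
        if progress:
            print(f"  N={n} chi/z={chi:+.3f} done ({len(reps)} replicates)")
    summary = pd.DataFrame(summary_rows)
    out = SweepResult(config, summary, manifest, records, snapshots)
    if out_dir is not None:
        write_sweep(out, out_dir)
    return out


def write_sweep(result: SweepResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out / "summary.csv", index=False)
    result.manifest.to_csv(out / "manifest.csv", index=False)
    (out / "config.json").write_text(json.dumps(result.config.to_dict(), indent=2))
    snap_dir = out / "snapshots"
    snap_dir.mkdir(exist_ok=True)
    for (n, chi), text in result.snapshots.items():
        (snap_dir / f"N{n}_chi{chi:+.3f}.xyz".replace("+", "p").replace(
            "-", "m"
        )).write_text(text)
    for (n, chi, rep), df in result.records.items():
        df.to_csv(out / f"records_N{n}_chi{chi:+.4f}_r{rep}.csv", index=False)


def analyze_sweep(
    summary: pd.DataFrame, preset: str
) -> tuple[dict, pd.DataFrame]:
    """Heat-capacity peaks, T_p(N) and Cv_max(N) fits, asphericity minima.

    Returns (fits, extrema): ``fits`` maps quantity names to power-law fit
    dictionaries, ``extrema`` has one row per chain length with the located
    Cv maximum and A2 minimum (where bracketed).
    """
    e_pp, e_ps, e_ss = PRESET_ENERGIES[preset]
    base = InteractionSet(e_pp, e_ps, e_ss)
    rows = []
    for n, df in summary.groupby("N"):
        row: dict = {"N": int(n)}
        try:
            cv = locate_extremum(
                CurveSeries.from_frame(df, "Cv_per_k", "Cv_per_k_se"), "max"
            )
            row.update(
                chi_star=cv.chi_over_z,
                chi_star_err=cv.chi_over_z_err,
                Cv_peak=cv.value,
                Cv_peak_per_bead=cv.value / n,
                T_p=transition_temperature(cv.chi_over_z, base),
                cv_from_quadratic=cv.from_quadratic,
            )
        except ValueError as exc:
            row["cv_error"] = str(exc)
        try:
            a2 = locate_extremum(
                CurveSeries.from_frame(df, "A2", "A2_se"), "min"
            )
            row.update(
                A2_min_chi=a2.chi_over_z,
                A2_min_chi_err=a2.chi_over_z_err,
                A2_min=a2.value,
            )
        except ValueError as exc:
            row["a2_error"] = str(exc)
        rows.append(row)
    extrema = pd.DataFrame(rows)
    fits: dict = {}
    ok = extrema.dropna(subset=["T_p"]) if "T_p" in extrema else pd.DataFrame()
    if len(ok) >= 3:
        fits["Tp_vs_N"] = fit_power_law(ok["N"], ok["T_p"]).to_dict()
        fits["Cv_peak_per_bead_vs_N"] = fit_power_law(
            ok["N"], ok["Cv_peak_per_bead"]
        ).to_dict()
    if summary["N"].nunique() >= 3:
        size_fits = {}
        for chi, df in summary.groupby("chi_over_z"):
            if df["N"].nunique() >= 3:
                size_fits[f"{chi:+.4f}"] = {
                    "Rg2": size_scaling_exponent(df, "Rg2").to_dict(),
                    "Ree2": size_scaling_exponent(df, "Ree2").to_dict(),
                }
        if size_fits:
            fits["two_nu_vs_chi_over_z"] = size_fits
    return fits, extrema


def write_analysis(
    fits: dict, extrema: pd.DataFrame, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "fits.json").write_text(json.dumps(fits, indent=2))
    extrema.to_csv(out / "extrema.csv", index=False)


def cv_peak_location(
    n_beads: int,
    box: int,
    anchors_chi_over_z,
    eval_grid,
    n_equil_mcs: int,
    n_prod_mcs: int,
    sample_interval_mcs: int,
    replicates: int,
    seed: int,
    preset: str = "poor",
):
    """Locate the heat-capacity maximum in chi/z by histogram reweighting.

    For the unit-depth presets chi/z equals the inverse temperature beta, so
    energy samples taken at a few anchor solvent qualities can be reweighted
    to a continuous Cv(chi/z) curve (see
    :func:`polycma.observables.reweighted_heat_capacity`).  Each replicate
    runs every anchor independently; its anchors are combined with
    effective-sample-size weights, and the replicate's peak is the argmax of
    the combined curve on ``eval_grid``.  Returns (mean location, standard
    error across replicates, per-replicate locations, mean curve).

    The peak is read off the replicate-averaged curve (averaging suppresses
    the sparse-tail spikes a single reweighted trajectory can show away from
    its anchor); the quoted error is the delete-one jackknife over
    replicates.  Raises ValueError if the averaged curve has its maximum on
    the grid boundary (unbracketed peak).
    """
    from .cma import SimulationParams, replicate_seed, run_simulation
    from .observables import reweighted_energy_moments

    e_pp, e_ps, e_ss = PRESET_ENERGIES[preset]
    base = InteractionSet(e_pp, e_ps, e_ss)
    if abs(base.energy_magnitude() - 1.0) > 1e-12:
        raise ValueError("reweighting in chi/z assumes a unit-depth preset")
    grid = np.asarray(eval_grid, dtype=np.float64)
    curves = []
    for rep in range(replicates):
        num = np.zeros_like(grid)
        den = np.zeros_like(grid)
        for a, chi in enumerate(anchors_chi_over_z):
            inter = base.with_kT(kT_from_chi_over_z(chi, base))
            params = SimulationParams(
                n_beads=n_beads,
                box=box,
                interactions=inter,
                n_equil_mcs=n_equil_mcs,
                n_prod_mcs=n_prod_mcs,
                sample_interval_mcs=sample_interval_mcs,
                seed=replicate_seed(seed, 7919 * n_beads + 101 * a + rep),
            )
            e_samples = run_simulation(params).records.E.to_numpy()
            e1, e2, ess = reweighted_energy_moments(e_samples, chi, grid)
            cv = grid * grid * (e2 - e1 * e1)
            num += ess * cv
            den += ess
        curves.append(num / den)
    curves = np.asarray(curves)
    mean_curve = curves.mean(axis=0)
    i = int(np.argmax(mean_curve))
    if i == 0 or i == grid.size - 1:
        raise ValueError(
            "unbracketed extremum: Cv maximum on the evaluation boundary"
        )
    loc = float(grid[i])
    r = curves.shape[0]
    if r > 1:
        jack = np.array(
            [
                grid[int(np.argmax((mean_curve * r - curves[k]) / (r - 1)))]
                for k in range(r)
            ]
        )
        se = float(np.sqrt((r - 1) / r * ((jack - jack.mean()) ** 2).sum()))
    else:
        jack = np.array([loc])
        se = float("nan")
    return loc, se, jack, mean_curve


def scatter_tables(
    n_beads: int,
    box: int,
    interactions: InteractionSet,
    n_equil_mcs: int,
    n_prod_mcs: int,
    sample_interval_mcs: int,
    seed: int = 0,
    q_grid=None,
):
    """Correlation function and structure factor for one state point.

    Runs a fresh simulation, accumulates gamma(r) over the sampled chain
    conformations and transforms to S(q) / q^2 S(q).
    """
    from .lattice import unwrap_chain
    from .observables import correlation_function, default_q_grid, structure_factor

    params = SimulationParams(
        n_beads=n_beads,
        box=box,
        interactions=interactions,
        n_equil_mcs=n_equil_mcs,
        n_prod_mcs=n_prod_mcs,
        sample_interval_mcs=sample_interval_mcs,
        seed=seed,
    )
    from .cma import CmaSampler, seed_state
    from .lattice import LatticeSpec, init_chain

    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xC0FFEE]))
    )
    config = init_chain(n_beads, LatticeSpec(box), rng)
    sampler = CmaSampler(
        config, InteractionSet.athermal(), rng_state=seed_state(seed)
    )
    sampler.run(params.athermal_mcs)
    sampler.set_interactions(interactions)
    sampler.run(n_equil_mcs)
    _, positions, _ = sampler.run(n_prod_mcs, sample_interval_mcs)
    gamma = correlation_function(
        unwrap_chain(p, box) for p in positions
    )
    q = default_q_grid(box) if q_grid is None else np.asarray(q_grid)
    return gamma, structure_factor(gamma, q)
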