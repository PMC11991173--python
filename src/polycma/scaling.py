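"""Extremum location, transition temperatures and power-law scaling fits.

The coil-globule transition shows up as a maximum of the heat capacity as a
function of solvent quality chi/z; its location maps to the transition
temperature through kT = z/chi * |E_PS - (E_PP + E_SS)/2| (T_p = 1/|chi/z|*
for unit-magnitude presets).  Transition temperatures and peak heights scale
with chain length as power laws T_p ~ N^alpha, Cv_max/kN ~ N^gamma, and the
chain size scales as <Rg^2>, <Ree^2> ~ N^(2 nu), with 2 nu = 3/2 for the
athermal 2D self-avoiding walk and 2 nu -> 1 in the collapsed (compact disk)
regime.

Extrema are located by a local quadratic fit through the five points around
the discrete extremum -- the minimal-assumption choice -- with the vertex
uncertainty propagated from the point noise.  Power laws are fitted by
weighted least squares of log y on log x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energetics import InteractionSet, temperature_from_chi
from .lattice import Z


@dataclass
class CurveSeries:
    """One observable versus chi/z at fixed chain length."""

    N: int
    chi_over_z: np.ndarray
    value: np.ndarray
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chi_over_z = np.asarray(self.chi_over_z, dtype=np.float64)
        self.value = np.asarray(self.value, dtype=np.float64)
        order = np.argsort(self.chi_over_z)
        self.chi_over_z = self.chi_over_z[order]
        self.value = self.value[order]
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=np.float64)[order]
        if np.any(np.diff(self.chi_over_z) <= 0):
            raise ValueError("chi/z grid must be strictly monotone")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, column: str, se_column: str | None = None):
        se = df[se_column].to_numpy() if se_column and se_column in df else None
        return cls(
            N=int(df["N"].iloc[0]),
            chi_over_z=df["chi_over_z"].to_numpy(),
            value=df[column].to_numpy(),
            stderr=se,
        )


@dataclass
class ExtremumResult:
    chi_over_z: float
    value: float
    chi_over_z_err: float
    from_quadratic: bool  # False when the fit degenerated to the grid point


@dataclass
class ScalingFit:
    """Power law y = prefactor * x^exponent from a log-log least squares."""

    prefactor: float
    exponent: float
    exponent_stderr: float
    prefactor_stderr: float
    r_squared: float
    fit_range: list

    def predict(self, x) -> np.ndarray:
        return self.prefactor * np.asarray(x, dtype=np.float64) ** self.exponent

    def to_dict(self) -> dict:
        return {
            "prefactor": self.prefactor,
            "exponent": self.exponent,
            "exponent_stderr": self.exponent_stderr,
            "prefactor_stderr": self.prefactor_stderr,
            "r_squared": self.r_squared,
            "fit_range": list(self.fit_range),
        }


def locate_extremum(series: CurveSeries, kind: str = "max") -> ExtremumResult:
    """Vertex of a local quadratic through the 5 points around the extremum.

    The extremum must be bracketed (not on the series boundary) and at least
    five points are required.  With point uncertainties available the vertex
    location error is propagated from the quadratic coefficients; otherwise
    it falls back to half the local grid spacing.
    """
    if kind not in ("max", "min"):
        raise ValueError("kind must be 'max' or 'min'")
    x, y = series.chi_over_z, series.value
    if x.size < 5:
        raise ValueError("need at least 5 points to bracket an extremum")
    i = int(np.argmax(y) if kind == "max" else np.argmin(y))
    if i == 0 or i == x.size - 1:
        raise ValueError(
            f"unbracketed extremum: discrete {kind} lies on the series boundary"
        )
    lo = max(0, min(i - 2, x.size - 5))
    window = slice(lo, lo + 5)
    xw, yw = x[window], y[window]
    sw = None if series.stderr is None else series.stderr[window]
    # quadratic y = a x^2 + b x + c
    w = None
    if sw is not None and np.all(np.isfinite(sw)) and np.all(sw > 0):
        w = 1.0 / sw  # numpy polyfit weights multiply the residuals
    coeffs, cov = np.polyfit(xw, yw, 2, w=w, cov="unscaled" if w is not None else True)
    a, b, c = coeffs
    concave_ok = a < 0 if kind == "max" else a > 0
    if not concave_ok or a == 0:
        # degenerate quadratic: fall back to the discrete extremum
        dx = 0.5 * max(x[i] - x[i - 1], x[i + 1] - x[i])
        return ExtremumResult(float(x[i]), float(y[i]), float(dx), False)
    xv = -b / (2.0 * a)
    yv = c - b * b / (4.0 * a)
    # propagate var(xv) from cov(a, b)
    da = b / (2.0 * a * a)
    db = -1.0 / (2.0 * a)
    var = da * da * cov[0, 0] + db * db * cov[1, 1] + 2 * da * db * cov[0, 1]
    if not (xw[0] <= xv <= xw[-1]):
        dx = 0.5 * max(x[i] - x[i - 1], x[i + 1] - x[i])
        return ExtremumResult(float(x[i]), float(y[i]), float(dx), False)
    return ExtremumResult(float(xv), float(yv), float(np.sqrt(max(var, 0.0))), True)


def transition_temperature(
    chi_over_z_star: float, interactions: InteractionSet
) -> float:
    """Map a transition location chi/z* to T_p via the chi(T) definition."""
    if chi_over_z_star == 0:
        raise ValueError("chi/z* = 0 has no finite transition temperature")
    return temperature_from_chi(Z * chi_over_z_star, interactions)


def fit_power_law(x, y, yerr=None) -> ScalingFit:
    """Weighted least squares of log y on log x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 points for a power-law fit")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive data")
    lx, ly = np.log(x), np.log(y)
    if yerr is not None:
        yerr = np.asarray(yerr, dtype=np.float64)
        if np.any(yerr <= 0) or not np.all(np.isfinite(yerr)):
            yerr = None
    if yerr is not None:
        w = y / yerr  # d(log y) = dy / y
        coeffs, cov = np.polyfit(lx, ly, 1, w=w, cov="unscaled")
    else:
        if x.size == 3:
            # cov needs dof > 0; use plain residual scaling on 3 points
            coeffs = np.polyfit(lx, ly, 1)
            resid = ly - np.polyval(coeffs, lx)
            dof = 1
            s2 = float(resid @ resid) / dof
            xm = lx.mean()
            sxx = float(((lx - xm) ** 2).sum())
            cov = np.array(
                [
                    [s2 / sxx, -s2 * xm / sxx],
                    [-s2 * xm / sxx, s2 * (1.0 / lx.size + xm * xm / sxx)],
                ]
            )
        else:
            coeffs, cov = np.polyfit(lx, ly, 1, cov=True)
    slope, intercept = coeffs
    pred = np.polyval(coeffs, lx)
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    pref = float(np.exp(intercept))
    return ScalingFit(
        prefactor=pref,
        exponent=float(slope),
        exponent_stderr=float(np.sqrt(max(cov[0, 0], 0.0))),
        prefactor_stderr=float(pref * np.sqrt(max(cov[1, 1], 0.0))),
        r_squared=r2,
        fit_range=x.tolist(),
    )


def size_scaling_exponent(
    summaries: pd.DataFrame, column: str = "Rg2"
) -> ScalingFit:
    """2*nu from <Rg^2> (or <Ree^2>) versus N at one solvent quality.

    ``summaries`` needs columns N and the chosen observable; an optional
    ``<column>_se`` column supplies weights.
    """
    if summaries["N"].nunique() < 3:
        raise ValueError("need at least 3 chain lengths for a scaling fit")
    df = summaries.sort_values("N")
    se_col = f"{column}_se"
    yerr = df[se_col].to_numpy() if se_col in df else None
    return fit_power_law(df["N"].to_numpy(), df[column].to_numpy(), yerr)


def default_chi_over_z_grid(n_points: int = 21, span: float = 2.0) -> np.ndarray:
    """The production sweep grid: chi/z uniformly spanning [-span, span]."""
    return np.linspace(-span, span, n_points)
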