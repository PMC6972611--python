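"""Per-phase drug amounts from NMR peak integrals and location of the LLPS miscibility gap.

When a supersaturated ibuprofen solution demixes, every proton signal splits
into a mother-phase peak (a) and a dense-phase twin (a*).  Because both species
are observed in the same spectrum of the same sample, the integral ratio
I(a*)/(I(a)+I(a*)) directly gives the fraction of drug bound in the dense
liquid phase; the amounts per total volume always sum to the invariant total
concentration (3 mM in the reference experiment).

Plotting the mother-phase IbuH concentration against the dense-phase amount
n*(Ibu)/V_total reveals two regimes: a linear rise, whose y-offset is the
binodal limit (lowest concentration at which two liquid phases can coexist),
and a saturation plateau, whose level is the spinodal limit (beyond it the
homogeneous solution is unstable).  Both are estimated here jointly with a
continuous two-segment (linear-then-constant) least-squares fit in which the
breakpoint is scanned and polished numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .speciation import protonated_fraction

__all__ = [
    "PartitionPoint",
    "PhaseBoundaryEstimate",
    "partition_from_integrals",
    "reduce_partition_table",
    "fit_binodal",
    "fit_spinodal",
]


@dataclass(frozen=True)
class PartitionPoint:
    """One sampled composition of a phase-separated titration sample."""

    pH: float
    I_a: float
    I_a_star: float
    n_star_per_V: float      # dense-phase drug amount per total volume, mM
    c_IbuH_L1: float         # protonated drug concentration in the mother phase, mM


@dataclass(frozen=True)
class PhaseBoundaryEstimate:
    """Binodal and spinodal limits of the liquid-liquid miscibility gap (mM)."""

    binodal: float
    binodal_se: float
    spinodal: float | None
    spinodal_se: float | None
    breakpoint: float | None
    slope: float
    slope_se: float
    r2_linear: float
    n_linear: int
    n_plateau: int
    plateau_detected: bool


def partition_from_integrals(I_a, I_a_star, c_tot):
    """Split the total drug concentration between the two liquid phases.

    The integrals of the mother-phase peak (a) and dense-phase peak (a*) are
    proportional to the drug amounts in each phase, and the amounts per total
    volume sum to ``c_tot`` exactly (conservation):

        n*_per_V  = c_tot * I_a* / (I_a + I_a*)
        mother    = c_tot - n*_per_V

    Parameters
    ----------
    I_a, I_a_star : float or array
        Peak integrals, arbitrary (but common) units, >= 0.
    c_tot : float
        Total drug concentration, mM.

    Returns
    -------
    (n_star_per_V, mother_total_per_V) in mM.
    """
    I_a = np.asarray(I_a, dtype=float)
    I_a_star = np.asarray(I_a_star, dtype=float)
    if np.any(I_a < 0) or np.any(I_a_star < 0):
        raise ValueError("peak integrals must be >= 0")
    total = I_a + I_a_star
    if np.any(total <= 0):
        raise ValueError("no signal: both integrals are zero")
    n_star = c_tot * I_a_star / total
    mother = c_tot - n_star
    if n_star.ndim:
        return n_star, mother
    return float(n_star), float(mother)


def reduce_partition_table(table: pd.DataFrame, c_tot: float, pKa: float) -> pd.DataFrame:
    """Reduce a raw partition table (pH, I_a, I_a_star) to fit-ready columns.

    For each sample the dense-phase amount comes from the integral split and
    the mother-phase IbuH concentration from the measured pH via mass action:
    the mother phase holds ``c_tot - n*`` of drug, of which the protonated
    fraction ``1/(1+10**(pH-pKa))`` is IbuH.

    Returns a copy with added columns ``n_star_mM`` and ``c_IbuH_L1_mM``.
    Tables already carrying those columns are passed through unchanged.
    """
    if {"n_star_mM", "c_IbuH_L1_mM"}.issubset(table.columns):
        return table.copy()
    missing = {"pH", "I_a", "I_a_star"} - set(table.columns)
    if missing:
        raise ValueError(f"partition table missing columns: {sorted(missing)}")
    out = table.copy()
    n_star, mother = partition_from_integrals(
        out["I_a"].to_numpy(), out["I_a_star"].to_numpy(), c_tot)
    out["n_star_mM"] = n_star
    out["c_IbuH_L1_mM"] = mother * protonated_fraction(out["pH"].to_numpy(), pKa)
    return out


def _two_segment_design(x: np.ndarray, breakpoint: float) -> np.ndarray:
    """Design matrix of the continuous linear-then-constant model.

    c(x) = b + s * min(x, x0): linear in (b, s) for a fixed breakpoint x0.
    """
    return np.column_stack([np.ones_like(x), np.minimum(x, breakpoint)])


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS fit returning (coef, covariance, sse)."""
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sse = float(resid @ resid)
    dof = max(len(y) - X.shape[1], 1)
    xtx_inv = np.linalg.pinv(X.T @ X)
    cov = xtx_inv * (sse / dof)
    return coef, cov, sse


def fit_binodal(n_star, c_IbuH, breakpoint: float):
    """Linear-extrapolation estimate of the binodal limit.

    Ordinary least squares of the mother-phase IbuH concentration on the
    dense-phase amount, restricted to points below ``breakpoint`` (the
    pre-plateau segment).  The y-intercept is the binodal limit: the lowest
    IbuH concentration at which a dense liquid phase can coexist.

    Returns
    -------
    (intercept, slope, intercept_se, slope_se) in mM / dimensionless.
    """
    x = np.asarray(n_star, dtype=float)
    y = np.asarray(c_IbuH, dtype=float)
    mask = x < breakpoint
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError(f"need >= 3 points below the breakpoint, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in n_star: cannot extrapolate")
    res = stats.linregress(x, y)
    return res.intercept, res.slope, res.intercept_stderr, res.stderr


def fit_spinodal(n_star, c_IbuH, breakpoint: float | None = None) -> PhaseBoundaryEstimate:
    """Joint binodal/spinodal estimate via a continuous two-segment fit.

    Fits c(x) = binodal + slope * min(x, x0): a linear rise joined continuously
    to a constant plateau at the breakpoint x0.  The plateau level
    ``binodal + slope * x0`` is the spinodal limit (the mother-phase
    composition saturates once the homogeneous solution becomes unstable);
    the linear-segment intercept is the binodal limit.

    The breakpoint is scanned over a dense grid spanning the interior of the
    data and the best candidate is polished with bounded scalar minimisation
    of the profile sum of squares, so noiseless piecewise data is recovered
    exactly.  Pass ``breakpoint`` to skip the scan and fix x0 manually.

    If the optimal breakpoint sits at the data edge (fewer than 2 points on
    the plateau), no plateau is detectable: a warning is raised and the
    spinodal is reported as undetermined (None).
    """
    x = np.asarray(n_star, dtype=float)
    y = np.asarray(c_IbuH, dtype=float)
    if len(x) < 6:
        raise ValueError(f"need >= 6 points spanning both segments, got {len(x)}")
    order = np.argsort(x)
    x, y = x[order], y[order]

    if breakpoint is None:
        # profile SSE over candidate breakpoints: dense grid, then polish
        lo = x[2]            # >= 3 points must stay on the linear segment
        hi = x[-1]
        grid = np.linspace(lo, hi, 512)
        sses = np.array([_ols(_two_segment_design(x, b), y)[2] for b in grid])
        k = int(np.argmin(sses))
        b_lo = grid[max(k - 1, 0)]
        b_hi = grid[min(k + 1, len(grid) - 1)]
        if b_hi > b_lo:
            res = minimize_scalar(
                lambda b: _ols(_two_segment_design(x, b), y)[2],
                bounds=(b_lo, b_hi), method="bounded",
                options={"xatol": 1e-12})
            breakpoint = float(res.x) if res.fun <= sses[k] else float(grid[k])
        else:
            breakpoint = float(grid[k])

    coef, cov, sse = _ols(_two_segment_design(x, breakpoint), y)
    intercept, slope = float(coef[0]), float(coef[1])
    n_linear = int(np.sum(x < breakpoint))
    n_plateau = int(np.sum(x >= breakpoint))
    plateau_detected = n_plateau >= 2 and breakpoint < x[-1]

    intercept_se = float(np.sqrt(max(cov[0, 0], 0.0)))
    slope_se = float(np.sqrt(max(cov[1, 1], 0.0)))
    lin_mask = x < breakpoint
    ss_tot = float(np.sum((y[lin_mask] - y[lin_mask].mean()) ** 2))
    lin_resid = y[lin_mask] - (intercept + slope * x[lin_mask])
    r2_linear = 1.0 - float(lin_resid @ lin_resid) / ss_tot if ss_tot > 0 else 1.0

    if not plateau_detected:
        warnings.warn(
            "no plateau detected (breakpoint at the data edge): "
            "spinodal is undetermined", stacklevel=2)
        return PhaseBoundaryEstimate(
            binodal=intercept, binodal_se=intercept_se,
            spinodal=None, spinodal_se=None, breakpoint=None,
            slope=slope, slope_se=slope_se, r2_linear=r2_linear,
            n_linear=n_linear, n_plateau=n_plateau, plateau_detected=False)

    spinodal = intercept + slope * breakpoint
    # delta method at fixed breakpoint: var = var_b + x0^2 var_s + 2 x0 cov
    var_spin = cov[0, 0] + breakpoint**2 * cov[1, 1] + 2 * breakpoint * cov[0, 1]
    spinodal_se = float(np.sqrt(max(var_spin, 0.0)))
    return PhaseBoundaryEstimate(
        binodal=intercept, binodal_se=intercept_se,
        spinodal=float(spinodal), spinodal_se=spinodal_se,
        breakpoint=float(breakpoint),
        slope=slope, slope_se=slope_se, r2_linear=r2_linear,
        n_linear=n_linear, n_plateau=n_plateau, plateau_detected=True)
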