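"""Stejskal-Tanner fitting of PFG-STE echo decays for per-phase self-diffusion.

In a pulsed-field-gradient stimulated-echo (PFG-STE) experiment the echo
intensity of a freely diffusing species decays as

    I(g) = I0 * exp(-b * D),   b = (gamma * g * delta)^2 * (Delta - delta/3)

for rectangular gradient pulses of strength ``g`` and length ``delta``
separated by the diffusion delay ``Delta``.  Because mother-phase and
dense-phase ibuprofen give resolved peaks, each phase yields its own decay
curve and its own diffusion coefficient; the ratio D/D* quantifies how much
translational motion is slowed inside the dense liquid phase.

Fitting is linear in log space (ln I vs b), matching the conventional DOSY
work-up; a nonlinear exponential refit is available for noise robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

GAMMA_1H = 2.675e8  # proton gyromagnetic ratio, rad s^-1 T^-1

__all__ = ["DecayCurve", "DiffusionFit", "b_factor", "fit_stejskal_tanner",
           "diffusion_ratio", "GAMMA_1H"]


def b_factor(g, delta, Delta, gamma=GAMMA_1H):
    """Stejskal-Tanner b-factor (s m^-2) for rectangular gradient pulses.

    b = (gamma * g * delta)^2 * (Delta - delta/3).  ``g`` may be an array.
    """
    if Delta <= delta / 3:
        raise ValueError(f"require Delta > delta/3, got Delta={Delta}, delta={delta}")
    g = np.asarray(g, dtype=float)
    out = (gamma * g * delta) ** 2 * (Delta - delta / 3.0)
    return out if out.ndim else float(out)


@dataclass
class DecayCurve:
    """One PFG-STE gradient series for a single resolved peak.

    Either gradient strengths plus pulse parameters are given (the b-factors
    are computed), or precomputed b-factors are supplied directly via
    :meth:`from_b` for instruments with their own pulse-shape corrections.
    """

    g: np.ndarray                  # gradient strengths, T m^-1
    intensity: np.ndarray          # echo intensities, a.u.
    delta_s: float = 2e-3          # gradient pulse length, s
    Delta_s: float = 0.1           # diffusion delay, s
    gamma: float = GAMMA_1H
    phase: str = "mother"          # "mother" | "dense"
    b: np.ndarray = field(default=None, repr=False)  # s m^-2; computed if None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.b is None:
            self.g = np.asarray(self.g, dtype=float)
            if len(self.g) != len(self.intensity):
                raise ValueError("g and intensity must have the same length")
            if np.any(self.g < 0):
                raise ValueError("gradient strengths must be >= 0")
            if self.delta_s <= 0 or self.Delta_s <= 0:
                raise ValueError("delta and Delta must be > 0")
            self.b = b_factor(self.g, self.delta_s, self.Delta_s, self.gamma)
        else:
            self.b = np.asarray(self.b, dtype=float)
            if len(self.b) != len(self.intensity):
                raise ValueError("b and intensity must have the same length")
        if len(self.intensity) < 4:
            raise ValueError("need >= 4 points in a decay curve")

    @classmethod
    def from_b(cls, b, intensity, phase: str = "mother") -> "DecayCurve":
        """Build a curve from precomputed b-factors (s m^-2)."""
        return cls(g=None, intensity=intensity, phase=phase,
                   b=np.asarray(b, dtype=float))


@dataclass(frozen=True)
class DiffusionFit:
    """Result of a Stejskal-Tanner fit: D (m^2 s^-1), amplitude, diagnostics."""

    D: float
    D_se: float
    I0: float
    I0_se: float
    r2: float
    phase: str = "mother"
    success: bool = True


def fit_stejskal_tanner(curve: DecayCurve, nonlinear: bool = False) -> DiffusionFit:
    """Extract the self-diffusion coefficient from one echo-decay curve.

    Default work-up is linear least squares of ln(I) on b; D is the negative
    slope and I0 the exponential of the intercept, with standard errors
    propagated from the linear fit.  With ``nonlinear=True`` the log-linear
    estimate seeds a nonlinear fit of I0*exp(-b*D), whose errors are weighted
    correctly when the noise is additive in intensity.

    A non-increasing curve (fitted D <= 0) is returned with
    ``success=False`` rather than raising, so batch pipelines can flag it.
    """
    b, I = curve.b, curve.intensity
    if np.any(I <= 0):
        raise ValueError("non-positive intensity: log-decay undefined")
    if len(np.unique(b)) < 2:
        raise ValueError("need at least 2 distinct b values")
    res = stats.linregress(b, np.log(I))
    D = -res.slope
    I0 = float(np.exp(res.intercept))
    fit = DiffusionFit(
        D=float(D), D_se=float(res.stderr),
        I0=I0, I0_se=float(I0 * res.intercept_stderr),
        r2=float(res.rvalue**2), phase=curve.phase,
        success=bool(D > 0))
    if not nonlinear or not fit.success:
        return fit
    popt, pcov = curve_fit(lambda bb, i0, d: i0 * np.exp(-bb * d),
                           b, I, p0=[I0, D])
    perr = np.sqrt(np.diag(pcov))
    pred = popt[0] * np.exp(-b * popt[1])
    ss_res = float(np.sum((I - pred) ** 2))
    ss_tot = float(np.sum((I - I.mean()) ** 2))
    return DiffusionFit(
        D=float(popt[1]), D_se=float(perr[1]),
        I0=float(popt[0]), I0_se=float(perr[0]),
        r2=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        phase=curve.phase, success=bool(popt[1] > 0))


def diffusion_ratio(D_mother: float, D_dense: float) -> float:
    """Ratio D/D* of mother-phase to dense-phase diffusion coefficients.

    The dimensionless ratio quantifies the slow-down of translational motion
    in the dense liquid phase.  Reports conventionally round it to the
    nearest integer; this function returns the unrounded value.
    """
    if D_mother <= 0 or D_dense <= 0:
        raise ValueError("diffusion coefficients must be > 0")
    return D_mother / D_dense
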