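"""Protolysis speciation of a weak-acid drug (ibuprofen) from pH and titration bookkeeping.

Ibuprofen (IbuH) is a weak monoprotic acid, IbuH <=> Ibu- + H+.  Its aqueous
solubility is dominated by the deprotonated form, so supersaturation of the
protonated acid can be dialled in by lowering the pH of an ibuprofen-sodium
solution with HCl.  This module provides the mass-action bookkeeping for that
experiment: the protonated fraction at a given pH, the mother-phase IbuH
concentration implied by a measured pH, and the full forward model of a
double-dosing titration (HCl plus IbuNa dosed together so the total drug
concentration stays constant).

All equilibrium constants are on the molar concentration scale with activity
coefficients set to 1; the solutions involved are <= 3 mM, so the ideal-dilute
approximation is adequate.  Note that the acid dissociation exponent ``pKa``
of ibuprofen is *not* fixed by this package: the default of 4.4 is a typical
literature-range value and should be set explicitly for quantitative work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SpeciationConfig",
    "SpeciationState",
    "protonated_fraction",
    "mother_phase_ibuh",
    "solve_titration_state",
]


@dataclass(frozen=True)
class SpeciationConfig:
    """Composition and dosing parameters of a double-dosing titration.

    Parameters
    ----------
    pKa : float
        Acid dissociation exponent of the drug (dimensionless).  Default 4.4;
        not a measured quantity of this package — set it for your compound.
    Kw : float
        Ion product of water on the molar scale.
    c_tot_mM : float
        Total (invariant) drug concentration, mM.
    c_hcl_mM : float
        HCl titrant stock concentration, mM.
    c_ibuna_mM : float
        Drug-sodium-salt titrant stock concentration, mM.
    rate_mL_per_min : float
        Dosing rate of each titrant, mL/min.
    v0_mL : float
        Initial volume of the titration vessel, mL.
    """

    pKa: float = 4.4
    Kw: float = 1e-14
    c_tot_mM: float = 3.0
    c_hcl_mM: float = 15.0
    c_ibuna_mM: float = 6.0
    rate_mL_per_min: float = 0.2
    v0_mL: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 < self.pKa < 14.0):
            raise ValueError(f"pKa must be in (0, 14), got {self.pKa}")
        for name in ("Kw", "c_tot_mM", "c_hcl_mM", "c_ibuna_mM",
                     "rate_mL_per_min", "v0_mL"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")

    @property
    def Ka(self) -> float:
        return 10.0 ** (-self.pKa)


@dataclass(frozen=True)
class SpeciationState:
    """Species concentrations (mM) and pH at one titration instant."""

    pH: float
    c_IbuH: float
    c_Ibu_minus: float
    c_Na: float
    c_Cl: float
    V_total: float

    @property
    def c_tot(self) -> float:
        """Total drug concentration (mM) in the homogeneous solution."""
        return self.c_IbuH + self.c_Ibu_minus


def protonated_fraction(pH, pKa):
    """Fraction of the drug in the protonated (neutral-acid) form.

    Mass action for IbuH <=> Ibu- + H+ gives
    ``f = 1 / (1 + 10**(pH - pKa))``; f = 1/2 at pH = pKa and the function is
    strictly decreasing in pH.  Accepts scalars or arrays.
    """
    pH = np.asarray(pH, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** (pH - np.asarray(pKa, dtype=float)))
    return out if out.ndim else float(out)


def mother_phase_ibuh(pH, c_Ibu_minus, pKa):
    """Protonated-drug concentration in the mother phase from the measured pH.

    Mass action rearranged for the coexisting dilute (mother) phase:
    ``c_IbuH = c_Ibu- * 10**(pKa - pH)``.  This is how the mother-phase IbuH
    concentration is computed from a pH electrode reading once the deprotonated
    concentration is known from titration bookkeeping.

    Parameters
    ----------
    pH : float or array
    c_Ibu_minus : float or array
        Deprotonated drug concentration, mM (must be >= 0).
    pKa : float

    Returns
    -------
    c_IbuH in mM, same shape as the inputs.
    """
    c = np.asarray(c_Ibu_minus, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_Ibu_minus must be >= 0")
    out = c * 10.0 ** (np.asarray(pKa, dtype=float) - np.asarray(pH, dtype=float))
    return out if out.ndim else float(out)


def _charge_balance_residual(h: float, na: float, cl: float, c_a: float,
                             Ka: float, Kw: float) -> float:
    """Charge-balance residual (molar): [Na+]+[H+] - [Cl-]-[OH-]-[Ibu-].

    ``h``, ``na``, ``cl``, ``c_a`` in mol/L; [Ibu-] follows mass action with
    total acid ``c_a``.
    """
    ibu_minus = c_a * Ka / (Ka + h)
    return na + h - cl - Kw / h - ibu_minus


def solve_titration_state(v_HCl_mL: float, v_IbuNa_mL: float,
                          cfg: SpeciationConfig) -> SpeciationState:
    """Solve the homogeneous (single-phase) speciation after titrant addition.

    Assumes volume additivity and no dense phase.  The initial vessel contains
    ``cfg.c_tot_mM`` of fully dissociated drug sodium salt in ``cfg.v0_mL``;
    ``v_HCl_mL`` of HCl stock and ``v_IbuNa_mL`` of IbuNa stock have been
    added.  Finds the unique physical proton concentration satisfying charge
    balance + mass action + mass conservation by bracketing log10[H+] on
    [-14, 0] and polishing with Brent's method.

    Raises
    ------
    ValueError
        For negative volumes.
    RuntimeError
        If the root-finder fails to bracket/converge; the message carries the
        endpoint residuals.
    """
    if v_HCl_mL < 0 or v_IbuNa_mL < 0:
        raise ValueError("titrant volumes must be >= 0")
    V = cfg.v0_mL + v_HCl_mL + v_IbuNa_mL
    if V <= 0:
        raise ValueError("total volume must be positive")
    # totals in mol/L
    c_a = (cfg.v0_mL * cfg.c_tot_mM + v_IbuNa_mL * cfg.c_ibuna_mM) / V * 1e-3
    na = c_a  # all drug enters as the fully dissociated sodium salt
    cl = v_HCl_mL * cfg.c_hcl_mM / V * 1e-3
    Ka, Kw = cfg.Ka, cfg.Kw

    def f(log_h: float) -> float:
        return _charge_balance_residual(10.0 ** log_h, na, cl, c_a, Ka, Kw)

    lo, hi = -14.0, 0.0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise RuntimeError(
            "charge-balance root not bracketed on pH [0, 14]: "
            f"residual(pH=14)={flo:.3e}, residual(pH=0)={fhi:.3e}"
        )
    log_h = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    # Newton polish on the residual in h to push it to ~1e-16 molar
    h = 10.0 ** log_h
    for _ in range(3):
        res = _charge_balance_residual(h, na, cl, c_a, Ka, Kw)
        dres = 1.0 + Kw / h**2 + c_a * Ka / (Ka + h) ** 2
        h = max(h - res / dres, 1e-16)
    residual = _charge_balance_residual(h, na, cl, c_a, Ka, Kw)
    if abs(residual) > 1e-12:
        raise RuntimeError(f"speciation solver did not converge: residual={residual:.3e} M")
    ibu_minus = c_a * Ka / (Ka + h)
    return SpeciationState(
        pH=-np.log10(h),
        c_IbuH=(c_a - ibu_minus) * 1e3,
        c_Ibu_minus=ibu_minus * 1e3,
        c_Na=na * 1e3,
        c_Cl=cl * 1e3,
        V_total=V,
    )
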