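"""Synthetic-data generators emulating the LLPS titration/NMR study conditions.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the estimators assume, so the full chain is testable
without instrument data: double-dosing titration logs (pH vs added volumes),
two-phase peak-integral tables obeying mass conservation, PFG-STE echo
decays, T1/T2 relaxation pairs, and NOESY intensity sets.

Ground-truth defaults reproduce the reference ibuprofen experiment: 3 mM
total drug titrated with 15 mM HCl + 6 mM drug-sodium salt at 0.2 mL/min
each (the double-dosing scheme keeps the total concentration invariant),
binodal 0.43 mM and spinodal 0.71 mM, mother/dense diffusion coefficients of
order 5e-10 / 2e-12 m^2/s, rotational correlation times of 0.15/0.9 ns, and
dense-phase interproton distances of ~2.0-2.8 angstrom calibrated on the
2.456 angstrom intramolecular reference.

Noise models: multiplicative Gaussian on every NMR intensity (fractional
sigma), additive Gaussian on pH readings (sigma in pH units).  Every
generator is a deterministic function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .diffusion import GAMMA_1H, DecayCurve, b_factor
from .noe import D_REF_DEFAULT, NoePeakSet
from .relaxation import RelaxationMeasurement, t1t2_ratio_from_tauc
from .speciation import SpeciationConfig, protonated_fraction, solve_titration_state

__all__ = [
    "ScenarioConfig",
    "generate_titration_series",
    "titration_onset",
    "generate_partition_series",
    "generate_pfgste_decay",
    "generate_relaxation_pair",
    "generate_noesy_intensities",
    "generate_peak_table",
    "write_fixture_set",
]

#: mother-phase peak positions (ppm) used for the two-phase peak table;
#: approximate ibuprofen 1H assignments, aliphatic (a, b, c aliases the
#: alpha-methyl / isopropyl-methyl / methine groups) plus the aromatic ring
_PEAK_PPM = {
    "b": (0.86, "aliphatic"),
    "a": (1.46, "aliphatic"),
    "c": (1.84, "aliphatic"),
    "ar1": (7.12, "aromatic"),
    "ar2": (7.24, "aromatic"),
}
#: dense-phase twin offsets, ppm (upfield)
_PPM_SHIFT = {"aliphatic": 0.3, "aromatic": 0.5}


@dataclass
class ScenarioConfig:
    """Ground truth and noise levels of one synthetic study scenario.

    Defaults reproduce the reference ibuprofen experiment; every field is a
    dial for robustness studies, but the defaults ARE the study conditions.
    """

    binodal_mM: float = 0.43
    spinodal_mM: float = 0.71
    slope: float = 0.5                 # d c(IbuH)_L1 / d n* on the rising segment
    c_tot_mM: float = 3.0
    pKa: float = 4.4
    titration: SpeciationConfig = field(default_factory=SpeciationConfig)
    # per-composition (n*(IbuH)/V in mM) diffusion ground truths, m^2/s
    diffusion_mM_D_Dstar: tuple = (
        (0.271, 555e-12, 16.3e-12),
        (0.328, 546e-12, 5.8e-12),
        (0.412, 498e-12, 2.48e-12),
        (0.616, 491e-12, 2.05e-12),
    )
    tau_c_mother_s: float = 0.15e-9
    tau_c_dense_s: float = 0.9e-9
    larmor_frequency_Hz: float = 400e6
    distances_angstrom: dict = field(
        default_factory=lambda: {"a*-b*": 2.04, "b*-c*": 2.71})
    d_ref_angstrom: float = D_REF_DEFAULT
    sigma_integral: float = 0.02       # fractional, on peak integrals
    sigma_decay: float = 0.01          # fractional, on echo intensities
    sigma_relax: float = 0.02          # fractional, on T1 and T2
    sigma_noe: float = 0.02            # fractional, on NOESY intensities
    sigma_pH: float = 0.01             # additive, pH units
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.binodal_mM < self.spinodal_mM < self.c_tot_mM):
            raise ValueError("require 0 < binodal < spinodal < c_tot")
        for name in ("sigma_integral", "sigma_decay", "sigma_relax",
                     "sigma_noe", "sigma_pH"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")

    @property
    def breakpoint_mM(self) -> float:
        """Dense-phase amount at which the mother phase saturates."""
        return (self.spinodal_mM - self.binodal_mM) / self.slope

    def c_ibuh_of_nstar(self, n_star):
        """Noiseless mother-phase IbuH concentration (mM) vs dense amount."""
        n_star = np.asarray(n_star, dtype=float)
        out = np.minimum(self.binodal_mM + self.slope * n_star, self.spinodal_mM)
        return out if out.ndim else float(out)


# ---------------------------------------------------------------- titration

def generate_titration_series(cfg: ScenarioConfig, t_end_min: float = 60.0,
                              n_steps: int = 121, noisy_pH: bool = False,
                              seed: int | None = None) -> pd.DataFrame:
    """Forward-model log of a double-dosing titration.

    HCl and drug-salt titrants are dosed at the configured (equal) rates so
    the total drug concentration stays invariant while the pH falls.  The
    homogeneous speciation model yields pH and c(IbuH) at each instant; the
    ``turbid`` flag marks compositions past the binodal, where a dense phase
    would scatter light.  (pH past the onset is extrapolated from the
    homogeneous model; real post-onset readings would deviate.)

    With ``noisy_pH`` an additive Gaussian electrode noise (cfg.sigma_pH) is
    put on the reported pH column; the noiseless value stays in ``pH_true``.
    """
    if t_end_min < 0 or n_steps < 1:
        raise ValueError("infeasible dosing: t_end_min >= 0 and n_steps >= 1 required")
    t = np.linspace(0.0, t_end_min, n_steps)
    rate = cfg.titration.rate_mL_per_min
    rows = []
    for ti in t:
        v = rate * ti
        state = solve_titration_state(v, v, cfg.titration)
        rows.append({"time_s": ti * 60.0, "v_hcl_mL": v, "v_ibuna_mL": v,
                     "pH_true": state.pH, "c_IbuH_mM": state.c_IbuH})
    df = pd.DataFrame(rows)
    df["turbid"] = df["c_IbuH_mM"] > cfg.binodal_mM
    if noisy_pH and cfg.sigma_pH > 0:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        df["pH"] = df["pH_true"] + rng.normal(0.0, cfg.sigma_pH, len(df))
    else:
        df["pH"] = df["pH_true"]
    return df[["time_s", "v_hcl_mL", "v_ibuna_mL", "pH", "pH_true",
               "c_IbuH_mM", "turbid"]]


def titration_onset(cfg: ScenarioConfig, t_max_min: float = 600.0):
    """Time and composition at which the titration crosses the binodal.

    Root-finds the dosing time where the homogeneous-model c(IbuH) equals the
    configured binodal limit.  Returns (t_onset_min, c_IbuH_mM).
    """
    rate = cfg.titration.rate_mL_per_min

    def excess(t_min: float) -> float:
        v = rate * t_min
        return solve_titration_state(v, v, cfg.titration).c_IbuH - cfg.binodal_mM

    if excess(0.0) >= 0:
        return 0.0, solve_titration_state(0.0, 0.0, cfg.titration).c_IbuH
    if excess(t_max_min) < 0:
        raise ValueError(f"binodal not reached within {t_max_min} min of dosing")
    t_on = brentq(excess, 0.0, t_max_min, xtol=1e-10)
    v = rate * t_on
    return float(t_on), float(solve_titration_state(v, v, cfg.titration).c_IbuH)


# ----------------------------------------------------------------- partition

def generate_partition_series(cfg: ScenarioConfig, n_points: int = 12,
                              seed: int | None = None,
                              integral_scale: float = 100.0) -> pd.DataFrame:
    """Synthetic two-phase peak-integral table spanning both fit segments.

    Dense-phase amounts n*(Ibu)/V are laid out on a grid crossing the
    saturation breakpoint; the mother-phase IbuH concentration follows the
    linear-then-plateau ground truth.  Observables are then back-computed the
    way the instrument would produce them: peak integrals split
    proportionally to the per-phase amounts (conservation exact before
    noise), with multiplicative Gaussian noise ``sigma_integral`` on each
    integral, and the pH that mass action assigns to each composition with
    additive electrode noise ``sigma_pH``.

    Returns a frame with the raw columns (``pH, I_a, I_a_star``) plus
    ``true_``-prefixed ground-truth columns for recovery checks.
    """
    if n_points < 6:
        raise ValueError("need n_points >= 6 to span both segments")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    # cover the rising segment and the plateau with a margin on both sides
    n_star = np.linspace(0.12 * cfg.breakpoint_mM, 1.95 * cfg.breakpoint_mM, n_points)
    c_ibuh = cfg.c_ibuh_of_nstar(n_star)
    mother_total = cfg.c_tot_mM - n_star
    if np.any(c_ibuh >= mother_total):
        raise ValueError("scenario infeasible: c(IbuH) exceeds mother-phase total")
    # pH consistent with the mother-phase protonation equilibrium
    c_ibu_minus = mother_total - c_ibuh
    pH_true = cfg.pKa + np.log10(c_ibu_minus / c_ibuh)
    p = n_star / cfg.c_tot_mM
    I_a = integral_scale * (1.0 - p) * (1.0 + rng.normal(0.0, cfg.sigma_integral, n_points))
    I_a_star = integral_scale * p * (1.0 + rng.normal(0.0, cfg.sigma_integral, n_points))
    pH_obs = pH_true + rng.normal(0.0, cfg.sigma_pH, n_points)
    return pd.DataFrame({
        "pH": pH_obs, "I_a": I_a, "I_a_star": I_a_star,
        "true_n_star_mM": n_star, "true_c_IbuH_L1_mM": c_ibuh,
        "true_pH": pH_true,
    })


# ----------------------------------------------------------------- diffusion

def default_gradient_schedule(D: float, n_steps: int = 16, delta_s: float = 2e-3,
                              Delta_s: float = 0.1, gamma: float = GAMMA_1H,
                              max_attenuation: float = 3.0) -> np.ndarray:
    """Linearly spaced gradient strengths reaching ~exp(-3) attenuation.

    Scales the maximum gradient to the expected diffusion coefficient, as an
    operator would when setting up a DOSY series for a slow or fast species.
    """
    b_unit = b_factor(1.0, delta_s, Delta_s, gamma)   # b at g = 1 T/m
    g_max = np.sqrt(max_attenuation / (D * b_unit))
    return np.linspace(g_max / n_steps, g_max, n_steps)


def generate_pfgste_decay(D: float, sigma: float | None = None,
                          schedule: np.ndarray | None = None,
                          seed: int | None = None, I0: float = 100.0,
                          delta_s: float = 2e-3, Delta_s: float = 0.1,
                          gamma: float = GAMMA_1H, n_steps: int = 16,
                          phase: str = "mother") -> DecayCurve:
    """Synthetic PFG-STE echo decay for a species of diffusivity ``D``.

    I(g) = I0 * exp(-b(g) * D) with multiplicative Gaussian noise of
    fractional width ``sigma``.  The gradient schedule defaults to
    :func:`default_gradient_schedule` for the given ``D``.
    """
    if D <= 0:
        raise ValueError("D must be > 0")
    sigma = 0.01 if sigma is None else sigma
    if schedule is None:
        schedule = default_gradient_schedule(D, n_steps=n_steps, delta_s=delta_s,
                                             Delta_s=Delta_s, gamma=gamma)
    b = b_factor(schedule, delta_s, Delta_s, gamma)
    I = I0 * np.exp(-b * D)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        I = I * (1.0 + rng.normal(0.0, sigma, len(b)))
    return DecayCurve(g=np.asarray(schedule, float), intensity=I,
                      delta_s=delta_s, Delta_s=Delta_s, gamma=gamma, phase=phase)


# ---------------------------------------------------------------- relaxation

def generate_relaxation_pair(tau_c: float, nu0: float, sigma: float = 0.02,
                             seed: int | None = None, T1_scale_s: float = 2.0,
                             peak: str = "a") -> RelaxationMeasurement:
    """Synthetic (T1, T2) measurement for a given rotational correlation time.

    The T1/T2 ratio follows the forward like-spin dipolar model at the proton
    Larmor frequency ``nu0``; the absolute scale is set by a nominal T1
    (``T1_scale_s``) since the dipolar prefactor cancels in the inversion.
    Gaussian fractional noise ``sigma`` is applied to both times, re-clipped
    to the physical ordering T1 >= T2.
    """
    if tau_c <= 0:
        raise ValueError("tau_c must be > 0")
    ratio = t1t2_ratio_from_tauc(tau_c, 2.0 * np.pi * nu0)
    T1, T2 = T1_scale_s, T1_scale_s / ratio
    if sigma > 0:
        rng = np.random.default_rng(seed)
        T1 = T1 * (1.0 + rng.normal(0.0, sigma))
        T2 = T2 * (1.0 + rng.normal(0.0, sigma))
        T2 = min(T2, T1)
    return RelaxationMeasurement(T1=T1, T2=T2, larmor_frequency=nu0, peak=peak)


# ----------------------------------------------------------------------- NOE

def generate_noesy_intensities(distances: dict | None = None,
                               d_ref: float = D_REF_DEFAULT, I_ref: float = 1.0,
                               sigma: float = 0.02, seed: int | None = None,
                               reference_pair: str = "a*-c*") -> NoePeakSet:
    """Synthetic NOESY cross-peak set from ground-truth distances.

    Each non-reference intensity follows the r^-6 forward model
    I = I_ref * (d_ref/d)^6; the reference pair is included at ``I_ref``.
    Multiplicative Gaussian noise ``sigma`` applies to every intensity,
    reference included (distance estimates only depend on intensity ratios).
    """
    if distances is None:
        distances = {"a*-b*": 2.04, "b*-c*": 2.71}
    if any(d <= 0 for d in distances.values()):
        raise ValueError("distances must be > 0")
    rng = np.random.default_rng(seed)
    intensities = {reference_pair: I_ref}
    for pair, d in distances.items():
        intensities[pair] = I_ref * (d_ref / d) ** 6
    if sigma > 0:
        intensities = {pair: I * (1.0 + rng.normal(0.0, sigma))
                       for pair, I in intensities.items()}
    return NoePeakSet(intensities=intensities, reference_pair=reference_pair,
                      d_ref=d_ref)


# ----------------------------------------------------------------- 1D peaks

def generate_peak_table(cfg: ScenarioConfig, n_star_mM: float = 0.0) -> pd.DataFrame:
    """Two-phase 1D peak list: mother-phase peaks plus dense-phase twins.

    Dense-phase twin peaks are offset upfield by 0.3 ppm (aliphatic) or
    0.5 ppm (aromatic); integrals split between the phases according to the
    partition model at dense-phase amount ``n_star_mM``.  A single-phase
    composition (``n_star_mM = 0``) emits no starred peaks.  Exercises
    real-data ingestion paths only; no lineshape physics.
    """
    if not (0.0 <= n_star_mM <= cfg.c_tot_mM):
        raise ValueError("n_star_mM must lie in [0, c_tot]")
    p = n_star_mM / cfg.c_tot_mM
    rows = []
    for label, (ppm, kind) in _PEAK_PPM.items():
        rows.append({"peak": label, "ppm": ppm, "kind": kind,
                     "phase": "mother", "integral": 100.0 * (1.0 - p)})
        if p > 0:
            rows.append({"peak": label + "*", "ppm": ppm - _PPM_SHIFT[kind],
                         "kind": kind, "phase": "dense", "integral": 100.0 * p})
    return pd.DataFrame(rows)


# -------------------------------------------------------------- fixture sets

def write_fixture_set(cfg: ScenarioConfig, out_dir, n_partition_points: int = 12,
                      titration_minutes: float = 40.0) -> dict:
    """Write the full synthetic input set plus a ground-truth manifest.

    Produces ``titration.csv``, ``partition.csv``, per-composition decay
    CSVs, ``relaxation.csv`` and ``noesy.csv`` under ``out_dir``, and a
    ``manifest.json`` recording the scenario ground truth, the seed, and the
    file roles — the input contract of :func:`llps_nmr.pipeline.run_pipeline`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = np.random.SeedSequence(cfg.seed)
    seeds = [int(s) for s in seq.generate_state(4 + 2 * len(cfg.diffusion_mM_D_Dstar))]

    titr = generate_titration_series(cfg, t_end_min=titration_minutes,
                                     noisy_pH=True, seed=seeds[0])
    titr[["time_s", "v_hcl_mL", "v_ibuna_mL", "pH"]].to_csv(
        out / "titration.csv", index=False)

    part = generate_partition_series(cfg, n_points=n_partition_points, seed=seeds[1])
    part[["pH", "I_a", "I_a_star"]].to_csv(out / "partition.csv", index=False)

    decays = []
    k = 4
    for comp, D, D_star in cfg.diffusion_mM_D_Dstar:
        for phase, Dval in (("mother", D), ("dense", D_star)):
            curve = generate_pfgste_decay(Dval, sigma=cfg.sigma_decay,
                                          seed=seeds[k], phase=phase)
            k += 1
            name = f"decay_{phase}_{comp:.3f}.csv"
            pd.DataFrame({"g_T_per_m": curve.g, "intensity": curve.intensity}).to_csv(
                out / name, index=False)
            decays.append({"file": name, "phase": phase, "composition_mM": comp,
                           "delta_s": curve.delta_s, "Delta_s": curve.Delta_s,
                           "gamma": curve.gamma})

    relax_rows = []
    for peak, tau in (("a", cfg.tau_c_mother_s), ("a*", cfg.tau_c_dense_s)):
        m = generate_relaxation_pair(tau, cfg.larmor_frequency_Hz,
                                     sigma=cfg.sigma_relax, seed=seeds[2], peak=peak)
        relax_rows.append({"peak": peak, "T1_s": m.T1, "T2_s": m.T2})
    pd.DataFrame(relax_rows).to_csv(out / "relaxation.csv", index=False)

    peaks = generate_noesy_intensities(cfg.distances_angstrom, cfg.d_ref_angstrom,
                                       sigma=cfg.sigma_noe, seed=seeds[3])
    noesy_rows = [{"pair": pair, "intensity": I,
                   "is_reference": pair == peaks.reference_pair}
                  for pair, I in peaks.intensities.items()]
    pd.DataFrame(noesy_rows).to_csv(out / "noesy.csv", index=False)

    manifest = {
        "seed": cfg.seed,
        "ground_truth": {
            "binodal_mM": cfg.binodal_mM, "spinodal_mM": cfg.spinodal_mM,
            "slope": cfg.slope, "c_tot_mM": cfg.c_tot_mM, "pKa": cfg.pKa,
            "diffusion_mM_D_Dstar": [list(row) for row in cfg.diffusion_mM_D_Dstar],
            "tau_c_mother_s": cfg.tau_c_mother_s,
            "tau_c_dense_s": cfg.tau_c_dense_s,
            "distances_angstrom": cfg.distances_angstrom,
        },
        "parameters": {
            "c_tot_mM": cfg.c_tot_mM, "pKa": cfg.pKa,
            "larmor_frequency_Hz": cfg.larmor_frequency_Hz,
            "d_ref_angstrom": cfg.d_ref_angstrom,
        },
        "inputs": {
            "titration": "titration.csv",
            "partition": "partition.csv",
            "decays": decays,
            "relaxation": "relaxation.csv",
            "noesy": "noesy.csv",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
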