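# Methods

This note documents the models behind `llps_nmr`, the choices made where the
design was open, and what the synthetic-data tests do and do not demonstrate.

## Scientific setting

Ibuprofen (IbuH) is a weak monoprotic acid whose neutral form is poorly
water-soluble. Lowering the pH of an ibuprofen-sodium solution converts Ibu⁻
to IbuH and drives the solution supersaturated; before any crystal appears,
the solution demixes into a dilute "mother" phase (L1) and a dense,
drug-enriched liquid phase. The dense phase is a nucleation precursor: it is
kinetically stabilized by strongly hindered molecular motion, and the
molecules inside it already sit at near-crystalline interproton distances.
The package quantifies this picture from five kinds of tabular NMR/titration
data, each handled by one module.

## Speciation (`speciation`)

Mass action for IbuH ⇌ Ibu⁻ + H⁺ at ideal-dilute activity (all
concentrations ≤ 3 mM) gives the protonated fraction
`f(pH) = 1/(1+10^(pH−pKa))` and the mother-phase relation
`c(IbuH) = c(Ibu⁻)·10^(pKa−pH)`. The forward titration model solves the
coupled charge balance `[Na⁺]+[H⁺] = [Cl⁻]+[OH⁻]+[Ibu⁻]`, water autoprotolysis
(Kw = 10⁻¹⁴) and acid mass action for the unique physical [H⁺], by Brent
bracketing on log₁₀[H⁺] ∈ [−14, 0] followed by a Newton polish; accepted
roots have charge-balance residuals below 10⁻¹² M.

Assumptions: volume additivity of titrants, activity coefficients of 1, no
ionic-strength correction, and negligible mother-phase volume loss to the
dense phase. **pKa is an input, not a result**: the default 4.4 is a typical
literature-range value for ibuprofen and must be set explicitly for
quantitative work on another compound (or another ionic background).

## Phase-boundary location (`partition`)

In a demixed sample every proton signal splits into a mother-phase peak (a)
and a dense-phase twin (a*). Since both phases are observed in one spectrum,
the integral split gives the dense-phase amount per total volume
`n*/V = c_tot·I(a*)/(I(a)+I(a*))`, and conservation fixes the mother-phase
total at `c_tot − n*/V` — the two outputs sum to `c_tot` by construction,
which the tests assert at machine precision. The mother-phase IbuH
concentration follows from the measured pH via the protonated fraction.

Plotting `c(IbuH)_L1` against `n*/V` exposes the miscibility gap: the
y-offset of the initial linear rise is the **binodal** limit, and the
saturation plateau is the **spinodal** limit (past it the dense-phase
composition no longer responds to added IbuH). Rather than hand-selecting
"low-concentration" points for the linear fit, both boundaries come from one
continuous two-segment model,

    c(x) = binodal + slope · min(x, x0),   spinodal = binodal + slope·x0,

linear in (binodal, slope) at fixed breakpoint x0. The profile sum of squares
is scanned over 512 breakpoint candidates spanning the interior of the data
and polished by bounded scalar minimisation (xatol 10⁻¹²), so noiseless
piecewise data is recovered exactly (< 10⁻⁶ mM). A manual breakpoint can be
passed instead. If the optimal breakpoint lands at the data edge (fewer than
two plateau points) the spinodal is reported as undetermined rather than
extrapolated. OLS is unweighted (integral noise treated as homoscedastic);
standard errors of the plateau level use the delta method at fixed x0, i.e.
they do not include breakpoint-location uncertainty.

The abscissa is taken to be `n*(Ibu)/V_total` (the dense-phase amount), the
reading most consistent with conservation bookkeeping; tables already
reduced to `n_star_mM, c_IbuH_L1_mM` are accepted as-is.

## Translational diffusion (`diffusion`)

PFG-STE echo decays follow Stejskal–Tanner,
`I(g) = I0·exp(−bD)` with `b = (γgδ)²(Δ−δ/3)` for rectangular gradient
pulses (¹H γ = 2.675×10⁸ rad s⁻¹ T⁻¹; defaults δ = 2 ms, Δ = 100 ms).
Instruments applying their own pulse-shape corrections can supply a
precomputed `b` column instead. The default work-up is linear least squares
of ln I on b (D = −slope, errors from the linear fit); with 1% multiplicative
intensity noise this is unbiased to well under 0.5% because multiplicative
noise is additive and homoscedastic in log space. A nonlinear exponential
refit is available for noise that is additive in intensity. Curves that do
not decay are flagged (`success=False`) rather than raised, so batch runs
can report partial failures. Mother- and dense-phase peaks are resolved, so
each phase is fit as its own single-exponential curve; no biexponential
deconvolution is attempted. The ratio D/D* is reported both raw and rounded
to the nearest integer (the convention for quoting slow-down factors).

## Rotational correlation times (`relaxation`)

For like-spin (¹H–¹H) dipolar relaxation with spectral density
`J(ω) = 2τc/(1+ω²τc²)`,

    1/T1 ∝ J(ω0) + 4J(2ω0)
    1/T2 ∝ (3/2)J(0) + (5/2)J(ω0) + J(2ω0),

the prefactor (and hence the interproton distances driving relaxation)
cancels in T1/T2, which is 1 in extreme narrowing and strictly increasing in
ω0τc. The inversion root-finds ω0τc by Brent bisection on a log grid
(bracket 10⁻⁸–10⁴); the forward/inverse roundtrip is exact to < 10⁻⁹
relative over 10 ps–100 ns, and agrees with a 10⁶-point brute-force grid
oracle to < 10⁻⁴. The exact spectral-density ratio is inverted numerically
rather than through a closed-form approximation — the numerical inversion
is exact within solver tolerance, and the independent grid oracle in the
test suite stands in as the cross-check. Measurements with T1/T2 ≤ 1+10⁻⁶
are in extreme narrowing: τc is then only bounded from above and the result
is flagged unconverged, carrying that bound. CSA and heteronuclear
contributions are ignored (dipolar mechanism assumed dominant), and the
Larmor frequency (default 400 MHz) is a required input for real data.

The dense/mother τc ratio ("contrast factor") quantifies rotational
slow-down; note that with translation slowed 34–239× but rotation only
5–7×, the two do not report the same viscosity, so no Stokes–Einstein/
Stokes–Debye viscosity is computed anywhere in the package.

## NOE distances (`noe`)

In the initial-rate regime NOESY cross-peak intensities scale as d⁻⁶, so one
peak of known geometry calibrates the rest:
`d = (I_ref/I)^{1/6}·d_ref`. The intramolecular (a)–(c) distance of
ibuprofen, 2.456 Å, is the reference. Intermolecular contributions to the
reference peak are neglected (they are suppressed by the same d⁻⁶
weighting); multi-contact peaks are modelled additively,
`I = I_ref·Σ(d_ref/dᵢ)⁶`, so a calibrated multi-contact peak returns the
r⁻⁶-weighted effective distance, which the closest contact dominates.
Distances above the ~5 Å NOE ceiling are flagged, not dropped. No
relaxation-matrix (spin-diffusion) treatment is attempted.

## Crystal contacts (`contacts`)

Minimum intra-/intermolecular proton-group distances are computed by an
exhaustive all-pairs scan over an explicit Cartesian cluster (extended XYZ
with per-atom molecule id and group label). At cluster scale the exhaustive
scan *is* the reference algorithm. Crystallographic symmetry expansion and
CIF parsing are out of scope; the published crystal-contact distances of S-
and racemic ibuprofen are shipped as clearly-labelled literature constants
for the comparison report only.

## Synthetic data (`synthetic`)

The generators emit every input the pipeline consumes, with the statistical
structure the estimators assume. Defaults are the reference study
conditions: 3 mM total drug; 15 mM HCl and 6 mM IbuNa titrants at 0.2
mL/min each (equal dosing keeps the total concentration invariant — the
point of the double-dosing scheme); binodal 0.43 mM, spinodal 0.71 mM;
per-composition diffusion ground truths of (555, 16.3), (546, 5.8),
(498, 2.48), (491, 2.05) ×10⁻¹² m²/s; dense-phase NOE distances 2.04 and
2.71 Å against the 2.456 Å reference. Values the study does not print were
fixed once at realistic levels and are config-exposed:

- linear-segment slope 0.5 mM/mM (breakpoint n* = 0.56 mM, inside the
  sampled 0.07–1.1 mM grid of the 12-point partition series);
- τc 0.15 ns (mother) and 0.9 ns (dense) at 400 MHz — a 6× contrast, the
  middle of the observed 5–7× range;
- initial titration volume 50 mL (sets only the time axis);
- noise: multiplicative Gaussian on all NMR intensities (2% integrals, 1%
  echo intensities, 2% T1/T2, 2% NOESY) and additive 0.01-unit Gaussian on
  pH readings — chosen to make recovery non-trivial but reliable.

Partition observables are back-computed the way the instrument would produce
them: integrals split proportionally to the per-phase amounts before noise,
and the pH of each composition follows from the mother-phase protonation
equilibrium, so the reduction path of the analysis is exercised end to end.
The titration generator's pH is the noiseless forward model by default (its
monotone decrease is a contract); electrode noise is applied where pH is a
measured input. The saturation model is the same hard changepoint the
estimator assumes — by design, so parameter recovery isolates estimator
error; a smooth-saturation stressor can be emulated by passing a manual
breakpoint to `fit_spinodal`, but model-mismatch robustness is not what the
recovery tests measure.

**What passing tests show**: the estimators are unbiased and precise at the
stated noise levels under the assumed noise model, and every formula
inverts its own forward model exactly. **What they do not show**: robustness
to peak overlap, baseline/phasing error, temperature drift, exchange
broadening, or noise structure different from multiplicative Gaussian —
none of which the generators emulate.

## Problem sizes

Recovery statistics use 50 replicates of 12-point partition series, 200
replicates of 16-point decay curves, 50 replicates of relaxation pairs, and
a 10⁶-point inversion oracle grid — sizes at which the Monte-Carlo error of
the reported medians/means is an order of magnitude below the tolerances
being checked, while the full suite runs in seconds.

## Known limitations

- No raw-spectrum processing: integrals, T1/T2, and NOESY intensities are
  inputs. No turbidity optics; turbidity appears only as a threshold flag.
- Boundary standard errors ignore breakpoint-location uncertainty.
- The speciation model is ideal-dilute; above ~10 mM ionic strength the
  missing activity corrections would bias pH-derived concentrations.
- The NOE ceiling flag uses a nominal 5 Å cutoff; the true detection limit
  depends on mixing time and correlation time.
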