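# Methods

## Slab model and derived quantities

An adsorbed protein layer is represented as N homogeneous slabs on a
Si / native-SiO₂ substrate, bounded by semi-infinite silicon (fronting)
and aqueous solvent (backing).  Slab *i* carries a thickness τᵢ (Å), a
protein volume fraction φᵢ ∈ [0, 1] and a Gaussian interfacial width
σᵢ (Å).  Protein and water are assumed to fill each slab completely
(φ_water = 1 − φ), so the slab SLD is the volume-weighted mixture of
the two component SLDs.  The protein SLD depends on the solvent
because labile hydrogens (amide and polar/charged side-chain protons)
exchange with solvent deuterium; we interpolate linearly in solvent
SLD between the H₂O and D₂O values of each species.  The shipped
constants for the mAb (COE-3 type IgG1, MW 144 827 g/mol,
V 171 740 Å³) and its Fab/Fc fragments include contrast-matched (CM4)
SLD values that agree with the linear interpolation to two decimals,
which is why no third anchor is used.

Derived quantities:

- **Adsorbed amount** Γᵢ = τᵢ φᵢ MW/(V N_A), converted to mg m⁻²
  (N_A = 6.02214076×10²³ mol⁻¹ exactly).  The prefactor MW/(V N_A) is
  the dry protein mass density (≈1.40 g/cm³ for the shipped IgG),
  making Γ the mass of a τφ-thick compact protein film.
- **Volume-fraction profile** φ(z), a step function with z = 0 at the
  oxide/solvent boundary and z positive into the solvent; optionally
  roughness-broadened with error-function transitions (these are
  antisymmetric about each boundary, so the integral ∫φ dz = Σ τᵢφᵢ is
  preserved).
- **Mass-center distance** z̄ = ∫zφ dz / ∫φ dz, computed analytically
  for step profiles and by the trapezoid rule for gridded ones.
- **Layer summary**: per-slab and total τ and Γ, thickness-weighted
  mean φ, per-slab mass fractions Γᵢ/Γ.  Totals are computed from
  unrounded slab values.

## Reflectivity forward model

Specular reflectivity is computed with the optical transfer-matrix
(Abeles) method.  The perpendicular wavevector in layer *i* is
kᵢ = sqrt((Q/2)² − 4π(ρᵢ − ρ_fronting)), taking the complex square
root with non-negative imaginary part so evanescent waves decay.
Interface Fresnel coefficients are damped by Névot–Croce factors
exp(−2kᵢkᵢ₊₁σ²).  The kernel returns R ∈ [0, 1] with R = 1 below the
critical edge Q_c = 4√(πΔρ); instrument effects (multiplicative scale,
additive background, Gaussian fractional resolution) are applied on
top.  Resolution smearing uses a 13-point Gaussian-weighted stencil
spanning ±3.5σ_Q with σ_Q = (dQ/Q)·Q/2.355; default dQ/Q = 0.04
(FWHM), typical of time-of-flight reflectometers.  A compiled (numba)
scalar-loop kernel and a pure-numpy reference implementation agree to
~1e-15 and the numpy path is used automatically when numba is absent.

Default substrate constants — Si 2.07×10⁻⁶ Å⁻², SiO₂ 3.41×10⁻⁶ Å⁻²,
15 Å oxide, 3 Å roughness — are literature-standard values for
polished wafers; all are configurable, as is solvent penetration into
the oxide (default 0).  Absorption is neglected (imaginary SLD = 0)
for these materials; polarized and off-specular scattering are out of
scope.

## Multi-contrast co-refinement

One structural parameter set (τᵢ, φᵢ, optionally σᵢ) is shared across
all contrasts; only instrument terms may vary per contrast (scales
fixed at 1 by default, backgrounds free within [0, 10⁻⁵]).  At every
objective evaluation the slab SLDs are rebuilt per contrast from φ and
the exchange-adjusted protein SLD, so the same structure must explain
every curve.  The objective is the normalized χ² =
Σ[(R_model − R_data)/δR]²/N pooled over all points; datasets lacking
uncertainties fall back to unweighted residuals with a warning.

Optimisation is a seeded differential-evolution global search
(Sobol initialisation, population ~12×n_params, ≤60 generations)
followed by a bounded trust-region least-squares polish with tight
tolerances; identical seeds give bit-identical results.  Default
bounds: τ ∈ [5, 120] Å, φ ∈ [0, 0.7], background ∈ [0, 10⁻⁵],
scale ∈ [0.9, 1.1].  Model evaluation batches all contrasts and
stencil points into one kernel call for speed.

**Slab-count selection** fits n = 1…max and picks the smallest n whose
relative χ² improvement to n+1 falls below 10%; on synthetic two-slab
data shaped like the published layer this selects 2 slabs while the
1-slab fit is an order of magnitude worse.

**Bootstrap.**  Data points are resampled with replacement within each
contrast; a resample that draws point *i* cᵢ times is refit by scaling
its uncertainty to δRᵢ/√cᵢ (exactly equivalent to duplicating rows in
least squares, with omitted points dropping out).  Residual resampling
(permuting standardized residuals onto the fitted curve) is available
by flag.  Each resample is refit locally from the full-data optimum —
resamples perturb the objective only slightly, so the basin does not
change — with slightly relaxed tolerances (xtol = ftol = 10⁻⁸,
≤120 evaluations) for speed.  Reported intervals are 68% and 95%
percentiles for parameters and for derived Γ, mass center and total
thickness; failed refits are skipped and counted.

**Calibration.**  `adlayer.calibration.bootstrap_coverage` repeats the
whole pipeline over independent noise realisations and scores how
often the 68% interval covers the generating truth.  At the default
study conditions (2% noise, three contrasts, 40 Q points per contrast,
200 resamples, 50 experiments) coverage lands near the nominal 68%.
A small upward bias of the fitted Γ (~0.5 of its standard error,
a nonlinearity/bound effect of the weighted fit) is visible in the
ensemble but does not push coverage outside 55–80%.

## Synthetic data

The generator emulates the study conditions: 2-slab layers on the
default substrate, three contrasts (D₂O 6.35, CM4 4.0, H₂O
−0.56 ×10⁻⁶ Å⁻²), Q log-spaced over 0.008–0.25 Å⁻¹ (80 points by
default; 40 in the calibration study for desk-scale runtime), 4% dQ/Q,
and Gaussian noise with σ = max(0.02·R, 5×10⁻⁷).  The noise is left
uncensored — weak points may fluctuate below zero, as real
background-subtracted reflectivity does; censoring at zero would bias
fits upward relative to the Gaussian model the refinement assumes.
Every dataset carries a JSON ground-truth sidecar sufficient to
recompute all summaries.  What this does not emulate: instrument-
specific Q-dependent resolution tables, correlated systematics
(misalignment, normalisation drift), surface heterogeneity, or
off-specular signal — so passing recovery tests demonstrates the
estimator works under the stated noise model, not that real-data
systematics are handled.

Pseudo-protein clouds are three uniform-density ellipsoids (two
Fab-like, 47.3 kDa each, semi-axes 40×25×22.5 Å; one Fc-like, 50.2 kDa)
summing to the 144.8 kDa antibody mass.  "Flat-on" rests the Fabs on
the surface (short 45 Å axis vertical) with the Fc beside them; its
natural mass center is ≈28 Å.  "Tilted" stands the 70 Å Fc axis along
z above surface-anchored Fabs, extending the 95%-mass reach by tens of
Å — mirroring the compact-vs-extended layer structures seen at the two
pH conditions.  If `center_z` is given the cloud is translated so its
mass center sits exactly there.

## Atomistic metrics

- Density profiles are mass histograms along z − z_surface; the
  surface plane defaults to the topmost surface-tagged atom.  Mass is
  conserved for any bin width; atoms below the plane are binned with a
  warning.
- Contact counts use a k-d tree: a protein atom is in contact if any
  surface atom lies within the cutoff (default 5 Å, closed boundary —
  an atom exactly at the cutoff counts).  No periodicity by default.
- RMSD is the unweighted root-mean-square deviation; optional
  superposition uses the Kabsch rigid-body alignment, and both raw and
  superposed values are meaningful (superposed ≤ raw).
- NR/MD profile comparison normalizes both curves to unit area
  (absolute normalisations of atomistic density and NR volume fraction
  are not commensurate) and reports mass-center difference, 95%-mass
  extents and the overlap integral of the unit-area shapes.

## Ellipsometry

De Feijter's relation Γ = τ(n_f − n₀)/(dn/dc) with dn/dc = 0.18 mL/g
(standard protein value at 630 nm) and ambient index n₀ = 1.335
(aqueous buffer at 630 nm; configurable — instrument vendors do not
publish their internal value).  Cauchy dispersion n(λ) = A + B/λ² is
interpreted with λ in µm (the usual ellipsometry convention for
B ≈ 0.003).  Kinetic series are reduced to a plateau (mean over the
final 20% of the time span) and a time-to-plateau (first time the
signal permanently enters a ±5% band around the plateau).

## Numerical choices and limitations

- Model-to-data interpolation, when grids differ, is linear in log R
  where R > 0.
- Out-of-range inverted volume fractions either raise (default) or
  clamp to [0, 1] with a warning, for noisy fitted SLDs.
- The χ² elbow threshold (10%) reproduces the expected 2-slab choice
  on synthetic data; it is a heuristic, not an information criterion.
- Slab order is surface-outward and not symmetric: reflectivity
  distinguishes inner from outer slabs through interference with the
  substrate, so no canonicalisation is applied.
- Bootstrap refits are local by design; if the objective had multiple
  competitive basins the intervals would understate the uncertainty.
- Problem sizes in the shipped studies (40–80 Q points, 200 resamples,
  50 calibration experiments) are the package's desk-scale defaults;
  all are parameters.
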