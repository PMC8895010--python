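# Methods

This note records the models implemented in `mesocluster`, the assumptions
behind them, the defaults and units, and the numerical choices — in enough
detail that a user can judge what a passing test suite does and does not
demonstrate about real data.

## Scientific setting

Concentrated solutions of small organic molecules (the reference system is
2-cyano-4'-methylbiphenyl, "OTBN", in methanol) can contain mesoscale
solute-rich clusters — liquid-like domains tens of nanometres across that
persist at a steady size and act as crystal-nucleation precursors.  A
cluster of pure monomers cannot be stable: the excess free energy per
molecule rises with concentration, so Fickian transport along the
chemical-potential gradient would dissolve it.  Stability requires a second
species.  The package implements the quantitative chain supporting a
monomer–dimer mechanism: dimers form in solution (NMR dilution series),
are transported (DOSY diffusion coefficients), accumulate in a cluster
whose interior favours them, and decay back to monomers at a rate that
fixes both the cluster's diffuse boundary and its steady radius.

## Solution thermodynamics from static light scattering

A Debye plot records `Kc/R_θ` against mass concentration `c`, where
`K = 4π²n²(dn/dc)²/(N_A λ⁴)` is the optical constant and `R_θ` the Rayleigh
ratio.  This ratio equals `(1/RT)∂Π/∂c` and is fitted with the osmotic
virial expansion

    Kc/R_θ = 1/Mw + 2·A2·c + 3·A3·c²

by weighted linear least squares (weights `1/σ²` when per-point
uncertainties are given, ordinary least squares otherwise).  The default
order fits `A3` but falls back to the two-parameter model when an F-test at
the 5% level cannot distinguish the cubic term from zero; shallow Debye
plots otherwise overfit.  The parameter covariance for `Mw` is obtained
from the linear-parameter covariance by the delta method.

The excess free energy per molecule between concentrations `c_L < c_H`
follows from the per-molecule chemical-potential increment
`dμ = dΠ/ρ_N`, `ρ_N = c·N_A/M`:

    Δg = (M·R·T/N_A) [ (1/Mw)·ln(c_H/c_L) + 2A2(c_H−c_L) + (3/2)A3(c_H²−c_L²) ]

Both the closed form and an adaptive quadrature of `(Kc/R_θ)(c)/c` are
implemented; they agree to ~1e-10 relative and the tests hold them to
1e-8.  Concentrations are held internally in g ml⁻¹; Δg is reported in J
and in units of k_BT.  Zero-angle (extrapolated) intensities are assumed;
no angular dependence, form factor or polydispersity is modelled.

## Monomer–dimer speciation and the NMR dilution isotherm

The dimerization constant convention is `k_D = [D]/[M]²` (no statistical
factor), with mass balance `c = [M] + 2[D]`.  Speciation is closed-form:

    [D] = (4·k_D·c + 1 − sqrt(8·k_D·c + 1)) / (8·k_D)

Two population conventions are exposed and deliberately kept apart —
`2[D]/c` (fraction of molecules bound in dimers) and `[D]/([M]+[D])`
(fraction of species that are dimers) — because quoted "dimer
populations" depend on the convention and the two differ materially at
accessible concentrations.

Under fast exchange the observed shift of a carbon is the nucleus-weighted
average of its monomer and dimer environments,

    δ_obs(c) = δ_M + (δ_D − δ_M) · 2[D]/c

Fitting uses a single global `k_D` with one `(δ_M, δ_D)` pair per carbon
(per-carbon independent `k_D` is available as a diagnostic).  The
optimizer is restarted from 8 log-spaced `k_D` values in 10⁻³–10² M⁻¹ and
the lowest-RSS solution wins; on well-conditioned data all starts converge
to the same optimum.  The pooled R² is `1 − RSS/TSS` with the total sum of
squares centred per carbon, computed on unweighted residuals.  A fit whose
`k_D` is within two standard errors of zero is flagged `flat_model`; this
is the expected outcome for association-insensitive carbons.

At the default design — 12 concentrations in 0.02–0.5 M, three carbons
with limiting-shift spans of 0.50/0.45/0.40 ppm, shift noise σ = 0.002 ppm
— the measured estimator dispersion is std(k_D)/k_D ≈ 5%.  The spans sit
at the informative end of the plausible 0.1–0.5 ppm range for
aromatic-stacking shifts; with substantially smaller spans the same noise
level no longer supports ±10% recovery, which bounds what a dilution
series of this size can determine.

## Diffusion: DOSY and Stokes–Einstein

Echo attenuation follows the Stejskal–Tanner relation
`I(g) = I₀·exp(−D·γ²g²δ²(Δ−δ/3))`.  A log-linear regression seeds a
nonlinear least-squares refinement of `(I₀, D)` with `D ≥ 0`; noiseless
data are recovered exactly and 1% multiplicative noise gives a median
recovery error below 2% at the default design (12 gradients to 0.5 T m⁻¹,
δ = 4 ms, Δ = 100 ms, chosen so the echo attenuates to ~32% at maximum
gradient — a realistic bipolar-LED depth; much shallower attenuation
cannot support percent-level D estimates).  Only the standard
Stejskal–Tanner exponent is modelled; bipolar-pulse corrections are not.

Stokes–Einstein, `D = k_BT/(6πη·r_H)`, links D to the hydrodynamic
radius, so species in the same solution obey `D·r_H = const`.  The dimer
coefficient is obtained by inverse-radius scaling `D₂ = D₁·r₁/r₂` from
the measured monomer value; with D₁ = 4×10⁻¹¹ m² s⁻¹, r₁ = 3.72 Å and
r₂ = 4.65 Å this gives D₂ = 3.2×10⁻¹¹ m² s⁻¹.  The radii themselves are
inputs (obtained upstream from a cylindrical hydrodynamic model); the
package does not compute radii from molecular geometry.

## Reaction–diffusion model of a stabilized cluster

Mass-action kinetics for 2M ⇌ D,

    dn₁/dt = −2k₁n₁² + 2k₂n₂ ,   dn₂/dt = k₁n₁² − k₂n₂ ,

conserve `n₁ + 2n₂` identically.  Bulk equilibrium fixes
`k₁n₁∞² = k₂n₂∞`, and `k₁/k₂ = k_D/(N_A·10³)` m³ converts the
solution-phase constant to number-density units.

Adding Fickian transport and linearizing about bulk equilibrium for a
spherically symmetric cluster, the dimer excess obeys a screened
equation `D₂∇²δn₂ = k₂δn₂` with decay length `Λ = sqrt(D₂/k₂)`.  Two
modelling choices here:

* **The monomer→dimer feedback term is dropped.**  The full linearization
  has an effective rate `k₂ + 4k₁n₁∞D₂/D₁`; the correction is of order
  the bulk dimer fraction and the model is used in the dilute-bulk regime
  where it is small.  This keeps `Λ = sqrt(D₂/k₂)` exact, which is also
  the relation used in reverse to infer k₂ from the observed cluster
  size: identifying Λ with the cluster radius R = 16 nm (half the 32 nm
  mean diameter — the diameter reading is the only one consistent with
  the derived k₂) gives k₂ = D₂/R² = 125000 s⁻¹.
* **The monomer field is slaved to the dimer field** through the steady
  flux-balance identity `D₁δn₁ + 2D₂δn₂ = 0`.  At steady state this
  combination is harmonic, bounded at the origin and vanishing at
  infinity, hence identically zero; it supplies the second boundary
  condition without further assumptions.

The cluster interior (r < R) is represented as a region whose local dimer
equilibrium is elevated by a constant plateau; `core_contrast` sets the
centre excess as a multiple of the bulk dimer density.  The interior
solution `Δ + A·sinh(r/Λ)/(r/Λ)` and exterior `B·(R/r)·e^{−(r−R)/Λ}` are
matched in value and radial flux at R, fixing (A, Δ, B) linearly.
Contrasts large enough to drive the monomer density negative are clipped
with a warning.  The sweep range 3–35 for the contrast is exposed as the
plausible core-to-bulk ratio; profile shapes are qualitatively invariant
across it (dimers enriched and monomers depleted inside, smooth monotone
decay to bulk with no sharp cluster boundary).

`evolve_rd` integrates the same linearized system in time by a
finite-volume method of lines (node-centred cells, spherical face areas,
logarithmic grid of 200 nodes spanning 0.1–50 Λ by default), with a
no-flux inner boundary and either clamped-bulk or closed outer boundary.
The interior forcing is volume-weighted in the cell containing R, which
is what keeps the discrete steady state within ~0.5% (L2) of the analytic
profile already at ~120 nodes.  The closed box conserves total molecules
to integrator tolerance because both the reaction exchange and the
telescoping face fluxes conserve exactly at the semi-discrete level.
Stiffness is handled by BDF with rtol 1e-8.  The full nonlinear kinetics
remain available through `reaction_rates` for zero-dimensional
(well-mixed) integrations and equilibrium checks.

## Cluster-radius evolution

The radius of a dimer-rich cluster follows the two-term equation

    dR/dt = (D₂/R)·σ_d − (k₂/3)·χ·R

diffusion-limited uptake of the surrounding dimer excess (∝ 1/R) against
reaction-limited loss from in-cluster dimer decay and monomer expulsion
(∝ R, a volume process per unit surface).  `σ_d` is a dimensionless
growth-drive coefficient bundling the thermodynamic driving force
(dimer osmotic-pressure excess in k_BT units); `χ` a shrink efficiency.
Both are explicit user parameters, not measured quantities.  The unique
fixed point

    R* = sqrt(3·σ_d·D₂/(χ·k₂))

is globally attracting since dR/dt is strictly decreasing in R.  The
package default σ_d = 1/3, χ = 1 is a consistency choice, not a measured
value: it makes R* coincide with the screening length Λ, so the steady
cluster radius and the dimer-halo decay length agree at 16 nm.  In
R²-space the equation is exactly linear, relaxing at rate 2χk₂/3
(≈ 8.3×10⁴ s⁻¹ at the defaults), so a 1 nm seed reaches 99% of R* in
≈ 5×10⁻⁵ s — growth to a stable size well inside a millisecond, from
below, without overshoot.  Integration uses LSODA at rtol 1e-8 with the
1/R drive floored at R = 1 pm.

## Synthetic data

The generators are the exact forward models of the three fitters, with
Gaussian noise: relative (2%) on `Kc/R_θ`, absolute (0.002 ppm) on
chemical shifts, relative (1%) on echo intensities.  Design defaults:
SLS at 12 concentrations over 10.0–98.2 mg ml⁻¹; NMR at 12
concentrations over 0.02–0.5 M for three carbons (plus an optional
association-insensitive carbon); DOSY at 12 gradients including g = 0.
Truth defaults regenerate the measured constants (k_D = 1.147 M⁻¹,
D₁ = 4×10⁻¹¹ m² s⁻¹).  Streams are split per generator from a single
integer seed, so one seed reproduces every dataset byte-for-byte.

What the generators do **not** emulate: baseline and phase artefacts in
NMR spectra, peak overlap, temperature drift, concentration errors in
sample preparation, angular dependence and dust spikes in light
scattering, convection and eddy-current artefacts in DOSY, and any
higher-order (trimer/isodesmic) association.  Passing recovery tests
therefore demonstrate estimator correctness and precision under the
assumed noise model, not robustness to structured experimental error.

## Numerical choices and degenerate inputs

* Virial design matrices with condition number > 1e12 or deficient rank
  raise a degenerate-data error; fewer points than parameters + 2 raise
  an underdetermined-fit error.
* The `Δg` integral diverges at c = 0; a zero lower limit is rejected.
* `speciate` handles `k_D = 0` and `c = 0` by the exact no-association
  limit rather than the (0/0) closed form.
* The interior profile shape `sinh(x)/x` switches to its quadratic Taylor
  form below x = 1e-8; `sinh` arguments are capped at 700 to avoid
  overflow on user-supplied wide grids.
* Ties in the radius equation: `steady_radius` requires strictly positive
  drive and shrink; zero shrink is a documented no-fixed-point signal.

## Known limitations

* The reaction–diffusion profiles are linearized; at bulk dimer fractions
  approaching the core contrast the neglected feedback term becomes
  comparable to k₂ and the analytic profile is only qualitative.
* σ_d is not identified by any measurement in the package; R* inherits
  its value.  Only the combination 3σ_d/χ matters.
* Hydrodynamic radii are inputs; no cylinder-model helper is provided.
* Surface-tension contributions to single-molecule exchange between
  cluster and bulk are acknowledged but not modelled.
* The third virial coefficient is barely identifiable from 12-point
  Debye plots at 2% noise; the F-test fallback usually (and correctly)
  removes it.
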