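# Methods

## Model and assumptions

The package treats arterial blood as an incompressible, anisotropic
Newtonian fluid in a rigid, straight, axisymmetric tube with fully
developed flow. Continuity then forces the radial velocity to vanish and
removes every geometric source of secondary motion, so any azimuthal
momentum is attributable to the constitutive law alone. The fourth-rank
viscosity tensor collapses, for this kinematics, to a 2×2 matrix relating
(τ_zr, τ_θr) to (∂_r u_z, ∂_r u_θ − u_θ/r). Dissipativity is enforced as
positive-definiteness of the *symmetric part* of that matrix — the
condition that guarantees non-negative dissipation for every strain state;
positive-definiteness of a non-symmetric matrix is otherwise ill-defined.
After normalising by the axial viscosity this reads δ > 0 and
δ > (β+γ)²/4.

The model deliberately excludes shear-thinning, viscoelastic memory and
yield-stress (thixotropic elasto-visco-plastic) behaviour: those
mechanisms dominate microcirculatory tubes, not the large-artery
(macrotube) limit targeted here, where the cell-free layer is a negligible
fraction of the lumen. Compliant walls, axial development and curved-pipe
(Dean) flow are likewise out of scope; curvature enters only through a
scaling bound (below).

## Nondimensionalisation and harmonic solver

Lengths are scaled by the radius R, velocities by U0 = |G0| R²/(ρ ν_zz)
built from the steady pressure-gradient amplitude, and time by the
fundamental cardiac frequency ω0, giving the Womersley number
α = R √(ω0/ν_zz). Each harmonic h of the driving gradient yields an
independent coupled two-point boundary-value problem for the complex
amplitudes (Û_z, Û_θ), discretised on N+1 Chebyshev–Gauss–Lobatto nodes
(ascending order, centerline first). Boundary rows are replaced in the
2(N+1) block system: no-slip for both components at the wall, symmetry
dÛ_z/dr = 0 and regularity Û_θ = 0 at the centerline. The singular
centerline rows of the cylindrical operators are populated with their
symmetric limits (L0 → 2f''(0), L1 → 3/2 f''(0)) but are always
overwritten by boundary rows, so the choice is inert. Systems are solved
by direct sparse LU; no iterative solvers anywhere.

Phase convention: amplitudes are real cosine coefficients and fields are
synthesised as u(r, t*) = Re Σ_h Û_h e^{2πi h t*}. With this e^{+iωt}
convention the classical isotropic Bessel solution uses
λ = e^{−iπ/4} α (the textbook i^{3/2} α under the evenness of J0); the
opposite square root of i pairs with the conjugate time convention and
yields the same real field.

Numerical choices:

* Differentiation matrices use the trigonometric-identity form of the CGL
  entries with the negative-sum trick and the centro-antisymmetry
  ("flipping") completion — the combination that keeps rounding controlled
  at N ≈ 180.
* Production resolution N = 150; every protocol accepts other N. The
  validation benchmark reaches an L∞ error ≤ 1e−13 against the Bessel
  solution for α ∈ [3, 20] at this resolution.
* Grid-refinement floors: in double precision the pointwise difference
  between solutions at different N plateaus near 4e−13 — the rounding of
  the assembled O(N⁴) operators and of the factorisation, not truncation.
  The grid-independence protocol therefore solves in 80-bit extended
  precision (an in-package pivoted elimination; LAPACK offers no extended
  path), where the N = 140 vs N = 180 residual of the thoracic-aorta case
  at peak phase falls to ~5e−17. The fast double-precision path remains
  the default everywhere else.
* Barycentric interpolation with the analytic CGL weights evaluates
  profiles off the nodes (peak localisation to 1e−4, pillbox sub-grids,
  cross-N comparisons).

## Physical scales and the bundled arterial records

Six arterial pressure-gradient records (aortic root, thoracic aorta,
femoral, carotid, iliac, brachial) are bundled, each with its radius,
Womersley number and six real harmonic amplitudes (h = 0…5, steady
amplitude normalised to 1 — the normalisation that defines U0). The
package's default physical constants are ρ = 1050 kg/m³,
ω0 = 2π·1.2 rad/s (a ~1.2 Hz heart rate) and ν_zz = 3.4955e−6 m²/s; the
viscosity is back-derived so that the single (ω0, ν_zz) pair reproduces
all six tabulated Womersley numbers from the tabulated radii to two
decimals, and is flagged as a calibration, not a measurement. The
gradient scale G0 defaults to 1 Pa/m; dimensionless results are
independent of it and dimensional forces scale as G0², so absolute
picoNewton values are configuration-dependent and only orderings,
distributions, ratios and spectra are treated as testable. All defaults
are overridable through the JSON config.

Parametric sweeps realise "the anisotropy ratio β" as β = γ with δ = 1:
swirl is sourced only by γ, and the observed zero swirl at β = 0 forces γ
to vanish with β, so a tied sweep is the only reading consistent with the
reported behaviour. Mono-harmonic runs use h = 1, a₁ = 1.

## Endothelial force post-processing

Because the Lamb vector is quadratic in the fields, harmonic amplitudes
cannot be combined in the complex plane; velocity and vorticity are first
synthesised on Nt = 256 uniform phases per cycle (ample for six forcing
harmonics and their quadratic products; force statistics change by <0.1%
beyond 256). The radial Lamb component is integrated over a pillbox of
thickness δ_EC = V_EC/A_EC hugging the wall, with the dimensionless
profile interpolated onto ≥64 uniform sub-grid points and integrated by
composite trapezoid. Defaults A_EC = 100 µm², V_EC = 100 µm³ (δ_EC = 1 µm)
are typical endothelial dimensions; the cell volume is a convention, not a
measured input, and both are configurable.

Wall traction τ_w uses the full constitutive law (including the ν_zθ
swirl-strain coupling) at the wall node. The radial force proxy for the
ratio χ(t) = |F_r|/|F_z| and angle φ(t) = atan2(F_r, F_z) evaluates ρ l_r
at the collocation point nearest the wall times A_ref δ_EC, with
A_ref = 100 µm²; where the axial force vanishes χ is reported as +∞ and φ
saturates at ±π/2.

Spectral reporting: force spectra use one-sided amplitudes over exactly
one cycle, converted to Parseval-consistent power; redistribution
comparisons across vessels use the pulsatile (non-DC) power, since the
cycle mean is not part of the harmonic cascade. Across-artery
distinctness of F_EC(t) is tested with the rank-based Kruskal–Wallis H
(chi-square tail, tie-corrected), the per-phase force values over one
cycle serving as samples.

## Geometric comparator

Curved-vessel transverse loading is represented only by a conservative
bound f_rc ≤ ρ u²(1+κ)/R (κ = R/𝓡; an alternative ρ u²(κ/R + 1/r)
scaling mode is provided, and for a µm-thin pillbox the two agree to
~δ_EC/R). The bulk velocity is the instantaneous area average of u_z,
integrated exactly by Gauss–Legendre quadrature of the spectral
interpolant. Both the geometric and the anisotropic pillbox forces are
decomposed into harmonic amplitudes; the geometric side is attenuated by
1/h — the first-order inertial transfer of the bulk cross-stream response
— and the steady component is excluded (the filter is undefined there).
Curvature bands default to 0.35–0.70 (aortic root), 0.20–0.40 (thoracic
aorta) and 0.10–0.60 (carotid). The per-harmonic oscillatory-layer
thickness is reported as δ_W,h = √2/(√h α), the classical Stokes-layer
prefactor; the prefactor is a reporting convention only and never enters
the solver. The quasi-steady acceleration-ratio estimate a_a/a_c is
exposed with β/(1+κ) as its documented, assumption-level formula.

## Known limitations

* The dimensionless swirl and axial-vorticity responses of the governing
  equations are maximal in the quasi-steady limit and decay ~α⁻² beyond
  α ≈ 2–3; they exhibit no interior peak over α ∈ [1, 25]. Reports of
  intermediate-α response maxima for this system could not be reproduced
  from these equations under any normalisation consistent with the
  nondimensionalisation above (amplitude, per-calibre dimensional, or
  fixed-phase observables); the sweep protocol exports the full curves so
  the structure can be inspected directly.
* The near-wall force grows monotonically with α only under the
  per-calibre dimensional conversion (vessel radius tied to α through the
  calibrated ω0, ν_zz — the arterial-tree reading); the dimensionless
  near-wall Lamb density decreases with α. Both observables are exported.
* With a cell-scale pillbox (δ_EC ≪ oscillatory-layer thickness) the
  1/h-filtered geometric amplitude remains above the anisotropic amplitude
  at every resolved harmonic for the aortic-root case; a crossover at
  moderate harmonics requires a control volume of oscillatory-layer scale.
  The comparator reports both spectra so either control-volume convention
  can be examined.
* Mono-harmonic pillbox force signals whose Lamb density does not change
  sign inside the pillbox stay band-limited to twice the forcing
  frequency; richer high-harmonic content appears only for multi-harmonic
  waveforms.
* The synthetic study conditions (waveform registry, calibrated scales)
  emulate the harmonic content and calibre range of the human arterial
  tree but not beat-to-beat variability, wall compliance or measured
  three-dimensional geometry; passing tests validate the solver and the
  force pipeline, not in-vivo force magnitudes.
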