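# Methods

`caillefit` analyzes X-ray diffuse scattering (XDS) from oriented stacks of
lipid bilayers on a solid support. Below ~80 nm length scales, the thermal
undulations of the membranes in such a stack are governed by the discrete
smectic free energy

    F = ∫ d²r Σ_n [ ½ κ (∇²_r u_n)² + ½ (B/d) (u_{n+1} − u_n)² ],

where u_n(r) is the out-of-plane displacement of membrane n, κ is the
bending modulus (J), B the inter-membrane compression modulus (J/Å⁴ in the
convention used here) and d the lamellar repeat spacing. Equipartition over
the Fourier modes of this functional yields the height–height correlation
function and, from it, the structure factor that shapes the off-specular
("diffuse") intensity on a 2-D detector. Fitting that shape determines κ
and B independently.

## The correlation function δu_n(r)

The mean-square height difference between points on membranes n layers
apart with lateral separation r is

    δu_n(r) = (2η/q1²) ∫₀^∞ dx [1 − J₀((r/ξ)√(2x)) (√(1+x²) − x)^{2n}]
                              / (x √(1+x²)),

with the Caillé parameters

    η = k_B T q1² / (8π √(Bκ)),     ξ = (κ/B)^{1/4},     q1 = 2π/d.

Numerical treatment (module `caillefit._quad`): the integrand is finite at
x → 0 (the bracket vanishes linearly) but the 1/x prefactor makes fixed
grids fail, and the Bessel factor oscillates rapidly for large r. We
substitute w = √(2x), which makes the Bessel phase exactly linear in the
integration variable, and use composite 8-point Gauss–Legendre panels:
geometrically growing panels resolve the smooth small-w structure, and any
panel wider than half a Bessel period is subdivided, so oscillations are
resolved exactly where their amplitude matters. Beyond the cutoff
(x ≈ 60, or Bessel phase ≈ 200 for small r) the remaining integral of the
"1" term is added analytically as asinh(2/W²); the neglected oscillatory
remainder is bounded well below 1e-6 relative. The public
`delta_u_exact` runs the scheme at two panel densities and raises if they
disagree beyond tolerance (defaults rtol 1e-6 / atol 1e-9, configurable),
which is what "adaptive" means here. The engine is cross-checked in the
test suite against `scipy.integrate.quad` on the same integrand.

A genuine property of the exact integral worth knowing: in the
radius-dominated regime (r/ξ ≫ √n) the n-dependence is subdominant and
carries tiny oscillatory corrections (~1e-5 relative), so δu_n(r) is only
monotone in n up to that level. Tests allow for this.

### Large-argument branch

For n ≥ 30 or r/ξ ≥ 1000 the expansion

    δu_n(r) = (4η/q1²) [ γ + ln(r/ξ) + ½ E₁(r²/(4nξ²)) ]

is used (γ is the Euler–Mascheroni constant, E₁ the exponential integral).
The additive γ + ln reading was fixed by numerical arbitration: across the
seam band n = 25…35, r = 800–1200 Å (unit scale) it agrees with the exact
quadrature to better than 1e-5 relative, while a multiplicative γ·ln
reading is off by ~47%. The branch thresholds are applied on the
unit-scale grid, where the reference table is built.

The n = 0 row has no asymptotic form (the E₁ argument diverges), and
resolving the Bessel oscillations of the exact integral out to r = 10⁶ Å
is prohibitively expensive; beyond 1000 Å the row is continued from the
last exact node with the analytic logarithmic slope
δu₀(r) = δu₀(r_a) + (4η/q1²) ln(r/r_a), which equals the expansion with
the E₁ term at its limit 0 and matches direct quadrature to ~1e-9 at
r ≈ 1500–3000 Å.

### Unit table and rescaling

δu depends on (ξ, η) only through δu_n(r; ξ, η) = η δu_n(r/ξ; 1, 1), so a
single reference table at (ξ, η) = (1, 1) — by default 10,000 log-spaced
radii over 10⁻⁴–10⁶ Å and layer separations 0…1000, built in a few
seconds — serves every parameter combination: rescaling relabels the
radius axis by ξ and multiplies the values by η (and by (q1_ref/q1)² for
the prefactor). This is what makes fitting affordable: each optimizer
step costs a rescale, not a re-quadrature.

## Finite-size weights

Coherently scattering domains are modeled as cylinders with Gaussian-
distributed diameter (L̄_r, σ_r) and height (L̄_z, σ_z):

    H_z(z) = ∫_z^∞ dL N(L; L̄_z, σ_z) (L − z)/d
           = [(L̄_z − z) Φ̄((z−L̄_z)/σ_z) + σ_z φ((z−L̄_z)/σ_z)] / d,

    H_r(r) = ∫_r^∞ dL N(L; L̄_r, σ_r) L² [cos⁻¹(r/L) − (r/L)√(1−(r/L)²)].

H_z is evaluated in closed form via the Gaussian cdf/pdf; H_r by 64-point
Gauss–Legendre quadrature over the Gaussian support. Choices made where
conventions in the literature are ambiguous: the H_r Gaussian uses σ_r
(some published forms print σ_z, an evident slip); both Gaussians carry the full
1/(σ√2π) normalization — any constant factor is absorbed by the per-cut
fit scales and cannot change fitted η or ξ; H_r is hard-zeroed beyond
L̄_r + 6σ_r (discarding a <1e-8 relative tail), which also truncates the
radial integration; H_z for negative layer index uses |n|d.

## Structure factor

With the q_z-only part isolated as

    Λ(r) = Σ_n H_z(|n|d) cos(q_z n d) G(r, n, q_z),
    G = exp(−q_z² δu_|n|(r)/2),

the structure factor is the Hankel-type transform

    S(q_z, q_par) = ∫₀^∞ r dr H_r(r) J₀(q_par r) Λ(r).

The correlation exponent G is the cumulant form for Gaussian height
differences; a literal exp(i q_z δu) is sometimes written but is
dimensionally inconsistent (δu is an area) and would make S complex. The n-sum runs
over −1000 < n < 1000 by default, truncated where H_z vanishes
(|n| ≲ (L̄_z + 6σ_z)/d); evenness in n halves the work. Λ is computed at
the table radii and interpolated cubically in log r onto the radial
integration grid (trapezoidal, 1 Å steps from 1 Å to the H_r support —
numerically identical to the nominal 10⁶ Å upper limit, ~100× cheaper;
the step is configurable). Extrapolation outside the table is an error,
not a guess. Trapezoidal noise can leave S slightly negative in the far
tail (~1e-5 of the peak); such values are clipped to zero and logged.

The instrumental beam profile is applied as a discrete convolution with a
unit-area Gaussian of width σ_q (Å⁻¹), truncated at ±5σ_q, with the
kernel renormalized over the in-range support at the profile edges (no
zero-padding artifacts). A 2-D map is built row by row; rows are
independent and the result does not depend on evaluation order.

A slow reference path (`caillefit._reference`) computes S by direct
quadrature of δu at every node of the dense radial grid — no table, no
rescaling, no interpolation — and agrees with the fast pipeline to
~1e-5 relative on the acceptance grid (tolerance 1%).

## Reduction

A flat detector subtends the spherical coordinates of reciprocal space.
Each pixel at signed offset k from the beam center maps to angles
θ (vertical) and Ξ (horizontal) either linearly, angle = PX·k/L, or with
the arctangent correction atan(PX·k/L) that removes the flat-detector
distortion; the historical "distorted/non-distorted" labels are kept on
the CLI flags, but the atan branch is the geometric truth and the default.
Then q_z = 4π sin θ/λ and q_par = 4π sin(Ξ/2)/λ — the asymmetric θ vs Ξ/2
convention reflects the reflectivity geometry of the meridional axis.
Intensities are never regridded: profiles and cuts are taken on pixel
rows/columns and labeled with q values. Uncertainties are Poisson with
var = max(counts, 1), propagated as variance/m under averaging.
Log-stored images are linearized as I = 10^stored (base 10; detector
vendors' convention — configurable).

The meridional reflectivity profile averages a 12-pixel-wide box about
q_par = 0; lamellar peak positions (local maxima above a prominence
threshold, refined to sub-pixel precision with a three-point parabola)
give d = 2πn/q_z(n) averaged over orders. Line cuts average a
user-chosen box around each requested q_z (or emit one cut per pixel
row). The background routine is deliberately rudimentary, matching its
description: the median of the outer 10% of points on each flank is
subtracted as a constant, negatives are floored at zero and counted.

## Fitting

Two or more cuts at distinct q_z are fitted simultaneously. The per-cut
multiplicative scales s_l, which absorb the form factor |F(q_z)|², are
profiled out in closed form (s_l = Σ Y y/σ² ÷ Σ Y²/σ²), so the nonlinear
search runs over (η, ξ) only — fewer dimensions, identical optimum. The
objective is the variance-weighted chi-square
χ² = Σ (s_l Y_l[k] − y_l[k])²/σ_l[k]²; a convention with σ to the first
power circulates in the literature and is available as
`linear_sigma_weighting=True`, but it makes χ² carry units and is not
the default. The optimizer is trust-region least squares (scipy
`least_squares`/trf, numerically differenced Jacobian) with a
Nelder–Mead simplex fallback — earlier implementations of this analysis
are variously described as Levenberg–Marquardt or as a derivative-free
minimizer, so both readings are covered. Model profiles
are computed on an internal uniform symmetric q_par grid fine enough to
sample the beam kernel, convolved, then cubic-interpolated onto the data
abscissae. The reported trace is the sequence of accepted (new-best)
steps and is nonincreasing by construction. Standard errors come from
the local quadratic expansion (inverse J'J, scaled by reduced χ²) and
are labeled approximate. Default bounds: η ∈ (0, 2], ξ ∈ [1, 10⁵] Å.

An optional exclusion window |q_par| < `qpar_min` (default 0, off)
removes the specular/beam-stop core from the objective. The diffuse
model does not describe the specular rod or substrate reflectivity, so
excluding a few pixels around q_par = 0 is standard practice when
fitting cuts through lamellar orders; the end-to-end tests use 0.02 Å⁻¹.

On convergence, κ = k_B T q1² ξ²/(8πη) and B = κ/ξ⁴ are reported in J
and k_BT (κ), and J/Å⁴ and erg/cm⁴ (B; 1 J/Å⁴ = 1e39 erg/cm⁴).

## Synthetic fixtures

The generator emulates a rotating-anode measurement of a POPC-like stack:
defaults η = 0.1, ξ = 60 Å, d = 53 Å (κ ≈ 20 k_BT, B ≈ 6×10¹² erg/cm⁴ at
298 K — typical for a well-hydrated fluid PC bilayer), domains
L̄_r = 3000 Å, σ_r = 1000 Å, L̄_z = 10d, σ_z = 2d, beam σ_q = 0.002 Å⁻¹,
λ = 1.5418 Å (Cu Kα), 100 µm pixels at 150 mm, q_z to ≈0.5 Å⁻¹ and
q_par to ≈±0.4 Å⁻¹ — ranges chosen so several lamellar orders and the
full diffuse decay are on the detector. Detector images are painted row
by row from exact structure-factor profiles; Gaussian specular peaks at
q_z = n q1 (amplitudes falling with order), a flat background and
Poisson or relative-Gaussian noise are added. The peak diffuse intensity
defaults to 5000 counts, i.e. ~1.4% counting noise at the peak. The
form factor enters only as a smooth positive q_z envelope (constant or
damped cosine) because the analysis absorbs it into per-cut scales.

The painter computes its pixel → q mapping from formulas written out
independently of the reduction module, so the geometry round-trip test
(agreement to 1e-9) is a genuine cross-check, not a tautology.

What the fixtures do not emulate: absolute intensities, mosaic spread,
instrument artifacts (e.g. window-material diffraction rings), flat-field
or absorption effects, and physical reflectivity of the substrate.
Passing tests therefore demonstrate correctness of the analysis chain
under the stated statistical model, not robustness to every systematic
present in real detector images.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the chain at the study
conditions above with: a 4000-node unit table (≈360 nodes/decade;
interpolation error ~1e-6), a 3 × 20 (q_z × q_par) grid for the
pipeline-vs-reference comparison, 141-point cuts at q_z = 3q1 and 3.5q1
for parameter recovery (one noiseless fit plus ten 1%-noise replicates),
and a 106 × 301-pixel painted image for the end-to-end run. The default
10,000 × 1001 table is built once in a dedicated shape test.

## Known limitations

- The constant-baseline background subtraction requires cuts that extend
  beyond the diffuse decay; sloped backgrounds bias it.
- Finite-size parameters (L̄_r, σ_r, L̄_z, σ_z) and σ_q are fixed inputs,
  never fitted; a badly wrong L̄_r biases η and ξ.
- Standard errors ignore parameter correlations with the profiled scales
  beyond the quadratic approximation.
- The rocking-scan convolution needed by fixed-detector synchrotron
  setups is out of scope.
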