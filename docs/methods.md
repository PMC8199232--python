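# Methods

## Geometry and conventions

The phantom is a plane slab of thickness *L* (default 2.0 mm) with a finite
lateral extent (disc of radius 15 mm); coordinates put *z* = 0 at the
illuminated surface, *z* increasing downward, with the beam centered on the
origin. An optional cylindrical vessel of diameter *D* (given in µm) runs
along *y* at axis depth *d* — measured from the illuminated surface to the
**axis**, so flipping the slab maps *d* to *L − d* and depth pairs summing to
*L* describe the same phantom viewed from either side. Containment requires
*d* − *D*/2000 > 0 and *d* + *D*/2000 < *L* (units mm).

Default refractive indices: background 1.50 (epoxy-like), blood 1.37,
ambient 1.00. All are configurable; the vessel wall is index-matched to the
background by default (`MCConfig.vessel_fresnel` enables Fresnel events
there), since the blood/background index difference is small compared with
the slab/air mismatch.

## Forward Monte Carlo

Weighted hop–drop–spin random walk (photon packets, implicit capture):

* **Launch.** Flat-top circular beam at normal incidence; the entry Fresnel
  reflection ((n_above − n_slab)²/(n_above + n_slab)²) is tallied as
  `R_specular` and the packet enters with the complementary weight.
* **Hop.** Free paths are sampled in optical depth and ray-marched through
  regions (background/vessel), so a step crossing the vessel wall
  automatically re-scales to the local attenuation coefficient. Analytic
  distances to the slab faces, the lateral disc and the vessel cylinder are
  used; boundary crossings advance by a 1e-7 mm nudge to avoid
  re-intersection.
* **Drop.** At each interaction, weight × μa/μt is deposited into the
  absorption tally of the current region (and the optional fluence voxel
  grid).
* **Spin.** Henyey–Greenstein deflection with the region's g; the g = 0 case
  reduces exactly to cosθ = 2u − 1.
* **Boundaries.** Top/bottom faces apply angle-dependent unpolarized Fresnel
  reflection (including total internal reflection); transmitted packets tally
  to `R_diffuse` or `T`. Packets crossing the lateral boundary are tallied to
  `E_side` and terminated.
* **Termination.** Low-weight packets (below 1e-4 by default) play roulette:
  they survive with probability 0.1 at **unchanged** weight, otherwise the
  residual weight is deposited as absorption at the termination site. This
  differs from the textbook roulette (which boosts survivors by 1/p and
  conserves energy only in expectation): here every unit of launched weight
  ends up in exactly one tally, so the energy budget sums to 1 to float
  rounding on every run. The price is a bias bounded by the roulette
  threshold (≤ 1e-4 absolute), far below the Monte Carlo noise at the photon
  budgets used (≥ 1e4 packets).

Reflectance reported for comparison with DRS measurements is `R_diffuse`
only ("the measured spectrum is diffuse"); the specular entry term is kept
separate and can be added back via a flag. Determinism: one integer seed per
run gives bit-identical tallies; spectral sweeps derive per-wavelength seeds
from the master seed and the wavelength index, so two sweeps with the same
master seed share random numbers wavelength-by-wavelength regardless of
geometry (common random numbers across scenarios).

## Adding–doubling and IAD

Azimuthally averaged 1-D radiative transfer discretized at quadrature
cosines on (0, 1]. The collimated beam direction is represented exactly by a
Gauss–Radau node at ν = 1; for refractive mismatch the quadrature is split
at the critical cosine (Gauss–Legendre below, Radau above) so the
total-internal-reflection discontinuity is integrated accurately. Default 16
streams. Layer operators are flux-normalized (R̃ = C^{1/2} R C^{1/2},
C = diag(2νᵢwᵢ)), turning star products into ordinary matrix products.

* **Slab construction.** Single-scatter initialization of a starter layer of
  optical thickness ≤ 1e-7, then repeated doubling to the target optical
  thickness. The starter thickness bounds the accumulated error at roughly
  τ × 1e-7; conservative-scattering checks hold to ~1e-5.
* **Phase function.** Henyey–Greenstein redistribution matrices from the
  Legendre expansion (χ_k = g^k), truncated when g^k < 1e-9, then
  symmetrically renormalized so scattering conserves energy on the discrete
  grid. With 16 streams the solver is accurate to ~1e-4 for g ≤ 0.8; higher
  anisotropy needs more streams (the Monte Carlo model is the reference in
  that regime). The inversions used here run at g = 0.
* **Boundaries.** Diagonal Fresnel operators in internal-angle
  representation; a lossless slab between totally reflecting angles makes
  the interreflection operator exactly singular (perfect waveguide modes
  that carry no incident energy), handled by a pseudo-inverse fallback.
* **Outputs.** Diffuse reflectance excludes the first-surface specular
  reflection of the collimated beam and transmittance includes the ballistic
  component — the same conventions as the Monte Carlo tallies, so the two
  routes are directly comparable (they agree within Monte Carlo standard
  errors on matched- and mismatched-boundary slabs).

**IAD inversion** reparameterizes to albedo *a* and optical thickness τ,
scans a coarse grid (9 albedos × 14 optical thicknesses) to seed a damped
2-D Newton iteration with a finite-difference Jacobian, and accepts when
both absolute residuals are below 1e-4. Among equivalent solutions the
smallest τ wins. If no seed converges, an infeasible-measurement error names
the best residual found — the signature of an unphysical pair or a wrong
g/n assumption. g defaults to 0 in inversion; a Mie estimate can be passed
instead.

## Mie anisotropy

Lorenz–Mie series with Bohren–Huffman recurrences: logarithmic derivative by
downward recurrence, Riccati–Bessel functions by upward recurrence,
truncation at the Wiscombe order x + 4x^{1/3} + 2. Validated against the
Rayleigh x⁴ law, a 4×-order brute-force summation, and the classic
benchmark (x = π·1.05/0.6328, m = 1.55 → Q_ext = 3.10543). Suspension
properties assume independent scatterers: μs = C·Q_sca·πr² (linear in
number density), g concentration-independent. Mass-fraction input converts
to number density via a configurable particle density (default 0.93 g/cm³,
soybean-oil-like). Note that for 0.5 µm lipid droplets in an epoxy-like
medium (n ≈ 1.46/1.50) the Mie anisotropy is of order 0.9 in the visible —
not near zero — which is why the 1-D inversion's g = 0 default should be
seen as a *convention* for reduced-parameter fitting rather than a physical
estimate; the forward Monte Carlo accepts the true g per region.

## IAD–FMC property extraction

Per wavelength, on a homogeneous (vessel-free) model:

1. IAD seed from (M_R, M_T).
2. Evaluate the Monte Carlo forward model with a fixed per-wavelength seed;
   residual = max of the relative R and T mismatches (denominator floored at
   1e-3 to avoid blow-up near zero signal).
3. Damped Newton step on (μa, μs): the Jacobian comes from finite
   differences of the cheap adding–doubling surrogate, the residual from MC
   under common random numbers, with step halving whenever the residual
   would increase. The residual sequence is therefore monotone
   non-increasing by construction.
4. Stop at tolerance (default 1%, the realistic MC noise floor at 1e5
   packets) or after `max_iter` (default 20); non-convergence is reported
   per wavelength, not raised.

Because the lateral extent (15 mm) dwarfs the beam (0.5 mm), the 1-D seed is
already close and refinement typically needs 0–3 iterations; the refinement
matters when side escape or finite-beam effects bias the 1-D estimate.

## Depth inversion

Aggregate = unweighted band mean of diffuse reflectance over 400–600 nm (the
hemoglobin absorption band, where the depth sensitivity is strongest);
band-resolved matching is available as an option. The solver:

1. evaluates the aggregate at the bracket endpoints (defaults to the
   containment-feasible depth range with a 0.05 mm margin),
2. verifies the measurement lies between them (a 3-MC-standard-error slack
   lets near-boundary cases clamp to an endpoint instead of failing),
3. detects the monotonicity direction from the endpoints rather than
   assuming it,
4. bisects, with every evaluation using the same master seed (common random
   numbers), until the bracket is narrower than 0.01 mm or an optional
   mismatch tolerance is met.

Iteration count is bounded by ⌈log₂(range/tolerance)⌉. A midpoint violating
the endpoint ordering by more than 3σ raises a non-monotonicity error. The
returned estimate carries the full (depth, reflectance) trace for audit.

## Synthetic phantom generator

Emulates a 2 mm epoxy/intralipid slab: background μs(λ) = 2 mm⁻¹ ×
(λ/500 nm)⁻¹, flat μa = 0.01 mm⁻¹, g = 0, n = 1.5 against air. The channel
carries a hemoglobin-*like* absorption template — Gaussians at 420, 542 and
577 nm on a decaying baseline, peak scaled to 30 mm⁻¹ by default — plus
modest scattering (6 mm⁻¹, g = 0.9, n = 1.37). These are fixture shapes
chosen to reproduce the qualitative spectroscopy (a dominant Soret-band dip
and secondary Q-band structure inside 400–600 nm), **not** literature blood
or intralipid data; no claim of spectral accuracy is made. "Measured"
spectra are forward-MC runs under a measurement seed derived independently
of any solver seed, multiplied by (1 + ε) with ε ~ N(0, noise²)
(default 1%), clipped to [0, 1]. Truth metadata (depth, diameter,
properties, seeds) is embedded for audit.

What passing tests on these fixtures do *not* show: performance on real
skin (no epidermis/melanin layer, no multi-vessel plexus, no instrument
response), or robustness to wrong assumed optical properties — the depth
inversion receives the same background/blood tables that generated the
measurement, as in a calibrated-phantom experiment.

## Problem sizes and numerical choices

* Tests and the acceptance script run 1e4–1e5 photon packets per wavelength
  and 3–10 wavelengths per spectrum — sizes chosen so the full pipeline
  (measurement synthesis plus bisection, about 100 MC runs per inversion)
  completes in minutes on one CPU while keeping band-mean MC noise near
  5e-4.
* Depth tolerance 0.01 mm; spectral-mismatch tolerance 1%; IAD residual
  tolerance 1e-4 absolute.
* At the 1e5-packet budget the deep/thin extreme (D = 100 µm at
  d = 1.8 mm) is noise-limited: the reflectance–depth slope there
  (~0.015 mm⁻¹) against the band-mean noise gives a one-sigma depth error
  near 3.5%, so individual runs can exceed 5% relative error while the
  shallow and mid-depth cases sit comfortably below it. More photons,
  not algorithm changes, is the remedy.

## Known limitations

* Single vessel, parallel to the surface; no epidermis/melanin layer; no
  polarization, fluorescence or time resolution.
* Adding–doubling accuracy degrades above g ≈ 0.8 at the default 16
  streams; raise `n_streams` or rely on the Monte Carlo route.
* Transmittance flip symmetry T(d) = T(L − d) holds only in the wide-beam
  (plane-parallel) limit; with a 0.5 mm spot the finite-beam geometry breaks
  it, which the tests respect by checking the invariance at a 6 mm spot.
* The joint (d, D) inversion is deliberately out of scope: diameter must be
  supplied (from imaging), otherwise the problem is ill-posed.
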