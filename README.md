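# drsvessel

Diffuse reflectance spectroscopy (DRS) of vessel-bearing skin phantoms:
forward Monte Carlo photon transport, inverse adding–doubling, and
bisection-based extraction of blood-vessel depth.

## The problem

Laser treatment of vascular skin lesions such as port wine stain needs the
geometry of the target capillaries — diameter and, critically, depth below
the surface — to choose treatment parameters. Vessel diameter is observable
with speckle imaging, but depth (typically 0.2–1.8 mm) is not. Diffuse
reflectance spectroscopy offers a cheap, non-invasive route: in the 400–600 nm
band, where hemoglobin absorbs strongly, the diffuse reflectance *R* of a
tissue slab containing a vessel rises with vessel depth *d* and falls with
vessel diameter *D*. With *D* known and the optical properties of the
background tissue and blood known, measuring *R* determines *d*.

`drsvessel` implements that inverse methodology end to end for a
laboratory-style phantom: a turbid slab (epoxy/intralipid-like) of thickness
*L* = 2 mm containing a single blood-filled cylindrical channel parallel to
the surface. It is aimed at researchers in tissue optics who want a
self-contained, testable reference implementation of the pipeline.

## The method

1. **Forward Monte Carlo** (`drsvessel.monte_carlo`). Weighted hop–drop–spin
   photon transport with a Henyey–Greenstein phase function, Fresnel
   boundaries, and a cylindrical vessel region. Every run satisfies the
   energy budget

   `R_specular + R_diffuse + T + Abs_background + Abs_vessel + E_side = 1`

   exactly (to float rounding): the tally bookkeeping never creates or
   destroys photon weight. Diffuse reflectance `R_diffuse` is the quantity
   compared with DRS measurements; the specular entry reflection is tallied
   separately.

2. **Adding–doubling and IAD** (`drsvessel.adding_doubling`). A 1-D
   radiative-transfer solver: the slab's reflection/transmission operators
   are built by repeated doubling of an optically thin starter layer, with
   Fresnel boundary layers added for refractive-index mismatch. The inverse
   (IAD) recovers (μa, μs) from a measured pair (M_R, M_T) by a damped
   Newton iteration in (albedo, optical thickness), with g fixed (default 0).

3. **Mie anisotropy** (`drsvessel.mie`). Lorenz–Mie efficiencies and
   asymmetry parameter g for the phantom's scattering particles, from
   particle size, indices and concentration.

4. **IAD–FMC property extraction** (`drsvessel.property_extraction`). The
   fast IAD estimate seeds an iterative Monte Carlo refinement that accounts
   for the finite beam and 3-D geometry, driving the relative mismatch
   between calculated and measured spectra below 1%.

5. **Depth inversion** (`drsvessel.depth_inversion`). With background and
   blood properties known, the band-mean (400–600 nm) diffuse reflectance is
   monotone in vessel depth; bisection between two bracketing depths locates
   the measured reflectance to 0.01 mm.

A synthetic-phantom generator (`drsvessel.synthetic`) emulates the
epoxy/intralipid slab with a hemoglobin-like absorber in the channel, so the
whole pipeline is testable without measured data.

## Worked example

Generate a synthetic "measurement" of a 300 µm vessel at 0.65 mm axis depth
(1% multiplicative noise, 50 000 photons per wavelength), then invert it:

```sh
$ drsvessel synth --out-dir demo --depth-mm 0.65 --diameter-um 300 \
      --photons 50000 --noise 0.01 --seed 7
wrote scenario to demo (truth depth 0.65 mm)

$ drsvessel depth --measured demo/measured.csv --config demo/model.json \
      --out demo/estimate.json
d_hat = 0.6469 mm (8 iterations)
```

`estimate.json` records the estimate, the bracket, the per-iteration trace
and the seed:

```json
{
  "d_hat_mm": 0.6469,
  "iterations": 8,
  "mismatch": 0.00198,
  "bracket_mm": [0.2, 1.8],
  "seed": 26045493
}
```

The recovered depth 0.6469 mm differs from the true 0.65 mm by 0.5%; the
`mismatch` field is the final relative difference between measured and
calculated band-mean reflectance (0.2%, at the Monte Carlo noise floor for
this photon budget). Other subcommands: `forward` (single-wavelength energy
budget), `sweep` (forward spectra), `iad` (1-D inversion), `iadfmc`
(IAD + MC refinement), `mie` (suspension optics).

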