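# Methods

This note documents the models inside `onlenspower`: what is computed,
under which assumptions, which knobs matter, and where the simplified
parts stop being trustworthy. Units are mm / N / MPa / diopters
throughout; the optical axis is z, positive toward the incoming light
(anterior), with the back-surface apex of the lens at the origin.

## 1. Tensile reduction and the material catalogue

A rectangular hydrogel strip (initial length `L0`, cross-section
`A0 = width × thickness`) pulled at constant strain rate gives records
`(t, F, L1)`. The reduction is deliberately elementary: engineering
stress `σ = F/A0`, engineering strain `ε = (L1 − L0)/L0`, and the
modulus is the least-squares gradient of σ on ε with its standard
error (`scipy.stats.linregress`). Hydrogels are linear elastic over the
load range a lens sees on-eye, so the whole record is fitted by
default; `strain_window` restricts the fit when a record extends into
the nonlinear regime. `pooled_modulus` fits each strip separately and
reports mean ± SD across strips, matching the usual "E ± sd over three
samples" presentation.

The catalogue holds four lens hydrogels. Each carries two moduli: the
manufacturer datasheet value (from tests to failure) and the value
measured at in-vivo-scale loads; the measured value drives simulation
by default because on-eye flexure never approaches failure loads.

| material | water | n (wet) | E measured (MPa) | E datasheet (MPa) |
|---|---|---|---|---|
| H77p0-Clear | 77 % | 1.3739 | 0.195 ± 0.027 | 0.17 |
| SiH74p5-Blue | 74.5 % | 1.3753 | 0.277 ± 0.019 | 0.35 |
| SiH74p5-Clear | 74.5 % | 1.3749 | 0.279 ± 0.010 | 0.35 |
| H64p0-Clear | 64 % | 1.3920 | 0.457 ± 0.013 | 0.37 |

All use ν = 0.49 (near-incompressible water-swollen polymer).

**Synthetic generator.** `synth_tensile` emulates the tensile protocol:
strain grows at 10 %/min (the protocol rate), stress is `E·ε` plus
additive Gaussian noise in MPa, forces are recovered through `A0`.
Defaults: 200 points, strip 20 × 5 × 0.55 mm (0.55 mm is the lathed
blank thickness; the 20 mm length and 5 mm width are realistic strip
dimensions, not protocol constants), `max_strain = 0.2`, and
`noise_sd = 0` unless asked for. The generator is linear-elastic by
construction: it does not emulate machine compliance, slack take-up,
viscoelastic relaxation or failure, so recovery tests validate the
reduction pipeline, not the behaviour of real records near failure.

## 2. Tri-curve lens design

**Back surface.** Rotationally symmetric, three concentric zones with
radii `(R1b, R2b, R3b) = (Bc, Bc+2, Bc−2)` from the base curve
`Bc = 8.5 mm`; zone centres on the axis are placed so the piecewise
spherical sag is continuous at the optic-zone (`d1 = 8 mm`) and
transient-zone (`d2`) joins. `d2` is not a catalogued value; the
default is the symmetric split `(d1 + D)/2` and it is an exposed free
parameter.

One geometric repair is unavoidable: the peripheral radius `Bc − 2 =
6.5 mm` is smaller than every catalogued semi-diameter (6.75–7.25 mm),
so an on-axis peripheral sphere physically cannot reach the lens edge.
When that happens (always, for the standard grid) the peripheral arc
keeps its 6.5 mm radius but its centre moves off-axis onto the
transient-zone normal at the join — a tangent (C1) continuation that
spans the aperture. `zone_centres` itself still returns the on-axis
centres for use inside their domain.

**Front surface.** The prescription `(SPH, CYL, axis)` becomes a
360-meridian power profile: a cosine between `Pmax = max(SPH+CYL, SPH)`
and `Pmin = min(SPH+CYL, SPH)` with period 180° in meridian angle,
circularly shifted (periodic cubic interpolation for sub-grid axes) so
the maxima sit on the cylinder-axis meridians. Each meridian's front
radius inverts the thick-lens maker's equation

    Rf = [Tc (n−1)² + n (n−1) R1b] / [n R1b P + n (n−1)],   P in mm⁻¹,

and the front sag follows `Zf = Tc − (Rf − √(Rf² − ρX²))/ρ` with shape
factor ρ = 0.75. This sag law closes before the lens edge at high plus
powers (at +20 D, `Rf/√ρ ≈ 6.9 mm < D/2`), so it governs the optic zone
only; outside `d1/2` the front surface is the back surface plus a
smoothstep thickness blend from the optic-zone-edge thickness to the
edge thickness `Te = 0.4 mm`. The junction is C0; it lies 2.3 pupil
radii outside the traced aperture.

**Ballast.** The prism-ballast law `Tj = Tc (1 − W sinθ)` with W = 0.2
above the horizontal and W = 1.0 below thickens the lower half. Applied
literally at every radius the per-meridian offset would make the apex
height multivalued and put diopters of spurious prism into the pupil,
so the offset `(Tj − Tc)` is tapered radially: zero across the optic
zone, smoothstep to full value at the edge. Orientation stability comes
from peripheral mass anyway; the optics stay clean.

**Minimum thickness.** If the thinnest point falls below 0.1 mm, the
central thickness grows in 0.01 mm steps until the bound holds. Two
variants exist. The default re-solves the front radii for the updated
`Tc` at each step, so the delivered thick-lens power stays exactly on
prescription (at +20 D the loop ends near `Tc = 0.56 mm`). The literal
variant (`recompute_front_on_thicken=False`, and the standalone
`enforce_min_thickness`) re-elevates the front rigidly with frozen
curvatures — simpler, but a thicker meniscus with unchanged curvatures
delivers more power (≈ +0.7 D at +20 D), which would corrupt any
comparison of traced against nominal power. The grid is 360 meridians ×
101 radial stations by default.

## 3. Conformance surrogate

The cornea is rigid (the anterior eye is orders of magnitude stiffer
than a hydrogel lens): a sphere of radius `Rc = 337.5/K` mm from
keratometric curvature `K = 43.7 D`, so `Rc = 7.7231 mm`; its 545 µm
posterior offset matters only to the FE export. The lens is pressed on
by two uniform pressures, tear-film `P1 = 43.6 mPa` and eyelid
`P2 = 8 mmHg = 1066.58 Pa`, treated as a single static sum.

How far the lens conforms is governed by one dimensionless group, the
ratio of plate bending rigidity to the pressure work scale over the
lens semi-diameter `a`:

    S = E t̄³ / [12 (1 − ν²) (P1 + P2) a³],

with `t̄` the area-weighted mean axial thickness. Per meridian, the back
surface polyline is decomposed into chord lengths and chord angles; the
chord angles are blended with the corneal circle's tangent field at
weight `w = S/(1+S)` and the polyline is reassembled from the apex.
Chord lengths are never touched, so meridional arc length is preserved
identically at every `w` (the membrane, inextensional-shell limit).
The corneal tangent field is evaluated at chord-consistent angles
(chords of the lens's own segment lengths inscribed in the corneal
circle), which makes both limits exact to machine precision: `w = 1`
returns the input lens and `w = 0` lands every node on the corneal
sphere. The front surface follows by co-rotating each original
back-to-front node offset with the local change in back tangent angle —
thickness is transported unchanged (thin shell, ν = 0.49), and the
rigid limit reproduces the front nodes exactly. Any node that dips
below the cornea is projected radially back to the sphere.

Under the catalogue moduli and stated loads, `S ≈ 1–6 × 10⁻³`: every
lens is floppy relative to the fitting pressures and drapes almost
completely, which matches the clinical picture for soft lenses. Two
consequences are worth stating plainly. First, EPC differences between
materials are then dominated by their refractive indices (EPC scales
with n − 1), not by their moduli: the modulus effect is present and has
the expected sign (stiffer ⇒ smaller |EPC| at fixed index) but is an
order of magnitude smaller, so a ranking of materials by |EPC| follows
the index, with the 64 % water-content hydrogel (highest n) showing the
largest |EPC| rather than the smallest. Second, the near-drape regime
makes EPC essentially geometric: smooth in lens power, without the
fluctuations a nonlinear contact solve exhibits.

The surrogate is frictionless and quasi-static (the 0.01 friction
coefficient is carried only into the FE export), keeps the lens centred
(no decentration or rotation), and models no tear-film fluid mechanics
beyond the constant `P1`. It replaces — by design — a nonlinear FE
contact solution; `export_fe_model` writes the genuine problem
(HEX8 structured meshes for lens and corneal slab, linear-elastic
material card, both pressures with the eyelid load ramped in halfway
through the step, sliding contact with μ = 0.01, cornea fixed, lens
centre pinned in X/Y) as an FEBio-dialect XML file for an external
solver. Both meshes are annular with a small central hole (a polar
structured grid degenerates at the pole); the "centre node" constraint
is applied to the innermost node ring.

## 4. Ray tracing and EPC

Surface fits: each interface's node cloud is fitted with a total-degree
8 bivariate polynomial over a 3.5 mm fitting aperture (inside the 8 mm
optic zone so the optic/periphery junction never enters the fit);
residual RMS is checked against 1 mm/1000. A hexapolar bundle (127 rays
at the default 6 rings) starts parallel to the axis, refracts
air → lens at the front and lens → air at the back. Intersections are
damped-Newton solves along the ray with tolerance 1e−11 mm. Refraction
uses the meridian-rotation construction — rotate the frame about z so
the local normal loses its y component, rotate the oriented normal
through the Snell angle about the plane-of-incidence axis, rotate back —
and every event is cross-checked against the closed-form vector Snell
law (`μ d + (μ cosφi − cosφt) m`), which also serves as the independent
oracle in the tests; a disagreement above 1e−8 aborts the trace. Total
internal reflection and aperture misses drop the ray and are counted.

Power is extracted two ways:

* **slope** (default): regress each exit ray's transverse slope on its
  entry height with cubic (Seidel) terms in the design matrix; the
  linear coefficient is the paraxial slope and its ±x/±y average times
  1000 is the equivalent power in D. The cubic terms absorb spherical
  aberration (worth up to ~0.2 D of bias at the sweep extremes if
  omitted) and the intercept absorbs prism, so the estimate matches the
  design thick-lens power to a few 0.001 D at a 1 mm pupil.
* **crossing**: per-ray closest approach to the optical axis, averaged,
  measured from the back apex and inverted — a back-vertex-style power
  that includes aberration and principal-plane offsets (≈ +0.24 D at
  +20 D). Reported alongside, selectable via `power_method="crossing"`.

EPC is traced(conformed) − traced(undeformed), both in air with
identical pupil settings (default semi-aperture 1.5 mm), isolating the
conformance effect; a `baseline="labelled"` switch compares against the
prescription instead. Near-afocal lenses report an infinite focal
length sentinel rather than a division blow-up. For toric lenses the
bundle power is the mean of the two principal powers; meridional fans
(`trace_meridian_fan`) give the per-meridian values.

## 5. Sweep and statistics

The full grid is 4 materials × {spherical, cylindrical} × powers
−10…+20 D in 1 D steps × diameters {13.5, 14.0, 14.5} mm; cylindrical
lenses carry the swept power entirely in the cylinder (SPH = 0, axis
90°), since a spherical component is not part of the stated design
grid. Per-cell failures are recorded, not fatal. The EPC table is split
at 5 D with the boundary in the upper region ("5–20 D"); within each
region and (lens type, diameter), material pairs are compared with
pooled-variance two-sample t-tests on the EPC values pooled across
powers (Welch variant available; no multiple-testing correction, noted
in the report), and each (material, lens type, diameter) gets a Pearson
correlation of EPC against power — undefined (missing), not zero, for
constant EPC. Acceptability is `|EPC| ≤ 0.25 D`, boundary inclusive,
with the largest contiguous acceptable power interval reported per
material. The whole pipeline is deterministic: only `synth_tensile`
consumes a seed.

## 6. Numerical choices and degenerate inputs

* Back-zone sag continuity at the joins is analytic; the property test
  bound is 1e−9 mm.
* `front_radius` rejects the singular denominator (`P = −(n−1)/R1b ≈
  −46 D`, far outside the grid); `front_sag` rejects apertures beyond
  `Rf/√ρ`; `zone_radii` rejects base curves ≤ 2 mm.
* The min-thickness loop is guarded at 200 iterations
  (design-infeasible error beyond it).
* Fit conditioning: monomials on the normalised disk at degree 8 are
  adequately conditioned for `lstsq`; rank deficiency raises. Residual
  RMS above 1 µm over the optic zone raises rather than silently
  degrading the trace.
* Normal incidence (zero plane-of-incidence axis) returns the incident
  direction unchanged; degenerate t-test variances fall back to the
  limiting p (1 for equal constants, 0 for distinct) and are flagged.
* The conformance monotonicity (deviation from the cornea vs E),
  impenetrability (clearance ≥ −1e−6 mm) and weight ordering
  (`w(E_stiff) > w(E_soft)`) are enforced as property tests.

## 7. Problem sizes used in the shipped analyses

The end-to-end checks run the +20 D spherical cell at all four
materials (D = 14 mm, 1.5 mm pupil), the cylindrical sweep over
5–20 D × 3 diameters × 4 materials (192 cells), the paraxial scan over
−10…+20 D at 1 mm pupil, and the tensile recovery at 200-point records;
the synthetic-data recovery statistics use 500 seeds. These sizes are
the package defaults for its own validation and reproduce in a few
minutes on one CPU.

## 8. Known limitations

* The conformance surrogate has no contact mechanics: no pressure
  redistribution, no edge lift-off, no post-lens tear film, no
  friction, no decentration/rotation. Its EPC is smooth in power and
  cannot reproduce solver-level fluctuations.
* In the near-drape regime the material ranking of |EPC| is set by
  refractive index, not modulus (§3); conclusions about *material*
  (as opposed to index) effects from the surrogate are limited to the
  small, correctly-signed modulus term.
* The cornea is a sphere; real corneas are aspheric and astigmatic, and
  corneal geometry shifts EPC curves up or down.
* Single wavelength, lens-in-air tracing: no tear-lens optics, no
  corneal power, no dispersion, no image-quality metrics.
* The tri-curve periphery (off-axis arc, thickness blend) is a
  documented repair of an infeasible on-axis construction; peripheral
  geometry beyond the optic zone should not be over-interpreted.
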