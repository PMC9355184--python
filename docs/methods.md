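# Methods

## The model eye

`photic_sim` traces light through a pseudophakic schematic eye of the
Liou–Brennan type: the anatomically based average eye (aspheric cornea,
decentered pupil, 5° angle between visual and optical axis) with the
crystalline lens replaced by an intraocular lens (IOL).  The scene is
rotationally symmetric about the optical axis except for the pupil.
Coordinates: origin at the corneal front vertex, +z posterior, +x nasal,
+y superior; all lengths in millimetres.

| boundary      | kind            | R (mm) | Q     | vertex z | semi-dia. | media            |
|---------------|-----------------|--------|-------|----------|-----------|------------------|
| cornea front  | conic           | 7.77   | −0.18 | 0.00     | 7.0       | air → cornea     |
| cornea back   | conic           | 6.40   | −0.60 | 0.50     | 7.0       | cornea → aqueous |
| iris plate    | plane, aperture | ∞      | –     | 3.66     | 2.25 (pupil) / 7.0 (plate) | aqueous |
| IOL front     | sphere          | 13.86  | 0     | 4.66     | 3.0 / 3.5 | aqueous → IOL    |
| IOL back      | conic + poly    | −11.66 | −1.5  | 5.63     | 3.0 / 3.5 | IOL → vitreous   |
| IOL edge      | cylinder band   | –      | –     | rim-to-rim | 3.0 / 3.5 | IOL ↔ humor   |
| retina        | hemisphere      | −12    | –     | 23.95    | 12.0      | terminal         |

Refractive indices: cornea 1.376, aqueous = vitreous 1.336, IOL 1.458
(hydrophilic acrylic), all at a single design wavelength — no
dispersion is modelled.  The IOL back surface carries even-polynomial
sag terms α₂ = −6.34·10⁻³ mm⁻¹, α₄ = 1.15·10⁻³ mm⁻³,
α₆ = −3.86·10⁻⁷ mm⁻⁵, α₈ = −2.47·10⁻⁸ mm⁻⁷ on top of the conic:

    z(r) = c r² / (1 + √(1 − (1+Q) c² r²)) + α₂r² + α₄r⁴ + α₆r⁶ + α₈r⁸ ,
    c = 1/R.

The α₂ term contributes vertex curvature; including it, the IOL powers
to ≈ 21 D and the whole eye to ≈ 60.3 D, so a collimated bundle along
the visual axis focuses on the fovea.

The IOL edge is a sharp cylindrical band at the optic semi-diameter,
spanning the axial gap between the front-rim and back-rim sags with the
center thickness fixed at 0.97 mm.  For the 6 mm optic this gives a
0.295 mm edge (consistent with the nominal 0.3 mm); for the 7 mm optic
the same surfaces leave only ≈ 0.10 mm of rim — the center thickness is
exposed as a config override (`iol_center_thickness_mm`) for users who
prefer to preserve the edge height instead.

The fovea is located by aiming the 0° chief ray: the incident direction
at the 5° visual-axis slant is launched such that, after the two corneal
refractions, it crosses the iris plane exactly at the decentered pupil
center (a 1-D Brent root search on the source offset); its retinal
intersection defines the fovea center.  With the nasal pupil decenter
the fovea lands ≈ 1.46 mm temporal of the retinal apex.

## Ray-tracing procedure

Propagation is non-sequential: at each event the nearest intersected
boundary among *all* scene surfaces is found and its rule applied, so
rays can revisit surfaces in any order (required for edge reflections
and lens-bypassing paths).

* Conic caps are intersected analytically through the implicit conic
  quadratic (selecting the vertex branch); the polynomial back surface
  is refined by Newton iteration to |Δz| < 10⁻⁹ mm.  Plane, cylinder
  and retinal sphere are closed-form.
* Refraction is the vector Snell law; total internal reflection (the
  IOL/humor critical angle is arcsin(1.336/1.458) ≈ 66.4°) reflects
  specularly.  Rays carry unit power throughout: no Fresnel
  partial-power splitting is applied, which isolates the idealized edge
  behaviours from surface ghost reflections.
* Edge modes: `reflective` mirrors at the cylinder; `antireflective`
  forces Snell transmission through it (a ray with no Snell solution is
  absorbed, keeping the mode pure-transmissive); `absorbing` terminates
  the ray.  The first edge contact is recorded per ray.
* The iris plate absorbs within its 14 mm diameter outside the pupil
  opening; the pupil opening is a non-interacting monitor that tallies
  each ray's first forward transit (Detector-P).
* Ties at the shared cap/edge rim resolve in favour of the caps; after
  every interaction the ray is advanced 10⁻⁹ mm to avoid
  self-reintersection; rays are capped at 50 events (`event_capped`),
  which affects ≲ 10⁻⁴ of rays only in reflective-edge sweeps near
  80–85°, where a small population enters trapped mirror/TIR orbits;
  the sweep driver logs any angle where the capped fraction exceeds
  10⁻⁴.

The engine exposes a per-ray API (`step`, `trace`) and a vectorized
bundle tracer (`trace_bundle`) driving the same event kernel; the test
suite asserts they agree ray for ray.  A cornea-only configuration is
validated against an independent 2×2 paraxial matrix model (< 1%
transverse error within 0.1 mm of the axis).

## Beam model (synthetic input)

Each swept angle θ (0–90°, default 1° steps) launches a collimated
bundle at θ_opt = θ − 5° to the optical axis (θ is measured from the
visual axis; the beam arrives from the nasal field at θ = 0 and swings
into the temporal field as θ grows).  Origins sample a uniform disc of
radius 8.5 mm oriented perpendicular to the beam — large enough to
cover the silhouette of the 14 mm corneal zone at every tilt, so the
incident irradiance is uniform in the beam cross-section — positioned
with every origin at least 10 mm in front of the cornea.  The default
2·10⁵ rays per angle keeps a six-variant desk study in minutes; the CLI
`--full-fidelity` flag raises it to 5·10⁶.  Monte-Carlo error of a
fraction p estimated from n pupil rays scales as √(p/n).

Because the bundle cross-section (not the pupil-plane footprint) is
uniformly sampled, the through-pupil power falls roughly as the
projected entrance area (∝ cos θ) times the corneal gain; it therefore
lies well above the cos²θ reference curve produced by a source of fixed
pupil-plane footprint.  All detector fractions are per-angle ratios to
the through-pupil power and are independent of this convention and of
the footprint overfill.

The generator emulates a distant point-like white-light glare source as
a monochromatic, perfectly collimated, unpolarized, unweighted bundle.
It does not model spectral content, source extent, scatter in the
media, or diffraction; passing tests demonstrate the geometry of the
edge-interaction channels, not a radiometric prediction for real
sources.

## Detectors

* **Detector-P** — power through the pupil opening (first forward
  transit), the per-angle normalizer.
* **Detector-N** — IOL-bypassing power: rays that transited the pupil,
  never touched any IOL surface, and continued into the posterior
  segment on the nasal (+x) side.  Ray history is the primary
  criterion; the nasal side is a secondary guard.  Bypassing rays that
  leave the 24 mm retinal aperture sideways at extreme obliquity are
  included, so N rises monotonically toward 90°.
* **Detector-E** — power whose history includes at least one edge-surface
  contact (counted once per ray, any edge mode).
* **Detector-F** — power terminating within the foveal patch, a chord
  disc of radius 0.75 mm (1.5 mm diameter fovea) about the
  visual-axis/retina intersection; chord vs geodesic radius differs
  negligibly at this size.

Per-angle fractions N/P, E/P, F/P are written as CSV together with
P(θ)/P(0°) and the cos²θ reference; a zero-pupil-power angle yields NaN
fractions (reported missing, never silently zero).  Per-angle seeds are
derived from the master seed and the angle value and logged in the run
manifest, so any single angle can be re-run in isolation with output
identical to its sweep row; a repeated run is byte-identical.

## What the simulation shows

With these study conditions the simulation resolves the three
edge-design regimes (values computed by `scripts/acceptance.py` at seed
1, 2·10⁵ rays/angle):

* IOL bypass (Detector-N) switches on at 26° for the 6 mm optic and 47°
  for the 7 mm optic, then grows monotonically toward 90°.  The onset is
  set by the clearance between the nasal pupil rim (x = 2.75 mm with the
  0.5 mm nasal pupil decenter) and the optic rim (3.0/3.5 mm): a
  0.25 mm change in that clearance moves the onset by roughly 10°, which
  makes the onset a sensitive probe of pupil/IOL geometry.
* Edge contact (Detector-E) begins 1–2° before bypass in each case,
  dominated by rays entering the front surface just inside its rim.
* A reflective edge returns a focused foveal band: rays entering the
  front surface near the rim, mirrored at the edge, exit the back
  surface toward the fovea when their internal slope is ≈ 0.2–0.3,
  i.e. in a narrow band around 28–32° incidence (peak ≈ 0.2 % of
  pupil power for the 6 mm optic).  A cylinder mirror preserves the
  axial slope, so steeper rays land peripherally — several mm from the
  fovea at high angles.  An anti-reflective (transmissive) edge removes
  this band; an absorbing edge removes all edge-mediated foveal light,
  leaving foveal power only within the patch's direct-capture range
  (≈ 2° around the visual axis, since the retinal image moves
  ≈ 0.29 mm per degree of field angle against the 0.75 mm patch
  radius).

## Design choices and limitations

* Aqueous and vitreous use the same index (1.336), so only the IOL
  interior needs medium tracking; "asphericity" is interpreted as the
  conic constant Q with additive even-polynomial terms (the standard
  even-asphere convention).
* No eye wall is modelled between the iris plate (14 mm diameter) and
  the retinal rim; the pupil-transit guard keeps such side paths out of
  every detector.
* Detector extents are idealizations; in particular the nasal detector
  is defined by ray history rather than a fixed patch of retina, and
  the foveal patch is exactly the anatomical 1.5 mm fovea.  Reported
  onset angles and foveal percentages shift substantially under other
  detector conventions (a wider foveal detector raises the near-axis
  capture range roughly in proportion to its radius).
* No Fresnel losses, polarization, coherence, scatter, chromatic
  dispersion, haptics, capsule, or tilt/decenter of the IOL.
* Results describe one average geometry; onsets and band positions move
  with pupil size, pupil decenter, anterior chamber depth and optic
  diameter, so they should not be generalized to individual eyes.
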