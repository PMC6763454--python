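# Methods

## Scientific setting

Human enamel is built from carbonated hydroxyapatite (HAP) nanocrystals
bundled into ~5-µm-wide rods and a space-filling interrod, partly wrapped
in organic sheaths. Polarization-dependent imaging contrast (PIC) mapping
measures, pixel by pixel, the orientation of the crystallographic c-axis —
a *director*: an unsigned axis for which d and −d are the same physical
orientation. The c-axis orientation is what sets local elastic anisotropy
and, through adjacent-crystal mis-orientation, how cracks are deflected.
This package implements the quantitative machinery around those maps: the
orientation/color codec, a linear-dichroism forward model with a per-pixel
inverse fit, a seeded synthetic-microstructure generator, neighbor
mis-orientation statistics, and the bi-crystal fracture/elasticity
calculations.

## Orientation parameterization and color codec

An orientation is the pair (c′, γ): c′ ∈ [−90°, +90°) is the
in-polarization-plane angle from vertical, γ ∈ [0°, 90°] the off-plane
angle. The unit director is

    u = cos γ sin c′,  w = sin γ,  v = cos γ cos c′,

with (u, w, v) = (in-plane horizontal, toward the beam, in-plane
vertical). Angular distance between directors is arccos|a·b| ∈ [0°, 90°];
the absolute value enforces sign-invariance. The sign of γ is not
observable from brightness, so γ ≥ 0 by convention; the absolute-dot
distance makes this choice harmless.

Display encoding: hue = 2·(90° − c′) mod 360° — the unique linear mapping
of the 180° director range onto the 360° hue wheel consistent with the
standard legend (cyan = 0°, green = +30°, yellow = +60°, blue = −30°,
magenta = −60°); brightness = 1 − γ/90 (linear; a cosine law would also be
compatible with "full color in-plane, black at 90°" and differs only in
mid-γ rendering — linear was chosen for exact invertibility and is used
consistently on both encode and decode, so no analysis result depends on
the choice). RGB↔HSB uses the standard hexcone transform; an 8-bit round
trip is exact to ±1 channel unit, which corresponds to ≈0.7° of hue —
orientation statistics computed from rendered colors therefore carry ~1°
of quantization noise (`stats.map_from_rgb` exposes this legacy path
deliberately).

## Dichroism forward model and per-pixel fit

X-ray linear dichroism at the Ca L-edge makes the two-energy ratio image
at polarization angle χ follow a Malus-law response

    R(χ) = A + B cos²γ cos²(χ − c′),

with baseline A (default 1) and calibration amplitude B (default 1,
a single config constant standing in for the instrument calibration).
A stack holds 19 ratio images at χ = 0°, 5°, …, 90°. The inverse problem
is linear after the identity cos²x = (1 + cos 2x)/2:

    R(χ) = m0 + m1 cos 2χ + m2 sin 2χ,
    c′ = ½ atan2(m2, m1)  (folded into [−90°, 90°)),
    amplitude = √(m1² + m2²) = B cos²γ / 2  ⇒  γ = arccos√(2·amplitude/B).

The fit is ordinary least squares against the fixed 19×3 design matrix —
deterministic, no initialization, exact on noiseless data, and vectorized
over all pixels at once. Noise is multiplicative Gaussian on ratios
(ratio images normalize illumination, so relative noise is the natural
model); its magnitude `noise_sigma` is configurable and zero by default.

Masking: a fitted amplitude below `mask_amplitude_threshold` (default 5%)
of the full second-harmonic amplitude B/2 marks a non-dichroic pixel —
an organic sheath, or an axis pointing into the beam (γ → 90° removes all
polarization dependence, so near-beam axes degrade gracefully into the
mask rather than into wrong angles; with the 5% default the γ cutoff sits
at ≈77°). An amplitude *above* B/2 beyond tolerance signals a wrong
calibration constant and raises; the tolerance widens with the declared
noise level (20·noise_sigma) because the per-pixel amplitude estimate
fluctuates above B/2 for in-plane pixels under noise, and the guard is
meant to catch gross (≈2×) calibration errors, not noise tails.

Error behaviour: δc′ ∝ noise/(B cos²γ), so in-plane pixels fit best and
the error grows toward the mask cutoff. At 1% ratio noise the median
|c′| error over γ ∈ [0°, 75°] is ≈0.3–0.5°.

## Synthetic enamel generator

The generator emulates the *derived products* of enamel imaging — the
orientation field statistics — not the imaging physics or amelogenesis:

* circular rod heads (diameter 5 µm, default 60 nm pixels) on a jittered
  hexagonal lattice; morphological head/tail keyhole shapes are not
  modeled because the downstream analyses consume orientation statistics,
  not silhouettes;
* a single co-oriented interrod orientation (+30° in-plane by default)
  with per-pixel jitter clipped at ±1°, so any two interrod pixels are
  within 2°;
* gradual intra-rod orientation drift with a per-rod overall spread drawn
  in the 30–90° band and never zero;
* organic sheath arcs (masked, non-dichroic) covering 80% of each rod
  boundary by default — the remaining unsheathed rod–interrod contacts
  produce the characteristic 30–60° spikes in adjacent-pixel histograms;
  half of the unsheathed arc instead blends smoothly into the interrod
  over a 3-px ring (the gradual head-to-tail transition);
* decussation bands: the image is split into horizontal bands, each
  "in-plane" or "out-of-plane"; rods in out-of-plane bands start with
  γ ∈ [65°, 88°] and render red-to-black.

Intra-rod drift comes in two forms. `generate_rod_orientations` is a
bounded random walk on the director sphere (per-step rotation
~N(0, step_sigma = 2°) about a uniform random axis, reflected at a
spherical cap of radius target/2 so the max pairwise spread — the cap
diameter — is bounded by the target and reaches ≥ 80% of it on long
walks). It is exposed for 1D line profiles. `generate_field`, however,
fills rod interiors with an isotropic smooth 2D tangent-displacement
field: two Gaussian random fields (correlation length = rod radius / 2)
give tangent-plane components, scaled so the pairwise diameter of the
displacement cloud equals the per-rod target spread, then the start
director is rotated along each pixel's tangent direction. A scanned 1D
walk leaves adjacent *rows* far apart in walk time and therefore rough
vertically; the 2D field is what makes orientation change gradually in
both image directions, which is precisely the property the
stride-doubling histograms measure. Per-rod target spreads are drawn
uniformly in [min_spread + 10°, 90°] (defaults), with a deterministic
regeneration loop guarding the realized-spread ≥ 30° contract.

Everything is a pure function of the config (including its seed): same
config, bit-identical field.

What the generator does *not* emulate — and what passing tests therefore
do not demonstrate about real data: keyhole rod cross-sections, 3D
structure and true decussation geometry, spatial correlation of the
interrod, instrument drift/registration error, and any calibrated
amplitude-vs-γ relation beyond the cos² law.

## Mis-orientation statistics

For stride s, every valid pixel contributes its angular distance to the
neighbor s pixels to the right and s pixels below (when present and
valid) — two pairs per pixel, no symmetric double counting; border pixels
simply contribute fewer pairs, and pairs touching masked pixels are
skipped. Distances are histogrammed in 0.5° bins over [0°, 90°] (the
terminal edge closed so a 90° distance is counted); counts always sum to
the number of pairs. Strides double 1, 2, 4, …, 256, probing orientation
change as a function of physical separation. `angle_at_frequency` reads
the largest bin whose count still reaches a given level — the last
crossing of the level on the histogram's descending tail. The published
analyses used a level of 10 000 counts on multi-megapixel maps (~0.1% of
stride-1 pairs); on the default 256×256 synthetic field the tests use the
proportionally scaled level round(n_pairs/1000) ≈ 123 so the readout sits
at the same relative depth of the tail.

`region_spread` reports a region's max pairwise distance exactly up to
5 000 valid pixels; larger regions use a seeded 10⁶-pair subsample
(approximate; within ~2° of exact on smooth fields, as tested).

## Fracture and elasticity

* **G_c**: the critical energy release rate is the external work to break
  the specimen per unit created crack area, G_c = L_z ∫₀^0.2 σ dε
  (trapezoidal; 1 GPa·nm = 1 J/m²). The gauge length L_z is an explicit
  parameter: the work integral is per unit volume, and multiplying by the
  specimen length along the load turns it into work per unit through-crack
  area.
* **K_IC** = √(G_c·E), the plane-stress conversion, reported in
  MPa·m^0.5; E defaults to 133.3 GPa (apatite). The plane-stress form is
  the one consistent with the reference value pair (5.87 J/m² ↔ 0.88
  MPa·m^0.5).
* **Periodicity angles**: a bi-crystal built in a periodic cell admits
  only discrete mis-orientations, l_x sin θ = a_z n with a_z = 6.86 Å;
  θ = arcsin(n·a_z/l_x), and l_x can be inferred from a known (θ, n).
  For l_x fixed by θ(n=1) = 14.1°, the set is 14.1°, 29.2°, 47.0°.
* **Elastic tensors**: hexagonal stiffness built from (C11, C12, C13,
  C33, C44) with C66 = (C11 − C12)/2 (the standard hexagonal relation);
  rotation about the out-of-plane y-axis (right-hand rule) by the Bond
  congruence M C Mᵀ in Voigt order (11, 22, 33, 23, 13, 12) — verified in
  tests against the full 4th-order index transformation. `layer_tensors`
  produces the per-layer stiffnesses θᵢ = i·Δθ for layered crack models
  (10 layers by default). Numeric elastic constants are inputs, never
  hard-coded.
* **Crack-tip strain profiles**: ε(y) = p·e^(−qy) + r by
  Levenberg–Marquardt with deterministic initialization (r₀ = min ε,
  p₀ = max − min, q₀ from a two-point log slope); the 3-parameter form
  keeps a far-field strain offset.
* **Mastication pressure**: F/A with N/mm² → GPa conversion; 1000 N on a
  1 mm² cusp is 1 GPa.

## Numerical choices and degenerate inputs

Angles are stored in degrees everywhere; radians are internal. c′
arithmetic folds through [−90°, 90°) with `fold_c_prime`; dot products
are clamped to [0, 1] before arccos. Directors are validated to unit norm
within 1e−6 at the distance API. A stride at or beyond the image size
yields an empty result, not an error; an empty region or a curve not
covering the strain range is an error. Exact-90° distances land in the
last histogram bin. The per-pixel harmonic fit clamps 2·amplitude/B into
[0, 1] before the arccos for γ.

## Problem sizes

Defaults are sized for interactive use: the default synthetic field is
256×256 px (15.4 µm at 60 nm/px, ~8 full rods), fit benchmarks run at
100×100, and the full multiscale histogram set on the default field takes
about a second. All sizes scale through the config objects.

## Known limitations

* B is a single scalar calibration; the true calibrated amplitude-vs-γ
  relation of apatite at the Ca L-edge is instrument-specific.
* Brightness-vs-γ linearity is a convention (see codec section).
* The generator's correlation length and step scale reproduce the
  qualitative histogram shape; no quantitative spatial correlation length
  for intra-rod drift is available to match.
* `region_spread` is approximate above 5 000 px (documented, seeded).
* G_c from a stress–strain curve depends on the chosen normalization
  (gauge length, full-cross-section crack); it is a parameterized
  definition, not a universal constant of the material.
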