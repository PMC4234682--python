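# Methods

## Model

The model represents achromatic surface appearance in a two-dimensional
space with orthogonal blackness (b) and whiteness (w) axes.  All composed
surface representations live in the non-negative quadrant.  Under a single
assumed illumination level the representations of all surfaces fall on the
*standard luminance gamut*, the segment of the line b/b₀ + w/w₀ = 1 between
its axis intercepts (0, w₀) and (b₀, 0).

**Photometric mapping.**  For a region of luminance L in a display with
maximum luminance L_max, the gamut-line parameter is t = κ·u with
u = log₁₀(L_max/L); the luminance vector is (t·b₀, (1−t)·w₀).  Anchoring is
highest-luminance-is-white with an absolute threshold: if L_max < L_white
the scene contains no white surface and a fixed dark-anchor offset
(t += t_dark) pushes all points toward blackness.  The contrast vector adds
c_w = k_w·(1−p)·log₁₀(L_T/L_L) in whiteness and c_b = k_b·p·log₁₀(L_H/L_T)
in blackness, where L_L and L_H are area-weighted geometric means of the
surround components below and above the target and p is the area fraction
of the higher component (overridable by hand, for displays whose effective
surround differs from the raster adjacency).  Both components are
non-negative by construction; pure increments carry only whiteness, pure
decrements only blackness, bracketing surrounds carry both (mixed gamut).

**Decompositions.**  The illuminant shift subtracts the pure-blackness
shadow vector (τ·b₀·κ·log₁₀(L_H^bright/L_H^dim), 0) from dim-framework
luminance vectors; the result lies on a comparison gamut exactly parallel
to the standard one with a smaller effective whiteness intercept, and the
pre-shift vector equals surface + shadow identically.  The framework
anchors are the highest-luminance regions *within* each framework — in
particular an increment target inside the shadow is its own framework
anchor, which is what makes its discounted blackness exactly zero.  The
transmittance shift decomposes each target pixel's coordinates about the
plain-view anchor P: ground_i = δ·(b_i − b_P, 0) for figural increments,
δ·(0, w_i − w_P) for decrements, figure_i the remainder.  At δ = 1 the
figure points line up on the constraint line through P, figure
displacement and ground vector are orthogonal, and every positively
shifted pixel's figure lies strictly closer to P than its undecomposed
point — the inequality that lets figure vectors group into one surface
layer.

**Gating.**  τ = τ_stim·τ_task composes multiplicatively: the task term
(brightness instructions 0, lightness instructions 1) can only act when the
stimulus supports a variable-illumination percept (τ_stim = 1).  δ ∈ [0, 1]
encodes scission strength and requires preserved contrast polarity around
the whole target perimeter (a mixed perimeter raises; callers set δ = 0).
Simultaneous τ ≠ 0 and δ ≠ 0 is rejected as unsupported: the model covers
one illumination step or one transparent medium at a time.

**Matching.**  A predicted match is the luminance L minimising the
Euclidean distance between the reference coordinates and the test-display
curve (the test region's luminance-plus-contrast coordinates as a function
of L on its own surround).  The distance metric is unweighted; every
blackness/whiteness asymmetry lives in the mapping constants.

## Parameters

| parameter | default | meaning |
|---|---|---|
| w₀ | 1 | whiteness intercept of the standard gamut |
| b₀ | 3 | blackness intercept; b₀/w₀ = 3 is the asymmetric scaling |
| κ | 1 | gamut parameter per unit log₁₀ luminance below anchor |
| k_w | 0.25 | contrast-whiteness gain |
| k_b | 0.75 | contrast-blackness gain; k_b/k_w = 3 |
| L_white | 25 cd/m² | absolute white-anchoring threshold |
| t_dark | 0.2 | dark-anchor offset when no white is present |

The intercept and gain ratios of 3 implement the estimate that blackness
varies at least three times as steeply as whiteness per unit log-luminance;
every qualitative prediction in the package holds for any positive values
respecting that ≥3 asymmetry.  Log base 10 is a convention; changing base
rescales κ, k_w, k_b.

## Numerical choices

* **Saturation.**  The public mapping clips the gamut parameter at t = 1 so
  presented points stay inside the segment.  The decomposition pipeline
  runs on the *extended* (unclipped) line: the illuminant shift must
  commute exactly with the log-luminance mapping for conservation and
  blackness constancy to be exact at large illumination ratios (the
  comparison-gamut coordinates of a deeply shadowed surface are reached
  from far down the extended standard line).  Saturation is thus a
  presentation-stage clamp, not part of the algebra.
* **Clamping.**  An illuminant shift that would drive blackness negative
  (possible only with inconsistent framework labelling or exploratory
  parameter sweeps) clamps to 0 and warns rather than erroring; rounding
  residue within 1e−12 is snapped silently.
* **Minimisation.**  Match prediction scans 512 log-spaced candidates and
  refines the bracket with bounded scalar minimisation to 1e−6 log units.
  The distance curve is continuous but only piecewise smooth (breakpoints
  where the candidate luminance crosses a surround component), so the
  coarse scan guards the refinement against the wrong piece; tests compare
  against a 10⁵-point exhaustive grid.
* **Degenerate inputs.**  Non-positive luminance is rejected (log
  undefined) rather than clamped; empty regions, isolated targets,
  ratio-inverted framework anchors and mixed-polarity perimeters raise
  with instructive messages.

## Synthetic displays

The generator emits the three display families the model is evaluated on,
as piecewise-constant region rasters with ground-truth parses.  Defaults
were chosen once to emulate the published display classes at realistic
photopic levels; the originals' exact luminance tables live in prior
publications and are user-overridable here.

* **Checkerboard**: reflectance palette {0.2, 0.4, 0.6, 0.9} rendered
  identically in a bright (100 cd/m²) and a dim (100/3 cd/m²) half —
  identically distributed reflectances across frameworks, the condition
  under which blackness constancy is exact — plus a derived low-reflectance
  check (r_max/k) whose bright rendering equals the dim r_max check's
  luminance pointwise (the equal-luminance pair of the illusion).
* **Paint/transparency/shadow display**: background reflectance 0.5 under
  100 vs 33.3 cd/m² illumination; both targets at 30 cd/m², making the
  left target a decrement in the bright field and the right target an
  equal-luminance increment in the dim field.  All six variants share one
  raster; Paint parses declare uniform illumination (τ_stim = 0),
  Trans/Shadow declare the illumination step (τ_stim = 1) and are
  deliberately identical to each other — the model does not distinguish a
  shadow from a transparency overlay.
* **Gradient-target (scission) display**: a 16-band target spanning
  40·(1±m) cd/m² for Michelson contrast m, flanked by a 16-band surround
  gradient hugging the target range — (0.75–0.95)×min for the blackish
  (increment) polarity, (1.05–1.25)×max for the whitish (decrement)
  polarity.  The narrow span reflects that the atmospheric gradient in
  such displays is a mild modulation around the target range rather than a
  multi-fold luminance step; it also keeps the reference display's anchor
  close to the matching display's, which is what places the predicted
  matches above the plain-view extremum for both polarities.  The rotated
  control re-emits the same raster with δ = 0.
* **Matching display**: a half-black/half-white checkered background at
  3 and 90 cd/m² (p = 0.5), candidate luminances 0.5–90 cd/m².

What the generator does *not* emulate: rendered object geometry, smooth
(non-discretised) gradients, photorealistic alpha compositing, chromatic
content, and observer noise.  Passing tests therefore demonstrate the
model's internal consistency and its qualitative agreement with the
published phenomena under these emulated photometries, not quantitative
agreement with any individual observer's settings on the original stimuli.

## Design choices where the design was open

* The decrement-polarity plain-view anchor is the blackest pixel *within
  the target region* (in plain view where the whitish medium is fully
  transparent), mirror-symmetric to the whitest-pixel anchor for
  increments.  This is the only choice that keeps the ground shifts
  non-negative and the row alignment, conservation and orthogonality
  properties simultaneously exact.
* Ground vectors are reported as displacements anchored at P (they lie
  along a single axis), not as absolute points; the absolute convention
  cannot keep conservation and orthogonality exact at once.
* τ composes multiplicatively — the minimal form in which the task term
  acts only when the stimulus term is non-zero.
* In the scission suite the δ = 1 reference is the figure representation
  of the plain-view extremum band; the δ = 0 (rotated) reference is the
  region-level brightness coordinates of the whole target.  The
  above-plain-view bias then follows from the heavier contrast-blackness
  weighting of the checkered matching display, and the rotated control
  collapses the polarity-linked spread.
* The region labeller is a deterministic tolerance-based connected-
  component pass (raster-scan order, running geometric mean); the model
  needs consistent region photometry, not a competitive segmentation.

## Known limitations

* One illumination step (bright/dim) per scene; no multi-level illumination
  hierarchies and no simultaneous illumination + transmittance variation.
* τ and δ are inputs supplied by the scene parse, not estimated from the
  image.
* Gradients are discretised into constant bands so that region statistics
  are well defined; band count is a parameter (default 16).
* Whiteness coordinates on the extended line can leave the unit segment
  for within-framework dynamic ranges above 10^(1/κ); such displays exceed
  the model's intended low-dynamic-range operating regime, though the
  blackness identities remain exact.
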