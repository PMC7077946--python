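# Methods

## Template geometry

The template models each of the six maxillary anterior teeth (FDI 13,
12, 11, 21, 22, 23) as an axis-aligned rectangular "aesthetic box" in a
millimetre frame, plus five connector zones and four reference
polylines.  Coordinate convention: x increases to the viewer's right, y
increases downward (raster-image convention), origin on the midline at
the central-incisor incisal-edge level.  The patient's right teeth (11,
12, 13) occupy x < 0.

Given the parameters below, the construction is:

* central box: width `W1 = central_width`, height `H1 = W1 / wh_ratio`,
  zenith at y = −H1, incisal edge at y = 0;
* lateral box: width `W2 = W1·r` with `r = regressive_factor`, zenith at
  −H1 + `lateral_zenith_drop`, incisal edge at −`incisal_step`;
* canine box: width `W3 = W2·r`, zenith and incisal edge level with the
  central's (the canine tip is treated as optically level with the
  central edges in a frontal view; the parallax of the canine's actual
  position is deliberately not modelled);
* boxes abut without gaps on each side and are mirrored exactly across
  x = 0;
* all five papilla tips sit on one horizontal line at
  y = −H1·`papilla_line_fraction`; each contact point sits `f·H1` below
  its papilla tip, where `f` is that pair's connector fraction.

Lateral box height is therefore `H1 − lateral_zenith_drop −
incisal_step` and canine box height is `H1`: these follow from the
zenith and incisal rules rather than being free parameters.

### Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| `central_width` | mm | 8.0 | mesiodistal width of a central incisor; the template's single scale input |
| `wh_ratio` | — | 0.80 | central incisor width/height |
| `regressive_factor` | — | 1/√2 ≈ 0.70711 | adjacent-width ratio (diagonal of the square) |
| `lateral_zenith_drop` | mm | 0.6 | lateral zenith below the central/canine zenith line |
| `incisal_step` | mm | 0.8 | lateral incisal edge above the central edges |
| `connector_fractions` | — | 0.50, 0.40, 0.30 | connector height / central height for central-central, central-lateral, lateral-canine |
| `papilla_line_fraction` | — | 0.70 | papilla-tip depth below the central zenith as a fraction of H1 |

The normative regressive constant is exactly 1/√2; the commonly quoted
"71 %" is its rounding to integer percent.  Validation requires the
connector fractions to be strictly decreasing in (0, 1) and
`papilla_line_fraction` to exceed the largest fraction so contact points
stay gingival to the incisal edge.

### Papillary line depth

There is no established normative height for the interdental papillae.
The package places all five papilla tips on one horizontal line at 70 %
of the central height and derives the contact points from the 50-40-30
fractions.  This reproduces the clinically described ordering (contact
between centrals most incisal, lateral-canine contact most gingival)
and makes the connector fractions exact.  The price is that the
papillary and contact-point lines cannot be mutually parallel — exact
50-40-30 heights and parallel lines are mathematically incompatible —
so the papillary line is kept level and the contact line slopes; the
report exposes the fitted angle between them
(`papillary_contact_parallelism`, 0° on the symmetric ideal template
because the least-squares line through symmetric points is level).

### Scale behaviour

Dimensionless parameters make ratios scale-free, but the zenith drop
and incisal step are absolute millimetre offsets.  Scale equivariance
therefore holds over the set of length-dimension parameters scaled
together: doubling `central_width`, `lateral_zenith_drop` and
`incisal_step` doubles every coordinate exactly (tested bitwise).

### Rendering

The rectangular boxes and the reference lines carry all metric meaning.
The rounded crown silhouettes in the SVG output are cosmetic only —
fixed quadratic-Bézier rounding of the box corners — and never enter
any metric.

## Landmark schema

34 named points (24 tooth points: zenith, incisal midpoint, mesial and
distal incisal corners per tooth; 5 papilla tips; 5 contact points) plus
two optional lip polylines (≥ 3 vertices).  FDI two-digit numbering is
normative; Universal numbering equivalents: 13→6, 12→7, 11→8, 21→9,
22→10, 23→11.  Coordinates are continuous positions with no half-pixel
centre offset (annotation tools differ; the convention is simply "no
offset applied").  Incisal corners must be annotated in pairs; any
other subset is valid and downstream metrics degrade gracefully.  Two
file dialects round-trip exactly: a JSON document and a `name,x,y`
table (lip vertices as `upper_lip[i]` rows; the reader uses pandas'
round-trip float parser because the default parser is lossy in the last
ulp).

## Metrics

**Orientation canonicalization.** Any metric reading a vertical offset
first rotates the landmark set so that the mean vector from each
patient-right landmark to its mirrored patient-left partner is
horizontal.  This gives invariance under global rotation and
translation; on bilaterally symmetric input the estimated angle is
exactly zero, so template-frame computations stay exact.

**Tolerance scaling.** Class tolerances are stated in mm (default
0.2 mm for the cervical/incisal line classes).  In a pixel frame they
are converted with the supplied mm-per-px scale when given; otherwise
they are multiplied by the measured mean central-crown height divided
by the ideal crown height (10 mm by default), which makes class labels
invariant under uniform scaling of the annotation.  Lengths are
reported in mm only when the frame is `template` or a scale is given;
otherwise they stay in input units and the mm fields are absent.

Definitions (y-down sign convention throughout):

* **Apparent widths**: Euclidean distance between a tooth's incisal
  corner pair; regressive ratios lateral/central and canine/lateral per
  side; dominance requires strictly decreasing widths on both sides.
* **Cervical line**: per side, `d = y(lateral zenith) − ½(y(central
  zenith) + y(canine zenith))`; positive `d` (lateral more incisal) on
  both sides beyond tolerance → convex, both negative → concave, else
  flat.  The ideal template gives d = +0.6 mm per side.
* **Incisal outline**: `s` = mean over sides of `y(central edge) −
  y(lateral edge)`; s > tol → soup plate (+0.8 mm on the ideal
  template), s < −tol → inverted, else flat plate.
* **Connector ratios**: `100·(y_contact − y_papilla)/H` with `H` the
  mean central crown height; central-lateral and lateral-canine
  averaged over sides.  Non-positive heights are flagged as annotation
  errors and excluded.
* **Smile arc**: least-squares quadratics `y = ax² + bx + c` (x centred
  on the midline — the vertical through `cp_11_21`, falling back to the
  mean mid-x of mirrored pairs) through the incisor incisal midpoints
  and through the lower-lip vertices.  A quadratic is the simplest form
  capturing the convex/flat/reverse trichotomy.  Canine tips are
  excluded from the incisal fit by default: in the template they sit
  level with the central edges (frontal-view parallax), which would
  cancel the curvature of a perfectly ideal smile; a config flag
  re-includes them.  Classification: flat when |a_incisal| is below the
  curvature tolerance (0.001 mm⁻¹, scale-adjusted); reverse when the
  incisal and lip curvatures have opposite signs; consonant when both
  open toward the gingiva (a < 0) with curvature ratio in [0.5, 2.0].
  The unspecified residual case — same sign but ratio out of range, or
  an essentially straight lip — is classified flat (non-consonant
  without inversion), with the Δa statistic exposing the mismatch.
  Fewer than three distinct x positions → undetermined.
* **Lip line**: crown coverage `c = (y_lip − y_zenith)/(y_incisal −
  y_zenith)` interpolated at each central incisor's x and averaged.
  c < 0 → high (gingival display reported in mm when the scale is
  known); c > 0.25 → low; boundaries fall to medium (deterministic
  tie-break to the middle class).  A lip polyline that does not span a
  central's x position contributes nothing; no centrals spanned →
  absent.
* **Symmetry**: mean Euclidean distance between each patient-left
  landmark and the reflection of its patient-right partner across the
  midline; 0 on the ideal template.
* **Aggregate report**: runs everything and, given template parameters,
  attaches signed deviations (regressive ratios vs `regressive_factor`,
  W/H vs `wh_ratio`, connector percentages vs fractions, zenith drop
  and incisal step vs their parameters, the mm ones only when mm are
  known).  Missing landmarks yield absent fields plus a flag, never an
  error.

Classification thresholds (0.2 mm line tolerance, 0.001 mm⁻¹ curvature
tolerance, [0.5, 2.0] consonance band, 0.25 lip coverage) are package
conventions — the underlying clinical definitions are qualitative — and
all are configurable via `MetricConfig`.

## Registration and overlay

A two-point similarity fit (uniform scale, rotation, translation; no
reflection or shear): with the anchor points as complex numbers,
σ = (q₂−q₁)/(p₂−p₁) gives scale |σ|, rotation arg σ, translation
q₁ − σp₁.  The fit is exact on its anchors and agrees with the analytic
similarity everywhere (property-tested on 200 seeded random instances).
Default anchors are the distal incisal corners of the two central
incisors, i.e. the combined central width — the natural choice given
that registration is defined by making the central widths coincide; any
two landmarks can be designated instead.  Two points are the minimal
well-posed input, and the rotation component absorbs tilted photographs.

Rendering is vector-first (SVG, 1 mm = 1 user unit when untransformed);
raster overlays are drawn directly at the photograph's pixel grid and
alpha-composited, so the photo is never resampled.  A transform placing
the template partly outside the canvas warns and clips rather than
refusing.

## Synthetic smiles

`make_smile` starts from the exact landmark export of the template and
applies one documented deterministic deformation per preset (gummy lip
lift, deep-bite central extension, inverted incisal outline, one-sided
shift, levelled edges), adds lip polylines (lower lip parallel to the
ideal incisal curve at a 2 mm gap; upper lip covering 10 % of the
central crowns, or lifted above the zeniths for the gummy preset), then
i.i.d. isotropic Gaussian noise per landmark with an explicit seed.
This emulates annotation scatter on an otherwise ideal frontal
geometry.  It does **not** emulate perspective or parallax, lens
distortion, lip-shape variation, occlusions, or anatomically correlated
deviations — so passing tests demonstrate correctness of the metric
definitions and robustness to annotation noise, not performance on real
photographs.

## Numerical choices and problem sizes

* All template constructions are closed-form; exactness tests assert at
  1e-9 or bitwise where the arithmetic is exact.
* Stochastic checks use 200 seeded replicates at 0.1 mm noise for class
  recovery (≥ 95 % required per label) and 200 seeded random transforms
  for the registration property; these sizes give stable pass/fail
  margins (the class-recovery signals sit 3–6 standard deviations from
  their thresholds) while keeping the suite fast.
* Degenerate inputs: coincident registration anchors raise; collinear-x
  curve fits return `undetermined`; empty landmark sets return an
  all-absent report.

## Known limitations

Strictly 2D and frontal: no 3D geometry, no perspective correction, no
tooth-axis angulation scoring (no accepted numeric rule exists; axes
are rendered as vertical box midlines only).  Apparent widths are
frontal-view projections; the canine's true mesiodistal width is
under-represented, which is accepted rather than corrected.  The ideal
template is a reference, not a norm — substantial individual variation
is expected and the deviations are meant to be read, not minimised.
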