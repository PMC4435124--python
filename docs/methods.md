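# Methods

## Scope and data model

The package models the computational path from a rover stopping at a
surveyed grapevine to per-plant fruit traits. Five stages are implemented
as separate modules: synthetic scene generation (`synthetic_scene`), berry
detection (`berry_detection`), pixel-to-mm calibration
(`size_calibration`), LDA color classification (`color_classifier`) and
acquisition-side data management (`field_catalog`), orchestrated by a thin
CLI (`cli`). Camera, vehicle and GigE transport are out of scope; the
acquisition protocol exists as a discrete-event simulator so that its
ordering guarantees are testable.

All image coordinates are 0-based with origin top-left, x = column,
y = row. A pixel belongs to a disk iff its center is within the radius
(strict Euclidean test); rendering and color extraction share this rule.
Field coordinates are UTM easting/northing in metres throughout; no
lat/lon conversion exists anywhere in the package.

## Synthetic scenes

The generator emulates night-time bunch-zone images: a dark background
(≈16/15/18 RGB) with low-frequency blurred clutter, a horizontal trellis
wire, a magenta reference label of known physical length fixed at the wire,
and clustered shaded circles for berries. Berries are placed by rejection
sampling around `cluster_count` cluster centers; a pair may overlap by at
most 30% of the smaller circle's area (`max_overlap`), enough to exercise
occlusion handling while keeping most berries resolvable. Packing failures
after a bounded number of attempts raise `PackingError` naming the spec.

Berry shading is radial: pixel value = base · (1 − 0.35 · (d/r)²), which
gives each berry the intensity falloff of a convex surface under frontal
LED light. The expected mean over the inner 0.8 r disk is therefore
base · (1 − 0.35 · 0.8²/2) in closed form; this analytic value is stored
in the ground truth, so color-extraction tests compare against an
expectation derived independently of the rendered pixels.

Per-class berry colors are trivariate Gaussians (means/SDs in
`CLASS_RGB_MEANS` / `CLASS_RGB_SDS`, channel correlation 0.5, clipped to
0..255). They were chosen once to reproduce the qualitative structure of
field RGB distributions: red (class 2) and rose (3) means sit about one
standard deviation apart per channel and overlap heavily; black (1) and
green (5) are far separated; grey (4) is moderately close to green. For
classification experiments one draw of the class distribution represents
one *image's* mean color — image-to-image variation is dominated by
genotype, and the per-image mean over many berries averages per-berry
noise away.

The default scene (400×300 px, 12 berries, radii 12–17 px at 0.4 mm/px,
50 mm label) puts berry diameters in the 9.6–13.6 mm range typical of wine
cultivars, at a resolution comparable to a bunch-zone crop from a field
camera. These defaults are deliberately modest in size so a 70-scene
benchmark (20 training + 50 evaluation) runs in seconds.

Plant grids use 2.0 m interrow spacing and 1.0 m vine spacing, rows
north-south, with uniform ±2 cm survey jitter per axis matching RTK-GPS
accuracy. Training direction is drawn per vine from the grid seed.

What the generator does **not** emulate: foliage occlusion, specular
highlights, depth-dependent scale (berries off the label plane), daylight
shadows (a demonstration-only gradient mode exists), and camera optics.
Passing benchmarks on these scenes therefore show algorithmic correctness
under controlled night-acquisition-like conditions, not field-grade
robustness.

## Berry detection

Candidates come from a circular Hough transform (scikit-image) on a Canny
edge map (σ = 1.6). Accumulators are perimeter-normalised; local maxima
above 0.35 enter a greedy non-maximum suppression: candidates are visited
in score order (ties toward smaller (y, x, r)) and accepted only if no
previously accepted circle's center is closer than 0.8 · (r₁ + r₂)/2.
Accepted circles are refined to sub-pixel precision by a Kasa algebraic
least-squares fit to edge points within ±2.5 px of the candidate ring;
refinements that move the circle more than ~3.5 px are rejected as capture
by neighbouring structure. The refinement is what brings diameter errors
from the ±1 px Hough quantisation (≈4–7% of diameter) down to the ~2%
observed.

The one-class vetting model is a Gaussian over a 7-vector per candidate
patch: per-channel mean, per-channel SD, and the slope of grey intensity
against normalised radial distance (clearly negative for shaded convex
berries). It is trained on positive patches only (≥10 required); the
acceptance threshold is the 0.99 quantile of training Mahalanobis
distances. The covariance gets a ridge of 10⁻⁶ · trace/dim on the diagonal
when its condition number exceeds 10¹⁰ (and always when the variance is
zero). Acceptance score is exp(−d²/2).

Known limitation: the quantile threshold rejects by construction about 1%
of true berries, and a bit more when the patch is contaminated by an
occluding neighbour; end-to-end recall on the standard benchmark is
therefore ~0.95–0.99 rather than 1.0, with precision ≈ 1.0 because clutter
rarely resembles a shaded disk in all seven features.

## Size calibration

The label is the largest connected component in a chroma window (default:
R ≥ 150, G ≤ 110, B ≥ 150 — the generator's magenta, a region of RGB space
no berry class occupies); components under 150 px are ignored. Scale is
read along the bbox major axis, robust to small rotations and to label
orientation. One calibration per image; a missing label flags the image
uncalibrated — its sizes stay in pixels and are excluded from mm
statistics rather than the image being dropped.

## Color classification

LDA is implemented directly (it is the package's statistical core): class
means, pooled within-class covariance with divisor N − K, proportional
priors, linear discriminants, softmax posteriors, ties toward the lower
class code. The same ridge policy as the one-class model guards
near-singular covariances. Tests cross-check predictions against a
brute-force Gaussian Bayes oracle (full log-densities with the pooled
covariance) and against scikit-learn's implementation.

Cross-validation is leave-one-out by default — deterministic, no fold-seed
ambiguity; k-fold is available behind a flag with a mandatory seed. A
training fold in which a class drops below the 2-sample fit minimum trains
without that class (it cannot be predicted in that fold) instead of
failing. Confusion matrices are oriented rows = predicted,
columns = real, in the order black, green, grey, red, rose; per-class
accuracy is 100 · diagonal / column-sum truncated toward zero — the only
rounding convention consistent with all reference pairs (197/202 → 97,
28/39 → 71, 13/22 → 59).

Priors (proportional vs uniform) and CV flavor were genuinely open; the
defaults above are this package's choices, documented as such.

## Field catalog

Filenames are `plantID_camera_cameraID_YYYYMMDDThhmmss.ext`; underscore is
the reserved separator and is rejected inside IDs, making the mapping
bijective (property-tested). Geotags live in a JSON sidecar (authoritative,
rounded to 1 mm / 0.001°) with a convenience copy in the PNG text header;
non-PNG containers degrade to sidecar-only with a warning. Stop positions
shift the vine's northing by ±0.25 m toward the training direction; the
offset is deliberately non-idempotent and guarded by a distinct
`StopPosition` type. Image-to-plant assignment trusts the filename's plant
ID against the plant table and only warns (never fails) when the recorded
GPS fix is more than 0.5 m — half the vine spacing, so a mismatch can never
silently point at the neighbouring vine — from the stop point.

The acquisition simulator serialises the per-plant handshake (position
message → synchronized trigger → per-camera record → acknowledgment) and
emits an event log; protocol-safety tests assert no trigger for plant i+1
precedes the acknowledgment for plant i. Stop fixes get ±2 cm jitter per
approach, the clock advances 15 s per vine, and injected camera faults log
the plant as incomplete while the protocol still acknowledges and
proceeds. The catalog is a single-file sqlite store; queries
(plant ID, spatial rectangle, date range) return records stable-ordered by
(plant_id, timestamp, camera_role).

## CLI

`simulate`, `phenotype`, `evaluate`, `catalog` wrap the library with YAML
configs and exit codes 0/2/3 (success / configuration error / data error).
`phenotype` needs a one-class model at run time: it trains on ground-truth
sidecar patches when they exist (synthetic runs) and otherwise
self-trains on the strongest half of the Hough candidates — adequate
because raw candidates on night scenes are overwhelmingly true berries.
The optional LDA color model is fitted from a labelled samples TSV given
in the config; without one, the predicted-class column stays empty.

## Benchmarks and problem sizes

The standard detection benchmark trains the one-class model on 20 scenes
and evaluates on 50 disjoint scenes (600 berries) with default scene
parameters and fixed seeds; matching is greedy in score order with
tolerances of half a radius on center and 35% on radius. Diameter error is
measured end-to-end in mm (label calibration included) against the truth
scale. These sizes keep the full test suite under half a minute while the
property bands (recall ≥ 0.95, precision ≥ 0.95, diameter RMSE ≤ 5%) are
measured on hundreds of berries. The color-classification simulation uses
500 samples with class counts 202/200/39/37/22, matching the composition
of the reference validation set.
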