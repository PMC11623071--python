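# Methods

## Overlap-aware fuzzy inference (ELSL)

A linguistic variable is a range `[s, e]` with a peak `m` ("midst"); its
membership profile is the distance ratio `(x−s)/((x−s)+(m−x))` below the
peak and the mirror image above it — a triangle when `m` is the midpoint.
The shipped configuration sets every midst to the interval midpoint: the
range tables define only start/end, the reference figures draw symmetric
profiles, and the half-span identity `min(x−s, e−x)` used by the normalizer
peaks at the midpoint, so any other choice would make the two formulations
disagree.

Where ranges overlap, classical triangular memberships can sum to more than
one. The engine instead normalizes every active variable's half-span by

    ΔD = Σ_active min(x − s_i, e_i − x)

so that in any region covered by two or more variables the active
memberships sum to exactly 1. Two step functions mediate the regimes:
`f_i` (1 iff `min(x−s_i, e_i−x) ≥ 0`) excludes variables whose range does
not contain x, and `N_x` (1 iff at most one variable is active) re-inserts
the `|m_i − x|` term of the single-variable ratio, making the normalized
form reduce *exactly* to the ratio profile in single-coverage regions.
Boundary convention: at `x = s` or `x = e` the variable counts as active but
its membership is 0 (zero numerator), so the two conventions are consistent.

Note the normalization makes memberships piecewise continuous *within* each
coverage regime but allows jumps where the regime changes: entering an
overlap region drops the `|m−x|` term, so the already-active variable's
membership steps up even though the newly-active variable enters at 0.

### Rules, implication, defuzzification

Rule activation is min-conjunction over antecedent memberships (standard
Mamdani AND; nothing in the method requires product). A fired rule's
activation is anchored into its consequent's output range,

    z_i = start_out + activation · (end_out − start_out),

so Noise rules (range 0–60) implicate into [0, 60] and Defect rules
(40–100) into [40, 100]; the crisp output is the plain arithmetic mean of
the `z_i` over fired rules, and the binary label is Defect iff `z ≥ 50`,
the midpoint of the printed 40–60 overlap (ties to Defect). Anchoring is a
deliberate design choice: both output ranges have the same width (60), so a
width-only implication would produce a z completely independent of *which*
rules fired — the crisp output would carry no label information and the
threshold classifier could never separate the classes. Anchoring is the
minimal reading under which the printed output ranges mean what they say.

When no rule fires (e.g. a faint large smudge: no rule pairs Low intensity
with Medium area) the engine returns the Noise label with `z = NaN` — no
evidence must never fire the pesticide pump.

### Known artifacts of the mean defuzzifier

Two quirks follow from averaging anchored implications and are worth
knowing before tuning ranges:

* **Dilution at band onsets.** When a new rule starts firing with a tiny
  activation, it contributes a nearly-constant `start_out` term to the mean
  and can pull z across the boundary; the decision surface is therefore not
  globally monotone in the features (e.g. around area 1,500 px, raising the
  intensity difference through 0.55 can momentarily flip Defect → Noise as
  the High-intensity rules enter weakly). Inside the unambiguous bands
  (contrast 0.6–0.8 with area 2,500–4,700 px for defects; contrast ≤ 0.15 or
  area ≤ 400 px for noise) the classification is uniform, and the tests
  assert exactly that separation.
* **Strong-noise overlap.** Because the Noise range extends to 60, a Noise
  rule fired near activation 1 alone yields z up to 60 ≥ 50 and is labelled
  Defect. This affects a narrow band (contrast ≈ 0.15–0.25 at areas near
  the Small peak) and is exercised deliberately by the boundary-straddling
  synthetic suite.
* **Outer-edge falloff.** The outermost triangular ranges fall back to 0 at
  the universe ends, so an extremely large spot (≳ 11,300 px) scores lower
  than a mid-sized one; areas beyond the universe top (12,000 px) are
  clamped to the top and flagged rather than extrapolated.

## Segmentation chain

Crop → grayscale (ITU-R 601 weights 0.2989/0.5870/0.1140) → 5×5 Gaussian
blur with σ = 8 (at that σ the kernel is nearly uniform — a gentle
pre-smoothing; both parameters configurable) → Canny edges → hole filling →
inversion, after which spot pixels are the dark pixels. The crop rectangle
is expected to lie *inside* the leaf: that keeps the leaf outline itself out
of the edge map, so filled regions are spots, not the whole leaf.

Canny thresholds default to automatic selection: high = Otsu's threshold of
the gradient-magnitude histogram, low = 0.4 × high; boundary handling is
reflective (zero padding would fabricate a frame-border edge). Sobel and
Prewitt edge maps (gradient magnitude over Otsu) are retained for
comparison runs only.

Spots are 8-connected components (fill-then-invert output has diagonal
contacts on curved boundaries; 4-connectivity would fragment them) of at
least 5 px (smaller specks make the intensity mean meaningless, and the
floor is far below the smallest area range boundary that matters, 800 px,
so it cannot change a defect call). Border-touching components are kept — a
pest at the crop edge is still a pest. Per spot: area, centroid, mean
intensity on the *unblurred* cropped grayscale, and the minimal enclosing
circle (Welzl's algorithm on the convex hull of the pixel coordinates) used
for red-circle annotation. The intensity feature divides the 0–255
difference by 255 to reach the classifier's 0–1 universe; the image mean
uses the cropped, unblurred grayscale.

## Sensor gates and actuation

Gates pass the raw value or substitute zero: moisture low-pass (pass iff
x ≤ 20 %), CO₂ high-pass (pass iff x ≥ 50 ppm), temperature band-pass (pass
iff 12 ≤ x ≤ 15 °C). Bounds are inclusive on the equation side; the
observable device switch sits exactly at the printed threshold either way.
The water pump is ON iff the moisture gate passed, the exhaust fan ON iff
the CO₂ gate passed; the temperature band is reported as a healthy/unhealthy
status with no actuator attached, and humidity is carried and logged but
drives no decision. Missing samples and physically impossible values
(moisture/humidity outside 0–100 %, negative ppm) are dropped during stream
cleaning and can never switch a device on (fail-safe OFF: spraying on no
data is the costly error). The monitor loop evaluates once per reading;
sampling cadence is a property of the stream, not of the logic.

## Synthetic scenes and streams

A scene is a bright leaf ellipse (base value 210) on a darker background
(60), with an optional linear illumination gradient, an optional shadow
polygon, planted circular spots (inclusive-radius rasterization, so the
pixel count stays within ~2 % of πr² for r ≥ 10), Gaussian pixel noise
(σ = 1.5), and a green tint whose channel weights are chosen so the
luminance conversion recovers the rendered intensity exactly. Ground truth
records every planted spot's label, geometry, planted value and contrast.

Scenario suites (all bit-reproducible from a seed):

* `unambiguous` — 50 scenes, 25 with 1–2 clear defects (planted contrast
  0.68–0.80, radius 30–38 px → areas ≈ 2,800–4,500) plus faint
  (contrast ≤ 0.15) or tiny (radius ≤ 10 px) noise blobs, 25 with noise
  only.
* `boundary` — 50 scenes whose spots straddle the linguistic boundaries
  (contrast near 0.2/0.45/0.55, areas near 800–5,000 px), with stronger
  gradients and periodic shadows; a stress suite.
* `table3-like` — 20 scenes whose pest-present pattern reproduces the
  bundled benchmark's "real" row (fifteen pest scenes).
* `empty` — spotless scenes.

Spot parameter bands were fixed once, chosen to straddle the classifier's
range boundaries; they are conditions of the evaluation, not tuning knobs.

What the generator does *not* emulate: leaf venation and 3-D texture,
specular highlights, camera optics, compression artifacts, occlusion and
multi-leaf scenes. Passing the synthetic suites therefore demonstrates that
segmentation + classification recover planted ground truth under controlled
nuisances (gradients, shadows, faint clutter), not field performance on
real foliage; the bundled twenty-trial table is the only link to real
imagery.

Sensor streams are base + linear drift + Gaussian jitter; dropouts appear
as missing samples and outliers exceed the channel's physical range, so
cleaning removes both.

## Problem sizes and numerics

Dense-grid membership checks use 10,000 points per universe with a 1e−9
normalization tolerance; the isolated-variable equivalence check uses 1,000
points × 20 random ranges at 1e−12 (the two code paths share no
arithmetic). Scene suites run 50 scenes per suite at 480×640 (analysis
region ≈ 256×368). Division-by-zero guards: a variable active with zero
denominator (only possible when every active half-span is zero) gets
membership 0; degenerate ranges (`start == end`) are rejected at
construction.

## Known limitations

* The decision surface's non-monotonicities (above) are inherent to the
  plain-mean defuzzifier; an activation-weighted mean would smooth them but
  is not what this engine specifies.
* Per-spot counts on real imagery over-segment (several detections per
  physical hole is common); only the frame-level binary call is evaluated
  against the benchmark table.
* The binary output set (Noise/Defect) is fixed; no learning or tuning of
  ranges from data is provided.
* Frames are ingested from files (one analyzed frame per second of footage
  upstream); live capture, transport and dashboards are out of scope — the
  JSON-lines actuation log is the IoT-report stand-in.
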