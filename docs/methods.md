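# Methods

`spermtrack` is a software-only search-assist toolkit for sperm retrieval
under the microscope during microdissection testicular sperm extraction
(Micro-TESE). In non-obstructive azoospermia, sperm in testicular tissue are
rare, often nearly immotile, and embedded in dense cell clutter, so the
embryologist's search is slow and error-prone. The toolkit covers the four
computational stages such an assist system needs — single-frame detection,
identity-preserving multi-object tracking, CASA kinematics, and an annotated
overlay — plus the evaluation machinery and a synthetic scene simulator that
provides exact ground truth.

## Coordinate and unit conventions

Pixels are continuous and 0-based with the origin at the top-left corner
(x rightward, y downward). Boxes are corner tuples `(x_min, y_min, x_max,
y_max)`; area is `(x_max−x_min)·(y_max−y_min)`. Physical quantities are in
micrometres and seconds via a `CalibrationProfile` (defaults 0.14 µm/pixel,
the scale of a 10× objective on a high-resolution camera, and 10 frames/s).
IoU of two zero-area boxes is an error rather than 0, so degenerate
annotations fail loudly.

## Synthetic scenes

The simulator emulates a bright-field-like Micro-TESE field of view: dark
objects on a light background (level 0.82 on a unit intensity scale),
Gaussian blur of 0.7 px standing in for optical softness, and additive
Gaussian sensor noise (σ = 0.02). Three object families are rendered:

* **Sperm phantoms.** An elliptical head (5 × 3 µm by default) with a thin
  trailing flagellum (45 µm long, so the whole cell is ≈ 50 µm; nominal
  width 0.3 µm, rasterized at a floor of ~1.6 px so a sub-resolution
  filament stays visible). The flagellum is one spatial sine arc (≈1.5
  wavelengths along the tail, amplitude 2 µm tapering toward the tip) whose
  phase advances with the beat frequency — enough curvature to make the
  curvilinear/average-path distinction in the kinematics meaningful.
* **Cell clusters.** Aggregates of 4–25 overlapping blobs of 2–6 µm,
  mimicking tissue-cell aggregates that range from single cells to large
  clumps.
* **Head-like debris.** Ellipses with axes sampled near the head's 5:3
  ratio — deliberately the worst case for a shape-based detector.

Head motion is closed-form: stationary, straight (`p0 + v·t·u`), or
sinusoidal (straight progression plus `A·sin(2πft)` perpendicular to the
heading). Ground truth therefore carries exact per-frame boxes (from the
rendered pixel masks), exact head coordinates, and analytic trajectories in
µm. With `occlusion_probability`, a cluster is parked on a sperm's tail
midpoint and painted after the sperm, reproducing partial-tail occlusion.

Everything is a deterministic function of the `SceneConfig`. The static
clutter layout is drawn from one generator seeded with the scene seed;
per-frame noise uses child streams derived from `(seed, frame_index)` so a
single frame can be re-rendered standalone at the same cost as inside a
full-scene render. Default scene calibration is 0.28 µm/pixel (a 2×-binned
acquisition), which keeps a 50 µm cell within a ~125 µm field at 448 px.

What the simulator does **not** model: point-spread physics, defocus,
illumination gradients, blood and vasculature, intensity texture inside
cells, and detector-specific artifacts of real cameras. Tests passing on
these scenes demonstrate algorithmic correctness and the documented failure
modes, not clinical-grade detection performance.

## Detection

Sperm in testicular tissue are often nearly stationary, so frame
differencing is useless; detection is single-frame and purely
morphological: Sobel gradient magnitude → binarization (Otsu by default; a
fixed threshold is available because automatic thresholds can fail under
unusual illumination) → hole filling → a morphological split of the
foreground into head-scale ("thick", surviving an opening with a
0.8 µm-radius disk) and tail-scale ("thin") sub-masks → connected-component
labeling with PCA shape statistics → explicit head–tail assembly.

Shape criteria are in physical units and config-exposed; the defaults
derive from sperm dimensions: head area 6–20 µm² (a 5 × 3 µm ellipse is
≈ 11.8 µm²; gradient filtering dilates the measured blob), head elongation
(eigenvalue ratio λ₁/λ₂) 1.3–4, tail principal extent ≥ 15 µm, tail
thickness ≤ 1.6 µm (the physical tail is 0.2–0.3 µm, but a sub-resolution
filament plus its gradient envelope measures a few pixels — at 0.28 µm/px
the rendered tail measures ≈ 1.3 µm), head–tail junction gap ≤ 3 µm,
head-axis/neck angular tolerance 45°. Tail thickness is measured as twice
the maximum of the Euclidean distance transform, which unlike the PCA minor
extent is insensitive to the tail's curvature.

Assembly pairs each head with the nearest tail whose proximal endpoint is
within the junction distance and angularly consistent with the head's
principal axis; a tail wanted by two heads goes to the nearer one. This
pairing is the candidate-reduction step: debris has head-like shape but no
adjacent filament, clusters fail every size window, so only genuine
head+tail configurations survive. Unpaired heads can optionally be emitted
at a reduced confidence (off by default) — turning this on trades recall
under tail occlusion against debris false positives, and the tests exercise
both sides of that trade.

Confidence is a product of per-criterion margin scores (1 at the middle of
an accepted range, 0.5 at its edge); it is an ordering, not a probability.
Any callable `frame -> list[Detection]` can replace the classical detector
in the tracker and pipeline, e.g. an adapter around a learned one-stage
detector; training such a model is out of scope here.

## Tracking

The tracker is the standard online SORT/DeepSORT design. Per track: a
constant-velocity Kalman filter over `(cx, cy, a, h)` (box center, aspect
ratio w/h, height) and their velocities, with process/measurement noise
scaled to box height (weights 1/20 and 1/160); a bounded gallery (50) of
appearance features; and lifecycle counters. Association per frame is a
matching cascade: confirmed tracks are visited by recency of last update,
each level solving a Hungarian assignment on cosine appearance cost with
pairs outside the χ²₀.₉₅(4 d.o.f.) = 9.4877 Mahalanobis gate or above the
0.4 cosine cap excluded; unconfirmed and just-missed tracks then get an IoU
association at threshold 0.3. Tentative tracks are confirmed after 3
consecutive hits and dropped on their first miss; confirmed tracks survive
up to 30 missed frames (`max_age`), which is what re-associates a sperm
that reappears after a tissue occlusion. Ids are never reused.

The appearance feature is an orientation-binned gradient histogram (4 × 4
cells × 8 unsigned-orientation bins on a 32 × 32 resized crop,
L2-normalized). Sperm are low-texture and nearly rigid, so a classical
descriptor carries the appearance signal this role needs; the extractor is
injectable for anything stronger.

Track positions feed kinematics as head points when the detector provides
them, box centers otherwise. Frames where a confirmed track was only
predicted are recorded as unobserved and excluded from kinematics by
default, because detection cannot be guaranteed in every frame and
predicted positions would bias the path metrics.

## Kinematics

Nine standard CASA parameters per trajectory (all positions in µm):
VCL (sampled path length over elapsed time), VSL (net displacement over
elapsed time), VAP (VCL of the smoothed average path), ALH (max or mean
perpendicular deviation of the raw path from the average path; reported as
deviation, with a doubling left to the caller, since some systems report
width), LIN = VSL/VCL, WOB = VAP/VCL, STR = VSL/VAP, BCF (sign changes of
the signed lateral deviation per second, with a 10⁻⁹ µm deadband so exactly
collinear paths register zero crossings), and MAD (mean absolute turning
angle between successive steps, degrees; zero-length steps skipped). Ratios
with zero denominators are reported missing rather than clamped.

Average-path smoothing is the one genuinely open choice — commercial CASA
smoothing is proprietary and systems are not mutually comparable — so it is
a centered moving average with window `round(fps/2)` forced odd (≈ half a
second), shrinking symmetrically at the ends so the smoothed path keeps the
raw endpoints; the window used is recorded in the analysis output. With
sampling at tens of frames per second this window spans roughly one beat
period of a typical flagellar beat, which is what makes ALH recover the
beat amplitude and BCF recover twice the beat frequency on simulated
swimmers (within 10 % and one crossing respectively, verified in tests).

A windowed VSL series — displacement between a head position and its
position one second later — is the motility index surfaced live in the
overlay, chosen because it stays robust when detection is intermittent;
the full nine-parameter report is written per track.

## Evaluation

Detections are matched greedily in descending confidence to the
highest-IoU unmatched truth box, counting only strictly above the IoU
threshold (default 0.45; ties on IoU break toward the lower truth index,
making the matcher deterministic). Precision/recall/F pool over frames; a
confidence sweep produces the PR curve; average precision is the literal
right-endpoint sum Σ(rᵢ−rᵢ₋₁)P(rᵢ) with r₀ = 0 (an interpolated PASCAL-style
envelope is available behind a flag, off by default); with one object
class mAP equals AP. Tracking quality is summarized as id switches (a truth
track's matched predicted id changing between consecutive matched frames),
fragmentations (matched → unmatched → matched gaps) and matched-frame
counts.

## Pipeline and latency

`pipeline.run` composes detect → track → incremental windowed VSL → overlay
per frame, then finalizes per-track kinematics. The overlay draws each
confirmed track's box, id, head circle and current windowed VSL on a copy
of the frame (inputs are never modified; rendering is pixel-deterministic).
Wall-clock per stage is recorded per frame; exceeding the 200 ms interactive
budget emits a warning and is never a test failure, since throughput is a
property of the host machine.

## Problem sizes used in the test suite

The benchmark scene is a 448 px (≈125 µm) field at 0.28 µm/px and 10 FPS
with three well-separated swimmers spanning the motility range of interest
(straight 4 µm/s, sinusoidal 3 µm/s with 3 µm × 1.5 Hz beat, stationary) —
low speeds chosen to match the near-stationary motility of testicular
sperm. Detector benchmarks pool 20 frames (60 instances); identity
preservation runs 100 frames; kinematic recovery uses analytic trajectories
at 10–50 FPS over 10 s. The cluttered variant adds three cell clusters, six
head-like debris and occlusion of every tail.

## Known limitations

* Detector thresholds are tuned to physical sperm dimensions, not learned;
  heavy clutter shifts the Otsu threshold and merges components, so recall
  degrades sharply under occlusion (by design, this mirrors the documented
  missed-detection mode rather than solving it).
* The appearance descriptor cannot distinguish visually identical sperm
  whose motion gates overlap; crossing trajectories of identical cells may
  still swap ids.
* BCF is a crossing count and is only meaningful when sampling exceeds
  twice the beat frequency.
* The simulator's intensity model is schematic; absolute confidences and
  thresholds do not transfer to real imagery without re-tuning.
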