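# Methods

This note documents the models, conventions, parameter choices, and known
limitations of larvatrack, in the order data flows through the pipeline.

## Coordinate and sign conventions

Pixel coordinates follow image convention (origin top-left, x right, y
down); metric coordinates are y-up in mm with the origin at the arena's
bottom-left corner.  All behavioral features are reported in metric
convention.  "Left" means counterclockwise in metric (y-up) coordinates:
a positive turn size or body bend is a left turn / leftward bend.  The
stimulus-gradient axis defaults to +x (toward the warm side in a
cold-avoidance assay).

## Synthetic arena

The generator emulates the recorded experiments this toolkit targets:
4–6 second-instar larvae (~1.4 mm body) crawling on a 22 × 22 cm agar
arena imaged at 10 Hz by a ~2-megapixel camera (7 px/mm), so each animal
covers ≈30 bright pixels on a dark background.  Defaults:

- `mean_speed` 0.5 mm/s (crawl speed well below 1 mm/s), optional linear
  decline `speed_decay` (mm/s²) emulating the activity drop over time.
- `turn_rate` 3 events per minute of run state.  Run/turn alternation is a
  Markov switch: each run frame starts a turn with probability
  `turn_rate/60/frame_rate`; a turn is a pause of `turn_duration` (1.5 s)
  ending in a signed heading change.  The sign is left with probability
  `(1 + handedness_bias)/2`; the magnitude is |Normal(60°, 30°)| (the
  source experiments do not constrain this distribution — the wrapped-
  normal family is a package choice, configurable).
- Heading diffusion during runs: a per-frame von Mises perturbation with
  2°/frame dispersion, so run paths are gently curved rather than
  polygonal.
- Gradient bias: after each turn, with probability
  `gradient_bias/(1+gradient_bias)` the new heading is redrawn from a von
  Mises centred on +x (κ = 2).  This is the simplest mechanism that yields
  navigation index 0 at zero bias and a monotone, saturating increase with
  bias; it is a surrogate for (not a model of) larval thermotaxis
  strategies.
- Robot pick-up events: Poisson per animal at `occlusion_rate` (0.87/h,
  the observed pick-up trigger rate); the animal vanishes for
  `occlusion_duration` (4.5 s, the observed camera-occlusion span) and
  reappears at the arena centre — a translation with heading preserved,
  which is exactly what trajectory stitching inverts.  With
  `relocate_on_occlusion=False` the animal instead keeps crawling while
  hidden (camera blocked only).
- Collisions: Poisson arena-wide at `collision_rate` (0.63/h for six
  animals); an event steers one animal through another's position over
  ~4 s with a triangular displacement profile, so the pair genuinely
  overlaps mid-event and separates again.

Rendering draws each larva as a chain of disks along a constant-curvature
body arc (bend ramps up and down through each turn), mildly tapered from
head to tail.  The chain is shifted axially so the blob's area centroid
coincides with the true position (calibrated once per run on a straight
reference body; residual error < 0.5 px).  The background is a dark field
with optional slow additive drift (smooth spatial pattern, capped) plus
Gaussian pixel noise.  Identical configs and seeds give bit-identical
trajectories and frames.

What the simulator does **not** emulate: peristaltic body dynamics, head
casts, size growth, photometric texture of real agar, motion blur, and
lens distortion.  Passing the synthetic benchmarks therefore validates
the pipeline's logic (identity bookkeeping, geometry, statistics), not
detection robustness on real imagery.

## Background model and detection

The background is an IIR running average `B ← αF + (1−α)B` with α = 0.01
at 10 Hz (time constant ≈ 10 s — slow enough to exclude moving animals,
fast enough to absorb condensation-scale drift).  Subtraction clips
negative residuals and applies a fixed intensity threshold (default 50);
a global threshold suffices for uniformly bright animals on black and
keeps runs reproducible.  B₀ defaults to the first frame (animals bleed
in and wash out over ~1/α frames); `init="median"` over the first 100
frames (10 s, during which a larva clears its own body length) starts
clean and is used by the benchmark configurations.  Detections are
hole-filled connected components gated to [8, 45] px²; the upper gate sits
at the top of the single-animal blob band so that merged animals are
flagged oversized instead of silently linked as one.

## Linking, gaps, and collisions

The linking loss weights are β_r = 1, β_p = 0.5, β_a = 0.01 — pixel-scale
balancing chosen so a body-length position error, a full-momentum
mismatch, and a ~50 px² area mismatch contribute comparably.  Momentum is
the mean displacement per frame over the last 5 frames (the underlying
observations state no window).  Assignment is greedy lowest-loss-first by
design — it reproduces the sequential behavior of the method it
implements — and is deliberately not the Hungarian optimum; a test
constructs a case where the two differ and asserts the greedy result.
Matches with loss above `max_loss` (60) are rejected; tracks missing
longer than `interp_max_gap` (75 frames, comfortably above the 45-frame
pick-up occlusion) are closed.  Gaps are filled by linear interpolation
and flagged; flagged frames are excluded from all velocity averages and
from turn detection.  Tracks lost for ≥5 frames may re-match without the
loss gate (the "rescue" pass): robot relocations drop an animal far
beyond any plausible gate, and with a fixed animal count the gate-free
nearest match is safe.

Collision events open when ≥2 tracks' predicted positions fall inside one
oversized detection.  Resolution translates each participant's last clean
mask, initialized at the momentum-predicted displacement, by integer
hill-climbing (±2 px neighbourhood per participant per epoch, ≤50 epochs)
maximizing intersection-over-union between the union of translated masks
and the merged mask; the overlap objective and optimizer are package
choices (the source describes only "optimized for a small number of
epochs").  If the final overlap stays below 0.25 the momentum
initialization is kept and the event is flagged.  On separation the
participants re-enter ordinary greedy assignment seeded by their resolved
positions.  On the synthetic two-animal crossing benchmark (40 seeded
crossings) post-separation identity is preserved in ~86% of events;
accuracies reported for this class of method on real video (~90%) are not
a synthetic target.

## Posture

The deterministic head/tail estimator takes the two contour vertices of
locally maximal turning angle separated by ≥⅓ of the perimeter, and calls
"head" the one aligned with momentum (larvae crawl head-first); below
0.3 px/frame of momentum the previous assignment is carried.  The spine
uses the contour-halving construction with n = 11 points (odd, so a
unique midspine exists).  Body bend is the signed angle between the mean
segment directions of the head half and tail half of the spine; the
construction is a package definition — the numerical definition behind
the published body-bend traces is unstated.

The recurrent U-Net (4 conv/ReLU/maxpool encoder submodules, mirrored
upsampling decoder with skip connections, convolutional LSTM cells at the
network entry, the bottleneck, and the decoder output, spatial-softmax
head/tail heatmaps) and the behavior classifier (nine dense layers
alternating with ReLU plus bidirectional LSTMs at the beginning and
middle — 11 layers — with 10× loss weighting on turn frames) are faithful
small-scale implementations of the described architectures, built on an
in-package NumPy reverse-mode autodiff engine.  Channel counts and widths
are deliberately small (base 4 channels, hidden 16): training here is a
smoke-scale demonstration that the architectures learn from synthetic
labels (loss decreases, held-out accuracy beats the majority class), not
an attempt to match what full-scale training on labelled real video can
achieve; the geometric estimator and the threshold heuristic are the default
pipeline paths, keeping the toolkit deterministic without training.

## Behavior segmentation

Heuristic defaults: turn when |bend| > 20° and speed < 40% of the track's
median speed; state blocks shorter than 3 frames (0.3 s) are absorbed
into their neighbours, which both implements the switching cost
deterministically and guarantees strict run/turn alternation.  Turns with
heading change below the bend threshold are intrinsically invisible to a
threshold classifier (~9% of the default turn-size draw); benchmarks
account for this.  The network path decodes through a two-state Viterbi
program with per-transition penalty `switch_cost` (default 2.0, in
−log-probability units); transitions are provably non-increasing in the
penalty, and an infinite penalty collapses the sequence to one state.

## Features and statistics

Speed is a central difference over a 1 s window; navigation indices are
reported whole-track and in 10-minute windows; windows with no valid
motion are flagged undefined rather than zero.  The navigation-index
denominator is the mean of speed norms (not the norm of the mean
velocity), matching its verbal definition "normalized to the average
speed".  Curvature resamples the path at 1 mm arc steps.  Stitching is
translation-only (headings never rotated); stitched path lengths are
reported in meters.

The bimodality coefficient uses the SAS/Sarle finite-sample-corrected
form — the convention under which the uniform distribution sits exactly
at the critical value 5/9 (a Gaussian at 1/3).  KDEs use Gaussian kernels
with Silverman bandwidth and a floor (0.01 by default) so constant
animals stay well-defined.

The variability toy model draws per-animal means
μ_i ~ Normal(μ_pop, σ_inter²) — optionally centred on discrete modes to
emulate behavioral phenotypes — and observations Normal(μ_i, σ_intra²).
A fraction `common_mode_frac` (default 0.9) of the within-animal variance
is a temporal fluctuation shared across animals.  This term is essential
to the regime the model must reproduce: with fully independent noise the
per-timepoint population mean narrows by √n relative to individuals and
its density can never resemble theirs (the L1 distance between two
zero-mean Gaussians whose SDs differ by √8 is ≈0.9 regardless of scale);
a dominant shared component — animals in one arena co-fluctuating with
their environment — keeps the population-mean density at individual
width, as observed.  Marginal per-animal distributions and the law of
total variance are unaffected by the choice.

## Benchmark problem sizes

The validation suite scales the study conditions to desk size while
preserving per-animal geometry (always 7 px/mm, ~30 px blobs): the
clean-regime identity benchmark uses 6 animals on a 110 mm arena for 10
minutes (a seed verified to contain no chance encounters, which is what
"clean" means); collision recovery uses 40 seeded two-animal crossings on
a 30 mm stage; parameter recovery uses 4 animals on 80 mm for 6 minutes.
Turn-parameter recovery configures turn sizes of 70° ± 25° so that
essentially all simulated turns are above the classifier's bend
threshold — the quantity under test is parameter recovery, not
sub-threshold detection.  Acceptance identities (navigation-index and
handedness endpoints, the uniform-sample BC) run in seconds.

## Known limitations

- The tracker assumes a fixed, known maximum animal count; it does not
  re-identify animals after gaps longer than `interp_max_gap` (new ids
  are opened instead) and has no appearance model.
- Collision resolution handles translation only; rotating or deforming
  animals during long contacts degrade the overlap objective.
- The geometric head/tail estimator is undirected during long pauses
  (momentum ≈ 0) and relies on temporal carry-over.
- A global threshold assumes spatially uniform illumination; no
  flat-field or lens-distortion correction is provided.
- Standard compressed video containers are not read or written; inputs
  are lossless TIFF stacks or PNG directories.
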