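# larvatrack

Tracking and behavior quantification for multi-animal *Drosophila* larva
video: from raw grayscale recordings (dark arena, bright animals, ~10 Hz)
to identity-preserved trajectories, body postures, run/turn ethograms, and
navigation statistics.  A built-in synthetic-arena simulator generates
videos with exhaustive ground truth, so every stage of the pipeline is
testable without recorded animals.

The toolkit is aimed at labs running long-duration crawling assays — hours
to days of continuous observation of a handful of larvae on an agar arena,
optionally under a stimulus gradient — where maintaining individual
identity through occlusions, robot pick-up events, and pairwise collisions
is the hard part of the analysis.

## Methods at a glance

**Detection.** Each frame is contrast-enhanced by subtracting a dynamic
background maintained with an infinite-impulse-response filter,
`B_t = α F_t + (1 − α) B_{t−1}`; larvae are the outermost contours of
bright pixel clusters within a size gate.

**Identity linking.** A detection *i* is linked to a track *j* by greedily
minimizing

```
L_ij = β_r ‖r_i − r_j‖ + β_p ‖p_i − p_j‖ + β_a |a_i − a_j|
```

(position, momentum, contour area; lowest loss first, then the next lowest
among the remaining pairs).  Missed frames are bridged by linear
interpolation; when two animals merge into one oversized contour, their
pre-collision contours are translated — initialized from momentum and
refined by bounded hill-climbing (≤50 epochs) — to best overlap the merged
contour, and the translated centroids stand in as positions.

**Posture.** Head and tail are located either geometrically (curvature
extrema of the contour, disambiguated by crawl direction) or by a
recurrent U-Net that emits head/tail probability heatmaps.  The contour is
split at head and tail into two halves, resampled, and averaged pairwise
into a spine; the middle spine point (the *midspine*) serves as a robust
animal position, and the angle between the spine halves is the body bend.

**Behavior.** Frames are segmented into runs and turns by a deterministic
heuristic (bend above threshold while speed drops) or a trainable
recurrent dense classifier; both decode through a dynamic program that
charges an explicit cost per state switch.  Turn events carry signed sizes
(positive = left) and drive the handedness index
`(N_left − N_right) / N_total`.

**Navigation statistics.** The navigation index `⟨v_x⟩/⟨v⟩` (+1 = straight
up-gradient, −1 = straight down-gradient) is computed per animal and per
time window; Sarle's bimodality coefficient
`BC = (g₁² + 1) / (g₂ + 3(n−1)²/((n−2)(n−3)))` with the critical value
`BC_crit = 5/9` separates unimodal from potentially bimodal navigation
phenotypes, and an intra-/inter-animal decomposition contrasts what a
typical individual does with what the population average suggests.

## Worked example

```python
import numpy as np
from larvatrack.config import PipelineConfig, SimConfig, BackgroundConfig
from larvatrack.simulate import simulate_trajectories, render_video
from larvatrack.pipeline import track_video, analyze_tracks

sim = SimConfig(n_animals=3, arena_side=60.0, duration=60.0,
                collision_rate=0.0, occlusion_rate=0.0, rng_seed=2)
cfg = PipelineConfig(sim=sim, background=BackgroundConfig(init="median"))

truth = simulate_trajectories(sim)              # ground-truth tables
tracks, events = track_video(render_video(truth), cfg)
per_frame, turn_events, report = analyze_tracks(tracks, cfg)
print(report["per_animal"][0])
```

prints (exactly, for this seed):

```
{'navigation_index': 0.3707351227491422, 'handedness': 0.2,
 'n_turns': 5, 'turn_rate_per_min': 5.0,
 'path_length_m': 0.02966081965046329,
 'mean_speed_mm_s': 0.4497867529414551}
```

i.e. animal 0 crawled about 3 cm in one minute at ~0.45 mm/s, made five
turns (three left, two right, handedness +0.2), and drifted toward +x
(navigation index 0.37 — short tracks are noisy; the index is only
meaningful over long observations).  The same pipeline is available from
the shell:

```bash
larvatrack simulate --config cfg.yaml --out sim/
larvatrack track sim/video.tif --config cfg.yaml --out trk/
larvatrack analyze trk/tracks.csv --config cfg.yaml --out report/
```

Video I/O uses lossless containers (multi-page TIFF stacks or PNG frame
directories), so round trips are bit-exact and runs are reproducible
byte-for-byte from the seed recorded in each output manifest.

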