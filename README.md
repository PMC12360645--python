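# wormtrack

A toolkit for high-resolution posture tracking of crawling nematodes in
grayscale video, built so that every stage is testable on synthetic data:

- **simulate** — synthetic crawling-worm recordings with per-frame
  ground-truth midlines: smooth undulation across multiple timescales,
  optional dwelling and coiling (self-intersecting) postures, static
  non-uniform backgrounds with egg-like distractors, 11-frame annotated
  clips, and overlap synthesis by stacking pairs of single-worm clips.
- **background** — static background estimation by rank-1 SVD of frames
  subsampled 1:400 in time, and per-pixel subtraction.
- **shapespace** — skeleton normalisation (equal-chord resampling, head-tail
  orientation) and a linear (PCA) posture space of dimension D = 72 used to
  encode/decode skeletons as coefficient vectors relative to a spatial
  offset.
- **predictor** — the grid detection contract: images padded to a multiple
  of 16, a 16 px cell grid (32 x 32 for 512 x 512 input) with up to 8
  skeleton slots per cell, target assignment within a 48 px centroid cutoff,
  confidence-thresholded decoding (0.5), and non-maximum suppression.
- **nnet** — a tiny numpy reference network (shared-weight per-cell MLP,
  Adam, confidence BCE + masked coefficient regression + latent consistency)
  that exercises the training/decoding contract at desk scale.
- **temporal** — 1:3 temporal downsampling and smoothing-spline
  interpolation over (x, y, t) of skeleton trajectories.
- **tracking** — optimal per-frame assignment with a spatial + latent cost
  and gap bridging, plus a greedy nearest-neighbour baseline for ablations.
- **metrics** — skeleton RMSD with head-tail alignment, nearest-segment
  midline distance, per-method failure classification (tierpsy / dtc / paf /
  omnipose rules), and tracking fidelity `1 - sum(mme_t) / sum(g_t)`.
- **screen** — phenotypic-screen statistics: exemplar behavioural features
  (midbody speed, tail curvature), per-feature Pearson correlation with a
  histogram modal value, one-way F-statistics, and Hedge's d effect sizes
  averaged across doses.

## Command-line interface

A single entry point `wormtrack` exposes the pipeline:

```sh
wormtrack simulate --n-worms 3 --duration 10 --seed 0 --out sim.h5
wormtrack subtract-bg --in sim.h5 --out resid.h5 --step 400
wormtrack fit-shapespace --skeletons sim.h5 --dim 72 --out space.h5
wormtrack make-clips --video resid.h5 --skeletons sim.h5 --out clips.h5
wormtrack train-mini --clips clips.h5 --shapespace space.h5 --seed 0 --out model.h5
wormtrack predict --video resid.h5 --model model.h5 --shapespace space.h5 --out dets.h5
wormtrack track --detections dets.h5 --out tracks.h5
wormtrack interpolate --detections tracks.h5 --out full.h5
wormtrack evaluate --pred full.h5 --truth sim.h5 --method dtc --out report.csv
wormtrack screen-stats --table-a a.csv --table-b b.csv --out stats.json
```

Videos are multi-page TIFF or HDF5 stacks (`frames` dataset); skeleton
tables are HDF5 groups (`frame`, `worm_id`, `points`, `confidence`) or CSV
(`frame, worm_id, point_index, x, y`).  Coordinates are 0-based pixels,
x = column, y = row, origin top-left.

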