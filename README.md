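# pitchfatigue

Detect pitcher fatigue from 2-D pose keypoints. The pipeline:

1. **pose_io** — read OpenPose-dialect JSON keypoint files (BODY_25 or
   COCO-18) and a pitch-event table; compute the elbow angle and trunk angle
   at each pitch's release frame plus the inter-pitch interval, yielding a
   per-pitch feature CSV.
2. **quantify** — split each game at the fatigue interval index `alpha` into
   non-fatigue/fatigue regimes, estimate the per-feature knots
   `x = mean + SD` (non-fatigue) and `y = mean + SD` (fatigue), and map every
   pitch's features to fatigue values `A1..A3 ∈ [0, 1]` with piecewise-linear
   ramps (elbow up, trunk down, interval up under fatigue).
3. **detect** — combine the fatigue values into the weighted total index
   `M_total` on a percent scale and find the fatigue point `R`, the first
   pitch with `M_total ≥ T`.
4. **evaluate** — leave-one-game-out cross-validation: pool the training
   games' fatigue points into `F_P`, score the held-out game with
   `A_f = 1 − |F_P − N·alpha| / N`, average across folds; grid-search
   `(alpha, W, T)`; optional SVM classifier on the fatigue-value triples.
5. **simulate** — seeded generators for synthetic sessions with a known
   fatigue onset and for keypoint frames realizing prescribed angles, so
   every stage is testable without external data.

## CLI

The console script `pitchfatigue` wires the stages together; every run
writes its outputs plus a `manifest.json` (config echo, version, seed) to
`--out`.

```bash
# synthetic fixtures: feature CSV + ground-truth sidecar (+ frames with --frames)
pitchfatigue simulate --config sim.yaml --seed 7 --out out/sim --frames

# keypoint frames + event CSV -> per-pitch feature CSV
pitchfatigue extract --frames-dir out/sim/frames --events out/sim/events.csv \
    --dialect BODY_25 --out out/features

# per-game feature bounds (the flat-file player-information store)
pitchfatigue quantify --features out/sim/features.csv --alpha 0.7 --out out/q

# fatigue-point detection report (JSON + CSV)
pitchfatigue detect --features out/sim/features.csv \
    --bounds out/q/bounds.json --out out/det

# leave-one-game-out cross-validation / parameter grid search
pitchfatigue cv   --features out/sim/features.csv --out out/cv
pitchfatigue grid --features out/sim/features.csv --config grid.yaml --out out/grid
```

A grid config lists the candidate values:

```yaml
grid:
  alphas: [0.7, 0.8]
  weights: [[0.7, 0.2, 0.1], [0.33, 0.33, 0.33]]
  thresholds: [50, 60]
```

Detection/scoring options (`params:` in a YAML config or keyword arguments):
weights `W1..W3`, threshold `T`, `persistence` (consecutive pitches required
at threshold), `search_window` (`full` or `alpha`), `pooling` (`absolute`
or `normalized` fatigue-point pooling), `clamp` (clamp negative fold
accuracies), and `degenerate` (`error` or `step` handling of zero-width
ramps). Both angle definitions per feature are supported
(`joint_interior`/`arm_elevation` for the elbow,
`shoulder_trunk`/`trunk_vertical` for the trunk) since 2-D keypoints admit
either reading.

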