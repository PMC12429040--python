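# abcells

Cell tracking and morphodynamic analysis for label-free time-lapse
microscopy, built for experiments on cultured stem cells (mesenchymal
and muscle stem cells are the motivating systems) where phenotype must
be read from brightfield morphology and motility alone.

The package has two halves:

* **Tracking** — a detection-agnostic multi-object tracker. Any
  detector that emits per-frame cell polygons (YOLO-style segmentation
  text, binary masks, or a classical adaptive-threshold fallback) feeds
  a cost-matrix assignment

  ```
  c(t, d) = w_iou·(1 − IoU(t̂, d)) + w_dist·min(‖x̂_t − x_d‖/g_t, 1)
          + w_feat·(1 − cos(f_t, f_d)) + w_area·|A_t − A_d|/max(A_t, A_d)
  ```

  solved per frame by the Hungarian method, with adaptive gating
  (g_t = base gate + gain·‖v_t‖), a relaxed fallback pass, division
  (split) recovery with generation counting, merge arbitration, and
  appearance-based re-identification after detection dropouts. Each
  cell carries a 24-dimension appearance vector (7 intensity
  statistics, 7 Hu moments, 7 normalized central moments, solidity,
  aspect ratio, fill factor; L2-normalized).

* **Analysis** — static morphometry (area, circularity 4πA/P²,
  eccentricity, orientation, solidity, boundary smoothness), a
  twelve-metric motility profile per trajectory (MSD, directional
  persistence, meandering index, mean turning angle, radius of
  gyration, arrest coefficient, shape–motion coupling, relative motion
  change, velocity cross-correlation, directionality ratio, mean speed,
  mean acceleration), and an autocorrelation-aware statistics engine:
  series are smoothed (moving average, window 15), cut into sliding
  windows, and compared across conditions with a Friedman test whose
  statistic is rescaled by the Bartlett effective sample size
  N_eff = N(1−Q)/(1+Q) for lag-1 autocorrelation Q, alongside a
  within-block permutation test (B = 1000) and Conover–Holm post hoc
  pairs. Bootstrap CIs (B = 10 000) and KS/Wasserstein distances round
  out the population comparisons.

A synthetic scene generator (Brownian / persistent / directed /
arrested motion, divisions, dropouts, AR(1) metric panels) provides
seeded ground truth for every component.

Defaults follow the reference acquisition: 0.5199 µm/px calibration,
350 s frame interval, 10 µm nearest-neighbor linking bound with 2-frame
gap interpolation, <100 px² artifact filter, 0.2 µm/frame arrest
threshold.

## Worked example

```python
import numpy as np
import abcells as ab

# a seeded 10-cell Brownian movie, rendered as polygon detections
frames, truth = ab.gen_scene(10, ab.Brownian(2.0), 60, seed=4,
                             image_size=(1200, 1200), min_spacing=110)
tracker = ab.Tracker()
table = tracker.run(frames)
print("tracks:", table.track_id.nunique(), "rows:", len(table))
print(ab.evaluate_tracking(table, truth, tracker.lineage))

# motility profile of one calibrated trajectory
calib = ab.DEFAULT_CALIBRATION_UM_PER_PX
tid, g = next(iter(table.groupby("track_id")))
traj = ab.Trajectory(int(tid), g.frame.to_numpy(),
                     g[["centroid_x_px", "centroid_y_px"]].to_numpy() * calib)
m = ab.motility_metrics(traj)
print(f"track {tid}: msd={m.msd:.2f} um^2  persistence={m.directional_persistence:.3f}  "
      f"arrest={m.arrest_coefficient:.2f}  mean_speed={m.mean_speed:.3f} um/frame")

# window-scan of four condition series diverging at frame 40
panel = ab.gen_grouped_series(4, 80, group_offsets=[0, 0, 0, 2.0],
                              noise_sd=1.0, changepoint=40, seed=4)
res = ab.sliding_scan(panel, seed=4)
sig = [r for r in res if not np.isnan(r.p_asymptotic) and r.p_asymptotic < 0.05]
print(f"windows tested: {len(res)}  significant: {len(sig)}")
```

prints

```
tracks: 10 rows: 600
{'identity_preservation': 1.0, 'id_switches': 0, 'split_recall': nan}
track 1: msd=36.13 um^2  persistence=-0.079  arrest=0.00  mean_speed=1.384 um/frame
windows tested: 52  significant: 32
```

Every true cell kept a single predicted identity for the whole movie
(`identity_preservation = 1.0`, no id switches; `split_recall` is NaN
because the scene contains no divisions). The Brownian track shows the
expected near-zero persistence, and the window scan flags a majority of
windows once the fourth condition's offset switches on.

The same flow is available from the shell:

```sh
abcell simulate --seed 4 --out run/simulate
abcell track    --seed 4 --out run/track   --detections run/simulate/detections.jsonl
abcell analyse  --seed 4 --out run/analyse --tracks run/track/tracks.csv
abcell evaluate --seed 4 --out run/evaluate --sim-dir run/simulate --track-dir run/track
```

Each stage writes CSV/JSON plus a manifest (config hash, seed, input
checksums) so any output directory can be re-run; identical seed and
config give byte-identical outputs.

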