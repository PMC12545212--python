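# octokin

Markerless 3D kinematics and whole-animal gait analysis of crawling octopus
arms, built for tracked-point data derived from orthographic depth maps
(e.g. from an underwater light-field camera watching *Muusoctopus robustus*
crawl over rough terrain).

An octopus arm is a muscular hydrostat: a boneless appendage whose volume
conservation couples bending, elongation and stiffening.  During forward
crawling, an arm anchors a medial portion (the "foot") on the substrate,
bends sharply around it, and stretches the weight-bearing proximal section
until release.  Quantifying that behaviour needs, per frame, the arm's 3D
centerline r(s), its curvature and its strain:

- curvature kappa(s, t) = |r' x r''| / |r'|^3  (mm^-1, the inverse bend
  radius), evaluated at regularly spaced arc-length stations along a simple
  interpolating spline through the tracked points;
- strain eps_i(t) = 100 * (L_i(t) / L_i(t0) - 1)  (%), the fractional change
  of arc length of each tracked arm segment, referenced to the configuration
  at substrate release (t0);
- per-arm stride statistics from ternary contact phase diagrams
  (contact / air / unknown): cycle duration (onset-to-onset), contact duty
  cycle (%), arms-in-contact counts with a penalized-spline trend and 95%
  band, bilateral-support fraction, and the touch-down order matrix.

The package covers the whole chain:

| module | role |
| --- | --- |
| `octokin.synth` | ground-truth generators: arm strides with known kappa/strain fields, observation noise and camera drift, 8-arm square-wave gaits, orthographic depth-stack rendering, calibration scenes |
| `octokin.io` | CSV/TIFF dialects: track tables, 3D trajectories, phase diagrams, depth stacks (uint16 TIFF + JSON sidecar) |
| `octokin.preprocess` | depth lookup (11 x 11 median), 5-frame z median, background-motion removal from reference points, moving-median outlier rejection, 20-frame smoothing and gap filling |
| `octokin.kinematics` | per-frame spline arm curves, 7-frame temporal stabilisation, curvature/strain (s, t) fields |
| `octokin.gait` | stride segmentation, duty-cycle statistics, contact counts, transition matrix |
| `octokin.aggregate` | head-width / median-cycle normalization and pooled binning across strides and individuals |
| `octokin.morpho` | point-to-point measurements (head/eye width), repeat statistics, calibration-error report |

## Worked example

Simulate one 10 s arm stride at 60 frames/s, render it into a depth-map
stack, run the full cleaning and reconstruction chain, and score the
recovered curvature/strain fields against the generator's exact truth:

```python
from octokin import ArmSimConfig, end_to_end_recovery

res = end_to_end_recovery(ArmSimConfig(seed=1))
print(f"kappa RMSE {res.kappa_rmse_pct_of_peak:.3f}% of peak")
print(f"strain RMSE {res.strain_rmse_pct_of_peak:.3f}% of peak")
```

prints

```
kappa RMSE 0.137% of peak
strain RMSE 0.323% of peak
```

i.e. with noise-free observations the pipeline reproduces the true
curvature field (peak 0.02 mm^-1, a 50 mm bend radius at the foot) to about
a tenth of a percent of the peak, and the strain field (peak 15% in the
proximal third) to a third of a percent, over the interior 90% of the arm.

Gait statistics from a synthetic phase diagram:

```python
from octokin import GaitSimConfig, simulate_gait, segment_strides, gait_stats

phase, truth = simulate_gait(GaitSimConfig(period_s=30.0, duty=0.6))
strides = segment_strides(phase, "L3")
stats = gait_stats(strides, phase.fps)
print(stats.per_stride[["cycle_s", "duty_pct"]].head(1))
```

prints

```
   cycle_s  duty_pct
0     30.0      60.0
```

recovering the simulated 30 s cycle and 60% contact duty exactly.

The same operations are available from the shell:

```sh
octokin simulate-arm --out-dir sim/
octokin render-depth --tracks sim/arm_truth_tracks.csv --out-dir depth/
octokin preprocess --tracks depth/tracks2d.csv --depth depth/depth.tiff --out traj.csv
octokin kinematics --trajectories traj.csv --arm L3 --release-frame 0 --out field.csv
octokin gait --phase phase.csv --out-dir gait/
```

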