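# gazelab

Quality analysis of **gaze-in-world** data from the integration of a mobile
eye tracker with optoelectronic motion capture.

When a head-mounted eye tracker is combined with motion capture, each
sample delivers the eye's position **A** (gaze origin) and a unit gaze
vector **ĝ** in the laboratory frame, so the point of gaze can be expressed
in world coordinates rather than scene-video pixels. For a standing
observer looking at the floor, the point of gaze along the
anterior–posterior axis is

```
a = angle(ĝ, -ẑ)            viewing angle from the vertical
C = A_z · tan(a)            look-ahead distance
D = A_x + C                 floor intercept (x, on the z = 0 plane)
```

Because `tan` is steep at large `a`, a *constant* angular accuracy covers a
floor span that grows non-linearly with viewing distance: 1.42° of visual
angle is ≈ 5.5 cm of floor at 1 m look-ahead but ≈ 60.6 cm at 6 m (eye
height 1.57 m). This package quantifies that effect on real or synthetic
recordings and evaluates the standard signal treatments around it. It is
written for researchers in perceptual-motor control, gait and sport science
who run integrated eye-tracking + mocap protocols and need per-target data
quality before interpreting gaze behavior.

## What it computes

* **Floor-intercept geometry** (`gazelab.geometry`) — viewing angle,
  look-ahead, exact ray/floor intersection, and the bidirectional mapping
  between a world-space error span and the visual angle it subtends:
  `angle = atan((L + MAE/2)/h) − atan((L − MAE/2)/h)` and its numeric
  inverse.
* **Viewing-period segmentation & screening** (`gazelab.segmentation`) —
  point-of-gaze velocity, deterministic detection of target-to-target
  transitions (speed peaks plus level jumps across dropout gaps), and a
  per-eye exclusion screen at 350 °/s peak angular velocity.
* **Accuracy & precision** (`gazelab.quality`) — per (eye, target): MAE,
  visual angle of the MAE, RMS-S2S (RMS of sample-to-sample displacement)
  and STD, combined across eyes; missing-data bookkeeping.
* **Signal treatment** (`gazelab.signal_processing`) — 4th-order zero-phase
  Butterworth low-pass with a fixed or residual-autocorrelation-selected
  cutoff, quintic-spline gap filling with a gap-size limit, and a
  Monte-Carlo study of treatment error versus gap size.
* **Synthetic recordings** (`gazelab.synthetic`) — a generator emulating
  the protocol (standing observer, six floor targets at 1–6 m fixated
  sequentially over 30 s at 50 Hz) with angular jitter, minimum-jerk
  saccades on the amplitude–velocity main sequence, postural sway, and
  Markov dropout, plus full ground truth for every sample.

## Worked example

```python
from gazelab import synthetic, pipeline
from gazelab.model import TargetSet

rec, truth = synthetic.synthesize_recording(synthetic.SimulationParams(seed=0))
report = pipeline.run_pipeline(rec, TargetSet.canonical())
print(report.summary())
```

```
Point-of-gaze quality report
------------------------------------------------------------
left eye: 9.60% missing
right eye: 6.47% missing

   eye target  x (m)   MAE (m) angle (deg) RMS-S2S (m)   STD (m)
  ...
  mean      0   1.00    0.0063       0.163      0.0107    0.0079
  mean      1   2.00    0.0113       0.157      0.0203    0.0144
  mean      2   3.00    0.0207       0.162      0.0357    0.0254
  mean      3   4.00    0.0294       0.143      0.0529    0.0383
  mean      4   5.00    0.0475       0.155      0.0819    0.0595
  mean      5   6.00    0.0730       0.171      0.1249    0.0939
```

Reading the output: under a constant 0.2° angular jitter the world-space
MAE grows ~12× from the 1 m to the 6 m target (0.0063 → 0.0730 m) — purely
geometric, since the visual angle of the MAE stays flat at ~0.16° — and
precision degrades the same way (RMS-S2S 0.011 → 0.125 m). The missing
percentages book the dropout the generator injected.

The same operations are available from a CLI (`gazelab simulate`,
`quality`, `filter`, `gapfill-eval`, `report`), and the `analysis/`
directory holds the numbered study scripts: world-space translation tables
(01), cohort simulation and missing-data summary (02), per-target quality
(03), filter-cutoff conditions (04), and the gap-size study (05). Each
writes its table under `results/`.

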