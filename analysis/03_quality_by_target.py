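#!/usr/bin/env python
"""Per-target accuracy and precision of the synthetic cohort.

Runs the full quality pipeline (screening, segmentation, metrics) on each
cohort recording and aggregates MAE, visual angle of MAE, RMS-S2S and STD
per floor target across participants.

Writes results/quality_by_target.csv.
"""

from pathlib import Path

import pandas as pd

from gazelab import pipeline, synthetic
from gazelab.model import TargetSet

N_PARTICIPANTS = 11

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)
targets = TargetSet.canonical()

frames = []
for seed in range(N_PARTICIPANTS):
    rec, _ = synthetic.synthesize_recording(synthetic.SimulationParams(seed=seed))
    rep = pipeline.run_pipeline(rec, targets)
    t = rep.table.query("eye == 'mean'").copy()
    t["participant"] = seed
    frames.append(t)
per = pd.concat(frames, ignore_index=True)

agg = (per.groupby(["target_id", "target_x"])
       [["mae_m", "visual_angle_deg", "rms_s2s_m", "std_m"]]
       .agg(["mean", "std"]).round(4))
agg.columns = ["_".join(c) for c in agg.columns]
agg = agg.reset_index()
agg.to_csv(out_dir / "quality_by_target.csv", index=False)

print("Across-eye metrics averaged over the cohort (mean over participants):")
print(agg.to_string(index=False))
grand = per.visual_angle_deg.mean()
print(f"\nOverall accuracy {grand:.2f} deg of visual angle. World-space MAE "
      f"grows {agg.mae_m_mean.iloc[-1] / agg.mae_m_mean.iloc[0]:.1f}x from the "
      "1 m to the 6 m target while the visual angle of the MAE stays nearly "
      "flat: under constant angular noise the world-space degradation with "
      "distance is purely geometric.")
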