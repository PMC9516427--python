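#!/usr/bin/env python
"""World-space translation of a constant visual-angle accuracy.

For a tracker accuracy of 1.42 deg and a 1.57 m standing eye height, compute
the world-space span that angle covers on an eye-height wall and centered on
floor targets 1-6 m ahead, plus the gaze amplitude between adjacent floor
targets. Shows the non-linear growth of floor-plane error with look-ahead
distance that motivates distance-aware quality reporting.

Writes results/geometry_spans.csv.
"""

from pathlib import Path

import pandas as pd

from gazelab import geometry

EYE_HEIGHT = 1.57
ANGLE = 1.42

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

rows = []
for L in range(1, 7):
    rows.append({
        "distance_m": L,
        "wall_span_cm": round(geometry.wall_span_for_angle(L, ANGLE) * 100, 1),
        "floor_span_cm": round(geometry.floor_span_for_angle(L, ANGLE, EYE_HEIGHT) * 100, 1),
        "viewing_angle_deg": round(geometry.target_separation_angle(0.0, L, EYE_HEIGHT), 2),
        "amplitude_from_previous_deg": round(
            geometry.target_separation_angle(L - 1, L, EYE_HEIGHT), 2) if L > 1 else None,
    })
df = pd.DataFrame(rows)
df.to_csv(out_dir / "geometry_spans.csv", index=False)

print(f"A constant {ANGLE} deg accuracy at eye height {EYE_HEIGHT} m translates to:")
print(df.to_string(index=False))
print("\nFloor spans grow super-linearly with distance "
      f"({df.floor_span_cm.iloc[-1] / df.floor_span_cm.iloc[0]:.1f}x from 1 m to 6 m, "
      "vs 6x on the wall); the largest between-target gaze amplitude is "
      f"{df.amplitude_from_previous_deg.max():.1f} deg (targets 1 to 2).")
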