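"""Render a short synthetic harvesting pass and inspect its ground truth.

Each frame is a front-view scene with three regions — uncut crop (left),
harvested stubble (right), background above the horizon — and comes with
a pixel-perfect class mask, the crop polygon and the analytic edge line.
The drift moves the crop/stubble boundary left a little every frame, the
way the visible crop shrinks during a pass.
"""

import numpy as np

from wscas import CROP, SceneSpec, generate_sequence

spec = SceneSpec(width=360, height=360, horizon_row=120,
                 edge_bottom_x=220.0, edge_angle_deg=4.0, noise_sigma=4.0, seed=0)
frames = generate_sequence(8, spec, drift_bottom_x=-6.0, drift_angle_deg=-0.5)

print("frame  crop_px  bottom_x  angle_deg")
for s in frames:
    n_crop = int((s.mask == CROP).sum())
    print(f"{s.frame_id:>5}  {n_crop:>7}  {s.gt_edge.bottom_x:>8.1f}  "
          f"{s.gt_edge.vertical_angle_deg:>9.2f}")

# crop_px shrinks monotonically as the edge drifts left; bottom_x is the
# column where the ground-truth edge meets the bottom row.
areas = [(s.mask == CROP).sum() for s in frames]
assert all(a >= b for a, b in zip(areas, areas[1:]))
print(f"\ncrop area shrank by {areas[0] - areas[-1]} px over {len(frames)} frames")
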