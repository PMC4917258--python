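"""Planar-wave conduction velocity on a homogeneous strip.

A 256-node strip (dx = 0.00625 cm, D = 0.00012 cm^2/ms) is stimulated
along its left edge; the activation map of the propagating wave gives the
conduction velocity by regression, away from stimulus and boundary.
Cultured atrial monolayers conduct at ~20-25 cm/s; the model is
calibrated to 22.2 cm/s.
"""

from nram import build_strip, planar_pacing
from nram.analysis import activation_map, conduction_velocity

grid = build_strip(nx=256, ny=2)
frames, recs, state, captured = planar_pacing(grid, cl=300.0, n_beats=1,
                                              frame_stride=1.0)
amap = activation_map(frames)
cv = conduction_velocity(amap, grid.dx, margin=30)
length_mm = grid.nx * grid.dx * 10
print(f"strip length          : {length_mm:6.1f} mm")
print(f"wave captured         : {bool(captured[0])}")
print(f"conduction velocity   : {cv:6.1f} cm/s")
print("(~22 cm/s: the planar speed of a confluent neonatal rat atrial "
      "monolayer)")
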