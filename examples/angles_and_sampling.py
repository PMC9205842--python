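"""Angular sampling schemes and acquisition-time bookkeeping.

Builds the conventional (onset) and half-step offset angle sets for a
dual-head camera, shows how the offset scheme doubles the number of distinct
view directions, and prints the acquisition-time factor when undersampling.
"""

import numpy as np

from offsetspect import (
    acquisition_time_factor,
    make_offset_angles,
    make_onset_angles,
    optimal_projection_number,
)

for n in (8, 60):
    onset = make_onset_angles(n)
    offset = make_offset_angles(n)
    directions = lambda g: len(np.unique(np.round(g.angles_deg % 180.0, 6)))
    print(f"n = {n}:")
    print(f"  onset angles  : {onset.angles_deg[:5]} ... step {360 / n}°")
    head1 = offset.angles_deg[offset.angles_deg < 180]
    head2 = offset.angles_deg[offset.angles_deg >= 180]
    print(f"  offset head 1 : {head1[0]:.1f}° ... {head1[-1]:.1f}°")
    print(f"  offset head 2 : {head2[0]:.1f}° ... {head2[-1]:.1f}°")
    print(f"  distinct directions: onset {directions(onset)}, offset {directions(offset)}")

print()
print(f"time factor 120 -> 8 views : {acquisition_time_factor(120, 8):.4f}  (= 1/15)")
print(f"time factor 120 -> 60 views: {acquisition_time_factor(120, 60):.2f}")
print()
d, bin_mm = 160.0, 3.2
print(
    f"sampling-theorem views for a {d:.0f} mm object at {bin_mm} mm bins: "
    f"{optimal_projection_number(d, bin_mm)} over 180°"
)
# the offset scheme reaches that direction count with half as many views,
# which is the whole point of shifting the second head by half a step
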