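"""Count-density linearity of reconstructions from few views.

Simulates the multi-cylinder phantom (six 40 mm cylinders at 0-800
counts/pixel in a 100 counts/pixel background), reconstructs 8-view
acquisitions, and prints the per-cylinder relative counts and the
correlation r between reconstructed and assigned densities.  r close to 1
means the method preserves quantification despite undersampling.
"""

import numpy as np

from offsetspect import (
    BlurModel,
    ImageGrid,
    ReconConfig,
    forward_project,
    linearity,
    make_multicylinder_phantom,
    make_offset_angles,
    make_onset_angles,
    reconstruct,
    scale_and_poisson,
)

truth, seg = make_multicylinder_phantom()
blur = BlurModel()

for mode, maker in (("onset", make_onset_angles), ("offset", make_offset_angles)):
    geom = maker(8)
    sino = scale_and_poisson(forward_project(truth, geom, blur), 75_000.0, seed=1)
    image = reconstruct(sino, ReconConfig(method="csir"))
    image = ImageGrid(np.maximum(image.values, 0.0), image.pixel_size_mm)
    res = linearity(image, seg)
    print(f"csir, 8 {mode} views:")
    print(f"  assigned (relative) : {np.round(res.true_relative, 3)}")
    print(f"  measured (relative) : {np.round(res.measured_relative, 3)}")
    print(f"  correlation r       : {res.r:.4f}")
    print()
print("linearity survives 8 offset views; 8 conventional views distort the")
print("low-count cylinders (streak contamination of the 80 mm² ROIs).")
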