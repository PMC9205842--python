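"""Point-source resolution and distortion under angular undersampling.

Simulates the resolution phantom (point sources 10 and 100 mm off center in
a uniform cylinder), reconstructs 8- and 120-view acquisitions with
TV-regularized EM on conventional (onset) and offset sampling, and prints
the FWHM and aspect ratio (radial/tangential FWHM) at the 100 mm source.
An aspect ratio of 1.0 means the point response stays isotropic; values
above 1 signal undersampling distortion.
"""

import numpy as np

from offsetspect import (
    BlurModel,
    ImageGrid,
    ReconConfig,
    aspect_ratio,
    forward_project,
    fwhm_xy,
    make_offset_angles,
    make_onset_angles,
    make_resolution_phantom,
    reconstruct,
    scale_and_poisson,
)

truth, _ = make_resolution_phantom()
blur = BlurModel()  # LEHR-like: about 10.9 mm FWHM at the 150 mm radius

print(f"collimator blur at 150 mm: {blur.fwhm_mm(150):.2f} mm FWHM")
print()
print(f"{'views':>5s} {'sampling':>8s} {'FWHM@100mm':>11s} {'ASR@100mm':>10s}")
for n in (8, 120):
    for mode, maker in (("onset", make_onset_angles), ("offset", make_offset_angles)):
        geom = maker(n)
        sino = scale_and_poisson(forward_project(truth, geom, blur), 75_000.0, seed=1)
        image = reconstruct(sino, ReconConfig(method="csir"))
        image = ImageGrid(np.maximum(image.values, 0.0), image.pixel_size_mm)
        fwhm = fwhm_xy(image, (0.0, 100.0))
        asr = aspect_ratio(image, (0.0, 100.0))
        print(f"{n:5d} {mode:>8s} {fwhm:9.1f} mm {asr:10.2f}")
print()
print("offset sampling keeps the aspect ratio near 1.0 even at 8 views,")
print("while 8 conventional views distort the off-center point response.")
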