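"""Extract the contour band a fracture detector consumes.

The band is the mask's dilation minus the mask itself: a ring tracing the
cortical outline of the vertebral body.  Pixel counts always conserve:
|band| = |dilate(mask)| - |mask|.
"""

import numpy as np

from spinemorph import PhantomSpec, generate_spine, make_contour_band
from spinemorph.contour import dilate

labels, truth = generate_spine(PhantomSpec(n_vertebrae=3, seed=1))
mask = labels == 2

band = make_contour_band(mask, radius_px=2, element_shape="square")
print(f"vertebra pixels: {int(mask.sum())}")
print(f"band pixels:     {band.n_pixels} (radius {band.dilation_radius_px}, "
      f"{band.element} element)")
print(f"conservation:    |dilate| - |mask| = "
      f"{int(dilate(mask, 2).sum()) - int(mask.sum())}")
assert not np.any(band.band & mask), "band never overlaps the body"
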