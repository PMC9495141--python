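"""Measure a cross-sectional area from a binary contour mask.

Rasterizes a known ellipse (standing in for an exported fillet-contour
segmentation), counts foreground pixels with the physical calibration, and
compares against the analytic area — the same operation applied to real
PNG/TIFF masks via `read_mask` plus a calibration sidecar.
"""

import math

import filletvol as fv

a, b, pixel_size = 1.5, 0.8, 0.005  # semi-axes (cm), calibration (cm/px)
mask = fv.rasterize_ellipse(a, b, pixel_size)
area = fv.area_from_mask(mask)
exact = math.pi * a * b

print(f"mask: {mask.grid.shape[0]} x {mask.grid.shape[1]} px at "
      f"{pixel_size} cm/px")
print(f"pixel-count area : {area:.4f} cm^2")
print(f"analytic area    : {exact:.4f} cm^2")
print(f"relative error   : {abs(area - exact) / exact:.2%}")
print("\nPixel counting with a center-inclusion rule converges to the true "
      "area as the pixel size shrinks; at 50 um it is within 1%.")
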