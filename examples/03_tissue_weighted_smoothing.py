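"""Tissue-weighted (VBQ) smoothing versus plain Gaussian smoothing.

Demonstrates the key property of q = G*(w p) / G*(w): a quantitative map that
is constant within a tissue class passes through unchanged, while plain
smoothing drags values across tissue boundaries.
"""

import numpy as np

import mpmaging as m
from mpmaging.vbq import smooth_gaussian

# a 1D-like phantom: left half WM with R1=1.0, right half GM with R1=0.65
shape = (40, 20, 20)
wm_prob = np.zeros(shape)
wm_prob[:20] = 1.0
r1 = np.where(wm_prob > 0, 1.0, 0.65)

plain = smooth_gaussian(r1, fwhm_mm=3.0, voxel_size_mm=1.0)
vbq, support = m.tissue_weighted_smooth(r1, wm_prob, fwhm_mm=3.0)

line = 10
print("voxels 16-23 across the WM/GM boundary (row through the volume):")
print("input:   ", np.round(r1[16:24, line, line], 4))
print("plain:   ", np.round(plain[16:24, line, line], 4))
print("vbq(WM): ", np.round(vbq[16:24, line, line], 4))
print("\nPlain smoothing blurs 1.0 toward 0.65 across the boundary;")
print("the tissue-weighted result stays at the WM value of 1.0 wherever the")
print("smoothed WM weight exceeds the support threshold, and is masked (nan)")
print("beyond it — quantitative values are preserved within the tissue class.")

masks = m.make_masks([m.build_phantom(m.default_geometry_spec(32)).tpms])
print(f"\nanalysis masks on the 32^3 phantom: GM {masks.gm.sum()} voxels, "
      f"WM {masks.wm.sum()} voxels, excluded {masks.n_excluded} "
      f"(neither GM nor WM average probability above 20%)")
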