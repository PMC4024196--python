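"""Spinal-cord morphometry: segmentation, area, posterior sectors, aging.

Segments a tilted cylinder phantom slice by slice with the 25%-drop region-
growing rule, corrects the cross-sectional area by the cosine of the
through-plane angulation, and runs the cord aging regressions on a simulated
cohort whose R2* slope preset is 0.031 1/s per year.
"""

import mpmaging as m
from mpmaging.validation import cord_recovery_study

radius, angulation = 5.02, 12.0
phantom = m.build_cord_phantom(radius, angulation)
seg = m.propagate_slices(phantom.volume, phantom.seed_voxel, n_slices=15,
                         angulation_deg=angulation,
                         voxel_size_mm=phantom.voxel_size_mm)
print(f"truth area pi*r^2 = {phantom.truth_area_mm2:.2f} mm^2")
print(f"mean in-plane area {seg.areas_mm2.mean():.2f} mm^2 "
      f"(ellipse-stretched by 1/cos({angulation:.0f}deg))")
print(f"cosine-corrected area {seg.corrected_area_mm2:.2f} mm^2")
print(f"centroid-drift angulation estimate {m.estimate_angulation(seg):.1f} deg")

left, right = m.posterior_sectors(seg.masks[7], span_deg=45.0)
frac = (left | right).sum() / seg.masks[7].sum()
print(f"posterior 45-deg bilateral sectors cover {100*frac:.1f}% of the cord")

out = cord_recovery_study(seed=4, n_subjects=138)
print(f"\ncohort of 138 cords: male mean area {out['area_male_mm2']:.1f} mm^2, "
      f"female {out['area_female_mm2']:.1f} mm^2")
lo, hi = out["r2star_slope_ci"]
print(f"cord R2* age slope {out['r2star_slope']:.4f} 1/s/yr "
      f"(95% CI {lo:.4f}-{hi:.4f}; preset {out['r2star_slope_truth']})")
print(out["regression"].to_string(index=False))
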