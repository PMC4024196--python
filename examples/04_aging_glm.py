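"""Voxel-wise aging GLM on a simulated cohort: MT-saturation decline.

Runs the full chain (simulate -> fit maps -> VBQ smoothing -> voxel-wise GLM
with age, sex, TIV and scanner) on a reduced cohort and reports recovered
per-ROI annual MT change against the generator presets, plus the genu-versus-
splenium rate-difference test.  Uses n=60 subjects on a 40^3 grid to stay
quick; the acceptance script runs the full n=138 / 48^3 study.
"""

import mpmaging as m
from mpmaging.glm import roi_difference_age_test

geometry = m.build_phantom(m.default_geometry_spec(40))
aging = m.default_aging_model()
spec = m.CohortSpec(n_subjects=60)

analysis = m.analyze_cohort(cohort_spec=spec, aging=aging, geometry=geometry,
                            seed=1, params=("mt_sat",), roi_erode=2)
print(f"analysis masks: GM {analysis.masks.gm.sum()} voxels, "
      f"WM {analysis.masks.wm.sum()} voxels")

for roi in ("genu", "splenium"):
    slope, ci, _ = m.pipeline.roi_slope_with_ci(analysis, roi, "mt_sat", "wm",
                                                erode=2)
    truth = aging.rois[roi].slope.mt_sat
    print(f"{roi:<10s} fitted {slope:+.5f} p.u./yr "
          f"(95% CI {ci[0]:+.5f} to {ci[1]:+.5f}), preset {truth:+.5f}")

# rate difference: per-subject ROI means, paired difference regressed on age
genu_mask = geometry.roi_mask("genu")
spl_mask = geometry.roi_mask("splenium")
vol = analysis.slope_volumes  # fitted slope maps, for reference
mt_means = {"genu": [], "splenium": []}
for _, sub, _vols in m.iter_cohort(spec, aging, geometry, m.default_protocol(),
                                   seed=1):
    mt_means["genu"].append(sub.maps["mt_sat"][genu_mask].mean())
    mt_means["splenium"].append(sub.maps["mt_sat"][spl_mask].mean())
d_slope, t, p = roi_difference_age_test(mt_means["genu"], mt_means["splenium"],
                                        analysis.manifest["age"])
print(f"\ngenu minus splenium rate: {d_slope:+.5f} p.u./yr "
      f"(t={t:.2f}, p={p:.2g}) — the genu demyelinates faster")
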