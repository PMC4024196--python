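"""Estimate R1, R2*, MT-saturation and PD* maps from simulated acquisitions.

Fits the four quantitative maps from one subject's weighted volumes — log-
linear R2* over the eight PD-weighted echoes, dual-flip-angle R1/amplitude,
the MT-saturation equation, and white-matter-calibrated PD* — and compares
ROI means against the simulator's ground truth.
"""

import numpy as np

import mpmaging as m

geometry = m.build_phantom(m.default_geometry_spec(48))
aging = m.default_aging_model()
spec = m.CohortSpec()
protocol = m.default_protocol()

rng = np.random.default_rng(5)
subject = m.sample_subject(spec, aging, geometry, 63.0, "F", 1, rng)
vols = m.simulate_acquisition(subject, protocol, spec, rng)

maps = m.fit_parameter_maps(
    vols.volumes["pdw"], vols.volumes["t1w"], vols.volumes["mtw"], protocol,
    f_t=vols.b1, wm_mask=geometry.label_volume == 3, mt_b1_correct=True,
)
print(f"valid voxels: {maps.qc['n_valid']}/{maps.qc['n_voxels']} "
      f"(background carries no signal); effective TE {maps.effective_te_s*1e3:.2f} ms")
print(f"WM PD* mean after calibration: "
      f"{np.nanmean(maps.pd_star[geometry.label_volume == 3]):.3f} %\n")

print(f"{'ROI':<16s} {'param':<7s} {'estimated':>10s} {'truth':>10s}")
for roi in ("genu", "splenium", "pallidum"):
    mask = geometry.roi_mask(roi)
    for param, est in (("r1", maps.r1), ("r2star", maps.r2star),
                       ("mt_sat", maps.mt_sat)):
        print(f"{roi:<16s} {param:<7s} {np.nanmean(est[mask]):>10.4f} "
              f"{subject.maps[param][mask].mean():>10.4f}")
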