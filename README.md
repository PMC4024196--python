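# mpmaging

Quantitative multiparameter mapping (MPM) of the aging brain, as a fully
simulatable, testable Python pipeline.

MPM protocols estimate four biologically interpretable maps from three spoiled
multi-echo FLASH acquisitions: the longitudinal relaxation rate R1 [s⁻¹], the
effective transverse relaxation rate R2* [s⁻¹] (iron-sensitive), the
magnetization-transfer saturation δ [p.u.] (myelin-sensitive), and the
effective proton density PD* [% water]. Cross-sectional aging studies regress
these maps voxel-wise on age to chart where myelin declines and iron
accumulates. This package implements the whole chain — and, because cohort
MRI data cannot be shipped, a forward simulator that generates synthetic
cohorts with *known* linear age trends so every stage can be validated by
parameter recovery. It is aimed at quantitative-MRI methods developers and at
anyone who wants an end-to-end, dependency-light reference implementation of
the voxel-based quantification (VBQ) analysis style.

## What is implemented

**Signal model and estimators** (`mpmaging.flash`). The spoiled FLASH
steady-state signal, either exact
(`S = A sin α (1−E1)/(1−cos α E1) e^{−TE·R2*}`, `E1 = e^{−TR·R1}`) or in the
small-angle rational approximation
(`S = A α TR·R1 / (α²/2 + TR·R1 + δ/100) e^{−TE·R2*}`). From three weighted
acquisitions (PDw and MTw at TR/α = 23.7 ms/6°, T1w at 18.7 ms/20°; six
common echoes 2.2–14.7 ms, PDw adding 17.2 and 19.7 ms):

* R2* by log-linear regression over the eight PD-weighted echoes;
* echo averaging to an effective TE of 8.45 ms;
* R1 and apparent amplitude by the dual-flip-angle rational solution with
  B1⁺-corrected flip angles `α·f_T`;
* MT saturation `δ = 100·[(A·α_MT/S_MT − 1)·R1·TR − α_MT²/2]`;
* PD* by polynomial receive-field correction of the amplitude map and a
  per-subject global scale pinning mean white-matter PD* to 69% water.

**VBQ / VBM preprocessing** (`mpmaging.vbq`). Tissue-weighted smoothing
`q = G★(w·p) / G★(w)` (3 mm FWHM) that preserves quantitative values within a
tissue class; Jacobian-modulated GM smoothing (6 mm) for morphometry; cohort
analysis masks by maximal average tissue probability with the strict 20%
GM/WM exclusion rule.

**Voxel-wise statistics** (`mpmaging.glm`). OLS GLM with intercept, age,
sex, total intracranial volume and scanner; one/two-tailed t contrasts and
F contrasts; family-wise error control by Freedman–Lane permutation of the
volume-wise maximum statistic (or Bonferroni); per-ROI slope tables.

**Spinal cord** (`mpmaging.cord`). Slice-wise region growing with the
25%-intensity-drop stopping rule, seed propagation across 15 slices,
cross-sectional area corrected by the cosine of the through-plane angulation,
bilateral 45° posterior-sector extraction, and one-tailed aging regressions.

**Synthetic cohorts** (`mpmaging.phantom`, `mpmaging.cohort`). A labeled
nested-sphere brain phantom with atlas-like ROIs (genu, splenium, optic
radiation, pallidum, putamen, motor cortex), partial-volume tissue
probability maps, smooth B1⁺/receive fields, and an aging model whose default
presets encode published annual rates (e.g. genu MT −0.0019 %/yr, splenium
−0.0005 %/yr, R1 declines of 0.0007–0.0016 s⁻¹/yr, deep-gray R2* increases up
to 0.22 s⁻¹/yr, cord R2* +0.031 s⁻¹/yr), plus a tilted-cylinder cord phantom
with analytic truth area.

**Orchestration** (`mpmaging.pipeline`, `mpmaging.validation`). An in-memory
end-to-end analysis (`analyze_cohort`), a staged file-based pipeline with
resume (`run_pipeline`: simulate → fit → vbq → glm → report, NIfTI/CSV/JSON
products), and validation studies used by the acceptance checks.

## Worked example

Estimating maps from one simulated subject (`examples/02_fit_parameter_maps.py`):

```
WM PD* mean after calibration: 69.000 %

ROI              param    estimated      truth
genu             r1          1.0458     1.0460
genu             r2star     19.8277    19.8174
genu             mt_sat      2.0749     2.0743
...
```

The calibration pins white-matter PD* to 69% exactly; ROI means of the fitted
R1/R2*/MT maps match the simulator's ground truth to a fraction of a percent
at the default 1% noise level.

Recovering aging rates on a reduced cohort (`examples/04_aging_glm.py`,
n=60 subjects, 40³ grid):

```
genu       fitted -0.00220 p.u./yr (95% CI -0.00252 to -0.00188), preset -0.00190
splenium   fitted -0.00071 p.u./yr (95% CI -0.00106 to -0.00036), preset -0.00050

genu minus splenium rate: -0.00166 p.u./yr (t=-7.67, p=2.2e-10)
```

Each preset lies inside the regression's 95% confidence interval, and the
genu-versus-splenium rate difference (the anterior corpus callosum
demyelinating faster) is clearly detected.

Cord morphometry (`examples/05_spinal_cord.py`): a 5.02 mm-radius cylinder
tilted by 12° is segmented to a cosine-corrected area of 79.39 mm² against a
truth of 79.17 mm², and the cohort regression recovers the cord R2* slope
0.0308 s⁻¹/yr against the preset 0.031.

All examples run in seconds to a few tens of seconds:

```bash
python examples/01_simulate_cohort.py
python examples/04_aging_glm.py
...
```

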