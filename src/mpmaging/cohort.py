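"""Synthetic aging cohort: ground-truth maps with linear age trends, forward-
simulated multi-echo FLASH acquisitions, and cohort generation.

The aging model assigns every tissue class and every named ROI a baseline
value at a reference age, an annual slope and a between-subject standard
deviation, separately for each of the four quantitative parameters
(R1 [1/s], R2* [1/s], MT saturation [p.u.], PD [% water]).  Default presets
encode the age-related rates a 3T multiparameter-mapping study of 138 adults
reports: MT-saturation decline of 0.0019 %/yr in the callosal genu versus
0.0005 %/yr in the splenium, R1 decline between 0.0007 (genu) and 0.0016
(optic radiation) 1/s per year, and R2* increase between 0.03 (cortex) and
0.22 (pallidum) 1/s per year.

The printed MT rates are 2-3 orders of magnitude below typical white-matter
MT-saturation levels (~2 p.u.); the presets store them verbatim as absolute
percent-units of the MT map per year, which is the natural reading of the
published units.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flash import flash_signal
from .phantom import (PhantomGeometry, build_cord_phantom, TISSUE_NAMES,
                      TISSUE_CODES)
from .protocol import AcquisitionProtocol

__all__ = [
    "ParamSet",
    "AgingEntry",
    "AgingModel",
    "default_aging_model",
    "CohortSpec",
    "GroundTruthSubject",
    "WeightedVolumes",
    "sample_subject",
    "simulate_acquisition",
    "iter_cohort",
    "generate_cohort",
    "sample_covariates",
    "CordCohortSpec",
    "simulate_cord_cohort",
]

PARAMS = ("r1", "r2star", "mt_sat", "pd")


@dataclass(frozen=True)
class ParamSet:
    """One value per quantitative parameter."""

    r1: float = 0.0
    r2star: float = 0.0
    mt_sat: float = 0.0
    pd: float = 0.0

    def get(self, name):
        return getattr(self, name)


@dataclass(frozen=True)
class AgingEntry:
    """Linear age model for one region: value = baseline + slope*(age-ref) + N(0, sd)."""

    baseline: ParamSet
    slope: ParamSet = ParamSet()
    sd: ParamSet = ParamSet()

    def __post_init__(self):
        if any(self.baseline.get(p) < 0 for p in PARAMS):
            raise ValueError("baselines must be non-negative")
        if self.baseline.pd > 100:
            raise ValueError("PD baseline cannot exceed 100% water")
        if any(self.sd.get(p) < 0 for p in PARAMS):
            raise ValueError("between-subject SDs must be non-negative")


@dataclass(frozen=True)
class AgingModel:
    """Per-tissue and per-ROI linear aging entries around a reference age."""

    tissues: dict[str, AgingEntry]
    rois: dict[str, AgingEntry] = field(default_factory=dict)
    reference_age: float = 46.6

    def entry_for(self, name: str) -> AgingEntry:
        if name in self.rois:
            return self.rois[name]
        return self.tissues[name]


def default_aging_model() -> AgingModel:
    """Default presets: plausible 3T mid-age baselines with the published rates.

    ROI slopes (per year): genu MT -0.0019, splenium MT -0.0005; genu R1
    -0.0007, optic radiation R1 -0.0016; pallidum R2* +0.22, putamen +0.12,
    motor cortex +0.03.  Between-subject SDs model residual variability after
    nuisance regression in a homogeneous ROI.
    """
    wm = AgingEntry(
        baseline=ParamSet(r1=1.0, r2star=20.0, mt_sat=2.0, pd=69.0),
        slope=ParamSet(r1=-0.0004, r2star=0.01, mt_sat=-0.0013, pd=0.01),
        sd=ParamSet(r1=0.01, r2star=0.5, mt_sat=0.02, pd=1.0),
    )
    gm = AgingEntry(
        baseline=ParamSet(r1=0.65, r2star=16.0, mt_sat=1.0, pd=83.0),
        slope=ParamSet(r1=-0.0002, r2star=0.01, mt_sat=-0.0005, pd=-0.01),
        sd=ParamSet(r1=0.01, r2star=0.5, mt_sat=0.02, pd=1.0),
    )
    csf = AgingEntry(baseline=ParamSet(r1=0.25, r2star=1.0, mt_sat=0.0, pd=100.0))
    roi_sd = ParamSet(r1=0.01, r2star=0.5, mt_sat=0.02, pd=1.0)
    rois = {
        "genu": AgingEntry(
            baseline=ParamSet(r1=1.05, r2star=19.0, mt_sat=2.1, pd=69.0),
            slope=ParamSet(r1=-0.0007, r2star=0.0, mt_sat=-0.0019, pd=0.0),
            sd=roi_sd,
        ),
        "splenium": AgingEntry(
            baseline=ParamSet(r1=1.08, r2star=21.0, mt_sat=2.2, pd=69.0),
            slope=ParamSet(r1=-0.0003, r2star=0.0, mt_sat=-0.0005, pd=0.0),
            sd=roi_sd,
        ),
        "optic_radiation": AgingEntry(
            baseline=ParamSet(r1=1.0, r2star=18.0, mt_sat=2.0, pd=69.0),
            slope=ParamSet(r1=-0.0016, r2star=-0.03, mt_sat=-0.0015, pd=0.02),
            sd=roi_sd,
        ),
        # deep-gray R2* baselines follow age-matched MPM reference values
        "pallidum": AgingEntry(
            baseline=ParamSet(r1=0.95, r2star=28.32, mt_sat=1.3, pd=75.0),
            slope=ParamSet(r1=0.0, r2star=0.22, mt_sat=-0.0005, pd=-0.02),
            sd=roi_sd,
        ),
        "putamen": AgingEntry(
            baseline=ParamSet(r1=0.85, r2star=20.74, mt_sat=1.2, pd=78.0),
            slope=ParamSet(r1=0.0, r2star=0.12, mt_sat=-0.0005, pd=-0.02),
            sd=roi_sd,
        ),
        "motor_cortex": AgingEntry(
            baseline=ParamSet(r1=0.70, r2star=17.0, mt_sat=1.1, pd=82.0),
            slope=ParamSet(r1=-0.0002, r2star=0.03, mt_sat=-0.0005, pd=-0.01),
            sd=roi_sd,
        ),
    }
    return AgingModel(tissues={"wm": wm, "gm": gm, "csf": csf}, rois=rois)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition knobs for cohort generation."""

    n_subjects: int = 138
    age_range: tuple[float, float] = (19.0, 75.0)
    age_sampling: str = "uniform"        # or "sparse_middle"
    male_fraction: float = 49.0 / 138.0
    scanner_assignment: str = "split"    # half/half, or "random"
    scanner_effect: float = 0.01         # multiplicative amplitude offset, scanner 2
    noise_sd_frac: float = 0.01          # of mean WM PDw first-echo signal
    b1_amplitude: float = 0.2            # f_T spans [1-a, 1+a]
    receive_amplitude: float = 0.3
    signal_model: str = "rational"
    noise_law: str = "gaussian"          # or "rician"
    atrophy_rate: float = 0.0            # GM-probability decline per year in atrophy ROIs
    atrophy_rois: tuple[str, ...] = ("motor_cortex",)
    head_size_sd: float = 0.04           # per-subject global TPM scale (brain-size variation)
    brain_threshold: float = 0.5         # tissue-sum threshold entering TIV

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        lo, hi = self.age_range
        if not (0 <= lo < hi <= 120):
            raise ValueError("age range must lie within [0, 120]")
        if self.b1_amplitude >= 1:
            raise ValueError("B1 amplitude must keep f_T positive")


@dataclass
class GroundTruthSubject:
    """Ground-truth parameter maps plus covariates for one simulated subject."""

    maps: dict[str, np.ndarray]          # r1, r2star, mt_sat, pd
    tpms: dict[str, np.ndarray]
    age: float
    sex: str                             # "M" / "F"
    scanner: int                         # 1 or 2
    tiv_mm3: float
    geometry: PhantomGeometry
    subject_id: str = "sub-000"
    cord_radius_mm: float | None = None
    cord_angulation_deg: float | None = None


@dataclass
class WeightedVolumes:
    """Simulated (or acquired) multi-echo volumes per weighting, plus fields."""

    volumes: dict[str, np.ndarray]       # name -> (..., n_echoes)
    b1: np.ndarray | float               # f_T map
    receive: np.ndarray | float
    noise_sd: float


def _smooth_field(shape, amplitude, kind):
    """Smooth multiplicative bias field on the unit cube.

    ``kind='radial'`` gives a center-bright paraboloid spanning
    [1-amplitude, 1+amplitude] (transmit-like); ``kind='linear'`` a gentle
    oblique gradient (receive-like).
    """
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    if kind == "radial":
        rho2 = (gx**2 + gy**2 + gz**2) / 3.0
        return 1.0 + amplitude * (1.0 - 2.0 * rho2)
    if kind == "linear":
        return 1.0 + amplitude * (0.6 * gx + 0.3 * gy + 0.1 * gz)
    raise ValueError(f"unknown field kind {kind!r}")


def sample_subject(cohort_spec: CohortSpec, aging: AgingModel,
                   geometry: PhantomGeometry, age: float, sex: str,
                   scanner: int, rng, subject_id: str = "sub-000") -> GroundTruthSubject:
    """Draw one subject's ground-truth maps from the linear aging model.

    Each region (tissue class, overridden by ROI membership) receives
    ``baseline + slope*(age - reference_age)`` plus a single region-level
    Gaussian draw of the between-subject SD, constant within the region.
    """
    lo, hi = cohort_spec.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside cohort range {cohort_spec.age_range}")
    for roi in aging.rois:
        try:
            geometry.roi_label(roi)
        except KeyError:
            raise ValueError(f"aging model names unknown ROI {roi!r}") from None

    rng = np.random.default_rng(rng)
    d_age = age - aging.reference_age
    maps = {p: np.zeros(geometry.shape) for p in PARAMS}

    regions: list[tuple[np.ndarray, AgingEntry]] = []
    for code, tname in TISSUE_NAMES.items():
        regions.append((geometry.label_volume == code, aging.tissues[tname]))
    for lbl, (name, _) in geometry.roi_table.items():
        if name in aging.rois:
            regions.append((geometry.roi_volume == lbl, aging.rois[name]))

    for mask, entry in regions:
        for p in PARAMS:
            value = entry.baseline.get(p) + entry.slope.get(p) * d_age
            sd = entry.sd.get(p)
            if sd > 0:
                value = value + rng.normal(0.0, sd)
            maps[p][mask] = value
    for p in PARAMS:
        np.clip(maps[p], 0.0, 100.0 if p == "pd" else None, out=maps[p])

    tpms = {k: v.copy() for k, v in geometry.tpms.items()}
    if cohort_spec.head_size_sd > 0:
        # global head-size factor: scales tissue probabilities (clipped to 1),
        # shifting the brain boundary so TIV varies across subjects
        head = rng.normal(1.0, cohort_spec.head_size_sd)
        for k in tpms:
            np.clip(tpms[k] * head, 0.0, 1.0, out=tpms[k])
    if cohort_spec.atrophy_rate > 0 and d_age > 0:
        factor = max(0.0, 1.0 - cohort_spec.atrophy_rate * d_age)
        for roi in cohort_spec.atrophy_rois:
            m = geometry.roi_mask(roi)
            tpms["gm"][m] *= factor

    tissue_sum = sum(tpms.values())
    tiv = geometry.voxel_volume_mm3 * int(
        np.count_nonzero(tissue_sum > cohort_spec.brain_threshold)
    )
    return GroundTruthSubject(
        maps=maps, tpms=tpms, age=age, sex=sex, scanner=scanner,
        tiv_mm3=tiv, geometry=geometry, subject_id=subject_id,
    )


def simulate_acquisition(subject: GroundTruthSubject,
                         protocol: AcquisitionProtocol,
                         cohort_spec: CohortSpec, rng) -> WeightedVolumes:
    """Forward-simulate the three multi-echo FLASH volumes for one subject.

    The per-voxel amplitude is the ground-truth PD scaled by the smooth
    receive field and the scanner gain; the excitation angle is the nominal
    angle times the smooth B1+ transmit factor; noise is additive Gaussian per
    echo image (optionally Rician), with SD set as a fraction of the mean
    white-matter first-echo PDw signal.
    """
    rng = np.random.default_rng(rng)
    shape = subject.geometry.shape
    f_t = _smooth_field(shape, cohort_spec.b1_amplitude, "radial")
    receive = _smooth_field(shape, cohort_spec.receive_amplitude, "linear")
    gain = 1.0 + (cohort_spec.scanner_effect if subject.scanner == 2 else 0.0)

    amplitude = subject.maps["pd"] * receive * gain
    r1 = subject.maps["r1"]
    r2s = subject.maps["r2star"]
    mt = subject.maps["mt_sat"]
    wm = subject.geometry.label_volume == TISSUE_CODES["wm"]

    def forward(w, delta):
        alpha = w.flip_rad * f_t
        out = np.empty(shape + (len(w.te_s),))
        for k, te in enumerate(w.te_s):
            out[..., k] = flash_signal(amplitude, r1, r2s, alpha, w.tr_s, te,
                                       delta, model=cohort_spec.signal_model)
        return out

    clean = {
        "pdw": forward(protocol.pdw, 0.0),
        "t1w": forward(protocol.t1w, 0.0),
        "mtw": forward(protocol.mtw, mt),
    }
    sigma = cohort_spec.noise_sd_frac * float(clean["pdw"][..., 0][wm].mean())
    volumes = {}
    for name, s in clean.items():
        if sigma > 0:
            if cohort_spec.noise_law == "rician":
                volumes[name] = np.sqrt(
                    (s + rng.normal(0.0, sigma, s.shape)) ** 2
                    + rng.normal(0.0, sigma, s.shape) ** 2
                )
            else:
                volumes[name] = s + rng.normal(0.0, sigma, s.shape)
        else:
            volumes[name] = s
    return WeightedVolumes(volumes=volumes, b1=f_t, receive=receive, noise_sd=sigma)


def sample_covariates(cohort_spec: CohortSpec, seed) -> pd.DataFrame:
    """Ages, sexes and scanner assignment for the whole cohort (deterministic)."""
    rng = np.random.default_rng(seed)
    n = cohort_spec.n_subjects
    lo, hi = cohort_spec.age_range
    if cohort_spec.age_sampling == "uniform":
        ages = rng.uniform(lo, hi, n)
    elif cohort_spec.age_sampling == "sparse_middle":
        # under-sample 35-55: draw thirds from the flanks, a thin middle
        parts = rng.uniform(0, 1, n)
        ages = np.where(
            parts < 0.45, rng.uniform(lo, 35.0, n),
            np.where(parts < 0.55, rng.uniform(35.0, 55.0, n),
                     rng.uniform(55.0, hi, n)),
        )
    else:
        raise ValueError(f"unknown age sampling {cohort_spec.age_sampling!r}")

    n_male = int(round(cohort_spec.male_fraction * n))
    sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
    rng.shuffle(sexes)
    if cohort_spec.scanner_assignment == "split":
        scanners = np.array([1] * (n // 2 + n % 2) + [2] * (n // 2))
        rng.shuffle(scanners)
    elif cohort_spec.scanner_assignment == "random":
        scanners = rng.integers(1, 3, n)
    else:
        raise ValueError("unknown scanner assignment rule")
    return pd.DataFrame({
        "subject_id": [f"sub-{i:03d}" for i in range(n)],
        "age": ages, "sex": sexes, "scanner": scanners,
    })


def iter_cohort(cohort_spec: CohortSpec, aging: AgingModel,
                geometry: PhantomGeometry, protocol: AcquisitionProtocol, seed):
    """Yield ``(row, GroundTruthSubject, WeightedVolumes)`` per subject.

    Streaming generation keeps only one subject's echo volumes in memory at a
    time.  Fully deterministic given ``seed`` (independent child streams per
    subject).
    """
    manifest = sample_covariates(cohort_spec, np.random.SeedSequence(seed))
    children = np.random.SeedSequence(seed).spawn(cohort_spec.n_subjects + 1)[1:]
    for (_, row), child in zip(manifest.iterrows(), children):
        rng = np.random.default_rng(child)
        subject = sample_subject(cohort_spec, aging, geometry, row["age"],
                                 row["sex"], int(row["scanner"]), rng,
                                 subject_id=row["subject_id"])
        vols = simulate_acquisition(subject, protocol, cohort_spec, rng)
        yield row, subject, vols


def generate_cohort(cohort_spec: CohortSpec, aging: AgingModel,
                    geometry: PhantomGeometry, protocol: AcquisitionProtocol,
                    seed, out_dir) -> pd.DataFrame:
    """Materialize a cohort to disk: NIfTI volumes (echo as 4th axis) + CSV manifest."""
    from pathlib import Path
    from .nifti import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for row, subject, vols in iter_cohort(cohort_spec, aging, geometry, protocol, seed):
        rec = dict(row)
        rec["tiv_mm3"] = subject.tiv_mm3
        sid = row["subject_id"]
        for name, data in vols.volumes.items():
            path = out / f"{sid}_{name}.nii"
            write_volume(path, data.astype(np.float32), geometry.voxel_size_mm)
            rec[f"path_{name}"] = str(path)
        b1 = np.broadcast_to(np.asarray(vols.b1, dtype=np.float32), geometry.shape)
        b1_path = out / f"{sid}_b1.nii"
        write_volume(b1_path, np.array(b1), geometry.voxel_size_mm)
        rec["path_b1"] = str(b1_path)
        for tissue, tpm in subject.tpms.items():
            tpath = out / f"{sid}_tpm_{tissue}.nii"
            write_volume(tpath, tpm.astype(np.float32), geometry.voxel_size_mm)
            rec[f"path_tpm_{tissue}"] = str(tpath)
        rows.append(rec)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


@dataclass(frozen=True)
class CordCohortSpec:
    """Generator presets for the cervical-cord aging sub-study.

    Radii reproduce the published mean cross-sectional areas (79.2 mm^2
    overall; 80.7 men / 76.6 women) with a radius SD matched to the published
    area SD (~7 mm^2); the cord R2* slope preset is the published
    0.031 1/s per year.
    """

    radius_mean_male_mm: float = math.sqrt(80.7 / math.pi)
    radius_mean_female_mm: float = math.sqrt(76.6 / math.pi)
    radius_sd_mm: float = 0.22
    angulation_range_deg: tuple[float, float] = (0.0, 12.0)
    r2star_baseline: float = 18.0
    r2star_slope: float = 0.031          # 1/s per year
    r2star_sd: float = 2.0
    mt_baseline: float = 1.6
    mt_slope: float = 0.0                # no significant cord MT aging observed
    mt_sd: float = 0.12
    n_slices: int = 15
    reference_age: float = 46.6


def simulate_cord_cohort(covariates: pd.DataFrame, spec: CordCohortSpec, seed):
    """Per-subject cord phantoms and true cord parameter values.

    Yields ``(row, CordPhantom, truth)`` where ``truth`` holds the subject's
    cord R2*, MT and truth area.  The intensity volume is T1w-like (bright
    cord / CSF rim / dark background) and drives the segmentation; parameter
    values are spatially constant within the cord.
    """
    children = np.random.SeedSequence(seed).spawn(len(covariates))
    ref = spec.reference_age
    for (_, row), child in zip(covariates.iterrows(), children):
        rng = np.random.default_rng(child)
        mean_r = (spec.radius_mean_male_mm if row["sex"] == "M"
                  else spec.radius_mean_female_mm)
        radius = max(2.0, rng.normal(mean_r, spec.radius_sd_mm))
        ang = rng.uniform(*spec.angulation_range_deg)
        d_age = row["age"] - ref
        truth = {
            "r2star": spec.r2star_baseline + spec.r2star_slope * d_age
            + rng.normal(0.0, spec.r2star_sd),
            "mt_sat": max(0.0, spec.mt_baseline + spec.mt_slope * d_age
                          + rng.normal(0.0, spec.mt_sd)),
            "area_mm2": math.pi * radius**2,
        }
        phantom = build_cord_phantom(radius, ang, n_slices=spec.n_slices, rng=rng)
        yield row, phantom, truth
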