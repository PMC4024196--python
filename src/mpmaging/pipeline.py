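"""End-to-end orchestration: simulate -> fit maps -> VBQ -> GLM -> report.

Two entry points are provided.  :func:`analyze_cohort` streams a synthetic
cohort through the full analysis in memory and returns the fitted voxel-wise
models and ROI slope tables — the workhorse for validation studies.
:func:`run_pipeline` is the staged, file-based variant: every stage writes its
products (NIfTI volumes, CSV tables, JSON sidecars) under an output directory,
records completion markers keyed to the configuration hash, and can resume a
partially completed run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (AgingModel, CohortSpec, default_aging_model, iter_cohort,
                     generate_cohort, PARAMS)
from .flash import fit_parameter_maps
from .glm import (build_design, fit_voxelwise, t_contrast, fwe_correct,
                  roi_slope_summary, DesignMatrix)
from .nifti import read_volume, write_volume
from .phantom import PhantomGeometry, build_phantom, default_geometry_spec
from .protocol import AcquisitionProtocol, default_protocol
from .vbq import tissue_weighted_smooth, make_masks, smooth_gaussian

__all__ = [
    "PipelineConfig",
    "CohortAnalysis",
    "analyze_cohort",
    "run_pipeline",
    "report",
    "AGE_TAILS",
]

# hypothesized directions for the age contrast per parameter
AGE_TAILS = {"mt_sat": "one-neg", "r1": "one-neg", "r2star": "two", "pd_star": "two"}

ANALYSIS_PARAMS = ("mt_sat", "r1", "r2star", "pd_star")


@dataclass
class CohortAnalysis:
    """Everything the in-memory pipeline computes for one synthetic cohort."""

    manifest: pd.DataFrame
    design: DesignMatrix
    masks: object                       # vbq.AnalysisMasks
    geometry: PhantomGeometry
    fits: dict                          # (param, tissue) -> GLMFit
    contrasts: dict                     # (param, tissue) -> ContrastResult
    slope_volumes: dict                 # (param, tissue) -> ndarray (nan outside)
    roi_tables: pd.DataFrame
    truth_slopes: pd.DataFrame
    qc: dict


def _truth_slope_table(aging: AgingModel, geometry: PhantomGeometry) -> pd.DataFrame:
    rows = []
    for lbl, (name, tissue) in sorted(geometry.roi_table.items()):
        entry = aging.entry_for(name)
        for p in PARAMS:
            rows.append({"roi": name, "tissue": tissue, "param": p,
                         "truth_slope": entry.slope.get(p)})
    return pd.DataFrame(rows)


def analyze_cohort(cohort_spec: CohortSpec | None = None,
                   aging: AgingModel | None = None,
                   geometry: PhantomGeometry | None = None,
                   protocol: AcquisitionProtocol | None = None,
                   seed: int = 0,
                   params=ANALYSIS_PARAMS,
                   vbq_fwhm_mm: float = 3.0,
                   mask_threshold: float = 0.20,
                   support_eps: float = 0.05,
                   fwe_method: str | None = None,
                   n_perm: int = 1000,
                   alpha: float = 0.05,
                   roi_erode: int = 2) -> CohortAnalysis:
    """Simulate a cohort and run map fitting, VBQ smoothing and the voxel GLM.

    Subjects are processed streaming (one set of echo volumes in memory at a
    time); tissue-weighted smoothed parameter maps are retained as float32.
    The age contrast uses the hypothesized tail per parameter (one-tailed
    decline for MT saturation and R1, two-tailed for R2* and PD*).  ROI slope
    summaries are taken over ROI cores eroded by ``roi_erode`` voxels to stay
    clear of boundary mixing from the smoothing kernel.
    """
    cohort_spec = cohort_spec or CohortSpec()
    aging = aging or default_aging_model()
    geometry = geometry or build_phantom(default_geometry_spec())
    protocol = protocol or default_protocol()
    voxel = geometry.voxel_size_mm

    smoothed: dict[tuple[str, str], list[np.ndarray]] = {
        (p, t): [] for p in params for t in ("gm", "wm")
    }
    tpm_sums = {c: np.zeros(geometry.shape) for c in ("gm", "wm", "csf")}
    rows = []
    qc_totals = {"n_mt_clamped": 0, "n_r2star_clamped": 0, "n_invalid": 0}
    wm_truth = geometry.label_volume == 3

    for row, subject, vols in iter_cohort(cohort_spec, aging, geometry,
                                          protocol, seed):
        # the transmit-field map is a pipeline input, so the MT readout angle
        # is corrected too (keeps the semi-quantitative MT map unbiased)
        maps = fit_parameter_maps(
            vols.volumes["pdw"], vols.volumes["t1w"], vols.volumes["mtw"],
            protocol, f_t=vols.b1, wm_mask=wm_truth, mt_b1_correct=True,
        )
        qc_totals["n_mt_clamped"] += maps.qc["n_mt_clamped"]
        qc_totals["n_r2star_clamped"] += maps.qc["n_r2star_clamped"]
        qc_totals["n_invalid"] += maps.qc["n_voxels"] - maps.qc["n_valid"]
        volumes = {"mt_sat": maps.mt_sat, "r1": maps.r1, "r2star": maps.r2star,
                   "pd_star": maps.pd_star, "a_app": maps.a_app}
        for p in params:
            for tissue in ("gm", "wm"):
                q, _ = tissue_weighted_smooth(
                    volumes[p], subject.tpms[tissue], vbq_fwhm_mm, voxel,
                    support_eps,
                )
                smoothed[(p, tissue)].append(q.astype(np.float32))
        for c in tpm_sums:
            tpm_sums[c] += smooth_gaussian(subject.tpms[c], vbq_fwhm_mm, voxel)
        rec = dict(row)
        rec["tiv_mm3"] = subject.tiv_mm3
        rows.append(rec)

    manifest = pd.DataFrame(rows)
    design = build_design(manifest)
    n = len(manifest)

    from .vbq import AnalysisMasks
    mean_probs = {c: s / n for c, s in tpm_sums.items()}
    stack = np.stack([mean_probs[c] for c in ("gm", "wm", "csf")])
    assigned = np.argmax(stack, axis=0)
    excluded = (mean_probs["gm"] <= mask_threshold) & (mean_probs["wm"] <= mask_threshold)
    masks = AnalysisMasks(gm=(assigned == 0) & ~excluded,
                          wm=(assigned == 1) & ~excluded,
                          excluded=excluded, mean_probs=mean_probs)

    fits, contrasts, slope_volumes = {}, {}, {}
    roi_rows = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFE]))
    for p in params:
        tail = AGE_TAILS.get(p, "two")
        for tissue in ("gm", "wm"):
            tissue_mask = getattr(masks, tissue)
            data = np.stack([m[tissue_mask] for m in smoothed[(p, tissue)]])
            usable = np.all(np.isfinite(data), axis=0)
            data = data[:, usable].astype(float)
            if data.shape[1] == 0:
                continue
            fit = fit_voxelwise(data, design)
            age_c = design.contrast("age")
            if fwe_method:
                res = fwe_correct(data, design, age_c, tail=tail,
                                  method=fwe_method, n_perm=n_perm, rng=rng,
                                  alpha=alpha)
            else:
                res = t_contrast(fit, age_c, tail=tail)
            fits[(p, tissue)] = fit
            contrasts[(p, tissue)] = res

            slope_vol = np.full(geometry.shape, np.nan)
            idx = np.flatnonzero(tissue_mask.ravel())[usable]
            slope_vol.ravel()[idx] = res.effect
            slope_volumes[(p, tissue)] = slope_vol

            sig = None
            if res.significant is not None:
                sig_vol = np.zeros(geometry.shape, dtype=bool)
                sig_vol.ravel()[idx] = res.significant
                sig = sig_vol
            table = roi_slope_summary(slope_vol, geometry.roi_volume,
                                      geometry.roi_table,
                                      significant_mask=sig, erode=roi_erode)
            table.insert(0, "param", p)
            table.insert(1, "analysis_tissue", tissue)
            roi_rows.append(table)

    roi_tables = pd.concat(roi_rows, ignore_index=True)
    return CohortAnalysis(
        manifest=manifest, design=design, masks=masks, geometry=geometry,
        fits=fits, contrasts=contrasts, slope_volumes=slope_volumes,
        roi_tables=roi_tables, truth_slopes=_truth_slope_table(aging, geometry),
        qc=qc_totals,
    )


def roi_slope_with_ci(analysis: CohortAnalysis, roi: str, param: str,
                      tissue: str = "wm", erode: int = 2):
    """Mean fitted age slope over an ROI core with its 95% confidence interval.

    The CI combines the per-voxel slope standard errors of the GLM (slopes of
    neighboring voxels are strongly correlated after smoothing, so the mean
    ROI standard error is used rather than a sqrt(n_voxels) reduction — a
    conservative choice).
    """
    from scipy import ndimage, stats

    fit = analysis.fits[(param, tissue)]
    res = analysis.contrasts[(param, tissue)]
    mask = analysis.geometry.roi_mask(roi)
    if erode > 0:
        mask = ndimage.binary_erosion(mask, iterations=erode)
    slope_vol = analysis.slope_volumes[(param, tissue)]
    sel = mask & np.isfinite(slope_vol)
    mean_slope = float(slope_vol[sel].mean())

    age_c = analysis.design.contrast("age")
    var_unit = float(age_c @ fit.xtx_inv @ age_c)
    tissue_mask = getattr(analysis.masks, tissue)
    idx_map = np.full(analysis.geometry.shape, -1, dtype=int)
    # recover the voxel ordering used in the fit
    finite = np.isfinite(slope_vol) & tissue_mask
    idx_map[finite] = np.arange(np.count_nonzero(finite))
    cols = idx_map[sel]
    se = float(np.sqrt(fit.sigma2[cols] * var_unit).mean())
    half = stats.t.ppf(0.975, fit.dof) * se
    return mean_slope, (mean_slope - half, mean_slope + half), se


# --------------------------------------------------------------------------
# staged, file-based pipeline


@dataclass
class PipelineConfig:
    """Serializable configuration; a saved config fully reproduces a run."""

    seed: int = 0
    geometry: dict = field(default_factory=lambda: {"size": 48})
    cohort: dict = field(default_factory=dict)       # CohortSpec overrides
    vbq: dict = field(default_factory=lambda: {
        "fwhm_mm": 3.0, "mask_fwhm_mm": 3.0, "threshold": 0.20,
        "support_eps": 0.05})
    stats: dict = field(default_factory=lambda: {
        "params": list(ANALYSIS_PARAMS), "fwe_method": None,
        "n_perm": 1000, "alpha": 0.05, "roi_erode": 2})
    cord: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "geometry": dict(self.geometry),
                "cohort": dict(self.cohort), "vbq": dict(self.vbq),
                "stats": dict(self.stats), "cord": dict(self.cord)}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        return cls(**raw)

    @property
    def hash(self) -> str:
        return hashlib.md5(self.to_yaml().encode()).hexdigest()[:12]

    def build(self):
        geometry = build_phantom(default_geometry_spec(self.geometry.get("size", 48)))
        cohort_spec = CohortSpec(**self.cohort)
        return cohort_spec, default_aging_model(), geometry, default_protocol()


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    marker = out / f"{stage}.done.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("config_hash") == cfg_hash
    except (json.JSONDecodeError, OSError):
        return False


def _mark_done(out: Path, stage: str, cfg_hash: str, **extra):
    payload = {"stage": stage, "config_hash": cfg_hash,
               "finished_unix": time.time(), **extra}
    (out / f"{stage}.done.json").write_text(json.dumps(payload, indent=1))


def run_pipeline(config: PipelineConfig, out_dir, resume: bool = False) -> dict:
    """Execute the staged pipeline, writing all products under ``out_dir``.

    Stages: ``simulate`` (cohort volumes + manifest), ``fit`` (parameter
    maps + QC sidecars), ``vbq`` (tissue-weighted smoothed maps + analysis
    masks), ``glm`` (slope/t/p maps + ROI tables), ``report``.  With
    ``resume=True`` stages whose completion marker matches the configuration
    hash are skipped.  Returns the run manifest (also saved as JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    cohort_spec, aging, geometry, protocol = config.build()
    voxel = geometry.voxel_size_mm
    h = config.hash
    run: dict = {"config_hash": h, "stages": {}, "software": "mpmaging 0.1.0"}
    stage = "simulate"

    try:
        t0 = time.time()
        sim_dir = out / "simulate"
        if not (resume and _stage_done(out, stage, h)):
            manifest = generate_cohort(cohort_spec, aging, geometry, protocol,
                                       config.seed, sim_dir)
            _mark_done(out, stage, h, n_subjects=len(manifest))
        manifest = pd.read_csv(sim_dir / "manifest.csv")
        run["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "fit"
        t0 = time.time()
        fit_dir = out / "fit"
        if not (resume and _stage_done(out, stage, h)):
            fit_dir.mkdir(exist_ok=True)
            wm_truth = geometry.label_volume == 3
            for _, row in manifest.iterrows():
                sid = row["subject_id"]
                pdw, _, _ = read_volume(row["path_pdw"])
                t1w, _, _ = read_volume(row["path_t1w"])
                mtw, _, _ = read_volume(row["path_mtw"])
                b1, _, _ = read_volume(row["path_b1"])
                maps = fit_parameter_maps(pdw, t1w, mtw, protocol, f_t=b1,
                                          wm_mask=wm_truth, mt_b1_correct=True)
                for name, vol in (("mt_sat", maps.mt_sat), ("r1", maps.r1),
                                  ("r2star", maps.r2star),
                                  ("pd_star", maps.pd_star)):
                    write_volume(fit_dir / f"{sid}_{name}.nii",
                                 vol.astype(np.float32), voxel)
                (fit_dir / f"{sid}_qc.json").write_text(json.dumps(maps.qc))
            _mark_done(out, stage, h)
        run["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "vbq"
        t0 = time.time()
        vbq_dir = out / "vbq"
        params = list(config.stats.get("params", ANALYSIS_PARAMS))
        if not (resume and _stage_done(out, stage, h)):
            vbq_dir.mkdir(exist_ok=True)
            cohort_tpms = []
            for _, row in manifest.iterrows():
                sid = row["subject_id"]
                tpms = {c: read_volume(row[f"path_tpm_{c}"])[0]
                        for c in ("gm", "wm", "csf")}
                cohort_tpms.append(tpms)
                for p in params:
                    vol, _, _ = read_volume(fit_dir / f"{sid}_{p}.nii")
                    for tissue in ("gm", "wm"):
                        q, _ = tissue_weighted_smooth(
                            vol, tpms[tissue], config.vbq["fwhm_mm"], voxel,
                            config.vbq["support_eps"])
                        write_volume(vbq_dir / f"{sid}_{p}_{tissue}.nii",
                                     q.astype(np.float32), voxel)
            masks = make_masks(cohort_tpms, fwhm_mm=config.vbq["mask_fwhm_mm"],
                               voxel_size_mm=voxel,
                               threshold=config.vbq["threshold"])
            write_volume(vbq_dir / "mask_gm.nii", masks.gm.astype(np.uint8), voxel)
            write_volume(vbq_dir / "mask_wm.nii", masks.wm.astype(np.uint8), voxel)
            _mark_done(out, stage, h, n_excluded=masks.n_excluded)
        run["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "glm"
        t0 = time.time()
        glm_dir = out / "glm"
        if not (resume and _stage_done(out, stage, h)):
            glm_dir.mkdir(exist_ok=True)
            design = build_design(manifest)
            gm_mask = read_volume(vbq_dir / "mask_gm.nii")[0].astype(bool)
            wm_mask = read_volume(vbq_dir / "mask_wm.nii")[0].astype(bool)
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFE]))
            roi_rows = []
            for p in params:
                tail = AGE_TAILS.get(p, "two")
                for tissue, mask in (("gm", gm_mask), ("wm", wm_mask)):
                    stacked = np.stack([
                        read_volume(vbq_dir / f"{row['subject_id']}_{p}_{tissue}.nii")[0][mask]
                        for _, row in manifest.iterrows()
                    ])
                    usable = np.all(np.isfinite(stacked), axis=0)
                    data = stacked[:, usable].astype(float)
                    if data.shape[1] == 0:
                        continue
                    age_c = np.zeros(design.matrix.shape[1])
                    age_c[design.column_index("age")] = 1.0
                    method = config.stats.get("fwe_method")
                    if method:
                        res = fwe_correct(data, design, age_c, tail=tail,
                                          method=method,
                                          n_perm=config.stats["n_perm"],
                                          rng=rng, alpha=config.stats["alpha"])
                    else:
                        res = t_contrast(fit_voxelwise(data, design), age_c,
                                         tail=tail)
                    idx = np.flatnonzero(mask.ravel())[usable]
                    for suffix, arr in (("slope", res.effect), ("t", res.stat),
                                        ("p", res.p_uncorrected)):
                        vol = np.full(geometry.shape, np.nan, dtype=np.float32)
                        vol.ravel()[idx] = arr
                        write_volume(glm_dir / f"{p}_{tissue}_{suffix}.nii",
                                     vol, voxel)
                    slope_vol = np.full(geometry.shape, np.nan)
                    slope_vol.ravel()[idx] = res.effect
                    table = roi_slope_summary(
                        slope_vol, geometry.roi_volume, geometry.roi_table,
                        erode=config.stats.get("roi_erode", 2))
                    table.insert(0, "param", p)
                    table.insert(1, "analysis_tissue", tissue)
                    roi_rows.append(table)
            pd.concat(roi_rows, ignore_index=True).to_csv(
                glm_dir / "roi_slopes.csv", index=False)
            _mark_done(out, stage, h)
        run["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "report"
        t0 = time.time()
        if not (resume and _stage_done(out, stage, h)):
            report(out, config)
            _mark_done(out, stage, h)
        run["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
    except Exception as exc:
        run["failed_stage"] = stage
        (out / "run_manifest.json").write_text(json.dumps(run, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    run["complete"] = True
    (out / "run_manifest.json").write_text(json.dumps(run, indent=1))
    return run


def report(out_dir, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Recovery report: fitted per-ROI age slopes against generator truth.

    Writes ``report/recovery.csv`` and a human-readable summary; returns the
    table.  Regeneration from the same products is deterministic.
    """
    out = Path(out_dir)
    roi_path = out / "glm" / "roi_slopes.csv"
    if not roi_path.exists():
        raise FileNotFoundError("GLM stage products missing; run the pipeline first")
    config = config or PipelineConfig.from_yaml((out / "config.yaml").read_text())
    _, aging, geometry, _ = config.build()

    fitted = pd.read_csv(roi_path)
    truth = _truth_slope_table(aging, geometry)
    truth = truth.rename(columns={"param": "param_truth"})
    merged = fitted.merge(
        truth, left_on=["roi", "tissue", "param"],
        right_on=["roi", "tissue", "param_truth"], how="left",
    ).drop(columns=["param_truth"])
    merged["error"] = merged["mean_slope"] - merged["truth_slope"]

    rep_dir = out / "report"
    rep_dir.mkdir(exist_ok=True)
    merged.to_csv(rep_dir / "recovery.csv", index=False)
    lines = ["ROI age-slope recovery (fitted vs generator truth)", ""]
    for _, r in merged.iterrows():
        if r["analysis_tissue"] != r["tissue"] or r["n_voxels"] == 0:
            continue
        lines.append(
            f"{r['param']:>8s} {r['roi']:<16s} fitted {r['mean_slope']:+.5f}"
            f"  truth {r['truth_slope']:+.5f}  error {r['error']:+.5f} /yr"
        )
    (rep_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return merged
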