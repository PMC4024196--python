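"""Voxel-wise general linear model with permutation family-wise-error control.

The design follows the aging-study model: intercept, age (years, left
unstandardized so betas read units/year), sex, total intracranial volume and
scanner.  Sex and scanner are coded as centered +/- 0.5 indicators so the
intercept is the grand mean.  One- and two-tailed t contrasts, extra-sum-of-
squares F contrasts, and family-wise error control by the permutation
distribution of the volume-wise maximum statistic (Freedman-Lane residual
permutation under the reduced model) or by Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "DesignMatrix",
    "build_design",
    "GLMFit",
    "fit_voxelwise",
    "ContrastResult",
    "t_contrast",
    "f_contrast",
    "fwe_correct",
    "roi_slope_summary",
    "roi_difference_age_test",
]

DESIGN_COLUMNS = ("intercept", "age", "sex", "tiv", "scanner")


@dataclass
class DesignMatrix:
    """n_subjects x p design with named columns in fixed order."""

    matrix: np.ndarray
    columns: tuple[str, ...]

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def contrast(self, name: str, sign: float = 1.0) -> np.ndarray:
        c = np.zeros(len(self.columns))
        c[self.column_index(name)] = sign
        return c


def build_design(manifest: pd.DataFrame) -> DesignMatrix:
    """Design matrix (intercept, age, sex, TIV, scanner) from a cohort manifest.

    ``sex`` is coded M=+0.5 / F=-0.5 and ``scanner`` 2=+0.5 / 1=-0.5.
    Raises on rank deficiency, naming the offending column(s).
    """
    required = {"age", "sex", "scanner"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks covariates: {sorted(missing)}")
    if manifest[list(required | ({"tiv_mm3"} & set(manifest.columns)))].isna().any().any():
        raise ValueError("manifest contains missing covariate values")

    n = len(manifest)
    sex = manifest["sex"].map({"M": 0.5, "F": -0.5})
    if sex.isna().any():
        raise ValueError("sex column must contain only 'M'/'F'")
    scanner = manifest["scanner"].astype(int).map({1: -0.5, 2: 0.5})
    tiv = manifest["tiv_mm3"] if "tiv_mm3" in manifest else pd.Series(np.zeros(n))
    x = np.column_stack([
        np.ones(n),
        manifest["age"].to_numpy(float),
        sex.to_numpy(float),
        tiv.to_numpy(float),
        scanner.to_numpy(float),
    ])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        degenerate = [
            DESIGN_COLUMNS[j] for j in range(1, x.shape[1])
            if np.isclose(np.std(x[:, j]), 0.0)
        ]
        raise ValueError(
            "design matrix is rank deficient"
            + (f" (constant columns: {degenerate})" if degenerate else "")
        )
    return DesignMatrix(matrix=x, columns=DESIGN_COLUMNS)


@dataclass
class GLMFit:
    """Per-voxel OLS fit sharing one pseudo-inverse across voxels."""

    beta: np.ndarray          # p x V
    sigma2: np.ndarray        # V (residual variance, RSS/dof)
    dof: int
    design: DesignMatrix
    xtx_inv: np.ndarray
    zero_variance: np.ndarray  # V bool — flagged, fit still returned


def fit_voxelwise(data: np.ndarray, design: DesignMatrix) -> GLMFit:
    """OLS of ``data`` (n_subjects x n_voxels) on the design, vectorized."""
    y = np.asarray(data, dtype=float)
    x = design.matrix
    if y.ndim != 2 or y.shape[0] != x.shape[0]:
        raise ValueError("data must be n_subjects x n_voxels, matching the design")
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    rank = np.linalg.matrix_rank(x)
    dof = x.shape[0] - rank
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / dof
    return GLMFit(
        beta=beta, sigma2=sigma2, dof=dof, design=design,
        xtx_inv=np.linalg.inv(x.T @ x),
        zero_variance=np.isclose(sigma2, 0.0),
    )


@dataclass
class ContrastResult:
    """Voxel-wise contrast: effect size, statistic, p maps, significance mask."""

    effect: np.ndarray        # c @ beta (units/year for the age contrast)
    stat: np.ndarray          # t or F
    stat_name: str
    dof: tuple
    p_uncorrected: np.ndarray
    tail: str                 # "one-neg" | "one-pos" | "two" | "F"
    p_fwe: np.ndarray | None = None
    significant: np.ndarray | None = None
    alpha: float = 0.05
    info: dict = field(default_factory=dict)


def t_contrast(fit: GLMFit, contrast, tail="two") -> ContrastResult:
    """t statistic for a single contrast vector, with the chosen tail.

    ``tail='one-neg'`` tests effect < 0 (e.g. MT or R1 decline with age),
    ``'one-pos'`` effect > 0, ``'two'`` any difference.
    """
    c = np.asarray(contrast, dtype=float).ravel()
    if c.size != fit.beta.shape[0]:
        raise ValueError("contrast length must equal the number of design columns")
    effect = c @ fit.beta
    var = fit.sigma2 * float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(np.where(var > 0, var, 1.0)), np.nan)
    if tail == "one-neg":
        p = stats.t.cdf(t, fit.dof)
    elif tail == "one-pos":
        p = stats.t.sf(t, fit.dof)
    elif tail == "two":
        p = 2.0 * stats.t.sf(np.abs(t), fit.dof)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p = np.where(np.isfinite(t), p, np.nan)
    return ContrastResult(effect=effect, stat=t, stat_name="t",
                          dof=(fit.dof,), p_uncorrected=p, tail=tail)


def f_contrast(fit: GLMFit, contrast_rows) -> ContrastResult:
    """Extra-sum-of-squares F test for a multi-row contrast."""
    c = np.atleast_2d(np.asarray(contrast_rows, dtype=float))
    if c.shape[1] != fit.beta.shape[0]:
        raise ValueError("contrast row length must equal the number of design columns")
    k = np.linalg.matrix_rank(c)
    if k < c.shape[0]:
        raise ValueError("contrast rows are linearly dependent")
    cb = c @ fit.beta                       # k x V
    middle = np.linalg.inv(c @ fit.xtx_inv @ c.T)
    quad = np.einsum("kv,kl,lv->v", cb, middle, cb)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(fit.sigma2 > 0, quad / (k * np.where(fit.sigma2 > 0,
                                                          fit.sigma2, 1.0)), np.nan)
    p = np.where(np.isfinite(f), stats.f.sf(f, k, fit.dof), np.nan)
    return ContrastResult(effect=cb[0] if k == 1 else quad, stat=f, stat_name="F",
                          dof=(k, fit.dof), p_uncorrected=p, tail="F")


def _tail_scores(t, tail):
    if tail == "one-neg":
        return -t
    if tail == "one-pos":
        return t
    return np.abs(t)


def fwe_correct(data, design: DesignMatrix, contrast, tail="two",
                method="maxT-perm", n_perm=1000, rng=None,
                alpha=0.05) -> ContrastResult:
    """Family-wise-error-adjusted voxel-wise p values for a t contrast.

    ``maxT-perm`` builds the null distribution of the volume-wise maximum
    statistic by Freedman-Lane permutation: residuals of the reduced model
    (design without the tested column) are permuted, the reduced-model fit
    added back, and the full-model statistic recomputed; the adjusted p of a
    voxel is the rank of its observed score within the permutation maxima.
    ``bonferroni`` multiplies the uncorrected p by the voxel count.
    """
    y = np.asarray(data, dtype=float)
    fit = fit_voxelwise(y, design)
    result = t_contrast(fit, contrast, tail=tail)
    v = y.shape[1]
    if method == "bonferroni":
        result.p_fwe = np.clip(result.p_uncorrected * v, 0.0, 1.0)
        result.significant = result.p_fwe <= alpha
        result.alpha = alpha
        result.info = {"method": method, "n_voxels": v}
        return result
    if method != "maxT-perm":
        raise ValueError(f"unknown FWE method {method!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100 for maxT permutation")

    c = np.asarray(contrast, dtype=float).ravel()
    tested = np.flatnonzero(c)
    if tested.size != 1:
        raise ValueError("maxT permutation supports single-column t contrasts")
    rng = np.random.default_rng(rng)

    keep = np.setdiff1d(np.arange(design.matrix.shape[1]), tested)
    z = design.matrix[:, keep]
    pz = np.linalg.pinv(z)
    fitted_reduced = z @ (pz @ y)
    resid_reduced = y - fitted_reduced

    x = design.matrix
    pinv = np.linalg.pinv(x)
    xtx_inv_cc = float(c @ np.linalg.inv(x.T @ x) @ c)
    dof = x.shape[0] - np.linalg.matrix_rank(x)
    n = y.shape[0]

    obs = _tail_scores(result.stat, tail)
    max_null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        y_star = fitted_reduced + resid_reduced[perm]
        beta = pinv @ y_star
        resid = y_star - x @ beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = (c @ beta) / np.sqrt(sigma2 * xtx_inv_cc)
        scores = _tail_scores(t_star, tail)
        max_null[i] = np.nanmax(scores)

    exceed = (max_null[None, :] >= obs[:, None]).sum(axis=1)
    p_fwe = (1.0 + exceed) / (n_perm + 1.0)
    p_fwe = np.where(np.isfinite(obs), p_fwe, np.nan)
    result.p_fwe = np.maximum(p_fwe, result.p_uncorrected)
    result.significant = result.p_fwe <= alpha
    result.alpha = alpha
    result.info = {"method": method, "n_perm": n_perm, "n_voxels": v}
    return result


def roi_slope_summary(slope_map, roi_volume, roi_table, significant_mask=None,
                      erode=0) -> pd.DataFrame:
    """Per-ROI summary of voxel-wise annual-change estimates.

    Parameters
    ----------
    slope_map : ndarray
        Voxel-wise age-slope estimates (units/year), nan outside the analysis.
    roi_volume, roi_table : labeled atlas volume and label -> (name, tissue).
    significant_mask : optional bool ndarray — restrict to significant voxels.
    erode : int
        Binary-erode each ROI by this many voxels before summarizing, to keep
        clear of partial-volume mixing at ROI boundaries.
    """
    slope = np.asarray(slope_map, dtype=float)
    rows = []
    for lbl, (name, tissue) in sorted(roi_table.items()):
        mask = roi_volume == lbl
        if erode > 0:
            mask = ndimage.binary_erosion(mask, iterations=erode)
        if significant_mask is not None:
            mask = mask & significant_mask
        vals = slope[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows.append({"roi": name, "tissue": tissue, "n_voxels": 0,
                         "mean_slope": np.nan, "min_slope": np.nan,
                         "max_slope": np.nan})
        else:
            rows.append({"roi": name, "tissue": tissue, "n_voxels": int(vals.size),
                         "mean_slope": float(vals.mean()),
                         "min_slope": float(vals.min()),
                         "max_slope": float(vals.max())})
    return pd.DataFrame(rows)


def roi_difference_age_test(values_a, values_b, ages):
    """Test whether two ROIs age at different rates.

    Regresses the per-subject difference of ROI means on age and t-tests the
    age coefficient (two-tailed).  Returns ``(slope_difference, t, p)``.
    """
    d = np.asarray(values_a, dtype=float) - np.asarray(values_b, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if d.size != ages.size or d.size < 3:
        raise ValueError("need matched ROI means and ages for at least 3 subjects")
    res = stats.linregress(ages, d)
    t = res.slope / res.stderr
    p = 2.0 * stats.t.sf(abs(t), d.size - 2)
    return float(res.slope), float(t), float(p)
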