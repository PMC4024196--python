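"""Voxel-based quantification (VBQ) and morphometry (VBM) preprocessing.

VBQ smooths a quantitative map within a tissue class by weighting it with the
tissue probability before Gaussian smoothing and renormalizing by the smoothed
weights::

    q = G * (w p) / G * (w)

which preserves quantitative values within the class (a within-tissue-constant
map passes through unchanged) and confines mixing to tissue boundaries.  VBM
instead smooths the Jacobian-modulated gray-matter probability, a local-volume
measure.  Analysis masks assign each voxel to its maximal average tissue class
and exclude voxels where neither GM nor WM probability exceeds 20%, so every
analyzed voxel belongs to exactly one tissue subspace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "fwhm_to_sigma",
    "smooth_gaussian",
    "tissue_weighted_smooth",
    "modulate_and_smooth",
    "make_masks",
    "AnalysisMasks",
]


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian FWHM -> standard deviation: sigma = FWHM / sqrt(8 ln 2)."""
    return fwhm / math.sqrt(8.0 * math.log(2.0))


def smooth_gaussian(volume, fwhm_mm, voxel_size_mm, truncate=4.0):
    """Zero-padded separable Gaussian smoothing with FWHM given in mm."""
    voxel = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float),
                            (np.asarray(volume).ndim,))
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / v for v in voxel]
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma_vox,
                                   mode="constant", truncate=truncate)


def tissue_weighted_smooth(param_map, tissue_prob, fwhm_mm=3.0,
                           voxel_size_mm=1.0, support_eps=0.05):
    """Tissue-weighted smoothing of a quantitative parameter map.

    Parameters
    ----------
    param_map : ndarray
        Quantitative map p (values only meaningful where tissue_prob > 0).
    tissue_prob : ndarray
        Tissue probability w in [0, 1], same shape.
    fwhm_mm : float
        Isotropic Gaussian kernel FWHM [mm] (3 mm for VBQ).
    support_eps : float
        Minimum smoothed weight; voxels below are masked (nan).

    Returns
    -------
    smoothed : ndarray with nan outside support
    support : ndarray of bool
    """
    p = np.asarray(param_map, dtype=float)
    w = np.asarray(tissue_prob, dtype=float)
    if p.shape != w.shape:
        raise ValueError("parameter map and tissue probability shapes differ")
    if fwhm_mm <= 0:
        raise ValueError("FWHM must be positive")
    wp = np.where(w > 0, w * np.nan_to_num(p), 0.0)
    num = smooth_gaussian(wp, fwhm_mm, voxel_size_mm)
    den = smooth_gaussian(w, fwhm_mm, voxel_size_mm)
    support = den > support_eps
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(support, num / np.where(support, den, 1.0), np.nan)
    return q, support


def modulate_and_smooth(gm_prob, jacobian=None, fwhm_mm=6.0, voxel_size_mm=1.0):
    """VBM local gray-matter volume: smooth the Jacobian-modulated GM probability.

    Smoothing conserves total tissue mass up to boundary truncation.
    """
    gm = np.asarray(gm_prob, dtype=float)
    if jacobian is None:
        mod = gm
    else:
        j = np.asarray(jacobian, dtype=float)
        if j.shape != gm.shape:
            raise ValueError("Jacobian shape differs from GM probability shape")
        if np.any(j <= 0):
            raise ValueError("Jacobian determinants must be positive")
        mod = gm * j
    return smooth_gaussian(mod, fwhm_mm, voxel_size_mm)


@dataclass
class AnalysisMasks:
    """Disjoint GM / WM analysis masks plus the exclusion count."""

    gm: np.ndarray
    wm: np.ndarray
    excluded: np.ndarray
    mean_probs: dict[str, np.ndarray]

    @property
    def n_excluded(self) -> int:
        return int(np.count_nonzero(self.excluded))


def make_masks(cohort_tpms, jacobians=None, fwhm_mm=3.0, voxel_size_mm=1.0,
               threshold=0.20) -> AnalysisMasks:
    """Cohort-level explicit GM/WM analysis masks.

    Per subject and class, the (optionally Jacobian-modulated) tissue
    probability map is smoothed at 3 mm FWHM; the smoothed maps are averaged
    across subjects; each voxel is assigned to the class with maximal average
    probability (ties broken in the fixed order GM > WM > CSF), and excluded
    when neither the GM nor the WM average exceeds ``threshold`` (strict).

    Parameters
    ----------
    cohort_tpms : sequence of dict
        One ``{"gm":, "wm":, "csf":}`` dict of volumes per subject.
    jacobians : optional sequence of ndarray
        Per-subject Jacobian-determinant volumes (default 1 everywhere).
    """
    cohort_tpms = list(cohort_tpms)
    if not cohort_tpms:
        raise ValueError("at least one subject is required")
    classes = ("gm", "wm", "csf")
    sums = {c: None for c in classes}
    for i, tpms in enumerate(cohort_tpms):
        j = None if jacobians is None else np.asarray(jacobians[i], dtype=float)
        for c in classes:
            vol = np.asarray(tpms[c], dtype=float)
            if j is not None:
                if np.any(j <= 0):
                    raise ValueError("Jacobian determinants must be positive")
                vol = vol * j
            sm = smooth_gaussian(vol, fwhm_mm, voxel_size_mm)
            sums[c] = sm if sums[c] is None else sums[c] + sm
    n = len(cohort_tpms)
    mean_probs = {c: sums[c] / n for c in classes}

    stack = np.stack([mean_probs[c] for c in classes])  # argmax order = tie order
    assigned = np.argmax(stack, axis=0)
    excluded = (mean_probs["gm"] <= threshold) & (mean_probs["wm"] <= threshold)
    gm_mask = (assigned == 0) & ~excluded
    wm_mask = (assigned == 1) & ~excluded
    return AnalysisMasks(gm=gm_mask, wm=wm_mask, excluded=excluded,
                         mean_probs=mean_probs)
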