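"""Spoiled gradient-echo (FLASH) signal model and the four MPM map estimators.

The forward model comes in two variants:

* ``ernst`` — the exact spoiled steady-state signal
  ``S = A sin(a) (1 - E1) / (1 - cos(a) E1) exp(-TE R2*)``, ``E1 = exp(-TR R1)``;
* ``rational`` — its small-flip-angle / short-TR rational approximation
  ``S = A a TR R1 / (a^2/2 + TR R1 + d/100) exp(-TE R2*)``,
  with the MT saturation ``d`` expressed in percent units (p.u.): the
  percentage of longitudinal magnetization removed per TR by the off-resonance
  pre-pulse.

The estimators invert the rational model: a log-linear fit over the PD-weighted
echo train for R2*, the dual-flip-angle solution for R1 and apparent amplitude,
the MT-saturation equation, and a per-subject white-matter calibration of the
amplitude map to effective proton density (PD*).  All estimators are pure
per-voxel functions vectorized over flattened arrays; invalid voxels are masked
and counted, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import AcquisitionProtocol

__all__ = [
    "flash_signal",
    "fit_r2star_loglinear",
    "average_echoes",
    "estimate_r1_amplitude",
    "estimate_mt_sat",
    "calibrate_pd",
    "fit_parameter_maps",
    "ParameterMaps",
    "WM_PD_REFERENCE",
]

#: Literature white-matter water content (percent) the PD* map is calibrated to.
WM_PD_REFERENCE = 69.0


def flash_signal(amplitude, r1, r2star, alpha_rad, tr_s, te_s, mt_sat_pu=0.0,
                 model="rational"):
    """Steady-state spoiled FLASH signal at one echo time.

    Parameters
    ----------
    amplitude : array_like
        Signal amplitude A (arbitrary units; proton density times receive gain).
    r1, r2star : array_like
        Longitudinal / effective transverse relaxation rates [1/s].
    alpha_rad : array_like
        True excitation flip angle [rad] (nominal angle times the B1+ factor).
    tr_s, te_s : float
        Repetition / echo time [s].
    mt_sat_pu : array_like
        MT saturation [percent units]; only nonzero for MT-weighted simulation
        and only supported by the rational model.
    model : {"rational", "ernst"}
    """
    amplitude = np.asarray(amplitude, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2star = np.asarray(r2star, dtype=float)
    alpha = np.asarray(alpha_rad, dtype=float)
    delta = np.asarray(mt_sat_pu, dtype=float)
    if tr_s <= 0 or te_s < 0:
        raise ValueError("TR must be positive and TE non-negative")
    if np.any(alpha <= 0):
        raise ValueError("flip angle must be positive")
    if np.any(r1 < 0) or np.any(r2star < 0) or np.any(delta < 0):
        raise ValueError("relaxation rates and MT saturation must be non-negative")

    decay = np.exp(-te_s * r2star)
    if model == "rational":
        tr_r1 = tr_s * r1
        return amplitude * alpha * tr_r1 / (alpha**2 / 2.0 + tr_r1 + delta / 100.0) * decay
    if model == "ernst":
        if np.any(delta != 0):
            raise ValueError("the Ernst model does not support an MT saturation term")
        e1 = np.exp(-tr_s * r1)
        return amplitude * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1) * decay
    raise ValueError(f"unknown signal model {model!r}")


def fit_r2star_loglinear(echo_signals, te_s):
    """Voxel-wise R2* from ordinary least squares of log-signal on echo time.

    Parameters
    ----------
    echo_signals : ndarray, shape (..., n_echoes)
        Signal per voxel per echo (echoes along the last axis).
    te_s : sequence of float
        Echo times [s], matching the last axis.

    Returns
    -------
    r2star : ndarray
        Estimated R2* [1/s]; ``nan`` where the voxel could not be fit.
    log_intercept : ndarray
        Fitted log-signal at TE=0; ``nan`` where masked.
    valid : ndarray of bool
        Voxels with all echoes positive (required for the log transform).
    """
    s = np.asarray(echo_signals, dtype=float)
    te = np.asarray(te_s, dtype=float)
    if s.shape[-1] != te.size:
        raise ValueError("echo axis length does not match number of echo times")
    if te.size < 2:
        raise ValueError("at least two echoes are required for the R2* fit")

    valid = np.all(s > 0, axis=-1) & np.all(np.isfinite(s), axis=-1)
    logs = np.where(s > 0, np.log(np.where(s > 0, s, 1.0)), 0.0)

    # Closed-form simple OLS slope/intercept, vectorized over voxels.
    te_c = te - te.mean()
    denom = np.sum(te_c**2)
    slope = logs @ te_c / denom
    intercept = logs.mean(axis=-1) - slope * te.mean()

    r2star = np.where(valid, -slope, np.nan)
    intercept = np.where(valid, intercept, np.nan)
    return r2star, intercept, valid


def average_echoes(multiecho, te_s, n_common=None):
    """Arithmetic mean over the echo train; increases SNR at an effective TE.

    Parameters
    ----------
    multiecho : ndarray, shape (..., n_echoes)
    te_s : sequence of float
    n_common : int, optional
        Number of leading echoes to average (the prefix common to all
        weightings).  Defaults to all echoes.

    Returns
    -------
    averaged : ndarray, shape (...)
    effective_te_s : float
        Mean of the echo times used.
    """
    s = np.asarray(multiecho, dtype=float)
    te = np.asarray(te_s, dtype=float)
    if s.shape[-1] != te.size:
        raise ValueError("echo axis length does not match number of echo times")
    n = s.shape[-1] if n_common is None else int(n_common)
    if not 1 <= n <= s.shape[-1]:
        raise ValueError("n_common out of range")
    return s[..., :n].mean(axis=-1), float(te[:n].mean())


def estimate_r1_amplitude(s_pdw, s_t1w, protocol: AcquisitionProtocol, f_t=1.0):
    """Dual-flip-angle R1 and apparent amplitude from PDw / T1w averaged signals.

    Uses the rational-approximation solution with B1-corrected true flip angles
    ``a_w = alpha_w * f_T``::

        R1    = 1/2 * (S_T1w a_T1 / TR_T1 - S_PDw a_PD / TR_PD)
                    / (S_PDw / a_PD - S_T1w / a_T1)
        A_app = S_PDw (a_PD^2/2 + TR_PD R1) / (a_PD TR_PD R1)

    The denominator is positive whenever the two weightings respect the
    flip-angle ordering (T1w angle above the Ernst angle, PDw below); voxels
    violating it are masked.

    Returns ``(r1, a_app, valid)`` with invalid voxels set to ``nan``.
    """
    s_pd = np.asarray(s_pdw, dtype=float)
    s_t1 = np.asarray(s_t1w, dtype=float)
    f_t = np.asarray(f_t, dtype=float)
    if np.any(f_t <= 0) or not np.all(np.isfinite(f_t)):
        raise ValueError("B1+ factor f_T must be finite and positive")

    a_pd = protocol.pdw.flip_rad * f_t
    a_t1 = protocol.t1w.flip_rad * f_t
    tr_pd = protocol.pdw.tr_s
    tr_t1 = protocol.t1w.tr_s

    valid = (s_pd > 0) & (s_t1 > 0) & np.isfinite(s_pd) & np.isfinite(s_t1)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = s_t1 * a_t1 / tr_t1 - s_pd * a_pd / tr_pd
        den = s_pd / a_pd - s_t1 / a_t1
        r1 = 0.5 * num / den
        valid &= (den > 0) & (r1 > 0)
        a_app = s_pd * (a_pd**2 / 2.0 + tr_pd * r1) / (a_pd * tr_pd * r1)
    r1 = np.where(valid, r1, np.nan)
    a_app = np.where(valid, a_app, np.nan)
    return r1, a_app, valid


def estimate_mt_sat(s_mtw, a_app, r1, protocol: AcquisitionProtocol, f_t=1.0,
                    mt_b1_correct=False, clamp_negative=True):
    """MT saturation [p.u.]: percentage loss of magnetization per TR from the pre-pulse.

    ::

        d = 100 * [ (A_app a_MT / S_MTw - 1) * R1 * TR_MT - a_MT^2 / 2 ]

    ``a_MT`` is the readout flip angle of the MT-weighted acquisition.  The MT
    map is semi-quantitative; by default the readout angle is left uncorrected
    for B1+ (``mt_b1_correct=False``) since the saturation itself also depends
    on the local pre-pulse amplitude.

    Returns ``(mt_sat, valid, n_clamped)``.
    """
    s_mt = np.asarray(s_mtw, dtype=float)
    a_app = np.asarray(a_app, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    a_mt = protocol.mtw.flip_rad * (np.asarray(f_t, dtype=float) if mt_b1_correct else 1.0)
    tr_mt = protocol.mtw.tr_s

    valid = (s_mt > 0) & np.isfinite(s_mt) & np.isfinite(a_app) & np.isfinite(r1)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 100.0 * ((a_app * a_mt / s_mt - 1.0) * r1 * tr_mt - a_mt**2 / 2.0)
    delta = np.where(valid, delta, np.nan)
    n_clamped = 0
    if clamp_negative:
        neg = valid & (delta < 0)
        n_clamped = int(np.count_nonzero(neg))
        delta = np.where(neg, 0.0, delta)
    return delta, valid, n_clamped


def _poly_design(shape, mask_idx, order):
    """Monomial design (total degree <= order) in [-1, 1]-normalized voxel coords."""
    coords = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    grids = np.meshgrid(*coords, indexing="ij")
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((grids[0] ** i * grids[1] ** j * grids[2] ** k).ravel())
    design = np.column_stack(cols)
    return design[mask_idx], design


def calibrate_pd(a_app, wm_mask, receive_correct=True, poly_order=3):
    """Calibrate the apparent amplitude map to effective proton density PD* [% water].

    A low-order 3D polynomial is fit to log-amplitude within white matter and
    divided out to remove the smooth receive-sensitivity field; a single global
    scale then pins the subject's mean white-matter PD* to the literature value
    of 69% water content.  No correction for R2* decay is applied (hence the
    star in PD*).

    Parameters
    ----------
    a_app : ndarray (3D)
        Apparent amplitude map; must be positive within ``wm_mask``.
    wm_mask : ndarray of bool
        White-matter calibration mask.
    receive_correct : bool
        Fit-and-divide the polynomial receive-field estimate before scaling.
    poly_order : int
        Total degree of the 3D polynomial fit to ``log(a_app)`` in WM.

    Returns
    -------
    pd_star : ndarray
        Calibrated PD* map (nan where amplitude was invalid).
    info : dict
        ``scale`` and, when fit, the estimated ``receive_field``.
    """
    a = np.asarray(a_app, dtype=float)
    wm = np.asarray(wm_mask, dtype=bool)
    if a.ndim != 3:
        raise ValueError("a_app must be a 3D volume")
    if not wm.any():
        raise ValueError("white-matter calibration mask is empty")
    wm_vals = a[wm]
    if not np.all(np.isfinite(wm_vals)) or np.any(wm_vals <= 0):
        raise ValueError("amplitude must be positive and finite within the WM mask")

    info: dict = {}
    corrected = a.copy()
    if receive_correct:
        idx = np.flatnonzero(wm.ravel())
        x_wm, x_all = _poly_design(a.shape, idx, poly_order)
        coef, *_ = np.linalg.lstsq(x_wm, np.log(wm_vals), rcond=None)
        log_field = (x_all @ coef).reshape(a.shape)
        log_field -= log_field[wm].mean()  # keep the WM-mean amplitude level
        field = np.exp(log_field)
        corrected = a / field
        info["receive_field"] = field
    scale = WM_PD_REFERENCE / corrected[wm].mean()
    info["scale"] = float(scale)
    return corrected * scale, info


@dataclass
class ParameterMaps:
    """Estimated quantitative maps with a shared validity mask and QC counters."""

    r1: np.ndarray            # [1/s]
    r2star: np.ndarray        # [1/s]
    mt_sat: np.ndarray        # [p.u.]
    a_app: np.ndarray         # apparent amplitude at the effective TE (a.u.)
    a0: np.ndarray            # amplitude extrapolated to TE=0 using fitted R2*
    pd_star: np.ndarray | None  # [% water], None until calibrated
    valid: np.ndarray         # bool
    f_t: np.ndarray | float   # B1+ factor used
    effective_te_s: float
    qc: dict = field(default_factory=dict)


def fit_parameter_maps(pdw, t1w, mtw, protocol: AcquisitionProtocol, f_t=1.0,
                       wm_mask=None, mt_b1_correct=False,
                       receive_correct=True) -> ParameterMaps:
    """Full map estimation from the three multi-echo weighted volumes.

    Parameters
    ----------
    pdw, t1w, mtw : ndarray, shape (..., n_echoes)
        Weighted multi-echo volumes (echo along the last axis).  The PDw train
        may carry extra late echoes: all of them enter the R2* fit, but only
        the echo prefix common to the three weightings is averaged.
    protocol : AcquisitionProtocol
    f_t : B1+ transmit factor (scalar or map).
    wm_mask : optional bool ndarray — enables PD* calibration.
    """
    common = protocol.common_echoes_ms()
    n_common = len(common)

    r2star, _, r2_valid = fit_r2star_loglinear(pdw, protocol.pdw.te_s)
    n_clamped_r2 = int(np.count_nonzero(r2_valid & (r2star < 0)))
    r2star = np.where(r2_valid & (r2star < 0), 0.0, r2star)

    s_pd, te_eff = average_echoes(pdw, protocol.pdw.te_s, n_common)
    s_t1, _ = average_echoes(t1w, protocol.t1w.te_s, n_common)
    s_mt, _ = average_echoes(mtw, protocol.mtw.te_s, n_common)

    r1, a_app, r1_valid = estimate_r1_amplitude(s_pd, s_t1, protocol, f_t)
    mt_sat, mt_valid, n_clamped_mt = estimate_mt_sat(
        s_mt, a_app, r1, protocol, f_t, mt_b1_correct=mt_b1_correct
    )
    valid = r2_valid & r1_valid & mt_valid

    # Mean decay factor over the averaged echoes; divides out of A_app to give
    # the TE=0 amplitude.  PD* deliberately keeps the decay (effective TE).
    te_common = np.asarray(protocol.pdw.te_s[:n_common])
    with np.errstate(over="ignore", invalid="ignore"):
        mean_decay = np.exp(-np.multiply.outer(r2star, te_common)).mean(axis=-1)
    a0 = np.where(valid & (mean_decay > 0), a_app / mean_decay, np.nan)

    pd_star = None
    qc = {
        "n_voxels": int(np.prod(r2star.shape)),
        "n_valid": int(np.count_nonzero(valid)),
        "n_r2star_clamped": n_clamped_r2,
        "n_mt_clamped": n_clamped_mt,
    }
    maps = ParameterMaps(
        r1=np.where(valid, r1, np.nan),
        r2star=np.where(valid, r2star, np.nan),
        mt_sat=np.where(valid, mt_sat, np.nan),
        a_app=np.where(valid, a_app, np.nan),
        a0=a0,
        pd_star=pd_star,
        valid=valid,
        f_t=f_t,
        effective_te_s=te_eff,
        qc=qc,
    )
    if wm_mask is not None:
        wm = np.asarray(wm_mask, dtype=bool) & valid
        maps.pd_star, info = calibrate_pd(
            np.where(valid, maps.a_app, np.nan), wm, receive_correct=receive_correct
        )
        maps.qc["pd_scale"] = info["scale"]
    return maps
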