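"""Digital phantoms: labeled brain-like geometry and the cervical-cord cylinder.

The brain phantom is a nested-sphere layout — a CSF shell, a cortical gray
ribbon and a white-matter core — carrying named spherical regions of interest
that stand in for atlas-labeled anatomy (callosal genu/splenium, optic
radiation, deep gray nuclei, motor cortex).  Deep-gray ROIs override the
underlying tissue to GM, mirroring the basal ganglia sitting inside white
matter.  Tissue probability maps are derived from the labels with a light
sub-voxel blur to emulate partial volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROISpec",
    "GeometrySpec",
    "PhantomGeometry",
    "default_geometry_spec",
    "build_phantom",
    "build_cord_phantom",
    "CordPhantom",
]

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
TISSUE_NAMES = {CSF: "csf", GM: "gm", WM: "wm"}
TISSUE_CODES = {v: k for k, v in TISSUE_NAMES.items()}


@dataclass(frozen=True)
class ROISpec:
    name: str
    tissue: str               # parent tissue: "gm" or "wm"
    center_frac: tuple[float, float, float]  # voxel center as fraction of shape
    radius_frac: float        # sphere radius as fraction of min(shape)


@dataclass(frozen=True)
class GeometrySpec:
    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_radius_frac: float = 0.46    # outer CSF boundary
    csf_thickness_frac: float = 0.045
    cortex_thickness_frac: float = 0.065
    rois: tuple[ROISpec, ...] = ()
    edge_softness_voxels: float = 0.5  # half-width of the partial-volume ramp


@dataclass
class PhantomGeometry:
    """Labeled phantom: tissue labels, ROI labels, derived tissue probability maps."""

    label_volume: np.ndarray           # tissue code per voxel (0..3)
    roi_volume: np.ndarray             # 0 = none, >=10 named ROI labels
    voxel_size_mm: tuple[float, float, float]
    roi_table: dict[int, tuple[str, str]]   # label -> (name, parent tissue)
    tpms: dict[str, np.ndarray] = field(default_factory=dict)  # csf/gm/wm in [0,1]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.label_volume.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def roi_label(self, name: str) -> int:
        for lbl, (nm, _) in self.roi_table.items():
            if nm == name:
                return lbl
        raise KeyError(f"no ROI named {name!r}")

    def roi_mask(self, name: str) -> np.ndarray:
        return self.roi_volume == self.roi_label(name)


def default_geometry_spec(size: int = 48) -> GeometrySpec:
    """Desk-scale brain phantom (size^3 voxels at 1 mm isotropic) with six ROIs.

    ROI placement (fractions of the grid): callosal genu anteriorly and
    splenium posteriorly in deep WM, an optic-radiation-like WM tract,
    pallidum- and putamen-like deep-gray nuclei, and a motor-cortex patch on
    the dorsal cortical ribbon.
    """
    # ROI radii are kept large relative to the 3 mm smoothing kernel, as the
    # real structures are, so kernel-scale partial-volume mixing stays small
    r_roi = 6.0 / 48.0
    r_small = 5.0 / 48.0
    rois = (
        ROISpec("genu", "wm", (0.50, 0.71, 0.50), r_roi),
        ROISpec("splenium", "wm", (0.50, 0.29, 0.50), r_roi),
        ROISpec("optic_radiation", "wm", (0.34, 0.46, 0.40), r_small),
        ROISpec("pallidum", "gm", (0.70, 0.50, 0.54), r_roi),
        ROISpec("putamen", "gm", (0.30, 0.58, 0.58), r_small),
        ROISpec("motor_cortex", "gm", (0.50, 0.50, 0.93), 7.0 / 48.0),
    )
    return GeometrySpec(shape=(size, size, size), rois=rois)


def build_phantom(spec: GeometrySpec) -> PhantomGeometry:
    """Deterministically rasterize a geometry spec into labels, ROIs and TPMs."""
    shape = spec.shape
    gm_names = [r.name for r in spec.rois if r.tissue == "gm"]
    wm_names = [r.name for r in spec.rois if r.tissue == "wm"]
    if not gm_names or not wm_names:
        raise ValueError("geometry spec must define at least one WM ROI and one GM ROI")

    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    # slightly off-grid center: avoids degenerate radial shells (many voxels at
    # identical radius) so partial-volume fractions spread smoothly
    center = [(n - 1) / 2.0 + o for n, o in zip(shape, (0.137, 0.291, 0.413))]
    rho = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))

    n_min = min(shape)
    r_brain = spec.brain_radius_frac * n_min
    r_gm = r_brain - spec.csf_thickness_frac * n_min
    r_wm = r_gm - spec.cortex_thickness_frac * n_min

    labels = np.full(shape, BACKGROUND, dtype=np.int16)
    labels[rho <= r_brain] = CSF
    labels[rho <= r_gm] = GM
    labels[rho <= r_wm] = WM

    # soft (partial-volume) radial membership: linear ramp of half-width e at
    # each spherical boundary; a voxel whose center is inside gets >= 0.5
    e = max(spec.edge_softness_voxels, 1e-6)

    def soft(dist, radius):
        return np.clip((radius - dist) / (2.0 * e) + 0.5, 0.0, 1.0)

    brain_frac = soft(rho, r_brain)
    gm_outer = soft(rho, r_gm)
    wm_frac = soft(rho, r_wm)
    tpms = {
        "csf": brain_frac - gm_outer,
        "gm": gm_outer - wm_frac,
        "wm": wm_frac,
    }

    roi_volume = np.zeros(shape, dtype=np.int16)
    roi_table: dict[int, tuple[str, str]] = {}
    for i, roi in enumerate(spec.rois):
        lbl = 10 + i
        c = [f * (n - 1) for f, n in zip(roi.center_frac, shape)]
        d = np.sqrt(sum((g - ci) ** 2 for g, ci in zip(grids, c)))
        mask = d <= roi.radius_frac * n_min
        if roi.tissue == "gm":
            # deep-gray nuclei carve GM out of WM; cortical ROIs stay in the ribbon
            deep = mask & (labels == WM)
            if np.any(deep):
                frac = soft(d, roi.radius_frac * n_min)
                moved = frac * tpms["wm"]
                tpms["gm"] += moved
                tpms["wm"] -= moved
            mask &= labels >= GM
            labels[mask] = GM
        else:
            mask &= labels == WM
        if np.any(roi_volume[mask] != 0):
            raise ValueError(f"ROI {roi.name!r} overlaps a previously defined ROI")
        roi_volume[mask] = lbl
        roi_table[lbl] = (roi.name, roi.tissue)

    return PhantomGeometry(
        label_volume=labels,
        roi_volume=roi_volume,
        voxel_size_mm=spec.voxel_size_mm,
        roi_table=roi_table,
        tpms=tpms,
    )


@dataclass
class CordPhantom:
    """Tilted-cylinder cervical-cord phantom with analytic truth."""

    volume: np.ndarray                 # (nx, ny, n_slices) intensity image
    voxel_size_mm: tuple[float, float, float]
    radius_mm: float
    angulation_deg: float
    seed_voxel: tuple[int, int, int]   # a voxel on the cord axis in slice 0
    cord_mask: np.ndarray              # truth mask (pixel-center rasterization)

    @property
    def truth_area_mm2(self) -> float:
        """Cross-sectional area perpendicular to the cord axis."""
        return math.pi * self.radius_mm**2


def build_cord_phantom(radius_mm, angulation_deg=0.0, n_slices=15,
                       voxel_size_mm=(0.5, 0.5, 1.0), cord_intensity=1.0,
                       rim_intensity=0.25, background_intensity=0.05,
                       rim_thickness_mm=1.0, noise_sd=0.0, rng=None,
                       margin_mm=6.0) -> CordPhantom:
    """Cylinder of given radius tilted about the left-right (x) axis.

    The cord runs along +z (caudal to rostral); tilting by ``angulation_deg``
    shears the center line in y.  Intensities: bright cord, darker CSF-like
    rim, dim background.  The in-plane cross-section is an ellipse of area
    ``pi r^2 / cos(angulation)``; the perpendicular (truth) area is ``pi r^2``.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    if not 0 <= angulation_deg < 45:
        raise ValueError("angulation must lie in [0, 45) degrees")
    dx, dy, dz = voxel_size_mm
    theta = math.radians(angulation_deg)
    half_y = (radius_mm + rim_thickness_mm) / math.cos(theta)
    drift = math.tan(theta) * (n_slices - 1) * dz
    nx = int(round(2 * (radius_mm + rim_thickness_mm + margin_mm) / dx))
    ny = int(round((2 * half_y + drift + 2 * margin_mm) / dy))
    cx = (nx - 1) / 2.0 * dx
    cy0 = half_y + margin_mm

    x = (np.arange(nx) * dx)[:, None, None]
    y = (np.arange(ny) * dy)[None, :, None]
    z = (np.arange(n_slices) * dz)[None, None, :]
    yc = cy0 + math.tan(theta) * z
    if float(yc.max()) + half_y > ny * dy:
        raise ValueError("cylinder exceeds volume bounds; increase margin")

    # perpendicular distance from the tilted axis (axis direction (0, sin, cos))
    ux, uy, uz = 0.0, math.sin(theta), math.cos(theta)
    rx, ry = x - cx, y - yc
    dot = ry * uy  # rz = 0 in each slice plane when measured at that z
    d2 = rx**2 + ry**2 - dot**2
    d = np.sqrt(np.maximum(d2, 0.0))

    vol = np.full((nx, ny, n_slices), background_intensity, dtype=float)
    rim = d <= radius_mm + rim_thickness_mm
    cord = d <= radius_mm
    vol[rim] = rim_intensity
    vol[cord] = cord_intensity
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        vol = vol + rng.normal(0.0, noise_sd, vol.shape)

    seed = (int(round(cx / dx)), int(round(cy0 / dy)), 0)
    return CordPhantom(
        volume=vol,
        voxel_size_mm=tuple(voxel_size_mm),
        radius_mm=float(radius_mm),
        angulation_deg=float(angulation_deg),
        seed_voxel=seed,
        cord_mask=cord,
    )
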