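"""Surgical-planning quantities derived from the perfusion model.

Given the territory partition, the tumor mask and the anatomy masks, this
module answers the questions a clamp plan needs: which segmental arteries
must be clamped (those whose territory the tumor enters or abuts), how many
lobar branches feed the tumor, how large the tumor-parenchyma contact
surface is, and the R/E/N/L nephrometry components that grade tumor
complexity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.filters import gaussian
from skimage.measure import marching_cubes

from .territories import TerritoryMap
from .volume import LabelVolume

__all__ = [
    "RenalComponents",
    "PlanReport",
    "determine_target_segments",
    "count_feeding_lobar",
    "compute_csa",
    "nephrometry",
    "build_plan_report",
]


@dataclass(frozen=True)
class RenalComponents:
    """R/E/N/L nephrometry components and their point values.

    Points follow the standard nephrometry tables: Radius (maximal tumor
    diameter, cm) 1/2/3 for <=4 / 4-7 / >=7; Exophytic fraction 1/2/3 for
    >=50% exophytic / <50% / entirely endophytic; Nearness to the collecting
    system or sinus (mm) 1/2/3 for >=7 / 4-7 / <=4; Location relative to the
    polar lines 1/2/3 for entirely polar / crossing a polar line / >50%
    between the polar lines.  The anterior/posterior descriptor carries no
    points.
    """

    radius_cm: float
    exophytic_fraction: float
    nearness_mm: float
    location_category: str

    @property
    def R_points(self) -> int:
        if self.radius_cm <= 4:
            return 1
        return 2 if self.radius_cm < 7 else 3

    @property
    def E_points(self) -> int:
        if self.exophytic_fraction >= 0.5:
            return 1
        return 2 if self.exophytic_fraction > 0 else 3

    @property
    def N_points(self) -> int:
        if self.nearness_mm >= 7:
            return 1
        return 2 if self.nearness_mm > 4 else 3

    @property
    def L_points(self) -> int:
        return {
            "entirely_polar": 1,
            "crosses_polar_line": 2,
            "mostly_between_polar_lines": 3,
        }[self.location_category]

    @property
    def total(self) -> int:
        return self.R_points + self.E_points + self.N_points + self.L_points

    def to_dict(self) -> dict:
        return {
            "radius_cm": self.radius_cm,
            "exophytic_fraction": self.exophytic_fraction,
            "nearness_mm": self.nearness_mm,
            "location_category": self.location_category,
            "R_points": self.R_points,
            "E_points": self.E_points,
            "N_points": self.N_points,
            "L_points": self.L_points,
            "total": self.total,
        }


@dataclass
class PlanReport:
    """Everything the clamp plan reports for one tumor."""

    target_segment_ids: list[int]
    feeding_lobar_ids: list[int]
    csa_cm2: float
    csa_method: str
    renal: RenalComponents
    abut_margin_mm: float

    @property
    def n_target_segments(self) -> int:
        return len(self.target_segment_ids)

    @property
    def n_feeding_lobar(self) -> int:
        return len(self.feeding_lobar_ids)

    def to_json(self) -> str:
        return json.dumps(
            {
                "target_segment_ids": self.target_segment_ids,
                "n_target_segments": self.n_target_segments,
                "feeding_lobar_ids": self.feeding_lobar_ids,
                "n_feeding_lobar": self.n_feeding_lobar,
                "csa_cm2": self.csa_cm2,
                "csa_method": self.csa_method,
                "abut_margin_mm": self.abut_margin_mm,
                "renal": self.renal.to_dict(),
            },
            indent=1,
            sort_keys=True,
        )


# ------------------------------------------------------- target determination


def _dilate_mm(mask: np.ndarray, spacing, margin_mm: float) -> np.ndarray:
    if margin_mm <= 0 or not mask.any():
        return mask
    d = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return d <= margin_mm


def _hit_ids(label_vol: LabelVolume, tumor: LabelVolume, margin_mm: float) -> list[int]:
    label_vol.require_aligned(tumor, "territory map/tumor")
    probe = _dilate_mm(tumor.binarize(), tumor.spacing, margin_mm)
    hit = label_vol.data[probe]
    ids = sorted(int(i) for i in np.unique(hit[hit > 0]))
    if not ids:
        raise ValueError(
            "tumor does not touch any territory (even after dilation); "
            "clamping guidance is undefined"
        )
    return ids


def determine_target_segments(
    tmap: TerritoryMap, tumor: LabelVolume, abut_margin_mm: float = 0.0
) -> list[int]:
    """Segment ids whose perfusion territory the tumor enters or abuts.

    The tumor mask is dilated by ``abut_margin_mm`` (physical mm) before the
    territory lookup, so tumors that abut but do not enter a territory still
    mark its artery as a clamping target.
    """
    return _hit_ids(tmap.segmental, tumor, abut_margin_mm)


def count_feeding_lobar(
    tmap: TerritoryMap, tumor: LabelVolume, abut_margin_mm: float = 0.0
) -> list[int]:
    """Lobar ids whose (finer) territory the tumor enters or abuts."""
    return _hit_ids(tmap.lobar, tumor, abut_margin_mm)


# ------------------------------------------------------------------------ CSA


def compute_csa(
    kidney: LabelVolume,
    tumor: LabelVolume,
    method: str = "mesh",
    smooth_sigma_vox: float = 1.0,
) -> float:
    """Contact surface area between tumor and kidney parenchyma, in cm².

    ``mesh`` (default, the area-element estimator): triangulate the tumor
    surface at the 0.5 iso-level of its Gaussian-smoothed indicator and sum
    the areas of triangles whose centroids fall inside the kidney mask.
    ``voxel_face``: sum the spacing-weighted areas of voxel faces between
    tumor-inside-kidney voxels and kidney-but-not-tumor voxels — a staircase
    upper bound on the smooth interface area.
    """
    kidney.require_aligned(tumor, "kidney/tumor")
    kid = kidney.binarize()
    tum = tumor.binarize()
    if not (tum & kid).any():
        return 0.0
    sp = np.asarray(tumor.spacing)
    if method == "mesh":
        f = gaussian(tum.astype(float), sigma=smooth_sigma_vox, preserve_range=True)
        f = np.pad(f, 1, mode="constant")
        verts, faces, _, _ = marching_cubes(f, level=0.5, spacing=tuple(sp))
        verts = verts - sp  # undo the one-voxel pad
        tri = verts[faces]
        centroids = tri.mean(axis=1)
        idx = np.rint(centroids / sp).astype(int)
        idx = np.clip(idx, 0, np.asarray(kid.shape) - 1)
        inside = kid[idx[:, 0], idx[:, 1], idx[:, 2]]
        v1 = tri[:, 1] - tri[:, 0]
        v2 = tri[:, 2] - tri[:, 0]
        areas = 0.5 * np.linalg.norm(np.cross(v1, v2), axis=1)
        return float(areas[inside].sum() / 100.0)  # mm^2 -> cm^2
    if method == "voxel_face":
        inside = tum & kid
        other = kid & ~tum
        total = 0.0
        face_area = [sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1]]
        for ax in range(3):
            a = np.swapaxes(inside, 0, ax)
            b = np.swapaxes(other, 0, ax)
            total += float(((a[:-1] & b[1:]) | (b[:-1] & a[1:])).sum()) * face_area[ax]
        return total / 100.0
    raise ValueError(f"unknown CSA method {method!r}")


# ---------------------------------------------------------------- nephrometry


def _tumor_max_diameter_mm(tum: np.ndarray, spacing) -> float:
    surf = tum & ~ndimage.binary_erosion(tum)
    pts = np.argwhere(surf) * np.asarray(spacing)
    if len(pts) < 2:
        return 0.0
    try:
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    except QhullError:
        pass  # degenerate (flat) tumors: brute-force over surface voxels
    return float(pdist(pts).max())


def nephrometry(
    kidney: LabelVolume,
    sinus_ucs: LabelVolume,
    tumor: LabelVolume,
    long_axis: Optional[np.ndarray] = None,
) -> RenalComponents:
    """Compute the R/E/N/L components from the three masks.

    The kidney long axis defaults to the first principal axis of the kidney
    mask; the polar lines are the planes normal to it at the extremes of the
    sinus/collecting-system extent, the convention of the nephrometry
    literature.
    """
    kidney.require_aligned(sinus_ucs, "kidney/sinus")
    kidney.require_aligned(tumor, "kidney/tumor")
    kid, sin, tum = kidney.binarize(), sinus_ucs.binarize(), tumor.binarize()
    if not tum.any():
        raise ValueError("empty tumor mask")
    if not sin.any():
        raise ValueError("empty sinus/collecting-system mask; nearness undefined")
    if not kid.any():
        raise ValueError("empty kidney mask")
    sp = np.asarray(tumor.spacing)

    diameter_cm = _tumor_max_diameter_mm(tum, sp) / 10.0

    frac_out = float((tum & ~kid).sum() / tum.sum())

    if (tum & sin).any():
        nearness = 0.0
    else:
        d = ndimage.distance_transform_edt(~sin, sampling=sp)
        nearness = float(d[tum].min())

    if long_axis is None:
        coords = np.argwhere(kid) * sp
        coords = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(coords, full_matrices=False)
        long_axis = vt[0]
    u = np.asarray(long_axis, float)
    u = u / np.linalg.norm(u)
    t_sin = (np.argwhere(sin) * sp) @ u
    lo, hi = float(t_sin.min()), float(t_sin.max())
    t_tum = (np.argwhere(tum) * sp) @ u
    if t_tum.max() < lo or t_tum.min() > hi:
        cat = "entirely_polar"
    elif float(((t_tum >= lo) & (t_tum <= hi)).mean()) > 0.5:
        cat = "mostly_between_polar_lines"
    else:
        cat = "crosses_polar_line"

    return RenalComponents(
        radius_cm=diameter_cm,
        exophytic_fraction=frac_out,
        nearness_mm=nearness,
        location_category=cat,
    )


def build_plan_report(
    tmap: TerritoryMap,
    kidney: LabelVolume,
    sinus_ucs: LabelVolume,
    tumor: LabelVolume,
    abut_margin_mm: float = 1.0,
    csa_method: str = "mesh",
) -> PlanReport:
    """Full clamp plan for one tumor: targets, feeding arteries, CSA, R/E/N/L."""
    targets = determine_target_segments(tmap, tumor, abut_margin_mm)
    feeding = count_feeding_lobar(tmap, tumor, abut_margin_mm)
    parents = {tmap.lobar_parent[l] for l in feeding}
    assert parents <= set(targets), "feeding lobar parents must be target segments"
    return PlanReport(
        target_segment_ids=targets,
        feeding_lobar_ids=feeding,
        csa_cm2=compute_csa(kidney, tumor, method=csa_method),
        csa_method=csa_method,
        renal=nephrometry(kidney, sinus_ucs, tumor),
        abut_margin_mm=abut_margin_mm,
    )
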