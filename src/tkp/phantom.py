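"""Synthetic kidney phantom: parenchyma, sinus, rooted artery tree and tumor.

The phantom emulates the structures a contrast-CT segmentation pipeline hands
to the perfusion model: an ellipsoidal kidney with a hilar sinus wedge, a
rooted arterial tree that enters at the hilum, splits into a known number of
segmental branches and bifurcates recursively below them (child radii follow
Murray's law), and a spherical tumor placed at a configurable depth relative
to the kidney surface.  Because the branch-level ground truth (centerlines,
generations, segmental membership) is retained, every downstream stage —
skeletonization, tree labeling, territory partition, clamp simulation,
nephrometry — can be validated without any imaging data.

All stochastic draws come from one seeded generator, so a
:class:`PhantomBundle` is a pure function of its :class:`PhantomParams`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .volume import LabelVolume, nearest_seed_assignment, write_volume

__all__ = [
    "PhantomParams",
    "Branch",
    "TreeTruth",
    "PhantomBundle",
    "grow_artery_tree",
    "rasterize_phantom",
    "generate_phantom",
    "write_phantom",
]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and sampling parameters of the synthetic kidney.

    Lengths are millimetres; the kidney long axis lies along the first grid
    axis and the hilum faces +y.  ``n_segmental`` first-generation branches
    leave the trunk tip; each then bifurcates ``branch_depth`` more times with
    opening angle ``branching_angle_deg`` jittered by ``angle_jitter_deg``.
    Child radii follow ``r_child = r_parent * 2**(-1/radius_decay_exponent)``
    (Murray's law at exponent 3).
    """

    grid_shape: tuple[int, int, int] = (100, 72, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kidney_semi_axes: tuple[float, float, float] = (40.0, 26.0, 22.0)
    sinus_fraction: float = 0.35
    n_segmental: int = 3
    branch_depth: int = 2
    branching_angle_deg: float = 50.0
    angle_jitter_deg: float = 8.0
    radius_root: float = 3.0
    radius_decay_exponent: float = 3.0
    tumor_radius: float = 12.0
    tumor_center_offset: float = -4.0
    tumor_direction: Optional[tuple[float, float, float]] = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_segmental < 1:
            raise ValueError("n_segmental must be >= 1")
        if self.branch_depth < 0:
            raise ValueError("branch_depth must be >= 0")
        if self.radius_root <= 0 or self.tumor_radius <= 0:
            raise ValueError("radii must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass
class Branch:
    """One straight branch of the ground-truth tree."""

    id: int
    parent: Optional[int]
    generation: int  # 0 = trunk, 1 = segmental, 2 = lobar, deeper below
    segment_id: Optional[int]  # inherited from the generation-1 ancestor
    lobar_id: Optional[int]  # inherited from the generation-2 ancestor
    start: np.ndarray  # mm
    end: np.ndarray  # mm
    radius: float  # mm

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "parent": self.parent,
            "generation": self.generation,
            "segment_id": self.segment_id,
            "lobar_id": self.lobar_id,
            "polyline_mm": [list(map(float, self.start)), list(map(float, self.end))],
            "radius_mm": float(self.radius),
            "length_mm": self.length,
        }


@dataclass
class TreeTruth:
    """Ground-truth branch list plus the hilar root hint (mm)."""

    branches: list[Branch]
    root_hint: np.ndarray

    @property
    def segment_ids(self) -> list[int]:
        return sorted({b.segment_id for b in self.branches if b.segment_id is not None})

    @property
    def lobar_ids(self) -> list[int]:
        return sorted({b.lobar_id for b in self.branches if b.lobar_id is not None})

    def lobar_to_segment(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for b in self.branches:
            if b.generation == 2:
                out[b.lobar_id] = b.segment_id
        return out

    def leaves(self) -> list[Branch]:
        parents = {b.parent for b in self.branches if b.parent is not None}
        return [b for b in self.branches if b.id not in parents]

    def to_json(self) -> str:
        return json.dumps(
            {
                "root_hint_mm": list(map(float, self.root_hint)),
                "branches": [b.to_dict() for b in self.branches],
            },
            indent=1,
            sort_keys=True,
        )


def _rotate(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    th = np.deg2rad(angle_deg)
    return (
        v * np.cos(th)
        + np.cross(axis, v) * np.sin(th)
        + axis * np.dot(axis, v) * (1 - np.cos(th))
    )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _inside_shrunk_ellipsoid(p, center, semi, margin) -> bool:
    s = np.maximum(np.asarray(semi) - margin, 1e-3)
    q = (np.asarray(p) - center) / s
    return float(q @ q) <= 1.0


def grow_artery_tree(params: PhantomParams) -> TreeTruth:
    """Grow the ground-truth arterial tree inside the kidney ellipsoid.

    The trunk enters from outside the hilum (+y) and ends inside the sinus;
    exactly ``n_segmental`` generation-1 branches fan out from its tip, and
    each bifurcates ``branch_depth`` further times.  Branch endpoints are kept
    inside the ellipsoid shrunk by the branch radius, so the rasterized tubes
    of generation >= 1 cannot poke outside the kidney.  Identical seeds give
    identical trees.
    """
    rng = np.random.default_rng([int(params.rng_seed) % (2**31), 0])
    shape = np.asarray(params.grid_shape)
    sp = np.asarray(params.spacing)
    center = (shape - 1) * sp / 2.0
    a, b, c = params.kidney_semi_axes
    semi = np.asarray([a, b, c], float)

    entry = center + np.array([0.0, b + 6.0, 0.0])
    trunk_tip = center + np.array([0.0, 0.32 * b, 0.0])
    decay = 2.0 ** (-1.0 / params.radius_decay_exponent)

    branches: list[Branch] = [
        Branch(0, None, 0, None, None, entry, trunk_tip, params.radius_root)
    ]
    next_id = 1
    next_lobar = 1

    n = params.n_segmental
    fan = np.linspace(-68.0, 68.0, n) if n > 1 else np.array([0.0])
    z_alt = [((-1) ** i) * (0.35 if n > 1 else 0.0) for i in range(n)]

    def place(start, direction, length, radius, parent, gen, seg, lob):
        nonlocal next_id
        # bend toward the kidney center and/or shrink until the endpoint
        # clears the boundary by the tube radius
        inward = _unit(center - start) if np.linalg.norm(center - start) > 1e-9 else direction
        for bend in (0.0, 0.2, 0.4, 0.6, 0.8):
            d = _unit(direction * (1 - bend) + inward * bend)
            trial = length
            for attempt in range(6):
                end = start + d * trial
                if _inside_shrunk_ellipsoid(end, center, semi, radius + 0.25):
                    br = Branch(next_id, parent, gen, seg, lob, start, end, radius)
                    branches.append(br)
                    next_id += 1
                    return br
                trial *= 0.8
        raise ValueError(
            "geometry overflow: branch cannot fit inside the kidney at this depth"
        )

    def bifurcate(parent_branch: Branch, depth_left: int):
        nonlocal next_lobar
        if depth_left <= 0:
            return
        d = _unit(parent_branch.end - parent_branch.start)
        for attempt in range(8):
            u = rng.normal(size=3)
            axis = np.cross(d, u)
            if np.linalg.norm(axis) > 1e-6:
                axis = _unit(axis)
                break
        else:
            raise ValueError("could not find a bifurcation axis")
        half = params.branching_angle_deg / 2.0
        r_child = parent_branch.radius * decay
        length = 0.62 * parent_branch.length
        for sgn in (+1, -1):
            ang = sgn * (half + rng.uniform(-params.angle_jitter_deg, params.angle_jitter_deg))
            cd = _unit(_rotate(d, axis, ang))
            gen = parent_branch.generation + 1
            lob = parent_branch.lobar_id
            if gen == 2:
                lob = next_lobar
                next_lobar += 1
            child = place(
                parent_branch.end, cd, length, r_child,
                parent_branch.id, gen, parent_branch.segment_id, lob,
            )
            bifurcate(child, depth_left - 1)

    r_seg = params.radius_root * decay
    seg_len = 0.45 * a
    for i in range(n):
        phi = np.deg2rad(fan[i] + rng.uniform(-params.angle_jitter_deg, params.angle_jitter_deg))
        base = np.array([np.sin(phi), -0.75 * np.cos(phi), z_alt[i]])
        d = _unit(base)
        lob = None
        if params.branch_depth == 0:
            # leaf segmental branches double as their own lobar vessels
            lob = next_lobar
            next_lobar += 1
        seg_branch = place(trunk_tip, d, seg_len, r_seg, 0, 1, i + 1, lob)
        bifurcate(seg_branch, params.branch_depth)

    return TreeTruth(branches=branches, root_hint=entry.copy())


# ------------------------------------------------------------- rasterization


def _coord_grids(shape, spacing):
    xs = [np.arange(shape[i]) * spacing[i] for i in range(3)]
    return np.meshgrid(*xs, indexing="ij", sparse=True)


def _capsule_mask(shape, spacing, p0, p1, radius):
    """Boolean mask of voxel centers within `radius` of segment p0-p1."""
    sp = np.asarray(spacing)
    lo = np.maximum(np.floor((np.minimum(p0, p1) - radius) / sp).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((np.maximum(p0, p1) + radius) / sp).astype(int) + 2, shape)
    if np.any(lo >= hi):
        return None, None
    sub = tuple(slice(lo[i], hi[i]) for i in range(3))
    xs = [np.arange(lo[i], hi[i]) * sp[i] for i in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij", sparse=True)
    d = p1 - p0
    L2 = float(d @ d)
    px, py, pz = X - p0[0], Y - p0[1], Z - p0[2]
    if L2 < 1e-12:
        t = 0.0
        dist2 = px**2 + py**2 + pz**2
    else:
        t = (px * d[0] + py * d[1] + pz * d[2]) / L2
        t = np.clip(t, 0.0, 1.0)
        dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
    return sub, dist2 <= radius * radius


@dataclass
class PhantomBundle:
    """Aligned phantom volumes plus the ground-truth tree."""

    kidney: LabelVolume
    sinus_ucs: LabelVolume
    vessels: LabelVolume
    tumor: LabelVolume
    truth: TreeTruth
    params: PhantomParams
    entry_corridor: LabelVolume  # trunk capsule; vessel voxels outside kidney+sinus

    def parenchyma(self) -> LabelVolume:
        """Kidney minus sinus/collecting system minus vessel voxels."""
        m = self.kidney.binarize() & ~self.sinus_ucs.binarize() & ~self.vessels.binarize()
        return self.kidney.like(m.astype(np.int32))

    def centerline_volume(self) -> LabelVolume:
        """Truth centerlines rasterized to voxels, labeled branch id + 1."""
        out = np.zeros(self.kidney.shape, dtype=np.int32)
        sp = np.asarray(self.kidney.spacing)
        step = 0.25 * float(sp.min())
        for b in self.truth.branches:
            L = b.length
            npts = max(int(np.ceil(L / step)) + 1, 2)
            ts = np.linspace(0.0, 1.0, npts)
            pts = b.start[None, :] + ts[:, None] * (b.end - b.start)[None, :]
            ijk = np.rint(pts / sp).astype(int)
            ok = np.all((ijk >= 0) & (ijk < np.asarray(self.kidney.shape)), axis=1)
            ijk = ijk[ok]
            out[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = b.id + 1
        return self.kidney.like(out)

    def painted_vessels_truth(self, level: str = "lobar") -> LabelVolume:
        """Vessel voxels labeled by the truth tree at segmental or lobar level.

        Each vessel voxel takes the branch label of its nearest truth
        centerline voxel and is then mapped to that branch's segment or lobar
        id; branches without an id at the requested level map to 0.
        """
        cl = self.centerline_volume()
        by_branch = nearest_seed_assignment(cl, self.vessels)
        lut = np.zeros(max(b.id for b in self.truth.branches) + 2, dtype=np.int32)
        for b in self.truth.branches:
            val = b.segment_id if level == "segmental" else b.lobar_id
            lut[b.id + 1] = 0 if val is None else val
        return self.kidney.like(lut[by_branch.data])


def rasterize_phantom(params: PhantomParams, truth: TreeTruth) -> PhantomBundle:
    """Voxelize the phantom onto its grid.

    Kidney = ellipsoid; sinus = hilar wedge spanning ``sinus_fraction`` of the
    long axis; vessels = union of capsules around the truth centerlines;
    tumor = sphere at ``tumor_center_offset`` mm outside (+) or inside (-)
    the kidney surface along ``tumor_direction``.
    """
    shape = tuple(params.grid_shape)
    sp = np.asarray(params.spacing)
    center = (np.asarray(shape) - 1) * sp / 2.0
    a, b, c = params.kidney_semi_axes
    X, Y, Z = _coord_grids(shape, sp)

    kidney = (
        ((X - center[0]) / a) ** 2 + ((Y - center[1]) / b) ** 2 + ((Z - center[2]) / c) ** 2
    ) <= 1.0

    half_extent = params.sinus_fraction * a  # half-width of the wedge along the long axis
    sinus = (
        kidney
        & (Y > center[1] + 0.30 * b)
        & ((((X - center[0]) / half_extent) ** 2 + ((Z - center[2]) / (0.6 * c)) ** 2) <= 1.0)
    )

    vessels = np.zeros(shape, dtype=bool)
    corridor = np.zeros(shape, dtype=bool)
    for br in truth.branches:
        if br.radius < 0.5 * float(sp.min()):
            warnings.warn(
                f"branch {br.id} radius {br.radius:.2f} mm below half the voxel size",
                stacklevel=2,
            )
        sub, m = _capsule_mask(shape, sp, br.start, br.end, br.radius)
        if sub is not None:
            vessels[sub] |= m
            if br.generation == 0:
                corridor[sub] |= m

    # tumor center: surface point along tumor_direction, pushed outward by offset
    rng = np.random.default_rng([int(params.rng_seed) % (2**31), 1])
    if params.tumor_direction is None:
        d = np.array(
            [rng.uniform(-0.8, 0.8), rng.uniform(-1.0, -0.25), rng.uniform(-0.7, 0.7)]
        )
    else:
        d = np.asarray(params.tumor_direction, float)
    d = _unit(d)
    # t such that center + t*d lies on the ellipsoid
    t = 1.0 / np.sqrt((d[0] / a) ** 2 + (d[1] / b) ** 2 + (d[2] / c) ** 2)
    surface = center + t * d
    grad = 2 * (surface - center) / np.asarray([a, b, c]) ** 2
    normal = _unit(grad)
    tcenter = surface + params.tumor_center_offset * normal
    tumor = (
        (X - tcenter[0]) ** 2 + (Y - tcenter[1]) ** 2 + (Z - tcenter[2]) ** 2
    ) <= params.tumor_radius**2

    if not np.any(tumor & kidney):
        raise ValueError("tumor does not intersect the kidney mask")

    def vol(m):
        return LabelVolume(m.astype(np.int32), tuple(sp))

    return PhantomBundle(
        kidney=vol(kidney),
        sinus_ucs=vol(sinus),
        vessels=vol(vessels),
        tumor=vol(tumor),
        truth=truth,
        params=params,
        entry_corridor=vol(corridor),
    )


def generate_phantom(params: PhantomParams | None = None, **kw) -> PhantomBundle:
    """Grow and rasterize a phantom in one call."""
    if params is None:
        params = PhantomParams(**kw)
    elif kw:
        raise TypeError("pass either params or keyword overrides, not both")
    return rasterize_phantom(params, grow_artery_tree(params))


def write_phantom(bundle: PhantomBundle, outdir: str | Path) -> Path:
    """Write the four NIfTI volumes plus truth.json and params.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(bundle.kidney, outdir / "kidney.nii.gz")
    write_volume(bundle.sinus_ucs, outdir / "sinus_ucs.nii.gz")
    write_volume(bundle.vessels, outdir / "vessels.nii.gz")
    write_volume(bundle.tumor, outdir / "tumor.nii.gz")
    (outdir / "truth.json").write_text(bundle.truth.to_json())
    (outdir / "params.json").write_text(json.dumps(asdict(bundle.params), sort_keys=True))
    return outdir
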