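"""Aneurysm sac morphology: direct geometric parameters and ratio indices.

Direct parameters are measured on the capped sac mesh (volumes by the
divergence theorem, as trimesh computes them) and on the planar neck
cross-section polygon. The six ratio indices follow the standard
Raghavan-style definitions used throughout the aneurysm-morphometry
literature:

    AR  = H_max / N_max                    aspect ratio
    SR  = H_max / parent vessel diameter   size ratio
    UI  = 1 - V_sac / V_convex_hull        undulation index
    NSI = 1 - (36*pi)^(1/3) * V^(2/3) / S  non-sphericity index
    BF  = W_max / N_max                    bottleneck factor
    CP  = 1/2 - h* / H                     conicity parameter

NSI is referenced to a sphere (NSI = 0 for a sphere, since a closed sphere
satisfies S^3 = 36*pi*V^2); ``nsi_reference="hemisphere"`` selects the
Raghavan-style (18*pi)^(1/3) constant instead, which is zero for a
hemispherical dome measured without its base.

with W_max the maximal sac width parallel to the neck plane and h* the
height above the neck plane of that maximal parallel cross-section. All
six are dimensionless and invariant to rigid motion and uniform scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import ConvexHull

from .segmentation import NeckPlane, SegmentationError

__all__ = [
    "SacGeometry",
    "MorphologyIndices",
    "direct_parameters",
    "ratio_indices",
    "neck_cross_section",
]


@dataclass(frozen=True)
class SacGeometry:
    """Direct geometric parameters of an isolated sac (mm / mm^2 / mm^3).

    Note N_max <= L_max is NOT guaranteed: an oblique neck loop on a
    squat sac can be wider than any sac chord.
    """

    H: float
    H_max: float
    L_max: float
    V_sac: float
    V_sacpar: float
    V_par: float
    S_sac: float
    S_sacpar: float
    N_max: float
    N_perimet: float
    N_area: float


@dataclass(frozen=True)
class MorphologyIndices:
    AR: float
    SR: float
    UI: float
    NSI: float
    BF: float
    CP: float


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def _loop_metrics(loop3d: np.ndarray, plane: NeckPlane) -> tuple[float, float, float]:
    """(max diameter, perimeter, area) of a closed planar loop."""
    e1, e2 = _plane_basis(plane.normal)
    rel = loop3d - plane.point
    uv = np.column_stack([rel @ e1, rel @ e2])
    closed = np.vstack([uv, uv[:1]])
    seg = np.diff(closed, axis=0)
    perimeter = float(np.linalg.norm(seg, axis=1).sum())
    area = float(abs(np.sum(closed[:-1, 0] * closed[1:, 1] - closed[1:, 0] * closed[:-1, 1])) / 2.0)
    if len(uv) >= 3:
        try:
            hull = ConvexHull(uv)
            hp = uv[hull.vertices]
        except Exception:
            hp = uv
    else:
        hp = uv
    diff = hp[:, None, :] - hp[None, :, :]
    diameter = float(np.sqrt((diff**2).sum(-1)).max())
    return diameter, perimeter, area


def _section_loops(mesh: trimesh.Trimesh, origin, normal) -> list[np.ndarray]:
    section = mesh.section(plane_origin=origin, plane_normal=normal)
    if section is None:
        return []
    return [np.asarray(d) for d in section.discrete]


def neck_cross_section(sac: trimesh.Trimesh, plane: NeckPlane) -> np.ndarray:
    """Neck polygon: the sac's planar opening at the neck plane.

    Sectioning the capped sac a hair above its cap recovers the cut loop.
    Using the sac (not sac+parent) avoids merging the neck polygon with
    slivers where the plane grazes the parent vessel tangentially.
    """
    eps = 1e-4 * float(np.linalg.norm(sac.extents))
    loops = _section_loops(sac, plane.point + eps * plane.normal, plane.normal)
    if not loops:
        raise SegmentationError("neck plane does not intersect the surface")
    # Largest by enclosed area.
    best, best_area = None, -1.0
    for loop in loops:
        _, _, area = _loop_metrics(loop, plane)
        if area > best_area:
            best, best_area = loop, area
    return best


def direct_parameters(
    sac: trimesh.Trimesh, sacpar: trimesh.Trimesh, plane: NeckPlane
) -> SacGeometry:
    """Measure the ten direct geometric parameters.

    H is the maximal perpendicular dome height above the neck plane; H_max
    the maximal distance from the neck-loop centroid to any sac vertex;
    L_max the sac mesh diameter in any direction. Volumes and areas come
    from the closed meshes; N_max / N_perimet / N_area from the planar
    neck polygon.
    """
    for m, name in ((sac, "sac"), (sacpar, "sac+parent")):
        if not m.is_watertight:
            raise SegmentationError(f"{name} mesh is not closed")
    sd = plane.signed_distance(sac.vertices)
    H = float(sd.max())
    loop = neck_cross_section(sac, plane)
    n_max, n_per, n_area = _loop_metrics(loop, plane)
    centroid = loop.mean(axis=0)
    H_max = float(np.linalg.norm(sac.vertices - centroid, axis=1).max())
    hull_pts = sac.convex_hull.vertices
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    L_max = float(np.sqrt((diff**2).sum(-1)).max())
    V_sac = float(sac.volume)
    V_sacpar = float(sacpar.volume)
    return SacGeometry(
        H=H,
        H_max=H_max,
        L_max=L_max,
        V_sac=V_sac,
        V_sacpar=V_sacpar,
        V_par=V_sacpar - V_sac,
        S_sac=float(sac.area),
        S_sacpar=float(sacpar.area),
        N_max=n_max,
        N_perimet=n_per,
        N_area=n_area,
    )


def _max_parallel_width(
    sac: trimesh.Trimesh, plane: NeckPlane, H: float, n_slices: int = 40
) -> tuple[float, float]:
    """(W_max, h*): widest cross-section parallel to the neck plane.

    Slices the sac at evenly spaced heights in [0, H); the width of a
    slice is the maximal diameter over its loops. Height 0 (the neck
    section itself) is included so a hemisphere yields h* = 0.
    """
    best_w, best_h = 0.0, 0.0
    for h in np.linspace(0.0, H * (1.0 - 1.0 / n_slices), n_slices):
        origin = plane.point + plane.normal * h
        loops = _section_loops(sac, origin, plane.normal)
        if not loops:
            continue
        w = max(_loop_metrics(loop, plane)[0] for loop in loops)
        if w > best_w + 1e-12:
            best_w, best_h = w, float(h)
    if best_w == 0.0:
        raise SegmentationError("sac has no cross-section parallel to the neck plane")
    return best_w, best_h


def ratio_indices(
    geometry: SacGeometry,
    sac: trimesh.Trimesh,
    parent_diameter: float,
    plane: NeckPlane,
    n_slices: int = 40,
    nsi_reference: str = "sphere",
) -> MorphologyIndices:
    """Compute the six ratio-based morphology indices for one sac."""
    if parent_diameter <= 0:
        raise ValueError("parent diameter must be positive")
    if geometry.N_max <= 0:
        raise ValueError("neck diameter must be positive")
    hull = sac.convex_hull
    if hull.volume <= 0:
        raise SegmentationError("degenerate convex hull")
    ui = 1.0 - geometry.V_sac / hull.volume
    k = {"sphere": 36.0, "hemisphere": 18.0}[nsi_reference] * math.pi
    nsi = 1.0 - k ** (1.0 / 3.0) * geometry.V_sac ** (2.0 / 3.0) / geometry.S_sac
    w_max, h_star = _max_parallel_width(sac, plane, geometry.H, n_slices=n_slices)
    return MorphologyIndices(
        AR=geometry.H_max / geometry.N_max,
        SR=geometry.H_max / parent_diameter,
        UI=ui,
        NSI=nsi,
        BF=w_max / geometry.N_max,
        CP=0.5 - h_star / geometry.H,
    )


def estimate_parent_diameter(graph, n_max: float) -> float:
    """Parent vessel diameter: twice the mean inscribed-sphere radius of
    branch centerline points within 3*N_max of the neck point."""
    pts = graph.points[~graph.aneurysm_mask]
    radii = graph.radii[~graph.aneurysm_mask]
    d = np.linalg.norm(pts - graph.neck_point, axis=1)
    near = d <= 3.0 * n_max
    if not near.any():
        near = slice(None)
    return float(2.0 * radii[near].mean())
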