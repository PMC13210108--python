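"""Volume preprocessing, centerline extraction, automatic neck isolation,
and per-vertex wall-displacement mapping.

The stage chain per examination is:

    HU volume --threshold--> binary mask --box smooth + linear resample-->
    occupancy --marching cubes--> surface mesh
    binary mask --3D thinning--> centerline graph --projection rule-->
    neck plane --plane cut--> isolated sac mesh
    phase meshes --nearest-vertex matching--> displacement field d_i(t)

All geometry is in mm world coordinates; voxel indexing is 0-based and the
world position of voxel (0,0,0) is the volume origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "BinaryVolume",
    "OccupancyVolume",
    "CenterlineGraph",
    "NeckPlane",
    "DisplacementField",
    "SegmentationError",
    "threshold_segment",
    "smooth_and_resample",
    "extract_isosurface",
    "extract_centerline",
    "identify_neck_plane",
    "cut_sac",
    "compute_displacement",
    "write_ply_with_scalar",
]

HU_THRESHOLD_DEFAULT = 180.0


class SegmentationError(RuntimeError):
    """Automatic processing failed; manual segmentation correction is out
    of scope, so failures surface as errors."""


@dataclass
class BinaryVolume:
    """Binary occupancy grid with spacing (mm/axis) and world origin."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("expected a 3-D volume")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on every axis")
        if not self.data.any():
            raise SegmentationError("empty foreground")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def foreground_volume(self) -> float:
        return float(self.data.sum()) * self.voxel_volume

    def world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing


@dataclass
class OccupancyVolume:
    """Real-valued occupancy in [0, 1] on a refined grid."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray


@dataclass
class NeckPlane:
    """Plane separating sac from parent arteries; normal points at the dome."""

    point: np.ndarray
    normal: np.ndarray
    cut_points: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValueError("zero plane normal")
        self.normal = self.normal / n
        self.point = np.asarray(self.point, dtype=float)

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.point) @ self.normal


@dataclass
class CenterlineGraph:
    """Skeleton graph in world coordinates with key-point labels.

    ``radii`` holds the inscribed-sphere radius (distance-transform value)
    at each point; ``aneurysm_mask`` marks sac-interior points; branches
    are connected runs of non-sac points that reach an original endpoint.
    """

    points: np.ndarray
    graph: nx.Graph
    radii: np.ndarray
    endpoints: np.ndarray
    branch_points: np.ndarray
    sac_point_index: int
    aneurysm_mask: np.ndarray
    neck_point_index: int
    branches: list

    @property
    def sac_point(self) -> np.ndarray:
        return self.points[self.sac_point_index]

    @property
    def neck_point(self) -> np.ndarray:
        return self.points[self.neck_point_index]

    @property
    def aneurysm_points(self) -> np.ndarray:
        return self.points[self.aneurysm_mask]

    @property
    def branch_centerline_points(self) -> np.ndarray:
        return self.points[~self.aneurysm_mask]


def threshold_segment(
    image: np.ndarray,
    spacing,
    origin=(0.0, 0.0, 0.0),
    threshold: float = HU_THRESHOLD_DEFAULT,
) -> BinaryVolume:
    """Fixed grey-level threshold segmentation (default 180 HU).

    Foreground is every voxel at or above the threshold; an empty result is
    a segmentation failure, not an empty volume.
    """
    mask = np.asarray(image, dtype=float) >= threshold
    if not mask.any():
        raise SegmentationError(f"no voxel reaches threshold {threshold} HU")
    return BinaryVolume(mask, spacing, origin)


def smooth_and_resample(mask: BinaryVolume, refine: int = 5) -> OccupancyVolume:
    """Box-smooth ([3,3,3] moving average) then linearly refine the grid.

    The occupancy stays in [0, 1] and total occupancy mass (occupancy times
    voxel volume) is conserved to well under 1%. ``refine`` is the per-axis
    refinement factor (5 reproduces the reference pipeline; smaller values
    trade resolution for speed).
    """
    occ = ndimage.uniform_filter(mask.data.astype(float), size=3, mode="nearest")
    if refine > 1:
        zoomed = ndimage.zoom(occ, refine, order=1, grid_mode=True, mode="grid-constant")
        new_spacing = mask.spacing / refine
        # grid_mode=True treats values as cell averages: voxel (0,0,0) of the
        # fine grid sits at the corner cell of the coarse voxel.
        new_origin = mask.origin - mask.spacing / 2.0 + new_spacing / 2.0
    else:
        zoomed, new_spacing, new_origin = occ, mask.spacing.copy(), mask.origin.copy()
    return OccupancyVolume(np.clip(zoomed, 0.0, 1.0), new_spacing, new_origin)


def extract_isosurface(occ: OccupancyVolume, level: float = 0.5) -> trimesh.Trimesh:
    """Marching-cubes isosurface at the occupancy midpoint, in world mm."""
    from skimage import measure

    if not (occ.data.min() < level < occ.data.max()):
        raise SegmentationError("isosurface level outside occupancy range")
    verts, faces, _, _ = measure.marching_cubes(occ.data, level=level, spacing=tuple(occ.spacing))
    verts = verts + occ.origin
    # marching_cubes already emits shared vertices; re-merging would weld
    # degenerate triangles into non-manifold edges.
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    # Keep the dominant watertight component; tiny specks are noise flotsam.
    if mesh.body_count > 1:
        parts = mesh.split(only_watertight=False)
        mesh = max(parts, key=lambda m: abs(m.volume) if m.is_volume else m.area)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


_NEIGHBOR_OFFSETS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
)


def extract_centerline(volume: BinaryVolume) -> CenterlineGraph:
    """Skeletonise the vessel-plus-sac mask and label its key points.

    3-D thinning produces a one-voxel-wide skeleton; the graph uses
    26-connectivity. The sac point is the skeleton point of maximal
    inscribed-sphere radius; skeleton points inside that maximal inscribed
    sphere are aneurysm (sac-interior) points, the rest are branch
    centerline points. The neck point is the degree->=3 junction nearest
    the sac (or, failing that, the nearest branch point to the sac).
    """
    from skimage.morphology import skeletonize

    lbl, n_comp = ndimage.label(volume.data)
    if n_comp != 1:
        raise SegmentationError(f"foreground has {n_comp} connected components; expected 1")
    skel = skeletonize(volume.data)
    idx = np.argwhere(skel)
    if len(idx) == 0:
        raise SegmentationError("skeletonization produced no points")
    edt = ndimage.distance_transform_edt(volume.data, sampling=volume.spacing)
    radii = edt[tuple(idx.T)]
    pts = volume.world(idx)

    voxel_set = {tuple(v): i for i, v in enumerate(map(tuple, idx))}
    g = nx.Graph()
    g.add_nodes_from(range(len(idx)))
    for i, v in enumerate(idx):
        for off in _NEIGHBOR_OFFSETS:
            nb = tuple(v + off)
            j = voxel_set.get(nb)
            if j is not None and j > i:
                g.add_edge(i, j)

    degrees = np.array([g.degree(i) for i in range(len(idx))])
    endpoints = np.flatnonzero(degrees == 1)
    branch_nodes = np.flatnonzero(degrees >= 3)

    sac_idx = int(np.argmax(radii))
    sac_pt = pts[sac_idx]
    sac_r = float(radii[sac_idx])
    aneurysm_mask = np.linalg.norm(pts - sac_pt, axis=1) < sac_r

    non_sac = np.flatnonzero(~aneurysm_mask)
    if len(non_sac) == 0:
        raise SegmentationError("no branch adjacent to the sac")
    # Neck point: junction closest to the sac, else nearest non-sac point.
    cand = [b for b in branch_nodes if not aneurysm_mask[b]]
    pool = cand if cand else list(non_sac)
    neck_idx = int(min(pool, key=lambda i: np.linalg.norm(pts[i] - sac_pt)))

    # Branches: connected runs of non-sac points (neck junction removed)
    # that contain an original endpoint — prunes the stub between sac and
    # junction, which has no free end.
    sub_nodes = [i for i in non_sac if i != neck_idx]
    sub = g.subgraph(sub_nodes)
    branches = []
    endpoint_set = set(endpoints.tolist())
    for comp in nx.connected_components(sub):
        if comp & endpoint_set:
            branches.append(np.array(sorted(comp)))
    if not branches:
        raise SegmentationError("no branch adjacent to the sac")

    return CenterlineGraph(
        points=pts,
        graph=g,
        radii=radii,
        endpoints=endpoints,
        branch_points=branch_nodes,
        sac_point_index=sac_idx,
        aneurysm_mask=aneurysm_mask,
        neck_point_index=neck_idx,
        branches=branches,
    )


def _ray_mesh_first_hits(mesh: trimesh.Trimesh, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """First ray-surface intersection per ray (vectorised Moller-Trumbore).

    Returns the hit points of the rays that intersect; rays that miss are
    dropped. Exhaustive over triangles (no spatial index needed), batched
    per ray.
    """
    tri = mesh.triangles
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    hits = []
    eps = 1e-9
    for o, d in zip(origins, dirs):
        p = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > eps
        inv = np.zeros_like(det)
        inv[ok] = 1.0 / det[ok]
        s = o - v0
        u = np.einsum("ij,ij->i", s, p) * inv
        q = np.cross(s, e1)
        v = np.einsum("j,ij->i", d, q) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        valid = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > eps)
        if valid.any():
            hits.append(o + d * t[valid].min())
    return np.asarray(hits).reshape(-1, 3)


def _project_branch_to_surface(
    graph: CenterlineGraph, surface: trimesh.Trimesh, branch: np.ndarray, max_rays: int = 120
) -> np.ndarray:
    """Project branch centerline points onto the surface toward the sac point."""
    pts = graph.points[branch]
    if len(pts) > max_rays:
        pick = np.linspace(0, len(pts) - 1, max_rays).round().astype(int)
        pts = pts[np.unique(pick)]
    dirs = graph.sac_point - pts
    norms = np.linalg.norm(dirs, axis=1)
    ok = norms > 1e-9
    pts, dirs = pts[ok], dirs[ok] / norms[ok, None]
    return _ray_mesh_first_hits(surface, pts, dirs)


def identify_neck_plane(graph: CenterlineGraph, surface: trimesh.Trimesh) -> NeckPlane:
    """Construct the neck cut plane from centerline-derived cut points.

    Per branch, centerline points are projected onto the surface toward
    the sac point; the projected point closest to the neck junction is that
    branch's cut point. With more than two branches the plane is fitted
    through the three cut points closest to the neck; with two, the plane
    passes through both cut points and its normal is the perpendicular
    from the cut-point line to the highest surface point of the dome.
    """
    neck = graph.neck_point
    sac = graph.sac_point
    cut_points = []
    for branch in graph.branches:
        surf_pts = _project_branch_to_surface(graph, surface, branch)
        if len(surf_pts) == 0:
            continue
        d = np.linalg.norm(surf_pts - neck, axis=1)
        cut_points.append(surf_pts[int(np.argmin(d))])
    if len(cut_points) < 2:
        raise SegmentationError("need at least two branch cut points to build a neck plane")
    cut_points = np.asarray(cut_points)

    if len(cut_points) > 2:
        order = np.argsort(np.linalg.norm(cut_points - neck, axis=1))
        p0, p1, p2 = cut_points[order[:3]]
        normal = np.cross(p1 - p0, p2 - p0)
        if np.linalg.norm(normal) < 1e-9:
            raise SegmentationError("degenerate collinear cut points")
        point = (p0 + p1 + p2) / 3.0
    else:
        c1, c2 = cut_points
        line = c2 - c1
        nl = np.linalg.norm(line)
        if nl < 1e-9:
            raise SegmentationError("coincident cut points")
        line = line / nl
        dome_dir = sac - neck
        dn = np.linalg.norm(dome_dir)
        if dn < 1e-9:
            raise SegmentationError("sac point coincides with neck point")
        dome_dir = dome_dir / dn
        # Highest surface point: maximal extent from the neck along the
        # provisional dome direction (frame-independent, no gravity axis).
        heights = (surface.vertices - neck) @ dome_dir
        top = surface.vertices[int(np.argmax(heights))]
        perp = (top - c1) - ((top - c1) @ line) * line
        if np.linalg.norm(perp) < 1e-9:
            raise SegmentationError("dome apex lies on the cut-point line")
        normal = perp
        point = (c1 + c2) / 2.0

    normal = normal / np.linalg.norm(normal)
    if (sac - point) @ normal < 0:
        normal = -normal
    plane = NeckPlane(point=point, normal=normal, cut_points=cut_points)
    if plane.signed_distance(sac[None])[0] <= 0:
        raise SegmentationError("sac point not on the positive side of the neck plane")
    return plane


def _weld_coincident(mesh: trimesh.Trimesh, tol: float = 1e-8) -> trimesh.Trimesh:
    """Merge exactly coincident vertices (slicing duplicates the cut line)."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    v = np.asarray(mesh.vertices)
    tree = cKDTree(v)
    pairs = np.array(sorted(tree.query_pairs(tol)))
    if len(pairs) == 0:
        return mesh
    adj = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(len(v), len(v))
    )
    _, labels = connected_components(adj + adj.T, directed=False)
    # labels are contiguous group ids; first member represents each group
    _, rep_idx = np.unique(labels, return_index=True)
    faces = labels[np.asarray(mesh.faces)]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    return trimesh.Trimesh(v[rep_idx], faces[ok], process=False)


def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Ordered vertex loops of the open boundary (edges used exactly once)."""
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = unique[counts == 1]
    if len(boundary) == 0:
        return []
    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    loops, seen = [], set()
    for start in adj:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nxt = next((n for n in adj[cur] if n != prev and n not in seen), None)
            if nxt is None:
                break
            loop.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        if len(loop) >= 3:
            loops.append(np.array(loop))
    return loops


def _cap_open_boundary(mesh: trimesh.Trimesh, outward: np.ndarray) -> trimesh.Trimesh:
    """Close planar boundary loops with a centroid fan facing ``outward``.

    A centroid fan reproduces the polygon's signed area even for mildly
    non-convex loops, so divergence-theorem volumes stay exact.
    """
    loops = _boundary_loops(mesh)
    if not loops:
        return mesh
    v = np.asarray(mesh.vertices)
    f = [np.asarray(mesh.faces)]
    verts = [v]
    offset = len(v)
    for loop in loops:
        pts = v[loop]
        centroid = pts.mean(axis=0)
        n = len(loop)
        fan = np.column_stack(
            [np.full(n, offset), loop, np.roll(loop, -1)]
        )
        # Orient the fan so its aggregate normal points along ``outward``.
        e1 = pts - centroid
        e2 = np.roll(pts, -1, axis=0) - centroid
        agg = np.cross(e1, e2).sum(axis=0)
        if agg @ outward < 0:
            fan = fan[:, [0, 2, 1]]
        verts.append(centroid[None])
        f.append(fan)
        offset += 1
    return trimesh.Trimesh(np.vstack(verts), np.vstack(f), process=False)


def cut_sac(
    surface: trimesh.Trimesh, plane: NeckPlane, volume_tolerance: float = 0.005
) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Split the closed surface at the neck plane into capped sac and rest.

    Returns (sac_mesh, remainder_mesh), both closed. Volume is conserved:
    the two halves sum to the original within ``volume_tolerance``
    (fractional). A plane missing the surface, or producing an empty sac,
    is an error.
    """
    sac = trimesh.intersections.slice_mesh_plane(
        surface, plane_normal=plane.normal, plane_origin=plane.point, cap=False
    )
    rest = trimesh.intersections.slice_mesh_plane(
        surface, plane_normal=-plane.normal, plane_origin=plane.point, cap=False
    )
    if sac is not None and len(sac.faces):
        sac = _cap_open_boundary(_weld_coincident(sac), -plane.normal)
    if rest is not None and len(rest.faces):
        rest = _cap_open_boundary(_weld_coincident(rest), plane.normal)
    if sac is None or len(sac.faces) == 0 or sac.volume <= 0:
        raise SegmentationError("neck plane produced an empty or zero-volume sac")
    if rest is None or len(rest.faces) == 0:
        raise SegmentationError("neck plane missed the surface")
    total = surface.volume
    if total > 0:
        loss = abs(sac.volume + rest.volume - total) / total
        if loss > volume_tolerance:
            raise SegmentationError(
                f"volume not conserved by neck cut (fractional loss {loss:.3%})"
            )
    return sac, rest


@dataclass
class DisplacementField:
    """Per-vertex, per-phase displacement on the reference-phase mesh.

    ``d[t, i]`` is the distance (mm) from reference vertex i to its
    matched (nearest) vertex on the phase-t mesh — non-negative by
    construction and identically zero at the reference phase. The
    amplitude map is the per-vertex maximum over phases.
    """

    reference_mesh: trimesh.Trimesh
    d: np.ndarray
    reference_phase: int

    @property
    def amplitude(self) -> np.ndarray:
        return self.d.max(axis=0)

    def to_dataframe(self):
        import pandas as pd

        n_phases, n_vert = self.d.shape
        return pd.DataFrame(
            {
                "vertex_id": np.tile(np.arange(n_vert), n_phases),
                "phase": np.repeat(np.arange(n_phases), n_vert),
                "d_mm": self.d.ravel(),
            }
        )


def compute_displacement(
    meshes: list[trimesh.Trimesh], reference_phase: int = 0
) -> DisplacementField:
    """Map wall displacement by nearest-vertex matching across phases.

    For each reference vertex r_i and phase t the displacement is the
    Euclidean magnitude ``d_i(t) = || v(t)_i - r_i ||`` to the nearest
    vertex v(t)_i of the phase-t mesh — the always-positive total-change
    convention. Nearest-vertex matching is exact for motion smaller than
    half the mesh edge length and a lower bound beyond that.
    """
    if not meshes:
        raise ValueError("no phase meshes supplied")
    ref = meshes[reference_phase]
    rv = np.asarray(ref.vertices)
    d = np.zeros((len(meshes), len(rv)))
    for t, mesh in enumerate(meshes):
        if mesh is None or len(mesh.vertices) == 0:
            raise SegmentationError(f"phase {t} mesh is empty")
        if t == reference_phase:
            continue
        tree = cKDTree(np.asarray(mesh.vertices))
        d[t], _ = tree.query(rv, k=1)
    return DisplacementField(ref, d, reference_phase)


def write_ply_with_scalar(mesh: trimesh.Trimesh, scalar: np.ndarray, path) -> None:
    """ASCII PLY with a per-vertex ``quality`` channel (displacement, mm)."""
    v = np.asarray(mesh.vertices)
    f = np.asarray(mesh.faces)
    scalar = np.asarray(scalar, dtype=float)
    if len(scalar) != len(v):
        raise ValueError("scalar length must match vertex count")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment aneupulse displacement map\n")
        fh.write(f"element vertex {len(v)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float quality\n")
        fh.write(f"element face {len(f)}\nproperty list uchar int vertex_indices\nend_header\n")
        for (x, y, z), q in zip(v, scalar):
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {q:.6f}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
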