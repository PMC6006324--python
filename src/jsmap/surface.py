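"""Bone surface meshing and joint-space patch extraction.

A binary bone mask becomes a closed triangulated surface (marching cubes on a
lightly smoothed mask, in world mm).  Opposing bone is projected onto the
surface by taking the maximum interpolated HU along each outward vertex
normal within a small search depth (~5 mm), which paints a bright patch where
the opposing bone sits.  The joint-space patch is cut from the surface along
a joint-margin polyline and re-triangulated to a roughly uniform target
resolution (around 4,000 vertices for a hip) so that profile sampling does
not undersample the joint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .volume_io import ImageVolume, sample_profiles


class SurfaceProjector:
    """Closest-point queries onto a triangulated surface.

    KD-tree over face centroids proposes candidate triangles; the exact
    point-triangle distance picks the winner.  ``k`` candidates is ample for
    reasonably uniform meshes.
    """

    def __init__(self, mesh: trimesh.Trimesh, k: int = 8):
        self.mesh = mesh
        self.triangles = np.asarray(mesh.triangles)
        self.face_normals = np.asarray(mesh.face_normals)
        self._tree = cKDTree(self.triangles.mean(axis=1))
        self.k = min(k, len(self.triangles))

    def project(self, points: np.ndarray,
                return_index: bool = False):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, fidx = self._tree.query(points, k=self.k)
        fidx = np.atleast_2d(fidx)
        n, k = fidx.shape
        tris = self.triangles[fidx.ravel()]
        rep = np.repeat(points, k, axis=0)
        closest = trimesh.triangles.closest_point(tris, rep)
        d2 = ((closest - rep) ** 2).sum(axis=1).reshape(n, k)
        best = d2.argmin(axis=1)
        rows = np.arange(n)
        out = closest.reshape(n, k, 3)[rows, best]
        if return_index:
            return out, fidx[rows, best]
        return out

    def distance(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.project(points) - np.atleast_2d(points),
                              axis=1)

    def normals_at(self, points: np.ndarray) -> np.ndarray:
        _, fi = self.project(points, return_index=True)
        return self.face_normals[fi]

    def interpolate(self, points: np.ndarray,
                    vertex_values: np.ndarray) -> np.ndarray:
        """Barycentric interpolation of a per-vertex field at the closest
        surface points."""
        closest, fi = self.project(points, return_index=True)
        faces = np.asarray(self.mesh.faces)[fi]
        tris = self.triangles[fi]
        bary = trimesh.triangles.points_to_barycentric(tris, closest)
        vals = np.asarray(vertex_values, dtype=float)[faces]
        return np.einsum("nk,nk...->n...", bary, vals)


@dataclass
class JointSpacePatch:
    """Open surface patch cut along the joint margin.

    ``boundary`` is the ordered loop of boundary vertex indices; every vertex
    carries an outward normal inherited from the parent bone surface winding.
    """

    mesh: trimesh.Trimesh
    boundary: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=int)

    @property
    def n_vertices(self) -> int:
        return len(self.mesh.vertices)

    @property
    def normals(self) -> np.ndarray:
        return np.asarray(self.mesh.vertex_normals)

    def vertex_adjacency(self) -> list[np.ndarray]:
        return _adjacency_lists(np.asarray(self.mesh.faces), self.n_vertices)

    def interior_mask(self, rings: int = 3) -> np.ndarray:
        """True for vertices at least ``rings`` edge-hops from the boundary."""
        adj = self.vertex_adjacency()
        dist = np.full(self.n_vertices, np.iinfo(np.int32).max, dtype=np.int64)
        frontier = list(np.unique(self.boundary))
        dist[frontier] = 0
        for d in range(1, rings + 1):
            nxt = []
            for v in frontier:
                for u in adj[v]:
                    if dist[u] > d:
                        dist[u] = d
                        nxt.append(u)
            frontier = nxt
        return dist > rings


def _adjacency_lists(faces: np.ndarray, n: int) -> list[np.ndarray]:
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    return [np.asarray(a, dtype=int) for a in adj]


def _edges_unique(faces: np.ndarray) -> np.ndarray:
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    return np.unique(np.sort(e, axis=1), axis=0)


def _boundary_vertices(faces: np.ndarray) -> np.ndarray:
    e = np.sort(np.vstack([faces[:, [0, 1]], faces[:, [1, 2]],
                           faces[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


def mesh_from_mask(mask_volume: ImageVolume, iso_level: float = 0.5,
                   smooth_voxels: float = 1.0,
                   normal_smooth_mm: float = 2.0) -> trimesh.Trimesh:
    """Closed outward-oriented surface of a binary mask, in world mm.

    Geometry: the mask is pre-smoothed with a 1-voxel Gaussian and marching
    cubes extracts the 0.5 isosurface, keeping the surface within a fraction
    of a voxel of the true boundary.  Normals: computed separately from the
    gradient of a *heavily* smoothed field (``normal_smooth_mm``, world
    units).  The split matters at 1.5 mm slices — the surface itself only
    anchors the profile sampling frame and the fit tolerates millimetre
    offsets, but staircase artefact in the normals tilts every sampling ray
    and biases the measured widths.  The largest connected component is kept
    and both winding and normals point away from the bone interior.
    """
    from scipy import ndimage
    from skimage import measure

    mask = np.asarray(mask_volume.data, dtype=float)
    if mask.max() <= 0:
        raise ValueError("mask is empty")
    geo_field = ndimage.gaussian_filter(mask, smooth_voxels, mode="nearest") \
        if smooth_voxels > 0 else mask
    verts_ijk, faces, grad_normals, _ = measure.marching_cubes(
        geo_field, level=iso_level)
    verts = mask_volume.voxel_to_world(verts_ijk)

    A = mask_volume.affine[:3, :3]
    if normal_smooth_mm > 0:
        sigma_vox = np.maximum(normal_smooth_mm / mask_volume.spacing, 1.0)
        normal_field = ndimage.gaussian_filter(mask, sigma_vox,
                                               mode="nearest")
        grads = np.gradient(normal_field)
        normals_ijk = np.stack([
            ndimage.map_coordinates(g, verts_ijk.T, order=1, mode="nearest")
            for g in grads], axis=1)
        normals = -normals_ijk @ np.linalg.inv(A)  # outward: toward lower mask
    else:
        normals = grad_normals @ np.linalg.inv(A)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.maximum(norms, 1e-12)

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    keep = np.arange(len(verts))
    parts_faces = trimesh.graph.connected_component_labels(
        mesh.face_adjacency, node_count=len(faces))
    if parts_faces.max() > 0:
        areas = np.bincount(parts_faces, weights=mesh.area_faces)
        faces = faces[parts_faces == areas.argmax()]
        keep = np.unique(faces)
        remap = -np.ones(len(verts), dtype=int)
        remap[keep] = np.arange(len(keep))
        verts, faces = verts[keep], remap[faces]
        normals = normals[keep]
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)

    trimesh.repair.fix_normals(mesh)
    faces = np.asarray(mesh.faces).copy()
    verts = np.asarray(mesh.vertices).copy()
    # orient: gradient normals must point away from the bone (toward lower
    # mask values, which marching_cubes 'descent' already gives); align the
    # winding with them so both conventions agree
    centred = verts - verts.mean(axis=0)
    if np.einsum("ij,ij->", normals, centred) < 0:
        normals = -normals
    wind = trimesh.Trimesh(verts, faces, process=False)
    agree = np.einsum("ij,ij->", np.asarray(wind.vertex_normals), normals)
    if agree < 0:
        faces = faces[:, ::-1]
    return trimesh.Trimesh(vertices=verts, faces=faces,
                           vertex_normals=normals, process=False)


def project_opposing_bone(
    mesh: trimesh.Trimesh,
    volume: ImageVolume,
    search_depth: float = 5.0,
    step: float = 0.25,
    order: int = 1,
) -> np.ndarray:
    """Per-vertex maximum HU along the outward normal within (0, search_depth].

    Bright values mark opposing bone; enlarging ``search_depth`` can only
    increase values (the sample grid is nested).
    """
    if search_depth <= 0:
        raise ValueError("search_depth must be > 0")
    t = step * np.arange(1, int(np.floor(search_depth / step)) + 1)
    values, oob = sample_profiles(volume, np.asarray(mesh.vertices),
                                  np.asarray(mesh.vertex_normals), t,
                                  order=order)
    values = np.where(oob, -np.inf, values)
    out = values.max(axis=1)
    # rays that never entered the grid fall back to the edge value policy
    bad = ~np.isfinite(out)
    if bad.any():
        vals2, _ = sample_profiles(volume, np.asarray(mesh.vertices)[bad],
                                   np.asarray(mesh.vertex_normals)[bad], t,
                                   order=order)
        out[bad] = vals2.max(axis=1)
    return out


def cut_patch(
    mesh: trimesh.Trimesh,
    boundary_polyline: np.ndarray,
    seed_point: np.ndarray | None = None,
    opposing_values: np.ndarray | None = None,
    snap_distance: float | None = None,
    source_id: str = "",
) -> JointSpacePatch:
    """Cut the mesh region enclosed by a closed joint-margin polyline.

    Polyline points snap to nearest mesh vertices; consecutive snaps are
    joined by shortest edge paths to form a closed vertex loop.  The enclosed
    side is the one containing ``seed_point`` or, failing that, the side with
    the higher mean opposing-bone value.  The loop itself belongs to the
    patch, so patch and complement partition the vertices with the loop as
    intersection.
    """
    poly = np.asarray(boundary_polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 3 or len(poly) < 4:
        raise ValueError("boundary polyline must be an (n, 3) loop")
    if np.linalg.norm(poly[0] - poly[-1]) > 1e-6:
        raise ValueError("boundary polyline is open (first point != last)")
    poly = poly[:-1]

    verts = np.asarray(mesh.vertices)
    faces = np.asarray(mesh.faces)
    edges = _edges_unique(faces)
    lens = np.linalg.norm(verts[edges[:, 0]] - verts[edges[:, 1]], axis=1)
    mean_edge = float(lens.mean())
    if snap_distance is None:
        snap_distance = 5.0 * mean_edge

    tree = cKDTree(verts)
    d, snapped = tree.query(poly)
    if d.max() > snap_distance:
        raise ValueError(
            f"polyline point {d.argmax()} is {d.max():.2f} mm from the mesh "
            f"(snap distance {snap_distance:.2f} mm)")
    # consecutive unique snapped vertices
    keep = np.concatenate([[True], snapped[1:] != snapped[:-1]])
    snapped = snapped[keep]
    if snapped[-1] == snapped[0] and len(snapped) > 1:
        snapped = snapped[:-1]
    if len(snapped) < 3:
        raise ValueError("polyline snaps to fewer than 3 distinct vertices")

    n = len(verts)
    graph = coo_matrix((lens, (edges[:, 0], edges[:, 1])), shape=(n, n))
    graph = graph + graph.T
    graph = graph.tocsr()

    loop: list[int] = []
    for a, b in zip(snapped, np.roll(snapped, -1)):
        seg_len = np.linalg.norm(verts[a] - verts[b])
        limit = max(4.0 * seg_len, 6.0 * mean_edge)
        dist, pred = dijkstra(graph, indices=a, return_predecessors=True,
                              limit=limit)
        if not np.isfinite(dist[b]):
            dist, pred = dijkstra(graph, indices=a, return_predecessors=True)
            if not np.isfinite(dist[b]):
                raise ValueError("boundary loop is not connectable on the mesh")
        path = [int(b)]
        while path[-1] != a:
            path.append(int(pred[path[-1]]))
        loop.extend(path[::-1][:-1])  # a ... predecessor of b
    if len(set(loop)) != len(loop):
        raise ValueError("boundary loop self-intersects on the mesh")
    loop_arr = np.asarray(loop, dtype=int)

    in_loop = np.zeros(n, dtype=bool)
    in_loop[loop_arr] = True
    # components of the mesh with the loop vertices removed
    keep_edges = ~(in_loop[edges[:, 0]] | in_loop[edges[:, 1]])
    sub = coo_matrix((np.ones(keep_edges.sum()),
                      (edges[keep_edges, 0], edges[keep_edges, 1])),
                     shape=(n, n))
    sub = sub + sub.T
    n_comp, labels = connected_components(sub.tocsr(), directed=False)
    labels = labels.copy()
    labels[in_loop] = -1

    comp_ids = [c for c in range(n_comp) if np.any(labels == c)]
    if len(comp_ids) > 2:
        # a simple loop splits a surface into at most two regions; more
        # regions mean the snapped loop crosses itself on the mesh
        raise ValueError("boundary loop self-intersects on the mesh "
                         f"({len(comp_ids)} enclosed regions)")
    if len(comp_ids) == 1:
        chosen = comp_ids  # loop does not separate the mesh: whole mesh
    elif seed_point is not None:
        seed_v = tree.query(np.asarray(seed_point, dtype=float))[1]
        if labels[seed_v] < 0:
            raise ValueError("seed point snaps onto the boundary loop itself")
        chosen = [labels[seed_v]]
    elif opposing_values is not None:
        vals = np.asarray(opposing_values, dtype=float)
        chosen = [max(comp_ids, key=lambda c: vals[labels == c].mean())]
    else:
        raise ValueError("need seed_point or opposing_values to pick a side")

    patch_mask = in_loop.copy()
    for c in chosen:
        patch_mask |= labels == c
    face_keep = patch_mask[faces].all(axis=1)
    new_index = -np.ones(n, dtype=int)
    patch_vids = np.flatnonzero(patch_mask)
    new_index[patch_vids] = np.arange(len(patch_vids))
    new_faces = new_index[faces[face_keep]]
    patch_mesh = trimesh.Trimesh(
        vertices=verts[patch_vids], faces=new_faces,
        vertex_normals=np.asarray(mesh.vertex_normals)[patch_vids],
        process=False)
    return JointSpacePatch(mesh=patch_mesh, boundary=new_index[loop_arr],
                           source_id=source_id)


# ---------------------------------------------------------------------------
# isotropic remeshing (edge split / collapse / tangential relax + projection)
# ---------------------------------------------------------------------------

def _split_long_edges(verts, faces, max_len):
    """One pass of longest-edge midpoint splits; crack-free and local."""
    verts = list(map(np.asarray, verts))
    faces = [tuple(f) for f in faces]
    # edge -> adjacent face indices
    changed = True
    passes = 0
    while changed and passes < 10:
        changed = False
        passes += 1
        edge_faces: dict[tuple[int, int], list[int]] = {}
        for fi, f in enumerate(faces):
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                edge_faces.setdefault((min(a, b), max(a, b)), []).append(fi)
        varr = np.asarray(verts)
        long_edges = [
            (np.linalg.norm(varr[a] - varr[b]), (a, b))
            for (a, b) in edge_faces
            if np.linalg.norm(varr[a] - varr[b]) > max_len
        ]
        if not long_edges:
            break
        long_edges.sort(reverse=True)
        dead_faces: set[int] = set()
        new_faces: list[tuple[int, int, int]] = []
        for _, (a, b) in long_edges:
            fids = edge_faces[(a, b)]
            if any(fi in dead_faces for fi in fids):
                continue
            m = len(verts)
            verts.append((varr[a] + varr[b]) / 2.0)
            for fi in fids:
                f = faces[fi]
                # keep winding of the original face
                tri = list(f)
                ia, ib = tri.index(a), tri.index(b)
                f1 = list(f)
                f1[ib] = m
                f2 = list(f)
                f2[ia] = m
                new_faces.append(tuple(f1))
                new_faces.append(tuple(f2))
                dead_faces.add(fi)
            changed = True
        faces = [f for fi, f in enumerate(faces) if fi not in dead_faces]
        faces.extend(new_faces)
    return np.asarray(verts), np.asarray(faces, dtype=int)


def _collapse_short_edges(verts, faces, min_len, protected, budget=None):
    """One pass of short-edge collapses to midpoints, avoiding ``protected``
    vertices (boundary) and touching each vertex at most once per pass."""
    verts = np.asarray(verts, dtype=float).copy()
    faces = np.asarray(faces, dtype=int)
    edges = _edges_unique(faces)
    lens = np.linalg.norm(verts[edges[:, 0]] - verts[edges[:, 1]], axis=1)
    order = np.argsort(lens)
    used = np.zeros(len(verts), dtype=bool)
    remap = np.arange(len(verts))
    n_done = 0
    for ei in order:
        if lens[ei] >= min_len:
            break
        a, b = edges[ei]
        if used[a] or used[b] or protected[a] or protected[b]:
            continue
        verts[a] = (verts[a] + verts[b]) / 2.0
        remap[b] = a
        used[a] = used[b] = True
        n_done += 1
        if budget is not None and n_done >= budget:
            break
    if n_done == 0:
        return verts, faces, 0
    faces = remap[faces]
    good = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) \
        & (faces[:, 2] != faces[:, 0])
    faces = faces[good]
    # drop unreferenced vertices
    ref = np.zeros(len(verts), dtype=bool)
    ref[faces] = True
    new_index = -np.ones(len(verts), dtype=int)
    new_index[ref] = np.arange(ref.sum())
    return verts[ref], new_index[faces], n_done


def _tangential_relax(verts, faces, protected, projector, iterations=2,
                      step=0.5):
    """Laplacian relaxation of interior vertices with re-projection onto the
    source surface; boundary (protected) vertices never move."""
    verts = np.asarray(verts, dtype=float).copy()
    adj = _adjacency_lists(np.asarray(faces), len(verts))
    free = np.flatnonzero(~protected)
    for _ in range(iterations):
        target = verts.copy()
        for v in free:
            if len(adj[v]):
                target[v] = verts[adj[v]].mean(axis=0)
        verts[free] += step * (target[free] - verts[free])
        verts[free] = projector.project(verts[free])
    return verts


def retriangulate(patch: JointSpacePatch, target_vertex_count: int,
                  iterations: int = 5) -> JointSpacePatch:
    """Isotropic remesh of an open patch to about ``target_vertex_count``
    vertices (within +/-10 %), preserving the boundary vertices exactly.

    Target edge length is derived from patch area assuming near-equilateral
    triangles; alternating split/collapse passes with tangential relaxation
    and projection keep the output within a small Hausdorff distance of the
    input surface.
    """
    if target_vertex_count < 100:
        raise ValueError("target vertex count must be >= 100")
    source = patch.mesh
    projector = SurfaceProjector(source)
    area = float(source.area)
    verts = np.asarray(source.vertices, dtype=float)
    faces = np.asarray(source.faces, dtype=int)
    boundary_pts = verts[np.unique(patch.boundary)]

    def protected_mask(v, f):
        bset = _boundary_vertices(np.asarray(f))
        mask = np.zeros(len(v), dtype=bool)
        mask[bset] = True
        return mask

    n_bound = len(boundary_pts)
    interior_target = max(target_vertex_count - n_bound, 50)
    L = float(np.sqrt(2.0 * area / (np.sqrt(3.0) * interior_target)))

    for _ in range(iterations):
        verts, faces = _split_long_edges(verts, faces, 1.35 * L)
        prot = protected_mask(verts, faces)
        verts, faces, _ = _collapse_short_edges(verts, faces, 0.75 * L, prot)
        prot = protected_mask(verts, faces)
        verts = _tangential_relax(verts, faces, prot, projector)
        lo, hi = 0.92 * target_vertex_count, 1.08 * target_vertex_count
        if lo <= len(verts) <= hi:
            break

    # final nudge into the +/-10 % band
    guard = 0
    while len(verts) > 1.08 * target_vertex_count and guard < 20:
        prot = protected_mask(verts, faces)
        excess = len(verts) - int(1.0 * target_vertex_count)
        verts, faces, done = _collapse_short_edges(
            verts, faces, np.inf, prot, budget=max(excess, 1))
        if done == 0:
            break
        prot = protected_mask(verts, faces)
        verts = _tangential_relax(verts, faces, prot, projector, iterations=1)
        guard += 1
    guard = 0
    while len(verts) < 0.92 * target_vertex_count and guard < 20:
        edges = _edges_unique(faces)
        lens = np.linalg.norm(verts[edges[:, 0]] - verts[edges[:, 1]], axis=1)
        deficit = int(0.95 * target_vertex_count) - len(verts)
        thresh = np.partition(lens, -min(deficit, len(lens) - 1))[
            -min(deficit, len(lens) - 1)]
        verts, faces = _split_long_edges(verts, faces, max(thresh, 1e-6))
        prot = protected_mask(verts, faces)
        verts = _tangential_relax(verts, faces, prot, projector, iterations=1)
        guard += 1

    # carry the source patch's (field-gradient) normals over by barycentric
    # interpolation at the closest source points; winding normals alone would
    # re-introduce staircase tilt on thick-slice data
    normals = projector.interpolate(verts,
                                    np.asarray(source.vertex_normals))
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.where(norms > 1e-9, normals / np.maximum(norms, 1e-12), 0.0)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces,
                           vertex_normals=normals, process=False)
    # boundary loop of the remeshed patch: order the topological boundary
    bverts = _boundary_vertices(faces)
    boundary = _order_boundary_loop(faces, bverts)
    return JointSpacePatch(mesh=mesh, boundary=boundary,
                           source_id=patch.source_id)


def _order_boundary_loop(faces: np.ndarray, bverts: np.ndarray) -> np.ndarray:
    e = np.sort(np.vstack([faces[:, [0, 1]], faces[:, [1, 2]],
                           faces[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    bedges = uniq[counts == 1]
    nbr: dict[int, list[int]] = {}
    for a, b in bedges:
        nbr.setdefault(a, []).append(b)
        nbr.setdefault(b, []).append(a)
    if not nbr:
        return bverts
    start = int(bedges[0, 0])
    loop = [start]
    prev = -1
    while True:
        nxt = [v for v in nbr[loop[-1]] if v != prev]
        if not nxt:
            break
        prev = loop[-1]
        loop.append(int(nxt[0]))
        if loop[-1] == start:
            loop.pop()
            break
        if len(loop) > len(bedges) + 1:
            break
    return np.asarray(loop, dtype=int)


def save_patch(patch: JointSpacePatch, path: str) -> None:
    patch.mesh.export(path)


def load_mesh(path: str) -> trimesh.Trimesh:
    m = trimesh.load(path, force="mesh", process=False)
    return trimesh.Trimesh(vertices=m.vertices, faces=m.faces, process=False)
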