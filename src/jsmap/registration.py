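"""Volume and surface registration onto common frames.

Volumes are aligned with mutual-information similarity registration (7 DOF:
rotation, translation, isotropic scale), backed by SimpleITK's Mattes MI
metric with a multi-resolution pyramid.  Surfaces are aligned with a scaled
iterative-closest-point similarity stage followed by a regularised 3D
thin-plate spline on subsampled correspondences; per-vertex measurements are
then transferred onto an average template surface by nearest-vertex lookup
so that subjects can be compared vertex-to-vertex.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .surface import JointSpacePatch, SurfaceProjector, _adjacency_lists, \
    _boundary_vertices
from .volume_io import ImageVolume


@dataclass
class SimilarityTransform:
    """x -> scale * rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * p @ self.rotation.T + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return SimilarityTransform(
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
            self.scale * other.scale)

    def inverse(self) -> "SimilarityTransform":
        Rin = self.rotation.T
        return SimilarityTransform(Rin, -Rin @ self.translation / self.scale,
                                   1.0 / self.scale)

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
                "scale": self.scale}

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]),
                   float(d["scale"]))


@dataclass
class TPSTransform:
    """3D thin-plate (biharmonic, U(r) = r) spline deformation.

    At ``lam = 0`` the map interpolates the control-point correspondences
    exactly; larger ``lam`` trades fidelity for smoothness (lower bending
    energy).
    """

    control_points: np.ndarray
    weights: np.ndarray          # (n, 3) radial-basis coefficients
    affine: np.ndarray           # (4, 3): row 0 constant, rows 1:4 linear
    lam: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.linalg.norm(p[:, None, :] - self.control_points[None, :, :],
                           axis=2)
        return d @ self.weights + np.hstack([np.ones((len(p), 1)), p]) \
            @ self.affine

    def bending_energy(self) -> float:
        """w^T K w — the spline's integral bending norm up to a constant."""
        d = np.linalg.norm(self.control_points[:, None, :]
                           - self.control_points[None, :, :], axis=2)
        return float(np.einsum("ij,ik,jk->", d, self.weights, self.weights))

    def to_dict(self) -> dict:
        return {"control_points": self.control_points.tolist(),
                "weights": self.weights.tolist(),
                "affine": self.affine.tolist(), "lambda": self.lam}


def fit_tps(source: np.ndarray, target: np.ndarray,
            lam: float = 0.0) -> TPSTransform:
    """Fit a 3D TPS mapping ``source`` landmarks to ``target``.

    Raises on degenerate (coplanar) control points, where the side
    conditions make the system singular.
    """
    X = np.asarray(source, dtype=float)
    Y = np.asarray(target, dtype=float)
    n = len(X)
    if n < 5:
        raise ValueError("need at least 5 control points")
    P = np.hstack([np.ones((n, 1)), X])
    if np.linalg.matrix_rank(P, tol=1e-8) < 4:
        raise ValueError("degenerate (coplanar) control points")
    K = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K + lam * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.zeros((n + 4, 3))
    b[:n] = Y
    sol = np.linalg.solve(A, b)
    return TPSTransform(control_points=X, weights=sol[:n], affine=sol[n:],
                        lam=lam)


def umeyama(src: np.ndarray, dst: np.ndarray,
            with_scale: bool = True) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``src`` onto ``dst``."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    cov = xd.T @ xs / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    if with_scale:
        var_s = (xs ** 2).sum() / len(src)
        scale = float(np.trace(np.diag(S) @ D) / var_s)
    else:
        scale = 1.0
    t = mu_d - scale * R @ mu_s
    return SimilarityTransform(R, t, scale)


def _farthest_point_sample(points: np.ndarray, k: int,
                           seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n = len(points)
    if k >= n:
        return np.arange(n)
    chosen = [int(rng.integers(n))]
    d = np.linalg.norm(points - points[chosen[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.asarray(chosen)


def register_surfaces(
    source: trimesh.Trimesh | JointSpacePatch,
    target: trimesh.Trimesh | JointSpacePatch,
    n_control: int = 200,
    lam: float = 0.01,
    icp_iterations: int = 100,
    seed: int = 0,
) -> tuple[SimilarityTransform, TPSTransform, dict]:
    """Similarity (scaled ICP) then TPS registration of two surfaces.

    Returns the two transforms plus a diagnostics dict with mean
    point-to-surface residuals after each stage; the TPS stage never worsens
    the similarity-stage residual on the control correspondences.
    """
    smesh = source.mesh if isinstance(source, JointSpacePatch) else source
    tmesh = target.mesh if isinstance(target, JointSpacePatch) else target
    src = np.asarray(smesh.vertices, dtype=float)
    projector = SurfaceProjector(tmesh)
    # correspondences landing on the open boundary of the target slide along
    # the rim and bias the fit; exclude them, plus a worst-distance tail
    tfaces = np.asarray(tmesh.faces)
    bverts = _boundary_vertices(tfaces)
    on_boundary = np.zeros(len(tfaces), dtype=bool)
    if len(bverts):
        bmask = np.zeros(int(tfaces.max()) + 1, dtype=bool)
        bmask[bverts] = True
        on_boundary = bmask[tfaces].any(axis=1)

    sim = SimilarityTransform.identity()
    cur = src
    prev_res = np.inf
    coarse = max(icp_iterations // 3, 5)
    for it in range(icp_iterations):
        matched, fidx = projector.project(cur, return_index=True)
        d = np.linalg.norm(matched - cur, axis=1)
        valid = np.ones(len(cur), dtype=bool)
        if it >= coarse:
            # refinement: drop rim-sliding and worst-distance correspondences
            valid = ~on_boundary[fidx]
            if valid.sum() < 10:
                valid = np.ones(len(cur), dtype=bool)
            valid &= d <= np.quantile(d[valid], 0.9)
        step = umeyama(cur[valid], matched[valid])
        sim = step.compose(sim)
        cur = step.apply(cur)
        res = float(d[valid].mean())
        if it > coarse and abs(prev_res - res) < 1e-12:
            break
        prev_res = res
    res_similarity = float(projector.distance(cur).mean())

    ctrl_idx = _farthest_point_sample(cur, n_control, seed=seed)
    ctrl_src = cur[ctrl_idx]
    ctrl_dst = projector.project(ctrl_src)
    tps = fit_tps(ctrl_src, ctrl_dst, lam=lam)
    warped = tps.apply(cur)
    res_tps = float(projector.distance(warped).mean())
    info = {"residual_similarity": res_similarity, "residual_tps": res_tps}
    return sim, tps, info


def transfer_values(
    source_vertices: np.ndarray,
    values: np.ndarray,
    average_surface: trimesh.Trimesh,
    similarity: SimilarityTransform | None = None,
    tps: TPSTransform | None = None,
    smooth_passes: int = 1,
) -> np.ndarray:
    """Carry per-vertex values onto the average surface.

    Each average-surface vertex takes the value of the nearest transformed
    source vertex; optional uniform Laplacian passes (step 0.5, convex
    combinations only, missing stays missing) then smooth the transferred
    field.
    """
    pts = np.asarray(source_vertices, dtype=float)
    if similarity is not None:
        pts = similarity.apply(pts)
    if tps is not None:
        pts = tps.apply(pts)
    tree = cKDTree(pts)
    _, idx = tree.query(np.asarray(average_surface.vertices))
    out = np.asarray(values, dtype=float)[idx]
    if smooth_passes > 0:
        adj = _adjacency_lists(np.asarray(average_surface.faces), len(out))
        for _ in range(smooth_passes):
            new = out.copy()
            for v in range(len(out)):
                if not np.isfinite(out[v]):
                    continue
                ring = [u for u in adj[v] if np.isfinite(out[u])]
                if ring:
                    new[v] = out[v] + 0.5 * (np.mean(out[ring]) - out[v])
            out = new
    return out


@dataclass
class AverageSurface:
    mesh: trimesh.Trimesh
    provenance: list[str] = field(default_factory=list)


def build_average_surface(
    surfaces: list[trimesh.Trimesh | JointSpacePatch],
    target_vertex_count: int | None = None,
    iterations: int = 2,
    register: bool = True,
    boundary_smooth_passes: int = 5,
    ids: list[str] | None = None,
) -> AverageSurface:
    """Surface- and edge-smoothed average of registered contributor surfaces.

    The first surface seeds the reference; each refinement pass registers
    every contributor to the current reference (optional — disable for
    pre-aligned inputs), samples each contributor at the reference vertices
    by closest point, and moves the reference by the smoothed mean offset
    field.  Boundary ("edge") smoothing runs along the open boundary loop
    only.  Averaging by offset fields makes a set of identical contributors
    an exact fixed point.
    """
    if len(surfaces) < 2:
        raise ValueError("need at least 2 surfaces to average")
    meshes = [s.mesh if isinstance(s, JointSpacePatch) else s
              for s in surfaces]
    ref = trimesh.Trimesh(np.asarray(meshes[0].vertices).copy(),
                          np.asarray(meshes[0].faces).copy(), process=False)
    for _ in range(iterations):
        offsets = np.zeros((len(meshes),) + ref.vertices.shape)
        for si, m in enumerate(meshes):
            if register:
                try:
                    sim, tps, _ = register_surfaces(m, ref)
                except ValueError as exc:
                    raise RuntimeError(
                        f"registration failed for surface {si}: {exc}"
                    ) from exc
                verts = tps.apply(sim.apply(np.asarray(m.vertices)))
            else:
                verts = np.asarray(m.vertices)
            moved = trimesh.Trimesh(verts, np.asarray(m.faces), process=False)
            proj = SurfaceProjector(moved)
            offsets[si] = proj.project(np.asarray(ref.vertices)) \
                - np.asarray(ref.vertices)
        mean_off = offsets.mean(axis=0)
        faces = np.asarray(ref.faces)
        # surface smoothing of the offset field (identical contributors
        # give a zero field, so the reference is then an exact fixed point)
        mean_off = _smooth_field(mean_off, faces, passes=2)
        # edge smoothing: extra Laplacian passes of the offset field along
        # the open boundary chain only
        bverts = _boundary_vertices(faces)
        if len(bverts) and boundary_smooth_passes > 0:
            nbr: dict[int, list[int]] = {int(v): [] for v in bverts}
            e = np.sort(np.vstack([faces[:, [0, 1]], faces[:, [1, 2]],
                                   faces[:, [2, 0]]]), axis=1)
            uniq, counts = np.unique(e, axis=0, return_counts=True)
            for a, b in uniq[counts == 1]:
                nbr[int(a)].append(int(b))
                nbr[int(b)].append(int(a))
            for _ in range(boundary_smooth_passes):
                upd = mean_off.copy()
                for v in bverts:
                    if len(nbr[int(v)]) >= 2:
                        mid = mean_off[nbr[int(v)]].mean(axis=0)
                        upd[v] = mean_off[v] + 0.5 * (mid - mean_off[v])
                mean_off = upd
        ref = trimesh.Trimesh(np.asarray(ref.vertices) + mean_off,
                              faces, process=False)

    faces = np.asarray(ref.faces)
    if target_vertex_count is not None:
        from .surface import retriangulate

        patch = JointSpacePatch(mesh=ref, boundary=_boundary_vertices(faces))
        ref = retriangulate(patch, target_vertex_count).mesh
    return AverageSurface(mesh=ref,
                          provenance=list(ids or map(str, range(len(meshes)))))


def _smooth_field(field: np.ndarray, faces: np.ndarray,
                  passes: int = 2, step: float = 0.5) -> np.ndarray:
    out = np.asarray(field, dtype=float).copy()
    adj = _adjacency_lists(faces, len(out))
    for _ in range(passes):
        new = out.copy()
        for v in range(len(out)):
            if len(adj[v]):
                new[v] = out[v] + step * (out[adj[v]].mean(axis=0) - out[v])
        out = new
    return out


# ---------------------------------------------------------------------------
# volume registration (mutual information, SimpleITK backend)
# ---------------------------------------------------------------------------

def register_volumes_mi(
    fixed: ImageVolume,
    moving: ImageVolume,
    init: SimilarityTransform | None = None,
    bins: int = 64,
    sampling_fraction: float | None = None,
) -> tuple[SimilarityTransform, dict]:
    """Similarity registration maximising mutual information.

    Returns the transform mapping fixed-space points into moving space (the
    resampling convention) and a diagnostics dict with initial/final metric
    values; the optimisation never returns a transform with lower MI than its
    initialisation.  Degenerate (constant) volumes yield the identity with a
    warning.
    """
    import SimpleITK as sitk

    from .volume_io import _to_sitk

    if float(np.ptp(fixed.data)) == 0 or float(np.ptp(moving.data)) == 0:
        warnings.warn("constant volume: mutual information has zero "
                      "gradient; returning identity transform")
        return SimilarityTransform.identity(), {"initial_metric": 0.0,
                                                "final_metric": 0.0}

    f = sitk.Cast(_to_sitk(fixed), sitk.sitkFloat32)
    m = sitk.Cast(_to_sitk(moving), sitk.sitkFloat32)

    tx = sitk.CenteredTransformInitializer(
        f, m, sitk.Similarity3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    tx = sitk.Similarity3DTransform(tx)
    if init is not None:
        tx.SetMatrix(tuple((init.scale * init.rotation).ravel()))
        tx.SetTranslation(tuple(init.translation))
        tx.SetCenter((0.0, 0.0, 0.0))

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    if sampling_fraction is not None:
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(sampling_fraction)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=300,
        gradientMagnitudeTolerance=1e-8)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(sitk.Similarity3DTransform(tx), inPlace=False)
    initial_metric = reg.MetricEvaluate(f, m)

    result = sitk.Similarity3DTransform(tx)
    reg.SetInitialTransform(result, inPlace=True)
    try:
        reg.Execute(f, m)
    except RuntimeError as exc:
        raise RuntimeError(f"MI registration diverged: {exc}") from exc
    reg.SetInitialTransform(sitk.Similarity3DTransform(result), inPlace=False)
    final_metric = reg.MetricEvaluate(f, m)
    # Mattes metric is negated MI: lower is better
    if final_metric > initial_metric + 1e-9:
        result = tx
        final_metric = initial_metric

    M = np.asarray(result.GetMatrix()).reshape(3, 3)
    scale = float(np.cbrt(np.linalg.det(M)))
    R = M / scale
    c = np.asarray(result.GetCenter())
    t = np.asarray(result.GetTranslation())
    translation = c + t - M @ c
    out = SimilarityTransform(R, translation, scale)
    return out, {"initial_metric": float(initial_metric),
                 "final_metric": float(final_metric)}


def save_transform(path: str, similarity: SimilarityTransform,
                   tps: TPSTransform | None = None) -> None:
    payload = {"similarity": similarity.to_dict()}
    if tps is not None:
        payload["tps"] = tps.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_transform(path: str):
    with open(path) as fh:
        payload = json.load(fh)
    sim = SimilarityTransform.from_dict(payload["similarity"])
    tps = None
    if "tps" in payload:
        d = payload["tps"]
        tps = TPSTransform(np.asarray(d["control_points"]),
                           np.asarray(d["weights"]),
                           np.asarray(d["affine"]), float(d["lambda"]))
    return sim, tps
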