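"""Semi-interactive tooth segmentation.

The slice-wise stage builds a pixel graph whose edge costs derive from
inverted gradient magnitude and chains globally minimal-cost paths
between user anchors (raster-scan dynamic programming, equivalent to
Dijkstra on the 8-connected grid).  The 3D stage interpolates the
resulting orthogonal contour stacks with an energy-minimizing
radial-basis implicit surface (triharmonic kernel plus linear trend),
rasterizes its sign into a mask, and extracts a triangle mesh.

Anchors and contours travel as JSON-lines records so interactive
editing can be replayed in batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.linalg import lu_factor as scipy_lu_factor, lu_solve as scipy_lu_solve
from scipy.spatial.distance import cdist
from skimage.measure import marching_cubes

from .imaging import IntensityWindow, ParameterError, VoxelVolume
from .mesh import MeshError, TriangleMesh, mask_to_mesh

__all__ = [
    "PlanarContour",
    "ContourSet",
    "ImplicitSurface",
    "BinaryMask",
    "edge_cost",
    "minimal_cost_path",
    "path_cost",
    "trace_contour",
    "fit_variational_surface",
    "rasterize_mask",
    "extract_surface_mesh",
    "ContourError",
]

_SQRT2 = float(np.sqrt(2.0))

# fixed neighbor enumeration order (dr, dc, step length): deterministic ties
_NEIGHBORS = (
    (-1, -1, _SQRT2),
    (-1, 0, 1.0),
    (-1, 1, _SQRT2),
    (0, -1, 1.0),
    (0, 1, 1.0),
    (1, -1, _SQRT2),
    (1, 0, 1.0),
    (1, 1, _SQRT2),
)


class ContourError(ValueError):
    """Degenerate or invalid contour geometry."""


@dataclass
class PlanarContour:
    """Closed polygon on one orthogonal slice plane.

    ``points`` are (row, col) pixel coordinates in the slice obtained by
    indexing the volume along ``plane_axis`` at ``plane_index``; the first
    point is not repeated at the end.
    """

    plane_axis: int
    plane_index: int
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if len(self.points) >= 2 and np.allclose(self.points[0], self.points[-1]):
            self.points = self.points[:-1]
        if len(self.points) < 3:
            raise ContourError("contour needs at least 3 distinct points")

    def to_world(self, spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
        """Lift slice points to 3D mm coordinates."""
        spacing = np.asarray(spacing, float)
        origin = np.asarray(origin, float)
        other = [a for a in range(3) if a != self.plane_axis]
        idx = np.zeros((len(self.points), 3))
        idx[:, self.plane_axis] = self.plane_index
        idx[:, other[0]] = self.points[:, 0]
        idx[:, other[1]] = self.points[:, 1]
        return origin + idx * spacing

    def inward_normals(self) -> np.ndarray:
        """Unit 2D normals pointing into the enclosed region.

        The tangent is estimated over a widened stencil so pixel-level
        jaggies from livewire paths do not flip individual normals."""
        p = self.points
        k = min(max(1, len(p) // 24), 4)
        nxt = np.roll(p, -k, axis=0)
        prv = np.roll(p, k, axis=0)
        tangent = nxt - prv
        # rotate tangent by +90deg; sign fixed by polygon orientation
        normal = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)
        ln = np.linalg.norm(normal, axis=1)
        ln[ln == 0] = 1.0
        normal /= ln[:, None]
        area2 = float(np.sum(p[:, 0] * nxt[:, 1] - nxt[:, 0] * p[:, 1]))
        if area2 < 0:
            normal = -normal
        return normal


@dataclass
class ContourSet:
    """Contours of one tooth, referenced to a common volume frame."""

    contours: list
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    tooth_label: str = "tooth"

    def __post_init__(self) -> None:
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float).ravel(), (3,)).astype(float)
        self.origin = np.asarray(self.origin, float).reshape(3)

    def axes(self) -> set:
        return {c.plane_axis for c in self.contours}

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"spacing": list(self.spacing), "origin": list(self.origin),
                                 "label": self.tooth_label}) + "\n")
            for c in self.contours:
                fh.write(json.dumps({"axis": c.plane_axis, "slice": c.plane_index,
                                     "points": c.points.tolist()}) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "ContourSet":
        with open(path) as fh:
            head = json.loads(fh.readline())
            contours = [
                PlanarContour(rec["axis"], rec["slice"], np.asarray(rec["points"]))
                for rec in map(json.loads, fh)
            ]
        return cls(contours, head["spacing"], head["origin"], head.get("label", "tooth"))


@dataclass
class BinaryMask:
    """Boolean grid aligned to a reference volume frame."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float).ravel(), (3,)).astype(float)
        self.origin = np.asarray(self.origin, float).reshape(3)

    @property
    def shape(self):
        return self.data.shape

    def volume_mm3(self) -> float:
        return float(self.data.sum() * np.prod(self.spacing))


# -- livewire --------------------------------------------------------------


def edge_cost(slice_image: np.ndarray) -> np.ndarray:
    """Pixel cost 1 - g/g_max from central-difference gradient magnitude.

    Strong edges get cost near 0.  A constant slice (zero gradient
    everywhere) yields uniform cost 1 — documented fallback, no error.
    """
    img = np.asarray(slice_image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ParameterError("edge_cost needs a 2D slice of at least 2x2 pixels")
    gr, gc = np.gradient(img)
    g = np.hypot(gr, gc)
    gmax = g.max()
    if gmax == 0:
        return np.ones_like(img)
    return 1.0 - g / gmax


def minimal_cost_path(cost: np.ndarray, start, end) -> np.ndarray:
    """Globally minimal-cost 8-connected path between two pixels.

    The accumulated cost is the sum over steps of destination-pixel cost
    times geometric step length (sqrt(2) on diagonals).  Distances are
    computed with an iterative raster-scan dynamic program: alternating
    forward and backward half-neighborhood sweeps until a full pass makes
    no update, which converges to the Dijkstra fixed point on this graph.
    Returns the path as an (k, 2) array of (row, col), start first.
    """
    cost = np.asarray(cost, dtype=np.float64)
    start = tuple(int(v) for v in start)
    end = tuple(int(v) for v in end)
    nr, nc = cost.shape
    for p in (start, end):
        if not (0 <= p[0] < nr and 0 <= p[1] < nc):
            raise ParameterError(f"path endpoint {p} outside {cost.shape} grid")
    if start == end:
        raise ParameterError("path endpoints must differ")

    dist = np.full(cost.shape, np.inf)
    dist[start] = 0.0
    pred = np.full((nr, nc, 2), -1, dtype=np.int64)
    forward = [n for n in _NEIGHBORS if (n[0], n[1]) < (0, 1)]  # NW N NE W
    backward = [n for n in _NEIGHBORS if (n[0], n[1]) > (0, -1)]  # E SW S SE
    changed = True
    while changed:
        changed = False
        for rows, cols, nbrs in (
            (range(nr), range(nc), forward),
            (range(nr - 1, -1, -1), range(nc - 1, -1, -1), backward),
        ):
            for r in rows:
                for c in cols:
                    best = dist[r, c]
                    bp = None
                    for dr, dc, ln in nbrs:
                        pr, pc = r - dr, c - dc
                        if 0 <= pr < nr and 0 <= pc < nc:
                            cand = dist[pr, pc] + cost[r, c] * ln
                            if cand < best:
                                best = cand
                                bp = (pr, pc)
                    if bp is not None:
                        dist[r, c] = best
                        pred[r, c] = bp
                        changed = True
    # predecessor links form a tree rooted at start (each was set on a
    # strict improvement), so backtracking terminates
    path = [end]
    cur = end
    guard = nr * nc + 1
    while cur != start:
        guard -= 1
        if guard == 0 or pred[cur][0] < 0:  # pragma: no cover - defensive
            raise RuntimeError("backtrack failed; inconsistent distance field")
        cur = tuple(pred[cur])
        path.append(cur)
    return np.asarray(path[::-1], dtype=np.int64)


def path_cost(cost: np.ndarray, path: np.ndarray) -> float:
    """Accumulated cost of a pixel path under the livewire step model."""
    path = np.asarray(path)
    steps = np.abs(np.diff(path, axis=0))
    lengths = np.where(steps.sum(axis=1) == 2, _SQRT2, 1.0)
    return float((cost[tuple(path[1:].T)] * lengths).sum())


def _preprocess_slice(slice_image, window: IntensityWindow | None, median_radius: int):
    img = np.asarray(slice_image, dtype=np.float64)
    if window is not None:
        y = (img - window.low) / (window.high - window.low)
        np.clip(y, 0.0, 1.0, out=y)
        img = window.out_low + y * (window.out_high - window.out_low)
    if median_radius >= 1:
        img = ndimage.median_filter(img, size=2 * median_radius + 1, mode="nearest")
    return img


def trace_contour(
    slice_image: np.ndarray,
    anchors,
    plane_axis: int = 2,
    plane_index: int = 0,
    window: IntensityWindow | None = None,
    median_radius: int = 1,
) -> PlanarContour:
    """Chain livewire segments through ordered anchors into a closed contour.

    The slice is windowed and median-filtered first; each consecutive
    anchor pair (and last back to first) contributes a minimal-cost path.
    """
    anchors = np.asarray(anchors, dtype=np.int64).reshape(-1, 2)
    if len(anchors) < 3:
        raise ContourError("need at least 3 anchors to close a contour")
    if len(np.unique(anchors, axis=0)) < 3:
        raise ContourError("anchors are degenerate (duplicates)")
    img = _preprocess_slice(slice_image, window, median_radius)
    cost = edge_cost(img)
    pieces = []
    for a, b in zip(anchors, np.roll(anchors, -1, axis=0)):
        seg = minimal_cost_path(cost, a, b)
        pieces.append(seg[:-1])  # drop joint, next piece starts with it
    poly = np.concatenate(pieces)
    # drop immediate duplicates
    keep = np.ones(len(poly), dtype=bool)
    keep[1:] = np.any(np.diff(poly, axis=0) != 0, axis=1)
    poly = poly[keep]
    if len(poly) < 3:
        raise ContourError("anchors produced a degenerate polygon")
    return PlanarContour(plane_axis, plane_index, poly.astype(float))


# -- variational implicit surface -----------------------------------------


@dataclass
class ImplicitSurface:
    """Triharmonic RBF interpolant f(x) = sum w_i |x-c_i|^3 + p(x).

    Sign convention: negative inside the object, zero on the surface.
    """

    centers: np.ndarray
    weights: np.ndarray
    polynomial: np.ndarray  # (4,): constant + linear coefficients

    def __call__(self, points: np.ndarray, chunk: int = 65536) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        out = np.empty(len(pts))
        for s in range(0, len(pts), chunk):
            block = pts[s : s + chunk]
            d = cdist(block, self.centers)
            out[s : s + chunk] = (d * d * d) @ self.weights
        out += self.polynomial[0] + pts @ self.polynomial[1:]
        return out if np.asarray(points).ndim > 1 else out[0]

    def evaluate_on_frame(self, frame: VoxelVolume) -> np.ndarray:
        ax = [frame.voxel_centers_axis(a) for a in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        return self(pts).reshape(frame.shape)

    def zero_level_mesh(self, frame: VoxelVolume, name: str = "surface") -> TriangleMesh:
        """Sub-voxel triangulation of the zero level set over a frame."""
        field = self.evaluate_on_frame(frame)
        if field.min() >= 0 or field.max() <= 0:
            raise MeshError("zero level set does not intersect the frame")
        verts, faces, _, _ = marching_cubes(field, level=0.0, spacing=tuple(frame.spacing))
        m = TriangleMesh(verts + frame.origin, faces, name).merged()
        return m if m.volume() >= 0 else m.flipped()


def fit_variational_surface(
    contours: ContourSet,
    normal_offset: float | None = None,
    interior_value: float = -1.0,
) -> ImplicitSurface:
    """Fit the energy-minimizing implicit surface through contour stacks.

    On-surface constraints (value 0) at every contour point; off-surface
    constraints at points displaced *inward* along the 2D contour normals
    by ``normal_offset`` mm (default: one in-plane voxel), with value
    ``interior_value`` (negative-inside convention).  Solved densely with
    the triharmonic kernel plus a linear polynomial; duplicate constraint
    points are removed before solving.
    """
    if len(contours.axes()) < 2:
        raise ParameterError("contours must span at least 2 distinct plane axes")
    pts = []
    vals = []
    for c in contours.contours:
        if normal_offset is None:
            other = [a for a in range(3) if a != c.plane_axis]
            offset = float(min(contours.spacing[other]))
        else:
            offset = float(normal_offset)
        world = c.to_world(contours.spacing, contours.origin)
        pts.append(world)
        vals.append(np.zeros(len(world)))
        inner2d = c.points + c.inward_normals() * (
            offset / contours.spacing[[a for a in range(3) if a != c.plane_axis]]
        )
        inner = PlanarContour(c.plane_axis, c.plane_index, inner2d).to_world(
            contours.spacing, contours.origin
        )
        pts.append(inner)
        vals.append(np.full(len(inner), float(interior_value)))
    P = np.concatenate(pts)
    V = np.concatenate(vals)
    if len(P) < 10:
        raise ParameterError("need at least 10 constraints to fit a surface")
    # deduplicate (exact, after rounding to nm) keeping first occurrence
    _, idx = np.unique(np.round(P * 1e6).astype(np.int64), axis=0, return_index=True)
    idx = np.sort(idx)
    P, V = P[idx], V[idx]
    n = len(P)
    d = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=2)
    K = d**3
    Q = np.concatenate([np.ones((n, 1)), P], axis=1)
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = Q
    A[n:, :n] = Q.T
    rhs = np.concatenate([V, np.zeros(4)])
    try:
        lu, piv = scipy_lu_factor(A)
        sol = scipy_lu_solve((lu, piv), rhs)
        for _ in range(2):  # iterative refinement: kernel is ill-conditioned
            r = rhs - A @ sol
            sol = sol + scipy_lu_solve((lu, piv), r)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ArithmeticError("singular interpolation system after deduplication") from exc
    surf = ImplicitSurface(P, sol[:n], sol[n:])
    resid = np.abs(surf(P) - V)
    scale = max(1.0, float(np.abs(V).max()))
    if resid.max() > 1e-6 * scale:
        raise ArithmeticError(f"interpolation residual {resid.max():.3g} exceeds tolerance")
    return surf


def rasterize_mask(surface: ImplicitSurface, frame: VoxelVolume) -> BinaryMask:
    """Voxel is inside iff the implicit value at its center is negative."""
    vals = surface.evaluate_on_frame(frame)
    return BinaryMask(vals < 0, frame.spacing, frame.origin)


def extract_surface_mesh(mask: BinaryMask, smooth_sigma: float = 0.6, name: str = "tooth") -> TriangleMesh:
    """Marching-cubes triangulation of a binary mask in world mm."""
    if not np.any(mask.data):
        raise MeshError("cannot extract a surface from an empty mask")
    return mask_to_mesh(mask.data, mask.spacing, mask.origin, smooth_sigma=smooth_sigma, name=name)
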