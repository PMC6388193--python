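"""Synthetic tooth/veneer phantoms with exact ground truth.

Everything here is deterministic under its seed.  Teeth are smooth
superellipsoid composites (two-cusp premolar, flat-faced incisor) meshed
by marching cubes; seated veneers are built by offsetting the labial
surface patch of a tooth by a prescribed spatially varying gap field, so
the true gap at every intaglio vertex is known by construction.

Axis conventions: x mesiodistal, y labio-lingual (labial = +y),
z occluso-apical (crown tip = +z, root = -z).  Units mm; gap fields µm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.measure import marching_cubes

from .imaging import ParameterError, VoxelVolume
from .mesh import MeshError, TriangleMesh, contains_points, voxelize, write_mesh

__all__ = [
    "ToothPhantomSpec",
    "GapFieldSpec",
    "GapField",
    "ScanSpec",
    "SeatedPair",
    "make_tooth",
    "make_veneer_region_box",
    "make_seated_pair",
    "voxelize_scene",
    "render_margin_image",
    "make_batch",
    "box_mesh",
]


@dataclass(frozen=True)
class ToothPhantomSpec:
    kind: str = "premolar"  # premolar | incisor
    crown_width: float = 7.0  # mesiodistal, mm
    crown_depth: float = 6.5  # labio-lingual
    crown_height: float = 7.0
    root_length: float = 11.0
    root_taper: float = 0.65  # apex radius fraction lost over the length
    bumpiness: float = 0.0  # mm amplitude of the seeded surface perturbation
    seed: int = 0
    mesh_pitch: float = 0.15

    def __post_init__(self):
        for name in ("crown_width", "crown_depth", "crown_height", "root_length", "mesh_pitch"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.kind not in ("premolar", "incisor"):
            raise ParameterError(f"unknown tooth kind {self.kind!r}")


@dataclass(frozen=True)
class GapFieldSpec:
    model: str = "uniform"  # uniform | normal | sinusoidal
    mean: float = 100.0  # µm
    sd: float = 0.0  # µm
    wavelength: float = 3.0  # mm spatial scale
    truncation: float = 0.0  # µm lower bound
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("uniform", "normal", "sinusoidal"):
            raise ParameterError(f"unknown gap model {self.model!r}")
        if self.truncation < 0:
            raise ParameterError("truncation must be >= 0")


class GapField:
    """Realized spatial gap field; callable on (n, 3) mm points, returns µm."""

    def __init__(self, spec: GapFieldSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        if spec.model == "normal":
            # smooth Gaussian random field by spectral superposition
            K = 48
            dirs = rng.normal(size=(K, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            self._k = dirs * (2 * np.pi / max(spec.wavelength, 1e-6))
            self._phase = rng.uniform(0, 2 * np.pi, K)
            self._amp = np.sqrt(2.0 / K)
        elif spec.model == "sinusoidal":
            self._dir = np.array([1.0, 0.0, 1.0]) / np.sqrt(2.0)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        s = self.spec
        if s.model == "uniform":
            g = np.full(len(p), s.mean)
        elif s.model == "sinusoidal":
            t = p @ self._dir
            g = s.mean + np.sqrt(2.0) * s.sd * np.sin(2 * np.pi * t / s.wavelength)
        else:
            z = self._amp * np.cos(p @ self._k.T + self._phase).sum(axis=1)
            g = s.mean + s.sd * z
        clipped = np.maximum(g, s.truncation)
        if np.any(g < 0):
            warnings.warn("gap realization went negative; clamped", stacklevel=2)
        return clipped


@dataclass(frozen=True)
class ScanSpec:
    spacing: float = 0.2  # mm: 0.2 CBCT-like, 0.0128 µCT-like
    phase_intensities: tuple = (
        ("background", 0.0),
        ("tooth", 100.0),
        ("veneer", 60.0),
    )
    noise_sd: float = 0.0
    blur_fwhm: float = 0.0  # mm
    seed: int = 0

    def intensity_map(self) -> dict:
        return dict(self.phase_intensities)


# -- implicit tooth fields -------------------------------------------------


def _superellipsoid(X, Y, Z, center, radii, p=(2.0, 2.0, 2.0)):
    u = np.abs((X - center[0]) / radii[0]) ** p[0]
    v = np.abs((Y - center[1]) / radii[1]) ** p[1]
    w = np.abs((Z - center[2]) / radii[2]) ** p[2]
    return u + v + w - 1.0


def _smooth_min(a, b, k=8.0):
    # log-sum-exp blend: C1 union of implicit solids
    return -np.logaddexp(-k * a, -k * b) / k


def _tooth_field(spec: ToothPhantomSpec, X, Y, Z, rng):
    w, d, h = spec.crown_width / 2, spec.crown_depth / 2, spec.crown_height / 2
    crown_c = (0.0, 0.0, h)
    if spec.kind == "premolar":
        body = _superellipsoid(X, Y, Z, crown_c, (w, d, h), p=(2.6, 2.6, 2.2))
        # two cusps: buccal and lingual bumps on the occlusal table
        cusp_b = _superellipsoid(X, Y, Z, (0.0, 0.45 * d, 1.75 * h), (0.55 * w, 0.5 * d, 0.55 * h))
        cusp_l = _superellipsoid(X, Y, Z, (0.0, -0.45 * d, 1.7 * h), (0.5 * w, 0.45 * d, 0.5 * h))
        f = _smooth_min(body, _smooth_min(cusp_b, cusp_l))
        root_r = (0.55 * w, 0.6 * d)
    else:
        # incisor: thin labio-lingually, flat labial face (high exponent on y)
        body = _superellipsoid(X, Y, Z, crown_c, (w, d, h), p=(2.8, 4.5, 2.0))
        edge = _superellipsoid(X, Y, Z, (0.0, 0.0, 1.6 * h), (0.8 * w, 0.5 * d, 0.6 * h))
        f = _smooth_min(body, edge)
        root_r = (0.45 * w, 0.55 * d)
    # tapered root going down from z=0; radius shrinks linearly to the apex
    L = spec.root_length
    shrink = np.clip(1.0 + Z / L * spec.root_taper, 0.25, 1.0)
    root = (
        (X / (root_r[0] * shrink)) ** 2
        + (Y / (root_r[1] * shrink)) ** 2
        + ((Z + 0.45 * L) / (0.55 * L)) ** 2
        - 1.0
    )
    f = _smooth_min(f, root)
    if spec.bumpiness > 0:
        K = 24
        dirs = rng.normal(size=(K, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        kvec = dirs * (2 * np.pi / 2.5)
        phase = rng.uniform(0, 2 * np.pi, K)
        P = np.stack([X, Y, Z], axis=-1)
        noise = np.sqrt(2.0 / K) * np.cos(P @ kvec.T + phase).sum(axis=-1)
        f = f + spec.bumpiness * noise / max(spec.crown_width, 1.0)
    return f


def make_tooth(spec: ToothPhantomSpec) -> TriangleMesh:
    """Watertight parametric tooth mesh, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    pitch = spec.mesh_pitch
    margin = 1.0
    w, d = spec.crown_width / 2 + margin, spec.crown_depth / 2 + margin
    gx = np.arange(-w * 1.3, w * 1.3 + pitch, pitch)
    gy = np.arange(-d * 1.4, d * 1.4 + pitch, pitch)
    gz = np.arange(-spec.root_length - margin, spec.crown_height * 1.45 + margin, pitch)
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    f = _tooth_field(spec, X, Y, Z, rng)
    if f.min() >= 0:
        raise ParameterError("degenerate tooth spec: empty solid")
    verts, faces, _, _ = marching_cubes(f, level=0.0, spacing=(pitch, pitch, pitch))
    verts = verts + np.array([gx[0], gy[0], gz[0]])
    m = TriangleMesh(verts, faces, f"{spec.kind}_{spec.seed}").merged()
    if m.volume() < 0:
        m = m.flipped()
    return m


def box_mesh(lo, hi, name: str = "box") -> TriangleMesh:
    """Axis-aligned box as 12 outward-wound triangles."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    x0, y0, z0 = lo
    x1, y1, z1 = hi
    v = np.array(
        [
            [x0, y0, z0], [x1, y0, z0], [x1, y1, z0], [x0, y1, z0],
            [x0, y0, z1], [x1, y0, z1], [x1, y1, z1], [x0, y1, z1],
        ]
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom
            [4, 5, 6], [4, 6, 7],  # top
            [0, 1, 5], [0, 5, 4],  # y0
            [2, 3, 7], [2, 7, 6],  # y1
            [1, 2, 6], [1, 6, 5],  # x1
            [3, 0, 4], [3, 4, 7],  # x0
        ]
    )
    return TriangleMesh(v, f, name)


def make_veneer_region_box(tooth: TriangleMesh, cervical_z: float | None = None,
                           labial_fraction: float = 0.25) -> TriangleMesh:
    """Box enclosing the labial face of the crown: the region a veneer covers."""
    lo, hi = tooth.bounds()
    if cervical_z is None:
        cervical_z = lo[2] + 0.72 * (hi[2] - lo[2])
    y_cut = lo[1] + labial_fraction * (hi[1] - lo[1])
    return box_mesh(
        [lo[0] - 0.5, y_cut, cervical_z],
        [hi[0] + 0.5, hi[1] + 2.0, hi[2] + 0.5],
        name="veneer_region",
    )


@dataclass
class SeatedPair:
    """Veneer seated on a tooth with known per-vertex gap truth."""

    tooth: TriangleMesh
    veneer: TriangleMesh
    intaglio_vertices: np.ndarray  # indices into veneer.vertices
    gap_truth_um: np.ndarray  # µm at each intaglio vertex
    gap_field: GapField


def _largest_face_component(mesh: TriangleMesh, face_sel: np.ndarray) -> np.ndarray:
    """Indices of the largest connected component among selected faces."""
    faces = mesh.faces[face_sel]
    ids = np.flatnonzero(face_sel)
    # faces connected iff sharing a vertex
    nv = mesh.n_vertices
    rows = np.repeat(np.arange(len(faces)), 3)
    cols = faces.ravel()
    m = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(faces), nv))
    adj = m @ m.T
    n, labels = connected_components(adj, directed=False)
    if n == 1:
        return ids
    counts = np.bincount(labels)
    return ids[labels == counts.argmax()]


def _smoothed_vertex_normals(mesh: TriangleMesh, iterations: int = 2) -> np.ndarray:
    vn = mesh.vertex_normals()
    e = np.unique(mesh.edges_sorted(), axis=0)
    for _ in range(iterations):
        acc = vn.copy()
        np.add.at(acc, e[:, 0], vn[e[:, 1]])
        np.add.at(acc, e[:, 1], vn[e[:, 0]])
        ln = np.linalg.norm(acc, axis=1)
        ln[ln == 0] = 1.0
        vn = acc / ln[:, None]
    return vn


def make_seated_pair(
    tooth: TriangleMesh,
    veneer_outer: TriangleMesh,
    gap: GapFieldSpec | GapField,
    shell_thickness: float = 0.5,
    region_pitch: float = 0.1,
) -> SeatedPair:
    """Seat a veneer over the tooth with a prescribed gap field.

    The veneer intaglio is the tooth surface patch inside ``veneer_outer``
    offset outward along smoothed vertex normals by the realized gap; the
    outer shell is the same patch offset by gap + ``shell_thickness``.
    Rim walls stitch the two sheets into a watertight solid.  The gap
    truth at each intaglio vertex is exact by construction.
    """
    gap_field = gap if isinstance(gap, GapField) else GapField(gap)
    inside = contains_points(veneer_outer, tooth.vertices, pitch=region_pitch)
    face_sel = inside[tooth.faces].all(axis=1)
    if not face_sel.any():
        raise MeshError("veneer region does not cover any tooth surface")
    keep = _largest_face_component(tooth, face_sel)
    patch_faces = tooth.faces[keep]
    used = np.unique(patch_faces)
    remap = -np.ones(tooth.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    pf = remap[patch_faces]
    pv = tooth.vertices[used]
    normals = _smoothed_vertex_normals(tooth)[used]
    g_um = gap_field(pv)
    g_mm = g_um / 1000.0
    inner_v = pv + normals * g_mm[:, None]
    outer_v = pv + normals * (g_mm + shell_thickness)[:, None]
    n = len(pv)
    # vertex layout: [0:n) intaglio, [n:2n) outer
    verts = np.concatenate([inner_v, outer_v])
    inner_faces = pf[:, ::-1]  # outward normal of the solid points at the tooth
    outer_faces = pf + n
    patch = TriangleMesh(pv, pf)
    rim = patch.boundary_edges()  # directed (a, b) as wound in the patch
    a, b = rim[:, 0], rim[:, 1]
    wall1 = np.stack([b + n, a + n, a], axis=1)
    wall2 = np.stack([a, b, b + n], axis=1)
    faces = np.concatenate([inner_faces, outer_faces, wall1, wall2])
    veneer = TriangleMesh(verts, faces, "veneer").merged()
    if veneer.volume() < 0:
        veneer = veneer.flipped()
    if not veneer.is_watertight():
        raise MeshError("stitched veneer is not watertight (patch topology too complex)")
    # merged() may reorder vertices; recover intaglio indices by matching
    order = {tuple(np.round(v, 9)): i for i, v in enumerate(veneer.vertices)}
    intaglio = np.array([order[tuple(np.round(v, 9))] for v in inner_v], dtype=np.int64)
    return SeatedPair(tooth, veneer, intaglio, g_um, gap_field)


# -- scene voxelization ----------------------------------------------------


def voxelize_scene(
    meshes,
    scan: ScanSpec,
    bounds=None,
    max_voxels: int = 6 * 10**7,
):
    """Rasterize labelled meshes into an intensity volume plus label mask.

    ``meshes`` is an ordered list of ``(label, TriangleMesh)``; later
    entries override earlier ones.  Intensity = phase value, then optional
    Gaussian blur (``blur_fwhm``) and additive Gaussian noise.  Returns
    ``(VoxelVolume, labels ndarray, label_names list)`` where the label
    array holds indices into ``["background"] + [labels...]``.
    """
    imap = scan.intensity_map()
    for label, _ in meshes:
        if label not in imap:
            raise ParameterError(f"no phase intensity for label {label!r}")
    sp = float(scan.spacing)
    if bounds is None:
        lo = np.min([m.bounds()[0] for _, m in meshes], axis=0) - 4 * sp
        hi = np.max([m.bounds()[1] for _, m in meshes], axis=0) + 4 * sp
    else:
        lo, hi = (np.asarray(b, float) for b in bounds)
    shape = tuple(np.ceil((hi - lo) / sp).astype(int) + 1)
    if np.prod(shape) > max_voxels:
        raise ParameterError(
            f"scene of {np.prod(shape):.2e} voxels at {sp} mm exceeds the "
            f"{max_voxels:.0e} budget; crop bounds or coarsen spacing"
        )
    origin = lo - sp * np.array([0.5 / np.pi, 0.5 / np.e, 0.25 / np.pi])
    labels = np.zeros(shape, dtype=np.uint8)
    names = ["background"]
    for li, (label, m) in enumerate(meshes, start=1):
        mask, _ = voxelize(m, sp, origin=origin, shape=shape)
        labels[mask] = li
        names.append(label)
    intensities = np.array([imap.get("background", 0.0)] + [imap[l] for l, _ in meshes])
    data = intensities[labels]
    if scan.blur_fwhm > 0:
        data = ndimage.gaussian_filter(data, sigma=scan.blur_fwhm / 2.3548 / sp)
    if scan.noise_sd > 0:
        rng = np.random.default_rng(scan.seed)
        data = data + rng.normal(0.0, scan.noise_sd, size=data.shape)
    return VoxelVolume(data, [sp] * 3, origin), labels, names


# -- margin images ---------------------------------------------------------

MARGIN_SIDES = ("cervical", "mesial", "distal")


def render_margin_image(
    tooth: TriangleMesh,
    veneer: TriangleMesh,
    side: str,
    pixel_size: float = 2.0,  # µm / pixel
    window_mm: float = 1.6,
    intensities=(0.05, 0.9, 0.55),  # background, tooth, veneer
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Orthographic cross-section image of the seated pair near one margin.

    The section plane is sagittal (normal x) for the cervical margin and
    axial (normal z) for mesial/distal; the image window is centered on
    the veneer rim on that side.  Returns ``(image, meta)`` where meta
    records the world frame of the image for ground-truth lookups.
    """
    if side not in MARGIN_SIDES:
        raise ParameterError(f"side must be one of {MARGIN_SIDES}")
    vlo, vhi = veneer.bounds()
    if side == "cervical":
        plane_axis, img_axes = 0, (1, 2)  # image rows=y, cols=z
        plane_pos = 0.5 * (vlo[0] + vhi[0])
        slab = np.abs(veneer.vertices[:, 0] - plane_pos) < 0.25
        if not slab.any():
            raise MeshError(f"veneer absent at {side} section")
        vi = veneer.vertices[slab]
        center = vi[np.argmin(vi[:, 2])][[1, 2]]
        rim_world = vi[np.argmin(vi[:, 2])]
    else:
        plane_axis, img_axes = 2, (0, 1)  # image rows=x, cols=y
        plane_pos = 0.5 * (vlo[2] + vhi[2])
        slab = np.abs(veneer.vertices[:, 2] - plane_pos) < 0.25
        if not slab.any():
            raise MeshError(f"veneer absent at {side} section")
        vi = veneer.vertices[slab]
        pick = np.argmin(vi[:, 0]) if side == "mesial" else np.argmax(vi[:, 0])
        center = vi[pick][[0, 1]]
        rim_world = vi[pick]
    # recenter a little toward the tooth so both edges sit inside the window
    tc = tooth.centroid()
    inplane = tc[list(img_axes)] - center
    nrm = np.linalg.norm(inplane)
    if nrm > 0:
        center = center + 0.2 * window_mm * inplane / nrm
    px_mm = pixel_size / 1000.0
    half = window_mm / 2.0
    n = int(round(window_mm / px_mm))
    masks = []
    for m in (tooth, veneer):
        # single-slice voxel grid whose z axis is the section normal
        axes_order = [img_axes[0], img_axes[1], plane_axis]
        perm_v = m.vertices[:, axes_order]
        pm = TriangleMesh(perm_v, m.faces)
        origin = np.array(
            [center[0] - half, center[1] - half, plane_pos - 0.5 * px_mm]
        ) + px_mm * np.array([0.31830988, 0.36787944, 0.0])
        mask, _ = voxelize(pm, px_mm, origin=origin, shape=(n, n, 1))
        masks.append(mask[:, :, 0])
    bg, ti, vi_ = intensities
    img = np.full((n, n), bg)
    img[masks[0]] = ti
    img[masks[1]] = vi_
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    meta = {
        "side": side,
        "pixel_size_um": pixel_size,
        "plane_axis": plane_axis,
        "plane_pos": plane_pos,
        "img_axes": img_axes,
        "window_origin": [center[0] - half, center[1] - half],
        "rim_world": [float(v) for v in rim_world],
    }
    return img, meta


def render_synthetic_margin(
    gap_profile,
    pixel_size: float = 2.0,
    shape: tuple = (400, 400),
    tooth_edge_col: float = 120.0,
    veneer_width_px: float = 200.0,
    intensities=(0.05, 0.9, 0.55),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw a margin image with an exactly known gap profile.

    ``gap_profile(row_positions_um)`` returns the gap in µm at each image
    row; the tooth occupies columns left of a straight edge and the
    veneer strip starts ``gap`` beyond it.  This isolates the measurement
    protocol from 3D projection effects.
    """
    nr, nc = shape
    rows = np.arange(nr)
    g_px = np.asarray(gap_profile(rows * pixel_size), float) / pixel_size
    cols = np.arange(nc)[None, :]
    bg, ti, vi = intensities
    img = np.full(shape, bg)
    img[np.broadcast_to(cols < tooth_edge_col, shape)] = ti
    start = tooth_edge_col + g_px[:, None]
    img[(cols >= start) & (cols < start + veneer_width_px)] = vi
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


def margin_station_world(meta: dict, station_rc: np.ndarray) -> np.ndarray:
    """World mm coordinates of image pixel positions (row, col)."""
    rc = np.atleast_2d(np.asarray(station_rc, float))
    px = meta["pixel_size_um"] / 1000.0
    out = np.zeros((len(rc), 3))
    out[:, meta["img_axes"][0]] = meta["window_origin"][0] + rc[:, 0] * px
    out[:, meta["img_axes"][1]] = meta["window_origin"][1] + rc[:, 1] * px
    out[:, meta["plane_axis"]] = meta["plane_pos"]
    return out


# -- batches ---------------------------------------------------------------


def make_batch(
    n: int,
    gap_mean: float,
    gap_sd: float,
    seed: int,
    out_dir=None,
    tooth_kwargs: dict | None = None,
    gap_model: str = "normal",
    pixel_size: float = 2.0,
):
    """Generate ``n`` seated veneer phantoms with per-veneer gap fields.

    Returns a manifest dict; when ``out_dir`` is given, writes veneer and
    tooth STLs, margin images (.npy), and ``manifest.json`` there.
    """
    rng = np.random.default_rng(seed)
    manifest = {"n": n, "gap_mean": gap_mean, "gap_sd": gap_sd, "seed": seed, "samples": []}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    results = []
    for i in range(n):
        tspec = ToothPhantomSpec(seed=int(rng.integers(2**31)), **(tooth_kwargs or {}))
        tooth = make_tooth(tspec)
        region = make_veneer_region_box(tooth)
        gspec = GapFieldSpec(
            model=gap_model, mean=gap_mean, sd=gap_sd, truncation=0.0,
            seed=int(rng.integers(2**31)),
        )
        pair = make_seated_pair(tooth, region, gspec)
        images = {}
        for side in MARGIN_SIDES:
            images[side] = render_margin_image(tooth, pair.veneer, side, pixel_size=pixel_size)
        rec = {
            "index": i,
            "tooth_seed": tspec.seed,
            "gap_seed": gspec.seed,
            "true_gap_mean_um": float(pair.gap_truth_um.mean()),
            "true_gap_median_um": float(np.median(pair.gap_truth_um)),
        }
        if out_dir is not None:
            write_mesh(tooth, out_dir / f"tooth_{i:02d}.stl")
            write_mesh(pair.veneer, out_dir / f"veneer_{i:02d}.stl")
            for side, (img, meta) in images.items():
                np.save(out_dir / f"margin_{i:02d}_{side}.npy", img)
                rec[f"margin_{side}"] = meta
        manifest["samples"].append(rec)
        results.append((pair, images))
    if out_dir is not None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return manifest, results
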