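"""Marginal and internal fit quantification.

Marginal gaps are measured on calibrated 2D margin images by shortest
edge-to-edge distance at evenly spaced stations (default six per image,
three sides per veneer, eighteen readings total).  Internal adaptation
comes from µCT-like volumes through indirect gap segmentation (mask
logic on a morphologically closed "combined" mask), mesh reconstruction,
and an inscribed-sphere 3D thickness map, summarized against a 200 µm
clinical cutoff.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage import measure
from skimage.filters import threshold_multiotsu

from .imaging import ParameterError, VoxelVolume
from .mesh import TriangleMesh, voxel_boolean
from .segmentation import BinaryMask, extract_surface_mesh
from .thickness import local_thickness

__all__ = [
    "MarginalGapMeasurement",
    "GapModel",
    "GapStatistics",
    "AnovaResult",
    "measure_marginal_gap",
    "segment_gap_indirect",
    "reconstruct_gap_model",
    "compute_thickness_map",
    "summarize_gap",
    "aggregate_per_sample_medians",
    "one_way_anova",
    "DetectionError",
    "DEFAULT_CUTOFF_UM",
]

DEFAULT_CUTOFF_UM = 200.0
MARGIN_SIDES = ("cervical", "mesial", "distal")


class DetectionError(RuntimeError):
    """Margin edges could not be found in the image."""


@dataclass
class MarginalGapMeasurement:
    side: str
    readings: np.ndarray  # µm
    pixel_size: float  # µm / pixel
    image_id: str = ""
    stations: np.ndarray | None = None  # (n, 2) image (row, col) positions

    def __post_init__(self):
        self.readings = np.asarray(self.readings, float)
        if np.any(self.readings < 0):
            raise ParameterError("gap readings must be non-negative")


@dataclass
class GapModel:
    mask: BinaryMask
    mesh: TriangleMesh | None
    thickness_um: np.ndarray | None = None  # per-voxel, 0 outside mask

    @property
    def empty(self) -> bool:
        return not bool(self.mask.data.any())

    def thickness_values(self) -> np.ndarray:
        if self.thickness_um is None:
            raise ParameterError("thickness map not computed yet")
        return self.thickness_um[self.mask.data]


@dataclass
class GapStatistics:
    mean: float
    sd: float
    median: float
    iqr: tuple
    fraction_below_cutoff: float
    cutoff: float = DEFAULT_CUTOFF_UM
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_um": self.mean,
            "sd_um": self.sd,
            "median_um": self.median,
            "q1_um": self.iqr[0],
            "q3_um": self.iqr[1],
            "fraction_below_cutoff": self.fraction_below_cutoff,
            "cutoff_um": self.cutoff,
            "n": self.n,
        }


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


# -- marginal protocol -----------------------------------------------------


def _three_class_thresholds(values: np.ndarray) -> tuple:
    """Deterministic 1D 3-means on intensities; returns the two midpoints
    between sorted cluster centers (robust to spiky noiseless histograms
    where binned Otsu degenerates)."""
    v = np.asarray(values, float).ravel()
    if v.size > 200_000:
        v = v[:: v.size // 200_000 + 1]
    vmin, vmax = float(v.min()), float(v.max())
    centers = np.array([vmin, 0.5 * (vmin + vmax), vmax])
    for _ in range(30):
        d = np.abs(v[:, None] - centers[None, :])
        lab = d.argmin(axis=1)
        new = np.array([v[lab == k].mean() if (lab == k).any() else centers[k] for k in range(3)])
        if np.allclose(new, centers):
            break
        centers = new
    centers.sort()
    return 0.5 * (centers[0] + centers[1]), 0.5 * (centers[1] + centers[2])


def _two_phase_masks(image: np.ndarray):
    """Split the image into the two foreground phases (brightest = tooth)."""
    img = np.asarray(image, float)
    finite = img[np.isfinite(img)]
    if np.ptp(finite) == 0:
        raise DetectionError("uniform image: no margin edges detectable")
    t1, t2 = _three_class_thresholds(img)
    mid = (img > t1) & (img <= t2)
    high = img > t2
    if not mid.any() or not high.any():
        raise DetectionError("could not find two foreground regions")
    # largest connected component of each phase
    out = []
    for m in (high, mid):  # tooth first
        lab, n = ndimage.label(m)
        if n == 0:
            raise DetectionError("foreground phase vanished after labelling")
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        out.append(lab == (1 + int(np.argmax(sizes))))
    return out[0], out[1]


def measure_marginal_gap(
    margin_image: np.ndarray,
    pixel_size: float,
    side: str = "cervical",
    n_stations: int = 6,
    facing_max_um: float = 400.0,
    image_id: str = "",
) -> MarginalGapMeasurement:
    """Shortest tooth-to-veneer edge distance at evenly spaced stations.

    The two margin edges are found by 3-class intensity segmentation and
    subpixel boundary tracing; stations are spread evenly along the
    longest veneer-boundary run that faces the tooth edge within
    ``facing_max_um``.  Readings are in µm.
    """
    if n_stations < 1:
        raise ParameterError("n_stations must be >= 1")
    tooth_mask, veneer_mask = _two_phase_masks(margin_image)
    tooth_curves = measure.find_contours(tooth_mask.astype(float), 0.5)
    veneer_curves = measure.find_contours(veneer_mask.astype(float), 0.5)
    if not tooth_curves or not veneer_curves:
        raise DetectionError("boundary tracing failed")
    tooth_edge = np.concatenate(tooth_curves)
    tree = cKDTree(tooth_edge)
    # the margin edge is the veneer boundary curve facing the tooth; open
    # curves (strip clipped by the image border) make "longest" unreliable
    def facing_score(curve):
        dc, _ = tree.query(curve[:: max(1, len(curve) // 64)])
        return np.median(dc)

    candidates = [c for c in veneer_curves if len(c) >= n_stations]
    if not candidates:
        raise ParameterError("veneer boundary shorter than the station count")
    veneer_edge = min(candidates, key=facing_score)
    d, _ = tree.query(veneer_edge)
    facing = d * pixel_size <= facing_max_um
    run = _longest_circular_run(facing)
    # trim rim-wall pixels at the run ends: their distance ramps up toward
    # the outer surface and is not a margin gap
    if len(run) > 8:
        core = d[run]
        ref = np.median(np.sort(core)[: max(4, len(core) // 2)])
        ok = core <= max(1.8 * ref, ref + 3.0)
        lo = 0
        hi = len(run)
        while lo < hi and not ok[lo]:
            lo += 1
        while hi > lo and not ok[hi - 1]:
            hi -= 1
        run = run[lo:hi]
    if len(run) < n_stations:
        raise ParameterError(
            f"facing margin of {len(run)} px is shorter than {n_stations} stations"
        )
    pick = np.linspace(0, len(run) - 1, n_stations + 2)[1:-1]  # avoid the rim ends
    stations = run[np.round(pick).astype(int)]
    readings = d[stations] * pixel_size
    return MarginalGapMeasurement(
        side=side,
        readings=readings,
        pixel_size=pixel_size,
        image_id=image_id,
        stations=veneer_edge[stations],
    )


def _longest_circular_run(flags: np.ndarray) -> np.ndarray:
    """Indices of the longest circular run of True values."""
    n = len(flags)
    if flags.all():
        return np.arange(n)
    if not flags.any():
        return np.arange(0)
    ext = np.concatenate([flags, flags])
    best_len, best_start = 0, 0
    cur = 0
    for i in range(2 * n):
        if ext[i]:
            cur += 1
            if cur > best_len:
                best_len, best_start = cur, i - cur + 1
        else:
            cur = 0
    best_len = min(best_len, n)
    return (np.arange(best_start, best_start + best_len)) % n


# -- indirect gap segmentation ---------------------------------------------


def _in_range(data: np.ndarray, rng) -> np.ndarray:
    lo, hi = rng
    return (data >= lo) & (data <= hi)


def auto_thresholds(volume: VoxelVolume) -> tuple:
    """3-class histogram split: returns (combined_range, enamel_range).

    Everything above the air/solid split counts as the combined entity;
    by default the same range is subtracted back out, so the gap mask is
    exactly the closing fill between the solid bodies.
    """
    th = threshold_multiotsu(volume.data.astype(np.float64), classes=3)
    hi = float(volume.data.max()) + 1
    return (float(th[0]), hi), (float(th[0]), hi)


def segment_gap_indirect(
    volume: VoxelVolume,
    combined_threshold=None,
    enamel_threshold=None,
    closing_radius: int | None = None,
    expected_gap_um: float = 200.0,
):
    """Indirect gap segmentation by mask logic.

    ``combined`` is the thresholded solid entity after morphological
    closing — the closing bridges the radiolucent gap between the bodies
    so the gap is swallowed into the combined mask.  ``enamel`` is the
    second thresholded mask, and ``gap = combined AND NOT enamel``.
    Default closing radius is twice the expected gap width.
    Returns ``(combined, enamel, gap)`` as :class:`BinaryMask`.
    """
    if combined_threshold is None or enamel_threshold is None:
        auto_c, auto_e = auto_thresholds(volume)
        combined_threshold = combined_threshold or auto_c
        enamel_threshold = enamel_threshold or auto_e
    if closing_radius is None:
        closing_radius = max(1, int(np.ceil(2.0 * expected_gap_um / 1000.0 / volume.spacing[0] / 2.0)))
    raw = _in_range(volume.data, combined_threshold)
    closed = _ball_closing(raw, int(closing_radius))
    enamel = _in_range(volume.data, enamel_threshold)
    if not np.all(closed | ~enamel):
        warnings.warn("enamel mask is not a subset of the combined mask", stacklevel=2)
    gap = closed & ~enamel
    sp, org = volume.spacing, volume.origin
    return BinaryMask(closed, sp, org), BinaryMask(enamel, sp, org), BinaryMask(gap, sp, org)


def _ball_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Euclidean closing with a ball of ``radius`` voxels via two distance
    transforms (orders of magnitude faster than structuring-element
    morphology at large radii)."""
    if radius < 1:
        return mask
    # pad so the world outside the scan counts as background; otherwise
    # the erosion cannot undo dilation that ran into the array border
    padded = np.pad(mask, radius + 1)
    dilated = ndimage.distance_transform_edt(~padded) <= radius
    closed = ndimage.distance_transform_edt(dilated) > radius
    crop = tuple(slice(radius + 1, radius + 1 + s) for s in mask.shape)
    return closed[crop]


# -- gap model + thickness -------------------------------------------------


def reconstruct_gap_model(
    combined: BinaryMask,
    enamel: BinaryMask,
    min_component_voxels: int = 10,
    mesh_booleans: bool = True,
) -> GapModel:
    """Build the 3D gap model: voxel mask logic plus mesh-route subtraction.

    The voxel gap keeps its largest connected component (tiny specks
    below ``min_component_voxels`` are noise).  The mesh route meshes
    both masks and subtracts them; an empty gap yields an empty model,
    not an error.
    """
    if combined.shape != enamel.shape:
        raise ParameterError("combined and enamel masks are not aligned")
    gap = combined.data & ~enamel.data
    lab, n = ndimage.label(gap)
    if n == 0:
        return GapModel(BinaryMask(gap, combined.spacing, combined.origin), None)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    if sizes[keep - 1] < min_component_voxels:
        return GapModel(
            BinaryMask(np.zeros_like(gap), combined.spacing, combined.origin), None
        )
    gap = lab == keep
    gap_mask = BinaryMask(gap, combined.spacing, combined.origin)
    mesh = None
    if mesh_booleans and enamel.data.any():
        m_comb = extract_surface_mesh(
            BinaryMask(combined.data, combined.spacing, combined.origin), name="combined"
        )
        m_enam = extract_surface_mesh(enamel, name="enamel")
        mesh = voxel_boolean(m_comb, m_enam, "difference", pitch=float(combined.spacing[0]))
        if mesh is not None:
            mesh.name = "gap"
    elif mesh_booleans:
        mesh = extract_surface_mesh(gap_mask, name="gap")
    return GapModel(gap_mask, mesh)


def compute_thickness_map(gap: GapModel) -> GapModel:
    """Fill the per-voxel local thickness (µm, inscribed-sphere diameter)."""
    if gap.empty:
        gap.thickness_um = np.zeros(gap.mask.shape)
        return gap
    sp_um = float(gap.mask.spacing[0]) * 1000.0
    gap.thickness_um = local_thickness(gap.mask.data, sp_um)
    return gap


def export_thickness_mesh(gap: GapModel, path, cmap_name: str = "jet") -> None:
    """Write the gap mesh with per-vertex thickness as ASCII PLY with colors."""
    if gap.mesh is None or gap.thickness_um is None:
        raise ParameterError("gap model needs both a mesh and a thickness map")
    mask = gap.mask
    idx = np.clip(
        np.round((gap.mesh.vertices - mask.origin) / mask.spacing).astype(int),
        0,
        np.array(mask.shape) - 1,
    )
    vals = gap.thickness_um[idx[:, 0], idx[:, 1], idx[:, 2]]
    # nearest in-mask value for vertices landing on background
    if (vals == 0).any() and mask.data.any():
        inside = np.argwhere(mask.data)
        tree = cKDTree(inside)
        miss = np.flatnonzero(vals == 0)
        _, j = tree.query(idx[miss])
        vals[miss] = gap.thickness_um[tuple(inside[j].T)]
    from matplotlib import colormaps

    cmap = colormaps[cmap_name]
    vmax = max(vals.max(), 1e-9)
    colors = (np.asarray(cmap(vals / vmax))[:, :3] * 255).astype(np.uint8)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {gap.mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float quality\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write(f"element face {gap.mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, q, c in zip(gap.mesh.vertices, vals, colors):
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {q:.3f} {c[0]} {c[1]} {c[2]}\n")
        for f in gap.mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def export_thickness_csv(gap: GapModel, path) -> None:
    """Per-voxel thickness table (world mm coordinates, thickness µm)."""
    if gap.thickness_um is None:
        raise ParameterError("thickness map not computed yet")
    idx = np.argwhere(gap.mask.data)
    world = gap.mask.origin + idx * gap.mask.spacing
    vals = gap.thickness_um[tuple(idx.T)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_mm", "y_mm", "z_mm", "thickness_um"])
        for p, t in zip(world, vals):
            w.writerow([f"{p[0]:.5f}", f"{p[1]:.5f}", f"{p[2]:.5f}", f"{t:.2f}"])


# -- statistics ------------------------------------------------------------


def summarize_gap(values, cutoff: float = DEFAULT_CUTOFF_UM) -> GapStatistics:
    """Mean, n-1 SD, median, linear-interpolation quartiles, and the
    fraction of values strictly below the cutoff."""
    v = np.asarray(values, float).ravel()
    if v.size == 0:
        raise ParameterError("summarize_gap needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return GapStatistics(
        mean=float(v.mean()),
        sd=sd,
        median=float(med),
        iqr=(float(q1), float(q3)),
        fraction_below_cutoff=float((v < cutoff).mean()),
        cutoff=float(cutoff),
        n=int(v.size),
    )


def aggregate_per_sample_medians(samples):
    """Per-sample medians, then mean/SD/IQR across samples.

    Matches "average median" reporting: each specimen contributes its
    median, and the batch statistic summarizes those medians.  Returns
    ``(mean, sd, (q1, q3), medians)``; SD is 0 (flagged by n=1) for a
    single sample.
    """
    if len(samples) == 0:
        raise ParameterError("need at least one sample")
    medians = np.array([np.median(np.asarray(s, float)) for s in samples])
    for s in samples:
        if len(np.asarray(s).ravel()) == 0:
            raise ParameterError("empty sample in batch")
    sd = float(medians.std(ddof=1)) if len(medians) > 1 else 0.0
    q1, q3 = np.percentile(medians, [25, 75])
    return float(medians.mean()), sd, (float(q1), float(q3)), medians


def one_way_anova(groups) -> AnovaResult:
    """Classic one-way ANOVA from sums of squares."""
    gs = [np.asarray(g, float).ravel() for g in groups]
    if len(gs) < 2:
        raise ParameterError("ANOVA needs at least two groups")
    if any(len(g) < 2 for g in gs):
        raise ParameterError("each group needs at least two values")
    allv = np.concatenate(gs)
    if np.ptp(allv) == 0:
        raise ParameterError("degenerate ANOVA: all values identical")
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    dfb = len(gs) - 1
    dfw = len(allv) - len(gs)
    if ssw == 0:
        raise ParameterError("degenerate ANOVA: zero within-group variance")
    f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(float(f), dfb, dfw, p)
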