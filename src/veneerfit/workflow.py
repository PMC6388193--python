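"""Pipeline composition: segment -> design -> assess, driven by one config.

Each stage consumes a config section and records every produced file
(with content hash) in a run manifest, so identical configs and seeds
reproduce identical hashes for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .assessment import (
    compute_thickness_map,
    export_thickness_csv,
    measure_marginal_gap,
    one_way_anova,
    reconstruct_gap_model,
    segment_gap_indirect,
    summarize_gap,
)
from .design import design_veneer
from .imaging import IntensityWindow, load_volume
from .mesh import read_mesh, write_mesh
from .phantoms import make_batch
from .segmentation import (
    ContourSet,
    extract_surface_mesh,
    fit_variational_surface,
    rasterize_mask,
    trace_contour,
)

__all__ = ["RunManifest", "run_pipeline", "StageError"]

log = logging.getLogger("veneerfit")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    config: dict
    tool_version: str = __version__
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    input_hashes: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def record_output(self, path) -> None:
        self.outputs[str(path)] = _sha256(path)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tool_version": self.tool_version,
                    "config": self.config,
                    "stages": self.stages,
                    "outputs": self.outputs,
                    "input_hashes": self.input_hashes,
                    "seeds": self.seeds,
                },
                fh,
                indent=1,
                default=str,
            )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as fh:
        return yaml.safe_load(fh)


# -- stages ----------------------------------------------------------------


def run_segment(cfg: dict, manifest: RunManifest) -> Path:
    vol = load_volume(cfg["volume"])
    manifest.input_hashes.setdefault(str(cfg["volume"]), "directory" if Path(cfg["volume"]).is_dir() else _sha256(cfg["volume"]))
    window = None
    if "window" in cfg:
        lo, hi = cfg["window"]
        window = IntensityWindow(lo, hi)
    radius = int(cfg.get("median_radius", 1))
    contours = []
    with open(cfg["anchors"]) as fh:
        records = [json.loads(line) for line in fh if line.strip()]
    for rec in records:
        axis, index = int(rec["axis"]), int(rec["slice"])
        slicer = [slice(None)] * 3
        slicer[axis] = index
        img = vol.data[tuple(slicer)]
        contours.append(
            trace_contour(img, rec["points"], plane_axis=axis, plane_index=index,
                          window=window, median_radius=radius)
        )
    cs = ContourSet(contours, vol.spacing, vol.origin, cfg.get("label", "tooth"))
    surf = fit_variational_surface(cs)
    mask = rasterize_mask(surf, vol)
    mesh = extract_surface_mesh(mask, name=cs.tooth_label)
    out = Path(cfg["out"])
    out.parent.mkdir(parents=True, exist_ok=True)
    write_mesh(mesh, out)
    manifest.record_output(out)
    return out


def run_design(cfg: dict, manifest: RunManifest) -> Path:
    incisor = read_mesh(cfg["incisor"])
    tooth = read_mesh(cfg["tooth"])
    for key in ("incisor", "tooth"):
        manifest.input_hashes.setdefault(str(cfg[key]), _sha256(cfg[key]))
    cp = cfg["cervical_plane"]
    mirror = cfg.get("mirror_plane")
    design = design_veneer(
        incisor,
        tooth,
        cervical_plane=(cp["point"], cp["normal"]),
        mirror_plane=(mirror["point"], mirror["normal"]) if mirror else None,
        insertion_axis=cfg.get("insertion_axis"),
        min_thickness=float(cfg.get("min_thickness", 0.5)),
        bevel_band=float(cfg.get("bevel_band", 0.3)),
        bevel_angle=float(cfg.get("bevel_angle", 45.0)),
        spacer=float(cfg.get("spacer", 0.1)),
    )
    out = Path(cfg["out"])
    out.parent.mkdir(parents=True, exist_ok=True)
    write_mesh(design.veneer, out)
    manifest.record_output(out)
    rep = design.thickness_report
    manifest.stages.setdefault("design", {})["thickness"] = {
        "min_mm": rep.min_mm,
        "median_mm": rep.median_mm,
        "violating_area_fraction": rep.violating_area_fraction,
    }
    return out


def _load_image(path):
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    from imageio import v3 as iio  # optional heavier dependency path

    return np.asarray(iio.imread(path), float)


def run_assess_margin(cfg: dict, manifest: RunManifest) -> Path:
    px = float(cfg["pixel_size_um"])
    per_side: dict[str, list] = {}
    for item in cfg["images"]:
        img = _load_image(item["path"])
        manifest.input_hashes.setdefault(str(item["path"]), _sha256(item["path"]))
        m = measure_marginal_gap(
            img, px, side=item.get("side", "cervical"),
            n_stations=int(cfg.get("n_stations", 6)), image_id=str(item["path"]),
        )
        per_side.setdefault(m.side, []).extend(m.readings.tolist())
    cutoff = float(cfg.get("cutoff_um", 200.0))
    result = {
        side: summarize_gap(vals, cutoff=cutoff).to_dict() for side, vals in per_side.items()
    }
    allv = [v for vals in per_side.values() for v in vals]
    result["overall"] = summarize_gap(allv, cutoff=cutoff).to_dict()
    if len(per_side) >= 2 and all(len(v) >= 2 for v in per_side.values()):
        a = one_way_anova(list(per_side.values()))
        result["anova"] = {
            "f": a.f_statistic, "df_between": a.df_between,
            "df_within": a.df_within, "p": a.p_value,
        }
    out = Path(cfg["out"])
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        json.dump(result, fh, indent=1)
    manifest.record_output(out)
    return out


def run_assess_internal(cfg: dict, manifest: RunManifest) -> Path:
    vol = load_volume(cfg["volume"])
    combined, enamel, _gap = segment_gap_indirect(
        vol,
        tuple(cfg["combined_threshold"]) if "combined_threshold" in cfg else None,
        tuple(cfg["enamel_threshold"]) if "enamel_threshold" in cfg else None,
        closing_radius=cfg.get("closing_radius"),
        expected_gap_um=float(cfg.get("expected_gap_um", 200.0)),
    )
    model = reconstruct_gap_model(combined, enamel, mesh_booleans=bool(cfg.get("mesh_booleans", True)))
    model = compute_thickness_map(model)
    out = Path(cfg["out"])
    out.parent.mkdir(parents=True, exist_ok=True)
    if model.empty:
        payload = {"empty": True}
    else:
        stats = summarize_gap(model.thickness_values(), cutoff=float(cfg.get("cutoff_um", 200.0)))
        payload = stats.to_dict()
        payload["gap_volume_mm3"] = model.mask.volume_mm3()
        if model.mesh is not None:
            payload["gap_mesh_volume_mm3"] = model.mesh.volume()
    with open(out, "w") as fh:
        json.dump(payload, fh, indent=1)
    manifest.record_output(out)
    if cfg.get("out_csv") and not model.empty:
        export_thickness_csv(model, cfg["out_csv"])
        manifest.record_output(cfg["out_csv"])
    return out


def run_phantom(cfg: dict, manifest: RunManifest) -> Path:
    out_dir = Path(cfg["out"])
    make_batch(
        n=int(cfg.get("n", 15)),
        gap_mean=float(cfg.get("gap_mean_um", 100.0)),
        gap_sd=float(cfg.get("gap_sd_um", 50.0)),
        seed=int(cfg.get("seed", 0)),
        out_dir=out_dir,
        gap_model=cfg.get("gap_model", "normal"),
        pixel_size=float(cfg.get("pixel_size_um", 2.0)),
    )
    manifest.seeds["phantom"] = int(cfg.get("seed", 0))
    for p in sorted(out_dir.iterdir()):
        if p.is_file():
            manifest.record_output(p)
    return out_dir


_STAGES = (
    ("phantom", run_phantom),
    ("segment", run_segment),
    ("design", run_design),
    ("assess_margin", run_assess_margin),
    ("assess_internal", run_assess_internal),
)


def run_pipeline(config, manifest_path=None) -> RunManifest:
    """Execute the configured stages in order, recording a manifest.

    Stages whose section is absent are skipped; a stage failure halts the
    pipeline with the failing stage named while earlier outputs remain on
    disk and in the manifest.
    """
    cfg = _load_config(config)
    manifest = RunManifest(config=cfg)
    for name, fn in _STAGES:
        if name not in cfg:
            continue
        t0 = time.time()
        log.info("[%s] starting", name)
        try:
            fn(cfg[name], manifest)
        except Exception as exc:
            manifest.stages.setdefault(name, {})["status"] = f"failed: {exc}"
            if manifest_path:
                manifest.save(manifest_path)
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest.stages.setdefault(name, {}).update(
            {"status": "ok", "seconds": round(time.time() - t0, 3)}
        )
        log.info("[%s] done in %.1fs", name, time.time() - t0)
    if manifest_path:
        manifest.save(manifest_path)
    return manifest
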