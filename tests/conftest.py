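"""Shared fixtures: analytic meshes, phantom teeth, and a tiny DICOM writer."""

from __future__ import annotations

import struct

import numpy as np
import pytest
from skimage.measure import marching_cubes

from veneerfit.mesh import TriangleMesh
from veneerfit.phantoms import ToothPhantomSpec, box_mesh, make_tooth, make_veneer_region_box


def sphere_mesh(radius: float, center=(0.0, 0.0, 0.0), pitch: float = 0.1) -> TriangleMesh:
    """Analytic sphere via marching cubes on the exact SDF."""
    c = np.asarray(center, float)
    n = int(np.ceil(2 * (radius + 3 * pitch) / pitch))
    g = np.linspace(-(radius + 3 * pitch), radius + 3 * pitch, n)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    F = np.sqrt(X**2 + Y**2 + Z**2) - radius
    v, f, _, _ = marching_cubes(F, 0.0, spacing=(g[1] - g[0],) * 3)
    v = v + (c - (radius + 3 * pitch))
    m = TriangleMesh(v, f, "sphere").merged()
    return m if m.volume() > 0 else m.flipped()


@pytest.fixture(scope="session")
def unit_cube() -> TriangleMesh:
    return box_mesh([0, 0, 0], [1, 1, 1], name="cube")


@pytest.fixture(scope="session")
def sphere5() -> TriangleMesh:
    return sphere_mesh(5.0, pitch=0.1)


@pytest.fixture(scope="session")
def premolar() -> TriangleMesh:
    return make_tooth(ToothPhantomSpec(kind="premolar", seed=11))


@pytest.fixture(scope="session")
def incisor() -> TriangleMesh:
    return make_tooth(
        ToothPhantomSpec(kind="incisor", crown_width=8.0, crown_depth=7.0, crown_height=9.5, seed=12)
    )


@pytest.fixture(scope="session")
def small_tooth() -> TriangleMesh:
    """Downsized tooth for µCT-resolution scenes."""
    return make_tooth(
        ToothPhantomSpec(crown_width=3.5, crown_depth=3.0, crown_height=3.5,
                         root_length=4.0, mesh_pitch=0.08, seed=2)
    )


@pytest.fixture(scope="session")
def small_region(small_tooth) -> TriangleMesh:
    return make_veneer_region_box(small_tooth)


# -- minimal DICOM writer (fixture plumbing only) --------------------------


def _el_short(group, elem, vr, value: bytes) -> bytes:
    if len(value) % 2:
        value += b" " if vr in (b"DS", b"IS", b"UI", b"LO") else b"\x00"
    return struct.pack("<HH2sH", group, elem, vr, len(value)) + value


def _el_long(group, elem, vr, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00"
    return struct.pack("<HH2s2xI", group, elem, vr, len(value)) + value


def write_dicom_slice(
    path,
    image: np.ndarray,
    pixel_spacing=(0.2, 0.2),
    slice_thickness: float = 0.2,
    position=(0.0, 0.0, 0.0),
    instance: int = 1,
) -> None:
    """Write one uncompressed explicit-VR little-endian DICOM slice."""
    img = np.ascontiguousarray(image, dtype=np.uint16)
    rows, cols = img.shape
    meta = _el_short(0x0002, 0x0010, b"UI", b"1.2.840.10008.1.2.1")
    body = b"".join(
        [
            _el_short(0x0018, 0x0050, b"DS", f"{slice_thickness:g}".encode()),
            _el_short(0x0020, 0x0013, b"IS", str(instance).encode()),
            _el_short(0x0020, 0x0032, b"DS",
                      "\\".join(f"{p:g}" for p in position).encode()),
            _el_short(0x0028, 0x0010, b"US", struct.pack("<H", rows)),
            _el_short(0x0028, 0x0011, b"US", struct.pack("<H", cols)),
            _el_short(0x0028, 0x0030, b"DS",
                      f"{pixel_spacing[0]:g}\\{pixel_spacing[1]:g}".encode()),
            _el_short(0x0028, 0x0100, b"US", struct.pack("<H", 16)),
            _el_short(0x0028, 0x0103, b"US", struct.pack("<H", 0)),
            _el_long(0x7FE0, 0x0010, b"OW", img.tobytes()),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + body)


def write_dicom_series(dirpath, volume: np.ndarray, spacing=(0.2, 0.2, 0.2)) -> None:
    """Volume is (nx, ny, nz); one file per z slice."""
    dirpath.mkdir(parents=True, exist_ok=True)
    for k in range(volume.shape[2]):
        write_dicom_slice(
            dirpath / f"slice_{k:03d}.dcm",
            volume[:, :, k].T,  # rows=y, cols=x
            pixel_spacing=(spacing[1], spacing[0]),
            slice_thickness=spacing[2],
            position=(0.0, 0.0, k * spacing[2]),
            instance=k + 1,
        )
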