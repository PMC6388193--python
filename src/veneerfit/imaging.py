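"""Volume I/O and preprocessing.

A :class:`VoxelVolume` is a 3D scalar grid with per-axis spacing and a
world-frame origin (mm, right-handed; voxel centers at
``origin + index * spacing``).  Supported containers are MetaImage
(.mhd + .raw, used for phantoms) and uncompressed single-frame DICOM
series.  Preprocessing is limited to the two filters the segmentation
protocol needs: intensity windowing and median filtering.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelVolume",
    "IntensityWindow",
    "load_volume",
    "save_volume",
    "window_normalize",
    "median_filter",
    "crop_roi",
    "MetadataError",
    "ParameterError",
]


class MetadataError(IOError):
    """Missing or inconsistent image metadata."""


class ParameterError(ValueError):
    """Invalid filter/crop parameter."""


@dataclass
class VoxelVolume:
    """3D scalar image with physical frame."""

    data: np.ndarray  # (nx, ny, nz)
    spacing: np.ndarray  # mm per axis
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ParameterError("volume data must be 3D")
        if min(self.data.shape) < 2:
            raise ParameterError("volume must have >= 2 voxels per axis")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float).ravel(), (3,)).astype(float)
        if np.any(self.spacing <= 0):
            raise ParameterError("spacing must be positive")
        self.origin = np.asarray(self.origin, float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_coords(self, index) -> np.ndarray:
        """World position (mm) of a voxel center given its index triple."""
        return self.origin + np.asarray(index, float) * self.spacing

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def copy_with(self, data: np.ndarray) -> "VoxelVolume":
        return VoxelVolume(data, self.spacing.copy(), self.origin.copy())


@dataclass(frozen=True)
class IntensityWindow:
    """Piecewise-linear clamp: [low, high] -> [out_low, out_high]."""

    low: float
    high: float
    out_low: float = 0.0
    out_high: float = 1.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ParameterError("window requires low < high")
        if not self.out_low < self.out_high:
            raise ParameterError("window requires out_low < out_high")


def window_normalize(vol: VoxelVolume, w: IntensityWindow) -> VoxelVolume:
    """Map intensities through the window: clamped linear rescale."""
    x = vol.data.astype(np.float64)
    y = (x - w.low) / (w.high - w.low)
    np.clip(y, 0.0, 1.0, out=y)
    return vol.copy_with(w.out_low + y * (w.out_high - w.out_low))


def median_filter(vol: VoxelVolume, radius: int) -> VoxelVolume:
    """Cubic (2r+1)^3 median with nearest-value border padding."""
    if int(radius) != radius or radius < 1:
        raise ParameterError("median radius must be an integer >= 1")
    out = ndimage.median_filter(vol.data, size=2 * int(radius) + 1, mode="nearest")
    return vol.copy_with(out)


def crop_roi(vol: VoxelVolume, bounds) -> VoxelVolume:
    """Sub-volume over half-open index ranges ``((x0,x1),(y0,y1),(z0,z1))``;
    the origin shifts so retained voxels keep their world coordinates."""
    bounds = [(int(a), int(b)) for a, b in bounds]
    if len(bounds) != 3:
        raise ParameterError("bounds must give a range per axis")
    for ax, (a, b) in enumerate(bounds):
        if not (0 <= a < b <= vol.shape[ax]):
            raise ParameterError(f"bounds {a}:{b} invalid for axis {ax} of size {vol.shape[ax]}")
    (x0, x1), (y0, y1), (z0, z1) = bounds
    data = vol.data[x0:x1, y0:y1, z0:z1].copy()
    origin = vol.origin + np.array([x0, y0, z0]) * vol.spacing
    return VoxelVolume(data, vol.spacing.copy(), origin)


# -- MetaImage (.mhd/.raw) -------------------------------------------------

_MET_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MET_NAMES = {np.dtype(v): k for k, v in _MET_TYPES.items()}


def save_volume(vol: VoxelVolume, path) -> None:
    """Write a MetaImage header + raw pair (``path`` ends in .mhd)."""
    path = Path(path)
    if path.suffix != ".mhd":
        raise ParameterError("save_volume expects an .mhd path")
    raw = path.with_suffix(".raw")
    data = vol.data
    if data.dtype not in _MET_NAMES:
        data = data.astype(np.float64)
    with open(path, "w") as fh:
        fh.write("ObjectType = Image\nNDims = 3\nBinaryData = True\n")
        fh.write("BinaryDataByteOrderMSB = False\n")
        fh.write("DimSize = %d %d %d\n" % vol.shape)
        fh.write("ElementSpacing = %.17g %.17g %.17g\n" % tuple(vol.spacing))
        fh.write("Offset = %.17g %.17g %.17g\n" % tuple(vol.origin))
        fh.write(f"ElementType = {_MET_NAMES[np.dtype(data.dtype)]}\n")
        fh.write(f"ElementDataFile = {raw.name}\n")
    # MetaImage raw order is x fastest; our arrays are (x, y, z)
    data.transpose(2, 1, 0).tofile(raw)


def _load_meta(path) -> VoxelVolume:
    head: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                k, v = line.split("=", 1)
                head[k.strip()] = v.strip()
    try:
        dims = [int(x) for x in head["DimSize"].split()]
        spacing = [float(x) for x in head.get("ElementSpacing", "1 1 1").split()]
        origin = [float(x) for x in head.get("Offset", "0 0 0").split()]
        dtype = _MET_TYPES[head["ElementType"]]
        datafile = head["ElementDataFile"]
    except KeyError as exc:
        raise MetadataError(f"{path}: missing MetaImage key {exc}") from exc
    raw = Path(path).parent / datafile
    data = np.fromfile(raw, dtype=dtype)
    if data.size != np.prod(dims):
        raise MetadataError(f"{raw}: raw size does not match DimSize")
    data = data.reshape(dims[2], dims[1], dims[0]).transpose(2, 1, 0)
    return VoxelVolume(data, spacing, origin)


# -- minimal DICOM reader --------------------------------------------------
#
# Supports uncompressed single-frame slices, implicit or explicit VR
# little endian.  Sequences and encapsulated transfer syntaxes are out of
# scope; files produced by CT/µCT console exports in that envelope load
# fine and anything else raises a clear error.

_EXPLICIT_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

_TAG_PIXEL_SPACING = (0x0028, 0x0030)
_TAG_SLICE_THICKNESS = (0x0018, 0x0050)
_TAG_IPP = (0x0020, 0x0032)
_TAG_SLICE_LOCATION = (0x0020, 0x1041)
_TAG_INSTANCE = (0x0020, 0x0013)
_TAG_ROWS = (0x0028, 0x0010)
_TAG_COLS = (0x0028, 0x0011)
_TAG_BITS_ALLOC = (0x0028, 0x0100)
_TAG_PIXEL_REP = (0x0028, 0x0103)
_TAG_SLOPE = (0x0028, 0x1053)
_TAG_INTERCEPT = (0x0028, 0x1052)
_TAG_PIXEL_DATA = (0x7FE0, 0x0010)


def _parse_one_element(buf: bytes, offset: int, explicit: bool):
    """Parse one data element; returns ((group, elem), value, next_offset)."""
    group, elem = struct.unpack_from("<HH", buf, offset)
    offset += 4
    if explicit and group != 0xFFFE:
        vr = buf[offset : offset + 2]
        if vr in _EXPLICIT_LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, offset + 4)
            offset += 8
        else:
            (length,) = struct.unpack_from("<H", buf, offset + 2)
            offset += 4
    else:
        (length,) = struct.unpack_from("<I", buf, offset)
        offset += 4
    if length == 0xFFFFFFFF:
        raise MetadataError("undefined-length DICOM element (encapsulated data?) unsupported")
    return (group, elem), buf[offset : offset + length], offset + length


def _parse_dicom_elements(buf: bytes, offset: int, explicit: bool):
    """Yield (tag, value-bytes) until the buffer is exhausted."""
    n = len(buf)
    while offset + 8 <= n:
        tag, val, offset = _parse_one_element(buf, offset, explicit)
        yield tag, val


def _read_dicom_slice(path):
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise MetadataError(f"{path}: missing DICM marker")
    # file meta group: always explicit VR little endian
    transfer = "1.2.840.10008.1.2.1"
    offset = 132
    while offset + 8 <= len(buf):
        group = struct.unpack_from("<H", buf, offset)[0]
        if group != 0x0002:
            break
        tag, val, offset = _parse_one_element(buf, offset, explicit=True)
        if tag == (0x0002, 0x0010):
            transfer = val.rstrip(b"\x00").decode(errors="replace").strip()
    if transfer == "1.2.840.10008.1.2":
        explicit = False
    elif transfer == "1.2.840.10008.1.2.1":
        explicit = True
    else:
        raise MetadataError(f"{path}: unsupported transfer syntax {transfer}")
    elements = dict(_parse_dicom_elements(buf, offset, explicit))
    try:
        rows = int.from_bytes(elements[_TAG_ROWS][:2], "little")
        cols = int.from_bytes(elements[_TAG_COLS][:2], "little")
        bits = int.from_bytes(elements[_TAG_BITS_ALLOC][:2], "little")
        pixels = elements[_TAG_PIXEL_DATA]
    except KeyError as exc:
        raise MetadataError(f"{path}: missing required DICOM tag {exc}") from exc
    if _TAG_PIXEL_SPACING not in elements:
        raise MetadataError(f"{path}: missing PixelSpacing")
    ps = [float(x) for x in elements[_TAG_PIXEL_SPACING].decode().strip("\x00 ").split("\\")]
    signed = int.from_bytes(elements.get(_TAG_PIXEL_REP, b"\x00\x00")[:2], "little") == 1
    dtype = {8: np.int8 if signed else np.uint8, 16: np.int16 if signed else np.uint16}.get(bits)
    if dtype is None:
        raise MetadataError(f"{path}: unsupported BitsAllocated {bits}")
    img = np.frombuffer(pixels, dtype=dtype, count=rows * cols).reshape(rows, cols)
    img = img.astype(np.float64)
    if _TAG_SLOPE in elements:
        img = img * float(elements[_TAG_SLOPE].decode().strip("\x00 ") or 1)
    if _TAG_INTERCEPT in elements:
        img = img + float(elements[_TAG_INTERCEPT].decode().strip("\x00 ") or 0)

    def _ds(tag, default=None):
        if tag not in elements:
            return default
        txt = elements[tag].decode(errors="replace").strip("\x00 ")
        return [float(x) for x in txt.split("\\")] if txt else default

    return {
        "image": img,  # (rows, cols) = (y, x)
        "pixel_spacing": ps,  # row, col spacing
        "ipp": _ds(_TAG_IPP),
        "slice_location": (_ds(_TAG_SLICE_LOCATION) or [None])[0],
        "instance": (_ds(_TAG_INSTANCE) or [None])[0],
        "slice_thickness": (_ds(_TAG_SLICE_THICKNESS) or [None])[0],
    }


def _load_dicom_series(path) -> VoxelVolume:
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = [_read_dicom_slice(p) for p in files]
    if not slices:
        raise MetadataError(f"{path}: no DICOM slices found")
    ps0 = slices[0]["pixel_spacing"]
    for s in slices:
        if not np.allclose(s["pixel_spacing"], ps0, atol=1e-9):
            raise MetadataError(f"{path}: heterogeneous pixel spacing across series")
        if s["image"].shape != slices[0]["image"].shape:
            raise MetadataError(f"{path}: heterogeneous slice dimensions")

    def sort_key(s):
        if s["ipp"] is not None:
            return s["ipp"][2]
        if s["slice_location"] is not None:
            return s["slice_location"]
        if s["instance"] is not None:
            return s["instance"]
        return 0.0

    slices.sort(key=sort_key)
    zs = [sort_key(s) for s in slices]
    if len(slices) > 1 and slices[0]["ipp"] is not None:
        dz = np.diff(zs)
        if np.ptp(dz) > 1e-6:
            raise MetadataError(f"{path}: non-uniform slice spacing")
        zspacing = float(dz[0])
    else:
        zspacing = slices[0]["slice_thickness"]
        if zspacing is None:
            raise MetadataError(f"{path}: cannot determine slice spacing")
    stack = np.stack([s["image"] for s in slices])  # (z, y, x)
    data = stack.transpose(2, 1, 0)  # (x, y, z)
    spacing = [ps0[1], ps0[0], zspacing]  # col, row, slice
    if slices[0]["ipp"] is not None:
        origin = [slices[0]["ipp"][0], slices[0]["ipp"][1], zs[0]]
    else:
        origin = [0.0, 0.0, 0.0]
    return VoxelVolume(data, spacing, origin)


def load_volume(path, kind: str = "auto") -> VoxelVolume:
    """Load a volume from a MetaImage file or a DICOM series directory."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"{path}: no such file or directory")
    if kind == "auto":
        kind = "dicom" if path.is_dir() else "meta"
    if kind in ("meta", "mhd"):
        return _load_meta(path)
    if kind == "dicom":
        return _load_dicom_series(path)
    raise ParameterError(f"unknown volume format tag {kind!r}")
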