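"""Raster and ROI input/output.

Conventions used throughout the package:

* Coordinates are 0-based ``(row, col) = (y, x)`` with the origin at the
  top-left pixel; ``x`` increases rightward, ``y`` downward.
* Polygon vertices are stored as ``(x, y)`` pairs in pixel coordinates,
  where integer coordinates address pixel *centers*.
* Physical scale is carried by ``pixel_size_um`` (µm per pixel, default
  0.5 µm as produced by automated whole-well confocal acquisition).
* Label masks are 16-bit: 0 is background, ``k > 0`` is object ``k``.
"""

from __future__ import annotations

import re
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from matplotlib.path import Path as MplPath

__all__ = [
    "WellImage",
    "LabelMask",
    "RoiEntry",
    "RoiSet",
    "read_well_image",
    "write_well_image",
    "read_label_mask",
    "write_label_mask",
    "read_roi_set",
    "write_roi_set",
    "rasterize_rois",
]

#: channel roles that must be present in a usable well image
REQUIRED_ROLES = ("nuclei", "membrane")
OPTIONAL_ROLES = ("brightfield",)
MAX_LABEL = 65535  # 16-bit label rasters; wells hold ~2000 candidates


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class WellImage:
    """Multi-channel 2-D raster of one culture well.

    Parameters
    ----------
    channels : dict of str to ndarray
        Map from channel role (``nuclei``, ``membrane``, optionally
        ``brightfield``) to a 2-D non-negative intensity raster.  All
        rasters must share one shape.
    pixel_size_um : float
        Physical pixel size in µm per pixel.
    name : str
        Well identifier.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.5
    name: str = "well"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {role: ch.shape for role, ch in self.channels.items()}
        if any(ch.ndim != 2 for ch in self.channels.values()):
            raise ValueError(f"all channels must be 2-D, got shapes {shapes}")
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shape mismatch: {shapes}")
        for role, ch in self.channels.items():
            if np.any(np.asarray(ch) < 0):
                raise ValueError(f"channel {role!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_size_um

    def px_to_um(self, px: float) -> float:
        return px * self.pixel_size_um


@dataclass
class LabelMask:
    """2-D integer label raster; 0 = background, k>0 = object k."""

    raster: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.raster)
        if r.ndim != 2:
            raise ValueError("label raster must be 2-D")
        if r.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        if r.max(initial=0) > MAX_LABEL:
            raise ValueError(f"more than {MAX_LABEL} labels not supported")
        self.raster = r.astype(np.uint16, copy=False)

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of positive labels present."""
        u = np.unique(self.raster)
        return u[u > 0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape


@dataclass
class RoiEntry:
    cell_id: int
    kind: str  # "nucleus" | "ensheathment"
    polygon: np.ndarray  # (n, 2) float array of (x, y) vertices

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float).reshape(-1, 2)
        if self.kind not in ("nucleus", "ensheathment"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if len(self.polygon) < 3:
            raise ValueError("polygons need at least 3 vertices")


@dataclass
class RoiSet:
    """A collection of traced polygons pairing nuclei with ensheathments.

    The nucleus/sheath pairing is encoded in the ROI name prefix
    ``cellK-nucleus`` / ``cellK-sheathJ``; every ensheathment entry's
    ``cell_id`` must match exactly one nucleus entry.
    """

    entries: list[RoiEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        nuclei = [e.cell_id for e in self.entries if e.kind == "nucleus"]
        if len(nuclei) != len(set(nuclei)):
            raise ValueError("duplicate nucleus entry for a cell_id")
        known = set(nuclei)
        for e in self.entries:
            if e.kind == "ensheathment" and e.cell_id not in known:
                raise ValueError(
                    f"ensheathment for cell {e.cell_id} has no nucleus entry"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def cell_ids(self) -> list[int]:
        return sorted({e.cell_id for e in self.entries if e.kind == "nucleus"})


# ---------------------------------------------------------------------------
# TIFF raster I/O
# ---------------------------------------------------------------------------

def read_well_image(
    path: str | Path,
    channel_map: dict[str, int],
    pixel_size_um: float = 0.5,
    name: str | None = None,
) -> WellImage:
    """Read a multi-plane TIFF into a :class:`WellImage`.

    ``channel_map`` assigns each channel role to a plane index, e.g.
    ``{"nuclei": 0, "membrane": 1}``.  Both required roles must be mapped.
    """
    path = Path(path)
    for role in REQUIRED_ROLES:
        if role not in channel_map:
            raise ValueError(f"missing required role {role!r} in channel_map")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D TIFF, got shape {data.shape}")
    channels = {}
    for role, idx in channel_map.items():
        if idx >= len(data):
            raise ValueError(f"plane {idx} for role {role!r} not in file "
                             f"({len(data)} planes)")
        channels[role] = np.asarray(data[idx])
    if len({c.shape for c in channels.values()}) > 1:
        raise ValueError("plane shape mismatch")
    return WellImage(channels, pixel_size_um=pixel_size_um,
                     name=name or path.stem)


def write_well_image(image: WellImage, path: str | Path) -> dict[str, int]:
    """Write a :class:`WellImage` as a multi-plane TIFF.

    Planes are written in canonical role order (nuclei, membrane,
    brightfield when present).  Returns the channel map used, suitable for
    :func:`read_well_image`.
    """
    order = [r for r in REQUIRED_ROLES + OPTIONAL_ROLES if r in image.channels]
    stack = np.stack([image.channels[r] for r in order])
    tifffile.imwrite(str(path), stack)
    return {r: i for i, r in enumerate(order)}


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    tifffile.imwrite(str(path), mask.raster.astype(np.uint16))


def read_label_mask(path: str | Path) -> LabelMask:
    return LabelMask(tifffile.imread(str(path)))


# ---------------------------------------------------------------------------
# ImageJ .roi polygon codec
# ---------------------------------------------------------------------------
# The ImageJ ROI container is a small big-endian binary record: a 64-byte
# header ("Iout" magic, type byte, bounding box, vertex count), the vertex
# coordinates as int16 offsets from the bounding box corner, and an optional
# second header carrying the ROI name as UTF-16BE.  Only polygon ROIs
# (type 0) are supported here, which is what tracing with the polygon tool
# produces.

_HEADER_SIZE = 64
_POLYGON_TYPE = 0

_NAME_RE = re.compile(r"^cell(\d+)[-_](nucleus|sheath|ensheathment)", re.I)


def _encode_roi(name: str, polygon: np.ndarray) -> bytes:
    poly = np.asarray(polygon, dtype=float)
    xs = np.round(poly[:, 0]).astype(int)
    ys = np.round(poly[:, 1]).astype(int)
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()) + 1, int(ys.max()) + 1
    n = len(poly)

    header = bytearray(_HEADER_SIZE)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)  # format version
    header[6] = _POLYGON_TYPE
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    h2_offset = _HEADER_SIZE + 4 * n
    struct.pack_into(">i", header, 60, h2_offset)

    coords = bytearray(4 * n)
    struct.pack_into(f">{n}h", coords, 0, *(xs - left))
    struct.pack_into(f">{n}h", coords, 2 * n, *(ys - top))

    header2 = bytearray(_HEADER_SIZE)
    name_bytes = name.encode("utf-16-be")
    struct.pack_into(">i", header2, 16, h2_offset + _HEADER_SIZE)
    struct.pack_into(">i", header2, 20, len(name))

    return bytes(header) + bytes(coords) + bytes(header2) + name_bytes


def _decode_roi(buf: bytes, fallback_name: str = "") -> tuple[str, np.ndarray]:
    if len(buf) < _HEADER_SIZE or buf[0:4] != b"Iout":
        raise ValueError("corrupt ROI record (bad magic)")
    roi_type = buf[6]
    if roi_type != _POLYGON_TYPE:
        raise ValueError(f"unsupported ROI type {roi_type}; only polygons")
    top, left, _bottom, _right = struct.unpack_from(">4h", buf, 8)
    (n,) = struct.unpack_from(">h", buf, 16)
    if n < 3 or len(buf) < _HEADER_SIZE + 4 * n:
        raise ValueError("corrupt ROI record (truncated coordinates)")
    xs = np.array(struct.unpack_from(f">{n}h", buf, _HEADER_SIZE)) + left
    ys = np.array(struct.unpack_from(f">{n}h", buf, _HEADER_SIZE + 2 * n)) + top

    name = fallback_name
    (h2,) = struct.unpack_from(">i", buf, 60)
    if h2 > 0 and len(buf) >= h2 + _HEADER_SIZE:
        name_off, name_len = struct.unpack_from(">2i", buf, h2 + 16)
        if name_off > 0 and name_len > 0 and len(buf) >= name_off + 2 * name_len:
            name = buf[name_off:name_off + 2 * name_len].decode("utf-16-be")
    return name, np.column_stack([xs, ys]).astype(float)


def _entry_from_name(name: str, polygon: np.ndarray) -> RoiEntry:
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(
            f"cannot parse cell id from ROI name {name!r}; expected "
            "'cellK-nucleus' or 'cellK-sheathJ'"
        )
    kind = "nucleus" if m.group(2).lower() == "nucleus" else "ensheathment"
    return RoiEntry(cell_id=int(m.group(1)), kind=kind, polygon=polygon)


def read_roi_set(path: str | Path) -> RoiSet:
    """Read a single ``.roi`` file or a ``.zip`` archive of ROI files.

    Vertex lists come back in image pixel coordinates (origin top-left, x
    rightward, y downward).  An empty archive yields an empty set.
    """
    path = Path(path)
    entries: list[RoiEntry] = []
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for info in sorted(zf.infolist(), key=lambda i: i.filename):
                if not info.filename.lower().endswith(".roi"):
                    continue
                name, poly = _decode_roi(zf.read(info),
                                         Path(info.filename).stem)
                entries.append(_entry_from_name(name, poly))
    else:
        name, poly = _decode_roi(path.read_bytes(), path.stem)
        entries.append(_entry_from_name(name, poly))
    return RoiSet(entries)


def write_roi_set(rois: RoiSet, path: str | Path) -> None:
    """Write a :class:`RoiSet` as a zip archive of ImageJ polygon ROIs."""
    path = Path(path)
    counters: dict[int, int] = {}
    with zipfile.ZipFile(path, "w") as zf:
        for e in rois.entries:
            if e.kind == "nucleus":
                name = f"cell{e.cell_id}-nucleus"
            else:
                counters[e.cell_id] = counters.get(e.cell_id, 0) + 1
                name = f"cell{e.cell_id}-sheath{counters[e.cell_id]}"
            zf.writestr(f"{name}.roi", _encode_roi(name, e.polygon))


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _fill_polygon(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd pixel-center fill of a simple polygon.

    A pixel belongs to the polygon iff its center passes the point-in-
    polygon test; centers lying exactly on the boundary are included.
    Restricted to the polygon's bounding box for speed.
    """
    h, w = shape
    poly = np.asarray(polygon, dtype=float)
    x0 = max(int(np.floor(poly[:, 0].min())), 0)
    x1 = min(int(np.ceil(poly[:, 0].max())), w - 1)
    y0 = max(int(np.floor(poly[:, 1].min())), 0)
    y1 = min(int(np.ceil(poly[:, 1].max())), h - 1)
    out = np.zeros(shape, dtype=bool)
    if x1 < x0 or y1 < y0:
        return out
    yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    # the vertex ring must be explicitly closed for contains_points
    mpath = MplPath(np.vstack([poly, poly[:1]]), closed=True)
    # boundary centers must count as inside regardless of winding: test with
    # a tiny outward and a tiny inward tolerance and take the union
    inside = mpath.contains_points(pts, radius=1e-6) \
        | mpath.contains_points(pts, radius=-1e-6)
    out[y0:y1 + 1, x0:x1 + 1] = inside.reshape(yy.shape)
    return out


def rasterize_rois(
    rois: RoiSet, shape: tuple[int, int]
) -> tuple[LabelMask, LabelMask]:
    """Rasterize a ROI set into paired nucleus and sheath label masks.

    Each ``cell_id`` becomes one label carried identically in both masks;
    a cell with no ensheathment entries appears only in the nucleus mask.
    """
    h, w = shape
    nuclei = np.zeros(shape, dtype=np.uint16)
    sheaths = np.zeros(shape, dtype=np.uint16)
    for e in rois.entries:
        poly = e.polygon
        if (poly[:, 0].min() < 0 or poly[:, 0].max() > w - 1
                or poly[:, 1].min() < 0 or poly[:, 1].max() > h - 1):
            raise ValueError(
                f"ROI for cell {e.cell_id} has out-of-bounds vertices"
            )
        if e.cell_id <= 0 or e.cell_id > MAX_LABEL:
            raise ValueError(f"cell_id {e.cell_id} outside 16-bit label range")
        filled = _fill_polygon(poly, shape)
        target = nuclei if e.kind == "nucleus" else sheaths
        target[filled] = e.cell_id
    return LabelMask(nuclei), LabelMask(sheaths)
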