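"""Point-cloud ingestion and row-frame preprocessing.

Readers/writers for the formats TLS vendors commonly export (PLY, LAS,
XYZ CSV), plus the geometric normalisation the downstream layering step
assumes: X along the crop row, Z as plant height, soil at z = 0.

All internal coordinates are in meters.  Unit conversion (cm/mm exports)
happens once, at ingestion.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "RowCloud",
    "read_cloud",
    "write_cloud",
    "to_row_frame",
    "extract_row",
    "filter_outliers",
    "CloudFormatError",
]

#: scale factors applied to raw file coordinates to obtain meters
UNIT_SCALES: Mapping[str, float] = {"m": 1.0, "cm": 0.01, "mm": 0.001}


class CloudFormatError(ValueError):
    """Raised when a point-cloud file does not parse under its format."""


@dataclass
class PointCloud:
    """An unordered 3D point set in meters, with optional integer label channels.

    Parameters
    ----------
    points
        ``(N, 3)`` float array of x/y/z coordinates in meters.
    labels
        Optional mapping of channel name to an ``(N,)`` integer array
        (e.g. ``cluster_id`` / ``tiller_id`` / ``kind`` for synthetic truth).
    """

    points: np.ndarray
    labels: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            if pts.size == 0:
                pts = pts.reshape(0, 3)
            else:
                raise ValueError(f"points must be (N, 3), got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        self.points = pts
        if self.labels is not None:
            clean = {}
            for name, lab in self.labels.items():
                lab = np.asarray(lab)
                if lab.shape != (len(pts),):
                    raise ValueError(
                        f"label channel {name!r} has {lab.shape}, expected ({len(pts)},)"
                    )
                clean[name] = lab.astype(np.int64)
            self.labels = clean

    def __len__(self) -> int:
        return len(self.points)

    def take(self, index: np.ndarray) -> "PointCloud":
        """Subset or reorder points (and labels) by integer/boolean index."""
        labels = (
            {k: v[index] for k, v in self.labels.items()} if self.labels else None
        )
        return type(self)(self.points[index], labels)


@dataclass
class RowCloud(PointCloud):
    """A single crop row in the row frame: X along the row, Z = height.

    ``ground_z`` is the soil height in the cloud's own frame (0 after
    :func:`to_row_frame`).  The row must be non-empty and no point may lie
    below ground beyond ``GROUND_TOL``.
    """

    ground_z: float = 0.0

    GROUND_TOL = 1e-6

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.points) == 0:
            raise ValueError("a RowCloud must contain at least one point")
        if np.min(self.points[:, 2]) < self.ground_z - self.GROUND_TOL:
            raise ValueError("points lie below the stated ground level")

    @property
    def row_axis_length(self) -> float:
        """Extent of the row along X, in meters."""
        x = self.points[:, 0]
        return float(x.max() - x.min())

    def take(self, index: np.ndarray) -> "RowCloud":
        labels = (
            {k: v[index] for k, v in self.labels.items()} if self.labels else None
        )
        return RowCloud(self.points[index], labels, ground_z=self.ground_z)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_FORMAT_SUFFIXES = {
    ".ply": "ply",
    ".las": "las",
    ".laz": "laz",
    ".csv": "xyz_csv",
    ".xyz": "xyz_csv",
    ".txt": "xyz_csv",
}


def _infer_format(path: Path) -> str:
    try:
        return _FORMAT_SUFFIXES[path.suffix.lower()]
    except KeyError:
        raise CloudFormatError(
            f"cannot infer point-cloud format from suffix {path.suffix!r}"
        ) from None


def read_cloud(path, format: str | None = None, units: str = "m") -> PointCloud:
    """Read a point cloud from PLY, LAS, or XYZ CSV.

    Parameters
    ----------
    path
        Input file.
    format
        ``"ply"``, ``"las"``, or ``"xyz_csv"``; inferred from the suffix when
        omitted.
    units
        Units of the coordinates in the file (``m``/``cm``/``mm``);
        coordinates are converted to meters.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if units not in UNIT_SCALES:
        raise ValueError(f"unknown unit {units!r}; expected one of {list(UNIT_SCALES)}")
    scale = UNIT_SCALES[units]

    if fmt == "ply":
        cloud = _read_ply(path)
    elif fmt == "las":
        cloud = _read_las(path)
    elif fmt == "laz":
        raise CloudFormatError(
            "LAZ (compressed LAS) is not supported; decompress to .las first"
        )
    elif fmt == "xyz_csv":
        cloud = _read_xyz_csv(path)
    else:
        raise CloudFormatError(f"unknown format {fmt!r}")

    if scale != 1.0:
        cloud = PointCloud(cloud.points * scale, cloud.labels)
    return cloud


def write_cloud(cloud: PointCloud, path, format: str | None = None) -> None:
    """Write a point cloud as ascii PLY or XYZ CSV (label channels included)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ply":
        _write_ply(cloud, path)
    elif fmt == "xyz_csv":
        _write_xyz_csv(cloud, path)
    else:
        raise CloudFormatError(f"unsupported output format {fmt!r}")


# -- XYZ CSV -----------------------------------------------------------------


def _read_xyz_csv(path: Path) -> PointCloud:
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    label_names: list[str] = []
    start = 0
    if lines:
        first = [f.strip() for f in lines[0].split(",")]
        try:
            float(first[0])
        except ValueError:
            # header row: x,y,z[,label...]
            if [c.lower() for c in first[:3]] != ["x", "y", "z"]:
                raise CloudFormatError(
                    f"{path}: line 1: expected header starting 'x,y,z', got {lines[0]!r}"
                )
            label_names = first[3:]
            start = 1
    coords: list[list[float]] = []
    labels: list[list[int]] = []
    ncol: int | None = None
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        fields = [f.strip() for f in ln.split(",")]
        if ncol is None:
            ncol = len(fields)
            if ncol < 3:
                raise CloudFormatError(f"{path}: line {lineno}: fewer than 3 columns")
        elif len(fields) != ncol:
            raise CloudFormatError(
                f"{path}: line {lineno}: expected {ncol} columns, got {len(fields)}"
            )
        try:
            coords.append([float(f) for f in fields[:3]])
            labels.append([int(float(f)) for f in fields[3:]])
        except ValueError as exc:
            raise CloudFormatError(f"{path}: line {lineno}: {exc}") from None
    pts = np.array(coords, dtype=float).reshape(-1, 3)
    lab_dict = None
    if ncol and ncol > 3:
        if not label_names:
            label_names = [f"label{i}" if i else "label" for i in range(ncol - 3)]
        arr = np.array(labels, dtype=np.int64).reshape(-1, ncol - 3)
        lab_dict = {name: arr[:, i] for i, name in enumerate(label_names)}
    return PointCloud(pts, lab_dict)


def _write_xyz_csv(cloud: PointCloud, path: Path) -> None:
    names = list(cloud.labels) if cloud.labels else []
    header = ",".join(["x", "y", "z"] + names)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i, (x, y, z) in enumerate(cloud.points):
            row = [f"{x:.9g}", f"{y:.9g}", f"{z:.9g}"]
            row += [str(int(cloud.labels[n][i])) for n in names]
            fh.write(",".join(row) + "\n")


# -- PLY ---------------------------------------------------------------------

_PLY_DTYPES = {
    "float": "<f4",
    "float32": "<f4",
    "double": "<f8",
    "float64": "<f8",
    "char": "<i1",
    "int8": "<i1",
    "uchar": "<u1",
    "uint8": "<u1",
    "short": "<i2",
    "int16": "<i2",
    "ushort": "<u2",
    "uint16": "<u2",
    "int": "<i4",
    "int32": "<i4",
    "uint": "<u4",
    "uint32": "<u4",
}


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise CloudFormatError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        while True:
            raw = fh.readline()
            if not raw:
                raise CloudFormatError(f"{path}: unexpected EOF in PLY header")
            line = raw.decode("ascii", "replace").strip()
            if not line or line.startswith("comment"):
                continue
            tok = line.split()
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                elements.append((tok[1], int(tok[2]), []))
            elif tok[0] == "property":
                if tok[1] == "list":
                    raise CloudFormatError(
                        f"{path}: list properties are not supported for point clouds"
                    )
                elements[-1][2].append((tok[2], tok[1]))
            elif tok[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise CloudFormatError(f"{path}: unsupported PLY format {fmt!r}")
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise CloudFormatError(f"{path}: PLY has no 'vertex' element")
        if elements and elements[0][0] != "vertex":
            raise CloudFormatError(f"{path}: 'vertex' must be the first PLY element")
        _, count, props = vertex
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise CloudFormatError(f"{path}: vertex element lacks property {axis!r}")
        try:
            dtype = np.dtype([(n, _PLY_DTYPES[t]) for n, t in props])
        except KeyError as exc:
            raise CloudFormatError(f"{path}: unsupported PLY property type {exc}") from None

        if fmt == "ascii":
            rows = []
            for i in range(count):
                line = fh.readline().decode("ascii", "replace").split()
                if len(line) != len(props):
                    raise CloudFormatError(
                        f"{path}: vertex record {i}: expected {len(props)} values, "
                        f"got {len(line)}"
                    )
                rows.append(tuple(line))
            data = np.array(rows, dtype=dtype) if rows else np.empty(0, dtype=dtype)
        else:
            buf = fh.read(dtype.itemsize * count)
            if len(buf) < dtype.itemsize * count:
                raise CloudFormatError(f"{path}: truncated PLY vertex data")
            data = np.frombuffer(buf, dtype=dtype, count=count)

    pts = np.column_stack([data["x"], data["y"], data["z"]]).astype(float)
    label_names = [n for n, t in props if n not in ("x", "y", "z") and "f" not in _PLY_DTYPES[t]]
    labels = {n: data[n].astype(np.int64) for n in label_names} or None
    return PointCloud(pts, labels)


def _write_ply(cloud: PointCloud, path: Path) -> None:
    names = list(cloud.labels) if cloud.labels else []
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment written by tillerscan\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        for n in names:
            fh.write(f"property int {n}\n")
        fh.write("end_header\n")
        for i, (x, y, z) in enumerate(cloud.points):
            row = [f"{x:.12g}", f"{y:.12g}", f"{z:.12g}"]
            row += [str(int(cloud.labels[n][i])) for n in names]
            fh.write(" ".join(row) + "\n")


# -- LAS (uncompressed, point formats 0-3) -----------------------------------


def _read_las(path: Path) -> PointCloud:
    data = path.read_bytes()
    if data[:4] != b"LASF":
        raise CloudFormatError(f"{path}: not a LAS file (missing 'LASF' signature)")
    if len(data) < 227:
        raise CloudFormatError(f"{path}: truncated LAS header")
    ver_major, ver_minor = data[24], data[25]
    (offset_to_points,) = struct.unpack_from("<I", data, 96)
    point_format = data[104]
    if point_format & 0x80:  # high bits set => LAZ compression
        raise CloudFormatError(f"{path}: LAZ-compressed points are not supported")
    if point_format > 3:
        raise CloudFormatError(
            f"{path}: LAS point data format {point_format} unsupported (expected 0-3)"
        )
    (record_len,) = struct.unpack_from("<H", data, 105)
    (n_points,) = struct.unpack_from("<I", data, 107)
    if n_points == 0 and ver_major == 1 and ver_minor >= 4 and len(data) >= 255:
        (n_points,) = struct.unpack_from("<Q", data, 247)
    sx, sy, sz = struct.unpack_from("<3d", data, 131)
    ox, oy, oz = struct.unpack_from("<3d", data, 155)
    if record_len < 12:
        raise CloudFormatError(f"{path}: LAS point record length {record_len} < 12")
    end = offset_to_points + n_points * record_len
    if end > len(data):
        raise CloudFormatError(f"{path}: truncated LAS point data")
    raw = np.frombuffer(
        data,
        dtype=np.dtype({"names": ["x", "y", "z"],
                        "formats": ["<i4", "<i4", "<i4"],
                        "offsets": [0, 4, 8],
                        "itemsize": record_len}),
        count=n_points,
        offset=offset_to_points,
    )
    pts = np.column_stack(
        [raw["x"] * sx + ox, raw["y"] * sy + oy, raw["z"] * sz + oz]
    ).astype(float)
    return PointCloud(pts)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def to_row_frame(cloud: PointCloud, row_direction, ground_z: float = 0.0) -> RowCloud:
    """Rigidly rotate/translate a cloud so X runs along the row and ground is z=0.

    ``row_direction`` is a 2D vector in the ground plane pointing along the
    row; Y becomes perpendicular to the row, Z is unchanged apart from the
    ``ground_z`` shift.  Pairwise distances are preserved exactly (rotation
    about Z plus translation).
    """
    if len(cloud) == 0:
        raise ValueError("cannot orient an empty cloud")
    d = np.asarray(row_direction, dtype=float).ravel()
    if d.shape != (2,) or not np.any(d):
        raise ValueError("row_direction must be a nonzero 2D vector")
    d = d / np.hypot(d[0], d[1])
    perp = np.array([-d[1], d[0]])
    xy = cloud.points[:, :2]
    new = np.column_stack([xy @ d, xy @ perp, cloud.points[:, 2] - ground_z])
    return RowCloud(new, cloud.labels, ground_z=0.0)


def extract_row(cloud: RowCloud, y_center: float, y_halfwidth: float) -> RowCloud:
    """Keep the points inside the band ``|y - y_center| <= y_halfwidth``."""
    if y_halfwidth <= 0:
        raise ValueError("y_halfwidth must be positive")
    mask = np.abs(cloud.points[:, 1] - y_center) <= y_halfwidth
    if not mask.any():
        raise ValueError(
            f"no points within |y - {y_center}| <= {y_halfwidth}; widen the band"
        )
    return cloud.take(mask)


def filter_outliers(cloud: RowCloud, k: int = 8, std_mult: float = 3.0) -> RowCloud:
    """Statistical outlier removal: drop points far from their k nearest neighbors.

    A point is removed when its mean distance to its ``k`` nearest neighbors
    exceeds the global mean of that statistic plus ``std_mult`` standard
    deviations.  Deterministic; intended to emulate the manual removal of
    floating noise (insects, airborne particles) above the canopy.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(cloud) <= k:
        raise ValueError(f"cloud has {len(cloud)} points; need more than k={k}")
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    thresh = mean_d.mean() + std_mult * mean_d.std()
    return cloud.take(mean_d <= thresh)
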