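"""Point-cloud and tree-metadata IO.

Clouds are held as double-precision metre coordinates, z-up.  Supported
formats are PLY (ASCII and binary little-endian, point elements only), plain
whitespace-delimited XYZ text, and — when :mod:`laspy` is importable — LAS
(read-only).  Tree metadata (site, tree id, planting year, scan year) travels
as a UTF-8 CSV with a header row.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import EmptyCloudError, PointCloudParseError, SchemaError

#: minimum cloud size admitted to metric estimation
MIN_METRIC_POINTS = 100

TREE_TABLE_COLUMNS = ("site", "tree_id", "planting_year", "scan_year")


@dataclass
class PointCloud:
    """A set of 3-D points for one tree, metric units, z-up.

    Parameters
    ----------
    points
        ``(n, 3)`` float64 array of x, y, z in metres.
    source_id
        Provenance label (file stem, synthetic tree id, ...).
    attributes
        Optional per-point attributes (e.g. intensity), preserved opaquely.
    """

    points: np.ndarray
    source_id: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3); got shape {pts.shape}")
        if pts.shape[0] == 0:
            raise EmptyCloudError(f"empty cloud ({self.source_id or 'unnamed'})")
        if not np.isfinite(pts).all():
            raise ValueError("point cloud contains non-finite coordinates")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]


@dataclass(frozen=True)
class TreeRecord:
    """Identity and dating of one tree; age = scan_year - planting_year."""

    site: str
    tree_id: str
    planting_year: int
    scan_year: int

    @property
    def age(self) -> int:
        return self.scan_year - self.planting_year

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise SchemaError(
                f"tree {self.tree_id!r}: scan_year {self.scan_year} must be "
                f"after planting_year {self.planting_year}"
            )


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "float": ("f4", 4), "float32": ("f4", 4),
    "double": ("f8", 8), "float64": ("f8", 8),
    "uchar": ("u1", 1), "uint8": ("u1", 1),
    "char": ("i1", 1), "int8": ("i1", 1),
    "short": ("i2", 2), "int16": ("i2", 2),
    "ushort": ("u2", 2), "uint16": ("u2", 2),
    "int": ("i4", 4), "int32": ("i4", 4),
    "uint": ("u4", 4), "uint32": ("u4", 4),
}


def _parse_ply_header(fh) -> tuple[str, int, list[tuple[str, str]], int]:
    """Return (format, n_vertices, [(name, type), ...], header_end_offset)."""
    magic = fh.readline()
    if magic.strip() != b"ply":
        raise PointCloudParseError("not a PLY file: missing 'ply' magic on line 1")
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    lineno = 1
    while True:
        raw = fh.readline()
        if not raw:
            raise PointCloudParseError("unexpected end of PLY header")
        lineno += 1
        tokens = raw.decode("ascii", errors="replace").split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            fmt = tokens[1]
        elif tokens[0] == "element":
            in_vertex = tokens[1] == "vertex"
            if in_vertex:
                n_vertex = int(tokens[2])
            elif int(tokens[2]) > 0:
                raise PointCloudParseError(
                    f"PLY line {lineno}: non-vertex element {tokens[1]!r} unsupported"
                )
        elif tokens[0] == "property" and in_vertex:
            if tokens[1] == "list":
                raise PointCloudParseError(
                    f"PLY line {lineno}: list properties unsupported for vertices"
                )
            props.append((tokens[2], tokens[1]))
        elif tokens[0] == "end_header":
            break
    if fmt is None or n_vertex is None:
        raise PointCloudParseError("PLY header lacks format or vertex element")
    if fmt not in ("ascii", "binary_little_endian"):
        raise PointCloudParseError(f"unsupported PLY format {fmt!r}")
    names = [p[0] for p in props]
    for axis in "xyz":
        if axis not in names:
            raise PointCloudParseError(f"PLY vertex element lacks property {axis!r}")
    return fmt, n_vertex, props, fh.tell()


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        fmt, n_vertex, props, offset = _parse_ply_header(fh)
        if n_vertex == 0:
            raise EmptyCloudError(f"empty cloud: {path}")
        names = [p[0] for p in props]
        if fmt == "ascii":
            data = np.loadtxt(fh, dtype=np.float64, ndmin=2)
            if data.shape != (n_vertex, len(props)):
                raise PointCloudParseError(
                    f"{path}: expected {n_vertex} x {len(props)} ASCII records, "
                    f"got {data.shape[0]} x {data.shape[1]}"
                )
            columns = {name: data[:, i] for i, name in enumerate(names)}
        else:
            dtype = np.dtype([(name, "<" + _PLY_DTYPES[t][0]) for name, t in props])
            buf = fh.read(n_vertex * dtype.itemsize)
            if len(buf) < n_vertex * dtype.itemsize:
                raise PointCloudParseError(
                    f"{path}: binary payload truncated at byte {offset + len(buf)}"
                )
            rec = np.frombuffer(buf, dtype=dtype)
            columns = {name: rec[name].astype(np.float64) for name in names}
    xyz = np.column_stack([columns.pop("x"), columns.pop("y"), columns.pop("z")])
    return PointCloud(xyz, source_id=path.stem, attributes=columns)


def _write_ply(cloud: PointCloud, path: Path, binary: bool) -> None:
    n = len(cloud)
    header = [
        "ply",
        "format binary_little_endian 1.0" if binary else "format ascii 1.0",
        f"element vertex {n}",
        "property double x",
        "property double y",
        "property double z",
        "end_header",
    ]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(cloud.points, dtype="<f8").tobytes())
        else:
            np.savetxt(fh, cloud.points, fmt="%.10g")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def _read_xyz(path: Path) -> PointCloud:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) < 3:
                raise PointCloudParseError(
                    f"{path}: line {lineno}: expected at least 3 columns, got {len(tokens)}"
                )
            try:
                rows.append([float(t) for t in tokens[:3]])
            except ValueError as exc:
                raise PointCloudParseError(
                    f"{path}: line {lineno}: non-numeric token ({exc})"
                ) from None
    if not rows:
        raise EmptyCloudError(f"empty cloud: {path}")
    return PointCloud(np.asarray(rows, dtype=np.float64), source_id=path.stem)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    np.savetxt(path, cloud.points, fmt="%.10g")


def _read_las(path: Path) -> PointCloud:
    try:
        import laspy
    except ImportError as exc:  # pragma: no cover - laspy optional
        raise PointCloudParseError(
            "LAS support requires the optional 'laspy' dependency "
            "(pip install tlscarbon[las])"
        ) from exc
    las = laspy.read(str(path))  # pragma: no cover
    xyz = np.column_stack([las.x, las.y, las.z]).astype(np.float64)
    return PointCloud(xyz, source_id=path.stem)


_FORMAT_SUFFIX = {".ply": "ply", ".xyz": "xyz", ".txt": "xyz", ".las": "las", ".laz": "las"}


def read_cloud(path, format: Optional[str] = None) -> PointCloud:
    """Read a per-tree point cloud.

    ``format`` is one of ``"ply"``, ``"xyz"``, ``"las"``; when omitted it is
    inferred from the file suffix.  Coordinates are returned in metres with
    the original point order preserved.
    """
    path = Path(path)
    fmt = (format or _FORMAT_SUFFIX.get(path.suffix.lower(), "")).lower()
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "las":
        return _read_las(path)
    raise ValueError(f"unknown point-cloud format {format or path.suffix!r}")


def write_cloud(cloud: PointCloud, path, format: Optional[str] = None,
                binary: bool = True) -> None:
    """Write a cloud as PLY (binary LE by default, ASCII with ``binary=False``) or XYZ."""
    path = Path(path)
    fmt = (format or _FORMAT_SUFFIX.get(path.suffix.lower(), "")).lower()
    if fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    elif fmt == "xyz":
        _write_xyz(cloud, path)
    else:
        raise ValueError(f"unsupported output format {format or path.suffix!r}")


# ---------------------------------------------------------------------------
# tree metadata table
# ---------------------------------------------------------------------------

def read_tree_table(path) -> list[TreeRecord]:
    """Read a tree metadata CSV into :class:`TreeRecord` rows.

    Requires columns ``site, tree_id, planting_year, scan_year``.  Rows whose
    scan year is not after the planting year are rejected, with the offending
    row numbers (1-based, excluding the header) named in the error.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected columns {TREE_TABLE_COLUMNS}")
    missing = [c for c in TREE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    bad = df.index[df["scan_year"] <= df["planting_year"]] + 1
    if len(bad):
        raise SchemaError(
            f"{path}: scan_year <= planting_year on row(s) {list(bad)}"
        )
    return [
        TreeRecord(str(r.site), str(r.tree_id), int(r.planting_year), int(r.scan_year))
        for r in df.itertuples()
    ]


def write_tree_table(records: list[TreeRecord], path) -> None:
    pd.DataFrame(
        [(r.site, r.tree_id, r.planting_year, r.scan_year) for r in records],
        columns=list(TREE_TABLE_COLUMNS),
    ).to_csv(path, index=False)
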