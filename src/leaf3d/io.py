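"""PLY reading/writing for colored (and optionally leaf-labeled) point clouds.

Handles the two PLY flavours produced by photogrammetry tools — ``ascii``
and ``binary_little_endian`` — restricted to vertex data: ``x, y, z``
coordinates, ``red, green, blue`` colours, and an optional integer ``leaf``
property carrying per-point segmentation labels.  Other vertex properties
are read and ignored; list properties are not supported.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .cloud import PointCloud

__all__ = ["read_ply", "write_ply"]

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


class PLYError(ValueError):
    """Malformed or unsupported PLY content."""


def _parse_header(fh) -> tuple[str, list[tuple[str, int, list[tuple[str, str]]]], int]:
    """Return (format, elements, header_end_offset).

    ``elements`` is a list of (name, count, [(prop_name, numpy_dtype), ...]).
    """
    magic = fh.readline()
    if magic.strip() != b"ply":
        raise PLYError("not a PLY file (missing 'ply' magic line)")
    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    lineno = 1
    while True:
        raw = fh.readline()
        lineno += 1
        if not raw:
            raise PLYError(f"unexpected end of header at line {lineno}")
        line = raw.decode("ascii", errors="replace").strip()
        if not line or line.startswith("comment") or line.startswith("obj_info"):
            continue
        tokens = line.split()
        if tokens[0] == "format":
            if tokens[1] not in ("ascii", "binary_little_endian"):
                raise PLYError(f"unsupported PLY format '{tokens[1]}' (line {lineno})")
            fmt = tokens[1]
        elif tokens[0] == "element":
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if not elements:
                raise PLYError(f"property before any element (line {lineno})")
            if tokens[1] == "list":
                elements[-1][2].append((tokens[-1], "list"))
            else:
                if tokens[1] not in _PLY_DTYPES:
                    raise PLYError(f"unknown property type '{tokens[1]}' (line {lineno})")
                elements[-1][2].append((tokens[-1], _PLY_DTYPES[tokens[1]]))
        elif tokens[0] == "end_header":
            break
        else:
            raise PLYError(f"unrecognized header line {lineno}: '{line}'")
    if fmt is None:
        raise PLYError("PLY header has no 'format' line")
    return fmt, elements, fh.tell()


def read_ply(path: str | os.PathLike) -> PointCloud:
    """Read a PLY point cloud with ``x,y,z`` and ``red,green,blue`` vertices.

    A ``leaf`` integer vertex property, if present, is loaded as per-point
    labels.  Raises :class:`PLYError` naming the missing property if the
    vertex element lacks coordinates or colours.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fmt, elements, offset = _parse_header(fh)
        try:
            name, count, props = next(e for e in elements if e[0] == "vertex")
        except StopIteration:
            raise PLYError("PLY file has no 'vertex' element") from None
        if elements[0][0] != "vertex":
            raise PLYError("only PLY files whose first element is 'vertex' are supported")
        for required in ("x", "y", "z", "red", "green", "blue"):
            if required not in [p[0] for p in props]:
                raise PLYError(f"vertex element is missing required property '{required}'")
        if any(dt == "list" for _, dt in props):
            raise PLYError("list properties on the vertex element are not supported")

        if fmt == "ascii":
            text = fh.read().decode("ascii", errors="replace").split("\n")
            rows = [ln.split() for ln in text if ln.strip()][:count]
            if len(rows) < count:
                raise PLYError(
                    f"expected {count} vertex rows, found {len(rows)}"
                )
            names = [p[0] for p in props]
            try:
                data = np.array(rows, dtype=np.float64)
            except ValueError as exc:
                raise PLYError(f"malformed ASCII vertex data: {exc}") from exc
            if data.shape[1] != len(names):
                raise PLYError(
                    f"vertex rows have {data.shape[1]} columns, header declares {len(names)}"
                )
            cols = {n: data[:, i] for i, n in enumerate(names)}
        else:
            dtype = np.dtype([(n, "<" + dt) for n, dt in props])
            buf = fh.read(count * dtype.itemsize)
            if len(buf) < count * dtype.itemsize:
                raise PLYError("binary vertex data truncated")
            rec = np.frombuffer(buf, dtype=dtype, count=count)
            cols = {n: rec[n] for n, _ in props}

    points = np.column_stack([cols["x"], cols["y"], cols["z"]]).astype(np.float64)
    colors = np.column_stack(
        [cols["red"], cols["green"], cols["blue"]]
    ).astype(np.uint8)
    labels = cols["leaf"].astype(np.int64) if "leaf" in cols else None
    return PointCloud(points, colors, labels)


def write_ply(
    path: str | os.PathLike,
    cloud: PointCloud,
    binary: bool = False,
) -> None:
    """Write a point cloud as PLY; labels, if present, go to a ``leaf`` property.

    Coordinates are stored as ``double`` so a write/read round trip preserves
    them exactly.
    """
    path = Path(path)
    n = len(cloud)
    props = [("x", "f8"), ("y", "f8"), ("z", "f8"),
             ("red", "u1"), ("green", "u1"), ("blue", "u1")]
    header_types = {"f8": "double", "u1": "uchar", "i4": "int"}
    if cloud.labels is not None:
        props.append(("leaf", "i4"))
    header = ["ply",
              f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {n}"]
    header += [f"property {header_types[dt]} {name}" for name, dt in props]
    header.append("end_header")

    rec = np.zeros(n, dtype=np.dtype([(name, "<" + dt) for name, dt in props]))
    rec["x"], rec["y"], rec["z"] = cloud.points.T
    rec["red"], rec["green"], rec["blue"] = cloud.colors.astype(np.uint8).T
    if cloud.labels is not None:
        rec["leaf"] = cloud.labels

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(rec.tobytes())
        else:
            fmt_parts = ["%.17g"] * 3 + ["%d"] * (len(props) - 3)
            lines = [
                " ".join(f % rec[name][i] for f, (name, _) in zip(fmt_parts, props))
                for i in range(n)
            ]
            fh.write(("\n".join(lines) + ("\n" if lines else "")).encode("ascii"))
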