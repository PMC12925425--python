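"""Minimal ESRI Shapefile codec: polygon records (.shp/.shx) + character DBF.

Supports only shape type 5 (Polygon).  Outer rings are clockwise per the
shapefile spec; counter-clockwise rings are treated as holes of the outer
ring containing them.  This is deliberately small: it exists so polygon
layers can be read without a compiled GIS stack, and written so tests can
round-trip.  Attribute values are stored as fixed-width character fields.
"""

from __future__ import annotations

import struct
from pathlib import Path

from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

_SHP_MAGIC = 9994
_SHP_VERSION = 1000
_POLYGON = 5
_NULL_SHAPE = 0


def _ring_is_ccw(ring) -> bool:
    # shoelace; > 0 means counter-clockwise
    area = 0.0
    for (x1, y1), (x2, y2) in zip(ring[:-1], ring[1:]):
        area += x1 * y2 - x2 * y1
    return area > 0.0


def _rings_to_polygon(rings) -> Polygon:
    outers = [r for r in rings if not _ring_is_ccw(r)]
    holes = [r for r in rings if _ring_is_ccw(r)]
    if len(outers) != 1:
        raise ValueError(
            f"only single-part polygon records are supported, got {len(outers)} outer rings"
        )
    shell = outers[0]
    assigned = []
    outer_poly = Polygon(shell)
    for h in holes:
        if not outer_poly.contains(Polygon(h).representative_point()):
            raise ValueError("hole ring outside the outer ring")
        assigned.append(h)
    return Polygon(shell, assigned)


def read_shp(path) -> list:
    """Read polygon geometries from a .shp file, in record order."""
    data = Path(path).read_bytes()
    magic, = struct.unpack(">i", data[0:4])
    if magic != _SHP_MAGIC:
        raise ValueError(f"{path}: not a shapefile (bad magic {magic})")
    shape_type, = struct.unpack("<i", data[32:36])
    if shape_type not in (_POLYGON, _NULL_SHAPE):
        raise ValueError(f"{path}: unsupported shape type {shape_type}")

    geoms = []
    pos = 100
    while pos < len(data):
        _, content_words = struct.unpack(">ii", data[pos : pos + 8])
        pos += 8
        end = pos + 2 * content_words
        rec_type, = struct.unpack("<i", data[pos : pos + 4])
        if rec_type == _NULL_SHAPE:
            raise ValueError(f"{path}: null shape record not supported")
        if rec_type != _POLYGON:
            raise ValueError(f"{path}: unsupported record shape type {rec_type}")
        num_parts, num_points = struct.unpack("<ii", data[pos + 36 : pos + 44])
        parts = struct.unpack(f"<{num_parts}i", data[pos + 44 : pos + 44 + 4 * num_parts])
        pts_off = pos + 44 + 4 * num_parts
        flat = struct.unpack(f"<{2 * num_points}d", data[pts_off : pts_off + 16 * num_points])
        points = [(flat[2 * k], flat[2 * k + 1]) for k in range(num_points)]
        bounds = list(parts) + [num_points]
        rings = [points[bounds[p] : bounds[p + 1]] for p in range(num_parts)]
        geoms.append(_rings_to_polygon(rings))
        pos = end
    return geoms


def read_dbf(path) -> list:
    """Read a DBF attribute table as a list of dicts (all values str)."""
    data = Path(path).read_bytes()
    num_records, header_len, record_len = struct.unpack("<IHH", data[4:12])
    fields = []
    pos = 32
    while data[pos] != 0x0D:
        name = data[pos : pos + 11].split(b"\x00")[0].decode("ascii")
        length = data[pos + 16]
        fields.append((name, length))
        pos += 32
    records = []
    pos = header_len
    for _ in range(num_records):
        if data[pos : pos + 1] == b"*":  # deleted record
            pos += record_len
            continue
        off = pos + 1
        rec = {}
        for name, length in fields:
            rec[name] = data[off : off + length].decode("latin-1").strip()
            off += length
        records.append(rec)
        pos += record_len
    return records


def write_shapefile(path, geoms, records) -> None:
    """Write single-part polygons + character attributes as .shp/.shx/.dbf.

    ``path`` may carry any of the three suffixes (or none); siblings are
    derived from its stem.
    """
    if len(geoms) != len(records):
        raise ValueError("geometry and record counts differ")
    base = Path(path).with_suffix("")

    contents = []
    for geom in geoms:
        if geom.geom_type != "Polygon":
            raise ValueError(f"only Polygon geometries supported, got {geom.geom_type}")
        g = orient(geom, sign=-1.0)  # CW exterior, CCW holes
        rings = [list(g.exterior.coords)] + [list(r.coords) for r in g.interiors]
        points = [pt for ring in rings for pt in ring]
        parts, off = [], 0
        for ring in rings:
            parts.append(off)
            off += len(ring)
        xs = [p[0] for p in points]
        ys = [p[1] for p in points]
        body = struct.pack("<i4d", _POLYGON, min(xs), min(ys), max(xs), max(ys))
        body += struct.pack(f"<ii{len(parts)}i", len(parts), len(points), *parts)
        body += struct.pack(f"<{2 * len(points)}d", *[c for p in points for c in p])
        contents.append(body)

    def header(total_words, bbox):
        h = struct.pack(">i5i", _SHP_MAGIC, 0, 0, 0, 0, 0)
        h += struct.pack(">i", total_words)
        h += struct.pack("<ii", _SHP_VERSION, _POLYGON)
        h += struct.pack("<8d", *bbox, 0.0, 0.0, 0.0, 0.0)
        return h

    union_bounds = None
    for g in geoms:
        b = g.bounds
        if union_bounds is None:
            union_bounds = list(b)
        else:
            union_bounds = [
                min(union_bounds[0], b[0]), min(union_bounds[1], b[1]),
                max(union_bounds[2], b[2]), max(union_bounds[3], b[3]),
            ]
    if union_bounds is None:
        union_bounds = [0.0, 0.0, 0.0, 0.0]

    shp = bytearray()
    shx = bytearray()
    offset_words = 50
    for k, body in enumerate(contents, start=1):
        words = len(body) // 2
        shx += struct.pack(">ii", offset_words, words)
        shp += struct.pack(">ii", k, words) + body
        offset_words += 4 + words
    base.with_suffix(".shp").write_bytes(header(50 + len(shp) // 2, union_bounds) + bytes(shp))
    base.with_suffix(".shx").write_bytes(header(50 + len(shx) // 2, union_bounds) + bytes(shx))

    field_names = list(records[0].keys()) if records else ["ID"]
    lengths = {
        name: max(1, min(254, max((len(str(r[name])) for r in records), default=1)))
        for name in field_names
    }
    record_len = 1 + sum(lengths.values())
    header_len = 32 + 32 * len(field_names) + 1
    dbf = bytearray()
    dbf += struct.pack("<4BIHH20x", 0x03, 26, 1, 1, len(records), header_len, record_len)
    for name in field_names:
        dbf += struct.pack(
            "<11sc4xBB14x", name.encode("ascii")[:11], b"C", lengths[name], 0
        )
    dbf += b"\x0d"
    for rec in records:
        dbf += b" "
        for name in field_names:
            dbf += str(rec[name]).encode("latin-1").ljust(lengths[name])[: lengths[name]]
    dbf += b"\x1a"
    base.with_suffix(".dbf").write_bytes(bytes(dbf))
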