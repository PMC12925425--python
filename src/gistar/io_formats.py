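"""File formats: polygon layers, population tables, result tables, FIPS ids.

The canonical internal tract identifier is the zero-padded 11-character
FIPS string (2-digit state, 3-digit county, 6-digit tract).  The
zero-stripped numeric rendering found in deposited CSVs is an output
option only.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

from . import _shp
from .errors import DuplicateIdError, FipsFormatError, TableFormatError

#: Attribute names probed for a layer's identifier when none is configured.
ID_FIELD_CANDIDATES = ("GEOID", "FIPS_ID", "FIPS", "GEOID20", "id", "ID")

_DIGITS = re.compile(r"^[0-9]+$")


@dataclass(frozen=True)
class FipsId:
    """An 11-digit census-tract FIPS identifier, split into components."""

    state: str
    county: str
    tract: str

    def __post_init__(self):
        for name, part, width in (
            ("state", self.state, 2),
            ("county", self.county, 3),
            ("tract", self.tract, 6),
        ):
            if len(part) != width or not _DIGITS.match(part):
                raise FipsFormatError(
                    f"{name} component must be {width} digits, got {part!r}"
                )

    @property
    def canonical(self) -> str:
        """Zero-padded 11-character string form."""
        return self.state + self.county + self.tract


def parse_fips(value) -> FipsId:
    """Parse a tract identifier from text or a number.

    Accepts the canonical 11-digit form and the 10-digit dialect produced
    by numeric storage dropping the single leading zero of state codes
    01–09 (the padding is restored before the 2/3/6 split).
    """
    if isinstance(value, FipsId):
        return value
    if isinstance(value, (int, np.integer)):
        text = str(int(value))
    elif isinstance(value, float):
        if not float(value).is_integer():
            raise FipsFormatError(f"non-integer FIPS value: {value!r}")
        text = str(int(value))
    else:
        text = str(value).strip()
    if not _DIGITS.match(text):
        raise FipsFormatError(f"FIPS id must be digits only, got {text!r}")
    if len(text) == 10:
        text = "0" + text
    if len(text) != 11:
        raise FipsFormatError(
            f"FIPS id must have 10 or 11 digits, got {len(text)} ({text!r})"
        )
    return FipsId(state=text[:2], county=text[2:5], tract=text[5:])


def format_fips(fips, pad: bool = True) -> str:
    """Render a FIPS id; ``pad=False`` gives the zero-stripped numeric form."""
    canonical = parse_fips(fips).canonical
    return canonical if pad else str(int(canonical))


# ---------------------------------------------------------------------------
# polygon layers


def _pick_id_field(properties: Mapping, id_field: Optional[str]) -> str:
    if id_field is not None:
        if id_field not in properties:
            raise TableFormatError(f"id field {id_field!r} not present in layer")
        return id_field
    for cand in ID_FIELD_CANDIDATES:
        if cand in properties:
            return cand
    raise TableFormatError(
        f"no identifier field found; tried {ID_FIELD_CANDIDATES}, "
        f"available: {sorted(properties)}"
    )


def read_polygon_layer(path, id_field: Optional[str] = None) -> dict:
    """Read a GeoJSON or Shapefile polygon layer as ``{id: geometry}``.

    The id is taken from ``id_field`` if given, else from the first
    matching candidate attribute, else (GeoJSON only) the feature ``id``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".geojson", ".json"):
        doc = json.loads(path.read_text())
        if doc.get("type") != "FeatureCollection":
            raise TableFormatError(f"{path}: expected a GeoJSON FeatureCollection")
        out: dict = {}
        for feat in doc.get("features", []):
            props = feat.get("properties") or {}
            if id_field is None and not props and "id" in feat:
                uid = str(feat["id"])
            else:
                uid = str(props[_pick_id_field(props, id_field)])
            if uid in out:
                raise DuplicateIdError(uid)
            out[uid] = geom_shape(feat["geometry"])
        return out
    if suffix == ".shp":
        geoms = _shp.read_shp(path)
        records = _shp.read_dbf(path.with_suffix(".dbf"))
        if len(geoms) != len(records):
            raise TableFormatError(f"{path}: .shp/.dbf record counts differ")
        out = {}
        for geom, rec in zip(geoms, records):
            uid = str(rec[_pick_id_field(rec, id_field)])
            if uid in out:
                raise DuplicateIdError(uid)
            out[uid] = geom
        return out
    raise TableFormatError(f"unsupported geometry format: {path.name!r}")


def read_tract_geometry(path, id_field: Optional[str] = None) -> dict:
    """Read a tract polygon layer, canonicalizing ids to 11-digit FIPS."""
    raw = read_polygon_layer(path, id_field=id_field)
    out = {}
    for uid, geom in raw.items():
        canonical = parse_fips(uid).canonical
        if canonical in out:
            raise DuplicateIdError(canonical)
        out[canonical] = geom
    return out


def write_geojson(polygons: Mapping, path, id_field: str = "GEOID") -> None:
    """Write ``{id: geometry}`` as a GeoJSON FeatureCollection."""
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {id_field: uid},
                "geometry": geom_mapping(geom),
            }
            for uid, geom in polygons.items()
        ],
    }
    Path(path).write_text(json.dumps(doc))


def write_shapefile(polygons: Mapping, path, id_field: str = "GEOID") -> None:
    """Write ``{id: polygon}`` as a .shp/.shx/.dbf trio."""
    ids = list(polygons)
    _shp.write_shapefile(
        path, [polygons[u] for u in ids], [{id_field: u} for u in ids]
    )


# ---------------------------------------------------------------------------
# population tables


def read_population_table(
    path,
    groups: Sequence[str],
    id_field: str = "FIPS_ID",
    total_field: str = "total",
) -> pd.DataFrame:
    """Read and validate a per-tract population CSV.

    Expects one row per tract with an identifier column, one integer count
    column per group, and a total-population column.  Groups are a subset
    of the population (not a partition): each group count and the sum of
    group counts must not exceed the total.

    Returns
    -------
    pandas.DataFrame
        Indexed by canonical FIPS, columns ``[*groups, "total"]``, int64.

    Raises
    ------
    TableFormatError
        Missing columns, empty table, non-integer or negative counts, or
        group > total; offending 1-based data row numbers are listed.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={id_field: str})
    needed = [id_field, total_field, *groups]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    if df.empty:
        raise TableFormatError(f"{path}: no tracts in population table")

    bad_rows: dict = {}

    def flag(mask, reason):
        for row in (np.flatnonzero(mask) + 1).tolist():
            bad_rows.setdefault(row, reason)

    count_cols = [total_field, *groups]
    numeric = {}
    for col in count_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        flag(vals.isna().to_numpy(), f"non-numeric {col!r}")
        with np.errstate(invalid="ignore"):
            flag((vals % 1 != 0).fillna(False).to_numpy(), f"non-integer {col!r}")
        flag((vals < 0).fillna(False).to_numpy(), f"negative {col!r}")
        numeric[col] = vals
    if not bad_rows:
        total = numeric[total_field]
        for g in groups:
            flag((numeric[g] > total).to_numpy(), f"{g!r} exceeds total")
        group_sum = sum(numeric[g] for g in groups)
        flag((group_sum > total).to_numpy(), "group sum exceeds total")
    if bad_rows:
        listing = "; ".join(f"row {r}: {why}" for r, why in sorted(bad_rows.items()))
        raise TableFormatError(f"{path}: invalid counts ({listing})")

    ids = [parse_fips(v).canonical for v in df[id_field]]
    dupes = pd.Series(ids).duplicated()
    if dupes.any():
        raise DuplicateIdError(ids[int(np.flatnonzero(dupes)[0])])

    out = pd.DataFrame(
        {g: numeric[g].astype("int64").to_numpy() for g in groups}
        | {"total": numeric[total_field].astype("int64").to_numpy()},
        index=pd.Index(ids, name="FIPS_ID"),
    )
    return out


# ---------------------------------------------------------------------------
# result tables


def result_columns(groups: Sequence[str]) -> list:
    """Column names of the output schema, in order (identifier first)."""
    cols = ["FIPS_ID"]
    for g in groups:
        cols += [f"{g}_Gstat", f"{g}_n_neigh"]
    return cols


def _format_cell(value, precision: int) -> str:
    if value is None:
        return ""
    if isinstance(value, (int, np.integer)) and not isinstance(value, bool):
        return str(int(value))
    v = float(value)
    if math.isnan(v):
        return ""
    return f"{v:.{precision}f}"


def write_results_csv(
    table: pd.DataFrame,
    path,
    pad_fips: bool = False,
    precision: int = 6,
) -> None:
    """Write the result table in the deposit schema.

    Z-scores are written with fixed ``precision`` decimals, indicator codes
    as bare integers (ASCII hyphen-minus), missing values as empty cells.
    ``pad_fips`` keeps the leading zero of the identifier.
    """
    groups = [c[: -len("_Gstat")] for c in table.columns if c.endswith("_Gstat")]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(result_columns(groups))
        for fips, row in table.iterrows():
            out = [format_fips(fips, pad=pad_fips)]
            for g in groups:
                out.append(_format_cell(row[f"{g}_Gstat"], precision))
                out.append(str(int(row[f"{g}_n_neigh"])))
            writer.writerow(out)


def read_results_csv(path) -> pd.DataFrame:
    """Read a deposit-schema CSV back into the in-memory result table.

    Gstat cells become int (indicator codes), float (Z-scores) or NaN;
    identifiers are canonicalized.  Inverse of :func:`write_results_csv`
    up to the declared float precision.
    """
    raw = pd.read_csv(path, dtype=str)
    if "FIPS_ID" not in raw.columns:
        raise TableFormatError(f"{path}: missing FIPS_ID column")
    groups = [c[: -len("_Gstat")] for c in raw.columns if c.endswith("_Gstat")]

    def parse_cell(text):
        if text is None or (isinstance(text, float) and math.isnan(text)) or text == "":
            return math.nan
        if re.match(r"^-?[0-9]+$", text):
            return int(text)
        return float(text)

    index = pd.Index([parse_fips(v).canonical for v in raw["FIPS_ID"]], name="FIPS_ID")
    data = {}
    for g in groups:
        data[f"{g}_Gstat"] = pd.Series(
            [parse_cell(v) for v in raw[f"{g}_Gstat"]], index=index, dtype=object
        )
        data[f"{g}_n_neigh"] = pd.Series(
            raw[f"{g}_n_neigh"].astype("int64").to_numpy(), index=index
        )
    return pd.DataFrame(data, index=index)
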