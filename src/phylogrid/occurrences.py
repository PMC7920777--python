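"""Read, clean, and spatially bin occurrence records into a presence grid.

The workflow mirrors standard herbarium/GBIF hygiene: parse delimited
records, discard rows with missing or exactly-zero coordinates and rows
falling outside the study boundary, then rasterize the survivors onto a
square grid (default 10 km cells) as presence/absence.

All spatial operations are planar, in meters. Latitude/longitude inputs
should be projected first (see :func:`equirectangular_project`); synthetic
landscapes use abstract Cartesian meters directly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, box, shape, mapping
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .presence import PresenceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "OccurrenceRecord", "Grid", "read_occurrences", "clean_occurrences",
    "build_grid", "rasterize_presence", "read_boundary_geojson",
    "equirectangular_project",
]

DEFAULT_COLUMN_MAP = {
    "taxon": "species",
    "lat": "decimalLatitude",
    "lon": "decimalLongitude",
}

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class OccurrenceRecord:
    """One georeferenced observation of a taxon.

    ``lon``/``lat`` are x/y in the working coordinate system (meters once
    projected); missing coordinates are carried as NaN sentinels until
    :func:`clean_occurrences` drops them.
    """

    taxon: str
    lat: float
    lon: float
    source: str = ""

    @property
    def has_missing_coord(self) -> bool:
        return not (math.isfinite(self.lat) and math.isfinite(self.lon))


@dataclass
class Grid:
    """Regular square grid of half-open cells [x0, x0+s) × [y0, y0+s).

    ``cell_ids`` lists only retained cells (those intersecting the boundary
    with positive area, when a boundary is given), ordered row-major from
    the lower-left origin. A point on a shared edge belongs to exactly one
    cell: the half-open rule assigns it to the cell of larger index.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_cols: int
    n_rows: int
    cell_ids: list[str]
    boundary: BaseGeometry | None = None
    _id_set: set[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self._id_set = set(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @staticmethod
    def cell_id(row: int, col: int) -> str:
        return f"r{row}_c{col}"

    def rowcol(self, x: float, y: float) -> tuple[int, int] | None:
        """(row, col) of the half-open cell containing (x, y), or None."""
        col = math.floor((x - self.origin_x) / self.cell_size)
        row = math.floor((y - self.origin_y) / self.cell_size)
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def cell_id_of(self, x: float, y: float) -> str | None:
        rc = self.rowcol(x, y)
        if rc is None:
            return None
        cid = self.cell_id(*rc)
        return cid if cid in self._id_set else None

    def cell_polygon(self, cell_id: str):
        row, col = self.parse_cell_id(cell_id)
        x0 = self.origin_x + col * self.cell_size
        y0 = self.origin_y + row * self.cell_size
        return box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)

    @staticmethod
    def parse_cell_id(cell_id: str) -> tuple[int, int]:
        r, c = cell_id.split("_")
        return int(r[1:]), int(c[1:])

    def to_geojson(self, path, properties: dict[str, dict] | None = None) -> None:
        """Write retained cells as a GeoJSON FeatureCollection.

        ``properties`` maps cell_id -> property dict merged into each feature.
        """
        feats = []
        for cid in self.cell_ids:
            props = {"cell_id": cid}
            if properties and cid in properties:
                props.update(properties[cid])
            feats.append({
                "type": "Feature",
                "geometry": mapping(self.cell_polygon(cid)),
                "properties": props,
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def equirectangular_project(
    lat: np.ndarray | float, lon: np.ndarray | float,
    lat0: float, lon0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Project geographic degrees to planar meters around (lat0, lon0).

    Equirectangular approximation: x = R·cos(lat0)·Δlon, y = R·Δlat
    (radians). Adequate for island-scale extents (a few hundred km);
    distortion grows with distance from the reference point.

    Returns (x, y) in meters.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    x = EARTH_RADIUS_M * np.cos(math.radians(lat0)) * np.radians(lon - lon0)
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return x, y


def read_boundary_geojson(path) -> BaseGeometry:
    """Load a polygon/multipolygon boundary from GeoJSON."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
        geom = geoms[0]
        for g in geoms[1:]:
            geom = geom.union(g)
    elif gj.get("type") == "Feature":
        geom = shape(gj["geometry"])
    else:
        geom = shape(gj)
    if not geom.is_valid:
        raise ValueError(f"invalid boundary geometry in {path}")
    return geom


def read_occurrences(
    path, column_map: dict[str, str] | None = None, delimiter: str = ",",
) -> list[OccurrenceRecord]:
    """Parse a delimited occurrence file into records.

    ``column_map`` maps the logical fields ``taxon``/``lat``/``lon`` to
    header names (Darwin-Core-ish defaults: species, decimalLatitude,
    decimalLongitude). Unparseable coordinate fields (e.g. "NA") become
    NaN sentinels for the cleaner; rows are never dropped here.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise FileNotFoundError(f"occurrence file not found: {path}")
    for key in ("taxon", "lat", "lon"):
        if cmap[key] not in df.columns:
            raise ValueError(
                f"mapped column {cmap[key]!r} (for {key}) not in header "
                f"{list(df.columns)}"
            )
    lat = pd.to_numeric(df[cmap["lat"]], errors="coerce")
    lon = pd.to_numeric(df[cmap["lon"]], errors="coerce")
    src = df[cmap["source"]] if cmap.get("source") in df.columns else [""] * len(df)
    records = [
        OccurrenceRecord(taxon=t, lat=la if pd.notna(la) else math.nan,
                         lon=lo if pd.notna(lo) else math.nan, source=s)
        for t, la, lo, s in zip(df[cmap["taxon"]], lat, lon, src)
    ]
    log.info("read %d occurrence rows from %s", len(records), path)
    return records


def clean_occurrences(
    records: list[OccurrenceRecord],
    boundary: BaseGeometry | None = None,
) -> tuple[list[OccurrenceRecord], pd.DataFrame]:
    """Drop records with missing coordinates, exact-zero coordinates, or
    coordinates outside the boundary.

    Zero is matched exactly (lat == 0 or lon == 0) — the convention for
    flagging placeholder coordinates in occurrence databases; no fuzzy
    tolerance. Survivor order is preserved. Returns (kept, rejection log);
    the log has one row per dropped record with a ``reason`` column.
    """
    if boundary is not None and not boundary.is_valid:
        raise ValueError("invalid boundary geometry")
    prepared = prep(boundary) if boundary is not None else None
    kept: list[OccurrenceRecord] = []
    rejected: list[dict] = []
    for rec in records:
        if rec.has_missing_coord:
            reason = "missing coordinate"
        elif rec.lat == 0 or rec.lon == 0:
            reason = "zero coordinate"
        elif prepared is not None and not prepared.covers(Point(rec.lon, rec.lat)):
            reason = "outside boundary"
        else:
            kept.append(rec)
            continue
        rejected.append(
            {"taxon": rec.taxon, "lat": rec.lat, "lon": rec.lon,
             "source": rec.source, "reason": reason}
        )
    logdf = pd.DataFrame(rejected, columns=["taxon", "lat", "lon", "source", "reason"])
    log.info("cleaning kept %d / %d records", len(kept), len(records))
    return kept, logdf


def build_grid(
    boundary_or_extent: BaseGeometry | tuple[float, float, float, float],
    cell_size: float = 10_000.0,
) -> Grid:
    """Lay a square grid over an extent or boundary polygon.

    The grid origin is the lower-left corner of the extent. With a boundary
    polygon, only cells whose intersection with the polygon has positive
    area are retained (cells merely touching an edge are not).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    if isinstance(boundary_or_extent, BaseGeometry):
        boundary = boundary_or_extent
        xmin, ymin, xmax, ymax = boundary.bounds
    else:
        boundary = None
        xmin, ymin, xmax, ymax = boundary_or_extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate extent")
    n_cols = max(1, math.ceil((xmax - xmin) / cell_size - 1e-9))
    n_rows = max(1, math.ceil((ymax - ymin) / cell_size - 1e-9))
    if n_cols == 1 and n_rows == 1:
        log.warning("cell_size >= extent span; grid collapses to a single cell")
    cell_ids = []
    for row in range(n_rows):
        for col in range(n_cols):
            cid = Grid.cell_id(row, col)
            if boundary is not None:
                x0 = xmin + col * cell_size
                y0 = ymin + row * cell_size
                cell = box(x0, y0, x0 + cell_size, y0 + cell_size)
                inter = cell.intersection(boundary)
                if inter.is_empty or inter.area <= 0:
                    continue
            cell_ids.append(cid)
    return Grid(origin_x=xmin, origin_y=ymin, cell_size=cell_size,
                n_cols=n_cols, n_rows=n_rows, cell_ids=cell_ids,
                boundary=boundary)


def rasterize_presence(
    records: list[OccurrenceRecord], grid: Grid,
) -> PresenceMatrix:
    """Bin cleaned records into a presence–absence matrix over the grid.

    Duplicate records of a taxon within one cell collapse to a single
    presence. Taxa with no surviving record are excluded; cells with no
    taxa are flagged "no records" and excluded from analysis (they remain
    listed on ``PresenceMatrix.empty_cells``).
    """
    pairs: list[tuple[str, str]] = []
    n_outside = 0
    taxa_order: dict[str, None] = {}
    for rec in records:
        cid = grid.cell_id_of(rec.lon, rec.lat)
        if cid is None:
            n_outside += 1
            log.warning("record of %s at (%s, %s) outside all grid cells; skipped",
                        rec.taxon, rec.lon, rec.lat)
            continue
        taxa_order.setdefault(rec.taxon, None)
        pairs.append((cid, rec.taxon))
    if n_outside:
        log.info("%d records fell outside the grid and were skipped", n_outside)
    taxa = list(taxa_order)
    full = PresenceMatrix.from_pairs(pairs, cells=list(grid.cell_ids), taxa=taxa)
    mat = full.drop_empty()
    log.info("rasterized %d presences: %d analyzable cells (%d empty), %d taxa",
             int(mat.incidence.sum()), mat.n_cells, len(mat.empty_cells), mat.n_taxa)
    return mat
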