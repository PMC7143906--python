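"""Block tessellation of a study area.

A study area (a polygon in a projected, metric CRS) is overlaid with an
axis-aligned square grid anchored at the lower-left corner of its bounding
box.  Each nonempty intersection of a grid cell with the area polygon
becomes a :class:`GridBlock`.  Along an irregular boundary (a coastline,
typically) cells are clipped and may come out much smaller than a full
cell; :func:`merge_small_blocks` absorbs such fragments into the neighbor
with which they share the longest boundary, so that the final analysis
units are all of comparable size.

Cells are half-open, ``[x0 + j*d, x0 + (j+1)*d) x [y0 + k*d, y0 + (k+1)*d)``,
so every point of the plane belongs to exactly one cell; this convention is
what :mod:`gwpressure.scoring` uses to assign boundary points unambiguously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from shapely import wkt as _wkt
from shapely.geometry import Polygon, MultiPolygon, shape as _shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

__all__ = [
    "StudyArea",
    "GridBlock",
    "ISOLATED_SENTINEL",
    "make_grid",
    "merge_small_blocks",
    "block_adjacency",
]

#: merged_from value marking an undersized block that had no neighbor to
#: merge into and was therefore kept as-is.
ISOLATED_SENTINEL = "__isolated__"

#: CRS identifiers the package refuses: cell sizes are meters, so input in
#: geographic (degree) coordinates would be silently wrong by ~5 orders of
#: magnitude.  Without a full CRS database only well-known geographic codes
#: can be caught; anything else is trusted to be projected and metric.
_GEOGRAPHIC_CRS_IDS = frozenset(
    {"EPSG:4326", "EPSG:4258", "EPSG:4269", "EPSG:4230", "WGS84", "WGS 84", "CRS84", "OGC:CRS84"}
)


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _as_polygonal(geom: BaseGeometry) -> BaseGeometry:
    if not isinstance(geom, (Polygon, MultiPolygon)):
        raise ValidationError(f"study area must be polygonal, got {geom.geom_type}")
    return geom


@dataclass(frozen=True)
class StudyArea:
    """The spatial universe of the analysis.

    Parameters
    ----------
    boundary:
        A valid (Multi)Polygon, vertices in a projected CRS with meter
        units.  Holes are allowed.
    crs_id:
        Free-text identifier of the coordinate reference system, e.g.
        ``"EPSG:32634"``.  Known geographic (degree) identifiers are
        rejected.
    """

    boundary: BaseGeometry
    crs_id: str = "unspecified"

    def __post_init__(self) -> None:
        _as_polygonal(self.boundary)
        if not self.boundary.is_valid:
            raise ValidationError("study-area polygon is invalid (self-intersecting?)")
        if self.boundary.area <= 0:
            raise ValidationError("study-area polygon has zero area")
        if self.crs_id.strip().upper().replace(" ", "") in {
            s.replace(" ", "") for s in _GEOGRAPHIC_CRS_IDS
        }:
            raise ValidationError(
                f"CRS {self.crs_id!r} is geographic (degrees); a projected metric CRS is required"
            )

    @property
    def area(self) -> float:
        """Area of the study region in m^2."""
        return self.boundary.area

    @classmethod
    def from_wkt(cls, text: str, crs_id: str = "unspecified") -> "StudyArea":
        return cls(_wkt.loads(text), crs_id)

    @classmethod
    def from_geojson(cls, obj: dict, crs_id: str = "unspecified") -> "StudyArea":
        """Build from a GeoJSON Polygon/MultiPolygon geometry or Feature."""
        if obj.get("type") == "Feature":
            obj = obj["geometry"]
        if obj.get("type") == "FeatureCollection":
            geoms = [_shape(f["geometry"]) for f in obj["features"]]
            return cls(unary_union(geoms), crs_id)
        return cls(_shape(obj), crs_id)


@dataclass
class GridBlock:
    """One analysis unit: a grid cell clipped to the study area, possibly a
    merged union of several such pieces.

    ``cells`` records the (row, col) grid indices making up the block; it is
    how point assignment maps a coordinate to its owning block in O(1).
    """

    block_id: str
    geometry: BaseGeometry
    nominal_area: float
    actual_area: float
    merged_from: list[str] = field(default_factory=list)
    neighbor_ids: list[str] = field(default_factory=list)
    cells: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.actual_area <= 0:
            raise ValidationError(f"block {self.block_id} has non-positive area")


def _block_id(row: int, col: int) -> str:
    return f"r{row:02d}c{col:02d}"


def make_grid(
    area: StudyArea,
    cell_size: float,
    *,
    origin: tuple[float, float] | None = None,
) -> list[GridBlock]:
    """Tile ``area`` with ``cell_size`` x ``cell_size`` squares.

    The grid is anchored at ``origin`` (default: lower-left corner of the
    area's bounding box).  Each cell with a nonempty intersection with the
    area polygon yields one block whose geometry is that intersection.
    Block ids encode the (row, col) cell index; ``neighbor_ids`` are filled
    with rook-style adjacency computed on the clipped geometries (positive
    shared boundary length; corner contact does not count).

    Returns blocks sorted by block_id, deterministically.
    """
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    boundary = area.boundary
    minx, miny, maxx, maxy = boundary.bounds
    x0, y0 = origin if origin is not None else (minx, miny)
    ncols = max(1, math.ceil((maxx - x0) / cell_size - 1e-12))
    nrows = max(1, math.ceil((maxy - y0) / cell_size - 1e-12))

    nominal = cell_size * cell_size
    blocks: list[GridBlock] = []
    # area tolerance: drop numerically empty slivers (< 1e-9 of a cell)
    min_keep = nominal * 1e-9
    for row in range(nrows):
        for col in range(ncols):
            cell = Polygon(
                [
                    (x0 + col * cell_size, y0 + row * cell_size),
                    (x0 + (col + 1) * cell_size, y0 + row * cell_size),
                    (x0 + (col + 1) * cell_size, y0 + (row + 1) * cell_size),
                    (x0 + col * cell_size, y0 + (row + 1) * cell_size),
                ]
            )
            piece = cell.intersection(boundary)
            if piece.is_empty or piece.area < min_keep:
                continue
            blocks.append(
                GridBlock(
                    block_id=_block_id(row, col),
                    geometry=piece,
                    nominal_area=nominal,
                    actual_area=piece.area,
                    cells=[(row, col)],
                )
            )
    blocks.sort(key=lambda b: b.block_id)
    adjacency = block_adjacency(blocks)
    for b in blocks:
        b.neighbor_ids = adjacency[b.block_id]
    return blocks


def block_adjacency(blocks: list[GridBlock]) -> dict[str, list[str]]:
    """Symmetric neighbor relation on clipped block geometries.

    Two blocks are neighbors iff their geometries share a boundary of
    positive length.  Corner (point) contact does not count.  Neighbor
    lists are sorted for determinism.
    """
    adjacency: dict[str, list[str]] = {b.block_id: [] for b in blocks}
    for i, a in enumerate(blocks):
        for b in blocks[i + 1 :]:
            if _shared_boundary_length(a.geometry, b.geometry) > 0.0:
                adjacency[a.block_id].append(b.block_id)
                adjacency[b.block_id].append(a.block_id)
    for ids in adjacency.values():
        ids.sort()
    return adjacency


def _shared_boundary_length(a: BaseGeometry, b: BaseGeometry) -> float:
    inter = a.intersection(b)
    if inter.is_empty:
        return 0.0
    return inter.length  # points contribute 0


def merge_small_blocks(
    blocks: list[GridBlock], min_area_fraction: float = 0.5
) -> list[GridBlock]:
    """Absorb undersized blocks into their best neighbor.

    A block whose ``actual_area`` is below ``min_area_fraction`` of the
    nominal cell area is unioned into the neighbor with which it shares the
    longest boundary (ties broken by smallest block_id).  The process
    repeats until no block is undersized; an undersized block with no
    neighbor at all is kept and flagged with ``merged_from ==
    [ISOLATED_SENTINEL]``.  Total area is conserved and the operation is
    idempotent.  Input blocks are not mutated.
    """
    if not blocks:
        raise ValueError("empty block list")
    if not (0 < min_area_fraction < 1):
        raise ValueError("min_area_fraction must lie in (0, 1)")

    pool: dict[str, GridBlock] = {
        b.block_id: GridBlock(
            block_id=b.block_id,
            geometry=b.geometry,
            nominal_area=b.nominal_area,
            actual_area=b.actual_area,
            merged_from=list(b.merged_from),
            neighbor_ids=list(b.neighbor_ids),
            cells=list(b.cells),
        )
        for b in blocks
    }

    while True:
        undersized = sorted(
            bid
            for bid, b in pool.items()
            if b.actual_area < min_area_fraction * b.nominal_area
            and b.merged_from != [ISOLATED_SENTINEL]
        )
        progressed = False
        for bid in undersized:
            if bid not in pool:  # absorbed earlier in this sweep
                continue
            small = pool[bid]
            lengths = {
                nid: _shared_boundary_length(small.geometry, pool[nid].geometry)
                for nid in small.neighbor_ids
                if nid in pool
            }
            candidates = [nid for nid, ln in lengths.items() if ln > 0.0]
            if not candidates:
                small.merged_from = [ISOLATED_SENTINEL]
                continue
            # longest shared boundary wins; ties -> smallest id
            best = min(candidates, key=lambda nid: (-lengths[nid], nid))
            target = pool[best]
            target.geometry = unary_union([target.geometry, small.geometry])
            target.actual_area = target.geometry.area
            target.merged_from = sorted(set(target.merged_from) | {bid} | set(small.merged_from))
            target.cells = sorted(set(target.cells) | set(small.cells))
            del pool[bid]
            # rewire neighbor links locally
            for nid in small.neighbor_ids:
                if nid in pool and nid != best:
                    nbr = pool[nid]
                    nbr.neighbor_ids = sorted(
                        (set(nbr.neighbor_ids) - {bid}) | {best}
                    )
            target.neighbor_ids = sorted(
                (set(target.neighbor_ids) | set(small.neighbor_ids)) - {bid, best}
            )
            progressed = True
        if not progressed:
            break

    merged = sorted(pool.values(), key=lambda b: b.block_id)
    # adjacency from scratch on the final geometries (merging can create
    # contacts the local rewiring missed)
    adjacency = block_adjacency(merged)
    for b in merged:
        b.neighbor_ids = adjacency[b.block_id]
    return merged
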