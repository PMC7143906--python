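"""Per-block weighted pressure scores.

Each pressure point is assigned to exactly one block and the block score
is the weighted sum over layers,

    score(block) = sum_i n_i * w_i,

with ``n_i`` the number of layer-*i* points in the block and ``w_i`` the
layer weight.  Scores are reported rounded to one decimal; the raw float
is kept alongside so conservation checks can be exact.

Point assignment follows the grid's half-open cell convention: a point on
an interior grid line belongs to the cell to its upper-right, so boundary
points are never double-counted.  For clipped or merged geometries the
point is verified against the final block polygon (boundary counts as
inside); a point covered by no block — i.e., outside the study area — is
tallied as unassigned and excluded from all scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from shapely.geometry import Point

from .geometry import GridBlock, ValidationError
from .layers import LayerRegistry, PressureLayer

__all__ = ["BlockScore", "assign_points", "block_score", "score_all"]

logger = logging.getLogger(__name__)


@dataclass
class BlockScore:
    """Layer counts and the weighted total for one block."""

    block_id: str
    counts: dict[str, int] = field(default_factory=dict)
    raw_total: float = 0.0

    @property
    def total(self) -> float:
        """Score rounded to 1 decimal (reporting precision)."""
        return round(self.raw_total, 1)


def _grid_frame(blocks: list[GridBlock]) -> tuple[float, float, float] | None:
    """Recover (x0, y0, cell_size) from the blocks' cell indices.

    The lower-left corner of any block's cell (row, col) sits at
    (x0 + col*d, y0 + row*d); a full (unclipped) interior cell pins the
    frame exactly, and any block bounds give upper bounds on x0, y0.
    Returns None when no block carries cell indices (externally built
    tessellations), in which case assignment falls back to pure
    geometry tests.
    """
    cells = [(b, rc) for b in blocks for rc in b.cells]
    if not cells:
        return None
    d = math.sqrt(blocks[0].nominal_area)
    x0 = min(b.geometry.bounds[0] - rc[1] * d for b, rc in cells)
    y0 = min(b.geometry.bounds[1] - rc[0] * d for b, rc in cells)
    return x0, y0, d


def assign_points(
    blocks: list[GridBlock],
    layer: PressureLayer,
    *,
    expected_crs: str | None = None,
) -> tuple[dict[str, int], int]:
    """Count the layer's points per block.

    Returns ``(counts, unassigned)`` where ``counts`` maps every block_id
    to its point count (zeros included) and ``unassigned`` is the number
    of points lying outside all blocks.  If both ``expected_crs`` and a
    layer CRS are declared and differ, a :class:`ValidationError` is
    raised rather than silently mixing coordinate systems.
    """
    layer_crs = getattr(layer, "crs_id", None)
    if expected_crs is not None and layer_crs is not None and layer_crs != expected_crs:
        raise ValidationError(
            f"layer {layer.name!r} CRS {layer_crs!r} != study CRS {expected_crs!r}"
        )

    ordered = sorted(blocks, key=lambda b: b.block_id)
    counts = {b.block_id: 0 for b in ordered}
    frame = _grid_frame(ordered)
    cell_owner: dict[tuple[int, int], GridBlock] = {
        rc: b for b in ordered for rc in b.cells
    }
    unassigned = 0
    for x, y in layer.points:
        block = None
        if frame is not None:
            x0, y0, d = frame
            rc = (math.floor((y - y0) / d), math.floor((x - x0) / d))
            candidate = cell_owner.get(rc)
            if candidate is not None and candidate.geometry.covers(Point(x, y)):
                block = candidate
        if block is None:
            # boundary/sliver fallback: first covering block in id order
            pt = Point(x, y)
            for b in ordered:
                if b.geometry.covers(pt):
                    block = b
                    break
        if block is None:
            unassigned += 1
        else:
            counts[block.block_id] += 1
    if unassigned:
        logger.warning(
            "layer %r: %d point(s) outside the study area, excluded from scores",
            layer.name,
            unassigned,
        )
    return counts, unassigned


def block_score(counts: dict[str, int], registry: LayerRegistry) -> BlockScore:
    """Evaluate ``sum_i n_i w_i`` for one block's layer counts.

    Layers absent from ``counts`` contribute zero.  Unknown layer names
    and negative counts are validation errors.
    """
    total = 0.0
    for name, n in counts.items():
        if name not in registry:
            raise ValidationError(f"unknown layer name {name!r} in counts")
        if n < 0:
            raise ValidationError(f"negative count {n} for layer {name!r}")
        total += n * registry.weight(name)
    return BlockScore(block_id="", counts=dict(counts), raw_total=total)


def score_all(
    blocks: list[GridBlock],
    registry: LayerRegistry,
    *,
    expected_crs: str | None = None,
) -> tuple[list[BlockScore], dict[str, int]]:
    """Score every block against every registry layer.

    Returns one :class:`BlockScore` per block (sorted by block_id) and a
    per-layer mapping of unassigned (outside-area) point counts.
    Conservation holds: the sum of raw totals equals
    ``sum_i (in-area points of layer i) * w_i`` up to float addition.
    """
    ordered = sorted(blocks, key=lambda b: b.block_id)
    per_block: dict[str, dict[str, int]] = {b.block_id: {} for b in ordered}
    unassigned: dict[str, int] = {}
    for layer in registry:
        counts, out = assign_points(ordered, layer, expected_crs=expected_crs)
        unassigned[layer.name] = out
        for bid, n in counts.items():
            per_block[bid][layer.name] = n
    scores = []
    for b in ordered:
        s = block_score(per_block[b.block_id], registry)
        s.block_id = b.block_id
        scores.append(s)
    return scores, unassigned
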