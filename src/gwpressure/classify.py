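"""Pressure classes and monitoring-well allocation.

Block scores are binned into K ordered pressure classes by upper edges on
the score rounded to one decimal; the default scheme has four classes
with upper edges 10.0, 20.0, 30.0 and +inf, and assigns 1, 2, 3 and 4
monitoring wells per block respectively.  The class intervals are
half-open, ``(edge[c-1], edge[c]]``, and class 1 also absorbs any score
down to 0 — every block gets at least the class-1 monitoring effort.

Well coordinates within a block are outside the scoring model; the
optional :func:`place_wells` siting modes (block centroid with a
deterministic jitter, or snapping to the heaviest pressure points) are a
convenience for map output only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point

from .geometry import GridBlock, ValidationError
from .layers import LayerRegistry
from .scoring import BlockScore

__all__ = [
    "ClassScheme",
    "WellAllocation",
    "AllocationSummary",
    "classify",
    "allocate_wells",
    "place_wells",
]

logger = logging.getLogger(__name__)


def _round_half_up_1dp(x: float) -> float:
    """Round to 1 decimal with halves away from zero.

    Plain ``round`` uses banker's rounding on binary floats, which makes
    the class of a score like 10.05 depend on its representation; the
    explicit rule keeps bin membership predictable.
    """
    return math.floor(abs(x) * 10.0 + 0.5) / 10.0 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ClassScheme:
    """Score breakpoints and the wells-per-class rule.

    ``edges`` are the upper bounds of classes 1..K (last one infinite);
    ``wells_per_class`` maps class index to well count and must be
    non-decreasing — more pressure never means fewer wells.
    """

    edges: tuple[float, ...] = (10.0, 20.0, 30.0, math.inf)
    wells_per_class: dict[int, int] = field(
        default_factory=lambda: {1: 1, 2: 2, 3: 3, 4: 4}
    )

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValidationError("scheme needs at least one class edge")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValidationError("class edges must be strictly increasing")
        if not math.isinf(self.edges[-1]):
            raise ValidationError("last class must be unbounded (edge = inf)")
        k = len(self.edges)
        if set(self.wells_per_class) != set(range(1, k + 1)):
            raise ValidationError(f"wells_per_class must cover classes 1..{k}")
        wells = [self.wells_per_class[c] for c in range(1, k + 1)]
        if any(w < 0 or w != int(w) for w in wells):
            raise ValidationError("well counts must be non-negative integers")
        if any(b < a for a, b in zip(wells, wells[1:])):
            raise ValidationError("well counts must be non-decreasing in class")

    @property
    def n_classes(self) -> int:
        return len(self.edges)


@dataclass
class WellAllocation:
    """Pressure class and well count for one block."""

    block_id: str
    pressure_class: int
    n_wells: int
    suggested_sites: list[tuple[float, float]] | None = None


@dataclass
class AllocationSummary:
    """Per-class block counts and the total number of wells."""

    blocks_per_class: dict[int, int]
    wells_per_class: dict[int, int]

    @property
    def total_blocks(self) -> int:
        return sum(self.blocks_per_class.values())

    @property
    def total_wells(self) -> int:
        return sum(self.wells_per_class.values())


def classify(score: float, scheme: ClassScheme | None = None) -> int:
    """Pressure class (1..K) of a score.

    The score is rounded to one decimal (half up) first, so that printed
    scores and class membership agree; the intervals
    ``(edge[c-1], edge[c]]`` partition [0, inf) with class 1 extended
    down to zero.
    """
    if score < 0:
        raise ValidationError(f"score must be non-negative, got {score}")
    scheme = scheme or ClassScheme()
    r = _round_half_up_1dp(score)
    for c, edge in enumerate(scheme.edges, start=1):
        if r <= edge:
            return c
    return scheme.n_classes  # unreachable: last edge is inf


def allocate_wells(
    scores: list[BlockScore], scheme: ClassScheme | None = None
) -> tuple[list[WellAllocation], AllocationSummary]:
    """Assign each block its pressure class and well count.

    Returns the per-block allocations (same order as ``scores``) plus a
    summary with per-class block counts and total wells.
    """
    scheme = scheme or ClassScheme()
    allocations = []
    blocks_per_class = {c: 0 for c in range(1, scheme.n_classes + 1)}
    for s in scores:
        c = classify(s.raw_total, scheme)
        blocks_per_class[c] += 1
        allocations.append(
            WellAllocation(
                block_id=s.block_id,
                pressure_class=c,
                n_wells=scheme.wells_per_class[c],
            )
        )
    wells_per_class = {
        c: n * scheme.wells_per_class[c] for c, n in blocks_per_class.items()
    }
    return allocations, AllocationSummary(blocks_per_class, wells_per_class)


def place_wells(
    allocation: WellAllocation,
    block: GridBlock,
    mode: str = "centroid",
    seed: int = 0,
    registry: LayerRegistry | None = None,
) -> WellAllocation:
    """Attach suggested well coordinates to an allocation.

    centroid
        Wells at the block centroid, jittered deterministically (seeded,
        ~2% of the block diagonal) into distinct in-block points; a
        centroid falling outside a concave block falls back to an interior
        representative point.
    pressure_weighted
        Wells at the in-block pressure points of highest layer weight
        (requires ``registry`` with point data); padded with centroid
        placement if the block holds fewer points than wells.
    none
        Leaves ``suggested_sites`` absent.
    """
    if mode == "none":
        allocation.suggested_sites = None
        return allocation
    if mode not in ("centroid", "pressure_weighted"):
        raise ValueError(f"unknown siting mode {mode!r}")

    n = allocation.n_wells
    sites: list[tuple[float, float]] = []
    if mode == "pressure_weighted":
        if registry is None:
            raise ValidationError("pressure_weighted siting needs a layer registry")
        in_block = sorted(
            (
                (-layer.weight, x, y)
                for layer in registry
                for (x, y) in layer.points
                if block.geometry.covers(Point(x, y))
            ),
        )
        sites = [(x, y) for _, x, y in in_block[:n]]

    if len(sites) < n:
        anchor = block.geometry.centroid
        if not block.geometry.covers(anchor):
            logger.info(
                "block %s: centroid outside concave geometry, using representative point",
                block.block_id,
            )
            anchor = block.geometry.representative_point()
        rng = np.random.default_rng(seed)
        minx, miny, maxx, maxy = block.geometry.bounds
        scale = 0.02 * math.hypot(maxx - minx, maxy - miny)
        if len(sites) < n:
            sites.append((anchor.x, anchor.y))
        while len(sites) < n:
            dx, dy = rng.normal(0.0, scale, size=2)
            p = Point(anchor.x + dx, anchor.y + dy)
            if block.geometry.covers(p) and (p.x, p.y) not in sites:
                sites.append((p.x, p.y))

    allocation.suggested_sites = sites[:n]
    return allocation
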